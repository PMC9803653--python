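"""Synthetic in-line holograms of polydisperse particle suspensions.

Every downstream stage (filtering, speckle statistics, network training,
mixture correction) is exercised on frames produced here, so the module is
first-class, tested code rather than a fixture.

Physics stand-in: each particle is an opaque disk (binary amplitude
transmittance) at its depth; a unit plane wave is propagated slice by slice
through the depth-sorted particle field with the angular-spectrum kernel, so
the shadow/diffraction of one slice illuminates the next (a coarse
approximation of adjacent-particle multiple scattering).  The recorded
intensity is |U|^2 at the focal plane.  Rigorous Mie/T-matrix scattering and
partial coherence are deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .optics import COARSE_PM, FINE_PM, OpticalConfig, SizeDistribution

__all__ = [
    "Hologram",
    "ParticleField",
    "expected_particle_count",
    "sample_particle_field",
    "propagate_hologram",
    "add_acquisition_noise",
    "simulate_stack",
    "generate_dataset",
]

#: 1 g/cm^3 expressed in ug/um^3.
_UG_PER_UM3 = 1e-6


@dataclass
class Hologram:
    """One grayscale intensity frame.

    ``intensity`` lives on the declared ``scale``: ``"unit"`` ([0, 1] floats)
    or ``"uint8"`` ([0, 255]).  ``labels`` carries the ground-truth mass
    concentrations (rho_f, rho_c) in ug/ml when known.
    """

    intensity: np.ndarray
    pixel_size: float = 250.0  # nm
    scale: str = "unit"
    labels: tuple[float, float] | None = None
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D array")
        if self.scale not in ("unit", "uint8"):
            raise ValueError("scale must be 'unit' or 'uint8'")
        if self.labels is not None and min(self.labels) < 0:
            raise ValueError("concentration labels must be non-negative")

    @property
    def max_value(self) -> float:
        return 1.0 if self.scale == "unit" else 255.0

    def to_uint8(self) -> "Hologram":
        if self.scale == "uint8":
            return self
        arr = np.clip(self.intensity * 255.0, 0, 255)
        return replace(self, intensity=arr, scale="uint8")

    def to_unit(self) -> "Hologram":
        if self.scale == "unit":
            return self
        return replace(self, intensity=self.intensity / 255.0, scale="unit")


@dataclass
class ParticleField:
    """Per-particle positions/diameters of one realized suspension.

    Lateral positions x, y in um within the field of view; z in um measured
    from the recording plane (so z >= focal_offset); diameters in um.
    ``realized_concentration`` maps class tag -> realized mass concentration
    in ug/ml (total realized particle mass over the imaged volume).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    diameter: np.ndarray
    class_tag: np.ndarray  # array of "fine" / "coarse"
    realized_concentration: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.diameter)


def _mean_particle_mass_ug(dist: SizeDistribution) -> float:
    """Mean mass (ug) of one particle under the truncated-normal diameters."""
    lo, hi = dist.diameter_bounds
    a = (lo - dist.mean_diameter) / dist.sd_diameter
    b = (hi - dist.mean_diameter) / dist.sd_diameter
    rv = stats.truncnorm(a, b, loc=dist.mean_diameter, scale=dist.sd_diameter)
    e_d3 = rv.moment(3)  # E[d^3], um^3
    return dist.material_density * _UG_PER_UM3 * np.pi / 6.0 * e_d3


def expected_particle_count(concentration: float, dist: SizeDistribution,
                            optics: OpticalConfig) -> float:
    """Poisson mean count: C * V / E[single-particle mass]."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if concentration == 0:
        return 0.0
    return concentration * optics.imaged_volume_ml() / _mean_particle_mass_ug(dist)


def sample_particle_field(
    concentrations: dict[str, float],
    size_dists: dict[str, SizeDistribution] | None = None,
    optics: OpticalConfig = OpticalConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> ParticleField:
    """Draw one random particle field at the requested mass concentrations.

    Parameters
    ----------
    concentrations : dict
        Mass concentration per class tag in ug/ml, e.g. ``{"fine": 3.0,
        "coarse": 1.0}``.  Zero means the class is absent.
    size_dists : dict, optional
        Diameter distribution per class tag; defaults to the fine/coarse
        Arizona-test-dust classes.
    """
    if size_dists is None:
        size_dists = {"fine": FINE_PM, "coarse": COARSE_PM}
    rng = np.random.default_rng(seed)
    fov_y, fov_x = optics.field_of_view_um()
    volume_ml = optics.imaged_volume_ml()
    z_lo = optics.focal_offset * 1000.0  # mm -> um
    z_hi = z_lo + optics.sample_depth

    xs, ys, zs, ds, tags = [], [], [], [], []
    realized: dict[str, float] = {}
    for tag, conc in sorted(concentrations.items()):
        if conc < 0:
            raise ValueError(f"negative concentration for class {tag!r}")
        dist = size_dists[tag]
        lam = expected_particle_count(conc, dist, optics)
        n = int(rng.poisson(lam)) if lam > 0 else 0
        lo, hi = dist.diameter_bounds
        a = (lo - dist.mean_diameter) / dist.sd_diameter
        b = (hi - dist.mean_diameter) / dist.sd_diameter
        d = stats.truncnorm.rvs(a, b, loc=dist.mean_diameter,
                                scale=dist.sd_diameter, size=n,
                                random_state=rng)
        xs.append(rng.uniform(0, fov_x, n))
        ys.append(rng.uniform(0, fov_y, n))
        zs.append(rng.uniform(z_lo, z_hi, n))
        ds.append(d)
        tags.append(np.full(n, tag, dtype=object))
        mass = dist.material_density * _UG_PER_UM3 * np.pi / 6.0 * np.sum(d**3)
        realized[tag] = mass / volume_ml
    return ParticleField(
        x=np.concatenate(xs) if xs else np.empty(0),
        y=np.concatenate(ys) if ys else np.empty(0),
        z=np.concatenate(zs) if zs else np.empty(0),
        diameter=np.concatenate(ds) if ds else np.empty(0),
        class_tag=np.concatenate(tags) if tags else np.empty(0, dtype=object),
        realized_concentration=realized,
    )


def _angular_spectrum_kernel(shape: tuple[int, int], pixel_um: float,
                             wavelength_um: float, dz_um: float) -> np.ndarray:
    """Transfer function exp(i 2 pi dz sqrt(1/lambda^2 - fx^2 - fy^2))."""
    m, n = shape
    fy = np.fft.fftfreq(m, d=pixel_um)[:, None]
    fx = np.fft.fftfreq(n, d=pixel_um)[None, :]
    arg = 1.0 / wavelength_um**2 - fx**2 - fy**2
    kernel = np.zeros((m, n), dtype=complex)
    prop = arg > 0
    kernel[prop] = np.exp(1j * 2 * np.pi * dz_um * np.sqrt(arg[prop]))
    return kernel


def _propagate(u: np.ndarray, dz_um: float, pixel_um: float,
               wavelength_um: float) -> np.ndarray:
    if dz_um == 0:
        return u
    kernel = _angular_spectrum_kernel(u.shape, pixel_um, wavelength_um, dz_um)
    return np.fft.ifft2(np.fft.fft2(u) * kernel)


def _stamp_disks(u: np.ndarray, xs_px: np.ndarray, ys_px: np.ndarray,
                 radii_px: np.ndarray) -> None:
    """Zero the field under each opaque disk (in place)."""
    m, n = u.shape
    for x0, y0, r in zip(xs_px, ys_px, radii_px):
        r_eff = max(r, 0.5)  # sub-resolution particles render as <=1 px
        y_lo = max(int(np.floor(y0 - r_eff)) - 1, 0)
        y_hi = min(int(np.ceil(y0 + r_eff)) + 2, m)
        x_lo = max(int(np.floor(x0 - r_eff)) - 1, 0)
        x_hi = min(int(np.ceil(x0 + r_eff)) + 2, n)
        if y_lo >= y_hi or x_lo >= x_hi:
            continue
        yy = np.arange(y_lo, y_hi)[:, None] - y0
        xx = np.arange(x_lo, x_hi)[None, :] - x0
        mask = yy**2 + xx**2 <= r_eff**2
        u[y_lo:y_hi, x_lo:x_hi][mask] = 0.0


def propagate_hologram(particle_field: ParticleField,
                       optics: OpticalConfig = OpticalConfig(),
                       n_slices: int = 16) -> Hologram:
    """Record the in-line hologram of a particle field.

    A unit plane wave enters at the far side of the volume; the field is
    propagated toward the recording plane, multiplying in the opaque-disk
    transmittance of each depth slice on the way (slices ordered far to
    near).  The result is deterministic in the particle field: records are
    sorted by depth internally, so particle order does not matter.

    Returns a unit-scale hologram; the raw relative intensity |U|^2 (1 for
    the empty field) is mapped to [0, 1] by I -> clip(I / 2, 0, 1), placing
    the flat reference at mid-scale 0.5.
    """
    pixel_um = optics.pixel_size_um
    wavelength_um = optics.wavelength / 1000.0
    m, n = optics.image_shape
    u = np.ones((m, n), dtype=complex)

    if len(particle_field) > 0:
        d_px = particle_field.diameter / pixel_um
        if np.any(d_px < 2):
            warnings.warn(
                "particle(s) below 2 px diameter: sub-resolution, rendered "
                "as <=1 px disks", stacklevel=2)
        order = np.argsort(particle_field.z)[::-1]  # far to near
        z = particle_field.z[order]
        x_px = particle_field.x[order] / pixel_um
        y_px = particle_field.y[order] / pixel_um
        r_px = particle_field.diameter[order] / (2 * pixel_um)

        # Bin depths into at most n_slices planes; stamp each bin's disks at
        # its mean depth, propagating between planes.
        edges = np.linspace(z[0], z[-1], n_slices + 1)
        bins = np.clip(np.digitize(z, edges[::-1]), 1, n_slices)
        current_z = z[0]
        for b in range(n_slices, 0, -1):  # far bins first
            sel = bins == b
            if not np.any(sel):
                continue
            z_plane = z[sel].mean()
            u = _propagate(u, current_z - z_plane, pixel_um, wavelength_um)
            _stamp_disks(u, x_px[sel], y_px[sel], r_px[sel])
            current_z = z_plane
        u = _propagate(u, current_z, pixel_um, wavelength_um)

    intensity = np.clip(np.abs(u) ** 2 / 2.0, 0.0, 1.0)
    return Hologram(intensity=intensity, pixel_size=optics.magnified_pixel_size,
                    scale="unit")


def synthetic_background(shape: tuple[int, int], amplitude: float,
                         seed: int | np.random.SeedSequence,
                         smoothing_px: float | None = None) -> np.ndarray:
    """Zero-mean smooth background pattern (dust/vibration stand-in).

    Low-frequency Gaussian-smoothed noise scaled so its RMS equals
    ``amplitude`` (on whatever intensity scale the caller uses).
    """
    if amplitude == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    sigma = smoothing_px if smoothing_px is not None else max(shape) / 20.0
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    raw -= raw.mean()
    rms = np.sqrt(np.mean(raw**2))
    return amplitude * raw / rms if rms > 0 else raw


def add_acquisition_noise(holo: Hologram, background_amplitude: float = 0.0,
                          noise_sd: float = 0.0,
                          seed: int | np.random.SeedSequence = 0,
                          background_seed: int | np.random.SeedSequence | None = None,
                          ) -> Hologram:
    """Add the stack-shared background pattern plus per-frame sensor noise.

    The background is generated from ``background_seed`` (falling back to
    ``seed``), so frames of one stack share it by passing the same
    background seed while varying ``seed`` per frame.  Output is clipped to
    the hologram's declared scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    out = holo.intensity.copy()
    if background_amplitude != 0:
        bg_seed = seed if background_seed is None else background_seed
        out = out + synthetic_background(out.shape, background_amplitude, bg_seed)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, out.shape)
    if background_amplitude != 0 or noise_sd > 0:
        out = np.clip(out, 0.0, holo.max_value)
    return replace(holo, intensity=out)


def simulate_stack(rho_f: float, rho_c: float, n_frames: int,
                   optics: OpticalConfig = OpticalConfig(),
                   seed: int | np.random.SeedSequence = 0,
                   background_amplitude: float = 0.05,
                   noise_sd: float = 0.02,
                   n_slices: int = 16) -> list[Hologram]:
    """Simulate a labeled stack of frames at one (rho_f, rho_c) condition.

    Each frame draws an independent particle field (particles move between
    exposures); the background pattern is shared across the stack.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    bg_seed, *frame_seeds = ss.spawn(n_frames + 1)
    frames = []
    for i, fs in enumerate(frame_seeds):
        field_seed, noise_seed = fs.spawn(2)
        pf = sample_particle_field({"fine": rho_f, "coarse": rho_c},
                                   optics=optics, seed=field_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # fine PM is sub-resolution by design
            holo = propagate_hologram(pf, optics, n_slices=n_slices)
        holo = add_acquisition_noise(holo, background_amplitude, noise_sd,
                                     seed=noise_seed, background_seed=bg_seed)
        holo.labels = (rho_f, rho_c)
        holo.frame_index = i
        frames.append(holo)
    return frames


def generate_dataset(design: list[tuple[str, float, float]],
                     frames_per_class: int,
                     optics: OpticalConfig = OpticalConfig(),
                     seed: int = 0,
                     out_dir=None,
                     splits: dict[str, float] | None = None,
                     **stack_kwargs) -> tuple[dict[str, list[Hologram]], pd.DataFrame]:
    """Simulate a labeled multi-class dataset and its manifest.

    Parameters
    ----------
    design : list of (class_id, rho_f, rho_c)
        One entry per concentration class; class ids must be unique.
    splits : dict, optional
        Fractions per split name applied as disjoint, contiguous frame
        ranges within each class (default all frames -> "train").
    out_dir : path-like, optional
        When given, frames are written as 8-bit grayscale TIFFs
        (``<class_id>/frame_<i>.tiff``) and the manifest as manifest.csv.

    Returns the in-memory stacks keyed by class id and the manifest
    DataFrame (columns class_id, rho_f_ugml, rho_c_ugml, split, frame_path,
    frame_index, seed).
    """
    if frames_per_class < 1:
        raise ValueError("frames_per_class must be >= 1")
    ids = [c[0] for c in design]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate class ids in design")
    if splits is None:
        splits = {"train": 1.0}
    frac_total = sum(splits.values())

    root = np.random.SeedSequence(seed)
    class_seeds = root.spawn(len(design))
    # disjoint contiguous frame ranges per split
    split_of_frame = []
    acc = 0.0
    bounds = []
    for name, frac in splits.items():
        acc += frac / frac_total
        bounds.append((name, int(round(acc * frames_per_class))))
    lo = 0
    for name, hi in bounds:
        split_of_frame += [name] * (hi - lo)
        lo = hi

    stacks: dict[str, list[Hologram]] = {}
    rows = []
    for (class_id, rho_f, rho_c), cs in zip(design, class_seeds):
        stack = simulate_stack(rho_f, rho_c, frames_per_class, optics,
                               seed=cs, **stack_kwargs)
        stacks[str(class_id)] = stack
        for i, holo in enumerate(stack):
            path = f"{class_id}/frame_{i:04d}.tiff"
            rows.append({"class_id": str(class_id), "rho_f_ugml": rho_f,
                         "rho_c_ugml": rho_c, "split": split_of_frame[i],
                         "frame_path": path, "frame_index": i, "seed": seed})
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        import tifffile
        from pathlib import Path
        out = Path(out_dir)
        for class_id, stack in stacks.items():
            (out / class_id).mkdir(parents=True, exist_ok=True)
            for i, holo in enumerate(stack):
                arr = holo.to_uint8().intensity.round().astype(np.uint8)
                tifffile.imwrite(out / class_id / f"frame_{i:04d}.tiff", arr)
        manifest.to_csv(out / "manifest.csv", index=False)
    return stacks, manifest
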