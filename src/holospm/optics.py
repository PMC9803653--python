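"""Optical configuration and closed-form optics of the holographic device.

The imaging geometry is an in-line digital holographic microscope: a
collimated laser (wavelength ``wavelength``) illuminates a suspension of
particulate matter, and the interference between scattered and unscattered
light is recorded on a sensor whose *magnified* pixel pitch is
``magnified_pixel_size``.  Everything downstream (simulation, filtering,
speckle statistics) is expressed on this pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "OpticalConfig",
    "SizeDistribution",
    "diffraction_limit",
    "field_of_view",
    "polydispersity_index",
    "filter_criterion_frequency",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry of the holographic recording.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in nm.
    numerical_aperture : float
        NA of the imaging objective, in (0, 1].
    magnified_pixel_size : float
        Effective (magnified) pixel pitch on the object side, in nm.
    image_shape : tuple of int
        (rows, cols) of a recorded frame, in pixels.
    sample_depth : float
        Thickness of the illuminated suspension contributing scatterers, in um.
    focal_offset : float
        Distance from the recording/focal plane to the near wall of the
        sample volume, in mm.
    """

    wavelength: float = 532.0
    numerical_aperture: float = 0.4
    magnified_pixel_size: float = 250.0
    image_shape: tuple[int, int] = (700, 700)
    sample_depth: float = 25_000.0
    focal_offset: float = 5.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.numerical_aperture <= 1:
            raise ValueError("numerical_aperture must lie in (0, 1]")
        if self.magnified_pixel_size <= 0:
            raise ValueError("magnified_pixel_size must be positive")
        if min(self.image_shape) <= 0:
            raise ValueError("image_shape entries must be positive")

    @property
    def pixel_size_um(self) -> float:
        return self.magnified_pixel_size / 1000.0

    def field_of_view_um(self) -> tuple[float, float]:
        """Lateral extent (rows, cols) of the frame in um."""
        m, n = self.image_shape
        return (m * self.pixel_size_um, n * self.pixel_size_um)

    def imaged_volume_ml(self) -> float:
        """Volume of suspension seen by one frame, in ml."""
        fy, fx = self.field_of_view_um()
        volume_um3 = fy * fx * self.sample_depth
        return volume_um3 * 1e-12  # 1 um^3 = 1e-12 ml


@dataclass(frozen=True)
class SizeDistribution:
    """Truncated-normal particle diameter distribution of one PM class.

    Diameters are in um; ``material_density`` is in g/cm^3 (default 2.65,
    silica-dominated mineral dust such as Arizona test dust).
    """

    mean_diameter: float
    sd_diameter: float
    diameter_bounds: tuple[float, float]
    material_density: float = 2.65

    def __post_init__(self) -> None:
        lo, hi = self.diameter_bounds
        if self.mean_diameter <= 0:
            raise ValueError("mean_diameter must be positive")
        if self.sd_diameter < 0:
            raise ValueError("sd_diameter must be non-negative")
        if not 0 < lo < hi:
            raise ValueError("diameter_bounds must be ordered and positive")
        if self.material_density <= 0:
            raise ValueError("material_density must be positive")

    def pdi(self) -> float:
        return polydispersity_index(self)


#: Fine PM class: diameters < 3 um.
FINE_PM = SizeDistribution(mean_diameter=1.256, sd_diameter=1.309,
                           diameter_bounds=(0.2, 3.0))
#: Coarse PM class: diameters 5-10 um.
COARSE_PM = SizeDistribution(mean_diameter=7.657, sd_diameter=1.286,
                             diameter_bounds=(5.0, 10.0))


def diffraction_limit(optics: OpticalConfig) -> float:
    """Rayleigh resolution limit 0.61*lambda/NA, in nm."""
    if optics.numerical_aperture == 0:
        raise ValueError("numerical aperture must be nonzero")
    return 0.61 * optics.wavelength / optics.numerical_aperture


def field_of_view(optics: OpticalConfig) -> tuple[float, float]:
    """Frame side lengths (rows, cols) in um."""
    return optics.field_of_view_um()


def polydispersity_index(dist: SizeDistribution) -> float:
    """PDI = (sd / mean)^2 of the diameter distribution.

    Dimensionless spread measure; ~1 for a very broad (fine dust)
    distribution, ~0.03 for a narrow (sieved coarse) one.
    """
    if dist.mean_diameter == 0:
        raise ValueError("mean diameter must be nonzero")
    return (dist.sd_diameter / dist.mean_diameter) ** 2


def filter_criterion_frequency(filter_size: float, image_side: int) -> float:
    """Gaussian filter size R expressed on the normalized frequency axis.

    A mask built with size ``R`` on an ``N``-pixel frame has its
    characteristic radius at R frequency-grid steps, i.e. R/N cycles/pixel:
    the fine/coarse signal-separation criterion.
    """
    if filter_size <= 0 or image_side <= 0:
        raise ValueError("filter_size and image_side must be positive")
    return filter_size / image_side
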