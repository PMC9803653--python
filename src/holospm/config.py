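"""Pipeline configuration: one YAML-serializable object per run.

Two execution profiles share the algorithm and differ only in scale:
``paper`` uses 700-px frames and the full network recipe; ``test`` uses
small frames and a reduced network so the full pipeline runs on one CPU in
minutes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .network import NetworkSpec, TrainingHyper
from .optics import OpticalConfig
from .preprocess import COARSE_BRANCH, FINE_BRANCH, PreprocParams

__all__ = ["SimulationParams", "PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class SimulationParams:
    """Dataset design of one end-to-end run (concentrations in ug/ml).

    Training data per class is ``train_stacks_per_class`` independent
    stacks of ``frames_per_stack`` frames each (stacks differ in their
    shared background pattern, so the model cannot key on a single stack's
    background fingerprint instead of concentration); evaluation and
    leakage measurement use fresh stacks.
    """

    fine_classes: tuple[float, ...] = (1.0, 3.0, 6.0, 8.0)
    coarse_classes: tuple[float, ...] = (1.0, 3.0, 8.0)
    mixture_classes: tuple[tuple[float, float], ...] = (
        (1.0, 3.0), (3.0, 1.0), (3.0, 8.0), (6.0, 3.0), (8.0, 8.0))
    train_stacks_per_class: int = 3
    frames_per_stack: int = 8
    eval_frames_per_stack: int = 8
    background_amplitude: float = 0.05
    noise_sd: float = 0.02
    n_slices: int = 16


@dataclass
class PipelineConfig:
    profile: str = "test"
    seed: int = 0
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    fine_preproc: PreprocParams = FINE_BRANCH
    coarse_preproc: PreprocParams = COARSE_BRANCH
    network: NetworkSpec = field(default_factory=NetworkSpec)
    k_grid_max: float = 1.5
    k_grid_step: float = 0.01
    out_dir: str = "holospm_run"

    def __post_init__(self) -> None:
        if self.profile not in ("paper", "test"):
            raise ValueError("profile must be 'paper' or 'test'")

    @classmethod
    def test_profile(cls, seed: int = 0) -> "PipelineConfig":
        """Desk-scale run: small frames, reduced network, same algorithm.

        280-px frames (16 tiles): coarse particles at 1-8 ug/ml are so
        massive that a (35 um)^2 column holds well under one per frame, so
        the smallest viable frame is larger than the fine branch alone
        would need.  The fine branch uses a mild contrast gain (C = 1):
        S, C, R are dataset-dependent knobs the method tunes by validation
        RMSE, and on synthetic holograms a strong gain saturates the
        high-pass segments into a self-normalized binary texture that
        erases the concentration signal.
        """
        optics = OpticalConfig(image_shape=(280, 280))
        tile = 70
        return cls(
            profile="test", seed=seed, optics=optics,
            simulation=SimulationParams(train_stacks_per_class=3,
                                        frames_per_stack=8,
                                        eval_frames_per_stack=8),
            fine_preproc=replace(FINE_BRANCH, tile_size=tile, contrast=1.0),
            coarse_preproc=replace(COARSE_BRANCH, tile_size=tile),
            network=NetworkSpec.test_profile(tile_size=tile, seed=seed),
        )

    @classmethod
    def paper_profile(cls, seed: int = 0) -> "PipelineConfig":
        """Full-scale recipe: 700-px frames, one 100-frame stack per class."""
        return cls(profile="paper", seed=seed,
                   optics=OpticalConfig(image_shape=(700, 700)),
                   simulation=SimulationParams(train_stacks_per_class=1,
                                               frames_per_stack=100,
                                               eval_frames_per_stack=30),
                   network=NetworkSpec(seed=seed))


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


def _tupled(seq):
    return tuple(tuple(v) if isinstance(v, list) else v for v in seq)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    optics = raw["optics"]
    optics["image_shape"] = tuple(optics["image_shape"])
    sim = raw["simulation"]
    for key in ("fine_classes", "coarse_classes"):
        sim[key] = tuple(sim[key])
    sim["mixture_classes"] = _tupled(sim["mixture_classes"])
    net = raw["network"]
    for key in ("encoder_widths", "decoder_widths", "regressor_widths"):
        if net[key] is not None:
            net[key] = tuple(net[key])
    net["dae_hyper"] = TrainingHyper(**net["dae_hyper"])
    net["reg_hyper"] = TrainingHyper(**net["reg_hyper"])
    return PipelineConfig(
        profile=raw["profile"], seed=raw["seed"],
        optics=OpticalConfig(**optics),
        simulation=SimulationParams(**sim),
        fine_preproc=PreprocParams(**raw["fine_preproc"]),
        coarse_preproc=PreprocParams(**raw["coarse_preproc"]),
        network=NetworkSpec(**net),
        k_grid_max=raw["k_grid_max"], k_grid_step=raw["k_grid_step"],
        out_dir=raw["out_dir"],
    )
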