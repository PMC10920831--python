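"""Configuration objects for the synthetic generator and the full pipeline.

Defaults encode the analysis parameters of the study design: the 10-cm /
2-cm/s approach rule, 2-s post-onset decoding windows, 5-fold cross-validation
with a 10-s train/validation gap, the 5-behavior session-inclusion minimum,
100 onset randomizations with the 95% classification rule, and the 10%
variance-inclusion filter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic feeding-assay session generator.

    The generator plants behavior-modulated Poisson firing convolved with a
    slow calcium-indicator kernel, and a pose track that physically realizes
    the behavioral schedule (straight 3 cm/s runs toward the food target
    during approach epochs, stationary at the target during eating, wall
    visits for rearing).
    """

    n_cells: int = 50
    duration: float = 600.0  # s
    behavior_rate: float = 30.0  # pose samples / s (video frame rate)
    trace_rate: float = 7.5  # trace samples / s (30 Hz downsampled by 4)

    # cell-type composition; fractions must sum to 1
    frac_eat_neg: float = 0.30
    frac_eat_pos: float = 0.10
    frac_approach_pos: float = 0.20
    frac_unmodulated: float = 0.40

    # event-rate model
    base_rate: float = 0.4  # Poisson events / s outside modulated epochs
    eat_neg_multiplier: float = 0.2
    eat_pos_multiplier: float = 3.0
    approach_pos_multiplier: float = 3.0
    multiplier_jitter_sigma: float = 0.25  # lognormal sigma on each multiplier

    # calcium kernel (GCaMP6s-like double exponential) and noise
    kernel_tau_rise: float = 0.2  # s
    kernel_tau_decay: float = 1.5  # s
    noise_sd: float = 0.05  # df/F

    # arena and behavioral schedule
    arena_radius: float = 25.0  # cm, circular
    target_xy: tuple[float, float] = (5.0, 0.0)
    approach_start_distance: float = 15.0  # cm from target at approach onset
    approach_speed: float = 3.0  # cm/s (above the 2 cm/s criterion)
    wander_speed: float = 1.5  # cm/s (below the 2 cm/s criterion)
    eat_duration: float = 8.0  # s
    rear_duration: float = 3.0  # s
    rear_wall_offset: float = 1.0  # cm inside the wall while rearing

    # photometry
    photometry_rate: float = 20.0  # Hz (alternating 405/470 LEDs)
    photometry_baseline_sig: float = 2.0  # a.u.
    photometry_baseline_ref: float = 1.0  # a.u.
    photometry_noise_sd: float = 0.01  # a.u.
    transient_amplitude: float = 0.5  # a.u., behavior-locked transients
    artifact_amplitude: float = 0.1  # a.u., shared motion/bleaching artifact
    artifact_timescale: float = 2.0  # s, smoothness of the shared artifact

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.behavior_rate <= 0 or self.trace_rate <= 0:
            raise ValueError("sampling rates must be positive")
        fracs = (
            self.frac_eat_neg,
            self.frac_eat_pos,
            self.frac_approach_pos,
            self.frac_unmodulated,
        )
        if any(f < 0 for f in fracs):
            raise ValueError("cell-type fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(
                f"cell-type fractions must sum to 1 (got {sum(fracs)!r})"
            )
        for name in (
            "base_rate",
            "eat_neg_multiplier",
            "eat_pos_multiplier",
            "approach_pos_multiplier",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kernel_tau_rise <= 0 or self.kernel_tau_decay <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.kernel_tau_rise >= self.kernel_tau_decay:
            raise ValueError("kernel_tau_rise must be < kernel_tau_decay")
        if self.photometry_rate <= 0:
            raise ValueError("photometry_rate must be positive")


@dataclass
class PipelineConfig:
    """Thresholds and sizes for the end-to-end analysis pipeline."""

    # behavior detection
    min_decrease: float = 10.0  # cm of distance-to-food decrease per approach
    min_speed: float = 2.0  # cm/s maintained during approach
    jitter_tolerance: float = 0.5  # cm/sample of allowed distance backtrack
    speed_smoothing: float = 0.2  # s boxcar for the speed estimate
    head_definition: str = "ear_midpoint"

    # trace preprocessing and peri-event analysis
    variance_fraction: float = 0.10
    pre_window: float = 5.0  # s before onset for modulation deltas
    post_window: float = 5.0  # s after onset

    # decoding
    window_after_onset: float = 2.0  # s
    n_folds: int = 5
    min_gap: float = 10.0  # s between training and validation samples
    min_count: int = 5  # behaviors per session for inclusion
    zscore_features: bool = True

    # bootstrap cell classification
    n_shuffles: int = 100
    quantile: float = 0.95

    # geometry
    n_components: int = 3
    silhouette_shuffles: int = 1000
    zscore_before_pca: bool = True
    distance_space: str = "full"  # "full" n-dim space or "pca"

    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def validate(self) -> None:
        for name in (
            "min_decrease",
            "min_speed",
            "variance_fraction",
            "window_after_onset",
            "min_gap",
            "pre_window",
            "post_window",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        if self.n_folds < 2 or self.n_shuffles < 1 or self.min_count < 0:
            raise ValueError("invalid fold/shuffle/count settings")
        self.generator.validate()


def _from_mapping(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat YAML/key-value config file into a :class:`PipelineConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen_raw = raw.pop("generator", {}) or {}
    if "target_xy" in gen_raw:
        gen_raw["target_xy"] = tuple(gen_raw["target_xy"])
    cfg = _from_mapping(PipelineConfig, raw)
    cfg.generator = _from_mapping(GeneratorConfig, gen_raw)
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    data["generator"]["target_xy"] = list(data["generator"]["target_xy"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
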