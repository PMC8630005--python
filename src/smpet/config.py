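"""Configuration objects for the smPET simulation and analysis pipeline.

Every stage of the pipeline is driven by a small, validated dataclass.  The
full pipeline is configured by :class:`PipelineConfig`, which nests one block
per stage and can be read from / written to YAML.  Unknown keys in a config
file are rejected rather than ignored, so typos fail before any computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import yaml

MODES = ("atp_cycling", "ampnp_onecolour", "apo")
BLEACH_POLICIES = ("censor", "drop_trace")
MODEL_SELECTIONS = ("bic", "fixed_mono", "fixed_bi")


class ConfigError(ValueError):
    """Raised when a configuration value or schema is invalid."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


@dataclass
class SimulationConfig:
    """Ground-truth generator settings for the two-state clamp model.

    Rates are in events per minute; times in seconds.  ``k_close`` governs the
    coupled open->closed transition of the shared clamp coordinate and
    ``k_open`` the reverse.  With probability ``p_uncoupled`` a closure event
    is reassigned to a single, randomly chosen colour channel (a failed
    closure attempt): it quenches that channel only and relaxes after an
    independent Exp(1/k_open) sojourn.
    """

    n_molecules: int = 50
    duration_s: float = 540.0          # traces typically span ~9 minutes
    frame_interval_s: float = 0.3      # 0.3 s two-colour, 1.0 s one-colour
    mode: str = "atp_cycling"
    k_close: float = 1.0               # min^-1
    k_open: float = 5.0                # min^-1
    p_uncoupled: float = 0.1
    sync_jitter_frames: int = 0
    k_bleach_green: float = 0.0        # min^-1, irreversible
    k_bleach_red: float = 0.0          # min^-1, irreversible
    o2_application_s: float = 600.0    # ampnp mode only
    dspo_mean_delay_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_molecules >= 0, "n_molecules must be >= 0")
        _require(self.mode in MODES, f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("k_close", "k_open", "k_bleach_green", "k_bleach_red"):
            v = getattr(self, name)
            _require(_finite(v) and v >= 0, f"{name} must be a finite rate >= 0, got {v!r}")
        _require(_finite(self.p_uncoupled) and 0.0 <= self.p_uncoupled <= 1.0,
                 f"p_uncoupled must be in [0, 1], got {self.p_uncoupled!r}")
        _require(_finite(self.frame_interval_s) and self.frame_interval_s > 0,
                 "frame_interval_s must be > 0")
        _require(_finite(self.duration_s) and self.duration_s >= self.frame_interval_s,
                 "duration_s must be >= frame_interval_s")
        _require(int(self.sync_jitter_frames) == self.sync_jitter_frames
                 and self.sync_jitter_frames >= 0,
                 "sync_jitter_frames must be an integer >= 0")
        _require(_finite(self.dspo_mean_delay_s) and self.dspo_mean_delay_s > 0,
                 "dspo_mean_delay_s must be > 0")
        _require(_finite(self.o2_application_s) and self.o2_application_s >= 0,
                 "o2_application_s must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s))

    @property
    def channels(self) -> tuple[str, ...]:
        if self.mode == "ampnp_onecolour":
            return ("green",)
        return ("green", "red")


@dataclass
class CameraModel:
    """Rendering model for diffraction-limited TIRF spots on an EMCCD frame.

    EM gain-register statistics are collapsed into a single ``gain`` scalar
    (counts per photon) plus Gaussian read noise; spots are 2-D Gaussians of
    integrated intensity ``photons_per_frame_open`` when fluorescent.
    """

    shape: tuple[int, int] = (512, 512)   # rows, cols
    pixel_size_nm: float = 130.0
    psf_sigma_px: float = 1.3
    photons_per_frame_open: float = 2000.0
    background_photons: float = 20.0      # per pixel per frame
    read_noise: float = 3.0               # rms counts
    gain: float = 1.0                     # counts / photon

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)  # type: ignore[assignment]
        _require(len(self.shape) == 2 and all(s > 0 for s in self.shape),
                 "shape must be two positive integers")
        _require(self.psf_sigma_px > 0, "psf_sigma_px must be > 0")
        _require(self.photons_per_frame_open > 0, "photons_per_frame_open must be > 0")
        _require(self.background_photons >= 0, "background_photons must be >= 0")
        _require(self.read_noise >= 0, "read_noise must be >= 0")
        _require(self.gain > 0, "gain must be > 0")
        # detectability: peak of an open-state spot clears the background by
        # at least 3 read-noise rms
        _require(self.peak_signal_counts >= 3.0 * self.read_noise,
                 "open-state spot peak must exceed background by >= 3x read noise")

    @property
    def peak_signal_counts(self) -> float:
        """Peak pixel value (above background) of an in-focus open-state spot."""
        return self.gain * self.photons_per_frame_open / (2.0 * math.pi * self.psf_sigma_px ** 2)


@dataclass
class TraceNoise:
    """Direct trace-level noise model (bypasses image rendering).

    A fluorescent frame has expected level ``level_open`` photons, a quenched
    or bleached frame ``level_background``; shot noise is Poisson in photons,
    scaled by ``gain``, with additive Gaussian read noise on top.
    """

    level_open: float = 500.0
    level_background: float = 50.0
    shot_noise: bool = True
    read_noise: float = 5.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        _require(self.level_open > self.level_background >= 0,
                 "level_open must exceed level_background >= 0")
        _require(self.read_noise >= 0, "read_noise must be >= 0")
        _require(self.gain > 0, "gain must be > 0")

    @classmethod
    def noiseless(cls, level_open: float = 500.0, level_background: float = 50.0) -> "TraceNoise":
        return cls(level_open=level_open, level_background=level_background,
                   shot_noise=False, read_noise=0.0)


@dataclass
class StepDetectionConfig:
    """Parameters of the smoothing + multiscale-product step detector."""

    smooth_sigma_frames: float = 1.5
    scales: tuple[int, ...] = (1, 2, 4)
    threshold_c: float = 3.0
    min_separation_frames: int = 3
    min_relative_amplitude: float = 0.25

    def __post_init__(self) -> None:
        self.scales = tuple(int(s) for s in self.scales)  # type: ignore[assignment]
        _require(self.smooth_sigma_frames > 0, "smooth_sigma_frames must be > 0")
        _require(len(self.scales) >= 1 and all(s > 0 for s in self.scales),
                 "scales must be positive")
        _require(all(b > a for a, b in zip(self.scales, self.scales[1:])),
                 "scales must be strictly increasing")
        _require(self.threshold_c > 0, "threshold_c must be > 0")
        _require(self.min_separation_frames >= 1, "min_separation_frames must be >= 1")
        _require(self.min_relative_amplitude > 0, "min_relative_amplitude must be > 0")


@dataclass
class AnalysisConfig:
    """Synchronicity pairing and dwell-time kinetics settings.

    ``sync_window_frames`` is the maximum |frame difference| for two
    same-direction steps in the two colour channels to count as one
    synchronous transition (default six frames = 1.8 s at 0.3 s/frame).
    """

    sync_window_frames: int = 6
    frame_interval_s: float = 0.3
    bleach_tail_policy: str = "censor"
    model_selection: str = "bic"
    o2_application_s: float | None = None

    def __post_init__(self) -> None:
        _require(int(self.sync_window_frames) == self.sync_window_frames
                 and self.sync_window_frames >= 0,
                 "sync_window_frames must be an integer >= 0")
        _require(self.frame_interval_s > 0, "frame_interval_s must be > 0")
        _require(self.bleach_tail_policy in BLEACH_POLICIES,
                 f"bleach_tail_policy must be one of {BLEACH_POLICIES}")
        _require(self.model_selection in MODEL_SELECTIONS,
                 f"model_selection must be one of {MODEL_SELECTIONS}")


@dataclass
class PipelineConfig:
    """Top-level pipeline configuration: one block per stage."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    camera: CameraModel = field(default_factory=CameraModel)
    trace_noise: TraceNoise = field(default_factory=TraceNoise)
    step_detection: StepDetectionConfig = field(default_factory=StepDetectionConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    render_images: bool = False
    output_dir: str = "smpet_out"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        # keep the analysis frame interval in lock-step with the simulator's
        # unless the user set it explicitly different on purpose
        _require(self.log_level.upper() in ("DEBUG", "INFO", "WARNING", "ERROR"),
                 f"unknown log_level {self.log_level!r}")

    def config_hash(self) -> str:
        """Stable SHA-256 over the full nested configuration."""
        blob = json.dumps(to_dict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


_BLOCK_TYPES = {
    "simulation": SimulationConfig,
    "camera": CameraModel,
    "trace_noise": TraceNoise,
    "step_detection": StepDetectionConfig,
    "analysis": AnalysisConfig,
}


def _from_dict(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {cls.__name__} block")
    kwargs = dict(data)
    for key in ("shape", "scales"):
        if key in kwargs and isinstance(kwargs[key], Sequence):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def pipeline_config_from_dict(data: dict) -> PipelineConfig:
    """Build and validate a :class:`PipelineConfig` from a plain nested dict."""
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in pipeline config")
    kwargs: dict = {}
    for key, value in data.items():
        if key in _BLOCK_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"{key} block must be a mapping")
            kwargs[key] = _from_dict(_BLOCK_TYPES[key], value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def to_dict(obj) -> dict:
    """Dataclass tree -> plain dict (tuples become lists, YAML/JSON-safe)."""
    d = dataclasses.asdict(obj)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return [clean(v) for v in x]
        if isinstance(x, list):
            return [clean(v) for v in x]
        return x

    return clean(d)


def load_pipeline_config(path) -> PipelineConfig:
    """Read a YAML (or JSON) pipeline config file; schema-validated."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("pipeline config must be a mapping at the top level")
    return pipeline_config_from_dict(data)


def save_pipeline_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=False)
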