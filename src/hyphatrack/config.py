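"""Configuration objects for simulation, rendering and detection.

All distances are in micrometres (µm) and all times in minutes unless a
field name says otherwise.  The simulator works on a discrete frame grid
with spacing ``frame_interval`` minutes; rates expressed "per interval"
refer to that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

__all__ = [
    "SimulationConfig",
    "ImagingConfig",
    "DetectionConfig",
    "SCENARIOS",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


#: Scenario presets for the anchored-oriC process.  The wild type keeps the
#: tip-proximal oriC at 1.4 +/- 0.4 µm from the tip; the segregation-protein
#: deletion scenarios place it further away and make it far more variable,
#: and populate new branches later.  The mutant anchor_sd values are nominal
#: AR(1) parameters chosen so that the *realized* tip-distance spread (after
#: truncation at the tip) reproduces the observed mutant/wild-type variance
#: ratios of ~6.3 and ~11.9 with realized s.d. ~1.0 and ~1.4 µm.
SCENARIOS = {
    "wild_type": dict(anchor_offset=1.4, anchor_sd=0.4, branch_populate_delay=3),
    "delta_parA": dict(anchor_offset=2.3, anchor_sd=1.05, branch_populate_delay=5),
    "delta_parB": dict(anchor_offset=2.5, anchor_sd=1.6, branch_populate_delay=6),
}


@dataclass
class SimulationConfig:
    """Parameters of the hyphal growth + chromosome dynamics simulator.

    Parameters
    ----------
    n_hyphae, n_frames
        Number of independent hyphae and frames per hypha.
    frame_interval
        Minutes between frames (default 10, matching typical time-lapse
        acquisition of slow-growing filamentous bacteria).
    extension_rate_mean, extension_rate_sd
        Mean and between-hypha s.d. of the tip extension rate, µm per
        interval.  Each hypha draws one rate; per-frame noise is added on
        top (``extension_noise_sd``).
    anchor_offset, anchor_sd
        Stationary mean and s.d. of the tip -> oriC1 distance for the
        anchored (tip-proximal) chromosome.
    anchor_relaxation
        Mean-reversion strength kappa in (0, 1] of the AR(1) anchor
        process ``d <- d + kappa*(offset - d) + eta``.
    coupling_base
        Geometric per-index decay of tip coupling for trailing oriCs:
        oriC j (j >= 2) receives a fraction ``coupling_base**j`` of each
        tip displacement, so its tip distance drifts when coupling < 1.
    n_chromosomes_initial
        Number of oriC objects present at frame 0 (tip-ordered).
    replication_schedule
        ``(oriC_index, start_frame, duration_frames)`` triples: a
        replisome appears next to the oriC holding the given tip index at
        ``start_frame`` and the focus splits ``duration_frames`` later.
    branch_schedule
        ``(frame, stem_position_um, populate_delay_frames, stall)``
        tuples describing branch emergence, chromosome entry delay and
        whether the branch stalls.
    scenario
        One of ``wild_type``/``delta_parA``/``delta_parB``; presets fill
        anchor parameters when they are left at ``None``.
    seed
        Master seed; per-hypha streams are derived as ``(seed, hypha_id)``.
    """

    n_hyphae: int = 1
    n_frames: int = 30
    frame_interval: float = 10.0
    extension_rate_mean: float = 0.7
    extension_rate_sd: float = 0.15
    extension_noise_sd: float = 0.15
    anchor_offset: Optional[float] = None
    anchor_sd: Optional[float] = None
    anchor_relaxation: float = 0.3
    coupling_base: float = 0.7
    n_chromosomes_initial: int = 3
    replication_schedule: Sequence[Tuple[int, int, int]] = field(default_factory=tuple)
    branch_schedule: Sequence[Tuple[int, float, int, bool]] = field(default_factory=tuple)
    scenario: str = "wild_type"
    seed: int = 0
    # -- secondary knobs (assumed values; the source data report none) --
    trailing_noise_sd: float = 0.15
    initial_spacing: float = 1.8
    initial_length: Optional[float] = None
    initial_split_separation: float = 0.5
    replisome_jitter: float = 0.04
    stall_growth_frames: int = 3
    branch_extension_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        preset = SCENARIOS[self.scenario]
        if self.anchor_offset is None:
            self.anchor_offset = preset["anchor_offset"]
        if self.anchor_sd is None:
            self.anchor_sd = preset["anchor_sd"]
        self.validate()

    def validate(self) -> None:
        if self.n_hyphae < 0 or self.n_frames < 2:
            raise ConfigurationError("need n_hyphae >= 0 and n_frames >= 2")
        if self.extension_rate_mean < 0:
            raise ConfigurationError("extension_rate_mean must be >= 0")
        if self.anchor_sd < 0:
            raise ConfigurationError("anchor_sd must be >= 0")
        if not (0.0 < self.anchor_relaxation <= 1.0):
            raise ConfigurationError("anchor_relaxation must be in (0, 1]")
        if not (0.0 <= self.coupling_base <= 1.0):
            raise ConfigurationError("coupling_base must be in [0, 1]")
        if self.n_chromosomes_initial < 1:
            raise ConfigurationError("need at least one chromosome")
        for idx, start, duration in self.replication_schedule:
            if not (1 <= idx):
                raise ConfigurationError(f"replication schedule index {idx} invalid")
            if start < 0 or duration < 1 or start + duration >= self.n_frames:
                raise ConfigurationError(
                    f"replication event ({idx}, {start}, {duration}) outside movie"
                )
        for frame, pos, delay, _stall in self.branch_schedule:
            if frame < 0 or frame >= self.n_frames:
                raise ConfigurationError("branch emergence frame outside movie")
            if pos < 0:
                raise ConfigurationError("branch stem position must be >= 0")
            if delay < 0:
                raise ConfigurationError("populate_delay must be >= 0")

    @property
    def default_initial_length(self) -> float:
        if self.initial_length is not None:
            return self.initial_length
        return self.anchor_offset + self.initial_spacing * self.n_chromosomes_initial + 1.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["replication_schedule"] = [list(x) for x in self.replication_schedule]
        d["branch_schedule"] = [list(x) for x in self.branch_schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["replication_schedule"] = [tuple(x) for x in d.get("replication_schedule", [])]
        d["branch_schedule"] = [tuple(x) for x in d.get("branch_schedule", [])]
        return cls(**d)


@dataclass
class ImagingConfig:
    """Rendering model: optics and camera for the synthetic microscope.

    ``pixel_size`` defaults to 0.065 µm/px and ``psf_sigma`` to 0.15 µm,
    i.e. a 100x oil objective with a diffraction-limited point-spread
    function; both configurable.
    """

    pixel_size: float = 0.065
    psf_sigma: float = 0.15
    spot_amplitude: dict = field(
        default_factory=lambda: {"fros": 400.0, "parb": 350.0, "replisome": 350.0}
    )
    background_level: float = 100.0
    read_noise_sd: float = 6.0
    poisson_noise: bool = True
    hypha_width: int = 7
    tube_intensity: float = 40.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ConfigurationError("pixel_size and psf_sigma must be > 0")
        if any(a < 0 for a in self.spot_amplitude.values()):
            raise ConfigurationError("spot amplitudes must be >= 0")
        if self.hypha_width < 1:
            raise ConfigurationError("hypha_width must be >= 1 px")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingConfig":
        return cls(**dict(d))


@dataclass
class DetectionConfig:
    """Focus detection parameters.

    ``threshold_mode='fraction_of_max'`` with ``threshold_value=0.5``
    reproduces the snapshot rule (focus called when intensity exceeds half
    the brightest signal in the hypha).  Time-lapse analyses default to a
    0.3 fraction so sub-dominant daughter foci survive thresholding, and
    rely on the persistence filter instead of manual vetting.
    """

    smoothing_window: int = 3
    threshold_mode: str = "fraction_of_max"
    threshold_value: float = 0.5
    min_separation: float = 0.4
    min_persistence_frames: int = 2
    dip_fraction: float = 0.1
    #: robust noise floor: peaks must also exceed this many noise s.d.
    #: (first-difference estimate); 0 disables.  Guards channels/frames
    #: with no true signal, where a fraction-of-max rule alone would
    #: call noise maxima.
    noise_floor_sigmas: float = 6.0

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigurationError("smoothing_window must be odd and >= 1")
        if self.threshold_mode not in ("fraction_of_max", "absolute"):
            raise ConfigurationError("threshold_mode must be fraction_of_max|absolute")
        if self.threshold_mode == "fraction_of_max" and not (0 < self.threshold_value <= 1):
            raise ConfigurationError("fractional threshold must be in (0, 1]")
        if self.min_separation < 0:
            raise ConfigurationError("min_separation must be >= 0")
        if self.min_persistence_frames < 1:
            raise ConfigurationError("min_persistence_frames must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionConfig":
        return cls(**dict(d))


def timelapse_detection_config(**overrides) -> DetectionConfig:
    """Detection defaults for time-lapse mode (lower threshold + persistence)."""
    kw = dict(threshold_value=0.3)
    kw.update(overrides)
    return DetectionConfig(**kw)
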