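"""Configuration objects for the simulator and the pipeline driver.

``SimConfig`` fixes every free parameter of the synthetic data generator:
collar duty cycle, per-behaviour acceleration signal models, behaviour
dwell times, the landscape (goose density surface and den locations), and
the true coefficients of the caching model used to draw per-burst digging
events. ``PipelineConfig`` collects the knobs of the analysis chain
(window length, GPS matching gap, den buffer, capture exclusion, the
algorithm roster and selection criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .behaviors import CATEGORIES, DIGGING, LOCOMOTOR_STATES


@dataclass
class SignalParams:
    """Acceleration signal model for one behaviour.

    ``static`` holds the quasi-static (gravity) component in g for the
    (sway, surge, heave) axes, ``amplitude`` the dynamic peak amplitude
    per axis in g, ``frequency`` the dominant stride/stroke frequency in
    Hz and ``noise_sd`` the white-noise SD in g.
    """

    static: tuple[float, float, float]
    amplitude: tuple[float, float, float]
    frequency: float
    noise_sd: float
    harmonic: float = 0.0  # relative amplitude of the 2f harmonic
    bursty: bool = False  # amplitude-modulated bursts with pauses


def _default_signal_params() -> dict[str, SignalParams]:
    # Qualitative contrasts: running is a fast, large-amplitude gait;
    # walking a slower, moderate one (running amplitude ~3x walking);
    # digging an irregular bursty signal with the muzzle pitched down
    # (negative surge static shift); motionless is gravity plus noise.
    return {
        "running": SignalParams(
            static=(0.0, 0.10, 0.90),
            amplitude=(0.25, 0.35, 0.65),
            frequency=3.5,
            noise_sd=0.06,
            harmonic=0.25,
        ),
        "walking": SignalParams(
            static=(0.0, 0.05, 0.95),
            amplitude=(0.08, 0.12, 0.22),
            frequency=2.0,
            noise_sd=0.04,
            harmonic=0.35,
        ),
        "digging": SignalParams(
            static=(0.0, -0.30, 0.75),
            amplitude=(0.30, 0.45, 0.55),
            frequency=4.5,
            noise_sd=0.08,
            bursty=True,
        ),
        "motionless": SignalParams(
            static=(0.0, 0.05, 0.98),
            amplitude=(0.0, 0.0, 0.0),
            frequency=0.0,
            noise_sd=0.02,
        ),
    }


@dataclass
class LandscapeParams:
    """Goose-density raster and den layout.

    The raster is an ``n_rows`` x ``n_cols`` grid of square cells of side
    ``cell_size_m`` (100 m -> 1 ha cells, so values are geese/ha
    directly). Density is a sum of Gaussian patches emulating the patchy
    structure of a nesting colony.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size_m: float = 100.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata_value: float = -9999.0
    # (x_m, y_m, peak geese/ha, sd_m) per patch
    patches: tuple[tuple[float, float, float, float], ...] = (
        (3000.0, 6500.0, 40.0, 900.0),
        (6500.0, 4000.0, 25.0, 1200.0),
        (5000.0, 8000.0, 15.0, 700.0),
    )
    n_dens: int = 12


@dataclass
class GlmmTruth:
    """True coefficients of the cloglog caching model, on the linear
    predictor scale: eta = b0 + b1*z_density + b2*brooding
    + b3*z_density*brooding + b4*female + b5*nonreproductive
    + b6*female*nonreproductive + u_fox + v_year."""

    b0: float = -1.35
    b1: float = 0.16
    b2: float = 0.04
    b3: float = -0.03
    b4: float = 0.59
    b5: float = 0.03
    b6: float = -1.05
    sigma_fox: float = 0.46
    sigma_year: float = 0.07

    def as_array(self):
        return [self.b0, self.b1, self.b2, self.b3, self.b4, self.b5, self.b6]


@dataclass
class SimConfig:
    seed: int = 0
    sampling_rate: float = 50.0  # Hz
    burst_duration: float = 30.0  # s
    burst_interval_min: float = 4.5  # min between burst starts
    fix_interval_min: float = 4.0  # min between GPS fixes
    window_s: float = 3.0  # classification window

    signal: dict[str, SignalParams] = field(default_factory=_default_signal_params)
    noise_scale: float = 1.0  # multiplies every behaviour's noise SD

    # Semi-Markov locomotor process: exponential dwell times (s) and an
    # embedded transition matrix over (running, walking, motionless).
    dwell_mean_s: dict[str, float] = field(
        default_factory=lambda: {"running": 80.0, "walking": 20.0, "motionless": 115.0}
    )
    # uniform embedded chain: from each state, jump to either other state
    transition: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "running": {"walking": 0.5, "motionless": 0.5},
            "walking": {"running": 0.5, "motionless": 0.5},
            "motionless": {"running": 0.5, "walking": 0.5},
        }
    )
    # movement speed (m/s) while in each locomotor state
    speed_m_s: dict[str, float] = field(
        default_factory=lambda: {"running": 3.0, "walking": 0.8, "motionless": 0.0}
    )
    turn_sd_rad: float = 0.6  # heading increment SD per 3-s step
    gps_jitter_m: float = 0.0  # optional Gaussian position error

    landscape: LandscapeParams = field(default_factory=LandscapeParams)
    glmm: GlmmTruth = field(default_factory=GlmmTruth)

    # digging overlay: a burst whose cloglog draw is 1 receives
    # 1 + Binomial(9, extra_dig_window_prob) digging windows
    extra_dig_window_prob: float = 0.25
    # digging draws are suppressed within this distance of a den unless
    # den-adjacent digging is explicitly allowed (lets the 50-m den
    # filter be exercised cleanly in tests)
    allow_den_adjacent_digging: bool = True
    den_digging_buffer_m: float = 50.0

    n_foxes: int = 4
    years: tuple[int, ...] = (2018, 2019)
    hours_per_fox: float = 24.0

    # goose phenology per year (month, day): incubation start, brooding
    # start, brooding end
    season_dates: dict[int, dict[str, tuple[int, int]]] = field(
        default_factory=lambda: {
            2018: {
                "incubation_start": (6, 19),
                "brooding_start": (7, 12),
                "brooding_end": (8, 3),
            },
            2019: {
                "incubation_start": (6, 12),
                "brooding_start": (7, 5),
                "brooding_end": (7, 27),
            },
        }
    )
    # tracking starts this many days after incubation start (negative ->
    # some pre-season bursts, exercising the phenology filter)
    start_offset_days: float = -0.05
    # split each fox-year's recording into an incubation session and a
    # brooding session so both period levels occur; with False, one
    # continuous session starts at incubation start + offset
    include_brooding_session: bool = True

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.burst_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("burst_duration x sampling_rate must be an integer")
        if self.glmm.sigma_fox < 0 or self.glmm.sigma_year < 0:
            raise ValueError("random-effect SDs must be non-negative")
        for state in LOCOMOTOR_STATES:
            if self.dwell_mean_s[state] <= 0:
                raise ValueError("dwell-time means must be positive")
        missing = set(CATEGORIES) - set(self.signal)
        if missing:
            raise ValueError(f"signal parameters missing for {sorted(missing)}")

    @property
    def samples_per_burst(self) -> int:
        return round(self.burst_duration * self.sampling_rate)

    @property
    def samples_per_window(self) -> int:
        return round(self.window_s * self.sampling_rate)

    @property
    def windows_per_burst(self) -> int:
        n, rem = divmod(round(self.burst_duration * 1000), round(self.window_s * 1000))
        if rem:
            raise ValueError("window_s must divide burst_duration")
        return n


DEFAULT_ALGORITHMS = (
    "knn3",
    "svm_linear",
    "svm_rbf",
    "decision_tree",
    "random_forest",
    "naive_bayes",
    "lda",
    "neural_net",
)


@dataclass
class PipelineConfig:
    """Analysis-chain knobs; defaults follow the study protocol
    (3-s windows, 30-s GPS gap, 50-m den buffer, 2-day capture
    exclusion, 5 folds)."""

    window_s: float = 3.0
    max_gps_gap_s: float = 30.0
    den_buffer_m: float = 50.0
    capture_exclusion_h: float = 48.0
    n_folds: int = 5
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    selection_criterion: str = "weighted_precision"
    seed: int = 0
    two_sd_standardization: bool = False
    annotation_clock_offset_s: float = 0.0

    def validate(self) -> None:
        for name, value in (
            ("window_s", self.window_s),
            ("max_gps_gap_s", self.max_gps_gap_s),
            ("den_buffer_m", self.den_buffer_m),
            ("capture_exclusion_h", self.capture_exclusion_h),
            ("n_folds", self.n_folds),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML mapping; unknown keys rejected."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "algorithms" in raw:
        raw["algorithms"] = tuple(raw["algorithms"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def dump_pipeline_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["algorithms"] = list(data["algorithms"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
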