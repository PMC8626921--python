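"""Synthetic biologging data with known ground truth.

Emulates the data a GPS-accelerometer collar study produces: 30-s
tri-axial bursts at 50 Hz every 4.5 min, a GPS fix every 4 min, a patchy
goose-density landscape with dens, behavioural annotation logs, and fox
metadata. The fox alternates locomotor states (running, walking,
motionless) under a semi-Markov process with exponential dwell times and
moves by a correlated random walk whose speed depends on the state.
Digging — the acceleration signature of food caching — is overlaid per
burst from a complementary log-log model with known coefficients, so the
whole analysis chain (classification, burst-GPS fusion, mixed-model
fitting) can be validated by parameter recovery.

The generator is deterministic: one global seed, split into independent
per-fox streams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behaviors import CATEGORIES, DIGGING, LOCOMOTOR_STATES, validate_behavior
from .config import SimConfig
from .raster import DensityRaster

#: reference epoch for annotation clocks (seconds in BORIS-style logs
#: are measured from this instant, shifted by the configured clock
#: offset)
ANNOTATION_EPOCH = pd.Timestamp("2018-01-01T00:00:00Z")

# raw ethogram names the annotation writer samples from, per category
RAW_NAME_POOL = {
    "running": ("running",),
    "walking": ("walking",),
    "digging": ("egg caching", "egg recovering", "eating from cache"),
    "motionless": ("sitting", "lying down", "standing"),
}


@dataclass
class TriaxialSignal:
    """Equal-length sample arrays (g) for the sway (lateral), surge
    (longitudinal) and heave (vertical) axes."""

    sway: np.ndarray
    surge: np.ndarray
    heave: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.sway = np.asarray(self.sway, dtype=float)
        self.surge = np.asarray(self.surge, dtype=float)
        self.heave = np.asarray(self.heave, dtype=float)
        if not (self.sway.shape == self.surge.shape == self.heave.shape):
            raise ValueError("axis arrays must have identical length")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.sway.size

    def as_array(self) -> np.ndarray:
        """(3, n_samples) array in (sway, surge, heave) order."""
        return np.stack([self.sway, self.surge, self.heave])


@dataclass
class SimulatedSeason:
    """Everything one simulated field campaign produces."""

    config: SimConfig
    bursts: pd.DataFrame  # fox_id, burst_id, year, start_time
    signals: np.ndarray  # (n_bursts, 3, samples_per_burst)
    gps: pd.DataFrame  # fox_id, timestamp, x_m, y_m
    metadata: pd.DataFrame  # fox_id, sex, reproductive, captures
    season_dates: pd.DataFrame  # year, incubation_start, brooding_start, brooding_end
    raster: DensityRaster
    dens: pd.DataFrame  # den_id, x_m, y_m
    truth_windows: pd.DataFrame  # burst_id, window_index, label
    truth_bursts: pd.DataFrame  # burst_id, digging, eta, p, density, ...
    random_effects: pd.DataFrame  # level, name, value
    density_mean: float
    density_sd: float


def _signal_array(
    behavior: str, n: int, rate: float, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """(3, n) acceleration array for one uninterrupted behaviour."""
    p = config.signal[behavior]
    t = np.arange(n) / rate
    noise_sd = p.noise_sd * config.noise_scale
    # collar posture varies between bouts: a random baseline offset per
    # axis, same magnitude as the sample noise, so the noise knob also
    # blurs the quasi-static (gravity) contrasts between behaviours
    posture = rng.normal(0.0, noise_sd, 3)
    out = np.empty((3, n))
    if p.bursty:
        # irregular digging bouts: on/off envelope, per-bout carrier
        # frequency drawn in [f-0.5, f+0.5] Hz, amplitude jitter
        env = np.zeros(n)
        carrier = np.zeros(n)
        i = 0
        while i < n:
            on = max(1, int(rng.uniform(0.4, 0.9) * rate))
            off = max(1, int(rng.uniform(0.2, 0.6) * rate))
            j = min(n, i + on)
            f = rng.uniform(p.frequency - 0.5, p.frequency + 0.5)
            phase = rng.uniform(0, 2 * np.pi)
            scale = rng.uniform(0.6, 1.3)
            carrier[i:j] = scale * np.sin(2 * np.pi * f * t[i:j] + phase)
            env[i:j] = 1.0
            i = j + off
        for k in range(3):
            out[k] = (
                p.static[k]
                + posture[k]
                + p.amplitude[k] * env * carrier
                + rng.normal(0.0, noise_sd, n)
            )
    else:
        phase0 = rng.uniform(0, 2 * np.pi)
        axis_phase = (0.0, np.pi / 4, np.pi / 2)  # gait phase lags
        for k in range(3):
            base = np.sin(2 * np.pi * p.frequency * t + phase0 + axis_phase[k])
            harm = p.harmonic * np.sin(
                4 * np.pi * p.frequency * t + 2 * (phase0 + axis_phase[k])
            )
            out[k] = (
                p.static[k]
                + posture[k]
                + p.amplitude[k] * (base + harm)
                + rng.normal(0.0, noise_sd, n)
            )
    return out


def simulate_behavior_signal(
    behavior: str, duration: float, config: SimConfig, seed: int
) -> TriaxialSignal:
    """One uninterrupted behaviour bout as a tri-axial signal.

    Running and walking are periodic gait signals with distinct dominant
    frequencies and amplitudes; digging is an irregular, amplitude-
    modulated bursty signal with the surge axis pitched down (head close
    to the ground); motionless is a near-constant gravity vector plus
    sensor noise. Deterministic for a given seed.
    """
    validate_behavior(behavior)
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    n = round(duration * config.sampling_rate)
    rng = np.random.default_rng(seed)
    arr = _signal_array(behavior, n, config.sampling_rate, config, rng)
    return TriaxialSignal(arr[0], arr[1], arr[2], config.sampling_rate)


def simulate_training_set(
    counts: dict[str, int], config: SimConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled 3-s windows drawn independently per class.

    Returns ``(signals, labels)`` with signals of shape
    ``(n, 3, samples_per_window)`` and labels an object array of
    category names. Used for classifier calibration experiments.
    """
    rng = np.random.default_rng(seed)
    n_samp = config.samples_per_window
    sigs, labels = [], []
    for behavior in CATEGORIES:
        for _ in range(int(counts.get(behavior, 0))):
            sigs.append(
                _signal_array(behavior, n_samp, config.sampling_rate, config, rng)
            )
            labels.append(behavior)
    order = rng.permutation(len(labels))
    return np.stack(sigs)[order], np.asarray(labels, dtype=object)[order]


def _fox_covariates(n_foxes: int, rng: np.random.Generator):
    """Sex and reproductive status per fox; every sex x status
    combination present whenever n_foxes >= 4 so the caching model's
    factorial design stays full rank on small campaigns."""
    sexes = rng.choice(["M", "F"], n_foxes)
    statuses = rng.choice(["yes", "no"], n_foxes)
    combos = [("M", "yes"), ("M", "no"), ("F", "yes"), ("F", "no")]
    if n_foxes >= 4:
        order = rng.permutation(n_foxes)[:4]
        for (sx, st), i in zip(combos, order):
            sexes[i] = sx
            statuses[i] = st
    return sexes, statuses


def simulate_landscape(
    config: SimConfig, seed: int
) -> tuple[DensityRaster, pd.DataFrame]:
    """Goose-density surface (sum of Gaussian patches) plus den sites.

    Dens are placed uniformly at random, at least one cell inside the
    raster boundary.
    """
    lp = config.landscape
    if lp.n_rows <= 0 or lp.n_cols <= 0:
        raise ValueError("landscape grid must have positive dimensions")
    rng = np.random.default_rng(seed)
    # cell centres
    xs = lp.xllcorner + (np.arange(lp.n_cols) + 0.5) * lp.cell_size_m
    ys_bottom = lp.yllcorner + (np.arange(lp.n_rows) + 0.5) * lp.cell_size_m
    ys = ys_bottom[::-1]  # row 0 = north
    gx, gy = np.meshgrid(xs, ys)
    values = np.zeros((lp.n_rows, lp.n_cols))
    for cx, cy, peak, sd in lp.patches:
        values += peak * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sd**2))
    raster = DensityRaster(
        values, lp.xllcorner, lp.yllcorner, lp.cell_size_m, lp.nodata_value
    )
    xmin, ymin, xmax, ymax = raster.extent
    margin = lp.cell_size_m
    dens = pd.DataFrame(
        {
            "den_id": [f"D{i + 1:02d}" for i in range(lp.n_dens)],
            "x_m": rng.uniform(xmin + margin, xmax - margin, lp.n_dens),
            "y_m": rng.uniform(ymin + margin, ymax - margin, lp.n_dens),
        }
    )
    return raster, dens


def _simulate_state_sequence(
    total_s: float, config: SimConfig, rng: np.random.Generator
) -> list[tuple[float, float, str]]:
    """Semi-Markov locomotor sequence as (start_s, end_s, state) segments."""
    states = list(LOCOMOTOR_STATES)
    seg = []
    t = 0.0
    state = rng.choice(states, p=_stationary_embedded(config))
    while t < total_s:
        dwell = rng.exponential(config.dwell_mean_s[state])
        seg.append((t, min(t + dwell, total_s), state))
        t += dwell
        probs = config.transition[state]
        nxt = [s for s in states if s != state]
        pvec = np.array([probs[s] for s in nxt])
        state = rng.choice(nxt, p=pvec / pvec.sum())
    return seg


def _stationary_embedded(config: SimConfig) -> np.ndarray:
    """Stationary distribution of the embedded jump chain."""
    states = list(LOCOMOTOR_STATES)
    P = np.zeros((3, 3))
    for i, s in enumerate(states):
        for j, s2 in enumerate(states):
            if s2 != s:
                P[i, j] = config.transition[s][s2]
        P[i] /= P[i].sum()
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmax(np.real(w))])
    pi = np.abs(pi)
    return pi / pi.sum()


def stationary_locomotor_distribution(config: SimConfig) -> dict[str, float]:
    """Long-run time fraction in each locomotor state.

    For a semi-Markov process this is the embedded-chain stationary
    distribution weighted by the mean dwell times.
    """
    pi = _stationary_embedded(config)
    m = np.array([config.dwell_mean_s[s] for s in LOCOMOTOR_STATES])
    p = pi * m
    p /= p.sum()
    return dict(zip(LOCOMOTOR_STATES, p))


def cloglog_probability(eta: np.ndarray) -> np.ndarray:
    """P(y=1) = 1 - exp(-exp(eta))."""
    return -np.expm1(-np.exp(np.clip(eta, -30.0, 30.0)))


def _season_start(config: SimConfig, year: int) -> pd.Timestamp:
    m, d = config.season_dates[year]["incubation_start"]
    return pd.Timestamp(year=year, month=m, day=d, tz="UTC") + pd.Timedelta(
        days=config.start_offset_days
    )


def season_dates_frame(config: SimConfig) -> pd.DataFrame:
    rows = []
    for year, dates in config.season_dates.items():
        row = {"year": year}
        for key, (m, d) in dates.items():
            row[key] = pd.Timestamp(year=year, month=m, day=d).date().isoformat()
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_fox_season(config: SimConfig) -> SimulatedSeason:
    """Simulate the full campaign: every configured fox in every year.

    Per fox-year the collar records a 30-s burst every 4.5 min and a GPS
    fix every 4 min (first record one interval after tracking start).
    Each burst's digging indicator is drawn from the cloglog model with
    the configured true coefficients, standardized local goose density,
    period, sex, status and the fox/year random intercepts; a positive
    draw converts >= 1 of the burst's 3-s windows to digging.
    """
    if config.n_foxes <= 0:
        raise ValueError("need at least one fox")
    if config.hours_per_fox <= 0:
        raise ValueError("recording duration must be positive")

    root = np.random.SeedSequence(config.seed)
    ss_land, ss_meta, ss_glmm, *ss_foxes = root.spawn(3 + config.n_foxes)
    raster, dens = simulate_landscape(config, ss_land)
    rng_meta = np.random.default_rng(ss_meta)
    rng_glmm = np.random.default_rng(ss_glmm)

    fox_ids = [f"F{i + 1:02d}" for i in range(config.n_foxes)]
    sexes, statuses = _fox_covariates(config.n_foxes, rng_meta)

    u_fox = rng_glmm.normal(0.0, config.glmm.sigma_fox, config.n_foxes)
    v_year = rng_glmm.normal(0.0, config.glmm.sigma_year, len(config.years))
    year_index = {y: i for i, y in enumerate(config.years)}

    den_xy = dens[["x_m", "y_m"]].to_numpy()
    xmin, ymin, xmax, ymax = raster.extent
    step_s = config.window_s
    burst_dt = config.burst_interval_min * 60.0
    fix_dt = config.fix_interval_min * 60.0
    wpb = config.windows_per_burst
    spw = config.samples_per_window

    def _sessions(year: int) -> list[tuple[pd.Timestamp, float]]:
        start = _season_start(config, year)
        if not config.include_brooding_session:
            return [(start, config.hours_per_fox)]
        m, d = config.season_dates[year]["brooding_start"]
        brood = pd.Timestamp(year=year, month=m, day=d, tz="UTC") + pd.Timedelta(days=1)
        half = config.hours_per_fox / 2.0
        return [(start, half), (brood, half)]

    burst_rows, gps_rows, win_rows = [], [], []
    meta_rows, truth_rows = [], []
    sig_blocks = []
    captures: dict[str, list[pd.Timestamp]] = {}

    # first pass: behaviour sequences, tracks, burst covariates
    pending = []  # (fox, year, start_ts, burst_times, labels per burst, ...)
    densities = []
    for fi, fox in enumerate(fox_ids):
        fox_streams = ss_foxes[fi].spawn(len(config.years))
        for yi, year in enumerate(config.years):
            rng = np.random.default_rng(fox_streams[yi])
            captures.setdefault(fox, []).append(
                _season_start(config, year) - pd.Timedelta(days=3)
            )
            burst_offset = 0
            for start_ts, sess_hours in _sessions(year):
                total_s = sess_hours * 3600.0
                # grid covers the tail of a burst starting at total_s
                n_steps = int(
                    np.ceil((total_s + config.burst_duration) / step_s)
                ) + 1
                n_bursts_per = int(np.floor(total_s / burst_dt))
                n_fixes_per = int(np.floor(total_s / fix_dt))
                segments = _simulate_state_sequence(
                    total_s + config.burst_duration, config, rng
                )
                # state label on the 3-s grid (state at interval midpoint)
                bounds = np.array([s[1] for s in segments])
                seg_states = np.array([s[2] for s in segments], dtype=object)
                mid = (np.arange(n_steps) + 0.5) * step_s
                idx = np.clip(np.searchsorted(bounds, mid), 0, len(segments) - 1)
                grid_states = seg_states[idx]
                # correlated random walk, reflecting at the raster boundary
                heading = rng.uniform(0, 2 * np.pi)
                pos = np.empty((n_steps + 1, 2))
                pos[0] = (
                    rng.uniform(
                        xmin + 0.1 * (xmax - xmin), xmax - 0.1 * (xmax - xmin)
                    ),
                    rng.uniform(
                        ymin + 0.1 * (ymax - ymin), ymax - 0.1 * (ymax - ymin)
                    ),
                )
                turns = rng.normal(0.0, config.turn_sd_rad, n_steps)
                speeds = np.array([config.speed_m_s[s] for s in grid_states])
                for i in range(n_steps):
                    heading += turns[i]
                    x = pos[i, 0] + speeds[i] * step_s * np.cos(heading)
                    y = pos[i, 1] + speeds[i] * step_s * np.sin(heading)
                    if not (xmin < x < xmax):
                        heading = np.pi - heading
                        x = np.clip(x, xmin + 1.0, xmax - 1.0)
                    if not (ymin < y < ymax):
                        heading = -heading
                        y = np.clip(y, ymin + 1.0, ymax - 1.0)
                    pos[i + 1] = (x, y)

                burst_times = (np.arange(1, n_bursts_per + 1)) * burst_dt
                fix_times = (np.arange(1, n_fixes_per + 1)) * fix_dt
                fix_pos = pos[np.round(fix_times / step_s).astype(int)]
                if config.gps_jitter_m > 0:
                    fix_pos = fix_pos + rng.normal(
                        0, config.gps_jitter_m, fix_pos.shape
                    )
                for t, (x, y) in zip(fix_times, fix_pos):
                    gps_rows.append(
                        {
                            "fox_id": fox,
                            "timestamp": start_ts + pd.Timedelta(seconds=float(t)),
                            "x_m": x,
                            "y_m": y,
                        }
                    )
                b_idx = np.round(burst_times / step_s).astype(int)
                b_pos = pos[b_idx]
                b_dens = raster.value_at(b_pos[:, 0], b_pos[:, 1])
                densities.append(b_dens)
                b_labels = [grid_states[k : k + wpb].copy() for k in b_idx]
                pending.append(
                    (
                        fi,
                        yi,
                        fox,
                        year,
                        start_ts,
                        burst_times,
                        b_pos,
                        b_dens,
                        b_labels,
                        rng,
                        burst_offset,
                    )
                )
                burst_offset += n_bursts_per
        meta_rows.append(
            {
                "fox_id": fox,
                "sex": sexes[fi],
                "reproductive": statuses[fi],
                "captures": ";".join(ts.isoformat() for ts in captures[fox]),
            }
        )

    all_d = np.concatenate(densities)
    d_mean = float(np.nanmean(all_d))
    d_sd = float(np.nanstd(all_d, ddof=1))
    if not np.isfinite(d_sd) or d_sd == 0:
        d_sd = 1.0

    g = config.glmm
    n_burst_total = 0
    for fi, yi, fox, year, start_ts, burst_times, b_pos, b_dens, b_labels, rng, burst_offset in pending:
        sd = config.season_dates[year]
        inc_start = pd.Timestamp(year=year, month=sd["incubation_start"][0], day=sd["incubation_start"][1], tz="UTC")
        brood_start = pd.Timestamp(year=year, month=sd["brooding_start"][0], day=sd["brooding_start"][1], tz="UTC")
        female = 1.0 if sexes[fi] == "F" else 0.0
        nonrep = 1.0 if statuses[fi] == "no" else 0.0
        for bi, t in enumerate(burst_times):
            ts = start_ts + pd.Timedelta(seconds=float(t))
            burst_id = f"{fox}-{year}-{burst_offset + bi + 1:05d}"
            z = (b_dens[bi] - d_mean) / d_sd if np.isfinite(b_dens[bi]) else 0.0
            brooding = 1.0 if ts >= brood_start else 0.0
            eta = (
                g.b0
                + g.b1 * z
                + g.b2 * brooding
                + g.b3 * z * brooding
                + g.b4 * female
                + g.b5 * nonrep
                + g.b6 * female * nonrep
                + u_fox[fi]
                + v_year[year_index[year]]
            )
            p = float(cloglog_probability(np.array(eta)))
            den_dist = float(
                np.sqrt(((den_xy - b_pos[bi]) ** 2).sum(axis=1)).min()
            )
            y = int(rng.random() < p)
            if (
                y == 1
                and not config.allow_den_adjacent_digging
                and den_dist < config.den_digging_buffer_m
            ):
                y = 0
            labels = b_labels[bi]
            if y == 1:
                n_dig = 1 + rng.binomial(wpb - 1, config.extra_dig_window_prob)
                which = rng.choice(wpb, size=n_dig, replace=False)
                labels[which] = DIGGING
            # render the burst signal window by window
            block = np.empty((3, wpb * spw))
            for w in range(wpb):
                block[:, w * spw : (w + 1) * spw] = _signal_array(
                    labels[w], spw, config.sampling_rate, config, rng
                )
                win_rows.append(
                    {
                        "fox_id": fox,
                        "burst_id": burst_id,
                        "window_index": w,
                        "label": labels[w],
                    }
                )
            sig_blocks.append(block)
            burst_rows.append(
                {
                    "fox_id": fox,
                    "burst_id": burst_id,
                    "year": year,
                    "start_time": ts,
                }
            )
            truth_rows.append(
                {
                    "burst_id": burst_id,
                    "fox_id": fox,
                    "year": year,
                    "digging": y,
                    "eta": eta,
                    "p": p,
                    "density": b_dens[bi],
                    "density_std": z,
                    "period": "brooding" if brooding else (
                        "incubation" if ts >= inc_start else "pre_season"
                    ),
                    "den_distance_m": den_dist,
                    "x_m": b_pos[bi, 0],
                    "y_m": b_pos[bi, 1],
                }
            )
            n_burst_total += 1

    re_rows = [
        {"level": "fox", "name": fox_ids[i], "value": u_fox[i]}
        for i in range(config.n_foxes)
    ] + [
        {"level": "year", "name": str(y), "value": v_year[year_index[y]]}
        for y in config.years
    ]

    return SimulatedSeason(
        config=config,
        bursts=pd.DataFrame(burst_rows),
        signals=np.stack(sig_blocks) if sig_blocks else np.empty((0, 3, wpb * spw)),
        gps=pd.DataFrame(gps_rows),
        metadata=pd.DataFrame(meta_rows),
        season_dates=season_dates_frame(config),
        raster=raster,
        dens=dens,
        truth_windows=pd.DataFrame(win_rows),
        truth_bursts=pd.DataFrame(truth_rows),
        random_effects=pd.DataFrame(re_rows),
        density_mean=d_mean,
        density_sd=d_sd,
    )


def simulate_covariate_table(
    config: SimConfig,
    seed: int,
    n_foxes: int = 16,
    n_fox_years: int = 23,
    bursts_per_fox_year: int = 2410,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analysis-table level simulation for mixed-model recovery studies.

    Skips signal synthesis entirely: draws per-burst covariates (raw
    goose density from a right-skewed patchy distribution, reproduction
    period, per-fox sex and status), standardizes density within the
    dataset, and draws the digging response from the cloglog model with
    the configured true coefficients and fox/year random intercepts.

    Returns ``(table, random_effects)``; the table carries the columns
    the mixed-model fitter expects (digging, density_std, period, sex,
    status, fox_id, year).
    """
    if n_fox_years > n_foxes * len(config.years):
        raise ValueError("more fox-years than fox x year combinations")
    rng = np.random.default_rng(seed)
    g = config.glmm
    fox_ids = [f"F{i + 1:02d}" for i in range(n_foxes)]
    sexes, statuses = _fox_covariates(n_foxes, rng)
    u_fox = rng.normal(0.0, g.sigma_fox, n_foxes)
    years = list(config.years)
    v_year = rng.normal(0.0, g.sigma_year, len(years))

    if n_fox_years < n_foxes:
        raise ValueError("every fox needs at least one tracked year")
    # every fox gets one year; remaining fox-years drawn without
    # replacement from the unused fox x year pairs
    base = [(f, int(rng.integers(len(years)))) for f in range(n_foxes)]
    remaining = [
        (f, y)
        for f in range(n_foxes)
        for y in range(len(years))
        if (f, y) not in set(base)
    ]
    extra_idx = rng.choice(len(remaining), size=n_fox_years - n_foxes, replace=False)
    chosen = base + [remaining[i] for i in extra_idx]

    rows = []
    for fi, yi in chosen:
        n = bursts_per_fox_year
        density = rng.gamma(shape=0.8, scale=6.0, size=n)
        brooding = (rng.random(n) < 0.45).astype(float)
        rows.append(
            pd.DataFrame(
                {
                    "fox_id": fox_ids[fi],
                    "year": years[yi],
                    "density": density,
                    "period": np.where(brooding == 1, "brooding", "incubation"),
                    "sex": sexes[fi],
                    "status": np.where(statuses[fi] == "yes", "reproductive", "nonreproductive"),
                    "_brooding": brooding,
                    "_female": 1.0 if sexes[fi] == "F" else 0.0,
                    "_nonrep": 1.0 if statuses[fi] == "no" else 0.0,
                    "_u": u_fox[fi],
                    "_v": v_year[yi],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    z = (df["density"] - df["density"].mean()) / df["density"].std(ddof=1)
    df["density_std"] = z
    eta = (
        g.b0
        + g.b1 * z
        + g.b2 * df["_brooding"]
        + g.b3 * z * df["_brooding"]
        + g.b4 * df["_female"]
        + g.b5 * df["_nonrep"]
        + g.b6 * df["_female"] * df["_nonrep"]
        + df["_u"]
        + df["_v"]
    ).to_numpy()
    p = cloglog_probability(eta)
    df["eta"] = eta
    df["p"] = p
    df["digging"] = (rng.random(len(df)) < p).astype(int)
    df = df.drop(columns=["_brooding", "_female", "_nonrep", "_u", "_v"])
    re = pd.DataFrame(
        [{"level": "fox", "name": fox_ids[i], "value": u_fox[i]} for i in range(n_foxes)]
        + [{"level": "year", "name": str(years[i]), "value": v_year[i]} for i in range(len(years))]
    )
    return df, re


def write_fixture_files(
    season: SimulatedSeason,
    directory: str | Path,
    annotation_offset_s: float = 0.0,
    annotated_bursts_per_fox_year: int = 2,
) -> dict[str, Path]:
    """Write the campaign to the plain-text formats the readers consume.

    The annotation log covers a random-but-deterministic subset of
    bursts; its clock is seconds since the annotation epoch minus
    ``annotation_offset_s``, i.e. accelerometry-clock seconds lead the
    annotation clock by exactly the configured offset.
    """
    from . import io as fio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "accelerometry": directory / "accelerometry.csv",
        "gps": directory / "gps.csv",
        "annotations": directory / "annotations.csv",
        "raster": directory / "goose_density.asc",
        "dens": directory / "dens.csv",
        "metadata": directory / "metadata.csv",
        "season": directory / "season.csv",
        "truth_windows": directory / "truth_windows.csv",
        "truth_bursts": directory / "truth_bursts.csv",
    }

    fio.write_accelerometry(season.bursts, season.signals, season.config.sampling_rate, paths["accelerometry"])
    fio.write_gps(season.gps, paths["gps"])
    season.raster.to_ascii(paths["raster"])
    season.dens.to_csv(paths["dens"], index=False)
    season.metadata.to_csv(paths["metadata"], index=False)
    season.season_dates.to_csv(paths["season"], index=False)
    season.truth_windows.to_csv(paths["truth_windows"], index=False)
    season.truth_bursts.to_csv(paths["truth_bursts"], index=False)

    # annotation events from ground truth for a subset of bursts
    rng = np.random.default_rng(np.random.SeedSequence([season.config.seed, 7]))
    events = []
    obs_counter = 0
    spw = season.config.window_s
    wpb = season.config.windows_per_burst
    tw = season.truth_windows.set_index(["burst_id", "window_index"])["label"]
    for (fox, year), grp in season.bursts.groupby(["fox_id", "year"], sort=True):
        k = min(annotated_bursts_per_fox_year, len(grp))
        pick = grp.iloc[rng.choice(len(grp), size=k, replace=False)]
        for _, brow in pick.iterrows():
            obs_counter += 1
            obs_id = f"OBS{obs_counter:03d}"
            t0 = (brow["start_time"] - ANNOTATION_EPOCH).total_seconds()
            labels = [tw.loc[(brow["burst_id"], w)] for w in range(wpb)]
            w = 0
            while w < wpb:
                w2 = w
                while w2 + 1 < wpb and labels[w2 + 1] == labels[w]:
                    w2 += 1
                raw = rng.choice(RAW_NAME_POOL[labels[w]])
                events.append(
                    {
                        "observation_id": obs_id,
                        "fox_id": fox,
                        "behavior_raw": raw,
                        "start_s": t0 + w * spw - annotation_offset_s,
                        "stop_s": t0 + (w2 + 1) * spw - annotation_offset_s,
                    }
                )
                w = w2 + 1
    pd.DataFrame(events).to_csv(paths["annotations"], index=False)
    return paths
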