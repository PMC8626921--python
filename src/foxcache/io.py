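"""Readers and writers for the plain-text interchange formats.

All tables are CSV with ISO-8601 UTC timestamps; the density surface is
an ESRI ASCII grid (see :mod:`foxcache.raster`). Accelerometry travels
in long form — one row per sample per axis — which is verbose but
unambiguous and diff-able.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import DensityRaster

log = logging.getLogger("foxcache")

AXIS_ORDER = ("sway", "surge", "heave")

_SCHEMAS = {
    "accelerometry": ["fox_id", "burst_id", "timestamp_utc_start", "axis", "sample_index", "value_g"],
    "gps": ["fox_id", "timestamp_utc", "x_m", "y_m"],
    "annotations": ["observation_id", "fox_id", "behavior_raw", "start_s", "stop_s"],
    "dens": ["den_id", "x_m", "y_m"],
    "metadata": ["fox_id", "sex", "reproductive", "captures"],
    "season": ["year", "incubation_start", "brooding_start", "brooding_end"],
}


def _check_schema(df: pd.DataFrame, kind: str, path) -> None:
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: {kind} file is missing columns {missing}")


def write_accelerometry(
    bursts: pd.DataFrame, signals: np.ndarray, rate: float, path: str | Path
) -> None:
    """Long-form accelerometry CSV (one row per axis sample)."""
    n_bursts, n_axes, n_samples = signals.shape
    if len(bursts) != n_bursts:
        raise ValueError("bursts table and signal array disagree in length")
    idx = np.arange(n_samples)
    frames = []
    for axis_i, axis in enumerate(AXIS_ORDER):
        frames.append(
            pd.DataFrame(
                {
                    "fox_id": np.repeat(bursts["fox_id"].to_numpy(), n_samples),
                    "burst_id": np.repeat(bursts["burst_id"].to_numpy(), n_samples),
                    "timestamp_utc_start": np.repeat(
                        bursts["start_time"].dt.strftime("%Y-%m-%dT%H:%M:%S%z").to_numpy(),
                        n_samples,
                    ),
                    "axis": axis,
                    "sample_index": np.tile(idx, n_bursts),
                    "value_g": signals[:, axis_i, :].reshape(-1),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.sort_values(["burst_id", "axis", "sample_index"], inplace=True, kind="stable")
    out.to_csv(path, index=False, float_format="%.6g")


def read_accelerometry(
    path: str | Path, expected_samples: int | None = None, rate: float = 50.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Read long-form accelerometry into a burst table plus a
    ``(n_bursts, 3, n_samples)`` array.

    Bursts whose per-axis sample counts disagree (or differ from
    ``expected_samples``) are rejected with a logged id; the remainder
    load normally.
    """
    df = pd.read_csv(path)
    _check_schema(df, "accelerometry", path)
    df["timestamp_utc_start"] = pd.to_datetime(df["timestamp_utc_start"], utc=True)
    rows, blocks = [], []
    for burst_id, grp in df.groupby("burst_id", sort=True):
        counts = grp.groupby("axis")["value_g"].count()
        if set(counts.index) != set(AXIS_ORDER) or counts.nunique() != 1:
            log.warning("burst %s rejected: incomplete axes %s", burst_id, dict(counts))
            continue
        n = int(counts.iloc[0])
        if expected_samples is not None and n != expected_samples:
            log.warning("burst %s rejected: %d samples, expected %d", burst_id, n, expected_samples)
            continue
        block = np.empty((3, n))
        for i, axis in enumerate(AXIS_ORDER):
            sub = grp[grp["axis"] == axis].sort_values("sample_index")
            block[i] = sub["value_g"].to_numpy()
        blocks.append(block)
        rows.append(
            {
                "fox_id": grp["fox_id"].iloc[0],
                "burst_id": burst_id,
                "start_time": grp["timestamp_utc_start"].iloc[0],
            }
        )
    bursts = pd.DataFrame(rows)
    if len(bursts):
        bursts["year"] = bursts["start_time"].dt.year
        perm = bursts.sort_values(["fox_id", "start_time"]).index.to_numpy()
        bursts = bursts.loc[perm].reset_index(drop=True)
        signals = np.stack([blocks[i] for i in perm])
    else:
        signals = np.empty((0, 3, expected_samples or 0))
    return bursts, signals


def write_gps(gps: pd.DataFrame, path: str | Path) -> None:
    out = gps.copy()
    out["timestamp_utc"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S%z"
    )
    out[["fox_id", "timestamp_utc", "x_m", "y_m"]].to_csv(path, index=False, float_format="%.3f")


def read_gps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, "gps", path)
    df["timestamp"] = pd.to_datetime(df["timestamp_utc"], utc=True)
    df = df.sort_values(["fox_id", "timestamp"], ignore_index=True)
    dup = df.groupby("fox_id")["timestamp"].apply(lambda s: s.duplicated().any())
    if dup.any():
        raise ValueError(f"{path}: non-increasing timestamps for foxes {list(dup[dup].index)}")
    return df[["fox_id", "timestamp", "x_m", "y_m"]]


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, "annotations", path)
    bad = df.index[df["stop_s"] <= df["start_s"]]
    if len(bad):
        raise ValueError(f"{path}: stop_s <= start_s on lines {[i + 2 for i in bad]}")
    return df


def read_dens(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, "dens", path)
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Fox metadata; the ``captures`` column holds ';'-joined ISO
    timestamps of capture events."""
    df = pd.read_csv(path)
    _check_schema(df, "metadata", path)
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"{path}: invalid sex values {sorted(bad_sex)}")
    bad_rep = set(df["reproductive"]) - {"yes", "no"}
    if bad_rep:
        raise ValueError(f"{path}: invalid reproductive values {sorted(bad_rep)}")
    return df


def capture_times(metadata: pd.DataFrame) -> dict[str, list[pd.Timestamp]]:
    out: dict[str, list[pd.Timestamp]] = {}
    for _, row in metadata.iterrows():
        raw = row.get("captures", "")
        if pd.isna(raw) or not str(raw):
            out[row["fox_id"]] = []
        else:
            out[row["fox_id"]] = [pd.Timestamp(s) for s in str(raw).split(";")]
    return out


def parse_season(df: pd.DataFrame) -> pd.DataFrame:
    """Convert ISO date strings of a season table to UTC timestamps."""
    out = df.copy()
    for col in ("incubation_start", "brooding_start", "brooding_end"):
        out[col] = pd.to_datetime(out[col]).dt.tz_localize("UTC")
    return out


def read_season(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, "season", path)
    return parse_season(df)


def read_raster(path: str | Path) -> DensityRaster:
    return DensityRaster.from_ascii(path)


def read_truth_windows(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_truth_bursts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df
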