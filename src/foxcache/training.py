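"""Training-set preparation: from annotation event logs to labelled
3-s windows.

Behavioural observations arrive as BORIS-style event logs (start/stop
seconds on the observer's clock). They are shifted onto the
accelerometry clock by a single numeric offset, mapped from raw
ethogram names onto the four analysis categories, and intersected with
the bursts' 3-s window grid. Only windows wholly covered by a single
mapped event are kept, so every training window contains one
uninterrupted behaviour; windows touching an event mapped to
"excluded" are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .behaviors import CATEGORIES
from .synthetic import ANNOTATION_EPOCH

EXCLUDED = "excluded"

#: default raw-name mapping; anything absent is excluded, never guessed
DEFAULT_ETHOGRAM_MAPPING: dict[str, str] = {
    "running": "running",
    "walking": "walking",
    "digging": "digging",
    "egg caching": "digging",
    "egg recovering": "digging",
    "eating from cache": "digging",
    "motionless": "motionless",
    "standing": "motionless",
    "sitting": "motionless",
    "lying down": "motionless",
}


@dataclass
class LabeledSequence:
    """One 3-s training window: signal slice plus its behaviour label."""

    burst_id: str
    fox_id: str
    window_index: int
    window_start_s: float  # seconds from burst start
    label: str
    signal: np.ndarray  # (3, samples_per_window)


def synchronize_annotations(events: pd.DataFrame, offset_s: float) -> pd.DataFrame:
    """Shift event times onto the accelerometry clock.

    ``offset_s`` is the signed amount by which the accelerometry clock
    leads the annotation clock; both ``start_s`` and ``stop_s`` are
    shifted by it, preserving order and durations.
    """
    if not np.isfinite(offset_s):
        raise ValueError("clock offset must be finite")
    out = events.copy()
    out["start_s"] = out["start_s"] + offset_s
    out["stop_s"] = out["stop_s"] + offset_s
    return out


def map_ethogram(
    raw_name: str, mapping: dict[str, str] | None = None
) -> str:
    """Map one raw ethogram name to a category or ``"excluded"``.

    Matching is case-insensitive with underscores treated as spaces.
    Unmapped names are excluded, never guessed.
    """
    if mapping is None:
        mapping = DEFAULT_ETHOGRAM_MAPPING
    if not mapping:
        raise ValueError("ethogram mapping is empty")
    key = str(raw_name).strip().lower().replace("_", " ")
    label = mapping.get(key, EXCLUDED)
    if label not in CATEGORIES and label != EXCLUDED:
        raise ValueError(f"mapping sends {raw_name!r} to unknown label {label!r}")
    return label


def load_ethogram_mapping(path: str | Path) -> dict[str, str]:
    """Two-column CSV raw_name,label -> mapping dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: mapping file needs raw_name,label columns")
    raw_col, label_col = df.columns[:2]
    mapping = {
        str(r).strip().lower().replace("_", " "): str(l).strip().lower()
        for r, l in zip(df[raw_col], df[label_col])
    }
    bad = {l for l in mapping.values() if l not in CATEGORIES and l != EXCLUDED}
    if bad:
        raise ValueError(f"{path}: unknown target labels {sorted(bad)}")
    return mapping


def extract_training_sequences(
    bursts: pd.DataFrame,
    signals: np.ndarray,
    events: pd.DataFrame,
    window_s: float = 3.0,
    rate: float = 50.0,
    mapping: dict[str, str] | None = None,
) -> list[LabeledSequence]:
    """Intersect synchronized events with the bursts' 3-s window grid.

    Windows are left-anchored to each burst's grid (0-3, 3-6, ... s from
    burst start). A window is labelled iff it is wholly covered by one
    event whose name maps to a category, and no event mapped to
    "excluded" overlaps it. Event times are accelerometry-clock seconds
    since the annotation epoch.
    """
    n_burst_samples = signals.shape[2] if len(signals) else 0
    spw = round(window_s * rate)
    if n_burst_samples and n_burst_samples % spw != 0:
        raise ValueError(
            f"window of {window_s} s does not divide the burst "
            f"({n_burst_samples} samples at {rate} Hz)"
        )
    ev = events.copy()
    ev["label"] = [map_ethogram(r, mapping) for r in ev["behavior_raw"]]
    out: list[LabeledSequence] = []
    for i, brow in bursts.reset_index(drop=True).iterrows():
        b0 = (brow["start_time"] - ANNOTATION_EPOCH).total_seconds()
        dur = n_burst_samples / rate
        fox_ev = ev[(ev["fox_id"] == brow["fox_id"]) & (ev["stop_s"] > b0) & (ev["start_s"] < b0 + dur)]
        if fox_ev.empty:
            continue
        n_windows = int(n_burst_samples // spw)
        for w in range(n_windows):
            w0, w1 = b0 + w * window_s, b0 + (w + 1) * window_s
            overlapping = fox_ev[(fox_ev["stop_s"] > w0) & (fox_ev["start_s"] < w1)]
            if (overlapping["label"] == EXCLUDED).any():
                continue
            covering = overlapping[
                (overlapping["start_s"] <= w0 + 1e-9) & (overlapping["stop_s"] >= w1 - 1e-9)
            ]
            if len(covering) != 1:
                continue
            out.append(
                LabeledSequence(
                    burst_id=brow["burst_id"],
                    fox_id=brow["fox_id"],
                    window_index=w,
                    window_start_s=w * window_s,
                    label=covering["label"].iloc[0],
                    signal=signals[i, :, w * spw : (w + 1) * spw],
                )
            )
    return out


def sequences_to_arrays(
    sequences: list[LabeledSequence],
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack sequences into ``(signals, labels, manifest)``."""
    if not sequences:
        raise ValueError("no training sequences extracted")
    signals = np.stack([s.signal for s in sequences])
    labels = np.asarray([s.label for s in sequences], dtype=object)
    manifest = pd.DataFrame(
        {
            "sequence_id": [f"{s.burst_id}:w{s.window_index}" for s in sequences],
            "burst_id": [s.burst_id for s in sequences],
            "fox_id": [s.fox_id for s in sequences],
            "window_index": [s.window_index for s in sequences],
            "label": labels,
        }
    )
    return signals, labels, manifest
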