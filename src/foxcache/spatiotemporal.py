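"""Burst-GPS fusion, covariate annotation and the exclusion cascade.

Each 30-s burst is associated to the closest GPS fix of the same fox,
provided the fix falls within 30 s of the burst interval (start to
end); unmatched bursts drop out of the analysis. Matched bursts are
annotated with local goose density (raster cell containing the fix),
goose reproduction period from year-specific phenology dates, distance
to the nearest den, and fox covariates. A fixed exclusion cascade then
removes records collected within two days of a capture, off the density
map, before the goose nesting period, or within 50 m of a den (digging
there may reflect den maintenance rather than foraging). The digging
response of a burst is 1 iff at least one of its 10 windows is
classified as digging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behaviors import DIGGING
from .raster import DensityRaster

log = logging.getLogger("foxcache")

FILTER_RULES = ("capture", "off_map", "pre_season", "near_den")


def digging_indicator(window_labels) -> int:
    """1 iff >= 1 of the burst's window labels is digging."""
    labels = list(window_labels)
    if len(labels) != 10:
        raise ValueError(f"expected 10 window labels per burst, got {len(labels)}")
    return int(any(l == DIGGING for l in labels))


def match_gps(
    bursts: pd.DataFrame,
    fixes: pd.DataFrame,
    max_gap_s: float = 30.0,
    burst_duration_s: float = 30.0,
) -> pd.DataFrame:
    """Assign each burst the closest same-fox GPS fix within
    ``max_gap_s`` of the burst interval.

    The gap of a fix is its distance in time to the interval
    [start, start + burst_duration] (zero if inside). Among eligible
    fixes the one with the smallest gap wins; on an exact tie the
    earlier fix is taken. Returns the burst table with ``x_m``, ``y_m``,
    ``fix_time`` and ``gap_s`` columns; unmatched bursts carry NaN and
    the matched count/fraction is logged.
    """
    out = bursts.copy().reset_index(drop=True)
    out["x_m"] = np.nan
    out["y_m"] = np.nan
    out["fix_time"] = pd.Series(pd.NaT, index=out.index, dtype="datetime64[ns, UTC]")
    out["gap_s"] = np.nan
    def _naive_utc(col):
        return pd.to_datetime(col, utc=True).dt.tz_localize(None).to_numpy()

    for fox, grp in out.groupby("fox_id"):
        fx = fixes[fixes["fox_id"] == fox].sort_values("timestamp")
        if fx.empty:
            continue
        ft = _naive_utc(fx["timestamp"])
        starts = _naive_utc(grp["start_time"])
        ends = starts + np.timedelta64(round(burst_duration_s * 1000), "ms")
        # gap to the interval, in seconds, for every fix x burst pair is
        # avoided: only fixes adjacent to the interval can be closest
        for i, (s, e) in zip(grp.index, zip(starts, ends)):
            lo = np.searchsorted(ft, s)
            hi = np.searchsorted(ft, e, side="right")
            candidates = []
            if hi > lo:  # fix inside the interval
                candidates.append((0.0, lo))
            if lo > 0:
                gap = (s - ft[lo - 1]) / np.timedelta64(1, "s")
                candidates.append((float(gap), lo - 1))
            if hi < len(ft):
                gap = (ft[hi] - e) / np.timedelta64(1, "s")
                candidates.append((float(gap), hi))
            if not candidates:
                continue
            gap, j = min(candidates, key=lambda c: (c[0], fx["timestamp"].iloc[c[1]]))
            if gap <= max_gap_s:
                out.loc[i, "x_m"] = fx["x_m"].iloc[j]
                out.loc[i, "y_m"] = fx["y_m"].iloc[j]
                out.loc[i, "fix_time"] = fx["timestamp"].iloc[j]
                out.loc[i, "gap_s"] = gap
    matched = out["x_m"].notna()
    log.info(
        "gps matching: %d of %d bursts matched (%.1f%%)",
        matched.sum(),
        len(out),
        100.0 * matched.mean() if len(out) else 0.0,
    )
    return out


def annotate_covariates(
    matched: pd.DataFrame,
    raster: DensityRaster,
    dens: pd.DataFrame,
    season: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Attach goose density, reproduction period, den distance and fox
    covariates to matched bursts.

    Density is the value of the raster cell containing the fix (NaN ->
    flagged off-map, consumed later by the filter cascade). The period
    is incubation for incubation_start <= t < brooding_start, brooding
    for brooding_start <= t <= brooding_end, pre_season before and
    post_season after. Den distance is the minimum Euclidean distance
    over all dens.
    """
    out = matched.copy()
    if "year" not in out.columns:
        out["year"] = pd.to_datetime(out["start_time"]).dt.year
    missing_years = set(out["year"].unique()) - set(season["year"].unique())
    if missing_years:
        raise ValueError(f"season table lacks years {sorted(missing_years)}")

    has_fix = out["x_m"].notna()
    density = np.full(len(out), np.nan)
    density[has_fix.to_numpy()] = raster.value_at(
        out.loc[has_fix, "x_m"].to_numpy(), out.loc[has_fix, "y_m"].to_numpy()
    )
    out["density"] = density
    out["off_map"] = has_fix & ~np.isfinite(density)

    den_xy = dens[["x_m", "y_m"]].to_numpy()
    dist = np.full(len(out), np.nan)
    if len(den_xy):
        pts = out.loc[has_fix, ["x_m", "y_m"]].to_numpy()
        d = np.sqrt(((pts[:, None, :] - den_xy[None, :, :]) ** 2).sum(axis=2))
        dist[has_fix.to_numpy()] = d.min(axis=1)
    out["den_distance_m"] = dist

    period = np.full(len(out), "", dtype=object)
    for _, srow in season.iterrows():
        sel = out["year"] == srow["year"]
        t = out.loc[sel, "start_time"]
        p = np.where(
            t < srow["incubation_start"],
            "pre_season",
            np.where(
                t < srow["brooding_start"],
                "incubation",
                # the end date is inclusive as a calendar day
                np.where(
                    t < srow["brooding_end"] + pd.Timedelta(days=1),
                    "brooding",
                    "post_season",
                ),
            ),
        )
        period[sel.to_numpy()] = p
    out["period"] = period

    meta = metadata.set_index("fox_id")
    out["sex"] = out["fox_id"].map(meta["sex"])
    out["status"] = out["fox_id"].map(
        meta["reproductive"].map({"yes": "reproductive", "no": "nonreproductive"})
    )
    return out


@dataclass
class FilterReport:
    retained: pd.DataFrame
    counts: dict[str, int]
    n_input: int

    @property
    def total_excluded(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "excluded": self.counts[r]} for r in FILTER_RULES]
        rows.append({"rule": "total_excluded", "excluded": self.total_excluded})
        rows.append({"rule": "retained", "excluded": len(self.retained)})
        return pd.DataFrame(rows)


def exclusion_total(rule_counts) -> int:
    """Total excluded across per-rule counts (the report's arithmetic
    identity: retained + total excluded = analysed input)."""
    return int(sum(rule_counts))


def apply_filters(
    records: pd.DataFrame,
    capture_times: dict[str, list[pd.Timestamp]] | None,
    den_buffer_m: float = 50.0,
    capture_exclusion_h: float = 48.0,
    rule_order: tuple[str, ...] = FILTER_RULES,
) -> FilterReport:
    """Exclusion cascade over annotated, matched records.

    Rules, applied in order with each exclusion attributed to the first
    matching rule: (capture) within ``capture_exclusion_h`` hours after
    any capture of that fox; (off_map) fix outside the density raster
    or on a NODATA cell; (pre_season) before that year's incubation
    start; (near_den) strictly closer than ``den_buffer_m`` to a den.
    The retained set is invariant to rule order; only the attribution
    of counts depends on it.
    """
    df = records.reset_index(drop=True)
    masks: dict[str, np.ndarray] = {}

    if capture_times is None:
        log.warning("capture dates missing: capture-proximity rule skipped")
        masks["capture"] = np.zeros(len(df), dtype=bool)
    else:
        m = np.zeros(len(df), dtype=bool)
        delta = pd.Timedelta(hours=capture_exclusion_h)
        for fox, times in capture_times.items():
            sel = (df["fox_id"] == fox).to_numpy()
            for t in times:
                after = (df["start_time"] >= t) & (df["start_time"] < t + delta)
                m |= sel & after.to_numpy()
        masks["capture"] = m

    masks["off_map"] = (~np.isfinite(df["density"].to_numpy(dtype=float)))
    masks["pre_season"] = (df["period"] == "pre_season").to_numpy()
    masks["near_den"] = (df["den_distance_m"].to_numpy(dtype=float) < den_buffer_m)

    if set(rule_order) != set(FILTER_RULES):
        raise ValueError(f"rule_order must permute {FILTER_RULES}")
    attributed = np.zeros(len(df), dtype=bool)
    counts: dict[str, int] = {}
    for rule in rule_order:
        hit = masks[rule] & ~attributed
        counts[rule] = int(hit.sum())
        attributed |= masks[rule]
    retained = df[~attributed].reset_index(drop=True)
    log.info(
        "filters: input %d, excluded %s (total %d), retained %d",
        len(df),
        counts,
        sum(counts.values()),
        len(retained),
    )
    return FilterReport(retained=retained, counts=counts, n_input=len(df))


def build_analysis_table(
    window_labels: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-burst digging indicators onto the covariate records.

    ``window_labels`` must carry burst_id/label with 10 windows per
    burst; the result adds a 0/1 ``digging`` column.
    """
    indicator = (
        window_labels.groupby("burst_id")["label"]
        .apply(lambda s: digging_indicator(list(s)))
        .rename("digging")
    )
    out = covariates.merge(indicator, on="burst_id", how="inner", validate="1:1")
    return out
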