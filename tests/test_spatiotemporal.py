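"""GPS matching, covariate annotation, the exclusion cascade and the
digging indicator."""

import numpy as np
import pandas as pd
import pytest

from foxcache.raster import DensityRaster
from foxcache.spatiotemporal import (
    FILTER_RULES,
    annotate_covariates,
    apply_filters,
    digging_indicator,
    exclusion_total,
    match_gps,
)

T0 = pd.Timestamp("2019-06-20T12:00:00Z")


def _bursts(offsets_s, fox="F01"):
    return pd.DataFrame(
        {
            "fox_id": fox,
            "burst_id": [f"b{i}" for i in range(len(offsets_s))],
            "start_time": [T0 + pd.Timedelta(seconds=s) for s in offsets_s],
        }
    )


def _fixes(offsets_s, fox="F01", x=100.0, y=200.0):
    n = len(offsets_s)
    return pd.DataFrame(
        {
            "fox_id": fox,
            "timestamp": [T0 + pd.Timedelta(seconds=s) for s in offsets_s],
            "x_m": np.full(n, x) + np.arange(n),
            "y_m": np.full(n, y),
        }
    )


class TestDiggingIndicator:
    def test_no_digging(self):
        assert digging_indicator(["motionless"] * 10) == 0

    def test_single_digging_window_suffices(self):
        assert digging_indicator(["digging"] + ["running"] * 9) == 1

    def test_all_digging(self):
        assert digging_indicator(["digging"] * 10) == 1

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            digging_indicator(["digging"] * 9)


class TestMatchGps:
    def test_fix_at_burst_start_matches_with_zero_gap(self):
        out = match_gps(_bursts([0.0]), _fixes([0.0]))
        assert out.loc[0, "gap_s"] == 0.0

    def test_fix_31s_after_burst_end_is_unmatched(self):
        out = match_gps(_bursts([0.0]), _fixes([61.0]))
        assert np.isnan(out.loc[0, "x_m"])
        # exactly at the 30-s boundary it matches
        out = match_gps(_bursts([0.0]), _fixes([60.0]))
        assert out.loc[0, "gap_s"] == 30.0

    def test_tie_prefers_earlier_fix(self):
        out = match_gps(_bursts([20.0]), _fixes([10.0, 60.0]))
        assert out.loc[0, "fix_time"] == T0 + pd.Timedelta(seconds=10)

    def test_fix_inside_interval_beats_nearby_outside_fix(self):
        out = match_gps(_bursts([0.0]), _fixes([-2.0, 15.0]))
        assert out.loc[0, "gap_s"] == 0.0
        assert out.loc[0, "fix_time"] == T0 + pd.Timedelta(seconds=15)

    def test_no_cross_fox_matching(self):
        out = match_gps(_bursts([0.0], fox="F01"), _fixes([0.0], fox="F02"))
        assert np.isnan(out.loc[0, "x_m"])

    def test_empty_fix_stream_leaves_all_unmatched(self):
        out = match_gps(_bursts([0.0, 300.0]), _fixes([]))
        assert out["x_m"].isna().all()


@pytest.fixture
def flat_raster():
    return DensityRaster(np.full((10, 10), 7.0), 0.0, 0.0, 100.0)


@pytest.fixture
def season_table():
    return pd.DataFrame(
        {
            "year": [2018, 2019],
            "incubation_start": [pd.Timestamp("2018-06-19", tz="UTC"), pd.Timestamp("2019-06-12", tz="UTC")],
            "brooding_start": [pd.Timestamp("2018-07-12", tz="UTC"), pd.Timestamp("2019-07-05", tz="UTC")],
            "brooding_end": [pd.Timestamp("2018-08-03", tz="UTC"), pd.Timestamp("2019-07-27", tz="UTC")],
        }
    )


@pytest.fixture
def metadata():
    return pd.DataFrame(
        {
            "fox_id": ["F01"],
            "sex": ["F"],
            "reproductive": ["yes"],
            "captures": ["2019-06-01T00:00:00+00:00"],
        }
    )


class TestCovariates:
    def test_fix_at_den_coordinates_has_zero_distance(
        self, flat_raster, season_table, metadata
    ):
        matched = _bursts([0.0])
        matched["x_m"], matched["y_m"] = 100.0, 200.0
        dens = pd.DataFrame({"den_id": ["D1"], "x_m": [100.0], "y_m": [200.0]})
        out = annotate_covariates(matched, flat_raster, dens, season_table, metadata)
        assert out.loc[0, "den_distance_m"] == 0.0
        assert out.loc[0, "density"] == 7.0
        assert out.loc[0, "sex"] == "F"
        assert out.loc[0, "status"] == "reproductive"

    @pytest.mark.parametrize(
        "when,expected",
        [
            ("2019-06-12T00:00:00Z", "incubation"),  # incubation start day
            ("2019-06-11T23:59:00Z", "pre_season"),
            ("2019-07-05T06:00:00Z", "brooding"),
            ("2019-07-27T23:00:00Z", "brooding"),  # inclusive end
            ("2019-07-28T12:00:00Z", "post_season"),
        ],
    )
    def test_period_boundaries(self, flat_raster, season_table, metadata, when, expected):
        matched = pd.DataFrame(
            {
                "fox_id": ["F01"],
                "burst_id": ["b0"],
                "start_time": [pd.Timestamp(when)],
                "x_m": [500.0],
                "y_m": [500.0],
            }
        )
        dens = pd.DataFrame({"den_id": [], "x_m": [], "y_m": []})
        out = annotate_covariates(matched, flat_raster, dens, season_table, metadata)
        assert out.loc[0, "period"] == expected

    def test_off_map_fix_flagged_not_errored(self, flat_raster, season_table, metadata):
        matched = _bursts([0.0])
        matched["x_m"], matched["y_m"] = -50.0, 200.0
        dens = pd.DataFrame({"den_id": ["D1"], "x_m": [0.0], "y_m": [0.0]})
        out = annotate_covariates(matched, flat_raster, dens, season_table, metadata)
        assert bool(out.loc[0, "off_map"])
        assert np.isnan(out.loc[0, "density"])

    def test_missing_year_rejected(self, flat_raster, metadata, season_table):
        matched = _bursts([0.0])
        matched["x_m"], matched["y_m"] = 1.0, 1.0
        matched["start_time"] = pd.Timestamp("2021-06-20T00:00:00Z")
        dens = pd.DataFrame({"den_id": [], "x_m": [], "y_m": []})
        with pytest.raises(ValueError, match="years"):
            annotate_covariates(matched, flat_raster, dens, season_table, metadata)

    def test_density_round_trips_from_generator(self, small_season):
        vals = small_season.raster.value_at(
            small_season.truth_bursts["x_m"].to_numpy(),
            small_season.truth_bursts["y_m"].to_numpy(),
        )
        np.testing.assert_allclose(vals, small_season.truth_bursts["density"])


def _toy_records():
    """10 records: 2 off-map, 1 pre-season, 3 near-den, 4 clean."""
    df = pd.DataFrame(
        {
            "fox_id": ["F01"] * 10,
            "burst_id": [f"b{i}" for i in range(10)],
            "start_time": [T0] * 10,
            "density": [np.nan, np.nan] + [5.0] * 8,
            "period": ["incubation"] * 2 + ["pre_season"] + ["incubation"] * 7,
            "den_distance_m": [500.0] * 3 + [10.0, 49.9, 0.0] + [500.0] * 4,
        }
    )
    return df


class TestFilters:
    def test_toy_counts_match_hand_enumeration(self):
        report = apply_filters(_toy_records(), {"F01": []})
        assert report.counts == {
            "capture": 0,
            "off_map": 2,
            "pre_season": 1,
            "near_den": 3,
        }
        assert len(report.retained) == 4
        assert report.n_input == len(report.retained) + report.total_excluded

    def test_den_buffer_is_strict(self):
        df = _toy_records().iloc[[4]].copy()  # 49.9 m
        assert len(apply_filters(df, {"F01": []}).retained) == 0
        df["den_distance_m"] = 50.0
        assert len(apply_filters(df, {"F01": []}).retained) == 1

    def test_capture_rule_excludes_48h_window(self):
        df = _toy_records().iloc[6:].copy()
        captures = {"F01": [T0 - pd.Timedelta(hours=47)]}
        report = apply_filters(df, captures)
        assert report.counts["capture"] == len(df)
        captures = {"F01": [T0 - pd.Timedelta(hours=49)]}
        assert apply_filters(df, captures).counts["capture"] == 0

    def test_missing_capture_dates_skips_rule_with_warning(self, caplog):
        report = apply_filters(_toy_records(), None)
        assert report.counts["capture"] == 0
        assert any("skipped" in r.message for r in caplog.records)

    def test_rule_permutation_changes_attribution_not_retained_set(self):
        df = _toy_records()
        # make one record violate two rules at once
        df.loc[2, "den_distance_m"] = 5.0
        base = apply_filters(df, {"F01": []})
        permuted = apply_filters(
            df, {"F01": []}, rule_order=("near_den", "pre_season", "off_map", "capture")
        )
        assert list(base.retained["burst_id"]) == list(permuted.retained["burst_id"])
        assert base.total_excluded == permuted.total_excluded
        assert base.counts != permuted.counts

    def test_reported_exclusion_totals_add_up(self):
        assert exclusion_total([5563, 2359, 3119]) == 11041


def test_partition_identity_on_simulated_campaign(small_season, season_table):
    """retained + per-rule exclusions + unmatched = all bursts."""
    from foxcache import io as fio

    matched = match_gps(small_season.bursts, small_season.gps)
    n_unmatched = int(matched["x_m"].isna().sum())
    have_fix = matched[matched["x_m"].notna()].reset_index(drop=True)
    cov = annotate_covariates(
        have_fix,
        small_season.raster,
        small_season.dens,
        fio.parse_season(small_season.season_dates),
        small_season.metadata,
    )
    report = apply_filters(cov, fio.capture_times(small_season.metadata))
    assert len(report.retained) + report.total_excluded + n_unmatched == len(
        small_season.bursts
    )
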