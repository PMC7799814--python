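"""Filtering, site-level binning and SPD summation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleodem import (
    AnalysisConfig,
    bin_dates,
    filter_dates,
    make_spd,
    region_summary,
    subset_spd,
    sum_spd,
)
from paleodem.errors import EmptySubsetError, SchemaError


def _dates(rows):
    return pd.DataFrame(rows)


class TestFilterDates:
    def test_large_error_excluded(self, config):
        df = _dates(
            {
                "lab_id": list("abcde"),
                "site_id": ["S"] * 5,
                "cra": [4000, 4100, 4200, 4300, 4400],
                "error": [30, 40, 350, 50, 60],
            }
        )
        assert len(filter_dates(df, config)) == 4

    def test_cra_outside_collection_window_excluded(self, config):
        df = _dates({"lab_id": ["a"], "site_id": ["S"], "cra": [7000], "error": [30]})
        assert filter_dates(df, config).empty

    def test_mixed_violations_logged(self, toy_dates, config):
        kept, log = filter_dates(toy_dates, config, return_log=True)
        assert len(kept) == 7
        assert len(log) == 3
        reasons = set(log["reason"])
        assert any("error" in r for r in reasons)
        assert any("window" in r for r in reasons)
        assert "marine reservoir" in reasons

    def test_non_anthropogenic_samples_excluded(self, config):
        df = _dates(
            {
                "lab_id": ["a", "b"],
                "site_id": ["S", "S"],
                "cra": [4000, 4100],
                "error": [30, 30],
                "anthropogenic": [True, False],
            }
        )
        kept, log = filter_dates(df, config, return_log=True)
        assert list(kept["lab_id"]) == ["a"]
        assert list(log["reason"]) == ["non-anthropogenic"]

    def test_missing_columns_raise(self, config):
        with pytest.raises(SchemaError):
            filter_dates(pd.DataFrame({"cra": [4000]}), config)


class TestBinDates:
    def test_complete_linkage_hand_example(self, synth_curve, config):
        # {4500, 4520} merge at d=20; the pair is 100 > 50 from 4600
        df = _dates(
            {"lab_id": list("abc"), "site_id": ["S"] * 3, "cra": [4500, 4520, 4600], "error": [30] * 3}
        )
        bins = bin_dates(df, synth_curve, config)
        members = sorted(sorted(b.member_ids) for b in bins)
        assert members == [["a", "b"], ["c"]]

    def test_chain_splits_at_complete_linkage_distance(self, synth_curve, config):
        # {4000, 4040} merge at 40; adding 4080 would give diameter 80 > 50
        df = _dates(
            {"lab_id": list("abc"), "site_id": ["S"] * 3, "cra": [4000, 4040, 4080], "error": [30] * 3}
        )
        bins = bin_dates(df, synth_curve, config)
        members = sorted(sorted(b.member_ids) for b in bins)
        assert members == [["a", "b"], ["c"]]

    def test_sites_never_share_bins(self, synth_curve, config):
        df = _dates(
            {"lab_id": list("ab"), "site_id": ["S1", "S2"], "cra": [4000, 4000], "error": [30, 30]}
        )
        assert len(bin_dates(df, synth_curve, config)) == 2

    def test_single_date_forms_single_bin(self, synth_curve, config):
        df = _dates({"lab_id": ["a"], "site_id": ["S"], "cra": [4000], "error": [30]})
        bins = bin_dates(df, synth_curve, config)
        assert len(bins) == 1 and bins[0].member_ids == ["a"]

    def test_rebinning_bin_members_is_idempotent(self, small_study, synth_curve, config):
        bins = bin_dates(small_study.dates, synth_curve, config)
        for b in bins[:25]:
            sub = small_study.dates[small_study.dates["lab_id"].isin(b.member_ids)]
            assert len(bin_dates(sub, synth_curve, config)) == 1


class TestSumSpd:
    def test_single_normalized_bin_reproduces_density(self, synth_curve, config):
        df = _dates({"lab_id": ["a"], "site_id": ["S"], "cra": [4000], "error": [30]})
        bins = bin_dates(df, synth_curve, config, normalize=True)
        spd = sum_spd(bins, config)
        d = bins[0].density
        lookup = dict(zip(d.grid, d.density))
        np.testing.assert_allclose(
            spd.value, [lookup.get(g, 0.0) for g in config.grid], atol=1e-12
        )

    def test_mass_equals_bin_count_for_interior_dates(self, synth_curve, config, rng):
        n = 12
        df = _dates(
            {
                "lab_id": [f"L{i}" for i in range(n)],
                "site_id": [f"S{i}" for i in range(n)],
                "cra": rng.uniform(3500, 4800, n).round(),
                "error": rng.uniform(20, 60, n).round(),
            }
        )
        bins = bin_dates(df, synth_curve, config, normalize=True)
        spd = sum_spd(bins, config)
        assert spd.mass == pytest.approx(len(bins), rel=1e-3)
        assert spd.meta["n_bins"] == len(bins) == n

    def test_mean_then_sum_algebra(self, synth_curve, config):
        # two dates in one bin contribute half of the same dates in two bins
        one = _dates(
            {"lab_id": ["a", "b"], "site_id": ["S", "S"], "cra": [4000, 4030], "error": [30, 30]}
        )
        two = one.assign(site_id=["S1", "S2"])
        spd_one = sum_spd(bin_dates(one, synth_curve, config), config)
        spd_two = sum_spd(bin_dates(two, synth_curve, config), config)
        np.testing.assert_allclose(spd_one.value, 0.5 * spd_two.value, atol=1e-12)

    def test_normalized_and_unnormalized_spds_correlate(self, small_study, synth_curve, config):
        # smooth curve → normalization barely changes the shape
        raw = make_spd(small_study.dates, synth_curve, config, normalize=False)
        norm = make_spd(small_study.dates, synth_curve, config, normalize=True)
        r, _ = stats.pearsonr(raw.value, norm.value)
        assert r > 0.9


class TestSubsets:
    def test_all_short_lived_subset_equals_full(self, synth_curve, config):
        df = _dates(
            {
                "lab_id": list("abcd"),
                "site_id": list("wxyz"),
                "cra": [4000, 4200, 4400, 4600],
                "error": [30] * 4,
                "material_class": ["short_lived"] * 4,
            }
        )
        full = make_spd(df, synth_curve, config)
        sub = subset_spd(df, synth_curve, config, material_class="short_lived")
        np.testing.assert_allclose(full.value, sub.value)

    def test_zone_subsets_add_to_full_spd(self, synth_curve, config, rng):
        n = 20
        df = _dates(
            {
                "lab_id": [f"L{i}" for i in range(n)],
                "site_id": [f"S{i}" for i in range(n)],  # one date per site
                "cra": rng.uniform(3500, 5200, n).round(),
                "error": [30.0] * n,
                "zone": ["above300"] * (n // 2) + ["below300"] * (n // 2),
            }
        )
        full = make_spd(df, synth_curve, config)
        parts = [
            subset_spd(df, synth_curve, config, zone=z) for z in ("above300", "below300")
        ]
        np.testing.assert_allclose(full.value, parts[0].value + parts[1].value, atol=1e-12)

    def test_unmatched_region_raises(self, toy_dates, synth_curve, config):
        with pytest.raises(EmptySubsetError):
            subset_spd(toy_dates, synth_curve, config, region="Nowhere")

    def test_region_summary_shares(self, small_study, synth_curve, config):
        bins = bin_dates(small_study.dates, synth_curve, config)
        summary = region_summary(small_study.dates, bins)
        assert summary["pct_dates"].sum() == pytest.approx(100.0)
        assert summary["n_bins"].sum() == len(bins)
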