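"""Footprint quantification: center tracks, MP/AMP calls, INDELs, Welch."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from pancistrome.footprints import (
    CoverageTrack,
    binding_frequency,
    call_amps,
    call_mps,
    filter_indels,
    fragment_center_track,
    indel_allele_coverage,
    indel_site_coverage,
    pool_replicates,
    rpgc_to_reads,
    treatment_response_test,
    wgs_control_filter,
)
from pancistrome.stats import binom_two_sided_p


def _track(values, scale=1.0):
    return CoverageTrack(chrom="chr1", values=np.asarray(values, float), scale=scale)


class TestFragmentCenterTrack:
    def test_odd_length_read_gives_centered_20bp_window(self, rng):
        # read [100, 151): middle base 125, window [115, 135)
        t = fragment_center_track([(100, 151)], 300, 300, 1, rng)
        covered = np.flatnonzero(t.values)
        assert covered.min() == 115 and covered.max() == 134

    def test_even_length_read_picks_one_of_two_windows(self):
        starts = set()
        for seed in range(40):
            t = fragment_center_track(
                [(100, 150)], 300, 300, 1, np.random.default_rng(seed)
            )
            starts.add(int(np.flatnonzero(t.values).min()))
        assert starts == {114, 115}

    def test_mass_conservation(self, rng):
        # one read at scale s contributes exactly 20 * s
        t = fragment_center_track([(40, 91)], 200, 1000.0, n_mapped=4, rng=rng)
        assert t.total_mass == pytest.approx(20 * 1000.0 / 4)

    def test_empty_read_set_is_empty_track(self, rng):
        t = fragment_center_track([], 100, 1000.0, n_mapped=1, rng=rng)
        assert t.total_mass == 0

    def test_negative_length_read_rejected(self, rng):
        with pytest.raises(ValueError):
            fragment_center_track([(50, 40)], 100, 1000.0, 1, rng)


class TestBindingFrequency:
    @pytest.mark.parametrize(
        "ref, pat, expected", [(7.5, 2.5, 0.75), (0.0, 5.0, 0.0), (3.0, 0.0, 1.0)]
    )
    def test_ratio(self, ref, pat, expected):
        assert binding_frequency(ref, pat) == pytest.approx(expected)

    def test_no_reads_is_missing_not_error(self):
        assert np.isnan(binding_frequency(0.0, 0.0))

    def test_negative_coverage_rejected(self):
        with pytest.raises(ValueError):
            binding_frequency(-1.0, 2.0)

    @given(
        ref=st.floats(0, 100, allow_nan=False),
        pat=st.floats(0, 100, allow_nan=False),
    )
    def test_allele_swap_maps_f_to_one_minus_f(self, ref, pat):
        f = binding_frequency(ref, pat)
        g = binding_frequency(pat, ref)
        if ref + pat > 0:
            assert f + g == pytest.approx(1.0)
        else:
            assert np.isnan(f) and np.isnan(g)


def _mp_frame(rows):
    df = pd.DataFrame(
        rows, columns=["site_id", "line", "condition", "reads_ref", "reads_pat",
                       "rpgc_ref", "rpgc_pat"]
    )
    return df


class TestCallMps:
    def test_threshold_and_peak_rules(self):
        cov = _mp_frame(
            [
                ("a", "L1", "WW", 27, 2, 8.0, 0.6),   # MP
                ("b", "L1", "WW", 23, 23, 7.0, 7.0),  # 7 is not > 7
                ("c", "L1", "WW", 167, 167, 50.0, 50.0),  # out of peak
                ("d", "L1", "WW", 30, 0, 9.0, 0.0),   # other allele has no read
            ]
        )
        in_peak = pd.Series([True, True, False, True], index=list("abcd"))
        mps = call_mps(cov, in_peak).set_index("site_id")
        assert bool(mps.loc["a", "is_mp"])
        assert not mps.loc[["b", "c", "d"], "is_mp"].any()

    def test_missing_peak_annotation_is_an_error(self):
        cov = _mp_frame([("a", "L1", "WW", 10, 10, 3.0, 3.0)])
        with pytest.raises(ValueError, match="peak"):
            call_mps(cov, pd.Series(dtype=bool))


class TestCallAmps:
    def _amp_input(self, counts):
        rows = [
            (f"s{i}", "L1", "WW", k, n - k, k * 0.3, (n - k) * 0.3)
            for i, (k, n) in enumerate(counts)
        ]
        df = _mp_frame(rows)
        df["in_peak"] = True
        df["is_mp"] = True
        df["binding_frequency"] = df["reads_ref"] / (df["reads_ref"] + df["reads_pat"])
        df["is_amp"] = False
        return df

    def test_balanced_counts_are_not_amp(self):
        out = call_amps(self._amp_input([(25, 50)]))
        assert out["p_binomial"].iloc[0] == pytest.approx(1.0)
        assert not out["is_amp"].any()

    def test_extreme_imbalance_is_amp(self):
        # 50 vs 5 reads: exact two-sided binomial p = 2.1358e-10 (R binom.test)
        out = call_amps(self._amp_input([(50, 55)]))
        assert out["p_binomial"].iloc[0] == pytest.approx(2.1358426138817774e-10)
        assert out["is_amp"].all()

    def test_invalid_fdr_rejected(self):
        with pytest.raises(ValueError, match="fdr"):
            call_amps(self._amp_input([(25, 50)]), fdr=1.5)

    def test_pvalues_match_scipy_binomtest_oracle(self, rng):
        ks = rng.integers(0, 21, size=40)
        ns = rng.integers(1, 21, size=40)
        ks = np.minimum(ks, ns)
        out = call_amps(self._amp_input(list(zip(ks, ns))))
        oracle = [sps.binomtest(int(k), int(n), 0.5).pvalue for k, n in zip(ks, ns)]
        assert np.allclose(out["p_binomial"], oracle, atol=1e-10, rtol=0)

    def test_amp_subset_of_mp(self, small_data):
        pooled = pool_replicates(small_data.coverage["WW"])
        in_peak = small_data.sites.set_index("site_id")["in_peak"]
        out = call_amps(call_mps(pooled, in_peak))
        assert (out.loc[out["is_amp"], "is_mp"]).all()


class TestWgsFilter:
    def test_percentile_thresholds_exclude_extreme_amps(self, rng):
        n = 500
        ratios = pd.Series(
            rng.uniform(0.4, 0.6, size=n), index=[f"s{i}" for i in range(n)]
        )
        df = pd.DataFrame(
            {
                "site_id": ratios.index,
                "line": "L1",
                "condition": "WW",
                "is_mp": True,
                "is_amp": True,
            }
        )
        lo, hi = np.percentile(ratios, [5, 95])
        out = wgs_control_filter(df, ratios)
        excluded = out.loc[out["wgs_excluded"], "wgs_ratio"]
        kept = out.loc[~out["wgs_excluded"], "wgs_ratio"]
        assert ((excluded < lo) | (excluded > hi)).all()
        assert ((kept >= lo) & (kept <= hi)).all()
        assert not out.loc[out["wgs_excluded"], "is_amp"].any()

    def test_median_ratio_amp_is_retained(self):
        ratios = pd.Series(
            np.linspace(0.3, 0.7, 41), index=[f"s{i}" for i in range(41)]
        )
        df = pd.DataFrame(
            {"site_id": ratios.index, "line": "L1", "condition": "WW",
             "is_mp": True, "is_amp": False}
        )
        df.loc[20, "is_amp"] = True  # ratio 0.5, the median
        out = wgs_control_filter(df, ratios)
        assert out["is_amp"].sum() == 1

    def test_few_mps_warns(self):
        ratios = pd.Series([0.5] * 5, index=[f"s{i}" for i in range(5)])
        df = pd.DataFrame(
            {"site_id": ratios.index, "line": "L1", "condition": "WW",
             "is_mp": True, "is_amp": False}
        )
        with pytest.warns(UserWarning, match="unreliable"):
            wgs_control_filter(df, ratios)


class TestIndels:
    def test_deletion_flank_average(self):
        v = np.zeros(300)
        v[197:200] = 4.0  # 3 bp before the deletion point at 200
        v[200:203] = 4.0  # 3 bp after
        assert indel_allele_coverage(_track(v), 200, 200, "deletion") == pytest.approx(4.0)

    def test_insertion_average_includes_zero_bases(self):
        v = np.zeros(300)
        v[100:110] = 2.0
        v[105] = 12.0
        assert indel_allele_coverage(_track(v), 100, 110, "insertion") == pytest.approx(3.0)

    def test_length_filter_excludes_55bp(self):
        indels = pd.DataFrame({"length": [1, 2, 50, 55], "alt_count": [5, 5, 5, 5]})
        kept = filter_indels(indels)
        assert kept["length"].tolist() == [2, 50]

    def test_site_coverage_back_converts_reads(self):
        ref = np.zeros(300)
        ref[100:110] = 3.0  # insertion on the reference allele
        pat = np.zeros(300)
        pat[47:53] = 0.9
        rec = indel_site_coverage(
            {"carrier": "ref", "ins_start": 100, "ins_end": 110, "del_pos": 50},
            _track(ref, scale=0.3),
            _track(pat, scale=0.3),
        )
        assert rec["rpgc_ref"] == pytest.approx(3.0)
        assert rec["rpgc_pat"] == pytest.approx(0.9)
        assert rec["reads_ref"] == 10 and rec["reads_pat"] == 3


class TestRpgcToReads:
    def test_rounds_half_away_from_zero(self):
        assert rpgc_to_reads(7.5, 1.0) == 8
        assert rpgc_to_reads(7.4, 1.0) == 7
        assert rpgc_to_reads(np.array([0.3, 0.45]), 0.3).tolist() == [1, 2]


class TestTreatmentResponse:
    def test_identical_samples_not_significant(self):
        res = treatment_response_test([10, 11, 9], [10, 11, 9])
        assert res.pvalue == pytest.approx(1.0)
        assert not res.significant

    def test_strong_shift_detected_with_direction(self):
        # Welch formula: |t| = 10 / sqrt(0.04/3 + 0.25/3) = 32.163
        res = treatment_response_test([10.0, 10.2, 9.8], [20.0, 19.5, 20.5])
        assert res.statistic == pytest.approx(32.16337604513386)
        assert res.pvalue < 0.001
        assert res.direction == 1 and res.significant

    def test_single_replicate_condition_is_an_error(self):
        with pytest.raises(ValueError):
            treatment_response_test([5.0], [6.0, 7.0])
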