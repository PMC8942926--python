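"""M-value pathway, motif overrepresentation, activity judgement, overlaps."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demethtf.array_validation import (beta_to_m, call_diff_probes,
                                       demeth_probe_ratio, judge_activity,
                                       m_to_beta, original_m_bias,
                                       overlap_matrix, overrep_curve,
                                       sample_background,
                                       scan_genome_matches)
from demethtf.synthetic_fixtures import make_array_activity_fixture


def m_table_from_deltas(deltas, mock=3.0):
    idx = pd.Index([f"cg{i}" for i in range(len(deltas))], name="probe_id")
    return pd.DataFrame({"mock": mock, "tf": mock + np.asarray(deltas)},
                        index=idx)


WORKED_DELTAS = [-3, -2.5, -2, -1.9, 0, 1, 2, 2.1, -0.5, 0.3]


class TestMValues:
    def test_half_beta_is_zero(self):
        assert beta_to_m(0.5) == 0.0

    def test_antisymmetry_about_half(self):
        assert beta_to_m(0.8) == pytest.approx(2.0)
        assert beta_to_m(0.2) == pytest.approx(-2.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_to_m(1.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-19.9, 19.9))
    def test_round_trip_identity(self, m):
        assert beta_to_m(m_to_beta(m)) == pytest.approx(m, abs=1e-9)


class TestCallDiffProbes:
    def test_worked_ten_probe_fixture(self):
        out = call_diff_probes(m_table_from_deltas(WORKED_DELTAS), "tf", "mock")
        assert (out["direction"] == "demethylated").sum() == 3
        assert (out["direction"] == "methylated").sum() == 2
        assert demeth_probe_ratio(out) == pytest.approx(1.5)

    def test_threshold_is_inclusive(self):
        out = call_diff_probes(m_table_from_deltas([-2.0]), "tf", "mock")
        assert len(out) == 1 and out.loc[0, "direction"] == "demethylated"

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            call_diff_probes(m_table_from_deltas([0.0]), "tfX", "mock")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-6, 6), min_size=1, max_size=50),
           st.floats(0.5, 4.0))
    def test_count_monotone_in_threshold(self, deltas, thr):
        table = m_table_from_deltas(deltas)
        low = call_diff_probes(table, "tf", "mock", m_threshold=thr)
        high = call_diff_probes(table, "tf", "mock", m_threshold=thr + 0.5)
        assert len(high) <= len(low)

    def test_ratio_sentinel_when_nothing_methylated(self):
        out = call_diff_probes(m_table_from_deltas([-3.0, -2.5]), "tf", "mock")
        assert demeth_probe_ratio(out) == math.inf

    def test_ratio_requires_probes(self):
        with pytest.raises(ValueError):
            demeth_probe_ratio(pd.DataFrame({"direction": []}))


class TestSampleBackground:
    def _manifest(self, n=50):
        return pd.DataFrame({"probe_id": [f"cg{i}" for i in range(n)],
                             "chrom": "chr1", "pos": np.arange(n) * 100})

    def test_disjoint_from_exclusion(self):
        manifest = self._manifest()
        exclude = {f"cg{i}" for i in range(10)}
        bg = sample_background(manifest, 20, exclude, seed=1)
        assert len(bg) == 20
        assert not set(bg["probe_id"]) & exclude

    def test_reproducible_under_seed(self):
        manifest = self._manifest()
        a = sample_background(manifest, 10, set(), seed=5)
        b = sample_background(manifest, 10, set(), seed=5)
        assert a.equals(b)

    def test_insufficient_pool_rejected(self):
        with pytest.raises(ValueError):
            sample_background(self._manifest(5), 10, set(), seed=1)


@pytest.fixture(scope="module")
def activity_fixture():
    return make_array_activity_fixture(seed=17, planted=True)


def _diff_and_probes(fixture, seed=11):
    m = pd.DataFrame(beta_to_m(fixture.beta.values), index=fixture.beta.index,
                     columns=fixture.beta.columns)
    diff = call_diff_probes(m, "tf", "mock")
    demeth = set(diff.loc[diff["direction"] == "demethylated", "probe_id"])
    fg = fixture.manifest[fixture.manifest["probe_id"].isin(demeth)]
    fg = fg.reset_index(drop=True)
    bg = sample_background(fixture.manifest, len(fg), demeth, seed)
    return diff, fg, bg, m


class TestOverrepCurve:
    def test_planted_motif_peaks_near_probes(self, activity_fixture):
        fx = activity_fixture
        _, fg, bg, _ = _diff_and_probes(fx)
        curve = overrep_curve(fx.genome_index, fg, bg, fx.pwm)
        peak = curve.bin_centers[np.argmax(curve.score)]
        assert abs(peak) <= 500  # planting jitter is +/- 300

    def test_identical_sets_give_zero_curve(self, activity_fixture):
        fx = activity_fixture
        _, fg, _, _ = _diff_and_probes(fx)
        curve = overrep_curve(fx.genome_index, fg, fg, fx.pwm)
        assert np.all(curve.score == 0.0)

    def test_antisymmetric_under_label_swap(self, activity_fixture):
        fx = activity_fixture
        _, fg, bg, _ = _diff_and_probes(fx)
        idx = scan_genome_matches(fx.genome_index, fx.pwm)
        a = overrep_curve(fx.genome_index, fg, bg, fx.pwm, match_index=idx)
        b = overrep_curve(fx.genome_index, bg, fg, fx.pwm, match_index=idx)
        np.testing.assert_allclose(a.score, -b.score)

    def test_size_mismatch_rejected(self, activity_fixture):
        fx = activity_fixture
        _, fg, bg, _ = _diff_and_probes(fx)
        with pytest.raises(ValueError, match="same size"):
            overrep_curve(fx.genome_index, fg, bg.iloc[:-1], fx.pwm)

    def test_empty_foreground_rejected(self, activity_fixture):
        fx = activity_fixture
        empty = fx.manifest.iloc[:0]
        with pytest.raises(ValueError, match="empty foreground"):
            overrep_curve(fx.genome_index, empty, empty, fx.pwm)


class TestJudgeActivity:
    def test_planted_tf_judged_positive(self, activity_fixture):
        fx = activity_fixture
        _, fg, bg, _ = _diff_and_probes(fx)
        curve = overrep_curve(fx.genome_index, fg, bg, fx.pwm)
        positive, p, stat = judge_activity(curve, seed=3)
        assert positive and p < 0.01 and stat > 0

    def test_decoy_motif_judged_negative(self, activity_fixture):
        fx = activity_fixture
        _, fg, bg, _ = _diff_and_probes(fx)
        curve = overrep_curve(fx.genome_index, fg, bg, fx.decoy_pwm)
        positive, _, _ = judge_activity(curve, seed=3)
        assert not positive

    def test_degenerate_alpha_always_positive(self, activity_fixture):
        fx = activity_fixture
        _, fg, bg, _ = _diff_and_probes(fx)
        curve = overrep_curve(fx.genome_index, fg, bg, fx.decoy_pwm)
        positive, _, _ = judge_activity(curve, alpha=1.01, seed=3)
        assert positive

    def test_too_few_permutations_rejected(self, activity_fixture):
        fx = activity_fixture
        _, fg, bg, _ = _diff_and_probes(fx)
        curve = overrep_curve(fx.genome_index, fg, bg, fx.pwm)
        with pytest.raises(ValueError):
            judge_activity(curve, n_perm=10)


class TestOverlapMatrix:
    def test_diagonal_is_hundred(self):
        mat = overlap_matrix({"A": {1, 2, 3}, "B": {3, 4}})
        assert mat.loc["A", "A"] == 100.0 and mat.loc["B", "B"] == 100.0

    def test_asymmetric_subset_example(self):
        mat = overlap_matrix({"P": {"a", "b", "c", "d"}, "S": {"c", "d"}})
        assert mat.loc["P", "S"] == 50.0
        assert mat.loc["S", "P"] == 100.0

    def test_disjoint_sets_share_nothing(self):
        mat = overlap_matrix({"A": {1}, "B": {2}, "C": {3}})
        off = mat.values[~np.eye(3, dtype=bool)]
        assert (off == 0.0).all()

    def test_empty_primary_yields_nan_row(self, caplog):
        with caplog.at_level("WARNING"):
            mat = overlap_matrix({"A": set(), "B": {1}})
        assert mat.loc["A"].isna().all()
        assert mat.loc["B", "B"] == 100.0


class TestOriginalMBias:
    def test_hypermethylated_demeth_probes_detected(self, activity_fixture):
        fx = activity_fixture
        diff, _, _, m = _diff_and_probes(fx)
        out = original_m_bias(diff, m["mock"])
        assert out["demethylated"]["median"] > out["all"]["median"]
        assert out["p"] < 0.01
        assert out["auc"] > 0.5

    def test_random_subsample_is_unbiased(self):
        rng = np.random.default_rng(8)
        all_m = pd.Series(rng.normal(0, 2, 4000),
                          index=[f"cg{i}" for i in range(4000)])
        chosen = rng.choice(all_m.index, 300, replace=False)
        diff = pd.DataFrame({"probe_id": chosen, "direction": "demethylated"})
        out = original_m_bias(diff, all_m)
        assert abs(out["auc"] - 0.5) < 0.06

    def test_single_probe_summaries_without_test(self):
        all_m = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        diff = pd.DataFrame({"probe_id": ["b"], "direction": ["demethylated"]})
        out = original_m_bias(diff, all_m)
        assert out["demethylated"]["median"] == 2.0
        assert math.isnan(out["p"])
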