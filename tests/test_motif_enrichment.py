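"""PWM scanning, site-probability curves, and the enrichment indices."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demethtf.io_formats import GenomeIndex, PwmRecord
from demethtf.motif_enrichment import (SiteProbabilityCurve, adjust_log_p,
                                       c_value, central_enrichment,
                                       enrich_dataset, log_binomial_tail,
                                       scan_best_site,
                                       site_probability_curve)
from demethtf.synthetic_fixtures import consensus_pwm, make_planted_regions


def unit_pwm(consensus, motif_id="M"):
    rows = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        rows[i, "ACGT".index(b)] = 1.0
    return PwmRecord(motif_id, ("TF",), rows)


def log_tail_oracle(k, n, num=1, den=11):
    """Exact log P(X >= k), X ~ Binomial(n, num/den), by integer summation."""
    total = sum(math.comb(n, i) * num**i * (den - num) ** (n - i)
                for i in range(k, n + 1))
    return math.log(total) - n * math.log(den)


class TestScanBestSite:
    def test_forward_match(self):
        site = scan_best_site("TTACGTTT", unit_pwm("ACGT"))
        assert site.start == 2 and site.strand == "+"
        # midpoint = start + 1 (left of middle), window center = 4
        assert site.offset == -1

    def test_reverse_strand_match(self):
        site = scan_best_site("TTCGTTTT", unit_pwm("AACG"))
        assert site.strand == "-" and site.start == 2

    def test_tie_broken_toward_center(self):
        # palindromic motif at starts 0 and 4; offset 1 is closer to center
        site = scan_best_site("ACGTACGT", unit_pwm("ACGT"))
        assert site.offset == 1 and site.strand == "+"

    def test_below_threshold_returns_none(self):
        assert scan_best_site("TTTTTTTT", unit_pwm("ACGT"),
                              score_threshold_fraction=0.5) is None

    def test_mostly_n_sequence_skipped(self):
        assert scan_best_site("NNNNNNACGT", unit_pwm("ACGT")) is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_strand_symmetry_of_reverse_complement_pwm(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.dirichlet(np.full(4, 0.4), size=6)
        pwm = PwmRecord("M", ("TF",), mat)
        rc = PwmRecord("Mrc", ("TF",), mat[::-1, ::-1].copy())
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        a = scan_best_site(seq, pwm)
        b = scan_best_site(seq, rc)
        assert (a is None) == (b is None)
        if a is not None:
            assert a.score == pytest.approx(b.score, abs=1e-9)
            assert a.offset == b.offset  # same genomic interval wins


class TestSiteProbabilityCurve:
    def test_center_planted_mass_at_zero(self):
        pwm = consensus_pwm("m", "TGATTACATA", ("TF",))
        regions = make_planted_regions(pwm, 100, 0, 0, seed=1, window=220)
        curve = site_probability_curve(regions, pwm, 0.7)
        assert curve.prob[curve.offsets == 0] == pytest.approx(1.0)
        assert curve.n_sites == 100

    def test_absent_motif_gives_empty_curve(self):
        pwm = consensus_pwm("m", "TGATTACATA", ("TF",))
        rng = np.random.default_rng(0)
        regions = ["".join("AT"[i] for i in rng.integers(0, 2, 220))
                   for _ in range(50)]
        curve = site_probability_curve(regions, pwm, 0.9)
        assert curve.n_sites == 0

    def test_uniform_placement_is_uniform(self):
        pwm = consensus_pwm("m", "TGATTACATA", ("TF",))
        W, n = 110, 5000
        half = 45
        regions = make_planted_regions(pwm, n, -half, half, seed=2, window=W)
        curve = site_probability_curve(regions, pwm, 0.7)
        n_off = 2 * half + 1
        occupied = curve.prob[np.abs(curve.offsets) <= half]
        bound = 5 * math.sqrt(1 / (n * n_off))
        assert np.abs(occupied - 1 / n_off).max() < bound

    def test_permutation_invariance(self):
        pwm = consensus_pwm("m", "TGATTACATA", ("TF",))
        regions = make_planted_regions(pwm, 60, -40, 40, seed=3, window=220)
        a = site_probability_curve(regions, pwm, 0.7)
        b = site_probability_curve(regions[::-1], pwm, 0.7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_unequal_window_lengths_rejected(self):
        pwm = consensus_pwm("m", "TGATTACATA", ("TF",))
        with pytest.raises(ValueError):
            site_probability_curve(["A" * 50, "A" * 60], pwm)


def synthetic_curve(counts_by_offset, n_regions, window=2200):
    offsets = np.arange(window) - window // 2
    counts = np.zeros(window, dtype=np.int64)
    for off, cnt in counts_by_offset.items():
        counts[off + window // 2] = cnt
    return SiteProbabilityCurve("m", offsets, counts, n_regions)


class TestCentralEnrichment:
    def test_against_exact_summation(self):
        curve = synthetic_curve({0: 40, 500: 60}, 100)
        log_p, conc = central_enrichment(curve)
        assert conc == pytest.approx(0.40)
        assert log_p == pytest.approx(log_tail_oracle(40, 100), abs=1e-9)

    def test_null_rate_sits_near_even_odds(self):
        # k = n * p0 exactly: the upper tail holds about half the mass
        curve = synthetic_curve({0: 100, 600: 1000}, 1200)
        log_p, conc = central_enrichment(curve)
        assert conc == pytest.approx(100 / 1100)
        assert abs(log_p - math.log(0.5)) < 0.1
        assert log_p == pytest.approx(log_tail_oracle(100, 1100), abs=1e-9)

    def test_deep_tail_stays_finite(self):
        curve = synthetic_curve({0: 5000}, 5000)
        log_p, conc = central_enrichment(curve)
        assert conc == 1.0
        assert math.isfinite(log_p)
        assert log_p == pytest.approx(5000 * math.log(1 / 11), rel=1e-9)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            central_enrichment(synthetic_curve({}, 10))


class TestAdjustLogP:
    def test_bonferroni_in_log_space(self):
        assert adjust_log_p(-510.0, 600) == pytest.approx(-510 + math.log(600))
        assert adjust_log_p(-510.0, 600) < -500

    def test_capped_at_zero(self):
        assert adjust_log_p(0.0, 600) == 0.0

    def test_single_motif_identity(self):
        assert adjust_log_p(-3.5, 1) == -3.5


class TestCValue:
    def test_step_curve_closed_form(self):
        counts = {o: (20 if abs(o) < 100 else 10)
                  for o in range(-1100, 1100)}
        curve = synthetic_curve(counts, 1000)
        assert c_value(curve) == pytest.approx(2.0)

    def test_uniform_curve_is_one(self):
        curve = synthetic_curve({o: 5 for o in range(-1100, 1100)}, 1000)
        assert c_value(curve) == pytest.approx(1.0)

    def test_zero_over_zero_sentinel(self):
        assert c_value(synthetic_curve({0: 10}, 10)) == 1.0

    def test_mass_only_inside_boundary_gives_inf(self):
        assert c_value(synthetic_curve({-90: 10}, 10)) == math.inf

    def test_scale_invariance(self):
        base = {o: (7 if abs(o) < 100 else 3) for o in range(-300, 300)}
        a = synthetic_curve(base, 100)
        b = synthetic_curve({o: 13 * c for o, c in base.items()}, 1300)
        assert c_value(a) == pytest.approx(c_value(b))

    def test_narrow_curve_rejected(self):
        narrow = SiteProbabilityCurve("m", np.arange(-50, 50),
                                      np.zeros(100, dtype=np.int64), 10)
        with pytest.raises(ValueError):
            c_value(narrow)


class TestLogBinomialTail:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 200), st.data())
    def test_matches_integer_oracle(self, n, data):
        k = data.draw(st.integers(0, n))
        assert log_binomial_tail(k, n, 1 / 11) == pytest.approx(
            log_tail_oracle(k, n), abs=1e-9)

    def test_degenerate_bounds(self):
        assert log_binomial_tail(0, 10, 0.5) == 0.0
        assert log_binomial_tail(11, 10, 0.5) == -math.inf


class TestEnrichDataset:
    def _bins(self, n):
        return pd.DataFrame({"chrom": "chr1",
                             "start": 2000 + 200 * 11 * np.arange(n)})\
            .assign(end=lambda d: d["start"] + 200)

    def test_zero_demethylated_bins_rejected(self, wgbs_fixture):
        with pytest.raises(ValueError, match="zero demethylated"):
            enrich_dataset(self._bins(0), wgbs_fixture.genome_index,
                           wgbs_fixture.pwms)

    def test_min_regions_enforced(self, wgbs_fixture):
        with pytest.raises(ValueError, match="need >="):
            enrich_dataset(self._bins(5), wgbs_fixture.genome_index,
                           wgbs_fixture.pwms, min_regions=50)

    def test_empty_pwm_collection_rejected(self, wgbs_fixture):
        with pytest.raises(ValueError, match="empty PWM"):
            enrich_dataset(self._bins(60), wgbs_fixture.genome_index, [])

    def test_deterministic_given_inputs(self, wgbs_fixture, pipeline):
        fx = wgbs_fixture
        again = enrich_dataset(pipeline["demeth"], fx.genome_index, fx.pwms,
                               dataset_id="target")
        for a, b in zip(pipeline["results"], again):
            assert a == b
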