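"""Central motif enrichment over demethylated-bin windows.

Each demethylated 200-bp bin is extended by five bins on either side
(2,200-bp window).  For every PWM the single best log-odds site per window
(both strands) is located; the distribution of best-site offsets from the
window center is the site-probability curve.  Three indices are derived
from the curve:

* ``log_p`` / ``log_adj_p`` — one-sided binomial tail probability that as
  many best sites fall inside the central bin as observed, under a uniform
  null; Bonferroni-adjusted in natural-log space over the motifs tested.
* ``concentration`` — fraction of best sites inside the central bin.
* ``c_value`` — ratio of mean site probability just inside vs just outside
  the upstream bin boundary ([-100,-80) over [-120,-100) offsets for 200-bp
  bins).  Values above 1.2 flag the boundary artifact that CpG-containing
  motifs show in bisulfite data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import gammaln

from .binned_methylome import DEFAULT_BIN_SIZE
from .io_formats import GenomeIndex, PwmRecord

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BINS = 5
DEFAULT_SCORE_FRACTION = 0.7
DEFAULT_MIN_REGIONS = 50

# sequence encoding: A C G T N -> 0 1 2 3 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_N_PENALTY = -1e4  # one N in a site sinks it below any sane threshold


def encode_sequence(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _score_matrices(pwm: PwmRecord) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward and reverse-complement L x 5 log2-odds matrices and max score."""
    lo = pwm.log_odds()
    fwd = np.concatenate([lo, np.full((pwm.length, 1), _N_PENALTY)], axis=1)
    rev = fwd[::-1][:, [3, 2, 1, 0, 4]]
    max_score = float(lo.max(axis=1).sum())
    return fwd, rev, max_score


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Scores of all length-L sites along one sequence (or a batch)."""
    L = matrix.shape[0]
    if codes.ndim == 1:
        windows = sliding_window_view(codes, L)
        return matrix[np.arange(L), windows].sum(axis=-1)
    n_pos = codes.shape[1] - L + 1
    scores = np.zeros((codes.shape[0], n_pos))
    for l in range(L):
        scores += matrix[l][codes[:, l:l + n_pos]]
    return scores


@dataclass(frozen=True)
class Site:
    """Best motif site in one window; offset is midpoint minus window center."""

    offset: int
    strand: str
    score: float
    start: int


@dataclass
class SiteProbabilityCurve:
    """Distribution of best-site offsets across scored regions.

    ``counts[i]`` is the number of regions whose best site midpoint sits at
    ``offsets[i]``; each region contributes one best site or nothing.
    """

    motif_id: str
    offsets: np.ndarray
    counts: np.ndarray
    n_regions: int
    n_skipped: int = 0

    @property
    def prob(self) -> np.ndarray:
        return self.counts / max(self.n_regions, 1)

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


@dataclass
class EnrichmentResult:
    """Per-motif enrichment indices for one dataset."""

    motif_id: str
    dataset_id: str
    n_regions: int
    n_sites: int
    n_central: int
    concentration: float
    log_p: float
    log_adj_p: float
    c_value: float


def _best_from_scores(fwd: np.ndarray, rev: np.ndarray, threshold: float,
                      mid_shift: int, center: int) -> tuple[int, str, float, int] | None:
    """Pick the best site from per-start score vectors of one window.

    Ties on score are broken by smaller |offset|, then forward strand, then
    smaller offset.
    """
    scores = np.concatenate([fwd, rev])
    n = len(fwd)
    best = scores.max(initial=-np.inf)
    if best < threshold - 1e-9:
        return None
    idx = np.flatnonzero(scores == best)
    starts = np.where(idx < n, idx, idx - n)
    offsets = starts + mid_shift - center
    is_rev = idx >= n
    order = np.lexsort((offsets, is_rev, np.abs(offsets)))
    j = order[0]
    return (int(offsets[j]), "-" if is_rev[j] else "+",
            float(best), int(starts[j]))


def scan_best_site(sequence: str, pwm: PwmRecord,
                   score_threshold_fraction: float = 0.0) -> Site | None:
    """Locate the single best site for ``pwm`` on either strand.

    Returns None when the sequence is more than half N or no site reaches
    ``score_threshold_fraction`` times the maximum achievable score.
    """
    codes = encode_sequence(sequence)
    if len(codes) < pwm.length:
        raise ValueError("sequence shorter than motif")
    if (codes == 4).mean() > 0.5:
        logger.warning("region skipped: more than 50%% N")
        return None
    fwd_m, rev_m, max_score = _score_matrices(pwm)
    threshold = score_threshold_fraction * max_score
    hit = _best_from_scores(_window_scores(codes, fwd_m),
                            _window_scores(codes, rev_m),
                            threshold, (pwm.length - 1) // 2, len(codes) // 2)
    return Site(*hit) if hit is not None else None


def site_probability_curve(regions: Sequence[str] | np.ndarray, pwm: PwmRecord,
                           score_threshold_fraction: float = DEFAULT_SCORE_FRACTION,
                           ) -> SiteProbabilityCurve:
    """Build the best-site offset distribution over equal-length regions."""
    if isinstance(regions, np.ndarray) and regions.ndim == 2:
        codes = regions
    else:
        if len(regions) == 0:
            raise ValueError("no regions")
        lengths = {len(r) for r in regions}
        if len(lengths) != 1:
            raise ValueError("regions must share one window length")
        codes = np.stack([encode_sequence(r) for r in regions])
    W = codes.shape[1]
    if W < pwm.length:
        raise ValueError("window shorter than motif")

    keep = (codes == 4).mean(axis=1) <= 0.5
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.warning("%s: skipped %d regions with >50%% N", pwm.motif_id, n_skipped)
    codes = codes[keep]
    if codes.shape[0] == 0:
        raise ValueError("zero scoreable regions")

    fwd_m, rev_m, max_score = _score_matrices(pwm)
    threshold = score_threshold_fraction * max_score
    fwd = _window_scores(codes, fwd_m)
    rev = _window_scores(codes, rev_m)

    center = W // 2
    mid_shift = (pwm.length - 1) // 2
    offsets = np.arange(W) - center
    counts = np.zeros(W, dtype=np.int64)
    for i in range(codes.shape[0]):
        hit = _best_from_scores(fwd[i], rev[i], threshold, mid_shift, center)
        if hit is not None:
            counts[hit[0] + center] += 1
    return SiteProbabilityCurve(pwm.motif_id, offsets, counts,
                                int(codes.shape[0]), n_skipped)


def log_binomial_tail(k: int, n: int, p0: float) -> float:
    """Natural log of P(X >= k) for X ~ Binomial(n, p0).

    Summed term-by-term in log space, so tails far below the smallest
    representable linear probability (counts up to ~1e6) stay finite.
    """
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    if k <= 0:
        return 0.0
    if k > n:
        return -math.inf
    i = np.arange(k, n + 1)
    log_pmf = (gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
               + i * math.log(p0) + (n - i) * math.log1p(-p0))
    peak = log_pmf.max()
    return float(peak + np.log(np.exp(log_pmf - peak).sum()))


def central_enrichment(curve: SiteProbabilityCurve,
                       central_width: int = DEFAULT_BIN_SIZE,
                       ) -> tuple[float, float]:
    """One-sided binomial tail log-p and concentration of the central window.

    The null places each best site uniformly over the offsets; the central
    window is the ``central_width`` offsets around zero, so the null success
    probability is central_width / window_width (1/11 for the defaults).
    """
    half = central_width // 2
    central = (curve.offsets >= -half) & (curve.offsets < central_width - half)
    n = curve.n_sites
    if n == 0:
        raise ValueError("no sites on the curve")
    k = int(curve.counts[central].sum())
    p0 = central.sum() / len(curve.offsets)
    log_p = log_binomial_tail(k, n, p0)
    return min(log_p, 0.0), k / n


def adjust_log_p(log_p: float, n_motifs: int) -> float:
    """Bonferroni adjustment in natural-log space, capped at 0."""
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    return min(0.0, log_p + math.log(n_motifs))


def c_value(curve: SiteProbabilityCurve, bin_size: int = DEFAULT_BIN_SIZE) -> float:
    """Boundary-artifact statistic for CpG-containing motifs.

    Mean site probability over offsets in (-100, -80] divided by the mean
    over (-120, -100] for 200-bp bins (strips scale with ``bin_size``); the
    upstream bin boundary at -100 falls in the outer strip.  0/0 yields the
    neutral sentinel 1.0; a finite numerator over a zero denominator yields
    +inf.
    """
    scale = bin_size / DEFAULT_BIN_SIZE
    inner_lo, inner_hi = -100 * scale, -80 * scale
    outer_lo, outer_hi = -120 * scale, -100 * scale
    if curve.offsets.min() > outer_lo:
        raise ValueError("curve too narrow for the boundary strips")
    prob = curve.prob
    inner = (curve.offsets > inner_lo) & (curve.offsets <= inner_hi)
    outer = (curve.offsets > outer_lo) & (curve.offsets <= outer_hi)
    num = prob[inner].mean()
    den = prob[outer].mean()
    if den == 0.0:
        return 1.0 if num == 0.0 else float("inf")
    return float(num / den)


def extract_regions(diff_bins: pd.DataFrame, genome_index: GenomeIndex,
                    bin_size: int = DEFAULT_BIN_SIZE,
                    flank_bins: int = DEFAULT_FLANK_BINS) -> np.ndarray:
    """Fetch the target-bin +/- flank windows as an encoded sequence batch.

    Windows overrunning a chromosome end are discarded.
    """
    width = (2 * flank_bins + 1) * bin_size
    rows = []
    for chrom, start, end in zip(diff_bins["chrom"], diff_bins["start"],
                                 diff_bins["end"]):
        wstart = start - flank_bins * bin_size
        wend = end + flank_bins * bin_size
        if wstart < 0 or wend > genome_index.chrom_sizes.get(chrom, -1):
            continue
        seq = genome_index.fetch(chrom, wstart, wend)
        assert len(seq) == width
        rows.append(encode_sequence(seq))
    if not rows:
        return np.zeros((0, width), dtype=np.uint8)
    return np.stack(rows)


def enrich_dataset(demeth_bins: pd.DataFrame, genome_index: GenomeIndex,
                   pwms: Sequence[PwmRecord], dataset_id: str = "dataset",
                   bin_size: int = DEFAULT_BIN_SIZE,
                   flank_bins: int = DEFAULT_FLANK_BINS,
                   score_threshold_fraction: float = DEFAULT_SCORE_FRACTION,
                   min_regions: int = DEFAULT_MIN_REGIONS,
                   return_curves: bool = False):
    """Run central enrichment for every motif over the demethylated bins.

    Returns a list of :class:`EnrichmentResult` (plus the per-motif curves
    when ``return_curves``).  Motifs with zero passing sites get neutral
    indices (log_p 0, concentration 0, c_value 1) rather than an error, so
    uninformative motifs stay visible in the output.
    """
    if not pwms:
        raise ValueError("empty PWM collection")
    if len(demeth_bins) == 0:
        raise ValueError("zero demethylated bins")
    if len(demeth_bins) < min_regions:
        raise ValueError(
            f"only {len(demeth_bins)} demethylated bins; need >= {min_regions}")
    codes = extract_regions(demeth_bins, genome_index, bin_size, flank_bins)
    if codes.shape[0] == 0:
        raise ValueError("all windows overran chromosome ends")

    results, curves = [], {}
    for pwm in pwms:
        curve = site_probability_curve(codes, pwm, score_threshold_fraction)
        if curve.n_sites == 0:
            res = EnrichmentResult(pwm.motif_id, dataset_id, curve.n_regions,
                                   0, 0, 0.0, 0.0, 0.0, 1.0)
        else:
            log_p, conc = central_enrichment(curve, central_width=bin_size)
            half = bin_size // 2
            central = (curve.offsets >= -half) & (curve.offsets < bin_size - half)
            res = EnrichmentResult(
                pwm.motif_id, dataset_id, curve.n_regions, curve.n_sites,
                int(curve.counts[central].sum()), conc, log_p,
                adjust_log_p(log_p, len(pwms)), c_value(curve, bin_size))
        results.append(res)
        curves[pwm.motif_id] = curve
    if return_curves:
        return results, curves
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "motif_id": r.motif_id,
        "dataset_id": r.dataset_id,
        "n_regions": r.n_regions,
        "n_sites": r.n_sites,
        "n_central": r.n_central,
        "concentration": r.concentration,
        "log_p": r.log_p,
        "log_adj_p": r.log_adj_p,
        "c_value": r.c_value,
    } for r in results])
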