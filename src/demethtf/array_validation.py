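"""Computational arm of the in vitro demethylation assay.

TF-overexpressing cells are profiled on a methylation array against a
mock-infected control.  Probes whose M-value (log2 beta odds) moves by at
least 2 are differential; demethylated probes are those where methylation
drops under TF overexpression.  Motif overrepresentation around
demethylated probes is scored against an equal number of randomly chosen
background probes within +/- 5 kb, and a label-swap permutation test on the
central part of the difference curve judges demethylation-promoting
activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io_formats import GenomeIndex, PwmRecord
from .motif_enrichment import _score_matrices, _window_scores, encode_sequence

logger = logging.getLogger(__name__)

DEFAULT_M_THRESHOLD = 2.0
DEFAULT_FLANK = 5000
DEFAULT_POS_BIN_WIDTH = 100
DEFAULT_MATCH_FRACTION = 0.8  # matchPWM-style min-score fraction

DIFF_PROBE_COLUMNS = ["probe_id", "m_mock", "m_tf", "delta_m", "direction"]


def beta_to_m(beta, epsilon: float = 1e-6):
    """M = log2(beta / (1 - beta)), with beta clamped away from {0, 1}."""
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, epsilon, 1 - epsilon)
    m = np.log2(b / (1 - b))
    return float(m) if np.isscalar(beta) else m


def m_to_beta(m):
    m = np.asarray(m, dtype=float)
    b = np.exp2(m) / (1 + np.exp2(m))
    return float(b) if b.ndim == 0 else b


def call_diff_probes(m_table: pd.DataFrame, tf_condition: str,
                     mock_condition: str,
                     m_threshold: float = DEFAULT_M_THRESHOLD) -> pd.DataFrame:
    """Probes with |M_tf - M_mock| >= m_threshold (inclusive).

    ``demethylated`` means the M-value decreased under TF overexpression.
    """
    for cond in (tf_condition, mock_condition):
        if cond not in m_table.columns:
            raise ValueError(f"condition {cond!r} absent from the M table")
    sub = m_table[[mock_condition, tf_condition]].dropna()
    delta = sub[tf_condition] - sub[mock_condition]
    hit = np.abs(delta) >= m_threshold
    out = pd.DataFrame({
        "probe_id": sub.index[hit],
        "m_mock": sub[mock_condition][hit].values,
        "m_tf": sub[tf_condition][hit].values,
        "delta_m": delta[hit].values,
    })
    out["direction"] = np.where(out["delta_m"] < 0, "demethylated", "methylated")
    return out.reset_index(drop=True)


def demeth_probe_ratio(diff_probes: pd.DataFrame) -> float:
    """Demethylated over methylated probe count; +inf when none methylated."""
    if len(diff_probes) == 0:
        raise ValueError("no differential probes")
    n_de = int((diff_probes["direction"] == "demethylated").sum())
    n_me = len(diff_probes) - n_de
    if n_me == 0:
        logger.info("no methylated probes; ratio is +inf")
        return float("inf")
    return n_de / n_me


def sample_background(manifest: pd.DataFrame, n: int, exclude: set,
                      seed: int | np.random.Generator) -> pd.DataFrame:
    """Uniformly sample ``n`` probes without replacement, disjoint from ``exclude``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = manifest[~manifest["probe_id"].isin(exclude)]
    if len(pool) < n:
        raise ValueError(f"only {len(pool)} probes available, need {n}")
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool.iloc[np.sort(idx)].reset_index(drop=True)


def scan_genome_matches(genome_index: GenomeIndex, pwm: PwmRecord,
                        score_threshold_fraction: float = DEFAULT_MATCH_FRACTION,
                        ) -> dict[str, np.ndarray]:
    """All motif match midpoints per chromosome, both strands, above threshold.

    One genome-wide scan per motif; probe-window counting then reduces to
    binary search, which keeps repeated overrepresentation runs cheap.
    """
    fwd_m, rev_m, max_score = _score_matrices(pwm)
    threshold = score_threshold_fraction * max_score - 1e-9
    mid_shift = (pwm.length - 1) // 2
    out = {}
    for chrom, size in genome_index.chrom_sizes.items():
        codes = encode_sequence(genome_index.fetch(chrom, 0, size))
        if len(codes) < pwm.length:
            out[chrom] = np.zeros(0, dtype=np.int64)
            continue
        fwd = _window_scores(codes, fwd_m)
        rev = _window_scores(codes, rev_m)
        starts = np.flatnonzero((fwd >= threshold) | (rev >= threshold))
        out[chrom] = np.sort(starts + mid_shift)
    return out


@dataclass
class OverrepCurve:
    """Foreground-minus-background motif match counts around probe positions.

    ``fg_counts`` / ``bg_counts`` are (n_pairs, n_bins) per-probe histograms
    of match offsets; ``score`` is their summed difference over n_probes.
    """

    motif_id: str
    bin_edges: np.ndarray
    fg_counts: np.ndarray
    bg_counts: np.ndarray

    @property
    def n_probes(self) -> int:
        return self.fg_counts.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def score(self) -> np.ndarray:
        return (self.fg_counts.sum(axis=0)
                - self.bg_counts.sum(axis=0)) / self.n_probes


def _probe_histograms(matches: Mapping[str, np.ndarray], probes: pd.DataFrame,
                      edges: np.ndarray) -> np.ndarray:
    counts = np.zeros((len(probes), len(edges) - 1), dtype=np.int64)
    for i, (chrom, pos) in enumerate(zip(probes["chrom"], probes["pos"])):
        mids = matches.get(chrom)
        if mids is None or len(mids) == 0:
            continue
        lo = np.searchsorted(mids, pos + edges[0])
        hi = np.searchsorted(mids, pos + edges[-1])
        if hi > lo:
            counts[i] = np.histogram(mids[lo:hi] - pos, bins=edges)[0]
    return counts


def overrep_curve(genome_index: GenomeIndex, fg_probes: pd.DataFrame,
                  bg_probes: pd.DataFrame, pwm: PwmRecord,
                  flank: int = DEFAULT_FLANK,
                  pos_bin_width: int = DEFAULT_POS_BIN_WIDTH,
                  score_threshold_fraction: float = DEFAULT_MATCH_FRACTION,
                  match_index: Mapping[str, np.ndarray] | None = None,
                  ) -> OverrepCurve:
    """Motif match-count difference curve around fg vs bg probe positions.

    Probe pair i = (fg[i], bg[i]); pairs whose windows are clipped at a
    chromosome end are dropped together so the two sets stay the same size.
    """
    if len(fg_probes) == 0:
        raise ValueError("empty foreground probe set")
    if len(fg_probes) != len(bg_probes):
        raise ValueError("foreground and background must be the same size")
    if match_index is None:
        match_index = scan_genome_matches(genome_index, pwm,
                                          score_threshold_fraction)

    def in_range(df):
        sizes = df["chrom"].map(genome_index.chrom_sizes)
        return (df["pos"] - flank >= 0) & (df["pos"] + flank <= sizes)

    ok = (in_range(fg_probes).values & in_range(bg_probes).values)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d probe pairs clipped at chromosome ends", n_dropped)
    fg, bg = fg_probes[ok], bg_probes[ok]
    if len(fg) == 0:
        raise ValueError("no probe pairs survive end clipping")

    edges = np.arange(-flank, flank + pos_bin_width, pos_bin_width)
    return OverrepCurve(pwm.motif_id, edges,
                        _probe_histograms(match_index, fg, edges),
                        _probe_histograms(match_index, bg, edges))


def judge_activity(curve: OverrepCurve, n_perm: int = 1000,
                   center_halfwidth: int = 500, alpha: float = 0.01,
                   seed: int | np.random.Generator = 0,
                   ) -> tuple[bool, float, float]:
    """Permutation test for a central enrichment peak in the curve.

    The statistic is the mean score over offset bins within
    +/- center_halfwidth; the null swaps foreground/background labels per
    probe pair.  Returns (positive, empirical p, observed statistic).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = curve.bin_centers
    central = np.abs(centers) <= center_halfwidth
    if not central.any():
        raise ValueError("no offset bins inside the central window")
    diff = curve.fg_counts[:, central] - curve.bg_counts[:, central]
    per_pair = diff.sum(axis=1) / (curve.n_probes * central.sum())
    observed = float(per_pair.sum())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(per_pair)))
    null = signs @ per_pair
    p = float((1 + np.sum(null >= observed - 1e-12)) / (n_perm + 1))
    return p < alpha, p, observed


def overlap_matrix(demeth_sets: Mapping[str, set]) -> pd.DataFrame:
    """Percentage of each primary TF's demethylated probes shared with others.

    entry(primary, secondary) = 100 * |primary & secondary| / |primary|;
    asymmetric by construction.  Empty primary sets yield a NaN row.
    """
    if not demeth_sets:
        raise ValueError("no demethylated probe sets")
    names = list(demeth_sets)
    mat = np.full((len(names), len(names)), np.nan)
    for i, a in enumerate(names):
        pa = demeth_sets[a]
        if not pa:
            logger.warning("TF %s has no demethylated probes; row is NaN", a)
            continue
        for j, b in enumerate(names):
            mat[i, j] = 100.0 * len(pa & demeth_sets[b]) / len(pa)
    return pd.DataFrame(mat, index=names, columns=names)


def original_m_bias(diff_probes: pd.DataFrame, mock_m_all: pd.Series) -> dict:
    """Mock-condition M-value bias of demethylated probes vs all probes.

    Reports quartile summaries of both distributions plus a one-sided
    Mann-Whitney comparison (demethylated greater), with the rank statistic
    normalized to an AUC in [0, 1].  With fewer than two demethylated
    probes the test is skipped (statistic and p are NaN).
    """
    if len(mock_m_all) == 0:
        raise ValueError("empty probe universe")
    demeth_ids = diff_probes.loc[diff_probes["direction"] == "demethylated",
                                 "probe_id"]
    demeth_m = mock_m_all.loc[mock_m_all.index.intersection(demeth_ids)]
    if len(demeth_m) == 0:
        raise ValueError("no demethylated probes with mock M-values")

    def summary(x):
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"q1": float(q1), "median": float(med), "q3": float(q3),
                "n": int(len(x))}

    out = {"demethylated": summary(demeth_m), "all": summary(mock_m_all)}
    if len(demeth_m) < 2:
        logger.info("single demethylated probe; rank test skipped")
        out.update(auc=float("nan"), p=float("nan"))
        return out
    u, p = mannwhitneyu(demeth_m, mock_m_all, alternative="greater")
    out.update(auc=float(u / (len(demeth_m) * len(mock_m_all))), p=float(p))
    return out
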