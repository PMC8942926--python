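"""Differentially methylated bin calling against the ESC reference.

Replicates are averaged upstream, so each bin carries one aggregate 2x2
count table (methylated / unmethylated in reference vs target).  We test it
with a two-sided Fisher exact test, correct with Benjamini-Hochberg, and
emit bins passing a strict > 50-point methylation difference at q < 1e-4.
A bin is "demethylated" when the target lost methylation relative to the
reference, "methylated" when it gained.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .binned_methylome import BinMethylome

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 50.0
DEFAULT_Q = 1e-4

DIFF_COLUMNS = ["chrom", "start", "end", "percent_ref", "percent_target",
                "delta", "p", "q", "direction"]

_TIE_SLACK = 1e-7


# cached log-factorials cover any realistic per-bin depth; larger inputs
# fall back to gammaln on the fly
_LOG_FACT = gammaln(np.arange(1, 2**16 + 2))


def _log_fact(n):
    n = np.asarray(n)
    if n.max(initial=0) < len(_LOG_FACT):
        return _LOG_FACT[n]
    return gammaln(n + 1.0)


def _log_comb(n, k):
    return _log_fact(n) - _log_fact(k) - _log_fact(n - k)


def bin_exact_test(n_meth_ref: int, n_total_ref: int,
                   n_meth_tgt: int, n_total_tgt: int) -> float:
    """Two-sided Fisher exact p for one bin's aggregate 2x2 count table.

    Enumerates the hypergeometric support and sums the probabilities of all
    tables no more likely than the observed one (ties included with a small
    relative slack against floating-point noise).
    """
    if n_total_ref <= 0 or n_total_tgt <= 0:
        raise ValueError("both totals must be positive")
    if not (0 <= n_meth_ref <= n_total_ref and 0 <= n_meth_tgt <= n_total_tgt):
        raise ValueError("methylated counts must lie within totals")
    k = n_meth_ref + n_meth_tgt
    n = n_total_ref + n_total_tgt
    lo = max(0, k - n_total_tgt)
    hi = min(k, n_total_ref)
    support = np.arange(lo, hi + 1)
    log_pmf = (_log_comb(n_total_ref, support)
               + _log_comb(n_total_tgt, k - support)
               - _log_comb(n, k))
    log_obs = log_pmf[n_meth_ref - lo]
    keep = log_pmf[log_pmf <= log_obs + np.log1p(_TIE_SLACK)]
    peak = keep.max()
    p = float(np.exp(peak) * np.exp(keep - peak).sum())
    return min(1.0, max(p, np.nextafter(0, 1)))


def adjust_q(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_diff_bins(ref: BinMethylome, tgt: BinMethylome,
                   delta_threshold: float = DEFAULT_DELTA,
                   q_threshold: float = DEFAULT_Q) -> pd.DataFrame:
    """Call differential bins between a target profile and the reference.

    Only bins covered in both profiles are tested; q-values are computed
    over that co-covered set.  Emitted bins satisfy |delta| > delta_threshold
    and q < q_threshold, both strict.
    """
    if ref.bin_size != tgt.bin_size or len(ref.table) != len(tgt.table):
        raise ValueError("profiles disagree on binning")
    both = (ref.table["covered"].values & tgt.table["covered"].values)
    if not both.any():
        logger.warning("no co-covered bins between %s and %s",
                       ref.dataset_id, tgt.dataset_id)
        return pd.DataFrame(columns=DIFF_COLUMNS)

    r = ref.table.loc[both]
    t = tgt.table.loc[both]
    p = np.array([
        bin_exact_test(mr, tr_, mt, tt)
        for mr, tr_, mt, tt in zip(r["n_meth"].values, r["n_total"].values,
                                   t["n_meth"].values, t["n_total"].values)
    ])
    q = adjust_q(p)
    delta = t["percent"].values - r["percent"].values

    emit = (np.abs(delta) > delta_threshold) & (q < q_threshold)
    out = pd.DataFrame({
        "chrom": r["chrom"].values[emit],
        "start": r["start"].values[emit],
        "end": r["end"].values[emit],
        "percent_ref": r["percent"].values[emit],
        "percent_target": t["percent"].values[emit],
        "delta": delta[emit],
        "p": p[emit],
        "q": q[emit],
    })
    out["direction"] = np.where(out["delta"] < 0, "demethylated", "methylated")
    return out.reset_index(drop=True)


def demeth_meth_ratio(diff_bins: pd.DataFrame) -> float:
    """Fraction of differential bins that are demethylated."""
    if len(diff_bins) == 0:
        raise ValueError("no differential bins")
    return float((diff_bins["direction"] == "demethylated").mean())
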