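"""Four-criterion selection of TFBM-TF candidates across datasets.

A (motif, TF) pair is selected when all four hold:

1. concentration > 0.12 in at least one cell or tissue dataset;
2. log-adjusted p-value < -500 (natural log) in at least one dataset;
3. the average C-value over datasets is < 1.2;
4. the TF's mean expression over non-ESC samples exceeds its ESC expression.

Motif-to-TF mapping is many-to-many, so one motif can yield several pairs
and several motifs can point at one TF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .motif_enrichment import EnrichmentResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionThresholds:
    concentration: float = 0.12
    log_adj_p: float = -500.0
    c_value: float = 1.2


SELECTION_COLUMNS = ["motif_id", "tf_name", "max_concentration", "min_log_adj_p",
                     "avg_c_value", "mean_expression", "esc_expression",
                     "pass_concentration", "pass_log_adj_p", "pass_c_value",
                     "pass_expression", "selected"]


def _per_motif_stats(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([{
        "motif_id": r.motif_id,
        "dataset_id": r.dataset_id,
        "concentration": r.concentration,
        "log_adj_p": r.log_adj_p,
        "c_value": r.c_value,
    } for r in results])
    if df.empty:
        raise ValueError("empty enrichment input")

    def avg_finite_c(values):
        finite = [v for v in values if math.isfinite(v)]
        if len(finite) < len(values):
            logger.info("excluded %d infinite C-values from the average",
                        len(values) - len(finite))
        return float(np.mean(finite)) if finite else float("inf")

    return df.groupby("motif_id").agg(
        max_concentration=("concentration", "max"),
        min_log_adj_p=("log_adj_p", "min"),
        avg_c_value=("c_value", avg_finite_c),
    ).reset_index()


def select_tfbm_tfs(results: Sequence[EnrichmentResult],
                    motif_tf_map: Mapping[str, Sequence[str]],
                    expression: pd.DataFrame,
                    esc_sample: str,
                    thresholds: SelectionThresholds = SelectionThresholds(),
                    ) -> pd.DataFrame:
    """Evaluate the four criteria for every (motif, TF) pair.

    ``expression`` is a gene x sample table containing ``esc_sample``; TFs
    missing from it fail the expression criterion (logged).  All
    inequalities are strict.
    """
    if esc_sample not in expression.columns:
        raise ValueError(f"expression table lacks sample {esc_sample!r}")
    stats = _per_motif_stats(results)
    non_esc = [c for c in expression.columns if c != esc_sample]
    if not non_esc:
        raise ValueError("expression table has no non-ESC samples")

    rows = []
    for rec in stats.itertuples(index=False):
        tfs = motif_tf_map.get(rec.motif_id, [rec.motif_id])
        for tf in tfs:
            if tf in expression.index:
                mean_expr = float(expression.loc[tf, non_esc].mean())
                esc_expr = float(expression.loc[tf, esc_sample])
                pass_expr = mean_expr > esc_expr
            else:
                logger.warning("TF %s absent from the expression table; "
                               "expression criterion fails", tf)
                mean_expr, esc_expr, pass_expr = float("nan"), float("nan"), False
            flags = {
                "pass_concentration": rec.max_concentration > thresholds.concentration,
                "pass_log_adj_p": rec.min_log_adj_p < thresholds.log_adj_p,
                "pass_c_value": rec.avg_c_value < thresholds.c_value,
                "pass_expression": pass_expr,
            }
            rows.append({
                "motif_id": rec.motif_id,
                "tf_name": tf,
                "max_concentration": rec.max_concentration,
                "min_log_adj_p": rec.min_log_adj_p,
                "avg_c_value": rec.avg_c_value,
                "mean_expression": mean_expr,
                "esc_expression": esc_expr,
                **flags,
                "selected": all(flags.values()),
            })
    return pd.DataFrame(rows, columns=SELECTION_COLUMNS)


def summarize_pairs(records: pd.DataFrame) -> tuple[int, int, int]:
    """(selected pairs, distinct motifs, distinct TFs) among selected records."""
    sel = records.loc[records["selected"].astype(bool)]
    return (len(sel), sel["motif_id"].nunique(), sel["tf_name"].nunique())
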