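"""Fixed-width genome tiling and per-bin methylation aggregation.

The genome is tiled into 200-bp bins by default (TF-driven demethylation
extends roughly 194 bp to either side of a binding site, so one bin spans
the expected footprint).  Per-bin methylation is the unweighted mean of the
per-CpG percentages; sequencing depth enters only through the
tags-per-billion coverage filter (a bin is covered when its share of the
library exceeds 100 tags per billion, strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CpgCall

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 200
DEFAULT_COVERAGE_TPB = 100.0

BIN_COLUMNS = ["chrom", "start", "end", "n_cpgs", "n_meth", "n_total",
               "percent", "tpb", "covered"]


@dataclass(frozen=True)
class Bin:
    """One fixed-width genomic tile; ``index`` is its ordinal on the chromosome."""

    chrom: str
    start: int
    end: int
    index: int


@dataclass
class BinMethylome:
    """Per-bin methylation profile for one dataset.

    ``table`` columns: chrom, start, end, n_cpgs, n_meth, n_total, percent,
    tpb, covered.  ``percent`` is NaN for uncovered bins.
    """

    dataset_id: str
    bin_size: int
    total_tags: int
    coverage_tpb: float
    table: pd.DataFrame

    @property
    def n_covered(self) -> int:
        return int(self.table["covered"].sum())


def tile_genome(chrom_sizes: Mapping[str, int],
                bin_size: int = DEFAULT_BIN_SIZE) -> list[Bin]:
    """Tile every chromosome into ``floor(len / bin_size)`` bins.

    The trailing partial bin is dropped so that every bin has exactly
    ``bin_size`` bases and the enrichment window geometry stays exact.
    """
    if not chrom_sizes:
        raise ValueError("empty chrom_sizes")
    if bin_size < 50:
        raise ValueError(f"bin_size must be >= 50, got {bin_size}")
    bins: list[Bin] = []
    for chrom in chrom_sizes:
        n = chrom_sizes[chrom] // bin_size
        for i in range(n):
            bins.append(Bin(chrom, i * bin_size, (i + 1) * bin_size, i))
    return bins


def _empty_table(chrom_sizes: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    frames = []
    for chrom, size in chrom_sizes.items():
        n = size // bin_size
        starts = np.arange(n, dtype=np.int64) * bin_size
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + bin_size,
        }))
    return pd.concat(frames, ignore_index=True)


def aggregate_bins(calls: Sequence[CpgCall],
                   chrom_sizes: Mapping[str, int],
                   bin_size: int = DEFAULT_BIN_SIZE,
                   total_tags: int | None = None,
                   coverage_tpb: float = DEFAULT_COVERAGE_TPB,
                   dataset_id: str = "dataset") -> BinMethylome:
    """Aggregate per-CpG calls into a :class:`BinMethylome`.

    Bin percent is the unweighted mean of per-CpG percentages; the
    tags-per-billion value is the bin's total count over the library total,
    scaled by 1e9.  Calls outside every bin are tallied and logged.
    """
    table = _empty_table(chrom_sizes, bin_size)
    if total_tags is None:
        total_tags = int(sum(c.n_total for c in calls))
    if total_tags <= 0:
        raise ValueError("total_tags must be positive")

    n_bins = len(table)
    offsets = {}
    off = 0
    for chrom, size in chrom_sizes.items():
        offsets[chrom] = off
        off += size // bin_size

    n_cpgs = np.zeros(n_bins, dtype=np.int64)
    sum_pct = np.zeros(n_bins, dtype=float)
    n_meth = np.zeros(n_bins, dtype=np.int64)
    n_total = np.zeros(n_bins, dtype=np.int64)
    unbinned = 0
    for c in calls:
        base = offsets.get(c.chrom)
        idx = c.pos // bin_size
        if base is None or idx >= chrom_sizes[c.chrom] // bin_size:
            unbinned += 1
            continue
        j = base + idx
        n_cpgs[j] += 1
        sum_pct[j] += c.percent
        n_meth[j] += c.n_meth
        n_total[j] += c.n_total
    if unbinned:
        logger.warning("%s: %d CpG calls fell outside all bins", dataset_id, unbinned)

    tpb = n_total / total_tags * 1e9
    covered = (n_cpgs > 0) & (tpb > coverage_tpb)
    percent = np.full(n_bins, np.nan)
    percent[covered] = sum_pct[covered] / n_cpgs[covered]

    table["n_cpgs"] = n_cpgs
    table["n_meth"] = n_meth
    table["n_total"] = n_total
    table["percent"] = percent
    table["tpb"] = tpb
    table["covered"] = covered
    return BinMethylome(dataset_id, bin_size, total_tags, coverage_tpb, table)


def average_replicates(replicates: Sequence[BinMethylome],
                       dataset_id: str | None = None) -> BinMethylome:
    """Average replicate profiles into one per-dataset profile.

    Per bin, the percent is the unweighted mean over replicates in which the
    bin is covered; a bin is covered in the output when covered in at least
    one replicate.  Aggregate counts are summed for the downstream exact test.
    """
    if not replicates:
        raise ValueError("empty replicate list")
    first = replicates[0]
    for rep in replicates[1:]:
        if rep.bin_size != first.bin_size or len(rep.table) != len(first.table):
            raise ValueError("replicates disagree on binning")
        if not (rep.table["start"].values == first.table["start"].values).all():
            raise ValueError("replicates disagree on bin coordinates")
    if len(replicates) == 1:
        rep = replicates[0]
        return BinMethylome(dataset_id or rep.dataset_id, rep.bin_size,
                            rep.total_tags, rep.coverage_tpb, rep.table.copy())

    pct = np.stack([r.table["percent"].values for r in replicates])
    cov = np.stack([r.table["covered"].values for r in replicates])
    n_any = cov.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_pct = np.where(n_any > 0,
                            np.nansum(np.where(cov, pct, 0.0), axis=0)
                            / np.maximum(n_any, 1),
                            np.nan)

    table = first.table[["chrom", "start", "end"]].copy()
    for col in ("n_cpgs", "n_meth", "n_total"):
        table[col] = np.sum([r.table[col].values for r in replicates], axis=0)
    total_tags = int(sum(r.total_tags for r in replicates))
    table["percent"] = mean_pct
    table["tpb"] = table["n_total"].values / total_tags * 1e9
    table["covered"] = n_any > 0
    table.loc[~table["covered"], "percent"] = np.nan
    return BinMethylome(dataset_id or first.dataset_id, first.bin_size,
                        total_tags, first.coverage_tpb, table)


def write_binmeth(bm: BinMethylome, path) -> None:
    from .io_formats import write_tsv

    out = bm.table[BIN_COLUMNS].copy()
    out.insert(0, "dataset_id", bm.dataset_id)
    out["total_tags"] = bm.total_tags
    write_tsv(out, path, float_format="%.10g")


def read_binmeth(path) -> BinMethylome:
    df = pd.read_csv(path, sep="\t")
    dataset_id = str(df["dataset_id"].iloc[0]) if len(df) else "dataset"
    total_tags = int(df["total_tags"].iloc[0]) if len(df) else 1
    bin_size = int(df["end"].iloc[0] - df["start"].iloc[0]) if len(df) else DEFAULT_BIN_SIZE
    table = df[BIN_COLUMNS].copy()
    return BinMethylome(dataset_id, bin_size, total_tags, DEFAULT_COVERAGE_TPB, table)
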