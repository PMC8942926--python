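"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based, half-open (BED native).  Dialects that
are 1-based on disk are converted on read.  Methylation percentages are
always recomputed from counts, never trusted from the file.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_VALID_BASES = frozenset("ACGTN")

CPG_DIALECTS = ("bedgraph_counts", "cov_table")


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# CpG methylation calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpgCall:
    """One CpG cytosine with bisulfite counts.

    ``pos`` is the 0-based position of the cytosine.  ``percent`` is always
    derived from the counts.
    """

    chrom: str
    pos: int
    n_meth: int
    n_total: int

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if not (0 <= self.n_meth <= self.n_total):
            raise ValueError(
                f"invalid counts n_meth={self.n_meth}, n_total={self.n_total}"
            )
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")

    @property
    def percent(self) -> float:
        return 100.0 * self.n_meth / self.n_total


def read_cpg_calls(path, dialect: str = "cov_table") -> list[CpgCall]:
    """Read per-CpG methylation calls; emitted sorted by (chrom, pos).

    Dialects
    --------
    ``bedgraph_counts``
        chrom, start, end, percent, n_meth, n_unmeth.  The file percent is
        ignored; counts rule.
    ``cov_table``
        chrom, pos, n_meth, n_total.
    """
    if dialect not in CPG_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {CPG_DIALECTS}")
    calls: list[CpgCall] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "bedgraph_counts":
                    if len(fields) < 6:
                        raise ValueError("expected 6 fields")
                    chrom, start = fields[0], int(fields[1])
                    n_meth, n_unmeth = int(fields[4]), int(fields[5])
                    call = CpgCall(chrom, start, n_meth, n_meth + n_unmeth)
                else:
                    if len(fields) < 4:
                        raise ValueError("expected 4 fields")
                    chrom, pos = fields[0], int(fields[1])
                    n_meth, n_total = int(fields[2]), int(fields[3])
                    call = CpgCall(chrom, pos, n_meth, n_total)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def write_cpg_calls(calls: Iterable[CpgCall], path) -> None:
    """Write calls in the ``cov_table`` dialect, sorted by (chrom, pos)."""
    rows = sorted(calls, key=lambda c: (c.chrom, c.pos))
    with open(path, "wt") as fh:
        for c in rows:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.n_meth}\t{c.n_total}\n")


# ---------------------------------------------------------------------------
# Genome access
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Chromosome sizes plus random access to uppercase DNA sequence.

    Every fetch is validated against ``chrom_sizes``; out-of-range requests
    raise unless ``clip=True``.  Returned strings contain only A/C/G/T/N.
    """

    def __init__(self, chrom_sizes: Mapping[str, int],
                 fetcher: Callable[[str, int, int], str]):
        if not chrom_sizes:
            raise ValueError("empty chrom_sizes")
        self.chrom_sizes = dict(chrom_sizes)
        self._fetch = fetcher

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str]) -> "GenomeIndex":
        seqs = {name: seq.upper() for name, seq in sequences.items()}

        def fetch(chrom, start, end):
            return seqs[chrom][start:end]

        return cls({name: len(seq) for name, seq in seqs.items()}, fetch)

    @classmethod
    def from_fasta(cls, path) -> "GenomeIndex":
        import pyfaidx

        fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)
        sizes = {name: len(fasta[name]) for name in fasta.keys()}

        def fetch(chrom, start, end):
            return str(fasta[chrom][start:end])

        return cls(sizes, fetch)

    def fetch(self, chrom: str, start: int, end: int, clip: bool = False) -> str:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        size = self.chrom_sizes[chrom]
        if clip:
            start, end = max(0, start), min(size, end)
        elif start < 0 or end > size or start > end:
            raise ValueError(f"interval {chrom}:{start}-{end} outside [0,{size})")
        seq = self._fetch(chrom, start, end).upper()
        if not set(seq) <= _VALID_BASES:
            seq = "".join(b if b in _VALID_BASES else "N" for b in seq)
        return seq


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 fields")
            sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise FormatError(f"{path}: no chromosomes")
    return sizes


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PWM collections
# ---------------------------------------------------------------------------

@dataclass
class PwmRecord:
    """A position probability matrix with its associated TF gene symbols.

    ``matrix`` is L x 4 over (A, C, G, T), row-stochastic.  ``background``
    is the base-frequency model used for log-odds scoring.
    """

    motif_id: str
    tf_names: tuple[str, ...]
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if self.matrix.shape[0] < 2:
            raise ValueError(f"{self.motif_id}: motif length must be >= 2")
        sums = self.matrix.sum(axis=1)
        if np.any((sums < 0.99) | (sums > 1.01)):
            raise ValueError(f"{self.motif_id}: row sums outside [0.99, 1.01]")
        self.matrix = self.matrix / sums[:, None]
        if not np.isclose(self.background.sum(), 1.0, atol=1e-3):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @property
    def has_cpg(self) -> bool:
        return "CG" in self.consensus

    def log_odds(self, floor: float = 1e-4) -> np.ndarray:
        """L x 4 log2-odds matrix with zero probabilities floored at ``floor``."""
        p = np.maximum(self.matrix, floor)
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background[None, :])


def _parse_block_pwms(text: str, path) -> list[tuple[str, np.ndarray]]:
    records: list[tuple[str, np.ndarray]] = []
    name, rows = None, []

    def flush():
        if name is None:
            return
        if len(rows) < 2:
            raise FormatError(f"{path}: motif {name}: fewer than 2 rows")
        records.append((name, np.array(rows, dtype=float)))

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name, rows = line[1:].split()[0], []
        else:
            if name is None:
                raise FormatError(f"{path}: line {lineno}: data before header")
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 probabilities")
            rows.append([float(x) for x in fields])
    flush()
    return records


def _parse_meme_pwms(path) -> tuple[list[tuple[str, np.ndarray]], np.ndarray]:
    from Bio import motifs as bio_motifs

    with _open_text(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    out = []
    background = np.full(4, 0.25)
    for m in record:
        counts = np.array([m.counts[b] for b in ALPHABET], dtype=float).T
        totals = counts.sum(axis=1, keepdims=True)
        out.append((m.name, counts / totals))
        bg = getattr(m, "background", None)
        if bg:
            background = np.array([bg[b] for b in ALPHABET], dtype=float)
    return out, background


def read_tf_map(path) -> dict[str, list[str]]:
    """Two-column TSV motif_id -> tf_name; many-to-many, one row per pair."""
    mapping: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            mapping.setdefault(fields[0], [])
            if fields[1] not in mapping[fields[0]]:
                mapping[fields[0]].append(fields[1])
    return mapping


def read_pwm_collection(path, tf_map_path=None) -> list[PwmRecord]:
    """Read a PWM collection in MEME minimal format or simple block format.

    Block format: ``>motif_id`` header followed by L rows of 4 probabilities.
    Motifs absent from the motif->TF map keep their own id as TF name.
    """
    with _open_text(path) as fh:
        head = fh.read(4096)
    if not head.strip():
        raise FormatError(f"{path}: empty PWM file")
    background = np.full(4, 0.25)
    if "MEME version" in head:
        raw_records, background = _parse_meme_pwms(path)
    else:
        with _open_text(path) as fh:
            raw_records = _parse_block_pwms(fh.read(), path)
    if not raw_records:
        raise FormatError(f"{path}: no motifs found")
    tf_map = read_tf_map(tf_map_path) if tf_map_path is not None else {}
    records = []
    for name, matrix in raw_records:
        tf_names = tuple(tf_map.get(name, [name]))
        records.append(PwmRecord(name, tf_names, matrix, background.copy()))
    return records


def write_pwm_collection(pwms: Sequence[PwmRecord], path) -> None:
    """Write motifs in the simple block format understood by the reader."""
    with open(path, "wt") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def write_tf_map(pwms: Sequence[PwmRecord], path) -> None:
    with open(path, "wt") as fh:
        for pwm in pwms:
            for tf in pwm.tf_names:
                fh.write(f"{pwm.motif_id}\t{tf}\n")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path, esc_sample: str | None = None) -> pd.DataFrame:
    """Gene x sample expression table (TPM-like, non-negative, no missing).

    Index is the gene symbol; columns are sample names.  If ``esc_sample``
    is given its absence is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene rows: {dupes}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing expression values (no imputation)")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative expression values")
    if esc_sample is not None and esc_sample not in df.columns:
        raise FormatError(f"{path}: missing required sample column {esc_sample!r}")
    return df


# ---------------------------------------------------------------------------
# Array probe manifests and beta/M tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeRecord:
    """One array probe interrogating a single CpG at a 0-based position."""

    probe_id: str
    chrom: str
    pos: int


def read_probe_manifest(path, one_based: bool = True) -> pd.DataFrame:
    """Probe manifest TSV: probe_id, chrom, pos (1-based on disk by default)."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    if df["probe_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate probe ids")
    df = df.copy()
    if one_based:
        df["pos"] = df["pos"].astype(int) - 1
    return df[["probe_id", "chrom", "pos"]]


def read_value_table(path) -> pd.DataFrame:
    """Probe x condition table of beta or M values, indexed by probe_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate probe rows")
    return df


# ---------------------------------------------------------------------------
# Generic tabular output
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable, path) -> None:
    """Write BED3+ lines sorted by (chrom, start); extra fields pass through."""
    rows = []
    for iv in intervals:
        if isinstance(iv, (tuple, list)):
            rows.append(tuple(iv))
        else:
            rows.append((iv.chrom, iv.start, iv.end))
    rows.sort(key=lambda r: (r[0], int(r[1])))
    with open(path, "wt") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 fields")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_tsv(frame: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Deterministic TSV output: header line, LF endings, fixed float format."""
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n",
                 float_format=float_format)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
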