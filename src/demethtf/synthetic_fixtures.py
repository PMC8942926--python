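"""Deterministic synthetic data with planted ground truth.

Every generator is a pure function of its parameters and a seed, so reruns
are byte-identical.  The WGBS fixture emulates the developmental setting:
an ESC-like reference methylome in which nearly every CpG is methylated
(around 90%), a differentiated target that drops to around 20% in planted
demethylated bins, and a smaller set of bins that gain methylation from
20%-methylated reference islands, at a 4:1 demethylated:methylated ratio.
A consensus motif is written at the centers of a fraction of demethylated
bins so that motif-recovery, selection and array-arm stages all have an
exact truth table.

Bisulfite counts are beta-binomial (real bisulfite data is overdispersed);
depth is Poisson around a mean of 30 with a floor of one read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array_validation import m_to_beta
from .binned_methylome import DEFAULT_BIN_SIZE
from .io_formats import ALPHABET, CpgCall, GenomeIndex, PwmRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the planted WGBS fixture."""

    seed: int = 17
    genome_length: int = 1_000_000
    n_chroms: int = 1
    cpg_density: float = 0.04
    bin_size: int = DEFAULT_BIN_SIZE
    n_demeth_bins: int = 400
    n_meth_bins: int = 100
    ref_level: float = 0.90
    alt_level: float = 0.20
    mean_depth: float = 30.0
    bb_concentration: float = 60.0
    planting_rate: float = 0.6
    offset_jitter: int = 10
    motif_length: int = 12
    n_decoys: int = 20
    min_bin_spacing: int = 6  # bins; keeps planted motifs out of neighbour windows


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _strip_cpg(codes: np.ndarray, rng: np.random.Generator) -> None:
    """Replace the G of every CG dinucleotide, repeating until none remain."""
    while True:
        cg = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
        if len(cg) == 0:
            return
        codes[cg + 1] = rng.choice([0, 1, 3], size=len(cg))


def make_genome(spec: FixtureSpec, rng: np.random.Generator | None = None,
                ) -> dict[str, str]:
    """Random genome with CpG dinucleotides planted at ``cpg_density``.

    Background composition is uniform with accidental CG dinucleotides
    removed; CpGs are then written at even positions with per-position
    probability tuned so the expected count is density x length.  The
    even-slot restriction keeps plantings from overlapping.
    """
    rng = rng or np.random.default_rng(spec.seed)
    if spec.cpg_density > 0.5:
        raise ValueError("infeasible cpg_density")
    genome = {}
    for c in range(spec.n_chroms):
        codes = rng.integers(0, 4, size=spec.genome_length).astype(np.uint8)
        _strip_cpg(codes, rng)
        if spec.cpg_density > 0:
            slots = np.arange(0, spec.genome_length - 1, 2)
            hit = slots[rng.random(len(slots)) < 2 * spec.cpg_density]
            codes[hit] = 1
            codes[hit + 1] = 2
        genome[f"chr{c + 1}"] = _BASES[codes].tobytes().decode("ascii")
    return genome


def find_cpg_positions(genome: Mapping[str, str]) -> dict[str, np.ndarray]:
    """0-based positions of the C of every CG dinucleotide."""
    out = {}
    for chrom, seq in genome.items():
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        out[chrom] = np.flatnonzero((codes[:-1] == ord("C"))
                                    & (codes[1:] == ord("G")))
    return out


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

def _random_consensus(length: int, rng: np.random.Generator,
                      with_cpg: bool = False) -> str:
    """Random consensus; CG-free (and safe at its edges) unless requested."""
    while True:
        cons = "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))
        if with_cpg:
            mid = length // 2
            cons = cons[:mid] + "CG" + cons[mid + 2:]
        if not with_cpg and "CG" in cons:
            continue
        if cons[0] == "G" or cons[-1] == "C":
            continue
        return cons


def consensus_pwm(motif_id: str, consensus: str, tf_names: Sequence[str],
                  consensus_prob: float = 0.97) -> PwmRecord:
    """Near-deterministic PWM around a consensus string."""
    off = (1 - consensus_prob) / 3
    matrix = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        matrix[i, ALPHABET.index(b)] = consensus_prob
    return PwmRecord(motif_id, tuple(tf_names), matrix)


def make_pwm_collection(spec: FixtureSpec, rng: np.random.Generator,
                        ) -> tuple[list[PwmRecord], str]:
    """Planted motif plus decoys; returns (collection, planted motif id).

    Half the decoys are sharp (a random match is essentially impossible),
    half are soft enough to pick up scattered background sites, so decoy
    curves span the realistic range from empty to flat.
    """
    planted = consensus_pwm("motif_planted",
                            _random_consensus(spec.motif_length, rng),
                            ("TF_PLANTED",))
    pwms = [planted]
    for i in range(spec.n_decoys):
        sharp = i % 2 == 0
        pwms.append(consensus_pwm(
            f"decoy_{i + 1:02d}",
            _random_consensus(spec.motif_length, rng),
            (f"TF_DECOY_{i + 1:02d}",),
            consensus_prob=0.97 if sharp else 0.60))
    return pwms, planted.motif_id


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def choose_planted_bins(spec: FixtureSpec, n_bins_per_chrom: Mapping[str, int],
                        rng: np.random.Generator) -> pd.DataFrame:
    """Sample non-adjacent bins for planting, labelled by direction.

    Bins are kept ``min_bin_spacing`` apart so that no planted motif falls
    inside another planted bin's enrichment window, and at least 5 bins from
    each chromosome end so every window fits.
    """
    n_wanted = spec.n_demeth_bins + spec.n_meth_bins
    candidates = []
    for chrom, n in n_bins_per_chrom.items():
        for i in range(5, n - 5):
            candidates.append((chrom, i))
    order = rng.permutation(len(candidates))
    taken: dict[str, list[int]] = {}
    chosen = []
    for idx in order:
        chrom, i = candidates[idx]
        used = taken.setdefault(chrom, [])
        if any(abs(i - j) < spec.min_bin_spacing for j in used):
            continue
        used.append(i)
        chosen.append((chrom, i))
        if len(chosen) == n_wanted:
            break
    if len(chosen) < n_wanted:
        raise ValueError("genome too small for the requested planted bins")
    df = pd.DataFrame(chosen, columns=["chrom", "bin_index"])
    df["start"] = df["bin_index"] * spec.bin_size
    df["end"] = df["start"] + spec.bin_size
    df["direction"] = (["demethylated"] * spec.n_demeth_bins
                       + ["methylated"] * spec.n_meth_bins)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def plant_motifs(genome: dict[str, str], bins: pd.DataFrame, pwm: PwmRecord,
                 rate: float, offset_jitter: int, rng: np.random.Generator,
                 bin_size: int = DEFAULT_BIN_SIZE,
                 center_offset: int = 0,
                 ) -> tuple[dict[str, str], pd.DataFrame]:
    """Write the motif consensus near bin centers for a Bernoulli(rate) subset.

    ``center_offset`` shifts the planted site midpoint from the bin center;
    the jitter is uniform on [-offset_jitter, +offset_jitter].  Returns the
    edited genome and a truth table of exact planted offsets.
    """
    cons = pwm.consensus
    if len(cons) > bin_size // 2:
        raise ValueError("consensus too long for the bin")
    arrays = {c: bytearray(s.encode("ascii")) for c, s in genome.items()}
    mid_shift = (len(cons) - 1) // 2
    truth = []
    for row in bins.itertuples(index=False):
        if rng.random() >= rate:
            continue
        jit = int(rng.integers(-offset_jitter, offset_jitter + 1)) if offset_jitter else 0
        offset = center_offset + jit
        start = row.start + bin_size // 2 + offset - mid_shift
        if start < 0 or start + len(cons) > len(arrays[row.chrom]):
            raise ValueError("planted site collides with a chromosome end")
        arrays[row.chrom][start:start + len(cons)] = cons.encode("ascii")
        truth.append({"chrom": row.chrom, "bin_start": row.start,
                      "offset": offset, "site_start": start})
    edited = {c: bytes(a).decode("ascii") for c, a in arrays.items()}
    return edited, pd.DataFrame(truth, columns=["chrom", "bin_start", "offset",
                                                "site_start"])


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------

def _beta_binomial(mean: np.ndarray, depth: np.ndarray, concentration: float,
                   rng: np.random.Generator) -> np.ndarray:
    a = np.clip(mean, 1e-3, 1 - 1e-3) * concentration
    b = concentration - a
    p = rng.beta(a, b)
    return rng.binomial(depth, p)


def simulate_methylome(genome: Mapping[str, str], planted_bins: pd.DataFrame,
                       spec: FixtureSpec,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[list[CpgCall], list[CpgCall]]:
    """Reference (ESC-like) and target CpG calls with planted differences.

    Reference CpGs sit near ``ref_level`` everywhere except planted
    methylated bins, which start as ``alt_level`` islands; the target drops
    to ``alt_level`` in demethylated bins and rises to ``ref_level`` in
    methylated bins.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    demeth = {(r.chrom, r.bin_index) for r in planted_bins.itertuples()
              if r.direction == "demethylated"}
    meth = {(r.chrom, r.bin_index) for r in planted_bins.itertuples()
            if r.direction == "methylated"}
    ref_calls, tgt_calls = [], []
    for chrom, positions in find_cpg_positions(genome).items():
        bin_idx = positions // spec.bin_size
        in_demeth = np.array([(chrom, i) in demeth for i in bin_idx])
        in_meth = np.array([(chrom, i) in meth for i in bin_idx])
        ref_mean = np.where(in_meth, spec.alt_level, spec.ref_level)
        tgt_mean = np.where(in_demeth, spec.alt_level,
                            np.where(in_meth, spec.ref_level, spec.ref_level))
        for means, sink in ((ref_mean, ref_calls), (tgt_mean, tgt_calls)):
            depth = np.maximum(1, rng.poisson(spec.mean_depth, size=len(positions)))
            n_meth = _beta_binomial(means, depth, spec.bb_concentration, rng)
            sink.extend(CpgCall(chrom, int(p), int(m), int(d))
                        for p, m, d in zip(positions, n_meth, depth))
    return ref_calls, tgt_calls


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def make_expression_table(pwms: Sequence[PwmRecord], planted_motif_id: str,
                          rng: np.random.Generator,
                          esc_sample: str = "ESC") -> pd.DataFrame:
    """TPM-like table: planted TFs above the ESC level, decoy TFs below."""
    samples = [esc_sample, "tissue_a", "tissue_b", "tissue_c"]
    rows = {}
    for pwm in pwms:
        for tf in pwm.tf_names:
            if pwm.motif_id == planted_motif_id:
                vals = [5.0] + list(np.round(rng.uniform(25, 45, size=3), 2))
            else:
                vals = [20.0] + list(np.round(rng.uniform(1, 8, size=3), 2))
            rows[tf] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df.index.name = "gene"
    return df


# ---------------------------------------------------------------------------
# Full WGBS fixture
# ---------------------------------------------------------------------------

@dataclass
class WgbsFixture:
    spec: FixtureSpec
    genome: dict[str, str]
    genome_index: GenomeIndex
    ref_calls: list[CpgCall]
    tgt_calls: list[CpgCall]
    pwms: list[PwmRecord]
    planted_motif_id: str
    planted_bins: pd.DataFrame
    motif_truth: pd.DataFrame
    expression: pd.DataFrame
    esc_sample: str = "ESC"

    @property
    def motif_tf_map(self) -> dict[str, list[str]]:
        return {p.motif_id: list(p.tf_names) for p in self.pwms}

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def make_default_fixture(seed: int = 17,
                         spec: FixtureSpec | None = None) -> WgbsFixture:
    """Build the end-to-end fixture: genome, motifs, methylomes, expression."""
    spec = replace(spec or FixtureSpec(), seed=seed)
    rng = np.random.default_rng(spec.seed)
    genome = make_genome(spec, rng)
    n_bins = {c: len(s) // spec.bin_size for c, s in genome.items()}
    planted_bins = choose_planted_bins(spec, n_bins, rng)
    pwms, planted_id = make_pwm_collection(spec, rng)
    genome, motif_truth = plant_motifs(
        genome, planted_bins[planted_bins["direction"] == "demethylated"],
        pwms[0], spec.planting_rate, spec.offset_jitter, rng, spec.bin_size)
    ref_calls, tgt_calls = simulate_methylome(genome, planted_bins, spec, rng)
    expression = make_expression_table(pwms, planted_id, rng)
    return WgbsFixture(spec, genome, GenomeIndex.from_dict(genome),
                       ref_calls, tgt_calls, pwms, planted_id,
                       planted_bins, motif_truth, expression)


# ---------------------------------------------------------------------------
# Boundary-artifact regions (C-value fixtures)
# ---------------------------------------------------------------------------

def make_planted_regions(pwm: PwmRecord, n_regions: int,
                         offset_low: int, offset_high: int,
                         seed: int, window: int = 2200) -> list[str]:
    """CG-free random windows with the consensus planted at a uniform offset.

    ``offset_low``/``offset_high`` bound the planted site midpoint offset
    from the window center (inclusive); edge-planting just inside the
    upstream bin boundary reproduces the boundary artifact for CpG motifs.
    """
    rng = np.random.default_rng(seed)
    cons = pwm.consensus.encode("ascii")
    mid_shift = (len(cons) - 1) // 2
    center = window // 2
    if (center + offset_low - mid_shift < 0
            or center + offset_high - mid_shift + len(cons) > window):
        raise ValueError("planted offsets overrun the window")
    regions = []
    for _ in range(n_regions):
        codes = rng.integers(0, 4, size=window).astype(np.uint8)
        _strip_cpg(codes, rng)
        arr = bytearray(_BASES[codes].tobytes())
        offset = int(rng.integers(offset_low, offset_high + 1))
        start = center + offset - mid_shift
        arr[start:start + len(cons)] = cons
        regions.append(bytes(arr).decode("ascii"))
    return regions


# ---------------------------------------------------------------------------
# Methylation-array fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpicSpec:
    """Study conditions for the synthetic methylation-array assay."""

    seed: int = 17
    n_probes: int = 50_000
    planted_fraction: float = 0.05
    delta_m: float = -3.0
    noise_sd: float = 0.3
    hyper_m: float = 3.0
    hypo_m: float = -3.0
    mode_sd: float = 0.5
    hyper_weight: float = 0.6
    probe_spacing: int = 20


def simulate_epic(spec: EpicSpec, rng: np.random.Generator | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Index]:
    """Synthetic array: manifest, per-condition beta table, planted probe ids.

    Mock M-values are a two-mode mixture (hypermethylated around +3,
    hypomethylated around -3); a planted fraction of probes shifts by
    ``delta_m`` in the TF condition, and every probe gets Gaussian
    measurement noise on top.
    """
    if not (0 <= spec.planted_fraction <= 1):
        raise ValueError("planted_fraction must lie in [0, 1]")
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_probes
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")
    manifest = pd.DataFrame({
        "probe_id": probe_ids,
        "chrom": "chr1",
        "pos": np.arange(n) * spec.probe_spacing + 10_000,
    })
    hyper = rng.random(n) < spec.hyper_weight
    m_mock = np.where(hyper, rng.normal(spec.hyper_m, spec.mode_sd, n),
                      rng.normal(spec.hypo_m, spec.mode_sd, n))
    planted = rng.choice(n, size=int(round(spec.planted_fraction * n)),
                         replace=False)
    shift = np.zeros(n)
    shift[planted] = spec.delta_m
    m_tf = m_mock + shift + rng.normal(0, spec.noise_sd, n)
    beta = pd.DataFrame({"mock": m_to_beta(m_mock), "tf": m_to_beta(m_tf)},
                        index=probe_ids)
    return manifest, beta, probe_ids[np.sort(planted)]


@dataclass
class ArrayActivityFixture:
    genome_index: GenomeIndex
    manifest: pd.DataFrame
    beta: pd.DataFrame
    pwm: PwmRecord
    decoy_pwm: PwmRecord
    fg_probe_ids: pd.Index


def make_array_activity_fixture(seed: int = 17, planted: bool = True,
                                n_probes: int = 4000, n_fg: int = 150,
                                genome_length: int = 400_000,
                                plant_rate: float = 0.8,
                                plant_halfwidth: int = 300,
                                delta_m: float = -3.0,
                                ) -> ArrayActivityFixture:
    """Array assay fixture with (optionally) a motif planted near fg probes.

    The foreground probes are hypermethylated in mock and shift by
    ``delta_m`` under TF overexpression; with ``planted`` the assay motif is
    written within +/- ``plant_halfwidth`` of most of them, which is what an
    actively demethylating TF leaves behind.  The decoy motif is never
    planted.
    """
    rng = np.random.default_rng(seed)
    gspec = FixtureSpec(seed=seed, genome_length=genome_length, cpg_density=0.01)
    genome = make_genome(gspec, rng)
    chrom = next(iter(genome))
    flank = 5000
    positions = np.sort(rng.choice(
        np.arange(flank, genome_length - flank), size=n_probes, replace=False))
    manifest = pd.DataFrame({
        "probe_id": [f"cg{i:06d}" for i in range(n_probes)],
        "chrom": chrom,
        "pos": positions,
    })
    fg_idx = np.sort(rng.choice(n_probes, size=n_fg, replace=False))
    fg_ids = pd.Index(manifest["probe_id"].values[fg_idx])

    pwm = consensus_pwm("motif_assay", _random_consensus(12, rng), ("TF_ASSAY",))
    decoy = consensus_pwm("motif_decoy", _random_consensus(12, rng), ("TF_DECOY",))
    if planted:
        arr = bytearray(genome[chrom].encode("ascii"))
        cons = pwm.consensus.encode("ascii")
        for pos in positions[fg_idx]:
            if rng.random() < plant_rate:
                start = int(pos + rng.integers(-plant_halfwidth, plant_halfwidth + 1))
                arr[start:start + len(cons)] = cons
        genome = {chrom: bytes(arr).decode("ascii")}

    m_mock = np.where(rng.random(n_probes) < 0.6,
                      rng.normal(3.0, 0.5, n_probes),
                      rng.normal(-3.0, 0.5, n_probes))
    m_mock[fg_idx] = rng.normal(3.0, 0.5, n_fg)
    shift = np.zeros(n_probes)
    shift[fg_idx] = delta_m
    m_tf = m_mock + shift + rng.normal(0, 0.3, n_probes)
    beta = pd.DataFrame({"mock": m_to_beta(m_mock), "tf": m_to_beta(m_tf)},
                        index=pd.Index(manifest["probe_id"], name="probe_id"))
    return ArrayActivityFixture(GenomeIndex.from_dict(genome), manifest, beta,
                                pwm, decoy, fg_ids)


# ---------------------------------------------------------------------------
# On-disk emission (CLI `simulate`)
# ---------------------------------------------------------------------------

def write_fixture(fixture: WgbsFixture, outdir) -> None:
    """Emit every input file the CLI stages consume, all plain text."""
    from pathlib import Path

    from .io_formats import (write_cpg_calls, write_fasta, write_pwm_collection,
                             write_tf_map, write_tsv)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(fixture.genome, out / "genome.fa")
    with open(out / "chrom.sizes", "wt") as fh:
        for chrom, size in fixture.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    write_cpg_calls(fixture.ref_calls, out / "ref_calls.tsv")
    write_cpg_calls(fixture.tgt_calls, out / "target_calls.tsv")
    write_pwm_collection(fixture.pwms, out / "motifs.pwm")
    write_tf_map(fixture.pwms, out / "motif_tf_map.tsv")
    fixture.expression.reset_index().to_csv(out / "expression.tsv", sep="\t",
                                            index=False, lineterminator="\n")
    write_tsv(fixture.planted_bins, out / "truth_bins.tsv")
    write_tsv(fixture.motif_truth, out / "truth_motifs.tsv")


MINI_SPEC = FixtureSpec(genome_length=240_000, n_demeth_bins=80, n_meth_bins=20,
                        n_decoys=5)

PRESETS = {"default": FixtureSpec(), "mini": MINI_SPEC}
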