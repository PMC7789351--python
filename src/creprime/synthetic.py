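"""Synthetic genome, gene models, peak lists and expression table generator.

The generator emulates the study design the pipeline targets: six cell
types (one multipotent stem population and five unipotent lineages) with
planted peak-sharing structure:

* ``common_all`` peaks accessible in all six cell types;
* ``exclusive_<stem>_<L>`` peaks accessible in the stem population and one
  lineage only — the planted primed CREs, placed in non-promoter space
  inside the regulatory domain of a target gene whose expression is
  restricted to that lineage, with the lineage's motif consensus written
  into the genome at the peak center at a configurable rate;
* ``lineage_unique_<L>`` / ``stem_unique`` peaks accessible in one cell
  type only;
* ``promoter_<gene>`` peaks overlapping the TSS window of a gene,
  accessible wherever the gene is expressed;
* ``background`` peaks accessible in a random subset of >= 3 cell types.

Generation is truth-first: class labels, coordinates and sequence edits
are drawn before any file is emitted, and the returned
:class:`SyntheticTruth` records the clean (pre-noise) structure so
downstream evaluation never depends on re-inference.  All randomness flows
from a single seed; identical parameters yield byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import RegulatoryDomain, build_regulatory_domains
from .core import (
    CELL_TYPES,
    LINEAGES,
    STEM,
    AnalysisConfig,
    ExpressionTable,
    GeneModel,
    Peak,
    PeakSet,
    PWM,
    pwm_from_counts,
)
from . import io as cio


class CapacityError(RuntimeError):
    """Requested structure does not fit in the synthetic genome."""


@dataclass
class SyntheticParams:
    """Knobs of the synthetic study.

    Defaults describe a compact two-chromosome 2 Mb genome with 60 genes
    and a few hundred planted peaks — small enough to regenerate in
    seconds, large enough that every downstream stage sees non-trivial
    structure.  `n_exclusive_per_lineage` may be a single int or a
    {lineage: count} mapping (e.g. to give one lineage extra peaks shared
    with the stem population).
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 60
    n_common_peaks: int = 80
    n_exclusive_per_lineage: int | Mapping[str, int] = 15
    n_unique_per_lineage: int = 20
    n_stem_unique: int = 20
    n_background: int = 60
    promoter_peak_fraction: float = 0.3
    peak_width: tuple[int, int] = (150, 300)
    motif_planting_rate: float = 0.9
    fragment_depth: int = 5
    fragment_length: int = 80
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_chroms, self.n_genes, self.n_common_peaks,
            self.n_unique_per_lineage, self.n_stem_unique, self.n_background,
            self.fragment_depth,
        ]
        counts.extend(self.exclusive_counts().values())
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for rate in (self.promoter_peak_fraction, self.motif_planting_rate, self.noise_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.peak_width[0] < 20 or self.peak_width[0] > self.peak_width[1]:
            raise ValueError("peak widths must be >= 20 bp and min <= max")
        if self.n_chroms * self.chrom_length < 10 * self.n_genes * 3000:
            raise CapacityError(
                "genome too small: need total length >= 10 * n_genes * 3000 bp"
            )

    def exclusive_counts(self) -> dict[str, int]:
        if isinstance(self.n_exclusive_per_lineage, Mapping):
            unknown = set(self.n_exclusive_per_lineage) - set(LINEAGES)
            if unknown:
                raise ValueError(f"unknown lineages {sorted(unknown)}")
            return {L: int(self.n_exclusive_per_lineage.get(L, 0)) for L in LINEAGES}
        return {L: int(self.n_exclusive_per_lineage) for L in LINEAGES}

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic run (clean, pre-noise labels)."""

    peak_class: dict[str, str]
    intervals: dict[str, tuple[str, int, int]]
    clean_presence: pd.DataFrame  # peak name x cell type, bool
    planted_motifs: dict[str, list[str]]
    target_gene: dict[str, str]
    primed: dict[str, list[tuple[str, str]]]  # lineage -> [(peak, gene)]
    expression: ExpressionTable

    def exclusive_names(self, lineage: str) -> set[str]:
        key = f"exclusive_{STEM}_{lineage}"
        return {n for n, c in self.peak_class.items() if c == key}

    def primed_names(self, lineage: str) -> set[str]:
        return {name for name, _ in self.primed.get(lineage, [])}


# ---------------------------------------------------------------------------
# placement helpers

import bisect as _bisect


class _Occupancy:
    """Disjoint blocked intervals per chromosome, with a safety gap."""

    def __init__(self, gap: int = 10) -> None:
        self.gap = gap
        self._chrom: dict[str, tuple[list[int], list[int]]] = {}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        starts, ends = self._chrom.setdefault(chrom, ([], []))
        i = _bisect.bisect_left(starts, end + self.gap)
        return not (i > 0 and ends[i - 1] + self.gap > start)

    def block(self, chrom: str, start: int, end: int) -> None:
        starts, ends = self._chrom.setdefault(chrom, ([], []))
        i = _bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


class _ForbiddenZones:
    """Promoter-window exclusion zones for non-promoter peak placement.

    Zones are TSS windows widened on the left by the maximum peak width, so
    a single point query on the peak start suffices.  Zones may overlap, so
    membership uses a running maximum of zone ends.
    """

    def __init__(self, genes: Sequence[GeneModel], halfwidth: int, max_width: int) -> None:
        self._zones: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            per_chrom.setdefault(g.chrom, []).append(
                (g.tss - halfwidth - max_width, g.tss + halfwidth)
            )
        for chrom, zones in per_chrom.items():
            zones.sort()
            starts = np.array([z[0] for z in zones], dtype=np.int64)
            ends = np.maximum.accumulate([z[1] for z in zones])
            self._zones[chrom] = (starts, ends)

    def allows(self, chrom: str, start: int) -> bool:
        entry = self._zones.get(chrom)
        if entry is None:
            return True
        starts, max_ends = entry
        i = int(np.searchsorted(starts, start, side="right"))
        return not (i > 0 and max_ends[i - 1] > start)


# ---------------------------------------------------------------------------
# default motif set

_LINEAGE_CONSENSUS = {
    "MkP": ("RUNX1", "TGTGGTTT"),
    "EP": ("GATA1", "AGATAAGA"),
    "GM": ("CEBPA", "TTGCGCAA"),
    "B": ("CTCF", "CCACCAGG"),
    "T": ("TCF7", "CTTTGTTC"),
}
_DECOY_CONSENSUS = {
    "KLF4": "GGGGTGGG",
    "NFE2": "TGACTCAG",
    "SPI1": "GAGGAAGT",
}


def consensus_pwm(motif_id: str, consensus: str, strength: int = 20) -> PWM:
    """A sharp PWM whose argmax per column spells the given consensus."""
    counts = np.zeros((4, len(consensus)))
    for j, base in enumerate(consensus.upper()):
        counts["ACGT".index(base), j] = strength
    return pwm_from_counts(motif_id, counts)


def default_lineage_pwms() -> tuple[list[PWM], dict[str, str]]:
    """The built-in motif panel and the lineage -> motif-id designation.

    Motifs are named after transcription factors characteristic of each
    hematopoietic lineage, plus three decoys that are never planted.
    """
    pwms = [consensus_pwm(mid, cons) for mid, cons in _LINEAGE_CONSENSUS.values()]
    pwms.extend(consensus_pwm(mid, cons) for mid, cons in _DECOY_CONSENSUS.items())
    lineage_motifs = {L: _LINEAGE_CONSENSUS[L][0] for L in LINEAGES}
    return pwms, lineage_motifs


# ---------------------------------------------------------------------------
# genome + genes

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_genome(
    params: SyntheticParams, rng: np.random.Generator | None = None
) -> tuple[dict[str, bytearray], list[GeneModel]]:
    """Random i.i.d. A/C/G/T chromosomes with non-overlapping gene bodies.

    Genes are packed into per-chromosome slots (round-robin) so bodies can
    never collide; strands are random; each gene gets 2-4 equal-width
    exons with the remainder as introns.  Deterministic under the seed.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    genome: dict[str, bytearray] = {}
    for chrom in params.chrom_names():
        codes = rng.integers(0, 4, size=params.chrom_length)
        genome[chrom] = bytearray(_BASE_BYTES[codes].tobytes())

    genes: list[GeneModel] = []
    if params.n_genes == 0:
        return genome, genes
    margin = 5000
    body_min, body_max = 3000, 6000
    per_chrom = [params.n_genes // params.n_chroms] * params.n_chroms
    for i in range(params.n_genes % params.n_chroms):
        per_chrom[i] += 1
    gene_no = 0
    for chrom, k in zip(params.chrom_names(), per_chrom):
        if k == 0:
            continue
        usable = params.chrom_length - 2 * margin
        slot = usable // k
        if slot < body_max + 2000:
            raise CapacityError(
                f"cannot pack {k} gene bodies into {chrom} without overlap"
            )
        for s in range(k):
            body_len = int(rng.integers(body_min, body_max + 1))
            slot_start = margin + s * slot
            start = slot_start + int(rng.integers(0, slot - body_len + 1))
            end = start + body_len
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 5))
            bounds = np.linspace(start, end, 2 * n_ex, dtype=int)
            exons = tuple(
                (int(bounds[2 * j]), int(bounds[2 * j + 1])) for j in range(n_ex)
            )
            tss, tts = (start, end) if strand == "+" else (end, start)
            gene_no += 1
            genes.append(
                GeneModel(f"gene_{gene_no:04d}", chrom, strand, tss, tts, exons)
            )
    return genome, genes


# ---------------------------------------------------------------------------
# peak lists, expression, fragments, truth


def _sample_interval(
    rng: np.random.Generator,
    params: SyntheticParams,
    occupancy: _Occupancy,
    forbidden: _ForbiddenZones | None,
    chroms: Sequence[str],
    region: tuple[str, int, int] | None = None,
    retries: int = 2000,
) -> tuple[str, int, int]:
    wmin, wmax = params.peak_width
    for _ in range(retries):
        width = int(rng.integers(wmin, wmax + 1))
        if region is None:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            lo, hi = 0, params.chrom_length - width
        else:
            chrom, rs, re = region
            lo, hi = max(0, rs), min(params.chrom_length, re) - width
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        if forbidden is not None and not forbidden.allows(chrom, start):
            continue
        if occupancy.is_free(chrom, start, start + width):
            occupancy.block(chrom, start, start + width)
            return chrom, start, start + width
    raise CapacityError("could not place a peak after bounded retries; "
                        "reduce peak counts or enlarge the genome")


def _plant(genome: dict[str, bytearray], chrom: str, center: int, motif: str) -> None:
    start = center - len(motif) // 2
    genome[chrom][start : start + len(motif)] = motif.encode("ascii")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def generate_peaklists(
    params: SyntheticParams,
    genome: dict[str, bytearray],
    genes: Sequence[GeneModel],
    pwms: Sequence[PWM],
    lineage_motifs: Mapping[str, str] | None = None,
    cfg: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, PeakSet], dict[str, PeakSet], ExpressionTable, SyntheticTruth]:
    """Plant the full sharing structure and emit per-cell-type peak lists.

    Returns (peak sets, fragment sets, expression table, truth).  The
    genome is edited in place where motif consensus sequences are planted.
    With noise_rate > 0 each present bit drops out independently with that
    probability (dropout noise); the truth keeps the clean labels.
    """
    cfg = cfg or AnalysisConfig()
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    if lineage_motifs is None:
        lineage_motifs = {L: _LINEAGE_CONSENSUS[L][0] for L in LINEAGES}
    by_id = {p.motif_id: p for p in pwms}
    for L in LINEAGES:
        if lineage_motifs.get(L) not in by_id:
            raise ValueError(f"pwms missing designated motif for lineage {L}")

    chroms = params.chrom_names()
    chrom_lengths = {c: params.chrom_length for c in chroms}
    ct_index = {ct: i for i, ct in enumerate(CELL_TYPES)}

    # --- expression patterns: reserve lineage-restricted target genes
    gene_ids = [g.gene_id for g in genes]
    shuffled = list(gene_ids)
    rng.shuffle(shuffled)
    targets_per_lineage = max(1, min(4, len(genes) // 15)) if genes else 0
    lineage_targets: dict[str, list[str]] = {}
    cursor = 0
    excl_counts = params.exclusive_counts()
    for L in LINEAGES:
        take = min(targets_per_lineage, max(0, len(shuffled) - cursor))
        if take == 0 and excl_counts[L] > 0:
            raise CapacityError("not enough genes to assign lineage-restricted targets")
        lineage_targets[L] = shuffled[cursor : cursor + take]
        cursor += take
    expression_patterns: dict[str, list[str]] = {}
    for L, targets in lineage_targets.items():
        for g in targets:
            expression_patterns[g] = [L]
    for g in shuffled[cursor:]:
        if rng.random() < 0.5:
            expression_patterns[g] = list(CELL_TYPES)  # housekeeping
        else:
            size = int(rng.integers(3, 6))
            picks = rng.choice(len(CELL_TYPES), size=size, replace=False)
            expression_patterns[g] = [CELL_TYPES[i] for i in sorted(picks)]
    expression = ExpressionTable.from_dict(
        {g: expression_patterns[g] for g in gene_ids}, CELL_TYPES
    )

    domains = {
        d.gene_id: d
        for d in build_regulatory_domains(genes, cfg, chrom_lengths)
    }

    occupancy = _Occupancy(gap=10)
    forbidden = _ForbiddenZones(genes, cfg.promoter_halfwidth, params.peak_width[1])

    peak_class: dict[str, str] = {}
    intervals: dict[str, tuple[str, int, int]] = {}
    presence_rows: list[np.ndarray] = []
    names: list[str] = []
    planted_motifs: dict[str, list[str]] = {}
    target_gene: dict[str, str] = {}
    primed: dict[str, list[tuple[str, str]]] = {L: [] for L in LINEAGES}

    def add(name: str, cls: str, iv: tuple[str, int, int], present: Sequence[str]) -> None:
        names.append(name)
        peak_class[name] = cls
        intervals[name] = iv
        row = np.zeros(len(CELL_TYPES), dtype=bool)
        for ct in present:
            row[ct_index[ct]] = True
        presence_rows.append(row)

    for i in range(params.n_common_peaks):
        iv = _sample_interval(rng, params, occupancy, forbidden, chroms)
        add(f"common_{i:04d}", "common_all", iv, CELL_TYPES)

    for i in range(params.n_stem_unique):
        iv = _sample_interval(rng, params, occupancy, forbidden, chroms)
        add(f"stemu_{i:04d}", "stem_unique", iv, (STEM,))

    for L in LINEAGES:
        for i in range(params.n_unique_per_lineage):
            iv = _sample_interval(rng, params, occupancy, forbidden, chroms)
            add(f"uniq_{L}_{i:04d}", f"lineage_unique_{L}", iv, (L,))

    for i in range(params.n_background):
        iv = _sample_interval(rng, params, occupancy, forbidden, chroms)
        size = int(rng.integers(3, 6))
        picks = rng.choice(len(CELL_TYPES), size=size, replace=False)
        add(f"bg_{i:04d}", "background", iv, [CELL_TYPES[j] for j in sorted(picks)])

    for L in LINEAGES:
        motif = by_id[lineage_motifs[L]]
        cons = motif.consensus()
        targets = lineage_targets[L]
        for i in range(excl_counts[L]):
            gene = targets[i % len(targets)]
            d = domains[gene]
            region = (d.chrom, d.ext_start, d.ext_end)
            iv = _sample_interval(rng, params, occupancy, forbidden, chroms, region)
            name = f"excl_{L}_{i:04d}"
            add(name, f"exclusive_{STEM}_{L}", iv, (STEM, L))
            target_gene[name] = gene
            primed[L].append((name, gene))
            if rng.random() < params.motif_planting_rate:
                seq = cons if rng.random() < 0.5 else cons.translate(_COMPLEMENT)[::-1]
                chrom, s, e = iv
                _plant(genome, chrom, (s + e) // 2, seq)
                planted_motifs[name] = [motif.motif_id]

    # promoter peaks: enough to make up promoter_peak_fraction of all peaks
    n_nonprom = len(names)
    pf = params.promoter_peak_fraction
    n_prom = int(round(pf / (1.0 - pf) * n_nonprom)) if pf < 1 else 0
    if n_prom and not genes:
        raise CapacityError("promoter peaks requested but no genes generated")
    gi = 0
    placed = 0
    attempts = 0
    while placed < n_prom:
        if attempts > 50 * n_prom:
            raise CapacityError("cannot fit requested promoter peaks in TSS windows")
        gene = genes[gi % len(genes)]
        gi += 1
        attempts += 1
        hw = cfg.promoter_halfwidth
        wmin, wmax = params.peak_width
        width = int(rng.integers(wmin, min(wmax, 2 * hw - 1) + 1))
        lo = max(0, gene.tss - hw)
        hi = min(params.chrom_length, gene.tss + hw) - width
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        if not occupancy.is_free(gene.chrom, start, start + width):
            continue
        occupancy.block(gene.chrom, start, start + width)
        name = f"prom_{gene.gene_id}_{placed:04d}"
        add(
            name,
            f"promoter_{gene.gene_id}",
            (gene.chrom, start, start + width),
            expression_patterns[gene.gene_id],
        )
        target_gene[name] = gene.gene_id
        placed += 1

    clean = pd.DataFrame(
        np.array(presence_rows, dtype=bool).reshape(len(names), len(CELL_TYPES)),
        index=names,
        columns=list(CELL_TYPES),
    )

    # dropout noise: each present bit is lost independently with prob
    # noise_rate, emulating a peak caller missing a truly accessible site
    drop = rng.random(clean.shape) < params.noise_rate
    noisy = clean.to_numpy() & ~drop

    scores = np.round(rng.uniform(50, 950, size=clean.shape), 2)
    peaksets: dict[str, PeakSet] = {}
    fragments: dict[str, PeakSet] = {}
    for c, ct in enumerate(CELL_TYPES):
        peaks = []
        frags = []
        for r, name in enumerate(names):
            if not noisy[r, c]:
                continue
            chrom, s, e = intervals[name]
            peaks.append(Peak(chrom, s, e, name, float(scores[r, c])))
            flen = min(params.fragment_length, e - s)
            for k in range(params.fragment_depth):
                fs = int(rng.integers(s, e - flen + 1))
                frags.append(Peak(chrom, fs, fs + flen, f"frag_{name}_{k}", 0.0))
        peaksets[ct] = PeakSet(ct, peaks)
        fragments[ct] = PeakSet(ct, frags)

    truth = SyntheticTruth(
        peak_class=peak_class,
        intervals=intervals,
        clean_presence=clean,
        planted_motifs=planted_motifs,
        target_gene=target_gene,
        primed=primed,
        expression=expression,
    )
    return peaksets, fragments, expression, truth


# ---------------------------------------------------------------------------
# one-call bundle + on-disk emission


@dataclass
class SyntheticDataset:
    params: SyntheticParams
    genome: dict[str, bytearray]
    genes: list[GeneModel]
    peaksets: dict[str, PeakSet]
    fragments: dict[str, PeakSet]
    expression: ExpressionTable
    truth: SyntheticTruth
    pwms: list[PWM] = field(default_factory=list)
    lineage_motifs: dict[str, str] = field(default_factory=dict)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def generate_dataset(
    params: SyntheticParams,
    pwms: Sequence[PWM] | None = None,
    lineage_motifs: Mapping[str, str] | None = None,
    cfg: AnalysisConfig | None = None,
) -> SyntheticDataset:
    """Generate genome, genes and peak lists in one deterministic call."""
    if pwms is None:
        pwms, default_map = default_lineage_pwms()
        lineage_motifs = lineage_motifs or default_map
    genome, genes = generate_genome(params)
    peaksets, fragments, expression, truth = generate_peaklists(
        params, genome, genes, pwms, lineage_motifs, cfg
    )
    return SyntheticDataset(
        params, genome, genes, peaksets, fragments, expression, truth,
        list(pwms), dict(lineage_motifs or {}),
    )


def write_synthetic_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Emit the dataset in the same formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_fasta(dataset.genome, outdir / "genome.fa")
    cio.write_gene_table(dataset.genes, outdir / "genes.tsv")
    cio.write_expression_table(dataset.expression, outdir / "expression.tsv")
    cio.write_pwm_jaspar(dataset.pwms, outdir / "motifs.jaspar")
    for ct, ps in dataset.peaksets.items():
        cio.write_bed(ps, outdir / f"{ct}.peaks.bed")
    for ct, ps in dataset.fragments.items():
        cio.write_bed(ps, outdir / f"{ct}.fragments.bed")
    truth = dataset.truth
    payload = {
        "peak_class": truth.peak_class,
        "intervals": {k: list(v) for k, v in truth.intervals.items()},
        "planted_motifs": truth.planted_motifs,
        "target_gene": truth.target_gene,
        "primed": {L: [list(t) for t in v] for L, v in truth.primed.items()},
        "lineage_motifs": dataset.lineage_motifs,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


__all__ = [
    "CapacityError",
    "SyntheticParams",
    "SyntheticTruth",
    "SyntheticDataset",
    "consensus_pwm",
    "default_lineage_pwms",
    "generate_genome",
    "generate_peaklists",
    "generate_dataset",
    "write_synthetic_dataset",
]
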