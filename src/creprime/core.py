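"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open (BED convention) everywhere; readers for
1-based sources must convert at the boundary.  Peak scores are monotone
significance values (higher = more significant); any positive scale is
accepted.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical cell-type order: the multipotent stem population first, then the
#: five unipotent/mature lineages (megakaryocyte progenitor, erythroid
#: progenitor, granulocyte/macrophage, B lymphocyte, T lymphocyte).
CELL_TYPES: tuple[str, ...] = ("HSC", "MkP", "EP", "GM", "B", "T")
STEM: str = "HSC"
LINEAGES: tuple[str, ...] = CELL_TYPES[1:]

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class Peak:
    """A scored genomic interval (one line of a BED6 record)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.name or '?'}: start must be < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.score < 0:
            raise ValueError(f"peak {self.name or '?'}: score must be >= 0")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"peak {self.name or '?'}: bad strand {self.strand!r}")
        if not self.name:
            object.__setattr__(self, "name", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.name)


class PeakSet:
    """An ordered collection of peaks for one cell type.

    Peaks are kept sorted by (chrom, start, end, name) and names must be
    unique within the set.
    """

    def __init__(self, cell_type: str, peaks: Iterable[Peak] = ()) -> None:
        self.cell_type = cell_type
        self.peaks: list[Peak] = sorted(peaks, key=Peak.sort_key)
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate peak name {dup!r} in set {cell_type!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.cell_type == other.cell_type and self.peaks == other.peaks

    def __repr__(self) -> str:
        return f"PeakSet({self.cell_type!r}, n={len(self)})"

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def filtered(self, min_score_quantile: float | None) -> "PeakSet":
        """Keep peaks whose score is at or above the given quantile.

        Stands in for upstream significance filtering of input peak lists.
        """
        if min_score_quantile is None or not self.peaks:
            return self
        cut = float(np.quantile([p.score for p in self.peaks], min_score_quantile))
        return PeakSet(self.cell_type, (p for p in self.peaks if p.score >= cut))


@dataclass(frozen=True)
class GeneModel:
    """One gene: strand-aware TSS/TTS plus its exon structure.

    For "+" genes tss < tts; for "-" genes tss > tts (the TSS is the
    transcription start in genome coordinates, so it sits at the high end of
    a minus-strand gene body).  Exons are half-open, sorted, non-overlapping
    and contained in the gene body.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tts")
        lo, hi = self.body_start, self.body_end
        prev = lo
        for s, e in self.exons:
            if s >= e or s < prev or e > hi:
                raise ValueError(
                    f"gene {self.gene_id}: bad exon ({s},{e}) for body [{lo},{hi})"
                )
            prev = e

    @property
    def body_start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def body_end(self) -> int:
        return max(self.tss, self.tts)


@dataclass
class AnalysisConfig:
    """All fixed analysis parameters, in base pairs unless noted.

    promoter_halfwidth
        Promoter window is [TSS - w, TSS + w) (default 500 bp).
    hist_window / hist_bin
        Signal-profile window around peak centers and its bin width.
    basal_upstream / basal_downstream / max_extension
        Basal-plus-extension regulatory-domain rule (2 kb / 1 kb / 1 Mb).
    alpha_promoter_test
        Significance level for the promoter-depletion test.
    top_k_motifs
        How many enrichment results to report, ranked by p-value.
    tts_flank
        Half-width of the transcription-termination flank folded into the
        "coding" annotation category.
    motif_threshold_fraction
        A motif hit requires a log-odds score of at least this fraction of
        the matrix's maximum attainable score.
    strict_lineage_restriction
        If True (default), "expressed only in lineage L" additionally
        requires absence of expression in the stem population.
    """

    promoter_halfwidth: int = 500
    hist_window: tuple[int, int] = (-500, 500)
    hist_bin: int = 5
    basal_upstream: int = 2000
    basal_downstream: int = 1000
    max_extension: int = 1_000_000
    alpha_promoter_test: float = 0.001
    top_k_motifs: int = 10
    score_filter_quantile: float | None = None
    rng_seed: int = 0
    tts_flank: int = 250
    motif_threshold_fraction: float = 0.8
    strict_lineage_restriction: bool = True

    def __post_init__(self) -> None:
        for attr in ("promoter_halfwidth", "hist_bin", "basal_upstream",
                     "basal_downstream", "max_extension", "tts_flank"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        lo, hi = self.hist_window
        if lo != -hi or hi <= 0:
            raise ValueError("hist_window must be symmetric around 0")
        if (hi - lo) % self.hist_bin != 0:
            raise ValueError("hist_window span must be divisible by hist_bin")
        if not 0 < self.alpha_promoter_test < 1:
            raise ValueError("alpha_promoter_test must be in (0, 1)")
        if not 0 < self.motif_threshold_fraction <= 1:
            raise ValueError("motif_threshold_fraction must be in (0, 1]")
        if self.score_filter_quantile is not None and not (
            0 <= self.score_filter_quantile < 1
        ):
            raise ValueError("score_filter_quantile must be in [0, 1)")

    def with_updates(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


class ExpressionTable:
    """Binary gene-by-cell-type expression flags.

    Emulates normalized expression-database patterns collapsed to
    expressed / not-expressed per cell type.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        if frame.index.has_duplicates:
            raise ValueError("duplicate gene_id in expression table")
        self.frame = frame.astype(bool)

    @classmethod
    def from_dict(
        cls, patterns: Mapping[str, Iterable[str]], cell_types: Sequence[str] = CELL_TYPES
    ) -> "ExpressionTable":
        """Build from {gene_id: iterable of cell types where expressed}."""
        rows = {
            g: [ct in set(cts) for ct in cell_types] for g, cts in patterns.items()
        }
        return cls(pd.DataFrame.from_dict(rows, orient="index", columns=list(cell_types)))

    @property
    def cell_types(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    def is_expressed(self, gene_id: str, cell_type: str) -> bool:
        if cell_type not in self.frame.columns:
            raise KeyError(f"cell type {cell_type!r} not in expression table")
        if gene_id not in self.frame.index:
            return False
        return bool(self.frame.at[gene_id, cell_type])

    def expressed_in(self, gene_id: str) -> set[str]:
        if gene_id not in self.frame.index:
            return set()
        row = self.frame.loc[gene_id]
        return set(row.index[row])

    def restricted_to(
        self,
        gene_id: str,
        lineage: str,
        lineages: Sequence[str] = LINEAGES,
        stem: str = STEM,
        strict: bool = True,
    ) -> bool:
        """True iff the gene is expressed in `lineage` and in no other lineage.

        With strict=True, expression in the stem population also disqualifies.
        """
        expressed = self.expressed_in(gene_id)
        if lineage not in expressed:
            return False
        others = set(lineages) - {lineage}
        if expressed & others:
            return False
        if strict and stem in expressed:
            return False
        return True


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-column base probabilities (rows A,C,G,T)."""

    motif_id: str
    matrix: np.ndarray = field(repr=False)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25), repr=False
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", np.asarray(self.background, float))
        if m.shape[0] != 4 or m.shape[1] < 4:
            raise ValueError(f"PWM {self.motif_id}: need a 4 x L (L >= 4) matrix")
        colsums = m.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: columns must sum to 1")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PWM):
            return NotImplemented
        return (
            self.motif_id == other.motif_id
            and self.matrix.shape == other.matrix.shape
            and np.allclose(self.matrix, other.matrix)
            and np.allclose(self.background, other.background)
        )

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """4 x L log2(p / background) matrix; zero probabilities map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background[:, None])

    def max_score(self) -> float:
        """Maximum attainable log-odds score (bits)."""
        return float(self.log_odds().max(axis=0).sum())


def pwm_from_counts(
    motif_id: str, counts: np.ndarray, pseudocount: float = 1.0
) -> PWM:
    """Build a PWM from a 4 x L count matrix with a per-cell pseudocount."""
    c = np.asarray(counts, dtype=float) + pseudocount
    if (c <= 0).any():
        raise ValueError(f"PWM {motif_id}: negative counts")
    return PWM(motif_id, c / c.sum(axis=0, keepdims=True))
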