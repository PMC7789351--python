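"""Peak annotation relative to gene models.

Each peak falls into exactly one category with precedence
promoter > coding > intron > intergenic:

* promoter — overlaps [TSS - w, TSS + w) of any gene (w = 500 bp default);
* coding — overlaps any exon or a +/- `tts_flank` window around a TTS;
* intron — overlaps a gene body but no exon;
* intergenic — none of the above.

Distances to the nearest TSS are measured from the peak midpoint and signed
by gene strand (negative = upstream of the TSS).
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AnalysisConfig, GeneModel, Peak, PeakSet

CATEGORIES = ("promoter", "coding", "intron", "intergenic")


@dataclass(frozen=True)
class AnnotationRecord:
    peak_name: str
    category: str
    nearest_gene: str | None
    tss_distance: int | None  # signed, bp; None when no genes exist


class _GeneIndex:
    """Per-chromosome interval arrays for the four category tests."""

    def __init__(self, genes: Sequence[GeneModel], cfg: AnalysisConfig) -> None:
        self.cfg = cfg
        self.promoter: dict[str, list[tuple[int, int]]] = {}
        self.coding: dict[str, list[tuple[int, int]]] = {}
        self.body: dict[str, list[tuple[int, int]]] = {}
        self.tss: dict[str, list[tuple[int, str, str]]] = {}  # (pos, gene, strand)
        w = cfg.promoter_halfwidth
        f = cfg.tts_flank
        for g in genes:
            self.promoter.setdefault(g.chrom, []).append((g.tss - w, g.tss + w))
            self.tss.setdefault(g.chrom, []).append((g.tss, g.gene_id, g.strand))
            coding = self.coding.setdefault(g.chrom, [])
            coding.extend(g.exons)
            coding.append((g.tts - f, g.tts + f))
            self.body.setdefault(g.chrom, []).append((g.body_start, g.body_end))
        for d in (self.promoter, self.coding, self.body):
            for ivs in d.values():
                ivs.sort()
        self._tss_sorted: dict[str, tuple[np.ndarray, list[tuple[int, str, str]]]] = {}
        for chrom, entries in self.tss.items():
            entries.sort()
            self._tss_sorted[chrom] = (
                np.array([t[0] for t in entries], dtype=np.int64),
                entries,
            )

    @staticmethod
    def _hits(intervals: list[tuple[int, int]] | None, start: int, end: int) -> bool:
        if not intervals:
            return False
        # intervals may overlap each other (exons of different genes), so a
        # linear scan over start-sorted candidates is used; per-chromosome
        # lists are short at the scales this package targets
        i = bisect.bisect_left(intervals, (end, end))
        return any(e > start for _, e in intervals[:i])

    def nearest_tss(self, chrom: str, pos: int) -> tuple[str, int] | None:
        entry = self._tss_sorted.get(chrom)
        if entry is None:
            return None
        positions, entries = entry
        i = int(np.searchsorted(positions, pos))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(entries):
                tss, gene, strand = entries[j]
                dist = pos - tss if strand == "+" else tss - pos
                if best is None or abs(dist) < abs(best[1]):
                    best = (gene, dist)
        return best


def classify_peak(
    peak: Peak, genes: Sequence[GeneModel] | _GeneIndex, cfg: AnalysisConfig
) -> AnnotationRecord:
    """Classify one peak; precedence promoter > coding > intron > intergenic."""
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes, cfg)
    s, e, chrom = peak.start, peak.end, peak.chrom
    if index._hits(index.promoter.get(chrom), s, e):
        category = "promoter"
    elif index._hits(index.coding.get(chrom), s, e):
        category = "coding"
    elif index._hits(index.body.get(chrom), s, e):
        category = "intron"
    else:
        category = "intergenic"
    nearest = index.nearest_tss(chrom, peak.midpoint)
    gene, dist = nearest if nearest else (None, None)
    return AnnotationRecord(peak.name, category, gene, dist)


def annotate_peakset(
    peaks: PeakSet, genes: Sequence[GeneModel], cfg: AnalysisConfig | None = None
) -> tuple[pd.Series, list[AnnotationRecord]]:
    """Annotate every peak; returns (category counts, per-peak records).

    The counts are an exhaustive disjoint partition: they always sum to the
    number of input peaks.
    """
    cfg = cfg or AnalysisConfig()
    index = _GeneIndex(genes, cfg)
    records = [classify_peak(p, index, cfg) for p in peaks]
    counts = pd.Series(0, index=list(CATEGORIES), dtype=int)
    for r in records:
        counts[r.category] += 1
    counts["total"] = len(records)
    return counts, records


def promoter_fraction(
    peaks: PeakSet, genes: Sequence[GeneModel], cfg: AnalysisConfig | None = None
) -> float:
    """Fraction of peaks classified as promoter; errors on an empty set."""
    if len(peaks) == 0:
        raise ValueError("promoter_fraction is undefined for an empty peak set; "
                         "handle empty inputs upstream")
    counts, _ = annotate_peakset(peaks, genes, cfg)
    return counts["promoter"] / counts["total"]


__all__ = [
    "CATEGORIES",
    "AnnotationRecord",
    "classify_peak",
    "annotate_peakset",
    "promoter_fraction",
]
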