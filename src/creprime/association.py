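"""Regulatory-domain gene association and priming calls.

Gene association follows the basal-plus-extension rule: each gene gets a
strand-aware basal domain (2 kb upstream, 1 kb downstream of the TSS),
extended outward on each side until the nearest neighboring basal domain or
a 1 Mb cap, clipped to the chromosome.  A peak is associated with every
gene whose extended domain it overlaps.

A primed cis-regulatory element (CRE) for lineage L is a non-promoter
master peak accessible exclusively in the stem population and L, with at
least one associated gene whose expression is restricted to L.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .annotation import AnnotationRecord
from .core import (
    LINEAGES,
    STEM,
    AnalysisConfig,
    ExpressionTable,
    GeneModel,
    Peak,
    PeakSet,
)
from .intervals import MasterPeakList, build_master_list, exclusive_shared, overlap_pairs


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    basal_start: int
    basal_end: int
    ext_start: int
    ext_end: int

    def __post_init__(self) -> None:
        if not (self.ext_start <= self.basal_start < self.basal_end <= self.ext_end):
            raise ValueError(f"domain {self.gene_id}: basal not contained in extended")


def _basal(gene: GeneModel, cfg: AnalysisConfig) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tss - cfg.basal_upstream, gene.tss + cfg.basal_downstream
    return gene.tss - cfg.basal_downstream, gene.tss + cfg.basal_upstream


def build_regulatory_domains(
    genes: Sequence[GeneModel],
    cfg: AnalysisConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension domains for every gene.

    Extension on each side stops at the nearest neighboring basal boundary,
    at `max_extension` from the basal edge, or at the chromosome edge,
    whichever comes first.  Only basal domains block extension; extended
    domains may overlap freely.  Genes sharing a TSS are kept (tie-broken
    by gene_id order) with a warning.
    """
    cfg = cfg or AnalysisConfig()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    domains: list[RegulatoryDomain] = []
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.tss, g.gene_id))
        tss_seen: dict[int, str] = {}
        for g in gs:
            if g.tss in tss_seen:
                warnings.warn(
                    f"genes {tss_seen[g.tss]} and {g.gene_id} share TSS {g.tss} "
                    f"on {chrom}; domains tie-broken by gene_id order",
                    stacklevel=2,
                )
            tss_seen.setdefault(g.tss, g.gene_id)
        basals = [_basal(g, cfg) for g in gs]
        chrom_len = None if chrom_lengths is None else chrom_lengths.get(chrom)
        for i, g in enumerate(gs):
            s, e = basals[i]
            others = [b for j, b in enumerate(basals) if j != i]
            # left: blocked entirely by any basal straddling our start
            if any(os <= s < oe for os, oe in others):
                ext_s = s
            else:
                left_ends = [oe for _, oe in others if oe <= s]
                ext_s = max([s - cfg.max_extension] + left_ends)
            if any(os < e <= oe for os, oe in others):
                ext_e = e
            else:
                right_starts = [os for os, _ in others if os >= e]
                ext_e = min([e + cfg.max_extension] + right_starts)
            ext_s = max(ext_s, 0)
            if chrom_len is not None:
                ext_e = min(ext_e, chrom_len)
            # basal itself is only floored/capped, never shrunk below its span
            bs, be = max(s, 0), e if chrom_len is None else min(e, chrom_len)
            domains.append(
                RegulatoryDomain(g.gene_id, chrom, bs, be, min(ext_s, bs), max(ext_e, be))
            )
    domains.sort(key=lambda d: (d.chrom, d.ext_start, d.gene_id))
    return domains


def associate_peaks(
    peaks: PeakSet | Sequence[Peak], domains: Sequence[RegulatoryDomain]
) -> dict[str, list[str]]:
    """Map each peak name to the genes whose extended domain it overlaps."""
    peak_list = sorted(peaks, key=Peak.sort_key)
    dom_shims = sorted(
        (
            Peak(d.chrom, d.ext_start, d.ext_end, f"dom{i}")
            for i, d in enumerate(domains)
        ),
        key=Peak.sort_key,
    )
    dom_ids = {f"dom{i}": d.gene_id for i, d in enumerate(domains)}
    out: dict[str, list[str]] = {p.name: [] for p in peak_list}
    for i, j in overlap_pairs(peak_list, dom_shims):
        out[peak_list[i].name].append(dom_ids[dom_shims[j].name])
    for name in out:
        out[name].sort()
    return out


@dataclass(frozen=True)
class PrimedCRE:
    peak_name: str
    chrom: str
    start: int
    end: int
    stem: str
    lineage: str
    genes: tuple[str, ...]
    restricted_genes: tuple[str, ...]  # associated genes expressed only in lineage
    motifs: tuple[str, ...] = ()

    @property
    def primed(self) -> bool:
        return len(self.restricted_genes) > 0


def call_primed_cres(
    master: MasterPeakList,
    stem: str,
    lineages: Sequence[str],
    domains: Sequence[RegulatoryDomain],
    expression: ExpressionTable,
    annotation_records: Sequence[AnnotationRecord],
    motif_presence: Mapping[str, pd.DataFrame] | None = None,
    cfg: AnalysisConfig | None = None,
) -> list[PrimedCRE]:
    """Call primed CREs for every (stem, lineage) pair.

    Candidates are the non-promoter peaks exclusively shared between the
    stem population and one lineage; a candidate is primed when at least
    one associated gene is expressed in that lineage and in no other
    lineage (and, with `strict_lineage_restriction`, not in the stem
    either).  `motif_presence` optionally maps lineage -> a boolean
    peaks x motifs frame (that lineage's top enriched motifs); matching
    motifs are listed per CRE.
    """
    cfg = cfg or AnalysisConfig()
    for lineage in lineages:
        if lineage not in expression.cell_types:
            raise ValueError(f"lineage {lineage!r} absent from expression table")
    category = {r.peak_name: r.category for r in annotation_records}
    results: list[PrimedCRE] = []
    for lineage in lineages:
        candidates = exclusive_shared(master, stem, lineage)
        nonpromoter = [p for p in candidates if category.get(p.name) != "promoter"]
        assoc = associate_peaks(nonpromoter, domains)
        presence = None if motif_presence is None else motif_presence.get(lineage)
        for p in nonpromoter:
            genes = tuple(assoc.get(p.name, ()))
            restricted = tuple(
                g
                for g in genes
                if expression.restricted_to(
                    g, lineage, lineages, stem, strict=cfg.strict_lineage_restriction
                )
            )
            if not restricted:
                continue
            motifs: tuple[str, ...] = ()
            if presence is not None and p.name in presence.index:
                row = presence.loc[p.name]
                motifs = tuple(sorted(row.index[row.astype(bool)]))
            results.append(
                PrimedCRE(
                    p.name, p.chrom, p.start, p.end, stem, lineage,
                    genes, restricted, motifs,
                )
            )
    return results


def similarity_matrix(
    peaksets: Mapping[str, PeakSet] | MasterPeakList,
) -> tuple[pd.DataFrame, list[str]]:
    """Jaccard similarity between cell types over master presence bits.

    J(a, b) = |rows with a AND b| / |rows with a OR b|.  Returns the
    symmetric matrix (diagonal 1) and the average-linkage dendrogram leaf
    order, a qualitative stand-in for accessibility-profile clustering.
    """
    master = (
        peaksets if isinstance(peaksets, MasterPeakList) else build_master_list(peaksets)
    )
    labels = list(master.cell_types)
    if len(labels) < 2:
        raise ValueError("similarity_matrix needs >= 2 cell types")
    P = master.presence.astype(bool)
    n = len(labels)
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            union = (P[:, i] | P[:, j]).sum()
            inter = (P[:, i] & P[:, j]).sum()
            J[i, j] = J[j, i] = inter / union if union else 0.0
    frame = pd.DataFrame(J, index=labels, columns=labels)
    dist = squareform(1.0 - J, checks=False)
    linkage = hierarchy.linkage(dist, method="average")
    order = [labels[i] for i in hierarchy.leaves_list(linkage)]
    return frame, order


__all__ = [
    "RegulatoryDomain",
    "build_regulatory_domains",
    "associate_peaks",
    "PrimedCRE",
    "call_primed_cres",
    "similarity_matrix",
]
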