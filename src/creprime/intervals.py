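"""Interval set algebra over peak lists.

Overlap means >= 1 shared base pair at literal coordinates on the same
chromosome.  The master list is built by selection, not fusion: among any
group of transitively overlapping peaks the most significant one is kept
with its original coordinates, mirroring non-overlapping significance
filtering of concatenated peak lists.
"""
from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Peak, PeakSet


def overlaps(a: Peak, b: Peak) -> bool:
    """True iff the two peaks share at least one base pair."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


class _ChromIndex:
    """Existence queries against a static interval set, per chromosome.

    Intervals are sorted by start; a prefix running-maximum of ends answers
    "does anything here overlap [s, e)?" with two binary searches.
    """

    def __init__(self, peaks: Iterable[Peak]) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        per_chrom: dict[str, list[Peak]] = {}
        for p in peaks:
            per_chrom.setdefault(p.chrom, []).append(p)
        for chrom, ps in per_chrom.items():
            ps.sort(key=lambda p: (p.start, p.end))
            starts = np.fromiter((p.start for p in ps), dtype=np.int64, count=len(ps))
            ends = np.fromiter((p.end for p in ps), dtype=np.int64, count=len(ps))
            self._by_chrom[chrom] = (starts, np.maximum.accumulate(ends))

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, max_ends = entry
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and max_ends[i - 1] > start


def overlap_pairs(
    a: Sequence[Peak], b: Sequence[Peak]
) -> Iterator[tuple[int, int]]:
    """Sweep-line enumeration of all overlapping index pairs (i, j).

    Both sequences must be sorted by (chrom, start); runs in
    O(n + m + #overlaps) amortized because each b-interval enters and
    leaves the active list once per a-run that can see it.
    """
    a_by_chrom: dict[str, list[int]] = {}
    b_by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(a):
        a_by_chrom.setdefault(p.chrom, []).append(i)
    for j, p in enumerate(b):
        b_by_chrom.setdefault(p.chrom, []).append(j)
    for chrom, ai in a_by_chrom.items():
        bj = b_by_chrom.get(chrom)
        if not bj:
            continue
        active: list[int] = []
        k = 0
        for i in ai:
            pa = a[i]
            while k < len(bj) and b[bj[k]].start < pa.end:
                active.append(bj[k])
                k += 1
            # prune intervals that can no longer overlap any later a
            # (a is sorted by start, so ends <= pa.start are dead)
            active = [j for j in active if b[j].end > pa.start]
            for j in active:
                # start check is required: a is sorted by start, not end, so
                # an interval admitted for an earlier, longer a may start
                # beyond this a's end
                if b[j].start < pa.end:
                    yield i, j


@dataclass
class MasterPeakList:
    """Non-overlapping union peaks plus a peaks x cell-types presence matrix."""

    peaks: list[Peak]
    cell_types: tuple[str, ...]
    presence: np.ndarray  # bool, shape (n_peaks, n_cell_types)
    provenance: list[dict[str, list[str]]] = field(default_factory=list)
    source: list[str] = field(default_factory=list)  # cell type of each kept peak

    def __post_init__(self) -> None:
        if self.presence.shape != (len(self.peaks), len(self.cell_types)):
            raise ValueError("presence matrix shape mismatch")
        if len(self.peaks) and not self.presence.any(axis=1).all():
            raise ValueError("every master peak must be present somewhere")

    def __len__(self) -> int:
        return len(self.peaks)

    def column(self, cell_type: str) -> np.ndarray:
        return self.presence[:, self.cell_types.index(cell_type)]

    def signature(self, i: int) -> tuple[bool, ...]:
        return tuple(bool(x) for x in self.presence[i])

    def presence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence,
            index=[p.name for p in self.peaks],
            columns=list(self.cell_types),
        )

    def subset(self, mask: np.ndarray) -> PeakSet:
        idx = np.flatnonzero(mask)
        return PeakSet("master_subset", [self.peaks[i] for i in idx])


def build_master_list(peaksets: Mapping[str, PeakSet]) -> MasterPeakList:
    """Select a non-overlapping master peak list from several cell types.

    Greedy by significance: repeatedly keep the highest-scoring remaining
    peak and discard everything overlapping it.  Ties resolve by
    (chrom, start, end, name, cell type) so the result is deterministic and
    independent of input ordering.  The presence bit (p, c) is set iff cell
    type c contributed any peak overlapping kept peak p.
    """
    if not peaksets:
        raise ValueError("build_master_list needs at least one peak set")
    cell_types = tuple(peaksets)
    pool: list[tuple[float, str, int, int, str, str, Peak]] = []
    for label, ps in peaksets.items():
        for p in ps:
            pool.append((-p.score, p.chrom, p.start, p.end, p.name, label, p))
    pool.sort(key=lambda t: t[:6])

    kept: list[tuple[Peak, str]] = []
    kept_intervals: dict[str, tuple[list[int], list[int]]] = {}
    for *_, label, p in pool:
        starts, ends = kept_intervals.setdefault(p.chrom, ([], []))
        i = bisect.bisect_left(starts, p.end)
        # kept intervals are mutually disjoint, so only the predecessor can
        # reach into [start, end)
        if i > 0 and ends[i - 1] > p.start:
            continue
        starts.insert(i, p.start)
        ends.insert(i, p.end)
        kept.append((p, label))

    kept.sort(key=lambda t: t[0].sort_key())
    master_peaks = [
        Peak(p.chrom, p.start, p.end, f"{label}|{p.name}", p.score, p.strand)
        for p, label in kept
    ]
    source = [label for _, label in kept]

    presence = np.zeros((len(master_peaks), len(cell_types)), dtype=bool)
    provenance: list[dict[str, list[str]]] = [dict() for _ in master_peaks]
    for c, label in enumerate(cell_types):
        src = list(peaksets[label])
        for i, j in overlap_pairs(master_peaks, src):
            presence[i, c] = True
            provenance[i].setdefault(label, []).append(src[j].name)
    return MasterPeakList(master_peaks, cell_types, presence, provenance, source)


def source_peak_name(master_name: str) -> str:
    """Strip the cell-type prefix master peaks carry ("HSC|pk3" -> "pk3")."""
    return master_name.split("|", 1)[-1]


def presence_signatures(master: MasterPeakList) -> dict[str, tuple[bool, ...]]:
    """Map master peak name -> boolean presence tuple in cell-type order."""
    return {p.name: master.signature(i) for i, p in enumerate(master.peaks)}


def signature_class_sizes(master: MasterPeakList) -> dict[tuple[bool, ...], int]:
    """Partition of the master list by presence signature (class -> size)."""
    sizes: dict[tuple[bool, ...], int] = {}
    for i in range(len(master)):
        sig = master.signature(i)
        sizes[sig] = sizes.get(sig, 0) + 1
    return sizes


def exclusive_shared(master: MasterPeakList, stem: str, lineage: str) -> PeakSet:
    """Master peaks present in exactly {stem, lineage} and nowhere else."""
    if stem == lineage:
        raise ValueError("stem and lineage must differ")
    for label in (stem, lineage):
        if label not in master.cell_types:
            raise ValueError(f"unknown cell type {label!r}")
    want = np.array([ct in (stem, lineage) for ct in master.cell_types])
    mask = (master.presence == want).all(axis=1)
    ps = master.subset(mask)
    ps.cell_type = f"{stem}_{lineage}_exclusive"
    return ps


def overlap_fraction(query: PeakSet, track: PeakSet) -> tuple[int, float]:
    """(count, fraction) of query peaks overlapping >= 1 track peak."""
    if len(query) == 0:
        warnings.warn("overlap_fraction: empty query set", stacklevel=2)
        return 0, 0.0
    index = _ChromIndex(track)
    count = sum(index.any_overlap(p.chrom, p.start, p.end) for p in query)
    return count, count / len(query)


__all__ = [
    "overlaps",
    "overlap_pairs",
    "MasterPeakList",
    "build_master_list",
    "presence_signatures",
    "signature_class_sizes",
    "source_peak_name",
    "exclusive_shared",
    "overlap_fraction",
]
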