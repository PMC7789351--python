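"""Pairwise gained/lost accounting and fragment signal profiles.

"Gained" and "lost" use the same overlap predicate as the rest of the
package (>= 1 shared bp): a peak in the non-reference cell type with no
overlapping reference peak is gained; a reference peak with no overlap in
the other cell type is lost.  Percentages follow the convention of
normalizing by the non-reference cell type's peak count, and the
gained:lost ratio rescales gained + lost to 100%.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import AnalysisConfig, Peak, PeakSet
from .intervals import _ChromIndex, overlap_pairs


@dataclass(frozen=True)
class GainLossSummary:
    reference: str
    other: str
    n_ref: int
    n_other: int
    gained: int
    lost: int

    @property
    def pct_gained(self) -> float:
        return 100.0 * self.gained / self.n_other

    @property
    def pct_lost(self) -> float:
        return 100.0 * self.lost / self.n_other

    @property
    def pct_altered(self) -> float:
        return self.pct_gained + self.pct_lost

    @property
    def ratio_gained(self) -> float:
        total = self.gained + self.lost
        return 100.0 * self.gained / total if total else float("nan")

    @property
    def ratio_lost(self) -> float:
        total = self.gained + self.lost
        return 100.0 * self.lost / total if total else float("nan")

    def as_row(self) -> dict:
        return {
            "reference": self.reference,
            "other": self.other,
            "n_ref": self.n_ref,
            "n_other": self.n_other,
            "gained": self.gained,
            "lost": self.lost,
            "pct_gained": self.pct_gained,
            "pct_lost": self.pct_lost,
            "pct_altered": self.pct_altered,
            "ratio_gained": self.ratio_gained,
            "ratio_lost": self.ratio_lost,
        }


def gained_lost(ref: PeakSet, other: PeakSet) -> GainLossSummary:
    """Count peaks gained/lost in `other` relative to the reference."""
    if len(other) == 0:
        raise ValueError("gained_lost: `other` must be non-empty (denominator)")
    ref_index = _ChromIndex(ref)
    other_index = _ChromIndex(other)
    gained = sum(
        not ref_index.any_overlap(p.chrom, p.start, p.end) for p in other
    )
    lost = sum(
        not other_index.any_overlap(p.chrom, p.start, p.end) for p in ref
    )
    return GainLossSummary(
        ref.cell_type, other.cell_type, len(ref), len(other), gained, lost
    )


def count_peaks(peaksets: Mapping[str, PeakSet] | Iterable[PeakSet]) -> pd.Series:
    """Peak counts per cell type."""
    if isinstance(peaksets, Mapping):
        items = [(label, len(ps)) for label, ps in peaksets.items()]
    else:
        items = [(ps.cell_type, len(ps)) for ps in peaksets]
    return pd.Series(dict(items), dtype=int, name="n_peaks")


@dataclass
class SignalProfile:
    """Mean per-base fragment coverage in fixed bins around peak centers."""

    bin_centers: np.ndarray  # bp relative to peak midpoint
    values: np.ndarray  # mean coverage depth per bin, averaged over peaks

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "mean_coverage": self.values})


def signal_profile(
    fragments: PeakSet | Iterable[Peak],
    peaks: PeakSet,
    cfg: AnalysisConfig | None = None,
    cutsites: bool = False,
) -> SignalProfile:
    """Average fragment coverage around peak midpoints.

    For each peak, fragment base-pair coverage is accumulated per position
    in a symmetric window about the midpoint, summed per `hist_bin` bin,
    divided by the bin width (coverage depth) and averaged over peaks.
    With cutsites=True only the two fragment end positions are counted
    (insertion-site semantics) instead of whole-fragment spans.
    """
    cfg = cfg or AnalysisConfig()
    if len(peaks) == 0:
        raise ValueError("signal_profile requires at least one peak")
    lo, hi = cfg.hist_window
    span = hi - lo
    nbins = span // cfg.hist_bin
    frag_list = sorted(fragments, key=Peak.sort_key)
    windows = [
        Peak(p.chrom, p.midpoint + lo, p.midpoint + hi, f"w{i}")
        for i, p in enumerate(peaks)
    ]
    windows_sorted = sorted(windows, key=Peak.sort_key)
    pileup = np.zeros(span, dtype=float)
    for wi, fj in overlap_pairs(windows_sorted, frag_list):
        w = windows_sorted[wi]
        f = frag_list[fj]
        if cutsites:
            for pos in (f.start, f.end - 1):
                if w.start <= pos < w.end:
                    pileup[pos - w.start] += 1.0
        else:
            a = max(f.start, w.start) - w.start
            b = min(f.end, w.end) - w.start
            pileup[a:b] += 1.0
    binned = pileup.reshape(nbins, cfg.hist_bin).sum(axis=1)
    values = binned / cfg.hist_bin / len(peaks)
    centers = np.arange(nbins) * cfg.hist_bin + lo + cfg.hist_bin / 2.0
    return SignalProfile(centers, values)


__all__ = ["GainLossSummary", "gained_lost", "count_peaks", "SignalProfile", "signal_profile"]
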