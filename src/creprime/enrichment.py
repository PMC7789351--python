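"""PWM motif scanning and motif enrichment against a custom background.

Scanning scores every window on both strands with log2-odds against a
uniform base background; a hit requires at least `motif_threshold_fraction`
of the matrix's maximum attainable score.  Enrichment of a target peak set
versus a background peak set uses a one-sided hypergeometric (Fisher) test
on per-peak hit presence, with Benjamini-Hochberg q-values added; ranking
uses the raw p-value.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, Peak, PeakSet, PWM
from .intervals import _ChromIndex

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


def encode_sequence(seq: str | bytes | bytearray) -> np.ndarray:
    """Encode a DNA string to int codes A=0..T=3; anything else (N) is -1."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(bytes(seq), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifHit:
    peak_name: str
    motif_id: str
    offset: int  # 0-based window start within the scanned sequence
    strand: str
    score: float  # log-odds, bits


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    target_hits: int
    target_total: int
    background_hits: int
    background_total: int
    p_value: float
    q_value: float
    rank: int


def _window_scores(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    L = logodds.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win >= 0).all(axis=1)
    scores = np.full(n, -np.inf)
    if valid.any():
        idx = np.where(valid)[0]
        scores[idx] = logodds[win[idx], np.arange(L)].sum(axis=1)
    return scores


def scan_motif(
    pwm: PWM,
    sequence: str | bytes | np.ndarray,
    threshold_fraction: float = 0.8,
    peak_name: str = "",
) -> list[MotifHit]:
    """Scan both strands of a sequence for PWM hits.

    A hit is any window scoring >= threshold_fraction * max attainable
    score.  A degenerate matrix with a non-positive maximum score (e.g. the
    uniform PWM) yields no hits by definition.  Reverse-strand hits are
    reported at the forward-coordinate window start.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    codes = sequence if isinstance(sequence, np.ndarray) else encode_sequence(sequence)
    max_score = pwm.max_score()
    if max_score <= 0:
        return []
    cutoff = threshold_fraction * max_score
    lo = pwm.log_odds()
    hits: list[MotifHit] = []
    # reverse strand == scanning the forward sequence with the
    # reverse-complemented matrix
    for strand, matrix in (("+", lo), ("-", lo[::-1, ::-1])):
        scores = _window_scores(codes, matrix)
        for off in np.where(scores >= cutoff)[0]:
            hits.append(MotifHit(peak_name, pwm.motif_id, int(off), strand, float(scores[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def peak_sequences(peaks: Iterable[Peak], genome: Mapping[str, object]) -> list[np.ndarray]:
    """Extract encoded sequences at literal peak coordinates."""
    cache: dict[str, np.ndarray] = {}
    out = []
    for p in peaks:
        if p.chrom not in cache:
            seq = genome[p.chrom]
            cache[p.chrom] = (
                seq if isinstance(seq, np.ndarray) else encode_sequence(seq)
            )
        out.append(cache[p.chrom][p.start : p.end])
    return out


def _has_hit(
    codes: np.ndarray, logodds_fwd: np.ndarray, logodds_rev: np.ndarray, cutoff: float
) -> bool:
    for matrix in (logodds_fwd, logodds_rev):
        scores = _window_scores(codes, matrix)
        if scores.size and scores.max() >= cutoff:
            return True
    return False


def sequences_with_hit(
    seq_matrix: np.ndarray, pwm: PWM, threshold_fraction: float = 0.8
) -> np.ndarray:
    """Vectorized per-row hit flags for a batch of equal-length sequences.

    `seq_matrix` is an (n, L_seq) int-code array (see
    :func:`encode_sequence`).  Returns a boolean vector: row has >= 1 hit
    on either strand.
    """
    max_score = pwm.max_score()
    n = seq_matrix.shape[0]
    if max_score <= 0:
        return np.zeros(n, dtype=bool)
    cutoff = threshold_fraction * max_score
    lo = pwm.log_odds()
    L = lo.shape[1]
    if seq_matrix.shape[1] < L:
        return np.zeros(n, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(seq_matrix, L, axis=1)
    valid = (win >= 0).all(axis=2)
    out = np.zeros(n, dtype=bool)
    cols = np.arange(L)
    for matrix in (lo, lo[::-1, ::-1]):
        scores = matrix[win, cols].sum(axis=2)
        out |= ((scores >= cutoff) & valid).any(axis=1)
    return out


def annotate_motifs_in_peaks(
    peaks: PeakSet,
    genome: Mapping[str, object],
    pwms: Sequence[PWM],
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Boolean peaks x motifs presence matrix (>= 1 hit anywhere in peak)."""
    cfg = cfg or AnalysisConfig()
    seqs = peak_sequences(peaks, genome)
    data = np.zeros((len(peaks), len(pwms)), dtype=bool)
    for j, pwm in enumerate(pwms):
        max_score = pwm.max_score()
        if max_score <= 0:
            continue
        cutoff = cfg.motif_threshold_fraction * max_score
        lo = pwm.log_odds()
        rev = lo[::-1, ::-1]
        for i, codes in enumerate(seqs):
            data[i, j] = _has_hit(codes, lo, rev, cutoff)
    return pd.DataFrame(
        data, index=[p.name for p in peaks], columns=[m.motif_id for m in pwms]
    )


def motif_enrichment(
    target: PeakSet,
    background: PeakSet,
    genome: Mapping[str, object],
    pwms: Sequence[PWM],
    cfg: AnalysisConfig | None = None,
    top_k: int | None = None,
) -> list[EnrichmentResult]:
    """Rank motifs by one-sided hypergeometric enrichment in the target set.

    Background peaks overlapping any target peak are removed before
    testing.  For each motif, with N = targets + backgrounds, K = peaks
    with a hit anywhere, n = target peaks and k = target peaks with a hit,
    the p-value is P[X >= k] under the hypergeometric null.  Results are
    BH-adjusted and returned sorted by ascending p (ties broken by motif
    id); by default the top `cfg.top_k_motifs` are reported.
    """
    cfg = cfg or AnalysisConfig()
    if len(target) == 0 or len(background) == 0:
        raise ValueError("motif_enrichment requires non-empty target and background")
    target_index = _ChromIndex(target)
    bg_peaks = [
        p for p in background if not target_index.any_overlap(p.chrom, p.start, p.end)
    ]
    if not bg_peaks:
        raise ValueError("background is empty after removing target-overlapping peaks")
    bg = PeakSet(background.cell_type, bg_peaks)

    t_presence = annotate_motifs_in_peaks(target, genome, pwms, cfg)
    b_presence = annotate_motifs_in_peaks(bg, genome, pwms, cfg)
    n_t, n_b = len(target), len(bg)
    N = n_t + n_b
    pvals, rows = [], []
    for pwm in pwms:
        k_t = int(t_presence[pwm.motif_id].sum())
        k_b = int(b_presence[pwm.motif_id].sum())
        K = k_t + k_b
        p = float(stats.hypergeom.sf(k_t - 1, N, K, n_t))
        pvals.append(min(p, 1.0))
        rows.append((pwm.motif_id, k_t, k_b))
    qvals = stats.false_discovery_control(np.array(pvals), method="bh")
    order = sorted(range(len(pwms)), key=lambda i: (pvals[i], rows[i][0]))
    results = []
    for rank, i in enumerate(order, start=1):
        motif_id, k_t, k_b = rows[i]
        results.append(
            EnrichmentResult(
                motif_id, k_t, n_t, k_b, n_b, pvals[i], float(max(qvals[i], pvals[i])), rank
            )
        )
    k = cfg.top_k_motifs if top_k is None else top_k
    return results[:k] if k else results


def promoter_fraction_test(
    k_promoter: int, n_total: int, background_fraction: float
) -> float:
    """Exact one-sided binomial p-value for promoter depletion.

    P[X <= k | n, f]: the probability of seeing this few promoter peaks if
    the set followed the cell type's genome-wide promoter fraction f.
    """
    if not 0 < background_fraction < 1:
        raise ValueError("background_fraction must be in (0, 1)")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if k_promoter > n_total:
        raise ValueError("k_promoter cannot exceed n_total")
    return float(stats.binom.cdf(k_promoter, n_total, background_fraction))


__all__ = [
    "MotifHit",
    "EnrichmentResult",
    "encode_sequence",
    "scan_motif",
    "peak_sequences",
    "sequences_with_hit",
    "annotate_motifs_in_peaks",
    "motif_enrichment",
    "promoter_fraction_test",
]
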