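"""Motif scanning, enrichment statistics and the depletion test."""
from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from creprime import (
    AnalysisConfig,
    Peak,
    PeakSet,
    PWM,
    annotate_motifs_in_peaks,
    motif_enrichment,
    promoter_fraction_test,
    scan_motif,
)
from creprime.core import pwm_from_counts
from creprime.enrichment import encode_sequence, sequences_with_hit
from creprime.synthetic import consensus_pwm


def _pure_pwm(motif_id, consensus):
    """Probability-1 consensus PWM (no pseudocount)."""
    m = np.zeros((4, len(consensus)))
    for j, b in enumerate(consensus):
        m["ACGT".index(b), j] = 1.0
    return PWM(motif_id, m)


class TestScanMotif:
    def test_consensus_hit_on_forward_strand(self):
        hits = scan_motif(_pure_pwm("A4", "AAAA"), "GGAAAAGG", 0.9)
        assert [(h.offset, h.strand) for h in hits] == [(2, "+")]
        assert hits[0].score == pytest.approx(4 * math.log2(4))

    def test_reverse_strand_hit_where_minus_strand_reads_consensus(self):
        # the minus strand of window AAAA reads TTTT, so motif TTTT hits there
        hits = scan_motif(_pure_pwm("T4", "TTTT"), "GGAAAAGG", 0.9)
        assert [(h.offset, h.strand) for h in hits] == [(2, "-")]

    def test_uniform_pwm_yields_no_hits(self):
        uniform = PWM("U", np.full((4, 5), 0.25))
        assert scan_motif(uniform, "ACGTACGTACGT", 0.5) == []

    def test_n_windows_are_skipped(self):
        assert scan_motif(_pure_pwm("A4", "AAAA"), "NNNNNNNN", 0.5) == []
        hits = scan_motif(_pure_pwm("A4", "AAAA"), "NAAAAN", 0.9)
        assert [(h.offset, h.strand) for h in hits] == [(1, "+")]

    def test_sequence_shorter_than_motif_gives_empty_list(self):
        assert scan_motif(_pure_pwm("A6", "AAAAAA"), "AAA", 0.5) == []

    def test_agrees_with_per_window_log_odds_oracle(self):
        """Brute force: score every window of random 1 kb sequences by hand."""
        rng = np.random.default_rng(12)
        pwm = pwm_from_counts("R", rng.integers(0, 20, size=(4, 7)))
        lo = pwm.log_odds()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            cutoff = 0.7 * pwm.max_score()
            expected = []
            for off in range(1000 - 7 + 1):
                win = seq[off : off + 7]
                fwd = sum(lo["ACGT".index(b), j] for j, b in enumerate(win))
                rc = "".join(comp[b] for b in reversed(win))
                rev = sum(lo["ACGT".index(b), j] for j, b in enumerate(rc))
                if fwd >= cutoff:
                    expected.append((off, "+", fwd))
                if rev >= cutoff:
                    expected.append((off, "-", rev))
            got = scan_motif(pwm, seq, 0.7)
            assert [(h.offset, h.strand) for h in got] == [
                (o, s) for o, s, _ in sorted(expected)
            ]
            for h, (_, _, sc) in zip(got, sorted(expected)):
                assert h.score == pytest.approx(sc)

    def test_batch_hit_flags_agree_with_scan(self):
        rng = np.random.default_rng(3)
        pwm = consensus_pwm("B", "TGACGTCA", strength=8)
        mat = rng.integers(0, 4, size=(40, 120))
        flags = sequences_with_hit(mat, pwm, 0.75)
        for row, flag in zip(mat, flags):
            seq = "".join("ACGT"[c] for c in row)
            assert flag == bool(scan_motif(pwm, seq, 0.75))


class TestMotifEnrichment:
    def _fixture(self, rng, n_target=10, n_bg=100, plant=8, bg_plant=10):
        """Target/background peaks on a random genome with planted consensus."""
        cons = "TGTGGTTT"
        chrom_len = 200 * (n_target + n_bg) + 400
        seq = list("".join(rng.choice(list("ACGT"), size=chrom_len)))
        peaks, cursor = [], 100
        for i in range(n_target + n_bg):
            peaks.append(Peak("chr1", cursor, cursor + 150, f"pk{i}"))
            cursor += 200
        for p in peaks[:plant] + peaks[n_target : n_target + bg_plant]:
            mid = p.midpoint
            seq[mid : mid + len(cons)] = list(cons)
        genome = {"chr1": "".join(seq)}
        target = PeakSet("t", peaks[:n_target])
        background = PeakSet("b", peaks[n_target:])
        return target, background, genome

    def test_p_value_is_exact_hypergeometric_tail(self, cfg):
        rng = np.random.default_rng(8)
        target, background, genome = self._fixture(rng)
        pwm = consensus_pwm("RUNX1", "TGTGGTTT")
        (res,) = motif_enrichment(target, background, genome, [pwm], cfg)
        k, K, n, N = (
            res.target_hits,
            res.target_hits + res.background_hits,
            res.target_total,
            res.target_total + res.background_total,
        )
        # independent oracle: explicit tail sum of the hypergeometric pmf
        tail = sum(
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
            for x in range(k, min(K, n) + 1)
        )
        assert res.p_value == pytest.approx(tail, rel=1e-9)
        assert res.target_hits >= 8  # all planted targets recovered

    def test_small_case_matches_full_enumeration(self):
        """For N <= 30 the tail equals enumeration over all target subsets."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            p_impl = float(stats.hypergeom.sf(k - 1, N, K, n))
            p_enum = sum(
                math.comb(K, x) * math.comb(N - K, n - x)
                for x in range(k, min(K, n) + 1)
            ) / math.comb(N, n)
            assert p_impl == pytest.approx(p_enum, rel=1e-12, abs=1e-15)

    def test_absent_motif_has_p_one(self, cfg):
        rng = np.random.default_rng(21)
        target, background, genome = self._fixture(rng, plant=0, bg_plant=0)
        pwm = consensus_pwm("X", "ACACACAC", strength=50)
        # probability of a chance 8-mer consensus hit is ~1.5e-5 per window;
        # with no planting the expected tail is the whole distribution
        (res,) = motif_enrichment(target, background, genome, [pwm], cfg)
        if res.target_hits == 0:
            assert res.p_value == pytest.approx(1.0)

    def test_background_peaks_overlapping_target_are_removed(self, cfg):
        rng = np.random.default_rng(2)
        target, background, genome = self._fixture(rng)
        overlapping = PeakSet(
            "b2", list(background.peaks) + [
                Peak(p.chrom, p.start + 10, p.end + 10, f"ov{i}")
                for i, p in enumerate(target.peaks)
            ]
        )
        res1 = motif_enrichment(target, background, genome,
                                [consensus_pwm("R", "TGTGGTTT")], cfg)
        res2 = motif_enrichment(target, overlapping, genome,
                                [consensus_pwm("R", "TGTGGTTT")], cfg)
        assert res1[0].background_total == res2[0].background_total

    def test_empty_target_or_background_rejected(self, cfg):
        ps = PeakSet("x", [Peak("chr1", 0, 50, "a")])
        with pytest.raises(ValueError):
            motif_enrichment(PeakSet("t", []), ps, {"chr1": "A" * 100}, [], cfg)

    def test_ranking_and_q_value_invariants(self, dataset, cfg):
        from creprime import build_master_list, exclusive_shared

        master = build_master_list(dataset.peaksets)
        target = exclusive_shared(master, "HSC", "MkP")
        bg = PeakSet("bg", [
            Peak(p.chrom, p.start, p.end, f"{ct}|{p.name}", p.score)
            for ct, ps in dataset.peaksets.items() if ct not in ("HSC", "MkP")
            for p in ps
        ])
        genome = {c: bytes(s) for c, s in dataset.genome.items()}
        results = motif_enrichment(target, bg, genome, dataset.pwms, cfg)
        assert [r.rank for r in results] == list(range(1, len(results) + 1))
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)
        for r in results:
            assert 0 <= r.p_value <= 1 and r.q_value >= r.p_value
        assert results[0].motif_id == dataset.lineage_motifs["MkP"]


class TestAnnotateMotifsInPeaks:
    def test_matrix_agrees_with_per_peak_scans(self, cfg):
        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        genome = {"chr1": seq}
        peaks = PeakSet("p", [
            Peak("chr1", i * 200, i * 200 + 150, f"p{i}") for i in range(20)
        ])
        pwms = [consensus_pwm("M1", "TGACTCAG", 6), consensus_pwm("M2", "AGATAAGA", 6)]
        matrix = annotate_motifs_in_peaks(peaks, genome, pwms, cfg)
        for p in peaks:
            for pwm in pwms:
                direct = bool(scan_motif(
                    pwm, seq[p.start:p.end], cfg.motif_threshold_fraction, p.name
                ))
                assert matrix.at[p.name, pwm.motif_id] == direct

    def test_planted_consensus_is_detected(self, dataset, cfg):
        genome = {c: bytes(s) for c, s in dataset.genome.items()}
        by_id = {m.motif_id: m for m in dataset.pwms}
        planted = [
            (name, motifs[0]) for name, motifs in dataset.truth.planted_motifs.items()
        ]
        peaks = PeakSet("pl", [
            Peak(*dataset.truth.intervals[name], name=name) for name, _ in planted
        ])
        matrix = annotate_motifs_in_peaks(peaks, genome, dataset.pwms, cfg)
        for name, motif_id in planted:
            assert matrix.at[name, motif_id]
        # hit percentage identity: column mean equals hit count / n peaks
        col = matrix[planted[0][1]]
        assert col.mean() == col.sum() / len(peaks)


class TestPromoterFractionTest:
    def test_zero_promoters_closed_form(self):
        assert promoter_fraction_test(0, 100, 0.4) == pytest.approx(0.6**100)

    def test_all_promoters_is_one(self):
        assert promoter_fraction_test(50, 50, 0.3) == pytest.approx(1.0)

    def test_at_expectation_is_near_half(self):
        n, f = 200, 0.37
        k = round(n * f)
        # independent oracle: explicit binomial CDF sum
        p_oracle = sum(
            math.comb(n, x) * f**x * (1 - f) ** (n - x) for x in range(k + 1)
        )
        p = promoter_fraction_test(k, n, f)
        assert p == pytest.approx(p_oracle, rel=1e-9)
        assert 0.45 <= p <= 0.65

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            promoter_fraction_test(10, 5, 0.5)
        with pytest.raises(ValueError):
            promoter_fraction_test(1, 5, 1.5)

    def test_exclusive_shared_sets_are_promoter_depleted(self, dataset, cfg):
        """Planted primed CREs are non-promoter, so each exclusively shared
        set shows depletion, and the pooled set (larger n) rejects at the
        configured alpha; a single 15-peak set cannot beat the exact test's
        (1-f)^n floor, so per-lineage sets are held to 0.05."""
        from creprime import LINEAGES, annotate_peakset, build_master_list, exclusive_shared
        from creprime.core import PeakSet as PS

        master = build_master_list(dataset.peaksets)
        hsc_counts, _ = annotate_peakset(dataset.peaksets["HSC"], dataset.genes, cfg)
        background_fraction = hsc_counts["promoter"] / hsc_counts["total"]
        pooled_k, pooled_n = 0, 0
        for lineage in LINEAGES:
            shared = exclusive_shared(master, "HSC", lineage)
            counts, _ = annotate_peakset(PS("s", shared.peaks), dataset.genes, cfg)
            p = promoter_fraction_test(
                counts["promoter"], counts["total"], background_fraction
            )
            assert p < 0.05
            pooled_k += counts["promoter"]
            pooled_n += counts["total"]
        assert promoter_fraction_test(
            pooled_k, pooled_n, background_fraction
        ) < cfg.alpha_promoter_test
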