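# Methods

This note documents the models, conventions and numerical choices behind
`creprime`, in the order the pipeline runs.

## Coordinates, scores and overlap

All intervals are 0-based half-open (BED convention) internally; readers
for 1-based gene tables convert at the boundary (`read_gene_table(...,
one_based=True)`). Two intervals overlap iff they share ≥ 1 bp on the same
chromosome at literal coordinates; abutting half-open intervals do not
overlap. Peak scores are monotone significance values (higher = more
significant); any positive scale is accepted, since only the rank order is
used.

## Master peak-list

The six peak lists are pooled and resolved greedily by significance:
repeatedly keep the highest-scoring remaining peak and discard every peak
overlapping it. This is *selection*, not fusion — kept peaks retain their
original coordinates — mirroring non-overlapping significance filtering of
a concatenated peak list. Ties resolve by (chrom, start, end, name, cell
type), so the result is deterministic and invariant to input ordering; a
property test permutes inputs to verify this. The presence bit (peak,
cell type) is set iff that cell type contributed any peak overlapping the
kept peak; provenance records the contributing peak names. Greedy
selection is not optimal weighted interval scheduling; it is the
documented, reproducible choice. Master peak names are prefixed with the
contributing cell type (`HSC|pk3`) to stay unique;
`source_peak_name` strips the prefix.

Overlap queries use a start-sorted array with a running maximum of ends
(existence queries) and a sweep-line merge join (pair enumeration); both
are tested against naive all-pairs scans on ≥ 1000 random fixtures.

## Annotation

Categories form an exhaustive, disjoint partition with precedence
**promoter > coding > intron > intergenic**:

* promoter — overlaps `[TSS − w, TSS + w)` of any gene; `w` = 500 bp
  (`promoter_halfwidth`). The half-open window is our documented
  convention for the boundary case at exactly +w.
* coding — overlaps an exon or a ±250 bp TTS flank (`tts_flank`); the TSS
  flank is subsumed by the promoter window under the precedence rule.
* intron — overlaps a gene body but no exon;
* intergenic — none of the above.

Distance to the nearest TSS is measured from the peak midpoint and signed
by gene strand (negative = upstream). The partition identity
Σ categories = total is asserted on every synthetic run and on the bundled
published reference counts table, whose eight rows all satisfy it (master
row: 13,171 + 5,243 + 34,137 + 31,692 = 84,243; non-promoter count
84,243 − 13,171 = 71,072).

Promoter depletion of an exclusively shared set is tested with the exact
one-sided binomial `P[X ≤ k | n, f]` against the cell type's genome-wide
promoter fraction `f`. Note the exact test has a hard floor of
`(1 − f)^n`: a 15-peak set with `f ≈ 0.27` cannot reach p < 0.001 even
with zero promoter peaks, so small per-lineage sets are judged at 0.05 and
the pooled set at the configured α = 0.001.

## Gained / lost accounting

For a reference list R (the stem population) and another list O:
`gained = |{o ∈ O : no overlap in R}|`, `lost = |{r ∈ R : no overlap in
O}|`. Percentages are normalized by |O|, and `ratio_gained/ratio_lost`
rescale gained + lost to 100 %. "Unique" means no ≥ 1 bp overlap — the
same predicate as everywhere else — not a name comparison. The summary
identities (`pct_altered = pct_gained + pct_lost`,
`ratio_gained + ratio_lost = 100`) are exact by construction and asserted
on random fixtures.

## Signal profiles

Fragment coverage is accumulated per position in a symmetric ±500 bp
window about each peak midpoint, summed into 5-bp bins, divided by the bin
width (average depth per position) and averaged over peaks. A fragment
spanning the whole window therefore yields a flat profile of 1.0. A
`cutsites` mode counts only the two fragment end positions, for
insertion-site semantics. Whole-fragment coverage is the default because
the histogram semantics of shifted-fragment pileups are otherwise
underdetermined.

## Motif scanning and enrichment

PWMs are probability matrices (rows A, C, G, T); JASPAR-style count input
gets a per-cell pseudocount of 1 before column normalization, so no
probability is exactly zero and log-odds stay finite. Scanning scores
every window with `log2(p_b(j) / 0.25)` summed over columns; the reverse
strand is scanned by reverse-complementing the matrix, so hits are
reported at forward window starts. Windows containing N are skipped. A
hit requires ≥ `motif_threshold_fraction` (default 0.8) of the matrix's
maximum attainable score — a relative threshold keeps planted-consensus
recovery robust across matrices of different information content. A
degenerate matrix whose maximum score is ≤ 0 (e.g. the uniform PWM)
yields no hits by definition.

Enrichment of a target set versus a custom background (background peaks
overlapping the target are removed first) uses the one-sided
hypergeometric tail on per-peak hit presence: with N = targets +
backgrounds, K = peaks with ≥ 1 hit, n = targets, observed k,
`p = P[X ≥ k]`. Benjamini–Hochberg q-values are reported; ranking uses
raw p with motif-id tie-break, and the top `top_k_motifs` (default 10) are
returned. The exact hypergeometric was chosen over a ZOOPS-binomial with
GC-matched background because it is parameter-free and reproducible;
GC/length matching is a stated non-goal. Being discrete, the test is
mildly conservative: at the calibration fixture's size (100 + 200
sequences of 300 bp, per-sequence hit probability ≈ 0.20) its exact
attained level at α = 0.05 is ≈ 0.037, which is what the type-I
calibration check measures across 1000 null fixtures.

## Regulatory domains and priming calls

Basal domains are strand-aware `[TSS − 2000, TSS + 1000)` (mirrored for
minus-strand genes). Extension on each side stops at the nearest
neighboring **basal** boundary, at 1 Mb from the basal edge, or at the
chromosome edge, whichever comes first; only basal domains block
extension, so extended domains may overlap freely, and a basal domain
straddling a neighbor's edge blocks extension entirely on that side.
Genes sharing a TSS are kept with a warning, tie-broken by gene id.
Curated regulatory domains (an external annotation source) are not
implemented. Association is monotone in the extension cap — enlarging it
never removes a gene from a peak's association set — and this is property
tested.

A primed CRE for lineage L is a master peak that is (i) non-promoter,
(ii) exclusively shared between the stem population and L, and (iii)
associated with ≥ 1 gene expressed in L and in no other lineage.
Whether expression in the stem population disqualifies is a config flag
(`strict_lineage_restriction`); the default is strict (absent in the stem
too), since the showcase priming examples in this setting are
lineage-only patterns, and the lenient variant remains available because
no formal threshold rule exists for "expressed only in". Each record
lists which of the lineage's top-k enriched motifs occur in the peak when
a motif-presence matrix is supplied.

## Synthetic data

The generator is truth-first: class labels, coordinates and sequence edits
are drawn before any file is written, and `SyntheticTruth` stores the
clean structure so evaluation never depends on re-inference. Defaults
describe a two-chromosome, 2 Mb genome with 60 non-overlapping genes
(bodies 3–6 kb, random strand, 2–4 exons) and, per run: 80 common peaks,
15 exclusively shared peaks per lineage (each placed in non-promoter space
inside its target gene's extended regulatory domain, the target expressed
only in that lineage), 20 unique peaks per cell type (plus 20 stem-unique),
60 background peaks present in random ≥ 3-subsets of cell types, and
promoter peaks at TSS windows of expressed genes sized so they make up 30 %
of all planted peaks. Background subsets of size ≥ 3 can never collide
with the two-bit exclusive signature, which is what makes noise-free
recovery exact. Peak widths are 150–300 bp, placed with a 10-bp gap so
all planted peaks are mutually disjoint and the master list equals the
planted set. Lineage motifs (8-bp consensus matrices named after
characteristic hematopoietic factors, plus never-planted decoys) are
written into the genome at the peak center on a random strand at rate 0.9.
Fragments (80 bp, 5 per present peak) are placed uniformly inside peaks.

Noise models **dropout**: each present bit is lost independently with
probability `noise_rate`, emulating a peak caller missing a truly
accessible site. Dropout never invents presence; at rate ε a planted
exclusive peak keeps its exact two-bit signature with probability
(1 − ε)², i.e. ≈ 0.90 at ε = 0.05, and recovery degrades monotonically
with ε. The generator does not model Tn5 insertion bias, GC bias or
fragment-size mixtures, and peaks are planted disjoint — so passing tests
demonstrate the correctness of the set algebra, statistics and calls, not
robustness to overlapping or biased real-world peak calls.

All randomness flows from a single seed; identical parameters produce
byte-identical emitted files (tested).

## Problem sizes

Default synthetic runs use a 2 Mb genome with ~480 planted peaks, chosen
so a full study (generation through priming calls) completes in under a
second and the complete multi-seed recovery, calibration and ranking
checks finish in well under a minute each. Oracle-equivalence checks use
1000 random fixtures of ≤ 12 intervals; the enrichment calibration uses
1000 fixtures of 300 sequences × 300 bp.

## Known limitations

* The master list selects representative peaks rather than merged spans;
  tools that fuse intervals will report different coordinates.
* The hypergeometric enrichment ignores GC composition and peak length;
  with a GC-biased background its p-values are optimistic.
* One TSS per gene row; multi-isoform promoters must be collapsed
  upstream.
* Published headline percentages from the real mouse dataset (peak counts
  per cell type, shared-peak percentages) depend on raw data processed
  through an external alignment/peak-calling pipeline and are out of
  scope; only the printed annotation-count identities are checked.
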