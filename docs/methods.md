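# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the synthetic data does and does not emulate,
and the numerical choices a maintainer would want to know.

## Pipeline overview

Two adapter-ligated small-RNA libraries are processed through:

1. **Preprocessing** — 3′ adapter trimming, dropping ambiguous reads,
   collapsing to unique tags with per-library counts, a 19–30 nt length
   filter, and TPM normalization.
2. **ncRNA filtering and conserved annotation** — tags matching rRNA,
   tRNA, snoRNA or snRNA references (exact substring, either orientation)
   are removed; a conserved miRNA is a tag equal (full length,
   U/T-insensitive) to a known mature sequence, with at least 5 counts in
   one library. Families are derived from the `miR<number>` stem of the
   reference names.
3. **Novel discovery** — unannotated tags (plus rRNA-matching tags, which
   are deliberately re-admitted so rRNA-derived miRNAs remain
   discoverable) are mapped by exact substring search to transcript/EST and
   rRNA references; candidate precursor windows around each hit are folded
   and scored against hairpin-annotation criteria; the best passing window
   becomes the precursor. Tags accepted on opposite arms of one precursor
   are linked as mature/star partners.
4. **Target prediction** — expectation-scored complementarity search over
   one or more transcript sets with priority ordering.
5. **qPCR analysis** — comparative-Ct fold changes with t-test
   significance, plus geNorm/NormFinder reference-gene stability.

All internal coordinates are 0-based half-open; GFF3 export converts to
1-based inclusive.

## Secondary structure model

The folder maximizes a weighted pair count (G:C = 3, A:U = 2, G:U wobble
= 1; minimum hairpin loop 3 nt) by the classic O(n³) interval dynamic
program. This is not a thermodynamic model: weights approximate relative
pair stabilities and suffice to decide hairpin-criteria questions
(single-stem topology, duplex pairing of the mature). Free-energy
structures from an external folder can be supplied as Vienna dot-bracket
files and evaluated identically.

Determinism and tie-breaking: a position is left unpaired whenever that is
optimal; otherwise it pairs with the *outermost* (rightmost) partner that
achieves the optimum. The outermost preference matters: preferring the
innermost partner reconstructs equal-score variants of long perfect stems
with spurious internal bulges, whereas the outermost choice recovers the
contiguous stem. Scores and structures are invariant under U↔T input.

Because the DP matrix holds the optimal score of every subinterval, one
fold of a region (mapped tag ± 150 nt flank) serves all candidate windows
within it; discovery reads each window's structure out of the shared
matrix, which is what keeps the sliding-window search fast at
100k-reads-per-library scale.

## Hairpin annotation criteria

A mature placement passes when all of the following hold (defaults in
parentheses, all overridable):

- the window folds into a single stem-loop (`n_stems == 1`, counted as the
  number of terminal loops);
- the mature lies wholly within one arm, not overlapping the terminal
  loop;
- unpaired mature bases (counted over the whole mature) ≤ `max_mismatch`
  (4);
- asymmetric-bulge nucleotides, summed over internal loops between
  consecutive paired mature positions as |unpaired_mature −
  unpaired_opposite|, ≤ `max_bulge_nt` (2);
- mature length within `mature_len` (19–25 nt);
- a star interval exists: the partners of the mature minus its 2-nt 3′
  overhang, extended 2 nt at the high-index end (the star's own 3′
  overhang), all falling on the opposite arm and disjoint from the mature.

Star *expression* is not required by default (in-silico prediction only);
`require_star_tag=True` restricts output to miRNAs whose star sequence is
itself present among the tags.

Window scheme: for each length in {80, 120, 160, 200, 250, 300}, windows
containing the mature at the 5′ edge, centered, and 3′ edge placements
plus every start aligned to an absolute 10-nt grid, within ±150 nt of the
hit and clipped at source ends. The absolute grid means nearby tags — a
mature and its star — enumerate identical windows, making "partners share
the precursor window" well-defined; after per-tag best selection
(highest fold score, ties to the shortest then leftmost window),
overlapping opposite-arm records are re-anchored to the best window in
which both matures pass and cross-linked. These window parameters are this
package's own concrete choices, bracketing typical plant pre-miRNA sizes
(~70–300 nt).

Exact substring search replaces a short-read aligner for tag→reference
mapping: tags are 19–30 nt and annotation demands perfect matches, so the
exact search is both faster and stricter; antisense hits are found via the
reverse complement. A consequence of designing perfect mature/star duplexes
is that a mature can also map antisense onto its own star arm; either
orientation describes the same physical hairpin, and either may be
reported depending on which window scores higher (G:U wobble is not
symmetric under reverse complement, so the two orientations rarely tie).

## Target expectation score

For an alignment of the miRNA (5′→3′) against the reverse complement of a
site: mismatch 1.0, G:U 0.5, gap 2.0; penalties double when the miRNA
position (1-based from the 5′ end) lies in the core, positions 2–13. A gap
column takes the position of the most recent miRNA base consumed (minimum
1). Sites are scanned at every transcript start over window lengths M−g …
M+g (g = `max_gaps`, default 1) by a small dynamic program; overlapping
reportable sites are reduced greedily (lowest expectation, then leftmost),
and sites with expectation ≤ `max_expectation` (default 3.0) are reported.
A penalized column at positions 9–11 calls translational inhibition,
otherwise cleavage; the call is reported, never filtered on. With
`max_expectation = 0` the output provably coincides with an exact string
search for the reverse complement.

The default cutoff is a stand-in: published uses of this scoring family
vary the threshold, and no count of predicted targets is treated as a
reference value.

## qPCR model and statistics

Technical replicates are averaged per biological replicate before any
statistic; biological replicates (≥ 2, default 3) are the unit of
analysis. ΔCt = Ct_target − Ct_reference per replicate; ΔΔCt = mean
ΔCt(mature) − mean ΔCt(early); fold change = 2^−ΔΔCt with the early group
as calibrator (fold change 1 by convention). Significance: unpaired
two-tailed pooled-variance (equal-variance) Student t on the two ΔCt
samples — equal variance follows the reporting convention the analysis
mirrors, not a data-driven choice; Welch is deliberately not used. A
result is differentially expressed when fold change > 2 or < 0.5 *and*
p < 0.05. No multiple-testing correction is applied by default (per-assay
testing); Benjamini–Hochberg is available as an option.

Degenerate t-test inputs follow a fixed convention: zero pooled variance
with equal means → p = 1; with unequal means → p = 0.

geNorm: M_j is the mean over other assays k of the SD (ddof = 1) of
log2(q_j/q_k) across samples; ranking is ascending in M and the iterative
trace removes the worst assay per round down to the final pair. The
NormFinder-style statistic is a simplified two-group decomposition on log2
quantities — sqrt(variance of group means + mean within-group variance) —
not the full mixed-model estimator. Relative quantities are 2^−Ct rescaled
per assay to geometric mean 1 (the rescaling cancels in all pairwise
log-ratios).

## Synthetic data: what it emulates, and what it does not

The generator emulates the observable structure of a pooled-tissue plant
small-RNA study: two libraries of 3′-adapter-ligated reads (TruSeq
small-RNA adapter, constant quality, fixed read length, per-base
substitution errors at 1% by default); conserved matures spiked from a
synthetic miRBase-style reference (120 entries across real plant family
numbers, 20–22 nt); designed novel stem-loop precursors (mature + 14-nt
extension + 8–11 nt A/C loop + reverse complements, ~80 nt) embedded in
EST-like transcripts and in rRNA backbones; one precursor carrying planted
matures on both arms; and degradation fragments (uniform 15–30 nt
substrings of the backbones, avoiding planted hairpin windows). Element
abundances are log-normal (σ = 1) with a floor of 10 reads for planted
miRNA elements so every planted element clears the 5-count annotation
threshold; degradation takes 30% of each library. Defaults — 50 spikes, 18
transcript hairpins + 2 rRNA hairpins, 1 arm-paired, 100k reads per
library — are the study conditions the validation operates under.

The mature is placed at the outer end of the designed stem because
maximum-weight folding adds opportunistic pairs next to the loop; placed
loop-adjacent, those pairs read as asymmetric bulges inside the mature
duplex. Designs are validated against the same criteria and the same
window search the discovery stage uses (including a common passing window
for arm pairs), with bounded redraws; planted sequences are additionally
required to trim cleanly (no chance adapter-like stretch) and to be absent
from the mature reference.

Not emulated: indel sequencing errors, quality-score structure, tissue
mixture proportions within a pooled library, multiplexed barcodes,
expression-correlated GC bias, and genuine thermodynamic folding of the
backbones. Passing tests on this data therefore demonstrate the
correctness of the pipeline's logic and thresholds under controlled truth,
not performance on real libraries, where adapter variants, sequencing
artefacts and paralogous loci add noise the manifest cannot capture.

The qPCR simulator draws Ct = base_ct − log2(quantity) + N(0, σ) per
technical measurement (base 25, σ = 0.2 by default, 3 biological × 3
technical replicates), with designed fold changes per assay and tissue
echoing magnitudes observed in real durum-wheat development studies
(0.038 … 4.982), and candidate reference assays with per-assay noise for
stability benchmarking.

One integer seed drives every draw (per-stage offsets); identical
configurations give byte-identical FASTA/FASTQ/TSV/JSON outputs.

## Numerical and engineering choices

- Adapter trimming: leftmost adapter-prefix match, ≥ 6 nt overlap, ≤ 1
  mismatch — deterministic and standard for small-RNA inserts; reads
  without an adapter or containing N are dropped as low quality.
- The length filter retains 19–30 nt inclusive (strict reading of
  "longer than 18, shorter than 31"); both bounds are configuration keys.
- TPM denominators use the post-trim, post-length-filter clean-read total,
  before ncRNA removal.
- Degenerate inputs raise explicit errors: empty mature interval or
  mature outside the window, zero quantities in stability analysis,
  missing qPCR groups, adapters shorter than 6 nt, unbalanced dot-bracket
  strings (with the offending index).
- The t-test p-value uses the analytic t survival function; folding and
  site-scanning inner loops are JIT-compiled, with scores kept integral
  (half-penalty units for the target scan) so comparisons are exact.
- Tables are written with fixed float formatting and sorted keys so reruns
  are bit-identical; timings appear only in logs, never in outputs.

## Validation sizes

The automated checks run at: 200 random sequences (length ≤ 12) for the
folding oracle; ~211 hairpins (all simulator designs + 200 random
negatives) for the criteria oracle; the full default study (50 spikes, 20
hairpins, 2 × 100k reads) for spike-in recovery; 2000 simulated null
assays for t-test calibration; 100 seeded simulations for geNorm ranking;
and two complete pipeline reruns at 20k reads per library for determinism.
These sizes were chosen to give tight binomial bounds while keeping the
whole validation suite fast on a single CPU.

## Known limitations

- The base-pair-maximization folder over-pairs relative to thermodynamic
  models; borderline hairpins should be re-checked with an external folder
  through the Vienna import path.
- Exact-substring mapping misses tags with SNPs or sequencing errors
  against the reference — consistent with the perfect-match annotation
  policy, but worth remembering on real data; an external aligner can be
  plugged in upstream by supplying hits.
- The NormFinder statistic is the simplified two-group form.
- rRNA-derived discovery depends on rRNA reference naming (`rRNA*`
  prefixes) to route filtered tags back into the search.
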