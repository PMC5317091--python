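# Methods

## Pattern model

Patterns are strings over `{A,C,G,T,N}` with case as an annotation layer:
uppercase marks highly conserved positions, lowercase weakly conserved
ones. Matching is case-insensitive; case only feeds the
conserved-palindromic-position arithmetic. The distance model is ungapped
Hamming distance at non-wildcard positions — the repeat families this
package targets are short and unindelled, so gapped alignment would add
free parameters without explanatory power. A genome `N` at a non-wildcard
pattern position counts as a mismatch: masked or ambiguous stretches can
then never contribute phantom exact hits. Ambiguity codes other than `N`
in input genomes are collapsed to `N` on load (with a warning) for the
same reason: the mismatch model stays two-valued plus wildcard.

## Scanning

The scanner vectorizes the mismatch count per start position (one numpy
comparison per non-wildcard pattern position, O(w·L) overall), reports all
overlapping occurrences (counts are raw, no greedy masking), and includes
origin-wrapping windows exactly once on circular chromosomes. Wrapping
hits keep `start ∈ 1..L` and may have `end > L`; downstream consumers
fold coordinates back onto the circle.

Self-reverse-complementary patterns are scanned on one strand only — a
reverse pass is provably identical (the reverse-complement involution
maps windows to windows preserving distance). Non-palindromic consensi
are scanned with the pattern and its reverse complement, both passes in
forward-strand coordinates, with the duplicate pass suppressed when the
consensus happens to be self-reverse-complementary.

Orientation of a site is read off its central dinucleotide: `GA` →
forward, `TC` → reverse, anything else goes to the Hamming-nearest of the
two and ties (e.g. `TA`, or any `N`) are reported `ambiguous`, never
arbitrarily assigned.

Conservation profiles count bases per position within a mismatch stratum;
a position is flagged conserved when its modal base reaches a threshold
fraction of sites, default 0.75. The threshold quantifies "highly
conserved" in a field where the phrase is rarely given a number; it is
configurable, and the profile matrix itself (rows A,C,G,T,N) is always
emitted so other cutoffs can be applied post hoc.

## Background model and enrichment

The null is an order-k Markov chain fit to the analyzed genome with
pseudocount 1 (default k = 2, which absorbs dinucleotide and
codon-adjacent composition without modeling genes). The probability that
a background window lies within mismatch budget m of a pattern is
computed by exact dynamic programming over (context, mismatches-used)
states — O(w · 4^k · m) — so wildcards marginalize analytically and no
word enumeration or Monte-Carlo sampling is ever needed, at any budget.

Expected counts use the window-probability approximation
E = (L − w + 1)·p (L windows when circular), ignoring self-overlap
autocorrelation. A startup check warns when a pattern can overlap itself
at a shift ≤ w/2, where the resulting clumping would make the Poisson
tail anticonservative; the default 18-nt core cannot. Significance is the
Poisson upper tail, with Benjamini–Hochberg adjustment across whatever
batch is being tested.

De novo discovery enumerates spaced palindromes X·N^s·revcomp(X) for arm
lengths 6–8 and spacers 2–4 (defaults) by comparing rolling arm codes
against reverse-complement codes at the spacer offset — one vectorized
pass per (arm, spacer) pair. Candidates observed at least twice (a repeat
needs recurrence) are scored against the background; the BH family size
is the full hypothesis space (all 4^a arms per combination), not just the
observed candidates, which is what keeps the null calibration honest:
a chance doubled palindrome in 50 kb has p ≈ 5e-6, well above the
family-wise BH threshold (~4e-8 at rank 1). Candidates whose cores nest
inside a more significant candidate's core (wildcard-aware, any offset)
are merged away, so one planted family yields one reported candidate.

## Genomic context

Coding overlap means ≥1 shared bp with a CDS; compound (join) loci are
judged by their envelope (min start, max end per locus_tag). Flank
orientation uses CDS plus rRNA/tRNA — a gap bounded by a tRNA is still a
genuine intergenic gap — resolved circularly, so every intergenic site on
a circular chromosome has both flanks; linear genomes yield `edge` at the
ends. Upstream distances are gap lengths (bases strictly between the site
and the gene's 5′ coordinate, strand-aware; 0 = adjacent), not coordinate
offsets; the alternative convention differs by one and callers can add it
back trivially.

The replichore split is the half-open circular arc [ori, ori + ⌈L/2⌉) for
the first half. The origin coordinate is a required input; the cumulative
GC-skew helper (global minimum ≈ origin, maximum ≈ terminus) provides a
hint but is never silently substituted. The half × central-dinucleotide
association is tested by chi-square on the 2×d contingency table, with
degenerate tables (one populated row or column) reported as p = 1.

Spatial statistics are deliberately two-fold and unthresholded: the
one-sample KS distance/p of positions/L against uniform, and the
coefficient of variation of circular inter-site gaps (1 at Poisson, >1
clustered). "Weak clustering" is a reader's judgement; the package
reports the numbers.

## Synthetic data

The generator emulates a small bacterial chromosome carrying a REP-like
family, with defaults set to the study conditions this package models:

| parameter | default | meaning |
|---|---|---|
| length | 100 kb | chromosome size (scaled-down from Mb-scale genomes for test-speed; all statistics are per-window and scale-free) |
| gc_target | 0.451 | genome G+C fraction |
| markov_order | 0 | background order (k=1 adds a +20% same-base transition bias) |
| mismatch_spec | 38×0 + 5×1 | planted sites per mismatch stratum |
| gene_density | 0.88 | CDS coverage; genes gamma-length ~900 bp, gaps rescaled to pin coverage exactly |
| orientation_mix | .35/.15/.15/.35 | adjacent-pair strand frequencies (++, +−, −+, −−) via a two-state strand chain |
| coding_fraction | 13/38 | fraction of sites planted inside CDSs |
| intergenic_class_bias | .04/.36/.60 | divergent/convergent/codirectional preference of intergenic sites (the family avoids promoter-rich divergent intervals) |
| dinuc_bias | GA-rich first half, TC-rich second | central dinucleotide distributions per replichore |
| wildcard_bias | 0.75 | probability the flanking wildcard positions take their weak-consensus base |

Planted sites instantiate the core, draw the central dinucleotide from
the half-dependent bias, then mutate exactly the specified number of
non-wildcard positions — so central dinucleotides and mismatch counts are
independent by construction, as they are in the element modeled (the
central pair is unconstrained by the core). Sites are placed fully inside
a CDS or fully inside a gap (2 bp margins) so the context truth is
unambiguous, and kept ≥2 bp apart. After planting, the background is
scrubbed: any scan hit within the largest requested budget that is not in
the truth table has its non-planted bases re-rolled (bounded rounds,
error on failure), making the truth exhaustive at that budget. All
randomness flows through one generator keyed by a single seed; identical
configs regenerate byte-identical fixtures.

What the generator does **not** emulate: real gene length/strand
autocorrelation structure, skew-correlated background composition between
replichores, mobile elements, or repeat families other than the planted
one. Passing the end-to-end tests therefore demonstrates correctness of
the measurement chain on genomes with known truth, not biological
generality of the defaults.

## Numerical choices and degenerate inputs

- Empty feature tables degrade to `edge` context calls with a warning,
  not an error; empty hit lists yield profiles with n_sites = 0 and no
  conserved flags.
- Orientation ties are `ambiguous`; replichore boundary is half-open;
  BH-adjusted p-values are capped at 1.
- KS input positions are required in [1, L]; fewer than two positions is
  an error (no spacing exists).
- Expected-count DP tolerances: probabilities are exact up to float64
  rounding; transition rows are validated to sum to 1 ± 1e−9.
- The characterization report is deterministic given inputs: rerunning on
  identical inputs yields byte-identical JSON.

## Problem sizes in the test suite

Unit and acceptance tests run on 50–100 kb fixtures with the default 43
planted sites, 200 randomized scanner-oracle triples (L ≤ 5 kb, w ≤ 10),
and 100-run null calibrations at 50 kb. These sizes give stable
statistics (binomial standard errors of a few percent on the calibration
fractions) while keeping the whole suite under a minute.

## Known limitations

- Enrichment ignores word self-overlap clumping (warned, not corrected);
  an exact compound-Poisson treatment is out of scope.
- Only `N` degeneracy is supported in patterns, not the full IUPAC set,
  and there is no PWM scoring or gapped matching.
- Single-chromosome analyses only; multi-record inputs require selecting
  one record.
- Discovery assumes the element is a spaced palindrome with equal-length
  arms; asymmetric or gapped-arm repeats will be found only via their
  palindromic sub-cores.
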