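# palcore

Discovery and characterization of short palindromic repeat elements
(REP-like sequences) in bacterial genomes.

Many bacterial chromosomes carry high-copy, strongly palindromic intergenic
repeats — the repetitive extragenic palindrome (REP) family and its
relatives. A typical representative is an 18-nt element with a degenerate
core `nAACCGTTnnAACGGTTn`: two conserved 7-bp inverted arms around a
variable central dinucleotide whose identity (GA versus its complement TC)
encodes the element's strand direction. Characterizing such a family
requires a chain of analyses that is usually done with one-off scripts:
mismatch-tolerant scanning, per-position conservation profiling,
overrepresentation statistics against a composition-matched null,
classification of each site's genomic context (inside a CDS, or in a
divergent / convergent / codirectional intergenic interval), strand
asymmetry across the two replichores, and spatial clustering statistics.
`palcore` packages that chain as a tested, reusable library and CLI for
microbial genomicists.

## The model

For a degenerate pattern *P* of length *w* over `{A,C,G,T,N}` (N = wildcard)
and a window *W*, the distance is ungapped Hamming distance at non-wildcard
positions:

d(P, W) = |{ i : P_i ≠ N and W_i ≠ P_i }|

A scan at budget *m* reports every forward-strand start whose window has
d ≤ m; palindromic (self-reverse-complementary) patterns need only one
strand pass because d(P, W) = d(P, revcomp(W)) whenever P = revcomp(P).
Non-palindromic consensi (e.g. the Rex repressor operator
`TTGTGAANNNNTTCACAA`) are scanned on both strands.

Overrepresentation is judged against an order-k Markov background fit to
the genome itself (default k = 2). The expected number of windows within
budget *m* is

E = (L − w + 1) · P_bg(d(P, ·) ≤ m),

with the probability computed exactly by dynamic programming over
(context, mismatches-used) states, and the observed count compared via a
Poisson upper tail: z = (obs − E)/√E, p = P(X ≥ obs | X ~ Poisson(E)).
De novo discovery enumerates every spaced palindrome X·N^s·revcomp(X)
(arm 6–8 bp, spacer 2–4 bp by default) in one vectorized pass and
Benjamini–Hochberg-adjusts over the full hypothesis family.

Context classification reads the strands of the flanking genes left→right:
(−,+) is divergent (start-to-start, promoter-rich), (+,−) convergent
(stop-to-stop, regulatory-poor), otherwise codirectional; any ≥1 bp CDS
overlap wins. The replichore split assigns position *x* to the first half
iff (x − ori) mod L < ⌈L/2⌉, with the origin coordinate always an explicit
input.

A first-class synthetic-genome generator plants core occurrences with
controlled mismatch strata, replichore-biased central dinucleotides and a
CDS tiling at a target density, and returns an exhaustive truth table, so
every pipeline stage is verifiable without any downloads.

## Worked example

```python
import palcore as pc

fx = pc.simulate(pc.SimulationConfig(seed=7))      # 100-kb fixture, known truth
report = pc.run_characterization(
    fx.genome, fx.features, pc.PALINDROME_CORE, ori=1, max_mismatch=1
)
```

prints (via the snippet in `docs/methods.md`'s terms):

```
genome: 100,000 bp, G+C 45.0 mol%, CDS coverage 88%
exact core sites: 38, within one mismatch: 43
context (<=1 mm): {'coding_overlap': 17, 'intergenic_divergent': 4,
                   'intergenic_convergent': 10, 'intergenic_codirectional': 12}
central dinucleotides: {'AA': 5, 'GA': 24, 'TC': 12, 'TA': 1, 'TT': 1}
half x dinucleotide association p = 1.9e-06
exact sites KS uniformity p = 0.79
exact-core enrichment: observed 38 vs expected 0.00053, z = 1642
```

Reading: the scan recovered all 38 exact and 5 one-mismatch planted sites;
the element is massively overrepresented versus the order-2 Markov null
(0.0005 expected); GA-type central dinucleotides concentrate in the first
replication half and TC-type in the second (chi-square p ≈ 2e-6); exact
sites are spatially compatible with uniformity (KS p = 0.79).

The same pipeline runs on real data:

```bash
palcore report --fasta genome.fasta --gff annotation.gff3 \
    --core nAACCGTTnnAACGGTTn --max-mismatch 4 --ori 1 --out report/
palcore consensus --fasta genome.fasta --consensus TTGTGAANNNNTTCACAA --max-dev 2
palcore discover --fasta genome.fasta --arm 6:8 --spacer 2:4 --top 20
```

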