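# Methods

`locrep` analyses *local repeats* (LRs): sequences that recur several times,
discontinuously, within a single genomic locus and rarely or never elsewhere.
They sit between tandem repeats (adjacent copies of a short motif) and
interspersed transposable elements (TEs, genome-wide), and are operationally
defined here — as in the lncRNA loci where they were first characterized — by
a locality fraction: the share of a family's genomic instances falling inside
one host locus.

## Pipeline model

The analysis chain is: TE masking → de-novo repeat discovery → tandem
filtering → genome-wide instance mapping → locality classification →
length-normalized burden statistics, with ChIP enrichment and phylogenetics
as parallel branches. Each stage is deterministic given its inputs and seed.

### De-novo discovery (k-mer seeding, X-drop extension)

Every exact k-mer (k = 16) occurring at least `min_count` (default 3) times
in the masked genome seeds a candidate family; forward and reverse-complement
occurrences pool under the canonical (lexicographically smaller) form. Seeds
are processed in descending occurrence count. Extension is greedy and
gapless, one column at a time in each direction: the consensus base is the
majority over the live copies (alphabetical tie-break), and the running score
accumulates `n_agree − n_disagree − c`, where `c = 2` is the per-column
length penalty of the family objective
`Σ per-copy alignment score − c·consensus_length`. Extension in a direction
stops when the running score drops more than `x_drop` (default 20) below its
maximum, and the consensus is trimmed to the max-scoring extent. Copies whose
cumulative identity to the growing consensus falls below `min_identity`
(default 0.8) leave the live set; small indels are absorbed by that
tolerance rather than modelled.

The length penalty must live inside the running score, not only in the final
objective: the expected raw majority-vote column score on random background
is *positive* for small copy numbers (+0.375 at n = 3, +0.25 at n = 4,
crossing zero only around n ≈ 7), so an unpenalized X-drop would never fire
and extension would run away until the identity floor destroyed the family.
With the penalty, background drift is negative at every copy number while a
true repeat column at divergence d contributes ≈ n(1 − 2d) − c > 0 for the
regimes of interest (e.g. +0.4 at n = 3, d = 0.10).

Exact 16-mer seeds miss diverged copies (a given 16-mer survives in a copy
with probability (1 − d)^16 ≈ 0.19 at d = 0.10), which is why the original
workflow re-maps its consensus library genome-wide afterwards. Discovery
therefore completes each accepted family by mapping its consensus back over
the unclaimed genome (see mapping, below) before tombstoning the claimed
positions; this is what gives per-family instance recall ≳ 0.9 rather than
the ~0.5 that seed-and-extend alone achieves at 10% divergence.

### Tandem detection and routing

The tandem detector compares the sequence to itself at every lag p in
[1, 2000]: a lag-match position qualifies when *any* period-length window
covering it has self-match fraction ≥ `purity_min` (0.8) — the dilation
keeps the detector exactly mirror-symmetric under sequence reversal. Runs
separated by gaps ≤ 2p merge by transitive closure (order-independent, so
also reversal-safe); a closed group whose merged purity falls below the
threshold falls back to its constituent runs. A call needs at least
max(2p, 6) matched positions; the floor of 6 is what admits a
three-copy trinucleotide array while suppressing most chance mono/dinucleotide
matches — some chance micro-calls on random background are unavoidable at
0.8 purity and are tolerated as noise (they cover negligible base pairs and
cannot re-route a repeat family). Overlapping calls at different periods
resolve in favour of the smallest period whose purity is within 0.05 of the
cluster's best, collapsing harmonics.

Routing: a discovered family goes to the TR catalogue when ≥ 50% of its
instance base pairs lie inside detected arrays, or when ≥ 50% of its
consecutive instance pairs are adjacent (gap ≤ 10 bp); everything else is an
LR candidate. The two thresholds are this package's choices; the upstream
procedure states only that tandem repeats were removed.

### Instance mapping and locality

Consensi are mapped genome-wide by exact 12-mer seeding on both strands.
Seed hits are clustered by *diagonal* (genome position − consensus offset,
band = max(20, 0.15·length)) rather than plain proximity so that adjacent
copies of the same family stay separate; each cluster is verified by an
edlib infix alignment of the seeded consensus span against the candidate
window. Hits require identity ≥ 0.7 over ≥ 50% of the consensus length;
overlapping hits keep the best identity.

A family is LOCAL when ≥ 80% of its mapped instances (an instance counts as
inside when ≥ 50% of its bases overlap the gene span, introns included) fall
in a single host gene — 0.8 promotes the observed "at least 80% within the
locus" summary into the decision threshold, as no other operational cutoff is
stated. Outside instances are annotated with two descriptive diagnostics —
shorter than the in-locus median length, and > 250 kb from the nearest other
outside instance — recorded as flags, never vetoes. Per-gene burdens count
instances (not families; a flag flips this), divided by gene span length in
kb; tandem burden counts overlapping arrays.

### Burden statistics

Gene classes differ in length, so comparisons draw equal-sized subsamples
matched per decile of the pooled log10-length distribution. Null ensembles
re-place the annotation's windows (length multiset preserved exactly,
windows non-overlapping within a permutation) uniformly over the genome, or
over unannotated space in intergenic mode; 100 permutations by default,
permutation i seeded seed + i. Group comparison is the two-sided
Mann–Whitney rank-sum test (scipy), with CDF tables emitted for plotting.
The power/calibration experiments use count-level simulation (per-gene
Poisson counts at 25 vs 6 LRs per 100 kb on log-normal gene lengths, equal
TR rates) — the regime in which a fourfold burden difference at 200 genes
per class is essentially always detected at p < 10⁻³ while the TR
comparison stays null.

### ChIP enrichment with multi-mapping reads

Reads aligning to n locations count 1/n at each, with n capped at the 20
best alignments (ties broken by coordinate). Coverage over a region set is
the mean weighted depth over the union of region bases, scaled per million
weighted reads so unequal library depths cannot pose as enrichment.
Enrichment = (ChIP + ε)/(input + ε) with ε = 0.1 per-million units on both
sides. Significance: 100 random region sets with the same length multiset,
drawn from non-N genome space (masked bases carry no alignments and would
deflate the rate), are scored identically; their mean enrichment is the rate
λ of a Poisson null, and p = P(X ≥ ⌈observed⌉) — the ceiling makes the
discrete test conservative on a continuous ratio.

The read simulator draws ChIP start positions with a fold-F weight over the
bound family and a background weight chosen so the family's coverage *ratio*
equals F: on a finite synthetic genome a plain multiplier is diluted by its
own contribution to the library total (at 16% bound fraction, a nominal
fold-10 realizes only ≈ 4), whereas a real genome's background is
effectively infinite. Each read is reported at every genomic position within
1 mismatch (pigeonhole on the two read halves), so reads from near-identical
repeat copies genuinely multi-map; no other sequencing-error model is
applied. Calibration experiments use a 20 kb genome, a 100 bp × 6-copy bound
family at 2% divergence, 50 bp reads at 100× depth, 100 null and 30 bound
replicates — sizes chosen to estimate the two rates with useful precision at
desk scale.

### Motif scanning

PFMs become log2-odds with a pseudocount of 0.8 per cell over the
background. Both strands are scanned; a window's match p-value is computed
exactly by dynamic programming over the per-column score distribution. For
widths ≤ 12 the DP states are exact partial sums accumulated left-to-right —
bit-for-bit identical to brute-force word enumeration — and wider motifs
fall back to a 10⁻⁴ score grid. Hits at p ≤ 10⁻⁶ are reported with
Benjamini–Hochberg q-values over all windows tested per motif (untested
corrections would be anti-conservative; unreported windows have larger
p-values, so hit ranks are global ranks).

### Phylogenetics

The built-in progressive aligner (guide order by single-linkage on shared
8-mer distance; profile-profile global DP at match +1, mismatch −1, gap open
−4, gap extend −1, diagonal-then-up tie-break) replaces an external MSA
tool; externally aligned FASTA is ingested verbatim via `--msa`. Distances
are Jukes–Cantor on gap/N-excluded columns (p-distance available);
saturation (p ≥ 0.75) maps to a ceiling of 10 substitutions/site so NJ stays
defined. Neighbor joining follows Saitou–Nei (minimize
Q(i,j) = (n−2)d(i,j) − r_i − r_j; label-order tie-break; negative branch
lengths clamped to 0 with the deficit moved to the sister). Bootstrap
supports are the percentage of column-resampled replicates (replicate i
seeded seed + i) containing each bipartition of the original-data tree; the
consensus report lists bipartitions above 50%. Supports are reported on the
original tree rather than a majority-rule consensus topology — the most
direct reading of the stated procedure; the >50% bipartition list covers the
other interpretation.

The two-clade ortholog regime (leaf branches 0.0537, stems 0.2321
substitutions/site under Jukes–Cantor) reproduces the observed ~90%
within-clade / ~60% cross-clade identity contrast; simulated orthologs are
indel-free by design, so their equal-length sequences are used directly as
alignment columns in the end-to-end experiments while the aligner is
exercised by its own tests.

## The synthetic-data generator

`firre_like` is the default study condition: one 500 kb chromosome at GC
0.45, 13 local families with consensus lengths 100–750 bp (median 167) and
copy numbers 3–40 (median 12) paired inversely so each family fits its
15 kb lncRNA-class host gene, divergence cycling 2–10%, 8 families fully
local and 5 at locality fraction 0.85, two dispersed families, five tandem
arrays (periods 3–120), 20 TE copies from a 2-element library, and 5
mRNA-class genes without planted repeats. Outside copies of a local family
are truncated to 60% of the consensus — the discriminating signal mirroring
the observation that dispersed instances are shorter than in-locus ones —
and placed ≥ 250 kb apart when the genome permits. Copy spacing within a
locus is uniform (no spacing distribution is stated anywhere authoritative).
`demo` is a 60 kb, 4-family version of the same structure for smoke tests
and determinism checks.

What the generator does *not* emulate: sequencing error beyond 1-mismatch
multi-mapping, paired-end reads, indel evolution in orthologs, GC
heterogeneity along the genome, nested/fragmented TEs, and segmental
duplications. Passing tests therefore demonstrate the statistical machinery
under the stated planted conditions, not robustness to every artefact of
real genomes.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere internally; GTF converts at
  the I/O boundary.
- All randomness flows from `numpy.random.default_rng(seed)`; replicated
  stages use seed + stream-index so any stage can be re-run in isolation.
- Ties: majority-vote bases break alphabetically; NJ joins break by label
  order; capped alignments break by coordinate.
- Zero-input guards: empty FASTA, zero-length intervals, all-N k-mers,
  empty region lists, < 2 instances, < 3 taxa, n_perm < 10 and n_boot < 2
  all raise with specific messages rather than degrading silently.
- The weighted-read total is computed as kept/n per read in one division, so
  weight sums are exact (not 20 × (1/20) float accumulation).

## Known limitations

- Discovery is gapless; families with frequent indels fragment or lose
  copies at the identity floor.
- The tandem detector is a lag-correlation contract replacement for a full
  alignment-based tool: no statistical score model, copy-number estimates
  are length/period, and borderline-purity arrays near 0.8 may fragment.
- The locality classifier needs a gene annotation; repeats local to an
  unannotated region are called DISPERSED.
- The Poisson null applies a discrete distribution to a continuous ratio;
  with λ ≈ 1 the test cannot reject below observed ≈ 4, making it
  conservative — adequate for the fold-10 regime it serves.
- NJ is consistent only on (near-)additive matrices; heavily saturated
  distance estimates can distort deep branches despite the JC ceiling.
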