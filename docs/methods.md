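# Methods

## Module extraction

The extraction procedure is a greedy, top-down search for the largest
non-overlapping, strongly intra-correlated subsets of a parent gene set in
SOMAmer space. Its assumptions: relative abundances are log10-transformed
and fully normalized upstream, so Pearson correlation is a meaningful
similarity; one sample per participant (the earliest visit, date ties
broken by smallest sample id) removes the pseudo-replication that repeat
visits would otherwise inject into correlation estimates; and the matrix
is complete — missing values are rejected at load rather than imputed,
since normalized SomaScan matrices contain none.

A single hierarchical-clustering dendrogram is built per round on the
distance d = 1 − r and cut at every K between `k_min` and `k_max`. With
the defaults K = 2..5 this considers ∑K = 14 raw clusters; nested cuts
regenerate identical member sets, which are deduplicated (first
occurrence, i.e. smallest K, kept) before ranking so that ranking operates
on distinct candidates. Clusters pass if their size n ≥ `n_min` (default
10, the conventional minimum pathway size) and their summary pairwise
correlation r̄ ≥ `r_min` (default 0.5, a deliberately conservative
robustness threshold). Ranking is size first, r̄ second; residual ties are
broken by the lexicographically smallest sorted member list so builds are
byte-reproducible. The winner becomes the next child, its rows and columns
are deleted, and the loop repeats until no candidate passes or fewer than
max(`n_min`, `k_max`) SOMAmers remain — both conditions are needed to make
the loop total.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k_min`, `k_max` | 2, 5 | dendrogram cut range (unitless cluster counts) |
| `n_min` | 10 | minimum module size (SOMAmers) |
| `r_min` | 0.5 | minimum summary pairwise Pearson correlation |
| `linkage_method` | `ward` | scipy linkage on d = 1 − r |
| `distance` | `signed` | d = 1 − r; `absolute` gives d = 1 − \|r\| |
| `statistic` | `mean` | summary of pairwise correlations; `median` available |

**Linkage.** Ward linkage on d = 1 − r is the default. Complete and
average linkage share a failure mode on this problem: merging two diffuse
background groups costs more (their maximum/mean pairwise distance is
large) than absorbing a single background feature into a tight cluster, so
the K = 2..5 cuts hand each tight block a halo of background SOMAmers. In
planted-block simulations (blocks of 20 and 12 at within-r 0.7–0.8, 500
samples) Ward recovers the blocks at Jaccard ≥ 0.9 in 50/50 seeds while
complete and average fail in all seeds. Both remain available through
`linkage_method` for users who want the classical agglomerative variants.

**Distance.** The signed transform d = 1 − r makes anti-correlated
SOMAmers maximally distant, so extracted modules are sign-coherent
(up- and down-regulated arms are never merged); 1 − |r| is available
behind the `distance` flag for users who want magnitude-only clustering.

**Summary statistic.** The mean of the n(n−1)/2 pairwise correlations is
the default; the median is available via `statistic="median"` and is more
robust to a few outlying pairs in large clusters. Which one a given
published repository used can matter near the 0.5 threshold, which is why
both are first-class options.

Correlation p-values (two-sided, from t = r√((m−2)/(1−r²)) on m−2 degrees
of freedom) are computed and carried along for reporting and network
export (`significant_links`), but play no role in extraction itself — the
gates are size and correlation magnitude, not significance.

## Symbol → SeqId translation

Translation maps each set's symbols through the annotation table
(many-to-many: one protein may have several SOMAmers and vice versa) and
takes the union of SeqIds, sorted and deduplicated. An exact symbol match
always wins; the alias table is consulted only when the direct lookup is
empty, so adding aliases can only grow a translated set, never change an
existing match. Aliases mapping to two different official symbols are
rejected at load — an arbitrary silent choice would make builds
untestable. Symbols compare case-sensitively. Parent identifiers encode
the set's 1-based position in the *source* collection, so identifiers are
stable when the `n_min` gate changes.

## Preranked GSEA

The engine implements the weighted Kolmogorov running-sum statistic. The
step variable is normalized so the running sum closes at zero; the ES is
the signed maximal |E_m|, with the first maximum taken on exact ties.
Member weights use scalar libm `pow` and a correctly rounded (`fsum`)
denominator so scores are bit-reproducible across platforms and agree
exactly with a naive reference evaluation.

Null distributions come from gene-set permutations: random same-size sets
drawn uniformly without replacement from the ranked universe (vectorized,
one `argsort` per batch). Three conventions are deliberate choices:

- **NES** divides the ES by the mean |null ES| over null draws *of the
  same sign* — the standard sign-stratified normalization that makes
  scores comparable across set sizes.
- **Nominal p** uses a +1 pseudocount in numerator and denominator, so it
  is never exactly zero and is conservative at the extremes (p = 1/(N+1)
  when the observed ES beats all N same-sign nulls). Only nominal p is
  reported; no multiple-testing correction is applied across a collection.
- **Per-set substreams**: each set's permutation stream is seeded from the
  root seed plus a CRC32 hash of the set id, so adding or removing sets
  from a collection never changes any other set's null, NES or p.

Degenerate cases: a set that is empty after restriction to the universe is
an error (skipped with a warning at collection level); a set spanning the
whole universe is an error (both step denominators vanish); if all member
scores are exactly zero under a positive weight, the member weights fall
back to uniform (the continuous p → 0 limit) with a warning. Ranked-list
ties are ordered identifier-ascending.

The rank metric is r = sign × (−log₁₀ p) with p floored at 1e−300 to keep
scores finite when upstream tools underflow. The differential models that
produce (sign, p) — moderated t-statistics, mixed-model likelihood-ratio
tests — are consumed as exported tables, not refit here; a bare OLS + Wald
helper exists solely to drive synthetic end-to-end runs.

## Parent/child characterization

For a parent set and one child module, three means over Pearson
correlations are reported: within-parent, within-child, and the cross
block between child members and parent-only members (undefined when the
child exhausts the parent). By default only the first child per parent is
summarized, as multi-child parents are rare. Enrichment comparisons use
paired Wilcoxon signed-rank and paired t-tests on |ES| (or |NES|),
two-sided, with the exact signed-rank null for up to 25 non-zero pairs and
a continuity-corrected normal approximation above; zero differences are
dropped by default (Pratt handling is configurable).

## Synthetic data

The generator draws zero-mean Gaussian samples from a block-structured
correlation matrix: planted blocks with a specified within-block r
(optionally split into anti-correlated arms via a sign pattern), a
background with configurable (default zero) correlation, and a
configurable block-versus-background cross-correlation, which may be
negative to reproduce the regime where extracted modules contrast with
their background. The implied matrix is validated positive semi-definite
at construction (eigenvalue tolerance −1e−8) and sampled through its
eigendecomposition. Ranked-list simulation plants an enriched set by
inflating −log₁₀ p by a constant shift with a consistent sign over a
Uniform(0,1) background.

What the generator does *not* emulate: SomaScan hybridization, plate and
volume effects (normalized away upstream), heavy-tailed or skewed
marginals, missingness, and the dependence structure of real biological
pathways. Passing tests therefore demonstrate the correctness and power
of the algorithms under clean, known truth — not that any particular real
cohort will yield modules of a particular size.

## Problem sizes

The test suite and the acceptance script run deliberately desk-scale
configurations chosen to make the checked properties sharp: 200 random
GSEA instances at n ≤ 50 for oracle equivalence; 50 seeded replicates of
62 SOMAmers × 500 samples for planted recovery; 100 random sets at 2000
permutations over a 500-feature universe for null calibration; 50
end-to-end replicates (45 SOMAmers × 300 samples, 1000-feature ranked
universe, shift 1.0 on the −log₁₀ p scale) for the parent-versus-child
comparison. Regenerating a full public repository from a complete
annotation and gene-set download is supported by the same code paths but
is a data-scale exercise, not part of the automated checks.

## Known limitations

- Top-down extraction cannot discover de novo modules outside annotated
  parent sets.
- Gene-set overlap/redundancy across a collection is not corrected.
- Only gene-set permutation nulls are implemented (no phenotype
  permutation, no FDR q-values, no leading-edge extraction).
- Pairwise-complete correlation on matrices with missing values is not
  supported; complete matrices are required.
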