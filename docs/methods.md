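# Methods

## Model and procedure

The unit of analysis is the *domain architecture*: the N-to-C ordered
sequence of superfamily domains and unassigned gap regions along a
protein. Two architectures are identical only if their token sequences
are identical — domain order, repeats and gap positions all matter.
Runs of consecutive gap tokens are collapsed to a single gap before
comparison, because the length of one unassigned stretch carries no
information at this resolution; leading and trailing gaps are retained.
An `ignore_gaps` switch removes gaps entirely for users who prefer
domain-composition identity.

For genome *g*, `N_d(g)` counts the distinct architectures containing
superfamily *d*. Counting runs over every protein row of the assignment
table with no length, score or isoform filtering; a domain repeated
within one architecture counts that architecture once. Duplicated
(genome, protein) input rows are an error rather than last-wins, since a
silent overwrite would hide upstream corruption.

The plasticity potential of a domain set is the median of its members'
`N_d(g)` (midpoint of the two central values at even cardinality). The
median, not the mean, keeps the statistic insensitive to the extremely
plastic outlier domains that dominate the right tail of the count
distribution.

### Randomisation null

The null resamples *B* domain sets of the same size, uniformly *without*
replacement, from the genome's annotatable repertoire — the domains
present in the genome that carry at least one annotation. Without
replacement because a domain set is a set; the annotatable restriction
keeps observed and null sets on the same support. For the same reason,
term members absent from the genome are dropped from the observed set
(effective size *k*) rather than scored as zero: the null can never draw
a zero-count domain, so scoring absences as zero would bias every term
downward. Terms whose effective set is empty are flagged
`not-scoreable`.

The null mean uses the sample mean and the null SD the *B*−1 (sample)
denominator. The exhaustive-enumeration oracle used in tests reports
population moments; at B = 2000 the O(1/B) discrepancy is far below the
Monte-Carlo error the tests allow for.

### P-values, degenerate nulls, FDR

The empirical p-value is directional: the fraction of null replicates
with median ≥ the observed value when the score is positive, ≤ when
negative, and 1 exactly at zero (maximally conservative). The raw
fraction can be 0 at resolution 1/B, so the default report is the
add-one form (1 + count)/(1 + B), which stays in (0, 1] and keeps the
FDR step well defined; `p_correction="raw"` restores the literal
fraction. When every replicate median is identical (σ = 0 — inevitable
when k equals the universe size, and possible on heavily tied count
distributions even at large B) the score is undefined and the row is
flagged `degenerate-null` rather than returned as ±∞.

FDR uses Benjamini–Hochberg step-up, by default across the scored terms
of one genome (scores are defined per genome); `fdr_family="global"`
pools all (term, node) pairs of a lineage trajectory instead.

Per-term RNG streams are derived from (seed, genome id, term id) through
a SHA-256 mix, so results are bit-reproducible and independent of term
iteration order. An optional `share_null_per_k` reuses one stream per
(genome, set size), a legitimate optimisation when many terms share a
size; the default keeps per-term streams.

### Ancestral repertoires

Each observed architecture is an independent presence/absence character
on a rooted, fully resolved binary species tree. Under Dollo parsimony —
justified by the rarity of convergent re-invention of the same
architecture — the minimum-event reconstruction is unique: one gain at
the most recent common ancestor of the possessing leaves, presence on
the minimal spanning subtree below it, losses at the maximal absent
subtrees. A brute-force search over all single-gain assignments confirms
this on every tree shape up to six leaves and on random eight-leaf
instances. Polytomies are rejected outright: resolving them arbitrarily
would silently change ancestral counts. Branch lengths are ignored;
unlabeled internal nodes get deterministic postorder ids. Reconstruction
is per-architecture; no joint constraint across architectures sharing
domains is imposed.

Ancestral `N_d` at internal node *v* counts the reconstructed present
architectures containing *d*. Lineage trajectories score every term at
every node on the root-to-leaf path, each node against its own
annotatable universe.

## Synthetic data: what it emulates, what it does not

The generator reproduces the three structural features the method relies
on: (1) per-superfamily architecture-count targets drawn from a Zipf law
(default exponent 3, placing ≈ 83 % of domains at a single architecture
with a long plastic tail); (2) genomes realised from those targets as
tandem-repeat architectures of each domain, which makes the rebuilt
count matrix reproduce the targets *exactly* — the round-trip oracle
behind the counting tests; (3) single-gain architecture evolution on a
pure-birth tree with independent per-branch losses (default 0.2),
returning the true presence matrix for reconstruction tests. An optional
mixed mode adds random two-domain architectures, trading exact count
control for combinatorial realism.

Real data differ in ways the generator deliberately omits: architectures
share domains combinatorially (tandem repeats decouple them), domain
insertions are biased toward protein termini, losses are not i.i.d.
across branches, and annotation sets overlap hierarchically. Passing
tests therefore demonstrate correctness of the machinery under the
model's own assumptions, not biological conclusions about any genome.

## Calibration diagnostics

Directional empirical p-values of a discrete median statistic are not
uniform under the null — ties concentrate them at a few values, and the
sign-conditional tail halves the range — although they remain valid
(super-uniform). The calibration suite therefore checks uniformity of
the randomised (fuzzy) upper-tail probability integral transform,
(G + V·(E + 1))/(B + 1) with V ~ U(0,1), which is exactly Uniform(0, 1)
for any discrete null when the observed set is itself a random draw.
The reported p-values are untouched by this; the transform exists only
as a diagnostic.

Planted-term recovery has an asymmetry worth knowing: on a power-law
universe the *low*-diversity term's members sit on the count-1 atom, the
very mode of the null, so no sample size can make it significant — only
its sign is recoverable (and even the sign is undefined when the null
collapses onto the atom entirely). The significance-based recovery suite
therefore uses a maximal-spread diversity profile (counts 1…n), where
both planted directions are always detectable; sign-only recovery is
checked separately under the power-law profile.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `B` | 2000 | null replicates; the floor recommended for stable tail estimates |
| `seed` | 0 | root of all derived RNG streams |
| `p_correction` | add-one | (1+count)/(1+B) vs raw count/B |
| `fdr_family` | per-genome | BH family: one genome's terms, or pooled |
| `share_null_per_k` | off | one null per (genome, k) across equal-size terms |
| `zipf_exponent` | 3.0 | synthetic diversity tail index (> 1) |
| `loss_prob` | 0.2 | per-branch architecture loss probability (< 1) |
| `ignore_gaps` | off | drop gap tokens from architecture identity |

## Problem sizes in the test suite

The statistical suites run at the scale the checks need, chosen as:
oracle-equivalence on universes of 3–12 domains at B = 20 000 over 20
seeds; calibration with 200 random terms on a 1000-superfamily genome at
B = 2000; planted-sign recovery over 100 replicates on a 100-domain
universe with k = 10; Dollo equivalence exhaustively to six leaves
(945 shapes × 63 patterns) plus 200 random eight-leaf instances and 1000
forward-simulated architectures on a 16-leaf tree.

## Known limitations

* The calibration band on the mean PP-score (±0.1 over 200 terms) is
  only ~1.5 standard errors wide; a small fraction of seeds will fall
  outside it by chance even with a perfectly calibrated null.
* Empirical p-values are bounded below by 1/(1+B); genome-wide scans at
  stringent FDR need B well above the default.
* Dollo parsimony underestimates ancestral repertoires whenever an
  architecture was lost in all sampled descendants of a lineage, and the
  reconstruction is conservative by design (reconstructed ⊆ true in the
  forward simulations).
* Ontology structure is taken as given: annotation files are assumed
  already propagated; no graph-aware (true-path) reasoning is performed.
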