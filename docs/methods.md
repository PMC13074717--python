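# Methods

haplokit analyses sequence variation at a single targeted locus surveyed by
direct Sanger sequencing across populations or managed collections. Its
reference use case is a conservation-genetics survey of a 594 bp coding
fragment of the antifreeze-protein gene *AnAFP* in the endangered desert
shrub *Ammopiptanthus nanus*: one wild population (Y, n = 29) and two ex
situ collections with contrasting management histories (T, n = 30, actively
managed; K, n = 16, passively maintained). The question such a survey asks
is whether rare sequence variants present in the wild are retained in the
collections, and whether an observed absence of variation can be explained
by sample-size disparity alone.

## Input model and curation rules

The input is a curated multiple-sequence alignment (equal-length rows over
`A C G T - N`) plus a sample→population map. Each row is one individual's
consensus sequence; because direct amplicon sequencing does not resolve
allelic phase, a "haplotype" throughout is a **consensus sequence class** —
a distinct combination of states over the variable columns — and all
carrier counts are individuals, not chromosomes.

Curation conventions, chosen to be conservative for Sanger consensus data:

- **Indels as characters.** Each gap-bearing column is an independent
  single-column indel site; the gap is a fifth character state. Adjacent
  gap columns are *not* merged into one event: the reference dataset's two
  indels are adjacent single-base events and are counted as two sites.
- **Ambiguity.** A column containing any `N` is excluded from variant
  calling and class definition entirely (not just for the affected record),
  mirroring the rule that positions that cannot be assigned unambiguously
  are dropped from sequence-class definition.
- **Reference state.** Absent an external reference sequence, the majority
  state at each variable column stands in as the reference allele in
  reports. For the bundled dataset this reproduces the conventional
  ref/var assignment (`-`/C at position 54, A/`-` at position 55).
- **Coding consequence.** Indel sites are annotated frameshift when the
  event span is not a multiple of 3. This is a reference-based in silico
  annotation only; the reports flag it as such.
- **Coordinates.** Columns are 0-based internally; every report is 1-based,
  and the fragment's first column is CDS position 1.

## Diversity statistics

For a population of n sequences over L columns:

- S — number of variable columns within the population (indels included).
- h — number of distinct sequence classes.
- Hd — Nei's haplotype diversity with small-sample correction,
  `Hd = n/(n-1) · (1 - Σ p_i²)`.
- k̄ — mean number of pairwise differences over all C(n,2) pairs, counting
  any state mismatch (including base↔gap) as one difference.
- π — nucleotide diversity per site, `π = k̄ / L`, normalised by the **full**
  alignment length L including indel and N-excluded columns. The
  alternative (excluding indel columns from L) was rejected because it
  cannot reproduce the reference dataset's printed per-site values
  (e.g. π = (29/435)/594 ≈ 0.00011 for T).

k̄ is carried as an exact rational (a ratio of integer totals) wherever an
exact zero matters.

### A note on the reference dataset's Y row

For the wild population Y (classes 22/4/3 across two variable sites) the
formulas above give Hd = 332/812 ≈ 0.409 and π ≈ 0.00074. The survey this
dataset reconstructs printed Hd = 0.197 and π = 0.00044 for the same
composition; those cells are arithmetically inconsistent with the printed
class counts under the standard estimators (no composition of 29 sequences
in 3 classes with 22 in the majority class yields Hd = 0.197). haplokit
follows the formulas and the counts; the Y-row Hd/π cells are therefore not
reproduction targets. The S, h, and carrier-count cells, and the T and K
rows, reproduce exactly.

## Hudson sequence-based FST

Pairwise differentiation uses the Hudson–Slatkin–Maddison sequence-based
estimator: `FST = 1 - Hw/Hb`, with `Hw = (k̄_A + k̄_B)/2` (unweighted) and
`Hb` the mean difference count over all n_A·n_B between-population pairs.
Computation is exact-rational; the T–K comparison yields Hw = Hb = 1/30
exactly, hence FST = 0.0000 — reproducing the published value and
illustrating why near-monomorphic comparisons are uninformative.

Properties worth knowing:

- Two populations with *identical polymorphic composition* give exactly
  `FST = -1/(n-1)` — the estimator's finite-sample bias, which vanishes as
  n grows. (Hw uses C(n,2) pair means, which exceed the between-population
  mean by the factor n/(n-1).) Identical monomorphic populations have
  Hb = 0; this degenerate case is reported as FST = 0 with a flag and a
  logged warning, since 1 − 0/0 is undefined.
- A fixed difference between two internally monomorphic populations gives
  FST = 1, the estimator's maximum.

The multi-population "overall" value uses unweighted means of the
per-population k̄ and of the pairwise between-means. For the reference
composition this gives 107/1645 ≈ 0.0650. The published pairwise values for
Y–T and Y–K and the published overall value are not reproducible from the
published counts under this (or any standard unweighted) form of the
estimator, so they are not reproduction targets; the estimator's property
tests stand in for them.

## Neutrality statistics

Tajima's D (1989) is computed with S counting indel sites and k̄ as above
(per pair, not per site): `D = (k̄ - S/a1) / sqrt(e1·S + e2·S(S-1))` with
the standard constant set (retained in the result object for audit). Fu &
Li's tests are implemented in their outgroup-free starred form D*/F* with
the corrected (Simonsen et al. 1995) coefficients, using η (mutations,
counted as states−1 per site) and η_s (singletons: non-majority states
carried by exactly one sequence). All statistics are reported NA when
S = 0, and require n ≥ 4. At the reference locus polymorphism is far too
low for these tests to carry inferential weight; they are reported for
completeness only.

## Rarefaction

To ask whether a monomorphic small collection could look monomorphic by
sampling alone, each larger population is repeatedly subsampled without
replacement to the smallest collection's size (g = 16 by default) for
B = 1000 replicates; each replicate records S and h within the subsample,
and the summary reports the proportion of replicates retaining polymorphism
(S > 0), means, sample standard deviations (ddof = 1), and 95% resampling
intervals taken as order statistics at ranks ⌈0.025·B⌉ and ⌊0.975·B⌋
(integers, no interpolation — reproducing interval reports like "1–2").
Retention is reported both to one decimal and as a nearest-integer percent,
the two styles such surveys print.

Closed-form oracles accompany the Monte-Carlo engine. A site whose minor
state has m carriers among N sequences segregates in a subsample of g with
probability `1 - [C(N-m,g) + C(m,g)]/C(N,g)`; summing over sites gives
E[S], and summing class-presence probabilities `1 - C(N-c,g)/C(N,g)` gives
E[h]. For the reference dataset these give E[S] = 1.8916 and E[h] = 2.8916
for Y and 16/30 ≈ 0.533 for T's singleton — the values the Monte-Carlo
means and retention fluctuate around (binomial SE at B = 1000 is ≈ 1.6
percentage points, which is why a published retention of 53.6% and a rerun
at another seed can differ by a few points while describing the same
distribution).

Reproducibility: each population's RNG stream is derived from
(seed, population label) via numpy's `SeedSequence`, so results are
bit-reproducible for a seed and adding a population never perturbs
another's draws.

## Median-joining network

Relationships among classes are summarised as a median-joining network over
the variable columns (all characters equally weighted; the gap is an
ordinary fifth state):

1. **ε-relaxed minimum-spanning links.** A candidate link (u,v) of Hamming
   weight w is retained iff `w ≤ f(u,v) + ε`, where f(u,v) is the minimax
   connection weight from a Kruskal sweep. ε = 0 (the default, matching the
   usual software default) retains exactly the union of all minimum
   spanning trees.
2. **Median insertion.** For every mutually linked triple, the per-column
   majority consensus is a candidate median vector; among unseen candidates
   that strictly reduce the spanning cost of the node set, the best
   (largest reduction; lexicographic key tie-break) is added, and the
   process repeats to fixpoint. Three-way column ties resolve to the state
   of the first node in label order — determinism is prioritised over
   matching any particular network program's byte output.
3. **Pruning.** Unobserved nodes of degree ≤ 2 are removed (lowest label
   first, links recomputed after each removal), so every surviving median
   vector is a genuine branching point.

The network's connection cost never exceeds the MST cost over observed
classes, and with ≤ 3 observed classes (as in the reference dataset, where
the network is the chain H2—H1—H3 with unit steps) it *is* the MST. On
two-site instances the construction is verified against exhaustive
Steiner-set search in the test suite.

## Synthetic data

`generate_alignment` realises a `PopulationSpec` — backbone length, planted
variant columns (substitution or single-column indel), classes defined by
carrier sets, per-population class counts, seed — as a concrete alignment:
random A/C/G/T backbone, variant states applied to carriers, record order
shuffled deterministically. Because every statistic in the package depends
only on the variant columns and class counts, the backbone content is
irrelevant by construction; this is also why the reference dataset
(`anafp_fixture`) is fully reconstructible from its printed composition
without the original sequences. The generator emulates curated consensus
alignments only: it plants clean variant columns on an arbitrary backbone
and does not model mutation processes, recombination, sequencing error, or
ambiguous sites — so passing tests certify the statistics pipeline, not
robustness to upstream curation failures.

`random_population_spec` draws specs for property tests: variant columns
without collision, class frequencies from a symmetric Dirichlet
(concentration configurable) realised as multinomial counts, population
sizes uniform on a range (default 8–30, the magnitude of the reference
collections).

## Problem sizes and numerical choices

The bundled analyses run at the reference survey's own scale (75 sequences,
594 columns, B = 1000 rarefaction replicates) in well under a second; the
randomized property tests use 50 specs for the Monte-Carlo/oracle
comparison and 100 small alignments (n ≤ 12) for the statistic oracles,
with agreement asserted to 1e-9 where computation is deterministic and to
4 Monte-Carlo standard errors where it is not. Exact rational arithmetic
decides every "exactly zero" claim (FST degeneracy, Hw = Hb); binomial
coefficients use exact integer arithmetic.

## Known limitations

- Single-locus scope: no multi-locus aggregation, no sliding windows, no
  confidence intervals on FST, and no significance testing of neutrality
  statistics.
- Indel handling is column-wise; a multi-column indel is counted once per
  column (the event-span argument to the consequence classifier exists
  precisely because the caller, not the alignment, knows the event length).
- The median-joining construction is the greedy cost-reducing variant
  described above; it is exact on the small instances checked exhaustively
  but, like all MJN heuristics, carries no global optimality guarantee.
- `N` is accepted but only as missing data; IUPAC ambiguity codes other
  than N are rejected rather than interpreted.
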