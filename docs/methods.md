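# Methods

## The food–nutrient network

A food-composition table lists, per food and nutrient, the amount contained
in one serving. After converting every amount to grams (metric mass units are
built in; non-mass units such as IU require an explicit per-nutrient factor
— there is no universal conversion, so none is silently applied), the table
pivots into the N×M weighted incidence matrix G. Link existence is strict
positivity, G_ia > 0; the binary incidence B drives everything set-based.
Foods with no nutrient rows are retained and flagged rather than dropped, so
record bookkeeping against the network stays aligned.

A record's nutrient profile is n = c f G with c = 1/Σ_ia f_i G_ia, which
puts n on the nutrient simplex. Nutritional distance is the unweighted
Jaccard distance between nutrient sets. Conventions for degenerate pairs:
two foods with empty nutrient sets get distance 0 (logged), an empty set
against a non-empty one gets 1 — both keep the matrix inside [0, 1]. The
food-similarity projection keeps edges with similarity s_ij = 1 − d_ij at or
above an inclusive threshold (default 0.85); a record's personal similarity
network is the subgraph induced by its consumed foods and is always an edge
subset of the reference projection at the same threshold.

Weighted (amount-sensitive) distances are deliberately not offered: nutrient
amounts span several orders of magnitude and would dominate any weighted
set comparison.

## Nestedness

NODF scores a binary matrix by pairwise overlaps: for rows i < j the term is
P_ij / min(k_i, k_j) (shared columns over the smaller degree) unless the
degrees tie, in which case the term is zero; column pairs contribute
symmetrically, and the total is divided by the number of row plus column
pairs. The tie rule makes the statistic invariant under row and column
permutations, so no pre-sorting is applied. Pair terms are totalled with
correctly-rounded summation (`math.fsum`), which makes the value independent
of evaluation order — a vectorized computation and an explicit pair loop
agree exactly, not just approximately.

Significance uses the bipartite configuration model: the maximum-entropy
distribution over bipartite graphs whose *expected* degree sequences equal
the observed ones, with link probabilities p_ia = x_i y_a / (1 + x_i y_a).
Full and empty rows/columns are peeled off first and pinned to p = 1 or 0
exactly (the peeling iterates, because pinning a full row can make a column
full or empty in the reduced problem); the remaining fitnesses are solved by
fixed-point iteration until every expected degree matches within 1e-8
(contractually ≤ 1e-6). The ensemble mean and standard deviation of NODF
are estimated from seeded Bernoulli samples (default 1,000) rather than by
analytic error propagation — identical contract, simpler to audit — and a
plug-in expectation (overlaps evaluated at the probability matrix) is
available as a cross-check. The test reports z = (observed − mean)/std and a
one-sided upper-tail normal p-value, the hypothesis being "more nested than
chance". A zero-variance ensemble (e.g. a complete bipartite graph, where
the model is fully frozen) is flagged degenerate instead of reporting z.

A structural fact worth knowing when interpreting z-scores: a *perfectly*
nested matrix is a threshold matrix — the unique matrix with its margins —
so its configuration model is frozen and nearly deterministic. Matrices
built as "perfect nesting plus noise" therefore score at or *below* their
degree-matched expectation; a strongly positive z requires overlap structure
beyond what the margins already force, which highly heterogeneous margins
leave no room for. The calibration property that a matrix drawn from a
fitted ensemble scores |z| ≤ 3 against its own refitted ensemble (≥ 95% of
draws) holds and is tested.

## Diversity and redundancy

Given a record's profile f (restricted to its consumed foods, where it sums
to one) and the pool distance matrix restricted to the same support:

* Gini-Simpson form: FD = GSI = 1 − Σ f_i², ND = Rao's Q = Σ_{i≠j} d_ij f_i
  f_j, NR = FD − ND. NR equals Σ_{i≠j} (1 − d_ij) f_i f_j, the expected
  nutrient overlap of two random food draws.
* Hill form of order q ≥ 0: FD_q = (Σ f_i^q)^{1/(1−q)}, with the entropy
  exponential at q = 1 (closed form, not a numerical limit). ND_q(Q′) uses
  the modified matrix Δ′ — off-diagonal distances unchanged, diagonal
  λ_i = mean distance from food i to the others (computed over the record's
  own food set) — and Q′ = Σ_ij d′_ij f_i f_j:
  ND_q(Q′) = [Σ_ij (d′_ij/Q′)(f_i f_j)^q]^{1/(2(1−q))} · Q′, with the
  exponential form at q = 1. NR_q = FD_q − ND_q(Q′), computed as a literal
  difference so the decomposition FD = ND + NR is exact to machine
  precision.

Degenerate conventions: a single-food record, or Q′ = 0 (all foods
nutritionally identical), gives ND = 0 and hence NR = FD — consistent with
the identical-foods extreme, where nutrient profiles coincide across any
diet. GSI relates to the order-2 Hill number by GSI = 1 − 1/FD_2. Zero
abundances are excluded from all sums (relevant for q ≤ 1).

Restricting the pool distance matrix to each record's support is an
optimisation for the quadratic (GSI/Rao) forms, where zero-abundance foods
contribute nothing; for the Hill form it is a semantic choice — the λ_i
diagonal averages over the record's own foods, not the whole pool — made so
that a record's redundancy depends only on what was actually eaten.

NR_q is continuous at q = 1 but not flat: its derivative in q scales with
the effective number of foods (roughly 1.5–3 for 20-food simplex profiles),
so finite differences at offset δ from q = 1 are of order a few × δ. The
suite asserts the linear shrinkage of that difference rather than a fixed
absolute band.

## Null models

Network randomizations (on B; distances are rebuilt from the randomized
incidence): **fnn1** places the same number of links uniformly; **fnn2**
redraws each food's nutrients keeping its degree; **fnn3** redraws each
nutrient's foods keeping its degree; **fnn4** preserves both degree
sequences exactly via checkerboard (2×2 swap) MCMC with 10×L swap attempts,
each swap preserving both margins by construction (a matrix with no
checkerboard — e.g. perfectly nested — is returned unchanged with a
warning).

Composition randomizations (records against the fixed network): **comp1**
reassigns each record's abundance values to a uniformly drawn food subset of
the pool with the same richness; **comp2** permutes the non-zero abundances
within each record across its own consumed foods; **comp3** permutes each
food's non-zero abundances across the records that consume it. The comp2
and comp3 scopes are the readings that keep record richness and per-food
consumer sets fixed while breaking the abundance–identity pairing; the
wider scopes (whole pool, all records) are available behind a
``whole_pool`` flag.

The observed-versus-null summary is a paired sign-flip permutation test
(default 10,000 resamples, seeded) on the median per-record difference
between observed NR and the per-record null mean across replicates,
one-sided for observed > null.

## Beta diversity and personalization

Bray-Curtis, root Jensen-Shannon divergence (log base 2, so disjoint
profiles score exactly 1), Yue-Clayton distance, and negative Spearman
correlation (raw −ρ, range [−1, 1], average ranks at ties). The first three
are symmetric, zero on identical profiles and bounded by [0, 1]; rJSD is a
metric. The personalization test compares intra-individual (same subject,
different timepoints) to inter-individual pairwise dissimilarities via
median(intra) − median(inter), with a one-sided subject-label permutation
test; permuting labels preserves the per-subject record counts, so the
intra pair count is invariant across permutations.

## Synthetic data

The generator supplies what restricted cohort data would: a composition
table with a nested incidence and a longitudinal cohort with personal food
signatures.

* **Network**: a perfect prefix ("triangular") incidence — row i filled in
  the first ⌈M(N−i)/N⌉ columns, giving decreasing fills and, when N = M,
  strictly distinct degrees both ways and NODF exactly 1 — degraded by
  moving a (1 − nestedness) fraction of links to uniformly random empty
  cells. Links that are last in their row or column are never moved, so the
  requested N×M shape survives the pivot. Nutrient amounts are log-uniform
  over three decades (1 mg–1 g per serving), mirroring the orders-of-
  magnitude spread of real composition tables. Foods split into 9
  contiguous groups.
* **Cohort**: each subject draws a Dirichlet preference vector over foods;
  each record mixes it (weight w = personalization, default 0.8) with a
  fresh draw, samples a richness from a truncated negative binomial
  (default mean 15, dispersion 5, floor 2 — sparse, overdispersed records
  like real recall data), picks that many foods weighted by the mix, and
  assigns abundances from a symmetric Dirichlet (concentration 1) scaled by
  the mix. Records are emitted in grams (2,000 g total). The noiseless
  limit (infinite concentration, zero richness dispersion) makes a
  fully-personalized subject's records identical — useful as an exact
  fixture. Everything is reproducible from the parameter object and its
  seed.

Default study conditions used by the acceptance script and the end-to-end
tests: 200 foods × 40 nutrients at nestedness 0.9; 50 subjects × 4
timepoints at personalization 0.8. Null-model contrasts use 100 replicates;
the personalization null calibration uses 100 independent small cohorts
(12 subjects × 3 timepoints, 300 permutations each). These sizes were
chosen as the smallest at which the directional effects are unambiguous.

What the generator does *not* emulate: real nutrient ontologies and their
correlated sub-nutrients (fatty-acid and amino-acid families), FNDDS
marginal amount distributions, seasonal or secular drift in diets, and
measurement error of recall instruments. Passing tests therefore
demonstrate the correctness and directional behaviour of the estimators,
not cohort-level effect sizes; headline numbers from restricted cohort data
are not reproduction targets.

## Known limitations

* The Jaccard distance ignores amounts entirely; two foods sharing trace
  quantities of the same nutrients are nutritionally identical to it.
* The configuration-model z-test is sampled, not analytic; with 1,000
  samples the standard error of the ensemble mean is about std/32, which is
  ample for directional conclusions but not for precise tail p-values.
* fnn4's checkerboard chain is run for a fixed attempt budget (10×L), which
  mixes well at desk scale but carries no formal mixing guarantee.
* Redundancy values depend on the nutrient resolution of the composition
  table; coarser nutrient panels mechanically raise overlap and hence NR.
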