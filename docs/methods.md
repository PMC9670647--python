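# Methods

`exposcreen` implements an ecological, exposome-wide screening pipeline for
county-level pregnancy-related mortality (PRM). The unit of analysis is the
U.S. county (keyed by 5-digit FIPS code); the outcome is the PRM *ratio* —
pregnancy-related deaths per 100,000 live births, with deaths and births
each summed over a 4-year window — computed for the total population and
for three race/ethnicity strata (non-Hispanic White, non-Hispanic Black,
Hispanic). Exposures are a counties × variables numeric table in which each
variable carries one of five exposome domains: built, social, natural,
health, and policy.

## Outcome construction and inclusion

A county enters the analysis for a stratum only when it recorded at least
`min_births` (default 1000, boundary inclusive) live births for that
stratum over the window. The rule stabilises the ratio: with few births, a
single death produces an artifactually enormous ratio. Exclusion never
depends on the death count, so zero-death counties are retained with a
ratio of exactly 0. Ratios are computed in exact rational arithmetic
(`Fraction`) before the final float conversion, so printed values are free
of intermediate rounding.

## Variable reduction

Exposure repositories are rife with repeated and collinear measures. Two
variables are treated as *autocorrelates* — informationally redundant —
when their Pearson correlation reaches 0.9. The reduction stage:

1. **Normality screen.** Shapiro–Wilk per variable, Benjamini–Hochberg
   FDR adjustment across variables (step-up: sort ascending,
   `adj_(i) = min_{j≥i} p_(j)·m/j`, capped at 1). The screen is
   informational: flags are logged, and Pearson is used regardless by
   default (a Spearman fallback exists but is off), because switching the
   measure per variable would make correlations incomparable across pairs.
2. **Autocorrelation graph.** A simple undirected graph with a vertex per
   variable and an edge for every autocorrelate pair. The default reads
   "at least 0.9" literally as signed r ≥ 0.9; an `absolute` mode (|r| ≥
   0.9) is available because near-perfect negative correlates are arguably
   duplicates too. The boundary is inclusive, implemented with a 1e-12
   slack so pairs whose correlation is exactly the threshold are not lost
   to floating-point rounding.
3. **Minimum dominating set.** The smallest vertex set S such that every
   variable is in S or adjacent to a member of S; variables outside S are
   removed. Solved exactly as an integer linear program (minimise Σx_v
   s.t. x_v + Σ_{u∈N(v)} x_u ≥ 1, x binary) with the HiGHS solver behind
   `scipy.optimize.milp`. A tiny secondary objective (per-vertex
   perturbations summing to < 1/2) makes the solver prefer alphabetically
   earlier variable names among optimal sets, so output is deterministic
   without affecting cardinality. The domination certificate is re-checked
   on every output. A greedy 1+ln(Δ+1)-approximation is available behind a
   flag for graphs too large for exact solution.
4. **Name filter.** Confidence-limit and margin-of-error variables are
   removed by case-insensitive name patterns (configurable; short tokens
   such as "moe" match only on word boundaries). In the synthetic data the
   planted uncertainty companions are exact copies of their sources, so
   they already fall to the dominating-set step; on real repositories,
   where uncertainty columns are correlated but not identical to their
   point estimates, this filter is the stage that removes them.

All pairwise correlations use pairwise-complete observations (missing
values are never imputed) with a minimum-overlap floor (`min_pairs`,
default 30 counties); pairs below the floor or with a constant margin have
no defined correlation and induce no edge.

## Supervised screening

For each stratum, the reduced table is restricted to included counties and
the PRM ratio is appended by FIPS linkage. Every exposure variable is
correlated with the outcome; entries are sorted by |r| descending with
alphabetical tie-breaks (published screens of this kind interleave signs
in descending magnitude, so magnitude is the sort key), subdivided into
the five domain sublists, and flagged as retained when |r| > 0.15
(strict). With four strata this yields the 24 lists (4 × [1 combined + 5
domain]) that downstream stages consume. The retention rule is on
magnitude because protective (negative) correlates are as informative as
risk (positive) ones. No multiplicity control is applied at this stage —
screening is deliberately permissive; inference happens downstream.

## Unsupervised paraclique mining

A complete weighted graph over all variables (outcome vertices included)
is thresholded at |r| ≥ t for t ∈ {0.15, 0.2, 0.3, 0.5, 0.7, 0.8} — data
inhomogeneity rules out a single threshold. For each graph and glom term
g ∈ {1, 2, 3}:

* the exact maximum clique is found by branch-and-bound with a
  greedy-colouring upper bound and lexicographic vertex order
  (deterministic; a configurable node budget guards against pathological
  dense graphs, with the error advising a higher threshold);
* the clique is *glommed*: every outside vertex adjacent to at least
  |seed| − g seed members joins. The one-pass rule evaluates candidates
  against the seed only, which preserves the closed-form density
  guarantee density ≥ [C(s,2) + m(s−g)] / C(s+m,2); an iterated variant
  (re-evaluating against the growing member set) is available for
  comparison but has no such guarantee;
* the paraclique's members are deleted and extraction repeats until the
  maximum clique falls below `min_clique` (default 3 — size-2 "cliques"
  are not dense subgraphs in any useful sense). Extracted paracliques are
  therefore pairwise vertex-disjoint. `glom()` itself rejects g ≥ |seed|
  (every vertex would join); during iterated extraction, late rounds whose
  seed clique is smaller than g clamp the term to |seed| − 1 rather than
  abort the loop.

A paraclique is retained for interpretation when it contains at least one
PRM ratio vertex.

## Bayesian network learning

Over each top-k screened list (per domain, plus a combined "overall" list;
k = 20) together with the outcome node, a directed acyclic graph is
learned by greedy hill-climbing on the decomposable linear-Gaussian BIC
score: per node, `logLik − (p/2)·ln N` with the MLE residual variance and
p = |parents| + 2 (maximising this is identical to minimising the common
−2·logLik + p·ln N form). Search starts from the empty DAG and applies the
single best arc addition, deletion, or reversal (steepest ascent) until no
move improves the score; ties break lexicographically on (move type,
parent, child), so runs are deterministic without random restarts. A
variance floor of 1e-12 guards exact collinearity; rank-deficient parent
sets are rejected naming the collinear parents; rows with missing values
are dropped complete-case per network. Variables are continuous rates and
percentages, so no discretisation is applied, and no standardisation by
default (a flagless design: the BIC of a linear-Gaussian model is
invariant to affine rescaling of individual variables).

The outcome node's parents in the learned DAG are its **direct
predictors**; the Markov blanket (parents, children, co-parents) and the
ancestor set are reported separately rather than conflated. No causal
reading is attached: greedy BIC search identifies a Markov-equivalence
representative, and the data are ecological.

Greedy search without restarts can stop in a single-move local optimum. On
three-node benchmarks with coefficients drawn uniform(−1, 1), the search
attains the exhaustively enumerated global optimum in roughly 9 of 10
simulated datasets; every miss is a certified local optimum (the
certificate is re-checked independently of the search bookkeeping) and
occurs at weak, near-unidentifiable coefficients.

## Synthetic data: what it emulates, and what it does not

Because the real inputs are restricted-use, the package generates data
with the structure the analysis assumes. All constructions are
equicorrelated Gaussian (x = √r·factor + √(1−r)·noise) so every planted
pairwise correlation is analytically known:

* **blocks** (default 10 × 4 variables at r = 0.95 > 0.9): each becomes a
  clique/connected component of the autocorrelation graph, and a clique is
  dominated by any single member, so the dominating set keeps exactly one
  representative per block;
* **clusters** (default 3 × 8 variables at r = 0.3): below the 0.9
  reduction threshold, above the paraclique thresholds. Cluster 1's latent
  factor is the *deprivation* score;
* **outcome**: births uniform on 500–20,000 (so a small fraction of
  counties falls under the 1000-birth rule, exercising inclusion),
  partitioned into strata by Dirichlet shares with means (0.60, 0.15,
  0.20, 0.05) and per-stratum rate multipliers (NH Black 2.2, NH White
  0.8, Hispanic 0.9) emulating the observed disparity; deaths Poisson with
  mean births × ratio/10⁵, log ratio = log 25 + 0.4·deprivation +
  0.1·noise. The log-linear link keeps rates positive; the emitted outcome
  is still the raw ratio the method analyses.

The model-implied correlation between a cluster-1 variable and the
*realized* ratio is computed in closed form — Cov(x, Y) = √c·β·E[R],
Var(Y) = Var(R) + 10⁵·E[R]·E[1/B] (log-normal spread plus Poisson
sampling attenuation, E[1/B] over included counties) — and recorded in the
truth record; the defaults give ≈ 0.25. This value was verified against
direct simulation at n = 20,000 before being relied on in tests. At the
standard 2000 counties the single-dataset sampling noise of a screened
correlation is ≈ 0.02, so recovery checks compare seed-averaged screened
values, not single draws, to the design value.

Deliberately not emulated: the 62,000-variable scale of a real repository,
spatial autocorrelation between neighbouring counties, non-Gaussian
marginals (real exposures are skewed rates and counts), and missingness
mechanisms. Passing tests therefore certify the algorithms — exactness of
the dominating set and clique solvers, the glom and density certificates,
score-based search behaviour, recovery of planted correlation structure —
not robustness to the messiness of real exposure data.

## Problem sizes and numerical choices

Default study conditions run 2000 counties and ~100 variables; the test
suite uses 300–500 counties for per-module checks and the full 2000 ×
5-seed design for recovery properties, which completes in seconds.
Exactness checks compare the ILP dominating set and the branch-and-bound
clique against brute-force enumeration on hundreds of random graphs of up
to 15 vertices, where exhaustive search is tractable. Threshold
comparisons carry a 1e-12 inclusive slack; correlations are clipped to
[−1, 1]; graph round-trip serialisation preserves weights to 6 decimals.
All randomness flows from a single integer seed through one
`numpy.random.Generator` per dataset, so every artifact is reproducible
byte-for-byte (run reports carry a content digest).
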