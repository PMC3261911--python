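# Methods

## The hierarchical model and its assumptions

The model is a discrete-generation, age-structured branching process in
the mean-field (average-count) approximation. Its assumptions:

* cells update synchronously once per generation; real time enters only
  through the division rate R (generations per day), k = R·t;
* CSC division outcomes are independent across cells and generations, so
  mean counts obey linear recursions and depend on the division-type
  probabilities only through δ = p₂ − p₀;
* CCs double deterministically (unit probability) until age N, then
  convert to the senescent pool *without a final division*, and newly
  senescent cells are first exposed to the death probability d one
  generation after conversion (B′ = (1 − d)B + C_N). This convention
  reproduces two structural facts of the model: the asymptotic senescent
  fraction (1 − δ)/(1 + δ + 2d) is independent of N, and it reaches 100%
  at δ = 0, d → 0. Alternative conventions (a final doubling into two
  senescent cells, same-step death) preserve the qualitative behavior but
  change the asymptotic coefficients;
* no cell–cell interactions, no spatial structure, no resource limits —
  branching-process idealizations that are least reliable in vivo.

The SA-β-gal–positive fraction of an experiment is identified with the
model's senescent fraction B/(S + ΣC + B).

## Closed forms and numerical choices

For a unit CSC seed, S(k) = (1+δ)^k, C_i(k) = (1−δ)2^{i−1}(1+δ)^{k−i}
for i ≤ min(k, N), and B(k) = (1−δ)2^{N−1}[(1+δ)^{k−N} − (1−d)^{k−N}]/(δ+d)
for k ≥ N. For a unit CC seed spread uniformly over ages 1..N, the age-j
cohort doubles N−j times, converts 2^{N−j}/N cells at generation N−j+1,
and decays by (1−d) per generation thereafter; it carries no CSCs, so it
is a transient contribution whenever δ > 0. A mixed initial condition
with CSC fraction f is the linear superposition of the two solutions,
with initial scale fixed to 1.

Numerical care:

* removable singularities (δ + d → 0 in the senescent pool; δ → 1 in the
  CC geometric sum) switch to their analytic limits inside a 1e−9 window,
  avoiding catastrophic cancellation;
* non-integer generation index: the closed forms are evaluated directly
  at real k, which bridges each exponential term geometrically between
  integer generations. At integer k this equals the recursion exactly
  (tested to 1e−12 over a grid including δ ∈ {−0.1, 0, 0.2, 0.9},
  N ∈ {1, 2, 5}, d ∈ {0, 0.1, 1}), and for the homeostatic case it
  reduces *exactly* to the continuous CPD formula
  CPD = k (k ≤ N), N − 1 + log₂(k − N + 2) (k > N);
* converged asymptotic fractions are obtained by iterating the recursion
  with per-step renormalization (the recursion is linear, so fractions
  are unchanged while overflow is impossible), stopping after five
  consecutive per-generation fraction changes below 1e−13 past the
  initial N-generation transient.

The stochastic null model follows the same pattern: recursion
C′ = (1+p−q−α)C, B′ = (1−d)B + αC, explicit solution with the analytic
limit at g = 1−d, and steady-state fractions
((p−q−α+d)/(p−q+d), α/(p−q+d)) in the growing regime. When senescent
decay dominates growth and the senescence channel is open, all cells end
senescent, (0, 1); a population that dies out entirely has no defined
fractions and raises a tagged error rather than returning NaN. Starting
from pure CCs the ratio B/C obeys a monotone linear map, so the senescent
fraction approaches its limit monotonically — no parameter choice can
produce an interior peak, which is the model-discriminating property.

## Monte-Carlo simulator

Generation-synchronous individual-based sampling with integer counts:
CSC division types are drawn from a multinomial (implemented as nested
conditional binomials), CC doubling and aging are deterministic, and
senescent survival is binomial. One master seed spawns per-realization
streams (`numpy` `SeedSequence.spawn`), so ensembles are bit-reproducible
and an ensemble of size one equals the corresponding single realization.
A population cap (default 10⁷ cells) freezes a run and flags it truncated
to keep desk-scale runtimes; mean-field comparison tests use parameters
that never reach the cap. The simulator also reports the fraction of
realizations in which the CSC lineage went extinct — demographic noise
that the mean-field recursion cannot show.

## Observables and fitting

CPD = log₂ x(t)/x₀. The joint melanoma-style fit stacks weighted
residuals of up to four curves (CPD and senescent fraction for each of
two subpopulations) that share (δ, N, d, R) and differ only in their
initial CSC fraction f. Choices, where the procedure was genuinely open:

* weights default to 1/σ per point when uncertainties are provided, unit
  otherwise; optional per-curve-type multipliers expose the documented
  sensitivity that precise growth curves can dominate the fit and
  suppress the senescence peak of the CSC-rich curve;
* N is continuous during optimization (a gradient method cannot step an
  integer) and rounded only for reporting;
* optimizer: `scipy.optimize.least_squares` (trust-region reflective,
  bounded: δ ∈ (−0.9, 0.999), N ∈ [1, 500], d ∈ [0, 1], R ∈ (0.05, 5],
  f ∈ [0, 1]) with multi-start — one data-driven start (early CPD slope
  → R; late slope → R·log₂(1+δ); senescence-peak day → N/R) plus
  seeded random starts, 16 total by default;
* covariance: Gauss–Newton (JᵀWJ)⁻¹ scaled by reduced χ²; t-statistic =
  estimate/SE. Non-convergence and parameters pinned at bounds are
  reported as flags on the result, never exceptions.

The homeostatic two-parameter (N, R) fit flags "senescence not
identifiable" when the fitted crossover N/R falls beyond the last
observation day: an exactly exponential CPD curve makes the likelihood
flat in N past that point, so the flag is tied to the observation window
rather than to the box bound alone.

An optional diagnostic compares the uniform-age CC initialization against
the steady-state age profile of the same model with a smaller senescence
generation (emulating cells sorted out of a younger culture). The growth
curves depend weakly on this unobservable choice (a few percent of the
CPD scale at the melanoma-like parameters), which justifies fitting with
the uniform-age closed form; the senescence-fraction transient is more
sensitive mid-course but re-converges once the initial cohorts have
senesced.

## Synthetic data: what it emulates, and what it does not

The growth-experiment generator evaluates the exact model at a
twice-weekly (3/4-day alternating) schedule over 140 days and adds
observation noise: Gaussian on CPD (default σ = 0.2, counting error) and
binomial scoring of 200 cells for the senescence fraction (the
mechanistic counterpart of scoring a stained field; a Gaussian mode with
clipping count is provided for χ² calibration studies). Default
subpopulation fractions f ∈ {0.05, 0.002} with δ = 0.15, N = 100,
d = 0.05, R = 1.1 place the senescence peak of the CSC-poor population
near day 91 and none for the CSC-rich one. The MSC generator produces
CPD-only homeostatic curves (default 25 points over 60 days, R = 0.9)
with per-donor N for donor-age panels. The colony generator draws
non-touching disks (≥ 2 px separation) with exact label-map truth.

Because the data are generated by the fitted model itself, passing
recovery tests demonstrates correctness and identifiability of the
*pipeline*, not of the biology: real cultures have passage-to-passage
correlations, imperfect sorting, marker reversibility and
non-branching-process interactions that these generators deliberately
omit.

## Treatments

Both drugs are sustained parameter changes from an onset generation.
Senescence induction replaces N by a smaller n_treated (over-age cohorts
convert on the next step — the handling of pre-existing older cohorts is
a convention, as is the sustained schedule); death induction multiplies
each CC's survival by (1 − p_d) per generation before division, with
CSCs drug-resistant. Neither touches the CSC recursion, so the
asymptotic growth rate (1 + δ) is provably unchanged; tests assert slope
equality to 1e−3 and CSC-fraction enrichment. The drug-induced excess
senescent fraction decays to zero under the senescence drug (the
asymptote is N-independent); a sustained death drug shifts the asymptotic
composition permanently while still sparing the growth rate.

## Colony analysis

Hand-rolled Otsu thresholding (256-bin between-class-variance maximum;
ties across a flat inter-mode gap resolve to the first maximizer, as in
standard implementations) with configurable polarity; Hoshen–Kopelman
labeling as a single raster pass with union-find (path halving) and dense
renumbering, for 4- or 8-connectivity (default 8: diagonally touching
colony pixels belong together); cluster statistics discard specks below
5 px by default. The labeler is verified against an independent
flood-fill oracle (`scipy.ndimage.label`) on random grids, and the Otsu
implementation against scikit-image's, which are never used in the
pipeline itself. Automatic thresholding stands in for manual
color selection, whose numeric threshold is not recoverable.

## Problem sizes and limitations

Default test and acceptance runs use 10⁴ Monte-Carlo realizations to 15
generations, 20 fit replicates of 164-point four-curve datasets, 100
random 64×64 grids and 256×256 plates — sizes chosen so the full suite
completes in well under a minute per component on one CPU while keeping
3-SE statistical checks meaningful. Known limitations: mean-field
recursions say nothing about extinction or demographic variance (use the
Monte-Carlo module); the fit assumes independent Gaussian/binomial
observation noise, while real CPD curves accumulate rescaling errors
across passages; N is a sharp threshold, whereas biological senescence
onset is dispersed; and treatments are idealized as permanent, perfectly
selective parameter changes.
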