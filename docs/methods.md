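# Methods

## Model

A participant's day-by-day behavioural record is modelled as a discrete-time
Markov chain over flattened pairs `(M, m)`: a slow clinical macro-state `M`
and a fast digital micro-state `m`, one transition per day. The two time
scales are expressed through the matrix structure, not through separate
processes: within-block transition mass (micro dynamics under a fixed
regime) is large, cross-block mass (regime changes) is small, so macro
sojourns are geometrically distributed with mean `1/(1 − dwell)` days —
weeks to months for dwell near 1 — while micro-states move daily.

Assumptions worth stating explicitly:

- **Homogeneity.** `P` is constant over time; covariate- or
  treatment-driven drift is out of scope.
- **First-order dependence.** Tomorrow's pair depends only on today's.
  Real behavioural streams have longer memory; the markers are defined on
  the best first-order description.
- **Stationarity for analytic markers.** The entropy rate
  `H = −Σ_i π_i Σ_j P_ij log₂ P_ij` weights rows by the unique stationary
  distribution, so irreducibility is checked (strongly-connected-component
  analysis of the positive-entry graph) before any stationary solve.
  Reducible inputs raise an error naming the communicating classes.
- `0·log 0 = 0`, logarithms base 2, units bits/day throughout.

## Macro-centric conditioning

The within-block sub-matrix of one macro-state is not stochastic (its rows
leak cross-macro mass). The conditional micro chain `P̃(M)` renormalizes
each within-block row to sum to one — the micro dynamics given that the
macro-state does not change — and `H_M` is the entropy rate of that chain
under its own stationary vector `π̃(M)`. Two constructions of `π̃(M)` are
defensible: the stationary vector of the renormalized block (default) or
the block slice of the global `π`, renormalized (`pi_source="global"`).
They differ when leak mass is asymmetric across micro-states; the default
is the entropy rate of the self-contained conditional process, which is
what the finite-window estimator below converges to.

When cross-macro mass is exactly zero, conditioning is the identity and
`H_M` equals the entropy rate of the standalone block — a property the test
suite checks exactly.

## Mixing and recurrence

`mixing_time(chain, ε)` is the smallest `t` with
`max_i TV(P^t[i,·], π) ≤ ε`, computed by repeated matrix powering with a
hard cap (default 10⁵ steps; periodic chains never mix and raise). The
default ε = 0.25 is the standard convention. `mean_recurrence_time` is
Kac's identity `1/π_i`. Both are proposed as flexibility/inertia proxies:
a long mixing time means the process takes long to forget its starting
condition; a long recurrence time of a low-complexity state means a sticky,
possibly maladaptive pattern.

## Finite-window plug-in estimation

Within a window of `T` days the transition probabilities are estimated by
row-normalized adjacent-pair counts, and the occupancy by the frequencies of
the first `T−1` symbols (transition sources), so the weighting matches the
counted transitions exactly. The occupancy is deliberately *not* the
stationary vector of the estimated matrix: source frequencies are
finite-sample stable and are the standard plug-in choice. Optional Laplace
smoothing (`pseudo_count`) exists but defaults to zero; unobserved
transitions drop out of the entropy sum.

The estimator is consistent (error < 0.01 at `T = 10⁵` in the tests) but
biased downward at small `T`, most strongly for high-entropy blocks, since
rare transitions are counted as zeros. The macro × T grids expose exactly
this signature: means rise monotonically toward the analytic value through
`T ∈ {15, 30, 90}` (the default grid). Windowed estimates are aggregated as
mean ± sd/√n over windows; with overlapping windows (step < T) estimates are
positively correlated and the SE is optimistic, so a non-overlapping mode
(step = T) and a replicate-level aggregation (`aggregate="replicates"`,
10 independent groups) are provided.

Conditional windows are simulated directly from the renormalized block
chain, started from `π̃(M)`, rather than by cutting fully-contained windows
out of free-running trajectories: with realistic dwell times a 90-day
window inside one macro run is vanishingly rare, and the block chain *is*
the process whose `H_M` the estimator targets. Segmentation of labelled
free-running trajectories (`macro_window_segments`, windows advancing by
`step` inside maximal macro runs) is available for realism and is how the
trajectory-based grid flags thin cells rather than failing.

## Symbolization and static measures

Ordinal symbolization maps each window of `order` consecutive values to its
rank permutation (ties broken earlier-index-first; invariant under strictly
monotone transforms; alphabet size `order!`). Approximate entropy follows
the classical definition: self-matches included, Chebyshev distance,
`r` defaulting to 0.2·sd. Lempel–Ziv complexity is the LZ76
exhaustive-history phrase count; block entropy is the Shannon entropy of
overlapping `k`-blocks, whose increment `H(2) − H(1)` estimates a Markov
chain's entropy rate. Each has an independent brute-force oracle in the
test suite (direct double-loop ApEn, a phrase-by-phrase LZ76 parser).

The threshold mapping from numeric features to the illustrative micro
alphabet `{R, W, N, F}` is plumbing only: how real device data map onto
behavioural micro-states is a study-design question this package cannot
settle, and the defaults make no clinical claim.

## Regime-shift detection

When macro labels are unobserved, sliding-window plug-in entropy over the
micro stream approximates the macro-centric rate of the prevailing regime,
so regime changes appear as mean shifts in the entropy series. Two
statistics are offered: maximum centered cumulative-sum excursion (CUSUM,
default) and best variance-reducing split (binary segmentation); both are
applied recursively and stopped by a permutation rule — the finite-B
permutation p-value (observed statistic included, a valid p-value under the
exchangeable null) at level α = 0.05 with 1000 reshuffles by default.
A fixed `threshold·sd` rule is available for online use. Detection is
invariant to adding a constant to the series.

Two practical caveats, both visible in the tests:

- Overlapping windows autocorrelate the entropy series and the permutation
  null assumes exchangeability, so step = T (non-overlapping) is the
  recommended setting for calibrated inference; with step = 1 the detector
  over-segments.
- Segment means carry the short-window downward bias, so classifying
  segments against *analytic* `H_M` references misassigns regimes at small
  `T`; the right references at window length `T` are the finite-`T`
  expected estimates (e.g. from `conditional_entropy_grid` at the same
  `T`), which is what the tests use.

`classify_regime` assigns the nearest reference value, returns
"indeterminate" when two references fall within a configurable band, and
breaks exact ties by label order. The "sustained deviation" alarm
(K = 3 consecutive windows outside baseline ± 2 sd) operationalizes
baseline-departure monitoring.

## Synthetic chain generator

`ChainRecipe` builds chains from interpretable parameters: per-macro daily
dwell probability (macro time scale), preference weights (where leaked mass
goes), and a Dirichlet concentration per macro (within-block entropy: rows
are drawn from a symmetric Dirichlet, so concentration → ∞ gives uniform
rows and `H_M → log₂ n_micro`, concentration < 1 gives peaked, low-entropy
rows). Cross-macro mass lands on destination micro-states proportionally to
the destination block's stationary distribution, keeping the scales
separable. The defaults (dwell 0.93–0.99, concentrations 8/6/2/0.8/4 over
five regimes A–E) sketch a plausible clinical trajectory with a persistent,
low-entropy stable regime; they are a demonstration, not a fit to any
dataset. Construction is exact: rows sum to one to machine precision and
`recover_recipe` round-trips dwell to 1e-9.

What the generator does *not* emulate: non-geometric dwell distributions,
time-varying transition probabilities, observation noise in the micro
symbols, and missing days. Passing tests on generated chains therefore show
estimator and detector correctness under the model's own assumptions, not
performance on real device data.

## The packaged reference matrix

The 20-state matrix ships digit-for-digit as printed in its source. Its
rows sum to between ≈ 0.55 and ≈ 1.05, so `validate_and_normalize` divides
each row by its sum, records the original sums, and warns for deviations
above 1% (18 of 20 rows). The source also prints analytic results for this
matrix (stable-state occupancy 0.5959, global rate ≈ 1.0 bits/day,
macro-centric rates 1.720/1.674/1.128/0.632/1.582); none of them follow
from the printed digits under row normalization, nor under the row repairs
we tried (missing mass to the diagonal, spread within the block, block
rescaling, transposition) — for instance the printed D rows leak ≈ 17% of
their (normalized) mass per day toward E while E returns ≈ 4%, which no row
repair can reconcile with D holding 60% occupancy. The exact generating
parameters were published only in a supplement that is not available, so
the package treats the printed digits as the data and reports what they
imply, keeping the discrepancy auditable in the normalization report. All
structural claims (block dominance of D as printed, modal ordering among
A–D, bias and separation signatures) are tested against the normalized
matrix itself.

## Numerical choices

- Stationary vectors: constrained least squares on `[Pᵀ − I; 1ᵀ]`, with a
  power-iteration fallback when the solve is ill-conditioned; both routes
  agree to 1e-9 on seeded random chains, and every returned vector satisfies
  `‖πP − π‖₁ < 1e-9`.
- Row stochasticity is enforced to 1e-9 after normalization; inverse-CDF
  sampling guards the final cumulative bin at exactly 1.
- Simulation splits one `SeedSequence` deterministically across replicate
  streams, so (chain, T, n_reps, seed) is bit-reproducible.
- Problem sizes in the shipped tests: 10⁶-day simulation oracles for
  stationary/recurrence/dwell checks (batch-means standard errors, since
  visits are autocorrelated), 200 windows per grid cell, 100 seeded runs ×
  500 permutations for detector error rates. These sizes give standard
  errors comfortably below the effects being checked.

## Known limitations

- No hidden-Markov inference of macro-states: labels are either given,
  simulated, or inferred indirectly via entropy-level classification.
- No bias-corrected entropy estimators (Miller–Madow, NSB); the plug-in
  estimator is the point of comparison, and its bias is characterized
  rather than removed.
- Permutation calibration assumes exchangeability within segments; strongly
  autocorrelated series (overlapping windows) inflate the false-alarm rate.
- Continuous-time dynamics, covariate effects and population-prior
  initialization are out of scope.
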