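# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `lagcausal`. Notation: **X** is an N-dimensional
stationary discrete-time process observed at T time points; lags τ are in
units of the sampling interval (2.8 s for the motor-task defaults).

## Assumptions

The discovered graph carries causal meaning under Causal Sufficiency (no
unobserved common drivers), the Causal Markov Condition and Faithfulness,
plus the absence of contemporaneous effects: any influence faster than
the sampling interval would appear at lag 0 and is *not* treated as
causal. Accordingly no lag-0 link is ever tested, stored or used; every
array over lags keeps index 0 as a structural placeholder (identity for
Ψ, zero for Φ).

## Discovery

**PC1 parent pre-selection.** For each target X^j_t, all N·τ_max lagged
components start as candidates. At cardinality q the algorithm tests each
candidate against the target conditional on the q strongest *other*
remaining candidates (one condition set per cardinality — the polynomial
PC1 variant, not full subset search), removing candidates with
p > pc_alpha after each sweep. A candidate's strength is its minimum
absolute statistic across sweeps; ties break by (source, lag) ascending so
runs are reproducible. `pc_alpha` defaults to `alpha`; `max_conds` can cap
q, and is otherwise unlimited (q is naturally bounded by the surviving
parent count).

**MCI.** Every ordered pair (i, j) and lag τ = 1..τ_max is tested
conditional on P(X^j_t) \ {X^i_{t−τ}} together with P(X^i_{t−τ}) shifted
by τ. Conditioning on the driver's own parents removes the
autocorrelation pathway that inflates false positives in pairwise
methods; on independent AR(1) series the measured cross-link detection
rate is statistically compatible with α (see `scripts/acceptance.py`).

**Windows and effective samples.** PC-phase tests use the common window
of length T − τ_max. MCI conditions reach lags up to 2τ_max (shifted
parents), so all MCI tests share a window of length T − 2τ_max; one
n_eff per phase, identical across tests. Analysis requires
T ≥ 2(τ_max + 1).

**Thresholding.** Links are retained at raw p ≤ α, treating α as a
regularization/model-selection knob (the number of tests makes calibrated
simultaneous inference impossible); optional Benjamini–Hochberg
correction over all lagged links is available but off by default.

**Complexity.** The PC phase needs at most N³τ_max² tests (complete
graph, iteratively increasing cardinality) and MCI exactly N²τ_max.
`count_ci_tests` exposes the bound; every run counts its actual tests and
asserts the bound. At N = 14, τ_max = 15 the bound is 620,340; a typical
fixture run uses ~6,000.

## Conditional-independence tests

**Partial correlation.** x and y are residualized on [1, Z] by least
squares; the residual correlation r is referred to a two-sided Student-t
null, t = r √(df / (1 − r²)), df = n − |Z| − 2. Singular designs raise
(no pseudo-inverse silently absorbing collinearity); n < |Z| + 3 raises.

**k-NN CMI.** Maximum-norm distances in the joint space X⊗Y⊗Z; ε_i is the
distance to the k-th neighbor of point i (self excluded); counts k_xz,
k_yz, k_z are the numbers of points *strictly* closer than ε_i in the
subspaces, each count including the point itself. Then
Î = ψ(k) + mean[ψ(k_z) − ψ(k_xz) − ψ(k_yz)]. With empty Z the estimator
degrades to the standard k-NN mutual-information form
ψ(k) + ψ(n) − mean[ψ(k_x) + ψ(k_y)]. Numerical choices: a deterministic
seeded jitter of 1e−10 × column scale breaks exact duplicates (which
would give zero ε); strict counting is implemented by shrinking the ball
radius by one ulp; estimates are not clipped at zero — small negative
values are estimator noise, and the test uses the permutation null, not
the sign. The permutation scheme shuffles x wholesale (a restricted
local-permutation scheme preserving the marginal dependence on Z would be
an improvement; the simple scheme is measured as adequately calibrated in
the test suite). p = (1 + #{permuted ≥ observed}) / (B + 1); B < 19 is
flagged since the smallest attainable p then exceeds 0.05. Defaults
k = 10, B = 200.

Default test: partial correlation (analytic, fast; appropriate for the
linear effect layer). The k-NN test is pluggable everywhere, and is the
estimator used by decomposed transfer entropy.

## Effect quantification

**Path coefficients Φ.** One joint least-squares regression per target on
all of its discovered parents over the common window, with intercept, on
standardized data — so coefficients are effects per standard deviation.
Joint (not pairwise) regression is required for path-coefficient
semantics. Non-parents are exactly zero. Collinear parent designs raise,
naming the offending parents.

**Causal effects Ψ.** Ψ(0) = I, Ψ(τ) = Σ_{s=1}^{τ} Φ(s) Ψ(τ−s). This is
the standard impulse-response accumulation of a linear lagged system: the
(j, i) entry at lag τ sums coefficient products over *every* directed
path i → j whose link lags total τ. It is verified two independent ways
in the tests: explicit path enumeration on sparse models, and noiseless
unit-impulse simulation of the generator (agreement < 1e−10 over 100
random stable models).

**Mediation.** Φ^{(k)} zeroes every coefficient whose *target* is k,
which removes all paths through k at any lag; Ψ^{(k)} follows from the
same recursion and MCE = Ψ − Ψ^{(k)}. When disjoint mediators partition
the paths of a pair, their MCEs sum to the pair's CE (tested on diamond
graphs).

**Aggregates.** CE^max_{i→j} = max_{0<τ≤τ_max} |Ψ_{ji}(τ)|;
ACE_i = mean_{j≠i} CE^max_{i→j}; ACS_j = mean_{i≠j} CE^max_{i→j};
AMCE_k = mean over C_k of max_τ |MCE_k(τ)|, where C_k is the set of
ordered pairs (i, j), i ≠ j, both ≠ k, that have at least one directed
path through k with total lag ≤ τ_max. Membership in C_k is decided
*structurally* (boolean path reachability on the link graph), not by
MCE ≠ 0 — parallel paths can cancel to a zero MCE while a path exists,
and such pairs legitimately belong to the average. AMCE = 0 when C_k is
empty. Matrix orientation is fixed once — first index target, second
source — and all exports re-label to explicit (source, target) columns.

**Mediation graphs.** For a query (i, j, τ) the time-resolved graph
places each link at every admissible offset and keeps exactly the nodes
lying on at least one directed path from i@t−τ to j@t (intersection of
descendants of the source and ancestors of the target in the unrolled
DAG). Nodes carry their MCE for the pair, edges the fitted coefficient;
a summary form collapses time. No connecting path yields an empty result,
not an error. Negative coefficients and effects are preserved end to end:
a negative CE means the source counteracts the other influences on the
target.

**Decomposed transfer entropy.** TE_{i→j} is estimated as
Σ_{τ=1}^{τ*} I(X^i_{t−τ}; X^j_t | S_τ) with S_τ = P(X^j_t) \ {X^i_{t−τ}}
∪ (P(X^i_{t−τ}) shifted by τ), each term by the k-NN estimator. The
graph-derived condition sets replace the infinite past with a finite
sufficient subset — and exclude irrelevant variables entirely, which the
tests verify by invariance to added disconnected components. If the
condition dimension is infeasible for the sample size the call fails
with advice to set `max_conds` (which truncates to the strongest
conditions).

## Synthetic generator

The generator realizes X_t = Σ_τ Φ(τ) X_{t−τ} + ε_t with sparse
user-specified links and i.i.d. Gaussian innovations (the noise law is a
modeling choice; nothing downstream assumes it beyond the tests' use of
Gaussian closed forms). Models are validated before simulation: duplicate
links and out-of-range indices raise, and the companion-matrix spectral
radius must be < 1, so every accepted model is stationary. Burn-in
defaults to 10 × max_lag and is discarded.

Innovation SDs are, in the generator's standard mode, calibrated (via the
discrete Lyapunov equation) so every component has unit stationary
variance. The data are then generated on the standardized scale and link
coefficients read directly as effects per standard deviation — without
this, standardized-scale regression recovers attenuated versions of the
generating coefficients and recovery bias cannot be assessed cleanly.

The packaged 14-ROI example network mimics a visually cued motor task:
moderate autolinks everywhere (0.40/0.45 — BOLD series are strongly
autocorrelated), and 14 cross-links at lags 1–5 tracing
visual → motor → premotor/thalamus/frontal pathways, including one
negative (counteracting) thalamic link. The study-scale fixture is
T = 280 samples at a 2.8 s interval.

An optional smoothing stage convolves each column with a positive
gamma-shaped kernel and decimates to a coarser sampling interval
(default 2.8 s when emulating BOLD). This is a stand-in for hemodynamic
blurring, not a physiological model: it reproduces the *sluggishness* of
BOLD, not its nonlinearity, vascular delays or physiological noise.
Consequently, passing tests demonstrate correctness of the statistical
machinery on processes with the stated structure — autocorrelated,
lag-sparse, linear, Gaussian — and calibration/power at realistic sample
sizes; they do not demonstrate that real BOLD series satisfy the
assumptions (indirect measurement, varying hemodynamics and inter-subject
variability remain genuine caveats for fMRI applications).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| τ_max | 15 | maximum tested lag (samples); choose where the lagged-dependence screen decays (`suggest_tau_max`, threshold 0.2 on absolute correlation) |
| α | 0.01 | link-retention threshold on raw p (regularization knob) |
| pc_alpha | = α | pre-selection threshold |
| CI test | parcorr | `cmiknn` for nonlinear dependence |
| k (CMI) | 10 | joint-space neighbors |
| B (permutations) | 200 | smallest p = 1/(B+1) |
| standardize | on | required for comparable Φ/Ψ scales |
| detrend | off | linear detrend before standardization |
| sampling interval | 2.8 s | recorded in all outputs |

Validation problem sizes (acceptance script and test suite) are chosen so
the whole suite runs in minutes on one core while keeping Monte-Carlo
error well inside the asserted tolerances: 50 replicates for estimator
calibration and false-positive measurement, 20 for recovery bias, 100
random models for the oracle equivalences, and the full 14-ROI, T = 280
fixture for the end-to-end run.

## Design choices made where the design was open

- The effect recursion is implemented in its standard impulse-response
  form (Ψ(τ) = Σ Φ(s)Ψ(τ−s) with Ψ(0) = I); path blocking zeroes
  coefficients *into* the mediator. Both choices are validated against
  brute-force oracles rather than taken on faith.
- The MCI phase uses a T − 2τ_max window so that shifted-parent
  conditions never index before the series start and all MCI tests share
  one n_eff.
- ROI labels must be unique (they name fixture files and export columns);
  the packaged ROI table uses ThalL/ThalR for the bilateral thalamus
  alongside the conventional Brodmann-area abbreviations.
- Missing values are rejected, never imputed: lagged causal analysis is
  sensitive to temporal structure and silent imputation can manufacture
  or destroy links.
- The CI test is pluggable in every stage rather than fixed, since linear
  and model-free tests trade power against generality; defaults favor the
  linear test that matches the linear effect layer.

## Known limitations

- Causal Sufficiency is assumed; no latent-confounder discovery.
- No contemporaneous-link handling: effects faster than the sampling
  interval are invisible by design.
- CE/MCE are linear measures even when discovery used the model-free
  test; no nonlinear effect quantification.
- Single-subject analysis only: aggregating graphs across subjects raises
  questions (inter-individual variability in timing and hemodynamics)
  that this package deliberately does not answer.
- The permutation scheme for the CMI test is the simple full shuffle;
  a local permutation scheme would preserve the X–Z dependence under H0
  more faithfully at small n.
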