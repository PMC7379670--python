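# Methods

## Model

A removal study exposes a closed population of `N` animals to capture;
captured animals are removed permanently.  Animals move between two latent
states — on site and available (state 1), off site and unavailable
(state 2) — so availability itself is a hidden Markov process.  Sampling
follows a robust design: primary periods `i = 1..T`, the `i`-th containing
secondary occasions `j = 1..k_i`.  The population is closed within a
primary period; between primaries `i` and `i+1` each remaining animal moves
1→2 with probability `phi12_i` and 2→1 with probability `phi21_i`
(first-order Markov).  The initial availability is `pi`; capture
probability at occasion `(i, j)` is `p_ij`.  With `D` animals removed and
`n0 = N − D` never removed, each animal falls into one of `K + 1`
multinomial cells ("removed at `(i, j)`" or "never removed") whose
probabilities follow from the forward recursion over the 2-vector of
state-occupancy-and-not-yet-removed probabilities.  Within a primary no
transition is applied between secondaries; a missing occasion simply has
`p = 0`.

The log-likelihood is the multinomial

    l = ln G(N+1) − ln G(n0+1) − Σ ln(n_ij!) + n0 ln L0 + Σ n_ij ln L_ij

with the gamma function replacing factorials so `n0` (hence `N`) is
estimated as a continuous parameter.  The multinomial coefficient is
included, so maximised log-likelihoods and AIC are comparable across models
on the same data.  Several populations removed independently (age groups,
species) multiply their likelihoods; shared parameters — capture
probabilities, baseline transitions, additive logit offsets `gamma_w` on
`phi12` for groups `w ≥ 2` — make the integrated model more precise than
separate fits.

Numerical note: the forward recursion is carried out in linear probability
space.  Its state is bounded below by `exp(K ln(1−p_max))`, which for any
realistic study length stays many orders of magnitude above double-precision
underflow, so no rescaling is applied; logs are taken once per cell.

## Constraints and model codes

The saturated model (`pi`, all `p_ij`, all `phi12_i`, `phi21_i`, `n0`) has
`K + 2T` parameters against `K` observed counts and cannot be estimated.
Constraints, named by one-letter codes, restore identifiability:

* `S` — `pi` is the mean over transitions of the first element of the
  stationary distribution of `Phi_i`, i.e.
  `pi = (1/(T−1)) Σ phi21_i / (phi12_i + phi21_i)`.
* `R` — random emigration, `phi12 + phi21 = 1` (the chance of being off
  site next period does not depend on the current state); `E` — even flow,
  `phi12 = phi21`; `V` — `phi12 + phi21 = v` with `v ∈ (0, 2)` an extra
  parameter.
* `t` — time-varying transitions; `2` — the last two transitions equal
  (transitions `T−2` and `T−1` in the convention that transition `i` acts
  between primaries `i` and `i+1`).
* `a` — additive group offset: `logit(phi12_{i,w}) = logit(phi12_i) + gamma_w`.
* `C` / `Z` / `T` — capture probability constant, logit-linear in a
  per-occasion covariate (`logit p_ij = alpha + beta z_ij`), or fully
  time-dependent.

Codes concatenate as `[R-|IR-]<pi><phi><p>` (`R-` robust design, `IR-`
integrated; no prefix for the single-secondary layout), e.g. `R-SRtC`,
`NNC`, `IR-S1,2RatZ` (subscripts after `S` name the populations whose
initial state is stationary).

Parameter counting follows two conventions, selected by the
`include_abundance` flag: AIC counts one `n0` per population; the
redundancy diagnostics exclude `n0`, since the cell probabilities do not
involve it.

## Estimation

Free parameters live on unconstrained scales — logit for probabilities,
`log` for `n0`, `logit(v/2)` for `v`, untransformed regression
coefficients — and the likelihood is maximised by L-BFGS with, by default,
10 random restarts around moment-flavoured starting values (capture
probability from the first within-primary depletion ratio, availability and
transitions at 0.5, `n0` at `D/2`).  Restarts matter because near-redundant
models have flat, multimodal surfaces.  Estimates whose logit exceeds 9.21
in absolute value (probability within 1e-4 of 0 or 1), or `n0 < 1e-4`, are
flagged as boundary estimates.

Standard errors come from the numerically differentiated observed
information (central differences, relative step 1e-4), transformed to the
natural scale by the delta method; `N̂ = n0 + D` inherits the `n0` standard
error.  At a boundary, or when the information is singular, standard errors
are withheld and the nonparametric bootstrap is the supported route.

The bootstrap resamples, within each population, the `D` observed removal
records over the occasion cells (multinomial with `D` fixed) and refits,
reporting empirical SDs and percentile intervals; a parametric alternative
(redraw full datasets from the fitted cells with index `round(N̂)`) is
available behind `scheme="parametric"`.  Resamples that fail to converge
are dropped and counted.  The record-resampling scheme conditions on `D`,
so it understates the component of abundance uncertainty coming from the
binomial variation of `D` itself; for the capture and transition parameters
the two schemes agree closely.

## Simulators and scenarios

Two generators produce removal data: an individual-based walk through the
state chain, and a direct multinomial draw from the cell probabilities.
They are distributionally identical (the suite checks pooled cell
frequencies by chi-square) and both are driven by per-replicate child
streams of a master seed, so any replicate is reproducible in isolation.

The scenario presets fix the study conditions used throughout the tests and
the acceptance script: two secondaries per primary, capture probability
0.3, random-emigration transitions, and abundance 500 (single population)
or 300/200 (integrated).  `const-s1`/`const-s2` use constant `phi12` 0.8 /
0.4 ("tend to stay off site" / "on site"); `tv-s1`/`tv-s2` use the
time-varying series `(0.8, 0.7, 0.8, 0.3, 0.6, 0.7, 0.8, 0.6, 0.6)` and
`(0.4, 0.4, 0.8, 0.4, 0.4, 0.8, 0.4, 0.4, 0.4)` at K = 20 (and
`(0.7, 0.2, 0.7, 0.7)`, `(0.3, 0.8, 0.3, 0.3)` at K = 10); the integrated
presets shift population 2 by `gamma_2 = −0.5` on the logit scale.  `pi` is
always the mean stationary availability implied by the transitions.  The
generator emulates demographic closure exactly: no births, deaths or
permanent emigration, no individual heterogeneity in `p`, and covariates
affecting capture only.  Passing recovery tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not
robustness to the heterogeneity, trap response or open-population dynamics
real data may contain.

Recovery studies in the tests and the acceptance script use 100 replicates
(200 for the baseline-bias demonstration) with 2 optimiser restarts per
fit; these sizes give Monte-Carlo error comfortably inside the asserted
tolerances (mean p̂ within 0.02, mean N̂ within 25, mean `gamma_2` within
0.15) while keeping a full run around a minute.

## Parameter-redundancy diagnostics

A model is parameter redundant (deficiency `d > 0`) when the map from
parameters to the sampling distribution is not locally injective.  The
diagnostic uses the cell probabilities as an exhaustive summary
`kappa(theta)` (length `K + 1` per population, `n0` excluded) and computes
`d = h − rank(d kappa / d theta)` numerically: central finite-difference
Jacobians (step 1e-5 on the natural scale) at five random interior
parameter draws, SVD, singular values above `1e-8 × s_max` counted, rank
the maximum over draws (the rank of an analytic matrix attains its generic
value almost everywhere; random draws avoid non-generic points).  The rank
is stable across draws and step sizes, which the suite asserts.  Covariate
models are evaluated with a fixed standardised synthetic covariate series,
since their rank requires covariate variation.

Full-rank models can still be *near redundant*: some eigenvalue of the
expected information `N Jᵀ diag(1/kappa) J` is nearly zero at relevant
parameter values and the corresponding combination is practically
inestimable.  The package flags near redundancy when the
smallest-to-largest eigenvalue ratio falls below 1e-6 at scenario-style
truths.  This classification is inherently threshold- and scenario-
dependent: with the default threshold only models whose information is
numerically singular at those truths flag (for instance the
free-everything robust model, whose truths sit exactly on the
random-emigration surface), and moderately ill-conditioned models (ratios
1e-5 to 1e-1) do not.  Users studying a specific design should inspect the
reported eigenvalue ratio rather than the flag alone.

For deficient models the estimable parameter combinations can be verified:
`estimable_combinations_check` constructs parameter pairs on a common level
set of the claimed combinations (step along the combination null space,
Gauss–Newton projection back) and requires identical cell probabilities to
1e-8, plus discrimination — different combination values must move the
cells.  For the single-secondary constant models the verified combinations
are `{pi·p, phi21·p, (phi12−1)p − phi12 − phi21}` (free model),
`{pi·p, (phi12−1)p}` (free `pi`, random emigration) and `{(phi12−1)p}`
(stationary `pi`, random emigration).  The third expression in the first
set is `trace(M) − 2` of the between-occasion update matrix
`M = [[ (1−p)(1−phi12), phi21 ], [ (1−p)phi12, 1−phi21 ]]`; note that it is
`phi21·p`, not `phi12·p`, that is estimable — level-set tracing shows
`phi12·p` varies freely along the non-identifiable direction.

## Geometric removal model baseline

The Moran–Zippin geometric removal model is the special case `pi = 1`,
`phi12 = 0` with occasions flattened to a single index (the suite asserts
exact nesting).  Its continuous-`n0` maximum differs slightly from the
textbook closed-form estimator, which implicitly replaces the digamma by
its log approximation: for catches (100, 60, 36) the closed form gives
exactly `(N, p) = (250, 0.4)` while the exact multinomial maximum over
integer `N` is `(247, 0.407)`; the package matches the exact optimum.
Fitted to data with temporary emigration, the GRM attributes
unavailability to low catchability: it underestimates `p` and reports all
of `n0` as animals still present, overstating the number actually
remaining on site at the end of the study — the quantity a mitigation
project is judged on — by an order of magnitude in the off-site-leaning
scenario.

## Design choices and limitations

* The single-secondary layout is simply a robust design with `k_i = 1`; no
  separate code path exists.
* Missing occasions are carried in the design and handled by forcing
  `p = 0`, which contributes nothing to the likelihood and permits no
  removals; how field studies should handle missed visits is a design
  question the package does not answer.
* `n0` is reported on its continuous scale (no integer rounding); an
  integer profile search is easy to build from `log_likelihood` and is used
  as an oracle in the tests.
* Mortality, recruitment, more than two latent states, non-Markovian
  emigration, spatial structure and Bayesian inference are out of scope.
* Symbolic redundancy analysis is not attempted; the numeric surrogate
  spot-checks specific designs (ranks verified at K = 8–20) and does not
  prove results for all `K`.
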