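# Methods

## The lineage model

`nsclineage` models the adult neurogenic lineage of the mouse
ventricular–subventricular zone as a compartmental ODE system in
whole-region cell counts: quiescent NSCs `Q`, active NSCs `A`, a chain of
`n + 1` transient-amplifying-progenitor (TAP) compartments `T0..Tn`
representing successive amplification divisions, and neuroblasts `N`:

    dQ/dt  = -r Q + 2 b pA A
    dA/dt  =  r Q - pA A
    dT0/dt = 2 (1 - b) pA A - pT T0
    dTi/dt = 2 pT T(i-1) - pT Ti          (1 <= i <= n)
    dN/dt  = 2 pT Tn - delta N

Quiescent cells activate at rate `r`; an active NSC divides at rate `pA`
either into two NSCs (probability `b`, the self-renewal fraction) or into
two TAPs.  TAPs amplify at rate `pT` through `n` doubling steps
(`n = 3` by default, after the biological estimate of three
amplification divisions) and mature into neuroblasts, which leave the
system at rate `delta`.

The structural rates are fixed at `pA = 0.95/day`, `pT = 0.81/day`,
`delta = 0.19/day`, and the total initial NSC pool at `NSC0 = 1900`
cells; these values are treated as known constants of the system, not
fitted, except where a perturbation experiment explicitly frees them.

## Feedback scenarios

The system parameters `r` and `b` are not constants but Hill-type
functions of lineage population sizes,

    r(c1, c2) = (r1 + r0 c1) / (K + c2),     b(c3) = b0 / (1 + beta c3),

where each `ci` is one of `Q`, `A`, `Q+A`, `T0`, `sumT`, `N`.  A
*scenario* is a wiring of these three slots.  The registry contains the
five canonical wild-type scenarios

    r(Q,A),b(A)    r(Q,A),b(Q)    r(Q,A),b(N)    r(Q+A),b(Q+A)    r(Q,T0),b(N)

(the shorthand `r(c)` means `r(c, c)`), their `+r1` extensions in which
the basal production term `r1 > 0` models activation driven by
non-lineage (niche) cells — used for the interferon-receptor knock-out
setting — and the Delta-Notch-Wnt scenario `r(Q,Q+A),b(Q)`.

## Steady states and stability

Because `dQ/dt + dA/dt = (2b - 1) pA A` exactly, the NSC pool can only
grow while the realized self-renewal exceeds one half.  For
`b0 <= 1/2` the only equilibrium is extinction and the pool is
monotonically non-increasing; for `b0 > 1/2` a unique positive
equilibrium appears at which `b = 1/2` exactly, pinning the inhibitor
population at `c3 = (2 b0 - 1)/beta`.

`steady_states` exploits this structure instead of a blind root search:
given the active pool `A`, the downstream cascade at equilibrium is
linear (`T0 = pA A / pT`, `Ti = 2 T(i-1)`, `N = 2^(n+1) pA A / delta`),
`Q` is the positive root of the quadratic obtained from `dA/dt = 0`, and
the single remaining condition `beta*c3(A) = 2 b0 - 1` is solved by a
bracketed scalar root-find in `A`, followed by a full-system `fsolve`
polish.  The bracket search fails exactly when `b0 <= 1/2`, so the
bifurcation threshold emerges numerically rather than from a hard-coded
test on `b0`.  (A damped-Newton search on the full system from the
closed-form seed of the `b(A)` scenario was considered; the scalar
reduction is exact for every registered scenario and cannot diverge, so
it was preferred.)

Stability is assessed from the eigenvalues of a forward-difference
Jacobian (forward so probes stay in the nonnegative orthant).  The
trivial equilibrium of the wild-type model is linearly degenerate — the
activation term is quadratic near the origin, contributing a zero
eigenvalue — so a marginal spectrum is resolved by a nonlinear probe of
the pool growth `d(Q+A)/dt` under a small perturbation of `A`, whose
sign is that of `2 b0 - 1`.

## Simulation

LSODA with `rtol = 1e-8`, `atol = 1e-10` by default (the explicit-signal
model is stiff at large kinetic speed-ups, and the lineage system itself
mixes day-scale division with year-scale population drift).  Fitting
loops use `rtol = 1e-6`, `atol = 1e-8` — well below the measurement
noise they serve.  The right-hand side is JIT-compiled; the grid path
goes through `odeint` (the low-overhead interface to the same LSODA
core).  Negative undershoots smaller than `1e-6` in magnitude are
clipped to zero inside the RHS as integrator noise; anything larger
raises, to distinguish solver jitter from a genuinely invalid state.

The chemotherapy (TMZ) model adds a death rate `-d` on `A` and every TAP
compartment.  A treated experiment is integrated in three regimes —
unperturbed pre-treatment parameters up to the treatment age, the
killing system during the (configurable, default 3-day) treatment
window, the unperturbed system afterwards — with the state passed
continuously across both switches.  The fitted post-treatment parameters
(`pT`, and `r0` for old mice) are interpreted as cell properties changed
by the treatment and therefore apply from the start of the window, not
only after it.  Section-level BrdU+ counts relate to whole-region
`A + sum(Ti)` through the scaling factor `rho` (whole-region = section
value times `rho`).

## Signal-explicit model and QSS reduction

The two effective signals obey

    dS_r/dt = R1 + R0 c1 - S_r - betaR c2 S_r
    dS_b/dt = 1 - S_b - betaB c3 S_b

with `r = rbar S_r`, `b = bbar S_b`.  Fast kinetics reduce this to the
Hill form with `r0 = rbar R0/betaR`, `r1 = rbar R1/betaR`,
`K = 1/betaR`, `b0 = bbar`, `beta = betaB`.  The reduction is
many-to-one (only the products `rbar R0`, `rbar R1` matter), so
`qss_expand` fixes the gauge `rbar = 1` unless told otherwise;
`reduce(expand(.))` is then an exact identity.  `simulate_full_signal`
initializes the signals at their quasi-steady values by default, so at
speed-ups of 1e3 the cell trajectory matches the reduced model to well
under 1%.

## Weighted-least-squares estimation

The cost is

    E = sum_j (1/sigma_j^2) sum_i (y_i^data - y_i^model)^2

over (age, observable) groups j and the mice i measured at that age.
The observables are NSC total `Q+A`, active fraction `A/(Q+A)`, TAP
total and NB total (whole-population settings), or section-scale BrdU+
counts (chemotherapy settings, including saline baselines).

**Weighting.**  With only a handful of mice per age, the per-group
sample variance has ~3 degrees of freedom and its reciprocal has
infinite expectation — raw inverse-variance weights let single
tight-by-chance groups dominate the fit.  The default weighting
therefore interpolates the per-age sample SDs of each observable with
the exponential decay model `sigma(t) = d0 + d1 exp(-d3 (t - t0))`
(the same model used for the likelihood and for single-mouse groups) and
weights every record by the interpolated SD at its age.  In recovery
experiments this roughly halves the error of the self-renewal
parameters.  `weighting="sample"` restores raw per-group weights.

**Free parameters per experiment.**  Wild type: `r0, K, b0, beta`.
Receptor knock-out: additionally `r1` and `pT`.  Chemotherapy, young
mice: post-treatment `pT`, death rate `d`, section scaling `rho` (all
other parameters held at their wild-type values); old mice additionally
free `r0`.

**Initial conditions.**  Time zero is the first observation age.  The
NSC pool starts at `NSC0` split by the mean observed active fraction at
the first age (fallback 0.3); the TAP total (split equally across
compartments, since data constrain only totals) and the NB count come
from the first-age data means.  Chemotherapy fits carry an explicit
`TmzContext` (pre-treatment parameters, initial state, start age)
because BrdU-only data cannot anchor the full state.

**Multistart.**  Start points are drawn log-uniformly inside the bounds
(`r0` in [1e-4, 10], `K` in [1, 1e5], `b0, beta` in (0, 1], `pT` in
[0.05, 2], `d` in [0, 10], `rho` in [1, 1e3]; zero-lower-bound
parameters get a small positive sampling floor).  A set of data-anchored
starts is added: the late-age NSC level approximates the positive
equilibrium, pinning `beta = (2 b0 - 1)/c3` over a grid of `b0` values,
and the first-age active fraction pins the activation rate through the
quasi-steady balance `A ~ r Q / pA`; depletion-type guesses
(`b0 < 1/2`) anchor `beta` to the early realized self-renewal implied by
the initial decline.  Every start receives one cost evaluation; the best
`n_refine` (default 12, always including the best anchored start) are
refined with trust-region-reflective least squares, and the refined
start with the smallest cost wins (ties to the lowest start index, so a
fixed seed reproduces the result bit-for-bit).  Screening-then-refining
keeps the default 500-start budget affordable without changing which
minimum is reported.

**Uncertainty.**  The covariance of the estimates is the Moore–Penrose
generalized inverse of `J^T J`, with `J` the central-difference Jacobian
of the weighted residual vector at the optimum; rank deficiency is
reported together with the dominant null-space directions (in practice
`K`, whose posterior the data leave wide).

## Model selection

`AIC = n ln(E/n) + 2k` and `AICc = AIC + 2k(k+1)/(n-k-1)` with `n` the
number of residuals (every mouse-age-observable triple) and `k` the
number of fitted parameters.  Akaike weights normalize `exp(-Delta/2)`.
The optional pooled ("overall") block sums `E` and `n` across settings
per scenario and counts each free-parameter symbol once; because the
per-setting fits were optimized independently this pooled score is
approximate, and is flagged as such in the table metadata.

## Bayesian machinery

Measurements are Gaussian and independent across ages.  Per-age SDs are
interpolated by the variance-decay model (fitted per observable by
least squares on ages with at least two mice; fewer than three such ages
degrade to a pooled SD with a warning).  The negative log-likelihood

    f(theta) = sum_i (y_i^model - mu_i)^2 / (2 sigma_i^2)
             + sum_i log(sigma_i sqrt(2 pi))

uses the per-(age, observable) data means `mu_i`; the initial state is
drawn from truncated Gaussians of the four first-age observables
(totals on [0, inf), fraction on [0, 1], exact truncated sampling by
rejection with a 100-attempt cap) and `f` is averaged over `n_ic_reps`
(default 10) realizations.

The Adaptive Metropolis sampler uses the classic scheme: Gaussian
proposals with covariance `s_d (cov(chain) + eps I)`, `s_d = 2.4^2/dim`,
adapted from iteration 1000 on (`eps = 1e-10`); before adaptation the
proposal covariance is the linearized covariance of the point fit when
available, else `1e-4 diag(init^2)`.  Bounds act as flat priors;
out-of-bounds proposals are rejected, which in particular enforces the
finite range required for the weakly identified `K`.  Default burn-in is
the first 20% of the chain.  Posterior-predictive bands redraw both
parameters (from the post-burn-in chain) and initial conditions.

## Synthetic data

The generator emulates cross-sectional mouse studies: at each of 10
log-spaced ages in [30, 700] days (8 ages in the recovery experiments),
`mice_per_age = 4` independent mice per observable, each drawn from a
truncated Gaussian centred on the true trajectory.  Truncation (rather
than clipping) keeps the active fraction inside [0, 1] without point
masses at the bounds.  Ground truth, seed and noise constants are stored
in the dataset metadata.

**Noise defaults.**  The SD follows the decay model with a coefficient
of variation of ~12% of the first-age level, decaying to ~4% of the
late-age level; the decay rate tracks each observable's own steepest
average log-decline so that the CV stays bounded relative to the current
mean even for observables that collapse early (NB counts fall by an
order of magnitude within the first weeks).  These levels describe
well-executed stereological counts; they were chosen, once, such that
the generator's central design property — recovery of the generating
`b0` and `beta` by the fitting pipeline — holds at the default study
size.  The identifiability analysis behind this choice is summarized
below.

**True parameters.**  `r0` such that the initial activation rate is
~0.05/day, `K = 100` cells, `b0 = 0.8`, `beta = 2e-3` /cell, initial
active fraction 0.05: the NSC pool declines from 1900 towards a positive
steady state of ~400 cells over the observation window with an active
fraction of a few percent, the regime of aged-mouse data.

**Initial state.**  The generator reconstructs its initial state through
the same observable-level convention the fitter uses (totals at flux
balance, TAP total split equally across compartments), so the pipeline
is exactly recoverable in the noise-free limit; a fit to replicate-free
data reproduces the generating parameters to better than 0.1%.

**What the generator does not emulate.**  Mouse-level longitudinal
correlation (each mouse is measured once; the real studies are likewise
cross-sectional), age-dependent mouse counts, litter effects, counting
bias, and any model misspecification: passing recovery tests show the
inference machinery is correct and calibrated under the model's own
assumptions, not that the model describes real tissue.

## Identifiability of the self-renewal feedback

In `1/b` the feedback is exactly linear in the inhibitor population, so
separating `b0` (the intercept at zero cells) from `beta` (the slope) is
a lever-arm extrapolation below the smallest population the trajectory
visits.  At equilibrium `b = 1/2` exactly, which anchors one end; the
other end comes from the transient, where the data constrain `b(t)`
pointwise mainly through the TAP influx `2(1 - b) pA A`.  Consequences:
(i) `b0` and `beta` are strongly correlated (visible in the fit
correlation matrix and the posterior); (ii) `K` and `r0` share an
analogous ridge in the activation function, with `K` the widest,
effectively unidentified parameter; (iii) reliable recovery of `b0` and `beta` to within 20% requires
per-age count noise at roughly the 10% CV level: at ~25% first-age CV
the global WLS minimum itself — not the optimizer — wanders beyond 20%
in `beta` for a noticeable fraction of noise realizations.

## Numerical choices, ties, degenerate inputs

- Equilibrium residual tolerance 1e-8 (relative, inf-norm over the RHS
  scaled by the state); eigenvalue stability margin 1e-9.
- Multistart cost ties within 1e-10 resolve to the lowest start index.
- Weight floor: group SDs below 1e-6 of the data scale (e.g. noise-free
  synthetic data) fall back to unit weights instead of exploding.
- `aicc` refuses `n <= k + 1` (the small-sample correction is undefined)
  and non-positive costs.
- The variance-decay fit constrains `d0, d1, d3 >= 0` and `d3 <= 1`;
  time is measured from the first data age.
- `sample_initial_conditions` resamples up to 100 times before giving up
  on a nonnegative draw.

## Known limitations

- The pooled AICc block compares independently optimized fits; a joint
  fit across settings would be needed for an exact pooled score.
- The linearized covariance underestimates uncertainty along the curved
  `b0`-`beta` and `r0`-`K` ridges; the MCMC posterior is the better
  uncertainty statement there.
- Scenario discrimination from wild-type-sized data is weak by nature
  (the scenarios differ mostly near and beyond the end of the
  observation window); the selection table reports weights, not a
  verdict.
- The chemotherapy model treats the killing rate `d` as constant over a
  fixed window; the true exposure profile of the drug is not modeled.
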