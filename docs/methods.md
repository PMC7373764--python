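# Methods

## The model

Microbial growth on phenol is self-inhibiting: phenol is both the sole
carbon source and a toxicant. The specific growth rate μ (h⁻¹) as a
function of substrate concentration S (mg/L) is modelled with the Haldane
substrate-inhibition law

    μ(S) = μ* · S / (Ks + S + S²/Ki)

with half-saturation constant Ks (mg/L) and inhibition constant Ki (mg/L).
The same law with an independent parameter triple (q*, Ks′, Ki′) describes
the specific degradation rate q. Two closed-form quantities follow from
setting dμ/dS = 0:

    Sm   = √(Ks · Ki)                — the concentration where the rate peaks
    μmax = μ* / (1 + 2 √(Ks/Ki))    — the true maximum rate

μ* is a *fitting parameter*, not an attainable rate: for finite Ki,
μmax < μ* strictly. The package reports the overestimation
100·(μ* − μmax)/μmax alongside every fit, because literature tables often
conflate the two. (Published tables in this field sometimes label the
fitted parameter "μmax" and the true maximum "μ*max"; the package follows
the unambiguous convention above — `rate_star` is the fitted parameter,
`true_max_rate` the analytical peak.) `ki=None` selects the Monod limit
μ*·S/(Ks+S) explicitly, where Sm is infinite and the true maximum equals
μ*.

An algebraic identity used as a standing self-check: evaluating the law at
Sm reproduces the closed-form maximum to 1e-12 relative.

## Rate extraction

Within the exponential phase, dX/dt = μX gives ln X linear in t, so μ is
the least-squares slope of ln(X/X₀) vs t; likewise dS/dt = −qS gives q as
the slope of −ln(S/S₀) vs t. Conventions and guards:

- Signs are chosen so that growth on a rising biomass series and depletion
  on a falling substrate series are both positive.
- Substrate points at or below a detection floor (1% of S₀ by default, or
  an absolute LOQ) are excluded: after exhaustion the first-order model no
  longer applies and the logarithm diverges.
- The reference time/value (t₀, X₀) is the first retained point of the
  window, not the nominal inoculum.
- At least 3 usable points are required; non-positive values inside the
  window are an error, not silently dropped.
- A flat series yields rate 0 with r² reported as 0 (the correlation is
  undefined there).

The fitting window is, by default, the full usable series up to substrate
exhaustion — the convention batch studies implicitly use. `window_mode:
auto` instead selects the contiguous window (≥ 3 points, configurable)
maximizing log-linear r², tie-broken by more points then earlier start;
this cleanly drops a lag phase at toxic S₀. If no window reaches r² ≥ 0.90
the best one is returned flagged `low_quality`. Note that very short
windows can be spuriously collinear in noisy data; raising `min_points`
(e.g. to 5) makes the flag meaningful for diagnostic use.

Replicates are reduced per replicate first, then averaged (mean ± SD per
substrate level), preserving the between-replicate error structure.

## Haldane fitting

The triple (rate*, Ks, Ki) is estimated by unweighted nonlinear least
squares on the (S₀, rate) points (an optional 1/rate² weighting exists
behind a flag). Numerical choices:

- Optimization in log-parameter space with bounds [1e-6, 1e6] on every
  parameter: enforces positivity and conditions the problem across the
  decades-wide ranges seen in phenol kinetics (Ki spans 0.87 to 59 000 mg/L
  in the literature table shipped with the package).
- The objective is multimodal for sparse grids, so a seeded multistart is
  on by default: a heuristic centre (rate* ← 2×max observed rate; Ks ← the
  half-maximum crossing on the rising limb, interpolated; Ki ← largest
  tested S₀) plus 10 log-uniform perturbations within a factor of 10.
- Trust-region reflective solver, ftol = xtol = 1e-14, gtol = 1e-10, at
  most 2000 evaluations per start. Ties among starts are broken by lowest
  SSR, then smallest Ks. Non-convergence of every start flags the result
  rather than raising.
- At least 4 distinct substrate levels are required (3 parameters + 1 df).
- Goodness of fit is 1 − SS_res/SS_tot about the observed mean; because
  some reports instead quote a squared Pearson correlation, that value is
  computed and reported alongside (`r2_pearson`), never used internally.

Identifiability: rate* is well determined whenever the grid brackets Sm;
Ki is weakly identified when the grid barely reaches into the inhibited
regime, and fits of Monod-generated data drive Ki to its upper bound
(reported, not clamped silently — a fitted Ki ≫ 10⁴·Ks should be read as
"no detectable inhibition").

## Synthetic batch cultures

The generator emulates the shake-flask design the analysis assumes:
initial phenol grid {41, 100, 200, 400, 600, 800, 980, 1117} mg/L
(spanning the 41–1117 mg/L range the emulated study covers), triplicates,
sampling every 12 h to 120 h, and a coupled system

    dX/dt = μ(S)·X,   dS/dt = −q(S)·S

with the study's fitted parameter defaults (growth 0.574/20.29/268.1,
degradation 1.244/9.152/517.5). Deliberate modelling choices:

- Growth and depletion are *separately parameterized first-order
  processes*, exactly as the batch model poses them — no yield coefficient
  links biomass produced to substrate consumed. A `yield_coefficient`
  option (dX/dt = Y·q(S)·S) exists for realism experiments but is off by
  default.
- Lag phase: substrate toxicity delays onset; the default rule freezes the
  state at (x₀, s₀) for 12 h when s₀ > 1000 mg/L, else no lag. A constant
  or a callable s₀ → hours can replace the rule.
- Inoculum x₀ = 20 mg/L dry biomass — a plausible dry-mass equivalent of a
  5% inoculum of a dense pre-culture; the emulated study reports CFU, not
  dry mass, so this is a convention, and nothing downstream depends on its
  exact value (specific rates are per-capita).
- Noise is multiplicative log-normal per observation with a given CV
  (default 0.05), parameterized to be unbiased in the mean and strictly
  positive. Replicates share the noise-free trajectory and differ only in
  noise; streams derive deterministically from (scenario seed, grid index,
  replicate), so runs are bit-reproducible.
- Integrator: fixed-step classical RK4, 200 internal steps per sampling
  interval. The dynamics are smooth and non-stiff at these scales; at this
  step the sampled values are converged to better than 1e-6 relative under
  step halving, and agree with an adaptive high-order reference
  integration at the same tolerance. The substrate equation has a
  power-law (≈1/t) tail as S → 0 because q(S) → 0 linearly; S is floored
  at 0 inside the derivative for safety but never crosses it.

What the generator does *not* emulate: yield-limited stationary phase
(biomass keeps creeping up while any substrate remains), pH/temperature
effects, heavy-metal inhibition, and cell death. Consequently, passing
recovery tests show the *statistical pipeline* is correct under the
model's own assumptions; they do not validate the Haldane model against
real cultures.

A consequence worth stating plainly: with instantaneous rates of order
1 h⁻¹ and 12-h sampling, most simulated cultures exhaust their phenol
within one or two sampling intervals, so slope-based rate extraction from
the default coarse design is data-poor — exactly the regime real batch
studies sit in. The pipeline therefore supports two rate sources:
`curves` (slope extraction, the batch-study convention; estimates are
window averages and
systematically below the instantaneous Haldane rate at S₀) and `direct`
(rate-level generation, bypassing curves), which is the route used to
verify exact parameter recovery. Short-window slope estimates converge to
the instantaneous rate as the window shrinks toward t = 0, and the test
suite verifies this on densely sampled scenarios.

## Calibration

Phenol concentration comes from a 4-aminoantipyrine colorimetric assay
whose standard curve is the fixed line A = 0.002447·C + 0.1423, calibrated
over 0–1200 mg/L; the package ships it as `PHENOL_A500`. Readings within
2% below the intercept are blank scatter and clamp to 0; further below is
an invalid-reading error. Extrapolation beyond the calibrated range warns
but proceeds. An optional `dilution_factor` (default 1) covers assay
protocols that dilute the supernatant before reading, in case the fixed
line does not already absorb that factor. The OD600 → dry-biomass
coefficient is deliberately *not* defaulted — it is instrument- and
strain-specific — and supplying OD input without it is a configuration
error raised before any computation.

## Pipeline and reproducibility

`run_pipeline` executes simulate/read → calibrate → extract rates → fit
each branch → derive → report, writing each stage's output before the next
starts (`curves.csv`, `rates.csv`, `rates_summary.csv`, `fit_<branch>.csv`,
`report.txt`, `summary.json`). Every output carries `#`-prefixed metadata:
tool version, seed, and a hash of the analysis settings (output location
excluded), so fixed config + seed gives byte-identical outputs. Rounding
happens only at the report layer — 2 decimals for the growth table, 3 for
the degradation table, matching field convention — never internally;
`summary.json` keeps full precision. Per-curve estimation failures
(insufficient points, exhausted series) are recorded in the summary and
skipped, not fatal; a branch with fewer than 4 usable substrate levels is
reported as unfitted.

## Known limitations

- Ki (and to a lesser degree Ks) confidence is not quantified; no
  bootstrap or profile-likelihood intervals.
- Only the Haldane law is implemented; Aiba/Yano/Edwards/Webb variants are
  out of scope (the fitting interface does not preclude them).
- The lag rule is a threshold heuristic, not a fitted lag model
  (no Gompertz/Baranyi).
- The endpoint summary `percent_degradation` implements the simple
  100·(C₀−Cₜ)/C₀ arithmetic used for microcosm/heavy-metal style
  endpoints; it does no kinetics.
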