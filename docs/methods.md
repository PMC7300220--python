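# Methods

This note records the model, the estimation machinery, the simulation
designs and the numerical choices behind `siropk`, and what the synthetic
data used throughout does and does not establish.

## Structural and statistical model

Sirolimus concentrations in children are described by a one-compartment
model with first-order oral absorption and first-order elimination. The
parameter set is exactly {CL/F, V/F, Ka}: apparent oral clearance (L/h),
apparent volume (L) — bioavailability F is folded into both and never
modelled separately — and the absorption rate constant (1/h). That
parameter set is the reason a one-compartment oral model is the right
structural choice: nothing richer is identifiable from sparse paediatric
TDM data, and Ka itself is not identifiable from trough-only sampling,
which is why it is fixed at 0.485/h throughout.

The concentration after a single oral dose D is

    C(t) = D*Ka / (V*(Ka - ke)) * (exp(-ke*t) - exp(-Ka*t)),  ke = CL/V,

superposed over the dosing history for multiple doses, with the analytic
accumulation formula for the steady-state pre-dose trough. Internally
doses are converted once from mg to ug so that concentrations in ug/L are
numerically ng/ml; this removes a whole class of silent 1000x errors.
When |Ka - ke| < 1e-10 the code switches to the analytic coincident-rate
limit (D*Ka*t/V)*exp(-Ka*t) (and its accumulation analogue) to avoid
catastrophic cancellation.

Between-subject variability is log-normal on CL/F and V/F:

    P_i = TV(P) * exp(eta_i),  eta_i ~ N(0, omega^2),

with a diagonal omega matrix (two independent random effects — all the
sparse data can support). Typical values carry allometric weight scaling
relative to a 70-kg standard, with fixed exponents 0.75 (CL/F) and
1 (V/F), plus any retained covariate multipliers (genotype factor, power
of a median-centred continuous covariate, or linear categorical form).
Residual error is combined proportional + additive:

    OBS = IPRED*(1 + eps1) + eps2,  Var(OBS | eta) = IPRED^2*s2_prop + s2_add.

One convention deserves emphasis: **all omega and sigma quantities in this
package are variances** (omega^2, sigma^2), matching the dominant reporting
convention of the estimation software family this model class comes from.
The reference parameter set used throughout (`siropk.model.FINAL_MODEL`) is
theta_CL = 6.48 L/h, theta_V = 124 L, Ka = 0.485/h, omega2_CL = 0.066,
omega2_V = 0.003, sigma2_prop = 0.312, sigma2_add = 1.249 (ng/ml)^2.

## FOCE-I estimation

The marginal likelihood of each subject's observations is approximated by
a Laplace expansion about the conditional mode of (eta_CL, eta_V), with
the residual variance evaluated at the eta-dependent individual prediction
("interaction"). Per subject,

    OFV_i = sum_j [ log(2*pi*V_j(eta^)) + r_j(eta^)^2 / V_j(eta^) ]
          + eta^' Omega^-1 eta^ + log|Omega| + log|F' V^-1 F + Omega^-1|,

where F = df/d_eta at the mode (the Gauss-Newton curvature; second
derivatives of f are neglected, the standard first-order-conditional
choice). As omega^2 -> 0 this reduces exactly to the fixed-effects
-2 log-likelihood; random effects with variance below 1e-12 are dropped
from the integration dimension rather than inverted.

*Inner problem.* The eta mode is found by a damped Newton iteration whose
Hessian uses the exact second derivative of the per-observation loss with
respect to the prediction (important here because sigma2_prop is large);
the Jacobian of the prediction is central-differenced (h = 1e-5). The
gradient tolerance is 1e-7 — tighter settings sit below the
finite-difference noise floor — giving OFV errors of order 1e-12.

*Outer problem.* (theta_CL, theta_V, omega^2s, sigma^2s, covariate
coefficients) are estimated by L-BFGS-B with all positive parameters on
the log scale (variances bounded below at 1e-8; boundary hits are reported,
not errors — the reference model's omega2_V = 0.003 sits near this regime).
Multi-start (default 3: the user start plus jittered starts, refined only
when they beat the primary optimum) guards against local minima. A final
Nelder-Mead polish (default 400 evaluations) follows: on trough-only
designs the likelihood has a long, nearly flat CL-V ridge on which the
quasi-Newton relative-improvement test can fire before the true minimum
is reached; the simplex slides along such ridges. Standard errors come
from the central finite-difference Hessian of the OFV at the optimum
(cov = 2*H^-1) and are reported as 100*SE/estimate. On 15-child
trough-only cohorts they are honestly enormous for V/F — the same
near-non-identifiability the original analysis shows in its bootstrap CI
for V/F of [27, 2126] L.

*Covariate selection.* Forward inclusion requires an OFV drop > 3.84
(chi-square, 1 df, P < 0.05), testing all remaining candidates against the
current model and taking the largest drop (ties by candidate order);
backward elimination from the full model removes any covariate whose
deletion raises the OFV by <= 6.64 (P < 0.01), weakest first. Candidates
whose fit fails are skipped and logged.

## Model qualification

*Bootstrap.* Subjects (not observations) are the resampling unit — the
only exchangeable unit in hierarchical data. Each replicate refits the
model (single-start); non-converged replicates are excluded and counted,
with a warning past 50% failures. Summaries are the replicate median,
2.5th/97.5th percentiles, and bias% = 100*(median - estimate)/estimate.
Default 1,000 replicates; seeded and bit-reproducible.

*Prediction-corrected VPC.* Observed and simulated concentrations are
corrected by obs * (bin-median PRED / subject-time PRED) with PRED the
population (eta = 0) prediction, binned into quantile-based time bins
(default 4 — appropriate for sparse designs). The simulated band per bin
pools all replicate values; the headline scalar is the fraction of
prediction-corrected observations inside the pooled simulated
2.5th-97.5th interval, which self-simulation calibrates to ~0.95.
Default 1,000 simulated replicates. Plot rendering is deliberately out of
scope; the numeric tables are the contract.

*Residual diagnostics.* IWRES = (obs - IPRED)/sd(IPRED) at the eta modes
with the interaction variance; WRES decorrelates each subject's residual
vector by the first-order model-implied covariance F*Omega*F' + V at
eta = 0 (no specific higher-order flavour is attempted).

## Monte-Carlo dose simulation

For each cell of the grid — weights {5, 10, 20, 30, 40, 50, 60} kg, daily
doses 0.01-0.10 mg/kg/day in steps of 0.01, once daily (tau = 24 h) and
twice daily (tau = 12 h, daily dose split exactly evenly) — 1,000 virtual
patients draw (eta_CL, eta_V) and their steady-state troughs are evaluated
analytically (equivalence with >= 100-dose superposition is tested to
1e-6 ng/ml). PTA is the fraction of troughs inside 5-15 ng/ml, bounds
inclusive. PTA is computed on model-predicted (residual-free) troughs by
default; an `include_residual` flag adds one draw of observation error per
trough (truncated at zero) for users who want the measured-concentration
view. Each grid cell derives an independent child seed from the run seed
and the cell coordinates, so tables are reproducible cell-by-cell.

*Recommendation rule.* For a weight bracket [w_lo, w_hi] the recommended
dose maximises min(PTA(w_lo), PTA(w_hi)) over the candidate doses, ties to
the lower dose. Only the grid endpoints are simulated, mirroring the
seven-point weight grid. The published selection additionally "considered"
a 95% concentration-interval safety criterion that is nowhere
operationalised; this rule is therefore an explicit approximation, and
`recommend_dose` returns the full per-candidate PTA audit table so any
alternative rule can be applied downstream. The once-daily 5-10 kg bracket
(0.10 mg/kg/day) is robust to this ambiguity; some other brackets,
especially twice-daily ones, may not be.

## Hardy-Weinberg testing

Biallelic genotype tables are tested by the Pearson chi-squared statistic
against expected proportions (p^2, 2pq, q^2), 1 df, **no continuity
correction** — the only convention that reproduces the printed P values of
the study's genotype table from its printed counts. Monomorphic variants
report chi2 = 0, P = 1 with a flag. Multi-allelic star-allele diplotypes
are out of scope, matching the table rows the study itself left untested.

## Synthetic cohorts: what they emulate and what they don't

The study's 15-child dataset is not public, so every analysis here runs on
synthetic cohorts drawn from the reference model: weights log-uniform over
10-50 kg (the study's observed range), oral dosing (default 0.05 mg/kg/day
once daily) continued for at least ten typical elimination half-lives
before sampling, and then either trough-only samples on 3 consecutive
dosing occasions (the TDM default) or a rich design of 6 post-dose samples
at 0.5, 1, 2, 4, 8 and 23.5 h (needed when V/F must be identified —
trough-only data barely constrains it). Observations apply one eta pair
per subject and independent combined residual error per sample, truncated
at zero.

Because generation uses exactly the estimator's model, parameter recovery
on these cohorts validates the estimation machinery — not the model's
adequacy for real children. Real TDM data differ in ways the generator
deliberately ignores: irregular dose histories and non-adherence, assay
lower limits (the study's immunoassay is linear only over 3.5-30 ng/ml),
concomitant-medication effects, and any model misspecification. Passing
recovery tests therefore says "the code estimates what it simulates",
nothing more.

Measured behaviour of the generation/estimation pair, for calibration of
expectations: on 100-subject rich-design cohorts the recovered theta_CL
runs +2% to +12% above truth across seeds (the well-known upward drift of
FOCE-I under a 56%-CV proportional error) and theta_V about -2% to -7%;
omega2_CL and sigma2_prop come back within a factor of two. Two components
are only weakly identified at these conditions and should not be
over-read: sigma2_add, because steady-state concentrations never get low
enough for the additive term to dominate (every prediction exceeds
~3 ng/ml), and omega2_V, whose generating value (5.5% CV) is swamped by
the proportional error — the profile likelihood in omega2_V is nearly
flat and the conditional estimates absorb approximation error into it, so
its point estimate drifts upward by an order of magnitude. The original
analysis shows the same weaknesses: its sigma2 carries a 55% relative SE
with a bootstrap CI of [0.010, 2.332], and its omega2_V bootstrap CI is
[0.003, 0.178].

## Problem sizes used by the shipped tests and scripts

Chosen to keep a full run inside a few minutes of a single CPU while
leaving every conclusion Monte-Carlo-stable: recovery fits use 100
subjects x 6 samples (single test and acceptance script) and 20 replicates
of 50 subjects (replicate-median test); covariate type-I calibration uses
20 replicate 10-subject cohorts; the quadrature oracle runs on 2-3
subjects with 40 Gauss-Hermite nodes per dimension; bootstrap unit tests
use 10 replicates of an 8-subject cohort (the analysis script defaults to
the full 1,000); VPC tests use 200 simulated replicates of a 40-subject
cohort (scripts default to 1,000); PTA cells always use 1,000 virtual
patients.

## Known limitations

- FOCE-I is an approximate marginal likelihood; with this model's large
  proportional error its small-sample bias on theta_CL is a few percent
  and is inherited by anything downstream of a fit.
- The dose-recommendation rule operationalises only the PTA criterion;
  the safety criterion of the source analysis is left to the audit table.
- No inter-occasion variability, no covariance between random effects,
  no absorption lag, no Michaelis-Menten elimination, no assay
  quantification limits.
- WRES uses the first-order linearisation; shrinkage and NPDE are not
  computed.
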