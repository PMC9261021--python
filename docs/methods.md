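# Methods

## Model

Pain within a treated episode is modelled on a latent continuous scale. For
episode *i*, observation *j* at time *t* (minutes relative to analgesic
administration; negative times are pre-administration scores):

    y* = mu_i(t) + u_i + e,   u_i ~ N(0, sigma_u^2),  e ~ N(0, 1)
    mu_i(t) = x_i' beta + I{t >= t0(arm)} [ level(arm) + l(arm) t + q(arm) t^2 ]

The observed 0–10 VNPS is the ordinal category of y* under strictly
increasing cut-points c_1 < … < c_10 (score k iff c_k < y* <= c_{k+1}, outer
cut-points at ±infinity). In two-arm fits the effective linear and quadratic
terms decompose into shared coefficients plus methoxyflurane interactions
(l = g1 + d1·d, q = g2 + d2·d), matching how treatment contrasts are
reported; onset levels are arm-specific.

Assumptions worth stating plainly: a single Gaussian random intercept
(exchangeable within-episode correlation; no autoregression), probit link,
unit residual scale, quadratic post-onset time profile with a discrete
latent jump at onset, and covariate effects constant over time.

### Identification

No free intercept is estimated; all K−1 cut-points are free and the residual
scale is 1. Adding a constant to all cut-points and the latent level leaves
the likelihood unchanged (tested), so any baseline latent level in a
generating process is absorbed into the fitted cut-points. Onset levels are
identified against the pre-onset observations (the baseline score enters at
t = 0, before every onset lag).

### Estimation

The episode random intercept is integrated out by Gauss–Hermite quadrature
(20 nodes by default; doubling the nodes moves small-instance
log-likelihoods by < 1e−8, and 20-node values agree with adaptive 1-D
numeric integration to ~1e−10). Optimisation is L-BFGS-B with an analytic
gradient on a transformed scale: cut-point increments on the log scale
(monotonicity by construction), log sigma_u, and design coefficients scaled
by their column maxima — the t and t² columns differ by two orders of
magnitude and unscaled optimisation terminates early on this badly
conditioned surface. Starting values: cut-points from inverse-normal
empirical cumulative frequencies, then a pooled (sigma_u pinned at ~0) fit,
then the full fit. Tight tolerances (gtol 1e−7, ftol 1e−13) matter: with
scipy defaults the estimates stop ~0.2 away from the optimum and
coverage degrades. Non-convergence is flagged on the results object, not
raised. The covariance is the inverse observed information, from central
finite differences of the analytic score; if the information matrix is
singular (e.g. an empty outcome category) a pseudo-inverse is used.

## Pathway functionals

All clinical functionals operate on the effective post-onset quadratic per
arm. Time to trough pain is the vertex −l/(2q) when q > 0 and the vertex
falls at/after onset; otherwise the result is flagged as a boundary (onset
for non-improving pathways, the 120-min search horizon for unboundedly
decreasing ones) and excluded from trough contrasts. Duration in severe
pain solves pathway(t) = c_severe by the quadratic formula, where c_severe
is the fitted cut-point between scores 6 and 7 (between moderate and severe
in the 4-level model); a never-exit flag is set when the pathway minimum
over [onset, 120] stays above the boundary. Scenario pathways "begin in
severe pain" at a configurable latent level, defaulting to 0.912 above the
severe boundary — the offset implied by the printed scenario (baseline
0.763 against boundary −0.149) — so the severe-exit duration depends only
on pathway coefficients, not on the absolute cut-point location.

Standard errors of functionals use the delta method with central-difference
gradients (relative step 1e−5) against the fitted covariance; for pathway
curves the functional is linear in the parameters and the band is exact.
The faster-relief hypothesis is one-sided: z = (comparator trough −
methoxyflurane trough)/se, p = 1 − Phi(z).

## Synthetic cohorts

The generator emulates the study's data structure: per-episode covariates
(sex 35.2% male, age ~ truncated normal 63.1 ± 22.9 on [18, 98], seven
trauma-presentation classes at the methoxyflurane-arm frequencies); a
baseline score at a negative lead time and a final score at a positive
time, both truncated normals with each arm's printed mean/sd/range (e.g.
methoxyflurane lead 8.4 ± 10.5 on [0, 85.5], final 26.1 ± 11.4 on
[1, 47.5]; comparator finals extend to ~80–87 min, which is what makes the
flatter comparator quadratic estimable); an optional protocol-style
5-minute score with probability 0.5, chosen so episodes average ~2.5 scores
as in the estimation samples. Scores are drawn from the model itself:
latent pathway plus episode intercept plus unit noise through the ordered
thresholds.

Default generating parameters are the printed per-protocol pathway
coefficients of the methoxyflurane-vs-Entonox comparison (three-decimal
print precision, hence approximate); cut-points anchor the severe/moderate
boundary at −0.149 with 0.45 spacing (chosen so a VNPS point spans roughly
0.45 latent units and the implied baseline distribution is predominantly
severe); sigma_u defaults to 0.5, a moderate within-episode correlation
(intraclass correlation 0.2) in the absence of a printed value. A separate
`trough_calibrated_params` variant recalibrates the linear terms so each
arm's vertex equals its printed trough time (26.41 vs 44.44 min): the
printed coefficients are rounded too coarsely to reproduce the printed
troughs (the morphine vertex from print is 55.5 min against a printed
42.77), so simulations of the *separation* in relief speed use the
trough-calibrated truth.

Baseline eligibility is emulated by rejection: each episode's baseline
category is redrawn until it matches a target drawn severe with probability
0.88 and moderate otherwise, so all baselines are moderate-to-severe. This
reproduces trial-style selection but conditions on the outcome, which the
likelihood does not model; parameter-recovery and test-calibration
simulations therefore switch enforcement off and draw purely from the
model, validating the estimator under its own assumptions. What passing
these simulations does not show: robustness to the selection above, to
non-quadratic true pathways, heaped scores (digit preference at 5 and 10),
informative observation times, or missingness — all present in real
prehospital data in unknown degree.

## Filtering and costing choices

Estimation-sample filters run in a fixed order (adult, trauma, conscious,
baseline moderate-to-severe, ≥2 scores with the first at/before
administration and the rest within the period of effect, single analgesic
for comparator arms) so attrition reports are deterministic; an episode is
counted at the first stage it fails. Licence-eligibility stages are by
default not enforced on the methoxyflurane arm — violations are retained as
flags (they enter the model as covariates) and removed only for the
per-protocol sample, mirroring the study design. The period of effect
defaults to 90 min for every arm: the printed baseline-to-final ranges run
to 87.3 min, so a shorter window would cut observed episodes. Baseline
imputation moves the nearest pre-administration score to t = 0 (it enters
the likelihood once); lead times over 30 min are flagged, not excluded.
A second methoxyflurane dose is split into an independent episode when it
falls more than a 15-min continuity gap after the first dose's 60-min
period of effect, each part keeping its own baseline.

Costs are computed on unrounded GBP and rounded half-up to the penny only
at reporting; differencing rounded figures loses a penny on the
methoxyflurane–Entonox increment (12.29 vs the correct 12.30) and is
asserted against as a regression. The paracetamol and combined component
lists include the syringe and drawing-up needle and count shared
consumables and the backup provision once in the combined strategy — the
reconstruction that reproduces every printed total exactly; it is a
reconstruction, the source text does not fully itemise these two lists.

## Simulation sizes and numerical tolerances

Heavy validation runs at desk scale, sizes chosen as the package's own
defaults: parameter recovery uses 200 cohorts of 200 episodes/arm (2–3
scores each); type-I-error calibration of the faster-relief test uses 500
replicates at 150 episodes/arm under truly equal pathways (replicates whose
estimated trough lies at a boundary are excluded from the rate — the
contrast is undefined there — and are required to be < 5%); power uses 25
replicates at 590 episodes/arm (the average printed arm size) under
trough-calibrated truth at alpha = 0.001. Oracle tolerances: quadrature vs
numeric integration 1e−6; vertex vs 0.001-step grid search 0.01 min;
severe-exit root residual 1e−9.

## Known limitations

Printed functional values (26.41/44.44-min troughs, 10.54-min severe
duration and their standard errors) are not reproducible exactly without
the restricted source data and unrounded estimates; the package treats them
as calibration context. The "observational rules" linking latent pain to
VNPS are implemented as standard interval censoring; richer rules (score
heaping) would need a different measurement model. Influence-potency tiers
for concomitant analgesics are generic binary covariates. The delta method
is first-order: trough-time SEs degrade when the quadratic coefficient is
near zero (flat pathways), which is also when boundary flags appear.
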