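# Methods

## Measurement model and metric

Every rated delirium sign or symptom is modeled as a graded response item:
for item *i* with K ordered categories, P(y_i ≥ k | θ) = logistic(λ_i θ −
τ_ik) for k = 1…K−1, with thresholds strictly increasing and loadings
non-negative (higher θ = more severe, by sign convention). The latent
delirium intensity θ describes one assessment — one person-day — not one
person; repeated days of the same person are scored cross-sectionally.

The model is identified by standardizing θ: mean 0, variance 1 in the
population, all loadings free (no marker variable). Everything is on the
**logit** metric with no 1.7 scaling constant. External parameters reported
on a probit or 1.7-scaled metric must be rescaled before comparison; for the
same reason, published parameter tables from other software can be expected
to agree with ours only up to an affine transform of the metric.

IRT locations are b_ik = τ_ik / λ_i (`fa_to_irt`). Item information uses
the graded-model form I_i(θ) = λ_i² Σ_k (P*_k(1−P*_k) − P*_{k+1}(1−P*_{k+1}))²
/ P_k with P*_k = P(y ≥ k); test information is the sum over items and
reliability is taken as I/(I+1).

## Estimation

Marginal maximum likelihood with a standard-normal latent prior,
approximated on a fixed grid of 61 equally spaced nodes on [−6, 6] with
normalized normal-density weights (a 49- vs 101-node grid changes the
marginal log-likelihood of a default synthetic cohort by < 1e-6; the
integrands are analytic and vanish at the grid ends, where the rectangle
rule converges super-algebraically). Adaptive quadrature is unnecessary at
unidimensional scale.

The EM algorithm alternates an E-step (posterior node weights per
assessment; missing item responses simply drop out of the likelihood term,
i.e. MAR-ignorable) with per-item M-steps. Each M-step maximizes the
expected complete-data log-likelihood by BFGS with analytic gradients over
an unconstrained reparameterization: the loading as log λ, thresholds as a
base value plus log-gaps, anchored at the fixed threshold when one is
constrained. This guarantees threshold ordering without constrained
solvers, including the step-4 case of free thresholds on both sides of a
fixed one. If the inner optimizer fails to improve an item's expected
log-likelihood the previous values are kept, so the marginal log-likelihood
is non-decreasing across iterations by the EM inequality. Convergence is
declared when no free parameter moves by more than `tol` (default 1e-4);
non-convergence is flagged on the result, never raised.

Degenerate inputs: an item whose observed responses all fall in one
category is flagged and excluded from estimation, with ±inf sentinel
thresholds making its characteristic curve constant (it contributes nothing
to scoring). A boundary category with zero observed responses likewise gets
a ±inf sentinel for its threshold; interior zero-count categories keep
finite thresholds (identified through the ordering). Assessments with no
observed items contribute zero to the likelihood and are scored at the
prior, EAP (0, 1) exactly.

Standard errors, where used in tests, come from the observed information
matrix (central finite differences of the marginal log-likelihood).
Repeated daily assessments are fitted as independent: clustering on person
affects standard errors, not point estimates, and cluster-robust SEs are
deliberately out of scope.

## The four-step co-calibration

1. Per instrument, a 2PL fit to the dichotomized seven shared-domain items
   (attention, disorganized thinking, orientation, perceptual disturbance,
   psychomotor disturbance, sleep/wake, memory). Dichotomization is
   absent-vs-any-symptom (cut 1) except sleep/wake disturbance, cut at
   moderate-or-worse (cut 2) because mild sleep disturbance is near-universal
   in hospitalized elders. Where an instrument rates a shared concept with
   two items (psychomotor agitation and retardation on the DRS-R-98 and
   CAM-S), the first-listed item represents the concept in step 1, keeping
   seven items per instrument; the other is calibrated in step 2.
2. Per instrument, a 2PL fit to all dichotomized items with shared items'
   loadings and thresholds fixed at step-1 values (fixed values are returned
   bit-identically).
3. Haebara linking of MDAS and CAM-S onto the DRS-R-98 metric. Anchor
   domains follow the instrument-pair lists: MDAS — disorganized thinking,
   orientation, perceptual disturbance, sleep/wake, delusions, memory (6;
   attention and psychomotor activity are deliberately not MDAS anchors);
   CAM-S — attention, disorganized thinking, orientation, perceptual
   disturbance, psychomotor agitation, sleep/wake, psychomotor retardation
   (7). The non-symmetric criterion (loss evaluated on the reference metric
   only, standard-normal weights at the 61 default nodes) is minimized by
   Nelder-Mead over (log A, B) from the identity, criterion tolerance 1e-8;
   a symmetric variant is available by flag. Target parameters transform as
   λ' = λ/A, τ' = τ + λ'B; scores as θ' = Aθ + B; locations as b' = Ab + B.
4. Per instrument, the full graded model with each item's loading and its
   **dichotomization-cut** threshold fixed to the linked binary values and
   the remaining thresholds free. For sleep items (cut 2) the fixed
   threshold is τ₂ with τ₁ free: the binary parameter estimated in steps
   1–3 is by construction the cut-point threshold, and fixing τ₁ instead
   would equate parameters estimated on different events. Because a
   literal reading would fix the first threshold regardless, that behavior
   is available via `PipelineConfig(step4_fixed_threshold="first")`; the
   default is "cut". Binary items have nothing free and pass through.

The CAM-S short form is never calibrated separately: it is scored from the
long-form calibration restricted to its four items, consistent with its
definition as a reduced score. The binary acute onset/fluctuation feature
enters the long-form sum score always, and the IRT models by default
(`include_onset_item=False` drops it from the models only); it is not an
anchor.

All instruments are calibrated on the same assessments (common persons), so
no between-group mean structure is estimated; the link absorbs any metric
differences and is near-identity when the instruments are generated on one
common metric.

## Crosswalks and reports

The test characteristic curve TCC(θ) = Σ_i Σ_{k≥1} P(y_i ≥ k | θ) is
strictly increasing; its inverse is found by bisection to 1e-6 on
[−6, 6], with scores at or beyond the curve's boundary values truncated to
±6 and flagged. Crosswalks tabulate, for every integer source score, the
equated θ and each target's expected score, raw and rounded half-up — raw
values are always retained because rounding discards up to half a point.
Curves are tabulated on θ ∈ [−3, 6] in steps of 0.01 (severity skews high
relative to the sample mean). Item-person maps flag category locations
strictly above 4 SD. Score correlations are Pearson correlations of
per-assessment EAP scores over assessments scored on both instruments.

Residual diagnostics replace estimator-specific fit indices: observed
polychoric correlations (two-step ML — probit thresholds from the marginal
cumulative proportions, then the bivariate-normal rectangle likelihood
maximized over ρ by bounded scalar search, tolerance 1e-4) are compared
with the model-implied latent-response correlations λ_iλ_j /
√((λ_i²+π²/3)(λ_j²+π²/3)), using the logistic residual variance π²/3
consistent with the logit link; the root-mean-square residual over item
pairs summarizes misfit. The probit/logit mismatch between the two sides
contributes a small systematic component (observed RMSR ≈ 0.05 even under
the generating model at cohort size), so RMSR is a comparative diagnostic,
not an absolute test.

## Synthetic cohort generator

The generator emulates the clustered daily-assessment design the analysis
assumes: `n_persons` = 352 persons; days per person drawn from a geometric
distribution truncated to 1–15 whose success probability is solved so the
expected total matches `target_total` = 1178 assessments (a uniform 1–15
option exists but averages 8 days/person and cannot reach that total);
latent intensity θ_{p,d} = u_p + e_{p,d} with u_p ∼ N(0, 0.5) and e ∼
N(0, 0.5), giving unit marginal variance and within-person correlation 0.5
(a stated placeholder — the real within-person correlation is unknown; an
exchangeable structure suffices because point estimation ignores
clustering). Responses are drawn from the graded model by inverting the
cumulative curves with one uniform draw each; missingness is completely at
random at rate 0.02 (the simplest mechanism consistent with codes being
"set to missing"). Everything is deterministic given the seed.

Generating item parameters place cognition items (orientation, attention,
memory) at the least intense locations and perceptual disturbance,
delusions, psychomotor signs, affect and consciousness well above the mean,
with several top-category locations beyond 4 SD — so top categories are
rare, as in real delirium cohorts. Shared-domain items carry identical
generating loadings and cut-boundary locations across instruments: the
anchors are measurement-invariant, which is the premise of the linking
design, and makes the true inter-instrument link the identity.

What the generator does **not** emulate: rater effects and inter-rater
disagreement, dementia subgroups, informative dropout or
missingness-related-to-severity, day-to-day autocorrelation beyond the
exchangeable intercept (an AR-type structure can be approximated only by
changing the variance split), and any violation of unidimensionality or of
anchor invariance. Passing recovery tests on these data therefore shows the
estimation and linking machinery is correct under the model's assumptions —
not that the assumptions hold in any particular clinical data set.

## Problem sizes used in validation

- Oracle equivalence: instances of 4 items × 50 assessments; marginal
  log-likelihood and EAP scores checked against Simpson integration over a
  2001-point grid (1e-6 / 1e-4).
- Four-step recovery: 10 replicated cohorts of ~3013 assessments (900
  persons); mean absolute bias over items of loadings ≈ 0.025 and of
  finite thresholds ≈ 0.043 in the acceptance run, against bounds 0.1 and
  0.15.
- Linking recovery: exact inversion of a planted (A, B) = (1.3, 0.4) to
  1e-4; re-estimated recovery of a planted θ-shift B = 0.5 over 25
  replicate calibration pairs of 4 binary anchors × 1000 assessments.
- Crosswalk/TCC Monte-Carlo checks: 4000–20000 simulated assessments per θ
  point, agreement within 3 Monte-Carlo standard errors.

## Known limitations

- Point estimates only: no cluster-robust or sandwich standard errors.
- No differential item functioning tests, no multidimensional models, no
  probit/WLSMV estimation.
- Crosswalks extrapolate poorly outside the score range where the TCC is
  informative; truncation flags mark boundary scores.
- The two-step design conditions step-4 thresholds on estimated (not known)
  loadings and cut thresholds, so their uncertainty is understated.
- Sparse top categories at extreme locations remain noisy at realistic
  cohort sizes; thresholds for unobserved boundary categories are reported
  as ±inf sentinels rather than extrapolated.
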