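# Methods

## Model

### Cause-specific Cox models

For right-censored competing-risks data `(tᵢ, δᵢ, xᵢ)` with status codes
0 (censored), 1, 2, the cause-k view recodes the competing event as
censored (`δ_k,i = 1{δᵢ = k}`) and models the cause-specific hazard
`h_k(t|x) = h_0k(t)·exp(x'β_k)` through the Cox partial likelihood. The
baseline hazards are never estimated. Tied event times use the Breslow
convention: each event at a tied time contributes the full risk-set sum.
The partial likelihood depends on times only through their ordering, so
any strictly increasing transformation of the times leaves every fit
unchanged (tested).

### Feature-weighted elastic net (fwcoxnet)

One cause-specific fit minimizes

    F(β, θ) = (1/n)·NLL(β) + λ Σⱼ wⱼ(θ)·(α|βⱼ| + (1−α)/2·βⱼ²),
    wⱼ(θ)   = Σₗ exp(zₗθ) / (p·exp(zⱼθ)),

over β and the scalar θ, where `z ≥ 0` are per-feature relevance scores.
Properties of the weight function that the implementation relies on (and
asserts): `θ = 0 ⇒ wⱼ = 1` (plain elastic net), `Σⱼ 1/wⱼ = p` (prior
information redistributes penalty, it cannot remove it), and only relative
magnitudes of `z` matter. Scores are rescaled to unit maximum before use;
θ is clipped to [−50, 50], at which point the disfavored side of the score
spectrum is effectively excluded (weights ~e⁵⁰).

The data term is scaled by 1/n so that the penalty level λ means the same
thing on cross-validation training sets of different sizes. This is a pure
reparameterization of the λ axis, which is selected by cross-validation
anyway.

### Optimization

*β-step.* With θ (hence `w`) fixed, F is minimized by IRLS around cyclic
coordinate descent: the Breslow NLL is expanded to second order in the
linear predictor using the diagonal of its Hessian (`hᵢ = eᵢA − eᵢ²B` with
the usual prefix-sum quantities), giving a penalized weighted least-squares
problem solved by soft-threshold coordinate updates with per-feature
penalty factors `λαwⱼ` / `λ(1−α)wⱼ`. Each IRLS step is accepted under
step-halving on the penalized objective, so the objective is monotone.
Coordinates are screened by the sequential strong rule and an active-set
scheme; a full Karush–Kuhn–Tucker sweep over all p coordinates admits any
violator and re-solves, so screening affects speed only. KKT optimality at
returned solutions is asserted in the tests at 1e−4 on the gradient scale.

*θ-step.* With β fixed, the data term is constant, so minimizing F over θ
reduces to minimizing `g(θ) = Σⱼ qⱼ wⱼ(θ)` with `qⱼ = α|βⱼ| + (1−α)/2 βⱼ²`
— a positive combination of exponentials of θ and therefore convex. The
generic `update_theta` routine runs gradient descent with backtracking
(initial step `t_init`, stopping when the relative decrease falls below
`thresh`) followed by a bounded scalar polish, which for a convex 1-D
function reaches the global minimum (verified against a 10 001-point grid).
The pathwise solver uses an equivalent golden-section kernel on a
compressed representation (distinct positive scores vs. the zero block),
costing O(#positive scores) per evaluation. `t_init` is honored by
`update_theta`; inside the path both routes land on the same global
minimizer of the convex 1-D problem.

*Alternation and path.* For each λ on a decreasing log-spaced grid
(default 100 points from λ_max = maxⱼ |gⱼ|/(αwⱼ) down to
λ_max·0.01 for n < p, λ_max·1e−4 otherwise; 50 points in the
proof-of-concept harness), β-steps and θ-steps alternate until the
relative objective decrease falls below `thresh` (default 1e−7) or 25
rounds. β is warm-started along the path. **θ restarts from 0 at every
path point**: warm-starting θ ratchets — once θ reaches a clip boundary at
one λ, features on the other side of the score spectrum receive ~e⁵⁰
penalty factors and can never re-enter at any later path point, which can
lock the fit into an anti-cooperative mode. With the neutral restart each
λ chooses its own basin from the data. The objective trace recorded per
path point is nonincreasing (asserted).

The path stops early once the active set exceeds the number of events of
the cause: a cause-specific Cox model with more coefficients than events
is saturated, cross-validation cannot prefer that region, and the dense
tail dominates runtime. λ is then selected among path points completed by
every fold. On probe replicates this truncation leaves the selected λ,
support, and θ identical to a full tight path. Path solves run at a
pathwise tolerance (weighted squared coordinate change < 1e−8, IRLS
relative objective change < 1e−7, matching common pathwise-solver
defaults); the full-data fit is re-polished at the selected λ at 1e−11 /
1e−10.

*Cross-validation.* λ is chosen to maximize the Verweij–Van Houwelingen
cross-validated partial log-likelihood: each fold contributes
`NLL(all data, β₋f) − NLL(training data, β₋f)`, summed over folds and
negated (the `lambda.min` rule; no 1-SE rule). Folds are drawn from the
run's seed; the stratified option splits events and non-events of the
cause proportionally (re-drawn if a training set would lack events;
unstratified folds raise instead). Fold paths are fit with the same
alternation as the full path, so the CV curve reflects the full procedure.
Coefficients are standardized internally (unit variance, centered) and
reported on the input scale.

### Cooperative alternation (CooPeR)

Both causes are initialized at their plain cross-validated elastic-net
solutions (θ frozen at 0). Each outer iteration refits cause 2 with
`z = |β̂₁|`, then cause 1 with `z = |β̂₂|` — cause 2 first, matching the
printed order of the algorithm. Absolute values are used because the
weight function responds to relative magnitudes and a protective
(negative) coefficient is evidence of relevance, not irrelevance.
Iteration stops when the L2 change of both coefficient vectors falls below
ε (default 1e−8) or after `mt_max_iter` rounds (default 3; 5 in the
proof-of-concept harness). λ is re-cross-validated inside every inner fit;
CV folds are re-drawn per inner fit from a deterministic seed stream, so a
run is bit-for-bit reproducible from its seed.

The order of causes matters in principle (information flows from cause 1's
initialization into cause 2's first refit); the implementation fixes cause
2 first, and swapping the event labels is therefore not exactly equivalent
to relabeling the output. Over 2–3 iterations the asymmetry is small but
not asserted to vanish. The algorithm is defined for exactly two causes.

## Simulation designs

### High-dimensional block-correlated design

Defaults: n = 400 observations, p = 5000 standard-normal covariates with
block structure made by a shared-factor construction
`xⱼ = √ρ·f + √(1−ρ)·eⱼ` (exact pairwise correlation ρ, unit marginals):

| block | size | ρ | cause-1 effects | cause-2 effects |
|---|---|---|---|---|
| B1 ("mutual") | 250 | 0.50 | +0.5 ×4 | +0.5 ×4 |
| B2 ("reversed") | 250 | 0.35 | +0.5 ×4 | −0.5 ×4 |
| B3.1 / B3.2 ("disjoint") | 500 (one ρ-block) | 0.05 | −0.5 ×4 (B3.1) | +0.5 ×4 (B3.2) |
| B4 ("cor. noise") | 500 | 0.32 | — | — |
| noise | 3500 | 0 | — | — |

Informative features are the first of their (sub-)block; each cause has 12
true effects. Event and censoring times follow the inverse-transform
construction for exponential baselines, `T_ik = −log(U_ik)/(λ·exp(xᵢ'β_k))`
and `C_i = −log(U_Ci)/λ_C` with λ = λ_C = 0.1; the observed time is the
minimum and the status records the winner (0 for censoring).

A caveat on the status mix: this effect layout is exchangeable between the
two causes (the informative blocks contribute symmetrically to both linear
predictors), so the two event probabilities are equal by construction —
Monte-Carlo gives ≈ 36% / 36% / 28%. The design this emulates is reported
with a 30% / 40% / 30% split, which cannot arise from the layout as stated;
the acceptance suite checks the proportions against those published targets
and the cause-1 check accordingly fails by about six percentage points.
This is a faithful-implementation discrepancy, not a bug; selection
behavior (which depends on the effect structure, not the split) reproduces
the published pattern.

### Proof-of-concept design

n = 1000, p = 14: three candidate covariates uniform on [−3, 3] and 11
independent standard-normal noise covariates, constant cause-specific
hazards `h_k(t|x) = h_0k·exp(x'β_k)` with independent exponential
censoring. Scenarios: A — X₁ has effect 1 on both causes (≈35%/35%
events); B — X₁ → cause 1 only, X₂ → cause 2 only (35%/35%); C — X₁ has
effect 1 on cause 1 and 0.25 on cause 2 (≈55%/7%); D — X₁,₂,₃ have effects
(1, 0.75, −0.5) on both causes (55%/7%; the common-cause prevalence for D
is not stated and is taken equal to C's). Baseline hazards and the
censoring rate are not stated either: they are calibrated by fixing the
censoring rate to 1 (status probabilities depend on rate ratios only) and
root-finding the two baseline rates so that the expected status
probabilities — computed exactly given x as rate ratios over a fixed
50 000-draw covariate sample — match the stated prevalences within 1.5
percentage points. Calibrations are memoized per scenario and reproduce
the targets in forward simulation (tested).

## Evaluation

Selection is scored per cause × block: selected ⇔ nonzero coefficient (or,
for importance-based methods, importance above the magnitude of the most
negative importance — the `vⱼ > |min v|` rule exposed as an adapter
utility); positive ⇔ nonzero true effect for that cause. PPV = TP/(TP+FP),
FPR = FP/(FP+TN), TPR and F1 analogously; PPV is reported as undefined
(NaN) where a block holds no true positives for the cause or nothing was
selected, and undefined values are excluded from medians. Replicate r of a
benchmark uses seed `base + r` for both data and fits; one cooperative run
per replicate yields both the CooPeR rows (final fits) and the Coxnet rows
(initial fits), so the baseline is exactly the algorithm's initialization.
Aggregation uses linear-interpolation (type-7) quantiles; the IQR is
reported both as q75−q25 and as the quartile pair.

## Desk-scale problem sizes

The shipped checks run, by choice, at sizes a single CPU handles in
minutes: the selection benchmark uses 10 replicates of the full n = 400,
p = 5000 design (medians of per-block metrics are stable at this replicate
count); the proof-of-concept bias comparison uses 100 replicates of
scenarios A and C and 50 of B at n = 1000 with 10-fold CV and a 50-point
λ path; the prior-information recovery check uses 50 replicates at n = 200,
p = 50 with 5 effects of ±1 under exponential censoring at rate 4.0
(≈10% events — a rare-event regime where prior information has room to
matter; with light censoring both arms recover all effects and the
comparison is vacuous). The status-proportion check simulates n = 30 000
with the 3500 zero-effect uncorrelated noise features omitted, which
leaves the status distribution unchanged.

## What the synthetic data does and does not show

The generators produce Gaussian covariates with exact block-factor
correlation, proportional hazards that hold exactly, and independent
exponential censoring. Passing tests therefore demonstrate the method's
behavior under its own assumptions; they say nothing about non-proportional
hazards, informative censoring, heavy-tailed or discrete covariates, batch
structure, or misspecified cause coding in real genomics data. The
correlated-noise block (B4) probes robustness to correlation without
signal, and block B2 probes opposite-signed shared effects — the magnitude
coupling is sign-free by design.

## Known limitations

- Two causes only; the alternation has no canonical generalization to
  K ≥ 3.
- Grouped prior information (matrix-valued Z) is out of scope; scores are
  a single vector (G = 1).
- The joint (β, θ) problem is non-convex; the alternation converges to a
  stationary pair that can depend on the fit order and, for pathological
  score/support configurations, on the per-λ restart policy documented
  above.
- θ at the clip boundary effectively restricts a model to the support of
  its prior scores; cause-specific effects invisible to the complementary
  model can then be suppressed (the disjoint-block behavior is expected to
  be no better than plain Coxnet, and can be slightly worse).
- No unpenalized (always-included) covariates, left truncation, or
  time-varying effects.
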