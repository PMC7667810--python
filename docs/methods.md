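# Methods

This note documents the models, numerical choices and limitations of
`plannsurv`, in the spirit of a statistical package's methods appendix.

## Discrete-time survival network

**Data transformation.** Exact right-censored times (t, d) are mapped to
person-period rows on a grid 0 = τ₀ < τ₁ < … < τ_k of half-open,
right-closed intervals I_j = (τ_{j−1}, τ_j]; an event at exactly τ_j
belongs to interval j. Times beyond τ_k must be administratively censored
first (`censor_at`); non-positive times are rejected. A subject observed
into interval m contributes training rows 1..m with the binary target 1
only on the last row of an event subject. A subject *censored strictly
inside* interval m contributes row m with target 0 by default — the
subject was observed in that interval — with a `censored_partial="drop"`
option for the stricter convention that discards the partially exposed
interval. Test-role expansion always yields k rows per subject so that a
full hazard profile can be queried. The interval enters the model as k
one-hot indicator columns ("time as k separate variables"), which lets the
importance layer attribute signal to individual intervals; a single
numeric midpoint encoding is available as an option
(`time_encoding="midpoint"`).

**Architecture and training.** Inputs are the p covariate columns plus the
k indicators. One or two hidden layers of equal width use sigmoid, ReLU or
tanh activations; the single output node is always sigmoid, so the output
is a hazard in (0, 1). Choices where the method's description is open, all
configurable:

- *Initialisation*: Glorot-uniform weights (±√(6/(fan_in+fan_out))),
  zero biases, seeded (`numpy` Generator).
- *Optimizer*: plain SGD with classical momentum
  (v ← μv − η·g; w ← w + v); defaults η = 0.2, μ = 0.9 match the tuned
  reference configuration; batch size 256 (or `"full"`), 50 epochs, with
  the per-epoch mean loss logged.
- *Loss*: class-weighted binary cross-entropy; the event class weight
  multiplies the loss of target-1 rows (weight 1 = unweighted, the tuned
  value). Hazards are clipped to [1e−7, 1−1e−7] inside the loss only.
- *Dropout*: inverted dropout on hidden activations only (inputs are never
  dropped), disabled at prediction time.
- *Standardisation*: continuous covariate columns (any column not entirely
  0/1) are standardised with training-set mean/sd stored on the model;
  dummies and interval indicators pass through.

Backpropagation is exact for the composite loss; the test suite checks the
analytic gradients against central finite differences on a ≤20-weight
network (away from the ReLU kink, where a two-sided difference quotient is
not a valid derivative estimate). Training is bit-reproducible given the
configuration seed; build and training consume independent seeded streams.

**Prediction.** Hazards come from a dropout-free forward pass;
S(τ_m|x) = ∏_{j≤m}(1−h_j(x)) is monotone non-increasing by construction.
Models serialise to self-describing JSON checkpoints (config, weights,
scaler, feature names).

## Connection-weight importance

For one hidden layer, Garson's partition: c_ij = |w_ij| / Σ_{i′}|w_{i′j}|
· |v_j|, importance_i = Σ_j c_ij, normalised to sum 1. For two hidden
layers the partition chains through both layers:
c_ijl = (|w_ij|/Σ_{i′}|w_{i′j}|) · (|u_jl|/Σ_{j′}|u_{j′l}|) · |v_l|. The
normalisation order for the two-layer extension is genuinely open; this
chain-partition reading is pinned down by the collapse property verified
in the tests — a size-1 second layer whose incoming weights equal a
one-layer model's output weights reproduces the one-layer importances to
1e−12. Biases are excluded (standard practice), importances are
sign-blind, and ranking ties break alphabetically for reproducible
reports. Dummy-level importances aggregate to parent variables through the
dataset's `group_map`; the k interval indicators pool into a single `time`
entry reported alongside (and a per-interval table is available).

## Cox baselines

The Breslow-tie log partial likelihood, score and observed information are
evaluated with suffix cumulative sums over time-sorted subjects; Breslow
ties keep the likelihood in its literal product form (the generators
produce tie-free event times, where Breslow and Efron coincide — the
cross-check against an independent implementation uses exactly that case).

- *Unpenalized fit*: Newton–Raphson with step-halving; convergence when
  the relative log-likelihood change is < 1e−9 (max 50 iterations);
  standard errors from the inverse observed information; covariates are
  centered so the reference prognostic index is 0. Divergent coefficients
  (|β| > 50) raise a monotone-likelihood diagnostic.
- *LASSO*: minimises −ℓ(β) + λΣ|β_j| on internally standardised covariates
  by cyclic coordinate descent on the local quadratic approximation, with
  step-halving on the penalized objective; coefficients return on the
  original scale, and `lasso_lambda_max` gives the full-shrinkage
  threshold max_j |∂ℓ/∂β_j(0)|. KKT stationarity at the solution is
  asserted in the tests with numerically differentiated scores.
- *CVPL*: the Verweij–van Houwelingen fold-wise form
  Σ_folds [ℓ(β̂₋fold) − ℓ₋fold(β̂₋fold)], with folds stratified by event
  status and seeded; ties on the λ grid resolve toward the sparser model.
- *Backward elimination*: factor groups (via `group_map`) are tested with
  approximate multi-df Wald statistics β_g′ Σ_gg⁻¹ β_g from the current
  fit — no per-candidate refitting (Lawless–Singhal style); the weakest
  group above `alpha_stay` (default 0.05; the stay threshold is a package
  default, as the selection method is usually reported without one) is
  dropped and the model refitted until all groups stay.
- *Prediction*: Ŝ(t|x) = exp(−H₀(t)·exp((x−x̄)′β)) with the Breslow step
  baseline; beyond the last event time the last value is carried forward.

## Evaluation metrics

- *C-index* (Harrell): comparable pairs are (i, j) with tᵢ < tⱼ and
  dᵢ = 1; score ties count 0.5; time-tied pairs are not comparable. It is
  computed only for models with a scalar risk ordering (Cox prognostic
  index, ensemble mortality); discrete-hazard networks are deliberately
  excluded.
- *Reverse Kaplan–Meier*: product-limit with the event indicator flipped;
  supplies Ĉ(t) and the left limit Ĉ(t−) (value just before t, Ĉ(0−)=1)
  and the median follow-up (first t with Ĉ ≤ 0.5).
- *IPCW Brier*: subjects with an event by t₀ contribute (0−Ŝ)²/Ĉ(tᵢ−);
  subjects under observation past t₀ contribute (1−Ŝ)²/Ĉ(t₀); subjects
  censored by t₀ contribute 0; the denominator is all n. A zero censoring
  estimate at a required evaluation point raises an error naming the
  subjects.
- *IBS*: trapezoid integration of the prediction-error curve divided by
  the horizon. A curve that starts after t = 0 is anchored with
  Err(0) = 0 (no prediction error at time zero); a curve already
  containing its t = 0 value is integrated as given, so a constant curve
  integrates to its constant. A `mean` rule is available as the
  alternative quadrature.
- *Calibration*: subjects are split into n_groups equal-sized groups
  (±1) by the deciles of predicted survival, with stable tie handling by
  subject order; each group reports mean prediction against Kaplan–Meier
  observed survival with 95% intervals on the log(−log) (exponential
  Greenwood) scale. Identical predictions collapse to a single group with
  a warning.

## Synthetic cohorts

The generators emulate the statistical structure of a large transplant
registry — not its variables. Defaults: n = 5000 subjects, 5 Bernoulli(0.5)
dummies and 3 standard-normal continuous covariates, log-hazard
coefficients (0.5, −0.3, 0.4, 0.2, −0.2, 0.3, −0.25, 0.15),
Weibull(shape 1.2, scale 12) baseline, independent exponential censoring at
rate 0.207 and a 10-year administrative horizon. The censoring rate was set
by bisection (`tune_censoring_rate`) so the observed event fraction at the
horizon is ≈31%, the regime the methods are meant for. The `nonlinear`
regime adds an interaction between the first two dummies and a threshold
term on the first continuous covariate, breaking the Cox model's
linearity; the `discrete_logistic` regime draws interval-by-interval from
hazards logit-linear in the inputs (intercept −3.2 per yearly interval,
i.e. a ≈4%/year baseline hazard and again ≈33% ten-year cumulative risk) —
the network's well-specified case. Closed-form true survival functions are
exposed for oracle tests; event times use inverse-transform sampling, and
everything is reproducible from the spec seed.

What passing tests on these cohorts do **not** show: behaviour under
informative censoring, time-varying covariates or effects, heavy
covariate correlation, the 97-variable scale of a real registry, or
real-data measurement artefacts. Problem sizes in the test suite (50–5000
subjects, networks of 2–16 hidden nodes, tens to a few hundred epochs) are
the package's reference experiment sizes; they make every stochastic check
reproducible with fixed seeds.

## Workflow

The split-sample protocol stratifies the 2/3–1/3 split by event status so
both parts share the event proportion. Network tuning is a grid search
scored by the mean fold IBS under 5-fold stratified cross-validation; the
censoring distribution for each fold's IPCW weights is estimated on the
fold-training data only, never on the validation fold, to avoid leakage.
Tuning ties prefer the smaller node size, then the lower dropout. The
comparison report evaluates every model's prediction-error curve at the
interval boundaries; random-survival-forest-style models can join through
an external-model contract (`predict_survival_matrix`, optional
`risk_score`) but no forest implementation is shipped.

## Known limitations

- At the administrative horizon itself the IPCW Brier score is only
  partially identified: subjects censored exactly at the horizon leave the
  weighted sum, so the year-10 point of a 10-year study underestimates the
  error there. Prediction-error curves are most trustworthy strictly
  inside the follow-up range.
- Breslow tie handling is literal but slightly biased under heavy event
  ties; the package targets continuous-time data where event ties are rare.
- The two-layer importance extension is one defensible reading of the
  weight-partition idea; published per-variable importance values from
  other implementations need not reproduce under it.
- No time-dependent covariates, no Bayesian (ARD) variant, and no more
  than two hidden layers.
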