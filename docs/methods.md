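# Methods

## Problem and model

`pancrisk` predicts a patient's risk of pancreatic ductal adenocarcinoma
(PDAC) from the longitudinal sequence of diagnosis and medication codes in
their electronic health record.  A *trajectory* is the ordered history up
to a prediction endpoint; the model outputs cumulative probabilities that
cancer occurs within 3, 6, 12, 36 and 60 months of that endpoint.

### Sequence encoder

Each event token is embedded (width `d`) and blended with a cosine time
encoding of its day-delta Δt to the endpoint:

    M = 2π · linspace(f_start, f_end, d)          (cycles/day)
    P = cos(Δt · M)
    X ← (P·W_scale) ⊙ X + (P·W_add)

The default frequency grid spans periods from 100 years down to 30 days
(`f_start = 1/36500`, `f_end = 1/30` cycles/day), covering both lifelong
drift and recent-event effects; the bounds are configurable.  Δt is
measured to the prediction endpoint, so the most recent event has Δt = 0.
Patient age — the dominant demographic risk factor — enters as one
prepended pseudo-token whose feature row is `cos(age_days · M)`; a config
switch (`encoder.age_mode: add`) instead adds that row to every event.
The token variant is the default because it leaves event Δt semantics
untouched.

### Transformer and risk head

`L` blocks of multi-head self-attention (each of `H` heads projects to
width `d`; concatenated heads are mixed by `W_agg ∈ R^{Hd×d}`), with
residual connections and layer normalisation around both the attention
and the two-layer ReLU feedforward, then a final linear layer and masked
mean pooling over positions give the trajectory encoding `z ∈ R^d`.
Attention uses row-wise softmax over keys (each query's weights sum to 1)
with scale `1/√d`; padded positions are masked out of both attention and
pooling, so batch composition cannot change a trajectory's prediction
(asserted in tests).

The risk head is a discrete-interval hazard regression:

    λ_t = ReLU(zᵀβ_t + b_t)      t = 1..5   (interval hazards ≥ 0)
    s_T = zᵀc + Σ_{t≤T} λ_t                  (cumulative score)
    p_T = sigmoid(s_T)

The baseline term `zᵀc` is deliberately *not* clamped, so probabilities
below 0.5 are reachable; monotonicity `p_1 ≤ … ≤ p_5` still holds exactly
because the increments are non-negative.

### Loss and censoring

Training minimises the mean binary cross-entropy over unmasked
(trajectory, interval) cells plus `(λ₂/2)‖θ‖²`.  Probabilities are clamped
to `[1e-7, 1−1e-7]` inside the loss.  Horizons extending beyond a
control's end of record are handled by a `censoring` switch:

* `mask` (package default for training): the cell is excluded from the
  loss via a censor mask;
* `zero_fill`: the cell is kept with label 0 — the convention matching
  the two-year control rule, under which only 24 months of follow-up are
  guaranteed anyway.

Evaluation runs in this package use `zero_fill` so that the 36-month AUROC
is computed over the whole evaluation population rather than the minority
with 36 observable months.

## Data preparation

Diagnosis codes are truncated to their first three characters (broad
ICD categories); medication codes on a user-supplied inactive-ingredient
stoplist are dropped.  For cancer patients, all events within an
exclusion window (0, 3 — the default — or 12 months, counted as
`round(months·30.44)` days) before diagnosis are removed to suppress
quasi-symptoms; an event exactly at the boundary is retained, and a
cancer exactly at a horizon boundary counts as within it.  Training
endpoints are drawn uniformly (without replacement) among eligible
events: strictly before `diagnosis − window` for cases, at least 730 days
before end of record for controls.  Evaluation uses the last four
eligible endpoints, deterministically.  Trajectories keep the most recent
`max_len` events (default 300; the cap is a free parameter of the
protocol).  Diagnosis and medication tokens share one vocabulary with
`DX:`/`RX:` prefixes; index 0 is a padding token frozen at the zero
embedding.

## Training protocol

Per epoch, four fresh random trajectories per patient are drawn and the
stream is balanced so that case-patient and control-patient trajectories
appear 1:1 (the minority stream kept whole, the majority subsampled).
Adam with initial learning rate 0.001 (default); after each epoch the
validation AUROC at the 36-month horizon is logged, and when it fails to
improve for more than 4 epochs (strict comparison) the best parameters
are reloaded and the learning rate halved.  The returned checkpoint is
the best-validation-AUROC epoch.  Default budget 20 epochs; the grid
protocol allows up to 100 with convergence checks every 5.  Splits are
patient-level 80:10:10.  The tuned architecture is L=1, H=16, d=64,
lr=0.001, no dropout; `grid_search` covers L∈{1,2,4}, H∈{4,8,16},
d∈{64,128}, lr∈{0.0005,0.001,0.005,0.01}, weight-decay∈{0,0.01,0.1,0.5},
dropout∈{0,0.1,0.2,0.5}, with ties broken toward the smaller model.

The model, baselines, training and attribution all run on a small
reverse-mode autodiff engine over numpy arrays written for this package
(`pancrisk.autodiff`), verified against finite differences to ~1e-9
relative error.  All randomness flows through explicit
`numpy.random.Generator` objects, so runs are bit-reproducible on one
thread.

## Evaluation metrics

* **AUROC** with a percentile bootstrap 95% CI over 100 resamples.
* **Top-N cohort**: one score per patient (max over their evaluation
  trajectories), ties broken by patient id; surveillance cohorts restrict
  to age ≥ 50 at prediction (configurable floor).
* **PPV** and **IR = PPV / incidence**.
* **SIR** = observed / expected cases, where expected sums the annual
  incidence table over strata and year offsets `T = {0..⌈months/12⌉−1}`
  (sub-year horizons query only t = 0); ages are floored when querying
  and patients age across band boundaries (`floor(age)+t`).  A variant that
  sums one extra year offset for multi-year windows is available behind
  `printed_T=true`; the default uses exactly the number of years the
  horizon spans.  The 95% CI is `(√N_obs ± 0.98)²/N_exp`,
  with the subtrahend clamped at zero.  This CI is an approximation: its
  empirical coverage is ~90% when the expected count is below ~5 and
  ~95% above ~10, which the calibration tests account for by using
  cohorts with expected counts near 10.
* **Calibration curve** over equal-width probability bins; **subgroup
  reports** by race, sex or age band; **time-to-event distribution**
  of prediction-to-diagnosis gaps in the high-risk cohort, with the
  fraction beyond 100 days.

## Attribution

Integrated Gradients with a midpoint Riemann sum (default 64 steps)
attributes the 36-month cumulative probability (configurable horizon) to
each event's embedding vector.  The baseline input is a same-length
sequence of the zero-embedding padding token with identical time deltas —
uninformative content, preserved temporal structure; the age token stays
fixed along the path.  Per-event scores sum the embedding coordinates
(preserving sign and completeness additivity), and the completeness gap
`|ΣIG − (F(x)−F(x_base))|` is always reported.  Globally, attribution
runs over the k highest- and k lowest-risk trajectories; per trajectory
the `⌈0.1·N⌉` highest-attributed events are flagged (per-trajectory
deciles, so a long trajectory cannot dominate), and a code's importance
is flagged occurrences / total occurrences — normalising away raw code
frequency.

## Synthetic cohorts

Real cohorts of this kind are access-restricted, so the package ships a
simulator whose defaults emulate realistic population margins: 86.7%
male; 80% White / 17% Black / 3% Other; ages 52–86 at end of record;
record spans 2–14 years; a mixed-Poisson visit process (per-patient rate
log-normal around 18 events/year, σ=0.8) giving heavy-tailed trajectory
lengths with a median near ~100 events; Zipf-distributed (exponent 1.1)
opaque code tokens over two streams (65% diagnoses); and a rare outcome
(0.13% of patients by default, the evaluation-cohort fraction —
development-style cohorts enrich this to a few percent, as case-control
designs routinely do).

Cancer onset follows an exponential time-to-event model with a
piecewise-constant age effect (multipliers 0.05/1.0/1.6/2.2/2.8 for
<50/50s/60s/70s/80+) in which *planted risk codes* multiply the hazard
from their first occurrence onward, and *order pairs* (A, B, m) multiply
it only when A's first occurrence precedes B's — an order-sensitive
signal invisible to bag-of-events representations.  The base rate is
calibrated by root finding so the expected case fraction matches the
target exactly; the generator records per-patient ground truth (carried
codes, integrated hazard modifier, hazard at end of record), making every
planted effect analytically checkable.  Controls keep their end of record
independent of case status to avoid length leakage.

What the simulator does **not** emulate: real ICD/RxNorm semantics and
co-occurrence structure, care-seeking dynamics (visit rate is independent
of health state), coding artefacts, or inter-patient correlation.
Passing tests therefore demonstrate that the machinery recovers known
signal under the stated generative model — not clinical performance on
real EHR data.

One property of this generator matters for testing: record length
confounds the *marginal* association between code carriage and case
status (longer records mean more carriage opportunity and more cumulative
hazard), so null checks on unit multipliers condition on exposure via the
generator's exact GLM form (binomial, cloglog link, offset
log integrated-modifier).

## Desk-scale problem sizes

The test suite and acceptance script shrink the experiments to sizes a
single CPU handles in minutes, chosen for statistical power:

* signal recovery: 20,000 patients, 5% cases, four planted codes at
  hazard ×8 (carriage 10–15% each; ranking by the generator's true hazard
  achieves AUROC ≈ 0.86 under these conditions, leaving clear headroom
  above the 0.75 recovery bar), transformer L=1, H=4, d=32, 6 epochs;
* SIR calibration: 50 replicates of 3,000 patients with a prospective
  snapshot endpoint drawn uniformly among events with ≥36 months of
  follow-up (endpoint choice independent of diagnosis, so a random
  ranking is exactly calibrated against the cohort's own table);
* architecture ordering: 5,000 patients with a single order pair
  (A01 before A02, hazard ×20) as the only signal, 12 epochs, d=16.

## Numerical choices and degenerate inputs

Float64 throughout; softmax is max-shifted; layer norm uses ε=1e-5;
probabilities are clamped only inside the loss (gradients pass through
within the clamp range).  An empty trajectory encodes to the bare age
token.  A patient with no eligible endpoint contributes nothing that
epoch (training) or to evaluation.  Strata with zero person-years carry a
missing incidence rate and raise a named error if queried.  Ties are
broken deterministically everywhere (patient id, then endpoint day, then
position).  Checkpoints serialize parameters, config, and vocabulary into
one `.npz` with a format version.

## Known limitations

* The autodiff engine is minimal by design: no GPU, no kernel fusion;
  desk-scale configs (d ≤ 64, ≤ 50k trajectories) are the intended
  envelope.
* The SIR confidence interval inherits the coverage behaviour of the
  classical square-root approximation at low expected counts.
* The simulator's independence assumptions (visit process vs. health
  state) mean quasi-symptom dynamics are only represented through the
  exclusion-window machinery, not emergent behaviour.
* Grid search is sequential; at desk scale a full 288-point grid is
  impractical — use the `budget` argument.
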