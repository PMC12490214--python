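# pancrisk

Pancreatic-cancer risk prediction from longitudinal electronic health
records: a transformer sequence model over time-stamped diagnosis and
medication codes, a five-interval cumulative-hazard head, surveillance
metrics (PPV, incidence ratio, standardized incidence ratio), and
Integrated-Gradients code attribution — exercised end to end on a bundled
synthetic-EHR cohort simulator with planted, analytically checkable risk
structure.

**Who it is for.** Researchers in clinical risk modelling who want a
tested, reproducible reference implementation of trajectory-based PDAC
risk prediction — the kind evaluated for surveillance programs — without
access to restricted clinical data.

## The model

A patient trajectory is the ordered event history up to a prediction
endpoint.  Each event token is embedded and modulated by a cosine
encoding of its day-delta Δt to the endpoint
(`P = cos(Δt · 2π linspace(f_start, f_end, d))`,
`X ← (P·W_scale)⊙X + (P·W_add)`), with patient age as a prepended
pseudo-token.  `L` multi-head self-attention blocks (residual + layer
norm, two-layer ReLU feedforward), a linear layer and mean pooling give a
fixed-length encoding `z`, from which a discrete-interval hazard head
predicts cumulative cancer probabilities at 3, 6, 12, 36 and 60 months:

    λ_t = ReLU(zᵀβ_t + b_t),   s_T = zᵀc + Σ_{t≤T} λ_t,   p_T = sigmoid(s_T)

so `p_1 ≤ … ≤ p_5` by construction.  Training uses balanced per-epoch
trajectory resampling (4 per patient), binary cross-entropy over the five
horizons, and plateau-triggered learning-rate halving with
best-checkpoint reload.  High-risk cohorts are evaluated with the
standardized incidence ratio

    SIR = N_observed / N_expected,   95% CI = (√N_obs ± 0.98)² / N_exp

where the expectation comes from an (age band × race × sex) annual
incidence table with year-by-year aging.  Integrated Gradients attributes
predictions to individual events; a code's global importance is the
fraction of its occurrences landing in the top decile of attributed
events, normalising away raw frequency.

Two baselines share the identical risk head: a bag-of-events linear
model (order-free normalized code frequencies) and a token-averaging
two-layer MLP (no attention).  Their gap to the transformer isolates the
value of modelling event interdependencies.

Since real cohorts of this kind are access-restricted, the package ships
a cohort simulator with realistic population margins (87% male,
80% White, heavy-tailed trajectory lengths, ~0.13% case fraction at
evaluation scale) with planted multiplicative risk codes and
order-sensitive code pairs; see `docs/methods.md` for the generative
model and its limits.

## Worked example

```sh
pancrisk run --config examples/quickstart.yaml --outdir experiments/quickstart
```

simulates 3,000 patients (8% cases, four planted hazard-×8 codes), trains
a small transformer (L=1, H=2, d=16, 8 epochs), evaluates the held-out
split and runs attribution — ~35 s on one CPU.  The run logs per-epoch
progress and writes `report.json`; the bundled config produces:

```
auroc          0.777   (95% CI 0.694–0.879)
sir  (top 50)  5.40    (95% CI 2.94–8.59)   observed 14, expected 2.6
ppv  (top 50)  0.28    ir 2.95
```

Read: the model's 36-month risk ranking separates future cases from
controls (AUROC 0.78); its top-50 high-risk cohort contains 5.4× the
cases expected from age/race/sex incidence alone (SIR), and 28% of the
flagged patients truly develop cancer within 36 months (PPV), ~3× the
cohort rate (IR).  In `importance.csv` the planted codes surface at the
top among recurrent codes — e.g. `M012` is flagged into the attribution
top decile in 38 of its 42 occurrences (importance 0.90).  Numbers vary
with the config seed and grow with cohort/model size (the acceptance
conditions below reach AUROC ≈ 0.82).

## Layout

| Module | Contents |
| --- | --- |
| `pancrisk.synthetic` | cohort simulator, incidence tables, JSONL I/O |
| `pancrisk.prep` | code normalization, exclusion windows, trajectory sampling, interval labels |
| `pancrisk.encoder` | time multipliers, cosine positional embedding, age encoding |
| `pancrisk.model` | transformer, hazard head, loss, checkpoints |
| `pancrisk.training` | balanced sampler, plateau schedule, Adam, grid search |
| `pancrisk.metrics` | AUROC+CI, top-N, PPV/IR, SIR+CI, subgroups, calibration |
| `pancrisk.attribution` | integrated gradients, code-importance aggregation |
| `pancrisk.baselines` | bag-of-events LR and token-averaging MLP |
| `pancrisk.cli` / `pancrisk.config` | `simulate / prepare / train / evaluate / attribute / baseline / run` |
| `pancrisk.autodiff` | minimal reverse-mode autodiff over numpy |
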