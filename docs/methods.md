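# Methods

This note documents the models and procedures implemented in `fedsepsis`,
the assumptions behind the synthetic cohorts, and the design decisions taken
where the underlying protocol left choices open.

## Sepsis-3 operationalization

A patient's event stream (hours from admission, hour 0) is scanned for:

- **Suspected infection** — at least two antimicrobial-dose events at
  distinct times (any agent) paired with a culture order. If the first dose
  precedes the culture, the culture must follow within 24 h; if the culture
  comes first, the first dose must follow within 72 h. All bounds are
  inclusive. The suspicion time is the earlier of (first dose, culture); one
  candidate window is produced per culture order.
- **Organ dysfunction** — a SOFA score at least 2 points above baseline at
  some time in [suspicion − 48 h, suspicion + 24 h]. The baseline is the
  latest score strictly before suspicion − 72 h, or 0 when no prior
  assessment exists. SOFA arrives as a precomputed score channel; computing
  sub-scores from raw organ measurements is out of scope. When several times
  qualify within one window, the earliest is kept (earliest clinical
  evidence).
- **Onset** — each qualifying (suspicion, dysfunction) pair contributes a
  candidate onset at the dysfunction time's window; among candidates the
  *latest* wins by default, with an `earliest` policy switch, since the
  "latest window where both criteria hold" convention conflicts with the
  earliest-onset convention used elsewhere in the literature.

Cohort selection keeps patients strictly older than 15 years; the episode
endpoint is the earliest of first onset, death, and discharge, and the
episode covers [max(0, endpoint − 48 h), endpoint] binned into half-open 1 h
windows [k, k+1).

## Synthetic cohorts

The generator produces the statistical shape the pipeline assumes, not
physiology:

- **Prevalence** ~ Bernoulli per patient, default 9.5 % septic.
- **Episode lengths** are drawn from 6 h-spaced classes within
  `episode_length_range` (default 12–48 h). Care-episode length
  distributions are peaked in practice, and the length-stratified splitter
  omits strata of ≤ 5 episodes — a generator spreading lengths uniformly
  over 37 distinct values would see most positive strata omitted at desk
  scale, which no real cohort of this kind exhibits.
- **Planted labels.** Every septic patient receives exactly one qualifying
  suspicion/dysfunction pair whose dysfunction time *is* the true onset
  (culture at suspicion, two doses within 72 h after it, SOFA 3 over a zero
  baseline at onset). Every non-septic patient violates one rule — a single
  dose, a 30 h dose-to-culture gap, a flat SOFA, or no treatment events —
  so labeler recovery is exact by construction, not statistically.
- **Tabular signal.** Channel values are Gaussian with fixed per-channel
  scales. Septic episodes add a linear mean-shift ramp reaching
  `signal_effect` (default 2.0) standard deviations at onset, ramping over
  the last `ramp_windows` (default 48, i.e. the whole capped episode). The
  full-episode ramp mirrors progressive pre-onset deterioration; it also
  means the lock rule fires early on synthetic septic episodes, so synthetic
  earliness values are large and not comparable to clinical ones.
- **Missingness** is Bernoulli per (window, channel); default rates spread
  linearly 0.30–0.85 across channels, emulating long-tailed EHR sparsity.
- **Notes** are token bags from two class-conditional mixtures over a small
  clinical vocabulary. Note signal strength is a separate dial
  (`note_signal_effect`, default 0.4, ~hourly notes): clinical text is a far
  weaker predictor than vitals/labs in comparable cohorts, and a shared dial
  would invert that ordering. At `note_signal_effect = 0` the class
  distributions are identical.

What passing tests on these cohorts shows: the labeling rules, featurization,
imputation, training loop, aggregation algebra, and metrics are implemented
correctly, and the qualitative orderings (multi-modal ≥ single-modality,
fewer clients ≥ many clients at fixed data) hold under a planted,
well-specified signal. What it does not show: performance on real EHRs,
whose signal structure, missingness mechanism, and note content are far less
benign.

## Featurization

Window cells are arithmetic means of the values falling in [k, k+1); empty
cells are masked. Episodes whose pooled non-text missingness reaches 90 %
are dropped (per-episode interpretation; a per-feature mode is provided —
the filtering sentence is ambiguous between the two). Splits are 80/10/10,
stratified by (label, episode length) with largest-remainder rounding;
strata of ≤ 5 episodes are omitted entirely to keep class and length
distributions comparable.

Imputation strategies:

- `cfmean` — last observation carried forward; cells before the first
  observation, and never-observed channels, take the global mean computed on
  the **training split only** (the leakage-safe reading of "global average
  across the whole data").
- `distinct` — missing cells become `floor(global max) + 1`, verified absent
  from every observed value.
- `gain` — see below.

After imputation (and modality assembly) all channels are z-scored with
training-split statistics. This step is standard practice rather than part
of the protocol being modeled: unscaled channels (means up to ~50) saturate
the LSTM gates.

## GAIN

Generator and discriminator are fully connected (two hidden layers of width
= feature count, ReLU, sigmoid output), trained with Adam (step 1e−3) on
min–max-normalized columns. Per iteration, the generator sees
`M∘X + (1−M)∘Z` with `Z ~ Uniform(0, 0.01)` plus the mask; the discriminator
sees the imputed matrix plus the hint `H = B∘M + 0.5(1−B)`,
`B ~ Bernoulli(hint_rate = 0.9)`, and is trained by cross-entropy on mask
recovery; the generator by the adversarial term on missing entries plus
`alpha` (default 100) × mean squared reconstruction error on observed
entries. A column with no observed entry is rejected (its normalization is
undefined). The full profile is 15 000 iterations at batch 512; tests and
desk experiments use a reduced profile (2 000 iterations, batch 128), which
already beats column-mean imputation on correlated MCAR data.

## Sequence model

Single- to triple-layer LSTM, standard gating; `eq8_literal=True` replaces
the output gate with the forget gate in `h_t = o · tanh C_t`, reproducing a
variant that appears in some formulations (the cell update is unchanged).
Forward, backprop-through-time, inverted dropout between layers, and Adam
are implemented directly on float64 arrays, so runs are bit-reproducible
under a seed and were validated against finite differences and a scalar-loop
oracle.

The per-window training target is the episode label for every window — the
protocol does not state a per-window target construction, and this choice is
consistent with lock-based early prediction. One epoch iterates balanced
batches (exactly ⌈b/2⌉ positives, resampled with replacement) until the
negative class has been covered once. Episode score for curve metrics is the
lock-window probability when a lock fired, else the maximum window
probability.

Desk-scale defaults: hidden size 32, one layer, batch 100, Adam step 1e−2,
1–2 epochs, cohorts of 1 200–2 000 episodes; the published search grid
(neurons 512–2048, etc.) remains available through `FULL_SEARCH_GRID` and
the random-search routine (uniform draws without replacement, tune-split
AUPRC as the selection metric, ties broken by draw order).

## Federated simulation

Training episodes are split into equal shards once; each round every client
trains from the broadcast weights over its shard (fresh local optimizer per
round — the protocol does not state whether optimizer state persists), and
the server aggregates:

- `simple` — `W_{r+1} = Σ_c (S_c/S) W_r^c` (FedAvg).
- `opt` — a server-optimizer step on the pseudo-gradient
  `Δ_r = W_r − Σ_c (S_c/S) W_r^c`; plain gradient descent with step 1.0
  (the default) reproduces `simple` exactly, and an adaptive-moment server
  optimizer is available.

Per-round metrics are always computed on the aggregated global model. A
one-client federation is numerically identical to centralized training with
the matched schedule. The socket transport (length-prefixed frames,
`npz`-serialized weights over localhost) is bit-exact with the in-process
path; client failure aborts the round rather than aggregating partially.

## Metrics

AUROC (trapezoidal; equals P(score⁺ > score⁻) + ½ P(tie)) and AUPRC (area
under the precision–recall step curve with ties grouped) are computed at the
episode level via scikit-learn and are cross-checked in the test suite
against exhaustive brute-force oracles on all small instances. Positive
calls use a strict > 0.5 threshold. Earliness is the median lead
(onset window − lock window, hours) over true-positive episodes and is
undefined (with a warning) when there are none. Report deltas are expressed
in percentage points, rounded half-up to two decimals.

## Known limitations

- The synthetic signal is a planted mean shift; no physiological coupling
  between channels, treatments, and SOFA trajectories.
- The pretrained text-embedding backend is an adapter stub; all shipped
  experiments use the deterministic surrogate.
- The federated simulation is synchronous and failure-free by design: no
  stragglers, client sampling, privacy mechanisms, or real devices.
- Probabilities are not calibrated; the 0.5 lock threshold is a protocol
  constant, not a tuned operating point.
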