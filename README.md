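# fedsepsis

A desk-scale, fully testable pipeline for **early sepsis detection from
sparse electronic health records**, with **simulated federated learning**.
It is aimed at researchers who want to study the *methodology* of
Sepsis-3-based early-warning models — labeling rules, missing-data handling,
multi-modal fusion, federated aggregation — without access to credentialed
clinical databases: every experiment runs on seeded synthetic cohorts with
planted ground truth, on one CPU, in minutes.

## What it implements

**Sepsis-3 labeling.** *Suspected infection* requires ≥2 antimicrobial doses
paired with a culture order (culture within 24 h after the first dose, or the
first dose within 72 h after the culture). *Organ dysfunction* is a SOFA
score ≥ 2 points above baseline inside [suspicion − 48 h, suspicion + 24 h],
the baseline being the latest score strictly before suspicion − 72 h (0 if
none). The onset is the latest window where both hold. Care episodes cover up
to 48 one-hour windows ending at the first onset, death, or discharge;
patients aged ≤ 15 years are excluded.

**Missingness strategies.** Three representations of the (often > 80 %
missing) feature matrix: carry-forward with global training means
(`cfmean`), a distinct integer sentinel absent from the whole dataset
(`distinct`), and **GAIN** — generative adversarial imputation in which a
generator fills missing cells and a hint-assisted discriminator tries to
recover the missingness mask (`gain`). GAIN is implemented from scratch in
NumPy with explicit backprop and Adam.

**Prediction.** A per-window LSTM (also pure NumPy, gates
`σ(W_x X_t + W_h h_{t−1} + b)`, cell `C_t = f·C_{t−1} + i·C*`,
`h_t = o·tanh C_t`) with a log-softmax two-class head. Training batches are
oversampled to exactly 50 % positive episodes. At inference the first window
whose positive probability exceeds 0.5 *locks* the episode's prediction;
later windows are ignored. Modalities: `non_text` (vitals/labs),
`clinical_text` (per-window note embeddings, short 768-dim mean or long
3072-dim concatenation of the last four encoder layers; a deterministic
surrogate backend by default), and `multi_modal` (their concatenation).

**Federated training.** Equal sharding over 1–10 clients; per round the
server broadcasts weights, clients train locally, and the server aggregates
by sample-size-weighted averaging (`simple`, FedAvg) or a server-optimizer
step on the pseudo-gradient `W_r − avg(W_r^c)` (`opt`). A length-prefixed
localhost socket transport mirrors the client/server deployment.

**Evaluation.** Episode-level AUPRC and AUROC, confusion counts, and
*earliness* — the median, over true positives, of hours between the lock
window and onset.

## Worked example

```
fedsepsis run --modality multi_modal --impute cfmean \
              --setting single_server --seed 1 --n-patients 1200
 auprc_pct  auroc_pct  earliness_h  n_episodes
    64.939  94.922195         29.0         122
```

A 1200-patient synthetic cohort (9.5 % septic) is generated, labeled with
the Sepsis-3 rules, featurized into ≤ 48-window episodes, split 80/10/10
stratified by class and length, imputed, fused with surrogate note
embeddings, and used to train the LSTM; the row reports test-split AUPRC
(64.9 %), AUROC (94.9 %), and median earliness (29 h — large because the
synthetic septic signal ramps from admission onward). The same preset in a
two-client federation:

```
fedsepsis run --modality non_text --impute cfmean --setting federated \
              --aggregation simple --n-clients 2 --n-rounds 5 \
              --seed 1 --n-patients 1200
 round  auprc_pct  auroc_pct  earliness_h  n_episodes
     1  60.497302  88.861589         29.0         122
     ...
     5  78.369547  94.594595         23.0         122
```

one row per aggregation round, computed on the aggregated global model.

The same flows are available as a library (`fedsepsis.pipeline.run_experiment`,
`fedsepsis.synth.generate_cohort`, `fedsepsis.sepsis3.label_cohort`, ...);
see `docs/methods.md` for the model details and design decisions.

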