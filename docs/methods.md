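# Methods

## Problem setting

`smokesense` models a two-phase smoking-cessation study design. During a
pre-quit phase (Phase 1, default 14 days) a smoker's phone passively records
accelerometer (ACC), gyroscope (GYR) and magnetometer (MAG) axes, ambient
light (L) and time of day (T), while the smoker logs every cigarette in
real time. After quitting, a post-quit phase (Phase 2, default 90 days)
records the same sensor channels while the participant reports smoking
lapses and craving episodes (intensity 1 = very low … 5 = very high, at
least once per day). The analysis asks whether the movement channels alone
predict, within a 5-minute window, that a smoking-related event is about
to be reported — the window length a just-in-time intervention needs.

Because no public cohort of this kind exists, the package ships a
synthetic-data generator that emulates the statistical structure the
analysis assumes, and every claim the test suite makes is a claim about
recovery of *known, injected* structure.

## Synthetic cohorts

Each participant-phase is a regular grid of sensor rows at 5 samples per
minute (12 s cadence), so 25 rows span exactly 5 minutes — the model's
input shape.

* **Inertial channels** (ACC/GYR/MAG × x,y,z): stationary AR(1) noise with
  lag-1 correlation 0.8, unit marginal variance and a per-axis constant
  offset. Units are arbitrary; no attempt is made at IMU physics (gravity,
  orientation, sensor fusion).
* **Light**: a rectified 24-h sinusoid peaking at midday plus half-normal
  noise. **Time of day**: minutes since midnight scaled to [0, 1]. The
  midnight wrap-around is left as a discontinuity; events are placed in
  waking hours, far from it.
* **Events**: homogeneous Poisson within waking hours (07:00–23:00).
  Phase 1 defaults to 10 smokes/day; Phase 2 to 1 lapse/week and ~1.3
  craving reports/day with at least one craving report forced per day
  (the reporting protocol). Craving levels are i.i.d. from a configurable
  5-vector (default mildly peaked at level 3). A configurable fraction of
  participants (default 3/17) report nothing in Phase 2.
* **Pre-event motif**: for a window of `pre_event_window` minutes
  (default 3) *before* each event, the inertial channels receive an
  additive oscillation with period `burst_period` (default 30 s, a slow
  hand-to-mouth-like cadence observable at the 12 s cadence) plus extra
  white noise with variance `variance_gain − 1` (default gain 3). The
  whole motif is scaled by the cohort-level `motif_amplitude`, a
  per-participant amplitude/phase jitter drawn once per participant
  (`subject_jitter`, default 0.2), and a per-event Dirichlet(2,2,2) draw
  of how strongly each of the three inertial sensors is involved (mean
  involvement set by `channel_weights`, default acc 1.0 / gyr 0.8 /
  mag 0.5). The per-event sensor weighting is a deliberate design choice:
  it makes the combined ACC-GYR-MAG input genuinely more informative than
  any single sensor, so the channel-ordering result is learnable rather
  than a trivial tie. Whether the real signature precedes, spans or
  follows events is unknowable from self-report data alone; the generator
  defaults to "precedes".
* **Missingness**: each row is independently dropped with probability
  `missing_prob` (default 0.02); dropped rows keep their timestamp but
  lose all channel values.

All randomness derives from `(config.seed, participant_id, stage label)`
through `numpy.random.SeedSequence`, so cohorts are bit-reproducible and
baseline, event placement, motif and missingness draws are mutually
independent streams (e.g. setting `motif_amplitude = 0` changes nothing
else about a cohort).

What the generator does **not** emulate: real activity structure (walking,
driving, sleep posture), device placement changes, label noise from
recall errors, non-stationary sensor drift, or correlations between
craving level and motif strength. Passing tests therefore demonstrate
that the pipeline and models recover the kind of structure the analysis
posits, at realistic sparsity and sampling rates — not that real phones
carry that structure.

## Pipeline

Streams are cut into consecutive non-overlapping 25-row windows aligned
to the stream start (alignment to clock time would change nothing
contractual); a trailing remainder is dropped. Windows with ≥13 of 25
rows missing are removed; smaller gaps are imputed by last observation
carried forward within the window (leading edge back-filled) so no
information leaks across windows. A window is labeled 1 iff at least one
event timestamp falls in `[start, start + 5 min)` — a half-open interval
partitioning time exactly — with the earliest contained event supplying
the kind/level metadata.

Class balancing subsamples the majority class (seeded, without
replacement) down to the minority count, after first excluding
majority-class windows above the 95th percentile of mean within-window
channel variance. This variance screen is our concrete operationalisation
of "noise removal" before downsampling: it removes the most
movement-contaminated background windows (including windows that overlap
the tail of a motif belonging to a neighbouring labeled window). The
percentile is configurable.

The within-subject split shuffles (seeded) and splits 90/10 per
participant, stratified by label whenever each class has ≥2 windows.

## Models

The four classifiers are implemented on a small reverse-mode autograd
engine over NumPy arrays (`smokesense.nn`), with convolution and pooling
built from a windowed-gather primitive and the LSTM from the standard
gate equations:

    f_t = σ(W_f·[h_{t−1}, x_t] + b_f)      (forget)
    i_t = σ(W_i·[h_{t−1}, x_t] + b_i)      (input)
    c̃_t = tanh(W_c·[h_{t−1}, x_t] + b_c)   (candidate)
    c_t = f_t ∗ c_{t−1} + i_t ∗ c̃_t
    o_t = σ(W_o·[h_{t−1}, x_t] + b_o)      (output)
    h_t = o_t ∗ tanh(c_t)

The backward direction runs the same recursion right-to-left and the
BiLSTM output is the per-step concatenation [h→_t, h←_t]. The stacked
model is

    input (25 × C) → conv(128 filters, 11-row kernel, ReLU, L2 penalty)
    → batch norm → max-pool (3, stride 1) → BiLSTM → dense 64 → dense 32
    → dense 1 → sigmoid

and the three baselines (LSTM, 1D-CNN, BiLSTM) share the dense head. The
11-row receptive field reads the convolution's index range `x_{i−10:i}`
literally; it is configurable because a 10-tap reading is equally
defensible. Batch normalisation follows the ReLU activation
(normalising the "feature map output" of the conv layer). The recurrent
classifiers use the final hidden state(s); the 1D-CNN flattens the pooled
map.

Training choices (unspecified by the study design, fixed here once):
Adam, learning rate 1e-3, batch size 32, ≤100 epochs with early stopping
(patience 10) on a 10% validation split carved from the training data,
binary cross-entropy from logits in the numerically stable form, L2
coefficient 1e-4 on convolution weights, forget-gate bias initialised to
1, He/Glorot-style scaled-normal weight initialisation. Inputs are
z-scored per channel with training-set statistics only. Every forward
operator is verified against an independent brute-force reference
(triple-loop convolution, scalar gate-by-gate LSTM) and every gradient
against central finite differences; training is bit-deterministic for a
fixed seed.

## Evaluation

* **Within-subject**: balance → select channels → 90/10 shuffled
  stratified split → train → score.
* **Phase transfer**: train on all (balanced) Phase-1 windows, score
  Phase-2 windows (balanced by default; a non-balanced mode reports
  PPV/NPV on the raw class ratio). Reports stratify accuracy by event
  kind (lapse vs craving), craving level, and hour of day.
* **LOPO**: for each participant with Phase-2 reports, train on the pooled
  balanced Phase-1 data of all others and score the held-out
  participant's (unbalanced) Phase-2 windows; per-participant ROC curves,
  their mean AUC, and lapse-only/craving-only AUC splits (participants
  lacking an event kind are excluded from that split). Train/test
  participant disjointness is asserted inside the fold loop.

Metrics: accuracy and confusion counts at threshold 0.5; PPV/NPV reported
as null (never 0) when undefined; ROC by full threshold sweep with
trapezoidal AUC, which equals the pairwise concordance probability (ties
half-weighted) — verified against a brute-force oracle. The Friedman test
ranks input types within each participant block (mean ranks on ties) and
uses Q = 12n/(k(k+1)) · Σ_j (R̄_j − (k+1)/2)², df = k − 1, with the
chi-square upper tail; on tie-free grids this matches
`scipy.stats.friedmanchisquare`. No tie-correction factor is applied,
matching the plain rank-sum form above. Grid experiments average cell
accuracies over participants (unweighted), since each cell is trained per
participant.

## Problem sizes in tests and the acceptance script

The generator's defaults are the full study design (17 participants,
14-day Phase 1, 90-day Phase 2). The test suite and
`scripts/acceptance.py` run scaled-down cohorts chosen as the package's
own verification conditions: single participants with 10 Phase-1 days at
12 smokes/day (~120 positive windows of 2,880), a 6-participant LOPO
cohort with 4 Phase-1 and 6 Phase-2 days, and compact models (16 filters,
hidden size 12, dense 24→12→1, ≤40 epochs). Signal-recovery checks use
motif amplitudes {0, 1, 3}: at 3 the within-window variance roughly
quadruples during the motif, a strong but not degenerate signature; at 0
the generator emits label structure with no signal, so every design must
fall to chance. Where single held-out test sets are small (~24 balanced
windows), checks average over three independently generated participants
to keep binomial noise below the asserted margins.

## Known limitations

* Synthetic units and spectra are arbitrary; no claim transfers to real
  phones without real data.
* The NumPy engine is single-threaded and sized for small experiments,
  not for the full 17 × 90-day cohort at 128 filters.
* Craving levels do not modulate motif strength, so level-stratified
  accuracy differences in synthetic runs reflect sampling noise only.
* The non-balanced (PPV/NPV) mode shares the balanced mode's trained
  model; it does not re-tune the decision threshold for prevalence.
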