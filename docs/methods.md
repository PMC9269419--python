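# Methods

This note records the modelling choices behind `synchar`, their defaults,
and what the bundled simulator does and does not establish about real
recordings.

## Event model and windowing

A log is an ordered sequence of timestamped sensor readings (integer
milliseconds since epoch, UTC; finer text precision truncated). Binary
sensors carry ON/OFF or OPEN/CLOSE tokens, numeric sensors a finite
decimal. Raw CASAS-style lines carry no room, but the encoder needs a
location channel per event, so a two-column sensor map supplies rooms;
unmapped sensors read "unknown". Unknown activity tokens are accepted and
appended to the vocabulary — coping with unannotated and novel activities
is the point of the method, so the reader must not reject them.

Windows are cut on a regular start grid. The admissible window length is
0.25–7 s (configuration error outside it) with a default of 2 s, and the
default hop is 200 ms. Length and hop are deliberately separate knobs:
overlap exists only when the hop is shorter than the length, so the fixed
200 ms figure is interpreted as the hop and the length stays configurable.
Windows are half-open [I, F); empty windows are dropped by default.

Window labels come from ground-truth segments by **majority time-overlap**
(ties to the earlier-starting segment; zero overlap ⇒ unlabeled), with a
strict-containment policy as an alternative. The label rule is an
implementation choice — annotation conventions say which events belong to
an activity, not which windows.

Each window becomes M parallel streams of T slots (default T = 128,
honoring the reference configuration's 128 input time steps; the scaled
experiments use T = 8). The default M = 3 keys the streams to the
sensor-id one-hot (S), the value scalar (V; binary → {1, 0}, numeric
min–max scaled to [0, 1] with bounds frozen on the training split to
avoid test leakage) and the location one-hot (P). Nothing in the
reference material fixes what the N parallel streams are, so a per-room
mode (one lane per room, [sensor one-hot, value] features) is offered as
an option. Events beyond T are truncated oldest-first, counted. All
streams share a feature width (the widest channel, zero-padded) so gate
weights can be shared across lanes.

## The synchronized peephole LSTM

All three gate peepholes — including the output gate's — read the
*previous* cell state c\_{t−1}. The common peephole variant feeds c\_t to
the output gate; the literal c\_{t−1} form is kept deliberately, and the
BPTT implementation differentiates exactly that form (the finite-
difference check would catch any mismatch). Gate and cell weights are
shared across lanes by default (per-lane weights are an option): the lane
superscripts in the model sit on states and outputs, not on weights.

The output head projects the concatenated final hidden states (width
M·h, default h = 128 giving 384; the 256-unit "output dimension" of the
reference configuration is interpreted as this projection width at its
M = 2 table setting — it cannot be a class count, which never exceeds 16).
A softmax completes the classifier; the reference text computes
cross-entropy but never names the output nonlinearity, and softmax is the
only standard choice. A printed form of the output equation reads the
lagged state h\_{t−1}; the default here projects h\_T — the state that has
seen the whole window is the only reading consistent with sequence
classification — and `literal_output_lag=True` restores the printed form.

Training: mean cross-entropy + Γ·Σ‖W‖² (biases and nothing else excluded
from the penalty; peephole vectors count as weights). Γ defaults to 1e−4
(no value is given anywhere; 1e−4 is the conventional small weight-decay
scale for networks of this size). Optimizer is Adam; the quoted
"momentum 0.5" maps onto Adam's first-moment decay β₁ = 0.5 since Adam
has no separate momentum knob (β₂ = 0.999, ε = 1e−8). The learning rate
warms up linearly from 0.001 to the per-dataset target (0.005/0.004/0.006)
over the first 10% of epochs and stays constant — the reference states
both a common starting rate and per-dataset rates but no schedule, and a
short warm-up is the simplest consistent reading. Dropout (rate 0.5,
inverted scaling) multiplies each lane's hidden output at every time
step, training mode only. Gradients are clipped by global L2 norm
(default threshold 5). Batch size defaults to 100.

## Adversarial regularization

The worst-case bounded input offset is the standard single-step
linearization r = ε·g/‖g‖₂ (or ε·sign(g) under the ∞-norm), where g is
the input gradient of the negative log-likelihood against a frozen
parameter copy — the printed argmin form denotes the log-likelihood
minimizer, i.e. the loss-maximizing direction. The training loss is
(1−λ)·L(x) + λ·L(x+r) with λ = 0.5 (no mixing weight is given; equal
weighting is the neutral default). ε defaults to 0.05 on the scale of the
[0, 1]-normalized channels (also not given). Perturbations act in the
encoded space with one-hot positions masked to zero by default: adding a
real offset to a token indicator has no physical reading; whether the
original method perturbed raw values or encoded inputs is unstated, and
the encoded-space choice is documented as ours. During training one
dropout mask per batch is shared between the clean and perturbed passes,
so the perturbation is computed against exactly the subnetwork being
trained. At ε = 0 the perturbation machinery is skipped entirely and the
trajectory is bitwise identical to plain supervised training.

No multi-step attacks and no virtual adversarial training on unlabeled
data: the training algorithm is single-step and label-conditioned.

## Self-training

After the initial adversarially regularized fit, pool windows whose top
class probability clears the threshold (default 0.95; thresholds are
named but never valued in the reference) receive their argmax class,
join the training set (unit sample weight by default — pseudo-labels are
treated as ordinary training data, with optional down-weighting), and
the model retrains. Default one round, configurable; a round accepting
nothing stops early. Ground-truth labels are never overwritten, the pool
only shrinks, and a tab-separated audit trail records every acceptance.
Unlabeled data is re-inferred each round rather than routed through any
recurrent feedback path — the literal reading of the stated loop.
Cold start (no labeled data) is unsupported.

## Evaluation

Confusion matrices store rows = actual, columns = predicted. The prose of
the source material says the opposite, but only the rows-actual
orientation reproduces its own printed per-class recall columns (e.g.
95/96.6 = 98.344 for the first Milan class); the tables win over the
prose and the package follows the tables. Per-class tp/fn/fp/tn tallies
give precision, recall, accuracy and F on the percent scale; division by
zero yields a flagged 0. Macro aggregates are unweighted class means;
micro accuracy is 100·trace/total. The three reference matrices ship
exactly as printed (fractional instance mass; one blank cell in the
House-C table read as 0) and `verify_fixture` recomputes all 84 printed
per-class values at half-away-from-zero 3-decimal rounding. Two
documented exceptions: the House-C matrix's micro accuracy computes to
98.104 while the accompanying prose prints 98.01 (reported, not forced);
and a quoted overall average of 98.154%/0.1571 has no derivable recipe
from printed values and is excluded from verification. Stratified K-fold
CV (default K = 10) falls back to unstratified folds with a warning when
a class has fewer than K members.

## The simulator

`synth_home` is a seeded semi-Markov generator: activities follow a
transition matrix with explicit log-normal dwell times (σ = 0.5 in log
space; medians from ~3 min for medication/toileting up to 2–2.5 h for
sleep) rather than per-event self-transitions, because real ADL segments
are minutes long and windows must mostly fall inside one segment. Active
sensors fire as Poisson streams (~30 events/min for engaged motion
sensors, 2/min during sleep, 6/min for doors); motion/door events come in
ON/OFF (OPEN/CLOSE) pairs; thermometers in the active rooms emit a
bounded random-walk temperature. Single resident throughout. Background
chatter (default 2% of events) from arbitrary sensors models noise
interference. Three presets match the shapes of well-known
single-resident recordings — 33/21/34 sensors and 15/16/11 activities
over 6/6/5 rooms. (One published outline lists 14 activity names for the
15-activity home; the 15-class vocabulary of its confusion matrix is
used.) Each activity emits from its own slice of its room's sensors, so
activities sharing a room share location but differ in sensor identity.
`hide_labels` keeps exactly ⌊fraction·N⌋ segments labeled, stratified by
class; `inject_novel_activity` adds an always-unannotated activity that
appears only after a cutover day.

**What the simulator does not emulate:** multi-resident interleaving,
sensor failures and drift, long-range daily structure (transitions are
uniform, not time-of-day dependent), and the heavy class imbalance and
annotation noise of real recordings. Passing the simulated experiments
therefore demonstrates the correctness and learning behavior of the
pipeline under its stated assumptions, not benchmark performance on the
real corpora — reproducing those published accuracies would need the
original recordings and roughly 12,000-epoch training runs, which is out
of scope here.

## Scaled experiment sizes

The standard desk-scale study (`synchar.experiments`) uses two simulated
days of the milan-like home, 2 s windows on a 60 s hop, T = 8 slots,
h = 16, batch 100, 120 epochs supervised / 60 epochs per self-training
phase, seeds 1–3. Under these conditions supervised training reaches
96–97.5% test accuracy; self-training with 10% labels is compared against
a supervised-only baseline on the same splits. At this scale the paired
self-training comparison carries a few points of seed-to-seed noise —
with ~90 labeled windows the retrain's optimization variance is of the
same order as the pseudo-labeling effect — so the non-inferiority check
averages over the three seeds.

## Numerical notes

- All array math is float64; gate activations are computed with a
  numerically stable split sigmoid.
- Probabilities are clipped at 1e−300 before the log in the loss.
- The forget-gate bias initializes at +1 (standard practice so early
  training does not wash out the cell state); other weights are uniform
  in ±0.1.
- Gradient checks compare against central differences at step 1e−6 with
  a 1e−9 absolute floor absorbing the oracle's own roundoff.
- Training aborts with a diagnostic naming the epoch if the loss turns
  non-finite.
- Determinism: one root seed is split (via seed sequences) into recorded
  per-stage seeds; identical config + seed gives bitwise-identical runs.

## Known limitations

- The literal c\_{t−1} output-gate peephole and the lagged-output option
  exist for fidelity, not because they help accuracy.
- No bidirectional variant (a table annotation mentions "Bi-LSTM" but
  nothing else describes bidirectionality; not implemented).
- One-hot sensor encodings only; no learned embeddings.
- The CLI's `evaluate` works from confusion CSVs; scoring arbitrary
  prediction files is not implemented.
- K-fold CV is provided as a utility and used in tests; the experiment
  pipeline reports single-split metrics.
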