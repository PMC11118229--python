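# Methods

## The recognition problem

A wearer of a lower-limb assistive device walks on level ground, alternating
between three steady walking activities — linear walking (LW), clockwise
circular walking (CW) and counterclockwise circular walking (CCW) — via four
single-cycle transition activities: LC (LW→CW), LCC (LW→CCW), CL (CW→LW) and
CCL (CCW→LW).  Each limb's gait cycle passes through eight events in fixed
cyclic order: initial contact (IC), loading response (LR), mid-stance (MSt),
terminal stance (TSt), pre-swing (PS), initial swing (IS), mid-swing (MSw)
and terminal swing (TSw).  The recognizer consumes twelve segment
angular-velocity channels (pelvis, chest, thighs, shanks; yaw/pitch/roll
rates) sampled at 100 Hz, and must report, online and per limb, the current
(activity, event) class out of 7 × 8 = 56 candidates — then, once a
transition activity is recognized, predict *when* the upcoming steady
activity's first heel contact (HC) will occur.

## Model

**Preprocessing.**  Every channel is filtered with a causal second-order
Butterworth low-pass at 6 Hz (walking content lies below 6 Hz); the filter
state is initialized to the first sample so constants pass unchanged.  Each
limb's recognizer is unilateral: it sees the four trunk channels plus its
own thigh/shank channels (eight features).

**Likelihood.**  For class m and feature f the class-conditional density is
an equal-width histogram over the training range,
P_f(l_f | g_m) = (h_{f,m}(b) + α) / (Σ_b h_{f,m}(b) + αB), with B = 20 bins
and add-α smoothing, α = 1.  Per-feature likelihoods combine as their
geometric mean P(s_t | g_m) = (∏_f P_f)^{1/F}, computed in log space.  The
geometric mean is a strictly monotone transform of the naive-Bayes log-sum
(rank-identical for any fixed observation) that stays in (0, 1] and hence
composes with the Bayesian update as a likelihood.  Out-of-range values
clamp to the end bins; with α = 0 zero bins floor at 1e-9.

**Recursion.**  The posterior over the surviving class set V_t follows
P(g_m | s_t) ∝ P(s_t | g_m) P(g_m | s_{t-1}), normalized by
P(s_t | s_{t-1}) = Σ_m P(s_t | g_m) P(g_m | s_{t-1}).  Activity and event
recognitions are the argmax of the corresponding marginal, declared when its
mass reaches θ = 0.9 (ties break to the lowest code).

**Elimination rule 1 (within limb).**  V_t is pruned to classes whose
likelihood is at least τ₁ = 0.01 of the sample's maximum, and — once an
event estimate exists — to classes whose event is the current estimate or
its cyclic successor.  If both constraints would empty V_t the event part is
dropped for that sample (the ratio part cannot empty the set).

**Elimination rules 2–3 (bilateral).**  The limbs exchange their potential
sets every sample.  A class survives rule 2 iff *some* activity on the other
side licenses its activity under the bilateral activity-pair table (23
allowed (right, left) pairs), and rule 3 — applied after rule 2 — iff some
event on the other side licenses its event under the bilateral event-pair
table (16 pairs, a symmetric relation arising from the half-cycle offset
between the limbs).  The left side queries the transposed tables.  The
existential quantifier is the only reading that never deletes jointly
consistent truths; within a rule both sides are updated simultaneously
against the other side's pre-rule set, and a rule that would empty a side is
skipped for that sample.  On the product-shaped sets rule 1 produces
(potential activities × admissible events) one pass of rules 2+3 is a fixed
point; on arbitrary class sets a second pass can prune further, which the
pipeline never encounters.

**Transition timing.**  Per limb, a gait-cycle clock records IC onsets; MGCT
is the mean of the last three completed cycle durations.  When a transition
activity is recognized with gait event e, the first HC of the upcoming
steady activity (LC→CW, LCC→CCW, CL→LW, CCL→LW) is predicted at
now + c(e)·MGCT with c = 0.9 (IC or LR), 0.7 (MSt), 0.5 (TSt), 0.4 (PS),
0.27 (IS), 0.13 (MSw); for TSw the HC is bounded *within* 0.13·MGCT and the
prediction carries an upper-bound flag.  These factors are the complements
of each event's end fraction in the standard gait-phase layout, which is how
the package derives its event phase bounds: IC [0, 0.02), LR [0.02, 0.10),
MSt [0.10, 0.30), TSt [0.30, 0.50), PS [0.50, 0.60), IS [0.60, 0.73),
MSw [0.73, 0.87), TSw [0.87, 1.0).  One prediction is issued per recognized
transition (re-issue on event change is available behind a flag).  Because
the factor assumes recognition at the event's *end*, a prediction issued at
phase φ inside event e is early by (end(e) − φ)·T — at most one event
duration, the method's intrinsic error budget.

## Numerical choices for online stability

Two choices depart from the plain recursion; both address the same budget
problem.  The geometric mean divides log-evidence by F = 8, so per-sample
evidence is small, while a 20 ms event such as IC spans two samples at
100 Hz and is further smeared by the causal filter's ~50 ms settling.

* **Event-progression hazard.**  The replay engine's prior includes a
  prediction step: fraction h = 0.15 of each class's mass flows to the class
  with the same activity and the successor event (expected dwell 1/h ≈ 7
  samples, the order of real event durations).  Without a dynamics term the
  posterior can only revise an entrenched event hypothesis by climbing out
  of the mass floor — a ~7–14 nat barrier that a short event cannot supply.
* **Mass floor.**  Surviving classes receive a prior floor of 1e-3, which
  bounds the evidence needed to revive a pruned activity hypothesis
  (≈ log(θ/floor) ≈ 6.8 nats) while keeping confident posteriors sharp.
* **Admissibility reference.**  The event used by rule 1's temporal
  admissibility is the MAP event estimate of the restricted posterior — a
  two-hypothesis sequential test that flips at posterior 0.5.  Reported
  recognitions remain θ-gated at 0.9.  Gating the chain itself at 0.9 would
  deadlock at IC for the evidence-budget reason above.

Remaining defaults: normalizer-zero samples reset the posterior to uniform
over V_t; degenerate (constant) training features widen their bin range by
one unit; decision latency is measured from the labeled segment onset.

## The synthetic generator

The original subject recordings are unavailable, so a seeded generator
stands in.  It emulates, by construction:

* the two ambulation protocols (direction 1: LW→LC→CW→CL→LW→LC→CW→CL→LW;
  direction 2 with LCC/CCW/CCL), steady segments of a configurable number of
  cycles (default 3) and single-cycle transitions;
* per-cycle durations of mean 1.1 s with 5 % CV (clipped to ±50 %);
* the eight-event phase structure above, and an exact half-cycle bilateral
  offset: the left limb's phase is the right limb's + 0.5 (mod 1), and the
  left limb's activity switches mid-(right-)cycle.  Under this construction
  every emitted bilateral (activity, event) label pair lies inside the two
  pair tables — the soundness property the elimination rules rely on;
* Gaussian class-conditional emissions.  Activity sets yaw-rate means with
  physical sign conventions (CW negative trunk yaw rate, CCW positive, LW
  near zero; transitions intermediate, loading trunk vs. thigh/shank
  differently so all seven activities have distinct signatures).  Thigh and
  shank pitch-rate means follow a sinusoid over the cycle phase — so the
  causally filtered signal stays close to the class statistics the
  recognizer learns — plus a heel-strike transient centered at cycle
  fraction 0.985 whose filter-delayed peak falls inside IC.  The
  ``separation`` scale (default 60 deg/s) multiplies all means; i.i.d.
  noise of SD 12 deg/s (~8 % of the ~150 deg/s signal amplitude, the order
  of stride-to-stride variability) is added to every channel.

All randomness flows from one seeded generator.  The simulator makes no
claim of biomechanical realism: there is no kinematic chain, no sensor bias
or drift, no double-support force coupling, and its emission distributions
are unimodal per (class, phase).  Passing tests on it demonstrate that the
inference machinery is correct under the model's own assumptions — not that
the pipeline reaches any particular accuracy on real IMU data.

## Evaluation conventions

Accuracy is reported at segment level (one majority verdict per labeled
activity segment, from confident per-sample decisions; undecided segments
count as wrong) and at sample level.  Surviving-class counts |V_t| are
recorded after all eliminations, before decision.  Timing per prediction:
MPT = real HC − issue time, MTD = real HC − predicted HC (positive =
prediction early); upper-bound (TSw) predictions are excluded from point
aggregates.  For the Bayes-limit checks the metric is segment-level
macro-averaged (balanced) recall with forced MAP verdicts: the protocol's
class frequencies are heavily imbalanced (LW alone is ~47 % of cycles), so
the raw accuracy of a label-independent predictor is not chance; balanced
recall of any truth-independent predictor is exactly 1/7 and approaches 1 in
the separable limit.

Standard problem sizes used in the test suite: one trial per direction for
training (~4 200 samples, all 56 classes present), five held-out trials
(three direction-1, two direction-2; 20 transitions, ~10 500 samples) for
the system comparison, and ~115 000 label samples for the exhaustive
table-consistency scan.

## Known limitations

* The unilateral system genuinely confuses transitions with their
  neighboring steady activities mid-cycle (the trunk-yaw level of LC's first
  half coincides with CL's); this is inherent to the emission design at any
  separation scale and is the motivation for the bilateral rules.
* IC occupies two samples and is smeared by the causal filter; per-sample
  event decisions around the cycle wrap lag by a few samples, so IC's row in
  an event confusion matrix is structurally weak even when the chain tracks
  correctly.
* The event-pair table admits boundary-adjacent pairs (e.g. right PS with
  left TSw) that the idealized half-cycle generator never emits; they exist
  to tolerate the timing jitter of real gait.
* Elimination rule 1's internals follow a reconstruction (likelihood-ratio
  pruning plus temporal admissibility); the original formulation is in a
  source that specifies it only by reference.
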