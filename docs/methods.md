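# Methods

## Problem and signal model

`seatsense` recognises what a seated person is doing — and how intense the
activity is — from a sensor cushion that reports six seat-pressure channels
(force-sensing resistors, FSRs) and two angular-velocity channels (a
gyroscope under the seat centre), all sampled at 10 Hz.  Five activities are
distinguished: reading, desk working, conversation, left-right / front-back
swinging, and exercise (e.g. lifting a weight).  They group into three
intensity levels anchored to MET ranges: light (1–3 METs: the three
sedentary tasks), moderate (3–6: swinging, the pressure-relief movement
recommended to wheelchair users) and vigorous (6–9: exercise).

The six FSR positions are expressed as relative grid distances on a 5×5
seat grid with the origin at the centre: Fsr1 (−1, 2), Fsr2 (1, 2),
Fsr3 (−2, 0), Fsr4 (2, 0), Fsr5 (−1, −2), Fsr6 (1, −2) — a layout symmetric
left/right and front/back, so its centroid is the origin.

## Centre of Pressure

The Centre of Pressure (CoP) is the force-weighted mean sensor position,

    CoP_x = Σ f_i x_i / Σ f_i,    CoP_y = Σ f_i y_i / Σ f_i.

Because the forces enter homogeneously, the CoP is invariant to rescaling
all forces by a positive constant; raw FSR readings in arbitrary units are
therefore sufficient and no force calibration is implemented.  A sample with
(near-)zero total force — threshold 1e-9 force units — has no defined CoP
and is flagged invalid; any analysis window containing such a sample is
dropped.  Valid CoP values are convex combinations of sensor coordinates and
lie inside the sensor hull ([−2, 2]² bounding box for the default layout).

No pre-filter is applied to the raw channels by default: the acquisition
smoothing used by cushion firmware is device-specific and unspecified, so
the package does not invent one.  An optional centred moving-average
smoother (`apply_moving_average`, width in samples) is available and off by
default.

## Features

The 4-channel signal (CoP_x, CoP_y, Gyro_x, Gyro_y) is segmented into
sliding windows of `tw` seconds (default 30) with 50% overlap; at 10 Hz the
default window holds N = 300 samples with a stride of 150.  A trailing
partial window is discarded.  Per window and channel, two features:

* **Std** — sample standard deviation (ddof = 1), the sway/swing amplitude.
* **ApEn** — approximate entropy, the Pincus regularity statistic:
  embedding vectors x(i) = (u(i), …, u(i+m−1)); C_i^m(r) = fraction of j
  with Chebyshev distance d[x(i), x(j)] ≤ r, self-match included;
  Φ^m = mean of ln C_i^m; ApEn = Φ^m − Φ^{m+1}.  Defaults m = 2 and
  r = 0.2 × (sample sd of the window).

Numerical conventions, chosen where the literature leaves room:

* Chebyshev (max-abs) distance — the standard choice for ApEn.
* Self-matches are counted (original convention; also keeps every C_i > 0
  so the logarithms are finite).
* A constant window has r = 0; ApEn is defined as 0 there (a perfectly
  regular series).  Constant windows are detected exactly
  (max = min), not via a floating-point sd threshold.
* Sample (n−1) standard deviation is used both as the Std feature and in
  the ApEn tolerance; at N = 300 the population/sample difference in r is
  < 0.2% and immaterial.
* ApEn's ≤-vs-< match comparison uses ≤.

The vectorised implementation builds the pairwise Chebyshev distance matrix
per window (O(N²·m) memory-bounded at N = 300) and is verified in the test
suite against an independent naive triple-loop implementation to 1e-10.
ApEn is invariant to affine transforms a·x + b (a ≠ 0) since r scales with
the sd; that invariance is property-tested.

Window labelling: the majority per-sample label, with windows whose majority
fraction is below 0.9 dropped (these straddle activity transitions).
Windows containing invalid-CoP samples are dropped too; drops are logged.

## Classifier

A C4.5-style decision tree specialised to numeric features: binary splits
`feature ≤ t` with t a midpoint between consecutive distinct observed
values.  At each node the split maximising the **gain ratio** (information
gain / split information, both in bits) among candidates with positive gain
and at least `min_leaf` instances per side is chosen.  Growth stops at pure
nodes, nodes under 2·min_leaf instances, or when no candidate has positive
gain.  Defaults: pruning confidence C = 0.25, min_leaf M = 2.

Pruning is pessimistic error-based with confidence C: each leaf's error
count is inflated by the upper confidence bound of the binomial error rate
(exact for zero errors, normal approximation with continuity correction
otherwise), and a subtree is replaced by a leaf when the leaf's pessimistic
error is no worse than the subtree's (plus the conventional 0.1 slack).
Only subtree replacement is implemented — no subtree raising — which keeps
the parameter semantics while simplifying the machinery; exact
node-for-node equivalence with WEKA's J48 is not a goal (J48 adds MDL
threshold corrections and raising heuristics that do not change the
accuracy-level behaviour on numeric features).

Determinism: ties in gain ratio break by feature name then lower threshold;
leaf-prediction ties break by lexicographic class order.  Training the same
rows twice yields byte-identical serialised models.  The evaluation harness
accepts any classifier satisfying the train/predict contract, so a library
tree can be swapped in as a cross-check (the test suite does this).

## Evaluation

* **Stratified 10-fold CV** on pooled windows (seeded shuffle).  Pooling
  windows across subjects is optimistic for subject generalisation because
  consecutive windows from one person are highly autocorrelated;
  stratification is a variance-reduction choice and is recorded in the
  report metadata, degrading to plain shuffled folds when a class has fewer
  than k instances.
* **Leave-one-subject-out (LOSO) CV**: one fold per subject, the honest
  protocol for a device meant to work on unseen sitters.  The pooled
  confusion matrix is the sum of per-subject matrices.
* Metrics all derive from the aggregate confusion matrix: per-class
  precision/recall/F (F = 2pr/(p+r), 0 when p + r = 0), overall accuracy
  (trace/total), and macro-F (unweighted mean of the five per-class F
  values).
* **Window sweep**: the full pipeline (CoP → features → 10-fold CV) per
  window length in [5, 60] s (step 5) and feature set, to expose the
  accuracy-vs-latency trade-off.  Short windows hurt ApEn most: its bias
  and variance grow as N shrinks.

## Synthetic cohort

No recording of the device is publicly available, so the generator emulates
the experiment the method targets: 8 subjects, all five activities,
50 minutes of data per activity, BMI spread (2, 4, 2) over
< 18.5 / [18.5, 25) / ≥ 25 with total seated load monotone in BMI.

Per activity block the latent CoP trajectory is

* **light** (reading / desk work / conversation): a stationary
  Ornstein-Uhlenbeck (OU) sway around the subject's resting point
  (relaxation 1 s) plus Poisson posture micro-shifts (2–3/min, ~0.1–0.15
  grid units).  The OU choice, rather than white noise, gives idle sitting
  its short-range autocorrelation — the minimal structure that makes ApEn
  informative.  The three light activities share dynamics and differ only
  in magnitude (jitter sd 0.010 / 0.020 / 0.035; gyro noise 0.5 / 1.0 /
  1.5 deg/s), deliberately making them confusable.
* **swing**: a sinusoid (amplitude 0.8 grid units, 0.4 Hz) on the chosen
  axis with a 0.2 cross-axis coupling, plus a small OU jitter.  The axis
  (left-right vs front-back) is drawn per subject.
* **exercise**: a fast large OU component (sd 0.65, relaxation 0.4 s) plus
  Poisson displacement bursts (12/min, amplitude ~1.5, 1–3 s, rough
  envelopes) and strong gyro shake (15 deg/s) — high-amplitude and
  irregular on both axes.

All amplitude values are free choices: the reference experiment reports no
quantitative signal amplitudes, so defaults are set once to realise the
qualitative structure the method assumes — windowed Std medians ordered
light < moderate < vigorous on every channel, swinging periodic, exercise
irregular — and the suite tests those orderings, not agreement with any
particular hardware.

Forces are realised from the latent CoP by projecting the subject's resting
weight distribution onto the constraint set {weights ≥ 0, Σw = 1,
CoP(w) = target} via alternating projections; the latent trajectory is
first clipped to the sensor hull shrunk by 10% so a strictly feasible
solution exists.  The realised CoP matches the latent one to ~1e-7 RMS
(tested), and per-sample total force is the subject's load modulated by a
3% breathing sinusoid plus a bounded slow drift (within ±20% by
construction).  Gyro channels are 30 deg/s per grid-unit/s times the
smoothed latent CoP velocity (gyro_x from the anterior-posterior axis,
gyro_y from the medial-lateral axis) plus the activity's Gaussian noise.

What the simulator does **not** capture: real pressure-map shapes and
sensor nonlinearity, contact-area changes, clothing/cushion mechanics,
heterogeneous personal movement styles beyond a scalar sway scale, or
drift/artefacts of real FSRs.  Accuracies measured on this cohort therefore
validate the pipeline's machinery and relative orderings (Std vs ApEn
features, k-fold vs LOSO, level vs activity), not field performance of any
physical cushion.

## Assessment summary

The per-session assessment routes each window through a trained tree,
maps activities to levels, and reports the fraction of windows per level
plus the longest uninterrupted run of light-level windows (the "sedentary
bout", in windows and in seconds: (run−1)·stride + tw).  This is the
minimal defensible reading of a per-period activity-assessment summary; no
further index is computed because none is formally defined for this
setting.

## Problem sizes

Default experiment sizes used by the reproduction script and the end-to-end
tests: 8 subjects × 5 activities × 50 min at 10 Hz (1.5 M samples,
~8 000 windows at tw = 30 s) for the main results, and the same cohort at
tw = 10 s (~24 000 windows) for the window-length comparison.  The
cross-validation protocols and the ApEn implementation run this scale on a
single CPU core in a few minutes.
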