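# Methods

## Synthetic cohort model

The generator emulates a chest-worn module recording triaxial
acceleration (100 Hz, units of g) and two bipolar ECG leads (1000 Hz)
during six activities of daily living.  It is built around the two
facts the pipeline is meant to detect: cardiac morphology is a property
of the *person* and is stable across activities, while posture and
movement are properties of the *activity*.

**ACC.**  Each axis is a gravity component plus oscillation plus white
noise.  The chest frame fixes y as longitudinal (gravity −1 g when
upright), x mediolateral, z anteroposterior; lying rotates gravity into
z, and stair tasks tilt the torso slightly forward (upstairs) or
backward (downstairs).  Dynamic activities add a fundamental sinusoid
at the subject's cadence (population baseline 1.9 steps/s) with a 30%
second harmonic; the fundamental amplitude is calibrated so the
oscillation's sample standard deviation equals the per-axis target
`osc_amp_g` (stairs 0.2 g on y, walking 0.12 g on y, floor cleaning
0.12 g concentrated on x/z).  Static activities (lying, resting) carry
no oscillation at all, so their only variability is the additive noise
(default 0.02 g).  A per-subject sensor-tilt jitter (rotation, so the
gravity magnitude is conserved exactly) models strap placement.

**ECG.**  Each lead is a beat train at `hr_rest × hr_multiplier` with
Gaussian RR jitter of 3% of the mean RR.  Every beat is the subject's
fixed template: five Gaussian bumps (P, Q, R, S, T) with per-subject
amplitudes, widths and wave centers (the R peak anchors the beat
clock).  Activity enters the ECG only through the heart-rate
multiplier (lying 0.95 … stairs 1.5), never through morphology.

**Separability knobs.**  `separability.subject` and
`separability.activity` in [0, 1] scale every inter-subject
(respectively inter-activity) spread linearly; at 0 all subjects
(activities) are statistically identical, at 1 the full documented
spread applies.  Activity parameters are blended toward the
across-activity mean (gravity renormalized to unit magnitude after
blending).

**Calibration of the subject spreads.**  The downstream observables
constrain what "fully separable subjects" can mean: per-lead min–max
normalization erases absolute scale and between-lead amplitude ratios;
the 5–15 Hz band-pass removes most P- and T-wave energy; and DTW
absorbs pure time rescaling, so wave widths and centers contribute
little.  Identity must therefore live in within-lead amplitude ratios
and in heart rate.  At full separability the generator draws resting
heart rate uniformly over 70 ± 20 bpm (a flat spread over the adult
range, chosen over a Gaussian to avoid clumping a small cohort into a
narrow band) and per-wave amplitude factors 1 + c·z with c = (0.6,
0.8, 0.25, 0.8, 0.6) for (P, Q, R, S, T) — large Q/S/T variation
(including occasional polarity flips, which occur clinically) and
moderate relative R variation.  Width CV 0.2, wave-center CV 0.15,
cadence spread 0.35 Hz, ACC gain log-sd 0.15, tilt sd 4°.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no motion artifacts in the ECG, no
electrode drift beyond what the band-pass would remove anyway, no
within-subject day-to-day morphology change, no heteroscedastic sensor
noise, no gyroscope/magnetometer, and beat morphology that is exactly
periodic up to RR jitter.  Real recordings are harder on the subject
task than this model at full separability.

## Preprocessing

Defaults: ACC low-pass Butterworth order 4 at 6 Hz; ECG band-pass
order 4 at 5–15 Hz, decimation 1000 → 500 Hz, min–max to [0, 1] per
channel per trial; 7 s segment starting at a 1 s offset.  Choices made
where the procedure is under-specified:

* All filters run zero-phase (forward–backward); applying this to the
  ACC as well keeps the two modalities temporally comparable (a causal
  mode exists via `acc_zero_phase=False`).
* The decimation anti-alias filter is a zero-phase 8th-order
  Butterworth at 0.8 × the new Nyquist (conventional guard band).
* Segments are cut at a fixed offset (1 s, past the filter transient)
  rather than by visual inspection — determinism over curation.
* Min–max precedes segment extraction (the order the conditioning
  steps are listed in); normalization is per channel per trial since
  the amplitude variability it addresses is per-recording.
* A constant channel normalizes to all zeros with a warning instead of
  raising, so degenerate inputs cannot abort a batch run.

## Dissimilarity

* **Lag search** is bounded at ±25% of the segment length; an
  unbounded search could align on near-zero overlaps.  Correlation is
  computed on the mean-removed overlap, scaled by the overlap norms
  (true normalized cross-correlation); exact ties resolve to the
  smallest |lag|, negative before positive.  Positive lag means the
  second sequence is advanced (x[t] pairs with y[t+τ]).
* **Trimming** removes up to floor(0.05 × overlap) samples, one at a
  time, always from the end whose boundary pointwise difference is
  currently larger (left end wins ties), stopping early when both
  boundary differences are zero.  End-only removal is the reading
  consistent with truncation "at the limits"; the 5% budget is shared
  by the pair.
* **DTW** is the classic full dynamic program (|x−y| local cost,
  symmetric match/insert/delete steps, no window), un-normalized by
  path length: segments have fixed duration, and the global per-channel
  min–max normalization absorbs scale anyway.  The DP inner loop is
  numba-compiled (~3 ns/cell).
* An optional `stride` subsamples both sequences immediately before
  the DP.  It defaults to 1 (off).  The recovery experiments in the
  test suite and acceptance script run ECG channels at stride 2
  (effective 250 Hz input; the preprocessed band is 5–15 Hz, so no
  band-limited information is lost) — this is the problem size at
  which a 1770-pair ECG matrix is computed in ~35 s.
* Raw per-channel distances are cached in the matrix object.  Because
  alignment, trimming and DTW are pairwise-local, a sub-cohort's
  "re-computed" dissimilarities differ from the full cohort's only in
  the per-channel min–max constants, so each clustering stage
  re-normalizes the cached raw tensor over the active subset's pairs.

## Embedding

The pair forces f_r = −C·K²/r·e^{α|D|} (repulsive) and
f_a = r²/K·e^{γ|D|} (attractive) are the negative radial gradient of
the pair potential

    U(r) = −C·K²·e^{α|D|}·ln r + r³·e^{γ|D|}/(3K),

so moving every node along its net force is exact gradient descent on
the total potential E = Σ_{i<j} U(r_ij).  The iteration uses a global
adaptive step (initial 0.05 K, grown 1.1× on acceptance, halved with
the move rejected when E would increase) with per-node displacements
capped at 0.1 K; E is therefore non-increasing over accepted steps and
is what `energy_trace` records.  Stopping: mean accepted displacement
below 1e−4 K, step underflow, or 500 iterations.  Initialization is
uniform in the unit cube (seeded); coincident nodes receive a seeded
1e−6 K jitter; final coordinates are centered at the origin.

Parameter defaults K = 1, C = 0.2, α = +1.5, γ = −1.5 give the
equilibrium distance r*(D) = K·C^{1/3}·e^{(α−γ)D/3}, strictly
increasing in D with r*(1)/r*(0) = e ≈ 2.7.  The sign convention
(attraction decaying, repulsion growing with dissimilarity) is what
makes similar trials cluster; with both exponents equal the layout
would ignore D entirely.  Rank fidelity is checked on dissimilarity
matrices derived from random 3D configurations with 20% multiplicative
noise — matrices a 3D layout can actually represent (an arbitrary
non-metric random matrix has no 3D realization and caps near Spearman
0.6 for any parameter choice; realizable ones embed at ≈ 0.95).

## Staged clustering

Per stage: re-normalize the active subset (see above), embed with a
stage-incremented seed, split in two by HAC on the 3D coordinates
(Ward linkage by default — compact, even splits suit 2-way peeling;
average/complete are available), and compute the silhouette of that
2-split *on the embedded coordinates*, which is the space the
clustering operates in.  If SC > 0.5 the smaller cluster is peeled (a
size tie peels the cluster whose smallest trial index is larger); when
only one cluster remains to assign after a peel, the remainder is that
cluster.  Otherwise the stage partitions the remainder directly into
the clusters still needed.  A peel that would leave fewer trials than
remaining clusters, or a stage smaller than `min_stage_size` (4),
forces the direct partition, so exactly `target_k` clusters always
result.  A 2-trial stage split into two singletons has SC 0 by the
singleton-contributes-0 convention (each singleton's silhouette term
is 0), forcing the direct partition.

## Metrics

NMI uses arithmetic-mean normalization of the two entropies (geometric
available by flag).  Classification metrics are computed after
Hungarian alignment of cluster ids to classes (maximum total overlap on
the contingency table; rectangular tables leave surplus clusters
unmapped, which counts against every class).  Precision/recall/F1 are
macro-averaged: the design is balanced (one trial per subject ×
activity), under which macro recall equals accuracy.  Dominant
frequency is the periodogram argmax with the DC bin excluded, no
smoothing; a constant channel reports 0.

## Problem sizes

Unit tests run on 3-subject cohorts (18 trials).  The recovery
experiments use the full 10-subject × 6-activity design (60 trials,
1770 pairs) over seeds 1–5: activity cohorts at separability
(activity 1.0, subject 0.3), subject cohorts at (0.3, 1.0), both
modalities clustered on each cohort for the cross-modality ordering.
The staged-clustering guarantee is exercised on 50 random small
cohorts (2–4 subjects × 2–4 activities, ACC at stride 4).  DTW oracle
checks enumerate all warping paths for 200 random pairs of length ≤ 8;
Hungarian checks enumerate all permutations for 100 random contingency
tables up to 6 × 6.

## Known limitations

* The subject task's difficulty is governed by the generator's
  morphology spreads; the defaults describe a *fully separable*
  cohort, not the harder real-world case (the pipeline's ceiling on
  real recordings is expected to be much lower).
* The force-directed layout is a local optimizer; different seeds give
  different (reflected/rotated) configurations, and only distance
  structure — not coordinates — is meaningful.
* HAC tie-breaking follows scipy's deterministic merge order; exotic
  exactly-tied configurations may merge differently than a textbook
  smallest-index rule.
* The ECG stride-2 recovery setting is a compute/fidelity trade; at
  stride 1 results are statistically indistinguishable on spot checks
  but ~4× slower.
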