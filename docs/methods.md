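# Methods

This note records the models behind each analysis stage, the choices made
where the field's conventions leave room, and what the synthetic
generators do and do not emulate.

## Signal model and beat handling

All channels are uniformly sampled series; ingest rejects gaps (a time
column deviating from the declared rate by more than 1 ppm is an error,
not something to interpolate over). Beats are anchored either on ECG R
waves (local maxima of the 5–25 Hz band-passed trace, the QRS energy
band) or on pressure feet. Beat intervals are half-open
`[onset_i, onset_{i+1})` so no sample is counted twice; implied periods
outside 0.33–2.0 s (30–180 beats/min) are treated as non-physiologic and
the offending beat is excluded.

Ensemble averaging linearly time-normalises each beat to the median beat
length before pointwise averaging — unequal beat lengths must be
reconciled somehow, and resampling to the median length distorts the
typical beat least. One artifact pass drops beats whose peak-to-trough
amplitude deviates more than 3 SD from the epoch median; this threshold
is a package choice (config key `artifact_sd`) since acquisition-side
screening rules are rarely published. Protocols that call for a minimum
number of distension waveforms per set are honoured as a warning
(`min_beats_warn`), never a hard failure.

## Pressure calibration

Brachial: affine map sending the waveform minimum/maximum to cuff
diastolic/systolic pressure. Cuff ingest mirrors the usual screening
procedure: readings are repeated until two consecutive ones agree within
5 mmHg, which are then averaged. MAP is the time integral of the
calibrated waveform over the cycle (`map_method: integral`); the
diastolic + PP/3 form factor is available as a config alternative but is
an approximation to the integral, not the default. Carotid: affine map
anchored on brachial diastolic and mean pressure, the standard
tonometric transfer — diastolic and mean pressures are nearly invariant
along the arterial tree whereas systolic pressure amplifies
peripherally, so carotid systolic pressure is an output. Both maps are
exactly affine, hence shape- (correlation-) preserving, and the carotid
beat's time-average equals brachial MAP to numerical precision.

## Stiffness and wave mechanics

**Foot detection** uses intersecting tangents: the crossing of the
horizontal line through the pre-upstroke minimum with the tangent at the
point of maximum upstroke slope. The derivative is smoothed with a 10 ms
moving average before the maximum-slope point is located; this does not
displace the foot on physiologic upstrokes (it is exact on
piecewise-linear ones) but keeps the localisation off noise spikes.
cfPWV aggregates per-beat Δt by the median, which is robust to isolated
mis-detections; the aggregation rule is a package choice.

**Characteristic impedance** is the time-domain ratio
max(dP/dt)/max(dQ/dt). This estimator assumes the early-systolic flow
acceleration is brief, so that at the moment of peak dQ/dt the windkessel
charging term (Q/C) contributes negligibly to dP/dt and the pressure
upstroke is forward-wave dominated. Its bias grows roughly as
1/(Zc·C·ω) with ω the upstroke angular rate — at low impedance with a
slow upstroke the estimate can be tens of percent high, which is a
property of the estimator, not an implementation artifact.

**Wave separation** is the linear time-domain split on pulsatile
components: ΔP = P − min(P), ΔQ = Q − Q(foot). Referencing flow at the
pressure foot rather than the cycle minimum keeps late-diastolic
negative flow dips from biasing ΔQ. Amplitudes of Pf and Pb are peak
minus foot value of each separated wave (peak-to-peak is a plausible
alternative the literature does not settle; the foot-referenced form is
used throughout and stated here so results are comparable). Pf + Pb
reconstructs ΔP identically for any input — this is asserted, not
hoped. When pressure and flow beats come from sweeps gated on different
anchors, `align_flow_to_pressure` rotates the flow beat so the two feet
coincide before Zc estimation and separation; without this the relative
rotation of the two waveforms makes the split meaningless.

Units are fixed: mmHg, mL/s, cm, s; Zc in mmHg·s/mL; β dimensionless.

## Doppler metrics

Per epoch, systolic/diastolic velocity are means of per-beat
maxima/minima (robust to single-beat spikes; a global max/min would not
be), and mean velocity is the epoch time-average. The resistive index is
the Pourcelot form (vs − vd)/vs. RI definitions are frequently left
implicit in clinical reports; the Pourcelot form is the one that
reproduces typical printed RI values from the corresponding printed
velocities, which is the validating evidence for adopting it. Per-subject
indices are computed from that subject's velocities and then averaged
across subjects — a mean of ratios. The ratio of group-mean velocities
is a different quantity and report tables must not mix the two.

## Breath-hold reactivity

The protocol schedule (paced breaths → hold → recovery, repeated) is an
explicit object; all windows derive from it. ΔETCO₂ follows the stated
rule exactly (post-hold peak minus mean of the last two paced
end-tidals). ΔMCAv has no equally standard definition, so it mirrors the
ΔETCO₂ construction: baseline over the last two paced-breath windows,
response as the post-hold peak of a 3 s moving average — symmetry with
the stated rule is the rationale. Repeats with ΔETCO₂ ≤ 0 (failed holds)
are excluded and logged, never silently dropped. Averaging across
repeats is the mean of per-repeat ratios. The identity
cvr_rel · baseline/100 = cvr_abs holds per repeat by construction and is
exercised in tests.

## Statistics

The 2×3 design is partitioned the classical mixed-model way: the group
effect is tested against subject-within-group variation; time and
group×time against the subject×time residual. With complete cases the
within factor is balanced across subjects, so the weighted-means
partition is exact (the five SS components sum to SS_total to 1e-8
relative, a tested invariant) even with unequal group sizes, and it
agrees with pingouin's mixed ANOVA to machine precision on both balanced
and unbalanced data. Partial η² = SS_effect/(SS_effect + SS_error-term).

Sphericity: uncorrected degrees of freedom are the primary report;
the Greenhouse–Geisser-corrected p (ε from the pooled within-group
covariance) rides along for the within-subject effects, since
three-level within factors commonly violate sphericity.

The normality gate runs one Shapiro–Wilk test on residuals pooled across
design cells (each value centred on its cell mean) and applies a natural
log on rejection at α = 0.05. Testing each of the six cells separately
and transforming on any rejection would carry a ~26% false-transform
rate under normality; the pooled-residual test keeps the gate's size at
α. Per-cell p values remain available as diagnostics, and undefined
cells (constant or n < 3) are flagged and excluded from the pool.

Post hoc families are explicit: time pairs within each group (m = 3 per
group, paired t), groups within each time (m = 3, Welch t), or time
pairs pooled (m = 3). Bonferroni adjustment is min(1, m·p). Group
descriptives use Welch's unequal-variance t and Pearson χ² without
continuity correction (the uncorrected statistic is the one that matches
the textbook hand formula; with the study-scale cell counts the
correction is immaterial).

## Synthetic generators

The generators exist so that every estimator can be checked against a
programmed truth; they are first-class, tested code.

- **Windkessel**: three-element model, P = p_wk + Zc·Q with
  C·dp_wk/dt = Q − p_wk/R, integrated by fixed-step RK4 at the signal
  rate. The ODE is linear, so the one-beat RK4 map is affine in the
  state; its fixed point is solved exactly and the emitted beats are
  periodic to machine precision — no warm-up transient can leak into
  the output at any heart rate. The default inflow has a quarter-sine
  acceleration phase (40 ms, steepest at ejection onset where Q ≈ 0)
  followed by a raised-cosine decay; this satisfies the validity
  condition of the time-domain Zc estimator, which recovers the
  programmed Zc within 2% over a zc ∈ {0.05, 0.1, 0.2} ×
  HR ∈ {50, 60, 80} grid. A half-sinusoid ejection is available
  (`flow_shape="half_sine"`) and demonstrates the estimator's upward
  bias when the acceleration phase is slow.
- **Transit pair**: the distal waveform is the proximal one delayed by
  distance/PWV via linear interpolation (sub-sample exact for smooth
  content); delays at or beyond one cardiac cycle are rejected because
  foot pairing would be ambiguous.
- **Velocity envelope**: per beat, a raised-cosine upstroke to v_sys and
  a raised-cosine decay back to v_dia whose width is solved by bisection
  on the sampled beat so the beat mean hits v_mean; infeasible
  (v_sys, v_dia, v_mean) triples raise an error naming the violated
  constraint rather than being clipped. Feasibility requires the beat
  mean fraction (v_mean − v_dia)/(v_sys − v_dia) below one half.
- **Breath-hold session**: a continuous capnogram with one expiratory
  plateau per paced breath (the analysis stage must find plateaus
  itself), a post-hold plateau at baseline + ΔETCO₂, and an MCAv rise
  whose post-hold plateau (≥ 3 s, so the pipeline's moving-average peak
  recovers it exactly) equals cvr_true·ΔETCO₂.
- **Cohort**: a compound-symmetry random-intercept model — cell mean
  plus cell SD times (√ρ·z_subject + √(1−ρ)·ε) — the minimal structure
  under which the mixed rm-ANOVA is exact, with the requested
  within-subject correlation ρ induced directly.
- **Whole study**: 21 + 20 subjects × 3 times with group-by-time
  parameter cells patterned on a high-sugar meal challenge in young
  versus middle-aged adults (carotid dilatation with falling stiffness
  and impedance in both groups; MCA pulsatility and reactivity rising in
  the young group only) and a subject-level random intercept (ρ = 0.7)
  carried across time points. Visit recordings are sized for the
  protocol windows (24 s tonometry/ECG at 250 Hz, 122 s MCA Doppler at
  100 Hz, four-repeat breath-hold session at 25 Hz), which keeps a full
  double-run determinism check in the tens of seconds. The carotid
  pressure and velocity channels are built from one propagating pulse
  (windkessel-shaped forward wave plus delayed, scaled backward wave;
  pressure sums the components, flow takes their difference) so the
  measured impedance and reflection metrics are physiologically
  coherent.

What the generators do **not** emulate: baroreflex and respiratory
modulation of beat-to-beat variability, probe-angle and insonation
artifacts, drift and movement noise, calibration error in the cuff
itself, true beat-to-beat coupling between channels (each channel's
noise is independent), or pharmacokinetics of the meal (glucose/insulin
are passed through as given values). Passing round-trip tests therefore
demonstrates correctness of the estimators under the stated signal
model, not robustness to every artifact of real recordings. One known
discretisation effect: at the 250 Hz visit sampling rate, interpolated
sub-sample delays slightly smooth the upstroke, so visit-level cfPWV
runs a few percent below the programmed wave speed; the 1 kHz recovery
check is exact to within 2% and study-level values remain
self-consistent.

## Degenerate inputs and tie-breaks

Flat beats cannot be calibrated (zero-amplitude error); a carotid beat
whose mean equals its minimum makes the two-point anchor singular; a
non-positive maximum slope means no foot; identical proximal/distal
waveforms give Δt = 0 and an ordering error rather than infinite PWV;
constant velocity envelopes return (c, c, c) rather than failing; a
constant ETCO₂ trace is accepted as degenerate (pre-extracted end-tidal
level) while a clearly breathing trace with fewer cycles than scheduled
is a protocol mismatch. Zero-variance post hoc contrasts are flagged
with p undefined. Visit-level stage failures null that stage's metrics
with an error code — a row never carries a silent partial value.

## Problem sizes in the verification suite

Oracle and recovery checks run at the sizes stated in their tests: 100
random beats for the reconstruction identity, a 9-condition windkessel
grid, a 3×3 breath-hold grid, 100 random datasets against the
brute-force ANOVA oracle, 2000 null replicates at n = 20/group for the
interaction size check, and a full 41-subject × 3-time double run for
determinism. These sizes make the whole suite complete in well under a
minute apiece while keeping Monte-Carlo error far inside the asserted
tolerances.
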