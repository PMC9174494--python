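# Methods

## The measurement problem

Newborn mice breathe with frequent respiratory pauses. In whole-body
plethysmography the chamber pressure rises with inspiration and returns to
an end-expiratory baseline with expiration; an apnea appears as one
abnormally long respiratory cycle flanked by cycles of normal duration.
Two phenomenologically distinct apnea types occur:

* **breath-holding apneas** — post-inspiratory retention of the inspired
  air: the trace holds a plateau above baseline, sometimes carrying
  resuming inspiratory efforts of growing amplitude, and typically ends
  with a small upward pressure shift followed by an abrupt deflation.
  The shift is often time-locked to a sub-millisecond broadband acoustic
  transient (a "click") consistent with re-opening of a closed upper
  airway, which makes this type a candidate obstructive event;
* **central-like apneas** — a pause at baseline after a complete normal
  breath, i.e. with the lung deflated.

The package quantifies, per recording: the cut-off respiratory cycle
duration (CORC) separating repetitive from apneic cycles, the apneic time
fraction (ATF, time in apneic cycles / recorded time) in total and per
type, click statistics in synchronized ultrasound audio, and ventilation
variables (F_R = 60/(Ti+Te) breaths/min as the only dimensionally valid
reading of the frequency formula, V_T as mean inspiratory amplitude in
µL, V_E = F_R·V_T/1000, optionally per gram — both normalizations are
exposed because the stated units imply a weight division that the formula
itself omits).

## Breath segmentation

The pressure trace (nominally 1 kHz) is low-pass filtered at 20 Hz and
referenced to a running baseline, defined as the 10th percentile over an
8 s window evaluated on a 250 ms grid. The window is deliberately longer
than the longest plausible apnea: a breath-hold plateau several seconds
long would capture any short-window median, while a low percentile over a
window that always contains some end-expiratory samples tracks the true
baseline through plateaus.

Inspiration onsets are found with a hysteresis detector on the detrended
signal (arm below 5%, fire above 15% of the running amplitude, the 99th
percentile of the detrended trace). Because the 20 Hz filter rounds the
inspiratory corner, each onset is then refined to the sub-sample upward
crossing of 4% of the running amplitude on a 60 Hz-filtered copy within
±30 ms. Achieved timing on noise-free synthetic data is ~1 ms median
duration error with a tail to ~5 ms from amplitude-dependent crossing
delays; at a noise SD of 5% of V_T, onset recall and precision stay
≥ 0.98. Cycles are onset-to-onset; Ti is onset-to-peak; apneic pauses are
absorbed into the enclosing cycle's Te, so cycle duration is the quantity
the CORC classifies. Cycles whose amplitude exceeds 5× the running median
amplitude are treated as movement artifacts and excluded (their time is
also removed from the ATF denominator); sync marks (trigger, knock) are
trimmed from the analyzed span.

Volume calibration divides a known injected volume (2.5 µL by default) by
the mean pressure-step amplitude across injections and is
scale-equivariant by construction.

## The CORC

**Poincaré method.** Cycles whose duration differs from both neighbors by
less than 3× the robust SD (1.4826·MAD) of first differences form the
repetitive set — operationally "followed and preceded by a cycle of about
the same duration". A single Gaussian is fitted to this set and
CORC = mean + k·SD with k = 4 by default: at the sample sizes involved
(hundreds of cycles) a 4-SD boundary leaves < 0.02 expected regular
cycles beyond it while sitting far below any programmed apnea.

**log-ThD method.** For a threshold duration ThD, ATF(ThD) is the time
fraction in cycles longer than ThD; over the clearly apneic range it is
close to linear in log(ThD). ATF is evaluated on a 40-point log-spaced
grid from 8 s down to the repetitive-cluster mean, a line is fitted where
ThD ≥ 3× the median duration (and ATF > 0), and the CORC is the largest
grid ThD below the fitted range where the observed ATF departs from the
extrapolated line by more than 3 residual SDs (floored at 1e-4). The
departure is tested two-sided: when the apneic duration distribution has
a gap above the regular cluster, the observed curve flattens below the
extrapolated line before it explodes upward inside the cluster, and the
first significant departure — in either direction — marks the end of the
homogeneous apneic population. On such series the numerical CORC value
can land anywhere in the gap; the *apnea set* it induces is then
identical to the Poincaré one, which is the agreement that matters and
the one asserted in tests (< 5% set difference on bimodal mixtures).
Degenerate inputs (no cycle above 3× the median, or no departure) return
the grid floor with a flagged diagnostic rather than an error.

An apneic cycle is any cycle longer than the CORC. Consecutive apneic
cycles violate the isolated-apnea assumption; they are counted
individually and flagged in the summary.

## Apnea typing

For each apneic cycle the pause window is the cycle minus one median
cycle length at the start (the leading breath) and 150 ms at the end (the
terminal deflation). The plateau level is the median detrended pressure
in that window, in units of the repetitive-population tidal amplitude.
Typing thresholds: breath-hold at level ≥ 0.3; central-like below 0.1
(lung deflated); between 0.1 and 0.3 the cycle is breath-hold if a click
falls within ±100 ms of the terminal deflation, otherwise it is flagged
ambiguous and ruled central-like — the deterministic stand-in for the
dual-reviewer manual tie-break. The terminal deflation is located as the
final fall of the pause below the deflated level (steepest-slope
definitions confuse resuming-effort decays with the terminal collapse
when the plateau is low). Resuming efforts are flagged when ≥ 2 peaks of
non-decreasing prominence (≥ 8% of V_T, ≥ 150 ms apart) ride on the
pause. The per-type ATF partition is exact by construction:
ATF_cl = ATF − ATF_bh.

## Clicks and clock synchronization

Audio (any rate ≥ 20 kHz; the simulator writes 50 kHz) is high-pass
filtered at 5 kHz; short-time energy in 0.25 ms frames is thresholded at
median + 8·1.4826·MAD; frames closer than a 10 ms refractory period merge
into one event. Events are kept when 0.4–2 ms long and spectrally flat
(≥ 0.4) *within the passband* — restricting flatness to the ≥ 6 kHz bins
matters because the high-pass zeroes the low-frequency bins and would
otherwise collapse the geometric mean for genuine broadband clicks. The
duration ceiling rejects knocks, trigger pulses and vocalization bouts;
the flatness floor rejects tonal ultrasonic vocalizations; the duration
floor rejects single-frame noise excursions, of which a median+8·MAD
threshold over ~10⁶ frames otherwise passes dozens.

The audio and pressure clocks drift relative to each other (crystal
rating ±50 ppm ⇒ ≥ 10 ms/min). Both channels carry a shared 10 ms
trigger pulse near the start and a chamber-knock impulse near the end;
each mark is located as the onset of the most prominent sustained pulse
(2 ms rectified moving-average envelope, half-peak onset refinement), and
a two-point linear map (offset from the trigger, drift from the knock
separation) brings audio times onto the pressure clock. On simulated
10-minute recordings with 50 ppm drift the post-correction click
alignment error stays below 2 ms (measured ~0.3–1 ms).

Peri-event histograms bin click offsets around alignment events in an
odd number of bins so one bin is centered on zero ([−bin/2, +bin/2),
ties to the earlier bin); the mode fraction is the fraction of events
whose nearest click falls in the central bin. Click-context fractions
assign each corrected click to the labeled breathing context containing
it (vocal / breath-hold / eupneic / central-like); fractions are over
assigned clicks and are flagged undefined when no click is assigned.

## The synthetic-data generator

The simulator is the package's verification instrument: it produces
paired pressure/audio recordings with complete ground truth from a
`SimProfile`. Regular cycle durations are truncated-normal
(mean 0.4 s, SD 0.04 s, floor 0.1 s — a neonatal breathing rate of
~150/min); apneic durations are uniform on (1, 4) s, strictly above
mean + 3 SD of the regular distribution so that apneas are genuinely
long. Amplitudes are ~N(V_T, 10%) with V_T = 8 µL and pup weight 1.4 g.
Waveforms: quarter-sine inspiration, exponential expiration; breath
holds plateau at 0.8·V_T with resuming efforts growing linearly from 0.2
to 1.0 of the retained headroom (present in 70% of events), a terminal
+0.15·V_T shift and a fast deflation; central-like apneas append a
baseline pause to a normal breath; vocal cycles add an expiratory
compression, a 17 kHz tone surrogate for the call (ending just before
the re-opening click), and a click at the compression re-opening.
Additive white pressure noise defaults to 3% of V_T.

Apnea placement is a two-state Markov chain: after an apneic cycle the
next cycle is forced regular (apneas are isolated by construction), and
the post-regular apnea probabilities are inflated to p/(1−p_bh−p_cl) so
the stationary per-cycle kind fractions equal the nominal probabilities.
This keeps the simulated ATF an unbiased realization of the closed form

    ATF_type = p_type·E[D_type] / Σ_k p_k·E[D_k],

which `expected_summary` evaluates exactly (truncated-normal mean for the
regular class) and `calibrate_apnea_rates` inverts. The registered
profiles are calibrated through that inversion to the cohort means they
stand for: mutant 29.3% total / 22.6% breath-hold; control 12.3% / 8.3%;
null 1.7% breath-hold with the control's central-like 4.0% (the null
central component is not separately reported and is assumed unchanged);
wild-type joint-audio 9.7% / 4.0% with a 69.5% breath-hold click
probability and the remaining click probabilities solved from the
measured context distribution (81.5 vocal / 15.0 breath-hold /
2.2 eupneic / 1.1 central-like %); a DREADD baseline at 5% total so that
the five-fold CNO transform lands at the reported ~25% plateau.
Treatment transforms re-derive rates through the same inversion: PTZ
shortens the regular cycle by 15% and scales the expected breath-hold
ATF to 0.35× (total drop ≈ 50%, comfortably beyond the stated 40%)
leaving central-like apneas untouched; CNO scales both types five-fold;
saline is the identity.

Audio is rendered at 50 kHz (the hardware's 250 kHz serves no detection
purpose at desk scale; all analysis code accepts any rate ≥ 20 kHz) with
a 0.003 noise floor, 0.5 ms broadband clicks, tone-burst USV surrogates,
and both sync marks; event times are mapped through the profile's clock
drift (default 50 ppm). Per-pup cohort seeds are the counter pairs
[seed, pup_index], so any pup is reproducible in isolation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: baseline drift and temperature/humidity
effects, movement artifacts beyond an amplitude ceiling, heavy-tailed or
autocorrelated cycle-duration variability, realistic USV syllable
structure, graded click amplitudes, chest-wall mechanics. Detector
parameters validated here are validated against this phenomenology only.

## Statistics

Group comparisons follow a normality gate at α = 0.05 (Shapiro–Wilk
below n = 20, D'Agostino–Pearson otherwise): Student's t (paired or
unpaired) when both samples pass, Mann–Whitney / Wilcoxon otherwise; the
result records which path was taken, and identical paired vectors return
p = 1 rather than a degenerate test. Percent change is on group means.
Under the null the gate's type-I error is ≈ 5% (simulation-checked).

## Problem sizes and numerical choices

Verification cohorts use the reported group sizes (17/17/10/10/13 pups)
at 300 s per recording — the recording length the protocol specifies —
and the joint-audio analyses use 6–10 pups × 300 s plus one 600 s
recording for the drift check; these sizes give 3-SE Monte-Carlo bands
of roughly ±1–3 percentage points on cohort ATF means. Residual-SD
floors (1e-4 on the ATF scale), the 1e-3 s sync-jitter default and the
0.01·median floor on the neighbor tolerance guard degenerate inputs
(constant series, noise-free fits). Ties in the peri-event central bin
go to the earlier bin; the cohort pipeline is deterministic given seeds.

## Known limitations

The CORC assumes a unimodal repetitive population; bimodal regular
breathing (e.g. sniffing bouts) would widen the fitted Gaussian and
inflate the CORC. The log-ThD method needs enough long cycles to anchor
the fit (≥ 3 nonzero grid points above 3× the median). Typing thresholds
(0.3 / 0.1 V_T) are declared choices validated on the simulator, not on
animal data; the click detector's parameters likewise. Audio analysis
assumes a single microphone channel and stationary noise floor.
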