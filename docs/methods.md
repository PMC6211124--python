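# Methods

## Problem and signal model

A pedometer observes a tri-axial accelerometer carried on the body
(typically in a trouser pocket) at a nominal 50 Hz. Each foot strike
produces one dominant burst in the acceleration signal. Counting those
bursts naively fails in three ways: *over-counting* (noise and secondary
oscillations counted as steps), *under-counting* (true bursts suppressed by
over-aggressive filtering or by validation rules that remove good peaks
together with bad ones), and *false walking* (the device moves — hand
gestures, pocket insertion, vehicle or leg vibration — while the user does
not walk).

All processing operates on the orientation-free magnitude

    Acc(j) = sqrt(Ax(j)^2 + Ay(j)^2 + Az(j)^2)

in g units, which reads 1 g for a still device in any pose. The pipeline
has four phases.

### Phase 1 — preprocessing

Magnitude first, then a low-pass at 3 Hz: step cadence stays below
3 steps/s at every walking speed, so everything above 3 Hz is sensor noise
or impact harmonics. The filter family is not dictated by the method, only
its cutoff; we use a 4th-order Butterworth applied forward–backward
(`filtfilt`). Zero-phase filtering matters: the timing features of Phase 4
(step intervals) are computed from peak sample indices, and a causal filter
would shift them by a cadence-dependent group delay. DC gain is exactly 1,
and odd reflection padding (about one second) suppresses edge transients.

### Phase 2 — walking-state classification

The mean magnitude over a sliding 2 s window (50% overlap) increases with
walking vigour, separating slow, normal and fast walking with two
thresholds M1 < M2 (window mean < M1 → slow, < M2 → normal, else fast).
Each sample, and hence each peak, inherits the state of the nearest window
centre; a recording may change state freely (that is what "free walking"
is). Still segments fall below M1 and are handled by the slow profile; they
produce no peaks anyway.

M1 and M2 carry no universal values — they depend on device, body position
and population. The defaults (M1 = 1.18 g, M2 = 1.26 g) are the midpoints
between the analytic window means of the synthetic generator's three
cadence presets (≈ 1.13 / 1.23 / 1.30 g, see below). **For real recordings
these two numbers are the first thing to recalibrate**; both are exposed in
the `[states]` config section.

Each state carries a parameter bundle used by Phase 3:

| state  | d (samples) | H (g) | Th_vib (g) | Ts (s) |
|--------|------------:|------:|-----------:|-------:|
| slow   | 14          | 0.20  | 0.08       | 0.635  |
| normal | 12          | 0.25  | 0.10       | 0.507  |
| fast   | 10          | 0.35  | 0.15       | 0.469  |

`d` shrinks with cadence (fast steps arrive sooner); the amplitude
thresholds H and Th_vib grow with the more vigorous signal. The
dynamic-threshold window is one step long minus a sample:
`win_size = round(Ts × fs) − 1` (round half-up; at 50 Hz this gives
31/24/22 samples). Ts is the mean step period of each gait speed.

### Phase 3 — peak detection under four constraints

1. **Minimal peak distance.** A sample is a candidate peak when it is ≥
   every sample within `d` positions on both sides (windows clipped at the
   recording edges, endpoints excluded). The `≥` admits plateaus; a
   flat-topped peak keeps its first index, and within any d-sample span
   only the higher peak survives (ties → earlier). Deterministic and
   identical to a left-to-right scan.
2. **Minimal peak prominence.** From the peak, extend a horizontal line
   left and right until a strictly higher sample or the window edge; the
   base on each side is the minimum of the traversed interval, and
   prominence = amplitude − max(left base, right base). This is the
   standard topographic prominence (scipy's definition agrees exactly, and
   the test suite cross-checks against it); peaks with prominence < H are
   shoulder bumps, not steps. The evaluation window is the same centred
   `win_size` window used below.
3. **Dynamic thresholding.** Per peak, `Aver_D = (max + min)/2` of the
   magnitude over a `win_size` window centred on the peak (clipped at the
   edges); the peak must clear this mid-range by `Th_D = 0.15 g`. Unlike a
   fixed height threshold this adapts to each person's stride amplitude.
4. **Vibration elimination.** `Vib_Eli = amplitude − 1 g` must reach
   Th_vib: peaks that merely flutter around gravity are shaking, not
   stepping.

Filters 2–4 are independent predicates — each only removes peaks — so the
surviving count is monotone non-increasing in every threshold, a property
the tests assert. Prominence and dynamic thresholding are invariant to a DC
offset of the signal; vibration elimination is deliberately anchored to the
1 g baseline.

In the integrated pipeline, candidates are collected per state on the
*full* signal: the constraint windows always see the whole recording, so a
classification boundary cannot truncate a peak's evidence (slicing the
signal at state changes was measurably lossy).

### Phase 4 — step confirmation

A surviving peak becomes a step when its timing and amplitude look like
gait:

* **Periodicity.** Natural step periods span roughly 0.45–0.65 s across
  slow to fast walking; we accept intervals in [0.35, 0.80] s (the natural
  band widened ~25% for inter-subject variability). The interval is
  measured to the previously *confirmed* peak, from sample indices divided
  by fs. A peak arriving after a gap > 0.80 s restarts a walking bout and
  is accepted as the bout's first step, which is what makes intermittent
  walking count correctly.
* **Similarity.** Steps of the same leg — peaks two apart — have nearly
  equal amplitude: `S_i = −|amp_{i+2} − amp_i|` must stay within
  s_tol = 0.3 g of zero, compared against the last-but-one confirmed peak
  of the current bout (skipped until the bout has two). The tolerance is
  set so clean strides (amplitude jitter ≲ 0.1 g) always pass while
  two-fold amplitude spikes fail; it has no published value and is config
  surface.
* **No cascade.** A failing peak is dropped alone. The
  periodicity/similarity/continuity method we compare against discards the
  comparison partner as well, which is exactly why it under-counts noisy
  recordings; rejecting only the offender is the fix.

Known limitation: because intervals are measured to the last confirmed
peak, a *sustained* train of sub-band transients (spacing ≈ 0.3 s) with
near-identical amplitudes would confirm every other transient if it ever
reached Phase 4. In practice Phase 3 removes such trains — after the 3 Hz
low-pass a ≳3 Hz transient train collapses towards its mid-range and fails
dynamic thresholding — and the false-walking tests confirm near-zero counts
end to end. The bout-start rule also means an isolated single transient
counts as one step by construction; rejecting it would require rejecting
genuine single steps after pauses.

### Evaluation

`Error = |E − T| / T × 100%` and accuracy = 100 − Error, where E is the
detected and T the true count.

## Synthetic gait generator

The generator is a parametric signal model designed to exercise every
pipeline stage with exact ground truth; it is not a biomechanical claim.

* **Walking.** Magnitude = 1 g baseline + one raised-cosine pulse per step
  (height `peak_amp` ± jitter, width `pulse_width_frac × Ts`) + a
  second-harmonic ripple (10% of peak_amp, tapered at the walk edges) +
  white Gaussian noise (default sd 0.02 g). Step times follow
  `Ts (1 + 0.05 z)` with the per-state Ts above. The scalar profile is
  embedded into three axes along one fixed random unit vector per recording
  (the pocket pose); the RMS magnitude recovers it exactly, which the
  self-consistency test checks to 1e-9.
* **Amplitude calibration.** Pulse heights default to 0.40/0.60/0.70 g
  (slow/normal/fast) and widths to 0.65/0.75/0.85 of Ts. Two constraints
  fix these: (i) after the mandatory 3 Hz low-pass, a periodic pulse train
  retains at most ≈ 0.55 × amplitude of peak-to-mid-range swing, so every
  state must stay comfortably above Th_D = 0.15 g — 0.40 g is about the
  smallest slow-walk pulse the pipeline itself could ever accept; (ii) each
  state's filtered prominence also clears the *next faster* state's H, so a
  window misclassified one state up loses no steps. The resulting mean
  magnitudes (1 + amp/2 × width/Ts ≈ 1.13/1.23/1.30 g) order the states and
  set M1/M2 as above.
* **False walking.** Vehicle vibration and leg tremor are band-limited
  noise around 1 g with excursions ≈ ±0.05 g, below every Th_vib. Hand
  motion and pocket insertion are one burst of rapid transients (width
  0.25 s, spacing 0.29–0.34 s ≈ 3 Hz — hand shaking is faster than gait and
  below the periodicity band) whose intensity is drawn once per gesture
  (0.35–0.6 g) and ramps up and dies out over the first and last quarter of
  the burst. Ground truth is always zero steps.
* **Sessions** concatenate segments with 0.5 s still gaps and merged
  ground truth; a detected step matches a true one within ±0.25 Ts.

What the generator does *not* emulate: real stride-to-stride waveform
variety, stair-specific morphology, arm-swing cross-talk, sensor bias and
saturation, or device-dependent noise colour. Passing the synthetic suite
therefore demonstrates the algorithm's mechanics — not field accuracy on
any particular device, for which M1/M2 (at least) must be recalibrated.

## Baseline counters

* `peak_only`: candidate peaks over a fixed height (default 1.1 g) with
  minimal peak distance — nothing else. Over-counts noisy signals and
  counts false walking wholesale.
* `psc` (periodicity + similarity + continuity): same candidates; bouts
  restart after gaps > 2 × t_max; the step interval is measured between
  *consecutive candidate peaks*, so an interloper invalidates its
  successor; and a similarity failure removes the comparison partner too
  (cascade). This reconstruction reproduces the documented failure modes —
  under-counting of noisy and intermittent walking, strength on false
  walking. The exact continuity rule of the original method is not public;
  ours ("no gap > 2 × t_max inside a bout") is labelled a reconstruction.

Both baselines consume the raw magnitude: the 3 Hz low-pass is part of the
proposed method, not of the references. The baseline contrast suite uses
walks with noise sd 0.08 g — the noisy low-cost-IMU regime where the
baselines' failure modes actually appear; at the default 0.02 g all three
methods are near-exact and the ranking degenerates to ties.

## Numerical and interface choices

* All thresholds live in g units internally; m/s² recordings are detected
  by their resting median magnitude (≈ 9.8) and divided by 9.80665 at
  ingestion. Auto-detection refuses signals whose median magnitude matches
  neither band rather than guessing.
* Irregular timestamps (> 1% deviation of the median interval) are
  resampled by linear interpolation to the declared rate; > 5% gap ratio
  warns.
* Windows of even length centred on index j cover j − w/2 … j + w/2 − 1,
  clipped (never shrunk) at the recording edges.
* `win_size = round(Ts × fs) − 1` uses round-half-up; floor would differ by
  at most one sample and measurably changes nothing, but half-up is
  symmetric across the three Ts values.
* Problem sizes in the tests and the acceptance script (60-step walks, 20
  seeds per state, one 500-step session, 20 false-walk sessions of 30
  transients) were chosen as the smallest sets whose sample statistics are
  stable across seeds.
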