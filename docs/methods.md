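# Methods

This note documents the models, numerical choices, and open design
decisions behind `soniquant`. It is the reference for *why* the defaults
are what they are; the README covers *how* to run things.

## The control problem

Microbubble-mediated blood-brain-barrier (BBB) disruption works in a
narrow exposure window: too little acoustic pressure and the barrier does
not open; too much and the bubbles collapse inertially, producing
subharmonic and broadband emissions and a risk of vascular damage. The
controller regulates a proxy for stable cavitation activity — the
harmonic enhancement **H**, the mean dB elevation of the 2nd and 3rd
harmonic bands (460 and 690 kHz for a 230 kHz drive) above the
pre-sonication noise floor — while watching the subharmonic (115 kHz) and
broadband (640–680 kHz) bands for danger signatures.

## Spectral band analysis

Band power is `10·log10` of the one-sided spectral power summed across a
bin, computed from a Hann-windowed FFT of the full 5 ms burst in a single
segment (bursts are short and stationary, so Welch averaging would only
widen the effective bin). The normalization is chosen so a pure tone of
amplitude A contributes A²/2 to its band; a tone at a band center places
≥ 99 % of its energy inside the 10 kHz bin at the default window length,
and the 40 kHz broadband bin never captures the main lobe of either
harmonic. Zero-energy bands are reported at a −120 dB sentinel so that
downstream arithmetic stays total.

Two noise floors are calibrated per sonication, each as the per-band mean
and sample SD over a burst ensemble:

* the **pre-sonication floor** (3.5 s acquisition before the exposure)
  is the reference for H;
* the **early-burst floor** (the first 8 s of 0.16 W bursts, before the
  microbubble bolus reaches the brain) is the reference for the event
  thresholds: subharmonic events at mean + 3.2 SD, broadband at
  mean + 3.9 SD.

The published protocol describes both floors but not which rule consumes
which; the assignment above mirrors their stated purposes. Threshold
comparisons are strict (`>`): boundary equality is a non-event. The
"broadband bin centered at 0.66 kHz" in the protocol description is read
as 0.66 MHz (the second hydrophone's resonance). Whether H averages the
two harmonic elevations in dB or in linear power is unspecified; the
dB-domain mean is used (and is what the goal band is expressed in).

## The proportional controller

Per-target state machine over a 75 s exposure with bursts every 101.6 ms
interleaved across 9 targets (per-target PRF ≈ 1.1 Hz):

| phase | window | behavior |
|---|---|---|
| `fixed_pre` | t < 8 s | hold 0.16 W; bursts feed the early floor |
| `controlling` | 8 ≤ t < 25 s | proportional updates, goal band [6.0, 7.5] dB |
| `frozen` | t ≥ 25 s | hold the mean power of all goal-band bursts |

The published description fixes the gain (P_gain = 0.0167 per dB), the
assumption that H in dB is proportional to pressure amplitude, and that
pressure scales as the square root of power — but not the algebraic form
of the update. The reconstruction used here applies a relative step in
the pressure (amplitude) domain whenever H is outside the goal band:

    a ← a · (1 + P_gain · (H_set − H)),   power = a²,

with H_set the goal-band midpoint (6.75 dB; the protocol gives a band,
not a setpoint). Power is clamped to (0, 0.39 W]. When H is inside the
band the power is held and recorded as a "goal hit". The law and gain are
configuration-swappable. Two consequences worth knowing:

* Because of the dead band, the loop settles at the *first* power whose H
  enters the band (typically just above the 6.0 dB edge when approaching
  from below), not at H_set. The fixed-point set is therefore the power
  interval mapping onto [6.0, 7.5] dB, and the convergence test asserts
  membership of that interval (±2 %) rather than a single point.
* The Methods-vs-Results discrepancy in the source protocol (upper edge
  "7.7" vs "7.5" dB) is resolved in favor of 7.5; the edge is a config
  field.

**Safety rule.** A subharmonic or broadband detection on a target's burst
cuts that target's power by 25 % and freezes it for the remainder of the
sonication; at most one reduction ever occurs per target. A reduction can
also fire after the 25 s end-of-control freeze ("at any time"), but a
reduced target is terminal. Reduction is per-target by default (power is
per-target); a global-freeze mode is available behind a config switch.

**Fallback.** If a target never achieves the goal band by 25 s the
published procedure is silent; the current power is held (conservative,
least surprise).

**Gating.** The microbubble arrival time is a plant parameter and the
8 s controller gate a controller parameter — deliberately decoupled, so a
mis-timed bolus is a representable fault condition.

## The synthetic plant

The plant maps (target, power, time) → burst spectrum:

* **Pressure**: p = 119 kPa · √(P / 0.16 W), the calibrated water-path
  anchor; the 0.16–0.39 W range maps to 119–186 kPa.
* **Bolus**: zero concentration before 8 s, raised-cosine ramp to peak
  over 1 s, then single-exponential clearance with a 40 s half-life.
  These kinetics are **synthetic** (Definity-like order of magnitude);
  no measured values exist for them in the modeled protocol.
* **Harmonics**: H = slope · (pressure · concentration · sensitivity),
  i.e. linear in pressure amplitude with an optional activation floor
  (default 0, pure proportionality — the controller's own working
  assumption). The default slope 0.0414 dB/kPa is calibrated so the goal
  midpoint is reached near 0.30 W at peak concentration, placing the
  operating point mid-range between the 0.16 W start and 0.39 W cap.
* **Events**: one latent uniform draw per burst is thresholded through
  band-specific sigmoids of the drive (width 8 kPa; subharmonic threshold
  220 kPa, inertial/broadband 230 kPa), so both event types co-occur on
  unstable bursts — mirroring their observed spatial co-localization.
  Event bursts add +25 dB to the affected band. The thresholds are set so
  that at the controller's operating drive (~163 kPa) events occur in
  well under 1 % of bursts, the rarity reported for controlled exposures
  in vivo; they are not fitted to any measured cavitation threshold.
* **Noise**: i.i.d. Gaussian band noise, SD 0.5 dB.
* **Randomness**: one seed spawns named per-target streams, so identical
  seeds give bit-identical logs and one target's noise never perturbs
  another's trajectory.

`PlantConfig.noise_free()` is the idealized verification plant: no noise,
no events, and an **infinite** clearance half-life, so the frozen-phase H
isolates controller behavior from the synthetic clearance kinetics.
`PlantConfig.zero_response()` is the adversary used to verify the power
cap. What the plant does **not** model: bubble dynamics
(Rayleigh–Plesset), skull reflections and standing waves, spatial focal
structure, or hydrophone transfer functions — passing tests show
closed-loop logic and calibration arithmetic are correct, not that the
controller would behave identically against real tissue.

## Relaxometry

R1 maps come from voxelwise nonlinear least squares of the
saturation-recovery model S(TR) = S0·(1 − e^(−TR·R1)) at the protocol TR
ladder (6000/3200/1600/800/400/200/100 ms). The fixed echo time (13.4 ms)
makes T2 decay a constant factor absorbed into S0. Fits are unweighted by
default despite unequal averages per TR (1/1/1/2/2/4/4); weights
∝ √averages are available behind a flag. Initialization is closed-form
and deterministic: S0 from the signal maximum, R1 = ln 2 / TR nearest
half-maximum. Non-converged or negative-rate voxels are masked out and
counted. At this ladder with 1 % Gaussian noise, recovery over the
physiological 0.3–2.0 s⁻¹ range shows |bias| < 1 % and RMSE < 3 %
(asserted in the suite).

Gadolinium quantification: [Gd] (mM) = ΔR1 / 4.44 s⁻¹mM⁻¹ (gadobutrol at
3 T), and µg/g = mM × 604.71 g/mol at an assumed tissue density of
1.0 g/cm³. Whether published µg/g figures use the chelate or the Gd³⁺
mass is ambiguous; the molar mass is configurable and mM is the primary
output. Hemispheric comparisons take voxels within 1.5 mm of the
sonication targets intersected with each structure label, and subtract
the mean over the mirror reflection about a configurable sagittal
midline (fractional midlines supported; reflections clip at the edge).
Coordinates are 0-based voxel indices; physical distances use the voxel
size (or image affine at the CLI).

## Outcome statistics

* **Doubling time**: V(t) = V0·2^(t/Td) by nonlinear least squares,
  warm-started from the log-linear regression, parametrized by rate 1/Td
  so flat series stay finite (Td = ∞, flagged); shrinking tumors yield a
  negative Td (a halving time), also flagged. Group values are reported
  as mean ± SD of per-animal fits; the core and hyperintense-volume
  channels are fit independently.
* **Kaplan–Meier / log-rank**: product-limit estimation and the
  chi-square log-rank test via `lifelines`. The median convention is
  "earliest t with S(t) ≤ 0.5"; when S lands exactly on ½ (even n,
  uncensored) the alternative midpoint convention (average with the next
  event time) is also reported — the two can differ by half an
  inter-event gap and both are exposed.
* **Concentrations**: geometric mean and geometric %CV
  (100·√(e^{s²}−1) with s² the sample variance of ln x); paired
  two-tailed t-tests on log-transformed sonicated/control pairs, with
  zero-variance differences flagged degenerate rather than returning a
  spurious p.
* **Exposure arithmetic**: HED (mg/m²) = mg/kg × Km (Km = 6 for rat);
  per-target PRF = 1/(n_targets × burst interval).

Hazard ratios are deliberately out of scope: they are not recoverable
from group summaries without per-subject times.

## Problem sizes and determinism

A full simulated sonication is 738 bursts (75 s / 101.6 ms); the R1
recovery surface uses 18 R1 values × 40 replicates; the log-rank
permutation reference uses 10⁴ label permutations on a 12-subject
fixture; doubling-time recovery uses 200 replicate series. All
stochastic components take explicit seeds (hypothesis runs
derandomized), so the suite and the acceptance script are reproducible
run-to-run.

## Known limitations

* The controller update law is a reconstruction from stated constraints,
  not a transcription of the original implementation; overshoot behavior
  may differ.
* The plant's clearance and event thresholds are synthetic calibrations;
  absolute event rates and frozen-phase H decay under the default
  (clearing) plant are illustrative, not predictive.
* Relaxometry ignores contrast-agent diffusion during the multi-TR scan
  and assumes given, registered masks; no registration is provided.
* The sign conventions for hemispheric deltas assume a left/right
  mirror-symmetric grid; oblique midlines are not supported.
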