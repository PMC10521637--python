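# Methods

## Problem and approach

Focused ultrasound with intravenous microbubbles (FUS-BBBO) opens the
blood-brain barrier transiently for drug delivery. Safety and efficacy hinge
on keeping microbubble activity in the stable-cavitation regime (harmonic
emissions, safe opening) and out of the inertial regime (broadband
emissions, vascular damage). Because the emissions detected from a given
subject depend on skull attenuation, injected microbubble dose and local
vasculature, a fixed absolute target is not transferable between subjects.

`cavicontrol` implements an individualized closed-loop controller: each
subject's own baseline stable cavitation level, measured with a brief
low-pressure "dummy" sonication in the presence of microbubbles, defines the
0 dB reference, and the controller regulates the per-pulse stable level to a
target expressed in dB above that baseline.

## Spectral dose metrics

Each 6.7 ms passive-cavitation-detection (PCD) trace, sampled at 40 MHz, is
transformed with an unwindowed (rectangular) FFT; the single-sided magnitude
spectrum has bin spacing `fs/N` ≈ 149 Hz. Two quantities are computed per
pulse:

- stable cavitation level: sum of magnitudes within ±20 kHz of the third
  harmonic of the 1.5 MHz drive (4.5 MHz), ~269 bins;
- inertial cavitation level: the same sum within 3.3 ± 0.02 MHz, a band
  between harmonics and ultraharmonics that responds only to broadband
  emission.

A bin contributes if its centre frequency lies in the closed band. Levels
are `20·log10(sum/ref)` relative to the per-subject baseline (the arithmetic
mean of the linear band sums over the 10 dummy pulses). Two conventions are
deliberately configurable because the processing chain does not force
either: the dB factor (20, amplitude-like, default — magnitudes rather than
powers are summed — vs 10) and the baseline averaging domain (linear
default vs dB/geometric). All controller comparisons use the same
convention, so the control law is convention-consistent. An optional
analysis gate (start/stop fraction of the pulse) is provided for transient
suppression and is off by default.

## Control law

- **Dummy phase**: 10 pulses at 200 kPa (2 Hz PRF, 5 s). Band sums are
  accumulated; their means become the baseline. 200 kPa is the lowest
  pressure at which microbubble emissions exceed the no-bubble background,
  and the exposure is below the threshold for barrier opening.
- **Ramp-up**: pressure rises one 13 kPa step per pulse (the waveform
  generator's minimum increment) until the measured stable level first
  reaches the target. The ramp nominally starts from zero; since a 0 kPa
  pulse emits nothing, the first transmitted ramp pulse is at 13 kPa
  (configurable to literal zero). The pulse that first reaches the target is
  counted as the last ramp pulse, because controller stability is defined
  over the maintain phase only.
- **Maintain**: bang-bang regulation with a closed tolerance band of
  ±0.4 dB: inside the band the pressure is held (a *good pulse*); above it
  the next pulse drops one step; below it the next pulse rises one step.
- The post-dummy (ramp + maintain) phase lasts `treatment_duration_s × prf`
  pulses; the default 120 s is an inferred, configurable value consistent
  with the infusion arithmetic (30 µL at 12.8 µL/min sustains 140.6 s of
  sonication including the 15 s pre-delay).
- Commanded pressure is clamped to [0, 1000] kPa. The cap has no physical
  counterpart in the protocol; it exists so a dead signal chain cannot drive
  unbounded ramping. Sessions that touch the cap are flagged and can be
  excluded from group statistics (`--strict`).
- Inertial cavitation is computed and logged on every post-dummy pulse but
  never feeds back into the control law; it is a safety readout only.

## Synthetic plant

The plant maps (commanded pressure, subject, time) to a PCD trace so the
closed loop can be exercised without hardware:

| parameter | default | meaning |
|---|---|---|
| `harmonic_amps_ref` | (1.0, 0.3, 0.1, 0.03) a.u. | tone amplitudes of f0..4f0 at 200 kPa, gain 1 |
| `pressure_exponent` α | 1.0 | harmonic amplitude ∝ (p/200 kPa)^α |
| `inertial_threshold_kPa` | 300 | centre of the logistic broadband onset |
| `onset_width_kPa` | 10 | logistic width of the onset |
| `broadband_amp` | 0.05 a.u. | broadband strength at full onset (pre-filter white-noise sigma) |
| `target_band_snr_db` | 20 | third-harmonic band SNR at 200 kPa, sets the sensor noise floor |
| `pulse_fluctuation_sd` | 0.05 | lognormal per-pulse multiplicative emission jitter |
| `gain_sd` | 0.3 | lognormal inter-subject emission gain spread |

Design notes:

- α = 1 makes the stable level (in dB) linear in `20·log10 p`, which places
  the study's target levels on both sides of the inertial threshold: a 2 dB
  target operates near `200·10^(2/20) ≈ 252 kPa` (below threshold, no
  broadband), a 4 dB target near 317 kPa (above it).
- The broadband component is white Gaussian noise passed through an ideal
  2.5–4.0 MHz band filter *without* renormalization: filtering removes
  out-of-band power, so `broadband_amp` sets the in-band amplitude spectral
  density on the same per-sample scale as the sensor noise floor. This
  choice controls where the 1 dB inertial-detection contour sits. With it,
  broadband becomes detectable from ≈ 280 kPa — just below the 300 kPa
  onset centre — so a 2 dB session (operating ≈ 250–270 kPa) produces
  essentially no inertial events while a 4 dB session produces them on
  every pulse. Renormalizing the filtered noise to unit variance would
  concentrate ~13× more power into the band and pull the detection contour
  down to ≈ 265 kPa, inside the 2 dB operating range, destroying the
  stable/inertial separation the model is meant to exhibit.
- The sensor noise floor is derived in closed form from the configured band
  SNR: for white noise of standard deviation σ, each rfft bin magnitude is
  Rayleigh with mean `σ·sqrt(N·π/4)`, so
  `σ = (A₃·N/2) / (10^(SNR/20) · n_bins · sqrt(N·π/4))`, with A₃ the
  third-harmonic reference amplitude and n_bins the bins in the ±20 kHz
  band.
- Per-pulse jitter of σ = 0.05 (lognormal) corresponds to
  `20/ln10 × 0.05 ≈ 0.43 dB` of level noise — comparable to both the
  ±0.4 dB tolerance and the ≈ 0.44 dB level change of one 13 kPa step. This
  is what keeps simulated good pulse rates near 60 % rather than 100 %: the
  maintain phase is genuinely exercised.
- Reproducibility: subject i's RNG stream is spawned from the master seed
  with spawn key (i), so a subject's session is bit-reproducible and
  independent of cohort size. Within a pulse the stream is consumed in a
  fixed order (jitter, harmonic phases, broadband noise, sensor noise).
- Infusion: the pump starts 15 s before sonication and availability ramps
  linearly to 1 over 15 s, so bubbles are fully available from the first
  dummy pulse; washout after pump stop is not modelled (availability clamps
  at 1).

### What the plant does and does not emulate

It reproduces inter-subject baseline spread, pressure-dependent harmonic
growth, a broadband onset above an inertial threshold, sensor noise and
pulse-to-pulse emission fluctuation. It does not model bubble dynamics
(Rayleigh–Plesset-type), skull aberration, perfusion kinetics, standing
waves, or slow drifts in bubble concentration. Consequently, passing
closed-loop tests shows the *controller and metrics* behave correctly
against a plausible monotone stochastic plant — not that in vivo good pulse
rates or damage thresholds are predicted. Two visible consequences: the
simulated inertial onset is sharp in pressure (inertial cavitation
probability jumps from ~0 % to ~100 % between 2 dB and 4 dB targets,
whereas animals show intermediate values), and simulated good pulse rates
cluster near 60 % for every target because the level noise is
target-independent by construction.

## Performance metrics

Good pulse rate = percentage of maintain-phase pulses classified in-range;
inertial cavitation probability = percentage of maintain-phase pulses whose
inertial level exceeds baseline by strictly more than 1 dB. Dummy and ramp
pulses are excluded from both denominators. Group summaries report mean and
sample (n−1) standard deviation per target; an SD over a single session is
reported as 0.

## Numerical choices and degenerate inputs

- Band sums accumulate sequentially over in-band bins so results do not
  depend on numpy's pairwise-summation blocking (the sums are also exactly
  reproducible by a loop oracle).
- Tolerance and threshold comparisons: the target band is closed
  (|Δ| ≤ 0.4 dB is in-range); the inertial event test is strict
  (> 1 dB). Boundary ties beyond these cases do not arise in floating
  point.
- `level_db` rejects non-positive inputs; a session whose dummy pulses
  produce non-positive band sums fails loudly rather than yielding −inf.
- A pulse at exactly 0 kPa emits nothing (the logistic tail is overridden);
  negative pressures are rejected.
- A pulse source failure mid-session finalizes the log with the recorded
  pulses and `status="source_error: ..."` instead of losing the session.

## Problem sizes used in validation

The validation suite runs most closed-loop scenarios on a reduced plant
scale — 10 MHz sampling, 1 ms pulses (10,000 samples, chosen so all
analysis frequencies stay on exact FFT bins), 20–90 s treatments — and the
reference experiment at full protocol scale: five subjects, target 2 dB,
40 MHz / 6.7 ms pulses, 120 s of post-dummy sonication (≈ 250 pulses and
≈ 750 FFTs of 268,000 samples per subject). The same full-scale experiment
is what `scripts/acceptance.py` recomputes.

## Known limitations

- The dB convention and baseline-averaging domain of the original
  acquisition chain are not documented; both are configurable and the
  defaults (20·log10, linear averaging) are stated assumptions.
- The plant's emission-versus-pressure law is not fitted to measured data;
  α, SNR and the onset parameters are stated model choices.
- Group seeds are derived as master+g, so different targets use different
  subject cohorts (as in the between-subjects in vivo design), not a
  repeated-measures design.
- The offline re-analysis path assumes the first k archive pulses are the
  dummy sonication (first-k convention) and that the archive's recorded
  pressures are the commanded ones.
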