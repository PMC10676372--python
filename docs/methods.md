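# Methods

This note documents the models, parameters and numerical choices behind
`sdlamina`, and what the synthetic testbed does and does not establish
about real recordings.

## Signal model and conventions

All times are seconds (double precision), voltages mV, positive polarity
graphed up.  Probe depths are µm below the pia, positive downward; channel
index increases with depth; the default geometry is 16 channels at
100–1600 µm with 100 µm spacing.  DC-coupled recordings carry the absolute
slow potential, so the −20 mV SD shifts are representable.

All band filters are 4th-order Butterworth sections applied
forward–backward (`sosfiltfilt`).  The zero-phase property is load-bearing:
SD onsets are read from derivative peak *times*, triggered averages and
Hilbert phases must not be skewed by filter delay.  Note that
forward–backward application squares the magnitude response, so the
effective roll-off is 8th-order.

## SD detection

SD′ is the negative-going derivative of the slow potential: the 1 Hz
lowpassed trace for laminar (rat-style) data, the 0.001–45 Hz bandpassed
trace for 200 Hz ECoG.  Onset candidates are local maxima of SD′ above
1 mV/s with a 120 s per-channel refractory period; candidates across
channels within 60 s are merged into one event; the stop depth is the
deepest channel whose SD′ peak exceeds 1 mV/s, and raising the threshold
can only shrink the invaded set (monotonicity).

Two localization details are this package's choices:

* a 5 s **edge guard** — zero-phase filtering has boundary transients, and
  derivative peaks within 5 s of the record edges are not trusted;
* in ECoG mode the central-difference derivative is smoothed with a 1 s
  moving average before peak picking.  At 200 Hz the derivative of in-band
  AC activity and noise otherwise exceeds 1 mV/s essentially everywhere
  (a 35 Hz component of 8 µV already differentiates to ~1.7 mV/s), while
  the SD fall lives below ~0.2 Hz and passes the smoother intact.

## Power classification

Power is estimated in 5 s sliding windows with a 1 s hop over 30 s epochs:
pre-SD at [−120, −90] s (ECoG) or [−40, −10] s (laminar) and SD at
[10, 40] s relative to the onset; the [0, 10] s gap keeps the DC-rise
spectral leakage out of the SD epoch.  ECoG windows use a Hann
periodogram; laminar windows a direct multitaper estimate with NW = 2.5
and K = 3 Slepian tapers (5 s × 0.5 Hz half-bandwidth; K pinned to 3
rather than 2NW−1).  The SD/pre ratio is the ratio of mean band powers and
the label comes from a two-sided Wilcoxon rank-sum test at α = 0.05
(exact method for untied samples of ≤ 25, normal approximation with tie
correction otherwise).

A calibration caveat: windows hopped by 1 s share 80% of their samples, so
the ~26 power values per epoch are strongly autocorrelated and the
rank-sum test is anticonservative on this windowing (measured null
rejection ~24% on white noise, ~13% on the delta-process simulations,
versus nominal 5%).  The classifier itself is correctly calibrated — fed
independent power samples its no-change rate is 95% ± 2% — and the huge
amplitude effects of real SDs dwarf the miscalibration, but marginal
labels on real data inherit it.  The windowing is kept as stated rather
than decorrelated, since it is part of the procedure being reproduced.

## CSD and generator decomposition

CSD is the second spatial difference of the FP divided by the squared
electrode spacing, smoothed across depth with a triangular (1, 2, 1)/4
kernel (edge-replicated so a depth-constant CSD is preserved), reported in
mV/µm² without conductivity scaling.  It nulls depth-linear fields exactly
and inverts planted dipoles to within numerical precision.

The generator decomposition models the laminar FP as u_m(t) = Σ V_mn
s_n(t).  Preprocessing subtracts a 0.6 s moving-average replica of each
channel (removing DC and infraslow content so the decomposition is driven
by delta and faster activity) and optionally excises stimulus epochs.  The
data are reduced to 5–6 principal components (capped at the effective
rank) and unmixed with FastICA; any non-Gaussianity-maximizing ICA is
acceptable here — the claim is the decomposition, not the estimator brand
— and plant-recovery tests are the arbiter.  Components carrying < 1% of
total variance are discarded; the reconstruction residual is bounded by
the discarded fraction.  ICA's sign/scale/permutation ambiguity is fixed
by storing unit-norm profiles whose largest-|weight| element is positive;
non-convergence triggers up to 3 re-runs with perturbed seeds.  Generator
power is the variance of s_n(t) under unit-norm profiles, compared between
two 40 s epochs placed outside ±5 s of any channel's onset (skipping the
high-frequency burst heralding the DC shift).

## Spiking and zones

The spike band is realized as a stationary db4 wavelet decomposition,
reconstructing the detail levels whose band centres fall in 250–4000 Hz.
The base threshold is 4 × STD of the quietest 100 s control fragment
(minimum-RMS 100 s window, 10 s hop).  During an SD the threshold becomes
4 × STD_hi(t) × [STD_band(ctrl)/STD_hi(ctrl)], with STD_hi the 10 s
sliding STD of the > 4 kHz reference band; at sampling rates ≤ 8 kHz the
reference band falls back to the top octave below Nyquist.  Spikes are
negative local minima below the threshold with 1 ms dead time; detections
at a stricter multiplier are a subset of those at a looser one.

MUA ratios use [−25, −10] s before the earliest onset versus [0, 15] s
after the deepest onset (1 s bins); burst duration uses a 100 ms-binned,
3-bin-smoothed rate against control mean + 3 STD.  The three-zone map
pools per-(SD, channel) δ-power, γ-power and MUA changes in 100 µm bins of
depth relative to the stop depth; per bin a signed-rank test on the log
ratios gives p-values, and labels are assigned by firing-based priority:
significant MUA decrease → depressed; significant MUA *and* γ increase →
sub-SD excited; otherwise unchanged.  (Delta changes are reported but do
not drive the label: volume-conducted delta from a spared deep generator
can rise in the deep zone even though local activity there is unchanged.)
Bins with fewer than 6 events are dropped — the exact two-sided
signed-rank cannot reach p ≤ 0.05 at n = 5.

Spike–gamma coupling takes phases from the analytic signal of the
30–150 Hz filtered LFP (phase 0 at the gamma peak, ±π at the trough) and
tests non-uniformity with the Rayleigh statistic using the standard
finite-n approximation; statistics are omitted below 10 spikes.

## Intracellular metrics

Recorded pipette potentials are corrected by subtracting the FP of the
probe channel nearest the cell (ties to the shallower channel), linearly
resampled onto the Em time base.  APs are 50 Hz-highpassed events above
5 mV with 2 ms dead time.  Slow metrics come from a < 0.2 Hz median
filter, implemented as block medians at 50 Hz followed by a 5 s rolling
median — ms-scale APs cannot leak through a block median.  Peak Em is the
filtered maximum in the SD window; the depolarization-block threshold is
the filtered Em at the last AP before a ≥ 5 s silence that begins while Em
is still rising (the threshold value is physiology; the silence rule is a
detector choice).  Sustained firing means APs span ≥ 80% of the SD window.
Bursts are runs whose instantaneous rate (1/ISI) stays ≥ 5 AP/s.

## The synthetic cortical column

The forward model generates what the analysis assumes, with every planted
quantity exposed as ground truth:

* **Delta generators.**  Four named generators — Main (polarity reversal
  at 300–400 µm, broad maximum over layers 4–5, gain 0.30 mV), L3 (gain
  0.18), L5/6 (deep maximum at ~1350 µm plus a 0.62-weight surface tail
  that realizes volume conduction, gain 0.18) and a flat extracortical
  Remote (gain 0.072) — drive negative-going UP/DOWN event trains (UP
  events 150–400 ms, quasi-periodic cycles of 0.40–0.64 s so the dominant
  power sits in the delta band).  Each generator gets a distinct base
  cycle; mutually incoherent sources make epoch powers additive, which
  keeps the power bookkeeping of the acceptance checks stable.  Each
  channel also carries a small independent local delta source (0.072 mV)
  and 30–150 Hz gamma noise; a superficial broadband "fast" source
  (8–45 Hz, gain 0.09) supplies the surface fast activity.  Sensor noise
  is white, 0.03 mV.
* **SDs.**  A plan specifies onset, stop depth, vertical speed (50 µm/s),
  amplitude (−20 mV), plateau (60 s) and a logistic fall with τ = 1.25 s,
  making the planted SD′ peak |A|/4τ = 4 mV/s.  Channels below the stop
  depth receive no shift.  A generator whose |profile|-mass median lies at
  or above the stop depth is silenced from the SD's arrival at its upper
  mass quartile until recovery; a spared deep delta generator is boosted
  ×1.6 in amplitude (×2.56 in power — the "roughly two-fold" deep-generator
  increase) while the SD lasts.  The isoguvacine configuration silences
  generators and spiking below 1000 µm outright.
* **Spiking.**  Inhomogeneous Poisson (thinning), base rate 8 Hz modulated
  by the locally dominant UP envelope; invaded channels burst ×4 for ~2 s
  at onset then fall to ×0.02; channels within 300 µm below the stop depth
  fire at ×3 with 60 Hz gamma modulation locked to a planted gamma LFP
  oscillation; deeper channels are untouched.
* **Wideband.**  Spikes are 1 ms biphasic templates on soft-clipped
  (bounded-tail) Gaussian noise — an amplifier-limited noise model chosen
  so that, at desk-scale record lengths, 4-STD crossings reflect planted
  events rather than Gaussian tail excursions; an SD can scale the noise
  STD to emulate the tissue-resistance rise that motivates the adaptive
  threshold.
* **ECoG.**  A surface-negative and a surface-positive delta source (50
  and 35 µV) plus the DC shift; depression suppresses both to 10%, boom
  suppresses the negative one and boosts the positive one ×2.2, no-change
  leaves both.
* **Intracellular.**  Rest −65 mV with 8 mV UP depolarizations; invaded
  cells ramp to −26 mV with APs ceasing at the planted −36 mV block
  threshold; cells ≤ 300 µm below the stop depth plateau at −47 mV with
  sustained gamma-locked firing; deeper cells shift ≤ 3 mV and keep
  half-amplitude UP states.  The recorded trace is Em + local FP, so the
  correction round-trip is exact at zero noise.

**What passing tests show — and don't.**  The testbed establishes that the
implementations recover what they are supposed to recover under the
model's assumptions: additive volume conduction with depth-fixed profiles,
stationary pre-SD statistics, bounded-tail wideband noise, steps-and-ramps
SD kinetics.  Real tissue has horizontally propagating SDs, drifting
electrodes, non-stationary anesthesia depth, spike waveform diversity and
heavy-tailed noise; none of those are modelled, so recovery rates here are
upper bounds, not field expectations.  Generator waveforms and SD recovery
kinetics are config-declared shapes, not biological claims.

## Problem sizes and determinism

The default batteries are desk-scale: 1 kHz LFP, 10 kHz wideband, 120–160 s
sessions, batches of 30–60 SDs, 1000-draw calibrations — the full
acceptance battery runs in a few minutes on one CPU.  All randomness flows
from `numpy.random.default_rng(seed)`; identical (config, seed) pairs give
byte-identical recordings, and the pipeline writes a rounded, key-sorted
summary JSON so end-to-end runs are hash-comparable.
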