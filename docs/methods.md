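# Methods

## Scope and model

`pilesound` computes the exposure metrics used to assess impulsive
pile-driving noise near offshore wind-farm construction — sound pressure
level (SPL), peak level (SPL_peak), single-strike sound exposure level
(SEL_ss), cumulative exposure (SEL_cum and its practical form SEL_cum,p)
and 1/3-octave band spectra — and the permutational statistics used to test
exposed-versus-control fish mortality. Because field recordings of this
kind are rarely redistributable, the package ships a synthetic-scene
generator whose ground truth is analytic; every pipeline stage is validated
against it.

All level metrics use the underwater reference pressure of 1 µPa and the
standard definitions: SPL is the time-mean-square level over an interval,
SPL_peak the level of the largest absolute instantaneous pressure, SEL the
level of the time integral of squared pressure (dB re 1 µPa²·s). SEL_cum is
the energy (decibel) sum of per-strike SEL values, which by construction
excludes the quiet time between strikes. The practical cumulative level

    SEL_cum,p = ⟨SEL_ss⟩ + 10·log₁₀(N)

is exact when all N strikes carry equal energy and is how exposure studies
extrapolate a cumulative dose from a mean per-strike level and a hammer
strike count.

## Calibration

A raw digital sample normalised to ±1 maps to pressure as
`p = raw × adc_fullscale_volts / (hydrophone_sensitivity × amplifier_gain)`.
Only the hydrophone sensitivity is usually known from a calibration sheet
(the default, 47.7 µV/Pa, is typical of a reference-grade measurement
hydrophone); amplifier gain and recorder full scale must be supplied by the
user. The defaults (unit gain, 1 V full scale) are documented placeholders:
relative structure is correct with them, absolute dB values are not
meaningful until the true chain is configured. WAV ingest accepts mono
PCM 8/16/24/32-bit and IEEE float; 24-bit samples arrive upshifted in
int32, so a single 2³¹ normalisation covers all integer widths. The
synthetic test path constructs `PressureSeries` directly in pascals and
does not depend on any calibration choice.

## Strike detection

Events are detected on an SPL time series: sliding windows of
`spl_window_s` advancing by `spl_hop_s`, each window's level computed from
its mean squared pressure (an O(n) cumulative-sum implementation).
A crossing is the first window start time at or above `threshold_db`
(default 170 dB re 1 µPa) occurring at least `min_gap_s` (default 0.50 s)
after the previous event's crossing; later super-threshold windows inside
the gap belong to the same strike. Each event spans `[t_cross − 0.20 s,
t_cross + 0.50 s)`, half-open, and events clipped by the file bounds are
kept and flagged `truncated` so event counts remain comparable with hammer
logs; their SEL integrates the available samples only.

The SPL window length is a package choice: 0.125 s with a 0.010 s hop is
short relative to the 1.4–1.5 s strike spacing of monopile hammering yet
long enough to average over many cycles of the dominant 125–200 Hz energy.
Both are configurable. Crossing times consequently lead the true strike
onset by up to one window length; the 0.20 s pre-window absorbs this.
Zero-energy windows carry a −∞ sentinel rather than raising, so silent
recordings analyse cleanly to zero events.

## 1/3-octave bands

Bands follow the base-10 definition, exact centers `1000·10^(n/10)` Hz with
edges at `center·10^(±1/20)`, labelled with the nominal preferred values
(25, 31.5, 40 … Hz). Edges are computed from the exact centers, so adjacent
bands tile the frequency axis exactly; a band's nominal label can differ
from its exact center by up to ~0.3 % (e.g. the "200 Hz" band spans
177.8–223.9 Hz). Band energies are rectangular sums of FFT periodogram bins
over the half-open `[lower, upper)` edge interval — exactly
Parseval-consistent with the broadband SEL, unlike a time-domain filter
bank — with DC/Nyquist bins weighted correctly for the one-sided transform.
Bands whose lower edge reaches Nyquist are dropped with a warning.
Averaging across events is done in the energy domain,
`10·log₁₀(mean 10^(L/10))`, the acoustics convention for mean spectra; the
dominant band is the maximum-level band with ties resolved to the lowest
center. Event spectra are integrated over the full 0.7 s event window.

## Synthetic scenes

A strike is a damped sinusoid `p(t) = A·e^(−t/τ)·sin(2πft)` over a 0.7 s
synthesis window, matching the event window so ≥ 99.9 % of strike energy is
captured by construction (with the default τ = 0.05 s the tail beyond the
window holds e⁻²⁸ of the energy). The amplitude A is solved in closed form
from the exponential-cosine integral so the continuous-time energy equals
the requested SEL_ss exactly; the discrete rendering agrees with the
analytic value to well under 0.05 dB at audio rates, and both are recorded
as ground truth. Scene defaults emulate measured monopile-driving
conditions at close range: 1.45 s mean spacing (0.05 s jitter), 183 dB
re 1 µPa²·s target SEL_ss (1 dB jitter), 160 Hz dominant frequency, ambient
white Gaussian noise at 136 dB re 1 µPa. The spectral rolloff of real
strikes above the dominant band is not modelled — a single damped sinusoid
is narrowband — so band-spectrum tests assert dominance, not spectral
shape. Real pile-driving recordings additionally contain propagation
multipath, slowly ramping hammer energy ("soft start") and non-Gaussian
ambient (vessel tones); passing tests therefore demonstrate correctness of
the metrics and detector logic under controlled conditions, not detector
robustness to every field artefact. All randomness flows from a mandatory
per-spec seed; equal specs render bit-identical scenes.

The mortality generator emulates the companion exposure experiment: four
experiments over two trips, exposed and control groups of six vials each,
20 fish/vial at 68 dph in trip 1 and 2 fish/vial at 115 dph in trip 2
(528 fish in total), a day-0 immediate assessment and a 14-day follow-up.
Deaths are per-fish Bernoulli draws with a group-specific daily hazard,
aggregated per vial and day; cumulative deaths are non-decreasing by
construction. Default hazards (0.007/day exposed, 0.0075/day control) give
14-day cumulative mortality of 9.4 % and 10.0 % — the magnitude reported
for 120-fish groups in this kind of experiment — and the group mean
converges to 1−(1−p)^d, which the tests verify at n = 10⁴ fish.

## PERMANOVA

The permutational ANOVA partitions the total sum of squared Euclidean
distances via the distance-based linear-model identity: with hat matrices
H_j of the cumulative design (intercept plus terms in entry order), the
sequential term sum of squares is the quadratic form of the projector
difference H_j − H_{j−1} applied to the (untransformed) response, term
degrees of freedom are rank increments, and

    pseudo-F_j = (SS_j / df_j) / (SS_res / df_res).

For a univariate response this reproduces classical sequential (type-I)
ANOVA exactly, which the tests verify against both `scipy.stats.f_oneway`
and statsmodels' `anova_lm(typ=1)`; scikit-bio's one-way PERMANOVA serves
as an additional independent oracle. Sequential decomposition was chosen
because the mortality designs name their factor order explicitly
(treatment, age, then days after exposure).

Significance uses unrestricted permutation of raw observations — the
simplest defensible scheme for balanced designs — with
`p = (#{F* ≥ F} + 1)/(n_perm + 1)`; designs with ≤ 8 observations can be
enumerated exactly. When the design admits few distinct permutations
(a warning fires below 20), the discrete permutation p is coarse, so a
continuous Monte-Carlo style p is also always reported: a Pearson type III
curve is moment-matched (mean, variance, skewness) to the permuted
pseudo-F values and its upper tail evaluated at the observed statistic.
This is an approximation to the proprietary construction used by the
PRIMER software, not a reimplementation of it; published p-values from that
software are therefore not comparison targets. A constant response yields
zero sums of squares and p = 1 by definition rather than a 0/0.

The immediate-mortality analysis unit is the vial (proportion dead per
vial at day 0), matching the experimental rationale for subdividing groups
into vials; the delayed analysis uses per-vial daily cumulative
proportions. Spearman correlation is the Pearson correlation of
average-tie ranks; R² is the squared Pearson correlation of an OLS fit.
Both are implemented directly and cross-checked against scipy in tests.

## Numerical choices and problem sizes

* Report tables carry full-precision dB plus an integer-rounded companion
  column (`round half away from zero`), matching how exposure tables are
  printed.
* Event intervals and band edges are half-open, so back-to-back segments
  share no sample and every periodogram bin lands in exactly one band.
* Detector fidelity is validated on batches of synthetic scenes drawn from
  the measured condition ranges (100–300 strikes, 1.39–1.49 s spacing,
  SEL_ss 181–188 dB, ambient 128–145 dB); batch sizes (20 scenes in the
  test suite, 6 in the acceptance script) keep a full run to tens of
  seconds while covering > 1000 strikes.
* Type-I error calibration uses 1000 null replicates with 199 permutations
  each; with 199 permutations the test is exact at α = 0.05
  (P(p ≤ 0.05) = 10/200).
* The 24-bit WAV round trip is asserted to the quantisation bound 2⁻²² of
  full scale.

## Known limitations

* Sound pressure only: particle motion, which all fish sense, is neither
  measured nor synthesized.
* No propagation modelling; scenes place the receiver at a fixed effective
  level rather than modelling range, spreading or sediment coupling.
* Single-channel audio; no resampling or lossy formats.
* The Monte-Carlo p-value is a moment-matched approximation; for designs
  with many distinct permutations the plain permutation p is preferable
  and is always reported alongside.
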