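# Methods

This note documents the models, conventions and numerical choices behind
`batarray`, in the order the processing chain applies them, and states what
the simulator does and does not emulate.

## Units, axes and conventions

All sample amplitudes are sound pressures in pascals; WAV files carry no
absolute-pressure convention, so the pascals-per-full-scale factor of each
channel is declared in the configuration, never embedded in the audio.
Channel 0 is the topmost microphone; microphone coordinates are metres along
the vertical array axis relative to the array midpoint (positive up). The
default geometry is four microphones spaced 1.30 m (3.90 m span). All times
are seconds from the start of the recording. dB sound-pressure levels are re
20 µPa; source levels are RMS re 20 µPa at a fixed 0.1 m reference distance,
the convention in bat bioacoustics.

Because the array is collinear, the acoustic inverse problem is rotationally
ambiguous about the axis: positions are reported in the half-plane
(perpendicular range r ≥ 0, axial coordinate z). This is a property of the
geometry, not of the solver.

## Calibration

Field microphones are equalized against a flat reference microphone by the
substitution method: both record the same played FM sweep, and the
reference-minus-target magnitude difference, estimated by Welch-averaged
periodograms (1024-point segments; grid spacing ≤ 500 Hz at ultrasonic
rates), is realized as a correction filter. Filters are designed by
frequency sampling with a raised-cosine (Hann) window, so they are exactly
linear phase; their group delay, (taps − 1)/2 samples, is removed on
application. Calibration is therefore timing-neutral: TDOAs are invariant
under it (verified to within one sample), so it may be applied before or
after localization with identical results. Correction gain is capped
(default +30 dB) because inverting a microphone's roll-off without bound
amplifies out-of-band noise; outside the measured band the response holds
the band-edge value rather than extrapolating.

## Noise profiling

Noise spectra are short-time power spectra averaged over all windows: Hann
window, 512-sample length, 256-sample overlap (the mean, not max-hold, of
the window spectra). Bin values are band power per bin, normalized so the
linear powers sum to the signal variance (Parseval with the window's noise
gain correction, delegated to `scipy.signal.welch`). External noise (e.g.
UAV rotors) is reported as per-bin dB excess over the blocked-microphone
system floor; silent bins are clamped at −180 dB to avoid −∞ propagation.

## Call detection and parameterization

The detection statistic is the magnitude envelope — band-limited (default
15–100 kHz, 4th-order zero-phase Butterworth), rectified, low-passed at
2 kHz — thresholded at the envelope's noise level plus 12 dB. For
multichannel data the envelope of each channel is normalized by its own
median (a robust noise estimate) and the maximum across channels is
thresholded, so a call is found whenever any microphone sees it, and the
detection bounds cover the earliest to latest arrival. Events separated by
less than 5 ms are merged; events shorter than 2 ms are discarded. These
defaults assume search-phase calls of vespertilionid bats; the terminal
phase of feeding buzzes (≥ 200 calls/s) would require a smaller merge gap.

Each call is then parameterized over its **95%-energy window**: the span
from the 2.5 % to the 97.5 % point of cumulative squared pressure within the
analysis window (the detection bounds padded by 20 %, extended across
channels by the array's maximum travel-time difference). The symmetric trim
is the common bioacoustic convention. Duration and RMS pressure are taken
over this window; by construction the window always holds 95 % ± 0.5 % of
the segment energy. Peak frequency is the maximum of the window's power
spectrum inside the analysis band, after smoothing over ~500 Hz to tame
FM-sweep ripple; minimum frequency is found by descending from the peak
toward 0 Hz until the spectrum falls more than 15 dB (configurable) below
the peak — a fixed-threshold low-edge criterion. Pulse intervals are
start-to-start spacings of consecutive 95%-energy windows on each call's
reference channel (the channel with the highest call RMS). Durations are
reported from the 95 % window, not the detection bounds.

## Localization

TDOAs are measured by standard cross-correlation of the band-limited
per-channel segments against the reference channel, with parabolic
interpolation around the integer-lag peak for sub-sample precision.
Phase-transform (GCC-PHAT) weighting was considered and rejected: for
high-SNR sweep signals it trades robustness for no accuracy gain. Delays
beyond the array's end-to-end travel time (plus a 0.5 ms guard) are
physically impossible and rejected; pairs whose normalized correlation peak
falls below 0.2 are dropped. Localization needs at least two usable delays
(two unknowns).

The (r, z) solver minimizes the squared misfit between measured and modelled
delays Δ_i = (d_i − d_ref)/c. For a collinear array the squared-distance
differences are *linear* in (d_ref, z), which gives a closed-form algebraic
starting point; it is refined by bounded (r ≥ 0) trust-region least squares.
When the algebraic start fails or fits poorly, a 5×5 multi-start grid over
r ∈ {1, 3, 5, 10, 20} m, z ∈ {−10, −5, 0, 5, 10} m guards against the local
minima of the hyperbolic objective near the axis. If two starts converge to
distinct minima with residuals within 1 %, the smaller-r solution is
preferred and the estimate is flagged ambiguous. Estimates beyond 30 m
(the practical localization range of arrays of this scale) are flagged
low-confidence rather than discarded. Emission time is the reference-channel
arrival time minus the modelled reference travel time d_ref/c. With exact
delays the solver recovers positions to < 1 cm over the whole working
volume; with 1 µs timing noise at 10 m range the median error is well under
1 m.

Sound speed is c = 331.3·√(1 + T/273.15) m/s; an optional first-order
moist-air correction (1 + 0.16·x_w, x_w the water-vapour molar fraction,
≈ +0.6 m/s at 20 °C/50 % RH) is off by default since the dry formula is
already within the accuracy of field temperature measurement.

## Propagation and source levels

Atmospheric absorption α(f), in dB/m, uses the standard humid-air closed
form — classical (viscous/thermal) attenuation plus the O₂ and N₂
vibrational relaxation terms with humidity- and pressure-dependent
relaxation frequencies. The implementation is validated against an
independent step-by-step transcription of the same closed form in the test
suite (e.g. α(40 kHz, 20 °C, 50 % RH, 101.325 kPa) = 1.3182 dB/m).

Transmission-loss compensation refers a received segment back to 0.1 m by
filtering with a linear-phase FIR of magnitude 10^(α(f)·(d − 0.1)/20) (group
delay removed) and multiplying by d/0.1. The compensation boost is capped at
+40 dB by default: at long range and high frequency an uncapped inverse
filter amplifies the noise floor into fictitious signal. Compensation is
applied to the analysis segment *first*; the 95%-energy window is then
recomputed on the compensated waveform, and the source level is
SL = 20·log₁₀(RMS/20 µPa) with an energy level E = SL + 10·log₁₀(duration).
Per-channel source levels are reported separately; the maximum across
channels serves as the on-axis proxy, since a directional emitter is
loudest on the microphone closest to its beam axis.

## Simulator

The simulator inverts the measurement chain: stylized single-harmonic FM
calls (linear-in-period sweep by default, raised-cosine onset/offset tapers
of 10 % each) are emitted along a trajectory — a straight 3-D line or
linearly interpolated (time, r, z) waypoints — and each call is, per
microphone: scaled by 0.1/d, filtered by the absorption loss over d − 0.1 m,
delayed by d/c with a 64th-order windowed-sinc fractional-delay
interpolator, and summed into the channel buffer with seeded white Gaussian
noise (and optionally spectrally shaped "drone" noise). One seed fixes all
randomness; identical scenarios are bit-identical.

Two synthesis conventions deserve emphasis, both chosen so that preset
parameters mean what a bioacoustician would measure:

* a preset's `duration_ms` is the **measured** (95%-energy-window) duration.
  A tapered call holds only ≈ 83 % of its physical length inside that
  window, so the synthesizer stretches the physical call accordingly
  (the factor is computed numerically from the taper shape);
* `source_level_db` is likewise RMS over the 95 % window at 0.1 m, matching
  the quantity the analysis chain reports.

The bundled `serotine_search` preset (55→25 kHz linear-period sweep, 15 ms,
150 ms interval, 130 dB) represents an *Eptesicus serotinus* search call;
the 25 kHz low edge and the duration/interval/level are the species-typical
search-phase values, while the 55 kHz upper bound is a stylized choice for
a downward FM sweep (the exact upper edge has little effect on any measured
parameter, since the sweep spends most of its energy near the low edge).
An optional approach model scales duration and interval linearly with range
inside a threshold (default 10 m, floor 0.3×), mimicking the qualitative
approach-phase pattern; it makes no claim to reproduce real attack
kinematics.

The reference verification scene is a straight pass from 20 m range to 2 m
and out again at 5 m/s, with the white noise floor set 30 dB below the
forward-modelled in-band received level of a call at 10 m — so calls inside
the 10-m source-level analysis range are received at ≥ 30 dB SNR. At this
scale the scene is ~8 s of 4-channel 375-kHz audio (~52 calls) and the full
chain runs in a few seconds.

What the simulator does **not** emulate: harmonics and beam directionality
(calls radiate omnidirectionally, so per-channel source levels differ only
by propagation), Doppler shift within a call, echoes/clutter, atmospheric
turbulence, real UAV rotor aeroacoustics, and multiple simultaneous bats.
Passing round-trip tests therefore demonstrates the correctness of the
processing chain under the stated physics, not detector robustness against
every confound of real field recordings.

## Degenerate inputs and tie-breaks

Zero-energy segments are rejected explicitly; an isolated impulse yields a
one-sample 95 % window. Silent spectra clamp at −180 dB. Clipped samples on
WAV export are counted and logged. Calls visible on fewer than two usable
channel pairs are flagged unlocalizable, and their source levels are not
reported. The minimum-frequency search never crosses below 0 Hz; if the
spectrum stays within 15 dB of the peak down to the band edge, the band
edge is reported.

## Known limitations

Detection thresholds are tuned for search-phase calls at ≥ 20 dB SNR;
overlapping calls (several bats, or buzz-phase rates) merge into single
detections. The 2-D half-plane output cannot separate left/right of the
array plane — by geometry, not implementation. Absorption compensation
trusts the localized distance; localization errors at long range propagate
into source levels at roughly 20·log₁₀ of the relative range error, which
is why source-level summaries are restricted to calls within 10 m.
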