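# Methods

## The generative model

`evokesim` samples epoched, multichannel electrophysiological-like signals.
Under no stimulation, each channel of each trial carries a single endogenous
oscillation whose instantaneous angular frequency `f_t` (radians/sample) and
amplitude `a_t` wander chaotically: both are AR(1) processes
`x_t = b x_{t-1} + e_t`, squashed into configurable closed ranges `rf` and
`ra`, after which the phase integrates the frequency (`phi_0 = 0`,
`phi_t = phi_{t-1} + f_t`) and the resting signal is
`x_t = a_t sin(phi_t) + eps_t` with Gaussian measurement noise. Channels are
sampled independently and are asymptotically uncorrelated; two consequences
worth knowing:

* because every trial starts at phase 0, trials are phase-aligned early in
  the epoch and decohere at a rate set by the spread of frequencies — tests
  of "no phase locking" must look past this transient;
* the squash map (a logistic centred at the AR mean, scaled by the process'
  stationary SD `sigma/sqrt(1-b^2)`) is smooth and monotone, so the
  constrained series has no clipping artefacts and the AR mean lands on the
  range midpoint. How the AR series is confined to its range is a modelling
  choice of this package; the innovation SDs are redundant with the squash
  scale and default to 1.

When a stimulus of condition *k* arrives at sample `tau`, each
stimulus-relevant channel responds per trial with probability `theta`
(non-relevant channels never respond). A responding channel combines up to
four effects, all timed by a response gate `g_t` in [0, 1]:

1. **Phase reset + entrainment.** Up to the gate peak the ongoing phase is
   pulled toward a per-trial target phase along the polar (shortest-arc)
   gradient, `phi_t = phi_{t-1} + (1-g_t) f_t + g_t grad_t`; the target is a
   von Mises draw around the condition's mean phase, reached exactly at the
   peak when the gate attains 1. Afterwards the oscillation entrains to a
   target frequency with decaying strength,
   `phi_t = phi_{t-1} + g_t f_k + (1-g_t) f_t`. The entrain update starts
   strictly *after* the peak — applying it already at the peak would prevent
   the reset from ever reaching the target exactly.
2. **Additive oscillation.** A damped sinusoid
   `y_t = g_t alpha_k sin(omega_k (t - tmax) + gamma_k)` superposed on the
   signal. The argument is anchored at the channel's gate peak `tmax`, so
   `gamma_k` is the oscillation's phase at maximal response. This anchoring
   is deliberate: the in-/anti-phase coupling between the oscillatory and the
   slow component is defined by the sign relation of their condition codes
   *at the response peak*, which only has consistent meaning across channels
   with heterogeneous frequencies and latencies if `gamma_k` is referenced to
   the peak (onset-referenced phases would put each channel at an arbitrary
   phase at its own peak).
3. **Amplitude modulation.** `a_t = (1 + g_t m_k) a_rest_t`: a proportional,
   gated increment of the ongoing amplitude (`m = 0.1` → +10% at the peak).
   Note this scales the *ongoing* oscillation; it carries condition
   information into a linear decoder only when that oscillation is
   phase-locked (e.g. by a phase reset). On its own it produces no
   cross-trial phase locking and no decodable signal.
4. **Additive slow response.** `z_t = g_t s_k`, with `s_k ~ N(zbar_k,
   sigma_z)` drawn once per trial and channel, usually timed by a much longer
   gate — the cross-frequency "slow" component whose condition difference
   drives late-trial decodability.

The composed signal is `x_t = a_t sin(phi_t) + z_t + y_t + eps_t`. Channels
that do not respond (or are not relevant) emit exactly their resting signal.

## The response gate

`G(t; tau)` is 0 before the latency `delta1 + tau`, rises over `delta2`
samples to exactly 1 at `tmax = delta1 + delta2 + tau`, falls back over
`delta3` samples and is 0 afterwards. Each side is a double-logarithmic curve
`1 - log(1 + (d / T_i)^zeta_i)` in the distance `d` from the peak; the scale
constants are solved analytically from the two boundary constraints per piece
(0 at the window edge, 1 at the peak): `T1 = delta2 / (e-1)^(1/zeta1)`,
`T2 = delta3 / (e-1)^(1/zeta2)`, with additive constants 1. Shape exponents
default to `zeta1 = 2`, `zeta2 = 4` (slower rise, sharper initial fall). A
faster-decaying Gaussian-kernel side is available (3-sigma over the window,
affinely renormalised onto [0, 1]).

Per-trial latency jitter adds `Uniform(0, sigma_delta1)` to `delta1`, either
one draw shared by all channels ("absolute") or independent draws per channel
("relative"); effective latencies are rounded to the sample grid. Durations
given in milliseconds convert through the sampling frequency (160 ms → 40
samples at 250 Hz).

## Decoding read-out

One LDA decoder per time point, on the raw channel values at that sample,
under stratified 10-fold cross-validation (the fold count and per-time-point
z-scoring, computed on training trials only, are this package's choices —
left open by the problem statement). Each decoder is tested at every time
point of the trial on the held-out trials; fold-averaged proportions correct
form the T × T temporal generalisation matrix (TGM). LDA uses the
least-squares solver with Ledoit–Wolf shrinkage of the shared covariance,
which stays well-conditioned with 32 channels and small per-fold counts.
Accuracy is proportion correct over two balanced classes, so chance is 0.5.

TGM features are operationalised as: the diagonal profile; `t_star`, the
earliest argmax of the diagonal; the "vertical slice" `accuracy[t_star, :]`;
`late_width`, the longest contiguous run of diagonal accuracy above
chance + 0.05 within the last 40% of the epoch (the broadening statistic —
the phenomenon is described qualitatively in the literature, the
operationalisation is ours); and `row_periodicity`, the largest normalised
non-DC spectral peak of the linearly detrended TGM rows, averaged over rows
(the "chequer" statistic).

The fitting sweep varies the gate's rise (`delta2`) and fall (`delta3`) over
a grid; per cell it generates several datasets, decodes them, averages the
TGMs and correlates (Pearson, over vectorised entries) against a reference
TGM supplied as a square CSV matrix. Cell failures are recorded per cell and
the sweep continues.

## Default study conditions

250 trials × 250 samples (1 s at 250 Hz) × 32 channels; ongoing angular
frequency range (0.01, 0.25π) rad/sample (0.4–10 Hz); amplitude range
(0.5, 1.5) signal units (unspecified upstream; chosen so the resting
oscillation has unit-scale amplitude); AR coefficients 0.99 for both
frequency and amplitude (slow, chaotic drift within a trial); measurement
noise SD 0.5 (moderate relative to the unit-scale oscillation). Effects:
activation probability 1/6 across all 32 relevant channels; effect
frequencies spread over 0.1–0.2 rad/sample (4–8 Hz) across channels;
latencies spread over 0–160 ms; conditions coded by oscillatory phases half a
cycle apart (±π/2) with von Mises spread 0.1; additive-oscillation amplitude
1.0; slow-response difference 0.5 (SD 0.1) with a slow gate rising over 10%
of the epoch and vanishing at 80%; fast gate rise/fall 15/22 samples (60/90
ms), matching the rise/fall the fitting sweep is designed to recover.

The diversity (regularity-contrast) design deviates in two documented ways:
its oscillatory gate spans ~70% of the epoch (several cycles — a chequer
cannot exist if the additive oscillation dies before completing one cycle)
and it has no slow response (a smooth component common to both arms would
dominate the row spectra and mask the contrast). The amplitude-modulation
design applies the modulation on a phase-reset effect, since only a
phase-locked ongoing oscillation turns an amplitude gain into decodable
signal gain (see above).

## Reduced-scale test conditions

The heavier end-to-end checks run at 100 trials × 125 samples × 16 channels
with activation probability 1/4 (raised from 1/6 to keep per-condition
information adequate at the smaller trial count), 10-fold CV, 5 seeds per
contrast arm; the shape-recovery sweep uses a 5×5 grid of
`delta2 ∈ {5..25}`, `delta3 ∈ {10..50}` samples with 3 runs per cell against
a 3-run reference at truth (15, 30). Latency spreads and the slow gate scale
proportionally with the epoch; the fast gate scales down with the epoch
(clipped below at 2 samples).

## Numerical choices, determinism, degenerate inputs

* One RNG stream per trial is split from the master seed
  (`numpy.random.SeedSequence.spawn`), with a fixed draw order (AR
  innovations, measurement noise, activations, per-effect latency jitter,
  target-phase deviation, slow levels), so datasets are bit-reproducible and
  resting values are unchanged by enabling effects elsewhere.
* The von Mises concentration is solved from the circular spread by matching
  the mean resultant length of a wrapped normal: `I1(k)/I0(k) =
  exp(-sigma^2/2)` via Brent's method; `sigma = 0` degenerates to a point
  mass.
* The polar gradient reduces differences modulo 2π into (−π, π], accepting
  unwrapped phases; phase series are stored unwrapped and only wrapped at
  comparison points.
* Degenerate ranges (`lower == upper`) yield a constant series with a
  warning; a zero-variance TGM makes correlation an explicit error; a flat
  TGM has periodicity 0 (power floor 1e-16) and its `t_star` ties break to
  the earliest sample.
* Config validation aggregates all invalid fields into one error message.

## What the simulations do and do not show

The generator emulates the statistical structure that time-resolved decoding
feeds on: condition-specific phase/amplitude/offset modifications, gated in
time, with probabilistic channel participation, frequency/latency diversity
and cross-frequency coupling. It does not emulate volume conduction or
sensor-space correlation (channels are uncorrelated "dipoles"; correlated
noise and mixing projections are out of scope), non-sinusoidal waveform
shape, coupled-oscillator interactions between channels, multiple endogenous
frequencies per channel, or any biophysics. Passing tests therefore show
that the decoding phenomenology (chequer patterns, broadening, coupling
signatures, amplitude scaling, shape recoverability) follows from these
signal-level mechanisms — not that real cortex implements them.

## Known limitations

* Two conditions are assumed wherever the in-/anti-phase channel coupling is
  used, and TGM decoding is implemented for exactly two balanced classes.
* The amplitude-modulation mechanism cannot, by construction, enhance
  decoding of an additive-oscillation code (it scales only the ongoing,
  non-coding oscillation).
* `late_width` and `row_periodicity` are simple, threshold-based statistics;
  they are meant for contrasts between configurations, not as calibrated
  estimators.
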