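# Methods

`ratefab` models how a behavioral rate code carried by inhibitory Purkinje
cell (PC) input is transmitted to a cerebellar nuclei (CN) neuron. It has
three layers: (1) fabrication of artificial spike trains (ASTs) that match
recorded spike-train statistics from manipulable rate templates, (2) the
statistical machinery used to validate them (CV, LV, spectra, event-aligned
PSTHs with shuffle/shift controls), and (3) a reduced conductance-based CN
neuron receiving 50 depressing inhibitory and 48 excitatory AST inputs.

## Rate templates

A template is the instantaneous rate R(t) on a 1 ms grid, built by
convolving each spike with a Gaussian. The default bandwidth is adaptive,
σ_i = mean of the 2k nearest ISIs (k = 3), so the kernel narrows where
firing is fast; a fixed-bandwidth mode exists. Kernels are truncated at the
record edges and renormalized per spike, making the template integral equal
the spike count (mass conservation, the invariant every template operation
preserves along with non-negativity).

Templates decompose multiplicatively into a slow component (Gaussian
smoothing, σ_slow = 100 ms by default — below the seconds-scale drift, above
spike-scale structure) and a dimensionless fast factor
`fast = template_norm / max(slow_norm, 1e-3)`; the floor bounds the division
in silent stretches. `fluctuation_gain` rescales the deviation of each
component from its mean and recombines them; on spectrally well-separated
inputs the slow-component SD scales exactly with the gain, on realistic
templates the two bands overlap at the 100 ms cut and the scaling is
approximate (~±10%), which the tests state explicitly.

## AST sampling

ASTs are inhomogeneous gamma renewal processes. The shape κ is set from the
target local variation via LV = 3/(2κ+1) (for gamma ISIs), so LV is an
input parameter while the CV emerges from LV plus the rate fluctuations.
Without refractory correction, sampling uses time rescaling: the cumulative
intensity Λ(t) advances by Gamma(κ, mean 1) increments — exact for constant
rate. With correction (default, t_ref = 1 ms), sampling is sequential: each
ISI is t_ref plus a gamma draw whose mean is max(1/R_local − t_ref, dt),
preserving the local mean rate and guaranteeing no ISI below t_ref. The dead
time slightly lowers the realized LV (≈0.27 for a 0.31 target at 65 Hz); an
optional re-calibration computes the LV of dead-time-shifted gamma ISIs by
generalized Gauss–Laguerre quadrature and inverts it for κ. It is off by
default in `SamplerConfig` and on inside the surrogate-recording generator,
whose contract is to hit the requested LV.

## Synthetic fixtures

No recorded data ship with the package; `io_fixtures` generates surrogates
with the statistical structure of the awake-mouse recordings the workflow
was designed around:

- PC-like: 64.9 Hz, LV 0.31, slow rate fluctuations (SD 10% of mean,
  correlation time 1 s) from a rectified AR(1) (single-pole low-passed
  Gaussian noise) — the simplest process with a controllable correlation
  time. MF-like: 20.4 Hz, LV 0.7. CN-like: 40 Hz, LV 0.5.
- Respiration: gamma renewal events at 3.9 Hz. The interval CV default
  (0.413) is chosen so the analytic gamma median equals 242 ms, matching
  both printed summary statistics of the rhythm (mean frequency and median
  interval); it is exposed as a parameter.

What the surrogates do not emulate: multimodal ISI structure, serial ISI
correlations beyond rate fluctuations, complex spikes, behavioral
non-stationarity beyond one AR(1) timescale. Tests passing on surrogates
therefore validate the algorithms' contracts, not any claim about new
recordings.

## Populations

All trains derive from one master template. Rate covariance is set by the
shift fraction SF: each train's template is (1−SF)·master + SF·(circularly
shifted master), on normalized rates, giving expected pairwise template
correlation (1−SF)²/((1−SF)²+SF²). Circular shifts preserve marginal
statistics exactly. Event-locked modulation is injected multiplicatively:
M(t) = Π_j [1 + BMS·(m(t−e_j) − 1)] with a unit-mean waveform m, product
composition for overlapping windows (kept multiplicative so rates stay
non-negative; exact for non-overlapping events), then rescaled to the
original mean rate. Exactly round(BMF·n) trains are modulated — the first
indices of a seeded shuffle, so BMF sweeps are nested.

The default waveform is a decaying cosinusoid at the 256 ms respiratory
period with an 11.4% trough at lag 0 — the shape a respiratory PSTH takes
under quasi-periodic breathing (side cycles decay as interval jitter
dephases the rhythm; envelope τ = 250 ms). A single raised-cosine bump is
also available. Both are normalized so the stated depth is exact relative
to the unit mean. Because the respiratory cycle (242 ms) is shorter than
the waveform support, injected troughs overlap; the realized PSTH depth of
a modulated population matches the nominal depth when measured against
shift-control baselines (verified by construction with non-overlapping
events, ±2 pp).

## Spike statistics

CV uses the n−1 sample SD of ISIs. LV = (1/(n−1)) Σ 3(T_i−T_{i+1})²/(T_i+T_{i+1})²
over successive ISI pairs: 0 for periodic, 1 for Poisson, 3/(2κ+1) for
gamma; insensitive to slow rate modulation, which is why CV > LV for
rate-modulated trains. Spectra are Welch periodograms (8 s Hann segments,
50% overlap) of 1 ms binned counts, with a multitaper option;
cross-correlograms are FFT correlations of binned counts.

## Event-aligned PSTH and significance

PSTHs are binned at 1 ms and smoothed with a boxcar (100 ms default; the
transmission analyses use 30 ms). Control bands come from 100 null PSTHs;
the default null circularly shifts the spike train by uniform offsets
(preserving both series' temporal statistics), with event-time shuffling as
an alternative. Because breathing is quasi-periodic, shift controls retain
re-aligned modulation at shifted phases and give conservative (wider) bands
than shuffles. Significance requires a run of ≥ 10 consecutive 1 ms bins
with |z| > 3 (both threshold and run length configurable; a 95th-percentile
mode exists). Null calibration on Poisson trains vs independent events
yields a false-positive rate ≲7% under the default rule. Modulation
amplitude is scored over the largest suprathreshold region as
∫(rate − control mean)dt in spikes per event (signed), plus the mean rate
increase in Hz and as % of the local control mean.

## Depressing PC→CN synapse

A deterministic one-state mean-field reduction of multi-site release:
between spikes the available fraction recovers as
a → 1 − (1−a)e^(−Δ/τ_rec); each spike's conductance weight is a, and
release then removes a fraction P_r. The periodic-input fixed point is
a* = (1−e^(−Δ/τ))/(1−(1−P_r)e^(−Δ/τ)); a gamma-input simulation mode is the
cross-check (they agree within 2%). "Steady-state depression" is reported
as 100×(1−mean weight), i.e. 60% depressed means weight 0.4 (the opposite
reading would report 40%; the convention is a documented choice and the
calibration targets are stated under it).

(P_r, τ_rec) are calibrated by relative least squares to three macroscopic
constraints: 60% depression at 75 Hz, and the unitary-conductance
adjustments 16 → 27.52 nS at half and 16 → 9.84 nS at double the 64.86 Hz
reference rate that keep rate × weight × G constant. The two-parameter
model cannot co-satisfy all three: its steady-state weight falls too
steeply with rate (the ratio w(r/2)/w(r) is ≥ ~1.3 for any parameters
producing ≥50% depression at 75 Hz, versus ~1.16 implied by the
conductance constraints). The fit lands at P_r = 0.0285, τ_rec = 500 ms
(the upper recovery bound), giving 51.4% at 75 Hz, 24.3 nS at half rate and
11.9 nS at double rate; residuals are returned by `calibrate_depression`
and the double-rate constraint is the one left unmet. A rate-dependent
release probability would fix this but is outside the one-state model.

Conductances are unit-peak dual exponentials (GABA: 0.5/14 ms, E = −70 mV;
AMPA: 0.3/3 ms; NMDA: 5/70 ms with 1 mM Jahr–Stevens Mg block), each spike
scaled by its depression weight.

## Reduced CN neuron

The CN neuron is a spiking point model: fast-spiking Na/K-dr kinetics, leak,
a tonic depolarizing drive (30 pA → 16.5 Hz spontaneous firing, regular, at
zero synaptic input), and a spike-triggered Ca pool (increment 0.75, decay
80 ms) activating SK (Hill-4, half-activation 3.5, g_SK = 12 nS default).
The SK parameters were set so the f-I curve (1 s equilibration, 1 s
measurement) is near-linear over the 10–100 Hz range (r² ≈ 0.985): the
non-saturating SK feedback cancels the type-I onset curvature. The SK scan
axis is a multiplier on g_SK, linearly mapping the 0–8 relative density
range of the original scan onto 0–48 nS.

A point neuron has no dendritic attenuation, so each synapse class carries a
somatic-efficacy factor (w_in = 0.055, w_ex = 0.35) mapping unitary
dendritic conductances onto effective somatic ones. They were calibrated
once so the standard operating points reproduce the recorded CN range:
G_in = 16 nS with G_ex = 3.5 nS gives ~20 Hz (fluctuation-driven: the mean
conductances alone produce 0 Hz) and with G_ex = 6 nS gives ~50 Hz. With
500 PC inputs, g_in is divided by 10 to match the mean conductance.

Integration is exponential-Euler at dt = 0.025 ms (halving dt changes spike
counts by <2%); synaptic waveforms are exact single-pole IIR filters of the
weighted spike impulse sequences; runs are deterministic given seed and
inputs. Spikes are upward 0 mV crossings.

What the reduction does and does not claim: directional and ordering
properties (LV < CV; rate monotone in G_in; CV higher for covarying inputs
at high G_in; PSTH score linear in BMS with BMF-dependent slope; inversion
and amplification of the inhibitory modulation, stronger at low rates; SK
dampening rate, CV and transmission; fewer spikes with 500 weak inputs than
50 strong ones) are asserted and reproduced. Quantities tied to the full
morphology (absolute rate surfaces, the size of the 500-input rate
collapse) are not. The measured amplification at the low-rate operating
point (~40–48% output peak from an 11.4% input trough) happens to sit in
the range reported for the full model, but the tests only assert the
inequalities.

## Problem sizes

The test suite uses 115-s records (the native record length of the
workflow) for all statistical recovery and detection-power checks — LV
recovery, respiratory-transmission significance, amplification and phase —
and 20-s simulations over ≥3–5 seeds for the directional CN-model checks;
the BMS-linearity sweep uses 60-s records with 2 seeds per grid point.
Null calibration uses 200 independent 120-s Poisson runs. The full suite
runs in ~3 minutes on one CPU.

## Known limitations

- The refractory correction preserves local mean rate but not the exact
  gamma ISI law; its LV bias is corrected only when re-calibration is on.
- Shift-control bands are conservative for strongly periodic behaviors.
- The depression model's rate dependence is steeper than the calibration
  targets jointly imply (see above); residuals quantify the compromise.
- The point CN model underestimates the contribution of fast conductance
  fluctuations relative to shared slow rate fluctuations, so input-count
  effects are directional rather than quantitative.
- Event windows wrap circularly at record edges (events within half a
  window of the edges borrow mass from the opposite end); with ≥100 events
  this is negligible.
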