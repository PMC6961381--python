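# Methods

## Model overview

The microcircuit contains one cell of each type. The CA1 pyramidal cell
(PC) has three compartments — soma (30 × 30 μm cylinder), apical
dendrite (400 × 3.2 μm), and a dendritic spine (1 × 1 μm) attached
100 μm from the soma through a 100 MΩ neck resistance. PV, SST and IN
are single-compartment models. Membrane capacitance is 1 μF/cm² and
axial resistivity 150 Ω·cm everywhere; axial conductances between
compartments follow the cylinder half-resistance rule, except the spine,
which couples through the fixed neck resistance (the 100 μm attachment
point is recorded as model metadata rather than resolved as extra cable
segments).

Channel kinetics are standard published hippocampal formulations,
identified by the `gating_scheme` field so they can be swapped:

| channel | scheme | source of the functional form |
| --- | --- | --- |
| Na, KDR | `rtm` | Traub–Miles rates as used in reduced PING models (Ermentrout & Kopell) |
| KA | `bg_a` | Borg-Graham-style sigmoidal activation/inactivation (τ 2 / 30 ms) |
| CaL | `hva_l` | high-voltage-activated, s² activation, E_Ca = +120 mV |
| KM | `yamada_m` | Yamada–Koch–Adams muscarinic K⁺ |
| AHP | `ca_ahp` | Ca-gated, α ∝ [Ca]², τ up to ~250 ms |
| H | `sigmoid_h` | sigmoidal activation (V½ = −80 mV), E_h = −30 mV |

Reversal potentials: E_Na = +55, E_K = −90, E_Ca = +120, E_h = −30 mV;
the leak reversal is a per-cell parameter.

## Reference parameter set

The cell geometries, conductance densities, synaptic weights and
plasticity constants in `config.DEFAULT_CONFIG` are this package's
reference parameter set. They were calibrated jointly so that the
default circuit satisfies, at the fixed experimental drive
(15 pA step + 20 pA, 5 Hz sine; Gaussian current noise σ = 50 pA at
10 kHz), all of:

1. the resting PC shows ~5 mV peak-to-peak subthreshold fluctuations
   under σ = 50 pA noise, with negligible spontaneous firing;
2. the PC fires a short gamma-frequency spike burst on every theta
   cycle of the drive;
3. PV has the fast-spiking (steeper, faster) f–I curve and SST the
   lower-gain curve, with PV > SST at every matched suprathreshold
   step; SST also fires at small currents where PV is silent, as
   low-threshold-spiking cells do;
4. with SST present the pairing protocol drives spine calcium beyond
   4 μM and potentiates the weight; with SST removed (all else equal,
   including the noise realizations of the remaining cells) calcium
   stays below threshold and the weight remains exactly 1.

These constraints interact strongly. In particular, the noise target
pins the PC's R/C ratio: with σ fixed at 50 pA, peak-to-peak voltage
noise scales as √(R²·Δ/τ_m), so the model PC is a relatively slow
(τ_m ≈ 15 ms, R_in ≈ 190 MΩ) cell resting ~3 mV below threshold
(rheobase ≈ 14 pA). A faster or more excitable cell either fires
spontaneously under the mandated noise or overshoots the fluctuation
band.

Two deliberate wiring choices where the underlying biology is
under-determined:

* **SST afferent and tonic activity.** SST receives a PC→SST excitatory
  synapse and, in addition, its leak reversal is set slightly
  depolarized (−54 mV) so it fires tonically at ~25–35 Hz. The tonic
  component is required by the timing of the protocol: CA3 events arrive
  on the *rising* phase of theta, ~100–150 ms after the previous
  cycle's burst, and an inhibitory conductance decaying with
  τ = 40 ms would otherwise have vanished by then. A tonically active
  SST cell keeps the feedforward interneuron under sustained
  inhibition across the whole cycle, which is also consistent with the
  spontaneous activity of low-threshold-spiking SST cells in slices.
* **Feedforward gating is passive.** The apical dendrite carries only a
  small Na conductance, so the backpropagating spike invades the spine
  decrementally. This is what lets the IN shunt on the proximal
  dendrite gate spine calcium: a strongly regenerative dendrite would
  propagate the spike regardless of inhibition and the disinhibition
  logic would disappear.

## Synapses and plasticity

Receptor models follow the standard forms: single-exponential AMPA
(τ = 7 ms), peak-normalized double-exponential conductances for
everything else (τ_rise 3 ms; τ_decay 15 ms excitatory / 40 ms
inhibitory; NMDA 4/21 ms), and the sigmoidal Mg block
B(V) = 1/(1 + ([Mg]/3.57 mM)·e^(−0.062V)) with [Mg] = 0.5 mM. The
printed source formulas for the NMDA voltage dependence and the
difference-of-exponentials sign are typographically inconsistent; the
conventional positive, peak-normalized forms are implemented. The
CA3→spine AMPA conductance defaults to 0.4 nS, which gives a ~2.6 mV
somatic EPSP at rest — conductances quoted in pS for this synapse are
taken to mean nS, since a 0.3 pS synapse would produce a ~20 nV EPSP.

Spine calcium is a single first-order pool:

d[Ca]/dt = γ·(f_NMDA·I_NMDA,Ca + I_CaL) − ([Ca] − [Ca]₀)/τ_Ca

with the NMDA calcium component computed against the calcium reversal
(+120 mV) so influx persists above the net-current reversal, f_NMDA =
0.1, τ_Ca = 20 ms, baseline 0.05 μM. The gain γ is derived from an
effective spine volume (0.5 μm³) and an endogenous buffer capacity
(110): γ = 1/(2F·V·(1+κ)) ≈ 0.09 μM per pA·ms. Volume and buffer
capacity are lumped calibration constants, not measurements.

The potentiation detector and weight readout are two deterministic
ODEs:

dP/dt = k_p·[Ca > θ_p]·(1 − P) − P/τ_p,
dW/dt = k_w·P·(w_max − W)

with θ_p = 4 μM, k_p = 0.5 /ms, τ_p = 50 ms, k_w = 0.0025 /ms,
w_max = 2. Both are advanced with exact exponential updates (the W step
uses the closed-form integral of P over the step), so the discrete
update is independent of step size wherever threshold crossings align
with step boundaries, W is non-decreasing and bounded by w_max, and W
stays exactly 1 if calcium never crosses θ_p. There is no depression
pathway: the rule models potentiation only. W multiplies the CA3→CA1
AMPA conductance at event delivery.

## Numerical integration

Gating variables advance by exponential (exact linear) updates at the
current voltage, which keeps them in [0, 1] unconditionally. Voltages
advance by a backward-Euler step with channel and synaptic conductances
frozen over the step; the resulting linear system across all coupled
compartments is solved exactly each step (Gaussian elimination with
partial pivoting on the ≤ 8-compartment matrix), which is what makes
the very stiff spine-neck coupling unconditionally stable. The internal
step defaults to 25 μs; outputs are emitted at 0.1 ms (10 kHz)
regardless of the internal step. Noise is drawn per output step (so its
statistics are independent of the internal step) and held across
substeps; each cell role has a fixed, independent noise stream keyed by
`(seed, role)`, so deleting one cell never perturbs the noise of the
others — the with/without-SST comparison differs *only* in the SST
pathway.

Integration failure (non-finite or |V| > 200 mV) raises an error
carrying the failure time. Spikes are upward crossings of 0 mV at the
soma with a 2 ms refractory period.

Accuracy: halving the internal step changes subthreshold trajectories
by well under 0.5 mV (sup-norm) and leaves spike counts unchanged, with
early spike times agreeing to < 0.2 ms and every interspike interval to
< 3 %. Absolute spike times late in a long tonic train are *not* a
stable convergence measure: with any fixed-step scheme of this order
the timing error accumulates roughly linearly along the train
(~0.4 ms per spike at 25 μs here), which is why the convergence tests
assert counts, early-spike times and ISIs rather than late absolute
times.

## Stimulation protocols

The theta drive is I(t) = 15 + 20·sin(2πt/200 ms) pA into the PC soma.
The pairing schedule is anchored by a noise-free calibration run of the
same network without CA3 input: the first PC spike of each theta cycle
is predicted, and one CA3 event is placed 10 ms before it, five times
at 5 Hz starting at the third cycle (a spikeless calibration cycle is a
protocol error). The events fall on the rising phase of theta (before
the cycle peak). Repetition runs use consecutive seeds; summaries
report peak spine calcium, final weight, and per-cell firing rates.

## What "gamma entrainment by PV" means here

Under this drive the PC's free-running burst rate already lies in the
20–120 Hz band — the oscillatory drive itself mimics gamma-frequency
spiking, and a single-cell model cannot fire faster than its
noise-constrained membrane allows. The causal contribution of the
PV→PC edge is therefore *pacing*: PV spikes follow each PC spike at a
fixed short lag, and their IPSPs delay the next PC spike toward the
period set by the 40 ms inhibitory decay. Removing the edge shortens
the median gamma-band ISI and increases the burst spike count, seed by
seed; PV's own rate and its gamma-phase locking to PC spikes are
unchanged by the presence or absence of the SST pathway. These two
contrasts are the package's formalization of "PV generates gamma
entrainment" and "SST does not affect it", and are what the property
tests assert.

## Analysis conventions

* Phase is measured in degrees in [−180, 180) with 0° at the waveform
  peak — the Hilbert analytic-signal angle has this property for any
  narrowband signal, so no extra shift is applied.
* Band-pass filters are 4th-order Butterworth applied forward-backward
  (zero phase); gamma defaults to 20–120 Hz, theta to 3–8 Hz.
* Welch spectra use Hann windows of 1 s with 50 % overlap; spectral
  peak ties resolve to the lowest frequency. Spectrograms use a 100 ms
  window and 1 ms step.
* The comodulogram bins theta phase into 20 bins of 18°; the
  modulation index uses 18 bins of 20°. Both bin counts are exposed as
  parameters; the defaults deliberately differ because the two source
  procedures specify different binnings. The comodulogram discards two
  slowest-theta periods at each trace edge, where filtfilt/Hilbert
  transients would otherwise bleed into the bins.
* MI = KL(P‖uniform)/log N with P the per-bin mean gamma amplitude
  normalized by its sum, with the 0·log 0 = 0 convention: MI = 0 for
  phase-independent amplitude, 1 when all amplitude falls in one bin,
  and MI is invariant under amplitude rescaling.
* The Watson–Williams test uses the standard F statistic with the
  1 + 3/(8κ̂) correction, κ̂ estimated from the pooled within-group
  resultant by the usual three-regime approximation. Its type-I error
  at α = 0.05 is verified by Monte Carlo to lie in [0.03, 0.07] for
  κ = 2, n = 30 per group.
* PV spike phases relative to the PC gamma rhythm treat each PC
  interspike interval as one gamma cycle with the PC spikes at the
  trough (±180°), consistent with the zero-at-peak convention.
* Intracellular metrics: R_in = (V₀ − V_steady)/I with I the commanded
  step magnitude; membrane τ by least-squares fit of
  V = V_steady + A·e^(−t/τ); EPSP slope by least-squares line between
  the 20 % and 80 % amplitude crossings (located by linear
  interpolation between samples); train amplitudes correct for overlap
  by extrapolating the pre-event value with the decay constant;
  charge integrates baseline-subtracted current with the baseline
  taken from the 5 ms before the window; stimulus–response curves use
  monotone (PCHIP) interpolation and report the first upward crossing
  of half-maximum.

## Synthetic-data generators

The generators replace the study's raw recordings with signals whose
ground truth is known exactly. The theta-gamma generator amplitude-
modulates a gamma sinusoid with a raised cosine of theta phase —
the simplest family whose zero-coupling member is *exactly* uncoupled
(so the MI null is a true zero, not a small number) and whose MI grows
strictly with the coupling-depth parameter. Phase-locked spike fixtures
are von Mises draws; PSC trains superpose peak-normalized
biexponentials with programmed per-event amplitudes (analytic total
charge: Σ aₖ·norm·(τ_d − τ_r)); passive steps follow
V = V_rest − IR(1 − e^(−t/τ)). Every generator is deterministic per
seed and returns its parameters and derived quantities as metadata.

What these fixtures do *not* emulate: 1/f background, measurement
filtering, electrode artefacts, non-stationary rhythms, correlated
noise, or multi-unit superposition. Passing the analysis tests
therefore shows the estimators recover known structure from clean
signals at the study's sampling rates, not that they are robust to all
features of experimental data.

## Sizes and runtimes

Default problem sizes were chosen to keep a full run comfortably
interactive on one CPU: pairing simulations are 1.7 s of biological
time at a 25 μs internal step, spectral and noise characterizations use
10 s runs, Monte-Carlo suites use 100–2000 replicates, and the
synthetic MI null uses a 60 s, 1 kHz signal. The complete test suite
runs in well under a minute after the JIT kernel compiles; the
acceptance script takes ~10 s.

## Known limitations

* One cell per type: no population averaging, no heterogeneity, and the
  "LFP" proxy is the PC somatic voltage (the model has no extracellular
  biophysics).
* Table-level parameters (geometry, densities, plasticity constants)
  are calibrated stand-ins that reproduce the circuit's qualitative
  regime and the calibrated quantitative targets; they are not fits to
  the original cell-by-cell data.
* The potentiation rule is threshold-deterministic; stochastic receptor
  gating, desensitization and depression are out of scope.
* Synaptic delays are a uniform 1 ms; noise is injected at the soma of
  every cell (a PC-only switch exists in the protocol options).
* The spike-time drift discussed under *Numerical integration* means
  long simulations should be compared through rates, ISIs and phase
  statistics, not absolute late spike times.
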