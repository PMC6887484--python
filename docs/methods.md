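# Methods

Conventions: time in ms, voltage in mV, conductance in nS, current in
pA, rates in spikes/s, positions in mm on the skin surface with the
receptive-field center at the origin.  Default integration step
`dt = 0.05 ms`.

## Ornstein–Uhlenbeck synaptic conductances

Synaptic bombardment is modeled as two independent OU conductance
processes (excitatory and inhibitory) with stationary mean `g0`,
stationary SD `sigma` and correlation time `tau`:

```
dg = (g0 - g) / tau dt + sqrt(2 / tau) sigma dW
```

The generator uses the **exact discretization**

```
g[n+1] = g0 + (g[n] - g0) a + sigma sqrt(1 - a^2) xi[n],   a = exp(-dt/tau)
```

which has the exact stationary law N(g0, sigma²) at every step and is
unconditionally stable (implemented as an AR(1) filter via
`scipy.signal.lfilter`).  An Euler–Maruyama variant (`method="euler"`)
serves as an independent cross-check at small `dt`.  Negative samples
are rectified to zero by default, matching a conductance's physical
domain.  Default kinetics: `tau = 3 ms` (excitatory), `10 ms`
(inhibitory); protocols use `sigma = g0 / 3`.

The synaptic current at voltage `V` is
`I = g_exc (V - E_exc) + g_inh (V - E_inh)` with `E_exc = 0 mV` and
`E_inh` in {−70 mV (normal chloride), −45 mV (dysregulated)}.

## Neuron models

Each cell is a three-variable conductance-based model (voltage `V`,
delayed-rectifier activation `w`, A-type inactivation `b`):

```
C dV/dt = -gL (V - EL) - gNa m_inf(V) (V - ENa) - gK w (V - EK)
          - gA a_inf(V) b (V - EK) - g_tonic (V - E_tonic) - I_syn + I_app
dw/dt   = phi_w (w_inf(V) - w) / tau_w(V)
db/dt   = (b_inf(V) - b) / tau_b
```

with Boltzmann steady states `x_inf(V) = 1/2 [1 + tanh((V - beta_x)/gamma_x)]`
and `tau_w(V) = 1 / cosh((V - beta_w)/(2 gamma_w))`.  Fast sodium
activation is instantaneous (`m_inf`).  `g_tonic` is a standing
(extrasynaptic) inhibitory conductance whose reversal `E_tonic` tracks
the chloride condition.

Integration uses **Heun's method** (explicit trapezoidal, second
order) in a numba-compiled loop; OU conductances are realized per
sample and converted to current from the instantaneous voltage (the
dynamic-clamp loop).  Spikes are upward crossings of −10 mV with a 1 ms
dead time.  At the default `dt = 0.05 ms`, halving the step leaves
suprarheobase spike counts of all canonical models unchanged.

Three canonical parameter sets (`canonical.yaml`) reproduce the
standard step-response phenotypes:

- `inhibitory_tonic` — tonic firing throughout a 500 ms suprarheobase
  step; carries `g_tonic > 0` (tonically inhibited).
- `excitatory_delayed` — first-spike latency > 100 ms at 1.1× rheobase
  (A-current mediated); no tonic conductance.
- `excitatory_single` — a single spike at every suprarheobase
  amplitude.

Classification protocol: rheobase by bisection (1 pA tolerance) on
500 ms steps, then steps at 1.1/1.5/2× rheobase; `single` = one spike
at every amplitude; `delayed` = latency > 100 ms; `tonic` = spikes into
the final 100 ms at every amplitude.  These canonical parameters were
derived by calibration against the phenotype definitions and then
frozen.

## Receptive-field model

A unit's spatial receptive field is the sum of three radial Gaussian
components: narrow excitation (`A_En`, `w_En`), broad excitation
(`A_Eb`, `w_Eb`) and inhibition (`A_I`, `w_I`) with `w_I > w_En`.  The
net drive at position `p` is

```
r(p) = max(E_n(p) + E_b(p) - kappa * I(p) - theta, 0)
```

where `kappa` scales inhibitory efficacy (1 at baseline, 0 when fully
disinhibited) and `theta` is the firing threshold.  Surround inhibition
masks the broad excitatory skirt at baseline; lowering `kappa` unmasks
it, expanding the firing field.  The **center** zone is where the unit
fires at baseline; the **surround** is the annulus recruited by
disinhibition.  Zone areas and mean drives are computed by grid
integration (0.1 mm resolution; validated against the radial closed
form to < 2%).

Tactile stimuli map to OU drive parameters: the excitatory mean
conductance is proportional to the summed excitatory tuning at the
stimulus position, the inhibitory mean to the summed inhibitory tuning
times `INH_DRIVE_GAIN = 1.2` (the inhibitory driving force near rest is
an order of magnitude smaller than the excitatory one, so equal
conductances would make the surround ineffective).  Brush and von Frey
filaments differ by a force scaling (`BRUSH_FORCE_SCALE = 0.6`; vF
forces 2–10 g).  Conditions act through `E_inh` (−70 baseline/glycine
block, −45 KCC2 block/BDNF, −65 BDNF+acetazolamide) and an
inhibitory-conductance factor (glycine block 0.25).  All of these
mapping constants were derived by calibration against the qualitative
direction checks and then frozen; none is adjusted at run time.

## Protocols

- **i-o curves**: excitatory mean conductance grid 1–6 nS,
  `g_inh0 = alpha * g_exc0` with `alpha` in {0.5, 2}, `sigma = g0/3`,
  20 trials of 5 s per grid point (first 500 ms discarded).  The
  model's tonic conductance is folded into the inhibitory OU channel.
  Spontaneous rate comes from a tonic-input-only trial set.  Slope and
  intercept by least squares.
- **co-stimulation**: 10 repetitions of 1 s center-alone vs
  center+mid-surround brush; ratio = costim rate / center rate.
- **RF mapping**: brush responses on a spatial grid per condition; vF
  force series at center and mid-surround.
- **GABA I-V**: voltage-clamp puff responses
  `I = g (V_hold - E_Cl) + noise` over a hold grid; `E_Cl` recovered by
  linear regression (reversal-potential estimation); chloride-extrusion
  capacity = shift in recovered `E_Cl` under transporter challenge.

## Spike-train analysis

- **Evoked rate**: stimulus-window rate minus the preceding baseline
  rate.
- **Adaptation**: the empirical CDF of pooled stimulus-aligned spike
  times is fitted with the truncated exponential CDF
  `(1 - exp(-t/tau)) / (1 - exp(-T/tau))` over `tau` in [1, 10⁴] ms.
  `tau <= 300 ms` → adapting, `tau >= 600 ms` → non-adapting, between →
  unclassified (an exclusion gap).
- **Connectivity**: cross-correlogram of spinal spikes around each
  afferent spike (±50 ms, 1 ms bins).  The causal peak count is tested
  against an exact binomial null whose rate is the negative-lag
  baseline regularized with one pseudocount; a connection is flagged
  when the tail probability falls below the 4-SD normal tail
  (≈3.2×10⁻⁵).  On constructed data this achieves ≥ 90% sensitivity at
  < 5% false positives on independent (non-co-modulated) pairs.
  Stimulus co-modulation produces genuine correlations; dataset-level
  false-positive counts are therefore reported as informative, not as
  an error rate (see FORMATS.md).

## Synthetic recordings

A dataset is a timeline of condition epochs, each containing blocks of
10 × (1 s on / 1 s off) stimuli per zone, preceded by quiet stretches.
Two backends generate unit spikes:

- **rate** (default): inhomogeneous Poisson — spontaneous rate per
  condition plus an evoked rate proportional to the RF net drive,
  thinned by `exp(-t/tau)` for adapting units.  Condition effects:
  chloride dysregulation zeroes inhibitory efficacy and adds 8 spk/s of
  spontaneous firing to tonically inhibited (non-adapting) units;
  acetazolamide mostly restores both; glycine block halves inhibitory
  amplitude only.
- **mechanistic**: full conductance-model simulation of every stimulus
  window and tonic-only gap via the stimulus-to-drive mapping.

RA afferents fire 200 spk/s bursts for 30 ms at stimulus onset and
offset; SA afferents fire 50 spk/s throughout.  Connected afferents
transmit each spike with probability 0.3 at 3 ms latency (0.3 ms
jitter) into the target unit's train.

All randomness descends from one master seed through
`numpy.random.SeedSequence` spawning, making datasets, protocols and
the acceptance script bit-reproducible.
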