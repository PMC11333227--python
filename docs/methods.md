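# Methods

## The model and its assumptions

spikefix simulates networks of leaky integrate-and-fire neurons on a
synchronous 1 ms clock with forward-Euler integration, the discretization
used by the SIMD-style datapath the package emulates.  The assumptions
baked into the step loop are:

* **Synchronous phases with one-step axonal delay.**  Each step runs, in
  order: decay of conductances and traces (and the undersampled θ decay
  when due), spike delivery, the layer-2 soma update (excitatory + output
  neurons), the layer-3 soma update (inhibitory neurons), postsynaptic
  plasticity and θ increments, recording.  A spike emitted by an internal
  neuron at step *t* reaches its targets at *t + 1*; externally injected
  input spikes act on the step they arrive.  Input-layer neurons are pure
  relays with no soma dynamics.
* **Single-step conductances.**  With `τ_ex = τ_ih = 1 ms` equal to the
  clock period, the Euler decay removes the whole conductance each step,
  so a delivered spike acts as a one-step current impulse.  This is kept
  (rather than switching to the exact-exponential operator, which is also
  implemented) because the emulated system declares the Euler method.
* **Current-based effect of conductances.**  `I = |k|·g_ex − |k|·g_ih`
  with the synaptic potential difference magnitude `|k| = 58 mV`:
  excitation depolarizes, inhibition hyperpolarizes.  (The sign convention
  is chosen so the winner-take-all circuit functions; the single printed
  constant would otherwise make excitatory input hyperpolarizing.)
* **Pair-based trace STDP.**  Traces apply per individual spike, not to
  rate averages.  When a pre and a post spike coincide in one step, the
  presynaptic update is applied first (deterministic tie-break), so a
  zero-lag pairing potentiates.
* **Learning-phase gating.**  STDP, θ increments and θ decay run only
  during training.  At test time the learned weights *and* the learned θ
  are retained and frozen; retaining θ preserves the excitability
  differences that homeostasis established.  Whether STDP stays enabled
  during the silent 150 ms pause is inert either way — no spikes occur,
  traces simply decay.

## The fixed-point number system

All state lives in signed integers of configurable width with saturating
arithmetic (never wrap-around) and round-to-nearest, ties away from zero,
applied once per multiply/divide.  Scales per quantity:

| quantity | scale (fixed16) | rationale |
|---|---|---|
| voltages (V, θ, I) | 10 μV / LSB | resolves the 0.01 mV θ increment (= 1 unit) inside a ±327.67 mV range |
| weights, conductances | 1.0 → 2^10 units | 144-synapse weight sums (≤ `W_norm` = 20) stay within 16 bits |
| STDP traces | 1.0 → 2^15 units | see below |

Per-mode defaults: `fixed8` uses 1 mV/LSB, weight 2^6, trace 2^9 (the
±127-unit range cannot hold −65 mV at 10 μV/LSB); `fixed32` uses 10 μV/LSB
with weight 2^20 and trace 2^25; `float` replaces every rounding and
saturation with exact real arithmetic and is the reference the quantized
modes are measured against.

**Quantization deadbands.**  The integer Euler decay `x ← x − round(x·dt/τ)`
is exactly zero once `|x| ≤ τ/(2·dt)` units.  Two consequences matter:

* *Traces*: at the weight scale the 0.01 trace increment is ~10 units and
  τ = 20 ms gives a deadband at 9 units — traces would freeze at ~90 % of
  the increment forever, and because subtractive normalization conserves
  total weight, the resulting spurious potentiation of rarely-active
  inputs drains weight away from the informative pixels and destroys
  learning.  This is why traces carry their own 2^15 scale: the deadband
  (9 units ≈ 3·10⁻⁴) drops two orders of magnitude below the increment,
  and a single extra rounding maps a trace onto the weight grid when it
  is applied.
* *Membrane*: with τ_m = 100 ms the soma deadband is 50 units = 0.5 mV, so
  under constant drive the quantized trajectory stalls up to 0.5 mV short
  of the real asymptote.  This is inherent to the 16-bit operating point
  and is left in place; the float mode, not the real-valued closed form,
  is therefore the reference for trajectory-level checks, while the
  fixed-point path is verified bit-exactly against an independent scalar
  simulator and per-step against the ≤ 0.5 LSB rounding bound.

A further 16-bit effect worth knowing: the synaptic current saturates at
32767 units = 327.67 mV, and the Euler division by τ_m caps any
single-step depolarization at ~3.3 mV.  No single spike can move a neuron
from rest across the 13 mV threshold gap in 16-bit mode — firing requires
temporal summation — whereas float mode has no such ceiling.  The strong
excitatory→inhibitory weight (17.5·w_max) therefore triggers the
inhibitory partner after a short burst rather than a single spike.

## Parameters

Soma: `V_th = −52 mV`, `V_rest = −65 mV`, `|k| = 58 mV`, `τ_m = 100 ms`,
R = 1 (dimensionless; its effect is absorbed into `|k|` and the weight
scales, and it is omitted from the reference constant set).  Synapse:
`τ_ex = τ_ih = 1 ms`, `τ_pre = τ_post = 20 ms`, `Δa_pre = +0.01`,
`Δa_post = −0.01`, `w_max = 1`, `W_norm = 20`.  Homeostasis:
`Δθ = 0.01 mV`, `τ_hom = 10^6 ms`, `t_spa_samp = 10 s`.  `dt = 1 ms`.
All are overridable through the key-value run configuration
(`RunConfig.from_dict` / YAML), and every experiment result embeds the
full resolved parameter echo.

Choices the reference constant set leaves open, fixed here as package
defaults:

* **Input rate for full intensity** — the pixel-intensity→rate constant is
  not public; the default 63.75 Hz for intensity 255 follows the
  unsupervised digit-classifier lineage this architecture descends from.
  All rate-dependent results are therefore qualitative, and the constant
  is a prominent config knob (`max_rate_hz`).
* **Static circuit weights** — excitatory→inhibitory (17.5·w_max) and
  inhibitory→excitatory (1.0·w_max) are only qualitatively constrained
  ("strong", "balanced"); the defaults make the inhibitory partner fire
  after a short excitatory burst without silencing the rest of the layer,
  and both are config knobs (`exc_inh`, `inh_exc`).
* **Initial plastic weights** — Uniform(0, w_max), seeded: competition
  needs symmetry breaking, and the first normalization pins the sums
  regardless.
* **Poisson generation** — per-step Bernoulli with p = rate·dt (p ≤ 0.2 at
  the defaults), a seeded PRNG standing in for the hardware noise source.
* **Prediction rule** — argmax of output-neuron spike counts over the
  350 ms window; ties resolve to the lowest class index, and an
  all-silent output layer is recorded as class 0 with a no-response flag.
* **θ decay scheduling** — uses global simulation time continuing across
  presentations, since the 10 s sampling interval spans many digits.
* **Excitatory in-degree** — the builder follows the literal connection
  rules (144 pixels + 1 teacher + 99 lateral = 244 afferents); the
  hardware description quotes 245 for the most-connected neuron, a
  one-connection discrepancy we do not reproduce.
* **Memory accounting** — the 1024×32-bit per-PE RAM calculator defaults
  to storing the 5-word parameter block for plastic synapses only (static
  synapses resolve from the connection map); with that policy the densest
  PE of the 10-class network uses 744 words ≈ 73 % of capacity.  The
  policy is a parameter, since a full-parameter allocation for a
  244-afferent neuron would not fit one RAM.

## The synthetic data generator

`synth_digits` emulates the downscaled handwritten-digit task: 12×12
grayscale images, intensities 0–255, built from ten fixed stroke
prototypes (rings, bars, brackets, diagonals at class-specific anchors;
each covers 15–30 % of the pixels, pairwise overlap < 40 % of the smaller
mask) plus i.i.d. Gaussian pixel noise truncated to [0, 255].  It
reproduces the *structure* of the task — sparse bright strokes on a dark
background, class-specific pixel correlations, balanced labels — but not
the within-class shape variability, stroke-thickness variation or
antialiased edges of real handwriting.  Passing the desk-scale tests
therefore demonstrates that the learning machinery (STDP + normalization +
homeostasis + teacher) separates noisy fixed prototypes; accuracy numbers
on it do not transfer to MNIST, for which the full-scale replication
script exists.

## Problem sizes used by the test suite

The desk-scale protocol is a 3-class task with groups of 10 (30
excitatory + 30 inhibitory neurons, 210 total), 600 training
presentations (1 epoch), 150 test samples, noise σ = 25, on seeds 1–3 —
small enough that the whole precision study (fixed8/fixed16/float × 3
seeds) trains nine networks in minutes, large enough that 16-bit accuracy
exceeds 90 % with no silent presentations.  Engine/oracle equivalence
uses 20 random 10-neuron networks × 1000 steps; the soma closed-form and
homeostasis checks run 10,000–25,000 scalar steps.

## Known limitations

* Bit-exact agreement with any particular hardware is not claimed: the
  physical datapath's rounding and overflow behaviour are not documented,
  and round-to-nearest/saturation were chosen here for bounded bias and
  stability.
* fixed8 is faithful to its width but nearly inert: the θ increment
  rounds to zero at 1 mV/LSB and trace resolution is marginal, so 8-bit
  learning collapses — consistent with the qualitative finding that 8-bit
  resolution underperforms, but not a calibrated model of any specific
  8-bit implementation.
* The simulator is clock-driven and sequential over steps; it reproduces
  event ordering, not timing or energy, of the emulated hardware.
* The interconnect, instruction set, multi-chip routing and monitoring
  hardware of the emulated platform are out of scope; the memory model is
  a capacity calculator only.
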