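"""Neuron and synapse update rules: LIF soma, conductance synapses,
trace-based STDP with clipping, subtractive weight normalization, and
adaptive-threshold homeostasis.

The rules here are the scalar, single-neuron form of the model — the
readable reference used by the unit tests and by small hand-built circuits.
The simulation engine applies the same rules vectorized over whole layers;
the two paths are held bit-identical by the engine's oracle-equivalence
tests.

Model summary (1 ms clock, forward Euler):

* Soma:  ``τ_m dV/dt = −(V − V_rest) + R·I``; on ``V ≥ V_th + θ`` the neuron
  fires and V resets to ``V_rest``.
* Current:  ``I = |k|·g_ex − |k|·g_ih`` where ``k`` is the synaptic potential
  difference (58 mV magnitude); conductances decay with 1 ms time constants,
  so at the default clock each delivered spike acts for exactly one step.
* STDP: presynaptic and postsynaptic activity traces ``a_pre``/``a_post``
  decay with 20 ms constants; a pre spike adds ``+Δa_pre`` to its trace and
  moves the weight by the current ``a_post`` (depression); a post spike adds
  ``Δa_post`` (negative) to its trace and moves the weight by the current
  ``a_pre`` (potentiation).  Weights clip to ``[0, w_max]``.
* Normalization: after each training pattern the plastic in-weights of every
  excitatory neuron are shifted by a common offset so their sum returns to
  ``W_norm`` (subtractive scaling; generates synaptic competition).
* Homeostasis: the effective threshold is ``V_th + θ``; each spike adds Δθ,
  and θ decays multiplicatively by ``e^(−t_samp/τ_hom)`` only at widely
  spaced sampling instants (10 s), since at the hardware resolution the
  per-millisecond decay of a 1000 s time constant is invisible.

All state is stored in integer units of a :class:`~spikefix.fixedpoint.FixedSpec`
(or plain floats in float mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .fixedpoint import FixedSpec, decay_step, sat_add, sat_mul_frac, saturate

# ---------------------------------------------------------------------------
# Parameter sets (defaults are the emulated system's operating point)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LIFParams:
    """Soma parameters.  Voltages in mV, times in ms."""

    v_th: float = -52.0
    v_rest: float = -65.0
    tau_m: float = 100.0
    r_mem: float = 1.0          # absorbed into k_mag / weight scales
    k_mag: float = 58.0         # |synaptic potential difference|
    tau_ex: float = 1.0
    tau_ih: float = 1.0
    dt: float = 1.0
    decay_method: str = "euler"

    def __post_init__(self):
        if min(self.tau_m, self.tau_ex, self.tau_ih, self.dt) <= 0:
            raise ValueError("time constants and dt must be positive")
        if self.v_th <= self.v_rest:
            raise ValueError("v_th must exceed v_rest")


@dataclass(frozen=True)
class STDPParams:
    """Pair-based trace STDP and subtractive normalization parameters."""

    tau_pre: float = 20.0
    tau_post: float = 20.0
    d_apre: float = 0.01
    d_apost: float = -0.01
    w_max: float = 1.0
    w_norm: float = 20.0
    n_stdp: int = 144

    def __post_init__(self):
        if self.tau_pre <= 0 or self.tau_post <= 0:
            raise ValueError("trace time constants must be positive")
        if self.w_max <= 0 or self.n_stdp < 1:
            raise ValueError("w_max must be positive and n_stdp >= 1")


@dataclass(frozen=True)
class HomeostasisParams:
    """Adaptive-threshold parameters; d_theta in mV, times in ms."""

    d_theta: float = 0.01
    tau_hom: float = 1e6
    t_spa_samp: float = 10_000.0

    def __post_init__(self):
        if min(self.d_theta, self.tau_hom, self.t_spa_samp) <= 0:
            raise ValueError("homeostasis parameters must be positive")

    @property
    def decay_factor(self) -> float:
        """Multiplicative θ decay applied at each sampling instant."""
        return math.exp(-self.t_spa_samp / self.tau_hom)


# ---------------------------------------------------------------------------
# State containers (values live in FixedSpec units)
# ---------------------------------------------------------------------------


@dataclass
class NeuronState:
    """Per-neuron state in quantized units."""

    v: float
    g_ex: float = 0
    g_ih: float = 0
    theta: float = 0
    homeostasis_on: bool = False
    fired: bool = False

    @classmethod
    def resting(cls, p: LIFParams, spec: FixedSpec,
                homeostasis_on: bool = False) -> "NeuronState":
        z = 0.0 if spec.is_float else 0
        return cls(v=spec.to_v_units(p.v_rest), g_ex=z, g_ih=z, theta=z,
                   homeostasis_on=homeostasis_on)


@dataclass
class SynapseState:
    """Per-synapse state: weight plus the two activity traces."""

    pre_id: int
    post_id: int
    w: float
    a_pre: float = 0
    a_post: float = 0
    plastic: bool = False
    sign: str = "excitatory"     # or "inhibitory"

    def __post_init__(self):
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"bad synapse sign {self.sign!r}")
        if self.plastic and self.sign != "excitatory":
            raise ValueError("plastic synapses are excitatory")


# ---------------------------------------------------------------------------
# Soma
# ---------------------------------------------------------------------------


def synaptic_current(g_ex, g_ih, p: LIFParams, spec: FixedSpec):
    """Total input current in voltage units: ``|k|·g_ex − |k|·g_ih``.

    Conductances are in weight units; one multiply maps them through the
    synaptic potential difference onto the voltage grid with a single
    rounding.
    """
    k_u = spec.to_v_units(p.k_mag)
    return sat_mul_frac(g_ex - g_ih, k_u, spec.weight_scale, spec)


def effective_threshold(state: NeuronState, p: LIFParams, spec: FixedSpec):
    """Adaptive firing threshold ``V_th + θ`` in voltage units."""
    return sat_add(spec.to_v_units(p.v_th), state.theta, spec)


def lif_step(state: NeuronState, i_syn, p: LIFParams,
             spec: FixedSpec) -> NeuronState:
    """One Euler step of the soma, then threshold test and reset.

    ``v ← v + (dt/τ_m)·(−(v − v_rest) + R·I)``; if the updated potential
    reaches the (possibly adapted) threshold the neuron fires and resets to
    ``v_rest``.  The drive term is accumulated exactly and rounded once.
    """
    v_rest_u = spec.to_v_units(p.v_rest)
    drive = (v_rest_u - state.v) + p.r_mem * i_syn
    if not spec.is_float:
        drive = int(drive)
    num, den = int(round(p.dt * 1000)), int(round(p.tau_m * 1000))
    v = sat_add(state.v, sat_mul_frac(drive, num, den, spec), spec)
    thr = effective_threshold(state, p, spec)
    if v >= thr:
        return replace(state, v=v_rest_u, fired=True)
    return replace(state, v=v, fired=False)


def decay_conductances(state: NeuronState, p: LIFParams,
                       spec: FixedSpec) -> NeuronState:
    """Exponential decay of both synaptic conductances (τ_ex, τ_ih)."""
    return replace(
        state,
        g_ex=decay_step(state.g_ex, p.tau_ex, p.dt, spec, p.decay_method),
        g_ih=decay_step(state.g_ih, p.tau_ih, p.dt, spec, p.decay_method),
    )


def inject_spike(state: NeuronState, syn: SynapseState,
                 spec: FixedSpec) -> NeuronState:
    """Deliver one presynaptic spike: add |w| onto the matching conductance."""
    if syn.sign == "excitatory":
        return replace(state, g_ex=sat_add(state.g_ex, syn.w, spec))
    return replace(state, g_ih=sat_add(state.g_ih, abs(syn.w), spec))


# ---------------------------------------------------------------------------
# STDP
# ---------------------------------------------------------------------------


def decay_traces(syn: SynapseState, p: STDPParams, spec: FixedSpec,
                 dt: float = 1.0, method: str = "euler") -> SynapseState:
    """Exponential decay of both activity traces (τ_pre, τ_post)."""
    return replace(
        syn,
        a_pre=decay_step(syn.a_pre, p.tau_pre, dt, spec, method),
        a_post=decay_step(syn.a_post, p.tau_post, dt, spec, method),
    )


def _clip_w(w, p: STDPParams, spec: FixedSpec):
    hi = spec.to_w_units(p.w_max)
    return min(max(w, 0), hi)


def trace_to_w(a, spec: FixedSpec):
    """Rescale a trace value onto the weight grid (one rounding).

    Traces live on a finer grid than weights (``trace_scale`` vs
    ``weight_scale``); applying a trace to a weight divides out the ratio.
    """
    return sat_mul_frac(a, spec.weight_scale, spec.trace_scale, spec)


def stdp_on_pre(syn: SynapseState, p: STDPParams,
                spec: FixedSpec) -> SynapseState:
    """Presynaptic spike: bump a_pre, depress w by the post trace."""
    if not syn.plastic:
        return syn
    a_pre = sat_add(syn.a_pre, spec.to_trace_units(p.d_apre), spec)
    w = _clip_w(sat_add(syn.w, trace_to_w(syn.a_post, spec), spec), p, spec)
    return replace(syn, a_pre=a_pre, w=w)


def stdp_on_post(syn: SynapseState, p: STDPParams,
                 spec: FixedSpec) -> SynapseState:
    """Postsynaptic spike: bump a_post, potentiate w by the pre trace."""
    if not syn.plastic:
        return syn
    a_post = sat_add(syn.a_post, spec.to_trace_units(p.d_apost), spec)
    w = _clip_w(sat_add(syn.w, trace_to_w(syn.a_pre, spec), spec), p, spec)
    return replace(syn, a_post=a_post, w=w)


def normalize_weights(weights, p: STDPParams, spec: FixedSpec):
    """Subtractive normalization of one neuron's plastic in-weights.

    ``fac_w = (W_norm − Σw_i)/N_stdp``; every weight is shifted by the same
    ``fac_w`` and clipped to ``[0, w_max]``.  When nothing clips, the sum
    returns exactly to ``W_norm`` in real arithmetic (to within N·0.5 LSB in
    fixed point, one rounding on the shared factor).
    """
    weights = list(weights)
    if len(weights) == 0:
        raise ValueError("cannot normalize an empty weight vector")
    n = len(weights)
    w_norm_u = spec.to_w_units(p.w_norm)
    total = sum(weights)
    if spec.is_float:
        fac = (w_norm_u - total) / n
    else:
        fac = sat_mul_frac(int(w_norm_u - total), 1, n, spec)
    return [_clip_w(sat_add(w, fac, spec), p, spec) for w in weights]


# ---------------------------------------------------------------------------
# Homeostasis
# ---------------------------------------------------------------------------


def threshold_adapt(state: NeuronState, h: HomeostasisParams, p: LIFParams,
                    spec: FixedSpec):
    """Effective threshold V_th + θ (θ is zero whenever homeostasis is off)."""
    return effective_threshold(state, p, spec)


def theta_on_spike(state: NeuronState, h: HomeostasisParams,
                   spec: FixedSpec) -> NeuronState:
    """Raise the adaptation magnitude by Δθ after a spike."""
    if not state.homeostasis_on:
        return state
    return replace(state,
                   theta=sat_add(state.theta, spec.to_v_units(h.d_theta),
                                 spec))


def theta_decay(state: NeuronState, h: HomeostasisParams, t_ms: float,
                spec: FixedSpec) -> NeuronState:
    """Undersampled multiplicative θ decay.

    Applied only when the global time is a positive multiple of the sampling
    interval ``t_spa_samp``; the decay factor over one interval is
    ``e^(−t_spa_samp/τ_hom)``.
    """
    if not state.homeostasis_on:
        return state
    if t_ms <= 0 or (t_ms % h.t_spa_samp) != 0:
        return state
    f = h.decay_factor
    if spec.is_float:
        return replace(state, theta=state.theta * f)
    from .fixedpoint import _round_half_away
    return replace(state,
                   theta=saturate(_round_half_away(state.theta * f), spec))
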