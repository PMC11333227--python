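"""Synchronous simulation engine.

Runs the clock-driven (1 ms) loop over virtual layers: input relays in
layer 1, excitatory and output neurons in layer 2, inhibitory neurons in
layer 3.  Within every step the phases are, in order:

1. decay conductances and plasticity traces; apply the undersampled
   homeostatic θ decay when the global time is a multiple of the sampling
   interval (training only);
2. deliver this step's external input spikes together with the *previous*
   step's internal spikes: conductance injection with the current weights,
   then (training only) the presynaptic STDP update on plastic synapses;
3. layer-2 soma update (excitatory + output neurons, adaptive threshold);
4. layer-3 soma update (inhibitory neurons);
5. (training only) postsynaptic STDP and θ increments for neurons that
   fired this step;
6. record spikes and monitored membrane potentials.

Internal spikes therefore become visible to their targets one step after
they occur (one-step axonal delay); external input spikes act on the step
they arrive.  Input-layer neurons relay external spikes without soma
dynamics.  In ``test`` mode every plastic weight, trace increment and θ is
frozen; learned values are retained and the adaptive threshold still uses
the learned θ.

The engine is vectorized over whole layers but implements exactly the
scalar rules of :mod:`spikefix.dynamics`; in the quantized modes its event
logs are bit-identical to a scalar reference simulator (enforced by test).
All engine arithmetic is int64 in the fixed modes (saturated to the spec's
width after every operation) and float64 in float mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig
from .encoding import SpikePlan, poisson_encode
from .fixedpoint import FixedSpec, _as_frac
from .network import LayerSpec, Netlist

# ---------------------------------------------------------------------------
# Configuration and logs
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Simulation-level settings wrapped around a resolved RunConfig."""

    run: RunConfig = field(default_factory=RunConfig)
    mode: str = "train"
    seed: int = 0
    record_membrane: Optional[Sequence[int]] = None  # default: output layer

    def __post_init__(self):
        if self.mode not in ("train", "test"):
            raise ValueError("mode must be 'train' or 'test'")


class SpikeEventLog:
    """Ordered (step, neuron_id) spike records (address-event style)."""

    def __init__(self):
        self._steps: list[int] = []
        self._ids: list[int] = []

    def extend(self, step: int, ids: np.ndarray) -> None:
        self._steps.extend([step] * len(ids))
        self._ids.extend(int(i) for i in ids)

    @property
    def steps(self) -> np.ndarray:
        return np.asarray(self._steps, dtype=np.int64)

    @property
    def ids(self) -> np.ndarray:
        return np.asarray(self._ids, dtype=np.int64)

    def __len__(self) -> int:
        return len(self._ids)

    def counts(self, ids: Sequence[int],
               t_max: Optional[int] = None) -> np.ndarray:
        """Spike count of each requested neuron id (optionally before t_max)."""
        steps, nids = self.steps, self.ids
        if t_max is not None:
            keep = steps < t_max
            nids = nids[keep]
        return np.array([int(np.sum(nids == i)) for i in ids])

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.steps, self.ids]),
                   fmt="%d", delimiter=",", header="step,neuron_id",
                   comments="")


class TraceLog:
    """Per-step membrane potential (and θ) of the monitored neurons."""

    def __init__(self, ids: Sequence[int]):
        self.ids = list(ids)
        self._v: list[np.ndarray] = []
        self._theta: list[np.ndarray] = []

    def append(self, v: np.ndarray, theta: np.ndarray) -> None:
        self._v.append(v.copy())
        self._theta.append(theta.copy())

    @property
    def v(self) -> np.ndarray:
        return np.asarray(self._v)

    @property
    def theta(self) -> np.ndarray:
        return np.asarray(self._theta)

    def to_csv(self, path) -> None:
        head = ",".join([f"v_{i}" for i in self.ids]
                        + [f"theta_{i}" for i in self.ids])
        np.savetxt(path, np.hstack([self.v, self.theta]), delimiter=",",
                   header="step-major; " + head, comments="# ")


# ---------------------------------------------------------------------------
# Saturating vectorized arithmetic
# ---------------------------------------------------------------------------


class _FixedOps:
    """Vectorized int64 arithmetic with round-half-away and saturation."""

    def __init__(self, spec: FixedSpec):
        self.qmin, self.qmax = spec.qmin, spec.qmax

    def sat(self, x):
        return np.clip(x, self.qmin, self.qmax)

    def rdiv(self, x, den: int):
        # round(x/den) to nearest, ties away from zero; den > 0
        return np.sign(x) * ((2 * np.abs(x) + den) // (2 * den))

    def mul_frac(self, x, num: int, den: int):
        return self.sat(self.rdiv(x * num, den))

    def decay(self, x, num: int, den: int):
        # Euler: x - round(x*num/den); num <= den
        return self.sat(x - self.rdiv(x * num, den))

    def scale_round(self, x, f: float):
        y = x * f
        return self.sat(np.sign(y) * np.floor(np.abs(y) + 0.5)).astype(
            np.int64)


class _FloatOps:
    """Real arithmetic; rounding and saturation are identities."""

    def sat(self, x):
        return x

    def rdiv(self, x, den):
        return x / den

    def mul_frac(self, x, num, den):
        return x * num / den

    def decay(self, x, num, den):
        return x * (1.0 - num / den)

    def scale_round(self, x, f):
        return x * f


# ---------------------------------------------------------------------------
# Network compilation
# ---------------------------------------------------------------------------


class CompiledNetwork:
    """Structure-of-arrays form of a (layers, netlist) pair.

    Static synapses become dense per-sign weight matrices; plastic synapses
    become a (pre × post) weight matrix plus boolean mask (plastic weights
    live in :class:`NetworkState`, since they learn).  Activity traces are
    stored per neuron: every plastic synapse sharing a presynaptic neuron
    sees the same ``a_pre`` (identical increments and decays), and likewise
    for ``a_post``, so the factored form is exact.
    """

    def __init__(self, layers: Sequence[LayerSpec], net: Netlist):
        self.layers = list(layers)
        self.netlist = net
        n = net.n_neurons
        self.n = n

        declared = sum(l.size for l in layers)
        if declared != n:
            raise ValueError(
                f"layer sizes sum to {declared} but netlist declares {n}")

        self.layer_ids: dict[str, np.ndarray] = {}
        vl: dict[int, list[int]] = {1: [], 2: [], 3: []}
        start = 0
        for spec in layers:
            ids = np.arange(start, start + spec.size)
            self.layer_ids.setdefault(spec.name, np.empty(0, dtype=int))
            self.layer_ids[spec.name] = np.concatenate(
                [self.layer_ids[spec.name], ids])
            vl[spec.virtual_layer].extend(ids.tolist())
            start += spec.size
        self.relay_ids = np.asarray(vl[1], dtype=int)
        self.internal_ids = np.asarray(sorted(vl[2] + vl[3]), dtype=int)
        self.homeo_mask = np.zeros(n, dtype=bool)
        self.homeo_mask[self.layer_ids.get(
            "excitatory", np.empty(0, dtype=int)).astype(int)] = True
        self.output_ids = self.layer_ids.get(
            "output", np.empty(0, dtype=int)).astype(int)

        relay_set = set(self.relay_ids.tolist())
        self.is_relay = np.zeros(n, dtype=bool)
        self.is_relay[self.relay_ids] = True

        static = [c for c in net.connections if not c.plastic]
        plastic = [c for c in net.connections if c.plastic]
        for c in plastic:
            if c.sign != "excitatory":
                raise ValueError("plastic synapses must be excitatory")
            if c.post in relay_set:
                raise ValueError("plastic synapse onto a relay neuron")

        # static dense matrices (dimensionless weights; quantized on init)
        self._static_ex = np.zeros((n, n))
        self._static_ih = np.zeros((n, n))
        for c in static:
            if c.sign == "excitatory":
                self._static_ex[c.pre, c.post] = c.w
            else:
                self._static_ih[c.pre, c.post] = abs(c.w)

        self.p_pre_ids = np.asarray(sorted({c.pre for c in plastic}),
                                    dtype=int)
        self.p_post_ids = np.asarray(sorted({c.post for c in plastic}),
                                     dtype=int)
        self.pre_index = np.full(n, -1, dtype=int)
        self.pre_index[self.p_pre_ids] = np.arange(len(self.p_pre_ids))
        self.post_index = np.full(n, -1, dtype=int)
        self.post_index[self.p_post_ids] = np.arange(len(self.p_post_ids))
        self._w0 = np.zeros((len(self.p_pre_ids), len(self.p_post_ids)))
        self.p_mask = np.zeros_like(self._w0, dtype=bool)
        for c in plastic:
            r = self.pre_index[c.pre]
            q = self.post_index[c.post]
            self._w0[r, q] = c.w
            self.p_mask[r, q] = True

    # -- state ----------------------------------------------------------

    def init_state(self, cfg: RunConfig) -> "NetworkState":
        return NetworkState(self, cfg)

    def to_netlist(self, state: "NetworkState") -> Netlist:
        """Netlist with the learned plastic weights and adaptive-threshold
        offsets written back (dimensionless / mV)."""
        import copy
        out = copy.deepcopy(self.netlist)
        spec = state.spec
        for c in out.connections:
            if c.plastic:
                r = self.pre_index[c.pre]
                q = self.post_index[c.post]
                c.w = float(state.w[r, q]) / spec.weight_scale
        theta_mv = {int(i): float(state.theta[i] * spec.lsb_mv)
                    for i in np.nonzero(state.theta)[0]}
        if theta_mv:
            out.neuron_params["theta_mv"] = (0.0, theta_mv)
        return out


class NetworkState:
    """All mutable simulation state, in quantized units."""

    def __init__(self, cnet: CompiledNetwork, cfg: RunConfig):
        spec = cfg.spec
        self.spec = spec
        self.cfg = cfg
        n = cnet.n
        dtype = np.float64 if spec.is_float else np.int64
        self.dtype = dtype
        v_rest_u = spec.to_v_units(cfg.lif.v_rest)
        self.v = np.full(n, v_rest_u, dtype=dtype)
        self.g_ex = np.zeros(n, dtype=dtype)
        self.g_ih = np.zeros(n, dtype=dtype)
        self.theta = np.zeros(n, dtype=dtype)
        # learned adaptive-threshold offsets persisted in the netlist
        if "theta_mv" in cnet.netlist.neuron_params:
            default, overrides = cnet.netlist.neuron_params["theta_mv"]
            self.theta[:] = spec.to_v_units(default)
            for nid, mv in overrides.items():
                self.theta[nid] = spec.to_v_units(mv)
        self.a_pre = np.zeros(n, dtype=dtype)
        self.a_post = np.zeros(n, dtype=dtype)
        self.prev_fired = np.zeros(n, dtype=bool)
        self.t_global = 0
        scale = spec.weight_scale
        if spec.is_float:
            self.w = cnet._w0 * scale
            self.static_ex = cnet._static_ex * scale
            self.static_ih = cnet._static_ih * scale
        else:
            def q(x):
                y = x * scale
                r = np.sign(y) * np.floor(np.abs(y) + 0.5)
                return np.clip(r, spec.qmin, spec.qmax).astype(np.int64)
            self.w = np.where(cnet.p_mask, q(cnet._w0), 0).astype(np.int64)
            self.static_ex = q(cnet._static_ex)
            self.static_ih = q(cnet._static_ih)

    def copy_plastic(self):
        """Snapshot of (plastic weights, theta) for phase-gating checks."""
        return self.w.copy(), self.theta.copy()


# ---------------------------------------------------------------------------
# The step loop
# ---------------------------------------------------------------------------


def run_presentation(cnet: CompiledNetwork, plan: np.ndarray | SpikePlan,
                     cfg: SimConfig, state: NetworkState
                     ) -> tuple[NetworkState, SpikeEventLog, TraceLog]:
    """Run one presentation (any number of steps) over a spike plan.

    ``plan`` is a (steps, n_relay) boolean array — or a
    :class:`~spikefix.encoding.SpikePlan`, whose columns must match the
    network's relay (input-layer) neurons in id order.  The state is
    advanced in place and also returned.  Logged step indices are local to
    this call.
    """
    if isinstance(plan, SpikePlan):
        plan = plan.spikes
    plan = np.asarray(plan, dtype=bool)
    if plan.ndim != 2 or plan.shape[1] != len(cnet.relay_ids):
        raise ValueError(
            f"plan has {plan.shape[1] if plan.ndim == 2 else '?'} columns; "
            f"network has {len(cnet.relay_ids)} input-layer neurons")

    run = cfg.run
    spec = run.spec
    train = cfg.mode == "train"
    ops = _FloatOps() if spec.is_float else _FixedOps(spec)

    lif, stdp, hom = run.lif, run.stdp, run.homeostasis
    def frac(tau):
        num, den = _as_frac(lif.dt, tau)
        return min(num, den), den   # dt >= tau: full removal, no overshoot

    dt_ex, dt_ih = frac(lif.tau_ex), frac(lif.tau_ih)
    dt_pre, dt_post = frac(stdp.tau_pre), frac(stdp.tau_post)
    dt_m = _as_frac(lif.dt, lif.tau_m)

    v_rest_u = spec.to_v_units(lif.v_rest)
    v_th_u = spec.to_v_units(lif.v_th)
    k_u = spec.to_v_units(lif.k_mag)
    wscale = spec.weight_scale
    w_max_u = spec.to_w_units(stdp.w_max)
    d_apre_u = spec.to_trace_units(stdp.d_apre)
    d_apost_u = spec.to_trace_units(stdp.d_apost)
    tscale = spec.trace_scale
    d_theta_u = spec.to_v_units(hom.d_theta)
    t_spa_steps = int(round(hom.t_spa_samp / lif.dt))
    theta_f = hom.decay_factor
    r_num, r_den = _r_mem_frac(lif.r_mem)

    internal = cnet.internal_ids
    homeo = cnet.homeo_mask
    rec_ids = np.asarray(cfg.record_membrane
                         if cfg.record_membrane is not None
                         else cnet.output_ids, dtype=int)

    log = SpikeEventLog()
    trace = TraceLog(rec_ids.tolist())
    have_plastic = cnet.p_mask.size > 0

    for t in range(plan.shape[0]):
        # -- 1: decays ---------------------------------------------------
        state.g_ex = ops.decay(state.g_ex, *dt_ex)
        state.g_ih = ops.decay(state.g_ih, *dt_ih)
        state.a_pre = ops.decay(state.a_pre, *dt_pre)
        state.a_post = ops.decay(state.a_post, *dt_post)
        if train and state.t_global > 0 \
                and state.t_global % t_spa_steps == 0:
            state.theta = np.where(homeo,
                                   ops.scale_round(state.theta, theta_f),
                                   state.theta)

        # -- 2: spike delivery -------------------------------------------
        ext_ids = cnet.relay_ids[plan[t]]
        prev_ids = np.nonzero(state.prev_fired)[0]
        if len(ext_ids) or len(prev_ids):
            delivered = np.concatenate([ext_ids, prev_ids])
            state.g_ex = ops.sat(state.g_ex
                                 + state.static_ex[delivered].sum(axis=0))
            state.g_ih = ops.sat(state.g_ih
                                 + state.static_ih[delivered].sum(axis=0))
            if have_plastic:
                rows = cnet.pre_index[delivered]
                rows = rows[rows >= 0]
                if len(rows):
                    state.g_ex[cnet.p_post_ids] = ops.sat(
                        state.g_ex[cnet.p_post_ids]
                        + state.w[rows].sum(axis=0))
                    if train:
                        pre_ids = delivered[cnet.pre_index[delivered] >= 0]
                        state.a_pre[pre_ids] = ops.sat(
                            state.a_pre[pre_ids] + d_apre_u)
                        dw = ops.mul_frac(state.a_post[cnet.p_post_ids],
                                          wscale, tscale)
                        upd = state.w[rows] + dw[None, :] * cnet.p_mask[rows]
                        state.w[rows] = np.clip(upd, 0, w_max_u)

        # -- 3+4: soma updates (layers 2 and 3 are independent) ----------
        i_syn = ops.mul_frac(state.g_ex[internal] - state.g_ih[internal],
                             k_u, wscale)
        if (r_num, r_den) != (1, 1):
            i_syn = ops.mul_frac(i_syn, r_num, r_den)
        drive = (v_rest_u - state.v[internal]) + i_syn
        v_new = ops.sat(state.v[internal] + ops.mul_frac(drive, *dt_m))
        thr = v_th_u + state.theta[internal]
        fired_int = v_new >= thr
        v_new = np.where(fired_int, v_rest_u, v_new)
        state.v[internal] = v_new
        fired = np.zeros(cnet.n, dtype=bool)
        fired[internal[fired_int]] = True

        # -- 5: postsynaptic plasticity and homeostasis ------------------
        if train:
            if have_plastic:
                post_fired = fired[cnet.p_post_ids]
                if post_fired.any():
                    ids = cnet.p_post_ids[post_fired]
                    state.a_post[ids] = ops.sat(state.a_post[ids]
                                                + d_apost_u)
                    cols = cnet.post_index[ids]
                    dw = ops.mul_frac(state.a_pre[cnet.p_pre_ids],
                                      wscale, tscale)
                    upd = state.w[:, cols] \
                        + dw[:, None] * cnet.p_mask[:, cols]
                    state.w[:, cols] = np.clip(upd, 0, w_max_u)
            bump = fired & homeo
            if bump.any():
                state.theta[bump] = ops.sat(state.theta[bump] + d_theta_u)

        # -- 6: record ---------------------------------------------------
        spiking = np.concatenate([ext_ids, internal[fired_int]])
        spiking.sort()
        log.extend(t, spiking)
        if len(rec_ids):
            trace.append(state.v[rec_ids], state.theta[rec_ids])

        state.prev_fired = fired
        state.t_global += 1

    return state, log, trace


def _r_mem_frac(r_mem: float) -> tuple[int, int]:
    from fractions import Fraction
    fr = Fraction(r_mem).limit_denominator(10_000)
    return fr.numerator, fr.denominator


# ---------------------------------------------------------------------------
# Normalization, training, prediction
# ---------------------------------------------------------------------------


def normalize_plastic(cnet: CompiledNetwork, state: NetworkState) -> None:
    """Subtractive normalization of every plastic column (per post neuron).

    Applied once per training pattern, after the presentation window and
    before the pause.
    """
    if cnet.p_mask.size == 0:
        return
    run = state.cfg
    spec = run.spec
    w_norm_u = spec.to_w_units(run.stdp.w_norm)
    w_max_u = spec.to_w_units(run.stdp.w_max)
    counts = cnet.p_mask.sum(axis=0)
    sums = state.w.sum(axis=0)
    if spec.is_float:
        fac = (w_norm_u - sums) / counts
    else:
        diff = w_norm_u - sums
        fac = np.sign(diff) * ((2 * np.abs(diff) + counts) // (2 * counts))
    state.w = np.clip(state.w + fac[None, :] * cnet.p_mask, 0, w_max_u)
    if not spec.is_float:
        state.w = state.w.astype(np.int64)


def train(cnet: CompiledNetwork, samples: Sequence, epochs: int,
          cfg: SimConfig, state: Optional[NetworkState] = None,
          progress: Optional[callable] = None) -> NetworkState:
    """Present labelled samples with the teacher signal and learn.

    Per epoch the sample order is reshuffled from the run seed; each sample
    is Poisson-encoded with a fresh derived seed, presented for the 350 ms
    window, the plastic in-weights of every excitatory neuron are
    subtractively normalized, and the 150 ms pause is then simulated.
    Returns the trained state (weights and θ retained).
    """
    for s in samples:
        if s.label is None:
            raise ValueError("training requires labelled samples")
    if cfg.mode != "train":
        raise ValueError("train() needs a SimConfig in train mode")
    if state is None:
        state = cnet.init_state(cfg.run)
    n_teachers = len(cnet.layer_ids.get("input_teacher", ()))
    enc = cfg.run.encoding
    master = np.random.default_rng(cfg.seed)
    pres = enc.present_steps
    for epoch in range(epochs):
        order = master.permutation(len(samples))
        for j, idx in enumerate(order):
            sample = samples[idx]
            enc_seed = int(master.integers(2 ** 31))
            plan = poisson_encode(sample, enc, mode="train",
                                  n_teachers=n_teachers, seed=enc_seed)
            run_presentation(cnet, plan.spikes[:pres], cfg, state)
            normalize_plastic(cnet, state)
            run_presentation(cnet, plan.spikes[pres:], cfg, state)
            if progress is not None:
                progress(epoch, j, len(samples))
    return state


def predict(log: SpikeEventLog, cnet: CompiledNetwork,
            window_steps: Optional[int] = None) -> tuple[int, bool]:
    """Classify a test presentation from its output-layer spike counts.

    Returns ``(class_index, no_response)``; ties go to the lowest class
    index, and an all-silent output layer yields class 0 with the
    no-response flag set.
    """
    counts = log.counts(cnet.output_ids, t_max=window_steps)
    if counts.size == 0 or counts.max() == 0:
        return 0, True
    return int(np.argmax(counts)), False


def evaluate(cnet: CompiledNetwork, samples: Sequence, cfg: SimConfig,
             state: NetworkState) -> tuple[list, list, int]:
    """Run test presentations; returns (predictions, labels, n_no_response).

    Weights and θ are frozen (the state is restored after each
    presentation is a no-op: test mode never mutates them); membrane and
    conductance state carries over between presentations, as on hardware.
    """
    test_cfg = SimConfig(run=cfg.run, mode="test", seed=cfg.seed,
                         record_membrane=cfg.record_membrane)
    n_teachers = len(cnet.layer_ids.get("input_teacher", ()))
    enc = cfg.run.encoding
    master = np.random.default_rng(test_cfg.seed + 0x5EED)
    pres = enc.present_steps
    preds, labels, n_silent = [], [], 0
    for sample in samples:
        enc_seed = int(master.integers(2 ** 31))
        plan = poisson_encode(sample, enc, mode="test",
                              n_teachers=n_teachers, seed=enc_seed)
        _, log, _ = run_presentation(cnet, plan.spikes, test_cfg, state)
        cls, silent = predict(log, cnet, window_steps=pres)
        preds.append(cls)
        labels.append(sample.label)
        n_silent += int(silent)
    return preds, labels, n_silent
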