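"""Deliberately naive scalar reference simulator.

Implements the same step semantics as the vectorized engine — phase order,
one-step axonal delay, integer rounding and saturation — but in plain
Python loops over individual neurons and synapses, with per-synapse
activity traces and its own arithmetic helpers.  It shares no code with
the engine; agreement between the two is the engine's correctness oracle.

Step phases:
1. decay conductances and traces; undersampled theta decay (train mode);
2. deliver external spikes and previous-step internal spikes: conductance
   injection with current weights, then (train) presynaptic STDP;
3/4. soma update for all internal neurons (layers 2 and 3 do not interact
   within a step);
5. (train) postsynaptic STDP and theta increments for firing neurons;
6. record (external relay spikes and internal spikes, id-sorted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


def rhalf(x: float) -> int:
    """Round to nearest, ties away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class RefSynapse:
    pre: int
    post: int
    w: int
    sign: str = "excitatory"
    plastic: bool = False
    a_pre: int = 0
    a_post: int = 0


@dataclass
class RefParams:
    """Dimensionless/physical parameters plus fixed-point scales."""

    width_bits: int = 16
    lsb_mv: float = 0.01
    wscale: int = 1 << 10
    tscale: int = 1 << 15
    v_th: float = -52.0
    v_rest: float = -65.0
    k_mag: float = 58.0
    tau_m: int = 100
    tau_ex: int = 1
    tau_ih: int = 1
    tau_pre: int = 20
    tau_post: int = 20
    d_apre: float = 0.01
    d_apost: float = -0.01
    w_max: float = 1.0
    d_theta: float = 0.01
    tau_hom: float = 1e6
    t_spa_samp: int = 10_000
    dt: int = 1


class ReferenceSimulator:
    """Scalar fixed-point simulator over an explicit synapse list."""

    def __init__(self, n: int, relay_ids, homeo_ids, synapses, p: RefParams,
                 mode: str = "train"):
        self.n = n
        self.p = p
        self.mode = mode
        self.relay_ids = list(relay_ids)
        self.relay_set = set(relay_ids)
        self.internal = [i for i in range(n) if i not in self.relay_set]
        self.homeo = set(homeo_ids)
        self.syn = synapses
        self.by_pre: dict[int, list[RefSynapse]] = {}
        self.by_post: dict[int, list[RefSynapse]] = {}
        for s in synapses:
            self.by_pre.setdefault(s.pre, []).append(s)
            if s.plastic:
                self.by_post.setdefault(s.post, []).append(s)
        self.qmin = -(1 << (p.width_bits - 1))
        self.qmax = (1 << (p.width_bits - 1)) - 1
        self.v_rest_u = self._q_v(p.v_rest)
        self.v_th_u = self._q_v(p.v_th)
        self.k_u = self._q_v(p.k_mag)
        self.w_max_u = self._sat(rhalf(p.w_max * p.wscale))
        self.d_apre_u = self._sat(rhalf(p.d_apre * p.tscale))
        self.d_apost_u = self._sat(rhalf(p.d_apost * p.tscale))
        self.d_theta_u = self._q_v(p.d_theta)
        self.v = [self.v_rest_u] * n
        self.g_ex = [0] * n
        self.g_ih = [0] * n
        self.theta = [0] * n
        self.prev_fired = [False] * n
        self.t_global = 0
        self.events: list[tuple[int, int]] = []

    # -- arithmetic -----------------------------------------------------

    def _sat(self, x: int) -> int:
        return min(max(x, self.qmin), self.qmax)

    def _q_v(self, mv: float) -> int:
        return self._sat(rhalf(mv / self.p.lsb_mv))

    def _rdiv(self, num: int, den: int) -> int:
        q = (2 * abs(num) + den) // (2 * den)
        return q if num >= 0 else -q

    def _decay(self, x: int, tau: int) -> int:
        num = min(self.p.dt, tau)
        return self._sat(x - self._rdiv(x * num, tau))

    # -- one step -------------------------------------------------------

    def step(self, ext_spiking: list[int], local_t: int) -> None:
        p = self.p
        train = self.mode == "train"
        # 1: decays
        for i in range(self.n):
            self.g_ex[i] = self._decay(self.g_ex[i], p.tau_ex)
            self.g_ih[i] = self._decay(self.g_ih[i], p.tau_ih)
        for s in self.syn:
            s.a_pre = self._decay(s.a_pre, p.tau_pre)
            s.a_post = self._decay(s.a_post, p.tau_post)
        if train and self.t_global > 0 \
                and self.t_global % p.t_spa_samp == 0:
            f = math.exp(-p.t_spa_samp / p.tau_hom)
            for i in self.homeo:
                self.theta[i] = self._sat(rhalf(self.theta[i] * f))
        # 2: delivery
        delivered = list(ext_spiking) \
            + [i for i in self.internal if self.prev_fired[i]]
        for pre in delivered:
            for s in self.by_pre.get(pre, []):
                if s.sign == "excitatory":
                    self.g_ex[s.post] = self._sat(self.g_ex[s.post] + s.w)
                else:
                    self.g_ih[s.post] = self._sat(self.g_ih[s.post]
                                                  + abs(s.w))
        if train:
            for pre in delivered:
                for s in self.by_pre.get(pre, []):
                    if s.plastic:
                        s.a_pre = self._sat(s.a_pre + self.d_apre_u)
                        dw = self._sat(self._rdiv(s.a_post * p.wscale,
                                                  p.tscale))
                        s.w = min(max(s.w + dw, 0), self.w_max_u)
        # 3+4: soma
        fired = [False] * self.n
        for i in self.internal:
            i_syn = self._sat(self._rdiv((self.g_ex[i] - self.g_ih[i])
                                         * self.k_u, p.wscale))
            drive = (self.v_rest_u - self.v[i]) + i_syn
            dv = self._sat(self._rdiv(drive * p.dt, p.tau_m))
            v_new = self._sat(self.v[i] + dv)
            if v_new >= self.v_th_u + self.theta[i]:
                fired[i] = True
                self.v[i] = self.v_rest_u
            else:
                self.v[i] = v_new
        # 5: postsynaptic plasticity + homeostasis
        if train:
            for i in self.internal:
                if not fired[i]:
                    continue
                for s in self.by_post.get(i, []):
                    s.a_post = self._sat(s.a_post + self.d_apost_u)
                    dw = self._sat(self._rdiv(s.a_pre * p.wscale, p.tscale))
                    s.w = min(max(s.w + dw, 0), self.w_max_u)
                if i in self.homeo:
                    self.theta[i] = self._sat(self.theta[i]
                                              + self.d_theta_u)
        # 6: record
        spiking = sorted(list(ext_spiking)
                         + [i for i in self.internal if fired[i]])
        for i in spiking:
            self.events.append((local_t, i))
        self.prev_fired = fired
        self.t_global += 1

    def run(self, plan) -> list[tuple[int, int]]:
        """plan: (steps, len(relay_ids)) boolean array-like."""
        for t, row in enumerate(plan):
            ext = [self.relay_ids[j] for j, on in enumerate(row) if on]
            self.step(ext, t)
        return self.events
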