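"""Saturating fixed-point number system for neuromorphic emulation.

All dynamical state in the simulator (membrane potentials, conductances,
plasticity traces, synaptic weights, adaptive thresholds) lives in a single
quantized integer number system that mirrors a SIMD processing-element
datapath: signed integers of a configurable width, with a physical quantum
(LSB) attached to voltages and a power-of-two scale attached to weight-like
quantities.  Arithmetic saturates at the representable bounds — it never
wraps — and every multiply/divide rounds once, to nearest, ties away from
zero.

The module also provides the discrete exponential-decay operator used by all
leak dynamics (membrane, conductances, plasticity traces), in two flavours:
a forward-Euler step ``x ← x − round(x·dt/τ)`` (the default) and the exact
multiplicative step ``x ← round(x·e^(−dt/τ))``.  Note that Euler with τ = dt
removes the whole value in one step; this degenerate behaviour is kept for
the 1 ms conductance time constants because the emulated hardware declares
the Euler method.

A ``float`` mode is available in which every operation degenerates to plain
real arithmetic; it is the reference against which the quantized modes are
compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

Number = Union[int, float, np.ndarray]

#: per-mode defaults: (width_bits, lsb_uv, weight_scale_bits, trace_scale_bits)
#: The 16-bit mode uses the canonical 10 uV/LSB quantum.  The 8-bit range
#: (+/-127 units) cannot hold a -65 mV resting potential at 10 uV/LSB, so its
#: voltage quantum is coarsened to 1 mV and the weight scale reduced to 2^6;
#: the 32-bit mode keeps the voltage quantum and widens the weight scale to
#: 2^20.  Plasticity traces carry their own finer scale: at the weight scale
#: a trace increment of 0.01 is ~10 units and the integer decay
#: x − round(x/20) has a deadband below 10 units, which would leave every
#: trace pinned near the increment size; the extra trace bits push that
#: deadband orders of magnitude below the increment.  "float" carries no
#: quantization at all.
MODE_DEFAULTS = {
    "fixed8": (8, 1000.0, 6, 9),
    "fixed16": (16, 10.0, 10, 15),
    "fixed32": (32, 10.0, 20, 25),
    "float": (64, 10.0, 10, 15),
}


@dataclass(frozen=True)
class FixedSpec:
    """Defines the quantized number system all simulator state lives in.

    Parameters
    ----------
    mode:
        One of ``fixed8``, ``fixed16``, ``fixed32``, ``float``.
    width_bits:
        Register width; representable units span
        ``[-2^(w-1), 2^(w-1) - 1]``.  Ignored in float mode.
    lsb_uv:
        Microvolts per unit for voltage-like quantities.
    weight_scale_bits:
        A dimensionless weight of 1.0 (the STDP ``w_max``) maps to
        ``2**weight_scale_bits`` units.
    trace_scale_bits:
        Scale for the STDP activity traces (a dimensionless trace value of
        1.0 maps to ``2**trace_scale_bits`` units); finer than the weight
        scale so trace decay is not swallowed by rounding.
    """

    mode: str = "fixed16"
    width_bits: int = 16
    lsb_uv: float = 10.0
    weight_scale_bits: int = 10
    trace_scale_bits: int = 15

    def __post_init__(self) -> None:
        if self.mode not in MODE_DEFAULTS:
            raise ValueError(f"unknown precision mode {self.mode!r}")
        if self.mode != "float" and self.width_bits not in (8, 16, 32):
            raise ValueError("width_bits must be one of 8, 16, 32")
        if self.lsb_uv <= 0:
            raise ValueError("lsb_uv must be positive")

    @classmethod
    def from_mode(cls, mode: str, **overrides) -> "FixedSpec":
        """Build a spec with the per-mode default scaling (overridable)."""
        if mode not in MODE_DEFAULTS:
            raise ValueError(f"unknown precision mode {mode!r}")
        width, lsb, wsb, tsb = MODE_DEFAULTS[mode]
        kw = dict(mode=mode, width_bits=width, lsb_uv=lsb,
                  weight_scale_bits=wsb, trace_scale_bits=tsb)
        kw.update(overrides)
        return cls(**kw)

    # -- representation bounds ------------------------------------------

    @property
    def is_float(self) -> bool:
        return self.mode == "float"

    @property
    def qmin(self) -> int:
        return -(1 << (self.width_bits - 1))

    @property
    def qmax(self) -> int:
        return (1 << (self.width_bits - 1)) - 1

    @property
    def lsb_mv(self) -> float:
        """Millivolts per voltage unit."""
        return self.lsb_uv * 1e-3

    @property
    def weight_scale(self) -> int:
        """Integer units representing a dimensionless weight of 1.0."""
        return 1 << self.weight_scale_bits

    # -- unit conversions -----------------------------------------------

    def to_v_units(self, mv: float) -> Number:
        """Quantize a voltage in mV onto the grid (float mode: identity-ish)."""
        return quantize(mv, self)

    def from_v_units(self, units: Number) -> Number:
        return np.asarray(units, dtype=float) * self.lsb_mv if isinstance(
            units, np.ndarray) else units * self.lsb_mv

    def to_w_units(self, w: float) -> Number:
        """Quantize a dimensionless weight/conductance/trace value."""
        if self.is_float:
            return float(w) * self.weight_scale
        return saturate(_round_half_away(float(w) * self.weight_scale), self)

    def from_w_units(self, units: Number) -> Number:
        return units / self.weight_scale

    @property
    def trace_scale(self) -> int:
        """Integer units representing a dimensionless trace value of 1.0."""
        return 1 << self.trace_scale_bits

    def to_trace_units(self, x: float) -> Number:
        """Quantize a dimensionless trace value or increment."""
        if self.is_float:
            return float(x) * self.trace_scale
        return saturate(_round_half_away(float(x) * self.trace_scale), self)


def _round_half_away(x: Number):
    """Round to nearest integer, ties away from zero (scalar or array)."""
    if isinstance(x, np.ndarray):
        return np.sign(x) * np.floor(np.abs(x) + 0.5)
    return math.copysign(math.floor(abs(x) + 0.5), x)


def saturate(x: Number, spec: FixedSpec) -> Number:
    """Clamp to the representable range (no wrap-around).  Identity in float."""
    if spec.is_float:
        return x
    if isinstance(x, np.ndarray):
        return np.clip(x, spec.qmin, spec.qmax)
    return min(max(int(x), spec.qmin), spec.qmax)


def quantize(value_mv: Number, spec: FixedSpec) -> Number:
    """Map a real voltage in mV to integer units of ``spec``.

    Round-to-nearest with ties away from zero, saturated to the
    representable range.  In float mode the value is only rescaled.
    """
    arr = np.asarray(value_mv, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot quantize non-finite value")
    scaled = arr / spec.lsb_mv
    if spec.is_float:
        out = scaled
    else:
        out = np.clip(_round_half_away(scaled), spec.qmin, spec.qmax)
    if np.isscalar(value_mv) or arr.ndim == 0:
        return float(out) if spec.is_float else int(out)
    return out if spec.is_float else out.astype(np.int64)


def sat_add(a: Number, b: Number, spec: FixedSpec) -> Number:
    """Saturating addition of two values sharing ``spec``."""
    return saturate(a + b, spec)


def sat_mul_frac(a: Number, num: int, den: int, spec: FixedSpec) -> Number:
    """Compute ``round(a * num / den)`` with one rounding, saturated.

    ``num``/``den`` is the exact rational multiplier (e.g. dt/τ); the
    product is formed in full precision before the single round.
    """
    if den == 0:
        raise ZeroDivisionError("sat_mul_frac: zero denominator")
    if spec.is_float:
        return a * num / den
    if isinstance(a, np.ndarray):
        prod = a.astype(np.int64) * int(num)
        d = int(den)
        if d < 0:
            prod, d = -prod, -d
        q = np.sign(prod) * ((2 * np.abs(prod) + d) // (2 * d))
        return np.clip(q, spec.qmin, spec.qmax)
    prod = int(a) * int(num)
    d = int(den)
    if d < 0:
        prod, d = -prod, -d
    q = (2 * abs(prod) + d) // (2 * d)
    q = q if prod >= 0 else -q
    return saturate(q, spec)


def _as_frac(dt: float, tau: float) -> tuple[int, int]:
    # dt and tau are in ms; the emulated timebase is integer ms, so the
    # ratio is represented exactly as a fraction of scaled integers.
    num = int(round(dt * 1000))
    den = int(round(tau * 1000))
    if num <= 0 or den <= 0:
        raise ValueError("dt and tau must be positive")
    return num, den


def decay_step(x: Number, tau: float, dt: float, spec: FixedSpec,
               method: str = "euler") -> Number:
    """One discrete step of exponential decay toward zero.

    euler:  ``x ← x − round(x·dt/τ)``   (default; degenerates to 0 at τ = dt)
    exact:  ``x ← round(x·e^(−dt/τ))``

    Both are contractions toward zero and both saturate.
    """
    num, den = _as_frac(dt, tau)
    if method == "euler":
        # dt >= tau removes the whole value in one step (never overshoots
        # past zero, keeping the operator a contraction).
        num = min(num, den)
        if spec.is_float:
            return x * (1.0 - num / den)
        return saturate(x - sat_mul_frac(x, num, den, spec), spec)
    if method == "exact":
        f = math.exp(-num / den)
        if spec.is_float:
            return x * f
        if isinstance(x, np.ndarray):
            return np.clip(_round_half_away(x * f), spec.qmin,
                           spec.qmax).astype(np.int64)
        return saturate(_round_half_away(x * f), spec)
    raise ValueError(f"unknown decay method {method!r}")
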