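"""Network construction, netlist text format, and on-chip memory accounting.

The digit-recognition network has four layers:

* **input** — 144 pixel-relay neurons (one per pixel of a 12×12 image) plus
  one teacher neuron per class.  These neurons have no soma dynamics; they
  forward externally generated spikes.
* **excitatory** — ``n_classes × group_size`` LIF neurons with homeostasis,
  grouped by class.  Every pixel connects to every excitatory neuron through
  a plastic synapse; each teacher connects statically (w = w_max) to its
  class group.
* **inhibitory** — one LIF partner per excitatory neuron.  Excitatory neuron
  *i* drives inhibitory neuron *i* through a strong static synapse, and
  inhibitory *i* in turn inhibits every excitatory neuron except *i*
  (winner-take-all lateral inhibition).
* **output** — one LIF neuron per class, driven by its class group with
  static weight ``8·w_max``.

Neuron ids are assigned contiguously in the order pixels, teachers,
excitatory, inhibitory, outputs (for the 10-class network:
0–143, 144–153, 154–253, 254–353, 354–363; 364 neurons in total).

The netlist text dialect has two sections.  ``@Netlist`` lists one synapse
per line as ``pre post weight plastic(0|1) sign(E|I)``; ``@Params`` lists
named per-neuron parameters as ``name default [id:value ...]``, including
the reserved ``n_neurons`` entry that declares the neuron count.  ``#``
starts a comment.  ``parse_netlist(write_netlist(n))`` is the identity.

Memory accounting mirrors a per-processing-element synaptic/neural RAM of
1024 × 32-bit words, with 5 words per stored synapse and 8 words per neuron,
and a 256-synapse-per-PE ceiling.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

LAYER_NAMES = ("input_pixel", "input_teacher", "excitatory", "inhibitory",
               "output")


@dataclass(frozen=True)
class LayerSpec:
    name: str
    size: int
    virtual_layer: int  # 1 = input, 2 = excitatory+output, 3 = inhibitory

    def __post_init__(self):
        if self.name not in LAYER_NAMES:
            raise ValueError(f"unknown layer name {self.name!r}")
        if self.size < 0 or self.virtual_layer not in (1, 2, 3):
            raise ValueError("bad layer size or virtual layer index")


@dataclass
class Connection:
    pre: int
    post: int
    w: float
    plastic: bool = False
    sign: str = "excitatory"


@dataclass
class Netlist:
    """Connection list plus keyed per-neuron initial parameters."""

    n_neurons: int
    connections: list = field(default_factory=list)
    #: name -> (default value, {neuron id: override})
    neuron_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        seen = set()
        for c in self.connections:
            if not (0 <= c.pre < self.n_neurons
                    and 0 <= c.post < self.n_neurons):
                raise ValueError(
                    f"synapse ({c.pre}, {c.post}) references an undeclared "
                    f"neuron (n_neurons={self.n_neurons})")
            if (c.pre, c.post) in seen:
                raise ValueError(f"duplicate synapse ({c.pre}, {c.post})")
            seen.add((c.pre, c.post))


@dataclass(frozen=True)
class WeightDefaults:
    """Static synapse strengths, in multiples of w_max."""

    w_max: float = 1.0
    exc_inh: float = 17.5     # excitatory -> inhibitory partner
    inh_exc: float = 1.0      # inhibitory -> all other excitatory
    out_scale: float = 8.0    # excitatory group -> output neuron
    teacher: float = 1.0      # teacher -> its class group


@dataclass
class MemoryMap:
    """Per-PE word usage of the synaptic/neural RAM."""

    pe_words: list
    pe_synapses: list
    capacity_words: int
    max_synapses: int

    @property
    def total_words(self) -> int:
        return int(sum(self.pe_words))

    @property
    def utilization(self) -> float:
        if not self.pe_words:
            return 0.0
        return max(self.pe_words) / self.capacity_words

    @property
    def over_capacity(self) -> list:
        return [i for i, w in enumerate(self.pe_words)
                if w > self.capacity_words]

    @property
    def over_synapse_limit(self) -> list:
        return [i for i, s in enumerate(self.pe_synapses)
                if s > self.max_synapses]


# ---------------------------------------------------------------------------
# Topology builder
# ---------------------------------------------------------------------------

N_PIXELS = 144


def layer_offsets(n_classes: int, group_size: int) -> dict:
    """Start id of each layer under the contiguous id convention."""
    n_exc = n_classes * group_size
    o = {}
    o["input_pixel"] = 0
    o["input_teacher"] = N_PIXELS
    o["excitatory"] = N_PIXELS + n_classes
    o["inhibitory"] = o["excitatory"] + n_exc
    o["output"] = o["inhibitory"] + n_exc
    o["total"] = o["output"] + n_classes
    return o


def build_digit_network(n_classes: int, group_size: int, seed: int,
                        weights: WeightDefaults | None = None
                        ) -> tuple[list, Netlist]:
    """Construct the 4-layer digit network.

    Plastic pixel→excitatory weights are initialized Uniform(0, w_max) from
    ``seed`` (symmetry breaking; the first normalization pins their sum).
    Returns ``(layers, netlist)``.
    """
    if n_classes < 1 or group_size < 1:
        raise ValueError("n_classes and group_size must be positive")
    wd = weights or WeightDefaults()
    n_exc = n_classes * group_size
    off = layer_offsets(n_classes, group_size)
    layers = [
        LayerSpec("input_pixel", N_PIXELS, 1),
        LayerSpec("input_teacher", n_classes, 1),
        LayerSpec("excitatory", n_exc, 2),
        LayerSpec("inhibitory", n_exc, 3),
        LayerSpec("output", n_classes, 2),
    ]
    rng = np.random.default_rng(seed)
    conns: list[Connection] = []

    exc0, inh0, out0 = off["excitatory"], off["inhibitory"], off["output"]
    # pixels -> excitatory, all-to-all, plastic
    init_w = rng.uniform(0.0, wd.w_max, size=(N_PIXELS, n_exc))
    for p in range(N_PIXELS):
        for e in range(n_exc):
            conns.append(Connection(p, exc0 + e, float(init_w[p, e]),
                                    plastic=True))
    # teacher c -> its class group, static at w_max
    for c in range(n_classes):
        for g in range(group_size):
            conns.append(Connection(N_PIXELS + c,
                                    exc0 + c * group_size + g,
                                    wd.teacher * wd.w_max))
    # excitatory i -> inhibitory partner i, strong static
    for i in range(n_exc):
        conns.append(Connection(exc0 + i, inh0 + i, wd.exc_inh * wd.w_max))
    # inhibitory i -> every excitatory except i
    for i in range(n_exc):
        for j in range(n_exc):
            if j != i:
                conns.append(Connection(inh0 + i, exc0 + j,
                                        wd.inh_exc * wd.w_max,
                                        sign="inhibitory"))
    # class group column -> its output neuron, static 8*w_max
    for c in range(n_classes):
        for g in range(group_size):
            conns.append(Connection(exc0 + c * group_size + g, out0 + c,
                                    wd.out_scale * wd.w_max))

    net = Netlist(n_neurons=off["total"], connections=conns)
    net.validate()
    return layers, net


# ---------------------------------------------------------------------------
# Netlist text format
# ---------------------------------------------------------------------------

_SIGN_CODE = {"excitatory": "E", "inhibitory": "I"}
_CODE_SIGN = {v: k for k, v in _SIGN_CODE.items()}


def write_netlist(net: Netlist) -> str:
    """Serialize a netlist to its two-section text form."""
    buf = io.StringIO()
    buf.write("# spikefix netlist\n@Netlist\n")
    for c in net.connections:
        buf.write(f"{c.pre} {c.post} {c.w!r} {int(c.plastic)} "
                  f"{_SIGN_CODE[c.sign]}\n")
    buf.write("@Params\n")
    buf.write(f"n_neurons {net.n_neurons}\n")
    for name, (default, overrides) in net.neuron_params.items():
        parts = [name, repr(default)]
        parts += [f"{nid}:{val!r}" for nid, val in sorted(overrides.items())]
        buf.write(" ".join(parts) + "\n")
    return buf.getvalue()


def parse_netlist(text: str) -> Netlist:
    """Parse the two-section netlist dialect; errors carry line numbers."""
    section = None
    seen_netlist = False
    conns: list[Connection] = []
    params: dict = {}
    n_neurons = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@"):
            if line not in ("@Netlist", "@Params"):
                raise ValueError(f"line {lineno}: unknown section {line!r}")
            section = line
            seen_netlist = seen_netlist or section == "@Netlist"
            continue
        if section == "@Netlist":
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"line {lineno}: connection needs 'pre post weight'")
            try:
                pre, post = int(parts[0]), int(parts[1])
                w = float(parts[2])
                plastic = bool(int(parts[3])) if len(parts) > 3 else False
                sign = _CODE_SIGN[parts[4]] if len(parts) > 4 else "excitatory"
            except (ValueError, KeyError) as exc:
                raise ValueError(
                    f"line {lineno}: malformed connection {line!r}") from exc
            conns.append(Connection(pre, post, w, plastic, sign))
        elif section == "@Params":
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"line {lineno}: parameter needs 'name default'")
            name = parts[0]
            try:
                default = float(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: bad default in {line!r}") from exc
            if name == "n_neurons":
                n_neurons = int(default)
                continue
            overrides = {}
            for tok in parts[2:]:
                try:
                    nid, val = tok.split(":")
                    overrides[int(nid)] = float(val)
                except ValueError as exc:
                    raise ValueError(
                        f"line {lineno}: bad override {tok!r}") from exc
            params[name] = (default, overrides)
        else:
            raise ValueError(
                f"line {lineno}: content before any @section: {line!r}")
    if not seen_netlist:
        raise ValueError("missing @Netlist section")
    if n_neurons is None:
        raise ValueError("missing n_neurons entry in @Params")
    net = Netlist(n_neurons=n_neurons, connections=conns,
                  neuron_params=params)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Memory accounting
# ---------------------------------------------------------------------------

SNRAM_WORDS = 1024
WORDS_PER_SYNAPSE = 5
WORDS_PER_NEURON = 8
MAX_SYNAPSES_PER_PE = 256


def memory_map(layers: list, net: Netlist,
               stored_params: str = "plastic",
               words_per_synapse: int = WORDS_PER_SYNAPSE,
               words_per_neuron: int = WORDS_PER_NEURON) -> MemoryMap:
    """Capacity accounting for the default PE assignment.

    PE *p* hosts the *p*-th neuron of each virtual layer (input neurons in
    layer 1, excitatory then output neurons in layer 2, inhibitory neurons
    in layer 3); the number of PEs is the largest layer population.  Each
    hosted neuron costs 8 words plus 5 words per afferent synapse with
    stored parameters.  ``stored_params`` selects which synapses carry the
    full parameter block: ``"plastic"`` (default; static synapses are
    resolved from the connection map alone) or ``"all"``.  Violations (over
    1024 words, or over 256 synapses per PE) are reported on the map, not
    raised.
    """
    if stored_params not in ("plastic", "all"):
        raise ValueError("stored_params must be 'plastic' or 'all'")
    vl: dict[int, list[int]] = {1: [], 2: [], 3: []}
    start = 0
    for spec in layers:
        ids = list(range(start, start + spec.size))
        vl[spec.virtual_layer].extend(ids)
        start += spec.size
    n_pe = max((len(v) for v in vl.values()), default=0)
    stored_deg = np.zeros(net.n_neurons, dtype=int)
    full_deg = np.zeros(net.n_neurons, dtype=int)
    for c in net.connections:
        full_deg[c.post] += 1
        if stored_params == "all" or c.plastic:
            stored_deg[c.post] += 1
    pe_words = [0] * n_pe
    pe_syn = [0] * n_pe
    for ids in vl.values():
        for slot, nid in enumerate(ids):
            pe_words[slot] += words_per_neuron + \
                words_per_synapse * int(stored_deg[nid])
            pe_syn[slot] += int(full_deg[nid])
    return MemoryMap(pe_words, pe_syn, SNRAM_WORDS, MAX_SYNAPSES_PER_PE)


def network_summary(layers: list, net: Netlist) -> dict:
    """JSON-serializable summary: layer sizes, degrees, memory report."""
    in_deg = np.zeros(net.n_neurons, dtype=int)
    out_deg = np.zeros(net.n_neurons, dtype=int)
    for c in net.connections:
        in_deg[c.post] += 1
        out_deg[c.pre] += 1
    mm = memory_map(layers, net)
    return {
        "layers": {l.name: l.size for l in layers},
        "n_neurons": net.n_neurons,
        "n_synapses": len(net.connections),
        "n_plastic": sum(1 for c in net.connections if c.plastic),
        "in_degree_max": int(in_deg.max(initial=0)),
        "out_degree_max": int(out_deg.max(initial=0)),
        "memory": {
            "total_words": mm.total_words,
            "peak_pe_utilization": mm.utilization,
            "over_capacity_pes": mm.over_capacity,
            "over_synapse_limit_pes": mm.over_synapse_limit,
        },
    }
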