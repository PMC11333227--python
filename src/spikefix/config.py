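"""Key-value run configuration.

A run is fully described by a flat mapping (usually loaded from YAML) whose
keys override the defaults of the parameter dataclasses: soma and synapse
constants, STDP and homeostasis constants, the fixed-point precision mode,
the encoding rates and the static network weights.  ``RunConfig.echo()``
returns the complete resolved parameter set for provenance; experiment
results embed it verbatim.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .dynamics import HomeostasisParams, LIFParams, STDPParams
from .encoding import EncodingConfig
from .fixedpoint import MODE_DEFAULTS, FixedSpec
from .network import WeightDefaults


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one simulation/experiment run."""

    lif: LIFParams = field(default_factory=LIFParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    homeostasis: HomeostasisParams = field(default_factory=HomeostasisParams)
    spec: FixedSpec = field(default_factory=FixedSpec)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    weights: WeightDefaults = field(default_factory=WeightDefaults)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        """Build from a flat key-value mapping.

        Recognized keys are the field names of the component dataclasses
        (``v_th``, ``tau_m``, ``d_apre``, ``w_norm``, ``d_theta``,
        ``present_ms``, ``max_rate_hz``, ``exc_inh`` ...) plus
        ``precision`` (fixed8|fixed16|fixed32|float), ``lsb_uv`` and
        ``weight_scale_bits``.  Unknown keys raise.
        """
        cfg = dict(cfg or {})
        mode = cfg.pop("precision", "fixed16")
        spec_over = {}
        for key in ("lsb_uv", "weight_scale_bits", "width_bits"):
            if key in cfg:
                spec_over[key] = cfg.pop(key)
        spec = FixedSpec.from_mode(mode, **spec_over)
        parts = {}
        for name, klass in (("lif", LIFParams), ("stdp", STDPParams),
                            ("homeostasis", HomeostasisParams),
                            ("encoding", EncodingConfig),
                            ("weights", WeightDefaults)):
            kw = {}
            for f in fields(klass):
                if f.name in cfg:
                    kw[f.name] = cfg.pop(f.name)
            parts[name] = klass(**kw)
        if cfg:
            raise ValueError(f"unknown config keys: {sorted(cfg)}")
        return cls(spec=spec, **parts)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def echo(self) -> dict:
        """Full resolved parameter set, JSON-serializable, for provenance."""
        return {
            "lif": asdict(self.lif),
            "stdp": asdict(self.stdp),
            "homeostasis": asdict(self.homeostasis),
            "precision": asdict(self.spec),
            "encoding": asdict(self.encoding),
            "weights": asdict(self.weights),
        }
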