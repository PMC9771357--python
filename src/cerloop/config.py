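"""Simulation configuration: population counts, neuron parameters, scaling.

The network represents a parasagittal stripe of cerebellar cortex plus its
deep-nuclear target: mossy fibers (MF), granule cells (GrC), Golgi cells
(GoC), Purkinje cells (PC), deep cerebellar nuclei cells (DCN), climbing
fibers (CF), and the molecular-layer interneurons -- basket cells (BC, a
subset of which are PC-MLIs receiving Purkinje feedback) and stellate
cells (SC).  All dynamics run on a fixed 1-ms clock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

#: populations that have intrinsic membrane dynamics (MF and CF are
#: source-only spike generators driven by the protocol layer)
DYNAMIC_POPULATIONS = ("grc", "goc", "pc", "bc", "sc", "dcn")
ALL_POPULATIONS = ("mf", "cf") + DYNAMIC_POPULATIONS

DEFAULT_COUNTS = {
    "mf": 600,
    "grc": 12000,
    "goc": 900,
    "pc": 24,
    "dcn": 8,
    "cf": 4,
    "bc": 96,
    "sc": 240,
    "pcmli": 9,
}

#: convergence counts (per-target source counts); these are invariant
#: under scaling so the operating point of each cell type is preserved
CONVERGENCE = {
    ("mf", "grc"): 4,     # each granule cell receives exactly 4 mossy fibers
    ("goc", "grc"): 4,
    ("mf", "goc"): 20,
    ("grc", "goc"): 100,
    ("grc", "bc"): 40,
    ("grc", "sc"): 40,
    ("bc", "pc"): 8,
    ("sc", "pc"): 30,
    ("pc", "pcmli"): 6,   # PC feedback onto the designated PC-MLI subset
    ("mf", "dcn"): 100,
    ("pc", "dcn"): 24,
}


class ConfigurationError(ValueError):
    """Raised for invalid population counts or malformed config files."""


@dataclass
class NeuronParams:
    """Leaky conductance-based point neuron with an adaptive threshold.

    Units: potentials in mV, time constants in ms.  Conductances are
    expressed relative to membrane capacitance, so ``g_leak`` is the
    inverse membrane time constant (1/ms) and synaptic increments are the
    dimensionless per-spike jumps of the two conductance accumulators.
    ``bias`` is an intrinsic depolarizing drive (mV/ms) used for
    pacemaking populations (PC, DCN).
    """

    g_leak: float = 0.1
    e_leak: float = -70.0
    e_exc: float = 0.0
    e_inh: float = -80.0
    tau_exc: float = 3.0
    tau_inh: float = 8.0
    theta0: float = -50.0
    dtheta: float = 6.0
    tau_theta: float = 30.0
    bias: float = 0.0
    v_reset: Optional[float] = None  # default: reset to e_leak

    def __post_init__(self) -> None:
        for name in ("tau_exc", "tau_inh", "tau_theta"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.g_leak < 0:
            raise ConfigurationError("g_leak must be >= 0")
        if self.e_inh >= self.theta0:
            raise ConfigurationError("inhibitory reversal must lie below threshold")
        if self.v_reset is None:
            self.v_reset = self.e_leak


def default_neuron_params() -> dict[str, NeuronParams]:
    """Per-population defaults, tuned so that with background mossy-fiber
    drive alone the populations sit in their in-vivo-like rate bands
    (PC simple spikes 40-100 Hz, granule cells sparse, DCN tonically
    active, MLIs at tens of Hz)."""
    return {
        "grc": NeuronParams(g_leak=0.20, tau_exc=6.0, tau_inh=12.0,
                            theta0=-50.0, dtheta=3.0, tau_theta=50.0),
        "goc": NeuronParams(g_leak=0.10, tau_exc=3.0, tau_inh=10.0,
                            theta0=-55.0, dtheta=6.0, tau_theta=50.0, bias=0.4),
        "pc": NeuronParams(g_leak=0.10, tau_exc=2.0, tau_inh=8.0,
                           theta0=-55.0, dtheta=5.0, tau_theta=25.0, bias=0.0),
        "bc": NeuronParams(g_leak=0.10, tau_exc=3.0, tau_inh=10.0,
                           theta0=-55.0, dtheta=6.0, tau_theta=40.0, bias=1.8),
        "sc": NeuronParams(g_leak=0.10, tau_exc=3.0, tau_inh=10.0,
                           theta0=-55.0, dtheta=6.0, tau_theta=40.0, bias=1.8),
        "dcn": NeuronParams(g_leak=0.08, tau_exc=5.0, tau_inh=12.0,
                            theta0=-55.0, dtheta=2.0, tau_theta=30.0, bias=7.18),
    }


#: per-projection synaptic weights (conductance increment per presynaptic
#: spike, in the dimensionless units of NeuronParams).  The granule->PC
#: weight is the *initial* value of the plastic parallel-fiber synapses.
DEFAULT_WEIGHTS = {
    ("mf", "grc"): 0.18,
    ("goc", "grc"): 0.22,
    ("mf", "goc"): 0.02,
    ("grc", "goc"): 0.02,
    ("grc", "pc"): 0.04,
    ("grc", "bc"): 0.006,
    ("grc", "sc"): 0.006,
    ("bc", "pc"): 0.55,
    ("sc", "pc"): 0.012,
    ("pc", "pcmli"): 0.15,
    ("mf", "dcn"): 0.006,
    ("pc", "dcn"): 0.03,
    ("cf", "pc"): 15.0,   # climbing-fiber input reliably fires the PC
}


@dataclass
class SimConfig:
    """Full simulation configuration.

    ``scale_factor`` uniformly down-scales the granule-layer populations
    (MF, GrC, GoC) for desk-scale runs while keeping convergence counts
    and the cortical-output / molecular-layer populations fixed, and
    rescaling per-spike increments of the scaled projections to preserve
    total mean input conductance.
    """

    dt: float = 1.0
    n_mf: int = DEFAULT_COUNTS["mf"]
    n_grc: int = DEFAULT_COUNTS["grc"]
    n_goc: int = DEFAULT_COUNTS["goc"]
    n_pc: int = DEFAULT_COUNTS["pc"]
    n_dcn: int = DEFAULT_COUNTS["dcn"]
    n_cf: int = DEFAULT_COUNTS["cf"]
    n_bc: int = DEFAULT_COUNTS["bc"]
    n_sc: int = DEFAULT_COUNTS["sc"]
    n_pcmli: int = DEFAULT_COUNTS["pcmli"]
    feedback_enabled: bool = True
    seed: int = 0
    scale_factor: Optional[float] = None
    neuron_params: dict = field(default_factory=default_neuron_params)
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    #: plastic parallel-fiber weight bounds [0, w_max]
    pf_w_max: float = 0.05
    #: extra depolarizing drive (mV/ms) given to the designated PC-MLIs,
    #: compensating the tonic Purkinje-collateral inhibition they receive
    #: so their baseline rate matches other basket cells
    pcmli_bias_extra: float = 10.0
    #: strength of the CR-dependent suppression of the US-evoked climbing
    #: fiber spike (nucleo-olivary feedback); 0 disables it
    nucleo_olivary_gain: float = 1.0
    cf_spontaneous_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.scale_factor is not None:
            self._apply_scale(self.scale_factor)
        self.validate()

    def _apply_scale(self, s: float) -> None:
        if not (0 < s <= 1):
            raise ConfigurationError("scale_factor must be in (0, 1]")
        for pop in ("mf", "grc", "goc"):
            key = f"n_{pop}"
            setattr(self, key, max(1, round(DEFAULT_COUNTS[pop] * s)))
        # preserve total mean parallel-fiber conductance onto PC/MLIs:
        # each PC receives n_grc/n_pc parallel fibers, so fewer granule
        # cells mean proportionally larger per-spike increments
        grc_ratio = DEFAULT_COUNTS["grc"] / self.n_grc
        w = dict(self.weights)
        w[("grc", "pc")] = w[("grc", "pc")] * grc_ratio
        self.weights = w
        self.pf_w_max = self.pf_w_max * grc_ratio

    def validate(self) -> None:
        if self.dt != 1.0:
            raise ConfigurationError("dt is fixed at 1 ms")
        for pop in ALL_POPULATIONS:
            if self.counts[pop] <= 0:
                raise ConfigurationError(f"population count n_{pop} must be > 0")
        if self.n_pcmli > self.n_bc:
            raise ConfigurationError("n_pcmli cannot exceed n_bc")
        if self.n_pcmli <= 0:
            raise ConfigurationError("n_pcmli must be > 0")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "mf": self.n_mf, "grc": self.n_grc, "goc": self.n_goc,
            "pc": self.n_pc, "dcn": self.n_dcn, "cf": self.n_cf,
            "bc": self.n_bc, "sc": self.n_sc,
        }

    # -- JSON round trip ---------------------------------------------------

    _SCALARS = ("dt", "n_mf", "n_grc", "n_goc", "n_pc", "n_dcn", "n_cf",
                "n_bc", "n_sc", "n_pcmli", "feedback_enabled", "seed",
                "scale_factor", "pf_w_max", "pcmli_bias_extra",
                "nucleo_olivary_gain", "cf_spontaneous_hz")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self._SCALARS}
        d["neuron_params"] = {p: asdict(np_) for p, np_ in self.neuron_params.items()}
        d["weights"] = {f"{a}->{b}": w for (a, b), w in self.weights.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        known = set(cls._SCALARS) | {"neuron_params", "weights"}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: d[k] for k in cls._SCALARS if k in d}
        if "neuron_params" in d:
            kwargs["neuron_params"] = {
                p: NeuronParams(**vals) for p, vals in d["neuron_params"].items()
            }
        if "weights" in d:
            kwargs["weights"] = {
                tuple(k.split("->")): float(v) for k, v in d["weights"].items()
            }
        # scale_factor was already applied before serialization
        kwargs.pop("scale_factor", None)
        return cls(**kwargs)
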