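"""The ten three-population demographic models.

All models share the fixed topology ((STH, PLN), DST): an ancestral
population splits into DST (desert) and an eastern ancestor E, which later
splits into STH (southern) and PLN (plains).  Parameters follow the
dadi/moments convention: relative sizes ``nu`` (units of N_ref), epoch
durations ``T`` (units of 2*N_ref generations) and scaled migration rates
``M = 2*N_ref*m`` (backward lineage-movement rates; ``m12`` is the rate at
which DST lineages trace back into STH).  Gene flow, where present, is
restricted to the adjacent pairs DST<->STH and STH<->PLN unless the model
name says "all".

The ``split_*`` family activates migration from each split onward; the
``refugia_*`` family imposes divergence in isolation followed by a
secondary-contact epoch, the variants differing in when contact begins
(adj_1: between the splits; adj_2: after the second split; adj_3: only in
a terminal sub-epoch) and in its pattern (barrier: no flow to or from
DST; asymmig: directional rates; symmig_all: every pair).  The two
headline models are refugia_adj_2 (secondary contact on both adjacent
pairs) and its nested barrier variant (refugia_adj_2 with the DST<->STH
rate pinned to zero), the riverine-barrier hypothesis.

The registry is declarative: each entry lists its free parameters and a
builder mapping a parameter dict to an :class:`~refugia._engine.EpochPlan`,
so a model structure can be corrected without touching solver code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._engine import EpochPlan

__all__ = [
    "POPS",
    "ENGINE_POPS",
    "ModelSpec",
    "DemographyModel",
    "get_model",
    "list_models",
    "nested_fixes",
    "NESTED_PAIRS",
    "ParameterError",
]

POPS = ("DST", "STH", "PLN")
#: engine population panel; E = eastern (STH+PLN) ancestor, ANC = root
ENGINE_POPS = ("DST", "STH", "PLN", "E", "ANC")
_DST, _STH, _PLN, _E, _ANC = range(5)


class ParameterError(ValueError):
    """Raised for non-positive sizes/durations or negative migration."""


def _sym(a: int, b: int, rate: float) -> dict:
    return {(a, b): rate, (b, a): rate}


def _assemble(recent, mid) -> EpochPlan:
    """Stack present-epoch specs into engine arrays.

    ``recent``: [(duration, {(i, j): M})] epochs with DST/STH/PLN alive,
    ordered from the present backward; ``mid``: same with DST/E alive.
    A final unbounded root epoch (ANC, size 1) is appended.
    """
    n_epochs = len(recent) + len(mid) + 1
    P = len(ENGINE_POPS)
    nu = np.ones((n_epochs, P))
    mig = np.zeros((n_epochs, P, P))
    relabel = np.tile(np.arange(P), (n_epochs, 1))
    durations = []
    e = 0
    for dur, pairs, sizes in recent + mid:
        durations.append(dur)
        for p, s in sizes.items():
            nu[e, p] = s
        for (i, j), rate in pairs.items():
            mig[e, i, j] = rate
        e += 1
    # entering the first mid epoch: STH, PLN -> E
    relabel[len(recent), [_STH, _PLN]] = _E
    # entering the root epoch: DST, E -> ANC
    relabel[n_epochs - 1, [_DST, _E, _STH, _PLN]] = _ANC
    boundaries = np.cumsum(durations)
    return EpochPlan(boundaries, nu, mig, relabel)


def _check(params: dict, names: tuple) -> dict:
    missing = set(names) - set(params)
    extra = set(params) - set(names)
    if missing or extra:
        raise ParameterError(
            f"parameter mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}")
    p = {k: float(v) for k, v in params.items()}
    for k, v in p.items():
        if not np.isfinite(v):
            raise ParameterError(f"{k} must be finite, got {v}")
        if k.startswith(("nu", "T")) and v <= 0:
            raise ParameterError(f"{k} must be positive, got {v}")
        if k.startswith("m") and v < 0:
            raise ParameterError(f"{k} must be non-negative, got {v}")
    return p


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry: a named model family with free parameters."""

    name: str
    param_names: tuple
    description: str
    builder: Callable = field(repr=False)

    @property
    def k(self) -> int:
        """Number of free parameters (counted from the registry)."""
        return len(self.param_names)

    def instantiate(self, params) -> "DemographyModel":
        if not isinstance(params, dict):
            params = dict(zip(self.param_names, params))
        return DemographyModel(self, _check(params, self.param_names))


@dataclass(frozen=True)
class DemographyModel:
    """A model family instantiated at concrete parameter values."""

    spec: ModelSpec
    params: dict

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def param_names(self) -> tuple:
        return self.spec.param_names

    @property
    def param_values(self) -> np.ndarray:
        return np.array([self.params[n] for n in self.param_names])

    def plan(self) -> EpochPlan:
        return self.spec.builder(self.params)

    def to_msprime(self, n_ref: float = 10_000.0):
        """Convert to an msprime Demography (diploid sizes ``nu * n_ref``,
        times ``T * 2 * n_ref`` generations, per-generation migration
        ``M / (2 * n_ref)``)."""
        from .simulate import plan_to_msprime

        return plan_to_msprime(self.plan(), n_ref)


def _b_split_nomig(p):
    return _assemble(
        recent=[(p["T2"], {}, {_DST: p["nu1"], _STH: p["nu2"], _PLN: p["nu3"]})],
        mid=[(p["T1"], {}, {_DST: p["nu1"], _E: p["nuA"]})])


def _b_split_symmig_adjacent(p):
    sz3 = {_DST: p["nu1"], _STH: p["nu2"], _PLN: p["nu3"]}
    return _assemble(
        recent=[(p["T2"], {**_sym(_DST, _STH, p["m1"]), **_sym(_STH, _PLN, p["m2"])}, sz3)],
        mid=[(p["T1"], _sym(_DST, _E, p["mA"]), {_DST: p["nu1"], _E: p["nuA"]})])


def _b_split_asymmig_adjacent(p):
    sz3 = {_DST: p["nu1"], _STH: p["nu2"], _PLN: p["nu3"]}
    rec = {(_DST, _STH): p["m12"], (_STH, _DST): p["m21"],
           (_STH, _PLN): p["m23"], (_PLN, _STH): p["m32"]}
    mid = {(_DST, _E): p["mA12"], (_E, _DST): p["mA21"]}
    return _assemble(
        recent=[(p["T2"], rec, sz3)],
        mid=[(p["T1"], mid, {_DST: p["nu1"], _E: p["nuA"]})])


def _b_split_sym_mig_all(p):
    sz3 = {_DST: p["nu1"], _STH: p["nu2"], _PLN: p["nu3"]}
    rec = {**_sym(_DST, _STH, p["m1"]), **_sym(_STH, _PLN, p["m2"]),
           **_sym(_DST, _PLN, p["m3"])}
    return _assemble(
        recent=[(p["T2"], rec, sz3)],
        mid=[(p["T1"], _sym(_DST, _E, p["mA"]), {_DST: p["nu1"], _E: p["nuA"]})])


def _b_refugia_adj_1(p):
    sz3 = {_DST: p["nu1"], _STH: p["nu2"], _PLN: p["nu3"]}
    sz2 = {_DST: p["nu1"], _E: p["nuA"]}
    return _assemble(
        recent=[(p["T2"], {**_sym(_DST, _STH, p["m1"]), **_sym(_STH, _PLN, p["m2"])}, sz3)],
        mid=[(p["T1b"], _sym(_DST, _E, p["mA"]), sz2),
             (p["T1a"], {}, sz2)])


def _b_refugia_adj_2(p):
    sz3 = {_DST: p["nu1"], _STH: p["nu2"], _PLN: p["nu3"]}
    return _assemble(
        recent=[(p["T2"], {**_sym(_DST, _STH, p["m1"]), **_sym(_STH, _PLN, p["m2"])}, sz3)],
        mid=[(p["T1"], {}, {_DST: p["nu1"], _E: p["nuA"]})])


def _b_refugia_adj_3(p):
    sz3 = {_DST: p["nu1"], _STH: p["nu2"], _PLN: p["nu3"]}
    return _assemble(
        recent=[(p["T2b"], {**_sym(_DST, _STH, p["m1"]), **_sym(_STH, _PLN, p["m2"])}, sz3),
                (p["T2a"], {}, sz3)],
        mid=[(p["T1"], {}, {_DST: p["nu1"], _E: p["nuA"]})])


def _b_refugia_barrier(p):
    sz3 = {_DST: p["nu1"], _STH: p["nu2"], _PLN: p["nu3"]}
    return _assemble(
        recent=[(p["T2"], _sym(_STH, _PLN, p["m2"]), sz3)],
        mid=[(p["T1"], {}, {_DST: p["nu1"], _E: p["nuA"]})])


def _b_refugia_asymmig_adjacent(p):
    sz3 = {_DST: p["nu1"], _STH: p["nu2"], _PLN: p["nu3"]}
    rec = {(_DST, _STH): p["m12"], (_STH, _DST): p["m21"],
           (_STH, _PLN): p["m23"], (_PLN, _STH): p["m32"]}
    return _assemble(
        recent=[(p["T2"], rec, sz3)],
        mid=[(p["T1"], {}, {_DST: p["nu1"], _E: p["nuA"]})])


def _b_refugia_symmig_all(p):
    sz3 = {_DST: p["nu1"], _STH: p["nu2"], _PLN: p["nu3"]}
    rec = {**_sym(_DST, _STH, p["m1"]), **_sym(_STH, _PLN, p["m2"]),
           **_sym(_DST, _PLN, p["m3"])}
    return _assemble(
        recent=[(p["T2"], rec, sz3)],
        mid=[(p["T1"], {}, {_DST: p["nu1"], _E: p["nuA"]})])


_REGISTRY = {
    s.name: s for s in [
        ModelSpec(
            "split_nomig", ("nu1", "nuA", "nu2", "nu3", "T1", "T2"),
            "Two splits, no gene flow at any stage.", _b_split_nomig),
        ModelSpec(
            "split_symmig_adjacent",
            ("nu1", "nuA", "nu2", "nu3", "mA", "m1", "m2", "T1", "T2"),
            "Symmetric adjacent gene flow active from each split "
            "(DST<->E, then DST<->STH and STH<->PLN).",
            _b_split_symmig_adjacent),
        ModelSpec(
            "split_asymmig_adjacent",
            ("nu1", "nuA", "nu2", "nu3", "mA12", "mA21", "m12", "m21",
             "m23", "m32", "T1", "T2"),
            "Asymmetric adjacent gene flow active from each split.",
            _b_split_asymmig_adjacent),
        ModelSpec(
            "split_sym_mig_all",
            ("nu1", "nuA", "nu2", "nu3", "mA", "m1", "m2", "m3", "T1", "T2"),
            "Symmetric gene flow between all pairs from each split.",
            _b_split_sym_mig_all),
        ModelSpec(
            "refugia_adj_1",
            ("nu1", "nuA", "nu2", "nu3", "mA", "m1", "m2", "T1a", "T1b", "T2"),
            "Isolation after the first split, then DST<->E secondary "
            "contact before the second split; adjacent flow afterwards.",
            _b_refugia_adj_1),
        ModelSpec(
            "refugia_adj_2",
            ("nu1", "nuA", "nu2", "nu3", "m1", "m2", "T1", "T2"),
            "Initial DST/(STH+PLN) split with no gene flow, then the "
            "STH/PLN split with adjacent secondary contact "
            "(DST<->STH and STH<->PLN).",
            _b_refugia_adj_2),
        ModelSpec(
            "refugia_adj_3",
            ("nu1", "nuA", "nu2", "nu3", "m1", "m2", "T1", "T2a", "T2b"),
            "Both splits in isolation; adjacent secondary contact only in "
            "a terminal sub-epoch.",
            _b_refugia_adj_3),
        ModelSpec(
            "refugia_barrier",
            ("nu1", "nuA", "nu2", "nu3", "m2", "T1", "T2"),
            "As refugia_adj_2 with a barrier to DST gene flow: secondary "
            "contact between STH and PLN only.",
            _b_refugia_barrier),
        ModelSpec(
            "refugia_asymmig_adjacent",
            ("nu1", "nuA", "nu2", "nu3", "m12", "m21", "m23", "m32", "T1", "T2"),
            "As refugia_adj_2 with directional (asymmetric) adjacent "
            "secondary contact.",
            _b_refugia_asymmig_adjacent),
        ModelSpec(
            "refugia_symmig_all",
            ("nu1", "nuA", "nu2", "nu3", "m1", "m2", "m3", "T1", "T2"),
            "As refugia_adj_2 with secondary contact between all pairs.",
            _b_refugia_symmig_all),
    ]
}

#: (full, nested) -> {full-model parameter: fixed value}
NESTED_PAIRS = {
    ("refugia_adj_2", "refugia_barrier"): {"m1": 0.0},
    ("refugia_adj_2", "split_nomig"): {"m1": 0.0, "m2": 0.0},
    ("refugia_barrier", "split_nomig"): {"m2": 0.0},
    ("refugia_symmig_all", "refugia_adj_2"): {"m3": 0.0},
    ("refugia_symmig_all", "refugia_barrier"): {"m1": 0.0, "m3": 0.0},
    ("refugia_symmig_all", "split_nomig"): {"m1": 0.0, "m2": 0.0, "m3": 0.0},
    ("refugia_asymmig_adjacent", "split_nomig"):
        {"m12": 0.0, "m21": 0.0, "m23": 0.0, "m32": 0.0},
    ("split_symmig_adjacent", "split_nomig"):
        {"mA": 0.0, "m1": 0.0, "m2": 0.0},
    ("split_sym_mig_all", "split_symmig_adjacent"): {"m3": 0.0},
    ("split_sym_mig_all", "split_nomig"):
        {"mA": 0.0, "m1": 0.0, "m2": 0.0, "m3": 0.0},
    ("split_asymmig_adjacent", "split_nomig"):
        {"mA12": 0.0, "mA21": 0.0, "m12": 0.0, "m21": 0.0,
         "m23": 0.0, "m32": 0.0},
}


def get_model(name: str) -> ModelSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(_REGISTRY)}") from None


def list_models() -> dict:
    """Registry metadata: name -> (k, param_names, description)."""
    return {
        name: {"k": s.k, "param_names": s.param_names,
               "description": s.description}
        for name, s in _REGISTRY.items()
    }


def nested_fixes(full: str, nested: str) -> dict:
    """The full-model parameters fixed (to 0) under the nested model."""
    try:
        return dict(NESTED_PAIRS[(full, nested)])
    except KeyError:
        raise ValueError(
            f"{nested!r} is not registered as nested within {full!r}") from None
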