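"""Parameter sets for the supported neuron and synapse models.

All quantities live in a single consistent unit system: pF, nS, mV, ms,
pA.  Firing rates are expressed in Hz at the API surface and converted to
events/ms internally.

Hodgkin-Huxley and Morris-Lecar parameters are frequently quoted in the
literature as per-area densities; here they are stored as absolute
conductances for a patch of membrane compatible with the absolute (nS)
quantal synaptic conductances.  For the HH cell the mapping is the common
cortical single-compartment convention (c_m = 200 pF, leak in nS as
quoted, active conductances in uS, i.e. a factor ``HH_ACTIVE_SCALE`` =
1000 relative to the density figures).  The Morris-Lecar cell has no such
standard absolute convention; its scale factors (``ML_*_SCALE`` below)
were calibrated once so that the cell is a type II oscillator whose
transfer function under Poisson bombardment is bell-shaped with a peak
near an 8 Hz excitatory input rate (see docs/methods.md).
"""

from __future__ import annotations

from typing import NamedTuple

import yaml

from .errors import ParameterError


class SynapseParams(NamedTuple):
    """Exponential-decay conductance synapse.

    ``Q_e``/``Q_i`` are the quantal conductance increments (nS) applied on
    each presynaptic spike, ``tau`` the shared decay time constant (ms),
    ``E_e``/``E_i`` the reversal potentials (mV).
    """

    Q_e: float = 1.5
    Q_i: float = 5.0
    tau: float = 5.0
    E_e: float = 0.0
    E_i: float = -80.0


class AdExParams(NamedTuple):
    """Adaptive exponential integrate-and-fire cell.

    Spike rule: whenever v exceeds ``v_t`` the neuron emits a spike, v is
    reset to ``v_rest`` and clamped there for ``T_refr`` ms, and the
    adaptation current w is incremented by ``b``.
    """

    c_m: float = 150.0      # pF
    g_L: float = 10.0       # nS
    E_L: float = -65.0      # mV
    Delta: float = 2.0      # mV, spike sharpness
    v_t: float = -50.0      # mV, spike trigger
    v_rest: float = -65.0   # mV, reset value
    T_refr: float = 5.0     # ms
    a: float = 4.0          # nS, subthreshold adaptation
    b: float = 60.0         # pA, spike-triggered adaptation
    tau_w: float = 500.0    # ms


class HHParams(NamedTuple):
    """Single-compartment Hodgkin-Huxley cell (Traub-Miles kinetics with a
    slow non-inactivating K+ current for spike-frequency adaptation).

    Spikes are detected as upward crossings of ``spike_threshold``.
    """

    c_m: float = 200.0          # pF
    g_L: float = 10.0           # nS
    g_Na: float = 20000.0       # nS
    g_K: float = 6000.0         # nS
    g_M: float = 30.0           # nS (0 for FS cells)
    E_L: float = -65.0          # mV
    E_Na: float = 50.0          # mV
    E_K: float = -90.0          # mV
    V_T: float = -53.5          # mV, kinetics offset
    tau_max: float = 400.0      # ms, slow K+ time-constant scale
    spike_threshold: float = 10.0  # mV


class MLParams(NamedTuple):
    """Morris-Lecar cell (calcium/potassium, type II excitability).

    ``I0`` is a constant bias current (pA).  ``phi`` (1/ms) sets the
    potassium gating rate.  Spikes are detected as upward crossings of
    ``spike_threshold``.
    """

    c_m: float = 150.0          # pF
    g_L: float = 20.0           # nS
    g_Ca: float = 80.0          # nS
    g_K: float = 160.0          # nS
    E_L: float = -50.0          # mV (-70 for FS cells)
    E_Ca: float = 120.0         # mV
    E_K: float = -84.0          # mV
    V1: float = -1.2            # mV, Ca activation midpoint
    V2: float = 18.0            # mV, Ca activation slope
    V3: float = 2.0             # mV, K activation midpoint
    V4: float = 30.0            # mV, K activation slope
    phi: float = 0.05           # 1/ms
    I0: float = 1300.0          # pA
    spike_threshold: float = 10.0  # mV


# Documented unit-calibration scale factors (see module docstring).
HH_ACTIVE_SCALE = 1000.0   # nS per quoted density unit for g_Na, g_K, g_M
ML_COND_SCALE = 1.0        # nS per quoted density unit for g_L, g_Ca, g_K

# Canonical cell types ------------------------------------------------------

ADEX_RS = AdExParams()
ADEX_FS = AdExParams(Delta=0.5, a=0.0, b=0.0)

HH_RS = HHParams()
HH_FS = HHParams(g_M=0.0)

ML_RS = MLParams(E_L=-50.0)
ML_FS = MLParams(E_L=-70.0)

SYNAPSE_DEFAULT = SynapseParams()          # AdEx and HH networks
SYNAPSE_ML = SynapseParams(Q_e=4.0, Q_i=10.0)

MODELS = ("adex", "hh", "ml")

_DEFAULTS = {
    ("adex", "rs"): ADEX_RS,
    ("adex", "fs"): ADEX_FS,
    ("hh", "rs"): HH_RS,
    ("hh", "fs"): HH_FS,
    ("ml", "rs"): ML_RS,
    ("ml", "fs"): ML_FS,
}

_PARAM_TYPES = {"adex": AdExParams, "hh": HHParams, "ml": MLParams}


def default_params(model: str, cell: str):
    """Default parameter set for (model, cell) with model in
    {'adex','hh','ml'} and cell in {'rs','fs'}."""
    try:
        return _DEFAULTS[(model.lower(), cell.lower())]
    except KeyError:
        raise ParameterError(f"unknown model/cell combination {model!r}/{cell!r}")


def default_synapse(model: str) -> SynapseParams:
    if model.lower() == "ml":
        return SYNAPSE_ML
    if model.lower() in MODELS:
        return SYNAPSE_DEFAULT
    raise ParameterError(f"unknown model {model!r}")


def validate_synapse(syn: SynapseParams) -> None:
    if not (syn.Q_e > 0 and syn.Q_i > 0 and syn.tau > 0):
        raise ParameterError("Q_e, Q_i and tau must be positive")
    if not syn.E_i < syn.E_e:
        raise ParameterError("inhibitory reversal must lie below excitatory reversal")


def validate_params(model: str, p) -> None:
    """Cheap invariant checks on a parameter set."""
    model = model.lower()
    if model == "adex":
        if not (p.c_m > 0 and p.g_L > 0 and p.tau_w > 0 and p.T_refr > 0):
            raise ParameterError("c_m, g_L, tau_w, T_refr must be positive")
        if not p.Delta > 0:
            raise ParameterError("Delta must be positive")
        if p.v_rest > p.v_t:
            raise ParameterError("v_rest must not exceed v_t")
    elif model == "hh":
        if not (p.c_m > 0 and p.g_L > 0 and p.g_Na > 0 and p.g_K > 0 and p.g_M >= 0):
            raise ParameterError("conductances must be positive (g_M >= 0)")
        if not (p.E_K < p.E_L < p.E_Na):
            raise ParameterError("require E_K < E_L < E_Na")
    elif model == "ml":
        if not (p.c_m > 0 and p.g_L > 0 and p.g_Ca > 0 and p.g_K > 0):
            raise ParameterError("conductances must be positive")
        if not (p.E_K < p.E_L < p.E_Ca):
            raise ParameterError("require E_K < E_L < E_Ca")
        if not (p.V2 > 0 and p.V4 > 0):
            raise ParameterError("V2 and V4 must be positive")
    else:
        raise ParameterError(f"unknown model {model!r}")


# Plain-text (YAML) round-tripping ------------------------------------------

def params_to_dict(p) -> dict:
    return dict(p._asdict())


def params_from_dict(model: str, d: dict):
    cls = _PARAM_TYPES.get(model.lower())
    if cls is None:
        raise ParameterError(f"unknown model {model!r}")
    try:
        return cls(**{k: float(v) for k, v in d.items()})
    except TypeError as exc:
        raise ParameterError(f"bad field for {model}: {exc}") from exc


def dump_params(path, model: str, cell_params: dict, synapse: SynapseParams) -> None:
    """Write a hierarchical config: model id, per-cell parameter sets, synapse."""
    doc = {
        "model": model,
        "cells": {name: params_to_dict(p) for name, p in cell_params.items()},
        "synapse": params_to_dict(synapse),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path):
    """Inverse of :func:`dump_params`; returns (model, cells dict, synapse)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    model = doc["model"]
    cells = {name: params_from_dict(model, d) for name, d in doc.get("cells", {}).items()}
    syn = SynapseParams(**{k: float(v) for k, v in doc["synapse"].items()})
    return model, cells, syn
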