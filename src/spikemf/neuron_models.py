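"""Single-neuron dynamics: AdEx, Hodgkin-Huxley and Morris-Lecar cells.

Provides elementary step/derivative functions, spike detection on voltage
traces, and seeded single-neuron simulations under Poissonian synaptic
bombardment (the raw material for transfer-function measurement).

Integration is fixed-step explicit Euler, dt = 0.1 ms for AdEx and
Morris-Lecar and dt = 0.01 ms for Hodgkin-Huxley (fast Na+ gating), which
is appropriate in the stochastic-input setting where trajectories are not
smooth anyway.  The heavy loops are numba-compiled; the thin Python
wrappers validate inputs and raise package exceptions.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
from numba import njit

from .errors import IntegrationError, ParameterError
from .params import (AdExParams, HHParams, MLParams, SynapseParams,
                     default_params, default_synapse, validate_params,
                     validate_synapse)

DEFAULT_DT = {"adex": 0.1, "hh": 0.01, "ml": 0.1}

_EXP_CAP = 30.0  # cap on the AdEx exponential argument, overflow guard


class SingleNeuronResult(NamedTuple):
    """Outcome of a single-neuron simulation."""

    spike_times: np.ndarray   # ms
    rate: float               # Hz, spike count / duration
    t: np.ndarray | None      # ms, only when recording was requested
    v: np.ndarray | None      # mV
    g_e: np.ndarray | None    # nS
    g_i: np.ndarray | None    # nS


# ---------------------------------------------------------------------------
# AdEx
# ---------------------------------------------------------------------------

@njit
def _adex_update(v, w, ge, gi, p, syn, dt):
    """One Euler step; returns (v, w, spiked)."""
    i_syn = ge * (syn.E_e - v) + gi * (syn.E_i - v)
    arg = (v - p.v_t) / p.Delta
    if arg > _EXP_CAP:
        arg = _EXP_CAP
    i_exp = p.g_L * p.Delta * math.exp(arg)
    dv = (p.g_L * (p.E_L - v) + i_exp - w + i_syn) / p.c_m
    dw = (-w + p.a * (v - p.E_L)) / p.tau_w
    v2 = v + dt * dv
    w2 = w + dt * dw
    if v2 > p.v_t + 5.0 * p.Delta:
        return p.v_rest, w2 + p.b, True
    return v2, w2, False


def adex_step(state, params: AdExParams, synapse: SynapseParams,
              g_e: float, g_i: float, dt: float):
    """Advance an AdEx neuron one Euler step.

    ``state`` is (v, w).  Returns ((v, w), spiked).  The caller is
    responsible for the refractory clock: during the refractory period
    this function must not be called for the voltage (v is clamped).
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    v, w = float(state[0]), float(state[1])
    if not (math.isfinite(v) and math.isfinite(w)):
        bad = "v" if not math.isfinite(v) else "w"
        raise IntegrationError(f"non-finite state variable {bad!r}")
    v2, w2, spiked = _adex_update(v, w, float(g_e), float(g_i), params, synapse, dt)
    if not (math.isfinite(v2) and math.isfinite(w2)):
        bad = "v" if not math.isfinite(v2) else "w"
        raise IntegrationError(f"integration produced non-finite {bad!r}")
    return (v2, w2), bool(spiked)


# ---------------------------------------------------------------------------
# Hodgkin-Huxley
# ---------------------------------------------------------------------------

@njit
def _hh_rates(v, V_T, tau_max):
    """Voltage-dependent gating rates (1/ms) and the slow-K+ steady state.

    The three removable singularities are evaluated by their analytic
    limits.  Returns (a_n, b_n, a_m, b_m, a_h, b_h, p_inf, tau_p).
    """
    x = v - V_T - 15.0
    if abs(x) < 1e-7:
        a_n = 0.032 * 5.0
    else:
        a_n = 0.032 * x / (-math.expm1(-x / 5.0))
    b_n = 0.5 * math.exp(-(v - V_T - 10.0) / 40.0)

    y = v - V_T - 13.0
    if abs(y) < 1e-7:
        a_m = 0.32 * 4.0
    else:
        a_m = 0.32 * y / (-math.expm1(-y / 4.0))
    z = v - V_T - 40.0
    if abs(z) < 1e-7:
        b_m = 0.28 * 5.0
    else:
        b_m = 0.28 * z / math.expm1(z / 5.0)

    a_h = 0.128 * math.exp(-(v - V_T - 17.0) / 18.0)
    b_h = 4.0 / (1.0 + math.exp(-(v - V_T - 40.0) / 5.0))

    p_inf = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    tau_p = tau_max / (3.3 * math.exp((v + 35.0) / 20.0)
                       + math.exp(-(v + 35.0) / 20.0))
    return a_n, b_n, a_m, b_m, a_h, b_h, p_inf, tau_p


def hh_gating_rates(v: float, params: HHParams):
    """Gating rates at voltage v; total on finite input.

    Returns (alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h, p_inf, tau_p).
    """
    if not math.isfinite(v):
        raise ParameterError("v must be finite")
    return _hh_rates(float(v), params.V_T, params.tau_max)


@njit
def _hh_deriv(v, n, m, h, p_gate, p, syn, ge, gi):
    i_syn = ge * (syn.E_e - v) + gi * (syn.E_i - v)
    a_n, b_n, a_m, b_m, a_h, b_h, p_inf, tau_p = _hh_rates(v, p.V_T, p.tau_max)
    dv = (p.g_L * (p.E_L - v)
          + p.g_Na * m ** 3 * h * (p.E_Na - v)
          + p.g_K * n ** 4 * (p.E_K - v)
          + p.g_M * p_gate * (p.E_K - v)
          + i_syn) / p.c_m
    dn = a_n * (1.0 - n) - b_n * n
    dm = a_m * (1.0 - m) - b_m * m
    dh = a_h * (1.0 - h) - b_h * h
    dp = (p_inf - p_gate) / tau_p
    return dv, dn, dm, dh, dp


def hh_derivatives(state, params: HHParams, synapse: SynapseParams,
                   g_e: float, g_i: float):
    """Time derivatives of (v, n, m, h, p) with synaptic conductances."""
    vals = [float(x) for x in state]
    if not all(math.isfinite(x) for x in vals):
        raise IntegrationError("non-finite state passed to hh_derivatives")
    return _hh_deriv(vals[0], vals[1], vals[2], vals[3], vals[4],
                     params, synapse, float(g_e), float(g_i))


@njit
def _hh_rest_state(p):
    """Steady gating at v = E_L (ignoring the tiny g_M shift of rest)."""
    a_n, b_n, a_m, b_m, a_h, b_h, p_inf, _ = _hh_rates(p.E_L, p.V_T, p.tau_max)
    return (p.E_L, a_n / (a_n + b_n), a_m / (a_m + b_m),
            a_h / (a_h + b_h), p_inf)


def hh_rest_state(params: HHParams):
    """Resting state (v, n, m, h, p) used to initialize simulations."""
    return _hh_rest_state(params)


# ---------------------------------------------------------------------------
# Morris-Lecar
# ---------------------------------------------------------------------------

@njit
def _ml_activation(v, p):
    m_ss = 0.5 * (1.0 + math.tanh((v - p.V1) / p.V2))
    n_ss = 0.5 * (1.0 + math.tanh((v - p.V3) / p.V4))
    tau_n = 1.0 / (2.0 * p.phi * math.cosh((v - p.V3) / (2.0 * p.V4)))
    return m_ss, n_ss, tau_n


def ml_activation(v: float, params: MLParams):
    """Steady-state activations (M_ss, N_ss) and the N time constant."""
    if not math.isfinite(v):
        raise ParameterError("v must be finite")
    return _ml_activation(float(v), params)


@njit
def _ml_deriv(v, n_gate, p, syn, ge, gi):
    i_syn = ge * (syn.E_e - v) + gi * (syn.E_i - v)
    m_ss = 0.5 * (1.0 + math.tanh((v - p.V1) / p.V2))
    n_ss = 0.5 * (1.0 + math.tanh((v - p.V3) / p.V4))
    dv = (p.g_L * (p.E_L - v)
          + p.g_Ca * m_ss * (p.E_Ca - v)
          + p.g_K * n_gate * (p.E_K - v)
          + i_syn + p.I0) / p.c_m
    # rate form of (N_ss - N) / tau_N; avoids dividing by a tau that
    # underflows for extreme voltages
    dn = (n_ss - n_gate) * 2.0 * p.phi * math.cosh((v - p.V3) / (2.0 * p.V4))
    return dv, dn


def ml_derivatives(state, params: MLParams, synapse: SynapseParams,
                   g_e: float, g_i: float):
    """Time derivatives of (v, N) with synaptic conductances and bias I0."""
    v, n = float(state[0]), float(state[1])
    if not (math.isfinite(v) and math.isfinite(n)):
        raise IntegrationError("non-finite state passed to ml_derivatives")
    return _ml_deriv(v, n, params, synapse, float(g_e), float(g_i))


# ---------------------------------------------------------------------------
# Spike detection
# ---------------------------------------------------------------------------

def detect_spikes(t: np.ndarray, v: np.ndarray, threshold: float) -> np.ndarray:
    """Spike times from a uniformly sampled voltage trace.

    One spike per upward crossing of ``threshold``; a new spike is only
    registered after the trace has fallen back below threshold.
    """
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    if v.size == 0:
        return np.empty(0)
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    return t[crossings]


# ---------------------------------------------------------------------------
# Single-neuron simulations under Poisson bombardment
# ---------------------------------------------------------------------------
#
# Synaptic input: K_e (K_i) independent presynaptic Poisson sources at rate
# nu_e (nu_i) each; the number of events in a time step is Binomial(K,
# nu*dt), which is exact for independent Bernoulli synapses.  Each event
# increments the exponential-decay conductance by the quantal Q.

@njit
def _sim_adex(p, syn, nu_e, nu_i, K_e, K_i, duration, dt, seed, record):
    np.random.seed(seed)
    n_steps = int(round(duration / dt))
    dec = math.exp(-dt / syn.tau)
    pe = nu_e * 1e-3 * dt
    pi = nu_i * 1e-3 * dt
    v = p.E_L
    w = 0.0
    ge = 0.0
    gi = 0.0
    refr = 0.0
    spikes = np.empty(n_steps // 10 + 64)
    n_sp = 0
    if record:
        tr_t = np.empty(n_steps)
        tr_v = np.empty(n_steps)
        tr_ge = np.empty(n_steps)
        tr_gi = np.empty(n_steps)
    else:
        tr_t = np.empty(0)
        tr_v = np.empty(0)
        tr_ge = np.empty(0)
        tr_gi = np.empty(0)
    for k in range(n_steps):
        ge = ge * dec + syn.Q_e * np.random.binomial(K_e, pe)
        gi = gi * dec + syn.Q_i * np.random.binomial(K_i, pi)
        if refr > 0.0:
            refr -= dt
            v = p.v_rest
            w = w + dt * (-w + p.a * (v - p.E_L)) / p.tau_w
        else:
            v, w, spiked = _adex_update(v, w, ge, gi, p, syn, dt)
            if spiked:
                if n_sp < spikes.size:
                    spikes[n_sp] = (k + 1) * dt
                n_sp += 1
                refr = p.T_refr
        if record:
            tr_t[k] = (k + 1) * dt
            tr_v[k] = v
            tr_ge[k] = ge
            tr_gi[k] = gi
        if not math.isfinite(v) or abs(v) > 500.0:
            return spikes[:0], -1, k, tr_t, tr_v, tr_ge, tr_gi
    return spikes[:min(n_sp, spikes.size)], n_sp, -1, tr_t, tr_v, tr_ge, tr_gi


@njit
def _sim_hh(p, syn, nu_e, nu_i, K_e, K_i, duration, dt, seed, record):
    np.random.seed(seed)
    n_steps = int(round(duration / dt))
    dec = math.exp(-dt / syn.tau)
    pe = nu_e * 1e-3 * dt
    pi = nu_i * 1e-3 * dt
    v, n, m, h, pg = _hh_rest_state(p)
    ge = 0.0
    gi = 0.0
    # capacity: spikes cannot be faster than ~1 kHz in this model
    spikes = np.empty(int(duration * 2.0) + 64)
    n_sp = 0
    prev_v = v
    if record:
        tr_t = np.empty(n_steps)
        tr_v = np.empty(n_steps)
        tr_ge = np.empty(n_steps)
        tr_gi = np.empty(n_steps)
    else:
        tr_t = np.empty(0)
        tr_v = np.empty(0)
        tr_ge = np.empty(0)
        tr_gi = np.empty(0)
    for k in range(n_steps):
        ge = ge * dec + syn.Q_e * np.random.binomial(K_e, pe)
        gi = gi * dec + syn.Q_i * np.random.binomial(K_i, pi)
        dv, dn, dm, dh, dp = _hh_deriv(v, n, m, h, pg, p, syn, ge, gi)
        prev_v = v
        v += dt * dv
        n += dt * dn
        m += dt * dm
        h += dt * dh
        pg += dt * dp
        if prev_v < p.spike_threshold <= v:
            if n_sp < spikes.size:
                spikes[n_sp] = (k + 1) * dt
            n_sp += 1
        if record:
            tr_t[k] = (k + 1) * dt
            tr_v[k] = v
            tr_ge[k] = ge
            tr_gi[k] = gi
        if not math.isfinite(v) or abs(v) > 500.0:
            return spikes[:0], -1, k, tr_t, tr_v, tr_ge, tr_gi
    return spikes[:min(n_sp, spikes.size)], n_sp, -1, tr_t, tr_v, tr_ge, tr_gi


@njit
def _sim_ml(p, syn, nu_e, nu_i, K_e, K_i, duration, dt, seed, record):
    np.random.seed(seed)
    n_steps = int(round(duration / dt))
    dec = math.exp(-dt / syn.tau)
    pe = nu_e * 1e-3 * dt
    pi = nu_i * 1e-3 * dt
    v = p.E_L
    _, n_gate, _ = _ml_activation(v, p)
    ge = 0.0
    gi = 0.0
    spikes = np.empty(int(duration * 0.5) + 64)
    n_sp = 0
    prev_v = v
    if record:
        tr_t = np.empty(n_steps)
        tr_v = np.empty(n_steps)
        tr_ge = np.empty(n_steps)
        tr_gi = np.empty(n_steps)
    else:
        tr_t = np.empty(0)
        tr_v = np.empty(0)
        tr_ge = np.empty(0)
        tr_gi = np.empty(0)
    for k in range(n_steps):
        ge = ge * dec + syn.Q_e * np.random.binomial(K_e, pe)
        gi = gi * dec + syn.Q_i * np.random.binomial(K_i, pi)
        dv, dn = _ml_deriv(v, n_gate, p, syn, ge, gi)
        prev_v = v
        v += dt * dv
        n_gate += dt * dn
        if prev_v < p.spike_threshold <= v:
            if n_sp < spikes.size:
                spikes[n_sp] = (k + 1) * dt
            n_sp += 1
        if record:
            tr_t[k] = (k + 1) * dt
            tr_v[k] = v
            tr_ge[k] = ge
            tr_gi[k] = gi
        if not math.isfinite(v) or abs(v) > 500.0:
            return spikes[:0], -1, k, tr_t, tr_v, tr_ge, tr_gi
    return spikes[:min(n_sp, spikes.size)], n_sp, -1, tr_t, tr_v, tr_ge, tr_gi


@njit
def _sim_passive(c_m, g_L, E_L, syn, nu_e, nu_i, K_e, K_i, duration, dt, seed):
    """Leak + synapses only (no spike mechanism); returns (t, v, ge, gi).

    Used to validate the subthreshold moment calculus against direct
    Monte-Carlo simulation.
    """
    np.random.seed(seed)
    n_steps = int(round(duration / dt))
    dec = math.exp(-dt / syn.tau)
    pe = nu_e * 1e-3 * dt
    pi = nu_i * 1e-3 * dt
    v = E_L
    ge = 0.0
    gi = 0.0
    tr_t = np.empty(n_steps)
    tr_v = np.empty(n_steps)
    tr_ge = np.empty(n_steps)
    tr_gi = np.empty(n_steps)
    for k in range(n_steps):
        ge = ge * dec + syn.Q_e * np.random.binomial(K_e, pe)
        gi = gi * dec + syn.Q_i * np.random.binomial(K_i, pi)
        dv = (g_L * (E_L - v) + ge * (syn.E_e - v) + gi * (syn.E_i - v)) / c_m
        v += dt * dv
        tr_t[k] = (k + 1) * dt
        tr_v[k] = v
        tr_ge[k] = ge
        tr_gi[k] = gi
    return tr_t, tr_v, tr_ge, tr_gi


_SIM_KERNELS = {"adex": _sim_adex, "hh": _sim_hh, "ml": _sim_ml}
_STATE_NAMES = {"adex": ("v", "w"), "hh": ("v", "n", "m", "h", "p"),
                "ml": ("v", "N")}


def simulate_single_neuron(model: str, params=None, synapse: SynapseParams = None,
                           nu_e: float = 0.0, nu_i: float = 0.0,
                           K_e: int = 400, K_i: int = 100,
                           duration: float = 10_000.0, dt: float = None,
                           seed: int = 0, record: bool = False,
                           cell: str = "rs") -> SingleNeuronResult:
    """Simulate one neuron under Poissonian synaptic bombardment.

    The neuron receives K_e excitatory presynaptic sources at ``nu_e`` Hz
    each and K_i inhibitory sources at ``nu_i`` Hz each.  Deterministic
    given ``seed``.  Returns spike times (ms), the output rate (Hz) and,
    when ``record`` is set, the voltage and conductance traces.
    """
    model = model.lower()
    if model not in _SIM_KERNELS:
        raise ParameterError(f"unknown model {model!r}")
    if nu_e < 0 or nu_i < 0:
        raise ParameterError("presynaptic rates must be non-negative")
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if params is None:
        params = default_params(model, cell)
    if synapse is None:
        synapse = default_synapse(model)
    validate_params(model, params)
    validate_synapse(synapse)
    if dt is None:
        dt = DEFAULT_DT[model]
    kern = _SIM_KERNELS[model]
    spikes, n_sp, bad_step, t, v, ge, gi = kern(
        params, synapse, float(nu_e), float(nu_i), int(K_e), int(K_i),
        float(duration), float(dt), int(seed) & 0x7FFFFFFF, record)
    if n_sp < 0:
        raise IntegrationError(
            f"non-finite membrane potential 'v' at t={bad_step * dt:.3f} ms "
            f"({model} single-neuron simulation)")
    # n_sp is the exact count even if the spike-time buffer saturated;
    # the returned rate is always based on the count
    rate = n_sp / duration * 1e3
    if record:
        return SingleNeuronResult(spikes, rate, t, v, ge, gi)
    return SingleNeuronResult(spikes, rate, None, None, None, None)


def simulate_passive_membrane(c_m: float, g_L: float, E_L: float,
                              synapse: SynapseParams,
                              nu_e: float, nu_i: float,
                              K_e: int = 400, K_i: int = 100,
                              duration: float = 10_000.0, dt: float = 0.1,
                              seed: int = 0):
    """Leak-plus-synapse membrane (no spikes); returns (t, v, g_e, g_i)."""
    if nu_e < 0 or nu_i < 0:
        raise ParameterError("presynaptic rates must be non-negative")
    validate_synapse(synapse)
    return _sim_passive(float(c_m), float(g_L), float(E_L), synapse,
                        float(nu_e), float(nu_i), int(K_e), int(K_i),
                        float(duration), float(dt), int(seed) & 0x7FFFFFFF)
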