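"""Random E/I networks of conductance-based neurons.

A directed Erdos-Renyi graph of N cells (a fraction ``frac_exc``
excitatory RS cells, the rest inhibitory FS cells) coupled through
exponential-decay conductance synapses.  Each cell additionally receives
an external excitatory Poisson stream delivered through ``K_e_ext``
independent synapses, each firing at ``nu_drive`` Hz plus an optional
time-varying stimulus rate.  Synaptic transmission is delayless on the
integration grid: a spike at step k increments its targets' conductances
at step k+1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import math
import numpy as np
from numba import njit

from .errors import IntegrationError, ParameterError
from .neuron_models import (DEFAULT_DT, _adex_update, _hh_deriv, _hh_rest_state,
                            _ml_activation, _ml_deriv)
from .params import (SynapseParams, default_params, default_synapse,
                     validate_params, validate_synapse)


@dataclass(frozen=True)
class NetworkConfig:
    """Network topology and external drive.

    ``p_conn`` is the independent connection probability for every ordered
    pair of distinct neurons.  ``nu_drive`` is the rate (Hz) of each of the
    ``K_e_ext`` external drive synapses per neuron.
    """

    N: int = 10_000
    frac_exc: float = 0.8
    p_conn: float = 0.05
    nu_drive: float = 4.0
    K_e_ext: int = 400
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_conn <= 1):
            raise ParameterError("p_conn must be in [0, 1]")
        if not (0 < self.frac_exc < 1):
            raise ParameterError("frac_exc must be in (0, 1)")
        if self.N < 2:
            raise ParameterError("N must be at least 2")
        if self.nu_drive < 0:
            raise ParameterError("nu_drive must be non-negative")

    @property
    def n_exc(self) -> int:
        return int(round(self.N * self.frac_exc))

    @property
    def n_inh(self) -> int:
        return self.N - self.n_exc


def scaled_config(N: int = 2500, K_e: int = 400, nu_drive: float = 4.0,
                  seed: int = 0, frac_exc: float = 0.8) -> NetworkConfig:
    """Reduced-size network preserving in-degrees.

    Keeping K_e (and hence K_i = K_e * (1-frac_exc)/frac_exc) fixed
    preserves the single-neuron input statistics that the mean field sees,
    so a smaller network remains comparable to the full-size one.
    """
    p = K_e / (N * frac_exc)
    return NetworkConfig(N=N, frac_exc=frac_exc, p_conn=p,
                         nu_drive=nu_drive, seed=seed)


@dataclass
class SpikeRaster:
    """Spikes of one network run: parallel arrays of neuron ids and times
    (ms, sorted by time), the excitatory flag per neuron, and duration."""

    neuron_ids: np.ndarray
    times: np.ndarray
    is_exc: np.ndarray
    duration: float

    @property
    def N(self) -> int:
        return self.is_exc.size

    def population(self, exc: bool) -> "SpikeRaster":
        mask = self.is_exc[self.neuron_ids] == exc
        return SpikeRaster(self.neuron_ids[mask], self.times[mask],
                           self.is_exc, self.duration)

    def spikes_of(self, i: int) -> np.ndarray:
        return np.sort(self.times[self.neuron_ids == i])

    def mean_rate(self, exc: Optional[bool] = None) -> float:
        """Mean per-neuron firing rate in Hz."""
        if exc is None:
            n, count = self.N, self.times.size
        else:
            n = int(np.sum(self.is_exc == exc))
            count = int(np.sum(self.is_exc[self.neuron_ids] == exc))
        return count / n / self.duration * 1e3 if n else 0.0

    def save(self, path) -> None:
        """Two-column text (neuron_id, t_ms) with a small header."""
        n_exc = int(self.is_exc.sum())
        header = f"N={self.N} n_exc={n_exc} duration_ms={self.duration}"
        np.savetxt(path, np.column_stack([self.neuron_ids, self.times]),
                   fmt=["%d", "%.3f"], header=header)

    @classmethod
    def load(cls, path) -> "SpikeRaster":
        with open(path) as fh:
            head = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in head)
        data = np.loadtxt(path, ndmin=2)
        n, n_exc = int(meta["N"]), int(meta["n_exc"])
        is_exc = np.zeros(n, dtype=np.bool_)
        is_exc[:n_exc] = True
        if data.size == 0:
            return cls(np.empty(0, int), np.empty(0), is_exc,
                       float(meta["duration_ms"]))
        return cls(data[:, 0].astype(int), data[:, 1], is_exc,
                   float(meta["duration_ms"]))


@dataclass
class PopulationRateSeries:
    """Windowed population rate: common time grid (window centers, ms) and
    one rate array (Hz) per population."""

    t: np.ndarray
    rate_e: np.ndarray
    rate_i: np.ndarray
    window: float


@dataclass
class PopulationRateSummary:
    mean_e: float
    mean_i: float
    var_e: float
    var_i: float
    acorr_time_e: float
    acorr_time_i: float


def build_connectivity(config: NetworkConfig):
    """Directed boolean adjacency, A[i, j] == presynaptic i projects to j.

    Every ordered pair (i != j) is connected independently with
    probability ``p_conn``; deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.N
    a = np.zeros((n, n), dtype=np.bool_)
    block = max(1, int(2e7) // n)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        a[lo:hi] = rng.random((hi - lo, n)) < config.p_conn
    np.fill_diagonal(a, False)
    return a


def _to_csr(adj: np.ndarray):
    """Out-edge CSR arrays (indptr, indices) from a dense boolean matrix."""
    counts = adj.sum(axis=1)
    indptr = np.zeros(adj.shape[0] + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = np.nonzero(adj)[1].astype(np.int64)
    return indptr, indices


def generate_poisson_train(rate: float, duration: float, seed: int = 0) -> np.ndarray:
    """Homogeneous Poisson spike train; times in ms, sorted."""
    if rate < 0:
        raise ParameterError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * 1e-3 * duration)
    return np.sort(rng.uniform(0.0, duration, n))


# ---------------------------------------------------------------------------
# Network integration kernels (one per neuron model)
# ---------------------------------------------------------------------------
# Common structure: per step, apply the synaptic increments accumulated on
# the previous step, decay conductances, draw external Poisson events,
# advance every neuron one Euler step, collect spikes.

@njit
def _net_adex(p_e, p_i, syn, is_exc, indptr, indices, n_steps, dt,
              k_ext, drive_rate, stim_rate, seed,
              sp_id, sp_t):
    np.random.seed(seed)
    n = is_exc.size
    dec = math.exp(-dt / syn.tau)
    v = np.empty(n)
    w = np.zeros(n)
    ge = np.zeros(n)
    gi = np.zeros(n)
    inc_e = np.zeros(n)
    inc_i = np.zeros(n)
    refr = np.zeros(n)
    for i in range(n):
        v[i] = p_e.E_L if is_exc[i] else p_i.E_L
    n_sp = 0
    cap = sp_id.size
    for k in range(n_steps):
        p_ext = (drive_rate + stim_rate[k]) * 1e-3 * dt
        for i in range(n):
            ge[i] = ge[i] * dec + inc_e[i] + syn.Q_e * np.random.binomial(k_ext, p_ext)
            gi[i] = gi[i] * dec + inc_i[i]
            inc_e[i] = 0.0
            inc_i[i] = 0.0
        for i in range(n):
            p = p_e if is_exc[i] else p_i
            if refr[i] > 0.0:
                refr[i] -= dt
                v[i] = p.v_rest
                w[i] += dt * (-w[i] + p.a * (v[i] - p.E_L)) / p.tau_w
                continue
            v2, w2, spiked = _adex_update(v[i], w[i], ge[i], gi[i], p, syn, dt)
            v[i] = v2
            w[i] = w2
            if not math.isfinite(v2):
                return n_sp, -1, k, i
            if spiked:
                refr[i] = p.T_refr
                if n_sp < cap:
                    sp_id[n_sp] = i
                    sp_t[n_sp] = (k + 1) * dt
                n_sp += 1
                q_is_e = is_exc[i]
                for jj in range(indptr[i], indptr[i + 1]):
                    tgt = indices[jj]
                    if q_is_e:
                        inc_e[tgt] += syn.Q_e
                    else:
                        inc_i[tgt] += syn.Q_i
    return n_sp, 0, -1, -1


@njit
def _net_hh(p_e, p_i, syn, is_exc, indptr, indices, n_steps, dt,
            k_ext, drive_rate, stim_rate, seed,
            sp_id, sp_t):
    np.random.seed(seed)
    n = is_exc.size
    dec = math.exp(-dt / syn.tau)
    v = np.empty(n)
    gn = np.empty(n)
    gm = np.empty(n)
    gh = np.empty(n)
    gp = np.empty(n)
    for i in range(n):
        p = p_e if is_exc[i] else p_i
        v0, n0, m0, h0, pp0 = _hh_rest_state(p)
        v[i] = v0
        gn[i] = n0
        gm[i] = m0
        gh[i] = h0
        gp[i] = pp0
    ge = np.zeros(n)
    gi = np.zeros(n)
    inc_e = np.zeros(n)
    inc_i = np.zeros(n)
    n_sp = 0
    cap = sp_id.size
    for k in range(n_steps):
        p_ext = (drive_rate + stim_rate[k]) * 1e-3 * dt
        for i in range(n):
            ge[i] = ge[i] * dec + inc_e[i] + syn.Q_e * np.random.binomial(k_ext, p_ext)
            gi[i] = gi[i] * dec + inc_i[i]
            inc_e[i] = 0.0
            inc_i[i] = 0.0
        for i in range(n):
            p = p_e if is_exc[i] else p_i
            dv, dn, dm, dh, dp = _hh_deriv(v[i], gn[i], gm[i], gh[i], gp[i],
                                           p, syn, ge[i], gi[i])
            pv = v[i]
            v[i] = pv + dt * dv
            gn[i] += dt * dn
            gm[i] += dt * dm
            gh[i] += dt * dh
            gp[i] += dt * dp
            if not math.isfinite(v[i]) or abs(v[i]) > 500.0:
                return n_sp, -1, k, i
            if pv < p.spike_threshold <= v[i]:
                if n_sp < cap:
                    sp_id[n_sp] = i
                    sp_t[n_sp] = (k + 1) * dt
                n_sp += 1
                q_is_e = is_exc[i]
                for jj in range(indptr[i], indptr[i + 1]):
                    tgt = indices[jj]
                    if q_is_e:
                        inc_e[tgt] += syn.Q_e
                    else:
                        inc_i[tgt] += syn.Q_i
    return n_sp, 0, -1, -1


@njit
def _net_ml(p_e, p_i, syn, is_exc, indptr, indices, n_steps, dt,
            k_ext, drive_rate, stim_rate, seed,
            sp_id, sp_t):
    np.random.seed(seed)
    n = is_exc.size
    dec = math.exp(-dt / syn.tau)
    v = np.empty(n)
    gn = np.empty(n)
    for i in range(n):
        p = p_e if is_exc[i] else p_i
        v[i] = p.E_L
        _, n_ss, _ = _ml_activation(p.E_L, p)
        gn[i] = n_ss
    ge = np.zeros(n)
    gi = np.zeros(n)
    inc_e = np.zeros(n)
    inc_i = np.zeros(n)
    n_sp = 0
    cap = sp_id.size
    for k in range(n_steps):
        p_ext = (drive_rate + stim_rate[k]) * 1e-3 * dt
        for i in range(n):
            ge[i] = ge[i] * dec + inc_e[i] + syn.Q_e * np.random.binomial(k_ext, p_ext)
            gi[i] = gi[i] * dec + inc_i[i]
            inc_e[i] = 0.0
            inc_i[i] = 0.0
        for i in range(n):
            p = p_e if is_exc[i] else p_i
            dv, dn = _ml_deriv(v[i], gn[i], p, syn, ge[i], gi[i])
            pv = v[i]
            v[i] = pv + dt * dv
            gn[i] += dt * dn
            if not math.isfinite(v[i]) or abs(v[i]) > 500.0:
                return n_sp, -1, k, i
            if pv < p.spike_threshold <= v[i]:
                if n_sp < cap:
                    sp_id[n_sp] = i
                    sp_t[n_sp] = (k + 1) * dt
                n_sp += 1
                q_is_e = is_exc[i]
                for jj in range(indptr[i], indptr[i + 1]):
                    tgt = indices[jj]
                    if q_is_e:
                        inc_e[tgt] += syn.Q_e
                    else:
                        inc_i[tgt] += syn.Q_i
    return n_sp, 0, -1, -1


_NET_KERNELS = {"adex": _net_adex, "hh": _net_hh, "ml": _net_ml}


def simulate_network(model: str, config: NetworkConfig,
                     params_e=None, params_i=None,
                     synapse: SynapseParams = None,
                     stimulus=None, duration: float = 10_000.0,
                     dt: float = None, adjacency: np.ndarray = None) -> SpikeRaster:
    """Simulate the E/I network and return its spike raster.

    ``stimulus`` is an optional :class:`~spikemf.mean_field.StimulusProfile`
    whose rate is added to the external-drive rate of every neuron (both
    populations are targeted).  Deterministic given ``config.seed``.
    """
    model = model.lower()
    if model not in _NET_KERNELS:
        raise ParameterError(f"unknown model {model!r}")
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if params_e is None:
        params_e = default_params(model, "rs")
    if params_i is None:
        params_i = default_params(model, "fs")
    if synapse is None:
        synapse = default_synapse(model)
    validate_params(model, params_e)
    validate_params(model, params_i)
    validate_synapse(synapse)
    if dt is None:
        dt = DEFAULT_DT[model]
    if adjacency is None:
        adjacency = build_connectivity(config)
    indptr, indices = _to_csr(adjacency)

    n_steps = int(round(duration / dt))
    if stimulus is None:
        stim = np.zeros(n_steps)
    else:
        from .mean_field import stimulus_rate
        stim = stimulus_rate(np.arange(1, n_steps + 1) * dt, stimulus)

    is_exc = np.zeros(config.N, dtype=np.bool_)
    is_exc[:config.n_exc] = True

    kern = _NET_KERNELS[model]
    cap_rate = 120.0  # Hz per neuron, spike-buffer headroom
    cap = int(config.N * duration * 1e-3 * cap_rate) + 1024
    for _attempt in range(3):
        sp_id = np.empty(cap, dtype=np.int64)
        sp_t = np.empty(cap)
        n_sp, status, bad_step, bad_neuron = kern(
            params_e, params_i, synapse, is_exc, indptr, indices,
            n_steps, float(dt), int(config.K_e_ext), float(config.nu_drive),
            stim, int(config.seed) & 0x7FFFFFFF, sp_id, sp_t)
        if status < 0:
            raise IntegrationError(
                f"non-finite state at t={bad_step * dt:.2f} ms, "
                f"neuron {bad_neuron} ({model} network)")
        if n_sp <= cap:
            return SpikeRaster(sp_id[:n_sp].copy(), sp_t[:n_sp].copy(),
                               is_exc, float(duration))
        cap = int(n_sp * 1.1) + 1024
    raise IntegrationError("spike buffer overflow")  # pragma: no cover


def population_rate(raster: SpikeRaster, window: float = 5.0):
    """Windowed population rates plus summary statistics.

    rate(t) = spike count in window / (window * population size).  The
    series covers the complete windows only.  The autocorrelation time is
    the first lag at which the normalized autocorrelation of the rate
    series drops below 1/e.
    """
    if window <= 0:
        raise ParameterError("window must be positive")
    if window > raster.duration:
        raise ParameterError("window larger than raster duration")
    n_win = int(raster.duration // window)
    edges = np.arange(n_win + 1) * window
    t = (edges[:-1] + edges[1:]) / 2.0

    out_rates = []
    out_summary = []
    for exc in (True, False):
        n_pop = int(np.sum(raster.is_exc == exc))
        mask = raster.is_exc[raster.neuron_ids] == exc if raster.times.size else \
            np.zeros(0, dtype=bool)
        counts, _ = np.histogram(raster.times[mask], bins=edges)
        rate = counts / (window * 1e-3 * n_pop) if n_pop else counts * 0.0
        out_rates.append(rate)
        out_summary.append((float(rate.mean()) if n_win else 0.0,
                            float(rate.var()) if n_win else 0.0,
                            _acorr_time(rate, window)))

    series = PopulationRateSeries(t, out_rates[0], out_rates[1], window)
    summary = PopulationRateSummary(
        mean_e=out_summary[0][0], mean_i=out_summary[1][0],
        var_e=out_summary[0][1], var_i=out_summary[1][1],
        acorr_time_e=out_summary[0][2], acorr_time_i=out_summary[1][2])
    return series, summary


def _acorr_time(rate: np.ndarray, window: float) -> float:
    """First lag (ms) where the normalized autocorrelation falls below 1/e."""
    x = rate - rate.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0 or x.size < 3:
        return 0.0
    for lag in range(1, x.size):
        c = float(np.dot(x[:-lag], x[lag:])) / denom
        if c < 1.0 / math.e:
            return lag * window
    return x.size * window
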