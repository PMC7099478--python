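"""Master-equation mean field over fitted transfer functions.

On a Markovian coarse-graining timescale T (~20 ms, short enough that the
population-rate autocorrelation has decayed, long enough that each neuron
fires at most once) the excitatory/inhibitory population rates nu_e, nu_i
and their covariances c_ee, c_ei, c_ii obey

    T dnu_mu/dt = F_mu - nu_mu + (1/2) sum_{l,h} c_lh d2F_mu/dnu_l dnu_h
    T dc_lh/dt  = delta_lh F_l (1/T - F_h) / N_l
                  + (F_l - nu_l)(F_h - nu_h)
                  + sum_m [dF_l/dnu_m c_hm + dF_h/dnu_m c_lm]
                  - 2 c_lh

with F_mu = F_mu(nu_e + nu_ext, nu_i) the fitted transfer functions and
N_l the population sizes.  At first order (covariances dropped) this is
the Wilson-Cowan rate model with a microscopically derived gain function.

Rates are in Hz, times in ms; the 1/T in the finite-size source term is
converted to Hz.  The external drive (plus any stimulus) is added to the
excitatory-rate argument of both transfer functions, matching the
network's external-synapse convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .errors import InstabilityError, ParameterError


class StimulusProfile(NamedTuple):
    """Asymmetric double-Gaussian rate envelope: amplitude A (Hz), peak
    time t0 (ms), rise time T1 (ms), decay time T2 (ms)."""

    A: float = 2.0
    t0: float = 2000.0
    T1: float = 100.0
    T2: float = 150.0


def stimulus_rate(t, stim: StimulusProfile):
    """Stimulus rate (Hz) at time t (ms); continuous, equal to A at t0."""
    if stim.T1 <= 0 or stim.T2 <= 0:
        raise ParameterError("stimulus rise/decay times must be positive")
    if stim.A < 0:
        raise ParameterError("stimulus amplitude must be non-negative")
    t = np.asarray(t, dtype=float)
    d = t - stim.t0
    rise = np.exp(-(d / stim.T1) ** 2)
    decay = np.exp(-(d / stim.T2) ** 2)
    return stim.A * np.where(d < 0, rise, decay)


class MeanFieldState(NamedTuple):
    """Population rates (Hz) and rate covariances (Hz^2) at one instant."""

    nu_e: float
    nu_i: float
    c_ee: float = 0.0
    c_ei: float = 0.0
    c_ii: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


@dataclass(frozen=True)
class MeanFieldParams:
    """T: Markovian timescale (ms); N_e, N_i: population sizes;
    step: finite-difference step (Hz) for transfer-function derivatives;
    order: 'first' (Wilson-Cowan) or 'second' (with covariances)."""

    T: float = 20.0
    N_e: int = 8000
    N_i: int = 2000
    step: float = 0.05
    order: str = "second"

    def __post_init__(self):
        if self.T <= 0:
            raise ParameterError("T must be positive")
        if self.N_e < 1 or self.N_i < 1:
            raise ParameterError("population sizes must be >= 1")
        if self.order not in ("first", "second"):
            raise ParameterError("order must be 'first' or 'second'")
        if self.step <= 0:
            raise ParameterError("derivative step must be positive")


def tf_derivatives(f: Callable, nu_e: float, nu_i: float, step: float = 0.05):
    """Value, gradient and Hessian of a transfer function at (nu_e, nu_i).

    Central finite differences; at the nu = 0 boundary the stencil is
    clamped at zero (one-sided).  The returned Hessian is symmetric by
    construction.  ``f`` must accept array arguments.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    e_lo, e_hi = max(nu_e - step, 0.0), nu_e + step
    i_lo, i_hi = max(nu_i - step, 0.0), nu_i + step
    es = np.array([e_lo, nu_e, e_hi])
    is_ = np.array([i_lo, nu_i, i_hi])
    ee, ii = np.meshgrid(es, is_, indexing="ij")
    vals = np.asarray(f(ee.ravel(), ii.ravel()), dtype=float).reshape(3, 3)

    a_e, b_e = nu_e - e_lo, e_hi - nu_e
    a_i, b_i = nu_i - i_lo, i_hi - nu_i
    value = vals[1, 1]
    grad = np.array([
        (vals[2, 1] - vals[0, 1]) / (a_e + b_e),
        (vals[1, 2] - vals[1, 0]) / (a_i + b_i),
    ])
    # unequal-spacing 3-point second derivative (exact for quadratics)
    if a_e > 0:
        d2e = 2.0 * (b_e * vals[0, 1] - (a_e + b_e) * vals[1, 1]
                     + a_e * vals[2, 1]) / (a_e * b_e * (a_e + b_e))
    else:
        d2e = _one_sided_second(f, nu_e, nu_i, step, axis=0)
    if a_i > 0:
        d2i = 2.0 * (b_i * vals[1, 0] - (a_i + b_i) * vals[1, 1]
                     + a_i * vals[1, 2]) / (a_i * b_i * (a_i + b_i))
    else:
        d2i = _one_sided_second(f, nu_e, nu_i, step, axis=1)
    mixed = (vals[2, 2] - vals[2, 0] - vals[0, 2] + vals[0, 0]) \
        / ((a_e + b_e) * (a_i + b_i))
    hess = np.array([[d2e, mixed], [mixed, d2i]])
    return value, grad, hess


def _one_sided_second(f, nu_e, nu_i, step, axis):
    """Forward 3-point second derivative for a point pinned at nu = 0."""
    if axis == 0:
        pts = np.array([[nu_e, nu_i], [nu_e + step, nu_i], [nu_e + 2 * step, nu_i]])
    else:
        pts = np.array([[nu_e, nu_i], [nu_e, nu_i + step], [nu_e, nu_i + 2 * step]])
    v = np.asarray(f(pts[:, 0], pts[:, 1]), dtype=float)
    return (v[0] - 2.0 * v[1] + v[2]) / step ** 2


def _tf_tensors(f_e, f_i, nu_e, nu_i, ext_rate, step):
    """F values, gradients and Hessians for both populations at the
    drive-shifted operating point; derivatives are with respect to the
    recurrent rates."""
    fe, ge, he = tf_derivatives(lambda a, b: f_e(a + ext_rate, b), nu_e, nu_i, step)
    fi, gi, hi = tf_derivatives(lambda a, b: f_i(a + ext_rate, b), nu_e, nu_i, step)
    return np.array([fe, fi]), np.array([ge, gi]), np.array([he, hi])


def mean_field_rhs(state: MeanFieldState, f_e: Callable, f_i: Callable,
                   params: MeanFieldParams, ext_rate: float = 0.0) -> np.ndarray:
    """Time derivative (per ms) of (nu_e, nu_i, c_ee, c_ei, c_ii)."""
    if ext_rate < 0:
        raise ParameterError("external rate must be non-negative")
    nu = np.array([state.nu_e, state.nu_i], dtype=float)
    c = np.array([[state.c_ee, state.c_ei], [state.c_ei, state.c_ii]])
    # RK4 substeps may probe slightly negative rates; evaluate F at the
    # clamped point while keeping the relaxation term on the raw state
    nu_ev = np.maximum(nu, 0.0)
    f, grad, hess = _tf_tensors(f_e, f_i, nu_ev[0], nu_ev[1], ext_rate, params.step)
    t = params.T
    if params.order == "first":
        dnu = (f - nu) / t
        return np.array([dnu[0], dnu[1], 0.0, 0.0, 0.0])

    corr = 0.5 * np.array([np.sum(c * hess[0]), np.sum(c * hess[1])])
    dnu = (f - nu + corr) / t
    n_pop = np.array([params.N_e, params.N_i], dtype=float)
    inv_t_hz = 1e3 / t  # 1/T expressed in Hz
    dc = np.empty((2, 2))
    for lam in range(2):
        for eta in range(2):
            finite = (f[lam] * (inv_t_hz - f[eta]) / n_pop[lam]
                      if lam == eta else 0.0)
            drift = (f[lam] - nu[lam]) * (f[eta] - nu[eta])
            coupling = float(grad[lam] @ c[eta] + grad[eta] @ c[lam])
            dc[lam, eta] = (finite + drift + coupling - 2.0 * c[lam, eta]) / t
    return np.array([dnu[0], dnu[1], dc[0, 0], 0.5 * (dc[0, 1] + dc[1, 0]),
                     dc[1, 1]])


_NU_CAP = 200.0  # Hz; beyond this the asynchronous-irregular theory is void


def _rk4_step(y, dt, rhs):
    k1 = rhs(y)
    k2 = rhs(y + 0.5 * dt * k1)
    k3 = rhs(y + 0.5 * dt * k2)
    k4 = rhs(y + dt * k3)
    return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def find_stationary_state(f_e: Callable, f_i: Callable,
                          params: MeanFieldParams, ext_rate: float = 0.0,
                          start: MeanFieldState = None, dt: float = 0.1,
                          tol: float = 1e-8, max_time: float = 10_000.0):
    """Settle the mean field to its stationary state.

    Integrates from nu = (1, 1) Hz, c = 0 until the state derivative norm
    drops below ``tol`` (Hz/ms); raises on divergence or non-convergence.
    For the second-order system the rate equations are settled first with
    the covariances frozen at zero (the drift term (F-nu)(F-nu) otherwise
    sources explosively large covariances during the approach), and the
    full system is then relaxed from that point.
    """
    if params.order == "second" and start is None:
        first = MeanFieldParams(T=params.T, N_e=params.N_e, N_i=params.N_i,
                                step=params.step, order="first")
        start = find_stationary_state(f_e, f_i, first, ext_rate=ext_rate,
                                      dt=dt, tol=tol, max_time=max_time)
    y = (start.as_array() if start is not None
         else np.array([1.0, 1.0, 0.0, 0.0, 0.0]))

    def rhs(arr):
        return mean_field_rhs(MeanFieldState(*arr), f_e, f_i, params, ext_rate)

    n_steps = int(max_time / dt)
    for _ in range(n_steps):
        y = _rk4_step(y, dt, rhs)
        y[0] = max(y[0], 0.0)
        y[1] = max(y[1], 0.0)
        if y[0] > _NU_CAP or y[1] > _NU_CAP or not np.all(np.isfinite(y)):
            raise InstabilityError("mean-field rates diverged "
                                   f"(nu=({y[0]:.1f}, {y[1]:.1f}) Hz)")
        if np.linalg.norm(rhs(y)) < tol:
            return MeanFieldState(*y)
    raise InstabilityError("mean field failed to reach stationarity "
                           f"within {max_time} ms")


@dataclass
class MeanFieldTrajectory:
    t: np.ndarray        # ms
    nu_e: np.ndarray     # Hz
    nu_i: np.ndarray     # Hz
    c_ee: np.ndarray     # Hz^2
    c_ei: np.ndarray
    c_ii: np.ndarray
    n_clamped: int = 0   # count of negative-rate clamp events

    def save(self, path) -> None:
        np.savetxt(path,
                   np.column_stack([self.t, self.nu_e, self.nu_i,
                                    self.c_ee, self.c_ei, self.c_ii]),
                   header="t_ms nu_e_Hz nu_i_Hz c_ee c_ei c_ii")


def integrate_mean_field(f_e: Callable, f_i: Callable, params: MeanFieldParams,
                         nu_drive: float = 0.0, stimulus: StimulusProfile = None,
                         duration: float = 4000.0, dt: float = 0.1,
                         sample_every: float = 5.0,
                         start: MeanFieldState = None) -> MeanFieldTrajectory:
    """Integrate the mean field under a (possibly time-varying) drive.

    Starts from the stationary state at the baseline drive unless
    ``start`` is given.  Rates are clamped at zero from below; clamping
    events are counted in the returned trajectory.
    """
    if dt > params.T / 20.0:
        raise ParameterError("dt must be at most T/20 for a stable scheme")
    if start is None:
        start = find_stationary_state(f_e, f_i, params, ext_rate=nu_drive)
    y = start.as_array()
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(sample_every / dt)))
    n_out = n_steps // stride + 1
    out = np.empty((n_out, 6))
    out[0] = (0.0, *y)
    n_clamp = 0
    j = 1
    for k in range(n_steps):
        t0 = k * dt

        def rhs_t(arr, t_base=t0):
            # stimulus evaluated at the RK substep midpoint is overkill for
            # envelopes this slow; step-start rate is used for all substeps
            ext = nu_drive + (float(stimulus_rate(t_base, stimulus))
                              if stimulus is not None else 0.0)
            return mean_field_rhs(MeanFieldState(*arr), f_e, f_i, params, ext)

        y = _rk4_step(y, dt, rhs_t)
        if y[0] < 0 or y[1] < 0:
            n_clamp += int(y[0] < 0) + int(y[1] < 0)
            y[0] = max(y[0], 0.0)
            y[1] = max(y[1], 0.0)
        if y[0] > _NU_CAP or y[1] > _NU_CAP or not np.all(np.isfinite(y)):
            raise InstabilityError(f"mean-field rates diverged at t={t0:.1f} ms")
        if (k + 1) % stride == 0 and j < n_out:
            out[j] = ((k + 1) * dt, *y)
            j += 1
    out = out[:j]
    return MeanFieldTrajectory(out[:, 0], out[:, 1], out[:, 2], out[:, 3],
                               out[:, 4], out[:, 5], n_clamped=n_clamp)
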