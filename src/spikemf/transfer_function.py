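"""Semianalytic transfer functions for conductance-based neurons.

The stationary transfer function F(nu_e, nu_i) maps presynaptic
excitatory/inhibitory rates to a neuron's output rate.  It is built in
three steps:

1. *Conductance moments.*  For Poissonian presynaptic trains through
   exponential-decay synapses, the mean and standard deviation of each
   conductance follow from shot-noise (Campbell) theorems:
   mu_G = nu K tau Q,  sigma_G = Q sqrt(nu K tau / 2).

2. *Voltage moments.*  Keeping only the leak and synaptic currents, the
   mean voltage is the conductance-weighted average of the reversal
   potentials; sigma_V and the voltage autocorrelation time tau_V follow
   from the synaptic efficacies U_s = Q_s (E_s - mu_V) / mu_G.

3. *Rate formula.*  The output rate is
   F = alpha / (2 tau_V) * erfc((V_thr_eff - mu_V) / (sqrt(2) sigma_V)),
   where the effective threshold V_thr_eff is a fitted second-order
   polynomial in the normalized moments (mu_V, sigma_V, tau_V^N), with
   tau_V^N = tau_V g_L / c_m.  The polynomial absorbs everything the
   moment calculus leaves out (spike currents, adaptation), which is why
   it must be fit to simulated rates of the actual neuron model.

The fit is two-stage: rates are first inverted to empirical thresholds
(exact inverse of the erfc formula) and the polynomial solved by ordinary
least squares in threshold space; a nonlinear refinement then minimizes
the rate-space residuals starting from that solution.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erfc, erfcinv

from .errors import FitError, IntegrationError, ParameterError
from .neuron_models import simulate_single_neuron
from .params import SynapseParams, default_params, default_synapse

# Normalization of the polynomial coordinates.  These only reparameterize
# the polynomial (a joint rescaling of centers/scales and coefficients
# leaves the predicted rate unchanged); the values below are the standard
# ones for this threshold expansion.
MU_V0, D_MU_V0 = -60.0, 10.0       # mV
SIGMA_V0, D_SIGMA_V0 = 4.0, 6.0    # mV
TAU_N0, D_TAU_N0 = 0.5, 1.0        # dimensionless

COEF_NAMES = ("P0", "P_muV", "P_sigmaV", "P_tauV", "P_muV2", "P_sigmaV2",
              "P_tauV2", "P_muVsigmaV", "P_muVtauV", "P_sigmaVtauV")


class SubthresholdMoments(NamedTuple):
    """Subthreshold statistics at one (or an array of) input-rate pair(s)."""

    mu_Ge: np.ndarray     # nS
    sigma_Ge: np.ndarray  # nS
    mu_Gi: np.ndarray     # nS
    sigma_Gi: np.ndarray  # nS
    mu_G: np.ndarray      # nS, total input conductance incl. leak
    tau_m_eff: np.ndarray  # ms
    mu_V: np.ndarray      # mV
    sigma_V: np.ndarray   # mV
    tau_V: np.ndarray     # ms
    tau_V_N: np.ndarray   # dimensionless, tau_V * g_L / c_m


def conductance_moments(nu_e, nu_i, K_e: int, K_i: int, synapse: SynapseParams):
    """Mean/std of the excitatory and inhibitory conductances (nS) for
    Poisson input at nu_e, nu_i Hz per synapse."""
    nu_e = np.asarray(nu_e, dtype=float)
    nu_i = np.asarray(nu_i, dtype=float)
    if np.any(nu_e < 0) or np.any(nu_i < 0):
        raise ParameterError("rates must be non-negative")
    re = nu_e * 1e-3  # events/ms
    ri = nu_i * 1e-3
    mu_ge = re * K_e * synapse.tau * synapse.Q_e
    sigma_ge = np.sqrt(re * K_e * synapse.tau / 2.0) * synapse.Q_e
    mu_gi = ri * K_i * synapse.tau * synapse.Q_i
    sigma_gi = np.sqrt(ri * K_i * synapse.tau / 2.0) * synapse.Q_i
    return mu_ge, sigma_ge, mu_gi, sigma_gi


def voltage_moments(nu_e, nu_i, g_L: float, c_m: float, E_L: float,
                    K_e: int, K_i: int, synapse: SynapseParams) -> SubthresholdMoments:
    """Subthreshold voltage statistics from the leak + synapse membrane."""
    mu_ge, s_ge, mu_gi, s_gi = conductance_moments(nu_e, nu_i, K_e, K_i, synapse)
    mu_g = mu_ge + mu_gi + g_L
    tau_m = c_m / mu_g
    mu_v = (mu_ge * synapse.E_e + mu_gi * synapse.E_i + g_L * E_L) / mu_g

    u_e = synapse.Q_e * (synapse.E_e - mu_v) / mu_g
    u_i = synapse.Q_i * (synapse.E_i - mu_v) / mu_g
    re = np.asarray(nu_e, dtype=float) * 1e-3
    ri = np.asarray(nu_i, dtype=float) * 1e-3
    tau = synapse.tau
    term_e = K_e * re * (u_e * tau) ** 2
    term_i = K_i * ri * (u_i * tau) ** 2
    var_v = term_e / (2.0 * (tau_m + tau)) + term_i / (2.0 * (tau_m + tau))
    sigma_v = np.sqrt(var_v)
    num = term_e + term_i
    den = term_e / (tau_m + tau) + term_i / (tau_m + tau)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau_v = np.where(den > 0, num / np.where(den > 0, den, 1.0), tau_m + tau)
    tau_v_n = tau_v * g_L / c_m
    return SubthresholdMoments(mu_ge, s_ge, mu_gi, s_gi, mu_g, tau_m,
                               mu_v, sigma_v, tau_v, tau_v_n)


@dataclass(frozen=True)
class ThresholdPolynomial:
    """Second-order polynomial V_thr_eff(mu_V, sigma_V, tau_V^N), mV.

    ``coeffs`` holds the ten terms in the order of :data:`COEF_NAMES`;
    centers/scales normalize the three coordinates.
    """

    coeffs: np.ndarray
    centers: tuple = (MU_V0, SIGMA_V0, TAU_N0)
    scales: tuple = (D_MU_V0, D_SIGMA_V0, D_TAU_N0)

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (10,):
            raise ParameterError("need exactly 10 polynomial coefficients")
        if not np.all(np.isfinite(c)):
            raise ParameterError("polynomial coefficients must be finite")
        if any(s == 0 for s in self.scales):
            raise ParameterError("normalization scales must be nonzero")
        object.__setattr__(self, "coeffs", c)

    def design_row(self, mu_v, sigma_v, tau_v_n) -> np.ndarray:
        """The ten polynomial terms, stacked along the last axis."""
        x = (np.asarray(mu_v, float) - self.centers[0]) / self.scales[0]
        y = (np.asarray(sigma_v, float) - self.centers[1]) / self.scales[1]
        z = (np.asarray(tau_v_n, float) - self.centers[2]) / self.scales[2]
        one = np.ones_like(x)
        return np.stack([one, x, y, z, x * x, y * y, z * z,
                         x * y, x * z, y * z], axis=-1)

    def __call__(self, mu_v, sigma_v, tau_v_n):
        return self.design_row(mu_v, sigma_v, tau_v_n) @ self.coeffs


def effective_threshold(moments: SubthresholdMoments,
                        poly: ThresholdPolynomial):
    """Effective threshold (mV) at the given subthreshold moments."""
    return poly(moments.mu_V, moments.sigma_V, moments.tau_V_N)


def _erfc_rate(mu_v, sigma_v, tau_v, v_thr, alpha):
    """Rate (Hz) of the erfc formula; 0 when sigma_V = 0 below threshold."""
    sigma_v = np.asarray(sigma_v, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (v_thr - mu_v) / (np.sqrt(2.0) * np.where(sigma_v > 0, sigma_v, 1.0))
    rate = alpha / (2.0 * tau_v) * erfc(arg) * 1e3
    zero_sigma = sigma_v <= 0
    if np.any(zero_sigma):
        sub = np.where(np.asarray(mu_v) < np.asarray(v_thr),
                       0.0, alpha / np.asarray(tau_v) * 1e3)
        rate = np.where(zero_sigma, sub, rate)
    return rate


@dataclass(frozen=True)
class TransferFunctionModel:
    """A fitted transfer function plus the synaptic/connectivity context
    needed to map (nu_e, nu_i) in Hz to an output rate in Hz."""

    poly: ThresholdPolynomial
    synapse: SynapseParams
    K_e: int = 400
    K_i: int = 100
    g_L: float = 10.0
    c_m: float = 150.0
    E_L: float = -65.0
    alpha: float = 1.0

    def __post_init__(self):
        if self.alpha < 1.0:
            raise ParameterError("alpha must be >= 1")

    def moments(self, nu_e, nu_i) -> SubthresholdMoments:
        return voltage_moments(nu_e, nu_i, self.g_L, self.c_m, self.E_L,
                               self.K_e, self.K_i, self.synapse)

    def rate(self, nu_e, nu_i):
        """Predicted output rate (Hz); vectorized over input rates."""
        m = self.moments(nu_e, nu_i)
        v_thr = effective_threshold(m, self.poly)
        return _erfc_rate(m.mu_V, m.sigma_V, m.tau_V, v_thr, self.alpha)

    def __call__(self, nu_e, nu_i):
        return self.rate(nu_e, nu_i)

    def save(self, path) -> None:
        """Delimited text: coefficient row (table column order) + context."""
        with open(path, "w") as fh:
            fh.write("# transfer-function model\n")
            fh.write("\t".join(COEF_NAMES) + "\n")
            fh.write("\t".join(f"{c:.8g}" for c in self.poly.coeffs) + "\n")
            ctx = dict(alpha=self.alpha, K_e=self.K_e, K_i=self.K_i,
                       g_L=self.g_L, c_m=self.c_m, E_L=self.E_L,
                       Q_e=self.synapse.Q_e, Q_i=self.synapse.Q_i,
                       tau=self.synapse.tau, E_e=self.synapse.E_e,
                       E_i=self.synapse.E_i)
            ctx.update({f"center{i}": v for i, v in enumerate(self.poly.centers)})
            ctx.update({f"scale{i}": v for i, v in enumerate(self.poly.scales)})
            for k, v in ctx.items():
                fh.write(f"{k}\t{v:.8g}\n")

    @classmethod
    def load(cls, path) -> "TransferFunctionModel":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        coeffs = np.array([float(x) for x in lines[1].split("\t")])
        ctx = {}
        for ln in lines[2:]:
            k, v = ln.split("\t")
            ctx[k] = float(v)
        poly = ThresholdPolynomial(
            coeffs,
            centers=(ctx["center0"], ctx["center1"], ctx["center2"]),
            scales=(ctx["scale0"], ctx["scale1"], ctx["scale2"]))
        syn = SynapseParams(Q_e=ctx["Q_e"], Q_i=ctx["Q_i"], tau=ctx["tau"],
                            E_e=ctx["E_e"], E_i=ctx["E_i"])
        return cls(poly, syn, K_e=int(ctx["K_e"]), K_i=int(ctx["K_i"]),
                   g_L=ctx["g_L"], c_m=ctx["c_m"], E_L=ctx["E_L"],
                   alpha=ctx["alpha"])


def predicted_rate(nu_e, nu_i, model: TransferFunctionModel):
    """Output rate (Hz) of the semianalytic transfer function."""
    nu_e = np.asarray(nu_e, float)
    nu_i = np.asarray(nu_i, float)
    if np.any(nu_e < 0) or np.any(nu_i < 0):
        raise ParameterError("rates must be non-negative")
    return model.rate(nu_e, nu_i)


def invert_rate(nu_out: float, moments: SubthresholdMoments,
                alpha: float = 1.0):
    """Effective threshold (mV) reproducing ``nu_out`` Hz at the given
    moments -- the exact inverse of the erfc rate formula."""
    nu_out = np.asarray(nu_out, float)
    tau_v = np.asarray(moments.tau_V, float)
    f_max = alpha / tau_v * 1e3  # erfc saturates at 2
    if np.any(nu_out <= 0) or np.any(nu_out >= f_max):
        raise ParameterError("output rate outside the attainable (0, alpha/tau_V) range")
    if np.any(np.asarray(moments.sigma_V) <= 0):
        raise ParameterError("sigma_V must be positive to invert the rate")
    y = 2.0 * tau_v * 1e-3 * nu_out / alpha  # erfc value in (0, 2)
    return moments.mu_V + np.sqrt(2.0) * moments.sigma_V * erfcinv(y)


# ---------------------------------------------------------------------------
# Measurement and fitting
# ---------------------------------------------------------------------------

def measure_transfer_function(model: str, params, synapse: SynapseParams,
                              grid: Sequence, K_e: int = 400, K_i: int = 100,
                              duration: float = 10_000.0, n_seeds: int = 4,
                              base_seed: int = 0, dt: float = None) -> pd.DataFrame:
    """Simulated output rate on a grid of (nu_e, nu_i) pairs.

    Each point is the mean over ``n_seeds`` independent simulations of
    ``duration`` ms; ``sem`` is the standard error over seeds.
    """
    grid = list(grid)
    if not grid:
        raise ParameterError("grid must be non-empty")
    rows = []
    for j, (nu_e, nu_i) in enumerate(grid):
        rates = [simulate_single_neuron(model, params, synapse,
                                        nu_e=nu_e, nu_i=nu_i, K_e=K_e, K_i=K_i,
                                        duration=duration, dt=dt,
                                        seed=base_seed + 1000 * j + s).rate
                 for s in range(n_seeds)]
        rates = np.asarray(rates)
        sem = rates.std(ddof=1) / np.sqrt(n_seeds) if n_seeds > 1 else 0.0
        rows.append((nu_e, nu_i, rates.mean(), sem))
    return pd.DataFrame(rows, columns=["nu_e", "nu_i", "rate", "sem"])


def build_fit_grid(model: str, params, synapse: SynapseParams,
                   nu_i_values: Sequence[float] = (0.5, 2, 4, 6, 8, 12, 16, 20),
                   n_e: int = 12, rate_max: float = 30.0,
                   scan_duration: float = 2000.0, seed: int = 0,
                   K_e: int = 400, K_i: int = 100, nu_e_cap: float = 512.0):
    """Locate, per nu_i row, n_e excitatory rates spanning outputs 0 to
    ~``rate_max`` Hz (or the full bell for cells with depolarization
    block), using short scout simulations and bisection."""
    grid = []
    for nu_i in nu_i_values:
        def rate_at(nu_e):
            return simulate_single_neuron(model, params, synapse, nu_e=nu_e,
                                          nu_i=nu_i, K_e=K_e, K_i=K_i,
                                          duration=scan_duration, seed=seed).rate
        # geometric scan upward until the target rate or a post-peak drop
        nu, peak, peak_nu, hi = 0.5, 0.0, 0.5, None
        prev_nu = 0.5
        while nu <= nu_e_cap:
            try:
                r = rate_at(nu)
            except IntegrationError:
                hi = prev_nu  # drive beyond the integrable range
                break
            if r >= rate_max:
                lo_b, hi_b = prev_nu, nu
                for _ in range(6):  # bisect the rate_max crossing
                    mid = 0.5 * (lo_b + hi_b)
                    if rate_at(mid) >= rate_max:
                        hi_b = mid
                    else:
                        lo_b = mid
                hi = hi_b
                break
            if r > peak:
                peak, peak_nu = r, nu
            elif peak > 1.0 and r < 0.5 * peak:
                hi = nu  # depolarization block: cover the full bell
                break
            prev_nu = nu
            nu *= 1.5
        if hi is None:
            hi = min(nu, nu_e_cap)
        for nu_e in np.linspace(hi / n_e, hi, n_e):
            grid.append((float(nu_e), float(nu_i)))
    return grid


def fit_transfer_function(samples: pd.DataFrame, g_L: float, c_m: float,
                          E_L: float, K_e: int, K_i: int,
                          synapse: SynapseParams, alpha: float = 1.0,
                          centers=(MU_V0, SIGMA_V0, TAU_N0),
                          scales=(D_MU_V0, D_SIGMA_V0, D_TAU_N0),
                          refine: bool = True):
    """Fit the threshold polynomial to measured rates.

    Stage 1 inverts the attainable measured rates to empirical thresholds
    and solves the ten-term polynomial by least squares; stage 2 refines
    the coefficients by minimizing the squared rate error of the erfc
    formula over all samples.  Returns (TransferFunctionModel, rms error
    in Hz over all samples).
    """
    need = {"nu_e", "nu_i", "rate"}
    if not need.issubset(samples.columns):
        raise FitError(f"samples must have columns {sorted(need)}")
    mom = voltage_moments(samples["nu_e"].to_numpy(), samples["nu_i"].to_numpy(),
                          g_L, c_m, E_L, K_e, K_i, synapse)
    rates = samples["rate"].to_numpy(dtype=float)
    f_max = alpha / mom.tau_V * 1e3
    ok = (rates > 0) & (rates < 0.98 * f_max) & (mom.sigma_V > 0)
    if int(ok.sum()) < 10:
        raise FitError("need at least 10 samples with nonzero measured rate "
                       "in the attainable range; broaden the grid")
    proto = ThresholdPolynomial(np.zeros(10), centers, scales)
    design = proto.design_row(mom.mu_V, mom.sigma_V, mom.tau_V_N)
    x_fit = design[ok]
    if np.linalg.matrix_rank(x_fit) < 10:
        raise FitError("degenerate sample design (rank-deficient); "
                       "use a broader (nu_e, nu_i) grid")
    thr_emp = invert_rate(rates[ok],
                          SubthresholdMoments(*[m[ok] for m in mom]), alpha)
    coeffs, *_ = np.linalg.lstsq(x_fit, thr_emp, rcond=None)

    if refine:
        def residual(c):
            v_thr = design @ c
            return _erfc_rate(mom.mu_V, mom.sigma_V, mom.tau_V, v_thr, alpha) - rates

        sol = least_squares(residual, coeffs, method="lm", max_nfev=20000)
        coeffs = sol.x

    poly = ThresholdPolynomial(coeffs, centers, scales)
    tf = TransferFunctionModel(poly, synapse, K_e=K_e, K_i=K_i,
                               g_L=g_L, c_m=c_m, E_L=E_L, alpha=alpha)
    rms = float(np.sqrt(np.mean((tf.rate(samples["nu_e"].to_numpy(),
                                         samples["nu_i"].to_numpy()) - rates) ** 2)))
    return tf, rms


def fit_cell(model: str, cell: str, params=None, synapse: SynapseParams = None,
             K_e: int = 400, K_i: int = 100, alpha: float = 1.0,
             nu_i_values=(0.5, 2, 4, 6, 8, 12, 16, 20), n_e: int = 12,
             duration: float = 10_000.0, n_seeds: int = 4, seed: int = 0):
    """Measure and fit the transfer function of one cell type end to end.

    Returns (TransferFunctionModel, measured samples, rms error in Hz).
    """
    model = model.lower()
    if params is None:
        params = default_params(model, cell)
    if synapse is None:
        synapse = default_synapse(model)
    grid = build_fit_grid(model, params, synapse, nu_i_values=nu_i_values,
                          n_e=n_e, seed=seed, K_e=K_e, K_i=K_i)
    samples = measure_transfer_function(model, params, synapse, grid,
                                        K_e=K_e, K_i=K_i, duration=duration,
                                        n_seeds=n_seeds, base_seed=seed)
    tf, rms = fit_transfer_function(samples, params.g_L, params.c_m, params.E_L,
                                    K_e, K_i, synapse, alpha=alpha)
    return tf, samples, rms


def load_reference_thresholds(model: str) -> dict:
    """Packaged reference threshold-coefficient sets (one per cell type)
    from the original calibration of the default parameterizations.

    These are shipped for orientation and regression comparison; they are
    tied to a particular normalization convention and need not coincide
    with a fresh fit (see docs/methods.md).
    """
    name = f"{model.lower()}_reference_thresholds.tsv"
    path = importlib.resources.files("spikemf").joinpath("data", name)
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for _, row in df.iterrows():
        coeffs = row[list(COEF_NAMES)].to_numpy(dtype=float)
        out[str(row["cell"]).lower()] = ThresholdPolynomial(coeffs)
    return out
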