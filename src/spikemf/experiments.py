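"""End-to-end validation experiments.

Three orchestrated protocols, each fully reproducible from a config plus
a seed and writing plain-text artifacts to an output directory:

* ``tf``          -- measure and fit the RS and FS transfer functions;
* ``spontaneous`` -- simulate the network's spontaneous activity and
                     compare population-rate statistics with the
                     first/second-order mean-field stationary state;
* ``stimulus``    -- drive network and mean field with the same
                     double-Gaussian stimulus and compare the responses.

Default experiment sizes are scaled for desk runs (N = 2,500 with the
connection probability adjusted to keep the in-degrees K_e = 400,
K_i = 100 of the full-size network, which preserves the single-neuron
input statistics the mean field sees); ``full=True`` restores N = 10^4.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .mean_field import (MeanFieldParams, StimulusProfile, find_stationary_state,
                         integrate_mean_field, stimulus_rate)
from .network import (NetworkConfig, population_rate, scaled_config,
                      simulate_network)
from .params import (HH_ACTIVE_SCALE, ML_COND_SCALE, default_params,
                     default_synapse, params_from_dict, params_to_dict)
from .transfer_function import TransferFunctionModel, fit_cell

log = logging.getLogger("spikemf.experiments")


@dataclass
class ExperimentConfig:
    """Resolved settings of one experiment run."""

    model: str = "adex"
    seed: int = 0
    full: bool = False
    N: int = 2500
    K_e: int = 400
    K_i: int = 100
    nu_drive: float = 4.0
    duration: float = 10_000.0
    window: float = 20.0
    # transfer-function fit settings
    nu_i_values: tuple = (0.5, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 20.0)
    n_e: int = 12
    tf_duration: float = 10_000.0
    tf_seeds: int = 4
    alpha: float = 1.0
    # mean field
    T: float = 20.0
    deriv_step: float = 0.05
    mf_dt: float = 0.1
    # stimulus
    A: float = 2.0
    t0: float = 2000.0
    T1: float = 100.0
    T2: float = 150.0
    # optional parameter overrides, keyed 'rs'/'fs'/'synapse'
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, **kw) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update(kw)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ParameterError(f"unknown config keys: {sorted(bad)}")
        if "nu_i_values" in doc:
            doc["nu_i_values"] = tuple(float(x) for x in doc["nu_i_values"])
        return cls(**doc)

    def resolve_cells(self):
        """(params_rs, params_fs, synapse) with overrides applied."""
        p_rs = default_params(self.model, "rs")
        p_fs = default_params(self.model, "fs")
        syn = default_synapse(self.model)
        if "rs" in self.overrides:
            p_rs = params_from_dict(self.model,
                                    {**params_to_dict(p_rs), **self.overrides["rs"]})
        if "fs" in self.overrides:
            p_fs = params_from_dict(self.model,
                                    {**params_to_dict(p_fs), **self.overrides["fs"]})
        if "synapse" in self.overrides:
            syn = syn._replace(**{k: float(v)
                                  for k, v in self.overrides["synapse"].items()})
        return p_rs, p_fs, syn

    def network_config(self) -> NetworkConfig:
        n = 10_000 if self.full else self.N
        return scaled_config(N=n, K_e=self.K_e, nu_drive=self.nu_drive,
                             seed=self.seed)

    def stimulus(self) -> StimulusProfile:
        return StimulusProfile(A=self.A, t0=self.t0, T1=self.T1, T2=self.T2)

    def checksum(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def effective_parameters(self) -> dict:
        p_rs, p_fs, syn = self.resolve_cells()
        return {
            "config": asdict(self),
            "cells": {"rs": params_to_dict(p_rs), "fs": params_to_dict(p_fs)},
            "synapse": params_to_dict(syn),
            "unit_scales": {"hh_active_nS_per_density": HH_ACTIVE_SCALE,
                            "ml_conductance_nS_per_density": ML_COND_SCALE},
        }


def _write_report(out_dir: Path, name: str, config: ExperimentConfig,
                  body: dict) -> dict:
    report = {"checksum": config.checksum(), "seed": config.seed,
              **config.effective_parameters(), name: body}
    with open(out_dir / "report.yaml", "w") as fh:
        yaml.safe_dump(_plain(report), fh, sort_keys=False)
    return report


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _stage(name, t0):
    log.info("%-12s done in %.1f s", name, time.time() - t0)
    return time.time()


def fit_both_cells(config: ExperimentConfig, out_dir: Path = None):
    """Fit RS and FS transfer functions; optionally write artifacts."""
    p_rs, p_fs, syn = config.resolve_cells()
    results = {}
    for cell, params in (("rs", p_rs), ("fs", p_fs)):
        t0 = time.time()
        tf, samples, rms = fit_cell(
            config.model, cell, params=params, synapse=syn,
            K_e=config.K_e, K_i=config.K_i, alpha=config.alpha,
            nu_i_values=config.nu_i_values, n_e=config.n_e,
            duration=config.tf_duration, n_seeds=config.tf_seeds,
            seed=config.seed + (0 if cell == "rs" else 7919))
        log.info("tf fit %s: rms %.3f Hz (%.1f s)", cell, rms, time.time() - t0)
        if out_dir is not None:
            samples.to_csv(out_dir / f"tf_samples_{cell}.tsv", sep="\t", index=False)
            tf.save(out_dir / f"tf_fit_{cell}.tsv")
        results[cell] = (tf, samples, rms)
    return results


def _max_gain(samples, tf, nu_i: float = 8.0):
    """Maximal local slope dF/dnu_e (fitted curve) on the nu_i row."""
    row = samples[np.isclose(samples["nu_i"], nu_i)]
    if row.empty:
        row = samples
    nu_hi = float(row["nu_e"].max())
    nus = np.linspace(0.1, nu_hi, 60)
    f = tf.rate(nus, np.full_like(nus, nu_i))
    return float(np.max(np.gradient(f, nus)))


def run_tf_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Measure + fit both cell types; report rms errors and gains."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if 8.0 not in tuple(config.nu_i_values):  # Figs.-style reference row
        config.nu_i_values = tuple(config.nu_i_values) + (8.0,)
    results = fit_both_cells(config, out_dir)
    body = {}
    for cell, (tf, samples, rms) in results.items():
        body[cell] = {"rms_Hz": float(rms),
                      "n_samples": int(len(samples)),
                      "max_gain": _max_gain(samples, tf)}
    body["gain_ratio_fs_over_rs"] = body["fs"]["max_gain"] / body["rs"]["max_gain"]
    return _write_report(out_dir, "transfer_function", config, body)


def run_spontaneous_experiment(config: ExperimentConfig, out_dir,
                               tf_pair=None) -> dict:
    """Spontaneous network activity vs mean-field stationary state."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if tf_pair is None:
        results = fit_both_cells(config, out_dir)
        tf_pair = (results["rs"][0], results["fs"][0])
        t0 = _stage("tf fit", t0)
    tf_e, tf_i = tf_pair

    net_cfg = config.network_config()
    p_rs, p_fs, syn = config.resolve_cells()
    raster = simulate_network(config.model, net_cfg, p_rs, p_fs, syn,
                              duration=config.duration)
    raster.save(out_dir / "raster.txt")
    series, summary = population_rate(raster, window=config.window)
    t0 = _stage("network", t0)

    mfp = MeanFieldParams(T=config.T, N_e=net_cfg.n_exc, N_i=net_cfg.n_inh,
                          step=config.deriv_step, order="second")
    st2 = find_stationary_state(tf_e, tf_i, mfp, ext_rate=config.nu_drive,
                                dt=config.mf_dt)
    st1 = find_stationary_state(tf_e, tf_i,
                                MeanFieldParams(T=config.T, N_e=net_cfg.n_exc,
                                                N_i=net_cfg.n_inh,
                                                step=config.deriv_step,
                                                order="first"),
                                ext_rate=config.nu_drive, dt=config.mf_dt)
    _stage("mean field", t0)

    np.savetxt(out_dir / "population_rates.tsv",
               np.column_stack([series.t, series.rate_e, series.rate_i]),
               header="t_ms rate_e_Hz rate_i_Hz")
    body = {
        "network": {"rate_e": raster.mean_rate(True),
                    "rate_i": raster.mean_rate(False),
                    "rate_var_e": summary.var_e, "rate_var_i": summary.var_i,
                    "acorr_time_e_ms": summary.acorr_time_e,
                    "acorr_time_i_ms": summary.acorr_time_i},
        "mean_field_first": {"nu_e": st1.nu_e, "nu_i": st1.nu_i},
        "mean_field_second": {"nu_e": st2.nu_e, "nu_i": st2.nu_i,
                              "c_ee": st2.c_ee, "c_ei": st2.c_ei,
                              "c_ii": st2.c_ii},
    }
    return _write_report(out_dir, "spontaneous", config, body)


def run_stimulus_experiment(config: ExperimentConfig, out_dir,
                            tf_pair=None) -> dict:
    """Time-dependent response of network and mean field to the stimulus."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if tf_pair is None:
        results = fit_both_cells(config, out_dir)
        tf_pair = (results["rs"][0], results["fs"][0])
        t0 = _stage("tf fit", t0)
    tf_e, tf_i = tf_pair
    stim = config.stimulus()

    net_cfg = config.network_config()
    p_rs, p_fs, syn = config.resolve_cells()
    raster = simulate_network(config.model, net_cfg, p_rs, p_fs, syn,
                              stimulus=stim, duration=config.duration)
    series, _ = population_rate(raster, window=config.window)
    t0 = _stage("network", t0)

    mfp = MeanFieldParams(T=config.T, N_e=net_cfg.n_exc, N_i=net_cfg.n_inh,
                          step=config.deriv_step, order="second")
    traj = integrate_mean_field(tf_e, tf_i, mfp, nu_drive=config.nu_drive,
                                stimulus=stim, duration=config.duration,
                                dt=config.mf_dt, sample_every=config.window)
    _stage("mean field", t0)

    np.savetxt(out_dir / "network_rates.tsv",
               np.column_stack([series.t, series.rate_e, series.rate_i]),
               header="t_ms rate_e_Hz rate_i_Hz")
    traj.save(out_dir / "meanfield_trajectory.tsv")

    # peak response relative to the pre-stimulus baseline
    def response(t, x):
        t = np.asarray(t)
        base = float(np.mean(x[(t > 200) & (t < stim.t0 - 4 * stim.T1)]))
        win = (t > stim.t0 - 2 * stim.T1) & (t < stim.t0 + 3 * stim.T2)
        dev = x[win] - base
        peak = float(dev[np.argmax(np.abs(dev))])
        return base, peak

    body = {}
    for label, t, xe, xi in (("network", series.t, series.rate_e, series.rate_i),
                             ("mean_field", traj.t, traj.nu_e, traj.nu_i)):
        be, pe = response(t, xe)
        bi, pi = response(t, xi)
        body[label] = {"baseline_e": be, "peak_response_e": pe,
                       "baseline_i": bi, "peak_response_i": pi}
    body["stimulus"] = dict(A=stim.A, t0=stim.t0, T1=stim.T1, T2=stim.T2)
    return _write_report(out_dir, "stimulus", config, body)
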