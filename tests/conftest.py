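"""Shared fixtures: fitted transfer functions and a reference network run.

The expensive artifacts (transfer-function fits, 10 s network simulations)
are session-scoped and shared across test modules.  Fit settings here are
smaller than the library defaults (fewer inhibitory rows, shorter
simulations) to keep the suite quick; the resulting fits are still
accurate to well under 1 Hz rms.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def adex_tf_pair():
    """Fitted AdEx (RS, FS) transfer functions plus their samples/rms."""
    from spikemf.transfer_function import fit_cell
    rs = fit_cell("adex", "rs", nu_i_values=(2, 4, 6, 8, 12, 16), n_e=10,
                  duration=10_000.0, n_seeds=2, seed=11)
    fs = fit_cell("adex", "fs", nu_i_values=(2, 4, 6, 8, 12, 16), n_e=10,
                  duration=10_000.0, n_seeds=2, seed=23)
    return {"rs": rs, "fs": fs}


@pytest.fixture(scope="session")
def ml_tf_pair():
    """Fitted Morris-Lecar (RS, FS) transfer functions."""
    from spikemf.transfer_function import fit_cell
    rs = fit_cell("ml", "rs", nu_i_values=(2, 4, 8, 12), n_e=8,
                  duration=5000.0, n_seeds=2, seed=31)
    fs = fit_cell("ml", "fs", nu_i_values=(2, 4, 8, 12), n_e=8,
                  duration=5000.0, n_seeds=2, seed=47)
    return {"rs": rs, "fs": fs}


@pytest.fixture(scope="session")
def adex_network_run():
    """Spontaneous activity of the scaled AdEx network (N=2500, in-degrees
    of the full-size network preserved), 10 s at 4 Hz drive."""
    from spikemf.network import scaled_config, simulate_network
    cfg = scaled_config(N=2500, K_e=400, nu_drive=4.0, seed=42)
    raster = simulate_network("adex", cfg, duration=10_000.0)
    return cfg, raster
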