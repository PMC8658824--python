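import numpy as np
import pandas as pd
import pytest

from thermoramp.assay_io import traces_from_readings
from thermoramp.simulate import SimulationSpec, simulate_ramp


@pytest.fixture(scope="session")
def clean_spec() -> SimulationSpec:
    """Noise-free default ramp: known Arrhenius line, duplicate dilution series."""
    return SimulationSpec(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_assay(clean_spec):
    return simulate_ramp(clean_spec)


@pytest.fixture(scope="session")
def clean_traces(clean_assay):
    groups = {
        cid: g[["time_s", "temperature_K", "absorbance"]].reset_index(drop=True)
        for cid, g in clean_assay.readings_si.groupby("cuvette_id", sort=False)
    }
    return traces_from_readings(groups, clean_assay.design)


@pytest.fixture()
def linear_trace():
    """Hand-built trace with exactly linear product accumulation (slope 2e-8 M/s)."""
    from thermoramp.assay_io import CuvetteTrace

    t = np.arange(0.0, 300.0, 30.0)
    data = pd.DataFrame(
        {
            "time_s": t,
            "temperature_K": 280.0 + 0.01 * t,
            "product_M": 2e-8 * t,
            "substrate_M": 1e-4 - 2e-8 * t,
            "out_of_range": False,
        }
    )
    return CuvetteTrace(cuvette_id="lin", s0=1e-4, data=data)


def brute_force_window_slope(t: np.ndarray, p: np.ndarray) -> float:
    """Independent two-pass OLS slope for one window (test oracle)."""
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    tbar, pbar = t.mean(), p.mean()
    num = 0.0
    den = 0.0
    for ti, pi in zip(t, p):
        num += (ti - tbar) * (pi - pbar)
        den += (ti - tbar) ** 2
    return num / den


def grid_search_mm(s, v, e0, kcat_range, km_range, rounds=10, grid=61):
    """Exhaustive grid-search Michaelis-Menten fit, refined to ~1e-4 relative.

    Independent of the Levenberg-Marquardt path: evaluates the residual sum
    of squares on a shrinking (kcat, KM) lattice. The first pass is
    log-spaced (both parameters are scale parameters); later passes zoom
    linearly around the incumbent with a generous margin so the correlated
    (kcat, KM) valley is not lost.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)

    def rss_grid(kcats, kms):
        rss = ((v[None, None, :] - kcats[:, None, None] * e0 * s[None, None, :]
                / (kms[None, :, None] + s[None, None, :])) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        return kcats[i], kms[j]

    best = rss_grid(
        np.geomspace(kcat_range[0], kcat_range[1], grid),
        np.geomspace(km_range[0], km_range[1], grid),
    )
    width = np.array([best[0], best[1]]) * 0.5
    for _ in range(rounds):
        lo = np.maximum(np.array(best) - width, 1e-12)
        hi = np.array(best) + width
        best = rss_grid(np.linspace(lo[0], hi[0], grid), np.linspace(lo[1], hi[1], grid))
        width = width * (6.0 / (grid - 1))
    return best
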