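"""Rolling-window ordinary least squares velocities.

During a temperature ramp the reaction velocity changes continuously, so a
single progress-curve slope is meaningless. Instead a short window (default
4 consecutive readings of one cuvette) is slid along each trace with step 1,
and the OLS slope of product concentration against time within the window is
taken as the instantaneous velocity. Each velocity is paired with the
window-mean temperature and window-mean substrate concentration for the
downstream Michaelis–Menten fits. Because a window needs ``window`` points,
the first ``window - 1`` positions yield no velocity and the terminal
temperatures of the gradient are not represented.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .assay_io import CuvetteTrace
from .errors import FittingError, InsufficientDataError

#: Default window size (readings per cuvette); small enough that the
#: temperature-driven change in velocity within a window is minor.
DEFAULT_WINDOW = 4

VELOCITY_COLUMNS = [
    "cuvette_id",
    "time_mid",
    "temperature_K",
    "substrate_M",
    "velocity_M_per_s",
    "window_start",
    "window_end",
]


def rolling_velocity(trace: CuvetteTrace, window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Velocities for one cuvette trace via rolling OLS, one row per window.

    A trace of n points yields exactly ``n - window + 1`` rows. The slope is
    the centred least-squares formula sum((t - tbar)(P - Pbar)) / sum((t - tbar)^2),
    so adding a constant to the product series leaves every velocity unchanged.

    Raises
    ------
    InsufficientDataError
        if ``window < 2`` or the trace has fewer points than ``window``.
    FittingError
        if a window has zero time variance (duplicate times).
    """
    if window < 2:
        raise InsufficientDataError(f"window must be >= 2, got {window}")
    n = len(trace)
    if n < window:
        raise InsufficientDataError(
            f"cuvette {trace.cuvette_id!r} has {n} points, fewer than window {window}"
        )
    t = trace.data["time_s"].to_numpy(dtype=float)
    p = trace.data["product_M"].to_numpy(dtype=float)
    temp = trace.data["temperature_K"].to_numpy(dtype=float)
    s = trace.data["substrate_M"].to_numpy(dtype=float)

    tw = sliding_window_view(t, window)
    pw = sliding_window_view(p, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", tc, tc)
    if np.any(denom == 0.0):
        idx = int(np.flatnonzero(denom == 0.0)[0])
        raise FittingError(
            f"zero time variance in window starting at index {idx} "
            f"of cuvette {trace.cuvette_id!r}"
        )
    slope = np.einsum("ij,ij->i", tc, pw) / denom

    starts = np.arange(n - window + 1)
    return pd.DataFrame(
        {
            "cuvette_id": trace.cuvette_id,
            "time_mid": tw.mean(axis=1),
            "temperature_K": sliding_window_view(temp, window).mean(axis=1),
            "substrate_M": sliding_window_view(s, window).mean(axis=1),
            "velocity_M_per_s": slope,
            "window_start": starts,
            "window_end": starts + window - 1,
        }
    )


def rolling_velocities(
    traces: list[CuvetteTrace], window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Concatenated velocity table for several cuvettes (tidy long form)."""
    if not traces:
        raise InsufficientDataError("no traces given")
    return pd.concat([rolling_velocity(tr, window) for tr in traces], ignore_index=True)
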