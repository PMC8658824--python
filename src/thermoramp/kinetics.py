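"""Temperature binning and per-bin Michaelis–Menten fits.

Velocities harvested along a temperature gradient are pooled across cuvettes
and partitioned into equal-width temperature bins. Within one bin the
temperature varies little, so the classical steady-state model

    v = kcat * E0 * S / (KM + S)

is fitted to (S, v) by unweighted non-linear least squares
(Levenberg–Marquardt), one independent fit per bin with no parameter sharing
between bins. Standard errors come from the residual-variance-scaled inverse
of the Jacobian normal matrix, the usual linearised covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

#: Bins with fewer points than this are skipped by :func:`fit_bins`.
DEFAULT_MIN_POINTS = 4


@dataclass
class TemperatureBin:
    """One equal-width temperature bin of pooled velocity points."""

    index: int
    temperature_mean: float
    lower: float
    upper: float
    points: pd.DataFrame  # rows of the velocity table

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class MichaelisMentenFit:
    """Michaelis–Menten parameters for one temperature bin.

    ``kcat`` in s^-1, ``km`` in M; ``vmax = kcat * e0`` by construction.
    ``converged`` is False when the optimiser failed; ``valid`` additionally
    requires positive parameters. Invalid fits are excluded from the
    Arrhenius stage rather than clamped.
    """

    temperature: float
    kcat: float
    kcat_se: float
    km: float
    km_se: float
    e0: float
    n_points: int
    rss: float
    converged: bool

    @property
    def vmax(self) -> float:
        return self.kcat * self.e0

    @property
    def valid(self) -> bool:
        return (
            self.converged
            and np.isfinite(self.kcat)
            and np.isfinite(self.km)
            and self.kcat > 0
            and self.km > 0
        )


def michaelis_menten(s, kcat, km, e0):
    """Steady-state velocity v = kcat*E0*S/(KM+S)."""
    s = np.asarray(s, dtype=float)
    return kcat * e0 * s / (km + s)


def bin_by_temperature(
    points: pd.DataFrame,
    n_bins: int,
    bounds: tuple[float, float] | None = None,
) -> list[TemperatureBin]:
    """Partition velocity points into equal-width temperature bins.

    ``bounds`` defaults to the observed (min, max) temperature. Points
    outside the bounds are excluded; the upper edge is inclusive. Empty bins
    are dropped with a logged notice, so the result may have fewer than
    ``n_bins`` entries.
    """
    if n_bins < 1:
        raise InsufficientDataError(f"n_bins must be >= 1, got {n_bins}")
    if len(points) == 0:
        raise InsufficientDataError("no velocity points to bin")
    temps = points["temperature_K"].to_numpy(dtype=float)
    lo, hi = bounds if bounds is not None else (float(temps.min()), float(temps.max()))
    if not lo < hi:
        # degenerate span (all points at one temperature): a single bin
        lo, hi = lo - 0.5, hi + 0.5
    inside = (temps >= lo) & (temps <= hi)
    if not inside.any():
        raise InsufficientDataError(f"no velocity points inside temperature bounds [{lo}, {hi}] K")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(temps, edges[1:-1], right=False)

    bins: list[TemperatureBin] = []
    for b in range(n_bins):
        mask = inside & (idx == b)
        if not mask.any():
            logger.info("temperature bin %d [%.2f, %.2f] K is empty; dropped", b, edges[b], edges[b + 1])
            continue
        member = points.loc[mask].reset_index(drop=True)
        bins.append(
            TemperatureBin(
                index=b,
                temperature_mean=float(member["temperature_K"].mean()),
                lower=float(edges[b]),
                upper=float(edges[b + 1]),
                points=member,
            )
        )
    return bins


def fit_michaelis_menten(
    bin: TemperatureBin,
    e0: float,
    initial_guess: tuple[float, float] | None = None,
    max_iterations: int = 10000,
) -> MichaelisMentenFit:
    """Fit (kcat, KM) to one bin's velocities by Levenberg–Marquardt NLS.

    Default initial guess: ``kcat0 = max(v)/E0``, ``KM0 = median(S)``.
    Non-convergence or non-positive parameter estimates are recorded in the
    ``converged``/``valid`` flags instead of raising, so the caller can
    exclude the bin downstream.
    """
    if e0 <= 0:
        raise InsufficientDataError("E0 must be positive")
    s = bin.points["substrate_M"].to_numpy(dtype=float)
    v = bin.points["velocity_M_per_s"].to_numpy(dtype=float)
    if len(s) < 3:
        raise InsufficientDataError(
            f"bin {bin.index} has {len(s)} points; need >= 3 for a two-parameter fit"
        )
    if len(np.unique(s)) < 2:
        raise InsufficientDataError(
            f"bin {bin.index} spans a single substrate concentration; KM is unidentifiable"
        )
    if initial_guess is None:
        kcat0 = float(np.max(v)) / e0
        if not np.isfinite(kcat0) or kcat0 <= 0:
            kcat0 = 1.0
        initial_guess = (kcat0, float(np.median(s)))

    def model(si, kcat, km):
        return michaelis_menten(si, kcat, km, e0)

    try:
        popt, pcov = curve_fit(model, s, v, p0=initial_guess, method="lm", maxfev=max_iterations)
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        popt = np.array([np.nan, np.nan])
        pcov = np.full((2, 2), np.nan)
        converged = False
    resid = v - model(s, *popt) if converged else np.full_like(v, np.nan)
    rss = float(np.sum(resid**2)) if converged else float("nan")
    se = np.sqrt(np.diag(pcov)) if converged else np.array([np.nan, np.nan])

    fit = MichaelisMentenFit(
        temperature=bin.temperature_mean,
        kcat=float(popt[0]),
        kcat_se=float(se[0]),
        km=float(popt[1]),
        km_se=float(se[1]),
        e0=e0,
        n_points=len(s),
        rss=rss,
        converged=converged,
    )
    if converged and not fit.valid:
        logger.warning(
            "bin %d (%.2f K): non-physical fit kcat=%.3g, KM=%.3g; flagged invalid",
            bin.index,
            bin.temperature_mean,
            fit.kcat,
            fit.km,
        )
    return fit


def fit_bins(
    bins: list[TemperatureBin],
    e0: float,
    min_points: int = DEFAULT_MIN_POINTS,
) -> list[MichaelisMentenFit]:
    """Fit every bin with at least ``min_points`` members; skip the rest with a warning."""
    fits: list[MichaelisMentenFit] = []
    for b in bins:
        if b.n_points < min_points or len(np.unique(b.points["substrate_M"])) < 2:
            logger.warning(
                "bin %d (%.2f K): only %d point(s); skipped (min_points=%d)",
                b.index,
                b.temperature_mean,
                b.n_points,
                min_points,
            )
            continue
        fits.append(fit_michaelis_menten(b, e0))
    return fits


def fits_table(fits: list[MichaelisMentenFit]) -> pd.DataFrame:
    """Tidy per-bin results table (temperature_K, kcat, kcat_se, KM, KM_se, n_points, converged)."""
    return pd.DataFrame(
        {
            "temperature_K": [f.temperature for f in fits],
            "kcat": [f.kcat for f in fits],
            "kcat_se": [f.kcat_se for f in fits],
            "KM": [f.km for f in fits],
            "KM_se": [f.km_se for f in fits],
            "n_points": [f.n_points for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
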