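"""Weighted Arrhenius regression and transition-state thermodynamics.

The per-bin turnover numbers kcat(T) follow the Arrhenius law

    kcat = A * exp(-Ea / (R T))      <=>      ln kcat = ln A - (Ea/R) * (1/T)

so a weighted least-squares line through (1/T, ln kcat), with weights
1/SE(kcat)^2, yields the activation energy from the slope and the
pre-exponential factor from the intercept. Transition-state theory (Eyring,
transmission coefficient kappa = 1) then converts the rate at a reference
temperature into the free-energy barrier:

    kcat(T) = (kB T / h) * exp(-dG‡ / (R T))
    dH‡ = Ea - R T,    T dS‡ = dH‡ - dG‡

All energies are in kcal/mol. Standard errors are propagated from the
regression covariance by the delta method; the dG‡ error comes from the
standard error of the fitted mean ln kcat at 1/T_ref.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .constants import CONSTANTS, PhysicalConstants
from .errors import FittingError, InsufficientDataError, ValidationError
from .kinetics import MichaelisMentenFit

logger = logging.getLogger(__name__)


def weighted_line_fit(x, y, w):
    """Weighted least-squares line y = intercept + slope*x.

    Minimises sum(w_i (y_i - b - m x_i)^2). Returns
    ``(intercept, slope, cov, wrss)`` where ``cov`` is the 2x2
    residual-variance-scaled parameter covariance ordered
    (intercept, slope) and ``wrss`` the weighted residual sum of squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValidationError("weights must be strictly positive")
    if np.allclose(x, x[0]):
        raise FittingError("degenerate design: all abscissae equal")
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    intercept, slope = (float(v) for v in res.params)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.asarray(res.cov_params(), dtype=float)
    wrss = float(np.sum(w * res.resid**2))
    return intercept, slope, cov, wrss


@dataclass
class ArrheniusFit:
    """Weighted line through (1/T, ln kcat).

    ``slope`` has units of kelvin and equals -Ea/R; ``intercept`` is ln A
    with A in s^-1. ``cov`` is ordered (intercept, slope). ``points`` keeps
    the per-point (temperature, 1/T, ln kcat, weight) table used for the fit
    (None for a line supplied directly, e.g. from a published regression).
    """

    slope: float
    intercept: float
    cov: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    n_points: int = 0
    wrss: float = 0.0
    points: pd.DataFrame | None = None

    @property
    def slope_se(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    @property
    def intercept_se(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @classmethod
    def from_line(cls, slope: float, intercept: float) -> "ArrheniusFit":
        """Wrap a known (slope, intercept) pair with zero covariance."""
        return cls(slope=float(slope), intercept=float(intercept))

    def ln_kcat(self, temperature: float) -> float:
        return self.intercept + self.slope / temperature

    def kcat(self, temperature: float) -> float:
        return math.exp(self.ln_kcat(temperature))


@dataclass
class ActivationParameters:
    """Activation thermodynamics at a reference temperature, kcal/mol.

    Invariants: ``delta_h == ea - R*t_ref`` and
    ``t_delta_s == delta_h - delta_g`` hold exactly by construction.
    ``kappa`` is the transmission coefficient, fixed at 1.
    """

    t_ref: float
    ea: float
    ea_se: float
    pre_exponential: float
    pre_exponential_se: float
    kcat_ref: float
    kcat_ref_se: float
    delta_g: float
    delta_g_se: float
    delta_h: float
    delta_h_se: float
    t_delta_s: float
    t_delta_s_se: float
    n_points: int = 0
    kappa: float = 1.0

    def confidence_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """t-based confidence interval (n-2 degrees of freedom) for one parameter.

        The half-width equals ``t_crit * SE``; equivalently the standard
        error can be recovered from a reported interval as
        half-width / t_crit.
        """
        value = getattr(self, name)
        se = getattr(self, f"{name}_se")
        if self.n_points < 3 or not np.isfinite(se):
            return (float("nan"), float("nan"))
        tcrit = stats.t.ppf(0.5 + level / 2.0, df=self.n_points - 2)
        return (value - tcrit * se, value + tcrit * se)

    def to_dict(self) -> dict:
        return {
            "T_ref_K": self.t_ref,
            "Ea_kcal_per_mol": self.ea,
            "Ea_se": self.ea_se,
            "A_per_s": self.pre_exponential,
            "A_se": self.pre_exponential_se,
            "kcat_at_T_ref_per_s": self.kcat_ref,
            "kcat_at_T_ref_se": self.kcat_ref_se,
            "dG_kcal_per_mol": self.delta_g,
            "dG_se": self.delta_g_se,
            "dH_kcal_per_mol": self.delta_h,
            "dH_se": self.delta_h_se,
            "TdS_kcal_per_mol": self.t_delta_s,
            "TdS_se": self.t_delta_s_se,
            "kappa": self.kappa,
            "n_points": self.n_points,
        }


def apply_temperature_cutoffs(
    fits: list[MichaelisMentenFit],
    t_min: float | None = None,
    t_max: float | None = None,
) -> list[MichaelisMentenFit]:
    """Keep converged, physically valid fits inside [t_min, t_max].

    This is the researcher-controlled step that eliminates bins where the
    enzyme is no longer active (e.g. approaching unfolding at the hot end).

    Raises
    ------
    InsufficientDataError
        if fewer than 3 fits survive (an Arrhenius line plus residual
        variance needs at least 3 points).
    """
    lo = -math.inf if t_min is None else float(t_min)
    hi = math.inf if t_max is None else float(t_max)
    if not lo < hi:
        raise ValidationError(f"t_min ({lo}) must be below t_max ({hi})")
    kept = [f for f in fits if f.valid and lo <= f.temperature <= hi]
    removed = len(fits) - len(kept)
    if removed:
        logger.info("temperature cut-offs [%.2f, %.2f] K removed %d fit(s)", lo, hi, removed)
    if len(kept) < 3:
        raise InsufficientDataError(
            f"only {len(kept)} usable Michaelis-Menten fits inside cut-offs [{lo}, {hi}] K; "
            "need >= 3 for the Arrhenius stage"
        )
    return kept


def weighted_arrhenius_fit(
    fits: list[MichaelisMentenFit],
    weight_scheme: str = "paper",
) -> ArrheniusFit:
    """Weighted regression of ln(kcat) on 1/T across temperature bins.

    ``weight_scheme``:

    * ``"paper"`` (default): w_i = 1 / SE(kcat_i)^2, i.e. the inverse squared
      standard error of kcat itself, applied to the log-scale regression.
    * ``"delta-log"``: w_i = (kcat_i / SE(kcat_i))^2, the first-order variance
      of ln kcat (SE(ln k) = SE(k)/k); statistically consistent with the
      log-scale regressand.
    """
    if weight_scheme not in ("paper", "delta-log"):
        raise ValidationError(f"unknown weight scheme {weight_scheme!r}")
    if len(fits) < 3:
        raise InsufficientDataError(f"need >= 3 fits for the Arrhenius regression, got {len(fits)}")
    kcat = np.array([f.kcat for f in fits], dtype=float)
    se = np.array([f.kcat_se for f in fits], dtype=float)
    temp = np.array([f.temperature for f in fits], dtype=float)
    if np.any(kcat <= 0):
        raise ValidationError("all kcat values must be positive to take logarithms")
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValidationError("all kcat standard errors must be finite and positive")

    x = 1.0 / temp
    y = np.log(kcat)
    w = 1.0 / se**2 if weight_scheme == "paper" else (kcat / se) ** 2
    intercept, slope, cov, wrss = weighted_line_fit(x, y, w)
    points = pd.DataFrame(
        {"temperature_K": temp, "inv_temperature": x, "ln_kcat": y, "weight": w}
    )
    return ArrheniusFit(
        slope=slope, intercept=intercept, cov=cov, n_points=len(fits), wrss=wrss, points=points
    )


def eyring_rate(
    delta_g: float, temperature: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Eyring rate k = (kB T / h) exp(-dG‡/(R T)), kappa = 1; dG‡ in kcal/mol."""
    return (constants.kB * temperature / constants.h) * math.exp(
        -delta_g / (constants.R_kcal * temperature)
    )


def eyring_delta_g(
    rate: float, temperature: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Invert the Eyring equation: dG‡ = R T ln(kB T / (h k)), kcal/mol."""
    if rate <= 0:
        raise ValidationError("rate must be positive")
    return constants.R_kcal * temperature * math.log(
        constants.kB * temperature / (constants.h * rate)
    )


def extrapolate_rate(
    delta_h: float,
    t_delta_s: float,
    t_ref: float,
    temperature: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Eyring rate at another temperature from (dH‡, TdS‡) measured at t_ref.

    Assumes dH‡ and dS‡ are temperature-independent: dS‡ = TdS‡/t_ref, and
    dG‡(T) = dH‡ - T dS‡.
    """
    delta_s = t_delta_s / t_ref
    delta_g = delta_h - temperature * delta_s
    return eyring_rate(delta_g, temperature, constants)


def activation_parameters(
    fit: ArrheniusFit,
    t_ref: float | None = None,
    constants: PhysicalConstants = CONSTANTS,
) -> ActivationParameters:
    """Transition-state activation parameters from an Arrhenius fit.

    ``t_ref`` defaults to the mean of the binned temperatures entering the
    fit; for a fit constructed from a bare line it must be given explicitly.
    """
    if t_ref is None:
        if fit.points is None or fit.points.empty:
            raise ValidationError("t_ref must be given for a fit without stored points")
        t_ref = float(fit.points["temperature_K"].mean())
    if t_ref <= 0:
        raise ValidationError("t_ref must be positive (kelvin)")

    R = constants.R_kcal
    b, m = fit.intercept, fit.slope
    cov = np.asarray(fit.cov, dtype=float)
    if not np.all(np.isfinite(cov)):
        cov = np.zeros((2, 2))

    ea = -m * R
    ln_k = b + m / t_ref
    if ln_k > 700 or b > 700:
        raise FittingError("overflow evaluating exp() for kcat(T_ref) or the pre-exponential factor")
    kcat_ref = math.exp(ln_k)
    a = math.exp(b)
    ln_q = math.log(constants.kB * t_ref / constants.h)  # attempt frequency term
    delta_g = R * t_ref * (ln_q - ln_k)
    delta_h = ea - R * t_ref
    t_delta_s = delta_h - delta_g

    def se(grad_b: float, grad_m: float) -> float:
        g = np.array([grad_b, grad_m])
        return float(np.sqrt(g @ cov @ g))

    se_lnk = se(1.0, 1.0 / t_ref)
    return ActivationParameters(
        t_ref=t_ref,
        ea=ea,
        ea_se=se(0.0, -R),
        pre_exponential=a,
        pre_exponential_se=a * se(1.0, 0.0),
        kcat_ref=kcat_ref,
        kcat_ref_se=kcat_ref * se_lnk,
        delta_g=delta_g,
        delta_g_se=R * t_ref * se_lnk,
        delta_h=delta_h,
        delta_h_se=se(0.0, -R),
        t_delta_s=t_delta_s,
        t_delta_s_se=se(R * t_ref, 0.0),
        n_points=fit.n_points,
    )
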