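"""AICc model comparison for Arrhenius lines.

Used to ask whether two (or more) experiments — e.g. a temperature-gradient
run and a classical stepwise run on the same enzyme — are described by one
common Arrhenius line or need separate lines. Candidates are scored with the
small-sample corrected Akaike information criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1)

computed on the weighted ln(kcat)-scale residuals (same weights as the
Arrhenius fit), with the residual variance counted as a fitted parameter
(k = #coefficients + 1). Evidence is summarised by Akaike weights
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arrhenius import ArrheniusFit, weighted_line_fit
from .errors import InsufficientDataError, ModelSelectionError

__all__ = [
    "aicc",
    "akaike_weights",
    "CandidateModel",
    "ComparisonResult",
    "compare_global_vs_separate",
]


def aicc(n: int, k: int, rss: float) -> float:
    """Corrected Akaike information criterion for a least-squares model.

    ``n`` observations, ``k`` parameters (coefficients + 1 for the residual
    variance), ``rss`` the (weighted) residual sum of squares.
    """
    if n <= 0:
        raise ModelSelectionError(f"n must be positive, got {n}")
    if not math.isfinite(rss) or rss < 0:
        raise ModelSelectionError(f"rss must be finite and non-negative, got {rss}")
    if rss == 0:
        raise ModelSelectionError("degenerate fit: zero residual sum of squares (AICc undefined)")
    if n - k - 1 <= 0:
        raise ModelSelectionError(f"AICc undefined for n={n}, k={k} (need n - k - 1 > 0)")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Normalised evidence weights across candidate AICc values.

    Invariant under adding a constant to every value; sums to 1.
    """
    values = np.asarray(aicc_values, dtype=float)
    if values.size < 2:
        raise ModelSelectionError("need at least two candidate models to weight")
    if not np.all(np.isfinite(values)):
        raise ModelSelectionError("all AICc values must be finite")
    delta = values - values.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class CandidateModel:
    """One scored candidate: its AICc inputs and fitted line coefficients."""

    name: str
    n: int
    k: int
    rss: float
    aicc: float
    coefficients: dict[str, float]


@dataclass
class ComparisonResult:
    """Candidates ordered by AICc with evidence weights; best model first."""

    models: list[CandidateModel]
    delta_aicc: np.ndarray
    weights: np.ndarray

    @property
    def preferred(self) -> str:
        return self.models[0].name

    def to_dict(self) -> dict:
        return {
            "preferred": self.preferred,
            "models": [
                {
                    "name": m.name,
                    "n": m.n,
                    "k": m.k,
                    "weighted_rss": m.rss,
                    "AICc": m.aicc,
                    "delta_AICc": float(d),
                    "wAICc": float(w),
                    "coefficients": m.coefficients,
                }
                for m, d, w in zip(self.models, self.delta_aicc, self.weights)
            ],
        }


def _as_xyw(data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, ArrheniusFit):
        data = data.points
    if isinstance(data, pd.DataFrame):
        return (
            data["inv_temperature"].to_numpy(dtype=float),
            data["ln_kcat"].to_numpy(dtype=float),
            data["weight"].to_numpy(dtype=float),
        )
    x, y, w = data
    return np.asarray(x, float), np.asarray(y, float), np.asarray(w, float)


def compare_global_vs_separate(
    datasets: Mapping[str, object],
    mode: str = "nested",
) -> ComparisonResult:
    """Compare one shared Arrhenius line against dataset-specific lines.

    ``datasets`` maps a label to either an :class:`ArrheniusFit`, its
    ``points`` DataFrame (columns ``inv_temperature``, ``ln_kcat``,
    ``weight``) or an ``(x, y, w)`` triple. Each dataset needs >= 3 points.

    ``mode``:

    * ``"nested"`` (default): candidates are ``global`` (one line through
      the pooled points, k = 3) and ``separate`` (one line per dataset,
      k = 2d + 1), both scored on all n pooled observations — the standard
      nested comparison.
    * ``"three-way"``: candidates are ``global`` plus each dataset's own
      line scored on its own points only, mirroring the three-value
      comparison produced by common graphing software.

    Per-dataset line fits are computed in both modes and returned among the
    models for ``"three-way"``; the nested mode reports them via the
    ``separate`` candidate's coefficients.
    """
    if mode not in ("nested", "three-way"):
        raise ModelSelectionError(f"unknown comparison mode {mode!r}")
    if len(datasets) < 2:
        raise InsufficientDataError("need at least two datasets to compare")

    parsed = {name: _as_xyw(d) for name, d in datasets.items()}
    for name, (x, y, w) in parsed.items():
        if len(x) < 3:
            raise InsufficientDataError(f"dataset {name!r} has {len(x)} points; need >= 3")

    # pooled single line
    xs = np.concatenate([p[0] for p in parsed.values()])
    ys = np.concatenate([p[1] for p in parsed.values()])
    ws = np.concatenate([p[2] for p in parsed.values()])
    n_total = len(xs)
    b_g, m_g, _, wrss_g = weighted_line_fit(xs, ys, ws)
    global_model = CandidateModel(
        name="global",
        n=n_total,
        k=3,
        rss=wrss_g,
        aicc=aicc(n_total, 3, wrss_g),
        coefficients={"slope": m_g, "intercept": b_g},
    )

    # per-dataset lines
    sub = {}
    for name, (x, y, w) in parsed.items():
        b_i, m_i, _, wrss_i = weighted_line_fit(x, y, w)
        sub[name] = (b_i, m_i, wrss_i, len(x))

    if mode == "nested":
        d = len(parsed)
        rss_sep = sum(v[2] for v in sub.values())
        separate = CandidateModel(
            name="separate",
            n=n_total,
            k=2 * d + 1,
            rss=rss_sep,
            aicc=aicc(n_total, 2 * d + 1, rss_sep),
            coefficients={
                name: {"slope": v[1], "intercept": v[0]} for name, v in sub.items()
            },
        )
        candidates = [global_model, separate]
    else:
        candidates = [global_model]
        for name, (b_i, m_i, wrss_i, n_i) in sub.items():
            candidates.append(
                CandidateModel(
                    name=name,
                    n=n_i,
                    k=3,
                    rss=wrss_i,
                    aicc=aicc(n_i, 3, wrss_i),
                    coefficients={"slope": m_i, "intercept": b_i},
                )
            )

    order = np.argsort([c.aicc for c in candidates], kind="stable")
    ordered = [candidates[i] for i in order]
    values = np.array([c.aicc for c in ordered])
    return ComparisonResult(
        models=ordered, delta_aicc=values - values.min(), weights=akaike_weights(values)
    )
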