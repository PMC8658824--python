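"""End-to-end orchestration: readings -> velocities -> bins -> Arrhenius -> thermodynamics.

The stages run in the method's canonical order: parse the long-form CSV,
convert absorbances to concentrations, take rolling-OLS velocities per
cuvette, pool and bin them by temperature, fit Michaelis–Menten kinetics in
each bin, filter by the researcher's temperature cut-offs, fit the weighted
Arrhenius line and derive the activation parameters. Every exclusion (failed
fit, cut-off) is logged with its reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import arrhenius as arr
from . import kinetics as kin
from . import velocity as vel
from .assay_io import AssayDesign, CsvFormat, CuvetteTrace, parse_instrument_csv, traces_from_readings
from .constants import CONSTANTS, PhysicalConstants

logger = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Everything the pipeline produced, from raw velocities to thermodynamics."""

    velocities: pd.DataFrame
    bins: list[kin.TemperatureBin]
    bin_fits: list[kin.MichaelisMentenFit]
    used_fits: list[kin.MichaelisMentenFit]
    arrhenius_fit: arr.ArrheniusFit
    activation: arr.ActivationParameters

    def bin_table(self) -> pd.DataFrame:
        return kin.fits_table(self.bin_fits)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the result bundle (CSV + JSON) into ``outdir``; returns the paths.

        JSON files are serialised with sorted keys and default float
        formatting, so re-running on identical inputs yields byte-identical
        output.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "bins": outdir / "bin_fits.csv",
            "points": outdir / "arrhenius_points.csv",
            "arrhenius": outdir / "arrhenius.json",
            "thermodynamics": outdir / "thermodynamics.json",
        }
        self.bin_table().to_csv(paths["bins"], index=False)
        self.arrhenius_fit.points.to_csv(paths["points"], index=False)
        arr_payload = {
            "slope_K": self.arrhenius_fit.slope,
            "intercept": self.arrhenius_fit.intercept,
            "slope_se": self.arrhenius_fit.slope_se,
            "intercept_se": self.arrhenius_fit.intercept_se,
            "n_points": self.arrhenius_fit.n_points,
            "weighted_rss": self.arrhenius_fit.wrss,
        }
        paths["arrhenius"].write_text(json.dumps(arr_payload, indent=2, sort_keys=True) + "\n")
        paths["thermodynamics"].write_text(
            json.dumps(self.activation.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        return paths


def analyze_traces(
    traces: list[CuvetteTrace],
    e0: float,
    window: int = vel.DEFAULT_WINDOW,
    n_bins: int = 10,
    t_min: float | None = None,
    t_max: float | None = None,
    t_ref: float | None = None,
    weight_scheme: str = "paper",
    min_points_per_bin: int = kin.DEFAULT_MIN_POINTS,
    constants: PhysicalConstants = CONSTANTS,
) -> AnalysisResult:
    """Run the full analysis on concentration traces with known E0."""
    velocities = vel.rolling_velocities(traces, window=window)
    bins = kin.bin_by_temperature(velocities, n_bins=n_bins)
    bin_fits = kin.fit_bins(bins, e0=e0, min_points=min_points_per_bin)
    used = arr.apply_temperature_cutoffs(bin_fits, t_min=t_min, t_max=t_max)
    fit = arr.weighted_arrhenius_fit(used, weight_scheme=weight_scheme)
    activation = arr.activation_parameters(fit, t_ref=t_ref, constants=constants)
    return AnalysisResult(
        velocities=velocities,
        bins=bins,
        bin_fits=bin_fits,
        used_fits=used,
        arrhenius_fit=fit,
        activation=activation,
    )


def analyze_readings(
    groups: Mapping[str, pd.DataFrame], design: AssayDesign, **kwargs
) -> AnalysisResult:
    """Analysis from parsed per-cuvette reading tables."""
    traces = traces_from_readings(groups, design)
    return analyze_traces(traces, e0=design.enzyme_concentration, **kwargs)


def analyze_file(
    path: str | Path,
    design: AssayDesign,
    fmt: CsvFormat | None = None,
    **kwargs,
) -> AnalysisResult:
    """Analysis straight from an instrument CSV file."""
    groups = parse_instrument_csv(path, fmt)
    return analyze_readings(groups, design, **kwargs)
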