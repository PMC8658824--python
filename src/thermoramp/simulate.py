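"""Synthetic temperature-ramp (and stepwise) assay generator.

Emulates a multi-position temperature-controlled cuvette changer running a
steady-state chromogenic assay while the block temperature ramps linearly.
For each cuvette the substrate depletion ODE

    dS/dt = -kcat(T(t)) * E0 * S / (KM + S),    kcat(T) = A exp(-Ea/(R T))

is integrated with a fixed-step classical Runge–Kutta (RK4) scheme (step
<= 1 s by default; fixed step so that runs are bit-reproducible across
platforms). Readings are emitted per cuvette at a regular sampling interval,
converted to absorbance by Beer–Lambert, and optionally perturbed with
additive Gaussian instrument noise. The output uses the same long-form CSV
dialect that :mod:`thermoramp.assay_io` parses (time in minutes, temperature
in Celsius), and every run carries its ground truth (kcat at each emitted
temperature) so that the full analysis pipeline can be validated against
known parameters.

Defaults correspond to a cold-active lipase assayed with a chromogenic
ester substrate: Ea = 15.325 kcal/mol, ln A = 32.06, KM = 200 uM, E0 = 1 nM,
a six-step 1:1 dilution series from 1 mM measured in duplicate (12 traces),
a 277.15 -> 298.15 K ramp at 2 K/min sampled once per cuvette per 1 K,
extinction coefficient 17,800 M^-1 cm^-1 in a 1 cm cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_io import AssayDesign
from .constants import CONSTANTS
from .errors import StabilityError, ValidationError

#: ln A of the default Arrhenius law (A in s^-1).
_DEFAULT_LN_A = 32.06
#: Instrument ramp-rate envelope, K/min; outside it we warn but proceed.
RAMP_RATE_ENVELOPE = (0.1, 10.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth parameters and instrument settings for one simulated run.

    ``sampling_interval`` (seconds between readings of the same cuvette)
    defaults to one reading per 1 K of ramp, i.e. ``60/ramp_rate``.
    ``dead_time`` staggers the cuvette read times round-robin, emulating the
    changer cycling through positions; it defaults to
    ``sampling_interval / n_cuvettes``.
    """

    ea: float = 15.325                       # kcal/mol
    ln_a: float = _DEFAULT_LN_A              # ln(A / s^-1)
    km: float = 2.0e-4                       # M
    e0: float = 1.0e-9                       # M
    s0: tuple[float, ...] = 2 * (1.0e-3, 5.0e-4, 2.5e-4, 1.25e-4, 6.25e-5, 3.125e-5)
    t_start: float = 277.15                  # K
    t_end: float = 298.15                    # K
    ramp_rate: float = 2.0                   # K/min
    sampling_interval: float | None = None   # s per cuvette
    noise_sd: float = 0.0                    # AU
    extinction_coefficient: float = 17800.0  # M^-1 cm^-1
    path_length: float = 1.0                 # cm
    seed: int | None = None
    dead_time: float | None = None           # s between successive cuvette reads
    max_step: float = 1.0                    # s, RK4 step cap
    km_van_t_hoff: float | None = None       # optional dH_vH (kcal/mol) for KM(T)

    def __post_init__(self) -> None:
        if self.e0 < 0:
            raise ValidationError("E0 must be non-negative")
        if self.km <= 0 or any(s <= 0 for s in self.s0):
            raise ValidationError("KM and all S0 values must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.max_step <= 0:
            raise ValidationError("max_step must be positive")
        if self.ramp_rate != 0 and not (
            RAMP_RATE_ENVELOPE[0] <= abs(self.ramp_rate) <= RAMP_RATE_ENVELOPE[1]
        ):
            warnings.warn(
                f"ramp rate {self.ramp_rate} K/min is outside the typical instrument "
                f"envelope {RAMP_RATE_ENVELOPE}; proceeding (no assumption on the rate is made)",
                stacklevel=2,
            )

    @property
    def pre_exponential(self) -> float:
        return math.exp(self.ln_a)

    def arrhenius_line(self) -> tuple[float, float]:
        """(slope, intercept) of the true ln kcat vs 1/T line: (-Ea/R, ln A)."""
        return (-self.ea / CONSTANTS.R_kcal, self.ln_a)

    def kcat(self, temperature):
        """True turnover number at a temperature (Arrhenius law)."""
        temperature = np.asarray(temperature, dtype=float)
        return self.pre_exponential * np.exp(-self.ea / (CONSTANTS.R_kcal * temperature))

    def km_at(self, temperature):
        """KM at a temperature; constant unless a van 't Hoff enthalpy is set."""
        if self.km_van_t_hoff is None:
            return np.full_like(np.asarray(temperature, dtype=float), self.km)
        t_mid = 0.5 * (self.t_start + self.t_end)
        temperature = np.asarray(temperature, dtype=float)
        return self.km * np.exp(
            -self.km_van_t_hoff / CONSTANTS.R_kcal * (1.0 / temperature - 1.0 / t_mid)
        )


@dataclass
class SimulatedAssay:
    """One simulated run: instrument-format readings plus ground truth.

    ``readings`` is in instrument units (sample, time [min], temperature
    [Celsius], absorbance); ``readings_si`` carries the same rows in
    seconds/kelvin together with the noise-free product concentration.
    """

    spec: SimulationSpec
    readings: pd.DataFrame
    readings_si: pd.DataFrame
    ground_truth: pd.DataFrame
    design: AssayDesign = field(repr=False, default=None)

    def write_csv(self, path: str | Path) -> Path:
        """Write the instrument-dialect long-form CSV that assay_io parses."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.readings.to_csv(path, index=False)
        return path

    def write_ground_truth(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.ground_truth.to_csv(path, index=False)
        return path


def _temperature_program(spec: SimulationSpec, duration: float):
    rate_per_s = spec.ramp_rate / 60.0

    def temp_at(t: float) -> float:
        return spec.t_start + rate_per_s * min(t, duration)

    return temp_at


def _integrate_substrate(
    spec: SimulationSpec, s0: float, sample_times: np.ndarray, duration: float
) -> np.ndarray:
    """Substrate concentration at each sample time via fixed-step RK4."""
    temp_at = _temperature_program(spec, duration)

    def dsdt(t: float, s: float) -> float:
        if s <= 0.0:
            return 0.0
        temperature = temp_at(t)
        kcat = spec.kcat(temperature)
        km = float(spec.km_at(temperature))
        return -float(kcat) * spec.e0 * s / (km + s)

    out = np.empty_like(sample_times)
    t, s = 0.0, float(s0)
    for i, t_target in enumerate(sample_times):
        span = t_target - t
        if span > 0:
            n_sub = max(1, int(math.ceil(span / spec.max_step)))
            dt = span / n_sub
            for _ in range(n_sub):
                k1 = dsdt(t, s)
                k2 = dsdt(t + dt / 2.0, s + dt / 2.0 * k1)
                k3 = dsdt(t + dt / 2.0, s + dt / 2.0 * k2)
                k4 = dsdt(t + dt, s + dt * k3)
                step = dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
                if s > 0 and -step > 0.2 * s:
                    raise StabilityError(
                        f"RK4 step consumes {-step / s:.0%} of the substrate in {dt:.3g} s; "
                        "reduce max_step"
                    )
                s = max(s + step, 0.0)
                t += dt
        out[i] = s
    return out


def _simulate(spec: SimulationSpec, duration: float, rng: np.random.Generator) -> SimulatedAssay:
    n_cuv = len(spec.s0)
    interval = spec.sampling_interval
    if interval is None:
        # one reading per cuvette per 1 K of ramp; 30 s if the ramp is flat
        interval = 60.0 / abs(spec.ramp_rate) if spec.ramp_rate else 30.0
    dead = spec.dead_time if spec.dead_time is not None else interval / n_cuv
    temp_at = _temperature_program(spec, duration)

    rows = []
    for i, s0 in enumerate(spec.s0):
        cid = f"c{i + 1}"
        times = np.arange(i * dead, duration + 1e-9, interval)
        substrate = _integrate_substrate(spec, s0, times, duration)
        product = s0 - substrate
        clean_abs = product * spec.extinction_coefficient * spec.path_length
        noise = rng.normal(0.0, spec.noise_sd, size=len(times)) if spec.noise_sd > 0 else 0.0
        temps = np.array([temp_at(t) for t in times])
        rows.append(
            pd.DataFrame(
                {
                    "cuvette_id": cid,
                    "time_s": times,
                    "temperature_K": temps,
                    "product_M": product,
                    "substrate_M": substrate,
                    "absorbance": clean_abs + noise,
                }
            )
        )
    si = pd.concat(rows, ignore_index=True).sort_values(
        ["time_s", "cuvette_id"], kind="stable"
    ).reset_index(drop=True)

    readings = pd.DataFrame(
        {
            "sample": si["cuvette_id"],
            "time": si["time_s"] / 60.0,
            "temperature": si["temperature_K"] - 273.15,
            "absorbance": si["absorbance"],
        }
    )
    temps_unique = np.unique(si["temperature_K"].to_numpy())
    ground_truth = pd.DataFrame(
        {
            "temperature_K": temps_unique,
            "kcat_true": spec.kcat(temps_unique),
            "KM_true": spec.km_at(temps_unique),
        }
    )
    design = AssayDesign(
        extinction_coefficient=spec.extinction_coefficient,
        path_length=spec.path_length,
        enzyme_concentration=spec.e0 if spec.e0 > 0 else 1e-12,
        s0={f"c{i + 1}": s for i, s in enumerate(spec.s0)},
        ramp_rate=spec.ramp_rate,
        temperature_range=(spec.t_start, spec.t_end),
    )
    return SimulatedAssay(
        spec=spec, readings=readings, readings_si=si, ground_truth=ground_truth, design=design
    )


def simulate_ramp(spec: SimulationSpec | None = None) -> SimulatedAssay:
    """Simulate one temperature-gradient run over [t_start, t_end]."""
    spec = spec or SimulationSpec()
    if spec.ramp_rate == 0:
        raise ValidationError("ramp_rate must be non-zero for a gradient run; use simulate_stepwise")
    duration = (spec.t_end - spec.t_start) / (spec.ramp_rate / 60.0)
    if duration <= 0:
        raise ValidationError("temperature program has non-positive duration")
    rng = np.random.default_rng(spec.seed)
    return _simulate(spec, duration, rng)


def simulate_stepwise(
    spec: SimulationSpec | None = None,
    temperatures: tuple[float, ...] = (277.15, 283.15, 288.15, 293.15),
    duration: float = 600.0,
) -> dict[float, SimulatedAssay]:
    """Simulate the classical design: one constant-temperature run per temperature.

    Each run reuses the spec's kinetics and noise model; per-run random
    streams are spawned deterministically from ``spec.seed``, so the ground
    truth is identical across seeds and only the noise differs.
    """
    spec = spec or SimulationSpec()
    seeds = np.random.SeedSequence(spec.seed).spawn(len(temperatures))
    out: dict[float, SimulatedAssay] = {}
    for temperature, seq in zip(temperatures, seeds):
        const = SimulationSpec(
            ea=spec.ea,
            ln_a=spec.ln_a,
            km=spec.km,
            e0=spec.e0,
            s0=spec.s0,
            t_start=temperature,
            t_end=temperature,
            ramp_rate=0.0,
            sampling_interval=spec.sampling_interval or 30.0,
            noise_sd=spec.noise_sd,
            extinction_coefficient=spec.extinction_coefficient,
            path_length=spec.path_length,
            seed=spec.seed,
            dead_time=spec.dead_time,
            max_step=spec.max_step,
            km_van_t_hoff=spec.km_van_t_hoff,
        )
        out[temperature] = _simulate(const, duration, np.random.default_rng(seq))
    return out
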