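"""Fermentation kinetics: specific growth and production rates for phenazines.

Over a fermentation window [t1, t2] (the exponential production stage,
typically 14-24 h):

* specific growth rate  mu = ln(X(t2)/X(t1)) / (t2 - t1)          [1/h]
* specific production   q  = dC / M / (Xbar * dt)                 [mmol/g/h]
  with dC in mg/L (so dC/M is mmol/L), M the molar mass in g/mol, and
  Xbar the window-average biomass (g/L dry weight) -- the logarithmic
  mean of the endpoint values by default, which equals the true time
  average for exponential growth;
* total phenazine mass rate = sum_i q_i * M_i / 1000              [g/g/h],
  needed because the three phenazines (PCA, 2-OH-PCA, 2-OH-PHZ) have
  different molecular weights.

Reported values follow the conventional precision: rates to 4 decimals,
mass rates to 2 significant figures, fold changes to 1 decimal (half-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "MolarMasses",
    "MOLAR_MASSES",
    "ANALYTES",
    "specific_growth_rate",
    "specific_production_rate",
    "total_phenazine_mass_rate",
    "fold_change",
    "rate_table",
    "read_tidy_csv",
]

ANALYTES = ("PCA", "2OHPCA", "2OHPHZ")


@dataclass(frozen=True)
class MolarMasses:
    """Molar masses in g/mol (C13H8N2O2, C13H8N2O3, C12H8N2O)."""

    PCA: float = 224.22
    OHPCA: float = 240.21
    OHPHZ: float = 196.20

    def of(self, analyte: str) -> float:
        return {"PCA": self.PCA, "2OHPCA": self.OHPCA, "2OHPHZ": self.OHPHZ}[analyte]


MOLAR_MASSES = MolarMasses()


@dataclass
class TimeSeries:
    """One strain's fermentation course.

    ``times`` in h (strictly increasing), ``biomass`` in g/L dry weight,
    ``concentrations`` per analyte in mg/L.
    """

    strain: str
    times: np.ndarray
    biomass: np.ndarray
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.biomass) != len(self.times):
            raise ValueError("biomass and times differ in length")
        if np.any(self.biomass < 0):
            raise ValueError("negative biomass")
        self.concentrations = {
            k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()
        }
        for k, v in self.concentrations.items():
            if len(v) != len(self.times):
                raise ValueError(f"{k}: concentration series length mismatch")
            if np.any(v < 0):
                raise ValueError(f"{k}: negative concentration")

    def _index(self, t: float) -> int:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise ValueError(f"time {t} h not sampled")
        return int(idx[0])


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 2) -> float:
    """Round half-up to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return _round_half_up(x, sig - 1 - exp)


def specific_growth_rate(series: TimeSeries, window: tuple[float, float]) -> float:
    """mu = ln(X(t2)/X(t1)) / (t2 - t1), in 1/h."""
    t1, t2 = window
    i1, i2 = series._index(t1), series._index(t2)
    x1, x2 = series.biomass[i1], series.biomass[i2]
    if x1 <= 0 or x2 <= 0:
        raise ValueError("biomass must be positive at both window endpoints")
    return math.log(x2 / x1) / (t2 - t1)


def specific_production_rate(
    series: TimeSeries,
    analyte: str,
    window: tuple[float, float],
    masses: MolarMasses = MOLAR_MASSES,
    biomass_mean: str = "logarithmic",
) -> float:
    """q = dC / M / (Xbar * dt), in mmol per g biomass per h.

    ``biomass_mean`` selects the window-average biomass: "logarithmic"
    (default; the log-mean of the endpoint values, which is the exact
    time average under exponential growth and makes the estimator
    unbiased for growth-associated production) or "arithmetic" (the
    plain endpoint mean).
    """
    if analyte not in series.concentrations:
        raise ValueError(f"analyte {analyte} missing from series {series.strain}")
    t1, t2 = window
    i1, i2 = series._index(t1), series._index(t2)
    dc = series.concentrations[analyte][i2] - series.concentrations[analyte][i1]
    x1, x2 = series.biomass[i1], series.biomass[i2]
    if biomass_mean == "arithmetic":
        xbar = (x1 + x2) / 2.0
    elif biomass_mean == "logarithmic":
        xbar = (x2 - x1) / math.log(x2 / x1) if not math.isclose(x1, x2) else x1
    else:
        raise ValueError(f"unknown biomass_mean {biomass_mean!r}")
    if xbar <= 0:
        raise ValueError("window-mean biomass must be positive")
    return dc / masses.of(analyte) / (xbar * (t2 - t1))


def total_phenazine_mass_rate(
    q_molar: dict[str, float], masses: MolarMasses = MOLAR_MASSES
) -> float:
    """Mass-basis total rate: sum_i q_i * M_i / 1000, in g/g/h.

    All three phenazine analytes must be present.
    """
    missing = [a for a in ANALYTES if a not in q_molar]
    if missing:
        raise ValueError(f"missing analytes: {missing}")
    return sum(q_molar[a] * masses.of(a) / 1000.0 for a in ANALYTES)


def fold_change(q_mutant: float, q_parent: float) -> float:
    if q_parent <= 0:
        raise ValueError("parent rate must be positive")
    return q_mutant / q_parent


def rate_table(
    series_by_strain: dict[str, TimeSeries],
    window: tuple[float, float],
    masses: MolarMasses = MOLAR_MASSES,
    biomass_mean: str = "logarithmic",
) -> pd.DataFrame:
    """Per-strain mu, per-analyte molar q, and total mass rate.

    Rates are reported at 4 decimals and the mass rate at 2 significant
    figures (half-up), matching the conventional report precision.
    """
    rows = []
    for strain, series in series_by_strain.items():
        q = {
            a: specific_production_rate(series, a, window, masses, biomass_mean)
            for a in ANALYTES
        }
        rows.append(
            dict(
                strain=strain,
                mu_per_h=_round_half_up(specific_growth_rate(series, window), 4),
                q_PCA_mmol_g_h=_round_half_up(q["PCA"], 4),
                q_2OHPCA_mmol_g_h=_round_half_up(q["2OHPCA"], 4),
                q_2OHPHZ_mmol_g_h=_round_half_up(q["2OHPHZ"], 4),
                q_total_g_g_h=round_sig(total_phenazine_mass_rate(q, masses), 2),
            )
        )
    return pd.DataFrame(rows)


def read_tidy_csv(path) -> dict[str, TimeSeries]:
    """Tidy CSV (strain, time_h, biomass_g_per_L, analyte, conc_mg_per_L) -> series."""
    df = pd.read_csv(path)
    required = {"strain", "time_h", "biomass_g_per_L", "analyte", "conc_mg_per_L"}
    if not required.issubset(df.columns):
        raise ValueError(f"tidy table needs columns {sorted(required)}")
    out: dict[str, TimeSeries] = {}
    for strain, grp in df.groupby("strain"):
        times = np.sort(grp["time_h"].unique())
        biomass = (
            grp.drop_duplicates("time_h").set_index("time_h")["biomass_g_per_L"].loc[times]
        )
        conc = {}
        for analyte, sub in grp.groupby("analyte"):
            conc[analyte] = sub.set_index("time_h")["conc_mg_per_L"].loc[times].to_numpy()
        out[str(strain)] = TimeSeries(
            strain=str(strain),
            times=times,
            biomass=biomass.to_numpy(),
            concentrations=conc,
        )
    return out
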