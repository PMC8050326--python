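"""Derived soil-carbon and pore-space quantities, plus descriptive
statistics with coefficient-of-variation classification.

Derivations (0-20 cm layer unless stated otherwise):

* total organic carbon          TOC = SOM / 1.724            (g kg-1)
* carbon stock                  Cstock = OC * Ds * E / 10    (Mg ha-1)
* daily emitted carbon          C-CO2 from FCO2 by unit conversion
  (umol CO2 m-2 s-1 -> g C m-2 d-1 -> Mg C ha-1 d-1, carbon basis, 12 g/mol)
* carbon decay constant         k = C-CO2 / Cstock           (d-1)
* macroporosity                 Macro = TPV - Micro          (%)
* air-filled pore space         AFPS = TPV - Ms              (%)

The coefficient of variation is classified by the Warrick-Nielsen
convention: low (< 12%), moderate (12-24%, boundaries inclusive),
high (> 24%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import PointDataset

#: SOM (organic matter) to organic carbon divisor (van Bemmelen factor).
SOM_TO_OC = 1.724

#: umol CO2 m-2 s-1 -> g C m-2 d-1: 1e-6 mol * 12 g C/mol * 86400 s.
UMOL_CO2_TO_G_C_PER_DAY = 1e-6 * 12.0 * 86400.0

#: g m-2 -> Mg ha-1.
G_M2_TO_MG_HA = 0.01

CV_THRESHOLDS = (12.0, 24.0)


@dataclass
class DerivedAttributes:
    """Per-sample derived quantities (scalar or array-valued)."""

    toc: float | np.ndarray          # g kg-1
    cstock: float | np.ndarray       # Mg ha-1
    daily_c_co2: float | np.ndarray  # Mg C ha-1 d-1
    k: float | np.ndarray            # d-1
    macroporosity: float | np.ndarray  # %
    afps: float | np.ndarray           # %


def toc_from_som(som) -> float | np.ndarray:
    """Total organic carbon (g kg-1) from organic matter content."""
    return np.asarray(som, dtype=float) / SOM_TO_OC if np.ndim(som) else float(som) / SOM_TO_OC


def carbon_stock(oc, bulk_density, depth_cm: float = 20.0):
    """Cstock (Mg ha-1) = OC (g kg-1) * Ds (g cm-3 = Mg m-3) * E (cm) / 10."""
    oc = np.asarray(oc, dtype=float)
    ds = np.asarray(bulk_density, dtype=float)
    if np.any(ds <= 0):
        raise ValueError("bulk density must be positive")
    if depth_cm <= 0:
        raise ValueError("layer depth must be positive")
    out = oc * ds * depth_cm / 10.0
    return out if out.ndim else float(out)


def daily_carbon_emission(fco2):
    """C-CO2 (Mg C ha-1 d-1) emitted per day from FCO2 (umol m-2 s-1)."""
    out = np.asarray(fco2, dtype=float) * UMOL_CO2_TO_G_C_PER_DAY * G_M2_TO_MG_HA
    return out if out.ndim else float(out)


def decay_constant(daily_c_co2, cstock):
    """k (d-1) = daily emitted carbon / carbon stock, per sample."""
    c = np.asarray(daily_c_co2, dtype=float)
    s = np.asarray(cstock, dtype=float)
    if np.any((s == 0) & (c != 0)):
        raise ValueError("decay constant undefined: zero carbon stock with nonzero flux")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(c == 0, 0.0, c / np.where(s == 0, 1.0, s))
    return out if out.ndim else float(out)


def derive_attributes(
    som,
    bulk_density,
    fco2,
    tpv,
    microporosity,
    soil_moisture,
    depth_cm: float = 20.0,
) -> DerivedAttributes:
    """All derived quantities from the measured physical/chemical columns.

    Parameters are in survey units: SOM g dm-3 (treated as g kg-1
    equivalent for the stock computation), Ds g cm-3, FCO2 umol m-2 s-1,
    TPV / microporosity / soil moisture in %.
    """
    tpv_a = np.asarray(tpv, dtype=float)
    micro_a = np.asarray(microporosity, dtype=float)
    ms_a = np.asarray(soil_moisture, dtype=float)
    if np.any(tpv_a < micro_a):
        raise ValueError("total pore volume below microporosity: negative macroporosity")
    if np.any(tpv_a < ms_a):
        raise ValueError("total pore volume below water-filled fraction: negative AFPS")
    toc = toc_from_som(som)
    cstock = carbon_stock(toc, bulk_density, depth_cm)
    c_co2 = daily_carbon_emission(fco2)
    k = decay_constant(c_co2, cstock)
    macro = tpv_a - micro_a
    afps = tpv_a - ms_a
    if np.ndim(som) == 0:
        macro, afps = float(macro), float(afps)
    return DerivedAttributes(toc, cstock, c_co2, k, macro, afps)


def append_derived(dataset: PointDataset, depth_cm: float = 20.0) -> PointDataset:
    """Append derived columns (TOC, Cstock, C_CO2, k, Macro, AFPS) to a
    survey table carrying SOM, Ds, FCO2, TPV, Micro and Ms columns."""
    d = derive_attributes(
        dataset.values("SOM"),
        dataset.values("Ds"),
        dataset.values("FCO2"),
        dataset.values("TPV"),
        dataset.values("Micro"),
        dataset.values("Ms"),
        depth_cm=depth_cm,
    )
    out = dataset
    for name, vals in [
        ("TOC", d.toc), ("Cstock", d.cstock), ("C_CO2", d.daily_c_co2),
        ("k", d.k), ("Macro", d.macroporosity), ("AFPS", d.afps),
    ]:
        if name not in out.frame.columns:
            out = out.with_column(name, vals)
    return out


@dataclass
class DescriptiveSummary:
    n: int
    mean: float
    se: float
    sd: float
    minimum: float
    maximum: float
    cv_percent: float
    skewness: float
    kurtosis: float
    cv_class: str


def classify_cv(cv_percent: float, thresholds: tuple[float, float] = CV_THRESHOLDS) -> str:
    low, high = thresholds
    if cv_percent < low:
        return "low"
    if cv_percent <= high:  # boundary values fall in the moderate class
        return "moderate"
    return "high"


def describe(values, thresholds: tuple[float, float] = CV_THRESHOLDS) -> DescriptiveSummary:
    """Descriptive summary: mean, SE, SD, min, max, CV%, bias-corrected
    skewness and excess kurtosis, and the CV variability class."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D sample of n >= 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    n = len(x)
    mean = float(x.mean())
    sd = 0.0 if x.max() == x.min() else float(x.std(ddof=1))
    if mean == 0.0:
        if sd == 0.0:
            cv = 0.0
        else:
            raise ValueError("CV undefined for zero-mean sample with nonzero spread")
    else:
        cv = 100.0 * sd / abs(mean)
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, bias=False, fisher=True))
    return DescriptiveSummary(
        n=n,
        mean=mean,
        se=sd / np.sqrt(n),
        sd=sd,
        minimum=float(x.min()),
        maximum=float(x.max()),
        cv_percent=cv,
        skewness=skew,
        kurtosis=kurt,
        cv_class=classify_cv(cv, thresholds),
    )
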