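"""Built-in reference parameter sets for a surveyed sugarcane field.

These tables describe an Oxisol sugarcane area after field reform in
Sao Paulo State (Brazil): a 90 m x 90 m regular grid of 100 points at
10 m spacing, surveyed for CO2 efflux (FCO2), soil temperature and
moisture, physical and chemical attributes; plus a two-region (R1 high
emission / R2 low emission) microbiological characterisation with nine
composite samples per region. They serve as the default targets of the
synthetic generators and as worked inputs for the spatial-dependence
classifier.

``variogram_table`` carries the fitted variogram parameters per
attribute (nugget C0, sill C0+C1, range a in metres, attribute units
squared; log-flagged attributes were natural-log transformed first) with
the published weak/moderate/strong spatial-dependence classes.
``descriptive_table`` carries per-attribute summary statistics.
``microbiology_table`` carries the per-region assay means and standard
errors. Cellulase means were not printed for this survey; the values
here are synthetic stand-ins consistent with the no-difference outcome,
and the standard errors throughout are calibrated to the assays' typical
dispersion and the reported contrast pattern rather than transcribed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import AttributeSpec, GroupVariableSpec, MicrobiologyConfig, SurveyConfig
from .variography import VariogramModel

GRID_EXTENT = 90.0
GRID_SPACING = 10.0
#: Maximum distance between sampling points (grid diagonal, metres).
MAX_DISTANCE = 127.28

# attribute, kind, C0, sill (C0+C1), class, range a, SSR, R2, RMSE, log?
_VARIOGRAM_ROWS = [
    ("FCO2", "spherical", 1.56e-1, 2.57e-1, "weak", 26.74, 6.33e-5, 0.97, 0.49, False),
    ("Ts", "spherical", 1.51e-1, 2.30e-1, "weak", 25.27, 9.44e-5, 0.89, 0.46, False),
    ("Ms", "spherical", 5.45e-3, 8.34e-3, "moderate", 53.74, 8.86e-7, 0.80, 1.52, True),
    ("Ds", "spherical", 4.84e-3, 7.52e-3, "weak", 32.35, 4.25e-7, 0.79, 0.08, False),
    ("Macro", "spherical", 7.28e0, 1.61e1, "moderate", 24.31, 2.42e0, 0.74, 3.92, False),
    ("Micro", "spherical", 1.36e1, 2.13e1, "moderate", 38.02, 5.50e-1, 0.98, 4.40, False),
    ("TPV", "spherical", 3.01e0, 7.00e0, "moderate", 36.97, 2.27e-1, 0.97, 2.34, False),
    ("AFPS", "spherical", 7.42e0, 1.67e1, "moderate", 45.00, 8.80e-1, 0.98, 4.08, False),
    ("Clay", "exponential", 5.02e0, 2.43e1, "moderate", 24.60, 5.03e0, 0.87, 4.78, False),
    ("Silt", "exponential", 1.94e0, 7.55e0, "moderate", 22.32, 5.56e-2, 0.99, 2.70, False),
    ("Sand", "spherical", 3.78e-1, 2.46e0, "strong", 53.98, 9.79e-2, 0.95, 1.22, False),
    ("SOM", "spherical", 6.89e0, 1.05e1, "weak", 30.87, 5.47e-1, 0.89, 3.18, False),
    ("Cstock", "spherical", 1.38e1, 2.87e1, "moderate", 26.06, 1.75e0, 0.96, 5.07, False),
    ("k", "spherical", 8.50e-9, 1.64e-8, "weak", 21.19, 1.67e-18, 0.84, 0.00, False),
    ("pH", "spherical", 3.11e-2, 5.71e-2, "weak", 23.20, 8.39e-6, 0.95, 0.23, False),
    ("P", "spherical", 2.16e-2, 2.49e-1, "strong", 28.20, 4.81e-3, 0.69, 12.86, True),
    ("K", "spherical", 8.67e-4, 2.02e-3, "moderate", 22.32, 8.37e-8, 0.67, 0.05, False),
    ("Ca", "spherical", 8.44e-2, 1.44e-1, "moderate", 29.77, 6.98e-5, 0.92, 1.36, True),
    ("Mg", "spherical", 8.10e-2, 1.61e-1, "moderate", 25.51, 1.57e-5, 0.99, 0.48, True),
    ("Al", "spherical", 2.00e-2, 5.57e-2, "moderate", 24.06, 3.39e-5, 0.85, 0.30, True),
    ("H_Al", "spherical", 6.90e1, 1.15e2, "weak", 25.37, 2.64e1, 0.90, 10.58, False),
    ("SB", "spherical", 7.01e-2, 1.37e-1, "weak", 23.19, 1.29e-4, 0.85, 1.86, True),
    ("CEC", "spherical", 3.86e-3, 2.85e-2, "moderate", 23.74, 1.21e-6, 0.99, 1.56, True),
    ("V", "spherical", 7.95e1, 1.39e2, "weak", 27.55, 1.11e2, 0.83, 11.22, False),
]

# attribute, mean, SE, SD, min, max, CV%, skewness, kurtosis
_DESCRIPTIVE_ROWS = [
    ("FCO2", 2.91, 0.06, 0.56, 1.83, 5.28, 19.33, 0.87, 2.17),
    ("Ts", 22.58, 0.06, 0.59, 20.01, 23.34, 2.62, -1.81, 4.40),
    ("Ms", 16.94, 0.17, 1.74, 13.90, 21.10, 10.29, 0.49, -0.52),
    ("Ds", 1.33, 0.01, 0.09, 1.08, 1.57, 6.91, -0.25, 0.55),
    ("Macro", 11.08, 0.48, 4.80, 1.95, 24.62, 43.35, 0.75, 0.17),
    ("Micro", 39.55, 0.48, 4.82, 26.37, 45.82, 12.18, -1.21, 0.78),
    ("TPV", 50.63, 0.45, 4.53, 31.14, 68.56, 8.94, 0.40, 8.10),
    ("AFPS", 33.68, 0.51, 5.09, 12.34, 54.46, 15.10, 0.00, 6.38),
    ("Clay", 61.58, 0.48, 4.83, 50.80, 68.80, 7.85, -0.58, -0.78),
    ("Silt", 20.23, 0.34, 3.36, 14.96, 34.23, 16.62, 1.29, 2.36),
    ("Sand", 17.20, 0.16, 1.57, 13.40, 20.36, 9.11, -0.23, -0.04),
    ("SOM", 32.17, 0.34, 3.40, 24.00, 43.00, 10.56, 0.32, 0.27),
    ("Cstock", 48.08, 0.59, 5.85, 32.40, 63.49, 12.99, 0.10, -0.10),
    ("k", 0.0007, 0.00, 0.0002, 0.0003, 0.0012, 23.03, 0.70, 0.82),
    ("pH", 5.01, 0.03, 0.26, 4.40, 5.50, 5.23, -0.24, -0.37),
    ("P", 28.13, 3.21, 32.08, 9.00, 188.00, 114.05, 3.06, 9.39),
    ("K", 0.15, 0.00, 0.05, 0.05, 0.30, 31.18, 0.88, 0.91),
    ("Ca", 3.36, 0.26, 2.64, 1.01, 25.15, 78.54, 6.19, 48.07),
    ("Mg", 1.21, 0.06, 0.57, 0.40, 3.72, 47.07, 1.93, 5.07),
    ("Al", 0.19, 0.03, 0.31, 0.00, 1.27, 162.16, 1.93, 3.47),
    ("H_Al", 49.33, 1.22, 12.23, 8.74, 78.98, 24.78, -0.36, 0.74),
    ("SB", 4.72, 0.31, 3.13, 1.54, 29.00, 66.26, 5.30, 37.40),
    ("CEC", 8.88, 0.29, 2.88, 6.48, 31.77, 32.46, 5.62, 40.84),
    ("V", 50.67, 1.22, 12.23, 21.02, 91.26, 24.13, 0.36, 0.74),
]

ATTRIBUTE_UNITS = {
    "FCO2": "umol m-2 s-1", "Ts": "degC", "Ms": "%", "Ds": "g cm-3",
    "Macro": "%", "Micro": "%", "TPV": "%", "AFPS": "%",
    "Clay": "%", "Silt": "%", "Sand": "%", "SOM": "g dm-3",
    "Cstock": "Mg ha-1", "k": "d-1", "pH": "-", "P": "mg dm-3",
    "K": "cmolc dm-3", "Ca": "cmolc dm-3", "Mg": "cmolc dm-3",
    "Al": "cmolc dm-3", "H_Al": "cmolc dm-3", "SB": "cmolc dm-3",
    "CEC": "cmolc dm-3", "V": "%",
}

#: FCO2 value bands (umol m-2 s-1) delineating the two emission regions.
REGION_BANDS = {"R1": (2.9, 4.2), "R2": (1.9, 2.7)}

# name, units, R1 mean, R2 mean, R1 SE, R2 SE, family, differs at p<0.01
_MICROBIOLOGY_ROWS = [
    ("16S", "copies g-1 soil", 4.3e9, 3.1e9, 0.9e9, 0.9e9, "log_normal", False),
    ("pmoA", "copies g-1 soil", 9.5e4, 2.9e4, 1.1e4, 0.5e4, "log_normal", True),
    ("nifH", "copies g-1 soil", 823.33, 3541.67, 400.0, 1800.0, "log_normal", False),
    ("dehydrogenase", "ug TPF g-1 24h-1", 33.02, 22.90, 1.4, 1.4, "normal", True),
    ("urease", "ug NH4-N g-1 3h-1", 41.15, 31.07, 1.4, 1.4, "normal", True),
    ("amylase", "ug glucose g-1 24h-1", 73.84, 64.81, 1.25, 1.25, "normal", True),
    ("cellulase", "ug glucose g-1 24h-1", 24.5, 23.0, 2.0, 2.0, "normal", False),
    ("MBC", "ug C g-1 soil", 41.35, 17.87, 3.2, 3.2, "normal", True),
    ("CN_ratio", "-", 12.18, 15.43, 0.45, 0.45, "normal", True),
]


def variogram_table() -> pd.DataFrame:
    """Fitted variogram parameters and dependence classes, one attribute per row."""
    df = pd.DataFrame(
        _VARIOGRAM_ROWS,
        columns=["attribute", "kind", "nugget", "sill", "sdi_class",
                 "range", "ssr", "r2", "rmse", "log_transformed"],
    )
    df["partial_sill"] = df["sill"] - df["nugget"]
    return df


def descriptive_table() -> pd.DataFrame:
    """Per-attribute summary statistics of the reference survey."""
    return pd.DataFrame(
        _DESCRIPTIVE_ROWS,
        columns=["attribute", "mean", "se", "sd", "minimum", "maximum",
                 "cv_percent", "skewness", "kurtosis"],
    )


def microbiology_table() -> pd.DataFrame:
    """Two-region assay means/SEs and whether the regions differ (p < 0.01)."""
    return pd.DataFrame(
        _MICROBIOLOGY_ROWS,
        columns=["variable", "units", "mean_r1", "mean_r2", "se_r1", "se_r2",
                 "family", "differs"],
    )


def reference_model(attribute: str) -> VariogramModel:
    """The fitted variogram model of one reference attribute."""
    tab = variogram_table().set_index("attribute")
    if attribute not in tab.index:
        raise KeyError(f"no reference variogram for {attribute!r}")
    row = tab.loc[attribute]
    return VariogramModel(
        kind=row["kind"],
        nugget=float(row["nugget"]),
        partial_sill=float(row["partial_sill"]),
        range_=float(row["range"]),
        attribute=attribute,
        log_transformed=bool(row["log_transformed"]),
    )


# Attributes whose simulated latent field is mixed with the FCO2 field, so
# that their maps co-vary with emission as observed (organic matter, pore
# structure, silt, exchangeable bases).
_DRIVER_CORRELATIONS = {
    "SOM": 0.6, "Macro": 0.6, "Silt": 0.5, "Ca": 0.5, "Mg": 0.5, "K": 0.5,
}

# Physical floors for non-log attributes whose mean is within ~3 SD of zero
# (taken from the observed minima); log-normal attributes are positive anyway.
_CLIP_MIN = {"Macro": 1.95, "K": 0.05}

# Measured columns simulated directly; TPV/AFPS and the carbon quantities
# are composed afterwards so the pore-space identities hold exactly.
_SIMULATED = [
    "FCO2", "Ts", "Ms", "Ds", "Macro", "Micro", "Clay", "Silt", "Sand",
    "SOM", "pH", "P", "K", "Ca", "Mg", "Al", "H_Al", "SB", "CEC", "V",
]


def default_survey_config(seed: int = 0, attributes: list[str] | None = None) -> SurveyConfig:
    """Survey generator parameterised by the reference field's structure.

    Simulates the measured attributes on the 100-point grid from their
    reference variogram models and target means; derived quantities
    (TPV, AFPS, TOC, Cstock, k, daily C-CO2) are composed downstream via
    :func:`soilgeo.soil_attributes.append_derived` and
    :func:`compose_survey`.
    """
    names = _SIMULATED if attributes is None else attributes
    desc = descriptive_table().set_index("attribute")
    specs = []
    for name in names:
        model = reference_model(name)
        specs.append(
            AttributeSpec(
                name=name,
                mean=float(desc.loc[name, "mean"]),
                model=model,
                units=ATTRIBUTE_UNITS.get(name, ""),
                log_normal=model.log_transformed,
                correlation=_DRIVER_CORRELATIONS.get(name),
                driver="FCO2" if name in _DRIVER_CORRELATIONS else None,
                clip_min=_CLIP_MIN.get(name),
            )
        )
    return SurveyConfig(
        extent=GRID_EXTENT, spacing=GRID_SPACING,
        attributes=tuple(specs), seed=seed,
    )


def compose_survey(dataset):
    """Add composed pore-space and carbon columns to a simulated survey.

    TPV = Macro + Micro and AFPS = TPV - Ms by definition, then
    TOC/Cstock/k/C_CO2 from the carbon arithmetic (0-20 cm layer).
    """
    from .soil_attributes import append_derived

    out = dataset
    if "TPV" not in out.frame.columns:
        out = out.with_column("TPV", out.values("Macro") + out.values("Micro"))
    return append_derived(out)


def default_microbiology_config(seed: int = 0) -> MicrobiologyConfig:
    """Two-region assay generator at the reference means/SEs (n = 9)."""
    specs = tuple(
        GroupVariableSpec(
            name=name, units=units, mean_r1=m1, mean_r2=m2,
            se_r1=s1, se_r2=s2, family=family,
        )
        for name, units, m1, m2, s1, s2, family, _ in _MICROBIOLOGY_ROWS
    )
    return MicrobiologyConfig(variables=specs, n_per_group=9, seed=seed)
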