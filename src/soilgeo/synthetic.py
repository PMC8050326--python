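"""Synthetic survey and two-group microbiology generators.

The generators emulate the statistical structure the downstream analysis
assumes: a 90 m x 90 m regular grid of 100 points (10 m spacing) whose
attribute fields are stationary Gaussian (or log-Gaussian) random fields
with prescribed variogram models, and two contrasting field regions
(R1, R2) sampled at nine composite points each, with prescribed group
means and standard errors per microbiological variable.

Sampling a random field is exact: the grid covariance matrix implied by
the variogram, ``C(h) = (C0+C1) - gamma(h)`` off the diagonal and
``C0+C1`` on it, is Cholesky-factorised (no spectral truncation; grids
are small). All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .dataset import PointDataset, regular_grid_coords
from .variography import VariogramModel, model_semivariance


@dataclass(frozen=True)
class AttributeSpec:
    """One simulated survey attribute.

    For ``log_normal`` attributes the variogram model lives on the natural
    log scale and ``mean`` is the target *arithmetic* mean (the latent
    Gaussian mean is moment-matched). ``correlation`` mixes this
    attribute's latent field with the named ``driver`` attribute's latent
    field at the requested coefficient.
    """

    name: str
    mean: float
    model: VariogramModel
    units: str = ""
    log_normal: bool = False
    correlation: float | None = None
    driver: str | None = None
    clip_min: float | None = None
    clip_max: float | None = None

    def __post_init__(self) -> None:
        if self.correlation is not None:
            if not -1.0 <= self.correlation <= 1.0:
                raise ValueError(f"correlation must lie in [-1, 1], got {self.correlation}")
            if not self.driver:
                raise ValueError(f"attribute {self.name!r} has a correlation but no driver")
        if self.log_normal and self.mean <= 0:
            raise ValueError(f"log-normal attribute {self.name!r} needs a positive mean")


@dataclass(frozen=True)
class SurveyConfig:
    """Grid geometry plus per-attribute field specifications."""

    extent: float = 90.0
    spacing: float = 10.0
    attributes: tuple[AttributeSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        ratio = self.extent / self.spacing
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("extent must be an integer multiple of spacing")
        names = [a.name for a in self.attributes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate attribute names: {sorted(dupes)}")
        for a in self.attributes:
            if a.driver is not None and a.driver not in names:
                raise ValueError(f"attribute {a.name!r} names unknown driver {a.driver!r}")


def simulate_grf(
    coords: np.ndarray,
    model: VariogramModel,
    mean: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Exact multivariate-normal sample of a stationary field on ``coords``.

    The covariance is ``sill - gamma(h)`` between distinct points and
    ``sill`` on the diagonal (the nugget contributes white noise). A
    zero-sill model returns the constant ``mean``. Reproducible for a
    fixed seed / generator state.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if model.sill == 0.0:
        return np.full(n, float(mean))
    cov = model.sill - squareform(model_semivariance(model, pdist(coords)))
    np.fill_diagonal(cov, model.sill)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        try:  # tolerate rounding-level indefiniteness only
            chol = np.linalg.cholesky(cov + 1e-10 * model.sill * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "assembled covariance is not positive definite for "
                f"{model.kind}(C0={model.nugget}, C1={model.partial_sill}, a={model.range_})"
            ) from exc
    return mean + chol @ rng.standard_normal(n)


def simulate_survey(config: SurveyConfig, rng: np.random.Generator | None = None) -> PointDataset:
    """Simulate one survey: a PointDataset with one column per attribute.

    Latent zero-mean fields are drawn per attribute in listed order; a
    correlated attribute is then the linear mixture
    ``rho * (sd_a/sd_d) * f_driver + sqrt(1-rho^2) * f_own``, which keeps
    the attribute's marginal variance and gives point-wise correlation
    ``rho`` with the driver's latent field. Log-normal attributes are
    exponentiated from the latent scale with moment-matched mean.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    coords = regular_grid_coords(config.extent, config.spacing)
    latent: dict[str, np.ndarray] = {}
    for spec in config.attributes:
        latent[spec.name] = simulate_grf(coords, spec.model, 0.0, rng)

    frame = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1]})
    for spec in config.attributes:
        z0 = latent[spec.name]
        if spec.correlation is not None:
            rho = spec.correlation
            driver_spec = next(a for a in config.attributes if a.name == spec.driver)
            sd_a = np.sqrt(spec.model.sill)
            sd_d = np.sqrt(driver_spec.model.sill)
            if sd_d == 0:
                raise ValueError(f"driver {spec.driver!r} has zero variance; cannot correlate")
            z0 = rho * (sd_a / sd_d) * latent[spec.driver] + np.sqrt(1.0 - rho**2) * z0
        if spec.log_normal:
            mu = np.log(spec.mean) - spec.model.sill / 2.0
            vals = np.exp(mu + z0)
        else:
            vals = spec.mean + z0
        if spec.clip_min is not None or spec.clip_max is not None:
            vals = np.clip(vals, spec.clip_min, spec.clip_max)
        frame[spec.name] = vals
    return PointDataset(frame, grid_spacing=config.spacing)


@dataclass(frozen=True)
class GroupVariableSpec:
    """One microbiological variable: per-region mean and standard error."""

    name: str
    mean_r1: float
    mean_r2: float
    se_r1: float
    se_r2: float
    family: str = "normal"  # or "log_normal"
    units: str = ""

    def __post_init__(self) -> None:
        if self.se_r1 < 0 or self.se_r2 < 0:
            raise ValueError(f"standard errors must be >= 0 for {self.name!r}")
        if self.family not in ("normal", "log_normal"):
            raise ValueError(f"unknown family {self.family!r} for {self.name!r}")
        if self.family == "log_normal" and (self.mean_r1 <= 0 or self.mean_r2 <= 0):
            raise ValueError(f"log-normal variable {self.name!r} needs positive means")


@dataclass(frozen=True)
class MicrobiologyConfig:
    """Two-region assay design: nine composite samples per region by default."""

    variables: tuple[GroupVariableSpec, ...]
    n_per_group: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")


def _draw(rng, family: str, mean: float, se: float, n: int) -> np.ndarray:
    sd = se * np.sqrt(n)  # SE is for the group mean of n samples
    if family == "normal":
        return rng.normal(mean, sd, n)
    # log-normal, moment-matched to the target arithmetic mean and SD
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def simulate_microbiology(
    config: MicrobiologyConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate the two-region assay table.

    Returns a tidy table with a ``region`` column (R1/R2) and one numeric
    column per variable; 2 * n_per_group rows.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_per_group
    data = {"region": ["R1"] * n + ["R2"] * n}
    for v in config.variables:
        r1 = _draw(rng, v.family, v.mean_r1, v.se_r1, n)
        r2 = _draw(rng, v.family, v.mean_r2, v.se_r2, n)
        data[v.name] = np.concatenate([r1, r2])
    return pd.DataFrame(data)
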