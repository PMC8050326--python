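"""Empirical variograms, permissible model fitting, and spatial-dependence
classification.

The semivariogram is estimated under the intrinsic hypothesis with the
classical Matheron estimator,

    gamma_hat(h) = 1/(2 N(h)) * sum_{pairs at separation ~h} [z(x_i+h) - z(x_i)]^2,

binned into half-open distance classes. Permissible isotropic models
(spherical, exponential, gaussian) are parameterised by nugget ``C0``,
partial sill ``C1`` and range ``a``; for the exponential and gaussian kinds
``a`` is the *practical* range (the distance at which the model reaches
95% of the partial sill), so fitted ranges are comparable across kinds.

Spatial dependence is classified weak / moderate / strong through a
spatial dependence index (SDI, %) that combines the structured-variance
share ``C1/(C0+C1)``, the range relative to half the maximum sampling
distance, and a model-shape factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .dataset import PointDataset

VARIOGRAM_KINDS = ("spherical", "exponential", "gaussian")

#: Model-shape factors of the spatial dependence index.
SDI_MODEL_FACTORS = {"spherical": 0.375, "exponential": 0.317, "gaussian": 0.504}

#: Class thresholds on SDI (%): weak <= 7 < moderate <= 15 < strong.
SDI_THRESHOLDS = (7.0, 15.0)

FIT_WEIGHTINGS = ("pair_counts", "equal", "cressie")


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic semivariogram model gamma(h).

    Attributes
    ----------
    kind
        One of ``spherical``, ``exponential``, ``gaussian``.
    nugget
        C0 >= 0, the discontinuity at the origin (micro-scale plus
        measurement variance), in squared attribute units.
    partial_sill
        C1 >= 0, the spatially structured variance; sill = C0 + C1.
    range_
        a > 0, metres. Practical range for exponential/gaussian kinds.
    log_transformed
        True when the attribute was natural-log transformed before
        variography (heavily skewed attributes such as P, Ca, Mg).
    """

    kind: str
    nugget: float
    partial_sill: float
    range_: float
    attribute: str = ""
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VARIOGRAM_KINDS:
            raise ValueError(f"unknown variogram kind {self.kind!r}; use one of {VARIOGRAM_KINDS}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError(f"nugget/partial sill must be >= 0, got C0={self.nugget}, C1={self.partial_sill}")
        if self.range_ <= 0:
            raise ValueError(f"range must be > 0, got {self.range_}")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h):
        return model_semivariance(self, h)


#: Decay rate of the practical-range convention: gamma(a) = C0 + 0.95 C1
#: exactly for the exponential and gaussian kinds (ln 20, not the common
#: "3" approximation, so fitted ranges are exactly comparable across kinds).
PRACTICAL_RANGE_RATE = math.log(20.0)


def model_semivariance(model: VariogramModel, h):
    """Evaluate gamma(h) with the gamma(0) = 0 convention.

    Vectorised over ``h`` (metres, >= 0). Spherical reaches the sill exactly
    at h = a; exponential and gaussian reach exactly 95% of C1 at h = a.
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValueError("separation distance h must be >= 0")
    c0, c1, a = model.nugget, model.partial_sill, model.range_
    if model.kind == "spherical":
        r = np.minimum(h_arr / a, 1.0)
        gamma = c0 + c1 * (1.5 * r - 0.5 * r**3)
    elif model.kind == "exponential":
        gamma = c0 + c1 * (1.0 - np.exp(-PRACTICAL_RANGE_RATE * h_arr / a))
    else:  # gaussian
        gamma = c0 + c1 * (1.0 - np.exp(-PRACTICAL_RANGE_RATE * h_arr**2 / a**2))
    gamma = np.where(h_arr == 0.0, 0.0, gamma)
    return float(gamma) if np.isscalar(h) or h_arr.ndim == 0 else gamma


@dataclass
class EmpiricalVariogram:
    """Binned Matheron estimate gamma_hat(h).

    ``lags`` holds the mean pair separation within each nonempty bin (on a
    regular grid the geometric bin centre can sit far from where the pairs
    actually are, which biases fitted ranges); bin edges are retained.
    """

    lags: np.ndarray
    semivariances: np.ndarray
    pair_counts: np.ndarray
    bin_width: float
    max_lag: float
    attribute: str = ""
    bin_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.semivariances = np.asarray(self.semivariances, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.semivariances < 0):
            raise ValueError("semivariances must be >= 0")
        if np.any(self.pair_counts < 1):
            raise ValueError("every reported bin needs at least one pair")

    @property
    def n_bins(self) -> int:
        return len(self.lags)


def empirical_variogram(
    dataset: PointDataset,
    attribute: str,
    bin_width: float | None = None,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Matheron semivariogram estimate in half-open distance bins.

    Defaults: ``bin_width`` = declared grid spacing (else the minimum
    pairwise distance); ``max_lag`` = half the maximum pairwise distance.
    Bins with no pairs are omitted. NaN attribute values raise rather than
    being dropped silently.
    """
    values = dataset.values(attribute)
    coords = dataset.coords
    if len(coords) < 2:
        raise ValueError("need at least two points for a variogram")
    dists = pdist(coords)
    if dists.max() == 0:
        raise ValueError("all points coincide; variogram undefined")
    if bin_width is None:
        bin_width = dataset.grid_spacing or float(dists[dists > 0].min())
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if max_lag is None:
        max_lag = float(dists.max()) / 2.0
    sq_diffs = pdist(values[:, None], metric="sqeuclidean")

    # half-open bin semantics: a pair at exactly max_lag is excluded
    in_range = dists < max_lag
    if not np.any(in_range):
        raise ValueError(f"no point pairs within max_lag={max_lag}")
    d = dists[in_range]
    s = sq_diffs[in_range]
    idx = np.floor(d / bin_width).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=s, minlength=n_bins)
    dsum = np.bincount(idx, weights=d, minlength=n_bins)
    nonempty = counts > 0
    lags = dsum[nonempty] / counts[nonempty]
    gammas = sums[nonempty] / (2.0 * counts[nonempty])
    edges = np.flatnonzero(nonempty) * bin_width
    return EmpiricalVariogram(
        lags=lags,
        semivariances=gammas,
        pair_counts=counts[nonempty],
        bin_width=float(bin_width),
        max_lag=float(max_lag),
        attribute=attribute,
        bin_edges=edges,
    )


@dataclass
class FitDiagnostics:
    """Goodness-of-fit of a variogram model to an empirical variogram.

    ``ssr`` uses the fit weighting; ``r2`` is the unweighted coefficient of
    determination against the bin-mean baseline; ``rmse`` is the
    leave-one-out kriging cross-validation error in raw attribute units
    (filled in when a dataset is available, else None).
    """

    ssr: float
    r2: float
    rmse: float | None = None
    n_bins: int = 0
    converged: bool = True
    message: str = ""


def _fit_weights(weighting: str, counts: np.ndarray, gamma_model: np.ndarray) -> np.ndarray:
    if weighting == "equal":
        return np.ones_like(gamma_model)
    if weighting == "pair_counts":
        return counts.astype(float)
    if weighting == "cressie":
        return counts / np.maximum(gamma_model, 1e-12) ** 2
    raise ValueError(f"unknown weighting {weighting!r}; use one of {FIT_WEIGHTINGS}")


def fit_variogram(
    emp: EmpiricalVariogram,
    kind: str = "spherical",
    weighting: str = "pair_counts",
    sample_variance: float | None = None,
) -> tuple[VariogramModel, FitDiagnostics]:
    """Weighted least-squares fit of a permissible model to ``emp``.

    Parameters are bounded (C0, C1 >= 0; a > 0) and the fit is
    deterministic. Initial values: nugget from the first bin, sill from the
    sample variance when given (else the mean of the upper half of the
    bins), range from the smallest lag whose semivariance reaches 95% of
    the sill guess.
    """
    if kind not in VARIOGRAM_KINDS:
        raise ValueError(f"unknown variogram kind {kind!r}")
    h = emp.lags
    g = emp.semivariances
    counts = emp.pair_counts
    if emp.n_bins < 4:
        raise ValueError(f"need >= 4 nonempty bins to fit 3 parameters, got {emp.n_bins}")

    sill0 = sample_variance if sample_variance is not None else float(np.mean(g[len(g) // 2:]))
    sill0 = max(sill0, 1e-12)
    c0_0 = min(float(g[0]), sill0)
    c1_0 = max(sill0 - c0_0, 1e-6 * sill0)
    reach = h[g >= 0.95 * sill0]
    a0 = float(reach[0]) if len(reach) else float(h[-1])
    a0 = min(max(a0, float(h[0])), 3.0 * float(h[-1]))

    def residuals(theta):
        c0, c1, a = theta
        model = VariogramModel(kind, max(c0, 0.0), max(c1, 0.0), max(a, 1e-9))
        gm = model_semivariance(model, h)
        w = _fit_weights(weighting, counts, gm)
        return np.sqrt(w) * (g - gm)

    lower = [0.0, 0.0, 1e-6]
    upper = [np.inf, np.inf, 3.0 * float(h[-1])]
    sol = least_squares(
        residuals,
        x0=[c0_0, c1_0, a0],
        bounds=(lower, upper),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"variogram fit did not converge: {sol.message} (status {sol.status})")
    c0, c1, a = sol.x
    model = VariogramModel(kind, float(c0), float(c1), float(a), attribute=emp.attribute)
    gm = model_semivariance(model, h)
    w = _fit_weights(weighting, counts, gm)
    ssr = float(np.sum(w * (g - gm) ** 2))
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - float(np.sum((g - gm) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    diag = FitDiagnostics(ssr=ssr, r2=r2, n_bins=emp.n_bins, converged=True, message=sol.message)
    return model, diag


def select_model(
    candidates: list[tuple[VariogramModel, FitDiagnostics]],
) -> list[tuple[VariogramModel, FitDiagnostics]]:
    """Rank fitted candidates: lowest SSR, ties by highest R2, then lowest
    cross-validation RMSE. Returns the full ranking; element 0 is the pick."""
    if not candidates:
        raise ValueError("no candidate models to select from")

    def key(item):
        _, d = item
        rmse = d.rmse if d.rmse is not None else math.inf
        return (d.ssr, -d.r2, rmse)

    return sorted(candidates, key=key)


@dataclass
class SDIResult:
    """Spatial dependence index and its weak/moderate/strong class."""

    sdi_percent: float
    dependence_class: str
    model_factor: float
    max_distance: float
    thresholds: tuple[float, float] = SDI_THRESHOLDS
    attribute: str = ""


def spatial_dependence_index(
    model: VariogramModel,
    max_distance: float,
    model_factors: dict[str, float] | None = None,
    thresholds: tuple[float, float] = SDI_THRESHOLDS,
) -> SDIResult:
    """Classify spatial dependence of a fitted variogram.

    SDI% = MF(kind) * [C1/(C0+C1)] * [min(a, MD/2)/(MD/2)] * 100,
    where MD is the maximum distance between sampling points. Classes:
    weak (SDI <= 7), moderate (7 < SDI <= 15), strong (SDI > 15), with
    factors and thresholds configurable. A zero-sill model has no spatial
    structure by convention: SDI = 0, class weak.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    factors = SDI_MODEL_FACTORS if model_factors is None else model_factors
    mf = factors[model.kind]
    if model.sill == 0:
        sdi = 0.0
    else:
        struct = model.partial_sill / model.sill
        half_md = max_distance / 2.0
        reach = min(model.range_, half_md) / half_md
        sdi = mf * struct * reach * 100.0
    low, high = thresholds
    if sdi <= low:
        cls = "weak"
    elif sdi <= high:
        cls = "moderate"
    else:
        cls = "strong"
    return SDIResult(
        sdi_percent=float(sdi),
        dependence_class=cls,
        model_factor=mf,
        max_distance=float(max_distance),
        thresholds=thresholds,
        attribute=model.attribute,
    )
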