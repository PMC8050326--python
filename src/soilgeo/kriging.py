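"""Ordinary kriging: best linear unbiased prediction with a Lagrange
multiplier enforcing unit-sum weights.

The prediction at an unsampled location x0 is ``z_hat(x0) = sum_i
lambda_i z(x_i)``, with the weights solving the semivariance form of the
ordinary-kriging system: the pairwise semivariance matrix (zero diagonal,
so observations are honoured exactly even with a nugget) bordered by the
unbiasedness row of ones. With n = 100 survey points the default
neighbourhood is global; a k-nearest option exists for larger inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist, pdist, squareform

from .dataset import PointDataset, RasterGrid
from .variography import VariogramModel, model_semivariance


@dataclass
class KrigingResult:
    """Predictions, kriging variances, and (optionally) the weights."""

    targets: np.ndarray
    predictions: np.ndarray
    variances: np.ndarray
    weights: np.ndarray | None = None
    lagrange: np.ndarray | None = None


def _ok_matrix(coords: np.ndarray, model: VariogramModel) -> np.ndarray:
    n = len(coords)
    gamma = squareform(model_semivariance(model, pdist(coords)))
    mat = np.empty((n + 1, n + 1))
    mat[:n, :n] = gamma  # gamma(0) = 0 on the diagonal: exact interpolator
    mat[n, :n] = 1.0
    mat[:n, n] = 1.0
    mat[n, n] = 0.0
    return mat


def ok_predict(
    dataset: PointDataset,
    attribute: str,
    model: VariogramModel,
    targets: np.ndarray,
    retain_weights: bool = False,
    n_neighbors: int | None = None,
) -> KrigingResult:
    """Ordinary-kriging prediction at ``targets`` (m x 2 array of metres).

    Weights sum to one by construction; the kriging variance is
    ``sum_i lambda_i gamma(x_i, x0) + mu`` with tiny negative values
    clamped to zero. Duplicate sample coordinates make the system
    singular and raise :class:`~soilgeo.dataset.DuplicateCoordinateError`.
    """
    values = dataset.values(attribute)
    coords = dataset.coords
    dataset.check_unique_coordinates()
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.shape[1] != 2:
        raise ValueError("targets must be an (m, 2) array of x/y metres")

    if n_neighbors is not None and n_neighbors < len(coords):
        return _ok_predict_local(coords, values, model, targets, n_neighbors, retain_weights)

    n = len(coords)
    lu = lu_factor(_ok_matrix(coords, model))
    g0 = model_semivariance(model, cdist(coords, targets))  # (n, m)
    rhs = np.vstack([g0, np.ones((1, targets.shape[0]))])
    sol = lu_solve(lu, rhs)  # (n+1, m)
    lam = sol[:n]
    mu = sol[n]
    preds = lam.T @ values
    variances = np.einsum("im,im->m", lam, g0) + mu
    variances = np.where(variances < 0, np.where(variances > -1e-9, 0.0, variances), variances)
    if np.any(variances < 0):
        raise FloatingPointError("kriging variance below numerical floor; check model parameters")
    return KrigingResult(
        targets=targets,
        predictions=preds,
        variances=variances,
        weights=lam.T.copy() if retain_weights else None,
        lagrange=mu.copy() if retain_weights else None,
    )


def _ok_predict_local(coords, values, model, targets, k, retain_weights):
    m = targets.shape[0]
    preds = np.empty(m)
    variances = np.empty(m)
    weights = np.full((m, len(coords)), np.nan) if retain_weights else None
    lagrange = np.empty(m) if retain_weights else None
    d_all = cdist(targets, coords)
    for j in range(m):
        idx = np.argsort(d_all[j])[:k]
        sub = coords[idx]
        mat = _ok_matrix(sub, model)
        g0 = model_semivariance(model, cdist(sub, targets[j : j + 1]))[:, 0]
        rhs = np.append(g0, 1.0)
        sol = np.linalg.solve(mat, rhs)
        lam, mu = sol[:k], sol[k]
        preds[j] = lam @ values[idx]
        var = lam @ g0 + mu
        variances[j] = 0.0 if -1e-9 < var < 0 else var
        if retain_weights:
            weights[j, idx] = lam
            lagrange[j] = mu
    return KrigingResult(targets, preds, variances, weights, lagrange)


def krige_map(
    dataset: PointDataset,
    attribute: str,
    model: VariogramModel,
    raster_spec: RasterGrid | None = None,
    cell_size: float = 1.0,
) -> tuple[RasterGrid, RasterGrid]:
    """Kriged map (and kriging-variance map) over a raster.

    Without an explicit ``raster_spec`` a raster is laid over the data
    extent with ``cell_size`` cells, centres aligned to the data minimum.
    """
    coords = dataset.coords
    if raster_spec is None:
        raster_spec = RasterGrid.from_extent(
            coords[:, 0].min(), coords[:, 1].min(),
            coords[:, 0].max(), coords[:, 1].max(),
            cell_size,
        )
    centers = raster_spec.cell_centers()
    res = ok_predict(dataset, attribute, model, centers)
    shape = (raster_spec.n_rows, raster_spec.n_cols)
    value_grid = RasterGrid(
        raster_spec.origin, raster_spec.cell_size,
        res.predictions.reshape(shape), raster_spec.nodata,
    )
    var_grid = RasterGrid(
        raster_spec.origin, raster_spec.cell_size,
        res.variances.reshape(shape), raster_spec.nodata,
    )
    return value_grid, var_grid


def loo_rmse(dataset: PointDataset, attribute: str, model: VariogramModel) -> float:
    """Leave-one-out cross-validation RMSE, in raw attribute units.

    Each sample is predicted by ordinary kriging from the remaining
    samples with the same variogram model.
    """
    values = dataset.values(attribute)
    coords = dataset.coords
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 samples for cross-validation")
    errors = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        sub = PointDataset(dataset.frame.loc[mask, ["x", "y", attribute]], dataset.grid_spacing)
        res = ok_predict(sub, attribute, model, coords[i : i + 1])
        errors[i] = values[i] - res.predictions[0]
        mask[i] = True
    return float(np.sqrt(np.mean(errors**2)))
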