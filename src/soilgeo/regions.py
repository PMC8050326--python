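"""Contrasting-emission region delineation and the two-group statistical
battery: pooled Student's t per variable, Hotelling's T-squared across
variables, Ward hierarchical clustering, and correlation-matrix PCA with
Kaiser retention and a |loading| >= 0.70 interpretation rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .dataset import RasterGrid


@dataclass
class RegionAssignment:
    """Per-cell region labels derived from value bands (band edges inclusive)."""

    labels: np.ndarray  # object array of "R1" / "R2" / ""
    high_band: tuple[float, float]
    low_band: tuple[float, float]

    def counts(self) -> dict[str, int]:
        flat = self.labels.ravel()
        return {
            "R1": int(np.sum(flat == "R1")),
            "R2": int(np.sum(flat == "R2")),
            "unassigned": int(np.sum(flat == "")),
        }


def delineate_regions(
    raster: RasterGrid | np.ndarray,
    low_band: tuple[float, float] = (1.9, 2.7),
    high_band: tuple[float, float] = (2.9, 4.2),
) -> RegionAssignment:
    """Label map cells R1 (high band) / R2 (low band) / unassigned.

    Defaults are the FCO2 emission bands (umol m-2 s-1) of the reference
    field. Bands must be disjoint; edges are inclusive. Nodata / NaN
    cells stay unassigned.
    """
    lo_min, lo_max = low_band
    hi_min, hi_max = high_band
    if lo_min > lo_max or hi_min > hi_max:
        raise ValueError("band bounds must be (min, max) with min <= max")
    if max(lo_min, hi_min) <= min(lo_max, hi_max):
        raise ValueError(f"bands overlap: low {low_band} vs high {high_band}")
    if isinstance(raster, RasterGrid):
        values = raster.values
        valid = np.isfinite(values) & (values != raster.nodata)
    else:
        values = np.asarray(raster, dtype=float)
        valid = np.isfinite(values)
    labels = np.full(values.shape, "", dtype=object)
    labels[valid & (values >= hi_min) & (values <= hi_max)] = "R1"
    labels[valid & (values >= lo_min) & (values <= lo_max)] = "R2"
    return RegionAssignment(labels=labels, high_band=high_band, low_band=low_band)


@dataclass
class TTestResult:
    variable: str
    t: float
    df: int
    p_value: float
    significant: bool
    alpha: float
    mean_a: float
    mean_b: float


def students_t(
    group_a,
    group_b,
    alpha: float = 0.01,
    equal_var: bool = True,
    variable: str = "",
) -> TTestResult:
    """Two-sided Student's t test (pooled variance by default; Welch on
    ``equal_var=False``).

    Degenerate zero-spread case: equal means give t = 0, p = 1; unequal
    means give an infinite statistic and p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    n1, n2 = len(a), len(b)
    diff = a.mean() - b.mean()
    if equal_var:
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
        se = np.sqrt(pooled * (1 / n1 + 1 / n2))
    else:
        v1, v2 = a.var(ddof=1) / n1, b.var(ddof=1) / n2
        se = np.sqrt(v1 + v2)
        df = int(np.floor((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)))) if se > 0 else n1 + n2 - 2
    if se == 0.0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(
        variable=variable, t=float(t), df=int(df), p_value=float(p),
        significant=bool(p < alpha), alpha=alpha,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
    )


def compare_groups(
    table: pd.DataFrame,
    group_column: str = "region",
    alpha: float = 0.01,
    equal_var: bool = True,
) -> list[TTestResult]:
    """Per-variable pooled t tests between the two groups of a tidy table.

    No multiple-testing correction is applied by default (each assay is
    reported at its own alpha); see :func:`holm_adjust` to add one.
    """
    groups = table[group_column].unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {list(groups)}")
    ga = table[table[group_column] == groups[0]]
    gb = table[table[group_column] == groups[1]]
    out = []
    for col in table.columns:
        if col == group_column:
            continue
        out.append(students_t(ga[col], gb[col], alpha=alpha, equal_var=equal_var, variable=col))
    return out


def holm_adjust(results: list[TTestResult]) -> list[TTestResult]:
    """Holm step-down adjusted copies of per-variable t results (optional)."""
    order = np.argsort([r.p_value for r in results])
    m = len(results)
    adjusted = [None] * m
    running = 0.0
    for rank, idx in enumerate(order):
        r = results[idx]
        p_adj = min(1.0, max(running, (m - rank) * r.p_value))
        running = p_adj
        adjusted[idx] = TTestResult(
            r.variable, r.t, r.df, p_adj, p_adj < r.alpha, r.alpha, r.mean_a, r.mean_b
        )
    return adjusted


@dataclass
class HotellingResult:
    t2: float
    f: float
    df1: int
    df2: int
    p_value: float


def hotelling_t2(matrix_a, matrix_b) -> HotellingResult:
    """Two-sample Hotelling T-squared test on n1 x p and n2 x p matrices.

    T2 uses the pooled covariance; the F transform is
    ``F = T2 (n1+n2-p-1) / ((n1+n2-2) p)`` on (p, n1+n2-p-1) degrees of
    freedom.
    """
    a = np.atleast_2d(np.asarray(matrix_a, dtype=float))
    b = np.atleast_2d(np.asarray(matrix_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the same variables")
    n1, p = a.shape
    n2 = b.shape[0]
    df2 = n1 + n2 - p - 1
    if df2 < 1:
        raise ValueError(f"too few samples for p={p} variables (n1+n2-p-1={df2})")
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = ((n1 - 1) * np.cov(a, rowvar=False) + (n2 - 1) * np.cov(b, rowvar=False)) / (n1 + n2 - 2)
    pooled = np.atleast_2d(pooled)
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; reduce the variable set "
            f"(p={p}, n1={n1}, n2={n2})"
        ) from exc
    t2 = (n1 * n2) / (n1 + n2) * float(diff @ sol)
    f = t2 * df2 / ((n1 + n2 - 2) * p)
    p_value = float(stats.f.sf(f, p, df2))
    return HotellingResult(t2=float(t2), f=float(f), df1=p, df2=df2, p_value=p_value)


@dataclass
class ClusteringResult:
    """Agglomerative (Ward) clustering of the sample rows."""

    linkage: np.ndarray          # scipy linkage matrix, heights on distance scale
    leaf_order: list[int]
    labels: np.ndarray           # cut labels, 1..n_groups
    cophenetic_r: float
    method: str = "ward"


def ward_cluster(matrix, n_groups: int = 2, method: str = "ward") -> ClusteringResult:
    """Hierarchical clustering with Euclidean distances and Ward linkage.

    Heights are on the distance scale (two singletons merge at their
    Euclidean distance); ties are broken deterministically by scipy's
    index ordering. ``method`` is configurable for other linkage variants.
    """
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not np.all(np.isfinite(x)):
        raise ValueError("clustering input contains non-finite values")
    if n_groups > n:
        raise ValueError(f"cannot cut {n} samples into {n_groups} groups")
    d = pdist(x)
    link = hierarchy.linkage(d, method=method)
    labels = hierarchy.fcluster(link, t=n_groups, criterion="maxclust")
    if n > 2:  # undefined (0/0) for a single merge
        coph, _ = hierarchy.cophenet(link, d)
    else:
        coph = float("nan")
    return ClusteringResult(
        linkage=link,
        leaf_order=hierarchy.leaves_list(link).tolist(),
        labels=labels,
        cophenetic_r=float(coph),
        method=method,
    )


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    explained_percent: np.ndarray
    loadings: pd.DataFrame        # variables x components, correlation scale
    scores: np.ndarray            # samples x components
    retained: list[str]           # Kaiser: eigenvalue > 1
    interpreted: dict[str, list[str]]  # per retained component, |loading| >= cutoff
    loading_cutoff: float = 0.70


def pca(
    matrix,
    variables: list[str] | None = None,
    standardize: bool = True,
    loading_cutoff: float = 0.70,
) -> PCAResult:
    """Principal components of the correlation matrix (default).

    Loadings are variable-component correlations (eigenvector times
    sqrt(eigenvalue)); components are retained by the Kaiser criterion
    (eigenvalue > 1) and variables with |loading| >= ``loading_cutoff``
    on a retained component are flagged for interpretation. Each
    component's sign is fixed so its largest-magnitude loading is
    positive.
    """
    if isinstance(matrix, pd.DataFrame):
        variables = list(matrix.columns) if variables is None else variables
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("need n >= 2 samples and p >= 2 variables")
    if variables is None:
        variables = [f"var{i+1}" for i in range(p)]
    sd = x.std(axis=0, ddof=1)
    if standardize and np.any(sd == 0):
        bad = [variables[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s) cannot be standardised: {bad}")
    xc = x - x.mean(axis=0)
    if standardize:
        xc = xc / sd
        mat = np.corrcoef(x, rowvar=False)
    else:
        mat = np.cov(x, rowvar=False)
    eigval, eigvec = np.linalg.eigh(mat)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| variable positive per component
    for j in range(p):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    loadings = eigvec * np.sqrt(eigval)
    explained = 100.0 * eigval / eigval.sum()
    comp_names = [f"PC{i+1}" for i in range(p)]
    load_df = pd.DataFrame(loadings, index=variables, columns=comp_names)
    scores = xc @ eigvec
    retained = [comp_names[i] for i in range(p) if eigval[i] > 1.0] if standardize else [
        comp_names[i] for i in range(p) if eigval[i] > eigval.mean()
    ]
    interpreted = {
        c: [v for v in variables if abs(load_df.loc[v, c]) >= loading_cutoff]
        for c in retained
    }
    return PCAResult(
        eigenvalues=eigval,
        explained_percent=explained,
        loadings=load_df,
        scores=scores,
        retained=retained,
        interpreted=interpreted,
        loading_cutoff=loading_cutoff,
    )
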