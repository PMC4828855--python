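"""Ecological distances and ordination (PCoA / NMDS).

Three abundance-based dissimilarities are supported, all bounded by [0, 1] on
relative-mode tables:

* Bray-Curtis, ``sum|x-y| / sum(x+y)``, evaluated on columns *as given* so
  that tables with taxa removed (columns summing to < 1) keep their meaning;
* Morisita-Horn, ``1 - 2*sum(x*y) / (sum x^2 + sum y^2)`` after per-pair
  renormalization to unit sum;
* Jensen-Shannon, the square root of the base-2 Jensen-Shannon divergence of
  the pair renormalized to probability vectors.

PCoA is classical metric scaling: Gower double-centering of the squared
distances followed by an eigendecomposition; axis k is ``v_k * sqrt(lambda_k)``
for positive eigenvalues.  Negative eigenvalues (non-Euclidean distances) are
reported but excluded from the variance-explained denominator.  NMDS minimizes
Kruskal stress-1 by SMACOF with isotonic regression, taking the best of
several restarts (the first initialized from PCoA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.spatial.distance import jensenshannon as _scipy_jensenshannon
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps
from sklearn.isotonic import IsotonicRegression

from .core_io import RELATIVE, AbundanceTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a named metric."""

    samples: list[str]
    d: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = self.d
        n = len(self.samples)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} does not match {n} samples")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValidationError("distance matrix has negative entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.samples, columns=self.samples)


@dataclass(frozen=True)
class Ordination:
    """Sample coordinates from PCoA or NMDS.

    ``varexp`` (PCoA) gives per-axis fractions of variability,
    ``max(l_k,0)/sum_j max(l_j,0)``; ``stress`` (NMDS) is Kruskal stress-1 of
    the returned configuration.
    """

    samples: list[str]
    coords: np.ndarray
    method: str
    eigenvalues: np.ndarray | None = None
    varexp: np.ndarray | None = None
    stress: float | None = None
    seed: int | None = None
    converged: bool = True

    def coords_frame(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.samples, columns=cols)


def _require_relative(table: AbundanceTable, op: str) -> None:
    if table.mode != RELATIVE:
        raise ValidationError(f"{op} expects a relative-mode table")


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on columns as given (no renormalization)."""
    _require_relative(table, "bray_curtis")
    X = table.values.T  # samples x taxa
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(X, metric=_scipy_braycurtis))
    if np.isnan(d).any():
        logger.warning("pair(s) of all-zero samples in Bray-Curtis; their distance set to 0")
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(samples=table.samples, d=d, metric="bray_curtis")


def morisita_horn(table: AbundanceTable) -> DistanceMatrix:
    """Morisita-Horn dissimilarity with per-pair renormalization to unit sum."""
    _require_relative(table, "morisita_horn")
    X = table.values.T
    sums = X.sum(axis=1)
    zero = sums == 0
    if zero.any():
        logger.warning("zero sample column(s) in Morisita-Horn; distances involving them set to 1")
    P = np.where(zero[:, None], 0.0, X / np.where(zero, 1.0, sums)[:, None])
    sq = (P * P).sum(axis=1)
    cross = P @ P.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * cross / (sq[:, None] + sq[None, :])
    d[zero, :] = 1.0
    d[:, zero] = 1.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(samples=table.samples, d=np.clip(d, 0.0, 1.0), metric="morisita_horn")


def jensen_shannon(table: AbundanceTable) -> DistanceMatrix:
    """Square root of the base-2 Jensen-Shannon divergence (bounded by 1)."""
    _require_relative(table, "jensen_shannon")
    X = table.values.T
    sums = X.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValidationError(f"sample {table.samples[zero[0]]!r} is all zero; JSD undefined")
    P = X / sums[:, None]
    d = squareform(pdist(P, metric=lambda a, b: _scipy_jensenshannon(a, b, base=2)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(samples=table.samples, d=np.clip(np.nan_to_num(d), 0.0, 1.0), metric="jensen_shannon")


METRICS = {"bray_curtis": bray_curtis, "morisita_horn": morisita_horn, "jensen_shannon": jensen_shannon}


def distance(table: AbundanceTable, metric: str) -> DistanceMatrix:
    try:
        return METRICS[metric](table)
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}") from None


def pcoa(D: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Axis signs are fixed deterministically: the coordinate with the largest
    absolute value on each axis is made positive.
    """
    n = len(D.samples)
    if n_axes < 1 or n_axes > n - 1:
        raise ValueError(f"n_axes must be in [1, {n - 1}]; got {n_axes}")
    d2 = D.d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    n_pos = int(positive.sum())
    if n_axes > n_pos:
        logger.warning("only %d positive eigenvalue(s); returning %d axes instead of %d", n_pos, n_pos, n_axes)
        n_axes = max(n_pos, 1)
    coords = eigvecs[:, :n_axes] * np.sqrt(np.maximum(eigvals[:n_axes], 0.0))
    for k in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = np.maximum(eigvals, 0.0).sum()
    varexp = np.maximum(eigvals[:n_axes], 0.0) / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    return Ordination(
        samples=D.samples, coords=coords, method="pcoa", eigenvalues=eigvals, varexp=varexp
    )


def kruskal_stress(d_obs: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities."""
    iu = np.triu_indices(d_obs.shape[0], k=1)
    dhat = squareform(pdist(coords))[iu]
    disp = IsotonicRegression().fit_transform(d_obs[iu], dhat)
    denom = (dhat ** 2).sum()
    return float(np.sqrt(((dhat - disp) ** 2).sum() / denom)) if denom > 0 else 0.0


def _smacof_nonmetric(d_obs: np.ndarray, init: np.ndarray, max_iter: int, tol: float) -> tuple[np.ndarray, float]:
    """Nonmetric SMACOF: alternate isotonic disparities and Guttman transforms."""
    n = d_obs.shape[0]
    iu = np.triu_indices(n, k=1)
    order = np.argsort(d_obs[iu], kind="stable")
    X = init.copy()
    iso = IsotonicRegression()
    old_stress = np.inf
    stress = np.inf
    for _ in range(max_iter):
        dist = squareform(pdist(X))
        dvec = dist[iu]
        disp_vec = iso.fit_transform(d_obs[iu][order], dvec[order])
        disparities = np.zeros_like(dvec)
        disparities[order] = disp_vec
        # normalize disparities to the scale of the configuration distances
        scale = np.sqrt((dvec ** 2).sum() / max((disparities ** 2).sum(), 1e-30))
        disparities = disparities * scale
        denom = (dvec ** 2).sum()
        stress = np.sqrt(((dvec - disparities) ** 2).sum() / max(denom, 1e-30))
        if old_stress - stress < tol:
            break
        old_stress = stress
        # Guttman transform
        Dhat = squareform(disparities)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, Dhat / dist, 0.0)
        Bmat = -ratio
        np.fill_diagonal(Bmat, ratio.sum(axis=1))
        X = Bmat @ X / n
    return X, float(stress)


def nmds(
    D: DistanceMatrix,
    n_axes: int = 2,
    restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> Ordination:
    """Nonmetric MDS minimizing Kruskal stress-1; best of ``restarts`` starts.

    The first start is the PCoA configuration; the rest are random Gaussians
    drawn from ``seed``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = len(D.samples)
    inits = [pcoa(D, n_axes=min(n_axes, n - 1)).coords[:, :n_axes]]
    inits.extend(rng.standard_normal((n, n_axes)) for _ in range(max(restarts - 1, 0)))
    best_X, best_stress = None, np.inf
    for init in inits:
        if init.shape[1] < n_axes:  # PCoA returned fewer axes than requested
            pad = np.zeros((n, n_axes - init.shape[1]))
            init = np.hstack([init, pad])
        X, stress = _smacof_nonmetric(D.d, init, max_iter=max_iter, tol=tol)
        if stress < best_stress:
            best_X, best_stress = X, stress
    final_stress = kruskal_stress(D.d, best_X)
    converged = np.isfinite(final_stress)
    # deterministic orientation, as for PCoA
    coords = best_X - best_X.mean(axis=0)
    for k in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]
    return Ordination(
        samples=D.samples, coords=coords, method="nmds", stress=final_stress, seed=seed, converged=converged
    )


def ordinate(table: AbundanceTable, metric: str = "bray_curtis", method: str = "pcoa",
             n_axes: int = 2, seed: int = 0, **kwargs) -> Ordination:
    """Convenience wrapper: distance matrix then PCoA or NMDS."""
    D = distance(table, metric)
    if method == "pcoa":
        return pcoa(D, n_axes=n_axes)
    if method == "nmds":
        return nmds(D, n_axes=n_axes, seed=seed, **kwargs)
    raise ValueError(f"unknown ordination method {method!r}")


def axis_taxon_correlation(
    ordination: Ordination,
    table: AbundanceTable,
    taxon: str,
    axis: int = 1,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation (and two-sided p) of a taxon's abundance with an ordination axis.

    ``axis`` is 1-based.  Returns (nan, nan) when either variable is constant.
    """
    if taxon not in table.data.index:
        raise ValidationError(f"taxon {taxon!r} is not a row of the table")
    if axis < 1 or axis > ordination.coords.shape[1]:
        raise ValueError(f"axis must be in [1, {ordination.coords.shape[1]}]")
    abund = table.data.loc[taxon, ordination.samples].to_numpy(dtype=float)
    coord = ordination.coords[:, axis - 1]
    if np.ptp(abund) == 0 or np.ptp(coord) == 0:
        logger.warning("constant abundance or axis; correlation undefined")
        return float("nan"), float("nan")
    if method == "pearson":
        r, p = sps.pearsonr(abund, coord)
    elif method == "spearman":
        r, p = sps.spearmanr(abund, coord)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)
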