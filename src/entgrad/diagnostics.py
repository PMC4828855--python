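"""Group covariance ellipses and the leave-dominant-taxa-out diagnostic.

The diagnostic asks whether apparent cluster separation in an ordination
reflects community structure beyond the two dominant genera.  Procedure:

1. ordinate the full table and fit a 2-standard-deviation Mahalanobis
   ellipse to each dominance group on axes 1-2;
2. delete the dominant taxa (Bacteroides, Prevotella) *without rescaling*
   the remaining proportions and re-ordinate;
3. compare, before vs after, the variance explained by axes 1-2 and the
   fraction of each group's samples falling inside every other group's
   ellipse, with group labels held fixed at their original values.

If the groups were gradient endpoints of a two-taxon see-saw, removal
collapses them: containment jumps and the leading axes lose variance.  If the
groups carry genuinely distinct secondary communities, the separation — and
hence low cross-containment — survives removal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AbundanceTable, ValidationError
from .ordination import Ordination, distance, pcoa

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupEllipse:
    """A k-standard-deviation covariance ellipse for one sample group.

    The boundary is the set of points at Mahalanobis distance ``n_sd`` from
    ``center`` under ``covariance``; its semi-axes lie along the covariance
    eigenvectors with lengths ``n_sd * sqrt(eigenvalue)``.
    """

    group: str
    center: np.ndarray
    covariance: np.ndarray
    n_sd: float = 2.0
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "center": [float(v) for v in self.center],
            "covariance": [[float(v) for v in row] for row in self.covariance],
            "n_sd": self.n_sd,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class RemovalDiagnosticReport:
    """Before/after comparison for the dominant-taxon removal diagnostic."""

    varexp_before: tuple[float, float]
    varexp_after: tuple[float, float]
    containment_before: dict[tuple[str, str], float]
    containment_after: dict[tuple[str, str], float]
    removed_taxa: list[str]
    metric: str

    def containment_change(self, points_group: str, ellipse_group: str) -> float:
        key = (points_group, ellipse_group)
        return self.containment_after[key] - self.containment_before[key]

    def to_dict(self) -> dict:
        def _enc(c: dict[tuple[str, str], float]) -> dict[str, float]:
            return {f"{a}|in|{b}": float(v) for (a, b), v in sorted(c.items())}

        return {
            "metric": self.metric,
            "removed_taxa": list(self.removed_taxa),
            "varexp_before": [float(v) for v in self.varexp_before],
            "varexp_after": [float(v) for v in self.varexp_after],
            "containment_before": _enc(self.containment_before),
            "containment_after": _enc(self.containment_after),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def fit_group_ellipses(
    ordination: Ordination, labels: pd.DataFrame, n_sd: float = 2.0, min_group_size: int = 3
) -> list[GroupEllipse]:
    """Fit per-group mean and unbiased covariance ellipses on axes 1-2.

    ``labels`` is the DataFrame from :func:`entgrad.community.classify_dominance`
    (columns ``sample_id`` and ``label``).  Groups smaller than
    ``min_group_size`` are skipped with a warning.
    """
    if ordination.coords.shape[1] < 2:
        raise ValidationError("ellipses need at least two ordination axes")
    coords = pd.DataFrame(ordination.coords[:, :2], index=ordination.samples, columns=["a1", "a2"])
    lab = labels.set_index("sample_id")["label"]
    ellipses = []
    for group in pd.unique(lab):
        members = lab.index[lab == group].intersection(coords.index)
        pts = coords.loc[members].to_numpy()
        if len(pts) < min_group_size:
            logger.warning("group %r has only %d sample(s); ellipse skipped", group, len(pts))
            continue
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
        degenerate = bool(np.linalg.matrix_rank(cov, tol=1e-12) < 2)
        if degenerate:
            logger.warning("group %r has a singular covariance (collinear points)", group)
        ellipses.append(GroupEllipse(group=str(group), center=center, covariance=cov, n_sd=n_sd, degenerate=degenerate))
    return ellipses


def mahalanobis_sq(points: np.ndarray, ellipse: GroupEllipse) -> np.ndarray:
    """Squared Mahalanobis distances of points to the ellipse center.

    For a degenerate (rank-deficient) covariance the distance is evaluated in
    the nondegenerate eigen-subspace via the pseudo-inverse.
    """
    delta = np.atleast_2d(points) - ellipse.center
    if ellipse.degenerate:
        inv = np.linalg.pinv(ellipse.covariance, rcond=1e-12)
    else:
        inv = np.linalg.inv(ellipse.covariance)
    return np.einsum("ij,jk,ik->i", delta, inv, delta)


def ellipse_containment(
    ordination: Ordination, ellipse: GroupEllipse, points_group: str, labels: pd.DataFrame
) -> float:
    """Fraction of a group's samples inside (or on) the ellipse."""
    coords = pd.DataFrame(ordination.coords[:, :2], index=ordination.samples, columns=["a1", "a2"])
    lab = labels.set_index("sample_id")["label"]
    members = lab.index[lab == points_group].intersection(coords.index)
    if len(members) == 0:
        raise ValidationError(f"group {points_group!r} has no samples in the ordination")
    m2 = mahalanobis_sq(coords.loc[members].to_numpy(), ellipse)
    return float(np.mean(m2 <= ellipse.n_sd ** 2 + 1e-12))


def remove_taxa(table: AbundanceTable, taxa: list[str]) -> AbundanceTable:
    """Delete taxon rows, leaving the remaining values un-rescaled."""
    missing = [t for t in taxa if t not in table.data.index]
    if missing:
        raise ValidationError(f"taxa not present in table: {missing}")
    return AbundanceTable(data=table.data.drop(index=list(taxa)).copy(), mode=table.mode)


def _pairwise_containment(
    ordination: Ordination, labels: pd.DataFrame, n_sd: float
) -> dict[tuple[str, str], float]:
    ellipses = {e.group: e for e in fit_group_ellipses(ordination, labels, n_sd=n_sd)}
    lab = labels.set_index("sample_id")["label"]
    groups = [str(g) for g in pd.unique(lab)]
    out: dict[tuple[str, str], float] = {}
    for ga in groups:
        for gb in groups:
            if ga == gb or gb not in ellipses:
                continue
            out[(ga, gb)] = ellipse_containment(ordination, ellipses[gb], ga, labels)
    return out


def dominance_removal_diagnostic(
    table: AbundanceTable,
    labels: pd.DataFrame,
    metric: str = "bray_curtis",
    taxa: list[str] | None = None,
    n_sd: float = 2.0,
) -> RemovalDiagnosticReport:
    """Run the full before/after removal comparison.

    ``labels`` must come from the ORIGINAL table; they are reused unchanged
    for the after-removal ordination so the comparison tracks the same sample
    groups.
    """
    taxa = ["Prevotella", "Bacteroides"] if taxa is None else list(taxa)
    if not taxa:
        raise ValueError("at least one taxon must be removed")
    ord_before = pcoa(distance(table, metric), n_axes=2)
    reduced = remove_taxa(table, taxa)
    ord_after = pcoa(distance(reduced, metric), n_axes=2)
    return RemovalDiagnosticReport(
        varexp_before=(float(ord_before.varexp[0]), float(ord_before.varexp[1])),
        varexp_after=(float(ord_after.varexp[0]), float(ord_after.varexp[1])),
        containment_before=_pairwise_containment(ord_before, labels, n_sd),
        containment_after=_pairwise_containment(ord_after, labels, n_sd),
        removed_taxa=taxa,
        metric=metric,
    )
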