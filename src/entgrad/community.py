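"""Dominant-taxon classification and the Prevotella ratio.

A sample is labelled by its most abundant genus: ``Prevotella`` or
``Bacteroides`` when one of those two dominates, ``Other`` otherwise.  The
Prevotella ratio, P/(P+B), turns the binary dominance call into a continuous
coordinate along the Bacteroides–Prevotella gradient: 0 means all Bacteroides
and no Prevotella, 1 the reverse.  Samples where both genera are absent have
an undefined ratio, encoded as NaN and excluded (with a count) from quantile
curves.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import RELATIVE, AbundanceTable, ValidationError

logger = logging.getLogger(__name__)

LABEL_PREVOTELLA = "Prevotella"
LABEL_BACTEROIDES = "Bacteroides"
LABEL_OTHER = "Other"

#: Abundance bands used for per-taxon distribution summaries.  The interior
#: cuts (5 %, 10 %, 40 %, 80 %) are the natural break points for genera that
#: range from background members to sample-dominating blooms.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 0.05),
    (0.05, 0.10),
    (0.10, 0.40),
    (0.40, 0.80),
    (0.80, 1.0),
)


def classify_dominance(
    table: AbundanceTable,
    prevotella_name: str = "Prevotella",
    bacteroides_name: str = "Bacteroides",
) -> pd.DataFrame:
    """Label every sample by its most abundant taxon.

    Returns a DataFrame with columns ``sample_id, label, dominant_taxon,
    dominant_abundance``.  Ties are broken by lexicographic taxon order and
    logged.
    """
    if table.mode != RELATIVE:
        raise ValidationError("classify_dominance expects a relative-mode table")
    for name in (prevotella_name, bacteroides_name):
        if name not in table.data.index:
            raise ValidationError(f"key taxon {name!r} is not a row of the table")
    # sort taxa lexicographically so argmax resolves ties toward the first name
    ordered = table.data.sort_index(kind="stable")
    values = ordered.to_numpy(dtype=float)
    top = values.argmax(axis=0)
    maxima = values.max(axis=0)
    ties = (values == maxima[None, :]).sum(axis=0) > 1
    rows = []
    for j, sample in enumerate(ordered.columns):
        taxon = str(ordered.index[top[j]])
        if ties[j]:
            logger.warning("sample %r has tied dominant taxa; chose %r lexicographically", sample, taxon)
        if taxon == prevotella_name:
            label = LABEL_PREVOTELLA
        elif taxon == bacteroides_name:
            label = LABEL_BACTEROIDES
        else:
            label = LABEL_OTHER
        rows.append(
            {"sample_id": sample, "label": label, "dominant_taxon": taxon, "dominant_abundance": maxima[j]}
        )
    return pd.DataFrame(rows, columns=["sample_id", "label", "dominant_taxon", "dominant_abundance"])


def prevotella_ratio(
    table: AbundanceTable,
    prevotella_name: str = "Prevotella",
    bacteroides_name: str = "Bacteroides",
) -> pd.DataFrame:
    """Per-sample P/(P+B) with columns ``sample_id, ratio, p_abund, b_abund``.

    ``ratio`` is NaN when both abundances are zero (undefined, never coerced
    to 0).
    """
    if table.mode != RELATIVE:
        raise ValidationError("prevotella_ratio expects a relative-mode table")
    for name in (prevotella_name, bacteroides_name):
        if name not in table.data.index:
            raise ValidationError(f"key taxon {name!r} is not a row of the table")
    p = table.data.loc[prevotella_name].to_numpy(dtype=float)
    b = table.data.loc[bacteroides_name].to_numpy(dtype=float)
    total = p + b
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, p / np.where(total > 0, total, 1.0), np.nan)
    return pd.DataFrame(
        {"sample_id": table.samples, "ratio": ratio, "p_abund": p, "b_abund": b}
    )


def ratio_quantile_curves(
    ratios: pd.DataFrame, groups: Mapping[str, str] | None = None
) -> dict[str, pd.DataFrame]:
    """Sorted ratio values against their empirical quantiles, per group.

    Each group's defined ratios are sorted and paired with quantiles
    ``i/(n-1)`` (a single value sits at quantile 0).  Undefined ratios are
    dropped; the number dropped is logged.  An ``"all"`` curve over every
    sample is always included.
    """
    curves: dict[str, pd.DataFrame] = {}
    n_undefined = int(ratios["ratio"].isna().sum())
    if n_undefined:
        logger.info("excluding %d sample(s) with undefined Prevotella ratio", n_undefined)
    defined = ratios.dropna(subset=["ratio"])

    def _curve(values: np.ndarray) -> pd.DataFrame:
        values = np.sort(values)
        n = len(values)
        q = np.zeros(1) if n == 1 else np.arange(n) / (n - 1)
        return pd.DataFrame({"quantile": q, "ratio": values})

    if len(defined):
        curves["all"] = _curve(defined["ratio"].to_numpy())
    if groups is not None:
        group_series = defined["sample_id"].map(dict(groups))
        for name in pd.unique(group_series.dropna()):
            vals = defined.loc[group_series == name, "ratio"].to_numpy()
            if len(vals) == 0:
                logger.warning("group %r has no defined ratios; omitted", name)
                continue
            curves[str(name)] = _curve(vals)
    return curves


def taxon_summary(
    table: AbundanceTable,
    top_n: int = 20,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    prevalence_threshold: float = 0.01,
) -> pd.DataFrame:
    """Distribution summaries for the ``top_n`` taxa by mean relative abundance.

    Per taxon: mean, quartiles, prevalence (fraction of samples at or above
    ``prevalence_threshold``), and the fraction of samples falling in each
    abundance band.  Bands are half-open except the last, which includes 1.
    """
    if table.mode != RELATIVE:
        raise ValidationError("taxon_summary expects a relative-mode table")
    if top_n > table.n_taxa:
        logger.warning("top_n=%d exceeds the %d available taxa; returning all", top_n, table.n_taxa)
        top_n = table.n_taxa
    means = table.data.mean(axis=1).sort_values(ascending=False, kind="stable")
    rows = []
    last = len(bands) - 1
    for taxon in means.index[:top_n]:
        x = table.data.loc[taxon].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        row = {
            "taxon": taxon,
            "mean": float(np.mean(x)),
            "quartile1": float(q1),
            "median": float(med),
            "quartile3": float(q3),
            "prevalence": float(np.mean(x >= prevalence_threshold)),
        }
        for k, (lo, hi) in enumerate(bands):
            inside = (x >= lo) & ((x <= hi) if k == last else (x < hi))
            row[f"band[{lo:g},{hi:g}{']' if k == last else ')'}"] = float(np.mean(inside))
        rows.append(row)
    return pd.DataFrame(rows)
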