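"""Reading, validation, filtering and merging of genus-by-sample abundance tables.

Tables are stored taxa-by-samples.  Two value modes are supported:

* ``relative`` — proportions of a sample's total assigned reads.  Column sums
  are at most 1; they may be *below* 1 when taxa have been removed, because
  downstream diagnostics deliberately work on un-rescaled proportions.
* ``count`` — nonnegative integer read counts.

All operations are pure: input tables are never mutated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RELATIVE = "relative"
COUNT = "count"

#: Column order of the sample-metadata TSV.
METADATA_COLUMNS = ["sample_id", "study", "population", "age", "truth_label", "truth_gradient"]


class ValidationError(ValueError):
    """An abundance table or metadata frame violates its contract."""


@dataclass(frozen=True)
class AbundanceTable:
    """A taxon-by-sample abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with taxa as the index (unique genus names) and samples as
        columns (unique sample IDs).  Values are nonnegative reals.
    mode:
        ``"relative"`` or ``"count"``.
    """

    data: pd.DataFrame
    mode: str

    def __post_init__(self) -> None:
        validate_table(self.data, self.mode)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, mode: str | None = None) -> "AbundanceTable":
        return AbundanceTable(data=data, mode=self.mode if mode is None else mode)


def validate_table(data: pd.DataFrame, mode: str) -> None:
    if mode not in (RELATIVE, COUNT):
        raise ValidationError(f"unknown mode {mode!r}; expected 'relative' or 'count'")
    if data.index.duplicated().any():
        dupes = data.index[data.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate taxon names: {dupes}")
    if data.columns.duplicated().any():
        dupes = data.columns[data.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample IDs: {dupes}")
    values = data.to_numpy(dtype=float)
    if np.isnan(values).any():
        taxon, sample = _first_offender(data, np.isnan(values))
        raise ValidationError(f"missing value at taxon {taxon!r}, sample {sample!r}")
    if (values < 0).any():
        taxon, sample = _first_offender(data, values < 0)
        raise ValidationError(f"negative value at taxon {taxon!r}, sample {sample!r}")
    if mode == RELATIVE:
        sums = values.sum(axis=0)
        bad = np.nonzero(sums > 1.0 + 1e-9)[0]
        if bad.size:
            raise ValidationError(
                f"relative-mode column {data.columns[bad[0]]!r} sums to {sums[bad[0]]:.6g} > 1"
            )
    else:
        if not np.allclose(values, np.round(values)):
            taxon, sample = _first_offender(data, ~np.isclose(values, np.round(values)))
            raise ValidationError(f"non-integer count at taxon {taxon!r}, sample {sample!r}")


def _first_offender(data: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return str(data.index[i]), str(data.columns[j])


def read_abundance_table(path, mode: str = "auto") -> AbundanceTable:
    """Read a TSV with taxa as rows and samples as columns.

    The first column holds taxon names (header cell ``taxon``); remaining
    header cells are sample IDs.  ``mode="auto"`` infers ``count`` iff all
    values are integral and some column sum exceeds 1.5, otherwise
    ``relative``.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ValidationError(f"malformed TSV {path}: {exc}") from exc
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    frame.index.name = "taxon"
    if not np.issubdtype(frame.to_numpy().dtype, np.number):
        bad = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
        raise ValidationError(f"non-numeric values in column(s) {bad}")
    if mode == "auto":
        values = frame.to_numpy(dtype=float)
        integral = np.allclose(values, np.round(values))
        mode = COUNT if integral and (values.sum(axis=0) > 1.5).any() else RELATIVE
    return AbundanceTable(data=frame.astype(float), mode=mode)


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write the table as TSV (first header cell ``taxon``)."""
    frame = table.data.copy()
    frame.index.name = "taxon"
    if table.mode == COUNT:
        frame = frame.round().astype(np.int64)
        frame.to_csv(path, sep="\t")
    else:
        frame.to_csv(path, sep="\t", float_format="%.12g")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample_id, study, population, age, truth columns)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "study": str, "population": str})
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata is missing the sample_id column")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate metadata sample_id values: {dupes}")
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    return meta[METADATA_COLUMNS]


def write_metadata(meta: pd.DataFrame, path) -> None:
    cols = [c for c in METADATA_COLUMNS if c in meta.columns]
    meta[cols].to_csv(path, sep="\t", index=False, float_format="%.12g")


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Normalize each sample column to proportions.  Idempotent on relative tables."""
    sums = table.values.sum(axis=0)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValidationError(f"sample {table.samples[zero[0]]!r} has zero total abundance")
    return AbundanceTable(data=table.data.div(pd.Series(sums, index=table.data.columns), axis=1), mode=RELATIVE)


def filter_low_abundance_taxa(table: AbundanceTable, threshold: float = 1e-4) -> AbundanceTable:
    """Keep taxa whose maximum relative abundance over all samples is > ``threshold``.

    The default 1e-4 (0.01 %) is the conventional floor below which genus-level
    assignments are dominated by sequencing noise.  Retained values are NOT
    renormalized, so proportions keep their original meaning.
    """
    if threshold < 0 or threshold >= 1:
        raise ValueError(f"threshold must be in [0, 1); got {threshold}")
    rel = table if table.mode == RELATIVE else to_relative(table)
    keep = rel.data.max(axis=1) > threshold
    return AbundanceTable(data=table.data.loc[keep.to_numpy()].copy(), mode=table.mode)


def filter_samples(table: AbundanceTable, metadata: pd.DataFrame, min_age: float = 13) -> AbundanceTable:
    """Drop samples younger than ``min_age`` years; samples with unknown age are kept.

    Child guts are compositionally distinct (e.g. Bifidobacterium-dominated),
    so adult-only analyses exclude them rather than confound the comparison.
    """
    ages = metadata.set_index("sample_id")["age"] if "sample_id" in metadata.columns else metadata["age"]
    keep: list[str] = []
    for sample in table.samples:
        age = ages.get(sample, np.nan)
        if pd.isna(age):
            logger.warning("sample %r has no recorded age; retained", sample)
            keep.append(sample)
        elif age >= min_age:
            keep.append(sample)
    if not keep:
        logger.warning("age filter at %g years removed every sample", min_age)
    return AbundanceTable(data=table.data[keep].copy(), mode=table.mode)


def merge_studies(tables: Sequence[AbundanceTable], study_ids: Sequence[str]) -> tuple[AbundanceTable, pd.DataFrame]:
    """Merge per-study relative tables over the union of their taxa.

    Sample IDs are prefixed with ``<study>:``; taxa absent from a study are
    filled with zeros.  Returns the merged table and a sample→study metadata
    frame.
    """
    if len(tables) != len(study_ids):
        raise ValueError("tables and study_ids must have equal length")
    for t, sid in zip(tables, study_ids):
        if t.mode != RELATIVE:
            raise ValidationError(f"study {sid!r}: merge requires relative mode")
    frames = []
    meta_rows = []
    for t, sid in zip(tables, study_ids):
        renamed = t.data.copy()
        renamed.columns = [f"{sid}:{s}" for s in t.samples]
        frames.append(renamed)
        meta_rows.extend({"sample_id": c, "study": sid} for c in renamed.columns)
    all_samples = [c for f in frames for c in f.columns]
    if len(set(all_samples)) != len(all_samples):
        seen, dup = set(), None
        for s in all_samples:
            if s in seen:
                dup = s
                break
            seen.add(s)
        raise ValidationError(f"colliding sample ID after study prefixing: {dup!r}")
    merged = pd.concat(frames, axis=1).fillna(0.0)
    # keep first-seen taxon order rather than concat's sorted union
    taxon_order: list[str] = []
    for t in tables:
        taxon_order.extend(x for x in t.taxa if x not in set(taxon_order))
    merged = merged.loc[taxon_order]
    meta = pd.DataFrame(meta_rows)
    return AbundanceTable(data=merged, mode=RELATIVE), meta


def to_pseudocounts(table: AbundanceTable, depth: int = 10000) -> AbundanceTable:
    """Convert proportions to pseudo-counts at a fixed nominal depth.

    ``round(relative * depth)`` with round-half-to-even; the default depth of
    10,000 reads keeps every taxon at or above the 1e-4 abundance floor at a
    count of at least one.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive; got {depth}")
    if table.mode != RELATIVE:
        raise ValidationError("to_pseudocounts expects a relative-mode table")
    counts = np.round(table.values * depth)
    return AbundanceTable(data=pd.DataFrame(counts, index=table.data.index, columns=table.data.columns), mode=COUNT)
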