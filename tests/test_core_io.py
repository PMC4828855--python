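import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entgrad.core_io import (
    COUNT,
    RELATIVE,
    AbundanceTable,
    ValidationError,
    filter_low_abundance_taxa,
    filter_samples,
    merge_studies,
    read_abundance_table,
    read_metadata,
    to_pseudocounts,
    to_relative,
    write_abundance_table,
)
from .conftest import make_table


def _write_tsv(tmp_path, text, name="t.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTable:
    def test_mode_auto_infers_count_for_integer_columns(self, tmp_path):
        p = _write_tsv(tmp_path, "taxon\tS1\tS2\nA\t100\t500\nB\t300\t500\nC\t600\t1000\n")
        t = read_abundance_table(p, mode="auto")
        assert t.mode == COUNT
        assert t.values.sum(axis=0).tolist() == [1000.0, 2000.0]

    def test_mode_auto_infers_relative_for_unit_columns(self, tmp_path):
        p = _write_tsv(tmp_path, "taxon\tS1\tS2\nA\t0.4\t0.9\nB\t0.6\t0.1\n")
        assert read_abundance_table(p).mode == RELATIVE

    def test_negative_entry_rejected_with_cell_location(self, tmp_path):
        p = _write_tsv(tmp_path, "taxon\tS1\tS2\nA\t0.4\t0.2\nB\t-0.1\t0.1\n")
        with pytest.raises(ValidationError, match="'B'.*'S1'"):
            read_abundance_table(p)

    def test_duplicate_taxon_rejected(self, tmp_path):
        p = _write_tsv(tmp_path, "taxon\tS1\nA\t0.4\nA\t0.2\n")
        with pytest.raises(ValidationError, match="duplicate taxon"):
            read_abundance_table(p)

    def test_roundtrip_preserves_values(self, tmp_path, rng):
        vals = rng.dirichlet(np.ones(7), size=5).T
        t = make_table(vals)
        path = tmp_path / "rt.tsv"
        write_abundance_table(t, path)
        back = read_abundance_table(path)
        # writer emits 12 significant digits
        np.testing.assert_allclose(back.values, t.values, rtol=5e-12)
        assert back.taxa == t.taxa and back.samples == t.samples


class TestToRelative:
    def test_normalizes_columns(self):
        t = make_table([[10], [30], [60]], mode=COUNT)
        rel = to_relative(t)
        np.testing.assert_allclose(rel.values[:, 0], [0.1, 0.3, 0.6])
        assert rel.mode == RELATIVE

    def test_idempotent(self, small_relative):
        once = to_relative(small_relative)
        np.testing.assert_allclose(to_relative(once).values, once.values)

    def test_zero_column_rejected(self):
        t = make_table([[0.0, 0.5], [0.0, 0.5]], samples=["empty", "ok"])
        with pytest.raises(ValidationError, match="empty"):
            to_relative(t)


class TestAbundanceFilter:
    def test_threshold_is_strict(self):
        t = make_table([[0.00005, 0.00005], [0.99995, 0.99995]], taxa=["rare", "dominant"])
        kept = filter_low_abundance_taxa(t, threshold=1e-4)
        assert kept.taxa == ["dominant"]

    def test_values_not_renormalized(self):
        t = make_table([[0.00005, 0.00005], [0.5, 0.5], [0.49995, 0.49995]])
        kept = filter_low_abundance_taxa(t)
        assert kept.values.sum(axis=0) == pytest.approx([0.99995, 0.99995])

    def test_threshold_zero_keeps_all_nonzero(self):
        t = make_table([[0.0, 0.0], [1.0, 1.0]], taxa=["never", "always"])
        assert filter_low_abundance_taxa(t, threshold=0.0).taxa == ["always"]

    def test_invalid_threshold(self, small_relative):
        with pytest.raises(ValueError):
            filter_low_abundance_taxa(small_relative, threshold=1.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0.0, 0.5), min_size=2, max_size=2).map(sorted))
    def test_monotone_in_threshold(self, thresholds):
        lo, hi = thresholds
        vals = np.linspace(0, 0.9, 18).reshape(6, 3)
        t = make_table(vals / vals.sum(axis=0, keepdims=True))
        taxa_hi = set(filter_low_abundance_taxa(t, hi).taxa)
        taxa_lo = set(filter_low_abundance_taxa(t, lo).taxa)
        assert taxa_hi <= taxa_lo


class TestAgeFilter:
    @pytest.fixture
    def meta(self):
        return pd.DataFrame(
            {"sample_id": ["S0", "S1", "S2"], "study": "x", "population": "x",
             "age": [5.0, 13.0, 40.0], "truth_label": None, "truth_gradient": None}
        )

    def test_children_removed_boundary_kept(self, meta):
        t = make_table(np.full((2, 3), 0.5))
        kept = filter_samples(t, meta, min_age=13)
        assert kept.samples == ["S1", "S2"]

    def test_unknown_age_retained(self, meta):
        meta.loc[0, "age"] = np.nan
        t = make_table(np.full((2, 3), 0.5))
        assert filter_samples(t, meta).samples == ["S0", "S1", "S2"]

    def test_all_adult_unchanged(self, meta):
        meta["age"] = 30.0
        t = make_table(np.full((2, 3), 0.5))
        assert filter_samples(t, meta).samples == t.samples


class TestMergeStudies:
    def test_union_of_taxa_with_zero_fill(self):
        t1 = make_table([[0.6], [0.4]], taxa=["A", "B"], samples=["x"])
        t2 = make_table([[0.3], [0.7]], taxa=["B", "C"], samples=["y"])
        merged, meta = merge_studies([t1, t2], ["s1", "s2"])
        assert merged.taxa == ["A", "B", "C"]
        assert merged.samples == ["s1:x", "s2:y"]
        np.testing.assert_allclose(merged.data["s2:y"].to_numpy(), [0.0, 0.3, 0.7])
        assert meta.loc[meta.sample_id == "s2:y", "study"].item() == "s2"

    def test_sample_count_conserved(self, rng):
        t1 = make_table(rng.dirichlet(np.ones(4), 3).T)
        t2 = make_table(rng.dirichlet(np.ones(4), 4).T)
        merged, _ = merge_studies([t1, t2], ["a", "b"])
        assert merged.n_samples == 7

    def test_per_study_roundtrip(self, rng):
        t1 = make_table(rng.dirichlet(np.ones(3), 2).T, taxa=["A", "B", "C"])
        t2 = make_table(rng.dirichlet(np.ones(2), 2).T, taxa=["B", "D"])
        merged, meta = merge_studies([t1, t2], ["u", "v"])
        sub = merged.data[[c for c in merged.samples if c.startswith("u:")]]
        np.testing.assert_allclose(sub.loc[["A", "B", "C"]].to_numpy(), t1.values)
        np.testing.assert_allclose(sub.loc["D"].to_numpy(), 0.0)

    def test_collision_rejected(self):
        t = make_table([[1.0]], taxa=["A"], samples=["x"])
        with pytest.raises(ValidationError, match="colliding"):
            merge_studies([t, t], ["s", "s"])

    def test_count_mode_rejected(self):
        t = make_table([[3.0]], taxa=["A"], samples=["x"], mode=COUNT)
        with pytest.raises(ValidationError, match="relative"):
            merge_studies([t], ["s"])


class TestPseudocounts:
    @pytest.mark.parametrize(
        "rel,expected", [(0.0001, 1), (0.25, 2500), (0.00004, 0)]
    )
    def test_rounding(self, rel, expected):
        t = make_table([[rel], [1 - rel]])
        counts = to_pseudocounts(t, depth=10000)
        assert counts.values[0, 0] == expected
        assert counts.mode == COUNT

    def test_column_sum_within_rounding_bound(self, rng):
        depth, n_taxa = 10000, 37
        t = make_table(rng.dirichlet(np.ones(n_taxa) * 0.3, size=10).T)
        counts = to_pseudocounts(t, depth=depth)
        sums = counts.values.sum(axis=0)
        assert (np.abs(sums - depth) <= n_taxa / 2).all()

    def test_invalid_depth(self, small_relative):
        with pytest.raises(ValueError):
            to_pseudocounts(small_relative, depth=0)


def test_metadata_roundtrip(tmp_path):
    meta = pd.DataFrame(
        {"sample_id": ["a", "b"], "study": ["s1", "s1"], "population": ["p", "q"],
         "age": [20.0, np.nan], "truth_label": [pd.NA, pd.NA], "truth_gradient": [0.25, 0.75]}
    )
    path = tmp_path / "meta.tsv"
    from entgrad.core_io import write_metadata
    write_metadata(meta, path)
    back = read_metadata(path)
    assert back["sample_id"].tolist() == ["a", "b"]
    assert back["truth_gradient"].tolist() == [0.25, 0.75]
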