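import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entgrad.core_io import COUNT, ValidationError
from entgrad.stats import (
    SparccConfig,
    bh_adjust,
    cross_study_consistency,
    nb_two_group_test,
    phi_proportionality,
    significance_filter,
    sparcc,
    spearman_screen,
)
from .conftest import lognormal_counts, make_table


def bh_bruteforce(p):
    """Independent step-up oracle: sorted minima of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, min(1.0, m * p[order[rank - 1]] / rank))
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_ties(self):
        np.testing.assert_allclose(bh_adjust([0.5, 0.5]), [0.5, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_bruteforce_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)


class TestSpearmanScreen:
    def _gradient_table(self, rng, n=60):
        target = np.linspace(0.1, 0.5, n)
        up = 0.1 + 0.4 * (target - target.min()) / np.ptp(target)
        down = 0.6 - up
        rest = 1.0 - (target + up * 0.2 + down * 0.2)
        vals = np.vstack([target, up * 0.2, down * 0.2, rest])
        return make_table(vals, taxa=["Prevotella", "friend", "foe", "bulk"])

    def test_monotone_taxon_has_rho_one(self, rng):
        t = self._gradient_table(rng)
        res = spearman_screen(t, "Prevotella").set_index("taxon")
        assert res.loc["friend", "statistic"] == pytest.approx(1.0)
        assert res.loc["foe", "statistic"] == pytest.approx(-1.0)

    def test_constant_target_rejected(self):
        t = make_table(np.full((2, 5), 0.5), taxa=["Prevotella", "x"])
        with pytest.raises(ValidationError, match="constant"):
            spearman_screen(t, "Prevotella")

    def test_null_type_one_error_rate(self, rng):
        # independent taxa: raw p < 0.05 should occur for ~5% of taxa
        n, d = 500, 200
        vals = rng.lognormal(0, 1, size=(d, n))
        vals /= vals.sum(axis=0)
        t = make_table(vals, taxa=["Prevotella"] + [f"T{k}" for k in range(d - 1)])
        res = spearman_screen(t, "Prevotella")
        frac = (res["p_raw"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.03)


class TestSignificanceFilter:
    def _row(self, **kw):
        base = dict(taxon="t", target="Prevotella", method="spearman", statistic=0.6,
                    p_raw=0.01, p_adj=0.04, mean_abundance=0.05, prevalence=0.9,
                    stat_significant=True, bio_significant=True, study="combined")
        base.update(kw)
        return base

    def test_passing_row_retained(self):
        res = pd.DataFrame([self._row()])
        assert len(significance_filter(res)) == 1

    def test_negative_correlation_rejected(self):
        res = pd.DataFrame([self._row(statistic=-0.7, p_adj=0.001, stat_significant=False)])
        assert len(significance_filter(res)) == 0

    def test_low_abundance_rejected(self):
        res = pd.DataFrame([self._row(mean_abundance=0.005, bio_significant=False)])
        assert len(significance_filter(res)) == 0

    def test_boundary_values_pass(self, rng):
        # inclusive thresholds: p_adj = 0.05, mean = 0.02, prevalence = 0.75
        n = 40
        target = np.linspace(0.1, 0.5, n)
        noise = rng.normal(0, 0.001, n)
        taxon = 0.02 + 0.01 * (target - target.mean()) + noise
        taxon[: int(n * 0.25)] = 0.009  # below the prevalence-at threshold in 25%
        bulk = 1 - target - np.abs(taxon)
        t = make_table(np.vstack([target, np.abs(taxon), bulk]),
                       taxa=["Prevotella", "edge", "bulk"])
        res = spearman_screen(t, "Prevotella").set_index("taxon")
        assert res.loc["edge", "prevalence"] == pytest.approx(0.75)
        assert bool(res.loc["edge", "bio_significant"]) == (res.loc["edge", "mean_abundance"] >= 0.02)


class TestSparcc:
    def test_too_few_taxa_rejected(self):
        t = make_table(np.ones((3, 12)), mode=COUNT)
        with pytest.raises(ValidationError, match="4 taxa"):
            sparcc(t, SparccConfig(seed=0))

    def test_relative_mode_rejected(self, small_relative):
        with pytest.raises(ValidationError, match="count"):
            sparcc(small_relative, SparccConfig(seed=0))

    def test_compositional_scale_invariance(self):
        t = lognormal_counts(n_samples=200, n_taxa=20, seed=8)
        scaled = make_table(t.values * 4, taxa=t.taxa, samples=t.samples, mode=COUNT)
        r1 = sparcc(t, SparccConfig(seed=3)).to_numpy()
        r2 = sparcc(scaled, SparccConfig(seed=3)).to_numpy()
        iu = np.triu_indices(20, 1)
        assert np.nanmax(np.abs(r1[iu] - r2[iu])) < 0.05

    def test_deterministic_under_seed(self):
        t = lognormal_counts(n_samples=60, n_taxa=10, seed=9)
        r1 = sparcc(t, SparccConfig(seed=11, n_resamples=5))
        r2 = sparcc(t, SparccConfig(seed=11, n_resamples=5))
        pd.testing.assert_frame_equal(r1, r2)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SparccConfig(exclusion_threshold=1.5)


class TestPhi:
    def test_exact_proportionality_gives_zero(self, rng):
        x = np.exp(rng.normal(0, 1, 100))
        M = np.vstack([x, 2 * x, np.full(100, 50.0)])
        t = make_table(M / M.sum(axis=0), taxa=["x", "y", "ref"])
        phi, sym = phi_proportionality(t, seed=1)
        assert phi.loc["x", "y"] == pytest.approx(0.0, abs=1e-10)
        assert sym.loc["x", "y"] < 0.01  # flagged proportional

    def test_independent_equal_variance_near_two(self, rng):
        n = 500
        a, b = np.exp(rng.normal(0, 1, n)), np.exp(rng.normal(0, 1, n))
        M = np.vstack([a, b, np.full(n, 1000.0)])
        t = make_table(M / M.sum(axis=0), taxa=["a", "b", "ref"])
        phi, _ = phi_proportionality(t, seed=1)
        assert phi.loc["a", "b"] == pytest.approx(2.0, abs=0.3)

    def test_constant_taxon_flagged_undefined(self, rng):
        n = 50
        x = rng.uniform(0.1, 0.5, n)
        # c1 is constant in relative terms, so var(log c1) = 0
        t = make_table(np.vstack([x, np.full(n, 0.2), 0.8 - x]), taxa=["x", "c1", "rest"])
        phi, _ = phi_proportionality(t, seed=1)
        assert np.isnan(phi.loc["c1", "x"])

    def test_zero_replacement_seed_reproducible(self, rng):
        vals = rng.dirichlet(np.ones(5), size=30).T
        vals[vals < 0.05] = 0.0
        t = make_table(vals)
        p1, _ = phi_proportionality(t, seed=7)
        p2, _ = phi_proportionality(t, seed=7)
        pd.testing.assert_frame_equal(p1, p2)

    def test_scale_invariance_without_zeros(self, rng):
        vals = rng.dirichlet(np.ones(4) * 5, size=40).T
        t = make_table(vals)
        scaled = make_table(vals * 0.5)
        p1, _ = phi_proportionality(t, seed=1)
        p2, _ = phi_proportionality(scaled, seed=1)
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-10)


def nb_counts(mu, alpha, n, rng):
    r = 1 / alpha
    return rng.negative_binomial(r, r / (r + mu), n)


class TestNbTwoGroup:
    def _null_table(self, rng, d=40, na=50, nb=50):
        X = np.vstack([nb_counts(100, 0.1, na + nb, rng) for _ in range(d)])
        t = make_table(X, taxa=[f"T{k}" for k in range(d)],
                       samples=[f"s{i}" for i in range(na + nb)], mode=COUNT)
        groups = {f"s{i}": ("A" if i < na else "B") for i in range(na + nb)}
        return t, groups

    def test_type_one_error_rate(self, rng):
        t, groups = self._null_table(rng)
        res = nb_two_group_test(t, groups)
        assert (res["p_raw"] < 0.05).mean() == pytest.approx(0.05, abs=0.03)

    def test_planted_fold_change_detected(self, rng):
        t, groups = self._null_table(rng)
        X = t.values.copy()
        X[0, 50:] = nb_counts(400, 0.1, 50, rng)
        t2 = make_table(X, taxa=t.taxa, samples=t.samples, mode=COUNT)
        res = nb_two_group_test(t2, groups).set_index("taxon")
        assert res.loc["T0", "p_adj"] < 0.01
        assert res.loc["T0", "statistic"] == pytest.approx(2.0, abs=0.5)

    def test_all_zero_taxon_excluded(self, rng):
        t, groups = self._null_table(rng, d=10)
        X = t.values.copy()
        X[3] = 0
        t2 = make_table(X, taxa=t.taxa, samples=t.samples, mode=COUNT)
        res = nb_two_group_test(t2, groups).set_index("taxon")
        assert np.isnan(res.loc["T3", "statistic"]) and np.isnan(res.loc["T3", "p_raw"])

    def test_small_group_rejected(self, rng):
        t, groups = self._null_table(rng, d=5, na=2, nb=10)
        with pytest.raises(ValidationError, match="3 samples"):
            nb_two_group_test(t, groups)


class TestCrossStudyConsistency:
    def _res(self, taxa_significant):
        rows = []
        for taxon in ["A", "B", "C"]:
            sig = taxon in taxa_significant
            rows.append(dict(taxon=taxon, target="Prevotella", method="spearman",
                             statistic=0.5 if sig else -0.5, p_raw=0.01, p_adj=0.01,
                             mean_abundance=0.05, prevalence=0.9,
                             stat_significant=sig, bio_significant=True, study="s"))
        return pd.DataFrame(rows)

    def test_partial_consistency_listed(self):
        out = cross_study_consistency(
            {"s1": self._res({"A"}), "s2": self._res({"A"}), "s3": self._res({"B"}), "s4": self._res(set())}
        ).set_index("taxon")
        assert out.loc["A", "studies"] == ["s1", "s2"]
        assert not out.loc["A", "consistent"]

    def test_nowhere_significant_absent(self):
        out = cross_study_consistency({"s1": self._res(set()), "s2": self._res(set())})
        assert len(out) == 0

    def test_everywhere_significant_consistent(self):
        out = cross_study_consistency({"s1": self._res({"C"}), "s2": self._res({"C"})}).set_index("taxon")
        assert bool(out.loc["C", "consistent"])

    def test_single_study_rejected(self):
        with pytest.raises(ValidationError):
            cross_study_consistency({"s1": self._res(set())})
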