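"""Association screens between dominant taxa and the rest of the community.

Compositional (constant-sum) abundance data induce spurious negative
correlations, so four complementary screens are provided:

* rank (Spearman) correlation with Benjamini-Hochberg FDR control;
* SparCC — log-ratio-variance inference of basis correlations under a
  sparsity assumption, with Dirichlet resampling and permutation-bootstrap
  pseudo p-values;
* Lovell phi proportionality, ``var(log x - log y) / var(log x)``, with
  uniform zero replacement;
* a simplified negative-binomial two-group Wald test with median-of-ratios
  size factors and method-of-moments dispersions (a deliberately plain
  differential-abundance test, with no shrinkage or independent filtering).

A finding is *statistically* significant when positively associated at
BH-adjusted p <= 0.05 (or phi < 0.01), and *biologically* significant when
the taxon has mean abundance >= 0.02 and prevalence >= 0.75 (counted at
>= 0.01 relative abundance) — rare or sporadic taxa cannot define a
community even when their correlation is real.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import COUNT, RELATIVE, AbundanceTable, ValidationError

logger = logging.getLogger(__name__)

ASSOCIATION_COLUMNS = [
    "taxon", "target", "method", "statistic", "p_raw", "p_adj",
    "mean_abundance", "prevalence", "stat_significant", "bio_significant", "study",
]

#: Dual significance thresholds for the screens.
P_ADJ_MAX = 0.05
PHI_MAX = 0.01
MEAN_ABUNDANCE_MIN = 0.02
PREVALENCE_MIN = 0.75
PREVALENCE_AT = 0.01


@dataclass(frozen=True)
class SparccConfig:
    """Settings for the SparCC estimator (the cited tool's documented defaults)."""

    n_resamples: int = 20
    exclusion_threshold: float = 0.1
    max_exclusions: int = 10
    n_bootstrap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples <= 0 or self.max_exclusions < 0 or self.n_bootstrap < 0:
            raise ValueError("SparCC counts must be positive")
        if not 0 < self.exclusion_threshold < 1:
            raise ValueError("exclusion_threshold must be in (0, 1)")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _abundance_summaries(rel: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Mean relative abundance and prevalence-at-0.01 for every taxon row."""
    mean = rel.mean(axis=1)
    prevalence = (rel >= PREVALENCE_AT).mean(axis=1)
    return mean, prevalence


def spearman_screen(
    table: AbundanceTable,
    target_taxon: str,
    sample_subset: list[str] | None = None,
    study: str = "combined",
) -> pd.DataFrame:
    """Spearman rho of every other taxon against ``target_taxon`` over a subset.

    BH adjustment is applied across the screened taxa.  Returns an
    association table (one row per non-target taxon).
    """
    if table.mode != RELATIVE:
        raise ValidationError("spearman_screen expects a relative-mode table")
    if target_taxon not in table.data.index:
        raise ValidationError(f"target taxon {target_taxon!r} is not in the table")
    subset = table.samples if sample_subset is None else list(sample_subset)
    if not subset:
        raise ValidationError("sample subset is empty")
    rel = table.data[subset]
    target = rel.loc[target_taxon].to_numpy(dtype=float)
    if np.ptp(target) == 0:
        raise ValidationError(f"target taxon {target_taxon!r} is constant over the subset")
    mean, prevalence = _abundance_summaries(rel)
    rows = []
    for taxon in rel.index:
        if taxon == target_taxon:
            continue
        x = rel.loc[taxon].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rho, p = np.nan, np.nan
        else:
            rho, p = sps.spearmanr(x, target)
        rows.append({"taxon": taxon, "statistic": rho, "p_raw": p})
    res = pd.DataFrame(rows)
    valid = res["p_raw"].notna()
    res["p_adj"] = np.nan
    res.loc[valid, "p_adj"] = bh_adjust(res.loc[valid, "p_raw"].to_numpy())
    res["target"] = target_taxon
    res["method"] = "spearman"
    res["mean_abundance"] = res["taxon"].map(mean)
    res["prevalence"] = res["taxon"].map(prevalence)
    res["stat_significant"] = (res["statistic"] > 0) & (res["p_adj"] <= P_ADJ_MAX)
    res["bio_significant"] = (res["mean_abundance"] >= MEAN_ABUNDANCE_MIN) & (res["prevalence"] >= PREVALENCE_MIN)
    res["study"] = study
    return res[ASSOCIATION_COLUMNS]


# ---------------------------------------------------------------------------
# SparCC

def _log_ratio_variance(frac: np.ndarray) -> np.ndarray:
    """t_ij = var over samples of log(f_i / f_j); frac is taxa x samples."""
    logf = np.log(frac)
    v = np.var(logf, axis=1, ddof=1)
    cov = np.cov(logf, ddof=1)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(t: np.ndarray, exclusion_threshold: float, max_exclusions: int) -> np.ndarray:
    """Solve for basis variances/correlations, iteratively excluding strong pairs.

    The sparsity approximation assumes most pairs are uncorrelated; pairs with
    |rho| above the threshold are removed from the linear system and it is
    re-solved, at most ``max_exclusions`` times.
    """
    D = t.shape[0]
    if D < 4:
        raise ValidationError(f"SparCC needs at least 4 taxa; got {D}")
    M = np.ones((D, D)) + np.diag(np.full(D, D - 2.0))
    t_work = t.copy()
    excluded_pairs: set[tuple[int, int]] = set()
    excluded_comp: set[int] = set()

    def _solve() -> tuple[np.ndarray, np.ndarray]:
        omega = np.linalg.solve(M, t_work.sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = 2.0 * np.sqrt(np.outer(omega, omega))
            # rho always uses the original variation matrix; exclusions only
            # drop equations from the basis-variance system
            rho = (omega[:, None] + omega[None, :] - t) / denom
        bad = omega <= 0
        if bad.any():
            logger.warning("nonpositive basis variance for %d taxa; correlations set to NaN", int(bad.sum()))
            rho[bad, :] = np.nan
            rho[:, bad] = np.nan
        np.fill_diagonal(rho, 1.0)
        return omega, np.clip(rho, -1.0, 1.0)

    omega, rho = _solve()
    for _ in range(max_exclusions):
        cand = np.abs(rho.copy())
        np.fill_diagonal(cand, 0.0)
        for i, j in excluded_pairs:
            cand[i, j] = cand[j, i] = 0.0
        for c in excluded_comp:
            cand[c, :] = cand[:, c] = 0.0
        cand = np.nan_to_num(cand)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded_pairs.add((min(i, j), max(i, j)))
        t_work[i, j] = t_work[j, i] = 0.0
        M[i, j] = M[j, i] = 0.0
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        # a component excluded from nearly all pairs no longer constrains the system
        for c in (i, j):
            n_exc = sum(1 for a, b in excluded_pairs if c in (a, b))
            if n_exc >= D - 3:
                excluded_comp.add(c)
        omega, rho = _solve()
    for c in excluded_comp:
        rho[c, :] = np.nan
        rho[:, c] = np.nan
        rho[c, c] = 1.0
    return rho


def sparcc(counts: AbundanceTable, config: SparccConfig | None = None) -> pd.DataFrame:
    """Estimate basis (latent absolute-abundance) correlations from counts.

    Each resampling round draws per-sample taxon fractions from
    Dirichlet(counts + 1), computes the log-ratio variation matrix, and solves
    the sparsity-approximation linear system; the returned matrix is the
    elementwise median over rounds.
    """
    config = config or SparccConfig()
    if counts.mode != COUNT:
        raise ValidationError("sparcc expects a count-mode table (see to_pseudocounts)")
    if counts.n_taxa < 4:
        raise ValidationError(f"SparCC needs at least 4 taxa; got {counts.n_taxa}")
    if counts.n_samples < 10:
        raise ValidationError(f"SparCC needs at least 10 samples; got {counts.n_samples}")
    rng = np.random.default_rng(config.seed)
    X = counts.values  # taxa x samples
    rounds = []
    for _ in range(config.n_resamples):
        frac = np.empty_like(X, dtype=float)
        for s in range(X.shape[1]):
            frac[:, s] = rng.dirichlet(X[:, s] + 1.0)
        t = _log_ratio_variance(frac)
        rounds.append(_basis_correlations(t, config.exclusion_threshold, config.max_exclusions))
    rho = np.nanmedian(np.stack(rounds), axis=0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=counts.taxa, columns=counts.taxa)


def sparcc_pvalues(
    counts: AbundanceTable, observed: pd.DataFrame, config: SparccConfig | None = None
) -> pd.DataFrame:
    """Two-sided pseudo p-values for SparCC correlations.

    The null is built by permuting each taxon's counts across samples
    independently, which preserves marginals while destroying covariation;
    p = (1 + #{|rho*| >= |rho|}) / (n_bootstrap + 1).
    """
    config = config or SparccConfig()
    if config.n_bootstrap <= 0:
        raise ValueError("n_bootstrap must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**16 + 1]))
    X = counts.values
    obs = np.abs(observed.to_numpy(dtype=float))
    exceed = np.zeros_like(obs)
    boot_cfg = SparccConfig(
        n_resamples=config.n_resamples,
        exclusion_threshold=config.exclusion_threshold,
        max_exclusions=config.max_exclusions,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed,
    )
    for b in range(config.n_bootstrap):
        perm = np.empty_like(X)
        for i in range(X.shape[0]):
            perm[i] = X[i, rng.permutation(X.shape[1])]
        shuffled = AbundanceTable(
            data=pd.DataFrame(perm, index=counts.data.index, columns=counts.data.columns), mode=COUNT
        )
        null_cfg = SparccConfig(
            n_resamples=boot_cfg.n_resamples,
            exclusion_threshold=boot_cfg.exclusion_threshold,
            max_exclusions=boot_cfg.max_exclusions,
            n_bootstrap=boot_cfg.n_bootstrap,
            seed=int(rng.integers(2**31 - 1)),
        )
        rho_b = np.abs(sparcc(shuffled, null_cfg).to_numpy())
        exceed += np.where(np.isnan(rho_b) | np.isnan(obs), 0.0, rho_b >= obs)
    p = (exceed + 1.0) / (config.n_bootstrap + 1.0)
    np.fill_diagonal(p, np.nan)
    return pd.DataFrame(p, index=observed.index, columns=observed.columns)


# ---------------------------------------------------------------------------
# phi proportionality

def phi_proportionality(
    table: AbundanceTable, seed: int, zero_low: float = 1e-8, zero_high: float = 2e-8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lovell proportionality phi(x|y) = var(log x - log y) / var(log x).

    Zeros are replaced by Uniform(zero_low, zero_high) draws fixed by
    ``seed``.  Returns the full asymmetric matrix (rows = x, columns = y) and
    the min-symmetrized view min(phi(x|y), phi(y|x)).  Rows with
    var(log x) = 0 (constant taxon) are NaN.
    """
    if table.mode != RELATIVE:
        raise ValidationError("phi_proportionality expects a relative-mode table")
    rng = np.random.default_rng(seed)
    X = table.values.copy()
    zeros = X == 0
    if zeros.any():
        X[zeros] = rng.uniform(zero_low, zero_high, size=int(zeros.sum()))
    logX = np.log(X)
    v = np.var(logX, axis=1, ddof=1)
    cov = np.cov(logX, ddof=1)
    lrv = v[:, None] + v[None, :] - 2.0 * cov  # var(log x_i - log x_j)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = lrv / v[:, None]
    constant = v == 0
    if constant.any():
        logger.warning("%d taxa are constant; their phi rows are undefined", int(constant.sum()))
        phi[constant, :] = np.nan
    np.fill_diagonal(phi, 0.0)
    phi_df = pd.DataFrame(phi, index=table.taxa, columns=table.taxa)
    sym = np.fmin(phi, phi.T)
    sym_df = pd.DataFrame(sym, index=table.taxa, columns=table.taxa)
    return phi_df, sym_df


# ---------------------------------------------------------------------------
# simplified negative-binomial two-group test

def _size_factors(X: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference).

    Uses taxa with no zero counts; if none exist, falls back to taxa nonzero
    in at least 90% of samples (zeros excluded from their geometric means).
    """
    full = (X > 0).all(axis=1)
    if full.any():
        ref_rows = X[full]
        with np.errstate(divide="ignore"):
            logref = np.mean(np.log(ref_rows), axis=1)
        ratios = np.log(ref_rows) - logref[:, None]
        return np.exp(np.median(ratios, axis=0))
    near = (X > 0).mean(axis=1) >= 0.9
    if not near.any():
        raise ValidationError("no taxa sufficiently prevalent for size-factor estimation")
    rows = X[near].astype(float)
    logrows = np.where(rows > 0, np.log(rows), np.nan)
    logref = np.nanmean(logrows, axis=1)
    ratios = logrows - logref[:, None]
    return np.exp(np.nanmedian(ratios, axis=0))


def nb_two_group_test(counts: AbundanceTable, group_labels: dict[str, str]) -> pd.DataFrame:
    """Simplified negative-binomial Wald test for a two-group abundance shift.

    Counts are normalized by median-of-ratios size factors; per-taxon
    dispersion alpha comes from pooled method-of-moments
    (var = mu + alpha*mu^2), floored at 1e-8; the Wald statistic tests the
    log2 fold-change of group means with a delta-method standard error.
    No dispersion shrinkage or independent filtering is applied.
    """
    if counts.mode != COUNT:
        raise ValidationError("nb_two_group_test expects a count-mode table")
    groups = pd.Series({s: group_labels[s] for s in counts.samples if s in group_labels})
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValidationError(f"need exactly two groups; got {list(names)}")
    ga, gb = names
    idx_a = [s for s in counts.samples if groups.get(s) == ga]
    idx_b = [s for s in counts.samples if groups.get(s) == gb]
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValidationError("both groups need at least 3 samples")
    X = counts.data[idx_a + idx_b].to_numpy(dtype=float)
    if (X.sum(axis=0) == 0).any():
        raise ValidationError("a sample has zero total counts")
    sf = _size_factors(X)
    norm = X / sf[None, :]
    na, nb_ = len(idx_a), len(idx_b)
    A, B = norm[:, :na], norm[:, na:]
    rel = counts.data[idx_a + idx_b].div(counts.data[idx_a + idx_b].sum(axis=0), axis=1)
    mean_rel, prevalence = _abundance_summaries(rel)
    rows = []
    for i, taxon in enumerate(counts.taxa):
        a, b = A[i], B[i]
        mu_a, mu_b = a.mean(), b.mean()
        if mu_a == 0 and mu_b == 0:
            rows.append({"taxon": taxon, "statistic": np.nan, "p_raw": np.nan})
            continue
        # pooled method-of-moments dispersion on within-group residuals
        var_pool = (a.var(ddof=1) * (na - 1) + b.var(ddof=1) * (nb_ - 1)) / (na + nb_ - 2)
        mu_pool = (mu_a * na + mu_b * nb_) / (na + nb_)
        alpha = max((var_pool - mu_pool) / mu_pool**2, 1e-8) if mu_pool > 0 else 1e-8
        if mu_a == 0 or mu_b == 0:
            rows.append({"taxon": taxon, "statistic": np.inf if mu_b > mu_a else -np.inf, "p_raw": np.nan})
            continue
        lfc = np.log2(mu_b / mu_a)
        se_log = np.sqrt(
            (mu_a + alpha * mu_a**2) / (na * mu_a**2) + (mu_b + alpha * mu_b**2) / (nb_ * mu_b**2)
        ) / np.log(2)
        z = lfc / se_log
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"taxon": taxon, "statistic": lfc, "p_raw": p})
    res = pd.DataFrame(rows)
    valid = res["p_raw"].notna()
    res["p_adj"] = np.nan
    res.loc[valid, "p_adj"] = bh_adjust(res.loc[valid, "p_raw"].to_numpy())
    res["target"] = f"{gb}_vs_{ga}"
    res["method"] = "nb_wald"
    res["mean_abundance"] = res["taxon"].map(mean_rel)
    res["prevalence"] = res["taxon"].map(prevalence)
    res["stat_significant"] = (res["statistic"] > 0) & (res["p_adj"] <= P_ADJ_MAX)
    res["bio_significant"] = (res["mean_abundance"] >= MEAN_ABUNDANCE_MIN) & (res["prevalence"] >= PREVALENCE_MIN)
    res["study"] = "combined"
    return res[ASSOCIATION_COLUMNS]


def significance_filter(results: pd.DataFrame) -> pd.DataFrame:
    """Keep rows passing BOTH the statistical and the biological filter.

    Boundaries are inclusive: p_adj = 0.05, mean = 0.02 and prevalence = 0.75
    all pass.
    """
    mask = results["stat_significant"].fillna(False) & results["bio_significant"].fillna(False)
    return results.loc[mask.to_numpy()].reset_index(drop=True)


def phi_results(
    phi_sym: pd.DataFrame, table: AbundanceTable, target_taxon: str, study: str = "combined"
) -> pd.DataFrame:
    """Association table for phi proportionality against one target taxon."""
    if target_taxon not in phi_sym.index:
        raise ValidationError(f"target taxon {target_taxon!r} is not in the phi matrix")
    rel = table.data
    mean, prevalence = _abundance_summaries(rel)
    rows = []
    for taxon in phi_sym.index:
        if taxon == target_taxon:
            continue
        phi = phi_sym.loc[taxon, target_taxon]
        rows.append({"taxon": taxon, "statistic": phi, "p_raw": np.nan, "p_adj": np.nan})
    res = pd.DataFrame(rows)
    res["target"] = target_taxon
    res["method"] = "phi"
    res["mean_abundance"] = res["taxon"].map(mean)
    res["prevalence"] = res["taxon"].map(prevalence)
    res["stat_significant"] = res["statistic"] < PHI_MAX
    res["bio_significant"] = (res["mean_abundance"] >= MEAN_ABUNDANCE_MIN) & (res["prevalence"] >= PREVALENCE_MIN)
    res["study"] = study
    return res[ASSOCIATION_COLUMNS]


def cross_study_consistency(per_study_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Which taxa pass the significance filter in which studies.

    Returns one row per taxon significant anywhere, with the list of studies
    and a ``consistent`` flag set when the taxon is significant in every
    study.
    """
    if len(per_study_results) < 2:
        raise ValidationError("cross-study consistency needs at least 2 studies")
    hits: dict[str, list[str]] = {}
    for study, res in per_study_results.items():
        for taxon in significance_filter(res)["taxon"]:
            hits.setdefault(taxon, []).append(study)
    all_studies = set(per_study_results)
    rows = [
        {"taxon": t, "studies": sorted(s), "n_studies": len(s), "consistent": set(s) == all_studies}
        for t, s in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["taxon", "studies", "n_studies", "consistent"])
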