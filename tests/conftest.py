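import numpy as np
import pandas as pd
import pytest

from entgrad.core_io import COUNT, RELATIVE, AbundanceTable


def make_table(values, taxa=None, samples=None, mode=RELATIVE) -> AbundanceTable:
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"T{k}" for k in range(values.shape[0])]
    samples = samples or [f"S{k}" for k in range(values.shape[1])]
    return AbundanceTable(data=pd.DataFrame(values, index=taxa, columns=samples), mode=mode)


@pytest.fixture
def small_relative() -> AbundanceTable:
    """3 taxa x 4 samples, columns summing to 1."""
    return make_table(
        [[0.5, 0.2, 0.0, 0.3],
         [0.3, 0.7, 0.4, 0.3],
         [0.2, 0.1, 0.6, 0.4]],
        taxa=["Bacteroides", "Prevotella", "Faecalibacterium"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160412)


def lognormal_counts(n_samples=200, n_taxa=30, rho=None, depth=10000, seed=0) -> AbundanceTable:
    """Counts from independent log-normal basis abundances, optionally with one
    planted basis correlation between the first two taxa."""
    rng = np.random.default_rng(seed)
    mu = rng.uniform(0, 2, n_taxa)
    cov = np.eye(n_taxa)
    if rho is not None:
        cov[0, 1] = cov[1, 0] = rho
    logs = rng.multivariate_normal(mu, cov, size=n_samples)
    frac = np.exp(logs)
    frac /= frac.sum(axis=1, keepdims=True)
    counts = np.array([rng.multinomial(depth, f) for f in frac])
    return make_table(counts.T, taxa=[f"T{k:02d}" for k in range(n_taxa)],
                      samples=[f"S{k}" for k in range(n_samples)], mode=COUNT)
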