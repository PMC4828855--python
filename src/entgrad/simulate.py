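"""Synthetic genus-level community tables with known ground truth.

Two competing generative models are encoded, matching the two hypotheses the
diagnostics are built to distinguish:

* **Gradient model** (logistic-normal): each sample has a latent position
  ``g`` in [0, 1]; per-taxon log-means are ``base + g * effect`` with
  positive effect on Prevotella and negative on Bacteroides, so the two
  dominant genera see-saw along a continuum while the remaining genera form
  an exchangeable power-law tail.  Log-abundances get independent Gaussian
  noise, are softmax-normalized to a composition, and counts are drawn
  Multinomial(depth, composition).  Optional planted correlates tie a tail
  taxon log-linearly to a dominant taxon.

* **Discrete model** (Dirichlet-multinomial mixture): each sample belongs to
  one of a few components, each with its own Dirichlet mean composition — a
  dominant genus plus, optionally, a distinct set of secondary genera, i.e.
  a genuine community signature that survives removal of the dominant taxa.

Multi-study collections concatenate per-study simulations with study-level
log-composition offsets (a crude batch effect).

Defaults emulate adult gut genus tables: 50 genera, 10,000 reads per sample,
only Bacteroides and Prevotella routinely exceeding 40 % relative abundance,
and a Prevotella ratio spanning the full [0, 1] range with a substantial
intermediate fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import COUNT, AbundanceTable

#: Realistic gut genus names for the head of the default inventory; the
#: remainder are filled with numbered placeholders.
_GUT_GENERA = [
    "Bacteroides", "Prevotella", "Faecalibacterium", "Lachnospiraceae", "Roseburia",
    "Ruminococcus", "Alistipes", "Coprococcus", "Blautia", "Dorea",
    "Oscillospira", "Dialister", "Parabacteroides", "Streptococcus", "Bifidobacterium",
    "Akkermansia", "Subdoligranulum", "Succinivibrio", "Eubacterium", "Clostridium",
]


def default_taxa(n_taxa: int = 50) -> list[str]:
    """The default genus inventory: named gut genera then numbered fillers."""
    if n_taxa < 10:
        raise ValueError("need at least 10 taxa")
    taxa = list(_GUT_GENERA[:n_taxa])
    taxa += [f"Genus{k:03d}" for k in range(len(taxa) + 1, n_taxa + 1)]
    return taxa


@dataclass(frozen=True)
class PlantedCorrelate:
    """A tail taxon tied log-linearly to a dominant taxon before softmax."""

    taxon: str
    target: str
    slope: float = 1.0
    noise_sd: float = 0.3
    intercept: float = -2.3


@dataclass(frozen=True)
class GradientModelConfig:
    n_samples: int = 200
    n_taxa: int = 50
    depth: int = 10000
    latent: tuple = ("uniform",)  # or ("beta", a, b)
    base_log_means: np.ndarray | None = None
    gradient_effect: np.ndarray | None = None
    noise_sd: np.ndarray | float = 0.5
    planted_correlates: tuple[PlantedCorrelate, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 10:
            raise ValueError("n_taxa must be at least 10")
        if self.depth < 100:
            raise ValueError("depth must be at least 100")


def _default_base_and_effect(taxa: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Power-law tail plus see-sawing dominants.

    At the gradient endpoints the favoured dominant sits ~e^3.7 above the
    largest tail genus; at mid-gradient both dominants are comparable to the
    tail head, so 'Other'-dominated samples occur there, as in real data.
    """
    n = len(taxa)
    base = np.empty(n)
    effect = np.zeros(n)
    rank = 0
    for k, taxon in enumerate(taxa):
        if taxon == "Bacteroides":
            base[k] = 3.7
            effect[k] = -3.0
        elif taxon == "Prevotella":
            base[k] = 0.7
            effect[k] = +3.0
        else:
            base[k] = 1.6 - 1.9 * np.log1p(rank)
            rank += 1
    return base, effect


def _draw_latent(config: GradientModelConfig, rng: np.random.Generator) -> np.ndarray:
    kind = config.latent[0]
    if kind == "uniform":
        return rng.uniform(0.0, 1.0, config.n_samples)
    if kind == "beta":
        _, a, b = config.latent
        return rng.beta(a, b, config.n_samples)
    raise ValueError(f"unknown latent distribution {config.latent!r}")


def simulate_gradient(config: GradientModelConfig) -> tuple[AbundanceTable, pd.DataFrame]:
    """Draw a count table plus metadata carrying the latent gradient."""
    rng = np.random.default_rng(config.seed)
    taxa = default_taxa(config.n_taxa)
    base, effect = _default_base_and_effect(taxa)
    if config.base_log_means is not None:
        base = np.asarray(config.base_log_means, dtype=float)
    if config.gradient_effect is not None:
        effect = np.asarray(config.gradient_effect, dtype=float)
    if base.shape != (config.n_taxa,) or effect.shape != (config.n_taxa,):
        raise ValueError("base_log_means and gradient_effect must have length n_taxa")
    noise_sd = np.broadcast_to(np.asarray(config.noise_sd, dtype=float), (config.n_taxa,))
    g = _draw_latent(config, rng)
    logits = base[None, :] + g[:, None] * effect[None, :]
    logits = logits + rng.normal(0.0, noise_sd, size=(config.n_samples, config.n_taxa))
    comp = _softmax(logits)
    if config.planted_correlates:
        index = {t: k for k, t in enumerate(taxa)}
        for pc in config.planted_correlates:
            if pc.taxon not in index or pc.target not in index:
                raise ValueError(f"planted correlate names unknown taxa: {pc}")
            # tie the correlate to the target's pre-softmax log weight: after
            # closure the pair's relative abundances stay log-linearly related
            # (planting on the post-closure composition would be cancelled by
            # the shared normalizer)
            tgt_logit = logits[:, index[pc.target]]
            logits[:, index[pc.taxon]] = (
                pc.intercept
                + pc.slope * tgt_logit
                + rng.normal(0.0, pc.noise_sd, config.n_samples)
            )
        comp = _softmax(logits)
    counts = np.empty((config.n_samples, config.n_taxa), dtype=np.int64)
    for s in range(config.n_samples):
        counts[s] = rng.multinomial(config.depth, comp[s])
    table = AbundanceTable(
        data=pd.DataFrame(counts.T, index=taxa, columns=[f"S{k:04d}" for k in range(config.n_samples)]),
        mode=COUNT,
    )
    meta = pd.DataFrame(
        {
            "sample_id": table.samples,
            "study": "synthetic",
            "population": "synthetic",
            "age": np.nan,
            "truth_label": pd.NA,
            "truth_gradient": g,
        }
    )
    return table, meta


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class DiscreteModelConfig:
    n_samples: int = 200
    n_taxa: int = 50
    n_components: int = 3
    mixture_weights: tuple[float, ...] = (0.45, 0.35, 0.20)
    component_alphas: np.ndarray | None = None
    concentration: float = 50.0
    secondary_structure: bool = True
    depth: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if len(w) != self.n_components or not np.isclose(w.sum(), 1.0) or (w < 0).any():
            raise ValueError("mixture_weights must be a simplex vector of length n_components")
        if self.depth < 100:
            raise ValueError("depth must be at least 100")


#: Dominant and (distinct) secondary genera for the three default components.
_DEFAULT_COMPONENTS = [
    ("Bacteroides", ["Alistipes", "Blautia", "Dorea"]),
    ("Prevotella", ["Succinivibrio", "Streptococcus", "Dialister"]),
    ("Faecalibacterium", ["Roseburia", "Coprococcus", "Oscillospira"]),
]


def default_component_alphas(config: DiscreteModelConfig) -> np.ndarray:
    """Dirichlet parameters for well-separated components.

    Each component's mean composition puts 0.35 on its dominant genus and,
    with ``secondary_structure``, 0.08 on each of three component-specific
    secondary genera; the rest follows the shared power-law tail.  Alphas are
    the mean scaled by ``concentration``.
    """
    taxa = default_taxa(config.n_taxa)
    if config.n_components > len(_DEFAULT_COMPONENTS):
        raise ValueError("default alphas support at most 3 components; pass component_alphas")
    tail = np.exp(-0.35 * np.arange(config.n_taxa))
    alphas = np.empty((config.n_components, config.n_taxa))
    all_dominants = [d for d, _ in _DEFAULT_COMPONENTS]
    for c in range(config.n_components):
        dominant, secondary = _DEFAULT_COMPONENTS[c]
        mean = np.zeros(config.n_taxa)
        # off-component dominants are nearly absent: real dominance groups are
        # close to mutually exclusive in the genera that define them
        special = {taxa.index(d): 0.004 for d in all_dominants}
        special[taxa.index(dominant)] = 0.35
        if config.secondary_structure:
            for s in secondary:
                special[taxa.index(s)] = 0.08
        remainder = 1.0 - sum(special.values())
        tail_mask = np.ones(config.n_taxa, dtype=bool)
        for idx in special:
            tail_mask[idx] = False
        mean[tail_mask] = remainder * tail[tail_mask] / tail[tail_mask].sum()
        for idx, val in special.items():
            mean[idx] = val
        alphas[c] = np.maximum(mean * config.concentration, 1e-3)
    return alphas


def simulate_discrete(config: DiscreteModelConfig) -> tuple[AbundanceTable, pd.DataFrame]:
    """Draw a Dirichlet-multinomial mixture table plus component labels."""
    rng = np.random.default_rng(config.seed)
    taxa = default_taxa(config.n_taxa)
    alphas = config.component_alphas
    if alphas is None:
        alphas = default_component_alphas(config)
    alphas = np.asarray(alphas, dtype=float)
    if alphas.shape != (config.n_components, config.n_taxa) or (alphas <= 0).any():
        raise ValueError("component_alphas must be positive with shape (n_components, n_taxa)")
    comps = rng.choice(config.n_components, size=config.n_samples, p=np.asarray(config.mixture_weights))
    counts = np.empty((config.n_samples, config.n_taxa), dtype=np.int64)
    for s in range(config.n_samples):
        composition = rng.dirichlet(alphas[comps[s]])
        counts[s] = rng.multinomial(config.depth, composition)
    table = AbundanceTable(
        data=pd.DataFrame(counts.T, index=taxa, columns=[f"S{k:04d}" for k in range(config.n_samples)]),
        mode=COUNT,
    )
    meta = pd.DataFrame(
        {
            "sample_id": table.samples,
            "study": "synthetic",
            "population": "synthetic",
            "age": np.nan,
            "truth_label": [f"component{c + 1}" for c in comps],
            "truth_gradient": np.nan,
        }
    )
    return table, meta


@dataclass(frozen=True)
class MultiStudyConfig:
    """Per-study simulations sharing one taxon inventory, with batch offsets."""

    studies: tuple[tuple[str, GradientModelConfig | DiscreteModelConfig, np.ndarray | None], ...]

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("at least one study required")
        n_taxa = {cfg.n_taxa for _, cfg, _ in self.studies}
        if len(n_taxa) != 1:
            raise ValueError("all studies must share the taxon inventory (same n_taxa)")


def simulate_multistudy(config: MultiStudyConfig) -> tuple[AbundanceTable, pd.DataFrame]:
    """Concatenate per-study tables, applying per-study log-composition offsets.

    An offset vector o shifts a study's compositions as
    ``p_i proportional to p_i * exp(o_i)`` before counts are drawn, emulating
    protocol- or population-level shifts shared by all samples of a study.
    """
    tables, metas = [], []
    for study_id, cfg, offset in config.studies:
        if isinstance(cfg, GradientModelConfig):
            table, meta = simulate_gradient(cfg)
        else:
            table, meta = simulate_discrete(cfg)
        if offset is not None:
            offset = np.asarray(offset, dtype=float)
            if offset.shape != (cfg.n_taxa,) or not np.isfinite(offset).all():
                raise ValueError(f"study {study_id!r}: offset must be finite with length n_taxa")
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7**5]))
            comp = table.values / table.values.sum(axis=0, keepdims=True)
            comp = comp * np.exp(offset)[:, None]
            comp = comp / comp.sum(axis=0, keepdims=True)
            counts = np.empty_like(table.values, dtype=np.int64)
            for s in range(table.n_samples):
                counts[:, s] = rng.multinomial(cfg.depth, comp[:, s])
            table = AbundanceTable(
                data=pd.DataFrame(counts, index=table.taxa, columns=table.samples), mode=COUNT
            )
        renamed = table.data.copy()
        renamed.columns = [f"{study_id}:{s}" for s in table.samples]
        tables.append(renamed)
        meta = meta.copy()
        meta["sample_id"] = renamed.columns
        meta["study"] = study_id
        meta["population"] = study_id
        metas.append(meta)
    all_cols = [c for t in tables for c in t.columns]
    if len(set(all_cols)) != len(all_cols):
        raise ValueError("colliding sample IDs after study prefixing")
    merged = pd.concat(tables, axis=1)
    return AbundanceTable(data=merged, mode=COUNT), pd.concat(metas, ignore_index=True)
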