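"""End-to-end orchestration: config, stage ordering, reports and plots.

``run_pipeline`` executes the stages in the order the analysis requires —
read/simulate and filter, classify dominance on the FULL table, ordinate,
run the dominant-taxon removal diagnostic (labels held fixed), then the
association screens — and writes a reproducible bundle: TSV/JSON outputs, a
``run.json`` manifest with every threshold and seed actually applied plus
file checksums, and best-effort plots.  TSV/JSON outputs are byte-identical
across runs with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import classify_dominance, prevotella_ratio, ratio_quantile_curves, taxon_summary
from .core_io import (
    COUNT,
    RELATIVE,
    AbundanceTable,
    ValidationError,
    filter_low_abundance_taxa,
    filter_samples,
    read_abundance_table,
    read_metadata,
    to_pseudocounts,
    to_relative,
    write_abundance_table,
    write_metadata,
)
from .diagnostics import dominance_removal_diagnostic, fit_group_ellipses
from .ordination import ordinate
from .simulate import (
    DiscreteModelConfig,
    GradientModelConfig,
    PlantedCorrelate,
    simulate_discrete,
    simulate_gradient,
)
from .stats import (
    MEAN_ABUNDANCE_MIN,
    P_ADJ_MAX,
    PHI_MAX,
    PREVALENCE_AT,
    PREVALENCE_MIN,
    SparccConfig,
    cross_study_consistency,
    nb_two_group_test,
    phi_proportionality,
    phi_results,
    significance_filter,
    sparcc,
    sparcc_pvalues,
    spearman_screen,
)

logger = logging.getLogger(__name__)

KEY_TAXA = ("Prevotella", "Bacteroides")
VALID_SCREENS = ("spearman", "phi", "sparcc", "nb")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; exactly one of ``table_path`` / ``synthetic``."""

    table_path: str | None = None
    metadata_path: str | None = None
    synthetic: dict | None = None
    metric: str = "bray_curtis"
    method: str = "pcoa"
    remove_taxa: tuple[str, ...] = KEY_TAXA
    screens: tuple[str, ...] = ("spearman", "phi")
    min_age: float = 13.0
    abundance_threshold: float = 1e-4
    pseudocount_depth: int = 10000
    n_sd: float = 2.0
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if (self.table_path is None) == (self.synthetic is None):
            raise ValueError("config needs exactly one input source: table_path or synthetic")
        unknown = set(self.screens) - set(VALID_SCREENS)
        if unknown:
            raise ValueError(f"unknown screens {sorted(unknown)}; valid: {VALID_SCREENS}")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if seed is not None:
            raw["seed"] = seed
        for key in ("remove_taxa", "screens"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
            elif key in raw:
                raw[key] = ()
        return cls(**raw)


def build_synthetic(params: dict, seed: int):
    """Instantiate and run a generator described by a config mapping."""
    params = dict(params)
    model = params.pop("model", "gradient")
    params.setdefault("seed", seed)
    if model == "gradient":
        planted = tuple(PlantedCorrelate(**p) for p in params.pop("planted_correlates", []))
        if "latent" in params:
            params["latent"] = tuple(params["latent"])
        cfg = GradientModelConfig(planted_correlates=planted, **params)
        return simulate_gradient(cfg)
    if model == "discrete":
        if "mixture_weights" in params:
            params["mixture_weights"] = tuple(params["mixture_weights"])
        cfg = DiscreteModelConfig(**params)
        return simulate_discrete(cfg)
    raise ValueError(f"unknown synthetic model {model!r}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@_stage("load")
def _load(config: PipelineConfig) -> tuple[AbundanceTable, pd.DataFrame | None]:
    if config.synthetic is not None:
        return build_synthetic(config.synthetic, config.seed)
    table = read_abundance_table(config.table_path)
    meta = read_metadata(config.metadata_path) if config.metadata_path else None
    return table, meta


def _run_screens(
    config: PipelineConfig,
    rel: AbundanceTable,
    counts: AbundanceTable,
    labels: pd.DataFrame,
    meta: pd.DataFrame | None,
    outdir: Path,
) -> dict[str, str]:
    """Per-target association screens over dominated subsets; TSV outputs."""
    files: dict[str, str] = {}
    lab = labels.set_index("sample_id")["label"]
    subsets = {
        "Prevotella": lab.index[lab == "Prevotella"].tolist(),
        "Bacteroides": lab.index[lab == "Bacteroides"].tolist(),
    }
    studies: dict[str, list[str]] = {}
    if meta is not None and meta["study"].nunique() > 1:
        for study, grp in meta.groupby("study"):
            studies[str(study)] = grp["sample_id"].tolist()

    def _emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"associations_{name}.tsv"
        _write_tsv(frame, path)
        files[path.name] = _sha256(path)

    per_study_spearman: dict[str, dict[str, pd.DataFrame]] = {}
    for screen in config.screens:
        if screen == "spearman":
            for target, subset in subsets.items():
                if len(subset) < 3:
                    logger.warning("skipping Spearman screen for %s: only %d samples", target, len(subset))
                    continue
                res = spearman_screen(rel, target, subset)
                _emit(f"spearman_{target}_combined", res)
                for study, members in studies.items():
                    both = [s for s in subset if s in set(members)]
                    if len(both) < 3:
                        continue
                    study_res = spearman_screen(rel, target, both, study=study)
                    _emit(f"spearman_{target}_{study}", study_res)
                    per_study_spearman.setdefault(target, {})[study] = study_res
        elif screen == "phi":
            _, sym = phi_proportionality(rel, seed=config.seed)
            for target in KEY_TAXA:
                if target in sym.index:
                    _emit(f"phi_{target}_combined", phi_results(sym, rel, target))
        elif screen == "sparcc":
            cfg = SparccConfig(seed=config.seed)
            rho = sparcc(counts, cfg)
            pvals = sparcc_pvalues(counts, rho, cfg)
            path = outdir / "sparcc_correlations.tsv"
            _write_tsv(rho.round(10), path, index=True)
            files[path.name] = _sha256(path)
            path = outdir / "sparcc_pvalues.tsv"
            _write_tsv(pvals.round(10), path, index=True)
            files[path.name] = _sha256(path)
        elif screen == "nb":
            groups = {s: l for s, l in lab.items() if l in ("Prevotella", "Bacteroides")}
            counts_sub = AbundanceTable(data=counts.data[list(groups)], mode=COUNT)
            res = nb_two_group_test(counts_sub, groups)
            _emit("nb_Prevotella_vs_Bacteroides_combined", res)
    for target, per_study in per_study_spearman.items():
        if len(per_study) >= 2:
            consistency = cross_study_consistency(per_study)
            consistency = consistency.assign(studies=consistency["studies"].map(",".join))
            path = outdir / f"cross_study_consistency_{target}.tsv"
            _write_tsv(consistency, path)
            files[path.name] = _sha256(path)
    return files


def _make_plots(rel, labels, ratios, ordination, curves, summary, meta, outdir: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    coords = ordination.coords_frame()
    palette = {"Bacteroides": "tab:red", "Prevotella": "tab:blue", "Other": "tab:gray"}

    fig, ax = plt.subplots(figsize=(6, 5))
    lab = labels.set_index("sample_id")["label"]
    for group, color in palette.items():
        pts = coords.loc[lab.index[lab == group].intersection(coords.index)]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=12, c=color, label=group)
    ax.legend()
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    fig.savefig(outdir / "ordination_dominance.png", dpi=120)
    plt.close(fig)
    made.append("ordination_dominance.png")

    fig, ax = plt.subplots(figsize=(6, 5))
    r = ratios.set_index("sample_id").loc[coords.index, "ratio"]
    sc = ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=12, c=r, cmap="rainbow")
    fig.colorbar(sc, label="Prevotella ratio")
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    fig.savefig(outdir / "ordination_ratio.png", dpi=120)
    plt.close(fig)
    made.append("ordination_ratio.png")

    if meta is not None and meta["population"].notna().any():
        fig, ax = plt.subplots(figsize=(6, 5))
        pops = meta.set_index("sample_id")["population"].reindex(coords.index)
        for pop in pd.unique(pops.dropna()):
            pts = coords.loc[pops.index[pops == pop]]
            ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=12, label=str(pop))
        ax.legend(fontsize=7)
        fig.savefig(outdir / "ordination_population.png", dpi=120)
        plt.close(fig)
        made.append("ordination_population.png")

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, curve in curves.items():
        style = {"lw": 2, "c": "black"} if group == "all" else {"lw": 1}
        ax.plot(curve["quantile"], curve["ratio"], label=group, **style)
    ax.set_xlabel("quantile")
    ax.set_ylabel("Prevotella ratio")
    ax.legend(fontsize=7)
    fig.savefig(outdir / "ratio_quantile_curves.png", dpi=120)
    plt.close(fig)
    made.append("ratio_quantile_curves.png")

    fig, ax = plt.subplots(figsize=(8, 4))
    top = summary["taxon"].tolist()
    ax.boxplot([rel.data.loc[t].to_numpy() for t in top], tick_labels=top)
    ax.set_ylabel("relative abundance")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "abundance_boxplot.png", dpi=120)
    plt.close(fig)
    made.append("abundance_boxplot.png")
    return made


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all configured stages and write the report bundle to ``outdir``.

    Returns the manifest dict (also written as ``run.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    table, meta = _load(config)
    if meta is not None and meta["age"].notna().any():
        table = filter_samples(table, meta, min_age=config.min_age)
    rel = to_relative(table) if table.mode == COUNT else table
    rel = filter_low_abundance_taxa(rel, threshold=config.abundance_threshold)
    counts = table if table.mode == COUNT else to_pseudocounts(rel, depth=config.pseudocount_depth)
    counts = AbundanceTable(data=counts.data.loc[rel.taxa, rel.samples], mode=COUNT)

    try:
        labels = classify_dominance(rel)
        ratios = prevotella_ratio(rel)
        groups = None
        if meta is not None and meta["population"].notna().any():
            groups = meta.set_index("sample_id")["population"].to_dict()
        curves = ratio_quantile_curves(ratios, groups)
        summary = taxon_summary(rel)
    except Exception as exc:
        raise PipelineError(f"stage 'classify' failed: {exc}") from exc
    _write_tsv(labels.merge(ratios[["sample_id", "ratio"]], on="sample_id"), outdir / "dominance_labels.tsv")
    curve_frames = [c.assign(group=g) for g, c in curves.items()]
    _write_tsv(pd.concat(curve_frames, ignore_index=True), outdir / "ratio_quantile_curves.tsv")
    _write_tsv(summary, outdir / "taxon_summary_top20.tsv")

    try:
        ordination = ordinate(rel, metric=config.metric, method=config.method, seed=config.seed)
    except Exception as exc:
        raise PipelineError(f"stage 'ordination' failed: {exc}") from exc
    coords = ordination.coords_frame()
    coords.index.name = "sample_id"
    _write_tsv(coords, outdir / "ordination_coords.tsv", index=True)
    sidecar = {
        "method": ordination.method,
        "metric": config.metric,
        "varexp": None if ordination.varexp is None else [float(v) for v in ordination.varexp],
        "eigenvalues": None if ordination.eigenvalues is None else [float(v) for v in ordination.eigenvalues],
        "stress": ordination.stress,
        "seed": config.seed,
    }
    (outdir / "ordination.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    try:
        removable = [t for t in config.remove_taxa if t in rel.data.index]
        report = dominance_removal_diagnostic(rel, labels, metric=config.metric, taxa=removable, n_sd=config.n_sd)
        (outdir / "removal_diagnostic.json").write_text(report.to_json())
        ellipses = fit_group_ellipses(ordination, labels, n_sd=config.n_sd)
        (outdir / "ellipses.json").write_text(
            json.dumps([e.to_dict() for e in ellipses], indent=2, sort_keys=True)
        )
    except Exception as exc:
        raise PipelineError(f"stage 'diagnostics' failed: {exc}") from exc

    files.update(_run_screens(config, rel, counts, labels, meta, outdir))

    for name in (
        "dominance_labels.tsv", "ratio_quantile_curves.tsv", "taxon_summary_top20.tsv",
        "ordination_coords.tsv", "ordination.json", "removal_diagnostic.json", "ellipses.json",
    ):
        files[name] = _sha256(outdir / name)

    if config.make_plots:
        try:
            _make_plots(rel, labels, ratios, ordination, curves, summary, meta, outdir)
        except Exception as exc:  # plots are best-effort
            logger.warning("plotting failed (%s); bundle is still valid", exc)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "metric": config.metric,
        "method": config.method,
        "screens": list(config.screens),
        "removed_taxa": list(config.remove_taxa),
        "thresholds": {
            "abundance_filter": config.abundance_threshold,
            "min_age": config.min_age,
            "p_adj_max": P_ADJ_MAX,
            "phi_max": PHI_MAX,
            "mean_abundance_min": MEAN_ABUNDANCE_MIN,
            "prevalence_min": PREVALENCE_MIN,
            "prevalence_at": PREVALENCE_AT,
            "n_sd": config.n_sd,
            "pseudocount_depth": config.pseudocount_depth,
        },
        "n_samples": rel.n_samples,
        "n_taxa": rel.n_taxa,
        "files": dict(sorted(files.items())),
    }
    (outdir / "run.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
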