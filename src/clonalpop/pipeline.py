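"""Config-driven end-to-end run: simulate or load genotypes, filter, screen
heterozygosity, call clonal groups, ordinate, fit admixture across a K
grid, classify groups/subgroups, and compute per-population statistics.

Every stage writes its table(s) into the output directory; ``report.md``
is regenerated from those files, so re-running with the same config (and
seed) reproduces byte-identical outputs.  Wall times live only in the
in-memory :class:`RunReport`, never in checksummed files.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import admixture, classify, clonality, popgen, structure
from .genotype import (FilterConfig, GenotypeMatrix, apply_filters,
                       heterozygosity_screen, read_vcf, write_vcf)
from .simulate import PRESETS, SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One end-to-end run.  Exactly one of ``vcf`` / ``preset`` / ``sim`` is set."""

    out_dir: str | Path
    vcf: str | Path | None = None
    metadata: str | Path | None = None   # sample CSV merged into a VCF input
    preset: str | None = None
    sim: SimulationConfig | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    clonality_cfg: clonality.ClonalityConfig | None = None   # None = calibrate
    classification: classify.ClassificationConfig = field(
        default_factory=classify.ClassificationConfig)
    K_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_sites: int = 5000
    seed: int = 0
    em_starts: int = 4
    cv_folds: int = 3
    make_plots: bool = False

    def __post_init__(self) -> None:
        sources = sum(x is not None for x in (self.vcf, self.preset, self.sim))
        if sources != 1:
            raise ValueError("exactly one input source (vcf, preset or sim) required")


@dataclass
class RunReport:
    manifest: list[str] = field(default_factory=list)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    attrition: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.parameters = {
        "seed": cfg.seed,
        "K_grid": list(cfg.K_grid),
        "min_presence": cfg.filters.min_presence_fraction,
        "min_maf": cfg.filters.min_maf,
        "single_snp_per_locus": cfg.filters.single_snp_per_locus,
        "gene_flow_tau": cfg.classification.gene_flow_tau,
    }

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self
            def __exit__(self, *exc):
                report.stage_seconds[name] = time.perf_counter() - self.t0
                return False
        return _T()

    def _write(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, **kw)
        report.manifest.append(name)

    # -- input -------------------------------------------------------------
    with _stage("input"):
        if cfg.vcf is not None:
            matrix = read_vcf(cfg.vcf)
            if cfg.metadata is not None:
                from .genotype import attach_sample_metadata, read_sample_metadata
                matrix = attach_sample_metadata(
                    matrix, read_sample_metadata(cfg.metadata))
            truth = None
        else:
            sim = cfg.sim or PRESETS[cfg.preset](seed=cfg.seed, n_sites=cfg.n_sites)
            matrix, truth = simulate_cohort(sim)
            write_vcf(matrix, out / "genotypes.vcf")
            report.manifest.append("genotypes.vcf")
            truth.to_csv(out / "truth")
            report.manifest += ["truth/true_Q.csv", "truth/true_labels.csv",
                                "truth/population_freqs.csv"]
        report.attrition["n_samples"] = matrix.n_samples
        report.attrition["n_sites_input"] = matrix.n_sites

    # -- filter ------------------------------------------------------------
    with _stage("filter"):
        matrix, filt = apply_filters(matrix, cfg.filters)
        report.attrition.update(
            n_sites_filtered=filt.n_retained,
            removed_presence=filt.removed_presence,
            removed_single_snp=filt.removed_single_snp,
            removed_maf=filt.removed_maf,
        )
        write_vcf(matrix, out / "genotypes.filtered.vcf")
        report.manifest.append("genotypes.filtered.vcf")

    # -- heterozygosity screen --------------------------------------------
    with _stage("het_screen"):
        het = heterozygosity_screen(matrix)
        _write(het, "het_screen.csv", index=False)

    # -- clonality ---------------------------------------------------------
    with _stage("clonality"):
        pairs = clonality.pairwise_conservation_table(matrix)
        replicate_pairs = [(s.replicate_of, s.sample_id)
                           for s in matrix.samples if s.replicate_of]
        if cfg.clonality_cfg is not None:
            clo_cfg = cfg.clonality_cfg
        else:
            rep_pcts = []
            for a, b in replicate_pairs:
                pc = clonality.count_pairwise_conservation(matrix, a, b)
                if not pc.inconclusive:
                    rep_pcts.append(pc.percent)
            if not rep_pcts:
                report.warnings.append(
                    "no technical replicates: clonal threshold defaults to 40%")
            clo_cfg = clonality.calibrate_threshold(rep_pcts)
        pairs = clonality.pairwise_conservation_table(matrix, cfg=clo_cfg)
        _write(pairs, "conservation_pairs.tsv", sep="\t", index=False)
        partition = clonality.call_clonal_groups(pairs, clo_cfg)
        clone_of = partition.clone_id_of()
        clones_df = pd.DataFrame(
            {"sample_id": matrix.sample_ids,
             "clone_id": [clone_of.get(s, "") for s in matrix.sample_ids]}
        )
        _write(clones_df, "clonal_groups.csv", index=False)
        report.parameters["clonal_threshold_percent"] = clo_cfg.threshold_percent

    # -- ordination and clustering ----------------------------------------
    with _stage("structure"):
        pca = structure.genotype_pca(matrix, n_components=5)
        pca_df = pca.coordinates.copy()
        _write(pca_df, "pca_coords.csv")
        _write(pd.DataFrame({"component": pca_df.columns,
                             "contribution_percent": pca.contributions}),
               "pca_contributions.csv", index=False)
        D = structure.ibs_distance(matrix)
        _write(D, "ibs_distance.csv")
        mds = structure.classical_mds(D, k=2)
        _write(mds.coordinates, "mds_coords.csv")
        tree = structure.upgma_tree(D)
        (out / "dendrogram.nwk").write_text(tree.newick() + "\n")
        report.manifest.append("dendrogram.nwk")

    # -- admixture ---------------------------------------------------------
    with _stage("admixture"):
        grid = [K for K in cfg.K_grid if K <= matrix.n_samples]
        if len(grid) < len(cfg.K_grid):
            report.warnings.append(
                f"K grid truncated to {grid}: only {matrix.n_samples} samples")
        cv = admixture.cross_validate(
            matrix, grid, n_folds=cfg.cv_folds, seed=cfg.seed,
            n_starts=max(1, cfg.em_starts // 2))
        _write(cv.errors, "cv_curve.csv", index=False)
        report.parameters["selected_K"] = cv.selected_K
        fits = {}
        for K in grid:
            fit = admixture.em_fit(matrix, K, n_starts=cfg.em_starts, seed=cfg.seed)
            fits[K] = fit
            admixture.write_q_table(fit, out / f"admixture_K{K}.Q")
            report.manifest.append(f"admixture_K{K}.Q")
        best = fits.get(3, fits[cv.selected_K])

    # -- classification ----------------------------------------------------
    with _stage("classification"):
        if best.K == 3:
            clonal_ids = set().union(*partition.groups) if partition.groups else set()
            anchors = classify.identify_anchor_clusters(
                best.Q, clonal_ids, cfg.classification)
            report.warnings += anchors.warnings
            assignment = classify.classify_subgroups(
                best.Q, anchors, cfg.classification)
            _write(assignment, "assignment.csv")
            regions = pd.Series(
                {s.sample_id: s.region_label for s in matrix.samples})
            if regions.notna().any():
                reg = classify.regional_structure_report(
                    assignment, regions, seed=cfg.seed)
                _write(reg.crosstab, "region_crosstab.csv")
                report.parameters["region_association_p"] = reg.p_value
        else:
            report.warnings.append(
                "no K=3 fit available; group classification skipped")
            assignment = None

    # -- population statistics --------------------------------------------
    with _stage("popstats"):
        if assignment is not None:
            labels = assignment.apply(
                lambda r: r["subgroup"] if r["group"] == "C" else r["group"], axis=1)
            counts = labels.value_counts()
            labels = labels[labels.map(counts) >= 2]
            stats, fst = popgen.population_summary(matrix, labels)
            _write(stats, "population_stats.csv")
            if not fst.empty:
                _write(fst, "fst_matrix.csv")

    # -- plots (optional) --------------------------------------------------
    if cfg.make_plots:
        with _stage("plots"):
            _plot(out, pca_df, pca.contributions, best, assignment)
            report.manifest += ["pca.png", "admixture_bar.png"]

    # -- report ------------------------------------------------------------
    with _stage("report"):
        text = make_report(out, report.parameters, report.warnings)
        (out / "report.md").write_text(text)
        report.manifest.append("report.md")

    missing = [m for m in report.manifest if not (out / m).exists()]
    if missing:
        raise RuntimeError(f"manifest entries missing on disk: {missing}")
    return report


def make_report(out_dir: str | Path, parameters: dict | None = None,
                warnings: list[str] | None = None) -> str:
    """Assemble a markdown summary from the tables saved in ``out_dir``.

    Reads only saved outputs, so regenerating the report from disk yields
    the identical text.
    """
    out = Path(out_dir)
    lines = ["# Cohort analysis report", ""]
    if parameters:
        lines.append("## Parameters")
        for k, v in sorted(parameters.items()):
            lines.append(f"- {k}: {v}")
        lines.append("")
    if warnings:
        lines.append("## Warnings")
        lines += [f"- {w}" for w in warnings]
        lines.append("")

    def _table(name: str, title: str, **kw) -> None:
        path = out / name
        if not path.exists():
            return
        df = pd.read_csv(path, **kw)
        lines.append(f"## {title}")
        lines.append(df.to_markdown(index=False))
        lines.append("")

    _table("population_stats.csv", "Per-population diversity")
    _table("fst_matrix.csv", "Pairwise Fst")

    clones_path = out / "clonal_groups.csv"
    if clones_path.exists():
        clones = pd.read_csv(clones_path).fillna("")
        grouped = clones[clones["clone_id"] != ""]
        lines.append("## Clonal groups")
        if grouped.empty:
            lines.append("no clonal groups detected")
        else:
            for cid, sub in grouped.groupby("clone_id"):
                lines.append(f"- {cid}: {', '.join(sub['sample_id'])}")
        lines.append("")

    _table("cv_curve.csv", "Admixture cross-validation")
    assign_path = out / "assignment.csv"
    if assign_path.exists():
        df = pd.read_csv(assign_path).fillna("")
        lines.append("## Group assignment")
        lines.append(df.to_markdown(index=False))
        lines.append("")
    _table("conservation_pairs.tsv", "Heterozygous-site conservation (pairs)",
           sep="\t")
    return "\n".join(lines) + "\n"


def _plot(out: Path, pca_df: pd.DataFrame, contributions, fit, assignment) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = (assignment["group"] if assignment is not None
              else pd.Series("?", index=pca_df.index))
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, sub in pca_df.groupby(groups):
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=str(g), s=18)
    ax.set_xlabel(f"PC1 ({contributions[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({contributions[1]:.1f}%)")
    ax.legend(title="group", fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "pca.png", dpi=120)
    plt.close(fig)

    Q = fit.Q
    fig, ax = plt.subplots(figsize=(8, 2.5))
    bottom = None
    x = range(len(Q))
    import numpy as np
    bottom = np.zeros(len(Q))
    for col in Q.columns:
        ax.bar(x, Q[col], bottom=bottom, width=1.0, label=col)
        bottom += Q[col].to_numpy()
    ax.set_xticks(list(x))
    ax.set_xticklabels(Q.index, rotation=90, fontsize=5)
    ax.set_ylabel("ancestry")
    fig.tight_layout()
    fig.savefig(out / "admixture_bar.png", dpi=120)
    plt.close(fig)
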