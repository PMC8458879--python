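"""End-to-end orchestration of the analysis stages from one configuration.

Stages communicate only through serialized TSV outputs, so any stage can
be re-run from the previous stage's files; a structured-text manifest
records every output path and record count. Reruns with an identical
configuration reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .cerna import (
    Thresholds,
    build_units,
    extend_to_mrna,
    transcripts_from_exon_table,
    units_to_frame,
)
from .coexpression import build_network, hub_genes
from .drivers import identify_drivers
from .enrichment import gsea_table, ora_table, rank_by_neglog_p
from .exceptions import ConfigError
from .landscape import (
    build_mutation_matrix,
    pairwise_cooccurrence,
    per_sample_burden,
    read_maf,
    substitution_spectrum,
    summarize_by_gene,
)
from .prognosis import (
    DEFAULT_EVAL_TIMES,
    auc_over_grid,
    km_estimate,
    lasso_cox_select,
    logrank_test,
    median_risk_groups,
    multivariate_cox,
    prepare_expression,
    score_samples,
    screen_univariate,
    split_cohort,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths, thresholds and seeds of a full pipeline run."""

    maf: str
    expression: str
    clinical: str
    annotation: str
    lncrna_fasta: str
    mirna_fasta: str
    targets: str | None = None
    gene_sets: str | None = None
    outdir: str = "cernamut_out"
    alpha_driver: float = 0.05
    fc_cut: float = 1.5
    min_carriers: int = 2
    coexpr_p: float = 0.01
    coexpr_r: float = 0.5
    align_score_min: float = 160.0
    energy_max: float = -20.0
    context_max: float = -0.4
    cox_alpha: float = 0.05
    train_fraction: float = 0.7
    n_perm: int = 1000
    eval_times: tuple[float, ...] = DEFAULT_EVAL_TIMES
    seed: int = 0
    top_cooccurrence_genes: int = 20

    def __post_init__(self):
        if not 0 < self.alpha_driver <= 1 or not 0 < self.coexpr_p <= 1:
            raise ConfigError("significance cutoffs must lie in (0, 1]")
        if self.fc_cut <= 0 or not 0 <= self.coexpr_r <= 1:
            raise ConfigError("fold-change / correlation cutoffs out of range")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.min_carriers < 1:
            raise ConfigError("min_carriers must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "eval_times" in raw:
            raw["eval_times"] = tuple(float(t) for t in raw["eval_times"])
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("maf", "expression", "clinical", "annotation", "lncrna_fasta",
                     "mirna_fasta"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        for name in ("targets", "gene_sets"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")


@dataclass
class RunManifest:
    stages: dict[str, dict] = field(default_factory=dict)

    def add(self, stage: str, outputs: dict[str, str], counts: dict[str, int]) -> None:
        self.stages[stage] = {"outputs": outputs, "counts": counts, "status": "ok"}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write(df: pd.DataFrame, outdir: Path, name: str, index: bool = False) -> str:
    path = outdir / name
    cio.write_tsv(df, path, index=index)
    return str(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage in dependency order, writing TSVs and a manifest.

    Any stage error aborts the run with the stage name in the log.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    t0 = time.time()

    # ---- landscape -----------------------------------------------------
    stage = "landscape"
    records = read_maf(config.maf)
    expression = cio.read_expression(config.expression)
    clinical = cio.read_tsv(config.clinical, index_col=0)
    samples = sorted({r.sample_id for r in records} | set(expression.columns))
    spectrum = substitution_spectrum(records)
    gene_summary = summarize_by_gene(records)
    burden = per_sample_burden(records).rename("n_mutations").to_frame()
    matrix = build_mutation_matrix(records, samples, config.min_carriers)
    top = gene_summary.head(config.top_cooccurrence_genes)["gene"]
    top = [g for g in top if g in matrix.counts.index]
    cooc = (
        pairwise_cooccurrence(matrix, top)
        if len(top) >= 2
        else pd.DataFrame()
    )
    outputs = {
        "spectrum": _write(spectrum, outdir, "landscape_spectrum.tsv"),
        "gene_summary": _write(gene_summary, outdir, "landscape_gene_summary.tsv"),
        "burden": _write(burden, outdir, "landscape_burden.tsv", index=True),
        "mutation_matrix": _write(matrix.counts, outdir, "mutation_matrix.tsv", index=True),
        "cooccurrence": _write(cooc, outdir, "landscape_cooccurrence.tsv"),
    }
    manifest.add(stage, outputs, {"mutations": len(records), "genes_retained": len(matrix.genes)})
    log.info("stage %s done (%.1fs)", stage, time.time() - t0)

    # ---- drivers -------------------------------------------------------
    stage = "drivers"
    driver_table = identify_drivers(matrix, expression, config.alpha_driver, config.fc_cut)
    drivers = list(driver_table.loc[driver_table["is_driver"], "gene"])
    outputs = {"driver_table": _write(driver_table, outdir, "driver_table.tsv")}
    manifest.add(stage, outputs, {"tested": len(driver_table), "drivers": len(drivers)})

    # ---- coexpression --------------------------------------------------
    stage = "coexpression"
    if drivers:
        edges, nodes, _ = build_network(drivers, expression, config.coexpr_p, config.coexpr_r)
        hubs = hub_genes(nodes)
    else:
        edges = pd.DataFrame(columns=["driver", "partner", "r", "p_value", "sign"])
        nodes = pd.DataFrame(columns=["gene", "degree", "is_driver"])
        hubs = []
    outputs = {
        "edges": _write(edges, outdir, "coexpression_edges.tsv"),
        "nodes": _write(nodes, outdir, "coexpression_nodes.tsv"),
    }
    manifest.add(stage, outputs, {"edges": len(edges), "hubs": len(hubs)})

    # ---- ceRNA disruption ---------------------------------------------
    stage = "cerna"
    exons = cio.read_gtf_exons(config.annotation)
    transcripts = transcripts_from_exon_table(exons)
    lnc_seqs = cio.read_fasta(config.lncrna_fasta, rna=True)
    mir_seqs = cio.read_fasta(config.mirna_fasta, rna=True)
    thresholds = Thresholds(config.align_score_min, config.energy_max, config.context_max)
    units = build_units(records, transcripts, lnc_seqs, mir_seqs, thresholds)
    unit_frame = units_to_frame(units)
    targets = (
        cio.read_tsv(config.targets)
        if config.targets
        else pd.DataFrame(columns=["mirna_id", "mrna_gene", "evidence"])
    )
    net_edges, _ = extend_to_mrna(units, targets)
    outputs = {
        "units": _write(unit_frame, outdir, "cerna_units.tsv"),
        "network": _write(net_edges, outdir, "cerna_network.tsv"),
    }
    manifest.add(stage, outputs, {"units": len(units), "network_edges": len(net_edges)})

    # ---- enrichment ----------------------------------------------------
    stage = "enrichment"
    counts = {}
    outputs = {}
    if config.gene_sets and not driver_table.empty:
        gene_sets = cio.read_gmt(config.gene_sets)
        ranked = rank_by_neglog_p(driver_table)
        gsea = gsea_table(ranked, gene_sets, n_perm=config.n_perm, seed=config.seed)
        universe = set(driver_table["gene"])
        query = set(drivers) & universe
        ora = (
            ora_table(query, gene_sets, universe) if query else pd.DataFrame()
        )
        outputs = {
            "gsea": _write(gsea, outdir, "enrichment_gsea.tsv"),
            "ora": _write(ora, outdir, "enrichment_ora.tsv"),
        }
        counts = {"gene_sets": len(gene_sets), "gsea_rows": len(gsea)}
    manifest.add(stage, outputs, counts or {"gene_sets": 0})

    # ---- survival ------------------------------------------------------
    stage = "survival"
    clinical = clinical.loc[[s for s in clinical.index if s in expression.columns]]
    candidates = (
        driver_table.loc[driver_table["p_value"] < config.alpha_driver, "gene"].tolist()
    )
    mrna_genes = (
        sorted(set(targets["mrna_gene"]) & set(expression.index)) if len(targets) else []
    )
    candidates = sorted(set(candidates) | set(mrna_genes))
    outputs = {}
    counts = {"candidates": len(candidates)}
    if candidates and clinical["event"].sum() >= 10:
        screen = screen_univariate(expression.loc[candidates], clinical, config.cox_alpha)
        outputs["univariate"] = _write(screen, outdir, "survival_univariate.tsv")
        selected = screen.loc[screen["selected"], "gene"].tolist()
        counts["univariate_selected"] = len(selected)
        if len(selected) >= 2:
            train, test = split_cohort(list(clinical.index), config.train_fraction, config.seed)
            lasso_genes, _ = lasso_cox_select(
                expression.loc[selected], clinical.loc[train],
                n_folds=min(10, int(clinical.loc[train, "event"].sum())), seed=config.seed,
            )
            counts["lasso_selected"] = len(lasso_genes)
            if lasso_genes:
                prepared = prepare_expression(expression, standardize=True)
                model, table = multivariate_cox(
                    prepared.loc[lasso_genes, train], clinical.loc[train]
                )
                model.to_tsv(outdir / "risk_model.tsv")
                outputs["risk_model"] = str(outdir / "risk_model.tsv")
                outputs["multivariate"] = _write(table, outdir, "survival_multivariate.tsv")
                auc_rows, km_rows = [], []
                for part, cohort in (("train", train), ("test", test)):
                    scores = score_samples(prepared[cohort], model)
                    groups = median_risk_groups(scores)
                    chi2, p = logrank_test(clinical.loc[cohort], groups)
                    aucs = auc_over_grid(scores, clinical.loc[cohort], config.eval_times)
                    aucs["cohort"] = part
                    auc_rows.append(aucs)
                    counts[f"logrank_p_{part}"] = p
                    for grp, curve in km_estimate(clinical.loc[cohort], groups).items():
                        curve["cohort"], curve["group"] = part, grp
                        km_rows.append(curve)
                outputs["auc"] = _write(pd.concat(auc_rows, ignore_index=True), outdir,
                                        "survival_auc.tsv")
                outputs["km_curves"] = _write(pd.concat(km_rows, ignore_index=True),
                                              outdir, "survival_km.tsv")
    manifest.add(stage, outputs, counts)

    manifest.write(outdir / "manifest.json")
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return manifest
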