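"""End-to-end orchestration of the integrative time-course analysis.

Stages: fold-change selection -> model-profile assignment with permutation
significance -> anti-correlation microRNA target calling with permutation
FDR -> pathway enrichment (up/down patterns, split by target status) and
pathway activity -> betweenness core nodes on the merged significant
pathway graphs -> promoter TFBS similarity of the pattern genes.  Every
randomized stage derives its stream from the single run seed by stage
name, so any stage can be re-run in isolation bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import centrality, io, motifs, pathways as pw, patterns
from ._rng import derive_seed
from .datasets import BUNDLE_FILES
from .integration import correlate_pairs, load_target_predictions, permutation_fdr

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "partition_by_target_status"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths, thresholds and permutation counts of a pipeline run."""

    gene_expr: Path
    mirna_expr: Path
    predictions: Path
    gmt: Path
    edges: Path
    genome: Path
    tss: Path
    pfms: Path
    out_dir: Path
    truth_true_pairs: Path | None = None

    up_fold: float = 2.0
    down_fold: float = 0.5
    mirna_fold: float = 1.5
    profile_c: int = 2
    profile_m: int = 50
    pattern_fdr: float = 0.05
    integration_fdr: float = 0.01
    activity_fdr: float = 0.01
    centrality_cut: float = 0.01
    pwm_fraction: float = 0.9
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.up_fold > 1 > self.down_fold > 0:
            raise ValueError("need up_fold > 1 > down_fold > 0")
        if self.mirna_fold <= 1:
            raise ValueError("mirna_fold must exceed 1")
        for name in ("pattern_fdr", "integration_fdr", "activity_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.pwm_fraction <= 1:
            raise ValueError("pwm_fraction must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for name in (
            "gene_expr", "mirna_expr", "predictions", "gmt", "edges",
            "genome", "tss", "pfms",
        ):
            setattr(self, name, Path(getattr(self, name)))
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_bundle_dir(cls, directory: str | Path, out_dir: str | Path, **overrides):
        """Point the pipeline at a written synthetic bundle directory."""
        directory = Path(directory)
        truth = directory / BUNDLE_FILES["truth_true_pairs"]
        return cls(
            gene_expr=directory / BUNDLE_FILES["gene_expr"],
            mirna_expr=directory / BUNDLE_FILES["mirna_expr"],
            predictions=directory / BUNDLE_FILES["predictions"],
            gmt=directory / BUNDLE_FILES["pathways"],
            edges=directory / BUNDLE_FILES["pathway_edges"],
            genome=directory / BUNDLE_FILES["genome"],
            tss=directory / BUNDLE_FILES["tss"],
            pfms=directory / BUNDLE_FILES["pfms"],
            out_dir=Path(out_dir),
            truth_true_pairs=truth if truth.exists() else None,
            **overrides,
        )


@dataclass
class RunReport:
    """Machine-readable run summary: counts, parameters, manifest, timings."""

    seed: int
    params: dict
    stages: dict[str, dict] = field(default_factory=dict)
    recovery: dict[str, float] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)  # file -> sha256
    timings_s: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def partition_by_target_status(
    pattern_genes: set[str], integration: pd.DataFrame
) -> tuple[set[str], set[str]]:
    """Split pattern genes into selected microRNA targets and the rest.

    ``integration`` is a permutation-FDR result table; genes selected there
    but absent from ``pattern_genes`` are logged and ignored, so the two
    returned sets always partition ``pattern_genes``.
    """
    if len(integration):
        selected = set(integration.loc[integration["selected"], "gene_id"])
    else:
        selected = set()
    extra = selected - set(pattern_genes)
    if extra:
        logger.info("%d selected targets outside the pattern gene set", len(extra))
    targets = set(pattern_genes) & selected
    return targets, set(pattern_genes) - targets


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage, write all outputs under ``config.out_dir``.

    Fully deterministic for a fixed seed (timings excepted).  Returns the
    :class:`RunReport`, which is also written as ``report.json``.
    """
    for name in ("gene_expr", "mirna_expr", "predictions", "gmt", "edges",
                 "genome", "tss", "pfms"):
        path = getattr(config, name)
        if not Path(path).exists():
            raise FileNotFoundError(f"input {name} missing: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = {
        k: str(v) if isinstance(v, Path) else v for k, v in asdict(config).items()
    }
    report = RunReport(seed=config.seed, params=params)
    written: list[Path] = []
    t_all = time.perf_counter()

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, *exc):
                report.timings_s[name] = round(time.perf_counter() - self_inner.t0, 3)
                return False

        return _Timer()

    def emit(filename: str, writer) -> None:
        path = out / filename
        writer(path)
        written.append(path)

    # ------------------------------------------------------------------ load
    gene_expr = io.read_expression(config.gene_expr)
    mirna_expr = io.read_expression(config.mirna_expr)
    predictions = load_target_predictions(config.predictions)
    gmt_nonempty = Path(config.gmt).stat().st_size > 0
    pathway_sets = (
        pw.PathwaySet.from_gmt(config.gmt)
        if gmt_nonempty
        else pw.PathwaySet(gene_sets={}, names={})
    )
    edges = io.read_edges(config.edges)
    genome = io.read_fasta(config.genome)
    tss = io.read_bed6(config.tss)
    pfms = io.read_pfms(config.pfms)
    pwms = [motifs.pwm_from_counts(c, mid, 1.0) for mid, c in pfms.items()]

    # --------------------------------------------------------- changed features
    with stage("select_changed"):
        changed_genes = patterns.select_changed_features(
            gene_expr, config.up_fold, config.down_fold
        )
        mirna_down = 1.0 / config.mirna_fold
        changed_mirnas = patterns.select_changed_features(
            mirna_expr, config.mirna_fold, mirna_down
        )
    report.stages["select_changed"] = {
        "genes_measured": len(gene_expr),
        "mirnas_measured": len(mirna_expr),
        "genes_changed": len(changed_genes),
        "mirnas_changed": len(changed_mirnas),
    }
    emit("changed_genes.tsv", lambda p: pd.Series(changed_genes, name="feature_id").to_csv(p, sep="\t", index=False))
    emit("changed_mirnas.tsv", lambda p: pd.Series(changed_mirnas, name="feature_id").to_csv(p, sep="\t", index=False))

    # ------------------------------------------------------- temporal patterns
    with stage("temporal_patterns"):
        prof_cfg = patterns.ProfileConfig(
            c=config.profile_c,
            m=config.profile_m,
            n_perm=config.n_perm,
            fdr_cut=config.pattern_fdr,
            seed=derive_seed(config.seed, "temporal_patterns"),
        )
        changed_expr = gene_expr.loc[changed_genes]
        profiles = patterns.generate_model_profiles(gene_expr.shape[1] + 1, prof_cfg)
        assignment = patterns.assign_profiles(changed_expr, profiles)
        assignment = patterns.profile_significance(assignment, changed_expr, prof_cfg)
        pattern_sets = patterns.label_patterns(assignment, changed_expr)
    up_genes, down_genes = pattern_sets["up"], pattern_sets["down"]
    pattern_genes = up_genes | down_genes
    report.stages["temporal_patterns"] = {
        "profiles": len(profiles),
        "assigned": len(assignment.assignments),
        "significant_profiles": int(assignment.profile_stats["significant"].sum()),
        "up_pattern_genes": len(up_genes),
        "down_pattern_genes": len(down_genes),
    }
    emit("profile_assignments.tsv", lambda p: io.write_table(assignment.assignments, p))
    emit("profile_stats.tsv", lambda p: io.write_table(assignment.profile_stats, p))

    # ------------------------------------------------------------- integration
    with stage("integration"):
        candidates = predictions.restrict(genes=pattern_genes, mirnas=changed_mirnas)
        pairs = correlate_pairs(gene_expr, mirna_expr, candidates)
        integration = permutation_fdr(
            pairs,
            gene_expr,
            mirna_expr,
            n_perm=config.n_perm,
            fdr_cut=config.integration_fdr,
            seed=derive_seed(config.seed, "integration"),
        )
    selected_pairs = integration[integration["selected"]] if len(integration) else integration
    report.stages["integration"] = {
        "candidate_pairs": len(candidates),
        "negative_pairs": len(pairs),
        "selected_pairs": len(selected_pairs),
        "selected_genes": selected_pairs["gene_id"].nunique() if len(selected_pairs) else 0,
        "selected_mirnas": selected_pairs["mirna_id"].nunique() if len(selected_pairs) else 0,
    }
    emit("integration.tsv", lambda p: io.write_table(integration, p))
    emit(
        "integration_edges.tsv",
        lambda p: io.write_table(
            selected_pairs[["mirna_id", "gene_id"]] if len(selected_pairs) else pd.DataFrame(columns=["mirna_id", "gene_id"]),
            p,
        ),
    )

    # ------------------------------------------------- enrichment and activity
    with stage("pathway_analysis"):
        background = set(gene_expr.index)
        up_targets, up_nontargets = partition_by_target_status(up_genes, integration)
        down_targets, down_nontargets = partition_by_target_status(down_genes, integration)
        enrich_tables = {}
        for label, genes in (
            ("up_all", up_genes),
            ("up_targets", up_targets),
            ("up_nontargets", up_nontargets),
            ("down_all", down_genes),
            ("down_targets", down_targets),
            ("down_nontargets", down_nontargets),
        ):
            if genes and len(pathway_sets):
                table = pw.enrich(genes, background, pathway_sets)
            else:
                table = pd.DataFrame(
                    columns=["pathway_id", "overlap", "list_size", "pathway_size", "p", "fdr", "significant"]
                )
            table.insert(0, "gene_list", label)
            enrich_tables[label] = table
        non_empty = [t for t in enrich_tables.values() if len(t)]
        enrichment = (
            pd.concat(non_empty, ignore_index=True)
            if non_empty
            else next(iter(enrich_tables.values()))
        )

        if len(pathway_sets):
            activity = pw.activity_significance(
                gene_expr,
                pathway_sets,
                n_perm=config.n_perm,
                fdr_cut=config.activity_fdr,
                seed=derive_seed(config.seed, "pathway_activity"),
            )
            sig_pathways = set(
                activity.stats.loc[activity.stats["significant"], "pathway_id"]
            )
            activity_tree = (
                pw.hierarchical_cluster(activity.activity)
                if activity.activity.shape[0] >= 2
                else None
            )
        else:
            activity = pw.ActivityProfile(
                activity=pd.DataFrame(), stats=pd.DataFrame(columns=["pathway_id", "significant"])
            )
            sig_pathways = set()
            activity_tree = None
    report.stages["pathway_analysis"] = {
        "pathways": len(pathway_sets),
        "enrichment_rows": len(enrichment),
        "significant_enrichments": int(enrichment["significant"].sum()) if len(enrichment) else 0,
        "significant_activity_pathways": len(sig_pathways),
        "up_targets": len(up_targets),
        "up_nontargets": len(up_nontargets),
        "down_targets": len(down_targets),
        "down_nontargets": len(down_nontargets),
    }
    emit("enrichment.tsv", lambda p: io.write_table(enrichment, p))
    emit("activity.tsv", lambda p: activity.activity.to_csv(p, sep="\t", float_format="%.10g"))
    emit("activity_stats.tsv", lambda p: io.write_table(activity.stats, p))
    if activity_tree is not None:
        emit(
            "activity_tree.txt",
            lambda p: Path(p).write_text(
                activity_tree.to_newick(list(activity.activity.index)) + "\n"
            ),
        )

    # --------------------------------------------------------------- core nodes
    with stage("core_nodes"):
        selected_targets = (
            set(selected_pairs["gene_id"]) if len(selected_pairs) else set()
        )
        graphs = [
            centrality.graph_from_edges(edges, pathway_id=pid)
            for pid in sorted(sig_pathways)
        ]
        merged = centrality.merge_graphs(graphs)
        cent = centrality.relative_betweenness(merged)
        core_all = centrality.select_core_nodes(cent, config.centrality_cut)
        core_targets = centrality.select_core_nodes(
            cent, config.centrality_cut, targets=selected_targets
        )
    report.stages["core_nodes"] = {
        "merged_nodes": merged.number_of_nodes(),
        "merged_edges": merged.number_of_edges(),
        "core_nodes": len(core_all),
        "core_mirna_targets": len(core_targets),
    }
    cent_table = cent.rename("centrality").reset_index()
    cent_table["core"] = cent_table["node"].isin(core_all)
    cent_table["core_mirna_target"] = cent_table["node"].isin(core_targets)
    emit("centrality.tsv", lambda p: io.write_table(cent_table, p))

    # ------------------------------------------------------------ promoter TFBS
    with stage("promoter_tfbs"):
        tss_pattern = tss[tss["name"].isin(pattern_genes)].reset_index(drop=True)
        promoters = motifs.extract_promoters(genome, tss_pattern)
        if promoters and pwms:
            profile = motifs.tfbs_profile_matrix(
                promoters, pwms, min_score_fraction=config.pwm_fraction
            )
            jaccard = motifs.jaccard_matrix(profile)
            tfbs_tree = (
                pw.hierarchical_cluster(1.0 - jaccard) if len(jaccard) >= 2 else None
            )
        else:
            profile = motifs.TFBSProfile(pd.DataFrame())
            jaccard = pd.DataFrame()
            tfbs_tree = None
    report.stages["promoter_tfbs"] = {
        "promoters": len(promoters),
        "pwms": len(pwms),
        "nonzero_cells": int((profile.counts.to_numpy() > 0).sum()) if profile.counts.size else 0,
    }
    emit("tfbs_counts.tsv", lambda p: profile.counts.to_csv(p, sep="\t"))
    emit("tfbs_jaccard.tsv", lambda p: jaccard.to_csv(p, sep="\t", float_format="%.10g"))
    if tfbs_tree is not None:
        emit(
            "tfbs_tree.txt",
            lambda p: Path(p).write_text(tfbs_tree.to_newick(list(jaccard.index)) + "\n"),
        )

    # ------------------------------------------------------- planted-truth audit
    if config.truth_true_pairs is not None and Path(config.truth_true_pairs).exists():
        truth = io.read_table(config.truth_true_pairs)
        true_set = set(zip(truth["mirna_id"], truth["gene_id"])) if len(truth) else set()
        called = (
            set(zip(selected_pairs["mirna_id"], selected_pairs["gene_id"]))
            if len(selected_pairs)
            else set()
        )
        candidate_set = set(zip(candidates.pairs["mirna_id"], candidates.pairs["gene_id"]))
        decoy_candidates = candidate_set - true_set
        tp = len(called & true_set)
        report.recovery = {
            "true_pairs": len(true_set),
            "called_pairs": len(called),
            "sensitivity": tp / len(true_set) if true_set else None,
            "precision": tp / len(called) if called else None,
            "specificity": (
                1.0 - len(called & decoy_candidates) / len(decoy_candidates)
                if decoy_candidates
                else None
            ),
        }

    report.timings_s["total"] = round(time.perf_counter() - t_all, 3)
    report.manifest = {p.name: _sha256(p) for p in written}
    report.to_json(out / "report.json")
    return report
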