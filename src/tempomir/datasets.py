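"""Synthetic time-course bundles with planted ground truth.

The generator emulates a pooled-replicate treatment time course measured
on mRNA and microRNA arrays: log2 expression ratios versus an untreated
time-0 control on a grid of post-treatment hours.  Planted structure
covers every downstream stage:

* temporal genes follow a saturating ramp to ``effect_log2`` (up) or its
  mirror image (down); everything else is pure noise around 0;
* each planted repression pair gives its microRNA the negated, scaled
  (k ~ U(0.5, 1)) clean profile of its target gene, so the pair is
  perfectly anti-correlated before noise; decoy predictions point at
  independent noise genes;
* gene-set 0 (1) is drawn from the up (down) genes, so its mean log2
  ratio shifts coherently — the planted active pathways; the other sets
  are random null genes;
* every pathway's directed graph is a hub star (first half of the member
  list feeds the hub, the hub feeds the rest), so the hub is the planted
  central node;
* two co-expression groups of promoters each share three planted motif
  consensus sequences; all other promoter sequence is uniform random.

All randomness flows from one seed through named streams, so equal
configs give byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from ._rng import derive_rng
from .integration import TargetPredictionMap
from .motifs import (
    PositionWeightMatrix,
    PromoterRecord,
    extract_promoters,
    pwm_from_counts,
    reverse_complement,
)
from .pathways import PathwaySet

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "generate_dataset",
    "null_dataset",
    "write_bundle",
    "read_bundle",
]

BUNDLE_FILES = {
    "gene_expr": "gene_expr.tsv",
    "mirna_expr": "mirna_expr.tsv",
    "predictions": "predictions.tsv",
    "pathways": "pathways.gmt",
    "pathway_edges": "pathway_edges.tsv",
    "genome": "genome.fasta",
    "tss": "tss.bed",
    "pfms": "pfms.jaspar",
    "truth_temporal_genes": "truth_temporal_genes.tsv",
    "truth_true_pairs": "truth_true_pairs.tsv",
    "truth_active_pathways": "truth_active_pathways.tsv",
    "truth_central_nodes": "truth_central_nodes.tsv",
    "truth_motif_groups": "truth_motif_groups.tsv",
}


class ConfigError(ValueError):
    """Invalid synthetic-data configuration; the message names the field."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic bundle.

    Defaults describe a modest but realistic design: 500 genes and 50
    microRNAs over the hour grid (1, 2, 4, 8, 12, 24) plus the implicit
    time-0 control, 15% up / 6% down temporal genes peaking at 2 log2
    units, 50 planted repression pairs among 20 decoy predictions per
    microRNA, and Gaussian measurement noise of 0.3 on log2 ratios.
    """

    n_genes: int = 500
    n_mirnas: int = 50
    time_points_h: tuple[float, ...] = (1, 2, 4, 8, 12, 24)
    frac_up: float = 0.15
    frac_down: float = 0.06
    n_true_pairs: int = 50
    decoys_per_mirna: int = 20
    effect_log2: float = 2.0
    noise_sd: float = 0.3
    n_pathways: int = 8
    pathway_size: int = 20
    n_pwms: int = 30
    motif_len: int = 8
    promoter_len: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_mirnas", "n_true_pairs", "decoys_per_mirna",
            "n_pathways", "pathway_size", "n_pwms", "motif_len", "promoter_len",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not (0 <= self.frac_up and 0 <= self.frac_down):
            raise ConfigError("frac_up and frac_down must be >= 0")
        if self.frac_up + self.frac_down > 1:
            raise ConfigError(
                f"frac_up + frac_down must be <= 1, got {self.frac_up + self.frac_down}"
            )
        tp = tuple(self.time_points_h)
        if any(t <= 0 for t in tp) or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigError(
                f"time_points_h must be strictly increasing and positive, got {tp}"
            )
        if self.n_true_pairs > self.n_mirnas:
            raise ConfigError(
                "n_true_pairs must be <= n_mirnas (each planted microRNA "
                "mirrors a single target)"
            )
        if self.n_true_pairs > self.n_up + self.n_down:
            raise ConfigError(
                "n_true_pairs must be <= the number of planted temporal genes"
            )
        if self.motif_len and self.promoter_len < 4 * self.motif_len:
            raise ConfigError("promoter_len too short for the planted motifs")
        if self.n_genes and not 500 <= self.promoter_len <= 2500:
            raise ConfigError(
                f"promoter_len must be in [500, 2500], got {self.promoter_len}"
            )

    @property
    def n_up(self) -> int:
        return round(self.frac_up * self.n_genes)

    @property
    def n_down(self) -> int:
        return round(self.frac_down * self.n_genes)

    @property
    def time_labels(self) -> list[str]:
        return [f"{t:g}h" for t in self.time_points_h]


@dataclass
class SyntheticTruth:
    temporal_genes: pd.DataFrame  # gene_id, direction
    true_pairs: pd.DataFrame  # mirna_id, gene_id, k
    active_pathways: pd.DataFrame  # pathway_id, direction
    central_nodes: pd.DataFrame  # pathway_id, node
    motif_groups: pd.DataFrame  # group, gene_id, matrix_ids (comma joined)

    @classmethod
    def empty(cls) -> "SyntheticTruth":
        return cls(
            temporal_genes=pd.DataFrame(columns=["gene_id", "direction"]),
            true_pairs=pd.DataFrame(columns=["mirna_id", "gene_id", "k"]),
            active_pathways=pd.DataFrame(columns=["pathway_id", "direction"]),
            central_nodes=pd.DataFrame(columns=["pathway_id", "node"]),
            motif_groups=pd.DataFrame(columns=["group", "gene_id", "matrix_ids"]),
        )


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    gene_expr: pd.DataFrame
    mirna_expr: pd.DataFrame
    predictions: TargetPredictionMap
    pathways: PathwaySet
    pathway_edges: pd.DataFrame
    genome: dict[str, str]
    tss: pd.DataFrame
    pwms: list[PositionWeightMatrix]
    pfm_counts: dict[str, np.ndarray]
    truth: SyntheticTruth

    @property
    def promoters(self) -> list[PromoterRecord]:
        return extract_promoters(self.genome, self.tss)


def _ramp(times: np.ndarray) -> np.ndarray:
    """Saturating ramp on [0, 1]: 1 - 2^(-t/tau), rescaled to peak at 1."""
    tau = times[-1] / 6.0
    raw = 1.0 - np.exp2(-times / tau)
    return raw / raw[-1]


def generate_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a full input bundle with planted ground truth."""
    return _generate(config, planted=True)


def null_dataset(config: SyntheticConfig) -> SyntheticBundle:
    """Same structure as :func:`generate_dataset` with zero planted effects.

    Expression is pure noise, predictions contain only decoys, pathways
    and graphs are drawn the same way, and all truth tables are empty.
    """
    return _generate(config, planted=False)


def _generate(config: SyntheticConfig, planted: bool) -> SyntheticBundle:
    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    mirnas = [f"mir{i:03d}" for i in range(config.n_mirnas)]
    times = np.asarray(config.time_points_h, dtype=float)
    T = len(times)

    # --- temporal structure -------------------------------------------------
    rng = derive_rng(config.seed, "temporal")
    perm = rng.permutation(config.n_genes)
    n_up, n_down = (config.n_up, config.n_down) if planted else (0, 0)
    up_idx = perm[:n_up]
    down_idx = perm[n_up: n_up + n_down]
    null_idx = perm[n_up + n_down:]

    clean = np.zeros((config.n_genes, T))
    if planted and T:
        ramp = config.effect_log2 * _ramp(times)
        clean[up_idx] = ramp
        clean[down_idx] = -ramp

    noise_rng = derive_rng(config.seed, "gene-noise")
    gene_vals = clean + noise_rng.normal(0.0, config.noise_sd, size=clean.shape)
    gene_expr = pd.DataFrame(
        gene_vals, index=pd.Index(genes, name="feature_id"), columns=config.time_labels
    )

    # --- planted repression pairs and microRNA profiles ---------------------
    pair_rng = derive_rng(config.seed, "pairs")
    temporal_idx = np.concatenate([up_idx, down_idx])
    mirna_clean = np.zeros((config.n_mirnas, T))
    pair_rows = []
    if planted and config.n_true_pairs:
        target_idx = pair_rng.choice(temporal_idx, size=config.n_true_pairs, replace=False)
        mirna_sel = pair_rng.choice(config.n_mirnas, size=config.n_true_pairs, replace=False)
        k = pair_rng.uniform(0.5, 1.0, size=config.n_true_pairs)
        for m_i, g_i, k_i in zip(mirna_sel, target_idx, k):
            mirna_clean[m_i] = -k_i * clean[g_i]
            pair_rows.append((mirnas[m_i], genes[g_i], float(k_i)))
    mirna_noise_rng = derive_rng(config.seed, "mirna-noise")
    mirna_vals = mirna_clean + mirna_noise_rng.normal(
        0.0, config.noise_sd, size=mirna_clean.shape
    )
    mirna_expr = pd.DataFrame(
        mirna_vals, index=pd.Index(mirnas, name="feature_id"), columns=config.time_labels
    )
    true_pairs = pd.DataFrame(pair_rows, columns=["mirna_id", "gene_id", "k"])

    # --- prediction table: planted pairs plus decoys ------------------------
    decoy_rng = derive_rng(config.seed, "decoys")
    pred_rows = [(m, g) for m, g, _ in pair_rows]
    taken = set(pred_rows)
    decoy_pool = null_idx if len(null_idx) else np.arange(config.n_genes)
    for m_i, mirna in enumerate(mirnas):
        if len(decoy_pool) == 0:
            break
        n_take = min(config.decoys_per_mirna, len(decoy_pool))
        for g_i in decoy_rng.choice(decoy_pool, size=n_take, replace=False):
            pair = (mirna, genes[g_i])
            if pair not in taken:
                taken.add(pair)
                pred_rows.append(pair)
    predictions = TargetPredictionMap(
        pd.DataFrame(pred_rows, columns=["mirna_id", "gene_id"])
    )

    # --- pathways: planted active sets, null sets, hub-star graphs ----------
    pw_rng = derive_rng(config.seed, "pathways")
    gene_sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    active_rows = []
    hub_rows = []
    for p in range(config.n_pathways):
        pid = f"pw{p:02d}"
        if planted and p == 0 and len(up_idx) >= 2:
            pool, label = up_idx, "up"
        elif planted and p == 1 and len(down_idx) >= 2:
            pool, label = down_idx, "down"
        else:
            pool, label = null_idx, None
        size = min(config.pathway_size, len(pool))
        if size < 2:
            continue
        chosen = pw_rng.choice(pool, size=size, replace=False)
        member_list = [genes[i] for i in chosen]
        members[pid] = member_list
        gene_sets[pid] = set(member_list)
        names[pid] = f"synthetic pathway {p}"
        if label is not None:
            active_rows.append((pid, label))
        hub_rows.append((pid, member_list[0]))

    edge_rows = []
    for pid, member_list in members.items():
        hub, rest = member_list[0], member_list[1:]
        half = len(rest) // 2
        for src in rest[:half]:
            edge_rows.append((pid, src, hub, "activation"))
        for dst in rest[half:]:
            edge_rows.append((pid, hub, dst, "activation"))
    pathway_edges = pd.DataFrame(edge_rows, columns=io.EDGE_COLUMNS)
    pathways = PathwaySet(gene_sets=gene_sets, names=names)

    # --- motifs and promoters -----------------------------------------------
    pwm_rng = derive_rng(config.seed, "pwms")
    pfm_counts: dict[str, np.ndarray] = {}
    pwms: list[PositionWeightMatrix] = []
    for j in range(config.n_pwms):
        mid = f"PWM{j:03d}"
        consensus = pwm_rng.integers(0, 4, size=config.motif_len)
        counts = np.ones((4, config.motif_len))
        counts[consensus, np.arange(config.motif_len)] = 17.0
        pfm_counts[mid] = counts
        pwms.append(pwm_from_counts(counts, mid, pseudocount=1.0))

    group_rows = []
    plant_at: dict[str, list[str]] = {g: [] for g in genes}
    if planted and config.n_pwms >= 6 and config.motif_len:
        group_size = min(6, len(up_idx), len(down_idx))
        for label, idx, matrix_ids in (
            ("up", up_idx[:group_size], ["PWM000", "PWM001", "PWM002"]),
            ("down", down_idx[:group_size], ["PWM003", "PWM004", "PWM005"]),
        ):
            for g_i in idx:
                plant_at[genes[g_i]] = matrix_ids
                group_rows.append((label, genes[g_i], ",".join(matrix_ids)))
    motif_groups = pd.DataFrame(group_rows, columns=["group", "gene_id", "matrix_ids"])

    seq_rng = derive_rng(config.seed, "promoters")
    bases = np.array(list("ACGT"))
    consensus_of = {p.matrix_id: p.consensus for p in pwms}
    genome: dict[str, str] = {}
    tss_rows = []
    for i, gene in enumerate(genes):
        promoter = "".join(bases[seq_rng.integers(0, 4, size=config.promoter_len)])
        offsets = np.linspace(
            config.promoter_len // 8,
            config.promoter_len // 2,
            num=max(1, len(plant_at[gene])),
            dtype=int,
        )
        for off, mid in zip(offsets, plant_at[gene]):
            motif = consensus_of[mid]
            promoter = promoter[:off] + motif + promoter[off + len(motif):]
        strand = "+" if i % 2 == 0 else "-"
        # the contig exactly covers the promoter window, so the promoter
        # string round-trips through extract_promoters (with truncation at
        # the contig edge when promoter_len < 2500)
        if strand == "+":
            tss_pos = min(2000, config.promoter_len)
            contig = promoter
        else:
            tss_pos = 499
            contig = reverse_complement(promoter)
        chrom = f"chr_{gene}"
        genome[chrom] = contig
        tss_rows.append((chrom, tss_pos, tss_pos + 1, gene, 0, strand))
    tss = pd.DataFrame(tss_rows, columns=io.BED6_COLUMNS)

    truth = SyntheticTruth(
        temporal_genes=pd.DataFrame(
            [(genes[i], "up") for i in up_idx] + [(genes[i], "down") for i in down_idx],
            columns=["gene_id", "direction"],
        ),
        true_pairs=true_pairs,
        active_pathways=pd.DataFrame(active_rows, columns=["pathway_id", "direction"]),
        central_nodes=pd.DataFrame(hub_rows, columns=["pathway_id", "node"]),
        motif_groups=motif_groups,
    ) if planted else SyntheticTruth.empty()

    return SyntheticBundle(
        config=config,
        gene_expr=gene_expr,
        mirna_expr=mirna_expr,
        predictions=predictions,
        pathways=pathways,
        pathway_edges=pathway_edges,
        genome=genome,
        tss=tss,
        pwms=pwms,
        pfm_counts=pfm_counts,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Serialize a bundle to its plain-text files; returns the manifest.

    The written files round-trip losslessly through the package readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in BUNDLE_FILES.items()}

    io.write_expression(bundle.gene_expr, paths["gene_expr"])
    io.write_expression(bundle.mirna_expr, paths["mirna_expr"])
    io.write_table(bundle.predictions.pairs, paths["predictions"])
    if len(bundle.pathways):
        bundle.pathways.to_gmt(paths["pathways"])
    else:
        paths["pathways"].write_text("")
    io.write_edges(bundle.pathway_edges, paths["pathway_edges"])
    io.write_fasta(bundle.genome, paths["genome"])
    io.write_bed6(bundle.tss, paths["tss"])
    io.write_pfms(bundle.pfm_counts, paths["pfms"])
    truth = bundle.truth
    io.write_table(truth.temporal_genes, paths["truth_temporal_genes"])
    io.write_table(truth.true_pairs, paths["truth_true_pairs"])
    io.write_table(truth.active_pathways, paths["truth_active_pathways"])
    io.write_table(truth.central_nodes, paths["truth_central_nodes"])
    io.write_table(truth.motif_groups, paths["truth_motif_groups"])
    return paths


def read_bundle(directory: str | Path) -> dict[str, object]:
    """Read a written bundle's analysis inputs back as in-memory objects."""
    directory = Path(directory)
    p = {k: directory / v for k, v in BUNDLE_FILES.items()}
    gmt_path = p["pathways"]
    pathways = (
        PathwaySet.from_gmt(gmt_path)
        if gmt_path.stat().st_size
        else PathwaySet(gene_sets={}, names={})
    )
    from .integration import load_target_predictions

    pfms = io.read_pfms(p["pfms"])
    return {
        "gene_expr": io.read_expression(p["gene_expr"]),
        "mirna_expr": io.read_expression(p["mirna_expr"]),
        "predictions": load_target_predictions(p["predictions"]),
        "pathways": pathways,
        "pathway_edges": io.read_edges(p["pathway_edges"]),
        "genome": io.read_fasta(p["genome"]),
        "tss": io.read_bed6(p["tss"]),
        "pwms": [pwm_from_counts(c, mid, 1.0) for mid, c in pfms.items()],
        "truth_true_pairs": io.read_table(p["truth_true_pairs"]),
        "truth_temporal_genes": io.read_table(p["truth_temporal_genes"]),
        "truth_central_nodes": io.read_table(p["truth_central_nodes"]),
        "truth_motif_groups": io.read_table(p["truth_motif_groups"]),
    }
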