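"""Gene-set enrichment, pathway activity, and activity clustering.

Enrichment is a two-sided Fisher's exact test per pathway with
Benjamini-Hochberg adjustment.  Pathway activity linearly combines the
log2 expression ratios of all measured member genes (unweighted mean) per
time point, to accumulate small coherent changes; its significance is
tested against random gene sets of equal size.  Activity profiles can be
hierarchically clustered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from . import io
from ._rng import derive_rng

__all__ = [
    "PathwaySet",
    "fisher_exact_2x2",
    "enrich",
    "pathway_activity",
    "activity_significance",
    "ActivityProfile",
    "ClusterResult",
    "hierarchical_cluster",
]

logger = logging.getLogger(__name__)


@dataclass
class PathwaySet:
    """Named gene sets: ``pathway_id -> (name, genes)``."""

    gene_sets: dict[str, set[str]]
    names: dict[str, str]

    def __post_init__(self) -> None:
        empty = [p for p, g in self.gene_sets.items() if not g]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "PathwaySet":
        raw = io.read_gmt(path)
        return cls(
            gene_sets={p: set(g) for p, (_, g) in raw.items()},
            names={p: name for p, (name, _) in raw.items()},
        )

    def to_gmt(self, path: str | Path) -> None:
        io.write_gmt(
            {p: (self.names.get(p, p), g) for p, g in self.gene_sets.items()}, path
        )

    def __len__(self) -> int:
        return len(self.gene_sets)

    def subset(self, pathway_ids: Iterable[str]) -> "PathwaySet":
        ids = [p for p in pathway_ids if p in self.gene_sets]
        return PathwaySet(
            gene_sets={p: self.gene_sets[p] for p in ids},
            names={p: self.names.get(p, p) for p in ids},
        )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Exact two-sided Fisher p for a 2x2 count table.

    Sums, over all tables with the observed margins, the hypergeometric
    probability of every table no more probable than the observed one.
    Computed in exact integer arithmetic (all tables with fixed margins
    share the denominator), so ties are handled without rounding.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"table cells must be nonnegative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("all-zero table")
    # weight of table with top-left k: C(r1, k) * C(r2, c1 - k)
    t_obs = comb(r1, a) * comb(r2, c)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numer = sum(
        w
        for k in range(lo, hi + 1)
        if (w := comb(r1, k) * comb(r2, c1 - k)) <= t_obs
    )
    return numer / comb(n, c1)


def enrich(
    gene_list: Iterable[str],
    background: Iterable[str],
    pathways: PathwaySet | Mapping[str, set[str]],
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of ``gene_list`` against ``background`` per pathway.

    Pathway genes are intersected with the background first; pathways
    disjoint from the background are excluded (logged).  Returns a
    DataFrame with columns pathway_id, overlap, list_size, pathway_size,
    p, fdr, significant, sorted by p.
    """
    gene_list = set(gene_list)
    background = set(background)
    if not background:
        raise ValueError("empty background")
    if not gene_list <= background:
        extra = sorted(gene_list - background)
        raise ValueError(f"gene list not contained in background, e.g. {extra[:5]}")
    sets = pathways.gene_sets if isinstance(pathways, PathwaySet) else pathways

    rows = []
    for pid, genes in sets.items():
        in_bg = set(genes) & background
        if not in_bg:
            logger.info("pathway %s disjoint from background; excluded", pid)
            continue
        a = len(gene_list & in_bg)
        b = len(gene_list) - a
        c = len(in_bg) - a
        d = len(background) - len(gene_list) - c
        rows.append((pid, a, len(gene_list), len(in_bg), fisher_exact_2x2([[a, b], [c, d]])))
    out = pd.DataFrame(
        rows, columns=["pathway_id", "overlap", "list_size", "pathway_size", "p"]
    )
    if len(out):
        _, fdr, _, _ = multipletests(out["p"], method="fdr_bh")
        out["fdr"] = fdr
        out["significant"] = out["fdr"] < fdr_cut
        out = out.sort_values(["p", "pathway_id"], kind="stable").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def pathway_activity(
    expr: pd.DataFrame, pathways: PathwaySet | Mapping[str, set[str]]
) -> pd.DataFrame:
    """Per-pathway, per-time activity: mean log2 ratio of measured members.

    Pathways with no measured gene are omitted (logged).  Rows are
    pathways, columns the time labels of ``expr``.
    """
    sets = pathways.gene_sets if isinstance(pathways, PathwaySet) else pathways
    measured = set(expr.index)
    rows, ids = [], []
    for pid, genes in sets.items():
        members = sorted(set(genes) & measured)
        if not members:
            logger.info("pathway %s has no measured genes; omitted", pid)
            continue
        rows.append(expr.loc[members].mean(axis=0).to_numpy())
        ids.append(pid)
    return pd.DataFrame(rows, index=pd.Index(ids, name="pathway_id"), columns=expr.columns)


@dataclass
class ActivityProfile:
    """Pathway activity over time plus permutation significance."""

    activity: pd.DataFrame
    stats: pd.DataFrame  # pathway_id, size, stat, p, fdr, significant


def activity_significance(
    expr: pd.DataFrame,
    pathways: PathwaySet | Mapping[str, set[str]],
    n_perm: int = 1000,
    fdr_cut: float = 0.01,
    seed: int = 0,
) -> ActivityProfile:
    """Compare each pathway's activity with random equal-size gene sets.

    The test statistic is the maximum over time of |activity|.  The null
    draws, per round, a random gene set of the same size from all measured
    genes; ``p = (1 + #{null stat >= observed}) / (1 + n_perm)``,
    Benjamini-Hochberg across pathways, significant iff fdr < fdr_cut.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    sets = pathways.gene_sets if isinstance(pathways, PathwaySet) else pathways
    activity = pathway_activity(expr, sets)
    vals = expr.to_numpy(dtype=float)
    n_genes = vals.shape[0]
    measured = set(expr.index)

    sizes = {
        pid: len(set(sets[pid]) & measured) for pid in activity.index
    }
    obs = activity.abs().max(axis=1)

    rng = derive_rng(seed, "activity-permutation")
    exceed = pd.Series(0, index=activity.index, dtype=int)
    unique_sizes = sorted(set(sizes.values()))
    null_stats: dict[int, np.ndarray] = {}
    for s in unique_sizes:
        stats = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(n_genes, size=s, replace=False)
            stats[i] = np.abs(vals[idx].mean(axis=0)).max()
        null_stats[s] = stats
    for pid in activity.index:
        exceed[pid] = int((null_stats[sizes[pid]] >= obs[pid] - 1e-12).sum())

    p = (1 + exceed.to_numpy()) / (1 + n_perm)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    stats_df = pd.DataFrame(
        {
            "pathway_id": activity.index,
            "size": [sizes[p_] for p_ in activity.index],
            "stat": obs.to_numpy(),
            "p": p,
            "fdr": fdr,
            "significant": fdr < fdr_cut,
        }
    ).reset_index(drop=True)
    return ActivityProfile(activity=activity, stats=stats_df)


@dataclass
class ClusterResult:
    """Agglomerative clustering output: merge tree and leaf ordering."""

    linkage: np.ndarray  # scipy linkage matrix
    leaves: list[str]  # row labels in dendrogram order

    def to_newick(self, labels: Sequence[str]) -> str:
        """Nested-parenthesis rendering of the merge tree with heights."""
        tree = to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return str(labels[node.id])
            left, right = render(node.get_left()), render(node.get_right())
            return f"({left},{right}):{node.dist:g}"

        return render(tree) + ";"


def hierarchical_cluster(
    profile_matrix: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of matrix rows.

    Deterministic given the input row order (scipy's tie rule).  Raises
    on non-finite distances or fewer than two rows.
    """
    if profile_matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    dists = pdist(profile_matrix.to_numpy(dtype=float), metric=metric)
    if not np.isfinite(dists).all():
        raise ValueError("non-finite distances")
    z = linkage(dists, method=method)
    order = leaves_list(z)
    return ClusterResult(linkage=z, leaves=[str(profile_matrix.index[i]) for i in order])
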