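"""Model-profile assignment of short expression time courses.

Changed features are selected by a linear fold-ratio cutoff, every feature
trajectory (control 0 prepended) is assigned to the most correlated member
of a fixed library of integer model profiles, and per-profile membership
counts are tested by permuting each feature's time points.  This follows
the short time-series miner approach: the profile library is enumerated
from all shapes that start at 0 and change by at most ``c`` integer units
per step, then thinned to ``m`` representatives by greedy maximin
dissimilarity (1 - Pearson correlation of shapes).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._rng import derive_rng

__all__ = [
    "ProfileConfig",
    "ModelProfile",
    "PatternAssignment",
    "select_changed_features",
    "generate_model_profiles",
    "assign_profiles",
    "profile_significance",
    "label_patterns",
]


@dataclass(frozen=True)
class ProfileConfig:
    """Parameters of profile generation and the permutation test.

    ``c`` bounds the integer change per step, ``m`` the library size,
    ``n_perm`` the number of time-point permutations, ``fdr_cut`` the BH
    threshold on the per-profile permutation p-values.
    """

    c: int = 2
    m: int = 50
    n_perm: int = 1000
    fdr_cut: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm}")
        if not 0 < self.fdr_cut < 1:
            raise ValueError(f"fdr_cut must be in (0, 1), got {self.fdr_cut}")


@dataclass(frozen=True)
class ModelProfile:
    profile_id: int
    shape: tuple[int, ...]  # integer level per time point, shape[0] == 0


@dataclass
class PatternAssignment:
    """Feature-to-profile assignment plus per-profile statistics.

    ``assignments`` has columns feature_id, profile_id, r (features with a
    zero-variance trajectory are absent).  ``profile_stats`` has one row
    per profile with its member count and, after
    :func:`profile_significance`, columns p, fdr and significant.
    """

    profiles: list[ModelProfile]
    assignments: pd.DataFrame
    profile_stats: pd.DataFrame
    unassigned: list[str] = field(default_factory=list)


def select_changed_features(
    expr: pd.DataFrame, up_fold: float = 2.0, down_fold: float = 0.5
) -> list[str]:
    """Features whose linear fold ratio leaves [down_fold, up_fold] somewhere.

    ``expr`` holds log2 ratios; a feature is kept iff its fold at some time
    point is strictly greater than ``up_fold`` or strictly less than
    ``down_fold``.
    """
    if not up_fold > 1 > down_fold > 0:
        raise ValueError(
            f"need up_fold > 1 > down_fold > 0, got ({up_fold}, {down_fold})"
        )
    folds = np.exp2(expr.to_numpy(dtype=float))
    keep = (folds > up_fold).any(axis=1) | (folds < down_fold).any(axis=1)
    return expr.index[keep].tolist()


def _standardize_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered and scaled to unit population variance.

    Returns (z, ok) where ok flags rows with nonzero variance; z rows with
    ok False are zeroed.
    """
    centered = mat - mat.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    ok = sd > 0
    z = np.zeros_like(centered)
    z[ok] = centered[ok] / sd[ok, None]
    return z, ok


def generate_model_profiles(T: int, config: ProfileConfig) -> list[ModelProfile]:
    """Enumerate and thin the integer model-profile library for T points.

    All ``(2c+1)**(T-1)`` shapes starting at level 0 are enumerated; the
    flat (constant) shape is dropped because it has no defined correlation.
    If more than ``m`` remain, ``m`` are chosen greedily to maximize the
    minimum pairwise dissimilarity 1 - Pearson r, seeded with the largest-
    norm shape (lexicographically smallest on ties).  Deterministic.
    """
    if T < 2:
        raise ValueError(f"need at least 2 time points, got {T}")
    if config.c == 0:
        if config.m > 1:
            warnings.warn(
                "c=0 admits only the flat profile; returning a single profile",
                stacklevel=2,
            )
        return [ModelProfile(0, (0,) * T)]

    steps = range(-config.c, config.c + 1)
    shapes = [
        (0, *itertools.accumulate(diffs))
        for diffs in itertools.product(steps, repeat=T - 1)
    ]
    shapes = [s for s in shapes if len(set(s)) > 1]  # drop the constant shape
    if len(shapes) <= config.m:
        return [ModelProfile(i, s) for i, s in enumerate(shapes)]

    arr = np.array(shapes, dtype=float)
    z, _ = _standardize_rows(arr)
    norms = (arr * arr).sum(axis=1)
    order = sorted(range(len(shapes)), key=lambda i: (-norms[i], shapes[i]))
    chosen = [order[0]]
    # min over chosen of 1 - r, updated incrementally
    min_dist = 1.0 - z @ z[chosen[0]] / T
    min_dist[chosen[0]] = -np.inf
    while len(chosen) < config.m:
        best = int(np.argmax(min_dist))
        # deterministic tie-break: lexicographically smallest shape
        ties = np.flatnonzero(min_dist == min_dist[best])
        if len(ties) > 1:
            best = min(ties, key=lambda i: shapes[i])
        chosen.append(best)
        min_dist = np.minimum(min_dist, 1.0 - z @ z[best] / T)
        min_dist[best] = -np.inf
    return [ModelProfile(i, shapes[idx]) for i, idx in enumerate(chosen)]


def _trajectories(expr: pd.DataFrame) -> np.ndarray:
    """Log2 trajectories with the control 0 prepended."""
    vals = expr.to_numpy(dtype=float)
    return np.hstack([np.zeros((vals.shape[0], 1)), vals])


def _assign(z_traj: np.ndarray, ok: np.ndarray, z_prof: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best profile index and its correlation per trajectory row.

    Ties go to the lowest profile index (argmax picks the first maximum).
    Rows with ok False get index -1.
    """
    T = z_prof.shape[1]
    corr = z_traj @ z_prof.T / T
    best = corr.argmax(axis=1)
    r = corr[np.arange(len(best)), best]
    best = np.where(ok, best, -1)
    return best, r


def assign_profiles(
    expr: pd.DataFrame, profiles: list[ModelProfile]
) -> PatternAssignment:
    """Assign each feature to the model profile maximizing Pearson r.

    The trajectory is the feature's log2 ratios with a 0 prepended for the
    control.  Zero-variance trajectories are left unassigned.
    """
    if not profiles:
        raise ValueError("empty profile list")
    traj = _trajectories(expr)
    prof = np.array([p.shape for p in profiles], dtype=float)
    if prof.shape[1] != traj.shape[1]:
        raise ValueError(
            f"profiles have {prof.shape[1]} points but trajectories have "
            f"{traj.shape[1]} (including the control)"
        )
    z_traj, ok = _standardize_rows(traj)
    z_prof, prof_ok = _standardize_rows(prof)
    if not prof_ok.all():
        bad = [profiles[i].profile_id for i in np.flatnonzero(~prof_ok)]
        if len(profiles) > 1:
            raise ValueError(f"constant profiles in a multi-profile library: {bad}")
    best, r = _assign(z_traj, ok, z_prof)

    assigned = best >= 0
    assignments = pd.DataFrame(
        {
            "feature_id": expr.index[assigned],
            "profile_id": [profiles[i].profile_id for i in best[assigned]],
            "r": r[assigned],
        }
    )
    counts = assignments["profile_id"].value_counts()
    stats = pd.DataFrame(
        {
            "profile_id": [p.profile_id for p in profiles],
            "count": [int(counts.get(p.profile_id, 0)) for p in profiles],
        }
    )
    return PatternAssignment(
        profiles=profiles,
        assignments=assignments,
        profile_stats=stats,
        unassigned=expr.index[~assigned].tolist(),
    )


def profile_significance(
    assignment: PatternAssignment, expr: pd.DataFrame, config: ProfileConfig
) -> PatternAssignment:
    """Permutation test of per-profile membership counts.

    Each round independently shuffles every feature's measured time points
    (the control anchor stays at 0), re-assigns all features, and records
    per-profile counts.  ``p = (1 + #{rounds with count >= observed}) /
    (1 + n_perm)``, Benjamini-Hochberg across profiles, significant iff
    fdr < ``fdr_cut``.
    """
    profiles = assignment.profiles
    prof = np.array([p.shape for p in profiles], dtype=float)
    z_prof, _ = _standardize_rows(prof)
    vals = expr.to_numpy(dtype=float)
    n, t = vals.shape
    obs = assignment.profile_stats["count"].to_numpy()

    rng = derive_rng(config.seed, "profile-significance")
    exceed = np.zeros(len(profiles), dtype=int)
    ids = np.array([p.profile_id for p in profiles])
    for _ in range(config.n_perm):
        keys = rng.random((n, t))
        perm = np.take_along_axis(vals, np.argsort(keys, axis=1), axis=1)
        z_traj, ok = _standardize_rows(_trajectories(pd.DataFrame(perm)))
        best, _ = _assign(z_traj, ok, z_prof)
        counts = np.bincount(best[best >= 0], minlength=len(profiles))
        exceed += counts >= obs

    p = (1 + exceed) / (1 + config.n_perm)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    stats = assignment.profile_stats.copy()
    stats["p"] = p
    stats["fdr"] = fdr
    stats["significant"] = fdr < config.fdr_cut
    assert (stats["profile_id"].to_numpy() == ids).all()
    return replace(assignment, profile_stats=stats)


def label_patterns(
    assignment: PatternAssignment, expr: pd.DataFrame
) -> dict[str, set[str]]:
    """Member genes of the significant up and down temporal patterns.

    A significant profile is labeled "up" when the mean final log2 ratio
    of its member features is positive, "down" when negative.  Returns
    ``{"up": genes, "down": genes}``.
    """
    stats = assignment.profile_stats
    if "significant" not in stats.columns:
        raise ValueError("run profile_significance first")
    out: dict[str, set[str]] = {"up": set(), "down": set()}
    final = expr.iloc[:, -1]
    sig_ids = set(stats.loc[stats["significant"], "profile_id"])
    for pid, group in assignment.assignments.groupby("profile_id"):
        if pid not in sig_ids:
            continue
        mean_final = final.loc[group["feature_id"]].mean()
        if mean_final > 0:
            out["up"].update(group["feature_id"])
        elif mean_final < 0:
            out["down"].update(group["feature_id"])
    return out
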