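"""Raw probe intensities to the per-feature log2-ratio expression matrix.

The preprocessing chain mirrors standard two-channel time-course array
practice: drop probes not measured above local background, quantile-normalize
the remaining intensities across samples, average duplicated spots per
feature, and express everything as log2 ratios against the untreated
(time-0) control column.

A raw intensity table is a DataFrame with columns ``probe_id``,
``feature_id`` and a ``signal_<label>`` / ``background_<label>`` pair per
sample.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "filter_well_measured",
    "quantile_normalize",
    "average_duplicates",
    "compute_ratios",
    "sample_labels",
]


def sample_labels(raw: pd.DataFrame) -> list[str]:
    """Sample labels of a raw intensity table, in column order."""
    labels = [c[len("signal_"):] for c in raw.columns if c.startswith("signal_")]
    for lab in labels:
        if f"background_{lab}" not in raw.columns:
            raise ValueError(f"sample {lab!r} has a signal but no background column")
    if not labels:
        raise ValueError("raw table has no signal_* columns")
    return labels


def filter_well_measured(raw: pd.DataFrame, fold: float = 1.4) -> list[str]:
    """Probes whose signal exceeds ``fold`` x local background somewhere.

    A probe is kept when ``signal > fold * background`` (strictly) in at
    least one sample; with a zero background any positive signal passes.
    Returns the kept probe ids in input order.
    """
    if fold <= 0:
        raise ValueError(f"fold must be positive, got {fold}")
    labels = sample_labels(raw)
    signal = raw[[f"signal_{s}" for s in labels]].to_numpy(dtype=float)
    background = raw[[f"background_{s}" for s in labels]].to_numpy(dtype=float)
    if (signal < 0).any() or (background < 0).any():
        raise ValueError("negative intensities in raw table")
    keep = (signal > fold * background).any(axis=1)
    return raw.loc[keep, "probe_id"].tolist()


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common per-rank cross-column mean.

    Each column is replaced by the mean, over columns, of the sorted values
    at its rank.  Ties within a column receive the mean of the rank means
    they span, so tied inputs stay tied and the column means are preserved.
    """
    if values.size == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    mat = values.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("non-finite values in matrix")
    rank_means = np.sort(mat, axis=0).mean(axis=1)

    out = np.empty_like(mat)
    n = mat.shape[0]
    for j in range(mat.shape[1]):
        order = np.argsort(mat[:, j], kind="stable")
        col_sorted = mat[order, j]
        # average the rank means across runs of tied input values
        assigned = rank_means.copy()
        start = 0
        for i in range(1, n + 1):
            if i == n or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    assigned[start:i] = rank_means[start:i].mean()
                start = i
        out[order, j] = assigned
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def average_duplicates(
    values: pd.DataFrame, probe_to_feature: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse probe rows to one row per feature by arithmetic mean.

    ``values`` is indexed by probe id; every probe must map to exactly one
    feature.  Feature rows appear in order of first occurrence.
    """
    unmapped = [p for p in values.index if p not in probe_to_feature]
    if unmapped:
        raise ValueError(f"probes without a feature mapping: {unmapped[:5]}")
    features = pd.Index([probe_to_feature[p] for p in values.index], name="feature_id")
    grouped = values.groupby(features, sort=False).mean()
    return grouped


def compute_ratios(
    intensities: pd.DataFrame, control_label: str, offset: float = 1.0
) -> pd.DataFrame:
    """log2 ratio of every sample against the control column.

    The control column is dropped from the output.  When any intensity in
    the matrix is exactly zero, ``offset`` is added to the whole matrix
    first so the logarithm is defined; otherwise values are used as given
    (which keeps the output invariant under global rescaling).
    """
    if control_label not in intensities.columns:
        raise ValueError(f"control column {control_label!r} not in matrix")
    mat = intensities.to_numpy(dtype=float)
    if (mat == 0).any():
        mat = mat + offset
    if (mat <= 0).any():
        raise ValueError("nonpositive intensities remain after offset")
    control = intensities.columns.get_loc(control_label)
    bad = mat[:, control] <= 0
    if bad.any():
        raise ValueError(
            "nonpositive control intensity for features: "
            f"{intensities.index[bad].tolist()[:5]}"
        )
    ratios = np.log2(mat / mat[:, [control]])
    out = pd.DataFrame(ratios, index=intensities.index, columns=intensities.columns)
    return out.drop(columns=[control_label])
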