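"""Promoter extraction, PWM scanning, and binding-site similarity.

Promoters are the window -2000..+500 around the transcription start site
in transcription direction (0-based half-open; minus-strand windows are
reverse-complemented so the returned sequence reads 5'->3' with the 2000
upstream bases first).  Position frequency matrices become probability
weight matrices with a Laplace pseudocount; a sliding window matches when
its summed weight score reaches ``min_score + f * (max_score - min_score)``
with f the minimum score fraction (an ``f * max_score`` convention is
available via ``threshold_mode="max"``).  Gene-gene similarity is the
Jaccard index of binarized binding-site presence, which by construction
ignores joint absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PromoterRecord",
    "PositionWeightMatrix",
    "TFBSProfile",
    "reverse_complement",
    "extract_promoters",
    "pwm_from_counts",
    "scan_pwm",
    "tfbs_profile_matrix",
    "jaccard_matrix",
]

UPSTREAM = 2000
DOWNSTREAM = 500

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte value -> base index (A=0 C=1 G=2 T=3, anything else 4)
_CODES = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
    _CODES[_b + 32] = _i  # lowercase


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    chrom: str
    tss: int  # 0-based
    strand: str
    sequence: str


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Probability-scale weights over A, C, G, T per motif position."""

    matrix_id: str
    weights: np.ndarray = field(repr=False)  # (4, width)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != 4 or w.shape[1] < 1:
            raise ValueError(f"weights must be 4 x width, got {w.shape}")
        if (w < 0).any() or not np.allclose(w.sum(axis=0), 1.0):
            raise ValueError("per-position weights must be nonnegative and sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @cached_property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @cached_property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    @cached_property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.weights.argmax(axis=0))


def pwm_from_counts(
    counts: np.ndarray, matrix_id: str = "", pseudocount: float = 1.0
) -> PositionWeightMatrix:
    """Counts (4 x width, rows A/C/G/T) to a probability weight matrix.

    ``weight(b, j) = (count(b, j) + pseudocount) / (colsum(j) + 4 pseudocount)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError(f"counts must be a nonempty 4 x width matrix, got {counts.shape}")
    if (counts < 0).any():
        raise ValueError("negative counts")
    colsum = counts.sum(axis=0)
    denom = colsum + 4.0 * pseudocount
    if (denom <= 0).any():
        raise ValueError("zero column sum with zero pseudocount")
    return PositionWeightMatrix(matrix_id, (counts + pseudocount) / denom)


def extract_promoters(
    genome: Mapping[str, str],
    tss_records: pd.DataFrame,
    upstream: int = UPSTREAM,
    downstream: int = DOWNSTREAM,
) -> list[PromoterRecord]:
    """Promoter windows around BED6 TSS records, truncated at contig ends.

    Plus strand: ``[tss - upstream, tss + downstream)``.  Minus strand:
    ``[tss - downstream + 1, tss + upstream + 1)`` reverse-complemented, so
    both read 5'->3' starting with the most upstream base.
    """
    out: list[PromoterRecord] = []
    for row in tss_records.itertuples(index=False):
        chrom, tss, gene, strand = str(row.chrom), int(row.start), str(row.name), row.strand
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} (TSS of {gene}) absent from genome")
        contig = genome[chrom]
        if strand == "+":
            lo, hi = tss - upstream, tss + downstream
        elif strand == "-":
            lo, hi = tss - downstream + 1, tss + upstream + 1
        else:
            raise ValueError(f"record {gene}: invalid strand {strand!r}")
        seq = contig[max(0, lo): min(len(contig), hi)].upper()
        if strand == "-":
            seq = reverse_complement(seq)
        out.append(PromoterRecord(gene, chrom, tss, strand, seq))
    return out


@dataclass
class ScanResult:
    count: int
    positions: list[tuple[int, str]]  # (window start on given strand's sequence, strand)


def _scan_one_strand(codes: np.ndarray, pwm: PositionWeightMatrix, threshold: float) -> np.ndarray:
    w = pwm.width
    if codes.size < w:
        return np.empty(0, dtype=int)
    # pad weights with a zero row for non-ACGT codes; such windows are dropped
    weights = np.vstack([pwm.weights, np.zeros((1, w))])
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    scores = weights[windows, np.arange(w)].sum(axis=1)
    valid = (windows < 4).all(axis=1)
    return np.flatnonzero(valid & (scores >= threshold - 1e-12))


def scan_pwm(
    seq: str,
    pwm: PositionWeightMatrix,
    min_score_fraction: float = 0.9,
    both_strands: bool = True,
    threshold_mode: str = "minmax",
) -> ScanResult:
    """Count PWM matches in a sequence.

    A window of width ``w`` scores the sum of its per-position weights and
    matches when the score reaches the threshold: with the default
    ``minmax`` mode ``min + f (max - min)``, with ``max`` mode ``f * max``.
    Windows containing a non-ACGT base are skipped; overlapping matches
    all count; with ``both_strands`` the reverse complement is scanned too
    and counts summed.  A sequence shorter than the motif yields 0.
    """
    if not 0 < min_score_fraction <= 1:
        raise ValueError(f"min_score_fraction must be in (0, 1], got {min_score_fraction}")
    if threshold_mode == "minmax":
        threshold = pwm.min_score + min_score_fraction * (pwm.max_score - pwm.min_score)
    elif threshold_mode == "max":
        threshold = min_score_fraction * pwm.max_score
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    positions: list[tuple[int, str]] = []
    fwd = _scan_one_strand(_encode(seq), pwm, threshold)
    positions += [(int(p), "+") for p in fwd]
    if both_strands:
        rev = _scan_one_strand(_encode(reverse_complement(seq)), pwm, threshold)
        positions += [(int(p), "-") for p in rev]
    return ScanResult(count=len(positions), positions=positions)


@dataclass
class TFBSProfile:
    """Gene x matrix binding-site match counts with a binary presence view."""

    counts: pd.DataFrame

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0


def tfbs_profile_matrix(
    promoters: Sequence[PromoterRecord],
    pwms: Sequence[PositionWeightMatrix],
    min_score_fraction: float = 0.9,
    both_strands: bool = True,
    threshold_mode: str = "minmax",
) -> TFBSProfile:
    """Match counts of every PWM in every promoter."""
    ids = [p.gene_id for p in promoters]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids among promoters")
    data = np.zeros((len(promoters), len(pwms)), dtype=int)
    for i, prom in enumerate(promoters):
        for j, pwm in enumerate(pwms):
            data[i, j] = scan_pwm(
                prom.sequence, pwm, min_score_fraction, both_strands, threshold_mode
            ).count
    counts = pd.DataFrame(
        data,
        index=pd.Index(ids, name="gene_id"),
        columns=pd.Index([p.matrix_id for p in pwms], name="matrix_id"),
    )
    return TFBSProfile(counts)


def jaccard_matrix(profile: TFBSProfile | pd.DataFrame, weighted: bool = False) -> pd.DataFrame:
    """Gene x gene Jaccard similarity of binding-site content.

    Default: |intersection| / |union| of binarized presence sets (joint
    absence contributes nothing).  ``weighted`` uses the count-weighted
    generalization sum(min) / sum(max) instead.  Genes with an empty
    profile get similarity 0 to everything and 1 to themselves.
    """
    counts = profile.counts if isinstance(profile, TFBSProfile) else profile
    x = counts.to_numpy(dtype=float)
    if weighted:
        mins = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=2)
        maxs = np.maximum(x[:, None, :], x[None, :, :]).sum(axis=2)
    else:
        b = (x > 0).astype(float)
        mins = b @ b.T
        sizes = b.sum(axis=1)
        maxs = sizes[:, None] + sizes[None, :] - mins
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(maxs > 0, mins / np.where(maxs > 0, maxs, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=counts.index, columns=counts.index)
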