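"""Pairwise community similarity and per-sample diversity metrics.

Bray-Curtis (BC) similarity is the workhorse of the package:

    BC_ij = 2 * C_ij / (S_i + S_j)

where ``C_ij`` is the sum over OTUs of the lesser of the two abundances
and ``S_i``, ``S_j`` are the sample sizes in the same units.  Three input
conventions are supported:

``abundance`` (default)
    Each vector is first converted to relative abundance, so ``S_i = S_j
    = 1`` and ``BC`` reduces to the shared proportional mass
    ``sum_k min(p_k, q_k)``.  Invariant to sequencing depth.
``counts``
    The raw-count form with ``S`` the read totals.
``presence``
    Vectors are binarized; ``BC`` becomes the Dice coefficient
    ``2|X n Y| / (|X| + |Y|)``.

BC is 1 when the two communities have identical composition and 0 when
they share no OTU, and it varies linearly in between — which is what makes
the similarity-budget (BC%) decomposition meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln
from scipy.stats import entropy

from .exceptions import UndefinedSimilarityError, ValidationError
from .io_tables import OTUTable

__all__ = [
    "BCPair",
    "DiversityResult",
    "bray_curtis",
    "dice_similarity",
    "jaccard_similarity",
    "shannon",
    "rarefaction_expected_richness",
    "upgma",
    "bc_similarity_matrix",
    "shannon_table",
]

_MODES = ("abundance", "counts", "presence")


@dataclass(frozen=True)
class BCPair:
    """One Bray-Curtis comparison, keeping the formula's ingredients.

    ``c_ij`` is the sum of the lesser values over shared OTUs, ``s_i`` and
    ``s_j`` the sample sizes, all in the units implied by ``mode``.
    """

    bc: float
    c_ij: float
    s_i: float
    s_j: float
    mode: str
    sample_i: str | None = None
    sample_j: str | None = None


@dataclass(frozen=True)
class DiversityResult:
    """Shannon-Wiener index and observed richness of one sample."""

    h: float
    richness: int
    sample_id: str | None = None


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D vector")
    if not np.all(np.isfinite(arr)) or (arr < 0).any():
        raise ValidationError(f"{name} must be finite and non-negative")
    return arr


def bray_curtis(
    x,
    y,
    mode: str = "abundance",
    sample_i: str | None = None,
    sample_j: str | None = None,
) -> BCPair:
    """Bray-Curtis similarity between two OTU vectors on a common universe."""
    if mode not in _MODES:
        raise ValidationError(f"mode must be one of {_MODES}, got {mode!r}")
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.shape != yv.shape:
        raise ValidationError("x and y must be keyed by the same OTU universe")

    if mode == "presence":
        xv = (xv > 0).astype(float)
        yv = (yv > 0).astype(float)

    s_i = float(xv.sum())
    s_j = float(yv.sum())
    if mode == "abundance":
        if s_i == 0 or s_j == 0:
            raise UndefinedSimilarityError(
                "abundance-mode Bray-Curtis is undefined for an all-zero sample"
            )
        xv = xv / s_i
        yv = yv / s_j
        s_i = s_j = 1.0
    elif s_i + s_j == 0:
        raise UndefinedSimilarityError(
            "Bray-Curtis is undefined when both samples are empty"
        )

    c_ij = float(np.minimum(xv, yv).sum())
    bc = 2.0 * c_ij / (s_i + s_j)
    return BCPair(bc=bc, c_ij=c_ij, s_i=s_i, s_j=s_j, mode=mode,
                  sample_i=sample_i, sample_j=sample_j)


def dice_similarity(x, y) -> float:
    """Dice coefficient on presence/absence profiles (binarized BC)."""
    return bray_curtis(x, y, mode="presence").bc


def jaccard_similarity(x, y) -> float:
    """|intersection| / |union| of the two supports."""
    xv = _as_vector(x, "x") > 0
    yv = _as_vector(y, "y") > 0
    if xv.shape != yv.shape:
        raise ValidationError("x and y must be keyed by the same OTU universe")
    union = int(np.sum(xv | yv))
    if union == 0:
        raise UndefinedSimilarityError("Jaccard is undefined for two empty sets")
    return float(np.sum(xv & yv)) / union


def shannon(x, base: float | None = None, sample_id: str | None = None) -> DiversityResult:
    """Shannon-Wiener diversity H = -sum p_i log(p_i); natural log by default."""
    xv = _as_vector(x, "x")
    if xv.sum() == 0:
        raise ValidationError("Shannon index is undefined for an all-zero sample")
    h = float(entropy(xv, base=base))
    richness = int(np.count_nonzero(xv))
    return DiversityResult(h=h, richness=richness, sample_id=sample_id)


def shannon_table(table: OTUTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon index and richness, with compartment/time columns."""
    rows = []
    for sid in table.sample_ids:
        res = shannon(table.counts[sid].to_numpy(), base=base, sample_id=sid)
        key = table.metadata[sid]
        rows.append(
            {
                "sample_id": sid,
                "compartment": key.compartment,
                "time_index": key.time_index,
                "shannon": res.h,
                "richness": res.richness,
            }
        )
    return pd.DataFrame(rows)


def rarefaction_expected_richness(counts: Sequence[int], depth: int) -> float:
    """Expected number of OTUs observed in a depth-read subsample.

    Hypergeometric expectation ``sum_i [1 - C(N - N_i, d) / C(N, d)]``
    evaluated via log-gamma for numerical stability.  Monotone
    non-decreasing in ``depth``; equals observed richness at full depth.
    """
    arr = np.asarray(counts)
    if (arr < 0).any() or not np.all(arr == np.floor(arr)):
        raise ValidationError("counts must be non-negative integers")
    arr = arr.astype(np.int64)
    n_total = int(arr.sum())
    if not 1 <= depth <= n_total:
        raise ValidationError(
            f"depth must be in [1, {n_total}], got {depth}"
        )

    def log_choose(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1.0) - gammaln(n - k + 1)

    nz = arr[arr > 0]
    rest = n_total - nz  # reads not belonging to OTU i
    p_absent = np.zeros(len(nz))
    feasible = rest >= depth  # otherwise OTU i is always drawn
    p_absent[feasible] = np.exp(
        log_choose(rest[feasible].astype(float), depth) - log_choose(float(n_total), depth)
    )
    return float(np.sum(1.0 - p_absent))


def upgma(dist, labels: Sequence[str]):
    """UPGMA (average-linkage) clustering of a distance matrix.

    Returns a rooted ultrametric :class:`skbio.TreeNode`; each merge sits at
    half its merge distance, so cophenetic tip-tip distances reproduce an
    ultrametric input exactly.
    """
    from skbio import TreeNode

    d = np.asarray(dist, dtype=float)
    labels = list(labels)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if d.shape[0] != len(labels):
        raise ValidationError("labels must match the matrix dimension")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValidationError("distance matrix must have a zero diagonal")
    if (d < 0).any():
        raise ValidationError("distances must be non-negative")
    if len(labels) < 2:
        raise ValidationError("need at least two labels")

    z = linkage(squareform(d, checks=False), method="average")
    nodes: list = [TreeNode(name=lab) for lab in labels]
    heights = [0.0] * len(labels)
    for i, j, merge_dist, _ in z:
        left, right = nodes[int(i)], nodes[int(j)]
        h = merge_dist / 2.0
        left.length = h - heights[int(i)]
        right.length = h - heights[int(j)]
        nodes.append(TreeNode(children=[left, right]))
        heights.append(h)
    return nodes[-1]


def bc_similarity_matrix(
    table: OTUTable | pd.DataFrame, mode: str = "abundance"
) -> pd.DataFrame:
    """All-pairs Bray-Curtis similarity between a table's samples."""
    df = table.counts if isinstance(table, OTUTable) else table
    samples = list(df.columns)
    n = len(samples)
    mat = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            bc = bray_curtis(
                df[samples[a]].to_numpy(), df[samples[b]].to_numpy(), mode=mode
            ).bc
            mat[a, b] = mat[b, a] = bc
    return pd.DataFrame(mat, index=samples, columns=samples)
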