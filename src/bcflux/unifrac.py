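"""Weighted UniFrac and newick tree handling.

Weighted UniFrac is the phylogeny-aware counterpart of Bray-Curtis used
here to sanity-check BC-based analyses: the raw form is

    d_wu(x, y) = sum_b l_b * |p_b - q_b|

over branches ``b`` with length ``l_b``, where ``p_b`` and ``q_b`` are the
relative-abundance mass of the tips descending from ``b`` in each sample.
The normalized form divides by ``sum_b l_b * (p_b + q_b)``.  On a star
tree with unit branch lengths the raw form collapses to
``2 * (1 - BC similarity)`` — the two metrics are then exactly linearly
related, which anchors the cross-metric correlation check.

Tree plumbing delegates to :mod:`skbio`.
"""

from __future__ import annotations

import io
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import pearsonr

from .exceptions import ValidationError
from .io_tables import OTUTable
from .metrics import bray_curtis

__all__ = [
    "parse_newick",
    "write_newick",
    "weighted_unifrac",
    "bc_unifrac_correlation",
    "CorrelationResult",
]


def parse_newick(text: str):
    """Parse a newick string into a :class:`skbio.TreeNode`.

    Tip labels must be unique; branch lengths must be non-negative where
    present.
    """
    from skbio import TreeNode
    from skbio.io import NewickFormatError, UnrecognizedFormatError

    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except (ValueError, NewickFormatError, UnrecognizedFormatError) as exc:
        raise ValidationError(f"newick parse error: {exc}") from exc

    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate tip labels: {dupes}")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValidationError(f"negative branch length at {node.name!r}")
    return tree


def write_newick(tree) -> str:
    """Serialize a tree back to a newick string."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def weighted_unifrac(
    tree,
    x,
    y,
    taxa: Sequence[str] | None = None,
    normalized: bool = False,
) -> float:
    """Weighted UniFrac distance between two abundance vectors on a tree.

    ``x`` and ``y`` are either mappings taxon -> abundance or array-likes
    parallel to ``taxa``.  Abundances are converted to relative abundance
    internally, so raw counts and float profiles are both fine.  The raw
    form sums ``l_b * |p_b - q_b|`` over branches; the normalized form
    divides by ``sum_b l_b * (p_b + q_b)``.  Both are invariant to where a
    (branch-length-preserving) root is placed.
    """
    if isinstance(x, dict) or isinstance(y, dict):
        if not (isinstance(x, dict) and isinstance(y, dict)):
            raise ValidationError("x and y must both be mappings or both arrays")
        taxa = sorted(set(x) | set(y))
        xv = np.array([x.get(t, 0.0) for t in taxa], dtype=float)
        yv = np.array([y.get(t, 0.0) for t in taxa], dtype=float)
    else:
        if taxa is None:
            raise ValidationError("taxa must be given with array inputs")
        taxa = list(taxa)
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or len(taxa) != len(xv):
        raise ValidationError("x, y and taxa must have matching lengths")
    if (xv < 0).any() or (yv < 0).any():
        raise ValidationError("abundances must be non-negative")
    sx, sy = xv.sum(), yv.sum()
    if sx == 0 or sy == 0:
        raise ValidationError("weighted UniFrac is undefined for an empty sample")
    xv = xv / sx
    yv = yv / sy

    tips = {tip.name for tip in tree.tips()}
    missing = sorted(set(taxa) - tips)
    if missing:
        raise ValidationError(f"taxa absent from the tree: {missing}")
    p_of = dict(zip(taxa, xv))
    q_of = dict(zip(taxa, yv))

    # postorder accumulation of descendant-tip mass per branch
    mass: dict[int, tuple[float, float]] = {}
    num = 0.0
    den = 0.0
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            p, q = p_of.get(node.name, 0.0), q_of.get(node.name, 0.0)
        else:
            p = sum(mass[id(c)][0] for c in node.children)
            q = sum(mass[id(c)][1] for c in node.children)
        mass[id(node)] = (p, q)
        if node.parent is not None:
            length = node.length or 0.0
            num += length * abs(p - q)
            den += length * (p + q)
    if not normalized:
        return float(num)
    return float(num / den) if den > 0 else 0.0


class CorrelationResult(NamedTuple):
    pearson_r: float
    r_squared: float
    n_pairs: int


def bc_unifrac_correlation(
    table: OTUTable,
    tree,
    mode: str = "abundance",
    normalized: bool = True,
) -> CorrelationResult:
    """Pearson correlation between BC similarity and weighted UniFrac distance.

    Computed over all unordered sample pairs of the table.  Because BC is a
    similarity and UniFrac a distance, a strong *negative* r (r^2 near 1)
    indicates the two views of beta diversity agree.
    """
    samples = table.sample_ids
    if len(samples) < 3:
        raise ValidationError("need at least 3 samples to correlate the metrics")
    taxa = table.otu_ids
    tips = {tip.name for tip in tree.tips()}
    missing = sorted(set(taxa) - tips)
    if missing:
        raise ValidationError(f"taxa absent from the tree: {missing}")

    bcs, wus = [], []
    for a, b in combinations(samples, 2):
        xv = table.counts[a].to_numpy()
        yv = table.counts[b].to_numpy()
        bcs.append(bray_curtis(xv, yv, mode=mode).bc)
        wus.append(weighted_unifrac(tree, xv, yv, taxa=taxa, normalized=normalized))
    r = float(pearsonr(bcs, wus).statistic)
    return CorrelationResult(pearson_r=r, r_squared=r * r, n_pairs=len(bcs))
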