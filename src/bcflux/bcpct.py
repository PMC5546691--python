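"""Spatio-temporal BC% decomposition of microbiota influence.

The method asks, for a focal sample (compartment X at time n): how much of
its community composition is accounted for by its own past versus by the
compartments it exchanges microbes with?  The focal sample is compared,
via Bray-Curtis similarity, against up to five spatio-temporally adjacent
samples:

* its own compartment at the previous sampled time (the *inner* term),
* each spatially adjacent compartment at time n (*spatial-current*), and
* each spatially adjacent compartment at the previous time
  (*spatial-previous*).

Treating the adjacent BC values as a budget summing to 100%, the inner
percentage measures community stability while the external percentages
(current + previous term per source compartment) measure the influence of
each neighbor compartment.  Percentages are invariant to a common
rescaling of the BC values, and by construction
``inner% + sum of external% = 100`` for every defined decomposition.

The model interface mirrors the fit/results split of statistical
modelling packages: :class:`BCPercentModel` holds the data and options,
``fit()`` runs the decompositions and returns :class:`BCPercentResults`
with the long-format trajectory, interaction-network aggregation,
summary table and stacked-area plot.

BC% quantifies a similarity budget, not directed microbial transfer: a
large external share is evidence of association with a neighbor
compartment, not causal proof of migration from it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_tables import OTUTable, SampleKey
from .metrics import bray_curtis

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyModel",
    "NeighborRole",
    "NeighborSlot",
    "BCDecomposition",
    "InteractionNetwork",
    "build_neighbor_set",
    "bc_decompose",
    "bcpct_timeseries",
    "interaction_network",
    "trajectory_frame",
    "BCPercentModel",
    "BCPercentResults",
]


class NeighborRole(str, Enum):
    """How a neighbor relates to the focal sample."""

    INNER = "inner"                      # same compartment, previous time
    SPATIAL_CURRENT = "spatial_current"  # adjacent compartment, same time
    SPATIAL_PREVIOUS = "spatial_previous"  # adjacent compartment, previous time


@dataclass(frozen=True)
class AdjacencyModel:
    """Which compartments exchange microbes directly.

    Edges are unordered compartment pairs; no self-edges.  Influence in the
    BC% sense is computed between a focal compartment and each adjacent one.
    """

    compartments: frozenset[str]
    edges: frozenset[frozenset[str]] = frozenset()

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValidationError(f"edge {set(e)} must join two compartments")
            if not e <= self.compartments:
                raise ValidationError(
                    f"edge {set(e)} references undeclared compartments"
                )

    @classmethod
    def from_pairs(
        cls, compartments: Iterable[str], pairs: Iterable[tuple[str, str]]
    ) -> "AdjacencyModel":
        return cls(
            compartments=frozenset(compartments),
            edges=frozenset(frozenset(p) for p in pairs),
        )

    @classmethod
    def fully_connected(cls, compartments: Iterable[str]) -> "AdjacencyModel":
        comps = list(compartments)
        return cls.from_pairs(comps, combinations(comps, 2))

    def neighbors(self, compartment: str) -> set[str]:
        if compartment not in self.compartments:
            raise ValidationError(f"unknown compartment {compartment!r}")
        return {
            next(iter(e - {compartment})) for e in self.edges if compartment in e
        }


@dataclass(frozen=True)
class NeighborSlot:
    """One adjacent sample, its role, and any substitution lag.

    ``lag`` is ``requested nominal time - actual time`` and is nonzero only
    when the nearest-earlier policy substituted an older sample for a
    missing one.
    """

    key: SampleKey
    role: NeighborRole
    lag: int = 0


_POLICIES = ("nearest-earlier", "drop-slot")


def _times_by_compartment(available: Iterable[SampleKey]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for k in available:
        out.setdefault(k.compartment, []).append(k.time_index)
    for c in out:
        out[c] = sorted(set(out[c]))
    return out


def _prev_time(times: Sequence[int], t: int) -> int | None:
    earlier = [s for s in times if s < t]
    return max(earlier) if earlier else None


def build_neighbor_set(
    focal: SampleKey,
    available: Iterable[SampleKey],
    adj: AdjacencyModel,
    policy: str = "nearest-earlier",
) -> list[NeighborSlot]:
    """Enumerate the focal sample's spatio-temporally adjacent samples.

    With all samples present and ``k`` adjacent compartments this yields
    ``2k + 1`` slots (the classic five for a fully connected three-
    compartment system).  "Previous" means the previous *sampled* time of
    the relevant compartment, so irregular sampling grids are handled
    naturally.  Missing spatial-current samples are handled per ``policy``:
    ``"nearest-earlier"`` substitutes that compartment's latest sample
    before time n (recording the lag); ``"drop-slot"`` leaves the slot out,
    renormalizing the budget over the remaining neighbors.
    """
    if policy not in _POLICIES:
        raise ValidationError(f"policy must be one of {_POLICIES}, got {policy!r}")
    avail = set(available)
    if focal not in avail:
        raise ValidationError(f"focal sample {focal} not among available samples")
    times = _times_by_compartment(avail)
    n = focal.time_index
    slots: list[NeighborSlot] = []

    t_inner = _prev_time(times.get(focal.compartment, []), n)
    if t_inner is not None:
        slots.append(
            NeighborSlot(SampleKey(focal.compartment, t_inner), NeighborRole.INNER)
        )

    for other in sorted(adj.neighbors(focal.compartment)):
        other_times = times.get(other, [])
        cur_time: int | None = None
        if n in other_times:
            cur_time = n
        elif policy == "nearest-earlier":
            cur_time = _prev_time(other_times, n)
        if cur_time is not None:
            slots.append(
                NeighborSlot(
                    SampleKey(other, cur_time),
                    NeighborRole.SPATIAL_CURRENT,
                    lag=n - cur_time,
                )
            )
        prev_ref = cur_time if cur_time is not None else n
        prev_time = _prev_time(other_times, prev_ref)
        if prev_time is not None:
            slots.append(
                NeighborSlot(
                    SampleKey(other, prev_time),
                    NeighborRole.SPATIAL_PREVIOUS,
                    # lag relative to the focal's nominal previous slot is not
                    # well defined on irregular grids; record offset from n
                    lag=n - prev_time,
                )
            )
    return slots


@dataclass(frozen=True)
class BCDecomposition:
    """BC% decomposition of one focal sample.

    ``terms`` pairs each neighbor slot with its raw BC value and its share
    of the 100% budget.  ``defined`` is False when the similarity budget is
    zero (the focal sample resembles none of its neighbors); undefined
    decompositions carry no percentages and are excluded from aggregates.
    ``boundary`` flags decompositions with fewer than the full slot set
    (e.g. the first time point, which has no previous samples).
    """

    focal: SampleKey
    terms: tuple[tuple[NeighborSlot, float, float | None], ...]
    inner_pct: float | None
    external_pct: Mapping[str, float]
    defined: bool
    boundary: bool

    @property
    def n_neighbors(self) -> int:
        return len(self.terms)

    @property
    def total_external_pct(self) -> float | None:
        if not self.defined:
            return None
        return float(sum(self.external_pct.values()))


def bc_decompose(
    focal: SampleKey,
    table: OTUTable,
    adj: AdjacencyModel,
    mode: str = "abundance",
    policy: str = "nearest-earlier",
) -> BCDecomposition:
    """Decompose one focal sample's similarity budget into BC percentages."""
    key_to_sid = {k: s for s, k in table.metadata.items()}
    if focal not in key_to_sid:
        raise ValidationError(f"no sample with key {focal}")
    slots = build_neighbor_set(focal, table.metadata.values(), adj, policy=policy)
    if not slots:
        raise ValidationError(f"sample {focal} has no spatio-temporal neighbors")

    # bray_curtis normalizes internally in abundance mode; raw counts suffice
    counts = table.counts
    focal_vec = counts[key_to_sid[focal]].to_numpy()
    if focal_vec.sum() == 0:
        raise ValidationError(f"focal sample {focal} has zero total count")

    bcs = []
    for slot in slots:
        vec = counts[key_to_sid[slot.key]].to_numpy()
        bcs.append(
            bray_curtis(
                focal_vec,
                vec,
                mode=mode,
                sample_i=key_to_sid[focal],
                sample_j=key_to_sid[slot.key],
            ).bc
        )
    total = float(sum(bcs))
    defined = total > 0.0

    adjacent = sorted(adj.neighbors(focal.compartment))
    full_slots = 1 + 2 * len(adjacent)
    boundary = len(slots) < full_slots

    if defined:
        pcts: list[float | None] = [100.0 * b / total for b in bcs]
    else:
        pcts = [None] * len(bcs)

    inner_pct: float | None = None
    external: dict[str, float] = {c: 0.0 for c in adjacent if any(
        s.key.compartment == c for s in slots)}
    if defined:
        # no inner slot (first time point) leaves the stability share at 0
        inner_pct = 0.0
        for slot, pct in zip(slots, pcts):
            assert pct is not None
            if slot.role is NeighborRole.INNER:
                inner_pct += pct
            else:
                external[slot.key.compartment] += pct
    return BCDecomposition(
        focal=focal,
        terms=tuple(zip(slots, (float(b) for b in bcs), pcts)),
        inner_pct=inner_pct,
        external_pct=external,
        defined=defined,
        boundary=boundary,
    )


def bcpct_timeseries(
    table: OTUTable,
    adj: AdjacencyModel,
    mode: str = "abundance",
    policy: str = "nearest-earlier",
) -> list[BCDecomposition]:
    """Decompose every sample that has at least one neighbor, in time order."""
    keys = sorted(
        table.metadata.values(), key=lambda k: (k.time_index, k.compartment)
    )
    if any(k.replicate is not None for k in keys):
        raise ValidationError(
            "replicate samples are ambiguous for neighbor lookup; pool or "
            "subset to one sample per (compartment, time) first"
        )
    times = sorted({k.time_index for k in keys})
    decomps: list[BCDecomposition] = []
    for key in keys:
        slots = build_neighbor_set(key, keys, adj, policy=policy)
        if not slots:
            continue
        decomps.append(bc_decompose(key, table, adj, mode=mode, policy=policy))
    if not decomps:
        raise ValidationError(
            "no sample has any spatio-temporal neighbor "
            f"(times={times}, adjacency={sorted(map(set, adj.edges))})"
        )
    n_undef = sum(1 for d in decomps if not d.defined)
    if n_undef:
        logger.warning(
            "%d of %d decompositions have a zero similarity budget and are "
            "reported as undefined",
            n_undef,
            len(decomps),
        )
    return decomps


def trajectory_frame(decomps: Iterable[BCDecomposition]) -> pd.DataFrame:
    """Long-format trajectory: one row per (focal sample, neighbor term)."""
    rows = []
    for d in decomps:
        for slot, bc, pct in d.terms:
            rows.append(
                {
                    "compartment": d.focal.compartment,
                    "time_index": d.focal.time_index,
                    "role": slot.role.value,
                    "source": slot.key.compartment,
                    "source_time": slot.key.time_index,
                    "lag": slot.lag,
                    "bc": bc,
                    "pct": np.nan if pct is None else pct,
                    "defined": d.defined,
                    "boundary": d.boundary,
                    "n_neighbors": d.n_neighbors,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class InteractionNetwork:
    """Windowed aggregate of BC% decompositions as a directed network.

    ``nodes`` maps each compartment to its mean inner BC% over the window
    (circle diameter in the usual visualization); ``edges`` maps
    ``(source, target)`` to the mean total external BC% that ``source``
    contributes to ``target`` (current + previous term).  ``edges_avg``
    reports the mean of the two terms' average instead of their sum (half
    the edge weight when both slots are present).  For every target with
    fully defined decompositions, node value + incoming edge weights = 100.
    """

    window: tuple[int, int]
    nodes: Mapping[str, float]
    edges: Mapping[tuple[str, str], float]
    edges_avg: Mapping[tuple[str, str], float]
    n_decompositions: int

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(window=self.window)
        for comp, inner in self.nodes.items():
            g.add_node(comp, inner_pct=inner)
        for (src, tgt), w in self.edges.items():
            g.add_edge(src, tgt, external_pct=w, external_pct_avg=self.edges_avg[(src, tgt)])
        return g

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "nodes": {c: v for c, v in self.nodes.items()},
            "edges": [
                {
                    "source": s,
                    "target": t,
                    "external_pct": w,
                    "external_pct_avg": self.edges_avg[(s, t)],
                }
                for (s, t), w in self.edges.items()
            ],
            "n_decompositions": self.n_decompositions,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def interaction_network(
    decomps: Sequence[BCDecomposition],
    windows: Sequence[tuple[int, int]],
) -> list[InteractionNetwork]:
    """Aggregate decompositions over time windows into interaction networks.

    Each window is an inclusive ``(t_min, t_max)`` range over focal time
    indices; only defined decompositions contribute.
    """
    networks = []
    for t0, t1 in windows:
        in_window = [
            d for d in decomps if d.defined and t0 <= d.focal.time_index <= t1
        ]
        if not in_window:
            raise ValidationError(f"window ({t0}, {t1}) contains no defined decomposition")
        nodes: dict[str, float] = {}
        edges: dict[tuple[str, str], float] = {}
        edges_avg: dict[tuple[str, str], float] = {}
        by_target: dict[str, list[BCDecomposition]] = {}
        for d in in_window:
            by_target.setdefault(d.focal.compartment, []).append(d)
        for target, ds in sorted(by_target.items()):
            nodes[target] = float(np.mean([d.inner_pct for d in ds]))
            sources = sorted({c for d in ds for c in d.external_pct})
            for src in sources:
                sums, avgs = [], []
                for d in ds:
                    if src not in d.external_pct:
                        continue
                    n_slots = sum(
                        1
                        for slot, _, _ in d.terms
                        if slot.key.compartment == src
                        and slot.role is not NeighborRole.INNER
                    )
                    sums.append(d.external_pct[src])
                    avgs.append(d.external_pct[src] / max(n_slots, 1))
                edges[(src, target)] = float(np.mean(sums))
                edges_avg[(src, target)] = float(np.mean(avgs))
        networks.append(
            InteractionNetwork(
                window=(t0, t1),
                nodes=nodes,
                edges=edges,
                edges_avg=edges_avg,
                n_decompositions=len(in_window),
            )
        )
    return networks


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class BCPercentModel:
    """BC% spatio-temporal influence model over an OTU table.

    Parameters
    ----------
    table
        Validated :class:`OTUTable` with compartment/time metadata.
    adjacency
        :class:`AdjacencyModel`; defaults to all compartments pairwise
        connected.
    mode
        ``"abundance"`` (relative abundance, default), ``"counts"`` or
        ``"presence"`` — the Bray-Curtis input convention.
    policy
        Missing-sample policy for spatial-current slots:
        ``"nearest-earlier"`` (default) or ``"drop-slot"``.

    Examples
    --------
    >>> model = BCPercentModel(table)
    >>> res = model.fit()
    >>> res.inner_series()          # compartment x time inner BC%
    >>> res.interaction_network()   # first/last-window networks
    """

    def __init__(
        self,
        table: OTUTable,
        adjacency: AdjacencyModel | None = None,
        mode: str = "abundance",
        policy: str = "nearest-earlier",
    ):
        if adjacency is None:
            adjacency = AdjacencyModel.fully_connected(table.compartments)
        self.table = table
        self.adjacency = adjacency
        self.mode = mode
        self.policy = policy

    @classmethod
    def from_dataframes(
        cls,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        **kwargs,
    ) -> "BCPercentModel":
        """Build from a counts DataFrame and a metadata DataFrame.

        ``metadata`` needs columns ``sample_id``, ``compartment``,
        ``time_index`` (``replicate`` optional).
        """
        meta = {}
        for row in metadata.itertuples(index=False):
            rep = getattr(row, "replicate", None)
            if rep is not None and (pd.isna(rep) or rep == ""):
                rep = None
            meta[str(row.sample_id)] = SampleKey(
                str(row.compartment), int(row.time_index), rep
            )
        return cls(OTUTable(counts, meta), **kwargs)

    @classmethod
    def from_files(
        cls, table_path, metadata_path, **kwargs
    ) -> "BCPercentModel":
        from .io_tables import read_otu_table

        return cls(read_otu_table(table_path, metadata_path), **kwargs)

    def fit(self) -> "BCPercentResults":
        """Run the decomposition for every sample with neighbors."""
        decomps = bcpct_timeseries(
            self.table, self.adjacency, mode=self.mode, policy=self.policy
        )
        return BCPercentResults(self, decomps)


class BCPercentResults:
    """Fitted BC% decompositions with aggregation, summary and plotting."""

    def __init__(self, model: BCPercentModel, decompositions: list[BCDecomposition]):
        self.model = model
        self.decompositions = decompositions
        self.trajectory = trajectory_frame(decompositions)

    # -- accessors ---------------------------------------------------------
    def inner_series(self, include_boundary: bool = True) -> pd.DataFrame:
        """Inner BC% per compartment (rows) and time (columns)."""
        rows = []
        for d in self.decompositions:
            if not d.defined:
                continue
            if not include_boundary and d.boundary:
                continue
            rows.append(
                {
                    "compartment": d.focal.compartment,
                    "time_index": d.focal.time_index,
                    "inner_pct": d.inner_pct,
                }
            )
        df = pd.DataFrame(rows)
        return df.pivot(index="compartment", columns="time_index", values="inner_pct")

    def external_series(self, target: str) -> pd.DataFrame:
        """Total external BC% on ``target`` per source compartment over time."""
        rows = []
        for d in self.decompositions:
            if d.focal.compartment != target or not d.defined:
                continue
            for src, pct in d.external_pct.items():
                rows.append(
                    {"source": src, "time_index": d.focal.time_index, "pct": pct}
                )
        df = pd.DataFrame(rows)
        return df.pivot(index="source", columns="time_index", values="pct")

    def _default_windows(self) -> list[tuple[int, int]]:
        times = sorted(
            {d.focal.time_index for d in self.decompositions if d.defined}
        )
        return [(times[0], times[0]), (times[-1], times[-1])]

    def interaction_network(
        self, windows: Sequence[tuple[int, int]] | None = None
    ) -> list[InteractionNetwork]:
        """Windowed interaction networks (default: first and last time point)."""
        if windows is None:
            windows = self._default_windows()
        return interaction_network(self.decompositions, windows)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary: per-compartment inner/external BC%."""
        inner = self.inner_series()
        lines = [
            "BC% spatio-temporal decomposition",
            f"  samples: {len(self.model.table.sample_ids)}, "
            f"OTUs: {len(self.model.table.otu_ids)}, "
            f"mode: {self.model.mode}, policy: {self.model.policy}",
            f"  decompositions: {len(self.decompositions)} "
            f"({sum(1 for d in self.decompositions if not d.defined)} undefined, "
            f"{sum(1 for d in self.decompositions if d.boundary)} boundary)",
            "",
            "Inner BC% by compartment and time:",
            inner.round(1).to_string(),
            "",
            "Mean external BC% (source -> target):",
        ]
        times = sorted({d.focal.time_index for d in self.decompositions if d.defined})
        nets = interaction_network(
            self.decompositions, [(times[0], times[-1])]
        )
        for (src, tgt), w in sorted(nets[0].edges.items()):
            lines.append(f"  {src} -> {tgt}: {w:6.1f}%")
        return "\n".join(lines)

    def plot_stacked(self, compartment: str | None = None, ax=None):
        """Stacked-area plot of the BC% budget over time (one compartment)."""
        import matplotlib.pyplot as plt

        comps = (
            [compartment]
            if compartment is not None
            else sorted({d.focal.compartment for d in self.decompositions})
        )
        if ax is None:
            fig, axes = plt.subplots(
                len(comps), 1, figsize=(7, 2.6 * len(comps)), squeeze=False
            )
            axes = [a for row in axes for a in row]
        else:
            if len(comps) != 1:
                raise ValidationError("pass a single compartment with an explicit ax")
            axes = [ax]
            fig = ax.figure
        traj = self.trajectory[self.trajectory["defined"]]
        for a, comp in zip(axes, comps):
            sub = traj[traj["compartment"] == comp]
            piv = (
                sub.assign(term=sub["source"] + ":" + sub["role"])
                .pivot_table(index="time_index", columns="term", values="pct",
                             aggfunc="sum")
                .fillna(0.0)
            )
            a.stackplot(piv.index, piv.T.to_numpy(), labels=list(piv.columns))
            a.set_ylabel(f"{comp} BC%")
            a.set_ylim(0, 100)
            a.legend(fontsize=6, ncol=2)
        axes[-1].set_xlabel("time")
        return fig
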