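"""Three-set OTU-sharing arithmetic (Venn regions and percentages).

Given three compartments, every OTU falls into one of seven exclusive
regions: unique to one compartment, shared by exactly one pair, or shared
by all three (the "core").  Regions can be derived either from OTU
memberships in a table, or from published inclusive counts (set totals,
pairwise intersections that *include* the triple overlap, and the triple
overlap) by inclusion-exclusion.  Percentages are reported per compartment
relative to that compartment's own OTU total, so differently sized
datasets stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import ConsistencyError, ValidationError
from .io_tables import OTUTable

__all__ = ["VennCounts3", "venn_from_memberships", "venn_from_counts",
           "sharing_percentages"]


@dataclass(frozen=True)
class VennCounts3:
    """Exclusive Venn region counts for three labelled sets.

    ``regions`` is keyed by sorted label tuples: three singletons (unique
    OTUs), three pairs (shared by exactly those two), and one triple.
    ``pairwise_inclusive`` keeps the inclusive pair counts (triple included)
    as supplied or derived.
    """

    labels: tuple[str, str, str]
    totals: Mapping[str, int]
    pairwise_inclusive: Mapping[tuple[str, str], int]
    triple: int
    regions: Mapping[tuple[str, ...], int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def region(self, *labels: str) -> int:
        return self.regions[tuple(sorted(labels))]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def venn_from_counts(
    labels: Sequence[str],
    totals: Mapping[str, int],
    pairwise_inclusive: Mapping[tuple[str, str], int],
    triple: int,
) -> VennCounts3:
    """Derive exclusive regions from inclusive counts by inclusion-exclusion.

    ``pairwise_inclusive[(a, b)]`` must count OTUs in both a and b
    *including* those also in the third set.  Raises
    :class:`ConsistencyError` if any derived region would be negative.
    """
    labels = tuple(sorted(labels))
    if len(labels) != 3 or len(set(labels)) != 3:
        raise ValidationError("exactly three distinct labels are required")
    pairs = {_pair_key(*k): int(v) for k, v in pairwise_inclusive.items()}
    expected_pairs = {_pair_key(a, b) for a, b in combinations(labels, 2)}
    if set(pairs) != expected_pairs:
        raise ValidationError(
            f"pairwise counts must cover exactly {sorted(expected_pairs)}"
        )
    if triple < 0 or any(v < 0 for v in totals.values()) or any(
        v < 0 for v in pairs.values()
    ):
        raise ValidationError("counts must be non-negative")

    regions: dict[tuple[str, ...], int] = {tuple(labels): int(triple)}
    for a, b in combinations(labels, 2):
        excl = pairs[_pair_key(a, b)] - triple
        if excl < 0:
            raise ConsistencyError(
                f"region {a}&{b} (exclusive) is negative: pairwise count "
                f"{pairs[_pair_key(a, b)]} < triple overlap {triple}"
            )
        regions[_pair_key(a, b)] = excl
    for a in labels:
        others = [o for o in labels if o != a]
        unique = (
            int(totals[a])
            - pairs[_pair_key(a, others[0])]
            - pairs[_pair_key(a, others[1])]
            + triple
        )
        if unique < 0:
            raise ConsistencyError(f"region unique-to-{a} is negative ({unique})")
        regions[(a,)] = unique
    return VennCounts3(
        labels=labels,
        totals={a: int(totals[a]) for a in labels},
        pairwise_inclusive=pairs,
        triple=int(triple),
        regions=regions,
    )


def venn_from_memberships(table: OTUTable) -> VennCounts3:
    """Exclusive Venn regions from a table grouped by compartment.

    An OTU belongs to a compartment if it has a nonzero count in any sample
    of that compartment.  Exactly three compartments are required.
    """
    groups = table.samples_by_compartment()
    if len(groups) != 3:
        raise ValidationError(
            f"exactly 3 compartments required, found {sorted(groups)}"
        )
    members = {
        comp: set(table.counts.index[(table.counts[sids] > 0).any(axis=1)])
        for comp, sids in groups.items()
    }
    labels = tuple(sorted(members))
    totals = {c: len(m) for c, m in members.items()}
    pairwise = {
        _pair_key(a, b): len(members[a] & members[b])
        for a, b in combinations(labels, 2)
    }
    triple = len(members[labels[0]] & members[labels[1]] & members[labels[2]])
    return venn_from_counts(labels, totals, pairwise, triple)


def sharing_percentages(v: VennCounts3, decimals: int | None = 1) -> pd.DataFrame:
    """Per-compartment percentage of each region class, long format.

    For each set, the unique region, the two exclusive pairwise regions and
    the triple region are expressed as percentages of that set's total; the
    four percentages of a set sum to 100 (within rounding).  ``decimals``
    rounds the output (``None`` keeps full precision).
    """
    rows = []
    for a in v.labels:
        total = v.totals[a]
        if total <= 0:
            raise ValidationError(f"set {a!r} has zero total; percentages undefined")
        others = [o for o in v.labels if o != a]
        parts = [
            ("unique", (a,)),
            (f"shared_{_pair_key(a, others[0])[0]}{_pair_key(a, others[0])[1]}",
             _pair_key(a, others[0])),
            (f"shared_{_pair_key(a, others[1])[0]}{_pair_key(a, others[1])[1]}",
             _pair_key(a, others[1])),
            ("core", tuple(v.labels)),
        ]
        for name, key in parts:
            count = v.regions[key]
            pct = 100.0 * count / total
            if decimals is not None:
                pct = round(pct, decimals)
            rows.append(
                {"set": a, "region": name, "count": count, "pct": pct}
            )
    return pd.DataFrame(rows)
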