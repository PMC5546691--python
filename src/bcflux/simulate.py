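"""Multi-compartment community simulator with known exchange dynamics.

The simulator produces OTU-count time series whose ground truth
(migration rates, drift strength) is known, so the BC% machinery can be
validated end to end: does the method recover which compartment
influences which, and does it see stabilization when exchange decays?

Latent dynamics per compartment ``c``::

    pi_c(t+1) = (1 - sum_c' m_t(c'->c)) * perturb(pi_c(t))
                + sum_c' m_t(c'->c) * pi_c'(t)

where ``perturb`` resamples the profile from a Dirichlet centered on it
(concentration * profile as the parameter vector; higher concentration =
weaker drift, infinite concentration = no drift).  Migration mixes the
*latent* profiles — exchange happens in the water column before any
sequencing — and observed counts are a multinomial draw at the configured
depth, modelling finite sequencing effort.

Defaults mirror a small aquaculture-scale survey: three compartments
(consumer A, substrate S, water W), 11 time points, ~8,000 reads per
sample, 300 OTUs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_tables import OTUTable, SampleKey

__all__ = ["SimConfig", "SimTruth", "simulate_system", "stabilizing_scenario",
           "make_random_tree"]

Migration = Mapping[tuple[str, str], float]


def _default_migration() -> Migration:
    # modest symmetric exchange between all pairs
    pairs = [("A", "S"), ("S", "A"), ("A", "W"), ("W", "A"), ("S", "W"), ("W", "S")]
    return {p: 0.05 for p in pairs}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    ``migration`` is either one mapping ``(source, target) -> rate`` used at
    every step, or a sequence of ``n_times - 1`` such mappings (one per
    transition).  Per-target immigration must sum to <= 1 at every step.
    ``drift_concentration`` is likewise scalar or per-step; ``math.inf``
    disables drift.  ``init_overlap`` is the fraction of the OTU pool shared
    by all compartments at t=0 (the rest is split into private pools);
    ``init_overlap=1.0`` additionally starts every compartment from the
    same initial community.
    """

    n_otus: int = 300
    compartments: tuple[str, ...] = ("A", "S", "W")
    n_times: int = 11
    depth: int = 8000
    migration: Migration | Sequence[Migration] = field(
        default_factory=_default_migration
    )
    drift_concentration: float | Sequence[float] = 200.0
    init_overlap: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_times < 2:
            raise ValidationError("n_times must be >= 2")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if not 0.0 <= self.init_overlap <= 1.0:
            raise ValidationError("init_overlap must be in [0, 1]")
        if self.n_otus < len(self.compartments):
            raise ValidationError("need at least one OTU per compartment")
        for step in self.migration_schedule():
            self._check_migration(step)

    def migration_schedule(self) -> list[Migration]:
        m = self.migration
        if isinstance(m, Mapping):
            return [m] * (self.n_times - 1)
        m = list(m)
        if len(m) != self.n_times - 1:
            raise ValidationError(
                f"per-step migration needs {self.n_times - 1} entries, got {len(m)}"
            )
        return m

    def drift_schedule(self) -> list[float]:
        d = self.drift_concentration
        if isinstance(d, (int, float)):
            return [float(d)] * (self.n_times - 1)
        d = [float(v) for v in d]
        if len(d) != self.n_times - 1:
            raise ValidationError(
                f"per-step drift needs {self.n_times - 1} entries, got {len(d)}"
            )
        return d

    def _check_migration(self, step: Migration) -> None:
        comps = set(self.compartments)
        incoming: dict[str, float] = {c: 0.0 for c in comps}
        for (src, tgt), rate in step.items():
            if src not in comps or tgt not in comps:
                raise ValidationError(f"migration edge ({src}, {tgt}) unknown")
            if src == tgt:
                raise ValidationError(f"self-migration ({src}) is not allowed")
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"migration rate {rate} outside [0, 1]")
            incoming[tgt] += rate
        for c, total in incoming.items():
            if total > 1.0 + 1e-12:
                raise ValidationError(
                    f"immigration into {c} sums to {total} > 1"
                )


@dataclass(frozen=True)
class SimTruth:
    """A simulated system: config, latent profiles, and the observed table.

    ``latent[c]`` is an ``(n_times, n_otus)`` array of exact relative-
    abundance profiles; ``table`` holds the multinomial count draws with
    sample ids ``f"{compartment}{time}"``.
    """

    config: SimConfig
    latent: Mapping[str, np.ndarray]
    table: OTUTable


def _perturb(pi: np.ndarray, concentration: float, rng: np.random.Generator) -> np.ndarray:
    if math.isinf(concentration):
        return pi
    out = np.zeros_like(pi)
    support = pi > 0
    alpha = concentration * pi[support]
    out[support] = rng.dirichlet(alpha)
    return out


def simulate_system(config: SimConfig, seed: int | None = None) -> SimTruth:
    """Simulate latent profiles and sequenced counts; reproducible from seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    comps = list(config.compartments)
    n = config.n_otus

    # initial pools: a shared block plus near-equal private blocks
    n_shared = int(round(config.init_overlap * n))
    private = n - n_shared
    sizes = [private // len(comps)] * len(comps)
    for i in range(private - sum(sizes)):
        sizes[i] += 1
    pools: dict[str, np.ndarray] = {}
    offset = n_shared
    for c, size in zip(comps, sizes):
        idx = np.concatenate(
            [np.arange(n_shared), np.arange(offset, offset + size)]
        ).astype(int)
        pools[c] = idx
        offset += size

    latent = {c: np.zeros((config.n_times, n)) for c in comps}
    if config.init_overlap == 1.0:
        # fully shared pool: all compartments start from one common community
        pi0 = rng.dirichlet(np.ones(n))
        for c in comps:
            latent[c][0] = pi0
    else:
        for c in comps:
            pi0 = np.zeros(n)
            pi0[pools[c]] = rng.dirichlet(np.ones(len(pools[c])))
            latent[c][0] = pi0

    mig = config.migration_schedule()
    drift = config.drift_schedule()
    for t in range(config.n_times - 1):
        step = mig[t]
        old = {c: latent[c][t] for c in comps}
        for c in comps:
            incoming = np.zeros(n)
            total_in = 0.0
            for (src, tgt), rate in step.items():
                if tgt == c and rate > 0:
                    incoming += rate * old[src]
                    total_in += rate
            new = (1.0 - total_in) * _perturb(old[c], drift[t], rng) + incoming
            latent[c][t + 1] = new / new.sum()

    otu_ids = [f"OTU{i:04d}" for i in range(n)]
    counts: dict[str, np.ndarray] = {}
    metadata: dict[str, SampleKey] = {}
    for t in range(config.n_times):
        for c in comps:
            sid = f"{c}{t}"
            counts[sid] = rng.multinomial(config.depth, latent[c][t])
            metadata[sid] = SampleKey(c, t)
    table = OTUTable(pd.DataFrame(counts, index=otu_ids), metadata)
    return SimTruth(config=config, latent=latent, table=table)


def stabilizing_scenario(
    n_times: int = 11,
    seed: int | None = None,
    compartments: tuple[str, ...] = ("A", "S", "W"),
) -> SimConfig:
    """A config encoding a system that stabilizes over time.

    Migration decays geometrically (factor 0.65 per step) from initially
    strong substrate<->consumer exchange, while the drift concentration
    grows mildly (50 * 1.2^t).  Early on, heavy immigration both perturbs
    each community and keeps the compartments alike (low inner BC%); as
    exchange dies out, persistent independent drift makes the compartments
    diverge from each other while each tracks its own past ever more
    closely — the regime in which inner BC% rises and external BC% falls.
    """
    if n_times < 4:
        raise ValidationError("a stabilizing scenario needs n_times >= 4")
    if tuple(compartments) != ("A", "S", "W"):
        raise ValidationError("the shipped scenario is defined for ('A','S','W')")
    m0: Migration = {
        ("S", "A"): 0.35,
        ("W", "A"): 0.06,
        ("A", "S"): 0.30,
        ("W", "S"): 0.07,
        ("S", "W"): 0.10,
        ("A", "W"): 0.05,
    }
    schedule = [
        {edge: rate * (0.65 ** t) for edge, rate in m0.items()}
        for t in range(n_times - 1)
    ]
    drift = [50.0 * (1.2 ** t) for t in range(n_times - 1)]
    return SimConfig(
        n_times=n_times,
        migration=schedule,
        drift_concentration=drift,
        init_overlap=0.3,
        seed=seed,
    )


def make_random_tree(otu_ids: Sequence[str], seed: int | None = None,
                     scale: float = 0.1):
    """Random bifurcating rooted tree over the ids (for UniFrac testing).

    Built by repeatedly joining two uniformly chosen subtrees; branch
    lengths are exponential with mean ``scale``.  ``n`` tips yield ``n - 1``
    internal nodes.
    """
    from skbio import TreeNode

    ids = list(otu_ids)
    if len(ids) < 2:
        raise ValidationError("need at least 2 OTU ids")
    if len(set(ids)) != len(ids):
        raise ValidationError("OTU ids must be unique")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=i, length=float(rng.exponential(scale))) for i in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = TreeNode(length=float(rng.exponential(scale)), children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root
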