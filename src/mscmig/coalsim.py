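"""Backward-in-time structured coalescent simulation with migration bands.

Simulates per-locus genealogies under a :class:`~mscmig.demography.DemographicModel`:
within population ``b`` each unordered pair of lineages coalesces at rate
``2/theta_b``; each lineage residing in the target population of a band
``s -> t`` jumps (backward in time) into the source population at rate
``M``; at each ancestral divergence time the lineages of the two child
populations merge into the parent.  Event scheduling uses exponential
competing risks with rates recomputed exactly at every population-boundary
time, so no discretization error is introduced.

Times are mutation-scaled (expected substitutions per site), matching the
units of ``tau`` and ``theta``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np

from .demography import DemographicModel, ModelArrays

__all__ = ["SampleConfig", "Genealogy", "simulate_genealogy",
           "simulate_locus_set", "genealogy_to_newick",
           "write_migration_events_tsv"]


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample counts per leaf population.

    ``counts`` maps leaf-population names to non-negative integers; the
    total must be at least 1.  Sample (tip) names are generated as
    ``<population>_<i>`` in a fixed order: populations sorted by name,
    indices from 0.
    """

    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("sample counts must be >= 0")
        if self.total < 1:
            raise ValueError("need at least one sampled lineage")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def tip_names(self) -> list[str]:
        return [f"{pop}_{i}" for pop in sorted(self.counts)
                for i in range(self.counts[pop])]

    def tip_pops(self) -> list[str]:
        return [pop for pop in sorted(self.counts)
                for _ in range(self.counts[pop])]


class Genealogy:
    """Labelled binary coalescent tree with per-lineage migration events.

    Nodes ``0 .. n_tips-1`` are tips (time 0); internal nodes are appended
    in coalescence order.  ``node_pop[i]`` is the population in which the
    node's lineages coalesced (for tips, the sampled population).  The edge
    of node ``i`` runs from ``time[i]`` up to ``time[parent[i]]``; its
    migration events ``(time, band_index)`` are stored in increasing time
    order.  Between events a lineage's population changes only by implicit
    merges at ancestral divergence times.
    """

    def __init__(self, n_tips: int, parent, child1, child2, time, node_pop,
                 events: list[list[tuple[float, int]]],
                 tip_names: list[str], model_arrays: ModelArrays):
        self.n_tips = n_tips
        self.parent = np.asarray(parent, dtype=np.int64)
        self.child1 = np.asarray(child1, dtype=np.int64)
        self.child2 = np.asarray(child2, dtype=np.int64)
        self.time = np.asarray(time, dtype=np.float64)
        self.node_pop = np.asarray(node_pop, dtype=np.int64)
        self.events = [list(ev) for ev in events]
        self.tip_names = list(tip_names)
        self.arrays = model_arrays

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def n_migrations(self) -> int:
        return sum(len(ev) for ev in self.events)

    def pop_on_edge(self, node: int, t: float) -> int:
        """Population of the lineage above ``node`` at time ``t``.

        ``t`` must lie within the edge (node time <= t < parent time; the
        root lineage extends to infinity).
        """
        arr = self.arrays
        p = int(self.node_pop[node])
        for ev_t, band in self.events[node]:
            if ev_t <= t:
                p = int(arr.band_src[band])
            else:
                break
        return arr.pop_at(p, t)

    def branch_lengths(self) -> np.ndarray:
        """Edge lengths in scaled time (0 for the root's virtual edge)."""
        out = np.zeros(self.n_nodes)
        has_par = self.parent >= 0
        out[has_par] = self.time[self.parent[has_par]] - self.time[has_par]
        return out

    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        order = np.argsort(self.time, kind="stable")
        return order

    def copy(self) -> "Genealogy":
        return Genealogy(self.n_tips, self.parent.copy(), self.child1.copy(),
                         self.child2.copy(), self.time.copy(),
                         self.node_pop.copy(), [list(e) for e in self.events],
                         self.tip_names, self.arrays)


def _resolve(model: DemographicModel | ModelArrays) -> ModelArrays:
    if isinstance(model, ModelArrays):
        return model
    return model.as_arrays()


def simulate_genealogy(model: DemographicModel | ModelArrays,
                       samples: SampleConfig,
                       rng: np.random.Generator | int) -> Genealogy:
    """Draw one genealogy under the structured coalescent with migration.

    Parameters
    ----------
    model : DemographicModel or ModelArrays
        The demography; all bands and divergence boundaries are honoured.
    samples : SampleConfig
        Haploid sample counts per leaf population.
    rng : numpy Generator or int seed
        Source of randomness; a given seed reproduces the genealogy exactly.
    """
    arr = _resolve(model)
    rng = np.random.default_rng(rng)
    tip_pops = samples.tip_pops()
    for pop in samples.counts:
        if pop not in arr.index or arr.pop_c1[arr.index[pop]] >= 0:
            raise ValueError(f"{pop!r} is not a leaf population of the model")
    n = samples.total
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    child1 = np.full(n_nodes, -1, dtype=np.int64)
    child2 = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    node_pop = np.zeros(n_nodes, dtype=np.int64)
    events: list[list[tuple[float, int]]] = [[] for _ in range(n_nodes)]
    node_pop[:n] = [arr.index[p] for p in tip_pops]

    if n == 1:
        return Genealogy(1, parent, child1, child2, time, node_pop, events,
                         samples.tip_names(), arr)

    pop_end = arr.pop_end
    boundaries = sorted(set(float(t) for t in arr.tau if t > 0))
    # active lineages: node index -> current population
    active: dict[int, int] = {i: int(node_pop[i]) for i in range(n)}
    x = 0.0
    next_node = n
    bi = 0
    nband = len(arr.band_M)
    while len(active) > 1:
        next_b = boundaries[bi] if bi < len(boundaries) else math.inf
        # per-population lineage counts
        kpop: dict[int, list[int]] = {}
        for node, p in active.items():
            kpop.setdefault(p, []).append(node)
        coal_rates = {}
        for p, nodes in kpop.items():
            k = len(nodes)
            if k >= 2:
                coal_rates[p] = k * (k - 1) / 2.0 * 2.0 / arr.theta[p]
        mig_rates = {}
        for j in range(nband):
            tgt = int(arr.band_tgt[j])
            lo = max(arr.tau[arr.band_src[j]], arr.tau[tgt])
            hi = min(pop_end[arr.band_src[j]], pop_end[tgt])
            if arr.band_M[j] > 0 and lo <= x < hi and tgt in kpop:
                mig_rates[j] = len(kpop[tgt]) * arr.band_M[j]
        total = sum(coal_rates.values()) + sum(mig_rates.values())
        if total > 0:
            wait = rng.exponential(1.0 / total)
        else:
            wait = math.inf
        if x + wait >= next_b:
            # advance to the boundary and merge child populations
            x = next_b
            bi += 1
            for node, p in list(active.items()):
                while pop_end[p] <= x:
                    p = int(arr.pop_parent[p])
                active[node] = p
            continue
        x += wait
        u = rng.uniform(0.0, total)
        acc = 0.0
        chosen = None
        for p, r in coal_rates.items():
            acc += r
            if u < acc:
                chosen = ("coal", p)
                break
        if chosen is None:
            for j, r in mig_rates.items():
                acc += r
                if u < acc:
                    chosen = ("mig", j)
                    break
        if chosen is None:  # numerical edge: fall back to last option
            chosen = ("mig", j) if mig_rates else ("coal", p)
        if chosen[0] == "coal":
            p = chosen[1]
            nodes = kpop[p]
            i_a, i_b = rng.choice(len(nodes), size=2, replace=False)
            a, b = nodes[i_a], nodes[i_b]
            node = next_node
            next_node += 1
            child1[node], child2[node] = min(a, b), max(a, b)
            parent[a] = parent[b] = node
            time[node] = x
            node_pop[node] = p
            del active[a], active[b]
            active[node] = p
        else:
            j = chosen[1]
            nodes = kpop[int(arr.band_tgt[j])]
            lin = nodes[int(rng.integers(len(nodes)))]
            events[lin].append((x, j))
            active[lin] = int(arr.band_src[j])
    return Genealogy(n, parent, child1, child2, time, node_pop, events,
                     samples.tip_names(), arr)


def simulate_locus_set(model: DemographicModel | ModelArrays,
                       samples: SampleConfig, n_loci: int,
                       seed: int) -> list[Genealogy]:
    """Simulate ``n_loci`` independent (unlinked) genealogies.

    Per-locus seeds are derived from ``seed`` with a counter-based spawn,
    so locus ``k`` is reproducible independently of the others.
    """
    if n_loci < 1:
        raise ValueError(f"n_loci must be >= 1, got {n_loci}")
    arr = _resolve(model)
    children = np.random.SeedSequence(seed).spawn(n_loci)
    return [simulate_genealogy(arr, samples, np.random.default_rng(ss))
            for ss in children]


def genealogy_to_newick(g: Genealogy) -> str:
    """Newick string with branch lengths in scaled time."""
    def rec(i: int) -> str:
        if g.child1[i] < 0:
            label = g.tip_names[i]
        else:
            label = f"({rec(int(g.child1[i]))},{rec(int(g.child2[i]))})"
        par = g.parent[i]
        if par < 0:
            return label
        return f"{label}:{g.time[par] - g.time[i]:.10g}"
    return rec(g.root) + ";"


def write_migration_events_tsv(genealogies: list[Genealogy], path) -> None:
    """Write all migration events as a TSV sidecar.

    Columns: locus index, lineage (lower node of the edge), event time,
    from-population, to-population (direction backward in time: the lineage
    leaves the band's target and enters its source).
    """
    buf = io.StringIO()
    buf.write("locus\tlineage\ttime\tfrom\tto\n")
    for k, g in enumerate(genealogies):
        arr = g.arrays
        for node in range(g.n_nodes):
            for t, j in g.events[node]:
                frm = arr.names[arr.band_tgt[j]]
                to = arr.names[arr.band_src[j]]
                buf.write(f"{k}\t{node}\t{t:.10g}\t{frm}\t{to}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
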