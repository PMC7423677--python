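"""Demographic models for multispecies coalescent inference with migration.

A demographic model is a rooted population tree with one mutation-scaled
size parameter per branch (``theta = 4*Ne*mu``), one mutation-scaled
divergence time per internal node (``tau = T*mu/g``), and a set of directed
migration bands between populations that coexist in time, each carrying a
mutation-scaled rate ``M = m/mu`` (``m`` = per-generation migration
probability).

Scaled parameters are what the sampler operates on; conversion to natural
units (individuals, years) requires an assumed mutation rate and generation
time, bundled here as a :class:`RateScale`.  Two presets are provided:
``COMBO_I`` (4e-9 mutations/bp/generation, 4.5 years/generation) and
``COMBO_II`` (1e-8, 3.0).

Conventions shared by every module in this package:

* Band direction ``source -> target`` reads **forward in time** (genes flow
  from source into target).  A backward-in-time simulation therefore moves
  lineages from the target population into the source population.
* A population exists on the half-open time interval ``[start, end)`` with
  ``start = 0`` for sampled (leaf) populations and ``start = tau`` for
  ancestral ones; ``end`` is the parent's ``tau`` (infinity for the root).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateScale",
    "COMBO_I",
    "COMBO_II",
    "PopulationTree",
    "MigrationBand",
    "DemographicModel",
    "ModelArrays",
    "band_time_span",
    "total_migration_rate",
    "theta_to_ne",
    "ne_to_theta",
    "tau_to_years",
    "years_to_tau",
    "wolf_dog_preset",
    "read_model_config",
    "write_model_config",
]


class InvalidModelError(ValueError):
    """Raised when a demographic model violates its structural invariants."""


@dataclass(frozen=True)
class RateScale:
    """A (mutation rate, generation time) pair used for unit conversion.

    Parameters
    ----------
    mu : float
        Mutation rate per base pair per generation.
    g : float
        Generation time in years.
    """

    mu: float
    g: float

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ValueError(f"mutation rate must be > 0, got {self.mu}")
        if not (self.g > 0):
            raise ValueError(f"generation time must be > 0, got {self.g}")


#: Slow-mutation / long-generation combination (4e-9 per bp per generation,
#: 4.5 years); favoured by recent pedigree-based canid estimates.
COMBO_I = RateScale(mu=4e-9, g=4.5)
#: Fast-mutation / short-generation combination (1e-8 per bp per generation,
#: 3 years); traditional in dog-domestication studies.
COMBO_II = RateScale(mu=1e-8, g=3.0)


def theta_to_ne(theta: float, scale: RateScale) -> float:
    """Convert a scaled population size to effective number of individuals.

    Uses ``theta = 4*Ne*mu``, i.e. ``Ne = theta / (4*mu)``.
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    return theta / (4.0 * scale.mu)


def ne_to_theta(ne: float, scale: RateScale) -> float:
    """Inverse of :func:`theta_to_ne`: ``theta = 4*Ne*mu``."""
    if ne < 0:
        raise ValueError(f"Ne must be >= 0, got {ne}")
    return 4.0 * ne * scale.mu


def tau_to_years(tau: float, scale: RateScale) -> float:
    """Convert a mutation-scaled divergence time to years: ``T = tau*g/mu``."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    return tau * scale.g / scale.mu


def years_to_tau(years: float, scale: RateScale) -> float:
    """Inverse of :func:`tau_to_years`: ``tau = T*mu/g``."""
    if years < 0:
        raise ValueError(f"years must be >= 0, got {years}")
    return years * scale.mu / scale.g


def total_migration_rate(M: float, tau_m: float) -> float:
    """Total migration rate ``m_tot = M * tau_m`` over a band's lifetime.

    ``tau_m`` is the time span of the band (overlap of the two populations'
    existence intervals, in scaled time).  Because ``M`` scales as ``1/mu``
    and ``tau_m`` as ``mu``, the product is independent of the assumed
    mutation rate.
    """
    if M < 0:
        raise ValueError(f"M must be >= 0, got {M}")
    if tau_m <= 0:
        raise ValueError(f"tau_m must be > 0, got {tau_m}")
    return M * tau_m


class PopulationTree:
    """Rooted tree of named populations with per-branch theta and per-node tau.

    Parameters
    ----------
    parent : dict
        Maps each non-root population name to its parent's name.
    tau : dict
        Divergence time (scaled) for every ancestral population; leaves are
        implicitly at time 0 and must not appear here.
    theta : dict
        Scaled size for every population including the root.
    """

    def __init__(self, parent: dict[str, str], tau: dict[str, float],
                 theta: dict[str, float]) -> None:
        self.parent = dict(parent)
        self.tau = dict(tau)
        self.theta = dict(theta)
        self._validate()

    def _validate(self) -> None:
        children: dict[str, list[str]] = {}
        for c, p in self.parent.items():
            children.setdefault(p, []).append(c)
        self.children = children
        # a single-population model (no parent entries) is allowed
        names = set(self.parent) | set(children) | set(self.theta)
        roots = [n for n in names if n not in self.parent]
        if len(roots) != 1:
            raise InvalidModelError(f"expected exactly one root, found {roots}")
        self.root = roots[0]
        self.populations = names
        self.leaves = sorted(n for n in names if n not in children)
        internal = set(names) - set(self.leaves)
        if set(self.tau) != internal:
            raise InvalidModelError(
                f"tau must be given for exactly the ancestral populations; "
                f"got {sorted(self.tau)}, expected {sorted(internal)}")
        if set(self.theta) != names:
            missing = names - set(self.theta)
            extra = set(self.theta) - names
            raise InvalidModelError(
                f"theta must cover every population (missing {sorted(missing)}, "
                f"unknown {sorted(extra)})")
        for n, th in self.theta.items():
            if not (th > 0):
                raise InvalidModelError(f"theta[{n}] must be > 0, got {th}")
        for n in internal:
            for c in children[n]:
                tc = self.tau.get(c, 0.0)
                if not (self.tau[n] > tc):
                    raise InvalidModelError(
                        f"tau[{n}]={self.tau[n]} must exceed child "
                        f"{c}'s time {tc}")

    def start_time(self, name: str) -> float:
        """Beginning of a population's existence interval (0 for leaves)."""
        return self.tau.get(name, 0.0)

    def end_time(self, name: str) -> float:
        """End of a population's existence interval (inf for the root)."""
        if name == self.root:
            return math.inf
        return self.tau[self.parent[name]]

    def copy(self) -> "PopulationTree":
        return PopulationTree(self.parent, self.tau, self.theta)


@dataclass(frozen=True)
class MigrationBand:
    """Directed gene-flow channel ``source -> target`` (forward in time)."""

    source: str
    target: str
    M: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise InvalidModelError("band source and target must differ")
        if self.M < 0:
            raise InvalidModelError(f"M must be >= 0, got {self.M}")

    @property
    def name(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass
class DemographicModel:
    """A population tree plus a list of migration bands."""

    tree: PopulationTree
    bands: list[MigrationBand] = field(default_factory=list)
    #: free-form notes, e.g. which preset values are placeholders
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set()
        for b in self.bands:
            for n in (b.source, b.target):
                if n not in self.tree.populations:
                    raise InvalidModelError(f"band population {n!r} not in tree")
            if (b.source, b.target) in seen:
                raise InvalidModelError(f"duplicate band {b.name}")
            seen.add((b.source, b.target))
            band_time_span(self, b)  # raises if intervals do not overlap

    def as_arrays(self) -> "ModelArrays":
        return ModelArrays.from_model(self)


def band_time_span(model: DemographicModel, band: MigrationBand) -> float:
    """Time span ``tau_m`` of a band: overlap of the two existence intervals.

    ``tau_m = min(end_s, end_t) - max(start_s, start_t)``; raises
    :class:`InvalidModelError` if the populations never coexist.
    """
    t = model.tree
    lo = max(t.start_time(band.source), t.start_time(band.target))
    hi = min(t.end_time(band.source), t.end_time(band.target))
    if not (hi > lo):
        raise InvalidModelError(
            f"band {band.name}: populations do not coexist "
            f"(overlap [{lo}, {hi}))")
    return hi - lo


class ModelArrays:
    """Flat array view of a model, shared by the simulator and the sampler.

    Populations are indexed with leaves first (sorted by name), then
    ancestral populations in order of increasing ``tau``.  ``pop_end[p]``
    is the parent's ``tau`` (``inf`` for the root).
    """

    def __init__(self, names, pop_parent, tau, theta, pop_c1, pop_c2,
                 band_src, band_tgt, band_M):
        self.names = list(names)
        self.index = {n: i for i, n in enumerate(self.names)}
        self.pop_parent = np.asarray(pop_parent, dtype=np.int64)
        self.tau = np.asarray(tau, dtype=np.float64)
        self.theta = np.asarray(theta, dtype=np.float64)
        self.pop_c1 = np.asarray(pop_c1, dtype=np.int64)
        self.pop_c2 = np.asarray(pop_c2, dtype=np.int64)
        self.band_src = np.asarray(band_src, dtype=np.int64)
        self.band_tgt = np.asarray(band_tgt, dtype=np.int64)
        self.band_M = np.asarray(band_M, dtype=np.float64)
        self.npop = len(self.names)
        self.n_leaves = int(np.sum(self.pop_c1 < 0))
        self.root = int(np.flatnonzero(self.pop_parent < 0)[0])

    @property
    def pop_end(self) -> np.ndarray:
        end = np.empty(self.npop)
        for p in range(self.npop):
            par = self.pop_parent[p]
            end[p] = math.inf if par < 0 else self.tau[par]
        return end

    @classmethod
    def from_model(cls, model: DemographicModel) -> "ModelArrays":
        t = model.tree
        internal = sorted(t.tau, key=lambda n: (t.tau[n], n))
        names = list(t.leaves) + internal
        index = {n: i for i, n in enumerate(names)}
        npop = len(names)
        pop_parent = np.full(npop, -1, dtype=np.int64)
        pop_c1 = np.full(npop, -1, dtype=np.int64)
        pop_c2 = np.full(npop, -1, dtype=np.int64)
        tau = np.zeros(npop)
        theta = np.zeros(npop)
        for n in names:
            i = index[n]
            theta[i] = t.theta[n]
            tau[i] = t.start_time(n)
            if n != t.root:
                pop_parent[i] = index[t.parent[n]]
        for n, kids in t.children.items():
            if len(kids) != 2:
                raise InvalidModelError(
                    f"population {n} must have exactly 2 children, "
                    f"got {len(kids)}")
            a, b = sorted(kids, key=lambda k: index[k])
            pop_c1[index[n]], pop_c2[index[n]] = index[a], index[b]
        band_src = [index[b.source] for b in model.bands]
        band_tgt = [index[b.target] for b in model.bands]
        band_M = [b.M for b in model.bands]
        return cls(names, pop_parent, tau, theta, pop_c1, pop_c2,
                   band_src, band_tgt, band_M)

    def band_window(self, j: int) -> tuple[float, float]:
        """Active time window [lo, hi) of band ``j``."""
        end = self.pop_end
        s, t = self.band_src[j], self.band_tgt[j]
        lo = max(self.tau[s], self.tau[t])
        hi = min(end[s], end[t])
        return lo, hi

    def pop_at(self, p: int, time: float) -> int:
        """Map population ``p`` forward through ancestral merges to ``time``."""
        end = self.pop_end
        while end[p] <= time:
            p = int(self.pop_parent[p])
        return p


# ---------------------------------------------------------------------------
# Published canid model preset
# ---------------------------------------------------------------------------

#: Divergence-time point estimates (years before present) under COMBO_I.
_PRESET_T_YEARS = {
    "ancDW": 36_000.0,        # wolf/dog ancestor
    "ancWOLF": 34_000.0,      # East Asian vs rest of wolves
    "ancIS-CR-IT-IB": 33_500.0,
    "ancCR-IT-IB": 10_800.0,
    "ancIT-IB": 10_300.0,
    "ancIB": 6_200.0,         # Portuguese vs Spanish wolf
}

#: Effective-size point estimates (individuals) under COMBO_I.
_PRESET_NE = {
    "ancDW": 94_000.0,
    "ancDOG": 12_000.0,
    "ancWOLF": 9_600.0,
    "ancIS-CR-IT-IB": 4_000.0,   # one tenth of ancCR-IT-IB
    "ancCR-IT-IB": 40_000.0,
    "ancIT-IB": 10_000.0,
    "ancIB": 3_000.0,
    "israeli": 50_000.0,
    "italian": 4_000.0,          # midpoint of the reported interval
    "portuguese": 3_800.0,       # midpoint of the reported interval
}

#: Placeholder values for parameters without a published point estimate.
_PRESET_PLACEHOLDER_NE = {
    "spanish": 12_000.0,   # three times the Italian size
    "croatian": 12_000.0,  # three times the Italian size
    "chinese": 20_000.0,
    "basenji": 5_000.0,
    "dingo": 5_000.0,
    "jackal": 50_000.0,
    "root": 100_000.0,
}
_PRESET_PLACEHOLDER_T = {
    "ancDOG": 0.9 * 36_000.0,  # dog-clade split: 90% of the wolf/dog split
    "root": 400_000.0,         # jackal outgroup divergence
}

#: Significant total migration rates (band, m_tot).  The dog->Spanish-wolf
#: band is proxied by the basenji (the model has no boxer leaf).
_PRESET_MTOT = {
    ("basenji", "israeli"): 0.15,
    ("dingo", "chinese"): 0.06,
    ("basenji", "spanish"): 0.20,
}


def wolf_dog_preset(scale: RateScale = COMBO_I) -> DemographicModel:
    """Nine-taxon canid model with published point estimates.

    Golden jackal outgroup; dog clade (basenji, dingo); wolf clade
    (chinese, (israeli, (croatian, (italian, (spanish, portuguese))))).
    Scaled parameters are obtained by converting the published year /
    individual point estimates under ``scale`` (default ``COMBO_I``).
    Parameters without a published point estimate carry documented
    placeholder values, listed in ``model.metadata['placeholders']``.
    """
    parent = {
        "jackal": "root", "ancDW": "root",
        "ancDOG": "ancDW", "ancWOLF": "ancDW",
        "basenji": "ancDOG", "dingo": "ancDOG",
        "chinese": "ancWOLF", "ancIS-CR-IT-IB": "ancWOLF",
        "israeli": "ancIS-CR-IT-IB", "ancCR-IT-IB": "ancIS-CR-IT-IB",
        "croatian": "ancCR-IT-IB", "ancIT-IB": "ancCR-IT-IB",
        "italian": "ancIT-IB", "ancIB": "ancIT-IB",
        "spanish": "ancIB", "portuguese": "ancIB",
    }
    t_years = dict(_PRESET_T_YEARS, **_PRESET_PLACEHOLDER_T)
    ne = dict(_PRESET_NE, **_PRESET_PLACEHOLDER_NE)
    tau = {n: years_to_tau(T, scale) for n, T in t_years.items()}
    theta = {n: ne_to_theta(v, scale) for n, v in ne.items()}
    tree = PopulationTree(parent, tau, theta)
    model = DemographicModel(tree, [], metadata={
        "scale": (scale.mu, scale.g),
        "placeholders": sorted(_PRESET_PLACEHOLDER_NE)
        + sorted(_PRESET_PLACEHOLDER_T),
    })
    bands = []
    for (src, tgt), mtot in _PRESET_MTOT.items():
        span = band_time_span(model, MigrationBand(src, tgt, 0.0))
        bands.append(MigrationBand(src, tgt, mtot / span))
    return DemographicModel(tree, bands, metadata=model.metadata)


# ---------------------------------------------------------------------------
# Model config file (key-value + Newick)
# ---------------------------------------------------------------------------

def _tree_to_newick(tree: PopulationTree) -> str:
    def rec(n: str) -> str:
        kids = tree.children.get(n)
        if not kids:
            return n
        inner = ",".join(rec(k) for k in sorted(kids))
        return f"({inner}){n}"
    return rec(tree.root) + ";"


def _newick_to_parent(newick: str) -> dict[str, str]:
    """Parse a labelled Newick string into a child->parent mapping."""
    import dendropy
    t = dendropy.Tree.get(data=newick, schema="newick",
                          suppress_internal_node_taxa=False)
    parent: dict[str, str] = {}

    def label(node) -> str:
        lab = node.taxon.label if node.taxon is not None else node.label
        if not lab:
            raise ValueError("every node in the model tree must be labelled")
        return lab.replace(" ", "_")

    for node in t.preorder_node_iter():
        if node.parent_node is not None:
            parent[label(node)] = label(node.parent_node)
    return parent


def write_model_config(model: DemographicModel, path) -> None:
    """Write a model as the plain-text config format (Newick + key-value)."""
    tree = model.tree
    lines = [f"tree {_tree_to_newick(tree)}"]
    if "scale" in model.metadata:
        mu, g = model.metadata["scale"]
        lines.append(f"scale mu {mu!r} gen {g!r}")
    for n in sorted(tree.theta):
        lines.append(f"theta {n} {tree.theta[n]!r}")
    for n in sorted(tree.tau):
        lines.append(f"tau {n} {tree.tau[n]!r}")
    for b in model.bands:
        lines.append(f"band {b.source} {b.target} {b.M!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_model_config(path) -> DemographicModel:
    """Read a model config written by :func:`write_model_config`."""
    parent = None
    theta: dict[str, float] = {}
    tau: dict[str, float] = {}
    bands: list[tuple[str, str, float]] = []
    meta: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            key = parts[0]
            try:
                if key == "tree":
                    parent = _newick_to_parent(" ".join(parts[1:]))
                elif key == "theta":
                    theta[parts[1]] = float(parts[2])
                elif key == "tau":
                    tau[parts[1]] = float(parts[2])
                elif key == "band":
                    bands.append((parts[1], parts[2], float(parts[3])))
                elif key == "scale":
                    meta["scale"] = (float(parts[2]), float(parts[4]))
                else:
                    raise ValueError(f"unknown directive {key!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if parent is None:
        raise ValueError(f"{path}: missing 'tree' line")
    tree = PopulationTree(parent, tau, theta)
    return DemographicModel(
        tree, [MigrationBand(s, t, M) for s, t, M in bands], metadata=meta)
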