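"""Synthetic data generation: scenario presets and admixture fixtures.

Every input the inference pipeline needs can be generated here, so the
whole analysis is testable without any downloads.  Scenario presets mirror
the validation design of the study this package reproduces:

* ``control`` — the full canid model with its published point estimates;
* ``reduced_split`` — control with the Portuguese/Spanish divergence time
  reduced by 90%;
* ``panmixia`` — control with the Portuguese and Spanish populations
  merged into a single panmictic Iberian population (whose size is the
  ancestral Iberian theta);
* ``toy2`` / ``toy3`` — small two- and three-population models for fast
  tests and parameter-recovery studies.

Defaults for the full scenarios are 15 000 unlinked loci of 1 kb, one
haploid sequence per sampled population; the toy scenarios sample two
haploid sequences per population (emulating one diploid genome each) so
that present-day population sizes are identifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .coalsim import Genealogy, SampleConfig, simulate_genealogy
from .demography import (DemographicModel, PopulationTree,
                         wolf_dog_preset)
from .seqevolve import LocusAlignment, evolve_jc69
from .ancestry_mask import AncestrySegmentSet, SitePanel

__all__ = ["Scenario", "make_scenario", "generate_dataset",
           "generate_admixture_fixture", "iberian_validation_scenario",
           "SCENARIO_NAMES"]

SCENARIO_NAMES = ("control", "reduced_split", "panmixia", "toy2", "toy3")

#: three-population toy model parameters: tree ((A,B)AB, C)root
TOY3_THETA = {"A": 0.0008, "B": 0.0008, "C": 0.001,
              "AB": 0.0012, "root": 0.0015}
TOY3_TAU = {"AB": 0.0008, "root": 0.002}

#: two-population toy model parameters: tree (A,B)root
TOY2_THETA = {"A": 0.001, "B": 0.001, "root": 0.002}
TOY2_TAU = {"root": 0.001}


@dataclass
class Scenario:
    """A named simulation condition: model + sampling + locus layout."""

    name: str
    model: DemographicModel
    samples: SampleConfig
    n_loci: int
    locus_length: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")


def _toy_model(theta: dict, tau: dict, parent: dict) -> DemographicModel:
    return DemographicModel(PopulationTree(parent, tau, theta))


def _panmixia_model(control: DemographicModel) -> DemographicModel:
    """Merge the Portuguese and Spanish wolves into one panmictic leaf."""
    tree = control.tree
    parent = {n: p for n, p in tree.parent.items()
              if n not in ("spanish", "portuguese", "ancIB")}
    parent["iberia"] = tree.parent["ancIB"]
    tau = {n: v for n, v in tree.tau.items() if n != "ancIB"}
    theta = {n: v for n, v in tree.theta.items()
             if n not in ("spanish", "portuguese", "ancIB")}
    theta["iberia"] = tree.theta["ancIB"]
    bands = [b for b in control.bands
             if b.source not in ("spanish", "portuguese")
             and b.target not in ("spanish", "portuguese")]
    return DemographicModel(PopulationTree(parent, tau, theta), bands,
                            metadata=dict(control.metadata))


def make_scenario(name: str, n_loci: int = 15_000, locus_length: int = 1_000,
                  seed: int = 0) -> Scenario:
    """Build a named scenario preset (see the module docstring)."""
    if name == "control":
        model = wolf_dog_preset()
        samples = SampleConfig({p: 1 for p in model.tree.leaves})
    elif name == "reduced_split":
        model = wolf_dog_preset()
        model.tree.tau["ancIB"] *= 0.1
        model = DemographicModel(model.tree.copy(), model.bands,
                                 metadata=dict(model.metadata))
        samples = SampleConfig({p: 1 for p in model.tree.leaves})
    elif name == "panmixia":
        model = _panmixia_model(wolf_dog_preset())
        samples = SampleConfig({p: 1 for p in model.tree.leaves})
    elif name == "toy2":
        model = _toy_model(TOY2_THETA, TOY2_TAU,
                           {"A": "root", "B": "root"})
        samples = SampleConfig({"A": 2, "B": 2})
    elif name == "toy3":
        model = _toy_model(TOY3_THETA, TOY3_TAU,
                           {"A": "AB", "B": "AB", "AB": "root", "C": "root"})
        samples = SampleConfig({"A": 2, "B": 2, "C": 2})
    else:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"choose from {SCENARIO_NAMES}")
    return Scenario(name, model, samples, n_loci, locus_length, seed)


def iberian_validation_scenario(kind: str, n_loci: int = 500,
                                locus_length: int = 1_000, seed: int = 0,
                                scale: float = 10.0) -> Scenario:
    """Desk-scale split-time validation on the Iberian subtree.

    Three sampled populations (Portuguese, Spanish, Italian wolves; two
    haploid sequences each) with the published point estimates, all theta
    and tau multiplied by ``scale``.  Because the coalescent likelihood
    depends on parameters only through their products with locus length,
    this uniform rescaling is information-equivalent to ``scale``-fold
    longer loci while preserving every relative quantity — in particular
    the ratio of split times the validation measures.  ``kind``:

    * ``control`` — parameters as published;
    * ``reduced_split`` — Portuguese/Spanish divergence 90% smaller;
    * ``panmixia`` — Portuguese and Spanish merged (one population of
      size theta_ancIB) until the present.
    """
    th = {"portuguese": 6.08e-5 * scale, "spanish": 1.92e-4 * scale,
          "italian": 6.4e-5 * scale, "ancIB": 4.8e-5 * scale,
          "ancIT-IB": 1.6e-4 * scale}
    ta = {"ancIB": 5.5111e-6 * scale, "ancIT-IB": 9.1556e-6 * scale}
    if kind == "control":
        pass
    elif kind == "reduced_split":
        ta["ancIB"] *= 0.1
    elif kind == "panmixia":
        th = {"iberia": th["ancIB"], "italian": th["italian"],
              "ancIT-IB": th["ancIT-IB"]}
        ta = {"ancIT-IB": ta["ancIT-IB"]}
        tree = PopulationTree({"iberia": "ancIT-IB",
                               "italian": "ancIT-IB"}, ta, th)
        return Scenario(kind, DemographicModel(tree),
                        SampleConfig({"iberia": 4, "italian": 2}),
                        n_loci, locus_length, seed)
    else:
        raise ValueError(f"unknown validation kind {kind!r}")
    tree = PopulationTree({"portuguese": "ancIB", "spanish": "ancIB",
                           "ancIB": "ancIT-IB", "italian": "ancIT-IB"},
                          ta, th)
    return Scenario(kind, DemographicModel(tree),
                    SampleConfig({"portuguese": 2, "spanish": 2,
                                  "italian": 2}),
                    n_loci, locus_length, seed)


@dataclass
class TruthRecord:
    """Generating parameters and genealogies for recovery scoring."""

    scenario: str
    seed: int
    theta: dict[str, float]
    tau: dict[str, float]
    bands: list[tuple[str, str, float]]
    genealogies: list[Genealogy] = field(repr=False, default_factory=list)
    checksum: str = ""

    def to_json(self, path) -> None:
        """Structured-text sidecar (without the bulky genealogies)."""
        with open(path, "w") as fh:
            json.dump({"scenario": self.scenario, "seed": self.seed,
                       "theta": self.theta, "tau": self.tau,
                       "bands": self.bands, "checksum": self.checksum},
                      fh, indent=1, sort_keys=True)


def dataset_checksum(loci: list[LocusAlignment]) -> str:
    h = hashlib.sha256()
    for aln in loci:
        h.update(aln.name.encode())
        h.update(aln.data.tobytes())
    return h.hexdigest()[:16]


def generate_dataset(scenario: Scenario
                     ) -> tuple[list[LocusAlignment], TruthRecord]:
    """Simulate genealogies and JC69 sequences for every locus.

    Deterministic per ``scenario.seed``; per-locus seeds are spawned with
    a counter-based split so each locus is independently reproducible.
    The truth record keeps the generating parameters and all genealogies
    so that recovery can be scored exactly.
    """
    arr = scenario.model.as_arrays()
    children = np.random.SeedSequence(scenario.seed).spawn(scenario.n_loci)
    loci = []
    genealogies = []
    for k, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        g = simulate_genealogy(arr, scenario.samples, rng)
        genealogies.append(g)
        loci.append(evolve_jc69(g, scenario.locus_length, rng,
                                name=f"locus{k}"))
    tree = scenario.model.tree
    truth = TruthRecord(
        scenario=scenario.name, seed=scenario.seed,
        theta=dict(tree.theta), tau=dict(tree.tau),
        bands=[(b.source, b.target, b.M) for b in scenario.model.bands],
        genealogies=genealogies, checksum=dataset_checksum(loci))
    return loci, truth


def generate_admixture_fixture(n_sites: int,
                               segment_spec: list[tuple[int, int, str]],
                               panel_fst: float = 0.8,
                               seed: int = 0,
                               site_spacing: int = 1_000,
                               n_copies: int = 20,
                               ploidy: int = 2,
                               chrom: str = "chr1"
                               ) -> tuple[SitePanel, AncestrySegmentSet]:
    """Synthetic admixed target with known ancestry segments.

    ``segment_spec`` lists ``(first_site, last_site_exclusive, label)`` in
    site indices and must tile ``range(n_sites)`` without overlap.  Sites
    are placed every ``site_spacing`` bp.  Panel frequencies are chosen as
    a complementary pair ``(p, 1-p)`` whose large-sample Hudson FST equals
    ``panel_fst`` (``p = (1 + sqrt(f/(2-f)))/2``); which source carries
    the higher frequency alternates randomly per site.  Target dosages are
    binomial draws from the true segment's source frequency.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    spec = sorted(segment_spec)
    covered = 0
    for start, end, label in spec:
        if label not in ("A", "B"):
            raise ValueError(f"label must be A or B, got {label!r}")
        if start != covered:
            raise ValueError("segments must tile the site range "
                             "without gaps or overlaps")
        covered = end
    if covered != n_sites:
        raise ValueError("segments must cover exactly n_sites sites")
    if not (0.0 <= panel_fst <= 1.0):
        raise ValueError("panel_fst must be in [0, 1]")
    rng = np.random.default_rng(seed)
    x = panel_fst / (2.0 - panel_fst)
    p_hi = 0.5 * (1.0 + np.sqrt(x))
    pos = np.arange(n_sites, dtype=np.int64) * site_spacing
    flip = rng.random(n_sites) < 0.5
    freq_a = np.where(flip, p_hi, 1.0 - p_hi)
    freq_b = 1.0 - freq_a
    alt_a = np.round(freq_a * n_copies).astype(np.int64)
    alt_b = np.round(freq_b * n_copies).astype(np.int64)
    labels = np.empty(n_sites, dtype="U1")
    for start, end, label in spec:
        labels[start:end] = label
    true_freq = np.where(labels == "A", freq_a, freq_b)
    target = rng.binomial(ploidy, true_freq).astype(np.int64)
    panel = SitePanel(np.full(n_sites, chrom), pos,
                      n_copies - alt_a, alt_a, n_copies - alt_b, alt_b,
                      target, ploidy)
    truth = AncestrySegmentSet([
        (chrom, int(pos[start]),
         int(pos[end - 1]) + (site_spacing if end < n_sites else 1), label)
        for start, end, label in spec])
    return panel, truth
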