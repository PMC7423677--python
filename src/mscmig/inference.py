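"""Bayesian MCMC over demographic parameters and per-locus genealogies.

The model is the multispecies coalescent with migration: per-locus
genealogies (topology, node times, per-lineage migration events) are latent
variables; demographic parameters are the per-population scaled sizes
``theta``, divergence times ``tau`` and band migration rates ``M``, each
with an independent Gamma prior.  Sequence data enter through the JC69
likelihood (Felsenstein pruning).  The sampler is Metropolis–Hastings with
the following move classes, applied once per iteration (one sweep):

* genealogy node-time slide (reflected uniform within the legal interval);
* lineage prune-and-regraft with full migration-path resampling (the path
  is resimulated under the structured coalescent conditional on the other
  lineages, which also proposes changes in the number of migration events
  with the correct path-density Hastings ratio);
* migration-event time resample within its legal window;
* multiplicative random-walk updates of each ``theta`` and ``M``;
* ``tau`` update with rubber-band rescaling of genealogy event times
  inside the three populations adjacent to the divergence.

Proposal windows are fixed during sampling (no adaptation, preserving
detailed balance).  The per-iteration hot loop is compiled with numba
(:mod:`mscmig._engine`); the pure-Python density and likelihood functions
in this module are the reference implementations the engine is tested
against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalsim import Genealogy, SampleConfig, simulate_genealogy
from .demography import DemographicModel, ModelArrays
from .seqevolve import LocusAlignment

__all__ = ["PriorSpec", "McmcSettings", "McmcTrace", "jc69_log_likelihood",
           "coalescent_migration_log_density", "run_mcmc", "ess"]


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gamma(shape, rate) priors per parameter class.

    Defaults follow the conventions of the original sampler this package
    reimplements: a diffuse Gamma(1, 10 000) on every ``theta`` and ``tau``
    and a very diffuse Gamma(0.002, 0.00001) on every migration rate ``M``.
    All values are configurable.
    """

    theta_shape: float = 1.0
    theta_rate: float = 10_000.0
    tau_shape: float = 1.0
    tau_rate: float = 10_000.0
    m_shape: float = 0.002
    m_rate: float = 0.00001

    def __post_init__(self) -> None:
        for f in ("theta_shape", "theta_rate", "tau_shape", "tau_rate",
                  "m_shape", "m_rate"):
            if not (getattr(self, f) > 0):
                raise ValueError(f"{f} must be > 0")


@dataclass(frozen=True)
class McmcSettings:
    """Run-length, thinning, seed and proposal-window configuration."""

    iterations: int = 20_000
    burn_in: int = 5_000
    sample_every: int = 10
    seed: int = 1
    #: node-time slide half-width; if None, set to theta scale at init
    window_node: float | None = None
    #: log-scale half-widths for multiplicative theta / M walks
    window_theta: float = 0.5
    window_m: float = 0.8
    #: tau slide half-width as a fraction of the initial legal interval
    window_tau_frac: float = 0.3
    #: absolute tau slide half-width (overrides window_tau_frac); use this
    #: when chaining runs via resume_from so the kernel stays homogeneous
    window_tau: float | None = None
    #: disable the burn-in window auto-tune (e.g. for chained runs)
    tune: bool = True
    #: draw initial theta/tau from the priors ("prior") or take them from
    #: the starting model ("model")
    init: str = "prior"

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.init not in ("prior", "model"):
            raise ValueError("init must be 'prior' or 'model'")


@dataclass
class McmcTrace:
    """Recorded posterior samples plus per-move acceptance rates.

    ``samples`` has one row per recorded iteration with columns ``iter``,
    ``theta_<pop>``, ``tau_<pop>``, ``m_<src>.<tgt>``, ``mtot_<src>.<tgt>``
    and ``logL`` (total data log-likelihood).
    """

    samples: pd.DataFrame
    acceptance: dict[str, float]
    settings: McmcSettings
    model: DemographicModel = None
    priors: PriorSpec = None

    def column(self, name: str) -> np.ndarray:
        if name not in self.samples.columns:
            raise KeyError(f"unknown trace column {name!r}")
        return self.samples[name].to_numpy()

    def to_tsv(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference likelihood and genealogy density (pure Python oracles)
# ---------------------------------------------------------------------------

def jc69_log_likelihood(aln: LocusAlignment, genealogy: Genealogy) -> float:
    """Felsenstein-pruning log-likelihood of an alignment under JC69.

    The root base distribution is uniform (1/4); ``N``/ambiguity cells
    contribute a partial likelihood of 1 for every compatible state;
    columns are independent.  By the pulley principle the result does not
    depend on where the (unrooted) root is placed along a branch.
    """
    g = genealogy
    if sorted(aln.sample_names) != sorted(g.tip_names):
        raise ValueError("alignment samples do not match genealogy tips")
    row_of = {s: i for i, s in enumerate(aln.sample_names)}
    data = aln.data[[row_of[t] for t in g.tip_names]]
    patterns, counts = np.unique(data, axis=1, return_counts=True)
    npat = patterns.shape[1]
    partial = np.zeros((g.n_nodes, npat, 4))
    blen = g.branch_lengths()
    if np.any(blen < 0):
        raise ValueError("negative branch length")
    for i in g.postorder():
        if g.child1[i] < 0:
            for s in range(4):
                partial[i, :, s] = (patterns[i] >> s) & 1
        else:
            partial[i] = 1.0
            for c in (int(g.child1[i]), int(g.child2[i])):
                e = math.exp(-4.0 * blen[c] / 3.0)
                p_same, p_diff = 0.25 + 0.75 * e, 0.25 - 0.25 * e
                tot = partial[c].sum(axis=1, keepdims=True)
                partial[i] *= p_diff * tot + (p_same - p_diff) * partial[c]
    site_l = 0.25 * partial[g.root].sum(axis=1)
    return float(np.dot(counts, np.log(site_l)))


def _edge_segments(g: Genealogy, arr: ModelArrays):
    """Per-lineage (start, end, pop) residence segments; None if invalid.

    Splits each edge at migration events and at implicit population merges,
    and validates every event against residence and its band's active
    window, and every coalescence against same-population residence.
    """
    pop_end = arr.pop_end
    segs: list[tuple[float, float, int]] = []
    final_pop = np.full(g.n_nodes, -1, dtype=np.int64)
    for i in range(g.n_nodes):
        par = int(g.parent[i])
        if par < 0:
            continue
        t0, p, top = float(g.time[i]), int(g.node_pop[i]), float(g.time[par])
        if top < t0:
            return None, None
        prev_t = t0
        for x, b in g.events[i]:
            if not (prev_t <= x <= top):
                return None, None
            prev_t = x
            while pop_end[p] <= x:
                segs.append((t0, float(pop_end[p]), p))
                t0, p = float(pop_end[p]), int(arr.pop_parent[p])
            segs.append((t0, x, p))
            if p != int(arr.band_tgt[b]):
                return None, None
            lo, hi = arr.band_window(b)
            if not (lo <= x < hi):
                return None, None
            p, t0 = int(arr.band_src[b]), x
        while pop_end[p] <= top:
            segs.append((t0, float(pop_end[p]), p))
            t0, p = float(pop_end[p]), int(arr.pop_parent[p])
        segs.append((t0, top, p))
        final_pop[i] = p
    for j in range(g.n_tips, g.n_nodes):
        for c in (int(g.child1[j]), int(g.child2[j])):
            if final_pop[c] != g.node_pop[j]:
                return None, None
    return segs, final_pop


def coalescent_migration_log_density(genealogy: Genealogy,
                                     model: DemographicModel | ModelArrays
                                     ) -> float:
    """Log-density of a genealogy under the structured coalescent.

    Product over time intervals of ``exp(-[sum_b k_b(k_b-1)/2 * 2/theta_b +
    sum_bands k_tgt * M] * dt)``, times ``2/theta_b`` per coalescence and
    ``M`` per migration event.  Returns ``-inf`` (not an exception) if any
    event violates population existence, residence, or uses a band with
    ``M = 0``; the process is considered complete at the grand MRCA (no
    factor above the root).
    """
    arr = model if isinstance(model, ModelArrays) else model.as_arrays()
    g = genealogy
    segs, _ = _edge_segments(g, arr)
    if segs is None:
        return -math.inf
    logd = 0.0
    for j in range(g.n_tips, g.n_nodes):
        logd += math.log(2.0 / arr.theta[g.node_pop[j]])
    for i in range(g.n_nodes):
        for _, b in g.events[i]:
            M = arr.band_M[b]
            if M <= 0:
                return -math.inf
            logd += math.log(M)
    # integral term over piecewise-constant intervals
    bps = sorted({t for s in segs for t in (s[0], s[1])})
    windows = [arr.band_window(j) for j in range(len(arr.band_M))]
    for a, b in zip(bps[:-1], bps[1:]):
        if b <= a:
            continue
        mid = 0.5 * (a + b)
        k = {}
        for s0, s1, p in segs:
            if s0 <= mid < s1:
                k[p] = k.get(p, 0) + 1
        rate = sum(kp * (kp - 1) / 2.0 * 2.0 / arr.theta[p]
                   for p, kp in k.items())
        for j, (lo, hi) in enumerate(windows):
            if lo <= mid < hi:
                rate += k.get(int(arr.band_tgt[j]), 0) * arr.band_M[j]
        logd -= rate * (b - a)
    return logd


def ess(samples: np.ndarray) -> float:
    """Effective sample size via initial-positive-sequence truncation.

    Autocorrelations are summed in adjacent pairs (lag 2k, 2k+1) until a
    pair sum goes non-positive (Geyer's initial positive sequence); the ESS
    is ``n / (1 + 2 * sum(rho))``, capped at ``n``.  A constant series is
    defined to have ESS ``n`` (with a warning).
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        warnings.warn("constant series: ESS defined as n", stacklevel=2)
        return float(n)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else rho[2 * k - 1]
        if pair <= 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


# ---------------------------------------------------------------------------
# Sampler front-end
# ---------------------------------------------------------------------------

def _compress_patterns(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(data, axis=1, return_counts=True)
    return patterns.T.copy(), counts.astype(np.float64)


def _draw_initial_model(arr: ModelArrays, priors: PriorSpec,
                        rng: np.random.Generator,
                        max_tries: int = 1000) -> ModelArrays:
    """Draw theta/tau/M from the priors subject to the tree's ordering."""
    theta = rng.gamma(priors.theta_shape, 1.0 / priors.theta_rate, arr.npop)
    order = np.argsort(arr.tau, kind="stable")
    tau = np.zeros(arr.npop)
    internal = [p for p in range(arr.npop) if arr.pop_c1[p] >= 0]
    for _ in range(max_tries):
        draw = rng.gamma(priors.tau_shape, 1.0 / priors.tau_rate,
                         len(internal))
        tau[:] = 0.0
        for p, v in zip(internal, draw):
            tau[p] = v
        ok = all(tau[p] > max(tau[arr.pop_c1[p]], tau[arr.pop_c2[p]])
                 for p in internal)
        if ok:
            break
    else:
        # fall back to sorted assignment (valid by construction)
        draw = np.sort(rng.gamma(priors.tau_shape, 1.0 / priors.tau_rate,
                                 len(internal)))
        by_depth = sorted(internal, key=lambda p: arr.tau[p])
        for p, v in zip(by_depth, draw):
            tau[p] = v
        for p in by_depth:  # enforce ordering strictly
            lo = max(tau[arr.pop_c1[p]], tau[arr.pop_c2[p]])
            if tau[p] <= lo:
                tau[p] = lo * (1 + 1e-6) + 1e-12
    # the very diffuse migration prior (shape << 1) underflows to 0 when
    # drawn from, which would freeze the multiplicative walk; start each
    # band at the prior mean instead
    M = np.full(len(arr.band_M), priors.m_shape / priors.m_rate)
    return ModelArrays(arr.names, arr.pop_parent, tau, theta, arr.pop_c1,
                       arr.pop_c2, arr.band_src, arr.band_tgt, M)


def run_mcmc(data: list[LocusAlignment], model0: DemographicModel,
             priors: PriorSpec | None = None,
             settings: McmcSettings | None = None,
             resume_from: dict | None = None) -> McmcTrace:
    """Sample the posterior of (theta, tau, M, genealogies) given loci.

    ``model0`` fixes the population-tree topology and the set of migration
    bands; its numeric values are used as the starting state when
    ``settings.init == "model"`` and are otherwise replaced by prior draws.
    Genealogies are initialised by simulation under the starting model
    (guaranteeing a finite prior density).  Deterministic given
    ``settings.seed``.

    ``resume_from`` accepts a previous trace's ``final_state`` to continue
    a chain (parameters and genealogies are taken from it instead of being
    re-initialised); the data must have the same samples and locus count.
    """
    from . import _engine

    priors = priors or PriorSpec()
    settings = settings or McmcSettings()
    if not data:
        raise ValueError("need at least one locus")
    arr0 = model0.as_arrays()
    rng = np.random.default_rng(settings.seed)
    if resume_from is not None:
        st = resume_from
        arr = ModelArrays(st["names"], st["pop_parent"], st["tau"].copy(),
                          st["theta"].copy(), st["pop_c1"], st["pop_c2"],
                          st["band_src"], st["band_tgt"], st["bM"].copy())
    else:
        arr = (_draw_initial_model(arr0, priors, rng)
               if settings.init == "prior" else arr0)

    # per-locus sample configuration must be identical across loci
    tip_names = data[0].sample_names
    pops = {}
    for s in tip_names:
        pop = s.rsplit("_", 1)[0] if "_" in s else s
        if pop not in arr.index:
            raise ValueError(
                f"cannot map sample {s!r} to a leaf population; name "
                f"samples '<population>_<i>' or after the population")
        pops[s] = pop
    counts: dict[str, int] = {}
    for s in tip_names:
        counts[pops[s]] = counts.get(pops[s], 0) + 1
    samples_cfg = SampleConfig(counts)
    canonical = samples_cfg.tip_names()
    canonical_pops = samples_cfg.tip_pops()
    if sorted(canonical) == sorted(tip_names):
        order_names = canonical
    else:  # e.g. one sample per population named exactly after it
        order_names = sorted(tip_names)
        canonical_pops = [pops[s] for s in order_names]
    ntips = len(order_names)

    # pack pattern data
    pats, wts = [], []
    for aln in data:
        if sorted(aln.sample_names) != sorted(tip_names):
            raise ValueError(f"locus {aln.name}: sample names differ")
        row_of = {s: i for i, s in enumerate(aln.sample_names)}
        sub = aln.data[[row_of[t] for t in order_names]]
        p, w = _compress_patterns(sub)
        pats.append(p)
        wts.append(w)
    nloci = len(data)
    maxpat = max(p.shape[0] for p in pats)
    pat = np.zeros((nloci, maxpat, ntips), dtype=np.uint8)
    patw = np.zeros((nloci, maxpat))
    npat = np.zeros(nloci, dtype=np.int64)
    for l, (p, w) in enumerate(zip(pats, wts)):
        npat[l] = p.shape[0]
        pat[l, : p.shape[0]] = p
        patw[l, : w.shape[0]] = w

    # initial genealogies: simulated under the initial model, or resumed
    nnod = 2 * ntips - 1
    K = 24
    if resume_from is not None:
        st = resume_from
        par, ch1, ch2 = st["par"].copy(), st["ch1"].copy(), st["ch2"].copy()
        tms, npo = st["tms"].copy(), st["npo"].copy()
        nev, evt, evb = st["nev"].copy(), st["evt"].copy(), st["evb"].copy()
        if par.shape != (nloci, nnod):
            raise ValueError("resume state does not match the data shape")
        if list(st["tip_names"]) != list(order_names):
            raise ValueError("resume state has a different sample order")
    else:
        par = np.zeros((nloci, nnod), dtype=np.int64)
        ch1 = np.zeros((nloci, nnod), dtype=np.int64)
        ch2 = np.zeros((nloci, nnod), dtype=np.int64)
        tms = np.zeros((nloci, nnod))
        npo = np.zeros((nloci, nnod), dtype=np.int64)
        nev = np.zeros((nloci, nnod), dtype=np.int64)
        evt = np.zeros((nloci, nnod, K))
        evb = np.zeros((nloci, nnod, K), dtype=np.int64)
        for l in range(nloci):
            g = simulate_genealogy(arr, samples_cfg, rng)
            par[l], ch1[l], ch2[l] = g.parent, g.child1, g.child2
            tms[l], npo[l] = g.time, g.node_pop
            for i in range(nnod):
                for k, (x, b) in enumerate(g.events[i][:K]):
                    evt[l, i, k] = x
                    evb[l, i, k] = b
                nev[l, i] = min(len(g.events[i]), K)

    internal_pops = np.array(
        [p for p in range(arr.npop) if arr.pop_c1[p] >= 0], dtype=np.int64)
    w_node = settings.window_node
    if w_node is None:
        w_node = float(np.median(arr.theta))
    w_tau = np.zeros(arr.npop)
    for p in internal_pops:
        if settings.window_tau is not None:
            w_tau[p] = settings.window_tau
        else:
            lo = max(arr.tau[arr.pop_c1[p]], arr.tau[arr.pop_c2[p]])
            w_tau[p] = max(settings.window_tau_frac * (arr.tau[p] - lo),
                           1e-3 * arr.tau[p], 1e-9)

    n_rec = (settings.iterations - settings.burn_in) // settings.sample_every
    nband = len(arr.band_M)
    rec_theta = np.zeros((n_rec, arr.npop))
    rec_tau = np.zeros((n_rec, len(internal_pops)))
    rec_M = np.zeros((n_rec, nband))
    rec_ll = np.zeros(n_rec)
    rec_it = np.zeros(n_rec, dtype=np.int64)
    acc = np.zeros((6, 2))  # move class x (accept, attempt)

    theta = arr.theta.copy()
    tau = arr.tau.copy()
    bM = arr.band_M.copy()
    out_ll = np.zeros(nloci)
    out_cd = np.zeros(nloci)
    engine_seed = int(rng.integers(1, 2**31 - 1))
    _engine.run_chain(
        int(settings.iterations), int(settings.burn_in),
        int(settings.sample_every), 1 if settings.tune else 0,
        engine_seed,
        arr.pop_parent, arr.pop_c1, arr.pop_c2, tau, theta,
        arr.band_src, arr.band_tgt, bM,
        par, ch1, ch2, tms, npo, nev, evt, evb,
        pat, patw, npat,
        float(priors.theta_shape), float(priors.theta_rate),
        float(priors.tau_shape), float(priors.tau_rate),
        float(priors.m_shape), float(priors.m_rate),
        float(w_node), float(settings.window_theta),
        float(settings.window_m), w_tau, internal_pops,
        rec_theta, rec_tau, rec_M, rec_ll, rec_it, acc,
        out_ll, out_cd)

    cols: dict[str, np.ndarray] = {"iter": rec_it}
    for j, name in enumerate(arr.names):
        cols[f"theta_{name}"] = rec_theta[:, j]
    for j, p in enumerate(internal_pops):
        cols[f"tau_{arr.names[p]}"] = rec_tau[:, j]
    pop_end_of = lambda tv, p: (math.inf if arr.pop_parent[p] < 0
                                else tv[arr.pop_parent[p]])
    for j in range(nband):
        s, t = int(arr.band_src[j]), int(arr.band_tgt[j])
        cols[f"m_{arr.names[s]}.{arr.names[t]}"] = rec_M[:, j]
    for j in range(nband):
        s, t = int(arr.band_src[j]), int(arr.band_tgt[j])
        spans = np.empty(n_rec)
        for r in range(n_rec):
            tv = np.zeros(arr.npop)
            for jj, p in enumerate(internal_pops):
                tv[p] = rec_tau[r, jj]
            lo = max(tv[s], tv[t])
            hi = min(pop_end_of(tv, s), pop_end_of(tv, t))
            spans[r] = max(hi - lo, 0.0)
        cols[f"mtot_{arr.names[s]}.{arr.names[t]}"] = rec_M[:, j] * spans
    cols["logL"] = rec_ll
    names = ["node_slide", "event_slide", "regraft", "theta", "M", "tau"]
    acceptance = {n: (acc[k, 0] / acc[k, 1] if acc[k, 1] else math.nan)
                  for k, n in enumerate(names)}
    trace = McmcTrace(pd.DataFrame(cols), acceptance, settings,
                      model=model0, priors=priors)
    # final sampler state, kept for diagnostics and engine-vs-oracle tests
    trace.final_state = {
        "names": arr.names, "pop_parent": arr.pop_parent,
        "pop_c1": arr.pop_c1, "pop_c2": arr.pop_c2,
        "band_src": arr.band_src, "band_tgt": arr.band_tgt,
        "tau": tau, "theta": theta, "bM": bM,
        "par": par, "ch1": ch1, "ch2": ch2, "tms": tms, "npo": npo,
        "nev": nev, "evt": evt, "evb": evb,
        "pat": pat, "patw": patw, "npat": npat,
        "ll": out_ll, "cd": out_cd,
        "tip_names": order_names, "tip_pops": canonical_pops,
    }
    return trace
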