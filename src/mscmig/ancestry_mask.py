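"""Local-ancestry masking of loci with foreign (dog-like) ancestry.

Given two source populations (A, e.g. dogs; B, e.g. reference wolves) with
per-site allele counts, and an admixed target genome, this module

1. keeps only highly informative sites (Hudson FST between the sources at
   or above a cutoff, 0.5 by default),
2. assigns each chromosome segment of the target to source A or B with a
   penalized-switch dynamic program (per-site emission cost = -log of the
   target genotype's probability under the labelled source's allele
   frequency; each label change costs a fixed switch penalty, 50 by
   default), and
3. removes every locus not fully contained in a segment of the kept label.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SitePanel", "AncestrySegmentSet", "hudson_fst",
           "weir_cockerham_fst", "filter_sites", "assign_ancestry",
           "mask_loci"]

FREQ_CLAMP = 1e-3  # allele frequencies are clamped to [eps, 1-eps]


@dataclass
class SitePanel:
    """Informative sites with source-population allele counts.

    Arrays are parallel, ordered, with strictly increasing positions within
    each chromosome.  ``ref*/alt*`` are allele copy counts in sources A and
    B; ``target`` is the target's alternate-allele dosage at each site
    (0/1 for a haploid target, 0/1/2 for a diploid one).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_a: np.ndarray
    alt_a: np.ndarray
    ref_b: np.ndarray
    alt_b: np.ndarray
    target: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        for f in ("pos", "ref_a", "alt_a", "ref_b", "alt_b", "target"):
            setattr(self, f, np.asarray(getattr(self, f), dtype=np.int64))
        n = self.pos.size
        for f in ("chrom", "ref_a", "alt_a", "ref_b", "alt_b", "target"):
            if getattr(self, f).size != n:
                raise ValueError(f"panel column {f} has wrong length")
        if np.any(self.ref_a < 0) or np.any(self.alt_a < 0) \
                or np.any(self.ref_b < 0) or np.any(self.alt_b < 0):
            raise ValueError("allele counts must be >= 0")
        if np.any((self.ref_a + self.alt_a) == 0) \
                or np.any((self.ref_b + self.alt_b) == 0):
            raise ValueError("each source needs > 0 allele copies per site")
        if np.any(self.target < 0) or np.any(self.target > self.ploidy):
            raise ValueError("target dosage out of range for ploidy")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def subset(self, keep: np.ndarray) -> "SitePanel":
        return SitePanel(self.chrom[keep], self.pos[keep], self.ref_a[keep],
                         self.alt_a[keep], self.ref_b[keep],
                         self.alt_b[keep], self.target[keep], self.ploidy)

    def freq_a(self) -> np.ndarray:
        return self.alt_a / (self.ref_a + self.alt_a)

    def freq_b(self) -> np.ndarray:
        return self.alt_b / (self.ref_b + self.alt_b)

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos,
            "refA_count": self.ref_a, "altA_count": self.alt_a,
            "refB_count": self.ref_b, "altB_count": self.alt_b,
            "target_genotype": self.target,
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, ploidy: int = 2) -> "SitePanel":
        df = pd.read_csv(path, sep="\t")
        return cls(df["chrom"].to_numpy(), df["pos"], df["refA_count"],
                   df["altA_count"], df["refB_count"], df["altB_count"],
                   df["target_genotype"], ploidy)


@dataclass
class AncestrySegmentSet:
    """Non-overlapping labelled genomic intervals (0-based half-open)."""

    segments: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, label in self.segments:
            if not (start < end):
                raise ValueError(f"empty segment {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals[:-1], ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping segments on {chrom}")

    def with_label(self, label: str) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, s, e, lab in self.segments if lab == label]

    def to_bed(self, path) -> None:
        rows = sorted(self.segments)
        with open(path, "w") as fh:
            for chrom, start, end, label in rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")

    @classmethod
    def from_bed(cls, path) -> "AncestrySegmentSet":
        segs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, start, end, label = line.split()[:4]
                segs.append((chrom, int(start), int(end), label))
        return cls(segs)


def hudson_fst(count_a: tuple[int, int], count_b: tuple[int, int]) -> float:
    """Hudson's FST estimator from (ref, alt) allele counts.

    ``[(pA-pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)] /
    [pA(1-pB) + pB(1-pA)]``.  May be negative; returns NaN (undefined)
    when the denominator is 0, i.e. both sources fixed for the same
    allele.  Requires at least 2 allele copies per source.
    """
    ra, aa = count_a
    rb, ab = count_b
    na, nb = ra + aa, rb + ab
    if na < 2 or nb < 2:
        raise ValueError(f"need >= 2 allele copies per source "
                         f"(got nA={na}, nB={nb})")
    pa, pb = aa / na, ab / nb
    num = ((pa - pb) ** 2 - pa * (1 - pa) / (na - 1)
           - pb * (1 - pb) / (nb - 1))
    den = pa * (1 - pb) + pb * (1 - pa)
    if den == 0.0:
        return math.nan
    return num / den


def weir_cockerham_fst(count_a, count_b) -> float:
    """Weir & Cockerham's two-population estimator (alternative option)."""
    ra, aa = count_a
    rb, ab = count_b
    na, nb = ra + aa, rb + ab
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 allele copies per source")
    n_bar = (na + nb) / 2.0
    pa, pb = aa / na, ab / nb
    p_bar = (na * pa + nb * pb) / (na + nb)
    s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / n_bar
    nc = (na + nb - (na ** 2 + nb ** 2) / (na + nb))
    msp = s2 * n_bar
    msg = (na * pa * (1 - pa) + nb * pb * (1 - pb)) / (na + nb - 2)
    num = msp - msg
    den = msp + (nc - 1) * msg
    if den == 0.0:
        return math.nan
    return num / den


def panel_fst(panel: SitePanel, estimator: str = "hudson") -> np.ndarray:
    """Per-site FST between the panel's two sources (NaN = undefined)."""
    fn = hudson_fst if estimator == "hudson" else weir_cockerham_fst
    return np.array([fn((panel.ref_a[i], panel.alt_a[i]),
                        (panel.ref_b[i], panel.alt_b[i]))
                     for i in range(panel.n_sites)])


def filter_sites(panel: SitePanel, fst_min: float = 0.5,
                 estimator: str = "hudson") -> SitePanel:
    """Retain sites whose FST is defined and at least ``fst_min``."""
    fst = panel_fst(panel, estimator)
    keep = ~np.isnan(fst) & (fst >= fst_min)
    return panel.subset(keep)


def _emission_costs(panel: SitePanel) -> np.ndarray:
    """(n_sites, 2) matrix of -log P(target | source-label frequency).

    Diploid targets assume Hardy–Weinberg at the source frequency; the
    frequency is clamped to [eps, 1-eps] so fixed panels stay finite.
    """
    g = panel.target.astype(float)
    k = float(panel.ploidy)
    binom = np.array([math.comb(panel.ploidy, int(gi)) for gi in g])
    costs = np.empty((panel.n_sites, 2))
    for j, freq in enumerate((panel.freq_a(), panel.freq_b())):
        p = np.clip(freq, FREQ_CLAMP, 1.0 - FREQ_CLAMP)
        costs[:, j] = -(np.log(binom) + g * np.log(p)
                        + (k - g) * np.log(1.0 - p))
    return costs


def assign_ancestry(panel: SitePanel,
                    switch_penalty: float = 50.0) -> AncestrySegmentSet:
    """Minimum-cost ancestry path per chromosome (penalized-switch DP).

    Minimises the sum of per-site emission costs plus
    ``switch_penalty * (number of label changes)`` over all 2^n label
    paths by dynamic programming.  Segments are maximal same-label runs;
    boundaries between differing-label neighbours fall at the midpoint
    between the two sites; the outermost boundaries are the first site's
    position and one past the last site's.
    """
    if panel.n_sites < 1:
        raise ValueError("empty panel")
    costs = _emission_costs(panel)
    segments: list[tuple[str, int, int, str]] = []
    for chrom in pd.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == chrom)
        c = costs[idx]
        n = idx.size
        # forward pass
        dp = np.empty((n, 2))
        back = np.zeros((n, 2), dtype=np.int8)
        dp[0] = c[0]
        for i in range(1, n):
            for s in range(2):
                stay = dp[i - 1, s]
                switch = dp[i - 1, 1 - s] + switch_penalty
                if switch < stay:
                    dp[i, s] = switch + c[i, s]
                    back[i, s] = 1 - s
                else:
                    dp[i, s] = stay + c[i, s]
                    back[i, s] = s
        labels = np.empty(n, dtype=np.int8)
        labels[-1] = int(np.argmin(dp[-1]))
        for i in range(n - 1, 0, -1):
            labels[i - 1] = back[i, labels[i]]
        pos = panel.pos[idx]
        run_start = int(pos[0])
        for i in range(1, n):
            if labels[i] != labels[i - 1]:
                mid = int((pos[i - 1] + pos[i]) // 2)
                segments.append((str(chrom), run_start, mid,
                                 "A" if labels[i - 1] == 0 else "B"))
                run_start = mid
        segments.append((str(chrom), run_start, int(pos[-1]) + 1,
                         "A" if labels[-1] == 0 else "B"))
    return AncestrySegmentSet(segments)


def mask_loci(loci: list[tuple[str, int, int]], keep: AncestrySegmentSet,
              keep_label: str = "B") -> list[tuple[str, int, int]]:
    """Retain loci fully contained in a single ``keep_label`` segment.

    Containment is half-open: a locus exactly equal to a segment is
    retained; one straddling a segment end is removed.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in keep.with_label(keep_label):
        by_chrom.setdefault(str(chrom), []).append((start, end))
    for ivals in by_chrom.values():
        ivals.sort()
    out = []
    for chrom, start, end in loci:
        for s, e in by_chrom.get(str(chrom), ()):
            if s <= start and end <= e:
                out.append((chrom, start, end))
                break
    return out
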