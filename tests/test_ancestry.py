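"""FST estimation, penalized-switch ancestry assignment, locus masking."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mscmig.ancestry_mask import (AncestrySegmentSet, SitePanel,
                                  assign_ancestry, filter_sites, hudson_fst,
                                  mask_loci, weir_cockerham_fst,
                                  _emission_costs)
from mscmig.synthetic_data import generate_admixture_fixture


class TestHudsonFst:
    def test_fixed_difference(self):
        assert hudson_fst((0, 10), (10, 0)) == pytest.approx(1.0)

    def test_equal_intermediate_frequencies(self):
        # p=q=0.5, n=10 each: the estimator's finite-sample corrections
        # push it to -1/9
        assert hudson_fst((5, 5), (5, 5)) == pytest.approx(-1 / 9)

    def test_undefined_when_both_fixed_same(self):
        assert math.isnan(hudson_fst((10, 0), (10, 0)))

    def test_minimum_copies_enforced(self):
        with pytest.raises(ValueError):
            hudson_fst((1, 0), (5, 5))

    def test_weir_cockerham_agrees_at_fixed_difference(self):
        assert weir_cockerham_fst((0, 20), (20, 0)) == pytest.approx(
            1.0, abs=0.01)


class TestFilterSites:
    def _panel(self, alt_a, alt_b, n=10):
        k = len(alt_a)
        return SitePanel(["chr1"] * k, np.arange(k) * 100,
                         [n - a for a in alt_a], alt_a,
                         [n - b for b in alt_b], alt_b, [0] * k)

    def test_threshold_is_inclusive(self):
        # FSTs here: 1.0 (fixed), ~0 (same freq), undefined (both fixed)
        p = self._panel([10, 5, 0], [0, 5, 0])
        kept = filter_sites(p, 0.5)
        assert list(kept.pos) == [0]
        everything_defined = filter_sites(p, -10.0)
        assert list(everything_defined.pos) == [0, 100]

    def test_empty_panel_stays_empty(self):
        p = self._panel([10], [0]).subset(np.zeros(1, dtype=bool))
        assert filter_sites(p, 0.5).n_sites == 0


class TestAssignAncestry:
    def test_uniform_target_single_segment(self):
        panel, truth = generate_admixture_fixture(
            50, [(0, 50, "A")], panel_fst=1.0, seed=3)
        segs = assign_ancestry(panel, 50.0)
        assert segs.segments == truth.segments

    def test_huge_penalty_forces_one_segment(self):
        panel, _ = generate_admixture_fixture(
            200, [(0, 100, "A"), (100, 200, "B")], panel_fst=0.9, seed=5)
        segs = assign_ancestry(panel, 1e9)
        assert len(segs.segments) == 1

    def test_split_panel_matches_exhaustive_minimum(self):
        panel, _ = generate_admixture_fixture(
            10, [(0, 5, "A"), (5, 10, "B")], panel_fst=1.0, seed=7)
        segs = assign_ancestry(panel, 0.5)
        labels = _labels_from_segments(panel, segs)
        assert list(labels[:5]) == [0] * 5 and list(labels[5:]) == [1] * 5
        assert _path_cost(panel, labels, 0.5) == pytest.approx(
            _brute_force_cost(panel, 0.5))

    def test_relabel_symmetry(self):
        panel, _ = generate_admixture_fixture(
            60, [(0, 30, "A"), (30, 60, "B")], panel_fst=0.85, seed=11)
        swapped = SitePanel(panel.chrom, panel.pos, panel.ref_b,
                            panel.alt_b, panel.ref_a, panel.alt_a,
                            panel.target, panel.ploidy)
        a = assign_ancestry(panel, 20.0)
        b = assign_ancestry(swapped, 20.0)
        flip = {"A": "B", "B": "A"}
        assert [(c, s, e, flip[lab]) for c, s, e, lab in a.segments] == \
            b.segments

    def test_empty_panel_rejected(self):
        panel, _ = generate_admixture_fixture(5, [(0, 5, "A")], seed=1)
        with pytest.raises(ValueError):
            assign_ancestry(panel.subset(np.zeros(5, dtype=bool)))

    @given(st.integers(2, 15), st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_dp_equals_exhaustive_search(self, n, seed):
        rng = np.random.default_rng(seed)
        panel, _ = generate_admixture_fixture(
            n, [(0, n, "A")], panel_fst=float(rng.uniform(0, 0.95)),
            seed=seed)
        panel.target = rng.integers(0, 3, n)
        penalty = float(rng.uniform(0.05, 5.0))
        segs = assign_ancestry(panel, penalty)
        labels = _labels_from_segments(panel, segs)
        assert _path_cost(panel, labels, penalty) == pytest.approx(
            _brute_force_cost(panel, penalty), rel=1e-9)


def _labels_from_segments(panel, segs):
    lab = np.empty(panel.n_sites, dtype=int)
    for chrom, s, e, label in segs.segments:
        m = (panel.pos >= s) & (panel.pos < e)
        lab[m] = 0 if label == "A" else 1
    return lab


def _path_cost(panel, labels, penalty):
    c = _emission_costs(panel)
    cost = sum(c[i, labels[i]] for i in range(panel.n_sites))
    cost += penalty * sum(labels[i] != labels[i - 1]
                          for i in range(1, panel.n_sites))
    return cost


def _brute_force_cost(panel, penalty):
    c = _emission_costs(panel)
    n = panel.n_sites
    best = math.inf
    for path in itertools.product((0, 1), repeat=n):
        cost = sum(c[i, path[i]] for i in range(n))
        cost += penalty * sum(path[i] != path[i - 1] for i in range(1, n))
        best = min(best, cost)
    return best


class TestSyntheticAccuracy:
    def test_three_segments_high_accuracy(self):
        panel, truth = generate_admixture_fixture(
            1000, [(0, 400, "A"), (400, 700, "B"), (700, 1000, "A")],
            panel_fst=0.8, seed=2)
        segs = assign_ancestry(panel, 50.0)
        got = _labels_from_segments(panel, segs)
        want = _labels_from_segments(panel, truth)
        assert np.mean(got == want) >= 0.95
        # every true segment recovered with small boundary error
        assert len(segs.segments) == len(truth.segments)

    def test_zero_differentiation_is_uninformative(self):
        panel, truth = generate_admixture_fixture(
            400, [(0, 200, "A"), (200, 400, "B")], panel_fst=0.0, seed=6)
        segs = assign_ancestry(panel, 0.0)
        got = _labels_from_segments(panel, segs)
        want = _labels_from_segments(panel, truth)
        assert abs(np.mean(got == want) - 0.5) < 0.15


class TestMaskLoci:
    KEEP = AncestrySegmentSet([("chr1", 0, 5000, "B"),
                               ("chr1", 5000, 9000, "A"),
                               ("chr2", 0, 2000, "B")])

    def test_contained_locus_retained(self):
        assert mask_loci([("chr1", 100, 1100)], self.KEEP, "B") == \
            [("chr1", 100, 1100)]

    def test_straddling_locus_removed(self):
        assert mask_loci([("chr1", 4500, 5500)], self.KEEP, "B") == []

    def test_exact_segment_match_retained(self):
        assert mask_loci([("chr2", 0, 2000)], self.KEEP, "B") == \
            [("chr2", 0, 2000)]

    def test_wrong_label_removed(self):
        assert mask_loci([("chr1", 5100, 6100)], self.KEEP, "B") == []


class TestSegmentSet:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            AncestrySegmentSet([("chr1", 0, 100, "A"),
                                ("chr1", 50, 150, "B")])

    def test_bed_round_trip(self, tmp_path):
        segs = AncestrySegmentSet([("chr1", 0, 100, "A"),
                                   ("chr1", 100, 300, "B")])
        p = tmp_path / "segs.bed"
        segs.to_bed(p)
        assert AncestrySegmentSet.from_bed(p).segments == \
            sorted(segs.segments)
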