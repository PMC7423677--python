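"""Demographic model invariants and parameter unit conversions."""

import pytest
from hypothesis import given, settings, strategies as st

from mscmig.demography import (COMBO_I, COMBO_II, DemographicModel,
                               InvalidModelError, MigrationBand,
                               PopulationTree, RateScale, band_time_span,
                               ne_to_theta, read_model_config, tau_to_years,
                               theta_to_ne, total_migration_rate,
                               wolf_dog_preset, write_model_config,
                               years_to_tau)


class TestConversions:
    def test_theta_ne_examples(self):
        assert theta_to_ne(4e-8, RateScale(1e-8, 3.0)) == 1.0
        assert theta_to_ne(0.0, COMBO_I) == 0.0
        # the same scaled size reads as 92 586 or 37 034 individuals
        theta = ne_to_theta(92_586, COMBO_I)
        assert round(theta_to_ne(theta, COMBO_II)) == 37_034

    def test_tau_years_examples(self):
        assert years_to_tau(36_000, COMBO_I) == pytest.approx(3.2e-5)
        assert tau_to_years(3.2e-5, COMBO_II) == pytest.approx(9_600)
        assert tau_to_years(0.0, COMBO_I) == 0.0

    @given(st.floats(1e-10, 1e3), st.floats(min_value=1e-10, max_value=1e9))
    @settings(derandomize=True, max_examples=50)
    def test_round_trips(self, mu_scale, value):
        scale = RateScale(mu_scale * 1e-9, 3.7)
        assert theta_to_ne(ne_to_theta(value, scale), scale) == \
            pytest.approx(value, rel=1e-12)
        assert years_to_tau(tau_to_years(value, scale), scale) == \
            pytest.approx(value, rel=1e-12)

    def test_cross_scale_factors_exact(self):
        # years ratio combo_i/combo_ii = (4.5/4e-9)/(3/1e-8) = 3.75,
        # individuals ratio = (1/4e-9)/(1/1e-8) = 2.5
        tau, theta = 7.77e-5, 3.3e-4
        assert tau_to_years(tau, COMBO_I) / tau_to_years(tau, COMBO_II) \
            == pytest.approx(3.75, rel=1e-14)
        assert theta_to_ne(theta, COMBO_I) / theta_to_ne(theta, COMBO_II) \
            == pytest.approx(2.5, rel=1e-14)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            RateScale(0.0, 3.0)
        with pytest.raises(ValueError):
            RateScale(1e-8, -1.0)
        with pytest.raises(ValueError):
            theta_to_ne(-1e-9, COMBO_I)
        with pytest.raises(ValueError):
            tau_to_years(-1e-9, COMBO_I)


class TestTotalMigrationRate:
    def test_arithmetic(self):
        assert total_migration_rate(150.0, 0.0002) == pytest.approx(0.03)
        assert total_migration_rate(0.0, 0.5) == 0.0

    def test_invariant_under_joint_rescaling(self):
        # M scales as 1/mu, tau_m as mu: the product is mu-free
        assert total_migration_rate(300.0, 0.0001) == \
            pytest.approx(total_migration_rate(150.0, 0.0002))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            total_migration_rate(-1.0, 0.1)
        with pytest.raises(ValueError):
            total_migration_rate(1.0, 0.0)


class TestTreeInvariants:
    def test_band_time_span_shared_parent(self, two_pop_model):
        band = MigrationBand("A", "B", 1.0)
        assert band_time_span(two_pop_model, band) == pytest.approx(0.001)

    def test_band_time_span_partial_overlap(self):
        # leaf existing [0, 0.002) vs ancestral pop [0.001, 0.003)
        tree = PopulationTree(
            {"A": "AB", "B": "AB", "AB": "root", "C": "root"},
            {"AB": 0.002, "root": 0.003},
            {n: 1e-3 for n in ("A", "B", "C", "AB", "root")})
        model = DemographicModel(tree)
        assert band_time_span(model, MigrationBand("C", "AB", 1.0)) == \
            pytest.approx(0.001)
        assert band_time_span(model, MigrationBand("AB", "C", 1.0)) == \
            pytest.approx(0.001)

    def test_disjoint_band_rejected(self):
        tree = PopulationTree(
            {"A": "AB", "B": "AB", "AB": "root", "C": "root"},
            {"AB": 0.002, "root": 0.003},
            {n: 1e-3 for n in ("A", "B", "C", "AB", "root")})
        with pytest.raises(InvalidModelError):
            DemographicModel(tree, [MigrationBand("A", "AB", 1.0)])

    def test_tau_ordering_enforced(self):
        with pytest.raises(InvalidModelError):
            PopulationTree(
                {"A": "AB", "B": "AB", "AB": "root", "C": "root"},
                {"AB": 0.003, "root": 0.002},
                {n: 1e-3 for n in ("A", "B", "C", "AB", "root")})

    def test_positive_theta_enforced(self):
        with pytest.raises(InvalidModelError):
            PopulationTree({"A": "root", "B": "root"}, {"root": 1e-3},
                           {"A": 0.0, "B": 1e-3, "root": 1e-3})


class TestPreset:
    def test_invariants_and_leaves(self):
        model = wolf_dog_preset()
        model.validate()
        for leaf in model.tree.leaves:
            assert model.tree.start_time(leaf) == 0.0
        assert len(model.tree.leaves) == 9

    def test_point_estimates_convert_back(self):
        tree = wolf_dog_preset().tree
        assert tau_to_years(tree.tau["ancDW"], COMBO_I) == \
            pytest.approx(36_000)
        assert tau_to_years(tree.tau["ancIB"], COMBO_I) == \
            pytest.approx(6_200)
        assert theta_to_ne(tree.theta["ancDW"], COMBO_I) == \
            pytest.approx(94_000)
        assert theta_to_ne(tree.theta["israeli"], COMBO_I) == \
            pytest.approx(50_000)

    def test_significant_band_totals(self):
        model = wolf_dog_preset()
        got = {b.name: total_migration_rate(b.M, band_time_span(model, b))
               for b in model.bands}
        assert got["basenji->israeli"] == pytest.approx(0.15)
        assert got["dingo->chinese"] == pytest.approx(0.06)
        assert got["basenji->spanish"] == pytest.approx(0.20)

    def test_placeholders_flagged(self):
        model = wolf_dog_preset()
        assert "chinese" in model.metadata["placeholders"]
        assert "ancDOG" in model.metadata["placeholders"]


def test_model_config_round_trip(tmp_path):
    model = wolf_dog_preset()
    path = tmp_path / "model.cfg"
    write_model_config(model, path)
    back = read_model_config(path)
    assert back.tree.parent == model.tree.parent
    assert back.tree.tau == pytest.approx(model.tree.tau)
    assert back.tree.theta == pytest.approx(model.tree.theta)
    assert [(b.source, b.target, b.M) for b in back.bands] == \
        [(b.source, b.target, b.M) for b in model.bands]
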