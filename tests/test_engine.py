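import pytest

from abx_carbon.engine import (
    EmissionResult,
    agent_dose_factors,
    agent_factors,
    average_sites,
    dose_emissions,
    dot_emissions,
    item_emissions,
    product_dose_result,
)
from abx_carbon.errors import DataValidationError
from abx_carbon.inventory import (
    AdminDailyBom,
    BomEntry,
    DrugProduct,
    InventoryBundle,
    InventoryItem,
)
from abx_carbon.reference_data import (
    DisposalMethod,
    DisposalScenario,
    EmissionFactorTable,
    SHORT_TON_G,
)
from abx_carbon.fixtures import FixtureSpec, generate_fixture

from helpers_oracle import naive_agent_factors, naive_dot

LF = DisposalMethod.LANDFILLED


def toy_bundle():
    """1 product, 1 site: vial 20 g glass + 0.08 box 30 g corrugated + bag 40 g."""
    items = {
        "VIAL": InventoryItem("VIAL", "vial", "drug_container", "glass", {"A": 20.0}),
        "BOX": InventoryItem("BOX", "box", "drug_packaging", "corrugated containers",
                             {"A": 30.0}),
        "BAG": InventoryItem("BAG", "bag", "preparation", "mixed plastics", {"A": 40.0}),
        "TUBE": InventoryItem("TUBE", "tubing", "administration", "mixed plastics",
                              {"A": 50.0}),
    }
    products = {"P1": DrugProduct("P1", "drugx", "1 g/50 mL", "local_compound", 2.0)}
    bom = [BomEntry("P1", "VIAL", "A", 1.0),
           BomEntry("P1", "BOX", "A", 0.08),
           BomEntry("P1", "BAG", "A", 1.0)]
    admin = {"A": AdminDailyBom("A", {"TUBE": 1.0})}
    return InventoryBundle(items=items, products=products, bom=bom, admin_daily=admin)


class TestItemEmissions:
    def test_zero_mass_is_zero(self, factor_table, scenario):
        item = InventoryItem("X", "x", "preparation", "glass", {"A": 1.0})
        assert item_emissions(item, 0.0, factor_table, scenario) == 0.0

    def test_one_short_ton_returns_factor_exactly(self, factor_table, scenario):
        item = InventoryItem("X", "x", "preparation", "glass", {"A": 1.0})
        f = factor_table.get("glass", LF)
        assert item_emissions(item, SHORT_TON_G, factor_table, scenario) == pytest.approx(
            f, rel=1e-15)

    def test_fifty_grams_glass_hand_computation(self, factor_table, scenario):
        item = InventoryItem("X", "x", "preparation", "glass", {"A": 50.0})
        expected = 50.0 / 907184.74 * factor_table.get("glass", LF)
        assert item_emissions(item, 50.0, factor_table, scenario) == pytest.approx(
            expected, rel=1e-12)


class TestDoseEmissions:
    def test_toy_product_hand_sum(self, factor_table, scenario):
        bundle = toy_bundle()
        result = dose_emissions(bundle.products["P1"], "A", bundle, factor_table,
                                scenario)
        f = factor_table.get
        expected_mtco2e = (20.0 * f("glass", LF)
                           + 0.08 * 30.0 * f("corrugated containers", LF)
                           + 40.0 * f("mixed plastics", LF)) / 907184.74
        assert result.mtco2e == pytest.approx(expected_mtco2e, rel=1e-12)
        assert result.waste_mass_g == pytest.approx(20 + 0.08 * 30 + 40, rel=1e-12)

    def test_zero_count_entry_contributes_zero(self, factor_table, scenario):
        bundle = toy_bundle()
        bundle.bom = [BomEntry("P1", "VIAL", "A", 0.0)]
        result = dose_emissions(bundle.products["P1"], "A", bundle, factor_table,
                                scenario)
        assert (result.mtco2e, result.waste_mass_g) == (0.0, 0.0)

    def test_doubling_counts_doubles_outputs(self, factor_table, scenario):
        bundle = toy_bundle()
        base = dose_emissions(bundle.products["P1"], "A", bundle, factor_table, scenario)
        bundle.bom = [BomEntry(e.product_id, e.item_id, e.site, 2 * e.count_per_dose)
                      for e in bundle.bom]
        doubled = dose_emissions(bundle.products["P1"], "A", bundle, factor_table,
                                 scenario)
        assert doubled.mtco2e == pytest.approx(2 * base.mtco2e, rel=1e-12)
        assert doubled.waste_mass_g == pytest.approx(2 * base.waste_mass_g, rel=1e-12)

    def test_missing_site_bom_rejected(self, factor_table, scenario):
        bundle = toy_bundle()
        with pytest.raises(DataValidationError, match="no BOM"):
            dose_emissions(bundle.products["P1"], "B", bundle, factor_table, scenario)

    def test_additivity_over_bom_partition(self, factor_table, scenario):
        bundle = toy_bundle()
        full = dose_emissions(bundle.products["P1"], "A", bundle, factor_table, scenario)
        total_m = total_w = 0.0
        all_entries = list(bundle.bom)
        for entry in all_entries:
            bundle.bom = [entry]
            part = dose_emissions(bundle.products["P1"], "A", bundle, factor_table,
                                  scenario)
            total_m += part.mtco2e
            total_w += part.waste_mass_g
        assert total_m == pytest.approx(full.mtco2e, rel=1e-12)
        assert total_w == pytest.approx(full.waste_mass_g, rel=1e-12)


class TestAverageSites:
    def test_single_site_identity(self):
        r = average_sites({"A": EmissionResult(1.5, 10.0)})
        assert (r.mtco2e, r.waste_mass_g) == (1.5, 10.0)

    def test_two_site_mean(self):
        r = average_sites({"A": EmissionResult(0.0, 10.0),
                           "B": EmissionResult(2.0, 20.0)})
        assert r.mtco2e == 1.0
        assert r.waste_mass_g == 15.0
        assert r.site_values == {"A": (0.0, 10.0), "B": (2.0, 20.0)}

    def test_empty_rejected(self):
        with pytest.raises(DataValidationError):
            average_sites({})

    def test_headline_equals_brute_force_mean(self):
        import random
        rng = random.Random(42)
        for _ in range(25):
            results = {f"S{i}": EmissionResult(rng.uniform(0, 2), rng.uniform(0, 100))
                       for i in range(rng.randint(2, 4))}
            r = average_sites(results)
            n = len(results)
            assert r.mtco2e == pytest.approx(
                sum(v.mtco2e for v in results.values()) / n, rel=1e-12)
            assert r.waste_mass_g == pytest.approx(
                sum(v.waste_mass_g for v in results.values()) / n, rel=1e-12)


class TestDotEmissions:
    def _structured_bundle(self):
        """Factors tuned so prep = 0.001 mtCO2e/dose and admin = 0.002 mtCO2e/day."""
        items = {
            "PREP": InventoryItem("PREP", "p", "preparation", "prepmat", {"A": 1.0}),
            "ADM": InventoryItem("ADM", "a", "administration", "admmat", {"A": 2.0}),
        }
        products = {"P1": DrugProduct("P1", "drugx", "1 g", "local_compound", 4.0)}
        bundle = InventoryBundle(
            items=items, products=products,
            bom=[BomEntry("P1", "PREP", "A", 1.0)],
            admin_daily={"A": AdminDailyBom("A", {"ADM": 1.0})})
        factor = SHORT_TON_G / 1000.0  # 1 g -> 0.001 mtCO2e
        table = EmissionFactorTable(
            entries={("prepmat", LF): factor, ("admmat", LF): factor},
            provenance="synthetic unit-test factors")
        return bundle, table

    def test_structure_prep_times_doses_plus_admin(self):
        bundle, table = self._structured_bundle()
        result = dot_emissions(bundle.products["P1"], bundle, table, DisposalScenario())
        assert result.mtco2e == pytest.approx(0.001 * 4 + 0.002, rel=1e-12)

    def test_halving_doses_per_day_halves_prep_term_only(self):
        bundle, table = self._structured_bundle()
        bundle.products["P1"].doses_per_day = 0.5
        result = dot_emissions(bundle.products["P1"], bundle, table, DisposalScenario())
        assert result.mtco2e == pytest.approx(0.001 * 0.5 + 0.002, rel=1e-12)

    def test_admin_per_dose_flag_scales_admin_term(self):
        bundle, table = self._structured_bundle()
        result = dot_emissions(bundle.products["P1"], bundle, table, DisposalScenario(),
                               admin_per_dose=True)
        assert result.mtco2e == pytest.approx((0.001 + 0.002) * 4, rel=1e-12)

    def test_admin_only_product_equals_daily_admin_total(self):
        bundle, table = self._structured_bundle()
        bundle.bom = [BomEntry("P1", "PREP", "A", 0.0)]
        result = dot_emissions(bundle.products["P1"], bundle, table, DisposalScenario())
        assert result.mtco2e == pytest.approx(0.002, rel=1e-12)

    def test_missing_admin_bom_is_error_not_zero(self, factor_table, scenario):
        bundle = toy_bundle()
        bundle.admin_daily = {}
        with pytest.raises(DataValidationError, match="administration daily BOM"):
            dot_emissions(bundle.products["P1"], bundle, factor_table, scenario)


class TestAgentAveraging:
    def _two_product_bundle(self):
        """Two products of one agent at 10 and 20 g waste/DOT (inert material)."""
        items = {
            "I1": InventoryItem("I1", "x", "drug_container", "m", {"A": 10.0}),
            "I2": InventoryItem("I2", "y", "drug_container", "m", {"A": 20.0}),
            "AD": InventoryItem("AD", "t", "administration", "m", {"A": 5.0}),
        }
        products = {
            "P1": DrugProduct("P1", "drugx", "1 g", "local_compound", 1.0),
            "P2": DrugProduct("P2", "drugx", "2 g", "local_compound", 1.0),
        }
        bundle = InventoryBundle(
            items=items, products=products,
            bom=[BomEntry("P1", "I1", "A", 1.0), BomEntry("P2", "I2", "A", 1.0)],
            admin_daily={"A": AdminDailyBom("A", {"AD": 0.0})})
        table = EmissionFactorTable(entries={("m", LF): 1.0},
                                    provenance="synthetic unit-test factors")
        return bundle, table

    def test_agent_mean_over_products(self):
        bundle, table = self._two_product_bundle()
        factors = agent_factors(bundle.products, bundle, table, DisposalScenario())
        assert len(factors) == 1
        assert factors[0].agent == "drugx"
        assert factors[0].n_products_averaged == 2
        assert factors[0].waste_g_per_dot == pytest.approx(15.0, rel=1e-12)

    def test_single_product_agent_identity(self):
        bundle, table = self._two_product_bundle()
        del bundle.products["P2"]
        bundle.bom = bundle.bom[:1]
        factors = agent_factors(bundle.products, bundle, table, DisposalScenario())
        dot = dot_emissions(bundle.products["P1"], bundle, table, DisposalScenario())
        assert factors[0].mtco2e_per_dot == dot.mtco2e
        assert factors[0].n_products_averaged == 1

    def test_agent_dose_grouping_partitions_products(self, factor_table, scenario,
                                                     tmp_path):
        bundle = generate_fixture(FixtureSpec(seed=11, n_agents=3,
                                              n_products_per_agent=2, n_items=14),
                                  tmp_path / "fx")
        factors = agent_dose_factors(bundle.products, bundle, factor_table, scenario)
        assert sum(f.n_products_averaged for f in factors) == bundle.n_products

    def test_matches_naive_oracle_on_generated_fixtures(self, factor_table, scenario,
                                                        tmp_path):
        for seed in range(6):
            bundle = generate_fixture(
                FixtureSpec(seed=seed, n_agents=3, n_products_per_agent=2,
                            n_items=14, n_sites=(seed % 3) + 1),
                tmp_path / f"fx{seed}")
            expected = naive_agent_factors(bundle, factor_table, scenario)
            got = agent_factors(bundle.products, bundle, factor_table, scenario)
            assert {f.agent for f in got} == set(expected)
            for f in got:
                assert f.mtco2e_per_dot == pytest.approx(expected[f.agent][0], rel=1e-12)
                assert f.waste_g_per_dot == pytest.approx(expected[f.agent][1], rel=1e-12)


class TestInvariants:
    def test_homogeneity_in_mass(self, factor_table, scenario):
        bundle = toy_bundle()
        base = dot_emissions(bundle.products["P1"], bundle, factor_table, scenario)
        k = 3.5
        for item in bundle.items.values():
            item.site_masses = {s: k * m for s, m in item.site_masses.items()}
        scaled = dot_emissions(bundle.products["P1"], bundle, factor_table, scenario)
        assert scaled.mtco2e == pytest.approx(k * base.mtco2e, rel=1e-12)
        assert scaled.waste_mass_g == pytest.approx(k * base.waste_mass_g, rel=1e-12)

    def test_scenario_change_touches_only_that_material(self, factor_table):
        bundle = toy_bundle()
        plain = DisposalScenario()
        glass_recycled = DisposalScenario(overrides={"glass": DisposalMethod.RECYCLED})
        product = bundle.products["P1"]
        base = dose_emissions(product, "A", bundle, factor_table, plain)
        changed = dose_emissions(product, "A", bundle, factor_table, glass_recycled)
        delta_glass = 20.0 / 907184.74 * (
            factor_table.get("glass", DisposalMethod.RECYCLED)
            - factor_table.get("glass", LF))
        assert changed.mtco2e - base.mtco2e == pytest.approx(delta_glass, rel=1e-12)
        assert changed.waste_mass_g == base.waste_mass_g
        # a product without glass is untouched
        bundle.bom = [e for e in bundle.bom if e.item_id != "VIAL"]
        a = dose_emissions(product, "A", bundle, factor_table, plain)
        b = dose_emissions(product, "A", bundle, factor_table, glass_recycled)
        assert a.mtco2e == b.mtco2e

    def test_waste_mass_independent_of_scenario(self, factor_table):
        bundle = toy_bundle()
        product = bundle.products["P1"]
        for sc in (DisposalScenario(),
                   DisposalScenario(default_method=DisposalMethod.COMBUSTED)):
            r = dose_emissions(product, "A", bundle, factor_table, sc)
            assert r.waste_mass_g == pytest.approx(62.4, rel=1e-12)

    def test_product_dose_result_averages_sites(self, worked_bundle, factor_table,
                                                scenario):
        product = worked_bundle.products["CFZ-3G-LC"]
        r = product_dose_result(product, worked_bundle, factor_table, scenario)
        per_site = [dose_emissions(product, s, worked_bundle, factor_table, scenario)
                    for s in ("siteA", "siteB")]
        assert r.mtco2e == pytest.approx(
            (per_site[0].mtco2e + per_site[1].mtco2e) / 2, rel=1e-12)
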