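"""Systemic balance, site storage, reconciliation and indices."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

import carbonledger as cl
from carbonledger import FluxCategory, FunctionalUnit, Site

from conftest import flux, ledger


class TestComputeBalance:
    def test_consortium_totals(self, coalvi):
        rep = cl.compute_balance(coalvi)
        assert rep.total_inputs == pytest.approx(379.0)
        assert rep.total_outputs == pytest.approx(295.7)
        assert rep.balance == pytest.approx(83.3)

    def test_empty_ledger(self):
        rep = cl.compute_balance(ledger())
        assert rep.balance == 0.0
        assert rep.efficiency is None

    def test_internal_only_ledger_balances_to_zero(self):
        rep = cl.compute_balance(
            ledger(flux("a", "plant", "animal", 10.0), flux("b", "animal", "soil", 4.0))
        )
        assert rep.total_inputs == 0.0
        assert rep.total_outputs == 0.0
        assert rep.balance == 0.0

    def test_invalid_ledger_raises_with_violations(self):
        bad = dataclasses.replace(
            flux("f1", "plant", "air", 1.0), category=FluxCategory.INPUT
        )
        with pytest.raises(cl.LedgerValidationError) as err:
            cl.compute_balance(ledger(bad))
        assert err.value.violations[0].flux_id == "f1"

    @given(st.integers(0, 2**31 - 1))
    def test_adding_internal_flux_leaves_balance_unchanged(self, seed):
        lg = cl.generate_synthetic_ledger(10, seed)
        before = cl.compute_balance(lg)
        lg.fluxes.append(flux("extra_internal", "soil", "plant", 123.4))
        after = cl.compute_balance(lg)
        assert after.total_inputs == before.total_inputs
        assert after.total_outputs == before.total_outputs
        assert after.balance == before.balance

    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 100.0))
    def test_scaling_fluxes_scales_results_but_not_efficiency(self, seed, c):
        lg = cl.generate_synthetic_ledger(12, seed)
        before = cl.compute_balance(lg)
        scaled = dataclasses.replace(lg)
        scaled.fluxes = [
            dataclasses.replace(f, amount_c=c * f.amount_c) for f in lg.fluxes
        ]
        after = cl.compute_balance(scaled)
        assert after.balance == pytest.approx(c * before.balance, rel=1e-9, abs=1e-9)
        assert after.air_change == pytest.approx(c * before.air_change, rel=1e-9, abs=1e-9)
        for site in before.site_storage:
            assert after.site_storage[site] == pytest.approx(
                c * before.site_storage[site], rel=1e-9, abs=1e-9
            )
        if before.efficiency is not None:
            assert after.efficiency == pytest.approx(before.efficiency, rel=1e-9)


class TestAirSiteChange:
    def test_consortium_net_removal(self, coalvi):
        # 261.3 released to air minus 357.4 taken up
        assert cl.air_site_change(coalvi) == pytest.approx(-96.1)

    def test_no_air_fluxes(self):
        assert cl.air_site_change(ledger(flux("a", "external", "plant", 5.0))) == 0.0

    def test_uptake_only(self):
        assert cl.air_site_change(ledger(flux("a", "air", "plant", 5.0))) == -5.0

    def test_closed_to_market_limit_mirrors_balance(self):
        """With all inputs from air and all outputs to air, air change = -balance."""
        lg = ledger(
            flux("in", "air", "plant", 100.0),
            flux("mid", "plant", "animal", 30.0),
            flux("out", "animal", "air", 60.0),
        )
        rep = cl.compute_balance(lg)
        assert cl.air_site_change(lg) == pytest.approx(-rep.balance)


class TestSiteGrossStorage:
    @pytest.mark.parametrize(
        "site, expected",
        [(Site.PLANT, 109.3), (Site.ANIMAL, 8.6), (Site.SOIL, 0.0)],
    )
    def test_consortium_storage(self, coalvi, site, expected):
        assert cl.site_gross_storage(coalvi, site) == pytest.approx(expected, abs=1e-9)

    def test_fossil_fluxes_never_enter_pools(self):
        lg = ledger(
            flux("fuel_in", "external", "plant", 15.6, fossil=True, material="oil"),
            flux("fuel_out", "plant", "air", 15.6, fossil=True, material="co2"),
        )
        assert cl.site_gross_storage(lg, Site.PLANT) == 0.0

    def test_exports_stay_in_pool(self):
        lg = ledger(
            flux("grow", "air", "plant", 10.0),
            flux("sold", "plant", "external", 4.0),
        )
        # market exports are not deducted from gross storage
        assert cl.site_gross_storage(lg, Site.PLANT) == pytest.approx(10.0)

    def test_boundary_site_rejected(self, coalvi):
        with pytest.raises(ValueError):
            cl.site_gross_storage(coalvi, Site.AIR)


class TestReconcile:
    def test_consortium_identity(self, coalvi):
        rep = cl.compute_balance(coalvi)
        recon = cl.reconcile(rep, coalvi)
        # 117.9 storage - 34.4 exports + 15.6 fossil in - 15.8 fossil out = 83.3
        assert recon.passed
        assert recon.conservation_residual == pytest.approx(0.0, abs=1e-9)
        assert recon.decomposition_residual == pytest.approx(0.0, abs=1e-9)

    def test_empty_ledger(self):
        lg = ledger()
        recon = cl.reconcile(cl.compute_balance(lg), lg)
        assert recon.conservation_residual == 0.0
        assert recon.decomposition_residual == 0.0

    @given(st.integers(0, 2**31 - 1))
    def test_conservation_holds_on_generated_ledgers(self, seed):
        lg = cl.generate_synthetic_ledger(30, seed)
        recon = cl.reconcile(cl.compute_balance(lg), lg)
        assert recon.passed


class TestIndices:
    def test_consortium_efficiency(self, coalvi):
        rep = cl.compute_balance(coalvi)
        assert rep.efficiency == pytest.approx(83.3 / 379.0, rel=1e-6)
        assert rep.efficiency == pytest.approx(0.2198, abs=5e-5)

    def test_efficiency_sign_follows_balance(self):
        lg = ledger(flux("in", "air", "plant", 100.0), flux("out", "soil", "air", 150.0))
        assert cl.efficiency(cl.compute_balance(lg)) == pytest.approx(-0.5)

    def test_efficiency_undefined_without_inputs(self):
        rep = cl.compute_balance(ledger(flux("out", "soil", "air", 1.0)))
        with pytest.raises(cl.UndefinedIndexError):
            cl.efficiency(rep)

    def test_consortium_intensity_per_hectare(self, coalvi):
        rep = cl.compute_balance(coalvi)
        # 379.0e3 t C over 70 632 ha
        assert rep.intensity["utilised agricultural area"] == pytest.approx(5.37, abs=0.01)

    def test_intensity_identity_fu(self):
        lg = ledger(flux("in", "air", "plant", 42.0))
        rep = cl.compute_balance(lg)
        assert cl.intensity(rep, FunctionalUnit("one", 1.0, "unit")) == pytest.approx(42.0)


class TestPerFuTable:
    def test_consortium_balance_per_fu(self, coalvi):
        rep = cl.compute_balance(coalvi)
        area = rep.per_fu["utilised agricultural area"]
        lw = rep.per_fu["LW slaughtered"]
        bal_ha = area.loc[area.label == "balance (inputs - outputs)", "per_fu"].item()
        bal_lw = lw.loc[lw.label == "balance (inputs - outputs)", "per_fu"].item()
        assert bal_ha == pytest.approx(1.18, abs=0.01)
        assert bal_lw == pytest.approx(2.24, abs=0.01)

    def test_per_fu_column_is_total_divided_by_quantity(self, coalvi):
        rep = cl.compute_balance(coalvi)
        fu = coalvi.functional_unit("LW slaughtered")
        table = rep.per_fu["LW slaughtered"]
        assert (table["per_fu"] * fu.quantity - table["total"]).abs().max() < 1e-9

    def test_identity_fu_table_equals_totals(self):
        lg = ledger(
            flux("in", "air", "plant", 10.0),
            fus=[FunctionalUnit("one", 1.0, "unit")],
        )
        rep = cl.compute_balance(lg)
        table = rep.per_fu["one"]
        assert (table["per_fu"] == table["total"]).all()

    def test_air_row_sign_follows_removal_convention(self, coalvi):
        # net atmospheric removal is negative in every column, including per LW
        rep = cl.compute_balance(coalvi)
        lw = rep.per_fu["LW slaughtered"]
        air = lw.loc[lw.label == "C stored: air", "per_fu"].item()
        assert air == pytest.approx(-2.58, abs=0.01)
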