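"""Pooled variation weighting and two-way sensitivity of the balance."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

import carbonledger as cl
from carbonledger import FluxCategory

from conftest import flux, ledger


class TestWeightedVariation:
    def test_weighted_mean_of_two_inputs(self):
        # (300*11 + 100*7) / 400 = 10
        lg = ledger(
            flux("a", "air", "plant", 300.0, variation=11.0),
            flux("b", "external", "animal", 100.0, variation=7.0),
        )
        assert cl.weighted_variation(lg, FluxCategory.INPUT) == pytest.approx(10.0)

    def test_constant_ranges_pool_to_themselves(self, coalvi):
        assert cl.weighted_variation(coalvi, FluxCategory.INPUT) == pytest.approx(10.0)
        assert cl.weighted_variation(coalvi, FluxCategory.OUTPUT) == pytest.approx(10.0)

    def test_single_flux_returns_own_variation(self):
        lg = ledger(flux("a", "soil", "air", 50.0, variation=7.5))
        assert cl.weighted_variation(lg, FluxCategory.OUTPUT) == pytest.approx(7.5)

    def test_missing_variation_listed_by_id(self):
        lg = ledger(
            flux("has", "air", "plant", 1.0, variation=5.0),
            flux("lacks", "external", "soil", 1.0),
        )
        with pytest.raises(cl.IncompleteVariationError, match="lacks"):
            cl.weighted_variation(lg, FluxCategory.INPUT)

    def test_internal_category_rejected(self, coalvi):
        with pytest.raises(ValueError):
            cl.weighted_variation(coalvi, FluxCategory.INTERNAL)

    @given(st.integers(0, 2**31 - 1))
    def test_bounded_by_component_ranges(self, seed):
        lg = cl.generate_synthetic_ledger(15, seed)
        for cat in (FluxCategory.INPUT, FluxCategory.OUTPUT):
            fluxes = lg.by_category(cat)
            if not fluxes:
                continue
            pooled = cl.weighted_variation(lg, cat)
            ranges = [f.variation_pct for f in fluxes]
            assert min(ranges) - 1e-9 <= pooled <= max(ranges) + 1e-9


class TestRoundVariation:
    @pytest.mark.parametrize(
        "value, expected",
        [(10.4, 10.0), (9.9, 10.0), (10.0, 10.0), (10.5, 11.0), (0.2, 0.0)],
    )
    def test_nearest_integer_half_away_from_zero(self, value, expected):
        assert cl.round_variation(value) == expected

    def test_none_mode_is_identity(self):
        assert cl.round_variation(10.4, mode="none") == 10.4

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cl.round_variation(-1.0)


class TestTwoWaySensitivity:
    def test_consortium_worst_corner_stays_positive(self, coalvi):
        result = cl.two_way_sensitivity(coalvi, 10.0, 10.0)
        # 379.0*0.9 - 295.7*1.1 = 15.83 (derived from the printed flux table)
        assert result.worst_case == pytest.approx(15.83, abs=0.01)
        assert result.worst_case > 0
        assert result.sign_robust
        assert result.grid[(0.9, 1.1)] == result.worst_case
        assert result.grid[(1.1, 0.9)] == result.best_case

    def test_zero_deltas_collapse_to_centre(self, coalvi):
        result = cl.two_way_sensitivity(coalvi, 0.0, 0.0)
        assert set(result.grid.values()) == {result.centre}
        assert result.worst_case == result.best_case == result.centre

    def test_zero_balance_is_never_sign_robust(self):
        lg = ledger(flux("in", "air", "plant", 10.0), flux("out", "plant", "air", 10.0))
        result = cl.two_way_sensitivity(lg, 5.0, 5.0)
        assert result.centre == 0.0
        assert not result.sign_robust

    def test_worst_and_best_bracket_centre(self, coalvi):
        result = cl.two_way_sensitivity(coalvi, 10.0, 10.0)
        assert result.worst_case <= result.centre <= result.best_case

    def test_internal_fluxes_unperturbed(self, coalvi):
        internal_total = sum(
            f.amount_c for f in coalvi.by_category(FluxCategory.INTERNAL)
        )
        assert internal_total > 0  # the scenario grid must not depend on them
        stripped = dataclasses.replace(coalvi)
        stripped.fluxes = [
            f for f in coalvi.fluxes if f.category is not FluxCategory.INTERNAL
        ]
        full = cl.two_way_sensitivity(coalvi, 10.0, 10.0)
        bare = cl.two_way_sensitivity(stripped, 10.0, 10.0)
        assert full.grid == bare.grid

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_multipliers(self, seed):
        lg = cl.generate_synthetic_ledger(10, seed)
        result = cl.two_way_sensitivity(lg, 20.0, 20.0, grid_points=3)
        by_out = {}
        for (im, om), b in result.grid.items():
            by_out.setdefault(om, []).append((im, b))
        for om, pairs in by_out.items():
            pairs.sort()
            balances = [b for _, b in pairs]
            assert balances == sorted(balances)  # nondecreasing in input multiplier

    @given(st.integers(0, 2**31 - 1))
    def test_matches_per_flux_brute_force_oracle(self, seed):
        """Corner balances equal re-summing each flux with its category multiplier."""
        lg = cl.generate_synthetic_ledger(6, seed)
        din, dout = 10.0, 10.0
        result = cl.two_way_sensitivity(lg, din, dout)
        for (im, om), got in result.grid.items():
            expected = 0.0
            for f in lg.fluxes:
                if f.category is FluxCategory.INPUT:
                    expected += f.amount_c * im
                elif f.category is FluxCategory.OUTPUT:
                    expected -= f.amount_c * om
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-9)

    def test_sensitivity_from_pooled_variation(self, coalvi):
        result = cl.sensitivity_from_variation(coalvi)
        assert result.delta_in_pct == 10.0
        assert result.delta_out_pct == 10.0
        assert result.sign_robust
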