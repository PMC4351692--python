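import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pfmfa.measurements import RateSet
from pfmfa.physiology import (
    biomass_carbon_rate,
    biomass_yield,
    branch_ratios,
    carbon_balance,
    change_map,
    classify_ratio,
    cofactor_balance,
    energy_charge,
    load_default_cofactor_map,
)


def _rates(uptake, biomass, co2=None, alginate=0.0):
    co2 = co2 if co2 is not None else max(uptake - biomass - alginate, 0.0)
    return RateSet(
        (uptake, 0.6), (biomass, 0.13), (max(co2, 1e-9), 0.61), (0.04, 0.001),
        (alginate, 1.0),
    )


class TestRateArithmetic:
    def test_main_wild_type_carbon_balance(self):
        assert carbon_balance(_rates(11.8, 1.4)) == pytest.approx(10.4)

    def test_pre_cle_carbon_balance(self):
        assert carbon_balance(_rates(11.0, 1.4)) == pytest.approx(9.6)

    def test_uptake_equals_biomass_gives_zero(self):
        assert carbon_balance(_rates(1.4, 1.4)) == pytest.approx(0.0)

    def test_negative_balance_rejected(self):
        with pytest.raises(ValueError):
            carbon_balance(_rates(1.0, 1.4))

    def test_wild_type_yield_is_12_percent(self):
        full, rounded = biomass_yield(_rates(11.8, 1.4))
        assert rounded == 12

    def test_mutant_yield_is_19_percent(self):
        full, rounded = biomass_yield(_rates(7.34, 1.4))
        assert rounded == 19

    def test_zero_uptake_zero_biomass_yield(self):
        assert biomass_yield(_rates(0.0, 0.0, co2=1e-9)) == (0.0, 0)

    def test_biomass_carbon_rate_matches_table(self):
        # content chosen so that mu = 0.04 gives the tabulated 1.4;
        # oracle by division: 1.4 / 0.04 = 35
        assert 1.4 / 0.04 == pytest.approx(35.0)
        assert biomass_carbon_rate(0.04, 35.0) == pytest.approx(1.4)
        assert biomass_carbon_rate(0.0, 35.0) == 0.0
        assert biomass_carbon_rate(0.08, 35.0) == pytest.approx(2 * 1.4)

    @given(
        st.floats(0.5, 20.0),
        st.floats(0.0, 0.45),
        st.floats(0.0, 0.3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_carbon_closure_identity(self, uptake, biomass_frac, alginate_frac):
        biomass = uptake * biomass_frac
        alginate = uptake * alginate_frac
        rs = _rates(uptake, biomass, alginate=alginate)
        co2 = carbon_balance(rs)
        y_full, _ = biomass_yield(rs)
        assert y_full / 100.0 * uptake + co2 + alginate == pytest.approx(uptake)


class TestBranchRatios:
    def test_mutant_icit_routes_22_percent_to_glyoxylate(self, mut_ref):
        df = branch_ratios(mut_ref.state, "ICIT")
        glx = df[df.reaction == "icl"].iloc[0]
        assert glx.percent_rounded == 22
        assert glx.flux == pytest.approx(0.33, abs=0.01)

    def test_wild_type_6pgn_split_61_39(self, wt_ref):
        df = branch_ratios(wt_ref.state, "PGN6")
        assert df[df.reaction == "edd"].iloc[0].percent_rounded == 61
        assert df[df.reaction == "gnd"].iloc[0].percent_rounded == 39

    def test_single_efflux_node_is_100_percent(self, wt_ref):
        df = branch_ratios(wt_ref.state, "G6P")
        assert df[df.reaction == "zwf"].iloc[0].percent == pytest.approx(
            100.0 * df[df.reaction == "zwf"].iloc[0].flux / df.attrs["influx"]
        )

    def test_percentages_sum_to_100_at_every_active_node(self, wt_ref, mut_ref):
        for state in (wt_ref.state, mut_ref.state):
            for met in state.model.balanced_ids:
                try:
                    df = branch_ratios(state, met)
                except ValueError:
                    continue  # inactive pool (e.g. GLX in the wild type)
                assert df.percent.sum() == pytest.approx(100.0, abs=1e-6)

    def test_zero_influx_node_rejected(self, wt_ref):
        with pytest.raises(ValueError, match="influx"):
            branch_ratios(wt_ref.state, "GLX")


class TestCofactors:
    def test_all_zero_flux_state_gives_zero_balances(self, model):
        from pfmfa.network import FluxState

        zero = FluxState(model, np.zeros(len(model.reactions)))
        bal = cofactor_balance(zero)
        assert bal == {"ATP": 0.0, "NADH": 0.0, "NADPH": 0.0}

    def test_wild_type_produces_more_nadh_and_nadph(self, wt_ref, mut_ref):
        wt = cofactor_balance(wt_ref.state)
        mut = cofactor_balance(mut_ref.state)
        assert wt["NADH"] > mut["NADH"]
        assert wt["NADPH"] > mut["NADPH"]

    def test_normalised_nadph_similar_between_strains(self, wt_ref, mut_ref):
        wt = cofactor_balance(wt_ref.state, normalise_by_uptake=True)
        mut = cofactor_balance(mut_ref.state, normalise_by_uptake=True)
        assert wt["NADPH"] == pytest.approx(mut["NADPH"], rel=0.15)

    def test_unknown_reaction_in_map_rejected(self, wt_ref):
        with pytest.raises(ValueError, match="unknown reaction"):
            cofactor_balance(wt_ref.state, {"nonexistent": {"ATP": 1.0}})

    def test_default_map_covers_only_model_reactions(self, model):
        cmap = load_default_cofactor_map()
        assert set(cmap) <= set(model.reaction_index)


class TestEnergyCharge:
    def test_pure_atp_is_one(self):
        assert energy_charge(1.7, 0.0, 0.0) == 1.0

    def test_pure_adp_is_half(self):
        assert energy_charge(0.0, 0.3, 0.0) == 0.5

    def test_pure_amp_is_zero(self):
        assert energy_charge(0.0, 0.0, 2.2) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            energy_charge(0.0, 0.0, 0.0)


class TestChangeMap:
    def test_identical_states_all_unchanged(self, wt_ref):
        df = change_map(wt_ref.state, wt_ref.state)
        active = df[df.value_a != 0.0]
        assert (active["class"] == "unchanged").all()

    def test_succinate_pool_increase_2_4_fold_flagged(self, wt_ref, mut_ref):
        df = change_map(wt_ref.state, mut_ref.state, {"succinate": 2.4})
        row = df[df.item == "succinate"].iloc[0]
        assert row["class"] == "increased"

    def test_ratio_exactly_1_5_is_unchanged(self):
        assert classify_ratio(1.5) == "unchanged"
        assert classify_ratio(1.5000001) == "increased"
        assert classify_ratio(0.5) == "unchanged"

    def test_zero_denominator_flagged_not_dropped(self, wt_ref, mut_ref):
        df = change_map(wt_ref.state, mut_ref.state)
        icl = df[df.item == "icl"].iloc[0]
        assert icl["class"] == "undefined"
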