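import numpy as np
import pytest

from pfmfa.labeling import DESIGNED_MIXTURE, simulate_mids
from pfmfa.synth import (
    DEFAULT_PANEL,
    RATE_TABLES,
    generate_cle_dataset,
    panel_emus,
    reference_flux_map,
    scenario_suite,
)


class TestReferenceMaps:
    def test_wild_type_icit_influx_reads_3_10(self, wt_ref):
        assert wt_ref.state.net("cs") == pytest.approx(3.10, abs=0.01)

    def test_mutant_glx_and_icit_anchors(self, mut_ref):
        assert mut_ref.state.net("icl") == pytest.approx(0.33, abs=0.01)
        assert mut_ref.state.net("cs") == pytest.approx(1.51, abs=0.01)

    def test_hallmark_anchors_within_tolerance(self, wt_ref, mut_ref):
        for ref in (wt_ref, mut_ref):
            for rid in ("gnd", "edd", "cs", "icl", "mae"):
                assert ref.state.net(rid) == pytest.approx(
                    ref.anchors[rid], abs=0.01
                ), (ref.strain, rid)

    def test_maps_are_steady_state_with_nonneg_irreversibles(self, wt_ref, mut_ref):
        for ref in (wt_ref, mut_ref):
            ref.state.check(tol=1e-9)

    def test_unknown_strain_rejected(self, model):
        with pytest.raises(ValueError, match="strain"):
            reference_flux_map("petunia", model)


class TestPanel:
    def test_panel_sizes_are_8_and_14(self):
        assert len(DEFAULT_PANEL.lc_compounds) == 8
        assert len(DEFAULT_PANEL.gc_compounds) == 14

    def test_every_compound_maps_to_a_model_pool(self, model):
        for spec in DEFAULT_PANEL.specs("wt"):
            met = model.metabolites[spec.pool]
            assert max(spec.positions) <= met.n_carbons

    def test_condition_rsds_match_study_values(self):
        assert DEFAULT_PANEL.lc_rsd == {"pre": 0.13, "wt": 0.10, "mut": 0.08}
        assert DEFAULT_PANEL.gc_rsd == {"pre": 0.10, "wt": 0.12, "mut": 0.15}
        assert DEFAULT_PANEL.lc_replicates["pre"] == 2


class TestDatasets:
    def test_zero_noise_equals_exact_simulation(self, model, mut_ref):
        ms = generate_cle_dataset("mut", rng_seed=4, noise_scale=0.0, model=model)
        emus = panel_emus(model, ms.specs)
        mids = simulate_mids(model, mut_ref.state, DESIGNED_MIXTURE, emus)
        for i, spec in enumerate(ms.specs):
            assert np.allclose(ms.mean(i), mids[spec.key], atol=1e-12)

    def test_same_seed_is_bit_identical(self, model):
        a = generate_cle_dataset("wt", rng_seed=9, model=model)
        b = generate_cle_dataset("wt", rng_seed=9, model=model)
        for i in a.replicates:
            assert np.array_equal(a.replicates[i], b.replicates[i])
        assert a.rates.uptake_c == b.rates.uptake_c

    def test_default_mixture_is_the_designed_blend(self):
        fracs = {
            tuple(c.labelled_positions): c.fraction for c in DESIGNED_MIXTURE.components
        }
        assert fracs[(1,)] == pytest.approx(0.6008)
        assert fracs[tuple(range(1, 7))] == pytest.approx(0.3992)

    def test_rates_drawn_at_printed_stds(self, model):
        draws = [
            generate_cle_dataset("mut", rng_seed=s, model=model).rates.uptake_c[0]
            for s in range(40)
        ]
        table = RATE_TABLES["mut"].uptake_c
        assert np.mean(draws) == pytest.approx(table[0], abs=3 * table[1] / np.sqrt(40))
        assert np.std(draws) == pytest.approx(table[1], rel=0.5)


class TestScenarioSuite:
    def test_suite_contains_exactly_three_cultivations(self, model):
        suite = scenario_suite(seed=2, model=model)
        assert set(suite) == {"wt", "mut", "pre"}

    def test_pre_cle_mixture_components_sum_to_one(self):
        from pfmfa.labeling import PRE_CLE_MIXTURE

        total = sum(c.fraction for c in PRE_CLE_MIXTURE.components)
        assert total == pytest.approx(1.0, abs=1e-12)
        fracs = sorted(c.fraction for c in PRE_CLE_MIXTURE.components)
        assert fracs == [pytest.approx(0.1965), pytest.approx(0.2031), pytest.approx(0.6004)]

    def test_main_cle_pair_differs_only_in_strain_noise_and_rates(self, model):
        suite = scenario_suite(seed=2, model=model)
        wt, mut = suite["wt"], suite["mut"]
        assert [s.compound for s in wt.specs] == [s.compound for s in mut.specs]
        assert [s.positions for s in wt.specs] == [s.positions for s in mut.specs]
        assert {s.rsd for s in wt.specs} != {s.rsd for s in mut.specs}
        assert wt.rates.uptake_c[0] != mut.rates.uptake_c[0]


class TestNoiseMonotonicity:
    def test_wider_noise_gives_wider_confidence_intervals(self, model):
        """Average linearised CI width over hallmark fluxes grows with the
        generator noise scale."""
        from pfmfa.fit import confidence_intervals, fit_fluxes
        from pfmfa.synth import DEFAULT_MIXTURES

        widths = {}
        for scale in (0.5, 2.0):
            per_seed = []
            for seed in (21, 22, 23):
                ms = generate_cle_dataset(
                    "mut", rng_seed=seed, noise_scale=scale, model=model
                )
                fit = fit_fluxes(
                    model, ms, ms.rates, DEFAULT_MIXTURES["mut"],
                    n_starts=2, rng_seed=seed, exclusion=False,
                )
                ci = confidence_intervals(fit, constrain_exchange="auto")
                tab = ci.table
                rows = tab[(tab.kind == "net") & tab.reaction.isin(
                    ["cs", "gnd", "edd", "mae"]) & tab.identifiable]
                per_seed.append(float((rows.ci_upper - rows.ci_lower).mean()))
            widths[scale] = np.mean(per_seed)
        assert widths[2.0] > widths[0.5]


class TestPanelIO:
    def test_panel_yaml_roundtrip(self):
        from pfmfa.synth import panel_from_yaml, panel_to_yaml

        text = panel_to_yaml(DEFAULT_PANEL)
        back = panel_from_yaml(text)
        assert back == DEFAULT_PANEL

    def test_measurement_table_roundtrip(self, model):
        from pfmfa.measurements import measurement_set_from_frame

        ms = generate_cle_dataset("wt", rng_seed=13, model=model)
        back = measurement_set_from_frame(ms.to_frame(), ms.specs, rates=ms.rates)
        for i in ms.replicates:
            assert np.allclose(back.replicates[i], ms.replicates[i])
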