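import numpy as np
import pytest

from pfmfa.fit import (
    FitProblem,
    confidence_intervals,
    fit_fluxes,
    goodness_of_fit,
    monte_carlo_intervals,
    objective,
)
from pfmfa.network import NetworkError
from pfmfa.synth import DEFAULT_MIXTURES, generate_cle_dataset, reference_flux_map

HALLMARKS = ("upt", "bm", "gnd", "edd", "cs", "mae", "fbp", "pyk", "pdh")


class TestObjective:
    def test_noise_free_data_from_same_vector_is_zero(self, model):
        ms = generate_cle_dataset("mut", rng_seed=1, noise_scale=0.0, model=model)
        pb = FitProblem(model, ms, ms.rates, DEFAULT_MIXTURES["mut"])
        p = pb.params_from_state(reference_flux_map("mut", model).state)
        assert pb.ssr(p) < 1e-10

    def test_one_std_perturbation_raises_ssr_by_one(self, toy_problem):
        tp = toy_problem
        ms = tp.dataset(0, noise_scale=0.0)
        pb = FitProblem(tp.model, ms, None, tp.mixture, basis=tp.basis, free_xch=["bd"])
        p = pb.params_from_state(tp.truth)
        assert pb.ssr(p) < 1e-18
        k = 0  # perturb the first included fraction by exactly one STD
        pb._means = pb._means.copy()
        pb._means[k] += pb._stds[k]
        assert pb.ssr(p) == pytest.approx(1.0, abs=1e-9)

    def test_ssr_matches_hand_summed_residuals(self, toy_problem):
        """Independent spreadsheet-style recomputation on a few residuals."""
        tp = toy_problem
        ms = tp.dataset(3)
        pb = FitProblem(tp.model, ms, None, tp.mixture, basis=tp.basis, free_xch=["bd"])
        p = pb.params_from_state(tp.truth)
        from pfmfa.labeling import simulate_mids

        mids = simulate_mids(tp.model, tp.truth, tp.mixture, tp.emus)
        expected = 0.0
        for i, spec in enumerate(ms.specs):
            sim = mids[spec.key]
            mean = ms.mean(i)
            std = ms.stds(i)
            expected += float(np.sum(((sim - mean) / std) ** 2))
        assert pb.ssr(p) == pytest.approx(expected, rel=1e-12)

    def test_row_order_invariance(self, toy_problem):
        tp = toy_problem
        ms = tp.dataset(5)
        p = np.array([0.25, 0.3])
        v1 = objective(p, tp.model, ms, None, tp.mixture, basis=tp.basis, free_xch=["bd"])
        from pfmfa.measurements import MeasurementSet

        order = [2, 0, 3, 1]
        ms2 = MeasurementSet(
            [ms.specs[i] for i in order],
            {k: ms.replicates[i] for k, i in enumerate(order)},
            strict=False,
        )
        v2 = objective(p, tp.model, ms2, None, tp.mixture, basis=tp.basis, free_xch=["bd"])
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestRecovery:
    def test_noise_free_recovery_is_exact(self, model, noise_free_fits):
        """Fitting noise-free data returns the generating net fluxes to
        1e-3 relative on the identifiable hallmark fluxes, for both strains."""
        for strain in ("wt", "mut"):
            ref = reference_flux_map(strain, model)
            fit = noise_free_fits[strain]
            assert fit.ssr < 1e-6
            for rid in HALLMARKS:
                true = ref.state.net(rid)
                got = fit.state.net(rid)
                assert got == pytest.approx(true, rel=1e-3, abs=1e-4), (strain, rid)

    def test_single_start_from_truth_matches_multistart(self, model, noise_free_fits):
        ms = generate_cle_dataset("mut", rng_seed=11, noise_scale=0.0, model=model)
        fit1 = fit_fluxes(
            model, ms, ms.rates, DEFAULT_MIXTURES["mut"],
            n_starts=1, rng_seed=5, exclusion=False,
        )
        fit_multi = noise_free_fits["mut"]
        assert fit1.ssr < 1e-6
        assert np.allclose(
            fit1.state.v_net, fit_multi.state.v_net, atol=1e-4
        )

    def test_near_optimal_starts_form_one_cluster(self, noise_free_fits):
        """Converged starts within 1% of the best SSR agree in free-flux
        space (unique optimum, no symmetric second basin)."""
        fit = noise_free_fits["wt"]
        best = min(r["ssr"] for r in fit.start_records if r["converged"])
        tol = max(best * 1.01, 1e-4)
        members = [
            r["params"][: fit.problem.n_net]
            for r in fit.start_records
            if r["converged"] and r["ssr"] <= tol
        ]
        assert members
        # compare on the identifiable free fluxes; the F1P-aldolase routing
        # is a documented sloppy direction of the labelling system
        free_ids = fit.problem.basis.free_ids
        idx = [i for i, rid in enumerate(free_ids) if rid != "f1pa"]
        scale = np.maximum(np.abs(fit.free_vector), 0.1)
        for p in members:
            dev = np.abs(p - fit.free_vector) / scale
            assert np.max(dev[idx]) < 1e-2

    def test_under_determined_fit_rejected(self, toy_problem):
        tp = toy_problem
        ms = tp.dataset(0)
        for i in list(ms.included):
            ms.included[i][:] = False
        ms.included[0][0] = True
        with pytest.raises(NetworkError, match="under-determined"):
            fit_fluxes(tp.model, ms, None, tp.mixture, n_starts=1,
                       basis=tp.basis, free_xch=["bd"])


class TestStatistics:
    def test_goodness_of_fit_noise_free_is_acceptable_low(self, noise_free_fits):
        g = goodness_of_fit(noise_free_fits["mut"])
        assert g["chi2"] < 1e-6
        assert g["verdict"] == "acceptable-low"

    def test_dof_error_when_overparametrised(self, noise_free_fits):
        fit = noise_free_fits["mut"]
        mask_backup = {i: m.copy() for i, m in fit.problem.measurements.included.items()}
        try:
            for i in fit.problem.measurements.included:
                fit.problem.measurements.included[i][:] = False
            fit.problem.measurements.included[0][:3] = True
            fit.problem._refresh_data()
            with pytest.raises(NetworkError, match="degrees of freedom"):
                goodness_of_fit(fit)
        finally:
            for i, m in mask_backup.items():
                fit.problem.measurements.included[i] = m
            fit.problem._refresh_data()

    def test_infinite_stds_cover_the_feasible_box(self, toy_problem):
        """With measurement STDs blown up the interval spans the whole
        feasible range of the split flux."""
        import dataclasses

        from pfmfa.measurements import MeasurementSet

        tp = toy_problem
        ms = tp.dataset(2)
        wide_specs = [dataclasses.replace(s, rsd=1e6) for s in ms.specs]
        ms = MeasurementSet(wide_specs, ms.replicates, strict=False)
        fit = fit_fluxes(tp.model, ms, None, tp.mixture, n_starts=1, rng_seed=0,
                         exclusion=False, basis=tp.basis, free_xch=["bd"])
        ci = confidence_intervals(fit, constrain_exchange=[])
        row = ci.table[(ci.table.reaction == "ab") & (ci.table.kind == "net")].iloc[0]
        assert (not row.identifiable) or row.sigma > 10.0

    def test_linearised_vs_monte_carlo_interval_widths(self, toy_problem):
        tp = toy_problem
        fit = tp.fit(1)
        ci = confidence_intervals(fit, constrain_exchange=[])
        row = ci.table[(ci.table.reaction == "ab") & (ci.table.kind == "net")].iloc[0]
        mc = monte_carlo_intervals(fit, n_resamples=200, rng_seed=3)
        sigma_mc = float(mc[mc.reaction == "ab"].sigma.iloc[0])
        assert row.sigma == pytest.approx(sigma_mc, rel=0.2)

    def test_constraining_exchange_never_decreases_ssr(self, toy_problem):
        tp = toy_problem
        fit = tp.fit(4)
        pb = fit.problem
        p = fit.params.copy()
        base = pb.ssr(p)
        for forced in (0.0, 0.5, 0.9):
            p2 = p.copy()
            p2[pb.n_net] = forced
            assert pb.ssr(p2) >= base - 1e-9
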