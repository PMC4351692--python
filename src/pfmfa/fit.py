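"""Weighted least-squares flux estimation with multistart globalisation.

Free fluxes (a stoichiometric basis of net fluxes plus bounded exchange
parameters) are estimated by minimising

    SSR = sum_f ((sim_f - meas_f) / STD_f)^2  +  sum_r ((sim_r - meas_r) / STD_r)^2

over included mass-isotopomer fractions f and extracellular rates r.  The
globalised strategy is multistart: bounded trust-region least squares from
``n_starts`` seeded random starting points (plus one rate-consistent
heuristic start), followed by a high-precision polish of the best basins
and a single measurement-exclusion pass with re-fit.  All final SSRs are
recorded to expose multimodality.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .labeling import LabelMixture, emu_decompose
from .measurements import MeasurementSet, RateSet, exclude_discrepant
from .network import (
    FluxState,
    NetworkModel,
    NetworkError,
    FreeFluxBasis,
    free_flux_basis,
    xch_flux_to_param,
    xch_param_to_flux,
)

PENALTY_WEIGHT = 1e3  # per-unit penalty residual on negative irreversible fluxes


class FitProblem:
    """Precompiled objective for one model + dataset + mixture."""

    def __init__(
        self,
        model: NetworkModel,
        measurement_set: MeasurementSet,
        rate_constraints: RateSet | None,
        mixture: LabelMixture,
        basis: FreeFluxBasis | None = None,
        free_xch: Sequence[str] | None = None,
    ) -> None:
        self.model = model
        self.measurements = measurement_set
        self.rates = rate_constraints
        self.mixture = mixture
        self.basis = basis or free_flux_basis(model)
        if free_xch is None:
            free_xch = model.manifest.get("free_exchange", [])
        self.free_xch = [r for r in free_xch if model.reactions[model.reaction_index[r]].reversible]
        self.n_net = self.basis.dim
        self.n_xch = len(self.free_xch)
        self.n_params = self.n_net + self.n_xch
        self.emus = [spec.emu(model) for spec in measurement_set.specs]
        self.system = emu_decompose(model, self.emus)
        self._E, self._e0 = self.basis.embedding
        # irreversible dependent rows needing a non-negativity penalty
        self.penalty_rows = np.array(
            [
                i
                for i in range(len(model.reactions))
                if not model.reactions[i].reversible
                and model.reactions[i].id not in self.basis.free_ids
            ],
            dtype=int,
        )
        self._xch_idx = np.array(
            [model.reaction_index[r] for r in self.free_xch], dtype=int
        )
        self._refresh_data()
        man = model.manifest
        self._sub_carbons = model.metabolites[model.substrate_id].n_carbons
        self._bm_carbon = man.get("biomass_carbon_mmolC_per_gDW", 0.0)
        if rate_constraints is not None:
            self._upt_i = model.reaction_index[man["uptake_reaction"]]
            self._bm_i = model.reaction_index[man["biomass_reaction"]]
            self._co2_i = model.reaction_index[man["co2_reaction"]]

    def _refresh_data(self) -> None:
        self._means, self._stds, self._index = self.measurements.flat()

    @property
    def n_residuals(self) -> int:
        n = len(self._means)
        if self.rates is not None:
            n += 4
        return n

    def flux_state(self, params: np.ndarray, check: bool = False) -> FluxState:
        params = np.asarray(params, dtype=float)
        v_net = self._E @ params[: self.n_net] + self._e0
        v_xch = np.zeros(len(self.model.reactions))
        if self.n_xch:
            v_xch[self._xch_idx] = xch_param_to_flux(params[self.n_net :])
        return FluxState(self.model, v_net, v_xch, check=check)

    def simulated_fractions(self, params: np.ndarray) -> np.ndarray:
        state = self.flux_state(params)
        solved = self.system.simulate(state, self.mixture)
        out = np.empty(len(self._index))
        for k, (i, m) in enumerate(self._index):
            out[k] = solved[self.measurements.specs[i].key][m]
        return out

    def residuals(self, params: np.ndarray) -> np.ndarray:
        state = self.flux_state(params)
        try:
            solved = self.system.simulate(state, self.mixture)
        except NetworkError as err:
            raise NetworkError(
                f"simulation failed at params {np.round(params, 4)}: {err}"
            ) from err
        res = np.empty(self.n_residuals + len(self.penalty_rows))
        k = 0
        for i, m in self._index:
            key = self.measurements.specs[i].key
            res[k] = (solved[key][m] - self._means[k]) / self._stds[k]
            k += 1
        if self.rates is not None:
            r = self.rates
            res[k] = (state.v_net[self._upt_i] * self._sub_carbons - r.uptake_c[0]) / r.uptake_c[1]
            res[k + 1] = (state.v_net[self._bm_i] * self._bm_carbon - r.biomass_c[0]) / r.biomass_c[1]
            res[k + 2] = (state.v_net[self._co2_i] - r.co2[0]) / r.co2[1]
            res[k + 3] = (state.v_net[self._bm_i] - r.growth_rate[0]) / r.growth_rate[1]
            k += 4
        res[k:] = PENALTY_WEIGHT * np.minimum(state.v_net[self.penalty_rows], 0.0)
        return res

    def ssr(self, params: np.ndarray) -> float:
        return float(np.sum(self.residuals(params) ** 2))

    # -- parameter box -----------------------------------------------------
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        u_hex = (
            self.rates.uptake_c[0] / self._sub_carbons
            if self.rates is not None
            else max(abs(self._e0).max(), 1.0)
        )
        hi = 2.5 * u_hex
        lo = np.empty(self.n_params)
        up = np.empty(self.n_params)
        for k, rid in enumerate(self.basis.free_ids):
            i = self.model.reaction_index[rid]
            rev = self.model.reactions[i].reversible
            if rid == self.model.manifest.get("biomass_reaction"):
                lo[k], up[k] = 0.0, 0.12
            elif rid == self.model.manifest.get("uptake_reaction"):
                lo[k], up[k] = 0.0, 1.5 * u_hex
            else:
                lo[k], up[k] = (-hi if rev else 0.0), hi
        lo[self.n_net :] = 0.0
        up[self.n_net :] = 0.99
        return lo, up

    def x_scale(self) -> np.ndarray:
        lo, up = self.bounds()
        scale = np.maximum((up - lo) / 4.0, 1e-3)
        return scale

    def heuristic_start(self) -> np.ndarray:
        u_hex = (
            self.rates.uptake_c[0] / self._sub_carbons if self.rates is not None else 1.0
        )
        mu = self.rates.growth_rate[0] if self.rates is not None else 0.04
        p = np.empty(self.n_params)
        for k, rid in enumerate(self.basis.free_ids):
            if rid == self.model.manifest.get("biomass_reaction"):
                p[k] = mu
            elif rid == self.model.manifest.get("uptake_reaction"):
                p[k] = u_hex
            else:
                p[k] = 0.25 * u_hex
        p[self.n_net :] = 0.3
        return p

    def params_from_state(self, state: FluxState) -> np.ndarray:
        p = np.empty(self.n_params)
        p[: self.n_net] = self.basis.extract(state.v_net)
        if self.n_xch:
            p[self.n_net :] = xch_flux_to_param(state.v_xch[self._xch_idx])
        return p


@dataclass
class FitResult:
    problem: FitProblem
    params: np.ndarray
    ssr: float
    start_records: list[dict] = field(default_factory=list)
    excluded: list[dict] = field(default_factory=list)

    @property
    def state(self) -> FluxState:
        return self.problem.flux_state(self.params, check=False)

    @property
    def free_vector(self) -> np.ndarray:
        return self.params[: self.problem.n_net]

    @property
    def dof(self) -> int:
        return self.problem.n_residuals - self.problem.n_params

    @property
    def chi2(self) -> float:
        return self.ssr


def objective(
    free_vector: Sequence[float],
    model: NetworkModel,
    measurement_set: MeasurementSet,
    rate_constraints: RateSet | None,
    mixture: LabelMixture,
    **kwargs,
) -> float:
    """Weighted SSR of a free-parameter vector (net frees + exchange params)."""
    problem = FitProblem(model, measurement_set, rate_constraints, mixture, **kwargs)
    params = np.asarray(free_vector, dtype=float)
    res = problem.residuals(params)
    return float(np.sum(res[: problem.n_residuals] ** 2))


def _local_fit(problem, x0, lo, up, scale, max_nfev, tight=False):
    x0 = np.clip(x0, lo + 1e-12, up - 1e-12)
    tol = 1e-12 if tight else 1e-9
    return optimize.least_squares(
        problem.residuals,
        x0,
        bounds=(lo, up),
        method="trf",
        x_scale=scale,
        ftol=tol,
        xtol=tol,
        gtol=None,
        max_nfev=max_nfev,
    )


def fit_fluxes(
    model: NetworkModel,
    measurement_set: MeasurementSet,
    rate_constraints: RateSet | None,
    mixture: LabelMixture,
    n_starts: int = 100,
    rng_seed: int = 0,
    exclusion: bool = True,
    n_polish: int = 3,
    coarse_max_nfev: int = 40,
    polish_max_nfev: int = 400,
    basis: FreeFluxBasis | None = None,
    free_xch: Sequence[str] | None = None,
) -> FitResult:
    """Multistart bounded weighted least squares.

    Start 1 is a rate-consistent heuristic; the remaining ``n_starts - 1``
    are drawn uniformly in the parameter box from ``rng_seed``.  Each start
    runs a coarse bounded least-squares pass; the ``n_polish`` best basins
    are then polished to tight tolerance.  After the best fit, the
    low-abundance/large-discrepancy exclusion rule is applied once and the
    fit repeated on the reduced dataset.  Reproducible bit-identically for
    a given (seed, n_starts).
    """
    problem = FitProblem(
        model, measurement_set, rate_constraints, mixture, basis=basis, free_xch=free_xch
    )
    if problem.n_params >= problem.n_residuals:
        raise NetworkError(
            f"under-determined fit: {problem.n_params} parameters, "
            f"{problem.n_residuals} residuals"
        )
    lo, up = problem.bounds()
    scale = problem.x_scale()
    rng = np.random.default_rng(rng_seed)
    starts = [problem.heuristic_start()]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(lo + (up - lo) * rng.uniform(size=problem.n_params))

    records: list[dict] = []
    solutions: list[tuple[float, np.ndarray]] = []
    for s_idx, x0 in enumerate(starts):
        try:
            sol = _local_fit(problem, x0, lo, up, scale, coarse_max_nfev)
            ssr = float(2.0 * sol.cost)
            solutions.append((ssr, sol.x))
            records.append(
                {"start": s_idx, "ssr": ssr, "params": sol.x.copy(), "converged": True}
            )
        except NetworkError:
            records.append({"start": s_idx, "ssr": np.inf, "converged": False})
    if not solutions:
        raise NetworkError("no start converged")
    solutions.sort(key=lambda t: t[0])
    best_ssr, best_x = solutions[0]
    for ssr, x in solutions[: max(n_polish, 1)]:
        sol = _local_fit(problem, x, lo, up, scale, polish_max_nfev, tight=True)
        ssr_p = float(2.0 * sol.cost)
        if ssr_p < best_ssr:
            best_ssr, best_x = ssr_p, sol.x
    excluded: list[dict] = []
    if exclusion:
        solved = problem.system.simulate(problem.flux_state(best_x), mixture)
        sim = {spec.key: solved[spec.key] for spec in measurement_set.specs}
        before = measurement_set.n_included()
        exclude_discrepant(measurement_set, sim)
        excluded = list(measurement_set.exclusion_log)
        if measurement_set.n_included() != before:
            problem._refresh_data()
            sol = _local_fit(problem, best_x, lo, up, scale, polish_max_nfev, tight=True)
            best_ssr, best_x = float(2.0 * sol.cost), sol.x
    # report SSR without the (inactive at optimum) bound penalties
    res = problem.residuals(best_x)
    best_ssr = float(np.sum(res[: problem.n_residuals] ** 2))
    return FitResult(problem, best_x, best_ssr, records, excluded)


# ---------------------------------------------------------------------------
# statistics


def goodness_of_fit(fit: FitResult) -> dict:
    """Chi-square assessment: SSR against the chi2(dof) central 95% band."""
    dof = fit.dof
    if dof <= 0:
        raise NetworkError(f"non-positive degrees of freedom ({dof})")
    lo, hi = stats.chi2.ppf([0.025, 0.975], dof)
    chi2 = fit.chi2
    if chi2 < lo:
        verdict = "acceptable-low"
    elif chi2 <= hi:
        verdict = "acceptable"
    else:
        verdict = "poor"
    return {"chi2": chi2, "dof": dof, "band95": (float(lo), float(hi)), "verdict": verdict}


def _whitened_jacobian(fit: FitResult, param_idx: np.ndarray, step: float = 1e-6) -> np.ndarray:
    problem = fit.problem
    base = fit.params.copy()
    r0 = problem.residuals(base)[: problem.n_residuals]
    lo, up = problem.bounds()
    J = np.zeros((len(r0), len(param_idx)))
    for col, k in enumerate(param_idx):
        h = step * max(abs(base[k]), problem.x_scale()[k])
        x = base.copy()
        if base[k] + h > up[k]:
            h = -h
        x[k] = base[k] + h
        J[:, col] = (problem.residuals(x)[: problem.n_residuals] - r0) / h
    return J


@dataclass
class ConfidenceIntervals:
    table: "object"  # pandas DataFrame
    cov_params: np.ndarray
    free_param_ids: list[str]
    constrained_xch: list[str]
    non_identifiable: list[str]


def confidence_intervals(
    fit: FitResult,
    constrain_exchange: Sequence[str] | str = "auto",
    level: float = 0.95,
    eig_cutoff: float = 1e-10,
) -> ConfidenceIntervals:
    """Linearised confidence intervals for every net and exchange flux.

    The covariance of the free parameters is the pseudo-inverse of the
    whitened normal matrix J'J; directions below the relative eigenvalue
    cutoff are flagged non-identifiable (unbounded intervals, never
    fabricated numbers).  For statistical assessment a configurable set of
    exchange fluxes is constrained at its point estimate ("auto": the upper
    half by exchange-flux magnitude), mirroring standard practice when
    exchange directions are weakly informed.  Intervals are truncated at
    feasibility bounds, producing asymmetric intervals such as [0, u] for a
    flux estimated at an active bound.
    """
    import pandas as pd

    problem = fit.problem
    model = problem.model
    n_net, n_xch = problem.n_net, problem.n_xch
    xch_vals = xch_param_to_flux(fit.params[n_net:]) if n_xch else np.array([])
    if constrain_exchange == "auto":
        order = np.argsort(xch_vals)[::-1]
        constrained = [problem.free_xch[i] for i in order[: n_xch // 2]]
    else:
        constrained = list(constrain_exchange)
    free_idx = np.array(
        [k for k in range(problem.n_params)
         if k < n_net or problem.free_xch[k - n_net] not in constrained],
        dtype=int,
    )
    J = _whitened_jacobian(fit, free_idx)
    JTJ = J.T @ J
    w, V = np.linalg.eigh(JTJ)
    wmax = float(w.max()) if len(w) else 1.0
    identifiable = w > eig_cutoff * wmax
    inv_w = np.where(identifiable, 1.0 / np.where(identifiable, w, 1.0), 0.0)
    cov = (V * inv_w) @ V.T
    param_ids = [
        problem.basis.free_ids[k] if k < n_net else f"xch:{problem.free_xch[k - n_net]}"
        for k in free_idx
    ]
    non_ident_dirs = V[:, ~identifiable]
    non_identifiable = []
    if non_ident_dirs.size:
        loading = np.abs(non_ident_dirs).max(axis=1)
        non_identifiable = [
            param_ids[i] for i in range(len(param_ids)) if loading[i] > 0.5
        ]
    z = stats.norm.ppf(0.5 + level / 2.0)
    # propagate to net fluxes: v_net = E @ p_net + e0 is linear
    E, _ = problem.basis.embedding
    net_cols = [i for i, k in enumerate(free_idx) if k < n_net]
    E_sub = E[:, [free_idx[i] for i in net_cols]]
    var_net = np.einsum("ij,jk,ik->i", E_sub, cov[np.ix_(net_cols, net_cols)], E_sub)
    var_net = np.maximum(var_net, 0.0)
    state = fit.state
    rows = []
    for i, rxn in enumerate(model.reactions):
        est = state.v_net[i]
        sigma = float(np.sqrt(var_net[i]))
        unbounded = any(
            (param_ids[net_cols[j]] in non_identifiable) and abs(E_sub[i, j]) > 1e-9
            for j in range(len(net_cols))
        )
        if unbounded:
            lo_ci, hi_ci = -np.inf, np.inf
        else:
            lo_ci, hi_ci = est - z * sigma, est + z * sigma
        if not rxn.reversible:
            lo_ci = max(lo_ci, 0.0)
        rows.append(
            {
                "reaction": rxn.id,
                "kind": "net",
                "estimate": est,
                "sigma": sigma if not unbounded else np.inf,
                "ci_lower": lo_ci,
                "ci_upper": hi_ci,
                "identifiable": not unbounded,
            }
        )
    for j, rid in enumerate(problem.free_xch):
        est = float(xch_vals[j])
        pid = f"xch:{rid}"
        if rid in constrained:
            rows.append(
                {"reaction": rid, "kind": "xch", "estimate": est, "sigma": 0.0,
                 "ci_lower": est, "ci_upper": est, "identifiable": True}
            )
            continue
        col = param_ids.index(pid)
        x = fit.params[n_net + j]
        dvdx = 1.0 / (1.0 - x) ** 2  # derivative of the exchange transform
        sigma = float(np.sqrt(max(cov[col, col], 0.0))) * dvdx
        if pid in non_identifiable:
            lo_ci, hi_ci, sigma = 0.0, np.inf, np.inf
        else:
            lo_ci, hi_ci = max(est - z * sigma, 0.0), est + z * sigma
        rows.append(
            {"reaction": rid, "kind": "xch", "estimate": est, "sigma": sigma,
             "ci_lower": lo_ci, "ci_upper": hi_ci, "identifiable": pid not in non_identifiable}
        )
    table = pd.DataFrame(rows)
    return ConfidenceIntervals(table, cov, param_ids, constrained, non_identifiable)


def monte_carlo_intervals(
    fit: FitResult,
    n_resamples: int = 200,
    rng_seed: int = 0,
    n_starts: int = 1,
    level: float = 0.95,
):
    """Monte-Carlo flux intervals by refitting on parametrically resampled data.

    Resamples the included fractions (and rates) around the best-fit
    simulation at the measurement STDs, refits from the best-fit parameters,
    and returns per-reaction net-flux standard deviations and percentile
    intervals.
    """
    import pandas as pd

    problem = fit.problem
    rng = np.random.default_rng(rng_seed)
    sim0 = problem.simulated_fractions(fit.params)
    stds = problem._stds
    lo, up = problem.bounds()
    scale = problem.x_scale()
    base_means = problem._means.copy()
    rates0 = problem.rates
    state0 = fit.state
    draws = []
    try:
        for _ in range(n_resamples):
            problem._means = sim0 + stds * rng.standard_normal(len(sim0))
            if rates0 is not None:
                problem.rates = RateSet(
                    (state0.v_net[problem._upt_i] * problem._sub_carbons
                     + rates0.uptake_c[1] * rng.standard_normal(), rates0.uptake_c[1]),
                    (state0.v_net[problem._bm_i] * problem._bm_carbon
                     + rates0.biomass_c[1] * rng.standard_normal(), rates0.biomass_c[1]),
                    (state0.v_net[problem._co2_i]
                     + rates0.co2[1] * rng.standard_normal(), rates0.co2[1]),
                    (state0.v_net[problem._bm_i]
                     + rates0.growth_rate[1] * rng.standard_normal(), rates0.growth_rate[1]),
                )
            sol = _local_fit(problem, fit.params, lo, up, scale, 4000, tight=True)
            draws.append(problem.flux_state(sol.x).v_net)
    finally:
        problem._means = base_means
        problem.rates = rates0
    draws = np.array(draws)
    alpha = (1.0 - level) / 2.0
    qlo, qhi = np.quantile(draws, [alpha, 1.0 - alpha], axis=0)
    return pd.DataFrame(
        {
            "reaction": [r.id for r in problem.model.reactions],
            "estimate": state0.v_net,
            "sigma": draws.std(axis=0, ddof=1),
            "ci_lower": qlo,
            "ci_upper": qhi,
        }
    )
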