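"""Optimal experimental design of the substrate label mixture.

Ranks candidate tracer mixtures by the Fisher information they yield about
the free fluxes at a reference flux distribution: J' Sigma^-1 J, where J is
the sensitivity of the simulated measurements (and rates) to the free
parameters and Sigma the measurement covariance at the stated RSDs.  The
default criterion is D-optimality on the identifiable subspace; A-optimality
(trace of the covariance) is available.  Local design only: no robust or
minimax design over flux uncertainty.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .fit import FitProblem
from .labeling import LabelMixture, MixtureComponent
from .measurements import MeasurementSet, MeasurementSpec, RateSet, simulate_measurements
from .network import FluxState, NetworkModel


def _problem_at_reference(
    model: NetworkModel,
    reference: FluxState,
    mixture: LabelMixture,
    specs: Sequence[MeasurementSpec],
    rates: RateSet | None,
) -> tuple[FitProblem, np.ndarray]:
    from .labeling import simulate_mids

    emus = [spec.emu(model) for spec in specs]
    true_mids = simulate_mids(model, reference, mixture, emus)
    ms = simulate_measurements(true_mids, specs, rng_seed=0, noise_scale=0.0)
    ms.rates = rates
    problem = FitProblem(model, ms, rates, mixture)
    params = problem.params_from_state(reference)
    return problem, params


def information_matrix(
    model: NetworkModel,
    reference_flux_state: FluxState,
    mixture: LabelMixture,
    specs: Sequence[MeasurementSpec],
    rate_constraints: RateSet | None = None,
    step: float = 1e-6,
    central: bool = False,
) -> np.ndarray:
    """Fisher information J' Sigma^-1 J over the free parameters.

    J is computed by finite differences of the whitened residual vector
    (measurement STDs at the panel RSDs with the 1% floor), forward by
    default, central when ``central`` is set.
    """
    problem, params = _problem_at_reference(
        model, reference_flux_state, mixture, specs, rate_constraints
    )
    n_res = problem.n_residuals
    r0 = problem.residuals(params)[:n_res]
    scales = problem.x_scale()
    J = np.zeros((n_res, problem.n_params))
    for k in range(problem.n_params):
        h = step * max(abs(params[k]), scales[k])
        xp = params.copy()
        xp[k] += h
        rp = problem.residuals(xp)[:n_res]
        if central:
            xm = params.copy()
            xm[k] -= h
            rm = problem.residuals(xm)[:n_res]
            J[:, k] = (rp - rm) / (2 * h)
        else:
            J[:, k] = (rp - r0) / h
    return J.T @ J


def d_criterion(info: np.ndarray, eig_cutoff: float = 1e-10) -> float:
    """Log-determinant of the information matrix on its identifiable subspace."""
    w = np.linalg.eigvalsh(info)
    wmax = float(w.max()) if len(w) else 0.0
    if wmax <= 0:
        return -np.inf
    keep = w > eig_cutoff * wmax
    return float(np.sum(np.log(w[keep])))


def a_criterion(info: np.ndarray, eig_cutoff: float = 1e-10) -> float:
    """Negative trace of the covariance on the identifiable subspace (larger = better)."""
    w = np.linalg.eigvalsh(info)
    wmax = float(w.max()) if len(w) else 0.0
    if wmax <= 0:
        return -np.inf
    keep = w > eig_cutoff * wmax
    return -float(np.sum(1.0 / w[keep]))


_CRITERIA = {"D": d_criterion, "A": a_criterion}

#: the three candidate fructose components for mixture design
COMPONENT_PATTERNS = {
    "1-13C": ((1,), 0.99),
    "U-13C": (tuple(range(1, 7)), 0.995),
    "12C": ((), 1.0),
}


def mixture_from_fractions(fractions: dict[str, float]) -> LabelMixture:
    comps = tuple(
        MixtureComponent(frac, *COMPONENT_PATTERNS[name])
        for name, frac in fractions.items()
        if frac > 0
    )
    return LabelMixture(6, comps)


@dataclass
class DesignResult:
    best_mixture: dict[str, float]
    best_criterion: float
    criterion: str
    landscape: pd.DataFrame
    information: np.ndarray


def design_mixture(
    model: NetworkModel,
    reference_flux_state: FluxState,
    component_set: Sequence[str] = ("1-13C", "U-13C"),
    criterion: str = "D",
    grid_step: float = 0.02,
    specs: Sequence[MeasurementSpec] | None = None,
    rate_constraints: RateSet | None = None,
) -> DesignResult:
    """Criterion-optimal tracer mixture over a simplex grid.

    Evaluates the information criterion for every grid composition of the
    candidate components and returns the best one with the full landscape.
    Ties break deterministically toward the lexicographically first grid
    point.  A single-component set yields a flat landscape (warned in the
    result's landscape, trivially 'optimal').
    """
    for name in component_set:
        if name not in COMPONENT_PATTERNS:
            raise ValueError(f"unknown mixture component {name!r}")
    if specs is None:
        from .synth import DEFAULT_PANEL

        specs = DEFAULT_PANEL.specs("wt")
    crit_fn = _CRITERIA[criterion]
    n = len(component_set)
    steps = int(round(1.0 / grid_step))
    rows = []
    best = None
    for counts in product(range(steps + 1), repeat=n - 1):
        if sum(counts) > steps:
            continue
        fracs = list(counts) + [steps - sum(counts)]
        composition = {
            name: c / steps for name, c in zip(component_set, fracs)
        }
        mixture = mixture_from_fractions(composition)
        info = information_matrix(
            model, reference_flux_state, mixture, specs, rate_constraints
        )
        value = crit_fn(info)
        rows.append({**composition, "criterion": value})
        if best is None or value > best[0] + 1e-12:
            best = (value, composition, info)
    landscape = pd.DataFrame(rows)
    return DesignResult(best[1], best[0], criterion, landscape, best[2])
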