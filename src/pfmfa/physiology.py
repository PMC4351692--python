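"""Rate bookkeeping and derived physiology.

Carbon balance, biomass yield, branch-point flux partitioning, cofactor
(ATP/NADH/NADPH) balances, adenylate energy charge and strain-vs-strain
change maps.  All ratio computations keep full precision internally and
round only for reporting.
"""
from __future__ import annotations

from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .measurements import RateSet
from .network import FluxState, NetworkModel


# ---------------------------------------------------------------------------
# rate arithmetic


def carbon_balance(rate_set: RateSet) -> float:
    """CO2 excretion as the difference between fructose uptake and biomass
    (and alginate) production, all in carbon-mole units."""
    co2 = rate_set.uptake_c[0] - rate_set.biomass_c[0] - rate_set.alginate_c[0]
    if co2 < 0:
        raise ValueError(
            f"negative carbon balance: uptake {rate_set.uptake_c[0]} < "
            f"biomass + alginate"
        )
    return co2


def biomass_yield(rate_set: RateSet) -> tuple[float, int]:
    """Biomass yield on carbon source Y_X/S in percent (full precision, rounded)."""
    uptake = rate_set.uptake_c[0]
    if uptake == 0:
        if rate_set.biomass_c[0] == 0:
            return 0.0, 0
        raise ValueError("zero uptake with non-zero biomass production")
    y = 100.0 * rate_set.biomass_c[0] / uptake
    return y, int(round(y))


def biomass_carbon_rate(growth_rate: float, biomass_carbon_content: float = 35.0) -> float:
    """Specific biomass carbon production mu * content, mmolC/(gDW h)."""
    if growth_rate < 0 or biomass_carbon_content < 0:
        raise ValueError("negative growth rate or carbon content")
    return growth_rate * biomass_carbon_content


# ---------------------------------------------------------------------------
# branch points


def branch_ratios(flux_state: FluxState, node_metabolite: str) -> pd.DataFrame:
    """Effluxes at a branch-point pool as percentages of its total influx.

    Net fluxes only: a reversible reaction counts on the side its net value
    flows.  The biomass drain appears as an efflux named by the drain
    reaction.  Percentages sum to 100 at any steady-state node.
    """
    model = flux_state.model
    if node_metabolite not in model.metabolites:
        raise ValueError(f"unknown metabolite {node_metabolite!r}")
    influx = 0.0
    effluxes: list[tuple[str, float]] = []
    for i, rxn in enumerate(model.reactions):
        v = flux_state.v_net[i]
        coef = 0.0
        for c, met in rxn.educts:
            if met == node_metabolite:
                coef -= c
        for c, met in rxn.products:
            if met == node_metabolite:
                coef += c
        if coef == 0.0:
            continue
        rate = coef * v  # positive = production of the node
        if rate > 0:
            influx += rate
        elif rate < 0:
            effluxes.append((rxn.id, -rate))
    if influx <= 0:
        raise ValueError(f"node {node_metabolite} has no positive influx")
    rows = [
        {
            "reaction": rid,
            "flux": flux,
            "percent": 100.0 * flux / influx,
            "percent_rounded": int(round(100.0 * flux / influx)),
        }
        for rid, flux in effluxes
    ]
    df = pd.DataFrame(rows)
    df.attrs["influx"] = influx
    df.attrs["node"] = node_metabolite
    return df


# ---------------------------------------------------------------------------
# cofactor balances


CofactorMap = dict[str, dict[str, float]]


def load_default_cofactor_map() -> CofactorMap:
    """Packaged ATP/NADH/NADPH stoichiometries per reaction.

    Textbook assignments for the packaged network; isocitrate dehydrogenase
    is NADPH-dependent, the pyruvate shunt generates NADPH (malic enzyme)
    and consumes ATP (pyruvate carboxylase).  Oxidative phosphorylation is
    outside the fitted network, so the ATP row is substrate-level only.
    Editable: the YAML file can be copied and adapted.
    """
    text = resources.files("pfmfa.data").joinpath("cofactor_map.yaml").read_text()
    raw = yaml.safe_load(text)
    return {rid: {k: float(v) for k, v in d.items()} for rid, d in raw.items()}


def cofactor_balance(
    flux_state: FluxState,
    cofactor_map: CofactorMap | None = None,
    normalise_by_uptake: bool = False,
) -> dict[str, float]:
    """Net ATP, NADH and NADPH production rates of the flux map.

    Signed sums of v_net times the per-reaction cofactor stoichiometry;
    with ``normalise_by_uptake`` the rates are divided by the carbon uptake
    rate (mmol cofactor per mmolC substrate).
    """
    model = flux_state.model
    cmap = cofactor_map if cofactor_map is not None else load_default_cofactor_map()
    for rid in cmap:
        if rid not in model.reaction_index:
            raise ValueError(f"cofactor map references unknown reaction {rid!r}")
    totals = {"ATP": 0.0, "NADH": 0.0, "NADPH": 0.0}
    for rid, stoich in cmap.items():
        v = flux_state.net(rid)
        for cof, coeff in stoich.items():
            totals[cof] += coeff * v
    if normalise_by_uptake:
        upt_id = model.manifest.get("uptake_reaction", "upt")
        uptake_c = flux_state.net(upt_id) * model.metabolites[model.substrate_id].n_carbons
        if uptake_c <= 0:
            raise ValueError("cannot normalise: zero uptake")
        totals = {k: v / uptake_c for k, v in totals.items()}
    return totals


# ---------------------------------------------------------------------------
# energy charge and change maps


def energy_charge(atp: float, adp: float, amp: float) -> float:
    """Adenylate energy charge (ATP + ADP/2) / (ATP + ADP + AMP)."""
    if atp < 0 or adp < 0 or amp < 0:
        raise ValueError("negative concentration")
    total = atp + adp + amp
    if total == 0:
        raise ValueError("all adenylate concentrations zero")
    return (atp + 0.5 * adp) / total


def classify_ratio(ratio: float, up: float = 1.5, down: float = 0.5) -> str:
    """Fold-change class: increased (> 150%), decreased (< 50%), else unchanged."""
    if np.isnan(ratio):
        return "undefined"
    if ratio > up:
        return "increased"
    if ratio < down:
        return "decreased"
    return "unchanged"


def change_map(
    flux_state_a: FluxState,
    flux_state_b: FluxState,
    metabolite_fold_changes: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Classified comparison of two flux maps (and optional pool changes).

    Per reaction the ratio b/a of net fluxes is classified as increased
    (> 1.5, strict), decreased (< 0.5) or unchanged; zero denominators are
    flagged ``undefined`` rather than dropped.  Provided metabolite
    fold-changes are classified with the same thresholds.
    """
    if flux_state_a.model is not flux_state_b.model:
        raise ValueError("flux states must share one model")
    rows = []
    for i, rxn in enumerate(flux_state_a.model.reactions):
        a = flux_state_a.v_net[i]
        b = flux_state_b.v_net[i]
        ratio = b / a if a != 0 else np.nan
        rows.append(
            {
                "item": rxn.id,
                "kind": "flux",
                "value_a": a,
                "value_b": b,
                "ratio": ratio,
                "class": classify_ratio(ratio),
            }
        )
    for met, ratio in (metabolite_fold_changes or {}).items():
        rows.append(
            {
                "item": met,
                "kind": "metabolite",
                "value_a": np.nan,
                "value_b": np.nan,
                "ratio": ratio,
                "class": classify_ratio(ratio),
            }
        )
    return pd.DataFrame(rows)
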