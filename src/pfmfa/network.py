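"""Atom-mapped metabolic network models and flux states.

A network model couples reaction stoichiometry with carbon-atom transitions
so that steady-state isotope labelling can be simulated on top of any flux
distribution.  Models are read from a plain-text format (one reaction per
line, FTBL-style positional atom naming) plus a JSON manifest that freezes
the expected pool/reaction counts and the free-flux parametrisation.

Flux conventions
----------------
Every reaction carries a net flux ``v_net`` in mmol/(gDW h), signed for
reversible reactions.  Reversible reactions additionally carry a
non-negative exchange flux ``v_xch``; the unidirectional rates are

    fwd = max(v_net, 0) + v_xch        bwd = max(-v_net, 0) + v_xch

Irreversible reactions must have ``v_net >= 0`` and ``v_xch = 0``.
Free exchange parameters live on [0, 1) and map to
``v_xch = beta * x / (1 - x)`` with ``beta`` = 1 mmol/(gDW h), a bounded,
scale-free parametrisation for this model family.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

STEADY_STATE_TOL = 1e-9
XCH_BETA = 1.0  # mmol/(gDW h) scale of the exchange-flux transform


class NetworkError(ValueError):
    """Raised for structurally invalid network models."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    balanced: bool

    def __post_init__(self) -> None:
        if self.n_carbons < 0:
            raise NetworkError(f"{self.id}: negative carbon count")


# One atom mapping alternative for a reaction.  For each product slot and
# each 1-based product carbon position it names the (educt slot, educt
# carbon position) the atom comes from.  Reactions through symmetric
# intermediates (succinate, fumarate) list several equally weighted
# alternatives.
@dataclass(frozen=True)
class AtomMap:
    # product_sources[p][c-1] = (educt_slot, educt_carbon) for product slot p
    product_sources: tuple[tuple[tuple[int, int], ...], ...]


@dataclass(frozen=True)
class Reaction:
    id: str
    educts: tuple[tuple[float, str], ...]
    products: tuple[tuple[float, str], ...]
    reversible: bool
    atom_maps: tuple[AtomMap, ...]
    ec_label: str | None = None

    @property
    def has_atom_map(self) -> bool:
        return len(self.atom_maps) > 0


class NetworkModel:
    """Validated atom-mapped network with a frozen parametrisation manifest."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        substrate_id: str,
        manifest: dict | None = None,
    ) -> None:
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise NetworkError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met
        self.reactions: list[Reaction] = list(reactions)
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate reaction ids {dup}")
        self.reaction_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.substrate_id = substrate_id
        self.manifest = dict(manifest or {})
        self._validate()

    # -- structure ---------------------------------------------------------
    @property
    def balanced_ids(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.balanced]

    @property
    def reversible_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.reversible]

    def stoich_matrix(self) -> np.ndarray:
        """Stoichiometric matrix over balanced metabolites (rows) x reactions."""
        rows = {m: i for i, m in enumerate(self.balanced_ids)}
        S = np.zeros((len(rows), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for coef, met in rxn.educts:
                if met in rows:
                    S[rows[met], j] -= coef
            for coef, met in rxn.products:
                if met in rows:
                    S[rows[met], j] += coef
        return S

    def _validate(self) -> None:
        for rxn in self.reactions:
            for coef, met in rxn.educts + rxn.products:
                if met not in self.metabolites:
                    raise NetworkError(f"{rxn.id}: unknown metabolite {met!r}")
                if coef <= 0:
                    raise NetworkError(f"{rxn.id}: non-positive coefficient for {met}")
            carriers = [
                met
                for coef, met in rxn.educts + rxn.products
                if self.metabolites[met].n_carbons > 0
            ]
            if not rxn.has_atom_map:
                # only the biomass drain (or fully carbon-free reactions) may
                # omit the atom map
                if carriers and not self._is_drain(rxn):
                    raise NetworkError(
                        f"{rxn.id}: carbon-carrying reaction without atom map"
                    )
                continue
            self._validate_atom_maps(rxn)

    def _is_drain(self, rxn: Reaction) -> bool:
        return all(
            self.metabolites[met].n_carbons == 0 or not self.metabolites[met].balanced
            for _, met in rxn.products
        ) and rxn.id == self.manifest.get("biomass_reaction", rxn.id)

    def _carbon_educts(self, rxn: Reaction) -> list[str]:
        return [m for _, m in rxn.educts if self.metabolites[m].n_carbons > 0]

    def _carbon_products(self, rxn: Reaction) -> list[str]:
        return [m for _, m in rxn.products if self.metabolites[m].n_carbons > 0]

    def _validate_atom_maps(self, rxn: Reaction) -> None:
        edu = self._carbon_educts(rxn)
        pro = self._carbon_products(rxn)
        n_in = sum(self.metabolites[m].n_carbons for m in edu)
        n_out = sum(self.metabolites[m].n_carbons for m in pro)
        if n_in != n_out:
            raise NetworkError(
                f"{rxn.id}: carbon imbalance ({n_in} educt vs {n_out} product carbons)"
            )
        for am in rxn.atom_maps:
            if len(am.product_sources) != len(pro):
                raise NetworkError(f"{rxn.id}: atom map covers wrong product count")
            used: set[tuple[int, int]] = set()
            for slot, met in enumerate(pro):
                nc = self.metabolites[met].n_carbons
                if len(am.product_sources[slot]) != nc:
                    raise NetworkError(
                        f"{rxn.id}: product {met} expects {nc} mapped carbons"
                    )
                for eslot, epos in am.product_sources[slot]:
                    if eslot >= len(edu):
                        raise NetworkError(f"{rxn.id}: atom map references missing educt")
                    if not 1 <= epos <= self.metabolites[edu[eslot]].n_carbons:
                        raise NetworkError(
                            f"{rxn.id}: position {epos} outside {edu[eslot]}"
                        )
                    if (eslot, epos) in used:
                        raise NetworkError(
                            f"{rxn.id}: educt carbon {edu[eslot]}#{epos} used twice"
                        )
                    used.add((eslot, epos))
            if len(used) != n_in:
                raise NetworkError(f"{rxn.id}: atom map drops educt carbons")

    def check_manifest(self) -> None:
        m = self.manifest
        checks = {
            "n_metabolites": len(self.metabolites),
            "n_balanced": len(self.balanced_ids),
            "n_reactions": len(self.reactions),
            "n_reversible": len(self.reversible_ids),
        }
        for key, actual in checks.items():
            if key in m and m[key] != actual:
                raise NetworkError(f"manifest mismatch for {key}: {m[key]} != {actual}")
        if "free_net_dim" in m:
            dim = len(self.reactions) - np.linalg.matrix_rank(self.stoich_matrix())
            if dim != m["free_net_dim"]:
                raise NetworkError(
                    f"manifest free_net_dim {m['free_net_dim']} != computed {dim}"
                )

    # -- serialisation -----------------------------------------------------
    def serialize(self) -> str:
        lines = ["@metabolites"]
        for met in self.metabolites.values():
            kind = "balanced" if met.balanced else "boundary"
            lines.append(f"{met.id} {met.n_carbons} {kind}")
        lines.append("@reactions")
        for rxn in self.reactions:
            lines.append(_format_reaction(self, rxn))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# parsing


_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?([A-Za-z0-9_]+)$")


def _parse_side(text: str) -> list[tuple[float, str]]:
    out = []
    text = text.strip()
    if not text:
        return out
    for term in text.split("+"):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise NetworkError(f"cannot parse stoichiometry term {term.strip()!r}")
        out.append((float(m.group(1) or 1.0), m.group(2)))
    return out


def _parse_atom_side(text: str) -> list[tuple[str, str]]:
    out = []
    for term in text.split("+"):
        term = term.strip()
        if "#" in term:
            met, letters = term.split("#", 1)
            out.append((met.strip(), letters.strip()))
        else:
            out.append((term, ""))
    return out


def _parse_atom_map(
    mets: Mapping[str, Metabolite],
    rxn_id: str,
    text: str,
    educt_ids: list[str],
    product_ids: list[str],
) -> AtomMap:
    lhs, _, rhs = text.partition("->")
    if not rhs:
        raise NetworkError(f"{rxn_id}: atom map lacks '->'")
    e_terms = [(m, s) for m, s in _parse_atom_side(lhs) if s]
    p_terms = [(m, s) for m, s in _parse_atom_side(rhs) if s]
    if [m for m, _ in e_terms] != educt_ids or [m for m, _ in p_terms] != product_ids:
        raise NetworkError(
            f"{rxn_id}: atom map species do not match carbon-carrying stoichiometry"
        )
    letter_src: dict[str, tuple[int, int]] = {}
    for slot, (met, letters) in enumerate(e_terms):
        if len(letters) != mets[met].n_carbons:
            raise NetworkError(f"{rxn_id}: {met} expects {mets[met].n_carbons} atoms")
        for pos, ch in enumerate(letters, start=1):
            if ch in letter_src:
                raise NetworkError(f"{rxn_id}: duplicate educt atom letter {ch!r}")
            letter_src[ch] = (slot, pos)
    product_sources = []
    for met, letters in p_terms:
        if len(letters) != mets[met].n_carbons:
            raise NetworkError(f"{rxn_id}: {met} expects {mets[met].n_carbons} atoms")
        srcs = []
        for ch in letters:
            if ch not in letter_src:
                raise NetworkError(f"{rxn_id}: product atom {ch!r} has no educt source")
            srcs.append(letter_src[ch])
        product_sources.append(tuple(srcs))
    return AtomMap(tuple(product_sources))


def parse_network(model_text: str, manifest: dict | None = None) -> NetworkModel:
    """Parse the plain-text network format into a validated :class:`NetworkModel`.

    The format has a ``@metabolites`` block (``id  n_carbons  balanced|boundary``)
    followed by ``@reactions``, one record per line::

        id: c1 A + c2 B -> c3 C | A#abc + B#de -> C#adc + ... | reversible | EC x.x.x.x

    Alternative atom mappings (symmetric intermediates) are separated by ``;``.
    A ``-`` in the atom field marks a mapless drain (biomass).
    """
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    substrate = None
    section = None
    for raw in model_text.splitlines():
        line = raw.split("//")[0].strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@"):
            section = line[1:].strip().lower()
            continue
        if section == "metabolites":
            parts = line.split()
            if len(parts) != 3 or parts[2] not in ("balanced", "boundary"):
                raise NetworkError(f"bad metabolite line {line!r}")
            metabolites.append(Metabolite(parts[0], int(parts[1]), parts[2] == "balanced"))
        elif section == "reactions":
            reactions.append(_parse_reaction_line(line, {m.id: m for m in metabolites}))
        elif section == "substrate":
            substrate = line
        else:
            raise NetworkError(f"line outside any section: {line!r}")
    if substrate is None:
        boundary = [m.id for m in metabolites if not m.balanced and m.n_carbons > 0]
        substrate = boundary[0] if boundary else ""
    model = NetworkModel(metabolites, reactions, substrate, manifest)
    if manifest:
        model.check_manifest()
    return model


def _parse_reaction_line(line: str, mets: Mapping[str, Metabolite]) -> Reaction:
    rid, _, rest = line.partition(":")
    rid = rid.strip()
    if not rest:
        raise NetworkError(f"reaction line without ':': {line!r}")
    fields = [f.strip() for f in rest.split("|")]
    if len(fields) < 3:
        raise NetworkError(f"{rid}: expected 'stoich | atoms | direction [| EC]'")
    stoich, atoms, direction = fields[0], fields[1], fields[2]
    ec = fields[3] if len(fields) > 3 and fields[3] else None
    if direction not in ("reversible", "irreversible"):
        raise NetworkError(f"{rid}: direction must be reversible|irreversible")
    lhs, _, rhs = stoich.partition("->")
    if not rhs.strip() and not lhs.strip():
        raise NetworkError(f"{rid}: empty stoichiometry")
    educts = tuple(_parse_side(lhs))
    products = tuple(_parse_side(rhs))
    for _, met in educts + products:
        if met not in mets:
            raise NetworkError(f"{rid}: unknown metabolite {met!r}")
    atom_maps: tuple[AtomMap, ...] = ()
    if atoms and atoms != "-":
        edu = [m for _, m in educts if mets[m].n_carbons > 0]
        pro = [m for _, m in products if mets[m].n_carbons > 0]
        atom_maps = tuple(
            _parse_atom_map(mets, rid, alt.strip(), edu, pro)
            for alt in atoms.split(";")
        )
    return Reaction(rid, educts, products, direction == "reversible", atom_maps, ec)


def _format_reaction(model: NetworkModel, rxn: Reaction) -> str:
    def side(terms):
        return " + ".join(
            (f"{c:g} {m}" if c != 1 else m) for c, m in terms
        )

    stoich = f"{side(rxn.educts)} -> {side(rxn.products)}"
    if rxn.has_atom_map:
        edu = model._carbon_educts(rxn)
        pro = model._carbon_products(rxn)
        alts = []
        for am in rxn.atom_maps:
            letters = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ"
            assign: dict[tuple[int, int], str] = {}
            k = 0
            for slot, met in enumerate(edu):
                for pos in range(1, model.metabolites[met].n_carbons + 1):
                    assign[(slot, pos)] = letters[k]
                    k += 1
            l_side = " + ".join(
                met
                + "#"
                + "".join(
                    assign[(slot, pos)]
                    for pos in range(1, model.metabolites[met].n_carbons + 1)
                )
                for slot, met in enumerate(edu)
            )
            r_side = " + ".join(
                met + "#" + "".join(assign[src] for src in am.product_sources[slot])
                for slot, met in enumerate(pro)
            )
            alts.append(f"{l_side} -> {r_side}")
        atom_field = " ; ".join(alts)
    else:
        atom_field = "-"
    direction = "reversible" if rxn.reversible else "irreversible"
    parts = [stoich, atom_field, direction]
    if rxn.ec_label:
        parts.append(rxn.ec_label)
    return f"{rxn.id}: " + " | ".join(parts)


# ---------------------------------------------------------------------------
# flux states and free-flux parametrisation


class FluxState:
    """Net and exchange fluxes over a model, at stoichiometric steady state."""

    def __init__(
        self,
        model: NetworkModel,
        v_net: np.ndarray,
        v_xch: np.ndarray | None = None,
        check: bool = True,
    ) -> None:
        self.model = model
        self.v_net = np.asarray(v_net, dtype=float).copy()
        n = len(model.reactions)
        self.v_xch = (
            np.zeros(n) if v_xch is None else np.asarray(v_xch, dtype=float).copy()
        )
        if self.v_net.shape != (n,) or self.v_xch.shape != (n,):
            raise NetworkError("flux vector length mismatch")
        if check:
            self.check()

    def check(self, tol: float = STEADY_STATE_TOL) -> None:
        resid = self.model.stoich_matrix() @ self.v_net
        if np.max(np.abs(resid)) > tol:
            bad = self.model.balanced_ids[int(np.argmax(np.abs(resid)))]
            raise NetworkError(
                f"steady state violated at {bad}: |S v| = {np.max(np.abs(resid)):.3g}"
            )
        for i, rxn in enumerate(self.model.reactions):
            if not rxn.reversible:
                if self.v_net[i] < -1e-9:
                    raise NetworkError(
                        f"negative net flux {self.v_net[i]:.3g} on irreversible {rxn.id}"
                    )
                if self.v_xch[i] != 0:
                    raise NetworkError(f"exchange flux on irreversible {rxn.id}")
            if self.v_xch[i] < 0:
                raise NetworkError(f"negative exchange flux on {rxn.id}")

    @property
    def fwd(self) -> np.ndarray:
        return np.maximum(self.v_net, 0.0) + self.v_xch

    @property
    def bwd(self) -> np.ndarray:
        return np.maximum(-self.v_net, 0.0) + self.v_xch

    def net(self, rxn_id: str) -> float:
        return float(self.v_net[self.model.reaction_index[rxn_id]])

    def xch(self, rxn_id: str) -> float:
        return float(self.v_xch[self.model.reaction_index[rxn_id]])

    def with_updates(self, net: Mapping[str, float] | None = None,
                     xch: Mapping[str, float] | None = None,
                     check: bool = True) -> "FluxState":
        v_net = self.v_net.copy()
        v_xch = self.v_xch.copy()
        for rid, val in (net or {}).items():
            v_net[self.model.reaction_index[rid]] = val
        for rid, val in (xch or {}).items():
            v_xch[self.model.reaction_index[rid]] = val
        return FluxState(self.model, v_net, v_xch, check=check)

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, rxn in enumerate(self.model.reactions):
            rows.append(
                {
                    "reaction": rxn.id,
                    "v_net": self.v_net[i],
                    "v_xch": self.v_xch[i] if rxn.reversible else np.nan,
                    "reversible": rxn.reversible,
                }
            )
        return pd.DataFrame(rows)


def xch_param_to_flux(x: np.ndarray | float) -> np.ndarray | float:
    """Map a free exchange parameter on [0, 1) to an exchange flux."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x >= 1)):
        raise NetworkError("exchange parameter outside [0, 1)")
    return XCH_BETA * x / (1.0 - x)


def xch_flux_to_param(v: np.ndarray | float) -> np.ndarray | float:
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise NetworkError("negative exchange flux")
    return v / (XCH_BETA + v)


class FreeFluxBasis:
    """Linear parametrisation of the steady-state net-flux space.

    Splits reactions into *free* columns (chosen from a preference list so
    that the packaged free fluxes are biochemically meaningful: uptake,
    growth, branch fluxes) and *dependent* columns solved from S v = 0.
    Optionally a set of reactions can be fixed at measured rates, which
    removes them from the free set and reduces the dimension.
    """

    def __init__(
        self,
        model: NetworkModel,
        fixed: Mapping[str, float] | None = None,
        candidates: Sequence[str] | None = None,
    ) -> None:
        self.model = model
        self.fixed = dict(fixed or {})
        S = model.stoich_matrix()
        n = S.shape[1]
        rank = np.linalg.matrix_rank(S)
        nullity = n - rank
        if candidates is None:
            candidates = model.manifest.get("free_net_candidates", [])
        pref_free = [model.reaction_index[r] for r in candidates if r in model.reaction_index]
        fixed_idx = [model.reaction_index[r] for r in self.fixed]
        for idx in fixed_idx:
            if idx in pref_free:
                pref_free.remove(idx)
        # build the dependent set greedily, preferring non-candidate columns,
        # never using fixed columns
        order = [j for j in range(n) if j not in pref_free and j not in fixed_idx]
        order += [j for j in pref_free]
        dep: list[int] = []
        cur_rank = 0
        for j in order:
            trial = dep + [j]
            r = np.linalg.matrix_rank(S[:, trial])
            if r > cur_rank:
                dep.append(j)
                cur_rank = r
            if cur_rank == rank:
                break
        if cur_rank < rank:
            raise NetworkError("could not build dependent flux set (over-constrained)")
        self.dep_idx = np.array(sorted(dep), dtype=int)
        free = [j for j in range(n) if j not in dep and j not in fixed_idx]
        self.free_idx = np.array(
            sorted(free, key=lambda j: (order.index(j) if j in order else n)), dtype=int
        )
        self.fixed_idx = np.array(fixed_idx, dtype=int)
        if len(self.free_idx) + len(self.fixed_idx) != nullity:
            # fixing a reaction that is stoichiometrically dependent would
            # over-determine the system
            raise NetworkError(
                "free dimension mismatch: fixed rates conflict with stoichiometry"
            )
        self.free_ids = [model.reactions[j].id for j in self.free_idx]
        self.dim = len(self.free_idx)
        # v_dep = D @ v_free + d0  with exact steady state
        S_dep = S[:, self.dep_idx]
        rhs_free = -S[:, self.free_idx]
        rhs_fixed = np.zeros(S.shape[0])
        if len(self.fixed_idx):
            vals = np.array([self.fixed[model.reactions[j].id] for j in self.fixed_idx])
            rhs_fixed = -S[:, self.fixed_idx] @ vals
        sol, *_ = np.linalg.lstsq(S_dep, np.hstack([rhs_free, rhs_fixed[:, None]]), rcond=None)
        resid = S_dep @ sol - np.hstack([rhs_free, rhs_fixed[:, None]])
        if np.max(np.abs(resid)) > 1e-8:
            raise NetworkError("dependent flux solve failed (rank-deficient system)")
        self._D = sol[:, :-1]
        self._d0 = sol[:, -1]
        # full embedding matrix: v_net = E @ v_free + e0
        self._E = np.zeros((n, self.dim))
        self._e0 = np.zeros(n)
        for k, j in enumerate(self.free_idx):
            self._E[j, k] = 1.0
        self._E[self.dep_idx, :] = self._D
        self._e0[self.dep_idx] = self._d0
        if len(self.fixed_idx):
            vals = np.array([self.fixed[model.reactions[j].id] for j in self.fixed_idx])
            self._e0[self.fixed_idx] = vals

    @property
    def embedding(self) -> tuple[np.ndarray, np.ndarray]:
        """(E, e0) with v_net = E @ free + e0."""
        return self._E, self._e0

    def embed_net(self, free_values: Sequence[float]) -> np.ndarray:
        free_values = np.asarray(free_values, dtype=float)
        if free_values.shape != (self.dim,):
            raise NetworkError(
                f"free vector length {free_values.shape} != dimension {self.dim}"
            )
        return self._E @ free_values + self._e0

    def extract(self, v_net: np.ndarray) -> np.ndarray:
        return np.asarray(v_net, dtype=float)[self.free_idx]


def free_flux_basis(
    model: NetworkModel,
    rate_constraints: Mapping[str, float] | None = None,
    candidates: Sequence[str] | None = None,
) -> FreeFluxBasis:
    """Free-flux parametrisation of the steady-state space.

    ``rate_constraints`` maps reaction ids to fixed net-flux values (hard
    constraints); the returned basis spans the remaining degrees of freedom.
    """
    return FreeFluxBasis(model, fixed=rate_constraints, candidates=candidates)


def embed_fluxes(
    model: NetworkModel,
    free_vector: Sequence[float],
    basis: FreeFluxBasis | None = None,
    xch: Mapping[str, float] | None = None,
) -> FluxState:
    """Embed a free-parameter vector into a full steady-state FluxState.

    Negative irreversible fluxes are reported, never clipped.
    """
    basis = basis or free_flux_basis(model)
    v_net = basis.embed_net(free_vector)
    v_xch = np.zeros(len(model.reactions))
    for rid, val in (xch or {}).items():
        v_xch[model.reaction_index[rid]] = val
    return FluxState(model, v_net, v_xch, check=True)


def carbon_closure(state: FluxState) -> dict[str, float]:
    """Carbon influx/efflux bookkeeping for a steady-state flux map.

    Returns carbon uptake, biomass carbon and CO2 efflux in mmolC/(gDW h);
    for any steady state these close to within the steady-state tolerance.
    """
    model = state.model
    uptake_c = 0.0
    co2_c = 0.0
    biomass_c = 0.0
    bm_id = model.manifest.get("biomass_reaction")
    for i, rxn in enumerate(model.reactions):
        v = state.v_net[i]
        for coef, met in rxn.educts:
            m = model.metabolites[met]
            if not m.balanced and m.n_carbons > 0:
                uptake_c += coef * m.n_carbons * v
        if rxn.id == bm_id:
            biomass_c += v * sum(
                coef * model.metabolites[met].n_carbons for coef, met in rxn.educts
            )
        for coef, met in rxn.products:
            m = model.metabolites[met]
            if not m.balanced and m.n_carbons > 0:
                co2_c += coef * m.n_carbons * v
    return {"uptake_c": uptake_c, "biomass_c": biomass_c, "co2_c": co2_c}


# ---------------------------------------------------------------------------
# packaged model


def load_packaged_model() -> NetworkModel:
    """The packaged reduced P. fluorescens SBW25 fructose network."""
    text = resources.files("pfmfa.data").joinpath("pfluorescens_sbw25.txt").read_text()
    manifest = json.loads(
        resources.files("pfmfa.data").joinpath("pfluorescens_sbw25_manifest.json").read_text()
    )
    return parse_network(text, manifest)
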