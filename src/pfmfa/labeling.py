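"""Steady-state isotope-labelling simulation by EMU decomposition.

An EMU (elementary metabolite unit) is a subset of a metabolite's carbon
atoms.  At isotopic steady state the mass-isotopomer distributions (MIDs)
of all EMUs of one size obey a linear balance system given the MIDs of
smaller EMUs, so the full cascade is solved size by size; condensation
reactions enter as convolutions of smaller EMU MIDs.  This is the standard
efficient simulation basis for stationary 13C flux analysis and is verified
in the test suite against a brute-force isotopomer oracle.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import FluxState, NetworkModel, NetworkError

MID_TOL = 1e-9


# ---------------------------------------------------------------------------
# label mixtures


@dataclass(frozen=True)
class MixtureComponent:
    """One positional isotopomer of the fed substrate.

    ``labelled_positions`` are the nominally 13C positions (1-based);
    ``enrichment`` is the fraction of those positions actually 13C.
    """

    fraction: float
    labelled_positions: tuple[int, ...]
    enrichment: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment outside [0, 1]")


@dataclass(frozen=True)
class LabelMixture:
    """Composition of the fed substrate over positional isotopomers."""

    n_carbons: int
    components: tuple[MixtureComponent, ...]
    natural_abundance: float = 0.0  # 13C probability of non-labelled positions

    def __post_init__(self) -> None:
        total = sum(c.fraction for c in self.components)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mixture fractions sum to {total!r}, not 1")
        for c in self.components:
            for p in c.labelled_positions:
                if not 1 <= p <= self.n_carbons:
                    raise ValueError(f"labelled position {p} outside substrate")

    def position_probabilities(self) -> list[np.ndarray]:
        """Per component, the 13C probability of each carbon position."""
        out = []
        for c in self.components:
            p = np.full(self.n_carbons, self.natural_abundance)
            if c.labelled_positions:
                p[np.array(c.labelled_positions) - 1] = c.enrichment
            out.append(p)
        return out


NATURAL_13C = 0.0107


def fructose_mixture(
    one_13c: float,
    u_13c: float,
    unlabelled: float = 0.0,
    enrichment_1: float = 0.99,
    enrichment_u: float = 0.995,
    natural_abundance: float = 0.0,
) -> LabelMixture:
    """Fructose feed from 1-13C, U-13C and unlabelled lots.

    Default enrichments are 99% (1-13C lots) and 99.5% (U-13C lot) mole/mole.
    """
    comps = []
    if one_13c:
        comps.append(MixtureComponent(one_13c, (1,), enrichment_1))
    if u_13c:
        comps.append(MixtureComponent(u_13c, tuple(range(1, 7)), enrichment_u))
    if unlabelled:
        comps.append(MixtureComponent(unlabelled, (), 1.0))
    return LabelMixture(6, tuple(comps), natural_abundance)


DESIGNED_MIXTURE = fructose_mixture(0.6008, 0.3992)
PRE_CLE_MIXTURE = fructose_mixture(0.6004, 0.2031, 0.1965)


def substrate_mid(mixture: LabelMixture, carbon_subset: Sequence[int]) -> np.ndarray:
    """Exact MID of the fed substrate over a carbon subset.

    Each position is an independent Bernoulli(13C probability) within one
    mixture component; the component MIDs are convolved position-wise and
    averaged over components.
    """
    subset = tuple(carbon_subset)
    if len(subset) == 0:
        raise ValueError("empty carbon subset")
    for p in subset:
        if not 1 <= p <= mixture.n_carbons:
            raise ValueError(f"position {p} outside substrate")
    mid = np.zeros(len(subset) + 1)
    for comp, probs in zip(mixture.components, mixture.position_probabilities()):
        comp_mid = np.array([1.0])
        for p in subset:
            q = probs[p - 1]
            comp_mid = np.convolve(comp_mid, [1.0 - q, q])
        mid += comp.fraction * comp_mid
    return mid


# ---------------------------------------------------------------------------
# EMU network decomposition


EmuKey = tuple[str, tuple[int, ...]]  # (metabolite id, sorted 1-based positions)


@dataclass(frozen=True)
class EMU:
    metabolite: str
    positions: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def key(self) -> EmuKey:
        return (self.metabolite, self.positions)


def make_emu(model: NetworkModel, metabolite: str, positions: Sequence[int]) -> EMU:
    met = model.metabolites.get(metabolite)
    if met is None:
        raise NetworkError(f"unknown metabolite {metabolite!r}")
    pos = tuple(sorted(positions))
    if len(set(pos)) != len(pos) or not pos:
        raise NetworkError(f"invalid carbon subset {positions!r} for {metabolite}")
    if pos[-1] > met.n_carbons or pos[0] < 1:
        raise NetworkError(f"positions {positions!r} outside {metabolite}")
    return EMU(metabolite, pos)


def _directed_reactions(model: NetworkModel) -> list:
    """Expand reversible reactions into two irreversible directions."""
    out = []
    for i, rxn in enumerate(model.reactions):
        if not rxn.has_atom_map:
            continue
        edu = tuple(model._carbon_educts(rxn))
        pro = tuple(model._carbon_products(rxn))
        fwd_maps = tuple(am.product_sources for am in rxn.atom_maps)
        out.append((i, True, edu, pro, fwd_maps))
        if rxn.reversible:
            # invert each map: product carbons become sources
            inv_maps = []
            for am in rxn.atom_maps:
                # source lookup: (eslot, epos) -> (pslot, ppos)
                inv: dict[tuple[int, int], tuple[int, int]] = {}
                for pslot, srcs in enumerate(am.product_sources):
                    for ppos, (eslot, epos) in enumerate(srcs, start=1):
                        inv[(eslot, epos)] = (pslot, ppos)
                new_sources = []
                for eslot, met in enumerate(edu):
                    nc = model.metabolites[met].n_carbons
                    new_sources.append(
                        tuple(inv[(eslot, epos)] for epos in range(1, nc + 1))
                    )
                inv_maps.append(tuple(new_sources))
            out.append((i, False, pro, edu, tuple(inv_maps)))
    return out


class EmuSystem:
    """Compiled EMU network for a fixed model + target set.

    The decomposition (which EMUs exist, how balances couple them) depends
    only on the network structure, so it is compiled once; evaluating MIDs
    for a particular flux state and mixture only refills the per-size linear
    systems.
    """

    def __init__(self, model: NetworkModel, targets: Sequence[EMU]):
        self.model = model
        self.targets = [make_emu(model, t.metabolite, t.positions) for t in targets]
        self._compile()

    # -- compilation -------------------------------------------------------
    def _compile(self) -> None:
        model = self.model
        dirs = _directed_reactions(model)
        # productions[met] = list of (dir_idx, pslot, weight, product_sources)
        productions: dict[str, list] = {}
        for d_idx, (ri, fwd, edu, pro, maps) in enumerate(dirs):
            for am in maps:
                w = 1.0 / len(maps)
                for pslot, met in enumerate(pro):
                    productions.setdefault(met, []).append((d_idx, pslot, w, am, edu))
        self._dirs = dirs
        terms: dict[EmuKey, list] = {}
        seen: set[EmuKey] = set()
        queue: list[EMU] = []

        def visit(emu: EMU) -> None:
            if emu.key not in seen:
                seen.add(emu.key)
                queue.append(emu)

        for t in self.targets:
            visit(t)
        while queue:
            emu = queue.pop()
            met = model.metabolites[emu.metabolite]
            if not met.balanced:
                continue  # boundary pools are inputs
            emu_terms = []
            for d_idx, pslot, w, am, edu in productions.get(emu.metabolite, []):
                srcs: dict[int, list[int]] = {}
                for p in emu.positions:
                    eslot, epos = am[pslot][p - 1]
                    srcs.setdefault(eslot, []).append(epos)
                sources = tuple(
                    make_emu(model, edu[eslot], sorted(pos))
                    for eslot, pos in sorted(srcs.items())
                )
                emu_terms.append((d_idx, w, sources))
                for s in sources:
                    visit(s)
            if not emu_terms:
                raise NetworkError(
                    f"balanced pool {emu.metabolite} has no production pathway"
                )
            terms[emu.key] = emu_terms
        self._terms = terms
        self.sizes = sorted({len(k[1]) for k in terms})
        self._per_size: dict[int, dict] = {}
        for size in self.sizes:
            keys = sorted(k for k in terms if len(k[1]) == size)
            index = {k: i for i, k in enumerate(keys)}
            diag = []      # (row, dir_idx, w)
            offdiag = []   # (row, col, dir_idx, w)
            rhs = []       # (row, dir_idx, w, source_keys)
            for k in keys:
                row = index[k]
                for d_idx, w, sources in terms[k]:
                    diag.append((row, d_idx, w))
                    if (
                        len(sources) == 1
                        and sources[0].key in index
                    ):
                        offdiag.append((row, index[sources[0].key], d_idx, w))
                    else:
                        rhs.append((row, d_idx, w, tuple(s.key for s in sources)))
            self._per_size[size] = {
                "keys": keys,
                "index": index,
                "diag": np.array([(r, d) for r, d, _ in diag], dtype=int),
                "diag_w": np.array([w for *_, w in diag]),
                "offdiag": np.array(
                    [(r, c, d) for r, c, d, _ in offdiag], dtype=int
                ).reshape(-1, 3),
                "offdiag_w": np.array([w for *_, w in offdiag]),
                "rhs": rhs,
            }
        self.n_emus = len(terms)

    def all_emus(self) -> list[EmuKey]:
        return sorted(self._terms, key=lambda k: (len(k[1]), k))

    # -- evaluation --------------------------------------------------------
    def _input_mid(
        self,
        key: EmuKey,
        mixture: LabelMixture,
        solved: Mapping[EmuKey, np.ndarray],
    ) -> np.ndarray:
        if key in solved:
            return solved[key]
        met, positions = key
        if met == self.model.substrate_id:
            return substrate_mid(mixture, positions)
        raise NetworkError(
            f"boundary pool {met} is not the substrate and has no labelling input"
        )

    def simulate(self, state: FluxState, mixture: LabelMixture) -> dict[EmuKey, np.ndarray]:
        if state.model is not self.model:
            raise NetworkError("flux state belongs to a different model")
        fwd, bwd = state.fwd, state.bwd
        rates = np.array(
            [fwd[ri] if is_fwd else bwd[ri] for ri, is_fwd, *_ in self._dirs]
        )
        solved: dict[EmuKey, np.ndarray] = {}
        for size in self.sizes:
            blk = self._per_size[size]
            n = len(blk["keys"])
            A = np.zeros((n, n))
            B = np.zeros((n, size + 1))
            d = blk["diag"]
            np.add.at(A, (d[:, 0], d[:, 0]), blk["diag_w"] * rates[d[:, 1]])
            od = blk["offdiag"]
            if len(od):
                np.add.at(
                    A, (od[:, 0], od[:, 1]), -blk["offdiag_w"] * rates[od[:, 2]]
                )
            conv_cache: dict[tuple[EmuKey, ...], np.ndarray] = {}
            for row, d_idx, w, src_keys in blk["rhs"]:
                rate = rates[d_idx]
                if rate == 0.0 and w:
                    continue
                mid = conv_cache.get(src_keys)
                if mid is None:
                    mid = self._input_mid(src_keys[0], mixture, solved)
                    for k in src_keys[1:]:
                        mid = np.convolve(mid, self._input_mid(k, mixture, solved))
                    conv_cache[src_keys] = mid
                B[row] += w * rate * mid
            # Pools with zero influx (inactive branch, e.g. the glyoxylate
            # shunt in the wild type) have zero consumption too at steady
            # state, so their MID couples to nothing: decouple them as
            # unlabelled rather than failing on a singular balance.
            dead = np.where(np.abs(np.diag(A)) < 1e-12)[0]
            for i in dead:
                A[i, :] = 0.0
                A[i, i] = 1.0
                B[i, :] = 0.0
                B[i, 0] = 1.0
            try:
                X = np.linalg.solve(A, B)
            except np.linalg.LinAlgError:
                dead = [
                    blk["keys"][i][0]
                    for i in range(n)
                    if A[i, i] == 0 or not np.any(A[i])
                ]
                raise NetworkError(
                    f"singular EMU balance system at size {size}; "
                    f"unfed/disconnected pools: {sorted(set(dead)) or 'cycle with zero flux'}"
                )
            if X.min() < -MID_TOL:
                raise NetworkError(
                    f"EMU solution has negative fraction {X.min():.3g} at size {size}"
                )
            X = np.clip(X, 0.0, None)
            X /= X.sum(axis=1, keepdims=True)
            for k, i in blk["index"].items():
                solved[k] = X[i]
        return solved


_SYSTEM_CACHE: dict[tuple[int, tuple[EmuKey, ...]], EmuSystem] = {}


def emu_decompose(model: NetworkModel, targets: Sequence[EMU]) -> EmuSystem:
    """Minimal EMU reaction network reaching all targets (cached per model)."""
    key = (id(model), tuple(t.key for t in targets))
    system = _SYSTEM_CACHE.get(key)
    if system is None:
        system = EmuSystem(model, targets)
        _SYSTEM_CACHE[key] = system
    return system


def simulate_mids(
    model: NetworkModel,
    state: FluxState,
    mixture: LabelMixture,
    targets: Sequence[EMU],
) -> dict[EmuKey, np.ndarray]:
    """Solve the EMU cascade and return MIDs for the requested target EMUs."""
    system = emu_decompose(model, targets)
    solved = system.simulate(state, mixture)
    out = {}
    for t in targets:
        key = (t.metabolite, tuple(sorted(t.positions)))
        if key in solved:
            out[key] = solved[key]
        else:  # target on the substrate itself
            out[key] = system._input_mid(key, mixture, solved)
    return out


def mids_to_frame(mids: Mapping[EmuKey, np.ndarray]):
    """Tidy export: compound, fragment (carbon subset string), mass shift, fraction."""
    import pandas as pd

    rows = []
    for (met, positions), mid in sorted(mids.items()):
        frag = ",".join(map(str, positions))
        for shift, frac in enumerate(mid):
            rows.append(
                {"compound": met, "fragment": frag, "mass_shift": shift, "fraction": frac}
            )
    return pd.DataFrame(rows)
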