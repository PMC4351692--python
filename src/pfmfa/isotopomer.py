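"""Brute-force full-isotopomer simulation: the verification oracle.

Solves the complete steady-state isotopomer balance system of a small
network by damped Gauss-Seidel fixed-point iteration over all 2^n binary
labelling patterns per pool.  Deliberately independent of the EMU cascade
implementation so the two can cross-check each other; guarded to small
networks (<= 22 total carbons over balanced pools).
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .labeling import EmuKey, LabelMixture, _directed_reactions
from .network import FluxState, NetworkModel, NetworkError

CARBON_GUARD = 22


class IsotopomerDistribution:
    """Per-metabolite fractions over binary labelling patterns.

    Patterns are indexed by bitmask with carbon 1 as the least significant
    bit; fractions of each metabolite sum to 1.
    """

    def __init__(self, model: NetworkModel, dists: Mapping[str, np.ndarray]):
        self.model = model
        self.dists = dict(dists)

    def mid(self, metabolite: str, positions: Sequence[int] | None = None) -> np.ndarray:
        """Marginalise the isotopomer distribution to an MID over a subset."""
        met = self.model.metabolites[metabolite]
        positions = tuple(positions or range(1, met.n_carbons + 1))
        dist = self.dists[metabolite]
        mid = np.zeros(len(positions) + 1)
        for pattern, frac in enumerate(dist):
            mass = sum((pattern >> (p - 1)) & 1 for p in positions)
            mid[mass] += frac
        return mid


def _substrate_distribution(mixture: LabelMixture) -> np.ndarray:
    n = mixture.n_carbons
    dist = np.zeros(2**n)
    for comp, probs in zip(mixture.components, mixture.position_probabilities()):
        for pattern in range(2**n):
            p = 1.0
            for pos in range(n):
                bit = (pattern >> pos) & 1
                p *= probs[pos] if bit else 1.0 - probs[pos]
            dist[pattern] += comp.fraction * p
    return dist


def enumerate_isotopomers(
    model: NetworkModel,
    state: FluxState,
    mixture: LabelMixture,
    tol: float = 1e-13,
    max_iter: int = 20000,
) -> IsotopomerDistribution:
    """Exact steady-state isotopomer distribution of every balanced pool."""
    balanced = [m for m in model.metabolites.values() if m.balanced and m.n_carbons > 0]
    total_carbons = sum(m.n_carbons for m in balanced)
    if total_carbons > CARBON_GUARD:
        raise NetworkError(
            f"oracle guard exceeded: {total_carbons} balanced carbons > {CARBON_GUARD}"
        )
    dirs = _directed_reactions(model)
    fwd, bwd = state.fwd, state.bwd
    rates = np.array([fwd[ri] if is_fwd else bwd[ri] for ri, is_fwd, *_ in dirs])

    dists: dict[str, np.ndarray] = {}
    for met in balanced:
        d = np.zeros(2**met.n_carbons)
        d[0] = 1.0
        dists[met.id] = d
    sub = model.metabolites[model.substrate_id]
    substrate_dist = _substrate_distribution(mixture)

    # Precompile production terms: for each balanced metabolite, a list of
    # (dir_index, weight, educt ids, index map from joint educt pattern to
    # this product's pattern).
    productions: dict[str, list] = {m.id: [] for m in balanced}
    influx: dict[str, float] = {m.id: 0.0 for m in balanced}
    for d_idx, (ri, is_fwd, edu, pro, maps) in enumerate(dirs):
        rate = rates[d_idx]
        for am in maps:
            w = 1.0 / len(maps)
            for pslot, pmet in enumerate(pro):
                if pmet not in productions:
                    continue
                nc = [model.metabolites[e].n_carbons for e in edu]
                n_joint = int(np.prod([2**c for c in nc])) if edu else 1
                idx_map = np.zeros(n_joint, dtype=np.int64)
                for joint in range(n_joint):
                    bits = []
                    rem = joint
                    for c in nc:
                        bits.append(rem & (2**c - 1))
                        rem >>= c
                    pat = 0
                    for ppos, (eslot, epos) in enumerate(am[pslot], start=1):
                        if (bits[eslot] >> (epos - 1)) & 1:
                            pat |= 1 << (ppos - 1)
                    idx_map[joint] = pat
                productions[pmet].append((d_idx, w, tuple(edu), idx_map))
                influx[pmet] += w * rate
    dead_pools = set()
    for met in balanced:
        if influx[met.id] <= 0:
            if not productions[met.id]:
                raise NetworkError(f"singular system: pool {met.id} has no production")
            # zero influx implies zero consumption at steady state; the pool
            # decouples and stays unlabelled
            dead_pools.add(met.id)

    def educt_dist(met_id: str) -> np.ndarray:
        if met_id == model.substrate_id:
            return substrate_dist
        if met_id in dists:
            return dists[met_id]
        raise NetworkError(f"boundary pool {met_id} has no labelling input")

    order = [m.id for m in balanced]
    for _ in range(max_iter):
        delta = 0.0
        for met_id in order:
            if met_id in dead_pools:
                continue
            new = np.zeros_like(dists[met_id])
            for d_idx, w, edu, idx_map in productions[met_id]:
                rate = rates[d_idx]
                if rate == 0.0:
                    continue
                # joint pattern index: educt slot 0 in the low bits, later
                # slots shifted up, matching the idx_map construction
                joint = np.array([1.0])
                for e in edu:
                    joint = np.multiply.outer(educt_dist(e), joint).ravel()
                new += w * rate * np.bincount(idx_map, weights=joint, minlength=len(new))
            new /= influx[met_id]
            delta = max(delta, float(np.max(np.abs(new - dists[met_id]))))
            dists[met_id] = new
        if delta < tol:
            break
    else:
        raise NetworkError("isotopomer fixed-point iteration did not converge")
    return IsotopomerDistribution(model, dists)


def joint_tandem_mid(
    distribution: IsotopomerDistribution,
    metabolite: str,
    precursor_positions: Sequence[int],
    fragment_positions: Sequence[int],
) -> np.ndarray:
    """Joint precursor/fragment mass-fraction matrix for a tandem MS transition.

    Entry [r, j] is the probability that the fragment carries j labelled
    carbons while the precursor complement (precursor minus fragment)
    carries r, i.e. the (n-m+1) x (m+1) grid of MRM transitions for a
    precursor with n and a fragment with m carbons.  Row sums give the
    complement MID, column sums the fragment MID, anti-diagonal sums the
    precursor MID.
    """
    precursor = tuple(sorted(precursor_positions))
    fragment = tuple(sorted(fragment_positions))
    if not set(fragment) <= set(precursor):
        raise NetworkError("fragment carbons not nested in precursor")
    complement = tuple(p for p in precursor if p not in fragment)
    n, m = len(precursor), len(fragment)
    out = np.zeros((n - m + 1, m + 1))
    dist = distribution.dists[metabolite]
    for pattern, frac in enumerate(dist):
        j = sum((pattern >> (p - 1)) & 1 for p in fragment)
        r = sum((pattern >> (p - 1)) & 1 for p in complement)
        out[r, j] += frac
    return out
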