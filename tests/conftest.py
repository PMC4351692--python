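import numpy as np
import pytest

from pfmfa.network import FluxState, NetworkModel, load_packaged_model, parse_network
from pfmfa.labeling import LabelMixture, MixtureComponent

# ---------------------------------------------------------------------------
# toy networks

CHAIN_TEXT = """
@metabolites
Sx 2 boundary
OUT 0 boundary
A 2 balanced
B 2 balanced
C 2 balanced
@substrate
Sx
@reactions
in: Sx -> A | Sx#ab -> A#ab | irreversible |
ab: A -> B | A#ab -> B#ab | irreversible |
bc: B -> C | B#ab -> C#ab | irreversible |
out: C -> OUT | - | irreversible |
"""

# diamond with asymmetric atom maps: the two arms permute carbons differently,
# so the split ratio is visible in positional labelling
DIAMOND_TEXT = """
@metabolites
Sx 3 boundary
OUT 0 boundary
A 3 balanced
B 3 balanced
C 3 balanced
D 3 balanced
@substrate
Sx
@reactions
in: Sx -> A | Sx#abc -> A#abc | irreversible |
ab: A -> B | A#abc -> B#abc | irreversible |
ac: A -> C | A#abc -> C#cab | irreversible |
bd: B -> D | B#abc -> D#abc | reversible |
cd: C -> D | C#abc -> D#acb | irreversible |
out: D -> OUT | - | irreversible |
"""

# condensation: substrate split into two C1 pools recombined into a C2 product
CONDENSATION_TEXT = """
@metabolites
Ux 2 boundary
OUT 0 boundary
E 1 balanced
F 1 balanced
G 2 balanced
@substrate
Ux
@reactions
split: Ux -> E + F | Ux#ab -> E#a + F#b | irreversible |
join: E + F -> G | E#a + F#b -> G#ba | irreversible |
out: G -> OUT | - | irreversible |
"""


def _flux_state(model: NetworkModel, net: dict, xch: dict | None = None) -> FluxState:
    v_net = np.zeros(len(model.reactions))
    v_xch = np.zeros(len(model.reactions))
    for rid, val in net.items():
        v_net[model.reaction_index[rid]] = val
    for rid, val in (xch or {}).items():
        v_xch[model.reaction_index[rid]] = val
    return FluxState(model, v_net, v_xch)


@pytest.fixture(scope="session")
def chain_model():
    return parse_network(CHAIN_TEXT)


@pytest.fixture(scope="session")
def diamond_model():
    return parse_network(DIAMOND_TEXT)


@pytest.fixture(scope="session")
def condensation_model():
    return parse_network(CONDENSATION_TEXT)


@pytest.fixture(scope="session")
def diamond_state(diamond_model):
    return _flux_state(
        diamond_model,
        {"in": 1.0, "ab": 0.3, "ac": 0.7, "bd": 0.3, "cd": 0.7, "out": 1.0},
        {"bd": 0.4},
    )


@pytest.fixture(scope="session")
def mix3():
    """Asymmetric 3-carbon feed: 50% 1-13C at 90% enrichment, 50% 2,3-13C."""
    return LabelMixture(
        3,
        (MixtureComponent(0.5, (1,), 0.9), MixtureComponent(0.5, (2, 3), 1.0)),
        natural_abundance=0.01,
    )


# ---------------------------------------------------------------------------
# small identifiable fit problem on the diamond network


class ToyProblem:
    """Diamond network, fixed uptake, 2 parameters (split flux + exchange)."""

    def __init__(self):
        from pfmfa.labeling import simulate_mids
        from pfmfa.measurements import MeasurementSpec
        from pfmfa.network import free_flux_basis

        self.model = parse_network(DIAMOND_TEXT)
        self.basis = free_flux_basis(
            self.model, rate_constraints={"in": 1.0}, candidates=["ab"]
        )
        self.truth = _flux_state(
            self.model,
            {"in": 1.0, "ab": 0.3, "ac": 0.7, "bd": 0.3, "cd": 0.7, "out": 1.0},
            {"bd": 0.4},
        )
        self.mixture = LabelMixture(
            3, (MixtureComponent(0.5, (1,), 0.95), MixtureComponent(0.5, (2, 3), 1.0))
        )
        self.specs = [
            MeasurementSpec("B", "B", (1, 2, 3), "LC", 0.05, 1),
            MeasurementSpec("C", "C", (1, 2, 3), "LC", 0.05, 1),
            MeasurementSpec("D", "D", (1, 2, 3), "LC", 0.05, 1),
            MeasurementSpec("D", "D", (1, 2), "LC", 0.05, 1),
        ]
        self.emus = [s.emu(self.model) for s in self.specs]
        self.true_mids = simulate_mids(self.model, self.truth, self.mixture, self.emus)

    def dataset(self, seed, noise_model="gaussian", noise_scale=1.0):
        from pfmfa.measurements import simulate_measurements

        return simulate_measurements(
            self.true_mids, self.specs, rng_seed=seed,
            noise_model=noise_model, noise_scale=noise_scale,
        )

    def fit(self, seed, n_starts=2, **kwargs):
        from pfmfa.fit import fit_fluxes

        ms = self.dataset(seed)
        return fit_fluxes(
            self.model, ms, None, self.mixture, n_starts=n_starts, rng_seed=seed,
            exclusion=False, basis=self.basis, free_xch=["bd"], **kwargs,
        )


@pytest.fixture(scope="session")
def toy_problem():
    return ToyProblem()


# ---------------------------------------------------------------------------
# packaged model and expensive shared fits


@pytest.fixture(scope="session")
def model():
    return load_packaged_model()


@pytest.fixture(scope="session")
def wt_ref(model):
    from pfmfa.synth import reference_flux_map

    return reference_flux_map("wt", model)


@pytest.fixture(scope="session")
def mut_ref(model):
    from pfmfa.synth import reference_flux_map

    return reference_flux_map("mut", model)


@pytest.fixture(scope="session")
def noise_free_fits(model):
    """Multistart fits of noise-free WT and mutant datasets (shared: slow)."""
    from pfmfa.fit import fit_fluxes
    from pfmfa.synth import DEFAULT_MIXTURES, generate_cle_dataset

    fits = {}
    for strain in ("wt", "mut"):
        ms = generate_cle_dataset(strain, rng_seed=11, noise_scale=0.0, model=model)
        fits[strain] = fit_fluxes(
            model, ms, ms.rates, DEFAULT_MIXTURES[strain],
            n_starts=3, rng_seed=5, exclusion=False,
        )
    return fits
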