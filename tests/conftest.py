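"""Shared fixtures: the GPR demonstration network, a seeded CA/HT toy
pair with its prepared evaluation context, and tiny hand-checkable
networks for the solver oracles."""

from __future__ import annotations

import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from actd.gpr_logic import build_gpr_model
from actd.metnet_io import Metabolite, Reaction, StoichiometricModel
from actd.nhde import build_context
from actd.toy_models import ToySpec, make_fig1_network, make_toy_pair


@pytest.fixture(scope="session")
def fig1():
    return make_fig1_network()


@pytest.fixture(scope="session")
def toy_pair():
    return make_toy_pair(ToySpec(expression_seed=1))


@pytest.fixture(scope="session")
def toy_ctx(toy_pair):
    return build_context(
        toy_pair.ca_model, toy_pair.ht_model,
        toy_pair.ca_gpr, toy_pair.ht_gpr,
    )


def make_model(reactions: list[Reaction], biomass: str, atp: str,
               model_id: str = "tiny") -> StoichiometricModel:
    met_ids = sorted({m for r in reactions for m in r.stoich})
    model = StoichiometricModel(
        id=model_id,
        metabolites=[Metabolite.from_id(m) for m in met_ids],
        reactions=reactions,
        biomass_rxn_id=biomass,
        atp_rxn_id=atp,
    )
    model.validate()
    return model


@pytest.fixture
def parallel_paths():
    """Forced demand of 10 through two parallel unit-yield paths.

    The only free dimension is the flux split x / (10 - x); the weighted
    flux-squared objective has the closed-form optimum
    x* = 10 * (1/c1) / (1/c1 + 1/c2).
    """

    def build(c1: float, c2: float):
        reactions = [
            Reaction("SRC", {"A[c]": 1}, 10, 10),
            Reaction("p1", {"A[c]": -1, "B[c]": 1}, 0, 10, gpr="G1"),
            Reaction("p2", {"A[c]": -1, "B[c]": 1}, 0, 10, gpr="G2"),
            Reaction("DM", {"B[c]": -1}, 0, 100),
        ]
        model = make_model(reactions, biomass="DM", atp="DM")
        weights = {"p1": c1, "p2": c2}
        return model, weights

    return build


@pytest.fixture
def chain_model():
    """Linear chain with a capped uptake: the FBA bottleneck is the cap."""
    reactions = [
        Reaction("SRC", {"A[c]": 1}, 0, 10),
        Reaction("r1", {"A[c]": -1, "B[c]": 1}, 0, 100, gpr="E1"),
        Reaction("r2", {"B[c]": -1, "bio[c]": 1}, 0, 100, gpr="E2"),
        Reaction("DM_bio", {"bio[c]": -1}, 0, 100),
    ]
    model = make_model(reactions, biomass="r2", atp="r2")
    gpr = build_gpr_model({r.id: r.gpr for r in reactions})
    return model, gpr
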