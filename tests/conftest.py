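import numpy as np
import pytest

from phenorecon import (
    MediaFormulation,
    MetaboliteSpec,
    MetabolicModel,
    ReactionSpec,
    make_truth_bundle,
)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study bundle (shared; treat as read-only)."""
    return make_truth_bundle()


@pytest.fixture(scope="session")
def toy3():
    """Three-step chain: uptake of A, transport, one isozyme-catalysed
    conversion, biomass drain of B.  Hand-solvable: objective = uptake."""
    mets = (
        MetaboliteSpec("A_e", compartment="e"),
        MetaboliteSpec("A_c", compartment="c"),
        MetaboliteSpec("B_c", compartment="c"),
    )
    rxns = (
        ReactionSpec.make("EX_A", {"A_e": -1.0}, lower_bound=0.0, is_exchange=True),
        ReactionSpec.make("T_A", {"A_e": -1.0, "A_c": 1.0}, gpr="gT"),
        ReactionSpec.make("R1", {"A_c": -1.0, "B_c": 1.0}, gpr="g1 or g2"),
        ReactionSpec.make("BIO", {"B_c": -1.0}, is_biomass=True),
    )
    return MetabolicModel(
        id="toy3",
        genes=frozenset({"gT", "g1", "g2"}),
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIO",
    )


@pytest.fixture(scope="session")
def media_A10():
    return MediaFormulation.make("mA", {"A_e": 10.0})


def random_small_model(rng: np.random.Generator, max_rxns: int = 8):
    """A random mass-balanced toy network with exchanges and a biomass drain,
    small enough for exhaustive vertex enumeration."""
    n_mets = int(rng.integers(2, 5))
    ext = [MetaboliteSpec(f"x{i}_e", compartment="e") for i in range(min(2, n_mets))]
    cyt = [MetaboliteSpec(f"m{i}_c", compartment="c") for i in range(n_mets)]
    mets = tuple(ext + cyt)
    rxns = []
    for i, e in enumerate(ext):
        rxns.append(
            ReactionSpec.make(f"EX_{e.id[:-2]}", {e.id: -1.0}, 0.0, 20.0, is_exchange=True)
        )
        rxns.append(
            ReactionSpec.make(
                f"T{i}", {e.id: -1.0, cyt[i % n_mets].id: 1.0},
                -20.0 if rng.random() < 0.3 else 0.0, 20.0,
            )
        )
    n_internal = int(rng.integers(1, max_rxns - len(rxns)))
    for k in range(n_internal):
        i, j = rng.choice(n_mets, size=2, replace=False)
        coeff = float(rng.integers(1, 3))
        rxns.append(
            ReactionSpec.make(
                f"R{k}", {cyt[i].id: -1.0, cyt[j].id: coeff},
                -20.0 if rng.random() < 0.4 else 0.0, 20.0,
            )
        )
    bio_src = cyt[int(rng.integers(0, n_mets))]
    rxns.append(ReactionSpec.make("BIO", {bio_src.id: -1.0}, 0.0, 20.0, is_biomass=True))
    return MetabolicModel(
        id="rand", genes=frozenset(), metabolites=mets,
        reactions=tuple(rxns), biomass_reaction_id="BIO",
    )
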