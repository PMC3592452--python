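import numpy as np
import pytest

from phenorecon import (
    MediaFormulation,
    PhenotypeRow,
    PhenotypeTable,
    Simulator,
    batch_predict,
    disabled_reactions,
    maximize_biomass,
    score_predictions,
    simulate_deletion,
)
from phenorecon.fba_engine import _media_lower_bounds

from lp_oracle import effective_bounds, max_biomass_bruteforce, model_matrices
from conftest import random_small_model


def test_toy3_hand_lp(toy3, media_A10):
    """Chain model: every unit of biomass needs one unit of A uptake, so the
    optimum equals the uptake bound."""
    sol = maximize_biomass(toy3, media_A10)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(10.0, abs=1e-6)
    assert sol.mass_balance_residual(toy3) <= 1e-6
    assert maximize_biomass(toy3, MediaFormulation.make("none", {})).objective_value == (
        pytest.approx(0.0, abs=1e-9)
    )


def test_biomass_bounds_zero(toy3, media_A10):
    from dataclasses import replace

    clamped = toy3.replace_reaction(
        replace(toy3.reaction("BIO"), lower_bound=0.0, upper_bound=0.0)
    )
    assert maximize_biomass(clamped, media_A10).objective_value == pytest.approx(0.0)


@pytest.mark.parametrize("backend", ["glpk", "scipy"])
def test_backends_agree(toy3, media_A10, backend):
    sol = maximize_biomass(toy3, media_A10, backend=backend)
    assert sol.objective_value == pytest.approx(10.0, abs=1e-6)


def test_oracle_equivalence_random_networks():
    """LP solutions match exhaustive vertex enumeration on 30 random
    networks of <= 8 reactions."""
    rng = np.random.default_rng(20240917)
    for _ in range(30):
        model = random_small_model(rng)
        uptakes = {
            r.stoichiometry[0][0]: float(rng.integers(1, 15))
            for r in model.exchange_reactions()
        }
        media = MediaFormulation.make("rand", uptakes)
        lp = maximize_biomass(model, media).objective_value
        S, c = model_matrices(model)
        lb, ub = effective_bounds(model, uptakes)
        brute = max_biomass_bruteforce(S, lb, ub, c)
        assert lp == pytest.approx(brute, abs=1e-6), model.reactions


def test_disabled_reactions(toy3):
    assert disabled_reactions(toy3, {"g1"}) == frozenset()  # isozyme survives
    assert disabled_reactions(toy3, {"g1", "g2"}) == frozenset({"R1"})
    assert disabled_reactions(toy3, {"gT"}) == frozenset({"T_A"})
    assert disabled_reactions(toy3, set()) == frozenset()
    assert disabled_reactions(toy3, {"unknown_gene"}) == frozenset()


def test_isozyme_subset_knockouts_never_disable(bundle):
    """Knocking any strict subset of one OR branch while another branch is
    intact leaves the reaction enabled."""
    model = bundle.truth_model
    checked = 0
    for r in model.reactions:
        branches = r.gpr.top_or_branches()
        if len(branches) < 2:
            continue
        from phenorecon.gpr import GPRRule

        for b in branches:
            sub = GPRRule(b).genes()
            assert r.id not in disabled_reactions(model, sub)
            checked += 1
    assert checked >= 2


def test_simulate_deletion(toy3, media_A10):
    call = simulate_deletion(toy3, {"g1", "g2"}, media_A10)
    assert call.predicted == "unviable" and call.objective_value == pytest.approx(0.0)
    assert simulate_deletion(toy3, {"g1"}, media_A10).predicted == "viable"
    # empty knockout reproduces the plain FBA verdict exactly
    base = maximize_biomass(toy3, media_A10)
    empty = simulate_deletion(toy3, set(), media_A10)
    assert empty.predicted == "viable"
    assert empty.objective_value == pytest.approx(base.objective_value, abs=1e-9)


def test_auxotroph_rescued_by_supplement(bundle):
    """A pathway knockout is unviable on minimal medium and viable once the
    pathway's end product is supplied — the thiamine-rescue pattern."""
    model = bundle.truth_model
    mm = bundle.media_set["mm_A"]
    # sever an unsupplemented pathway: its precursor has no media source
    last = max(
        int(r.id[1]) for r in model.reactions if r.id.startswith("R") and "_" in r.id
    )
    genes = set()
    for r in model.reactions:
        if r.id.startswith(f"R{last}_"):
            genes |= r.gpr.genes()
    assert simulate_deletion(model, genes, mm).predicted == "unviable"
    plus = mm.with_compound(f"prec{last}_e", 10.0)
    # the supplement only helps if the compound can be imported
    if model.exchange_for(f"prec{last}_e") is not None:
        assert simulate_deletion(model, genes, plus).predicted == "viable"


def test_media_bounds_convention(toy3, media_A10):
    lbs = _media_lower_bounds(toy3, media_A10)
    assert lbs == {"EX_A": -10.0}
    closed = _media_lower_bounds(toy3, MediaFormulation.make("none", {}))
    assert closed == {"EX_A": 0.0}


def test_nutrient_monotonicity(bundle):
    """Pointwise-richer media never decrease the biomass optimum."""
    model = bundle.truth_model
    sim = Simulator(model)
    rich = bundle.media_set["rich"]
    for name, media in bundle.media_set.items():
        up, rup = media.uptake_dict(), rich.uptake_dict()
        if all(up.get(c, 0) <= rup.get(c, 0) for c in up):
            assert sim.objective(media) <= sim.objective(rich) + 1e-6


def test_knockout_monotonicity(bundle):
    """Larger knockouts never grow faster: G subset H implies obj(H) <= obj(G)."""
    model = bundle.truth_model
    sim = Simulator(model)
    media = bundle.media_set["defined_rich"]
    rng = np.random.default_rng(7)
    genes = sorted(model.genes)
    for _ in range(20):
        g = rng.choice(genes, size=6, replace=False)
        G, H = set(g[:3]), set(g)
        objG = sim.objective(media, disabled_reactions(model, G))
        objH = sim.objective(media, disabled_reactions(model, H))
        assert objH <= objG + 1e-6


def test_mass_balance_residuals(bundle):
    model = bundle.truth_model
    sim = Simulator(model)
    for media in bundle.media_list():
        sol = sim.solve(media)
        assert sol.mass_balance_residual(model) <= 1e-6


def test_batch_predict_deterministic(bundle):
    defs = bundle.strain_defs()
    m1 = batch_predict(bundle.truth_model, defs, bundle.media_list())
    m2 = batch_predict(bundle.truth_model, defs, bundle.media_list())
    assert m1.to_frame().to_csv() == m2.to_frame().to_csv()
    assert len(m1.calls) == len(defs) * len(bundle.media_list())
    # a strain with no genes deleted matches the master row
    master = [c for c in m1.calls if c.strain_id == "master"]
    assert all(c.predicted == "viable" for c in master)


def test_batch_predict_empty_strains_errors(bundle):
    with pytest.raises(ValueError):
        batch_predict(bundle.truth_model, {}, bundle.media_list())


def test_score_predictions_hand_counts():
    from phenorecon.fba_engine import GrowthCall, PredictionMatrix

    obs = PhenotypeTable(
        (
            PhenotypeRow("s1", "LB", "viable"),
            PhenotypeRow("s2", "LB", "viable"),
            PhenotypeRow("s3", "LB", "unviable"),
            PhenotypeRow("s4", "LB", "unviable"),
        )
    )
    pred = PredictionMatrix(
        (
            GrowthCall("s1", "LB", "viable", 1.0),
            GrowthCall("s2", "LB", "unviable", 0.0),
            GrowthCall("s3", "LB", "unviable", 0.0),
            GrowthCall("s4", "LB", "viable", 1.0),
        )
    )
    rep = score_predictions(pred, obs)
    assert (rep.cell("LB", "+").n, rep.cell("LB", "+").correct) == (2, 1)
    assert (rep.cell("LB", "-").n, rep.cell("LB", "-").correct) == (2, 1)
    assert (rep.overall.n, rep.overall.correct) == (4, 2)
    assert rep.misclassified == (("s2", "LB"), ("s4", "LB"))


def test_score_perfect_and_policies(bundle):
    matrix = batch_predict(bundle.truth_model, bundle.strain_defs(), bundle.media_list())
    rep = score_predictions(matrix, bundle.phenotypes)
    assert rep.overall.percent == 100.0
    for cell in rep.cells:
        assert cell.correct <= cell.n
    # slow observations count toward the viable row under the default policy
    rows = list(bundle.phenotypes.rows)
    target = next(i for i, r in enumerate(rows) if r.call == "viable")
    rows[target] = PhenotypeRow(rows[target].strain_id, rows[target].media_name, "slow")
    rep2 = score_predictions(matrix, PhenotypeTable(tuple(rows)))
    assert rep2.overall.percent == 100.0


def test_score_missing_prediction_errors(bundle):
    matrix = batch_predict(
        bundle.truth_model, {"master": ()}, bundle.media_list()
    )
    with pytest.raises(ValueError, match="missing predictions"):
        score_predictions(matrix, bundle.phenotypes)


def test_revision_notes_scored_against_revised_call():
    from phenorecon.fba_engine import GrowthCall, PredictionMatrix

    obs = PhenotypeTable(
        (PhenotypeRow("s1", "MM", "viable", "cross-feeding; revised to -"),)
    )
    pred = PredictionMatrix((GrowthCall("s1", "MM", "unviable", 0.0),))
    rep = score_predictions(pred, obs)
    assert rep.overall.correct == 1  # the revised call, not the raw one


def test_cobra_cross_check(bundle, tmp_path):
    """Independent implementation check: cobrapy reads our SBML and computes
    the same biomass optimum on the same medium."""
    cobra = pytest.importorskip("cobra")
    from phenorecon import write_model_sbml

    path = tmp_path / "m.xml"
    write_model_sbml(bundle.truth_model, path)
    cm = cobra.io.read_sbml_model(str(path))
    media = bundle.media_set["mm_A"]
    uptakes = media.uptake_dict()
    medium = {}
    for ex in cm.exchanges:
        met = list(ex.metabolites)[0].id
        medium[ex.id] = uptakes.get(met, 0.0)
    cm.medium = {k: v for k, v in medium.items() if v > 0}
    for ex_id, v in medium.items():
        if v == 0:
            cm.reactions.get_by_id(ex_id).lower_bound = 0.0
    ours = maximize_biomass(bundle.truth_model, media).objective_value
    theirs = cm.optimize().objective_value
    assert ours == pytest.approx(theirs, abs=1e-6)
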