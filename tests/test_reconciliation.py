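import itertools
import logging

import pytest

from phenorecon import (
    MediaFormulation,
    MetaboliteSpec,
    MetabolicModel,
    PhenotypeRow,
    PhenotypeTable,
    ReactionSpec,
    batch_predict,
    score_predictions,
)
from phenorecon.hypotheses import (
    ERROR_CLASSES,
    FN_MEDIA_ADD,
    FN_REACTION_ADD,
    FP_MAKE_IRREVERSIBLE,
    FP_MEDIA_REMOVE,
    FP_REACTION_REMOVE,
    Hypothesis,
    apply_hypothesis,
)
from phenorecon.reconciliation import (
    ReconcilePolicy,
    classify_failures,
    enumerate_hypotheses,
    evaluate_hypothesis,
    reconcile_greedy,
    summarize_ledger,
)
from phenorecon.synthetic_data import (
    CandidateDB,
    PlantSpec,
    candidate_db_from_truth,
    plant_errors,
)

logging.disable(logging.WARNING)


def tiny_fixture():
    """Master + two single-gene strains; two media; one pathway per strain.

    X-pathway (gene gx) feeds biomass on both media; on medium 'supp' the
    end product is also importable, so the gx knockout grows there only.
    """
    mets = (
        MetaboliteSpec("n_e", compartment="e"),
        MetaboliteSpec("n_c", compartment="c"),
        MetaboliteSpec("p_e", compartment="e"),
        MetaboliteSpec("p_c", compartment="c"),
    )
    rxns = (
        ReactionSpec.make("EX_n", {"n_e": -1.0}, is_exchange=True),
        ReactionSpec.make("EX_p", {"p_e": -1.0}, is_exchange=True),
        ReactionSpec.make("T_n", {"n_e": -1.0, "n_c": 1.0}),
        ReactionSpec.make("T_p", {"p_e": -1.0, "p_c": 1.0}),
        ReactionSpec.make("SYN", {"n_c": -1.0, "p_c": 1.0}, gpr="gx"),
        ReactionSpec.make("BIO", {"p_c": -1.0}, is_biomass=True),
    )
    model = MetabolicModel(
        id="tiny", genes=frozenset({"gx", "gy"}), metabolites=mets,
        reactions=rxns, biomass_reaction_id="BIO",
    )
    media = {
        "min": MediaFormulation.make("min", {"n_e": 10.0}),
        "supp": MediaFormulation.make("supp", {"n_e": 10.0, "p_e": 10.0}),
    }
    strains = {"master": (), "dx": ("gx",), "dy": ("gy",)}
    obs = PhenotypeTable(
        tuple(
            PhenotypeRow(s, m, c)
            for (s, m), c in {
                ("master", "min"): "viable",
                ("master", "supp"): "viable",
                ("dx", "min"): "unviable",
                ("dx", "supp"): "viable",
                ("dy", "min"): "viable",
                ("dy", "supp"): "viable",
            }.items()
        )
    )
    return model, media, strains, obs


def test_classify_failures():
    model, media, strains, obs = tiny_fixture()
    matrix = batch_predict(model, strains, list(media.values()))
    assert classify_failures(matrix, obs) == []  # fixture is self-consistent
    # break it: close the supplement transporter
    broken, _ = apply_hypothesis(
        model, media, Hypothesis.make(FP_REACTION_REMOVE, reaction="T_p")
    )
    matrix2 = batch_predict(broken, strains, list(media.values()))
    fails = classify_failures(matrix2, obs)
    assert ("dx", "supp", "FN") in fails


def test_evaluate_single_fix_delta():
    """A hypothesis fixing exactly its prompting phenotype: net +1."""
    model, media, strains, obs = tiny_fixture()
    corrupted = model.drop_reactions({"T_p"})  # dx loses its supp rescue
    db = CandidateDB(reactions={"T_p": model.reaction("T_p")},
                     metabolites={m.id: m for m in model.metabolites})
    hyp = Hypothesis.make(FN_REACTION_ADD, reaction_ids=("T_p",))
    delta = evaluate_hypothesis(corrupted, media, hyp, strains, obs, db)
    assert delta.corrected == (("dx", "supp"),)
    assert delta.broken == ()
    assert delta.net == 1


def test_evaluate_media_removal_net_zero():
    """Removing a media compound one strain relies on corrects one
    prediction but breaks another (the chorismate-in-LB pattern)."""
    mets = (
        MetaboliteSpec("a_e", compartment="e"),
        MetaboliteSpec("a_c", compartment="c"),
        MetaboliteSpec("x_e", compartment="e"),
        MetaboliteSpec("x_c", compartment="c"),
    )
    rxns = (
        ReactionSpec.make("EX_a", {"a_e": -1.0}, is_exchange=True),
        ReactionSpec.make("EX_x", {"x_e": -1.0}, is_exchange=True),
        ReactionSpec.make("T_a", {"a_e": -1.0, "a_c": 1.0}, gpr="gb"),
        ReactionSpec.make("T_x", {"x_e": -1.0, "x_c": 1.0}),
        ReactionSpec.make("SYN_x", {"a_c": -1.0, "x_c": 1.0}, gpr="ga"),
        ReactionSpec.make("BIO", {"x_c": -1.0}, is_biomass=True),
    )
    model = MetabolicModel(
        id="chor", genes=frozenset({"ga", "gb"}), metabolites=mets,
        reactions=rxns, biomass_reaction_id="BIO",
    )
    media = {"LB": MediaFormulation.make("LB", {"a_e": 10.0, "x_e": 10.0})}
    strains = {"master": (), "da": ("ga",), "db": ("gb",)}
    # in reality: da cannot use external x (unstable), db can
    obs = PhenotypeTable(
        (
            PhenotypeRow("master", "LB", "viable"),
            PhenotypeRow("da", "LB", "unviable"),
            PhenotypeRow("db", "LB", "viable"),
        )
    )
    hyp = Hypothesis.make(FP_MEDIA_REMOVE, media="LB", compound="x_e")
    delta = evaluate_hypothesis(model, media, hyp, strains, obs)
    assert set(delta.corrected) == {("da", "LB")}
    assert set(delta.broken) == {("db", "LB")}
    assert delta.net == 0


def test_evaluate_identity_edit():
    model, media, strains, obs = tiny_fixture()
    hyp = Hypothesis.make(FN_MEDIA_ADD, media="supp", compound="p_e", uptake=10.0)
    delta = evaluate_hypothesis(model, media, hyp, strains, obs)
    assert delta.corrected == () and delta.broken == ()


def test_enumerate_covers_planted_fix(bundle):
    """The hypothesis set for a planted missing-reaction failure contains
    the true reaction addition, and that addition is minimal."""
    cm, cmed, truth = plant_errors(bundle, PlantSpec.single(FN_REACTION_ADD, seed=3))
    db = candidate_db_from_truth(bundle.truth_model, cm)
    matrix = batch_predict(cm, bundle.strain_defs(), list(cmed.values()))
    failures = classify_failures(matrix, bundle.phenotypes)
    hyps = enumerate_hypotheses(cm, cmed, db, failures, bundle.strain_defs())
    ids = {h.id for h in hyps}
    assert truth[0].id in ids
    # minimality by exhaustive subset check over the (small) db
    added = dict(truth[0].payload)["reaction_ids"]
    assert len(added) == 1  # single planted deletion: singleton gapfill


def test_enumerate_class_vocabulary():
    assert len(ERROR_CLASSES) == 12
    assert len({c.split("_")[0] for c in ERROR_CLASSES}) == 2  # FP and FN halves


def test_greedy_single_planted_error_recovery(bundle):
    for seed in (5, 6):
        cm, cmed, truth = plant_errors(
            bundle, PlantSpec.single(FP_MAKE_IRREVERSIBLE, seed=seed)
        )
        db = candidate_db_from_truth(bundle.truth_model, cm)
        rm, rmed, ledger = reconcile_greedy(
            cm, cmed, db, bundle.strain_defs(), bundle.phenotypes
        )
        assert len(ledger.entries) == 1
        assert ledger.residual_failures == ()
        final = batch_predict(rm, bundle.strain_defs(), list(rmed.values()))
        truth_matrix = batch_predict(
            bundle.truth_model, bundle.strain_defs(), bundle.media_list()
        )
        # phenotype-equivalent recovery: identical predictions everywhere
        assert final.lookup().keys() == truth_matrix.lookup().keys()
        for k, call in final.lookup().items():
            assert call.predicted == truth_matrix.lookup()[k].predicted


def test_greedy_error_free_inputs_empty_ledger(bundle):
    db = candidate_db_from_truth(bundle.truth_model, bundle.truth_model)
    rm, rmed, ledger = reconcile_greedy(
        bundle.truth_model, bundle.media_set, db,
        bundle.strain_defs(), bundle.phenotypes,
    )
    assert ledger.entries == ()
    assert ledger.residual_failures == ()
    assert rm.reactions == bundle.truth_model.reactions


def test_greedy_monotone_improvement_multi_error(bundle):
    spec = PlantSpec(
        {FN_REACTION_ADD: 1, FP_MEDIA_REMOVE: 1, FP_MAKE_IRREVERSIBLE: 1}, seed=11
    )
    cm, cmed, truth = plant_errors(bundle, spec)
    db = candidate_db_from_truth(bundle.truth_model, cm)
    rm, rmed, ledger = reconcile_greedy(
        cm, cmed, db, bundle.strain_defs(), bundle.phenotypes
    )
    accs = [ledger.entries[0].accuracy_before] + [
        e.accuracy_after for e in ledger.entries
    ]
    assert all(b > a for a, b in zip(accs, accs[1:]))  # strictly increasing
    assert all(e.delta.net > 0 for e in ledger.entries)
    final = batch_predict(rm, bundle.strain_defs(), list(rmed.values()))
    assert score_predictions(final, bundle.phenotypes).overall.percent >= accs[0]


def test_ledger_replay_determinism(bundle):
    spec = PlantSpec({FN_REACTION_ADD: 1, FP_MEDIA_REMOVE: 1}, seed=13)
    cm, cmed, _ = plant_errors(bundle, spec)
    db = candidate_db_from_truth(bundle.truth_model, cm)
    args = (cm, cmed, db, bundle.strain_defs(), bundle.phenotypes)
    _, _, ledger1 = reconcile_greedy(*args)
    _, _, ledger2 = reconcile_greedy(*args)
    assert ledger1.to_json() == ledger2.to_json()  # byte-identical
    # replaying accepted edits reproduces each logged corrected set
    model, media = cm, dict(cmed)
    for entry in ledger1.entries:
        delta = evaluate_hypothesis(
            model, media, entry.hypothesis, bundle.strain_defs(),
            bundle.phenotypes, db,
        )
        assert delta.corrected == entry.delta.corrected
        model, media = apply_hypothesis(
            model, media, entry.hypothesis,
            db=db.reactions, db_metabolites=db.metabolites,
        )


def test_gapfill_minimality_bruteforce(bundle):
    """No proper subset of an accepted reaction-addition set restores growth
    of the prompting strain (checked exhaustively for sets of size <= 3)."""
    cm, cmed, _ = plant_errors(bundle, PlantSpec.single(FN_REACTION_ADD, seed=21))
    db = candidate_db_from_truth(bundle.truth_model, cm)
    _, _, ledger = reconcile_greedy(cm, cmed, db, bundle.strain_defs(), bundle.phenotypes)
    from phenorecon.fba_engine import simulate_deletion

    for entry in ledger.entries:
        if entry.hypothesis.error_class != FN_REACTION_ADD:
            continue
        added = dict(entry.hypothesis.payload)["reaction_ids"]
        assert len(added) <= 3
        strain, media_name = entry.hypothesis.provenance
        genes = dict(bundle.strain_defs())[strain]
        for k in range(len(added)):
            for subset in itertools.combinations(added, k):
                m2, _ = apply_hypothesis(
                    cm, cmed,
                    Hypothesis.make(FN_REACTION_ADD, reaction_ids=subset),
                    db=db.reactions, db_metabolites=db.metabolites,
                ) if subset else (cm, cmed)
                call = simulate_deletion(m2, genes, cmed[media_name])
                assert call.predicted == "unviable"


def test_conflicting_errors_stay_in_residuals():
    """Two contradictory observations on compositionally identical media
    cannot both be satisfied; the loop leaves the conflict in residuals
    instead of accepting a net-zero churn edit."""
    mets = (
        MetaboliteSpec("a_e", compartment="e"),
        MetaboliteSpec("b_e", compartment="e"),
        MetaboliteSpec("p_c", compartment="c"),
    )
    rxns = (
        ReactionSpec.make("EX_a", {"a_e": -1.0}, is_exchange=True),
        ReactionSpec.make("EX_b", {"b_e": -1.0}, is_exchange=True),
        ReactionSpec.make("U_a", {"a_e": -1.0, "p_c": 1.0}),
        ReactionSpec.make("U_b", {"b_e": -1.0, "p_c": 1.0}),
        ReactionSpec.make("BIO", {"p_c": -1.0}, is_biomass=True),
    )
    model = MetabolicModel(
        id="conflict", genes=frozenset({"gz"}), metabolites=mets,
        reactions=rxns, biomass_reaction_id="BIO",
    )
    media = {
        "M1": MediaFormulation.make("M1", {"a_e": 10.0, "b_e": 10.0}),
        "M2": MediaFormulation.make("M2", {"a_e": 10.0, "b_e": 10.0}),
    }
    strains = {"master": (), "dz": ("gz",)}
    obs = PhenotypeTable(
        (
            PhenotypeRow("master", "M1", "viable"),
            PhenotypeRow("master", "M2", "viable"),
            PhenotypeRow("dz", "M1", "viable"),
            PhenotypeRow("dz", "M2", "unviable"),  # regulatory effect
        )
    )
    rm, rmed, ledger = reconcile_greedy(model, media, CandidateDB(), strains, obs)
    assert ("dz", "M2", "FP") in ledger.residual_failures
    assert all(e.delta.net > 0 for e in ledger.entries)


def test_summarize_ledger(bundle):
    spec = PlantSpec({FN_REACTION_ADD: 1, FP_MEDIA_REMOVE: 1}, seed=2)
    cm, cmed, _ = plant_errors(bundle, spec)
    db = candidate_db_from_truth(bundle.truth_model, cm)
    _, _, ledger = reconcile_greedy(cm, cmed, db, bundle.strain_defs(), bundle.phenotypes)
    df = summarize_ledger(ledger)
    assert list(df.columns) == ["error_class", "description", "edits", "strains", "phenotypes"]
    assert len(df) == 12
    assert df["edits"].sum() == len(ledger.entries)
    for _, row in df.iterrows():
        assert row["strains"] <= row["phenotypes"]
    empty = summarize_ledger(type(ledger)((), ()))
    assert (empty[["edits", "strains", "phenotypes"]].to_numpy() == 0).all()
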