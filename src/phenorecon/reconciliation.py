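"""Global reconciliation of model prediction errors against phenotypes.

The procedure mirrors large-scale model-curation practice:

1. for every misclassified (strain, media) pair, propose typed correction
   hypotheses drawn from the 12 error classes, each restricted to edits that
   flip the prompting prediction when applied in isolation;
2. implement each hypothesis on a copy, repeat the phenotype simulations,
   and record which predictions it corrects and which it breaks;
3. greedily accept the hypothesis with the best net effect (corrected minus
   broken; ties broken toward fewer breaks, smaller edits, lexicographic
   id), re-simulate, and iterate until no hypothesis is net-beneficial;
4. export the surviving unviable predictions as proposed validation
   (rescue) experiments rather than as executable steps.

Acceptance requires a strictly positive net, so overall accuracy increases
monotonically and the loop terminates.

For speed, candidate edits are screened against one shared LP in which all
candidate-database reactions are present but closed: every non-biomass edit
is then a bound override or a GPR re-evaluation, solved from a warm basis.
The accepted edit is always re-applied through
:func:`~phenorecon.hypotheses.apply_hypothesis` on the real model.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .core import (
    BIG,
    CYTOSOL,
    SLOW,
    UNVIABLE,
    VIABLE,
    MediaFormulation,
    MetabolicModel,
    PhenotypeTable,
    ReactionSpec,
)
from .fba_engine import (
    DEFAULT_EPSILON,
    GrowthCall,
    PredictionMatrix,
    Simulator,
    batch_predict,
    disabled_reactions,
    score_predictions,
)
from .hypotheses import (
    CLASS_DESCRIPTIONS,
    ERROR_CLASSES,
    FN_BIOMASS_REMOVE,
    FN_GPR_ADJUST,
    FN_ISOZYME_ADD,
    FN_MAKE_REVERSIBLE,
    FN_MEDIA_ADD,
    FN_REACTION_ADD,
    FP_BIOMASS_ADD,
    FP_GPR_ADJUST,
    FP_ISOZYME_REMOVE,
    FP_MAKE_IRREVERSIBLE,
    FP_MEDIA_REMOVE,
    FP_REACTION_REMOVE,
    RELAXING_CLASSES,
    RESTRICTING_CLASSES,
    Hypothesis,
    MediaSet,
    apply_hypothesis,
)
from .synthetic_data import CandidateDB

FP = "FP"  # predicted viable, observed unviable
FN = "FN"  # predicted unviable, observed viable


@dataclass(frozen=True)
class ReconcilePolicy:
    epsilon: float = DEFAULT_EPSILON
    max_gapfill_size: int = 3
    slow_policy: str = VIABLE
    default_uptake: float = 10.0
    #: db size above which gapfilling switches from exhaustive subset
    #: enumeration to greedy open-all-then-prune
    brute_force_db_limit: int = 15


@dataclass(frozen=True)
class PredictionDelta:
    corrected: tuple[tuple[str, str], ...]
    broken: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if set(self.corrected) & set(self.broken):
            raise ValueError("corrected and broken overlap")

    @property
    def net(self) -> int:
        return len(self.corrected) - len(self.broken)


@dataclass(frozen=True)
class LedgerEntry:
    hypothesis: Hypothesis
    delta: PredictionDelta
    accuracy_before: float
    accuracy_after: float


@dataclass(frozen=True)
class EditLedger:
    entries: tuple[LedgerEntry, ...]
    residual_failures: tuple[tuple[str, str, str], ...]  # (strain, media, FP|FN)

    def class_counts(self) -> dict[str, int]:
        counts = {cls: 0 for cls in ERROR_CLASSES}
        for e in self.entries:
            counts[e.hypothesis.error_class] += 1
        return counts

    def to_json(self, path=None) -> str:
        payload = {
            "entries": [
                {
                    "hypothesis": e.hypothesis.to_dict(),
                    "corrected": [list(p) for p in e.delta.corrected],
                    "broken": [list(p) for p in e.delta.broken],
                    "net": e.delta.net,
                    "accuracy_before": e.accuracy_before,
                    "accuracy_after": e.accuracy_after,
                }
                for e in self.entries
            ],
            "residual_failures": [list(f) for f in self.residual_failures],
            "class_counts": self.class_counts(),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def summarize_ledger(ledger: EditLedger):
    """Per-class summary: edits, unique strains and (strain, media)
    phenotypes touched — the dual-count convention of curation summaries."""
    import pandas as pd

    rows = []
    for cls in ERROR_CLASSES:
        entries = [e for e in ledger.entries if e.hypothesis.error_class == cls]
        pairs = {p for e in entries for p in e.delta.corrected}
        strains = {s for s, _ in pairs}
        rows.append(
            (cls, CLASS_DESCRIPTIONS[cls], len(entries), len(strains), len(pairs))
        )
    return pd.DataFrame(
        rows, columns=["error_class", "description", "edits", "strains", "phenotypes"]
    )


def classify_failures(
    pred: PredictionMatrix, obs: PhenotypeTable, slow_policy: str = VIABLE
) -> list[tuple[str, str, str]]:
    """Misclassified attempted pairs as (strain, media, FP|FN)."""
    plook = pred.lookup()
    out = []
    for row in obs.attempted():
        observed = row.effective_call()
        if observed == SLOW:
            observed = slow_policy
        call = plook.get((row.strain_id, row.media_name))
        if call is None:
            raise ValueError(f"no prediction for {(row.strain_id, row.media_name)}")
        if call.predicted == observed:
            continue
        out.append(
            (row.strain_id, row.media_name, FP if call.predicted == VIABLE else FN)
        )
    return sorted(out)


# --------------------------------------------------------------------------
# compiled edits: every hypothesis as (media, bound-overrides, GPR change)
# against the extended screening model
# --------------------------------------------------------------------------


class _Screen:
    """Shared screening LP: the current model plus all db reactions closed.

    Any non-biomass hypothesis becomes a media substitution, a set of bound
    overrides and/or one reaction's GPR change, so candidate tests and delta
    evaluations run on a single warm-started LP.  Biomass-composition edits
    rebuild a dedicated Simulator.
    """

    def __init__(
        self,
        model: MetabolicModel,
        media_set: MediaSet,
        db: CandidateDB,
        strain_defs: Mapping[str, tuple[str, ...]],
        policy: ReconcilePolicy,
    ):
        self.model = model
        self.media_set = media_set
        self.db = db
        self.policy = policy
        self.strain_defs = {k: tuple(v) for k, v in strain_defs.items()}
        self.db_specs = {
            rid: spec for rid, spec in db.reactions.items() if not model.has_reaction(rid)
        }
        closed = [
            replace(spec, lower_bound=0.0, upper_bound=0.0)
            for rid, spec in sorted(self.db_specs.items())
        ]
        new_mets = [
            db.metabolites[m]
            for m in sorted(
                {
                    met
                    for spec in closed
                    for met, _ in spec.stoichiometry
                    if met in db.metabolites
                }
            )
        ]
        ext = model.add_reactions(closed, new_mets) if closed else model
        self.ext_model = ext
        self.sim = Simulator(ext)
        self._disabled_cache: dict[str, frozenset[str]] = {}
        self._bio_sims: dict[str, Simulator] = {}

    def base_disabled(self, strain: str) -> frozenset[str]:
        d = self._disabled_cache.get(strain)
        if d is None:
            d = disabled_reactions(self.model, self.strain_defs[strain])
            self._disabled_cache[strain] = d
        return d

    def media(self, name: str) -> MediaFormulation:
        return self.media_set[name]

    def predict_base(self, strain: str, media_name: str) -> bool:
        obj = self.sim.objective(self.media(media_name), self.base_disabled(strain))
        return obj > self.policy.epsilon

    # -- hypothesis compilation ------------------------------------------

    def predict_under(self, hyp: Hypothesis, strain: str, media_name: str) -> bool:
        """Viability of (strain, media) with ``hyp`` applied."""
        cls = hyp.error_class
        p = dict(hyp.payload)
        media = self.media(media_name)
        disabled = self.base_disabled(strain)
        overrides: dict[str, tuple[float, float]] = {}

        if cls in (FP_BIOMASS_ADD, FN_BIOMASS_REMOVE):
            sim = self._biomass_sim(hyp)
            obj = sim.objective(media, disabled_reactions(sim.model, self.strain_defs[strain]))
            return obj > self.policy.epsilon

        if cls in (FP_MEDIA_REMOVE, FN_MEDIA_ADD):
            if p["media"] != media_name:
                pass  # other media are untouched by this hypothesis
            elif cls == FP_MEDIA_REMOVE:
                media = media.without_compound(p["compound"])
            else:
                media = media.with_compound(
                    p["compound"], float(p.get("uptake", self.policy.default_uptake))
                )
        elif cls == FP_REACTION_REMOVE:
            overrides[p["reaction"]] = (0.0, 0.0)
        elif cls == FN_REACTION_ADD:
            knocked = frozenset(self.strain_defs[strain])
            for rid in p["reaction_ids"]:
                spec = self.db_specs.get(rid)
                if spec is None:  # already present in the model
                    continue
                if spec.gpr.is_empty or spec.gpr.evaluate(knocked):
                    overrides[rid] = (spec.lower_bound, spec.upper_bound)
        elif cls == FP_MAKE_IRREVERSIBLE:
            rxn = self.model.reaction(p["reaction"])
            if p.get("side", "lower") == "lower":
                overrides[rxn.id] = (0.0, rxn.upper_bound)
            else:
                overrides[rxn.id] = (rxn.lower_bound, 0.0)
        elif cls == FN_MAKE_REVERSIBLE:
            rxn = self.model.reaction(p["reaction"])
            if p.get("side", "lower") == "lower":
                overrides[rxn.id] = (-BIG, rxn.upper_bound)
            else:
                overrides[rxn.id] = (rxn.lower_bound, BIG)
        elif cls in (FP_GPR_ADJUST, FN_GPR_ADJUST, FP_ISOZYME_REMOVE, FN_ISOZYME_ADD):
            rid = p["reaction"]
            rxn = self.model.reaction(rid)
            edited = _edited_gpr(rxn, hyp)
            knocked = frozenset(self.strain_defs[strain]) & self.model.genes
            now_disabled = not edited.is_empty and not edited.evaluate(knocked)
            disabled = (disabled | {rid}) if now_disabled else (disabled - {rid})
        else:  # pragma: no cover
            raise ValueError(cls)

        obj = self.sim.objective(media, disabled, overrides)
        return obj > self.policy.epsilon

    def _biomass_sim(self, hyp: Hypothesis) -> Simulator:
        key = hyp.id
        sim = self._bio_sims.get(key)
        if sim is None:
            m2, _ = apply_hypothesis(self.model, self.media_set, hyp)
            sim = Simulator(m2)
            self._bio_sims[key] = sim
        return sim


def _edited_gpr(rxn: ReactionSpec, hyp: Hypothesis):
    p = dict(hyp.payload)
    cls = hyp.error_class
    if cls == FP_GPR_ADJUST:
        return rxn.gpr.and_gene(p["gene"])
    if cls == FN_GPR_ADJUST:
        return rxn.gpr.without_genes(set(p["genes"]))
    if cls == FN_ISOZYME_ADD:
        return rxn.gpr.or_gene(p["gene"])
    # FP_ISOZYME_REMOVE
    from .gpr import GPRRule, parse_gpr

    target = parse_gpr(str(p["branch"])).canonical().root
    for b in rxn.gpr.top_or_branches():
        if GPRRule(b).canonical().root == target:
            return rxn.gpr.without_branch(b)
    raise ValueError(f"branch {p['branch']!r} absent from {rxn.id}")


# --------------------------------------------------------------------------
# step (i): hypothesis generation
# --------------------------------------------------------------------------


def enumerate_hypotheses(
    model: MetabolicModel,
    media_set: MediaSet,
    db: CandidateDB,
    failures: Sequence[tuple[str, str, str]],
    strain_defs: Mapping[str, tuple[str, ...]],
    policy: ReconcilePolicy = ReconcilePolicy(),
    screen: Optional[_Screen] = None,
) -> list[Hypothesis]:
    """Propose typed corrections for each failing (strain, media, FP|FN).

    Every returned hypothesis flips its prompting prediction when applied in
    isolation; the list is deduplicated and deterministically ordered.
    """
    if screen is None:
        screen = _Screen(model, media_set, db, strain_defs, policy)
    if any(t == FN for _, _, t in failures) and not db.reactions:
        import logging

        logging.getLogger(__name__).warning(
            "FN failures present but candidate db is empty; "
            "reaction-addition hypotheses unavailable"
        )

    seen: dict[str, Hypothesis] = {}

    def admit(hyp: Hypothesis, strain: str, media_name: str) -> None:
        if hyp.id in seen:
            return
        if screen.predict_under(hyp, strain, media_name) == (
            dict_type[(strain, media_name)] == FN
        ):
            seen[hyp.id] = hyp

    dict_type = {(s, m): t for s, m, t in failures}

    for strain, media_name, ftype in failures:
        prov = (strain, media_name)
        knocked = frozenset(strain_defs[strain]) & model.genes
        disabled = screen.base_disabled(strain)
        media = media_set[media_name]
        if ftype == FN:
            _fn_candidates(
                model, media, db, strain, media_name, knocked, disabled,
                policy, screen, admit, prov,
            )
        else:
            _fp_candidates(
                model, media, strain, media_name, knocked, disabled,
                policy, screen, admit, prov,
            )
    return [seen[k] for k in sorted(seen)]


def _fn_candidates(
    model, media, db, strain, media_name, knocked, disabled, policy, screen, admit, prov
):
    # single media-compound additions (importable compounds absent from medium)
    importable = sorted(
        r.stoichiometry[0][0]
        for r in model.exchange_reactions()
        if len(r.stoichiometry) == 1
    )
    present = media.compound_ids()
    for cid in importable:
        if cid not in present:
            admit(
                Hypothesis.make(
                    FN_MEDIA_ADD, prov, media=media_name, compound=cid,
                    uptake=policy.default_uptake,
                ),
                strain,
                media_name,
            )
    # single reversibility relaxations
    for r in model.reactions:
        if r.is_exchange or r.is_biomass or r.id in disabled:
            continue
        if r.lower_bound == 0.0 and r.upper_bound > 0.0:
            admit(
                Hypothesis.make(FN_MAKE_REVERSIBLE, prov, reaction=r.id, side="lower"),
                strain, media_name,
            )
        elif r.upper_bound == 0.0 and r.lower_bound < 0.0:
            admit(
                Hypothesis.make(FN_MAKE_REVERSIBLE, prov, reaction=r.id, side="upper"),
                strain, media_name,
            )
    # isozyme additions from the homolog-candidate table
    for gene, rid in db.isozyme_candidates:
        if model.has_reaction(rid) and gene not in knocked and rid in disabled:
            admit(
                Hypothesis.make(FN_ISOZYME_ADD, prov, reaction=rid, gene=gene),
                strain, media_name,
            )
    # GPR relaxations: drop the knocked genes from a disabled reaction's rule
    for rid in sorted(disabled):
        genes = tuple(sorted(model.reaction(rid).gpr.genes() & knocked))
        if genes:
            admit(
                Hypothesis.make(FN_GPR_ADJUST, prov, reaction=rid, genes=genes),
                strain, media_name,
            )
    # biomass-component removals
    for met, coeff in model.biomass.stoichiometry:
        if coeff < 0:
            admit(
                Hypothesis.make(FN_BIOMASS_REMOVE, prov, compound=met),
                strain, media_name,
            )
    # minimal reaction-addition sets (gapfilling)
    for rid_set in _gapfill_sets(db, strain, media_name, policy, screen):
        admit(
            Hypothesis.make(FN_REACTION_ADD, prov, reaction_ids=rid_set),
            strain, media_name,
        )


def _gapfill_sets(
    db: CandidateDB, strain: str, media_name: str, policy: ReconcilePolicy, screen: _Screen
) -> list[tuple[str, ...]]:
    """Minimal db subsets whose addition restores growth of the prompting
    strain: exhaustive for small dbs, greedy prune-from-all otherwise."""
    rids = sorted(screen.db_specs)
    if not rids:
        return []

    def grows(subset: tuple[str, ...]) -> bool:
        hyp = Hypothesis.make(FN_REACTION_ADD, reaction_ids=subset)
        return screen.predict_under(hyp, strain, media_name)

    found: list[tuple[str, ...]] = []
    if len(rids) <= policy.brute_force_db_limit:
        for size in range(1, min(policy.max_gapfill_size, len(rids)) + 1):
            for combo in itertools.combinations(rids, size):
                if any(set(f) <= set(combo) for f in found):
                    continue  # superset of a known minimal set
                if grows(combo):
                    found.append(combo)
        return found
    # greedy fallback: open everything, then drop reactions one by one
    if not grows(tuple(rids)):
        return []
    keep = list(rids)
    for rid in rids:
        trial = tuple(r for r in keep if r != rid)
        if trial and grows(trial):
            keep = list(trial)
    if len(keep) <= policy.max_gapfill_size:
        return [tuple(keep)]
    return []


def _fp_candidates(
    model, media, strain, media_name, knocked, disabled, policy, screen, admit, prov
):
    # single reaction removals and reversibility tightenings
    for r in model.reactions:
        if r.is_biomass or r.id in disabled:
            continue
        if not r.is_exchange:
            admit(
                Hypothesis.make(FP_REACTION_REMOVE, prov, reaction=r.id),
                strain, media_name,
            )
        if r.reversible and not r.is_exchange:
            admit(
                Hypothesis.make(FP_MAKE_IRREVERSIBLE, prov, reaction=r.id, side="lower"),
                strain, media_name,
            )
    # media-compound removals
    for cid in sorted(media.compound_ids()):
        admit(
            Hypothesis.make(FP_MEDIA_REMOVE, prov, media=media_name, compound=cid),
            strain, media_name,
        )
    # isozyme removals: prune one OR alternative that survives the knockout
    from .gpr import GPRRule

    for r in model.reactions:
        branches = r.gpr.top_or_branches()
        if len(branches) < 2 or r.id in disabled:
            continue
        for b in branches:
            admit(
                Hypothesis.make(
                    FP_ISOZYME_REMOVE, prov, reaction=r.id,
                    branch=GPRRule(b).to_string(),
                ),
                strain, media_name,
            )
    # GPR restrictions: require one knocked gene on a still-active reaction
    if knocked:
        anchor = sorted(knocked)[0]  # genes of one interval are co-deleted,
        # so any of them is phenotype-equivalent here
        for r in model.reactions:
            if r.is_biomass or r.is_exchange or r.id in disabled:
                continue
            admit(
                Hypothesis.make(FP_GPR_ADJUST, prov, reaction=r.id, gene=anchor),
                strain, media_name,
            )
    # biomass-component additions
    in_biomass = {m for m, c in model.biomass.stoichiometry if c < 0}
    for met in model.metabolites:
        if met.compartment == CYTOSOL and met.id not in in_biomass:
            admit(
                Hypothesis.make(FP_BIOMASS_ADD, prov, compound=met.id),
                strain, media_name,
            )


# --------------------------------------------------------------------------
# step (ii): global delta of one hypothesis
# --------------------------------------------------------------------------


def evaluate_hypothesis(
    model: MetabolicModel,
    media_set: MediaSet,
    hyp: Hypothesis,
    strain_defs: Mapping[str, tuple[str, ...]],
    obs: PhenotypeTable,
    db: Optional[CandidateDB] = None,
    policy: ReconcilePolicy = ReconcilePolicy(),
    current: Optional[PredictionMatrix] = None,
    screen: Optional[_Screen] = None,
) -> PredictionDelta:
    """Corrected and broken (strain, media) pairs relative to the current
    predictions; the input model/media are never modified.

    Purely relaxing edits can only flip unviable predictions (and purely
    restricting edits viable ones), so only the at-risk half of the matrix
    is re-simulated; biomass edits are re-simulated in full.
    """
    db = db if db is not None else CandidateDB()
    if screen is None:
        screen = _Screen(model, media_set, db, strain_defs, policy)
    if current is None:
        current = batch_predict(
            model, strain_defs, list(media_set.values()),
            epsilon=policy.epsilon, simulator=screen.sim,
        )
    plook = current.lookup()

    cls = hyp.error_class
    p = dict(hyp.payload)
    target_media = p.get("media")

    corrected, broken = [], []
    for row in obs.attempted():
        pair = (row.strain_id, row.media_name)
        if pair not in plook:
            continue
        if target_media is not None and row.media_name != target_media:
            continue
        before = plook[pair].predicted
        if cls in RELAXING_CLASSES and before == VIABLE:
            continue
        if cls in RESTRICTING_CLASSES and before == UNVIABLE:
            continue
        after = VIABLE if screen.predict_under(hyp, *pair) else UNVIABLE
        if after == before:
            continue
        observed = row.effective_call()
        if observed == SLOW:
            observed = policy.slow_policy
        was_ok = before == observed
        now_ok = after == observed
        if now_ok and not was_ok:
            corrected.append(pair)
        elif was_ok and not now_ok:
            broken.append(pair)
    return PredictionDelta(tuple(sorted(corrected)), tuple(sorted(broken)))


# --------------------------------------------------------------------------
# step (iii): greedy acceptance loop
# --------------------------------------------------------------------------


def reconcile_greedy(
    model: MetabolicModel,
    media_set: MediaSet,
    db: CandidateDB,
    strain_defs: Mapping[str, tuple[str, ...]],
    obs: PhenotypeTable,
    policy: ReconcilePolicy = ReconcilePolicy(),
    max_iterations: int = 200,
) -> tuple[MetabolicModel, MediaSet, EditLedger]:
    """Iteratively accept the best net-positive hypothesis until none remains.

    Returns the refined model, refined media set, and the full ledger with
    per-acceptance deltas and the residual unexplained failures.
    """
    media_set = dict(media_set)
    entries: list[LedgerEntry] = []

    for _ in range(max_iterations):
        screen = _Screen(model, media_set, db, strain_defs, policy)
        current = batch_predict(
            model, strain_defs, list(media_set.values()),
            epsilon=policy.epsilon, simulator=screen.sim,
        )
        report = score_predictions(current, obs, policy.slow_policy)
        failures = classify_failures(current, obs, policy.slow_policy)
        if not failures:
            break
        hyps = enumerate_hypotheses(
            model, media_set, db, failures, strain_defs, policy, screen=screen
        )
        best: Optional[tuple] = None
        for hyp in hyps:
            delta = evaluate_hypothesis(
                model, media_set, hyp, strain_defs, obs, db, policy,
                current=current, screen=screen,
            )
            if delta.net <= 0:
                continue
            key = (-delta.net, len(delta.broken), hyp.edit_size, hyp.id)
            if best is None or key < best[0]:
                best = (key, hyp, delta)
        if best is None:
            break
        _, hyp, delta = best
        model, media_set = apply_hypothesis(
            model, media_set, hyp, db=db.reactions, db_metabolites=db.metabolites
        )
        after_matrix = batch_predict(
            model, strain_defs, list(media_set.values()), epsilon=policy.epsilon
        )
        after_report = score_predictions(after_matrix, obs, policy.slow_policy)
        entries.append(
            LedgerEntry(
                hypothesis=hyp,
                delta=delta,
                accuracy_before=report.overall.percent,
                accuracy_after=after_report.overall.percent,
            )
        )

    final = batch_predict(
        model, strain_defs, list(media_set.values()), epsilon=policy.epsilon
    )
    residual = tuple(classify_failures(final, obs, policy.slow_policy))
    return model, media_set, EditLedger(tuple(entries), residual)


def proposed_validation_experiments(
    ledger: EditLedger,
    model: MetabolicModel,
    media_set: MediaSet,
    strain_defs: Mapping[str, tuple[str, ...]],
    policy: ReconcilePolicy = ReconcilePolicy(),
):
    """Residual unviable predictions exported as suggested rescue
    experiments (the wet-lab confirmation step is not executable here)."""
    import pandas as pd

    rows = [
        (strain, media, ftype, "propose media-supplementation rescue")
        for strain, media, ftype in ledger.residual_failures
    ]
    return pd.DataFrame(rows, columns=["strain", "media", "error_type", "suggestion"])
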