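"""Typed model/media edits: the 12 error classes and their application.

Every prediction error is either a false positive (model predicts growth,
strain is unviable) or a false negative (model predicts no growth, strain is
viable), and each admits six classes of corrective edit: biomass-composition
changes, GPR adjustments, isozyme additions/removals, reaction
additions/removals, reversibility changes and media-compound changes.

A :class:`Hypothesis` is one concrete edit with a deterministic id;
:func:`apply_hypothesis` applies it functionally to a (model, media set)
pair, leaving the originals untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .core import BIG, MediaFormulation, MetabolicModel, MetaboliteSpec, ReactionSpec
from .gpr import parse_gpr

# error-class identifiers; FP_* fix false positives (restrict the model),
# FN_* fix false negatives (relax the model)
FP_BIOMASS_ADD = "FP_biomass_add"
FN_BIOMASS_REMOVE = "FN_biomass_remove"
FP_GPR_ADJUST = "FP_gpr_adjust"
FN_GPR_ADJUST = "FN_gpr_adjust"
FP_ISOZYME_REMOVE = "FP_isozyme_remove"
FN_ISOZYME_ADD = "FN_isozyme_add"
FP_REACTION_REMOVE = "FP_reaction_remove"
FN_REACTION_ADD = "FN_reaction_add"
FP_MAKE_IRREVERSIBLE = "FP_make_irreversible"
FN_MAKE_REVERSIBLE = "FN_make_reversible"
FP_MEDIA_REMOVE = "FP_media_remove"
FN_MEDIA_ADD = "FN_media_add"

ERROR_CLASSES = (
    FP_BIOMASS_ADD,
    FN_BIOMASS_REMOVE,
    FP_GPR_ADJUST,
    FN_GPR_ADJUST,
    FP_ISOZYME_REMOVE,
    FN_ISOZYME_ADD,
    FP_REACTION_REMOVE,
    FN_REACTION_ADD,
    FP_MAKE_IRREVERSIBLE,
    FN_MAKE_REVERSIBLE,
    FP_MEDIA_REMOVE,
    FN_MEDIA_ADD,
)

#: classes that only relax the model (predictions can flip unviable->viable
#: but never the reverse); their FP_ counterparts only restrict.  Biomass
#: edits are in neither set: they are re-evaluated in full.
RELAXING_CLASSES = frozenset(
    {FN_GPR_ADJUST, FN_ISOZYME_ADD, FN_REACTION_ADD, FN_MAKE_REVERSIBLE, FN_MEDIA_ADD}
)
RESTRICTING_CLASSES = frozenset(
    {FP_GPR_ADJUST, FP_ISOZYME_REMOVE, FP_REACTION_REMOVE, FP_MAKE_IRREVERSIBLE, FP_MEDIA_REMOVE}
)

#: human-readable descriptions for ledger summary tables
CLASS_DESCRIPTIONS = {
    FP_BIOMASS_ADD: "Missing metabolites in biomass (compound added to biomass)",
    FN_BIOMASS_REMOVE: "Extra metabolites in biomass (compound removed from biomass)",
    FP_GPR_ADJUST: "Incorrect reaction GPR (requirement added)",
    FN_GPR_ADJUST: "Incorrect reaction GPR (requirement removed)",
    FP_ISOZYME_REMOVE: "Incorrect isozymes in GPR (isozyme removed)",
    FN_ISOZYME_ADD: "Isozymes missing from GPR (isozyme added)",
    FP_REACTION_REMOVE: "Extra pathways in model (reaction removed)",
    FN_REACTION_ADD: "Missing pathways in model (reactions added)",
    FP_MAKE_IRREVERSIBLE: "Under-constrained reversibility (made irreversible)",
    FN_MAKE_REVERSIBLE: "Over-constrained reversibility (made reversible)",
    FP_MEDIA_REMOVE: "Extra nutrients in media (compound removed)",
    FN_MEDIA_ADD: "Missing nutrients in media (compound added)",
}

#: stoichiometric coefficient for biomass-component additions; imposes the
#: dependency without distorting growth yields
BIOMASS_COMPONENT_COEFF = 1e-4


class EditError(ValueError):
    """An edit referenced an absent entity or could not be applied."""


@dataclass(frozen=True)
class Hypothesis:
    """One typed correction with the (strain, media) failure that prompted it."""

    error_class: str
    payload: tuple[tuple[str, object], ...]
    provenance: tuple[str, str] = ("", "")

    def __post_init__(self):
        if self.error_class not in ERROR_CLASSES:
            raise EditError(f"unknown error class {self.error_class!r}")

    @staticmethod
    def make(error_class: str, provenance: tuple[str, str] = ("", ""), **payload) -> "Hypothesis":
        canon = tuple(
            (k, tuple(v) if isinstance(v, (list, tuple, set, frozenset)) else v)
            for k, v in sorted(payload.items())
        )
        return Hypothesis(error_class, canon, provenance)

    @property
    def id(self) -> str:
        parts = []
        for k, v in self.payload:
            if isinstance(v, tuple):
                v = "+".join(str(x) for x in sorted(map(str, v)))
            parts.append(f"{k}={v}")
        return f"{self.error_class}:" + ",".join(parts)

    def get(self, key: str):
        for k, v in self.payload:
            if k == key:
                return v
        raise KeyError(key)

    @property
    def edit_size(self) -> int:
        rxns = dict(self.payload).get("reaction_ids")
        return len(rxns) if isinstance(rxns, tuple) else 1

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "error_class": self.error_class,
            "payload": {k: list(v) if isinstance(v, tuple) else v for k, v in self.payload},
            "provenance": list(self.provenance),
        }


MediaSet = dict[str, MediaFormulation]


def apply_hypothesis(
    model: MetabolicModel,
    media_set: MediaSet,
    hyp: Hypothesis,
    db: Optional[Mapping[str, ReactionSpec]] = None,
    db_metabolites: Optional[Mapping[str, MetaboliteSpec]] = None,
) -> tuple[MetabolicModel, MediaSet]:
    """Apply one edit to copies of the model/media set.

    ``db`` supplies the full reaction specs for reaction-addition
    hypotheses (payload stores only their ids so ledgers stay serializable).
    """
    cls = hyp.error_class
    p = dict(hyp.payload)

    if cls in (FP_MEDIA_REMOVE, FN_MEDIA_ADD):
        name = p["media"]
        if name not in media_set:
            raise EditError(f"unknown medium {name!r}")
        media = media_set[name]
        if cls == FP_MEDIA_REMOVE:
            if p["compound"] not in media.compound_ids():
                raise EditError(f"{p['compound']} not in medium {name}")
            media = media.without_compound(p["compound"])
        else:
            media = media.with_compound(p["compound"], float(p.get("uptake", 10.0)))
        new_set = dict(media_set)
        new_set[name] = media
        return model, new_set

    new_set = media_set
    if cls == FP_REACTION_REMOVE:
        rid = p["reaction"]
        if not model.has_reaction(rid):
            raise EditError(f"unknown reaction {rid!r}")
        model = model.drop_reactions({rid})
    elif cls == FN_REACTION_ADD:
        rids = p["reaction_ids"]
        if db is None:
            raise EditError("reaction-addition hypothesis needs a candidate db")
        missing = [r for r in rids if r not in db]
        if missing:
            raise EditError(f"reactions absent from db: {missing}")
        specs = [db[r] for r in rids if not model.has_reaction(r)]
        known = {m.id for m in model.metabolites}
        new_mets = []
        for spec in specs:
            for met, _ in spec.stoichiometry:
                if met not in known:
                    if db_metabolites and met in db_metabolites:
                        new_mets.append(db_metabolites[met])
                    else:
                        new_mets.append(MetaboliteSpec(met))
                    known.add(met)
        model = model.add_reactions(specs, new_mets)
    elif cls in (FP_MAKE_IRREVERSIBLE, FN_MAKE_REVERSIBLE):
        rid = p["reaction"]
        if not model.has_reaction(rid):
            raise EditError(f"unknown reaction {rid!r}")
        rxn = model.reaction(rid)
        side = p.get("side", "lower")
        if cls == FP_MAKE_IRREVERSIBLE:
            # tighten one side; never flips the primary direction
            if side == "lower":
                rxn = replace(rxn, lower_bound=0.0)
            else:
                rxn = replace(rxn, upper_bound=0.0)
        else:
            if side == "lower":
                rxn = replace(rxn, lower_bound=-BIG)
            else:
                rxn = replace(rxn, upper_bound=BIG)
        model = model.replace_reaction(rxn)
    elif cls in (FP_GPR_ADJUST, FN_GPR_ADJUST, FP_ISOZYME_REMOVE, FN_ISOZYME_ADD):
        rid = p["reaction"]
        if not model.has_reaction(rid):
            raise EditError(f"unknown reaction {rid!r}")
        rxn = model.reaction(rid)
        if cls == FP_GPR_ADJUST:
            rxn = replace(rxn, gpr=rxn.gpr.and_gene(p["gene"]))
        elif cls == FN_GPR_ADJUST:
            rxn = replace(rxn, gpr=rxn.gpr.without_genes(set(p["genes"])))
        elif cls == FN_ISOZYME_ADD:
            rxn = replace(rxn, gpr=rxn.gpr.or_gene(p["gene"]))
        else:  # FP_ISOZYME_REMOVE: payload names the branch canonically
            target = parse_gpr(str(p["branch"])).canonical().root
            branches = {b: b for b in rxn.gpr.top_or_branches()}
            match = None
            for b in branches:
                from .gpr import GPRRule

                if GPRRule(b).canonical().root == target:
                    match = b
                    break
            if match is None:
                raise EditError(f"branch {p['branch']!r} not found in GPR of {rid}")
            rxn = replace(rxn, gpr=rxn.gpr.without_branch(match))
        model = model.replace_reaction(rxn)
    elif cls in (FP_BIOMASS_ADD, FN_BIOMASS_REMOVE):
        bio = model.biomass
        stoich = bio.stoich_dict()
        comp = p["compound"]
        if cls == FP_BIOMASS_ADD:
            if not any(m.id == comp for m in model.metabolites):
                raise EditError(f"unknown compound {comp!r}")
            coeff = float(p.get("coeff", BIOMASS_COMPONENT_COEFF))
            stoich[comp] = stoich.get(comp, 0.0) - coeff
        else:
            if comp not in stoich:
                raise EditError(f"{comp!r} is not a biomass component")
            del stoich[comp]
        bio = replace(bio, stoichiometry=tuple(sorted(stoich.items())))
        model = model.replace_reaction(bio)
    else:  # pragma: no cover
        raise EditError(f"unhandled class {cls}")
    return model, new_set
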