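"""Rescue-metabolite search for knockouts predicted unviable.

An unviable prediction comes bundled with a metabolic explanation: the
knockout severed the biosynthesis of something growth requires.  Adding the
missing compound(s) to the medium should then restore growth — a testable
hypothesis.  This module scans single compounds, then pairs, then triples
(supersets of known rescues pruned) for minimal sets whose addition flips
the FBA verdict to viable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .core import MediaFormulation, MetabolicModel
from .fba_engine import DEFAULT_EPSILON, Simulator, disabled_reactions
from .synthetic_data import CandidateDB


class RescueError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateSupplement:
    compound_id: str
    #: db reactions that must be added to the model before this compound can
    #: be taken up (a deliberate model edit, reported but never silent)
    via_db_reactions: tuple[str, ...] = ()

    @property
    def requires_model_edit(self) -> bool:
        return bool(self.via_db_reactions)


@dataclass(frozen=True)
class RescueSet:
    strain_id: str
    media_name: str
    compounds: frozenset[str]
    predicted_objective_after: float
    requires_model_edit: bool = False

    def to_dict(self) -> dict:
        return {
            "strain": self.strain_id,
            "media": self.media_name,
            "compounds": sorted(self.compounds),
            "objective": self.predicted_objective_after,
            "requires_model_edit": self.requires_model_edit,
        }


def candidate_supplements(
    model: MetabolicModel,
    db: Optional[CandidateDB] = None,
    include_db_transporters: bool = False,
) -> list[CandidateSupplement]:
    """Compounds that could be added to a medium, deterministic order.

    By default: every extracellular compound with an exchange reaction.
    With ``include_db_transporters``, compounds importable only through
    candidate-db reactions are appended, flagged with the reactions needed.
    """
    out = [
        CandidateSupplement(r.stoichiometry[0][0])
        for r in sorted(model.exchange_reactions(), key=lambda r: r.id)
        if len(r.stoichiometry) == 1
    ]
    seen = {c.compound_id for c in out}
    if include_db_transporters and db is not None:
        # exchange reactions the db can contribute, by compound
        db_exchange = {
            spec.stoichiometry[0][0]: rid
            for rid, spec in db.reactions.items()
            if len(spec.stoichiometry) == 1
        }
        for rid in sorted(db.reactions):
            spec = db.reactions[rid]
            if len(spec.stoichiometry) < 2:
                continue
            ext = [
                m
                for m, coeff in spec.stoichiometry
                if coeff < 0
                and m in db.metabolites
                and db.metabolites[m].compartment == "e"
            ]
            for met in ext:
                if met in seen:
                    continue
                via = [rid]
                if model.exchange_for(met) is None:
                    if met not in db_exchange:
                        continue  # no uptake route even with the db
                    via.append(db_exchange[met])
                out.append(CandidateSupplement(met, tuple(sorted(via))))
                seen.add(met)
    out.sort(key=lambda c: (c.requires_model_edit, c.compound_id))
    return out


def find_rescues(
    model: MetabolicModel,
    gene_set: Iterable[str],
    media: MediaFormulation,
    candidates: Optional[Sequence[CandidateSupplement]] = None,
    max_size: int = 3,
    epsilon: float = DEFAULT_EPSILON,
    supplement_uptake: float = 10.0,
    strain_id: str = "strain",
    db: Optional[CandidateDB] = None,
) -> list[RescueSet]:
    """All minimal compound sets (size <= ``max_size``) whose addition to
    ``media`` makes the knockout viable.

    Errors if the strain is already viable ("no rescue needed").  Compounds
    already in the medium are skipped.  Sets containing a flagged candidate
    temporarily add its db transport reactions and are marked as requiring a
    model edit.
    """
    if max_size < 1:
        raise RescueError("max_size must be >= 1")
    gene_set = tuple(gene_set)
    if candidates is None:
        candidates = candidate_supplements(model, db)
    by_id = {c.compound_id: c for c in candidates}
    needed_rxns = sorted({r for c in candidates for r in c.via_db_reactions})
    work_model = model
    if needed_rxns:
        if db is None:
            raise RescueError("flagged candidates need the candidate db")
        from dataclasses import replace as _replace

        specs = [db.reactions[r] for r in needed_rxns]
        # present but closed until a flagged candidate is under test
        closed = [_replace(s, lower_bound=0.0, upper_bound=0.0) for s in specs]
        known = {x.id for x in model.metabolites}
        new_ids = sorted(
            {met for s in specs for met, _ in s.stoichiometry if met not in known}
        )
        mets = [db.metabolites[m] for m in new_ids if m in db.metabolites]
        work_model = model.add_reactions(closed, mets)
    sim = Simulator(work_model)
    disabled = disabled_reactions(work_model, gene_set)

    base = sim.objective(media, disabled)
    if base > epsilon:
        raise RescueError(
            f"strain {strain_id} is already viable on {media.name}: no rescue needed"
        )

    present = media.compound_ids()
    pool = [c for c in candidates if c.compound_id not in present]

    def test(combo: tuple[CandidateSupplement, ...]) -> float:
        m = media
        for c in combo:
            m = m.with_compound(c.compound_id, supplement_uptake)
        overrides = {}
        for c in combo:
            for rid in c.via_db_reactions:
                spec = db.reactions[rid]
                if len(spec.stoichiometry) == 1 and spec.stoichiometry[0][0] == c.compound_id:
                    # a db-supplied exchange: open uptake for the supplement
                    overrides[rid] = (-supplement_uptake, spec.upper_bound)
                else:
                    overrides[rid] = (spec.lower_bound, spec.upper_bound)
        return sim.objective(m, disabled, overrides)

    found: list[RescueSet] = []
    found_sets: list[frozenset[str]] = []
    for size in range(1, min(max_size, len(pool)) + 1):
        for combo in itertools.combinations(pool, size):
            ids = frozenset(c.compound_id for c in combo)
            if any(f <= ids for f in found_sets):
                continue  # superset of a known rescue: not minimal
            obj = test(combo)
            if obj > epsilon:
                found_sets.append(ids)
                found.append(
                    RescueSet(
                        strain_id=strain_id,
                        media_name=media.name,
                        compounds=ids,
                        predicted_objective_after=obj,
                        requires_model_edit=any(c.requires_model_edit for c in combo),
                    )
                )
    found.sort(key=lambda r: (len(r.compounds), tuple(sorted(r.compounds))))
    return found


def rescue_report(
    rescues: Sequence[RescueSet],
    obs_confirmations: Optional[Mapping[tuple[str, str], str]] = None,
    lost_functions: Optional[Mapping[str, str]] = None,
):
    """Tabulate rescues: strain, media, lost function, compounds, predicted
    growth, and experimental confirmation ("(+)", "(−)", or "(untested)")."""
    import pandas as pd

    obs_confirmations = obs_confirmations or {}
    lost_functions = lost_functions or {}
    rows = []
    for r in rescues:
        key = (r.strain_id, r.media_name)
        rows.append(
            (
                r.strain_id,
                r.media_name,
                lost_functions.get(r.strain_id, ""),
                "+".join(sorted(r.compounds)),
                "(+)",
                obs_confirmations.get(key, "(untested)"),
                "model edit required" if r.requires_model_edit else "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "strain", "media", "lost_function", "rescue_compounds",
            "predicted_growth", "confirmation", "notes",
        ],
    )


def rescues_to_json(rescues: Sequence[RescueSet], path=None) -> str:
    text = json.dumps([r.to_dict() for r in rescues], indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
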