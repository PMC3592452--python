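"""Core domain types: metabolic model, media, genome, intervals, phenotypes.

These are deliberately plain containers.  The stoichiometric matrix rows are
the metabolites (mass balance around each internal compound), the columns are
the reactions; flux bounds encode reversibility and directionality; GPR rules
tie reactions to the genes whose loss disables them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .gpr import GPRRule

#: default magnitude used for "unbounded" fluxes (mmol/gDW/h scale)
BIG = 1000.0

#: compartment tokens
CYTOSOL = "c"
EXTRACELLULAR = "e"

VIABLE = "viable"
SLOW = "slow"
UNVIABLE = "unviable"
NOT_ATTEMPTED = "not_attempted"
CALLS = (VIABLE, SLOW, UNVIABLE, NOT_ATTEMPTED)


class ModelValidationError(ValueError):
    """A model or table violated a structural invariant; loading fails loudly."""


@dataclass(frozen=True)
class MetaboliteSpec:
    id: str
    name: str = ""
    compartment: str = CYTOSOL


@dataclass(frozen=True)
class ReactionSpec:
    """One column of S with its bounds and gene rule.

    Exchange reactions have a single (extracellular) metabolite with
    coefficient -1: positive flux secretes the compound, negative flux takes
    it up, so media impose lower bounds on exchanges.
    """

    id: str
    stoichiometry: tuple[tuple[str, float], ...]
    lower_bound: float = 0.0
    upper_bound: float = BIG
    gpr: GPRRule = field(default_factory=GPRRule)
    is_exchange: bool = False
    is_biomass: bool = False
    name: str = ""

    def stoich_dict(self) -> dict[str, float]:
        return dict(self.stoichiometry)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound

    @staticmethod
    def make(
        id: str,
        stoichiometry: dict[str, float],
        lower_bound: float = 0.0,
        upper_bound: float = BIG,
        gpr: GPRRule | str = "",
        **kw,
    ) -> "ReactionSpec":
        from .gpr import parse_gpr

        if isinstance(gpr, str):
            gpr = parse_gpr(gpr)
        stoich = tuple(sorted(stoichiometry.items()))
        return ReactionSpec(
            id=id,
            stoichiometry=stoich,
            lower_bound=lower_bound,
            upper_bound=upper_bound,
            gpr=gpr,
            **kw,
        )


@dataclass(frozen=True)
class MetabolicModel:
    id: str
    genes: frozenset[str]
    metabolites: tuple[MetaboliteSpec, ...]
    reactions: tuple[ReactionSpec, ...]
    biomass_reaction_id: str
    #: GPR genes cited but absent from ``genes``; treated as always present
    orphan_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        self.validate()

    # -- lookups ----------------------------------------------------------

    def metabolite(self, met_id: str) -> MetaboliteSpec:
        return self._met_index()[met_id]

    def reaction(self, rxn_id: str) -> ReactionSpec:
        return self._rxn_index()[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index()

    def _met_index(self) -> dict[str, MetaboliteSpec]:
        idx = self.__dict__.get("_mets")
        if idx is None:
            idx = {m.id: m for m in self.metabolites}
            object.__setattr__(self, "_mets", idx)
        return idx

    def _rxn_index(self) -> dict[str, ReactionSpec]:
        idx = self.__dict__.get("_rxns")
        if idx is None:
            idx = {r.id: r for r in self.reactions}
            object.__setattr__(self, "_rxns", idx)
        return idx

    @property
    def biomass(self) -> ReactionSpec:
        return self.reaction(self.biomass_reaction_id)

    def exchange_reactions(self) -> tuple[ReactionSpec, ...]:
        return tuple(r for r in self.reactions if r.is_exchange)

    def exchange_for(self, compound_id: str) -> Optional[ReactionSpec]:
        """The exchange reaction draining/feeding an extracellular compound."""
        idx = self.__dict__.get("_exch")
        if idx is None:
            idx = {}
            for r in self.reactions:
                if r.is_exchange and len(r.stoichiometry) == 1:
                    idx[r.stoichiometry[0][0]] = r
            object.__setattr__(self, "_exch", idx)
        return idx.get(compound_id)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        met_set = set(met_ids)
        missing = sorted(
            {m for r in self.reactions for m, _ in r.stoichiometry if m not in met_set}
        )
        if missing:
            raise ModelValidationError(f"reactions reference missing metabolites: {missing}")
        biomass_flags = [r.id for r in self.reactions if r.is_biomass]
        if biomass_flags != [self.biomass_reaction_id]:
            raise ModelValidationError(
                f"exactly one biomass reaction required; flagged={biomass_flags}, "
                f"designated={self.biomass_reaction_id!r}"
            )
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id}: lower_bound {r.lower_bound} > upper_bound {r.upper_bound}"
                )
            if not all(map(math.isfinite, (r.lower_bound, r.upper_bound))):
                raise ModelValidationError(f"reaction {r.id}: non-finite bound")

    def gpr_orphans(self) -> frozenset[str]:
        cited = frozenset(g for r in self.reactions for g in r.gpr.genes())
        return cited - self.genes

    # -- functional edits (all return new models) -------------------------

    def with_reactions(self, reactions: Iterable[ReactionSpec]) -> "MetabolicModel":
        return replace(self, reactions=tuple(reactions))

    def replace_reaction(self, rxn: ReactionSpec) -> "MetabolicModel":
        return self.with_reactions(rxn if r.id == rxn.id else r for r in self.reactions)

    def add_reactions(
        self,
        reactions: Iterable[ReactionSpec],
        new_metabolites: Iterable[MetaboliteSpec] = (),
    ) -> "MetabolicModel":
        known = {m.id for m in self.metabolites}
        mets = list(self.metabolites) + [m for m in new_metabolites if m.id not in known]
        return replace(
            self, metabolites=tuple(mets), reactions=self.reactions + tuple(reactions)
        )

    def drop_reactions(self, rxn_ids: set[str] | frozenset[str]) -> "MetabolicModel":
        if self.biomass_reaction_id in rxn_ids:
            raise ModelValidationError("refusing to drop the biomass reaction")
        return self.with_reactions(r for r in self.reactions if r.id not in rxn_ids)


def remove_gene_reactions(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    """Remove every reaction whose GPR cites any of ``genes``.

    This is removal by *association*, used to build the master-strain model
    (mirroring a marker lesion such as a tryptophan-pathway gene deletion):
    a gene cited only in an OR branch still takes its reaction out, unlike a
    knockout simulation.
    """
    gene_set = set(genes)
    doomed = {r.id for r in model.reactions if r.gpr.genes() & gene_set}
    if model.biomass_reaction_id in doomed:
        raise ModelValidationError(
            "biomass reaction carries target genes; refusing association removal"
        )
    return model.drop_reactions(doomed)


@dataclass(frozen=True)
class MediaFormulation:
    """Named growth condition: extracellular compounds with max uptake rates."""

    name: str
    compounds: tuple[tuple[str, float], ...]  # compound id -> max uptake (>=0)
    unlimited_set: frozenset[str] = frozenset()

    def __post_init__(self):
        ids = [c for c, _ in self.compounds]
        if len(ids) != len(set(ids)):
            dupes = sorted({c for c in ids if ids.count(c) > 1})
            raise ModelValidationError(f"media {self.name}: duplicate compounds {dupes}")
        for c, u in self.compounds:
            if u < 0:
                raise ModelValidationError(f"media {self.name}: negative uptake for {c}")

    @staticmethod
    def make(
        name: str,
        compounds: dict[str, float],
        unlimited: Iterable[str] = (),
    ) -> "MediaFormulation":
        unlimited = frozenset(unlimited)
        limited = tuple(sorted((c, u) for c, u in compounds.items() if c not in unlimited))
        return MediaFormulation(name, limited, unlimited)

    def uptake_dict(self) -> dict[str, float]:
        d = dict(self.compounds)
        d.update({c: BIG for c in self.unlimited_set})
        return d

    def compound_ids(self) -> frozenset[str]:
        return frozenset(dict(self.compounds)) | self.unlimited_set

    def with_compound(self, compound_id: str, uptake: float) -> "MediaFormulation":
        d = dict(self.compounds)
        d[compound_id] = uptake
        return MediaFormulation(self.name, tuple(sorted(d.items())), self.unlimited_set)

    def without_compound(self, compound_id: str) -> "MediaFormulation":
        d = dict(self.compounds)
        d.pop(compound_id, None)
        return MediaFormulation(
            self.name, tuple(sorted(d.items())), self.unlimited_set - {compound_id}
        )


@dataclass(frozen=True)
class GenomeAnnotation:
    """Gene order along the chromosome plus the preserved-gene subset.

    Preserved genes (essential or operationally required) are never deleted;
    the maximal runs of non-preserved genes between them are the candidate
    deletion intervals.
    """

    gene_order: tuple[str, ...]
    preserved: frozenset[str]

    def __post_init__(self):
        if len(set(self.gene_order)) != len(self.gene_order):
            raise ModelValidationError("gene_order contains duplicates")
        extra = self.preserved - set(self.gene_order)
        if extra:
            raise ModelValidationError(f"preserved genes not in genome: {sorted(extra)}")


@dataclass(frozen=True)
class Interval:
    """A contiguous run of non-preserved genes deleted as one block."""

    id: str
    gene_ids: tuple[str, ...]

    def __post_init__(self):
        if not self.gene_ids:
            raise ModelValidationError(f"interval {self.id} is empty")


@dataclass(frozen=True)
class PhenotypeRow:
    strain_id: str
    media_name: str
    call: str
    revision_note: str = ""

    def effective_call(self) -> str:
        """The call to score against; a 'revised to X' note overrides it."""
        note = self.revision_note.lower()
        if "revised to" in note:
            tail = note.split("revised to", 1)[1].strip().split()[0].strip(".,;")
            mapping = {
                "+": VIABLE,
                "viable": VIABLE,
                "slow": SLOW,
                "-": UNVIABLE,
                "−": UNVIABLE,
                "unviable": UNVIABLE,
            }
            if tail in mapping:
                return mapping[tail]
        return self.call


@dataclass(frozen=True)
class PhenotypeTable:
    rows: tuple[PhenotypeRow, ...]

    def __post_init__(self):
        keys = [(r.strain_id, r.media_name) for r in self.rows]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ModelValidationError(f"duplicate (strain, media) rows: {dupes}")
        bad = sorted({r.call for r in self.rows} - set(CALLS))
        if bad:
            raise ModelValidationError(f"unknown phenotype calls: {bad}")

    def lookup(self) -> dict[tuple[str, str], PhenotypeRow]:
        return {(r.strain_id, r.media_name): r for r in self.rows}

    def attempted(self) -> tuple[PhenotypeRow, ...]:
        return tuple(r for r in self.rows if r.call != NOT_ATTEMPTED)
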