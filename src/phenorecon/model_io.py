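"""Read/write models (SBML), media, intervals and phenotype tables (TSV).

SBML support targets what constraint-based pipelines actually need: Level 3
with the fbc package (gene-product associations, flux-bound parameters,
objective) on write, and on read additionally the legacy Level 2 dialect in
which gene associations live in notes fields as ``GENE_ASSOCIATION: ...``
strings — the dialect of the era's published genome-scale models.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Optional

import libsbml
import pandas as pd

from .core import (
    BIG,
    CALLS,
    EXTRACELLULAR,
    Interval,
    GenomeAnnotation,
    MediaFormulation,
    MetaboliteSpec,
    MetabolicModel,
    ModelValidationError,
    PhenotypeRow,
    PhenotypeTable,
    ReactionSpec,
)
from .gpr import GPRRule, parse_gpr

__all__ = [
    "read_model_sbml",
    "write_model_sbml",
    "read_media_table",
    "write_media_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_intervals_table",
    "write_intervals_table",
    "parse_gpr",
]

#: default biomass-detection pattern when no fbc objective is declared
BIOMASS_PATTERN = r"(biomass|\bbio\b|^bio\d*$)"

#: default uptake (flux units) assigned to limited media compounds whose
#: recipes give concentrations rather than fluxes; growth yes/no calls are
#: invariant to a common scale on all uptakes
DEFAULT_UPTAKE = 10.0

_SBML_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str) -> str:
    """SBML ids must match [A-Za-z_][A-Za-z0-9_]*."""
    s = _SBML_BAD.sub("_", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = "_" + s
    return s


# --------------------------------------------------------------------------
# SBML
# --------------------------------------------------------------------------


def write_model_sbml(model: MetabolicModel, path: str) -> None:
    """Emit SBML Level 3 + fbc v2 readable by :func:`read_model_sbml`.

    Reactions with empty GPRs carry no gene-product association; the biomass
    reaction is declared as the (maximized) fbc objective.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites}) or ["c"]
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(_sid(comp))
        c.setConstant(True)
        c.setSize(1.0)

    for met in model.metabolites:
        s = sbml_model.createSpecies()
        s.setId(_sid(met.id))
        s.setName(met.name or met.id)
        s.setCompartment(_sid(met.compartment))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    for gene in sorted(model.genes | model.orphan_genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sid(gene))
        gp.setLabel(gene)

    bounds_seen: dict[float, str] = {}

    def bound_param(value: float) -> str:
        pid = bounds_seen.get(value)
        if pid is None:
            pid = f"fb_{len(bounds_seen)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bounds_seen[value] = pid
        return pid

    gene_label = {_sid(g): g for g in sorted(model.genes | model.orphan_genes)}

    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId(_sid(rxn.id))
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for met, coeff in rxn.stoichiometry:
            if coeff < 0:
                sr = r.createReactant()
            else:
                sr = r.createProduct()
            sr.setSpecies(_sid(met))
            sr.setStoichiometry(abs(coeff))
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            assoc = rplug.createGeneProductAssociation()
            # fbc accepts infix association strings directly
            assoc.setAssociation(_gpr_to_fbc_string(rxn.gpr), True)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(_sid(model.biomass_reaction_id))
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    # id sanitization must stay reversible for round-trips
    for met in model.metabolites:
        if _sid(met.id) != met.id:
            raise ModelValidationError(f"metabolite id {met.id!r} is not SBML-safe")
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")
    del gene_label


def _gpr_to_fbc_string(gpr: GPRRule) -> str:
    return gpr.to_string()


def read_model_sbml(
    path: str,
    biomass_pattern: str = BIOMASS_PATTERN,
) -> MetabolicModel:
    """Load an SBML model with flux bounds and gene associations.

    Accepts fbc constructs (preferred) or Level 2 conventions: kinetic-law
    parameters ``LOWER_BOUND``/``UPPER_BOUND`` and notes-field
    ``GENE_ASSOCIATION:`` strings.  The biomass reaction is the fbc objective
    if declared, otherwise the unique reaction whose id or name matches
    ``biomass_pattern`` (case-insensitive).
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ModelValidationError(f"SBML parse errors in {path}: {msgs}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"{path}: no model element")
    mplug = sbml_model.getPlugin("fbc")

    metabolites = []
    boundary = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        metabolites.append(
            MetaboliteSpec(sp.getId(), sp.getName() or "", sp.getCompartment() or "c")
        )
    met_ids = {m.id for m in metabolites}

    gene_by_id: dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_by_id[gp.getId()] = gp.getLabel() or gp.getId()

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    reactions = []
    unresolved: list[str] = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            sr = rx.getReactant(k)
            if sr.getSpecies() in boundary:
                continue
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for k in range(rx.getNumProducts()):
            sr = rx.getProduct(k)
            if sr.getSpecies() in boundary:
                continue
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        bad = [m for m in stoich if m not in met_ids]
        if bad:
            unresolved.extend(f"{rx.getId()}:{m}" for m in bad)
            continue

        lb, ub = None, None
        rplug = rx.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = params.get(rplug.getLowerFluxBound())
            ub = params.get(rplug.getUpperFluxBound())
        if lb is None or ub is None:
            kl = rx.getKineticLaw()
            if kl is not None:
                for k in range(kl.getNumParameters()):
                    p = kl.getParameter(k)
                    if p.getId() == "LOWER_BOUND":
                        lb = p.getValue()
                    elif p.getId() == "UPPER_BOUND":
                        ub = p.getValue()
        if lb is None:
            lb = -BIG if rx.getReversible() else 0.0
        if ub is None:
            ub = BIG
        lb = max(lb, -BIG) if math.isfinite(lb) else -BIG
        ub = min(ub, BIG) if math.isfinite(ub) else BIG

        gpr = GPRRule(None)
        if rplug is not None and rplug.getGeneProductAssociation() is not None:
            assoc = rplug.getGeneProductAssociation().getAssociation()
            text = libsbml.FbcAssociation.toInfix(assoc) if assoc is not None else ""
            text = text.replace("(", " ( ").replace(")", " ) ")
            gpr = parse_gpr(text)
            # map gene-product ids back to labels
            mapping = {g: gene_by_id.get(g, g) for g in gpr.genes()}
            if any(k != v for k, v in mapping.items()):
                gpr = _rename_genes(gpr, mapping)
        else:
            notes = rx.getNotesString() or ""
            m = re.search(r"GENE_ASSOCIATION:\s*([^<]*)", notes)
            if m:
                gpr = parse_gpr(m.group(1).strip())

        is_exchange = len(stoich) == 1 or rx.getId().startswith(("EX_", "R_EX_"))
        reactions.append(
            ReactionSpec.make(
                rx.getId(),
                stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=gpr,
                is_exchange=is_exchange,
                name=rx.getName() or "",
            )
        )
    if unresolved:
        raise ModelValidationError(f"unresolvable metabolite references: {unresolved}")

    biomass_id = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        objective = mplug.getActiveObjective() or mplug.getObjective(0)
        if objective is not None and objective.getNumFluxObjectives() > 0:
            biomass_id = objective.getFluxObjective(0).getReaction()
    if biomass_id is None:
        pat = re.compile(biomass_pattern, re.IGNORECASE)
        cands = [r.id for r in reactions if pat.search(r.id) or pat.search(r.name)]
        if not cands:
            raise ModelValidationError(
                f"{path}: no fbc objective and no reaction matching {biomass_pattern!r}"
            )
        biomass_id = cands[0]

    reactions = [
        ReactionSpec(
            id=r.id,
            stoichiometry=r.stoichiometry,
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            gpr=r.gpr,
            is_exchange=r.is_exchange and r.id != biomass_id,
            is_biomass=(r.id == biomass_id),
            name=r.name,
        )
        for r in reactions
    ]

    declared_genes = frozenset(gene_by_id.values())
    cited = frozenset(g for r in reactions for g in r.gpr.genes())
    genes = declared_genes | cited if declared_genes else cited
    orphans = cited - genes

    return MetabolicModel(
        id=sbml_model.getId() or "model",
        genes=genes,
        metabolites=tuple(metabolites),
        reactions=tuple(reactions),
        biomass_reaction_id=biomass_id,
        orphan_genes=orphans,
    )


def _rename_genes(gpr: GPRRule, mapping: dict[str, str]) -> GPRRule:
    from .gpr import BoolNode, GeneNode, Node

    def rec(node: Node) -> Node:
        if isinstance(node, GeneNode):
            return GeneNode(mapping.get(node.gene, node.gene))
        return BoolNode(node.op, tuple(rec(c) for c in node.children))

    return GPRRule(rec(gpr.root)) if gpr.root is not None else gpr


# --------------------------------------------------------------------------
# TSV tables: media, phenotypes, intervals
# --------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_media_table(path, name: Optional[str] = None) -> MediaFormulation:
    """Read a medium from TSV columns ``compound_id, name, max_uptake``.

    A blank ``max_uptake`` means unlimited (water, protons, inorganic ions).
    Negative uptakes and duplicate compounds are errors.
    """
    df = _read_tsv(path)
    required = {"compound_id", "max_uptake"}
    if not required <= set(df.columns):
        raise ModelValidationError(f"{path}: media table needs columns {sorted(required)}")
    compounds: dict[str, float] = {}
    unlimited: set[str] = set()
    seen: set[str] = set()
    for _, row in df.iterrows():
        cid = row["compound_id"].strip()
        if not cid:
            continue
        if cid in seen:
            raise ModelValidationError(f"{path}: duplicate compound {cid}")
        seen.add(cid)
        raw = str(row["max_uptake"]).strip()
        if raw == "" or raw.lower() in ("inf", "unlimited"):
            unlimited.add(cid)
        else:
            u = float(raw)
            if u < 0:
                raise ModelValidationError(f"{path}: negative uptake for {cid}")
            compounds[cid] = u
    media_name = name if name is not None else _stem(path)
    return MediaFormulation.make(media_name, compounds, unlimited)


def write_media_table(media: MediaFormulation, path) -> None:
    rows = [(c, "", f"{u:g}") for c, u in media.compounds]
    rows += [(c, "", "") for c in sorted(media.unlimited_set)]
    pd.DataFrame(rows, columns=["compound_id", "name", "max_uptake"]).to_csv(
        path, sep="\t", index=False
    )


_CALL_ALIASES = {
    "+": "viable",
    "viable": "viable",
    "slow": "slow",
    "-": "unviable",
    "−": "unviable",
    "unviable": "unviable",
    "na": "not_attempted",
    "not_attempted": "not_attempted",
}


def read_phenotype_table(path) -> PhenotypeTable:
    """Read observed viability calls from TSV ``strain, media, call[, note]``.

    Calls map '+' -> viable, 'slow' -> slow, '-' -> unviable; unknown tokens
    and duplicate (strain, media) pairs are errors.  Notes (e.g. cross-feeding
    revisions) are preserved verbatim.
    """
    df = _read_tsv(path)
    if not {"strain", "media", "call"} <= set(df.columns):
        raise ModelValidationError(f"{path}: phenotype table needs strain, media, call")
    rows = []
    for _, row in df.iterrows():
        raw = row["call"].strip().lower()
        if raw not in _CALL_ALIASES:
            raise ModelValidationError(f"{path}: unknown call token {row['call']!r}")
        rows.append(
            PhenotypeRow(
                strain_id=row["strain"].strip(),
                media_name=row["media"].strip(),
                call=_CALL_ALIASES[raw],
                revision_note=str(row.get("note", "")).strip(),
            )
        )
    return PhenotypeTable(tuple(rows))


def write_phenotype_table(table: PhenotypeTable, path) -> None:
    pd.DataFrame(
        [(r.strain_id, r.media_name, r.call, r.revision_note) for r in table.rows],
        columns=["strain", "media", "call", "note"],
    ).to_csv(path, sep="\t", index=False)


def read_intervals_table(path) -> tuple[Interval, ...]:
    """Read intervals from TSV ``interval_id, gene_id, order`` (one row per
    gene, order giving the within-interval position)."""
    df = _read_tsv(path)
    if not {"interval_id", "gene_id", "order"} <= set(df.columns):
        raise ModelValidationError(f"{path}: intervals table needs interval_id, gene_id, order")
    grouped: dict[str, list[tuple[int, str]]] = {}
    for _, row in df.iterrows():
        grouped.setdefault(row["interval_id"].strip(), []).append(
            (int(row["order"]), row["gene_id"].strip())
        )
    out = []
    for iid in sorted(grouped):
        genes = tuple(g for _, g in sorted(grouped[iid]))
        out.append(Interval(iid, genes))
    return tuple(out)


def write_intervals_table(intervals: Iterable[Interval], path) -> None:
    rows = [
        (iv.id, g, k) for iv in intervals for k, g in enumerate(iv.gene_ids)
    ]
    pd.DataFrame(rows, columns=["interval_id", "gene_id", "order"]).to_csv(
        path, sep="\t", index=False
    )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
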