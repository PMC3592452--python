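"""Ground-truth toy bundles: genome, network, media, intervals, phenotypes.

The generator emulates the design of a systematic interval-deletion study on
a prototrophic bacterium: linear biosynthetic pathways turn imported
nutrients into biomass precursors, a fraction of pathway steps carry isozyme
pairs, a pair of interchangeable nitrogen sources distinguishes two minimal
media, and precursor supplements distinguish rich from defined media.
Preserved genes (transporters plus a random essential-process fill) delimit
the contiguous deletion intervals, and observed phenotypes are the FBA
verdicts of the truth network itself, optionally perturbed by seeded noise.

:func:`plant_errors` corrupts a truth bundle with the inverse of any of the
12 correction classes, yielding a model whose prediction errors are known
exactly together with the ledger of true fixes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import (
    BIG,
    CYTOSOL,
    EXTRACELLULAR,
    UNVIABLE,
    VIABLE,
    GenomeAnnotation,
    Interval,
    MediaFormulation,
    MetaboliteSpec,
    MetabolicModel,
    PhenotypeRow,
    PhenotypeTable,
    ReactionSpec,
)
from .fba_engine import DEFAULT_EPSILON, PredictionMatrix, Simulator, batch_predict
from .gpr import parse_gpr
from .hypotheses import (
    BIOMASS_COMPONENT_COEFF,
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
    Hypothesis,
    MediaSet,
    apply_hypothesis,
)

DEFAULT_UPTAKE = 10.0


class SyntheticDataError(RuntimeError):
    pass


@dataclass(frozen=True)
class TruthBundle:
    genome: GenomeAnnotation
    truth_model: MetabolicModel
    media_set: MediaSet
    intervals: tuple[Interval, ...]
    phenotypes: PhenotypeTable
    seed: int

    def strain_defs(self, include_master: bool = True) -> dict[str, tuple[str, ...]]:
        defs: dict[str, tuple[str, ...]] = {}
        if include_master:
            defs["master"] = ()
        for iv in self.intervals:
            defs[iv.id] = iv.gene_ids
        return defs

    def media_list(self) -> list[MediaFormulation]:
        return list(self.media_set.values())


@dataclass(frozen=True)
class PlantSpec:
    counts: dict = field(default_factory=dict)  # error class -> count
    seed: int = 0

    def __post_init__(self):
        bad = sorted(set(self.counts) - set(ERROR_CLASSES))
        if bad:
            raise SyntheticDataError(f"unknown error classes: {bad}")
        if any(v < 0 for v in self.counts.values()):
            raise SyntheticDataError("counts must be >= 0")

    @staticmethod
    def single(error_class: str, seed: int = 0) -> "PlantSpec":
        return PlantSpec({error_class: 1}, seed)


def define_intervals(
    genome: GenomeAnnotation, exclude_singletons: bool = False
) -> tuple[Interval, ...]:
    """Maximal runs of contiguous non-preserved genes, in genome order.

    ``exclude_singletons`` drops single-gene runs, mirroring study designs
    that skip genes already known individually dispensable.
    """
    intervals = []
    run: list[str] = []
    counter = 0

    def flush():
        nonlocal counter, run
        if run and not (exclude_singletons and len(run) == 1):
            counter += 1
            intervals.append(Interval(f"i{counter:04d}", tuple(run)))
        run = []

    for gene in genome.gene_order:
        if gene in genome.preserved:
            flush()
        else:
            run.append(gene)
    flush()
    return tuple(intervals)


def make_truth_bundle(
    n_genes: int = 60,
    n_pathways: int = 6,
    isozyme_rate: float = 0.2,
    preserved_fraction: float = 0.3,
    seed: int = 42,
    chain_len: int = 2,
    uptake: float = DEFAULT_UPTAKE,
) -> TruthBundle:
    """Build a self-consistent toy study: truth network, four media, interval
    map, and noise-free phenotypes (the truth model's own FBA verdicts).

    Media roles mirror a rich complex medium (all precursor supplements it
    can carry), a defined rich medium (fewer supplements), and two minimal
    media differing only in nitrogen source.
    """
    if n_genes < 20:
        raise SyntheticDataError("n_genes must be >= 20")
    if not (0 <= isozyme_rate <= 1):
        raise SyntheticDataError("isozyme_rate must be in [0, 1]")
    if n_pathways < 3:
        raise SyntheticDataError("n_pathways must be >= 3")
    rng = np.random.default_rng(seed)

    P = n_pathways
    n_suppl = max(1, P - 2)  # pathways with an importable precursor
    n_def = max(1, n_suppl // 2)  # subset supplemented in the defined rich medium

    mets: dict[str, MetaboliteSpec] = {}
    rxns: list[ReactionSpec] = []
    roles: list[str] = []  # gene roles, mapped to names later

    def met(mid: str, comp: str) -> str:
        if mid not in mets:
            mets[mid] = MetaboliteSpec(mid, compartment=comp)
        return mid

    def exchange(cid: str) -> None:
        rxns.append(
            ReactionSpec.make(
                f"EX_{cid[:-2]}", {cid: -1.0}, lower_bound=0.0, upper_bound=BIG,
                is_exchange=True,
            )
        )

    gene_slots: dict[str, str] = {}  # role -> placeholder token

    def gene(role: str) -> str:
        token = f"@{role}"
        roles.append(role)
        gene_slots[role] = token
        return token

    # nutrient import + biosynthetic chain per pathway
    chain_rxn_genes: list[tuple[str, str]] = []  # (reaction id, role) for isozyme draws
    for j in range(P):
        nut_e = met(f"nut{j}_e", EXTRACELLULAR)
        nut_c = met(f"nut{j}_c", CYTOSOL)
        exchange(nut_e)
        rxns.append(
            ReactionSpec.make(
                f"T_nut{j}", {nut_e: -1.0, nut_c: 1.0}, gpr=gene(f"t_nut{j}")
            )
        )
        upstream = nut_c
        for step in range(chain_len):
            last = step == chain_len - 1
            product = met(f"prec{j}_c" if last else f"int{j}_{step}_c", CYTOSOL)
            rid = f"R{j}_{step}"
            role = f"enz{j}_{step}"
            rxns.append(
                ReactionSpec.make(rid, {upstream: -1.0, product: 1.0}, gpr=gene(role))
            )
            chain_rxn_genes.append((rid, role))
            upstream = product

    # precursor supplements (importable biosynthesis end-products)
    for j in range(n_suppl):
        prec_e = met(f"prec{j}_e", EXTRACELLULAR)
        prec_c = f"prec{j}_c"
        exchange(prec_e)
        rxns.append(
            ReactionSpec.make(
                f"T_prec{j}", {prec_e: -1.0, prec_c: 1.0}, gpr=gene(f"t_prec{j}")
            )
        )

    # two interchangeable nitrogen sources
    for tag in ("A", "B"):
        am_e = met(f"am{tag}_e", EXTRACELLULAR)
        am_c = met(f"am{tag}_c", CYTOSOL)
        exchange(am_e)
        rxns.append(
            ReactionSpec.make(
                f"T_am{tag}", {am_e: -1.0, am_c: 1.0}, gpr=gene(f"t_am{tag}")
            )
        )
        rxns.append(
            ReactionSpec.make(
                f"ASSIM_{tag}", {am_c: -1.0, met("nprec_c", CYTOSOL): 1.0},
                gpr=gene(f"assim_{tag}"),
            )
        )

    # spontaneous precursor interconversions (reversible in truth) chain the
    # supplemented pathways together: losing one biosynthesis route is
    # covered by its neighbours, so only joint losses are lethal
    for j in range(n_suppl - 1):
        rxns.append(
            ReactionSpec.make(
                f"CONV_{j}_{j+1}",
                {f"prec{j}_c": -1.0, f"prec{j+1}_c": 1.0},
                lower_bound=-BIG,
            )
        )

    # irreversible overflow of the last (unsupplemented) pathway's precursor
    # to an excretable waste compound present in the rich medium
    waste_c = met("waste_c", CYTOSOL)
    waste_e = met("waste_e", EXTRACELLULAR)
    rxns.append(ReactionSpec.make("OVERFLOW", {f"prec{P-1}_c": -1.0, waste_c: 1.0}))
    rxns.append(
        ReactionSpec.make("T_waste", {waste_c: -1.0, waste_e: 1.0}, lower_bound=-BIG)
    )
    exchange(waste_e)

    # biomass drains one unit of every precursor plus the nitrogen precursor
    bio_stoich = {f"prec{j}_c": -1.0 for j in range(P)}
    bio_stoich["nprec_c"] = -1.0
    rxns.append(
        ReactionSpec.make("BIOMASS", bio_stoich, is_biomass=True, name="biomass")
    )

    # isozymes: each chain step independently gains an OR-partner; at least
    # one isozyme reaction is guaranteed whenever the rate is positive
    iso_flags = rng.random(len(chain_rxn_genes)) < isozyme_rate
    if isozyme_rate > 0 and not iso_flags.any():
        iso_flags[0] = True
    iso_partner: dict[str, str] = {}
    for flag, (rid, role) in zip(iso_flags, chain_rxn_genes):
        if flag:
            iso_partner[rid] = gene(f"iso_{role}")

    # filler genes representing non-metabolic functions
    n_filler = n_genes - len(roles)
    if n_filler < 4:
        raise SyntheticDataError(
            f"n_genes={n_genes} too small for {len(roles)} metabolic roles"
        )
    for k in range(n_filler):
        gene(f"filler{k}")

    # genomic placement: shuffle roles onto positional gene names
    order = rng.permutation(len(roles))
    gene_names = [f"g{i:03d}" for i in range(len(roles))]
    role_to_name = {roles[order[i]]: gene_names[i] for i in range(len(roles))}

    def resolve(token: str) -> str:
        return role_to_name[token[1:]] if token.startswith("@") else token

    resolved_rxns = []
    for r in rxns:
        gpr_text = r.gpr.to_string()
        if gpr_text:
            # replace longest tokens first so "@x1" never clobbers "@x10"
            for role, tok in sorted(gene_slots.items(), key=lambda kv: -len(kv[1])):
                gpr_text = gpr_text.replace(tok, role_to_name[role])
            r = replace(r, gpr=parse_gpr(gpr_text))
        rid = r.id
        if rid in iso_partner:
            base = r.gpr.to_string()
            r = replace(r, gpr=parse_gpr(f"{base} or {resolve(iso_partner[rid])}"))
        resolved_rxns.append(r)

    # preserved genes: all transporters (nutrients stay importable in every
    # strain) plus a random fill of filler genes up to the target fraction
    preserved = {
        role_to_name[role]
        for role in roles
        if role.startswith(("t_nut", "t_prec"))
    }
    target = int(round(preserved_fraction * n_genes))
    fill_pool = sorted(
        role_to_name[role] for role in roles if role.startswith("filler")
    )
    n_fill = max(0, target - len(preserved))
    if n_fill > len(fill_pool):
        n_fill = len(fill_pool)
    preserved |= set(rng.choice(fill_pool, size=n_fill, replace=False)) if n_fill else set()

    genome = GenomeAnnotation(tuple(gene_names), frozenset(preserved))
    genes = frozenset(gene_names)
    model = MetabolicModel(
        id=f"toy_s{seed}",
        genes=genes,
        metabolites=tuple(mets[k] for k in sorted(mets)),
        reactions=tuple(resolved_rxns),
        biomass_reaction_id="BIOMASS",
    )

    nut_all = {f"nut{j}_e": uptake for j in range(P)}
    media_set: MediaSet = {
        "rich": MediaFormulation.make(
            "rich",
            {
                **nut_all,
                **{f"prec{j}_e": uptake for j in range(n_suppl)},
                "amA_e": uptake,
                "amB_e": uptake,
                "waste_e": uptake,
            },
        ),
        "defined_rich": MediaFormulation.make(
            "defined_rich",
            {
                **nut_all,
                **{f"prec{j}_e": uptake for j in range(n_def)},
                "amA_e": uptake,
                "amB_e": uptake,
            },
        ),
        "mm_A": MediaFormulation.make("mm_A", {**nut_all, "amA_e": uptake}),
        "mm_B": MediaFormulation.make("mm_B", {**nut_all, "amB_e": uptake}),
    }

    intervals = define_intervals(genome)
    bundle = TruthBundle(genome, model, media_set, intervals, PhenotypeTable(()), seed)

    # self-consistent phenotypes: the truth model's own verdicts
    sim = Simulator(model)
    for media in bundle.media_list():
        if sim.objective(media) <= DEFAULT_EPSILON:
            raise SyntheticDataError(
                f"seed {seed}: truth model unviable on {media.name}; regenerate with a new seed"
            )
    matrix = batch_predict(model, bundle.strain_defs(), bundle.media_list(), simulator=sim)
    phenotypes = PhenotypeTable(
        tuple(
            PhenotypeRow(c.strain_id, c.media_name, c.predicted) for c in matrix.calls
        )
    )
    return replace(bundle, phenotypes=phenotypes)


def simulate_observed_phenotypes(
    truth_model: MetabolicModel,
    intervals: tuple[Interval, ...],
    media_set: MediaSet,
    flip_rate: float = 0.0,
    seed: int = 0,
    include_master: bool = True,
) -> PhenotypeTable:
    """Truth-model FBA verdicts with each call independently flipped with
    probability ``flip_rate`` (observation noise for robustness tests)."""
    if not (0 <= flip_rate < 0.5):
        raise SyntheticDataError("flip_rate must be in [0, 0.5)")
    defs: dict[str, tuple[str, ...]] = {"master": ()} if include_master else {}
    defs.update({iv.id: iv.gene_ids for iv in intervals})
    matrix = batch_predict(truth_model, defs, list(media_set.values()))
    rng = np.random.default_rng(seed)
    rows = []
    for c in matrix.calls:
        call = c.predicted
        if flip_rate > 0 and rng.random() < flip_rate:
            call = UNVIABLE if call == VIABLE else VIABLE
        rows.append(PhenotypeRow(c.strain_id, c.media_name, call))
    return PhenotypeTable(tuple(rows))


# --------------------------------------------------------------------------
# planting model corruptions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateDB:
    """Reaction candidates for gapfilling plus isozyme homolog candidates."""

    reactions: dict[str, ReactionSpec] = field(default_factory=dict)
    metabolites: dict[str, MetaboliteSpec] = field(default_factory=dict)
    isozyme_candidates: tuple[tuple[str, str], ...] = ()  # (gene, reaction id)


def candidate_db_from_truth(
    truth_model: MetabolicModel, corrupted_model: MetabolicModel
) -> CandidateDB:
    """The oracle candidate database: truth reactions missing from the
    corrupted model, and every truth isozyme pair as a homolog candidate."""
    present = {r.id for r in corrupted_model.reactions}
    missing = {r.id: r for r in truth_model.reactions if r.id not in present}
    mets = {m.id: m for m in truth_model.metabolites}
    iso = []
    for r in truth_model.reactions:
        branches = r.gpr.top_or_branches()
        if len(branches) > 1:
            for g in sorted(r.gpr.genes()):
                iso.append((g, r.id))
    return CandidateDB(missing, mets, tuple(sorted(iso)))


def _predictions(model: MetabolicModel, bundle: TruthBundle, media_set: MediaSet) -> PredictionMatrix:
    return batch_predict(model, bundle.strain_defs(), list(media_set.values()))


def plant_errors(
    bundle: TruthBundle,
    spec: PlantSpec,
) -> tuple[MetabolicModel, MediaSet, tuple[Hypothesis, ...]]:
    """Corrupt the truth bundle with the inverse of each requested fix class.

    Every planted error is verified to change at least one phenotype
    prediction (else the next candidate site is drawn); the returned ledger
    holds the true corrective :class:`Hypothesis` for each planted error.
    """
    rng = np.random.default_rng(spec.seed)
    model = bundle.truth_model
    media_set = dict(bundle.media_set)
    ledger: list[Hypothesis] = []
    baseline = _predictions(model, bundle, media_set)

    for cls in ERROR_CLASSES:  # fixed order keeps runs reproducible
        for _ in range(spec.counts.get(cls, 0)):
            candidates = _plant_candidates(cls, model, media_set, bundle)
            if not candidates:
                raise SyntheticDataError(f"error class {cls} is not plantable in this model")
            order = rng.permutation(len(candidates))
            planted = False
            for idx in order:
                new_model, new_media, fix = _apply_plant(
                    cls, candidates[idx], model, media_set, bundle
                )
                after = _predictions(new_model, bundle, new_media)
                # a corrupted model must still describe a growing organism:
                # the master strain stays viable on at least one medium
                master_ok = any(
                    c.predicted == VIABLE
                    for c in after.calls
                    if c.strain_id == "master"
                )
                if master_ok and _n_differences(baseline, after) >= 1:
                    model, media_set = new_model, new_media
                    baseline = after
                    ledger.append(fix)
                    planted = True
                    break
            if not planted:
                raise SyntheticDataError(
                    f"error class {cls}: no candidate site changes any prediction"
                )
    return model, media_set, tuple(ledger)


def _n_differences(a: PredictionMatrix, b: PredictionMatrix) -> int:
    bl = b.lookup()
    return sum(1 for c in a.calls if bl[(c.strain_id, c.media_name)].predicted != c.predicted)


def _gene_interval_map(bundle: TruthBundle) -> dict[str, str]:
    return {g: iv.id for iv in bundle.intervals for g in iv.gene_ids}


def _plant_candidates(
    cls: str, model: MetabolicModel, media_set: MediaSet, bundle: TruthBundle
) -> list:
    """Deterministically ordered candidate sites for planting one error."""
    in_interval = _gene_interval_map(bundle)
    enzymatic = [
        r
        for r in model.reactions
        if not r.is_exchange and not r.is_biomass and not r.gpr.is_empty
    ]
    out: list = []
    if cls == FN_REACTION_ADD:
        out = sorted(r.id for r in enzymatic)
    elif cls == FP_REACTION_REMOVE:
        # bypass shortcut: nutrient -> precursor, skipping a gene-bearing chain
        mets = {m.id for m in model.metabolites}
        for j in range(64):
            if f"nut{j}_c" in mets and f"prec{j}_c" in mets:
                out.append((f"nut{j}_c", f"prec{j}_c", f"bypass{j}"))
    elif cls == FN_MEDIA_ADD:
        for name in sorted(media_set):
            for cid in sorted(dict(media_set[name].compounds)):
                out.append((name, cid))
    elif cls == FP_MEDIA_REMOVE:
        importable = {
            r.stoichiometry[0][0]
            for r in model.exchange_reactions()
            if len(r.stoichiometry) == 1
        }
        for name in sorted(media_set):
            for cid in sorted(importable - media_set[name].compound_ids()):
                out.append((name, cid))
    elif cls == FN_MAKE_REVERSIBLE:
        out = sorted(r.id for r in model.reactions if r.reversible and not r.is_exchange)
    elif cls == FP_MAKE_IRREVERSIBLE:
        out = sorted(
            r.id
            for r in model.reactions
            if not r.reversible and not r.is_exchange and not r.is_biomass
        )
    elif cls == FN_ISOZYME_ADD:
        for r in sorted(enzymatic, key=lambda r: r.id):
            branches = r.gpr.top_or_branches()
            if len(branches) < 2:
                continue
            for k, br in enumerate(branches):
                from .gpr import GPRRule

                br_genes = GPRRule(br).genes()
                others = [b for i, b in enumerate(branches) if i != k]
                other_genes = set().union(*(GPRRule(b).genes() for b in others))
                # removing this branch only matters if some other branch's
                # gene sits inside a deletion interval
                if any(g in in_interval for g in other_genes):
                    out.append((r.id, GPRRule(br).to_string()))
    elif cls == FP_ISOZYME_REMOVE:
        # bogus isozyme = a gene never co-deleted with the true genes
        bogus_pool = sorted(
            g
            for g in model.genes
            if g in bundle.genome.preserved
        )
        import zlib

        for r in sorted(enzymatic, key=lambda r: r.id):
            if any(g in in_interval for g in r.gpr.genes()) and bogus_pool:
                pick = zlib.crc32(r.id.encode()) % len(bogus_pool)
                out.append((r.id, bogus_pool[pick]))
    elif cls == FN_GPR_ADJUST:
        deletable_fillers = sorted(
            g for g in in_interval if g not in {x for r in enzymatic for x in r.gpr.genes()}
        )
        for r in sorted(enzymatic, key=lambda r: r.id):
            for g in deletable_fillers[:6]:
                out.append((r.id, g))
    elif cls == FP_GPR_ADJUST:
        for r in sorted(enzymatic, key=lambda r: r.id):
            genes = sorted(r.gpr.genes())
            if len(genes) == 1 and genes[0] in in_interval:
                out.append((r.id, genes[0]))
    elif cls == FP_BIOMASS_ADD:
        out = sorted(m for m, c in model.biomass.stoichiometry if c < 0)
    elif cls == FN_BIOMASS_REMOVE:
        in_biomass = {m for m, _ in model.biomass.stoichiometry}
        out = sorted(
            m.id
            for m in model.metabolites
            if m.compartment == CYTOSOL and m.id not in in_biomass
        )
    return out


def _apply_plant(
    cls: str, site, model: MetabolicModel, media_set: MediaSet, bundle: TruthBundle
) -> tuple[MetabolicModel, MediaSet, Hypothesis]:
    """Apply the inverse corruption for ``cls`` at ``site``; return the
    corrupted artifacts and the true corrective hypothesis."""
    if cls == FN_REACTION_ADD:
        rid = site
        return (
            model.drop_reactions({rid}),
            media_set,
            Hypothesis.make(cls, reaction_ids=(rid,)),
        )
    if cls == FP_REACTION_REMOVE:
        src, dst, rid = site
        bogus = ReactionSpec.make(rid, {src: -1.0, dst: 1.0})
        return (
            model.add_reactions([bogus]),
            media_set,
            Hypothesis.make(cls, reaction=rid),
        )
    if cls == FN_MEDIA_ADD:
        name, cid = site
        uptake = dict(media_set[name].compounds)[cid]
        new_set = dict(media_set)
        new_set[name] = media_set[name].without_compound(cid)
        return model, new_set, Hypothesis.make(cls, media=name, compound=cid, uptake=uptake)
    if cls == FP_MEDIA_REMOVE:
        name, cid = site
        new_set = dict(media_set)
        new_set[name] = media_set[name].with_compound(cid, DEFAULT_UPTAKE)
        return model, new_set, Hypothesis.make(cls, media=name, compound=cid)
    if cls == FN_MAKE_REVERSIBLE:
        rid = site
        rxn = replace(model.reaction(rid), lower_bound=0.0)
        return (
            model.replace_reaction(rxn),
            media_set,
            Hypothesis.make(cls, reaction=rid, side="lower"),
        )
    if cls == FP_MAKE_IRREVERSIBLE:
        rid = site
        rxn = replace(model.reaction(rid), lower_bound=-BIG)
        return (
            model.replace_reaction(rxn),
            media_set,
            Hypothesis.make(cls, reaction=rid, side="lower"),
        )
    if cls == FN_ISOZYME_ADD:
        rid, branch = site
        rxn = model.reaction(rid)
        target = parse_gpr(branch).canonical().root
        from .gpr import GPRRule

        match = next(
            b for b in rxn.gpr.top_or_branches() if GPRRule(b).canonical().root == target
        )
        rxn = replace(rxn, gpr=rxn.gpr.without_branch(match))
        # the fix re-adds the branch's gene as an isozyme (single-gene branch)
        gene = sorted(GPRRule(target).genes())[0]
        return (
            model.replace_reaction(rxn),
            media_set,
            Hypothesis.make(cls, reaction=rid, gene=gene),
        )
    if cls == FP_ISOZYME_REMOVE:
        rid, bogus_gene = site
        rxn = model.reaction(rid)
        rxn = replace(rxn, gpr=rxn.gpr.or_gene(bogus_gene))
        return (
            model.replace_reaction(rxn),
            media_set,
            Hypothesis.make(cls, reaction=rid, branch=bogus_gene),
        )
    if cls == FN_GPR_ADJUST:
        rid, g = site
        rxn = model.reaction(rid)
        rxn = replace(rxn, gpr=rxn.gpr.and_gene(g))
        return (
            model.replace_reaction(rxn),
            media_set,
            Hypothesis.make(cls, reaction=rid, genes=(g,)),
        )
    if cls == FP_GPR_ADJUST:
        rid, g = site
        rxn = model.reaction(rid)
        rxn = replace(rxn, gpr=rxn.gpr.without_genes({g}))
        return (
            model.replace_reaction(rxn),
            media_set,
            Hypothesis.make(cls, reaction=rid, gene=g),
        )
    if cls == FP_BIOMASS_ADD:
        comp = site
        bio = model.biomass
        stoich = bio.stoich_dict()
        del stoich[comp]
        bio = replace(bio, stoichiometry=tuple(sorted(stoich.items())))
        return (
            model.replace_reaction(bio),
            media_set,
            Hypothesis.make(cls, compound=comp, coeff=BIOMASS_COMPONENT_COEFF),
        )
    if cls == FN_BIOMASS_REMOVE:
        comp = site
        bio = model.biomass
        stoich = bio.stoich_dict()
        stoich[comp] = stoich.get(comp, 0.0) - BIOMASS_COMPONENT_COEFF
        bio = replace(bio, stoichiometry=tuple(sorted(stoich.items())))
        return (
            model.replace_reaction(bio),
            media_set,
            Hypothesis.make(cls, compound=comp),
        )
    raise SyntheticDataError(f"unhandled class {cls}")  # pragma: no cover
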