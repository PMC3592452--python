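# Methods

## Viability prediction

Growth is modeled as the optimum of the standard FBA linear program:
maximize the biomass flux subject to steady-state mass balance `S·v = 0`
over every metabolite and per-reaction bounds `lb ≤ v ≤ ub`. Exchange
reactions (single-metabolite boundary columns, coefficient −1) close the
balance of extracellular compounds: positive flux secretes, negative flux
takes up. A medium is a named map from extracellular compounds to maximum
uptake rates; applying it sets each exchange lower bound to −uptake for
listed compounds and 0 otherwise, while secretion keeps the model's own
upper bound. Compounds in a medium's unlimited set (water, protons,
inorganic ions in real formulations) get the default large bound
(1000 flux units, the conventional mmol/gDW/h scale).

Deletions are simulated by evaluating each reaction's GPR rule with the
deleted genes absent and fixing the flux of every failed reaction to zero in
both directions — the reactions stay in the model; outright removal is
reserved for constructing a master-background model whose marker lesions
(e.g. a tryptophan-pathway auxotrophy marker) must be mirrored by removing
all associated reactions. Genes cited by GPRs but absent from the model's gene
list are treated as always present (never knockable) and reported, which
avoids spurious lethality from annotation gaps.

A strain is viable when the optimum exceeds ε = 1e−6 (configurable). Since
v = 0 is always feasible the LP always has an optimum ≥ 0; the threshold
only guards against solver round-off. Only the objective value is
contract-bearing — flux vectors are reported but generally non-unique.

Two solver backends share one interface: GLPK through swiglpk (default; the
problem is constructed once per model and re-solved from a warm basis, with
knockouts, media and candidate edits applied as bound updates) and SciPy's
HiGHS `linprog`. Solver feasibility tolerance is 1e−9; all assertions on
objectives and mass-balance residuals use 1e−6. Because every bound is
finite, an unbounded objective can only arise from user models with
non-finite bounds, and is reported as an error naming the thermodynamic
inconsistency rather than silently clamped.

Scoring mirrors the layout of knockout-panel accuracy tables: per medium and
overall, the number of observed-viable and observed-unviable strains and how
many of each the model got right. Observed "slow" growth counts as viable by
default (slow colonies are still colonies); rows carrying a revision note
("… revised to −", the cross-feeding situation where neighbour colonies feed
an auxotroph on a plate) are scored against the revised call.

## Reconciliation

Twelve error classes cover the edit space: for false positives — add a
biomass component, restrict a GPR, remove an isozyme branch, remove a
reaction, make a reaction irreversible, remove a media compound; for false
negatives — the six inverses (remove a biomass component, relax a GPR, add
an isozyme, add reactions, make reversible, add a media compound).

Generation is per-failure and single-edit except reaction additions, which
are minimal sets up to a configurable cap (default 3) found by exhaustive
subset search for candidate databases of ≤ 15 reactions and by a greedy
open-all-then-prune pass above that. Isozyme additions come from a
user-supplied homolog-candidate table (gene → reactions); no sequence search
is performed. Biomass additions use a small fixed coefficient (1e−4
mmol/gDW) — enough to impose the dependency without distorting yields.
Reversibility edits touch one bound side only and never flip a reaction's
primary direction. GPR restrictions anchor on one deleted gene per prompting
strain; since the genes of an interval are only ever deleted together, any
choice of anchor is phenotype-equivalent. Every candidate must flip its
prompting prediction in isolation before it is evaluated globally.

Evaluation applies the edit to a copy, re-simulates, and returns the sets of
predictions corrected and broken. Purely relaxing edits can only flip
unviable predictions to viable (the feasible polytope only grows), and
purely restricting edits the reverse, so only the at-risk half of the
prediction matrix is re-solved; media edits touch only their own medium;
biomass-composition edits, which lack a clean monotonicity argument, are
re-simulated in full. For screening speed all candidate-database reactions
are kept in the LP with bounds fixed at zero and opened per test, so almost
every hypothesis reduces to bound updates on one warm-started LP; the
accepted edit is always re-applied structurally.

Acceptance is greedy with a strict rule: best (net corrected − broken), ties
broken by fewer breaks, then smaller edit, then lexicographic id. Strict
positivity guarantees that overall accuracy increases every iteration and
the loop terminates; it also forbids churn (net-zero swaps). Whether the
original curation efforts were strictly greedy is not knowable from
published summaries, so the policy object isolates this choice. Failures no
edit can fix without breaking something else remain in the residual list —
in practice these flag regulatory effects outside a purely metabolic model —
and are exported as proposed validation experiments rather than executed;
wet-lab confirmation is outside computational scope.

## Rescue search

For a knockout predicted unviable on a medium, the search scans single
compounds, then pairs, then triples (capped at 3 — reported rescues in
interval-deletion panels are 1–3 compounds, e.g. isoleucine+valine or
serine+tyrosine+phenylalanine), pruning supersets of found rescues, and
returns all minimal sets whose addition makes the strain viable. Supplements
are added at the medium's default limited-uptake value. Candidates are the
extracellular compounds with an exchange reaction; compounds importable only
through candidate-db transport reactions are offered only under an explicit
flag and marked as requiring a model edit, since adding a transporter is a
deliberate refinement, never a silent one.

## Synthetic data

The generator emulates the design of a systematic interval-deletion study,
not any particular organism. Defaults: 60 genes, 6 linear biosynthetic
pathways (nutrient → intermediate → precursor, every step gene-associated),
isozyme rate 0.2 per step (at least one isozyme pair is forced whenever the
rate is positive, so isozyme error classes are always plantable),
preserved fraction 0.3, uptake 10 flux units for every limited compound,
seed 42. These sizes keep the LP under ~100 reactions and a full
reconciliation under a second, which is what makes 50-seed recovery sweeps
per error class practical.

Structure: biomass drains one unit of each pathway precursor plus a nitrogen
precursor reachable from either of two interchangeable nitrogen sources
(distinct transport/assimilation genes). Four media mirror the usual study
panel: a rich medium carrying every importable precursor supplement, a
defined rich medium with half of them, and two minimal media differing only
in nitrogen source. All but the last two pathways have importable end
products; reversible interconversions chain the supplemented precursors
together, so single-pathway losses are buffered while joint losses are
lethal (the co-lethality pattern); an irreversible overflow reaction drains
the last pathway's precursor to an excretable waste compound present in the
rich medium, giving reversibility corruptions a phenotypically visible site.
Preserved genes are all transporters plus a random fill of non-metabolic
filler genes; intervals are the maximal runs of non-preserved genes in the
shuffled genome order. Phenotypes are the truth model's own FBA verdicts
(asserted 100% self-consistent), with optional seeded call-flipping noise.

The error planter applies the inverse of each class's correction, drawing
sites from a seeded RNG, and re-verifies two conditions per plant: at least
one prediction changes (otherwise the next site is drawn) and the master
strain stays viable on at least one medium — a corrupted model must still
describe an organism that grows, and without this constraint a single plant
can collapse the whole matrix to unviable and mask every later one.

What the generator does not emulate: operon/promoter structure and
polar-effect end-point curation, growth rates (phenotypes are binary),
compound instability, regulatory constraints, and annotation noise beyond
the planted classes. Passing recovery tests therefore shows the search and
acceptance machinery is sound on networks whose errors are in-class, not
that real model curation reduces to it: real discrepancies mix several
errors, include non-metabolic causes, and the candidate databases are far
larger and noisier than the truth-derived ones used here.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; candidate enumerations are sorted, ledgers
  serialize deterministically, and repeated runs are byte-identical.
* SBML is written as Level 3 + fbc v2 (gene-product associations, flux-bound
  parameters, maximize objective); the reader additionally accepts the
  legacy Level 2 dialect with `GENE_ASSOCIATION:` notes strings and
  kinetic-law `LOWER_BOUND`/`UPPER_BOUND` parameters, the format of the
  era's published genome-scale models. Biomass is identified by the fbc
  objective when present, else by a configurable id/name pattern
  (default: anything matching "biomass"/"bio").
* Media tables give flux bounds directly; when a recipe gives
  concentrations, one shared default uptake (10) is used for every limited
  compound — binary growth calls are invariant to a common scale on all
  uptakes.
* GPR strings canonicalize by flattening nested same-operator nodes and
  sorting children, so structurally equal rules compare equal after
  round-trips.
* The acceptance script and test suite size their sweeps (25 oracle
  networks, 50 seeds per error class, 3 bundles) to exercise every code
  path across distinct sites while a full run stays under a minute.
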