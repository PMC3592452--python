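"""Flux balance analysis: LP construction, knockout simulation, scoring.

The LP is the standard one: maximize biomass flux c.v subject to steady-state
mass balance S.v = 0 and per-reaction bounds lb <= v <= ub.  Media enter as
lower bounds on exchange reactions (uptake is negative exchange flux);
knockouts zero the bounds of every reaction whose GPR evaluates false with
the deleted genes absent.  v = 0 is always feasible, so the optimum exists
and is >= 0; a strain is called viable when the optimum exceeds a small
threshold epsilon guarding against solver round-off.

Two interchangeable solver backends are provided: GLPK (via swiglpk, default;
the problem is kept loaded and re-solved from a warm basis across knockouts)
and scipy's HiGHS linprog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import (
    BIG,
    NOT_ATTEMPTED,
    SLOW,
    UNVIABLE,
    VIABLE,
    MediaFormulation,
    MetabolicModel,
    PhenotypeTable,
)

#: default growth threshold on the biomass flux
DEFAULT_EPSILON = 1e-6

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class FbaError(RuntimeError):
    pass


class UnboundedObjectiveError(FbaError):
    """The biomass objective is unbounded: the model admits a free-energy
    loop feeding biomass without nutrient cost."""


@dataclass
class FluxSolution:
    objective_value: float
    fluxes: dict[str, float]
    status: str

    def mass_balance_residual(self, model: MetabolicModel) -> float:
        """max |S.v| over metabolites; ~0 for any valid optimal solution."""
        bal: dict[str, float] = {}
        for r in model.reactions:
            v = self.fluxes.get(r.id, 0.0)
            for met, coeff in r.stoichiometry:
                bal[met] = bal.get(met, 0.0) + coeff * v
        # exchange reactions are the system boundary: their metabolites are
        # balanced by construction (the exchange column closes the balance)
        return max((abs(x) for x in bal.values()), default=0.0)


def disabled_reactions(model: MetabolicModel, knocked_genes: Iterable[str]) -> frozenset[str]:
    """Reactions whose GPR evaluates false when ``knocked_genes`` are absent.

    Empty rules never disable; AND needs all leaves, OR any (isozymes
    survive the loss of a single branch).  Orphan genes are treated as
    present and thus never knockable.
    """
    knocked = frozenset(knocked_genes) & model.genes
    if not knocked:
        return frozenset()
    return frozenset(
        r.id for r in model.reactions if not r.gpr.is_empty and not r.gpr.evaluate(knocked)
    )


def _media_lower_bounds(model: MetabolicModel, media: MediaFormulation) -> dict[str, float]:
    """Exchange lower bounds implied by a medium: -uptake for listed
    compounds, 0 (closed) for everything else."""
    uptakes = media.uptake_dict()
    out = {}
    for r in model.exchange_reactions():
        if len(r.stoichiometry) != 1:
            continue
        met = r.stoichiometry[0][0]
        u = uptakes.get(met, 0.0)
        out[r.id] = -min(u, BIG)
    return out


# --------------------------------------------------------------------------
# solver backends
# --------------------------------------------------------------------------


class _ScipyBackend:
    """One-shot HiGHS solves through scipy.optimize.linprog."""

    def __init__(self, model: MetabolicModel):
        from scipy.sparse import csr_matrix

        self.model = model
        self.rxn_ids = [r.id for r in model.reactions]
        self.col = {rid: j for j, rid in enumerate(self.rxn_ids)}
        met_ids = [m.id for m in model.metabolites]
        row = {mid: i for i, mid in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            for met, coeff in r.stoichiometry:
                rows.append(row[met])
                cols.append(j)
                vals.append(coeff)
        self.S = csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(self.rxn_ids))
        )
        self.base_lb = np.array([r.lower_bound for r in model.reactions])
        self.base_ub = np.array([r.upper_bound for r in model.reactions])
        self.c = np.zeros(len(self.rxn_ids))
        self.c[self.col[model.biomass_reaction_id]] = -1.0  # linprog minimizes
        self.b = np.zeros(self.S.shape[0])

    def solve(
        self,
        media_lb: Mapping[str, float],
        disabled: frozenset[str],
        overrides: Mapping[str, tuple[float, float]] = {},
    ) -> FluxSolution:
        from scipy.optimize import linprog

        lb = self.base_lb.copy()
        ub = self.base_ub.copy()
        for rid, v in media_lb.items():
            lb[self.col[rid]] = v
        for rid, (lo, hi) in overrides.items():
            j = self.col[rid]
            lb[j], ub[j] = lo, hi
        for rid in disabled:
            j = self.col[rid]
            lb[j] = 0.0
            ub[j] = 0.0
        res = linprog(
            self.c,
            A_eq=self.S,
            b_eq=self.b,
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status == 3:
            raise UnboundedObjectiveError(
                "biomass objective unbounded: thermodynamically impossible loop"
            )
        if res.status != 0:
            # v=0 is feasible for any consistent model; anything else is a bug
            raise FbaError(f"LP solve failed with status {res.status}: {res.message}")
        fluxes = {rid: float(res.x[j]) for rid, j in self.col.items()}
        return FluxSolution(-float(res.fun), fluxes, OPTIMAL)


class _GlpkBackend:
    """Persistent GLPK problem; knockouts and media are bound updates only,
    so successive solves restart from the previous basis."""

    def __init__(self, model: MetabolicModel):
        import swiglpk as glp

        self.glp = glp
        self.model = model
        self.rxn_ids = [r.id for r in model.reactions]
        self.col = {rid: j + 1 for j, rid in enumerate(self.rxn_ids)}  # 1-based
        met_ids = [m.id for m in model.metabolites]
        row = {mid: i + 1 for i, mid in enumerate(met_ids)}

        lp = glp.glp_create_prob()
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        glp.glp_add_rows(lp, len(met_ids))
        glp.glp_add_cols(lp, len(self.rxn_ids))
        for i in range(1, len(met_ids) + 1):
            glp.glp_set_row_bnds(lp, i, glp.GLP_FX, 0.0, 0.0)
        self.base_bounds: list[tuple[float, float]] = []
        entries: list[tuple[int, int, float]] = []
        for j, r in enumerate(model.reactions, start=1):
            self.base_bounds.append((r.lower_bound, r.upper_bound))
            self._set_col(lp, j, r.lower_bound, r.upper_bound)
            for met, coeff in r.stoichiometry:
                entries.append((row[met], j, coeff))
        glp.glp_set_obj_coef(lp, self.col[model.biomass_reaction_id], 1.0)
        n = len(entries)
        ia, ja, ar = glp.intArray(n + 1), glp.intArray(n + 1), glp.doubleArray(n + 1)
        for k, (i, j, v) in enumerate(entries, start=1):
            ia[k], ja[k], ar[k] = i, j, v
        glp.glp_load_matrix(lp, n, ia, ja, ar)
        self.lp = lp
        self.parm = glp.glp_smcp()
        glp.glp_init_smcp(self.parm)
        self.parm.msg_lev = glp.GLP_MSG_OFF

    def _set_col(self, lp, j: int, lb: float, ub: float) -> None:
        glp = self.glp
        if lb == ub:
            glp.glp_set_col_bnds(lp, j, glp.GLP_FX, lb, ub)
        else:
            glp.glp_set_col_bnds(lp, j, glp.GLP_DB, lb, ub)

    def solve(
        self,
        media_lb: Mapping[str, float],
        disabled: frozenset[str],
        overrides: Mapping[str, tuple[float, float]] = {},
    ) -> FluxSolution:
        glp, lp = self.glp, self.lp
        touched: list[int] = []
        for rid, v in media_lb.items():
            j = self.col[rid]
            self._set_col(lp, j, v, self.base_bounds[j - 1][1])
            touched.append(j)
        for rid, (lo, hi) in overrides.items():
            j = self.col[rid]
            self._set_col(lp, j, lo, hi)
            touched.append(j)
        for rid in disabled:
            j = self.col[rid]
            self._set_col(lp, j, 0.0, 0.0)
            touched.append(j)
        try:
            ret = glp.glp_simplex(lp, self.parm)
            status = glp.glp_get_status(lp)
            if ret != 0 or status not in (glp.GLP_OPT, glp.GLP_FEAS):
                # warm basis occasionally goes stale after many bound flips;
                # retry from a fresh basis before giving up
                glp.glp_std_basis(lp)
                ret = glp.glp_simplex(lp, self.parm)
                status = glp.glp_get_status(lp)
            if status == glp.GLP_UNBND:
                raise UnboundedObjectiveError(
                    "biomass objective unbounded: thermodynamically impossible loop"
                )
            if ret != 0 or status != glp.GLP_OPT:
                raise FbaError(f"GLPK solve failed: ret={ret} status={status}")
            obj = glp.glp_get_obj_val(lp)
            fluxes = {
                rid: glp.glp_get_col_prim(lp, j) for rid, j in self.col.items()
            }
            return FluxSolution(float(obj), fluxes, OPTIMAL)
        finally:
            for j in set(touched):
                self._set_col(lp, j, *self.base_bounds[j - 1])

    def __del__(self):  # pragma: no cover
        try:
            self.glp.glp_delete_prob(self.lp)
        except Exception:
            pass


def _make_backend(model: MetabolicModel, backend: str):
    if backend == "glpk":
        try:
            return _GlpkBackend(model)
        except ImportError:  # pragma: no cover
            return _ScipyBackend(model)
    if backend == "scipy":
        return _ScipyBackend(model)
    raise ValueError(f"unknown backend {backend!r}")


# --------------------------------------------------------------------------
# simulator and prediction API
# --------------------------------------------------------------------------


class Simulator:
    """Caches the LP for one model and memoizes growth verdicts.

    The cache key is (media name, disabled reaction set); model edits require
    a fresh Simulator, which reconciliation creates per hypothesis.
    """

    def __init__(self, model: MetabolicModel, backend: str = "glpk"):
        self.model = model
        self.backend = _make_backend(model, backend)
        self._media_lb: dict[MediaFormulation, dict[str, float]] = {}
        self._obj_cache: dict[tuple, float] = {}

    def _bounds_for(self, media: MediaFormulation) -> dict[str, float]:
        cached = self._media_lb.get(media)
        if cached is None:
            cached = _media_lower_bounds(self.model, media)
            self._media_lb[media] = cached
        return cached

    def solve(
        self,
        media: MediaFormulation,
        disabled: frozenset[str] = frozenset(),
        overrides: Mapping[str, tuple[float, float]] = {},
    ) -> FluxSolution:
        sol = self.backend.solve(self._bounds_for(media), disabled, overrides)
        self._obj_cache[(media, disabled, tuple(sorted(overrides.items())))] = (
            sol.objective_value
        )
        return sol

    def objective(
        self,
        media: MediaFormulation,
        disabled: frozenset[str] = frozenset(),
        overrides: Mapping[str, tuple[float, float]] = {},
    ) -> float:
        key = (media, disabled, tuple(sorted(overrides.items())))
        obj = self._obj_cache.get(key)
        if obj is None:
            obj = self.backend.solve(
                self._bounds_for(media), disabled, overrides
            ).objective_value
            self._obj_cache[key] = obj
        return obj


@dataclass(frozen=True)
class GrowthCall:
    strain_id: str
    media_name: str
    predicted: str  # viable | unviable
    objective_value: float


@dataclass(frozen=True)
class PredictionMatrix:
    calls: tuple[GrowthCall, ...]

    def lookup(self) -> dict[tuple[str, str], GrowthCall]:
        return {(c.strain_id, c.media_name): c for c in self.calls}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (c.strain_id, c.media_name, c.predicted, c.objective_value)
                for c in self.calls
            ],
            columns=["strain", "media", "predicted", "objective"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def maximize_biomass(
    model: MetabolicModel, media: MediaFormulation, backend: str = "glpk"
) -> FluxSolution:
    """Solve max c.v s.t. S.v = 0 with media-derived uptake bounds."""
    return Simulator(model, backend).solve(media)


def simulate_deletion(
    model: MetabolicModel,
    gene_set: Iterable[str],
    media: MediaFormulation,
    epsilon: float = DEFAULT_EPSILON,
    simulator: Optional[Simulator] = None,
    strain_id: str = "strain",
) -> GrowthCall:
    """Knock out ``gene_set`` (zero flux through every disabled reaction) and
    call viability from the resulting biomass optimum."""
    sim = simulator if simulator is not None else Simulator(model)
    disabled = disabled_reactions(sim.model, gene_set)
    obj = sim.objective(media, disabled)
    predicted = VIABLE if obj > epsilon else UNVIABLE
    return GrowthCall(strain_id, media.name, predicted, obj)


def batch_predict(
    model: MetabolicModel,
    strain_defs: Mapping[str, Iterable[str]],
    media_set: Sequence[MediaFormulation],
    epsilon: float = DEFAULT_EPSILON,
    simulator: Optional[Simulator] = None,
    pairs: Optional[set[tuple[str, str]]] = None,
) -> PredictionMatrix:
    """One GrowthCall per (strain, media), in input order.

    ``pairs`` optionally restricts computation to a subset of the
    cross-product (used by reconciliation's incremental re-evaluation).
    """
    if not strain_defs:
        raise ValueError("strain_defs must be non-empty")
    sim = simulator if simulator is not None else Simulator(model)
    calls = []
    for strain_id, genes in strain_defs.items():
        disabled = disabled_reactions(sim.model, genes)
        for media in media_set:
            if pairs is not None and (strain_id, media.name) not in pairs:
                continue
            obj = sim.objective(media, disabled)
            predicted = VIABLE if obj > epsilon else UNVIABLE
            calls.append(GrowthCall(strain_id, media.name, predicted, obj))
    return PredictionMatrix(tuple(calls))


# --------------------------------------------------------------------------
# scoring against observations, split by observed phenotype sign
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AccuracyCell:
    media: str  # media name or "Overall"
    phenotype: str  # "+" | "-" | "all"
    n: int
    correct: int

    @property
    def percent(self) -> float:
        return 100.0 * self.correct / self.n if self.n else float("nan")


@dataclass(frozen=True)
class AccuracyReport:
    cells: tuple[AccuracyCell, ...]
    misclassified: tuple[tuple[str, str], ...]  # (strain, media) pairs

    def cell(self, media: str, phenotype: str) -> AccuracyCell:
        for c in self.cells:
            if c.media == media and c.phenotype == phenotype:
                return c
        raise KeyError((media, phenotype))

    @property
    def overall(self) -> AccuracyCell:
        return self.cell("Overall", "all")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(c.media, c.phenotype, c.n, c.correct, round(c.percent, 1)) for c in self.cells],
            columns=["media", "phenotype", "n", "correct", "percent"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def score_predictions(
    pred: PredictionMatrix,
    obs: PhenotypeTable,
    slow_policy: str = "viable",
) -> AccuracyReport:
    """Count correct predictions among observed-viable and observed-unviable
    strains, per medium and overall.

    ``slow_policy`` maps observed "slow" calls onto viable (default) or
    unviable.  Rows carrying a revision note are scored against the revised
    call; not-attempted rows are skipped.
    """
    if slow_policy not in (VIABLE, UNVIABLE):
        raise ValueError("slow_policy must be 'viable' or 'unviable'")
    plook = pred.lookup()
    missing = [
        (r.strain_id, r.media_name)
        for r in obs.attempted()
        if (r.strain_id, r.media_name) not in plook
    ]
    if missing:
        raise ValueError(f"missing predictions for observed pairs: {missing}")

    media_order: list[str] = []
    tall: dict[tuple[str, str], list[int]] = {}
    mis: list[tuple[str, str]] = []
    for r in obs.attempted():
        observed = r.effective_call()
        if observed == SLOW:
            observed = slow_policy
        sign = "+" if observed == VIABLE else "-"
        if r.media_name not in media_order:
            media_order.append(r.media_name)
        predicted = plook[(r.strain_id, r.media_name)].predicted
        ok = int(predicted == observed)
        if not ok:
            mis.append((r.strain_id, r.media_name))
        for key in ((r.media_name, sign), ("Overall", sign), ("Overall", "all")):
            n_corr = tall.setdefault(key, [0, 0])
            n_corr[0] += 1
            n_corr[1] += ok
    cells = []
    for media in media_order + ["Overall"]:
        for sign in ("+", "-"):
            n, corr = tall.get((media, sign), (0, 0))
            cells.append(AccuracyCell(media, sign, n, corr))
    n, corr = tall.get(("Overall", "all"), (0, 0))
    cells.append(AccuracyCell("Overall", "all", n, corr))
    return AccuracyReport(tuple(cells), tuple(sorted(mis)))
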