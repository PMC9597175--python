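"""Inner optimization problems: FBA (LP) and the weighted UFD (QP).

For each candidate perturbation the treated-cancer and perturbed-healthy
cells are simulated on the forward/backward-split model:

1. **FBA** maximizes the cell objective — biomass growth for the cancer
   (CA) model, ATP production for the healthy (HT) model — subject to
   steady state ``N (v_f - v_b) = 0`` and the (possibly regulated) split
   bounds.
2. **UFD** (uniform flux distribution) then minimizes the
   confidence-weighted squared flux ``sum_k c_k (v_f,k^2 + v_b,k^2)``
   over *internal* (non-exchange) reactions, holding the FBA optimum as a
   floor.  The weights come from RNA-seq-derived reaction confidence
   (1/4 high ... 1 other), so well-supported reactions are allowed to
   carry more flux.  The QP is convex; its solution is the representative
   flux pattern used for all membership grades.

Regulation of a candidate target perturbs the split bounds:

* an enzyme knockout zeroes every reaction it (and its merged redundant
  partners) exclusively catalyses; reactions still covered by another
  isozyme are instead pinned to within ``±epsilon`` of their basal
  (template) flux,
* up-/down-regulation moves the bound toward UB/LB by the convex
  combination ``(1-delta)*basal + delta*bound``,
* an antimetabolite (metabolite knockout) zeroes every producing
  reaction direction of the metabolite.

Templates — the unperturbed FBA+UFD states of each model — supply the
basal fluxes, the objective floors and the standard levels of all
membership specs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .fuzzy_grades import flow_rates
from .gpr_logic import GPRModel, isozyme_buffered
from .metnet_io import SplitModel, StoichiometricModel, split_reversible

__all__ = [
    "RegulationTarget",
    "RegulationScheme",
    "FluxState",
    "Template",
    "BoundConflictError",
    "ConfigurationError",
    "SolverSettings",
    "apply_gene_regulation",
    "apply_metabolite_regulation",
    "build_regulated_split",
    "solve_fba",
    "solve_ufd",
    "compute_template",
]

MODES = ("up", "down", "knockout")
DEFAULT_EPSILON = 0.03


class BoundConflictError(ValueError):
    """Regulation induced an empty bound interval on some reaction."""


class ConfigurationError(RuntimeError):
    """The unperturbed model cannot be solved; the setup is wrong."""


@dataclass(frozen=True)
class SolverSettings:
    feasibility_tol: float = 1e-9
    residual_tol: float = 1e-8
    floor_fraction: float = 1.0
    floor_slack: float = 1e-9
    qp_gtol: float = 1e-10
    qp_xtol: float = 1e-12
    qp_maxiter: int = 3000


DEFAULT_SETTINGS = SolverSettings()


@dataclass(frozen=True)
class RegulationTarget:
    target_id: str
    mode: str = "knockout"
    delta: float = 1.0
    kind: str = "enzyme"  # 'enzyme' | 'metabolite'

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown regulation mode {self.mode!r}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")


@dataclass
class RegulationScheme:
    targets: list[RegulationTarget]
    epsilon: float = DEFAULT_EPSILON
    induced_bounds: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")


@dataclass
class FluxState:
    v_f: dict[str, float]
    v_b: dict[str, float]
    v_biomass: float
    v_atp: float
    rates: dict[str, float]
    status: str  # 'optimal' | 'infeasible'
    objective_value: float = float("nan")
    residual: float = 0.0

    def net(self, rxn_id: str) -> float:
        return self.v_f.get(rxn_id, 0.0) - self.v_b.get(rxn_id, 0.0)

    def to_tsv(self, path) -> None:
        """Write the flux pattern as (reaction, v_f, v_b, net) rows."""
        import pandas as pd

        ids = sorted(self.v_f)
        pd.DataFrame(
            {
                "reaction": ids,
                "v_f": [self.v_f[i] for i in ids],
                "v_b": [self.v_b[i] for i in ids],
                "net": [self.net(i) for i in ids],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class Template:
    model_tag: str  # 'CA' | 'HT'
    basal_vf: dict[str, float]
    basal_vb: dict[str, float]
    rates: dict[str, float]
    v_biomass: float
    v_atp: float
    fba_optimum: float
    state: FluxState


def _zero_state(model: StoichiometricModel) -> FluxState:
    zeros = {r.id: 0.0 for r in model.reactions}
    return FluxState(
        v_f=dict(zeros),
        v_b=dict(zeros),
        v_biomass=0.0,
        v_atp=0.0,
        rates={model.metabolite(m.id).base_id: 0.0 for m in model.metabolites},
        status="infeasible",
    )


def _make_state(model: StoichiometricModel, x: np.ndarray,
                objective_value: float, residual: float) -> FluxState:
    n = len(model.reactions)
    vf = np.maximum(x[:n], 0.0)
    vb = np.maximum(x[n:], 0.0)
    ids = model.reaction_ids
    v_f = dict(zip(ids, vf.tolist()))
    v_b = dict(zip(ids, vb.tolist()))
    state = FluxState(
        v_f=v_f,
        v_b=v_b,
        v_biomass=(v_f[model.biomass_rxn_id] - v_b[model.biomass_rxn_id])
        if model.biomass_rxn_id else 0.0,
        v_atp=(v_f[model.atp_rxn_id] - v_b[model.atp_rxn_id])
        if model.atp_rxn_id else 0.0,
        rates=flow_rates(v_f, v_b, model),
        status="optimal",
        objective_value=objective_value,
        residual=residual,
    )
    return state


def _split_matrices(split: SplitModel) -> tuple[np.ndarray, list[tuple[float, float]]]:
    n_mat = split.base.stoichiometric_matrix()
    a_eq = np.hstack([n_mat, -n_mat])
    bounds = list(zip(split.vf_lb, split.vf_ub)) + list(zip(split.vb_lb, split.vb_ub))
    return a_eq, bounds


def _objective_row(split: SplitModel, rxn_id: str) -> np.ndarray:
    n = split.n_reactions
    row = np.zeros(2 * n)
    j = split.base.reaction_index(rxn_id)
    row[j] = 1.0
    row[n + j] = -1.0
    return row


def _objective_rxn(model: StoichiometricModel, objective: str) -> str:
    if objective == "biomass":
        rid = model.biomass_rxn_id
    elif objective == "atp":
        rid = model.atp_rxn_id
    else:
        raise ValueError(f"unknown objective {objective!r}")
    if rid is None:
        raise ConfigurationError(f"model {model.id!r}: {objective} reaction not set")
    return rid


# ---------------------------------------------------------------------------
# Regulation bounds
# ---------------------------------------------------------------------------

def _intersect(
    box: list[float], f_int: tuple[float, float] | None,
    b_int: tuple[float, float] | None, rxn_id: str, tol: float = 1e-9,
) -> None:
    if f_int is not None:
        box[0] = max(box[0], f_int[0])
        box[1] = min(box[1], f_int[1])
    if b_int is not None:
        box[2] = max(box[2], b_int[0])
        box[3] = min(box[3], b_int[1])
    if box[0] > box[1] + tol or box[2] > box[3] + tol:
        raise BoundConflictError(
            f"reaction {rxn_id!r}: regulation bounds conflict "
            f"(vf [{box[0]:g}, {box[1]:g}], vb [{box[2]:g}, {box[3]:g}])"
        )
    box[1] = max(box[1], box[0])
    box[3] = max(box[3], box[2])


def apply_gene_regulation(
    split: SplitModel,
    gpr: GPRModel,
    template: Template,
    scheme: RegulationScheme,
) -> SplitModel:
    """Apply enzyme-centric regulation bounds to a split model.

    Isozyme buffering is judged against the *whole* target set: a
    reaction whose catalysing enzymes are all targeted is shut down even
    if each one alone would be buffered by the other.
    """
    enzyme_targets = [t for t in scheme.targets if t.kind == "enzyme"]
    removing = frozenset(
        t.target_id for t in enzyme_targets if t.mode in ("knockout", "down")
    )
    eps = scheme.epsilon
    boxes: dict[str, list[float]] = {}

    for target in enzyme_targets:
        enzyme = gpr.enzyme(target.target_id)  # KeyError for unknown targets
        for rxn_id in sorted(enzyme.reaction_set):
            j = split.base.reaction_index(rxn_id)
            if rxn_id not in boxes:
                boxes[rxn_id] = [split.vf_lb[j], split.vf_ub[j],
                                 split.vb_lb[j], split.vb_ub[j]]
            box = boxes[rxn_id]
            lbf, ubf = split.vf_lb[j], split.vf_ub[j]
            lbb, ubb = split.vb_lb[j], split.vb_ub[j]
            bf = max(0.0, template.basal_vf.get(rxn_id, 0.0))
            bb = max(0.0, template.basal_vb.get(rxn_id, 0.0))
            d = target.delta
            buffered = target.mode in ("knockout", "down") and isozyme_buffered(
                gpr, rxn_id, removing
            )
            if target.mode == "up":
                f_int = ((1 - d) * bf + d * ubf, ubf)
                b_int = (lbb, (1 - d) * bb + d * lbb)
            elif buffered:
                f_int = (max((1 - eps) * bf, lbf), min((1 + eps) * bf, ubf))
                b_int = (max((1 - eps) * bb, lbb), min((1 + eps) * bb, ubb))
            elif target.mode == "down":
                f_int = (lbf, (1 - d) * bf + d * lbf)
                b_int = ((1 - d) * bb + d * ubb, ubb)
            else:  # knockout, not buffered
                f_int = (0.0, 0.0)
                b_int = (0.0, 0.0)
            _intersect(box, f_int, b_int, rxn_id)

    overrides = {rid: tuple(box) for rid, box in boxes.items()}
    scheme.induced_bounds.update(overrides)
    return split.with_bounds(overrides)


def apply_metabolite_regulation(
    split: SplitModel,
    model: StoichiometricModel,
    template: Template,
    scheme: RegulationScheme,
) -> SplitModel:
    """Apply metabolite-centric (antimetabolite) regulation bounds.

    Every producing direction of the target species — forward flux of
    reactions with a positive coefficient, backward flux of reversible
    reactions with a negative coefficient — is scaled by the delta convex
    combination, or zeroed for knockout.  Consuming directions are left
    untouched.  The target may be a full species id (``orot[c]``) or a
    base id matching every compartment copy.
    """
    met_targets = [t for t in scheme.targets if t.kind == "metabolite"]
    boxes: dict[str, list[float]] = {}
    met_ids = {m.id for m in model.metabolites}
    base_map: dict[str, list[str]] = {}
    for m in model.metabolites:
        base_map.setdefault(m.base_id, []).append(m.id)

    for target in met_targets:
        if target.target_id in met_ids:
            species = [target.target_id]
        elif target.target_id in base_map:
            species = base_map[target.target_id]
        else:
            raise KeyError(f"unknown metabolite target {target.target_id!r}")
        d = target.delta
        touched = 0
        for met_id in species:
            for rxn_id, coeff in model.producers_of(met_id):
                j = model.reaction_index(rxn_id)
                if rxn_id not in boxes:
                    boxes[rxn_id] = [split.vf_lb[j], split.vf_ub[j],
                                     split.vb_lb[j], split.vb_ub[j]]
                box = boxes[rxn_id]
                lbf, ubf = split.vf_lb[j], split.vf_ub[j]
                lbb, ubb = split.vb_lb[j], split.vb_ub[j]
                bf = max(0.0, template.basal_vf.get(rxn_id, 0.0))
                bb = max(0.0, template.basal_vb.get(rxn_id, 0.0))
                f_int = b_int = None
                if coeff > 0:  # forward direction produces the metabolite
                    touched += 1
                    if target.mode == "knockout":
                        f_int = (0.0, 0.0)
                    elif target.mode == "down":
                        f_int = (lbf, (1 - d) * bf + d * lbf)
                    else:
                        f_int = ((1 - d) * bf + d * ubf, ubf)
                elif ubb > 0:  # reverse direction of a reversible consumer
                    touched += 1
                    if target.mode == "knockout":
                        b_int = (0.0, 0.0)
                    elif target.mode == "down":
                        b_int = (lbb, (1 - d) * bb + d * lbb)
                    else:
                        b_int = ((1 - d) * bb + d * ubb, ubb)
                _intersect(box, f_int, b_int, rxn_id)
        if touched == 0:
            warnings.warn(
                f"metabolite target {target.target_id!r} has no producing "
                "reaction directions; regulation is a no-op",
                stacklevel=2,
            )

    overrides = {rid: tuple(box) for rid, box in boxes.items()}
    scheme.induced_bounds.update(overrides)
    return split.with_bounds(overrides)


def build_regulated_split(
    split: SplitModel,
    gpr: GPRModel,
    template: Template,
    scheme: RegulationScheme,
) -> SplitModel:
    """Apply both enzyme- and metabolite-centric targets of one scheme."""
    regulated = split
    if any(t.kind == "enzyme" for t in scheme.targets):
        regulated = apply_gene_regulation(regulated, gpr, template, scheme)
    if any(t.kind == "metabolite" for t in scheme.targets):
        regulated = apply_metabolite_regulation(
            regulated, split.base, template, scheme
        )
    return regulated


# ---------------------------------------------------------------------------
# FBA (LP)
# ---------------------------------------------------------------------------

def solve_fba(
    split: SplitModel,
    objective: str,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> FluxState:
    """Maximize the biomass or ATP net flux; infeasibility is a valid
    outcome (lethal perturbation) and returns a zero state."""
    model = split.base
    obj_rxn = _objective_rxn(model, objective)
    a_eq, bounds = _split_matrices(split)
    c = -_objective_row(split, obj_rxn)
    res = linprog(
        c,
        A_eq=a_eq,
        b_eq=np.zeros(a_eq.shape[0]),
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": settings.feasibility_tol,
            "dual_feasibility_tolerance": settings.feasibility_tol,
        },
    )
    if res.status == 2:
        return _zero_state(model)
    if res.status == 3:
        raise ConfigurationError(
            f"model {model.id!r}: unbounded {objective} objective "
            "(missing exchange caps)"
        )
    if not res.success:  # pragma: no cover - solver-dependent
        raise RuntimeError(f"LP solver failure: {res.message}")
    residual = float(np.max(np.abs(a_eq @ res.x))) if a_eq.size else 0.0
    return _make_state(model, res.x, float(-res.fun), residual)


# ---------------------------------------------------------------------------
# UFD (QP)
# ---------------------------------------------------------------------------

def _weight_vector(split: SplitModel, weights: dict[str, float]) -> np.ndarray:
    """Diagonal QP weights: c_k on both directions of internal reactions,
    0 on exchange reactions (outside the penalty set)."""
    n = split.n_reactions
    w = np.zeros(2 * n)
    internal = set(split.internal_set)
    for j, rxn in enumerate(split.base.reactions):
        if rxn.id in internal:
            ck = weights.get(rxn.id, 1.0)
            w[j] = ck
            w[n + j] = ck
    return w


def solve_ufd(
    split: SplitModel,
    weights: dict[str, float],
    floor: tuple[str, float],
    x0: np.ndarray | None = None,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> FluxState:
    """Minimize the confidence-weighted squared flux with an objective floor.

    ``floor`` is ``(objective, value)`` with the value taken from
    :func:`solve_fba` on the same bounded model; a vanishing slack keeps
    the floor numerically attainable at the LP vertex.
    """
    model = split.base
    obj_rxn = _objective_rxn(model, floor[0])
    floor_value = floor[1] - settings.floor_slack * max(1.0, abs(floor[1]))
    a_eq, box = _split_matrices(split)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    w = _weight_vector(split, weights)
    obj_row = _objective_row(split, obj_rxn)

    if x0 is None:
        fba = solve_fba(split, floor[0], settings)
        if fba.status != "optimal":
            return _zero_state(model)
        n = split.n_reactions
        ids = model.reaction_ids
        x0 = np.concatenate(
            [[fba.v_f[i] for i in ids], [fba.v_b[i] for i in ids]]
        )
    x0 = np.clip(x0, lo, hi)

    def fun(x):
        return float(w @ (x * x))

    def jac(x):
        return 2.0 * w * x

    def acceptable(x):
        if x is None:
            return False
        resid = float(np.max(np.abs(a_eq @ x))) if a_eq.size else 0.0
        return (
            resid <= settings.residual_tol
            and obj_row @ x >= floor_value - 1e-6
            and np.all(x >= lo - settings.residual_tol)
            and np.all(x <= hi + settings.residual_tol)
        )

    def run_slsqp(start, lo_run, hi_run):
        res = minimize(
            fun,
            np.clip(start, lo_run, hi_run),
            jac=jac,
            bounds=Bounds(lo_run, hi_run),
            constraints=[
                {"type": "eq", "fun": lambda x: a_eq @ x,
                 "jac": lambda x: a_eq},
                {"type": "ineq", "fun": lambda x: obj_row @ x - floor_value,
                 "jac": lambda x: obj_row},
            ],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        return np.clip(res.x, lo_run, hi_run)

    # SLSQP (active-set SQP) converges in a handful of iterations on this
    # QP and lands exactly on active bounds; the interior-point fallback
    # is more tolerant of difficult active sets but leaves O(barrier)
    # slack on inactive variables.
    candidates: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        x = run_slsqp(x0, lo, hi)
        if acceptable(x):
            candidates.append(x)
            # polish: pin near-zero dust to its zero bound and re-solve;
            # kept only if still feasible and no worse
            dust = (x < 1e-4) & (lo <= 0.0) & (x > 0.0)
            if np.any(dust):
                hi_p = hi.copy()
                hi_p[dust] = 0.0
                xp = run_slsqp(x, lo, hi_p)
                if acceptable(xp) and fun(xp) <= fun(x) + 1e-9 * (1 + fun(x)):
                    candidates.append(xp)
        if not candidates:
            res = minimize(
                fun,
                x0,
                jac=jac,
                hess=lambda x: np.diag(2.0 * w),
                bounds=Bounds(lo, hi),
                constraints=[
                    LinearConstraint(a_eq, 0.0, 0.0),
                    LinearConstraint(obj_row, floor_value, np.inf),
                ],
                method="trust-constr",
                options={
                    "gtol": settings.qp_gtol,
                    "xtol": settings.qp_xtol,
                    "maxiter": settings.qp_maxiter,
                },
            )
            x = np.clip(res.x, lo, hi)
            if acceptable(x):
                candidates.append(x)
    # prefer the most refined acceptable answer; the FBA start is always
    # feasible, so the QP never gets worse than it
    x = candidates[-1] if candidates else x0
    residual = float(np.max(np.abs(a_eq @ x))) if a_eq.size else 0.0
    return _make_state(model, x, float(fun(x)), residual)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def compute_template(
    model: StoichiometricModel,
    weights: dict[str, float],
    tag: str,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> Template:
    """Basal FBA+UFD state of an unperturbed model.

    The CA template maximizes biomass, the HT template ATP production;
    the UFD flux pattern at the optimum floor provides basal fluxes,
    metabolite flow rates and the standard levels of all membership
    specs.
    """
    if tag not in ("CA", "HT"):
        raise ValueError(f"template tag must be 'CA' or 'HT', got {tag!r}")
    objective = "biomass" if tag == "CA" else "atp"
    split = split_reversible(model)
    fba = solve_fba(split, objective, settings)
    if fba.status != "optimal":
        raise ConfigurationError(
            f"unperturbed {tag} model {model.id!r} is infeasible"
        )
    optimum = fba.objective_value
    ufd = solve_ufd(
        split, weights,
        (objective, settings.floor_fraction * optimum),
        settings=settings,
    )
    if ufd.status != "optimal":  # pragma: no cover - floor comes from FBA
        raise ConfigurationError(f"UFD failed on unperturbed {tag} model")
    return Template(
        model_tag=tag,
        basal_vf=dict(ufd.v_f),
        basal_vb=dict(ufd.v_b),
        rates=dict(ufd.rates),
        v_biomass=ufd.v_biomass,
        v_atp=ufd.v_atp,
        fba_optimum=optimum,
        state=ufd,
    )
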