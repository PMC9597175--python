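"""Nested hybrid differential evolution (NHDE) for the outer search.

The outer decision problem is mixed-integer: choose target identities
``z`` (enzymes or metabolites, one per slot) and continuous modulation
parameters ``delta`` to maximize the hierarchical decision grade
``eta_D``.  Every fitness evaluation nests the full inner pipeline —
regulated FBA + UFD on the cancer model and on the healthy model,
followed by all membership grades.

The evolutionary loop is a hybrid differential evolution:

* DE/rand/1 mutation on the continuous encoding (target slots are real
  numbers decoded by flooring; deltas live in [0, 1]),
* binomial crossover with one forced component,
* greedy one-to-one selection on the lexicographic key
  ``(eta_D, eta_TR)`` — the elite is never lost,
* migration: when the population's diversity around the best individual
  collapses, a fraction of it is re-randomized.

Fitness evaluations are memoized on ``(targets, modes, quantized
delta)``; the memo doubles as the result *archive*, so optimization
returns every distinct target set it visited, ranked by
``(eta_D, eta_MD)`` — screening reports top-k lists, not a single
winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fuzzy_grades import (
    GradeSet,
    MembershipSpec,
    SPEC_EPS,
    decision_grade,
    deviation_grade,
    grade_max,
    grade_min,
    mean_min,
    two_sided_specs_from_template,
)
from .gpr_logic import GPRModel
from .inner_solvers import (
    BoundConflictError,
    DEFAULT_SETTINGS,
    RegulationScheme,
    RegulationTarget,
    SolverSettings,
    Template,
    build_regulated_split,
    compute_template,
    solve_fba,
    solve_ufd,
)
from .metnet_io import SplitModel, StoichiometricModel, split_reversible

__all__ = [
    "NHDEParams",
    "Individual",
    "ArchiveEntry",
    "EvaluationContext",
    "build_context",
    "evaluate_targets",
    "step",
    "optimize",
]

#: template values below this are treated as zero when building the
#: comparison universe
ZERO_FLUX_TOL = 1e-6


@dataclass
class NHDEParams:
    population_size: int = 20
    mutation_factor: float = 0.5
    crossover_rate: float = 0.8
    max_generations: int = 200
    migration_tolerance: float = 1e-3
    migration_fraction: float = 0.8
    delta_quantum: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if not 0.0 < self.mutation_factor <= 2.0:
            raise ValueError("mutation_factor must lie in (0, 2]")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")


@dataclass
class Individual:
    z: tuple[int, ...]
    modes: tuple[str, ...]
    delta: tuple[float, ...]
    grades: GradeSet | None = None
    feasible: bool = True

    def key(self) -> tuple:
        return (self.z, self.modes, self.delta)


@dataclass
class ArchiveEntry:
    targets: tuple[RegulationTarget, ...]
    grades: GradeSet
    feasible: bool


# ---------------------------------------------------------------------------
# Evaluation context
# ---------------------------------------------------------------------------

@dataclass
class EvaluationContext:
    """Everything a fitness evaluation needs, prepared once."""

    ca_model: StoichiometricModel
    ht_model: StoichiometricModel
    ca_gpr: GPRModel
    ht_gpr: GPRModel
    ca_split: SplitModel
    ht_split: SplitModel
    ca_template: Template
    ht_template: Template
    epsilon: float
    settings: SolverSettings
    mortality_biomass_spec: MembershipSpec
    mortality_atp_spec: MembershipSpec
    viability_biomass_spec: MembershipSpec
    viability_atp_spec: MembershipSpec
    ca_flux_specs: dict[str, MembershipSpec]
    ht_flux_specs: dict[str, MembershipSpec]
    ca_rate_specs: dict[str, MembershipSpec]
    ht_rate_specs: dict[str, MembershipSpec]
    cache: dict[tuple, GradeSet] = field(default_factory=dict)


def _directional_values(template: Template) -> dict[str, float]:
    vals = {}
    for rid, v in template.basal_vf.items():
        vals[f"{rid}:f"] = v
    for rid, v in template.basal_vb.items():
        vals[f"{rid}:b"] = v
    return vals


def _state_flux_values(state) -> dict[str, float]:
    vals = {}
    for rid, v in state.v_f.items():
        vals[f"{rid}:f"] = v
    for rid, v in state.v_b.items():
        vals[f"{rid}:b"] = v
    return vals


def build_context(
    ca_model: StoichiometricModel,
    ht_model: StoichiometricModel,
    ca_gpr: GPRModel,
    ht_gpr: GPRModel,
    epsilon: float = 0.03,
    alpha: float = 1.0,
    w_min_factor: float = 0.1,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> EvaluationContext:
    """Compute both templates and freeze all membership specs.

    The comparison universe for the deviation grades is the set of
    internal reaction directions (and base metabolites) shared by both
    models that carry a nonzero flux (flow rate) in at least one
    template; all-zero elements have no deviation signal.
    """
    ca_template = compute_template(ca_model, ca_gpr.weights, "CA", settings)
    ht_template = compute_template(ht_model, ht_gpr.weights, "HT", settings)

    ca_dir = _directional_values(ca_template)
    ht_dir = _directional_values(ht_template)
    shared_internal = set(ca_model.internal_reaction_ids()) & set(
        ht_model.internal_reaction_ids()
    )
    flux_keys = sorted(
        key
        for rid in shared_internal
        for key in (f"{rid}:f", f"{rid}:b")
        if abs(ca_dir.get(key, 0.0)) > ZERO_FLUX_TOL
        or abs(ht_dir.get(key, 0.0)) > ZERO_FLUX_TOL
    )
    shared_bases = {m.base_id for m in ca_model.metabolites} & {
        m.base_id for m in ht_model.metabolites
    }
    rate_keys = sorted(
        b
        for b in shared_bases
        if abs(ca_template.rates.get(b, 0.0)) > ZERO_FLUX_TOL
        or abs(ht_template.rates.get(b, 0.0)) > ZERO_FLUX_TOL
    )
    if not flux_keys or not rate_keys:
        raise ValueError("CA/HT comparison universe is empty")

    def one_sided(kind, ub):
        return MembershipSpec(kind=kind, LB=0.0, UB=max(ub, SPEC_EPS))

    return EvaluationContext(
        ca_model=ca_model,
        ht_model=ht_model,
        ca_gpr=ca_gpr,
        ht_gpr=ht_gpr,
        ca_split=split_reversible(ca_model),
        ht_split=split_reversible(ht_model),
        ca_template=ca_template,
        ht_template=ht_template,
        epsilon=epsilon,
        settings=settings,
        mortality_biomass_spec=one_sided("min_one_sided", ca_template.v_biomass),
        mortality_atp_spec=one_sided("min_one_sided", ca_template.v_atp),
        viability_biomass_spec=one_sided("min_one_sided", ht_template.v_biomass),
        viability_atp_spec=one_sided("max_one_sided", ht_template.v_atp),
        ca_flux_specs=two_sided_specs_from_template(
            ca_dir, flux_keys, alpha, w_min_factor
        ),
        ht_flux_specs=two_sided_specs_from_template(
            ht_dir, flux_keys, alpha, w_min_factor
        ),
        ca_rate_specs=two_sided_specs_from_template(
            ca_template.rates, rate_keys, alpha, w_min_factor, nonnegative=False
        ),
        ht_rate_specs=two_sided_specs_from_template(
            ht_template.rates, rate_keys, alpha, w_min_factor, nonnegative=False
        ),
    )


# ---------------------------------------------------------------------------
# Fitness evaluation (the nested inner problems)
# ---------------------------------------------------------------------------

def _resolves(target: RegulationTarget, model: StoichiometricModel,
              gpr: GPRModel) -> bool:
    if target.kind == "enzyme":
        return any(e.id == target.target_id for e in gpr.feasible_enzymes)
    return target.target_id in {m.id for m in model.metabolites} or (
        target.target_id in {m.base_id for m in model.metabolites}
    )


def _inner_pipeline(ctx, split, gpr, template, targets, objective):
    """Regulate, FBA, then UFD.  Returns (state, status)."""
    applicable = [
        t for t in targets if _resolves(t, split.base, gpr)
    ]
    scheme = RegulationScheme(targets=applicable, epsilon=ctx.epsilon)
    regulated = build_regulated_split(split, gpr, template, scheme)
    fba = solve_fba(regulated, objective, ctx.settings)
    if fba.status != "optimal":
        return fba, "infeasible"
    ufd = solve_ufd(
        regulated,
        gpr.weights,
        (objective, ctx.settings.floor_fraction * fba.objective_value),
        settings=ctx.settings,
    )
    return ufd, ufd.status


def _targets_key(targets: tuple[RegulationTarget, ...],
                 quantum: float) -> tuple:
    items = []
    for t in targets:
        qd = 0.0 if t.mode == "knockout" else round(round(t.delta / quantum) * quantum, 9)
        items.append((t.kind, t.target_id, t.mode, qd))
    return tuple(sorted(items))


def evaluate_targets(
    targets: tuple[RegulationTarget, ...] | list[RegulationTarget],
    ctx: EvaluationContext,
    delta_quantum: float = 1e-3,
) -> GradeSet:
    """Grade one candidate target set through the full nested pipeline.

    Inner infeasibility (a lethal perturbation) maps the affected state
    to zero fluxes, which the membership functions then grade; a bound
    conflict marks the candidate infeasible with all grades zero.
    Results are memoized in the context.
    """
    targets = tuple(targets)
    key = _targets_key(targets, delta_quantum)
    if key in ctx.cache:
        return ctx.cache[key]

    try:
        ca_state, ca_status = _inner_pipeline(
            ctx, ctx.ca_split, ctx.ca_gpr, ctx.ca_template, targets, "biomass"
        )
        ht_state, ht_status = _inner_pipeline(
            ctx, ctx.ht_split, ctx.ht_gpr, ctx.ht_template, targets, "atp"
        )
    except BoundConflictError:
        grades = GradeSet(status_ca="bound_conflict", status_ht="bound_conflict")
        ctx.cache[key] = grades
        return grades

    eta_biomass_tr = grade_min(ca_state.v_biomass, ctx.mortality_biomass_spec)
    eta_atp_tr = grade_min(ca_state.v_atp, ctx.mortality_atp_spec)
    eta_tr = mean_min([eta_biomass_tr, eta_atp_tr])

    eta_biomass_pb = grade_min(ht_state.v_biomass, ctx.viability_biomass_spec)
    eta_atp_pb = grade_max(ht_state.v_atp, ctx.viability_atp_spec)
    eta_cv = mean_min([eta_biomass_pb, eta_atp_pb])

    f_ca, m_ca, f_bl, m_bl, eta_md = deviation_grade(
        _state_flux_values(ht_state),
        ht_state.rates,
        ctx.ca_flux_specs,
        ctx.ht_flux_specs,
        ctx.ca_rate_specs,
        ctx.ht_rate_specs,
    )
    grades = GradeSet(
        eta_biomass_tr=eta_biomass_tr,
        eta_atp_tr=eta_atp_tr,
        eta_tr=eta_tr,
        eta_biomass_pb=eta_biomass_pb,
        eta_atp_pb=eta_atp_pb,
        eta_cv=eta_cv,
        eta_f_pbca=f_ca,
        eta_m_pbca=m_ca,
        eta_f_pbbl=f_bl,
        eta_m_pbbl=m_bl,
        eta_md=eta_md,
        eta_d=decision_grade(eta_tr, eta_cv, eta_md),
        status_ca=ca_status,
        status_ht=ht_status,
    )
    ctx.cache[key] = grades
    return grades


# ---------------------------------------------------------------------------
# The evolutionary loop
# ---------------------------------------------------------------------------

@dataclass
class _Population:
    """Continuous encoding: Z in [0, n_s) per slot, D (delta) in [0, 1]."""

    groups: list[list[RegulationTarget]]
    Z: np.ndarray
    D: np.ndarray
    individuals: list[Individual]


def _decode(groups, zrow, drow, quantum, rng) -> Individual:
    slots = len(groups)
    idx = []
    for s in range(slots):
        n_s = len(groups[s])
        i = int(np.floor(zrow[s]))
        i = min(max(i, 0), n_s - 1)
        idx.append(i)
    # repair duplicate targets across slots (possible with overlapping groups)
    for s in range(1, slots):
        seen = {
            (groups[t].__getitem__(idx[t]).kind, groups[t][idx[t]].target_id)
            for t in range(s)
        }
        tries = 0
        while (
            (groups[s][idx[s]].kind, groups[s][idx[s]].target_id) in seen
            and tries < 50
        ):
            idx[s] = int(rng.integers(len(groups[s])))
            tries += 1
    modes = tuple(groups[s][idx[s]].mode for s in range(slots))
    delta = tuple(
        round(round(float(np.clip(drow[s], 0.0, 1.0)) / quantum) * quantum, 9)
        for s in range(slots)
    )
    return Individual(z=tuple(idx), modes=modes, delta=delta)


def _targets_of(groups, ind: Individual) -> tuple[RegulationTarget, ...]:
    return tuple(
        replace(groups[s][ind.z[s]], delta=ind.delta[s])
        for s in range(len(groups))
    )


def _fitness_key(ind: Individual) -> tuple[float, float]:
    if ind.grades is None or not ind.feasible:
        return (-1.0, -1.0)
    return (ind.grades.eta_d, ind.grades.eta_tr)


def _evaluate_individual(groups, ind, ctx, quantum,
                         visited: set | None = None) -> Individual:
    targets = _targets_of(groups, ind)
    if visited is not None:
        visited.add(_targets_key(targets, quantum))
    grades = evaluate_targets(targets, ctx, quantum)
    ind.grades = grades
    ind.feasible = grades.status_ca != "bound_conflict"
    return ind


def _diversity(pop: _Population, best: int) -> float:
    z_best, d_best = pop.Z[best], pop.D[best]
    zb = np.floor(pop.Z).astype(int)
    z_div = float(np.mean(zb != np.floor(z_best).astype(int)))
    d_div = float(np.mean(np.abs(pop.D - d_best)))
    return z_div + d_div


def step(
    pop: _Population,
    params: NHDEParams,
    ctx: EvaluationContext,
    rng: np.random.Generator,
    visited: set | None = None,
) -> _Population:
    """One generation: mutation, crossover, greedy selection, migration."""
    n, slots = pop.Z.shape
    keys = [_fitness_key(ind) for ind in pop.individuals]
    best = int(np.argmax([k[0] * 1e6 + k[1] for k in keys]))

    for i in range(n):
        choices = [j for j in range(n) if j != i]
        r1, r2, r3 = rng.choice(choices, size=3, replace=False)
        mz = pop.Z[r1] + params.mutation_factor * (pop.Z[r2] - pop.Z[r3])
        md = pop.D[r1] + params.mutation_factor * (pop.D[r2] - pop.D[r3])
        # binomial crossover over the concatenated (z, delta) genome
        trial_z = pop.Z[i].copy()
        trial_d = pop.D[i].copy()
        genome_len = 2 * slots
        j_rand = int(rng.integers(genome_len))
        for g in range(genome_len):
            if rng.random() < params.crossover_rate or g == j_rand:
                if g < slots:
                    trial_z[g] = mz[g]
                else:
                    trial_d[g - slots] = md[g - slots]
        for s in range(slots):
            n_s = len(pop.groups[s])
            trial_z[s] = float(np.clip(trial_z[s], 0.0, n_s - 1e-9))
        trial_d = np.clip(trial_d, 0.0, 1.0)
        trial = _decode(pop.groups, trial_z, trial_d, params.delta_quantum, rng)
        _evaluate_individual(pop.groups, trial, ctx, params.delta_quantum, visited)
        if _fitness_key(trial) >= _fitness_key(pop.individuals[i]):
            pop.Z[i] = trial_z
            pop.D[i] = trial_d
            pop.individuals[i] = trial

    keys = [_fitness_key(ind) for ind in pop.individuals]
    best = int(np.argmax([k[0] * 1e6 + k[1] for k in keys]))
    if _diversity(pop, best) < params.migration_tolerance:
        _migrate(pop, best, params, ctx, rng, visited)
    return pop


def _random_rows(groups, n, rng):
    slots = len(groups)
    z = np.column_stack(
        [rng.uniform(0, len(groups[s]), size=n) for s in range(slots)]
    )
    d = rng.uniform(0.0, 1.0, size=(n, slots))
    return z, d


def _migrate(pop, best, params, ctx, rng, visited=None) -> None:
    n = pop.Z.shape[0]
    others = [i for i in range(n) if i != best]
    n_migrate = max(1, int(round(params.migration_fraction * len(others))))
    picked = rng.choice(others, size=n_migrate, replace=False)
    z_new, d_new = _random_rows(pop.groups, n_migrate, rng)
    for row, i in enumerate(picked):
        pop.Z[i] = z_new[row]
        pop.D[i] = d_new[row]
        ind = _decode(pop.groups, pop.Z[i], pop.D[i], params.delta_quantum, rng)
        pop.individuals[i] = _evaluate_individual(
            pop.groups, ind, ctx, params.delta_quantum, visited
        )


def _archive_from_cache(ctx, visited) -> list[ArchiveEntry]:
    entries = []
    for key in visited:
        grades = ctx.cache[key]
        targets = tuple(
            RegulationTarget(target_id=tid, mode=mode, delta=qd, kind=kind)
            for kind, tid, mode, qd in key
        )
        entries.append(
            ArchiveEntry(
                targets=targets,
                grades=grades,
                feasible=grades.status_ca != "bound_conflict",
            )
        )
    entries.sort(
        key=lambda e: (
            -round(e.grades.eta_d, 9),   # grades tied at solver precision
            -round(e.grades.eta_md, 9),  # break deterministically by id
            tuple(t.target_id for t in e.targets),
        )
    )
    return entries


def optimize(
    candidate_groups: list[list[RegulationTarget]],
    params: NHDEParams,
    ctx: EvaluationContext,
) -> list[ArchiveEntry]:
    """Run NHDE over one candidate group per target slot.

    Returns the archive of all distinct evaluated target sets ranked by
    ``(eta_D, eta_MD)``; the first entry is the incumbent optimum.
    Seeded runs are reproducible.
    """
    if not candidate_groups or any(len(g) == 0 for g in candidate_groups):
        raise ValueError("every candidate group must be non-empty")
    rng = np.random.default_rng(params.seed)
    n = params.population_size
    visited: set[tuple] = set()
    z, d = _random_rows(candidate_groups, n, rng)
    individuals = [
        _evaluate_individual(
            candidate_groups,
            _decode(candidate_groups, z[i], d[i], params.delta_quantum, rng),
            ctx,
            params.delta_quantum,
            visited,
        )
        for i in range(n)
    ]
    pop = _Population(groups=candidate_groups, Z=z, D=d, individuals=individuals)
    for _ in range(params.max_generations):
        pop = step(pop, params, ctx, rng, visited)
    return _archive_from_cache(ctx, visited)
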