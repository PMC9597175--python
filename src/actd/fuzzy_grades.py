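"""Fuzzy membership grades for the anti-cancer target decision problem.

Every therapeutic goal is scored on [0, 1] by a linear membership
function:

* :func:`grade_min` — fuzzy minimization (1 below LB, ramp down to 0 at
  UB); used for the treated cancer cell's growth and ATP production and
  for the perturbed healthy cell's growth,
* :func:`grade_max` — fuzzy maximization (its mirror); used for the
  perturbed healthy cell's ATP production,
* :func:`grade_two_sided` — fuzzy similarity to a standard level ST with
  linear ramps to 0 at LB and UB; fuzzy *dissimilarity* is its complement.

Grade vectors are aggregated with the mean–min operator
``(mean + min) / 2``, which discriminates grade vectors of equal mean.
The module also computes compartment-pooled metabolite flow rates, the
overall metabolic-deviation grade (mean–min of four similarity /
dissimilarity grades of the perturbed healthy cell against the healthy
and cancer templates) and the hierarchical decision objective
``eta_D = (eta_TR + min{eta_TR, eta_CV, eta_MD}) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .metnet_io import StoichiometricModel

__all__ = [
    "MembershipSpec",
    "GradeSet",
    "grade_min",
    "grade_max",
    "grade_two_sided",
    "mean_min",
    "flow_rates",
    "two_sided_specs_from_template",
    "deviation_grade",
    "decision_grade",
]

#: floor applied to auto-built UBs so template values of exactly zero give
#: an indicator-like ramp instead of a degenerate spec
SPEC_EPS = 1e-6


@dataclass(frozen=True)
class MembershipSpec:
    """Parameters of one membership function."""

    kind: str  # 'min_one_sided' | 'max_one_sided' | 'two_sided'
    LB: float
    UB: float
    ST: float | None = None

    def __post_init__(self) -> None:
        if self.LB >= self.UB:
            raise ValueError(f"membership spec requires LB < UB, got {self}")
        if self.kind == "two_sided":
            if self.ST is None or not (self.LB <= self.ST <= self.UB):
                raise ValueError(f"two-sided spec requires LB <= ST <= UB: {self}")


def grade_min(FV: float, spec: MembershipSpec) -> float:
    """Fuzzy-minimization grade: 1 below LB, (UB-FV)/(UB-LB) inside, 0 above."""
    if FV < spec.LB:
        return 1.0
    if FV > spec.UB:
        return 0.0
    return (spec.UB - FV) / (spec.UB - spec.LB)


def grade_max(FV: float, spec: MembershipSpec) -> float:
    """Fuzzy-maximization grade: 0 below LB, (FV-LB)/(UB-LB) inside, 1 above."""
    if FV < spec.LB:
        return 0.0
    if FV > spec.UB:
        return 1.0
    return (FV - spec.LB) / (spec.UB - spec.LB)


def grade_two_sided(PB: float, spec: MembershipSpec) -> float:
    """Fuzzy similarity to ST: 1 at ST, ramps to 0 at LB and UB, clamped.

    Degenerate half-widths (ST == LB or ST == UB) collapse the ramp on
    that side to an indicator.
    """
    ST = spec.ST
    if PB >= ST:
        left = 1.0
    elif spec.ST > spec.LB:
        left = (PB - spec.LB) / (ST - spec.LB)
    else:
        left = 0.0
    if PB <= ST:
        right = 1.0
    elif spec.UB > ST:
        right = (spec.UB - PB) / (spec.UB - ST)
    else:
        right = 0.0
    return max(min(left, right, 1.0), 0.0)


def mean_min(grades: Sequence[float]) -> float:
    """Mean–min aggregation ``(mean(g) + min(g)) / 2``."""
    if len(grades) == 0:
        raise ValueError("mean_min of an empty grade list")
    g = np.asarray(grades, dtype=float)
    return float((g.mean() + g.min()) / 2.0)


# ---------------------------------------------------------------------------
# Metabolite flow rates
# ---------------------------------------------------------------------------

def flow_rates(
    v_f: Mapping[str, float] | np.ndarray,
    v_b: Mapping[str, float] | np.ndarray,
    model: "StoichiometricModel",
) -> dict[str, float]:
    """Compartment-pooled production rate per base metabolite.

    For each species copy (one per compartment) the producing
    contributions are summed: positive-coefficient forward fluxes plus
    reverse fluxes through negative-coefficient (consuming) directions —
    the backward term enters with ``-N_ij * v_b_j`` where ``N_ij < 0``,
    i.e. production via the reverse direction.  Copies sharing a base id
    are then pooled across compartments.
    """
    if not isinstance(v_f, Mapping):
        ids = model.reaction_ids
        v_f = dict(zip(ids, np.asarray(v_f, dtype=float)))
        v_b = dict(zip(ids, np.asarray(v_b, dtype=float)))
    rates: dict[str, float] = {}
    for rxn in model.reactions:
        vf = v_f.get(rxn.id, 0.0)
        vb = v_b.get(rxn.id, 0.0)
        for met_id, coeff in rxn.stoich.items():
            base = model.metabolite(met_id).base_id
            if coeff > 0:
                rates[base] = rates.get(base, 0.0) + coeff * vf
            else:
                rates[base] = rates.get(base, 0.0) - coeff * vb
    return rates


# ---------------------------------------------------------------------------
# Grade set and hierarchical objective
# ---------------------------------------------------------------------------

@dataclass
class GradeSet:
    """All membership grades of one evaluated candidate."""

    eta_biomass_tr: float = 0.0
    eta_atp_tr: float = 0.0
    eta_tr: float = 0.0
    eta_biomass_pb: float = 0.0
    eta_atp_pb: float = 0.0
    eta_cv: float = 0.0
    eta_f_pbca: float = 0.0
    eta_m_pbca: float = 0.0
    eta_f_pbbl: float = 0.0
    eta_m_pbbl: float = 0.0
    eta_md: float = 0.0
    eta_d: float = 0.0
    status_ca: str = "optimal"
    status_ht: str = "optimal"

    def as_dict(self) -> dict[str, float | str]:
        return dict(self.__dict__)


def decision_grade(eta_tr: float, eta_cv: float, eta_md: float) -> float:
    """Hierarchical objective ``(eta_TR + min{eta_TR, eta_CV, eta_MD}) / 2``.

    Cancer-cell mortality is the first priority: the decision grade never
    exceeds eta_TR and equals it when eta_TR is the smallest of the three.
    """
    return (eta_tr + min(eta_tr, eta_cv, eta_md)) / 2.0


# ---------------------------------------------------------------------------
# Deviation grades against templates
# ---------------------------------------------------------------------------

def two_sided_specs_from_template(
    values: Mapping[str, float],
    keys: Iterable[str],
    alpha: float = 1.0,
    w_min_factor: float = 0.1,
    nonnegative: bool = True,
) -> dict[str, MembershipSpec]:
    """Per-element two-sided specs anchored at template values.

    ST is the template value; the half-width is
    ``max(alpha * |ST|, w_min)`` with ``w_min = w_min_factor *
    median(|nonzero template values|)`` so zero-valued elements still get
    a scale-aware tolerance band.  For quantities that cannot be negative
    the LB is clipped at 0.
    """
    keys = list(keys)
    nonzero = [abs(values[k]) for k in keys if values.get(k, 0.0) != 0.0]
    w_min = w_min_factor * float(np.median(nonzero)) if nonzero else SPEC_EPS
    w_min = max(w_min, SPEC_EPS)
    specs = {}
    for k in keys:
        st = float(values.get(k, 0.0))
        w = max(alpha * abs(st), w_min)
        lb = max(0.0, st - w) if nonnegative and st >= 0 else st - w
        specs[k] = MembershipSpec(kind="two_sided", LB=lb, UB=st + w, ST=st)
    return specs


def deviation_grade(
    perturbed_flux: Mapping[str, float],
    perturbed_rates: Mapping[str, float],
    ca_flux_specs: Mapping[str, MembershipSpec],
    ht_flux_specs: Mapping[str, MembershipSpec],
    ca_rate_specs: Mapping[str, MembershipSpec],
    ht_rate_specs: Mapping[str, MembershipSpec],
) -> tuple[float, float, float, float, float]:
    """Overall metabolic-deviation grade of a perturbed healthy state.

    Returns ``(eta_f_pbca, eta_m_pbca, eta_f_pbbl, eta_m_pbbl, eta_md)``:
    mean per-element *dissimilarity* (1 - similarity) versus the cancer
    template, mean per-element *similarity* versus the healthy template —
    each for fluxes (f) and metabolite flow rates (m) — aggregated with
    the mean–min operator.  The spec maps define the comparison universe;
    it must be non-empty.
    """
    if not ca_flux_specs or not ht_flux_specs:
        raise ValueError("empty flux comparison universe")
    if not ca_rate_specs or not ht_rate_specs:
        raise ValueError("empty flow-rate comparison universe")

    def mean_grade(values, specs, complement):
        grades = []
        for key, spec in specs.items():
            g = grade_two_sided(float(values.get(key, 0.0)), spec)
            grades.append(1.0 - g if complement else g)
        return float(np.mean(grades))

    eta_f_pbca = mean_grade(perturbed_flux, ca_flux_specs, complement=True)
    eta_m_pbca = mean_grade(perturbed_rates, ca_rate_specs, complement=True)
    eta_f_pbbl = mean_grade(perturbed_flux, ht_flux_specs, complement=False)
    eta_m_pbbl = mean_grade(perturbed_rates, ht_rate_specs, complement=False)
    eta_md = mean_min([eta_f_pbca, eta_m_pbca, eta_f_pbbl, eta_m_pbbl])
    return eta_f_pbca, eta_m_pbca, eta_f_pbbl, eta_m_pbbl, eta_md
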