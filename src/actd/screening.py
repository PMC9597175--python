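"""Screening drivers: one-target enumeration, two-group pair search and
antimetabolite screening.

These drive the three study designs over a prepared
:class:`~actd.nhde.EvaluationContext`:

* :func:`enumerate_one_target` — brute-force evaluation of every
  candidate enzyme (or metabolite) individually,
* :func:`pair_search` — two-target search restricted to cross-group
  pairs (|G1| x |G2| combinations instead of C(n, 2)); exhaustive below
  a cap, NHDE above it,
* :func:`screen_antimetabolites` — the metabolite-centric pipeline in
  one- or two-target mode.

Results are ranked by the hierarchical key ``(eta_D, eta_MD, target
id)`` — mortality first, then side-effect grade — and round-trip to TSV.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .inner_solvers import RegulationTarget
from .nhde import (
    ArchiveEntry,
    EvaluationContext,
    NHDEParams,
    evaluate_targets,
    optimize,
)

__all__ = [
    "ScreeningResult",
    "enumerate_one_target",
    "pair_search",
    "count_search_space",
    "screen_antimetabolites",
    "enzyme_candidates",
    "metabolite_candidates",
]

_COLUMNS = [
    "targets", "modes", "delta", "eta_tr", "eta_cv", "eta_md", "eta_d",
    "status_ca", "status_ht",
]


@dataclass
class ScreeningResult:
    rows: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScreeningResult":
        rows = pd.read_csv(path, sep="\t", dtype={
            "targets": str, "modes": str, "delta": str,
            "status_ca": str, "status_ht": str,
        })
        return cls(rows=rows)


def _entries_to_result(entries: list[ArchiveEntry],
                       provenance: dict) -> ScreeningResult:
    records = []
    for e in entries:
        records.append(
            {
                "targets": "|".join(t.target_id for t in e.targets),
                "modes": "|".join(t.mode for t in e.targets),
                "delta": "|".join(f"{t.delta:g}" for t in e.targets),
                "eta_tr": e.grades.eta_tr,
                "eta_cv": e.grades.eta_cv,
                "eta_md": e.grades.eta_md,
                "eta_d": e.grades.eta_d,
                "status_ca": e.grades.status_ca,
                "status_ht": e.grades.status_ht,
            }
        )
    rows = pd.DataFrame.from_records(records, columns=_COLUMNS)
    return ScreeningResult(rows=rows, provenance=provenance)


def _rank(entries: list[ArchiveEntry]) -> list[ArchiveEntry]:
    # grades are rounded so that candidates tied at solver precision are
    # ordered deterministically by target id
    return sorted(
        entries,
        key=lambda e: (
            -round(e.grades.eta_d, 9),
            -round(e.grades.eta_md, 9),
            tuple(t.target_id for t in e.targets),
        ),
    )


def enzyme_candidates(ctx: EvaluationContext,
                      mode: str = "knockout") -> list[RegulationTarget]:
    """Feasible enzymes of the CA model as knockout candidates."""
    return [
        RegulationTarget(target_id=e.id, mode=mode, kind="enzyme")
        for e in ctx.ca_gpr.feasible_enzymes
    ]


def metabolite_candidates(ctx: EvaluationContext,
                          mode: str = "knockout") -> list[RegulationTarget]:
    """Internal CA metabolites with at least one producing direction."""
    model = ctx.ca_model
    exchange_mets = {
        next(iter(r.stoich)) for r in model.reactions if r.is_exchange and r.stoich
    }
    out = []
    for met in model.metabolites:
        if met.id in exchange_mets:
            continue
        producing = any(
            coeff > 0 or (coeff < 0 and model.reaction(rid).reversible)
            for rid, coeff in model.producers_of(met.id)
        )
        if producing:
            out.append(
                RegulationTarget(target_id=met.id, mode=mode, kind="metabolite")
            )
    return out


def enumerate_one_target(
    candidates: list[RegulationTarget],
    ctx: EvaluationContext,
) -> ScreeningResult:
    """Evaluate every candidate individually and rank the results."""
    if not candidates:
        warnings.warn("empty candidate list: returning empty result",
                      stacklevel=2)
        return ScreeningResult(rows=pd.DataFrame(columns=_COLUMNS))
    entries = []
    for cand in candidates:
        grades = evaluate_targets((cand,), ctx)
        entries.append(
            ArchiveEntry(
                targets=(cand,),
                grades=grades,
                feasible=grades.status_ca != "bound_conflict",
            )
        )
    return _entries_to_result(
        _rank(entries), {"design": "one_target", "n_candidates": len(candidates)}
    )


def count_search_space(n_candidates: int, k: int,
                       n_group2: int | None = None) -> int:
    """Candidate-combination count: C(n, k) unordered, or n1*n2 for the
    two-group design (``n_group2`` given)."""
    if n_group2 is not None:
        if n_candidates < 1 or n_group2 < 1:
            raise ValueError("group sizes must be positive")
        return n_candidates * n_group2
    if not 1 <= k <= n_candidates:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n_candidates}")
    return math.comb(n_candidates, k)


def pair_search(
    group1: list[RegulationTarget],
    group2: list[RegulationTarget],
    ctx: EvaluationContext,
    params: NHDEParams | None = None,
    exhaustive_cap: int = 2000,
) -> ScreeningResult:
    """Two-target search over cross-group pairs.

    Candidates shared with group1 are removed from group2.  Spaces of at
    most ``exhaustive_cap`` pairs are enumerated exactly; larger spaces
    are searched with NHDE using one slot per group.
    """
    if not group1 or not group2:
        raise ValueError("both candidate groups must be non-empty")
    g1_ids = {(t.kind, t.target_id) for t in group1}
    group2 = [t for t in group2 if (t.kind, t.target_id) not in g1_ids]
    if not group2:
        raise ValueError("group2 is empty after removing overlap with group1")
    space = count_search_space(len(group1), 2, n_group2=len(group2))
    provenance = {"design": "two_target", "space": space}

    if space <= exhaustive_cap:
        entries = []
        for a, b in itertools.product(group1, group2):
            grades = evaluate_targets((a, b), ctx)
            entries.append(
                ArchiveEntry(
                    targets=(a, b),
                    grades=grades,
                    feasible=grades.status_ca != "bound_conflict",
                )
            )
        provenance["method"] = "exhaustive"
        return _entries_to_result(_rank(entries), provenance)

    params = params or NHDEParams()
    entries = optimize([group1, group2], params, ctx)
    provenance["method"] = "nhde"
    return _entries_to_result(_rank(entries), provenance)


def screen_antimetabolites(
    metabolites: list[RegulationTarget] | None,
    ctx: EvaluationContext,
    params: NHDEParams | None = None,
    n_targets: int = 1,
    exhaustive_cap: int = 2000,
) -> ScreeningResult:
    """Metabolite-centric screening in one- or two-target mode.

    A knockout models antimetabolite inhibition: every producing
    direction of the metabolite is blocked.  The default candidate list
    is every internal metabolite with a producing reaction.
    """
    if metabolites is None:
        metabolites = metabolite_candidates(ctx)
    if n_targets == 1:
        return enumerate_one_target(metabolites, ctx)
    if n_targets != 2:
        raise ValueError("only one- and two-target modes are supported")
    half = (len(metabolites) + 1) // 2
    return pair_search(
        metabolites[:half], metabolites[half:], ctx,
        params=params, exhaustive_cap=exhaustive_cap,
    )
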