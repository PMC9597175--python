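"""Constraint-based metabolic model containers and I/O.

A :class:`StoichiometricModel` holds metabolites, reactions (with bounds,
gene–protein-reaction strings and confidence classes) and the identities of
the biomass and ATP-demand reactions.  Models are read and written in three
dialects:

* a two-file TSV bundle (``*_reactions.tsv`` + ``*_metabolites.tsv``) whose
  reaction rows carry a human-readable equation string such as
  ``"glc[c] -> 2 pyr[c] + 2 atp[c]"`` — hand-writable and diffable;
* a single JSON document;
* SBML Level 3 with the FBC extension, via :mod:`cobra`.

:func:`split_reversible` converts a model into the nonnegative
forward/backward flux form used by the inner flux-balance and
uniform-flux-distribution problems: every reaction *j* gets two variables
``v_f[j], v_b[j] >= 0`` with net flux ``v = v_f - v_b``, and the split
bounds reproduce the original net-flux interval exactly.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "SplitModel",
    "ModelFormatError",
    "ModelValidationError",
    "CONFIDENCE_CLASSES",
    "load_model",
    "save_model",
    "split_reversible",
]

CONFIDENCE_CLASSES = ("high", "medium", "negative", "other")

_COMPARTMENT_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[^\[\]]+)\]$")


class ModelFormatError(ValueError):
    """A model file could not be parsed."""


class ModelValidationError(ValueError):
    """A parsed model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A compartment-suffixed species, e.g. ``orot[c]``."""

    id: str
    base_id: str
    compartment: str

    @classmethod
    def from_id(cls, met_id: str) -> "Metabolite":
        m = _COMPARTMENT_RE.match(met_id)
        if m is None:
            # No explicit compartment: treat the whole id as the base and
            # place it in the default cytosol compartment.
            return cls(id=f"{met_id}[c]", base_id=met_id, compartment="c")
        return cls(id=met_id, base_id=m.group("base"), compartment=m.group("comp"))


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float
    ub: float
    gpr: str = ""
    confidence_class: str = "other"

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    @property
    def is_exchange(self) -> bool:
        """True for boundary reactions touching a single species."""
        return len(self.stoich) <= 1

    def validate(self) -> None:
        if self.lb > self.ub:
            raise ModelValidationError(
                f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}"
            )
        if not self.stoich and not self.is_exchange:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.confidence_class not in CONFIDENCE_CLASSES:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown confidence class "
                f"{self.confidence_class!r}"
            )
        for met, coeff in self.stoich.items():
            if coeff == 0 or not math.isfinite(coeff):
                raise ModelValidationError(
                    f"reaction {self.id!r}: coefficient {coeff} for {met!r}"
                )


@dataclass
class StoichiometricModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_rxn_id: str | None = None
    atp_rxn_id: str | None = None

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups ---------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites}

    def internal_reaction_ids(self) -> list[str]:
        """Non-exchange reactions (the UFD penalty set)."""
        return [r.id for r in self.reactions if not r.is_exchange]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense N with metabolites on rows, reactions on columns."""
        n = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoich.items():
                n[self._met_index[met_id], j] = coeff
        return n

    def producers_of(self, met_id: str) -> list[tuple[str, float]]:
        """(reaction id, coefficient) pairs with a nonzero coefficient."""
        return [
            (r.id, r.stoich[met_id]) for r in self.reactions if met_id in r.stoich
        ]

    # -- validation ------------------------------------------------------

    def validate(self, require_objectives: bool = True) -> None:
        if not self.reactions:
            raise ModelValidationError(f"model {self.id!r} has no reactions")
        seen_m: set[str] = set()
        for met in self.metabolites:
            if met.id in seen_m:
                raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
            seen_m.add(met.id)
            if not met.compartment:
                raise ModelValidationError(f"metabolite {met.id!r}: no compartment")
        seen_r: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            seen_r.add(rxn.id)
            rxn.validate()
            for met_id in rxn.stoich:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite "
                        f"{met_id!r}"
                    )
        if require_objectives:
            for label, rid in (("biomass", self.biomass_rxn_id),
                               ("ATP", self.atp_rxn_id)):
                if rid is None:
                    raise ModelValidationError(
                        f"model {self.id!r}: {label} reaction not configured"
                    )
                if rid not in self._rxn_index:
                    raise ModelValidationError(
                        f"model {self.id!r}: {label} reaction {rid!r} not found"
                    )


@dataclass
class SplitModel:
    """Forward/backward flux form of a stoichiometric model.

    Bound vectors are aligned with ``base.reactions``.  Irreversible
    reactions have ``vb_lb = vb_ub = 0``; a reaction forced backward
    (``ub < 0``) symmetrically has ``vf_lb = vf_ub = 0``.
    """

    base: StoichiometricModel
    vf_lb: np.ndarray
    vf_ub: np.ndarray
    vb_lb: np.ndarray
    vb_ub: np.ndarray

    @property
    def n_reactions(self) -> int:
        return len(self.base.reactions)

    @property
    def internal_set(self) -> list[str]:
        return self.base.internal_reaction_ids()

    def bounds_of(self, rxn_id: str) -> tuple[float, float, float, float]:
        j = self.base.reaction_index(rxn_id)
        return (self.vf_lb[j], self.vf_ub[j], self.vb_lb[j], self.vb_ub[j])

    def with_bounds(
        self, overrides: dict[str, tuple[float, float, float, float]]
    ) -> "SplitModel":
        """Copy with per-reaction (vf_lb, vf_ub, vb_lb, vb_ub) overrides."""
        new = SplitModel(
            base=self.base,
            vf_lb=self.vf_lb.copy(),
            vf_ub=self.vf_ub.copy(),
            vb_lb=self.vb_lb.copy(),
            vb_ub=self.vb_ub.copy(),
        )
        for rid, (flb, fub, blb, bub) in overrides.items():
            j = self.base.reaction_index(rid)
            new.vf_lb[j], new.vf_ub[j] = flb, fub
            new.vb_lb[j], new.vb_ub[j] = blb, bub
        return new


def split_reversible(model: StoichiometricModel) -> SplitModel:
    """Split each net flux v in [lb, ub] into v_f - v_b with v_f, v_b >= 0.

    ``vf_ub = max(0, ub)`` and ``vb_ub = max(0, -lb)``; positive lower
    bounds carry over to ``vf_lb`` (and mirrored for forced-backward
    reactions) so the net-flux feasible interval is preserved exactly.
    """
    n = len(model.reactions)
    vf_lb = np.zeros(n)
    vf_ub = np.zeros(n)
    vb_lb = np.zeros(n)
    vb_ub = np.zeros(n)
    for j, rxn in enumerate(model.reactions):
        vf_ub[j] = max(0.0, rxn.ub)
        vb_ub[j] = max(0.0, -rxn.lb)
        vf_lb[j] = max(0.0, rxn.lb)
        vb_lb[j] = max(0.0, -rxn.ub)
    return SplitModel(base=model, vf_lb=vf_lb, vf_ub=vf_ub, vb_lb=vb_lb, vb_ub=vb_ub)


# ---------------------------------------------------------------------------
# Equation-string dialect
# ---------------------------------------------------------------------------

_ARROW_RE = re.compile(r"\s*(<=>|<->|-->|->)\s*")


def _parse_side(side: str, sign: float, stoich: dict[str, float]) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ModelFormatError(f"empty term in equation side {side!r}")
        parts = term.split(None, 1)
        if len(parts) == 2:
            try:
                coeff = float(parts[0])
                met = parts[1].strip()
            except ValueError:
                coeff, met = 1.0, term
        else:
            coeff, met = 1.0, term
        stoich[met] = stoich.get(met, 0.0) + sign * coeff
    # cancel exact zeros created by a species on both sides
    for met in [m for m, c in stoich.items() if c == 0.0]:
        del stoich[met]


def parse_equation(equation: str) -> dict[str, float]:
    """Parse ``"2 A[c] + B[c] -> C[m]"`` into a stoichiometry map.

    ``->`` and ``<=>`` are interchangeable here: directionality comes from
    the bounds, not the arrow.  One side may be empty (boundary reaction).
    """
    pieces = _ARROW_RE.split(equation)
    if len(pieces) != 3:
        raise ModelFormatError(f"equation {equation!r}: expected one arrow")
    lhs, _, rhs = pieces
    stoich: dict[str, float] = {}
    _parse_side(lhs, -1.0, stoich)
    _parse_side(rhs, +1.0, stoich)
    return stoich


def format_equation(stoich: dict[str, float]) -> str:
    def fmt(items: list[tuple[str, float]]) -> str:
        terms = []
        for met, coeff in items:
            c = abs(coeff)
            terms.append(met if c == 1 else f"{c:g} {met}")
        return " + ".join(terms)

    lhs = sorted((m, c) for m, c in stoich.items() if c < 0)
    rhs = sorted((m, c) for m, c in stoich.items() if c > 0)
    return f"{fmt(lhs)} -> {fmt(rhs)}"


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_RXN_COLUMNS = ["id", "equation", "lb", "ub", "gpr", "confidence"]


def _load_tsv(path: Path, biomass_rxn_id: str | None,
              atp_rxn_id: str | None) -> StoichiometricModel:
    import pandas as pd

    rxn_path = Path(path)
    stem = rxn_path.name
    if "_reactions" not in stem:
        raise ModelFormatError(
            f"TSV models are loaded via their '*_reactions.tsv' file, got {stem!r}"
        )
    met_path = rxn_path.with_name(stem.replace("_reactions", "_metabolites"))
    try:
        rxn_df = pd.read_csv(rxn_path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ModelFormatError(f"{rxn_path}: {exc}") from exc
    missing = [c for c in _RXN_COLUMNS if c not in rxn_df.columns]
    if missing:
        raise ModelFormatError(f"{rxn_path}: missing columns {missing}")

    reactions = []
    for line_no, row in enumerate(rxn_df.itertuples(index=False), start=2):
        try:
            reactions.append(
                Reaction(
                    id=row.id,
                    stoich=parse_equation(row.equation),
                    lb=float(row.lb),
                    ub=float(row.ub),
                    gpr=row.gpr,
                    confidence_class=row.confidence or "other",
                )
            )
        except (ModelFormatError, ValueError) as exc:
            raise ModelFormatError(f"{rxn_path} line {line_no}: {exc}") from exc

    if met_path.exists():
        met_df = pd.read_csv(met_path, sep="\t", dtype=str, keep_default_na=False)
        if "id" not in met_df.columns:
            raise ModelFormatError(f"{met_path}: missing 'id' column")
        metabolites = [Metabolite.from_id(i) for i in met_df["id"]]
    else:
        met_ids = sorted({m for r in reactions for m in r.stoich})
        metabolites = [Metabolite.from_id(i) for i in met_ids]

    model_id = stem.replace("_reactions.tsv", "")
    return StoichiometricModel(
        id=model_id,
        metabolites=metabolites,
        reactions=reactions,
        biomass_rxn_id=biomass_rxn_id,
        atp_rxn_id=atp_rxn_id,
    )


def _save_tsv(model: StoichiometricModel, path: Path) -> None:
    import pandas as pd

    rxn_path = Path(path)
    if "_reactions" not in rxn_path.name:
        rxn_path = rxn_path.with_name(rxn_path.stem + "_reactions.tsv")
    met_path = rxn_path.with_name(rxn_path.name.replace("_reactions", "_metabolites"))
    pd.DataFrame(
        {
            "id": [r.id for r in model.reactions],
            "equation": [format_equation(r.stoich) for r in model.reactions],
            "lb": [repr(r.lb) for r in model.reactions],
            "ub": [repr(r.ub) for r in model.reactions],
            "gpr": [r.gpr for r in model.reactions],
            "confidence": [r.confidence_class for r in model.reactions],
        }
    ).to_csv(rxn_path, sep="\t", index=False)
    pd.DataFrame({"id": [m.id for m in model.metabolites]}).to_csv(
        met_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _load_json(path: Path, biomass_rxn_id: str | None,
               atp_rxn_id: str | None) -> StoichiometricModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
    try:
        metabolites = [Metabolite.from_id(m["id"]) for m in doc["metabolites"]]
        reactions = [
            Reaction(
                id=r["id"],
                stoich=dict(r["stoich"]),
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                gpr=r.get("gpr", ""),
                confidence_class=r.get("confidence", "other"),
            )
            for r in doc["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"{path}: malformed model document ({exc})") from exc
    return StoichiometricModel(
        id=doc.get("id", Path(path).stem),
        metabolites=metabolites,
        reactions=reactions,
        biomass_rxn_id=biomass_rxn_id or doc.get("biomass_rxn_id"),
        atp_rxn_id=atp_rxn_id or doc.get("atp_rxn_id"),
    )


def _save_json(model: StoichiometricModel, path: Path) -> None:
    doc = {
        "id": model.id,
        "biomass_rxn_id": model.biomass_rxn_id,
        "atp_rxn_id": model.atp_rxn_id,
        "metabolites": [{"id": m.id} for m in model.metabolites],
        "reactions": [
            {
                "id": r.id,
                "stoich": r.stoich,
                "lb": r.lb,
                "ub": r.ub,
                "gpr": r.gpr,
                "confidence": r.confidence_class,
            }
            for r in model.reactions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# SBML (via cobra)
# ---------------------------------------------------------------------------

def _load_sbml(path: Path, biomass_rxn_id: str | None,
               atp_rxn_id: str | None) -> StoichiometricModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    metabolites = [
        Metabolite(id=f"{m.id}", base_id=m.id.rsplit("_", 1)[0]
                   if "_" in m.id else m.id,
                   compartment=m.compartment or "c")
        for m in cm.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoich={m.id: c for m, c in r.metabolites.items()},
            lb=r.lower_bound,
            ub=r.upper_bound,
            gpr=r.gene_reaction_rule,
            confidence_class=(r.notes or {}).get("confidence", "other"),
        )
        for r in cm.reactions
    ]
    return StoichiometricModel(
        id=cm.id or Path(path).stem,
        metabolites=metabolites,
        reactions=reactions,
        biomass_rxn_id=biomass_rxn_id,
        atp_rxn_id=atp_rxn_id,
    )


def _save_sbml(model: StoichiometricModel, path: Path) -> None:
    import cobra
    import cobra.io

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment)
        for m in model.metabolites
    }
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id, lower_bound=rxn.lb, upper_bound=rxn.ub)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in rxn.stoich.items()})
        if rxn.gpr:
            cr.gene_reaction_rule = rxn.gpr
        cr.notes["confidence"] = rxn.confidence_class
    cobra.io.write_sbml_model(cm, str(path))


_LOADERS = {"tsv": _load_tsv, "json": _load_json, "sbml": _load_sbml}
_SAVERS = {"tsv": _save_tsv, "json": _save_json, "sbml": _save_sbml}


def _guess_format(path: Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ModelFormatError(f"cannot infer model format from {path}")


def load_model(
    path: str | Path,
    format: str | None = None,
    biomass_rxn_id: str | None = None,
    atp_rxn_id: str | None = None,
    validate: bool = True,
) -> StoichiometricModel:
    """Load and validate a model from TSV, JSON or SBML.

    Objective reaction ids may come from the file (JSON) or from the
    caller (typically a config file).  When ``validate`` is true the model
    must name resolvable biomass and ATP-demand reactions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _guess_format(path)
    if fmt not in _LOADERS:
        raise ModelFormatError(f"unknown model format {fmt!r}")
    model = _LOADERS[fmt](path, biomass_rxn_id, atp_rxn_id)
    if validate:
        model.validate(require_objectives=True)
    else:
        model.validate(require_objectives=False)
    return model


def save_model(model: StoichiometricModel, path: str | Path,
               format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt not in _SAVERS:
        raise ModelFormatError(f"unknown model format {fmt!r}")
    _SAVERS[fmt](model, path)
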