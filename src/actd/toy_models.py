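"""Self-contained fixture models: the four-reaction GPR demonstration
network and seeded cancer/healthy (CA/HT) toy model pairs.

The toy pair emulates the structure the screening pipeline assumes in
real tissue models without requiring any download:

* a shared core — glucose and glutamine uptake, glycolysis, a pentose
  branch, a TCA-like ATP module, a pyrimidine-like nucleotide branch
  feeding biomass, and an ATP maintenance demand;
* a CA model with boosted glucose uptake and an extra glutaminolysis
  branch (metabolic reprogramming), whose objective is biomass;
* an HT model without the reprogramming branch, whose objective is ATP;
* planted targets with known phenotypes: a CA-essential but
  HT-dispensable enzyme (nucleotide synthesis — the *ideal* target), a
  shared-essential enzyme (upper glycolysis — kills the healthy cell's
  ATP supply too), an isozyme pair buffering glycolysis (each alone is
  tolerated, together they are synthetic-lethal), a redundant enzyme
  pair and an enzyme complex;
* per-model log-normal expression with pathway-specific emphasis, so
  the RNA-seq-derived confidence weights differ between CA and HT.

All generation is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gpr_logic import GPRModel, build_gpr_model, parse_gpr
from .metnet_io import Metabolite, Reaction, StoichiometricModel

__all__ = ["ToySpec", "ToyPair", "GenerationError", "make_fig1_network",
           "make_toy_pair"]

_CORE_N_REACTIONS = 14  # HT core; CA adds the glutaminolysis branch
_CORE_N_METABOLITES = 10


class GenerationError(ValueError):
    """The requested toy-model dimensions are inconsistent."""


@dataclass
class ToySpec:
    n_metabolites: int = 14
    n_reactions: int = 20
    n_isozyme_pairs: int = 1
    n_redundant_enzymes: int = 1
    n_complexes: int = 1
    planted_essentials: list[str] = field(
        default_factory=lambda: ["Gcad", "Gglyc1"]
    )
    expression_seed: int = 0

    def validate(self) -> None:
        if self.n_reactions < _CORE_N_REACTIONS or self.n_reactions > 60:
            raise GenerationError(
                f"n_reactions must lie in [{_CORE_N_REACTIONS}, 60]"
            )
        if self.n_metabolites < _CORE_N_METABOLITES or self.n_metabolites > 40:
            raise GenerationError(
                f"n_metabolites must lie in [{_CORE_N_METABOLITES}, 40]"
            )
        if min(self.n_isozyme_pairs, self.n_redundant_enzymes,
               self.n_complexes) < 0:
            raise GenerationError("motif counts must be nonnegative")


@dataclass
class ToyPair:
    ca_model: StoichiometricModel
    ht_model: StoichiometricModel
    ca_gpr: GPRModel
    ht_gpr: GPRModel
    ca_expression: dict[str, float]
    ht_expression: dict[str, float]
    planted: dict[str, object]


def make_fig1_network() -> tuple[StoichiometricModel, GPRModel]:
    """The four-reaction GPR demonstration network.

    r2 and r3 share the redundant isozymes G2/G3 (identical reaction
    sets); r3 is additionally covered by the G4+G5 complex, making it
    the only isozyme-buffered reaction; r4 carries no gene association.
    """
    mets = [Metabolite.from_id(m) for m in
            ("A[c]", "B[c]", "C[c]", "D[c]", "E[c]")]
    reactions = [
        Reaction("r1", {"A[c]": -1, "B[c]": 1}, 0, 10, gpr="G1"),
        Reaction("r2", {"B[c]": -1, "C[c]": 1}, 0, 10, gpr="G2 or G3"),
        Reaction("r3", {"B[c]": -1, "D[c]": 1}, 0, 10,
                 gpr="G2 or G3 or (G4 and G5)"),
        Reaction("r4", {"C[c]": -1, "D[c]": -1, "E[c]": 1}, 0, 10, gpr=""),
    ]
    model = StoichiometricModel(
        id="fig1", metabolites=mets, reactions=reactions,
        biomass_rxn_id="r4", atp_rxn_id="r4",
    )
    model.validate()
    gpr = build_gpr_model({r.id: r.gpr for r in reactions})
    return model, gpr


# ---------------------------------------------------------------------------
# CA/HT toy pair
# ---------------------------------------------------------------------------

# gene -> pathway role, used to bias expression per model
_BIOMASS_GENES = ("Gglyc1", "Gglyc2a", "Gglyc2b", "Grpia", "Gcad", "Gcadb",
                  "Ggls")
_ATP_GENES = ("Gtca1", "Gtca2", "Gglnatp")


def _core_reactions(tag: str, rng: np.random.Generator) -> list[Reaction]:
    glc_cap = (10.0 if tag == "CA" else 6.0) + rng.uniform(-0.5, 0.5)
    gln_cap = 5.0 + rng.uniform(-0.25, 0.25)
    reactions = [
        Reaction("SRC_glc", {"glc[c]": 1}, 0, glc_cap),
        Reaction("SRC_gln", {"gln[c]": 1}, 0, gln_cap),
        Reaction("SNK_lac", {"lac[c]": -1}, 0, 100),
        Reaction("DM_biomass", {"biomass[c]": -1}, 0, 100),
        # ATP maintenance demand: the lower bound is the basal energy cost
        Reaction("DM_atp", {"atp[c]": -1}, 1, 100),
        Reaction("r_glyc1", {"glc[c]": -1, "g6p[c]": 1}, 0, 12,
                 gpr="Gglyc1"),
        Reaction("r_glyc2", {"g6p[c]": -1, "pyr[c]": 2, "atp[c]": 2}, 0, 12,
                 gpr="Gglyc2a or Gglyc2b"),
        # Gglyc2a is promiscuous: it also catalyses the overflow branch,
        # so the two glycolytic isozymes have distinct reaction sets
        Reaction("r_aux", {"pyr[c]": -1, "lac[c]": 1, "atp[c]": 1}, 0, 10,
                 gpr="Gglyc2a"),
        Reaction("r_ppp", {"g6p[c]": -1, "r5p[c]": 1}, 0, 10, gpr="Grpia"),
        Reaction("r_tca", {"pyr[c]": -1, "atp[c]": 3}, 0, 30,
                 gpr="Gtca1 and Gtca2"),
        # redundant enzyme pair: Gcad and Gcadb catalyse exactly the same
        # two nucleotide-synthesis reactions
        Reaction("r_nuc1", {"gln[c]": -1, "r5p[c]": -1, "orot[c]": 1}, 0, 10,
                 gpr="Gcad or Gcadb"),
        Reaction("r_nuc2", {"orot[c]": -1, "ump[c]": 1}, 0, 10,
                 gpr="Gcad or Gcadb"),
        Reaction("r_glnatp", {"gln[c]": -1, "atp[c]": 1}, 0, 2,
                 gpr="Gglnatp"),
        Reaction("r_bio",
                 {"ump[c]": -1, "pyr[c]": -2, "atp[c]": -3, "biomass[c]": 1},
                 0, 10, gpr=""),
    ]
    if tag == "CA":
        reactions.append(
            Reaction("r_glnpyr", {"gln[c]": -1, "pyr[c]": 1}, 0, 5,
                     gpr="Ggls")
        )
    return reactions


def _filler(spec: ToySpec, n_have_rxns: int, rng: np.random.Generator
            ) -> list[Reaction]:
    """Inert linear units (source -> conversion -> sink) used to pad the
    network to the requested size and to host extra GPR motifs."""
    reactions: list[Reaction] = []
    extra_iz = max(0, spec.n_isozyme_pairs - 1)
    extra_red = max(0, spec.n_redundant_enzymes - 1)
    extra_cx = max(0, spec.n_complexes - 1)
    unit = 0
    while n_have_rxns + len(reactions) < spec.n_reactions:
        a, b = f"fx{unit}a[c]", f"fx{unit}b[c]"
        cap = rng.uniform(1.0, 4.0)
        if extra_iz > 0:
            gpr1, gpr2 = (f"Giz{unit}a or Giz{unit}b", f"Giz{unit}a")
            extra_iz -= 1
        elif extra_red > 0:
            gpr1 = gpr2 = f"Gred{unit}a or Gred{unit}b"
            extra_red -= 1
        elif extra_cx > 0:
            gpr1, gpr2 = (f"Gcx{unit}a and Gcx{unit}b", f"Gf{unit}")
            extra_cx -= 1
        else:
            gpr1, gpr2 = (f"Gf{unit}a", f"Gf{unit}b")
        c = f"fx{unit}c[c]"
        reactions += [
            Reaction(f"SRC_fx{unit}", {a: 1}, 0, cap),
            Reaction(f"fr{unit}a", {a: -1, b: 1}, 0, cap, gpr=gpr1),
            Reaction(f"fr{unit}b", {b: -1, c: 1}, 0, cap, gpr=gpr2),
            Reaction(f"SNK_fx{unit}", {c: -1}, 0, 100),
        ]
        unit += 1
    return reactions


def _expression(genes: list[str], tag: str,
                rng: np.random.Generator) -> dict[str, float]:
    expr = {}
    for gene in sorted(genes):
        base = float(rng.lognormal(mean=1.0, sigma=0.5))
        if tag == "CA" and gene in _BIOMASS_GENES:
            base *= 4.0
        if tag == "HT" and gene in _ATP_GENES:
            base *= 4.0
        # a slice of the filler genes is silent, exercising 'not detected'
        if gene.startswith("Gf") and rng.random() < 0.3:
            base = 0.0
        expr[gene] = base
    return expr


def _assemble(tag: str, spec: ToySpec, rng: np.random.Generator
              ) -> tuple[StoichiometricModel, GPRModel, dict[str, float]]:
    reactions = _core_reactions(tag, rng)
    reactions += _filler(spec, len(reactions), rng)
    met_ids = sorted({m for r in reactions for m in r.stoich})
    model = StoichiometricModel(
        id=f"toy_{tag}",
        metabolites=[Metabolite.from_id(m) for m in met_ids],
        reactions=reactions,
        biomass_rxn_id="r_bio",
        atp_rxn_id="DM_atp",
    )
    model.validate()
    genes = sorted(
        {g for r in reactions if r.gpr for g in parse_gpr(r.gpr).genes()}
    )
    expr = _expression(genes, tag, rng)
    gpr = build_gpr_model({r.id: r.gpr for r in reactions}, expr_stats=expr)
    return model, gpr, expr


def make_toy_pair(spec: ToySpec | None = None) -> ToyPair:
    """Generate a paired CA/HT toy bundle with planted targets.

    The ``planted`` metadata names the feasible-enzyme ids of the ideal
    target (CA-essential, HT-dispensable), the shared-essential target
    and the synthetic-lethal isozyme pair.
    """
    spec = spec or ToySpec()
    spec.validate()
    rng = np.random.default_rng(spec.expression_seed)
    ca_model, ca_gpr, ca_expr = _assemble("CA", spec, rng)
    ht_model, ht_gpr, ht_expr = _assemble("HT", spec, rng)
    planted = {
        "ideal": "Gcad",                 # nucleotide synthesis, CA-only need
        "shared_essential": "Gglyc1",    # upper glycolysis, both cells need
        "isozyme_pair": ("Gglyc2a", "Gglyc2b"),
        "complex": "Gtca1+Gtca2",
        "redundant_removed": "Gcadb",
        "antimetabolite": "orot[c]",     # inhibiting it mirrors the Gcad hit
        "requested": list(spec.planted_essentials),
    }
    return ToyPair(
        ca_model=ca_model,
        ht_model=ht_model,
        ca_gpr=ca_gpr,
        ht_gpr=ht_gpr,
        ca_expression=ca_expr,
        ht_expression=ht_expr,
        planted=planted,
    )
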