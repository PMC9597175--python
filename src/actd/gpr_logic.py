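"""Gene–protein-reaction (GPR) Boolean logic and reaction confidence.

GPR rules link genes to the reactions they support: AND nodes are enzyme
complexes (all subunit genes required), OR nodes are isozymes (any branch
suffices).  This module

* parses rule strings into Boolean trees (:func:`parse_gpr`),
* expands each rule into its OR-branches and pools identical gene
  complexes across reactions into candidate enzymes
  (:func:`enumerate_enzymes`),
* collapses *redundant* enzymes — distinct complexes catalysing exactly
  the same reaction set, whose regulation is therefore interchangeable —
  into one feasible representative (:func:`reduce_redundant`),
* decides whether a reaction stays catalysable after a set of enzymes is
  removed (:func:`isozyme_buffered`); such reactions are held near their
  basal flux instead of being shut off,
* classifies genes into high/medium/low/not-detected expression groups
  (:func:`classify_genes`) and propagates the groups through the rules to
  per-reaction confidence weights c_k in {1/4, 1/2, 3/4, 1}
  (:func:`weight_reactions`) used by the uniform-flux-distribution QP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GPRRule",
    "Enzyme",
    "GPRModel",
    "GPRParseError",
    "GENE_GROUPS",
    "CONFIDENCE_WEIGHTS",
    "parse_gpr",
    "enumerate_enzymes",
    "reduce_redundant",
    "isozyme_buffered",
    "classify_genes",
    "weight_reactions",
    "build_gpr_model",
]

GENE_GROUPS = ("high", "medium", "low", "not_detected")

# gene group -> reaction confidence class -> weight
_GROUP_TO_CLASS = {
    "high": "high",
    "medium": "medium",
    "low": "negative",
    "not_detected": "other",
}
CONFIDENCE_WEIGHTS = {"high": 0.25, "medium": 0.5, "negative": 0.75, "other": 1.0}

# confidence ordering used for Boolean propagation (best first)
_GROUP_RANK = {g: i for i, g in enumerate(GENE_GROUPS)}


class GPRParseError(ValueError):
    """Malformed GPR string; message carries the offending position."""


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRRule:
    """Boolean tree: op is 'gene', 'and' or 'or'."""

    op: str
    gene: str | None = None
    children: tuple["GPRRule", ...] = ()

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.gene])
        return frozenset().union(*(c.genes() for c in self.children))

    def branches(self) -> list[frozenset[str]]:
        """Disjunctive normal form: one gene set per OR-branch."""
        if self.op == "gene":
            return [frozenset([self.gene])]
        if self.op == "or":
            out: list[frozenset[str]] = []
            for child in self.children:
                for b in child.branches():
                    if b not in out:
                        out.append(b)
            return out
        # AND: cross-product of child branch lists
        out = [frozenset()]
        for child in self.children:
            out = [a | b for a in out for b in child.branches()]
        dedup: list[frozenset[str]] = []
        for b in out:
            if b not in dedup:
                dedup.append(b)
        return dedup

    def evaluate(self, active: set[str] | frozenset[str]) -> bool:
        if self.op == "gene":
            return self.gene in active
        if self.op == "and":
            return all(c.evaluate(active) for c in self.children)
        return any(c.evaluate(active) for c in self.children)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op != "gene" and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


def _tokenize(rule: str) -> list[tuple[str, str, int]]:
    tokens = []
    i, n = 0, len(rule)
    while i < n:
        ch = rule[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
            continue
        j = i
        while j < n and not rule[j].isspace() and rule[j] not in "()":
            j += 1
        word = rule[i:j]
        low = word.lower()
        if low in ("and", "or"):
            tokens.append(("op", low, i))
        else:
            tokens.append(("gene", word, i))
        i = j
    return tokens


def parse_gpr(rule: str) -> GPRRule | None:
    """Parse a GPR string; an empty/whitespace rule parses to ``None``.

    Grammar: ``expr := term ('or' term)*; term := factor ('and' factor)*;
    factor := gene | '(' expr ')'``.  Errors report the character position.
    """
    tokens = _tokenize(rule)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def fail(expected: str):
        tok = peek()
        where = tok[2] if tok else len(rule)
        found = tok[1] if tok else "end of rule"
        raise GPRParseError(
            f"GPR parse error at position {where}: expected {expected}, "
            f"found {found!r} in {rule!r}"
        )

    def parse_factor() -> GPRRule:
        nonlocal pos
        tok = peek()
        if tok is None:
            fail("gene or '('")
        kind, value, _ = tok
        if kind == "gene":
            pos += 1
            return GPRRule(op="gene", gene=value)
        if kind == "paren" and value == "(":
            pos += 1
            node = parse_expr()
            tok2 = peek()
            if tok2 is None or tok2[1] != ")":
                fail("')'")
            pos += 1
            return node
        fail("gene or '('")

    def parse_term() -> GPRRule:
        nonlocal pos
        children = [parse_factor()]
        while (tok := peek()) is not None and tok[0] == "op" and tok[1] == "and":
            pos += 1
            children.append(parse_factor())
        if len(children) == 1:
            return children[0]
        flat: list[GPRRule] = []
        for c in children:
            flat.extend(c.children if c.op == "and" else (c,))
        return GPRRule(op="and", children=tuple(flat))

    def parse_expr() -> GPRRule:
        nonlocal pos
        children = [parse_term()]
        while (tok := peek()) is not None and tok[0] == "op" and tok[1] == "or":
            pos += 1
            children.append(parse_term())
        if len(children) == 1:
            return children[0]
        flat: list[GPRRule] = []
        for c in children:
            flat.extend(c.children if c.op == "or" else (c,))
        return GPRRule(op="or", children=tuple(flat))

    node = parse_expr()
    if pos != len(tokens):
        fail("end of rule")
    return node


# ---------------------------------------------------------------------------
# Enzymes
# ---------------------------------------------------------------------------

@dataclass
class Enzyme:
    """A gene complex (AND-set) with the reactions it catalyses.

    After redundancy reduction, ``group`` lists the gene sets of every
    merged enzyme (regulating any of them is equivalent).
    """

    id: str
    gene_set: frozenset[str]
    reaction_set: frozenset[str]
    group: tuple[frozenset[str], ...] = ()

    def all_genes(self) -> frozenset[str]:
        sets = self.group if self.group else (self.gene_set,)
        return frozenset().union(*sets)


def _enzyme_id(gene_set: frozenset[str]) -> str:
    return "+".join(sorted(gene_set))


def enumerate_enzymes(rules: dict[str, GPRRule | None]) -> list[Enzyme]:
    """One candidate enzyme per distinct OR-branch across all rules."""
    by_genes: dict[frozenset[str], set[str]] = {}
    for rxn_id, rule in rules.items():
        if rule is None:
            continue
        for branch in rule.branches():
            by_genes.setdefault(branch, set()).add(rxn_id)
    enzymes = [
        Enzyme(
            id=_enzyme_id(genes),
            gene_set=genes,
            reaction_set=frozenset(rxns),
            group=(genes,),
        )
        for genes, rxns in by_genes.items()
    ]
    enzymes.sort(key=lambda e: e.id)
    return enzymes


def reduce_redundant(
    enzymes: list[Enzyme],
) -> tuple[list[Enzyme], list[Enzyme]]:
    """Merge enzymes with identical reaction sets into one representative.

    The representative (smallest id) carries the merged ``group``; the
    returned ``removed`` list holds the non-representative members.
    """
    by_rxns: dict[frozenset[str], list[Enzyme]] = {}
    for enz in enzymes:
        by_rxns.setdefault(enz.reaction_set, []).append(enz)
    feasible: list[Enzyme] = []
    removed: list[Enzyme] = []
    for members in by_rxns.values():
        members = sorted(members, key=lambda e: e.id)
        rep = members[0]
        feasible.append(
            Enzyme(
                id=rep.id,
                gene_set=rep.gene_set,
                reaction_set=rep.reaction_set,
                group=tuple(m.gene_set for m in members),
            )
        )
        removed.extend(members[1:])
    feasible.sort(key=lambda e: e.id)
    return feasible, removed


@dataclass
class GPRModel:
    rules: dict[str, GPRRule | None]
    enzymes: list[Enzyme]
    feasible_enzymes: list[Enzyme]
    removed_enzymes: list[Enzyme]
    isozyme_reactions: frozenset[str]
    gene_groups: dict[str, str] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {e.id: e for e in self.feasible_enzymes}

    def enzyme(self, enzyme_id: str) -> Enzyme:
        try:
            return self._by_id[enzyme_id]
        except KeyError:
            raise KeyError(f"unknown feasible enzyme {enzyme_id!r}") from None

    def enzymes_for_gene(self, gene: str) -> list[Enzyme]:
        """Feasible enzymes whose (merged) gene sets contain ``gene``."""
        return [e for e in self.feasible_enzymes if gene in e.all_genes()]

    def enzymes_for_reaction(self, rxn_id: str) -> list[Enzyme]:
        return [e for e in self.feasible_enzymes if rxn_id in e.reaction_set]


def isozyme_buffered(
    gpr: GPRModel, reaction_id: str, target_enzyme_ids: set[str] | frozenset[str]
) -> bool:
    """True iff the reaction stays catalysable with the targets removed.

    Removal is gene-level: all genes of the targeted enzymes (including
    merged redundant partners) are switched off and the Boolean rule is
    re-evaluated, so a surviving branch that shares a subunit with a
    target does not count as buffering.
    """
    if reaction_id not in gpr.rules:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    rule = gpr.rules[reaction_id]
    if rule is None:
        return False
    killed: set[str] = set()
    for eid in target_enzyme_ids:
        killed |= gpr.enzyme(eid).all_genes()
    return rule.evaluate(rule.genes() - killed)


def _isozyme_reactions(rules: dict[str, GPRRule | None],
                       feasible: list[Enzyme]) -> frozenset[str]:
    """Reactions catalysed by >= 2 distinct feasible enzymes."""
    count: dict[str, int] = {}
    for enz in feasible:
        for rid in enz.reaction_set:
            count[rid] = count.get(rid, 0) + 1
    return frozenset(r for r, c in count.items() if c >= 2 and rules.get(r))


# ---------------------------------------------------------------------------
# Expression classification and confidence weights
# ---------------------------------------------------------------------------

def classify_genes(
    expr_stats: dict[str, float],
    quantiles: tuple[float, float, float] = (0.25, 0.5, 0.75),
) -> dict[str, str]:
    """Assign each gene to high/medium/low/not_detected by expression.

    Thresholds are the given quantiles of the *positive* expression
    values; zeros (and values under the first threshold) fall into
    ``not_detected``.
    """
    if any(v < 0 for v in expr_stats.values()):
        bad = min(expr_stats, key=expr_stats.get)
        raise ValueError(f"negative expression for gene {bad!r}")
    positive = np.array([v for v in expr_stats.values() if v > 0], dtype=float)
    if positive.size == 0:
        return {g: "not_detected" for g in expr_stats}
    t1, t2, t3 = np.quantile(positive, quantiles)
    groups = {}
    for gene, value in expr_stats.items():
        if value <= 0 or value < t1:
            groups[gene] = "not_detected"
        elif value < t2:
            groups[gene] = "low"
        elif value < t3:
            groups[gene] = "medium"
        else:
            groups[gene] = "high"
    return groups


def _rule_group(rule: GPRRule, gene_groups: dict[str, str]) -> str:
    """OR takes the most-confident branch, AND the least-confident gene."""
    if rule.op == "gene":
        return gene_groups.get(rule.gene, "not_detected")
    child = [_rule_group(c, gene_groups) for c in rule.children]
    if rule.op == "or":
        return min(child, key=_GROUP_RANK.__getitem__)
    return max(child, key=_GROUP_RANK.__getitem__)


def weight_reactions(
    rules: dict[str, GPRRule | None], gene_groups: dict[str, str]
) -> dict[str, float]:
    """Per-reaction confidence weight c_k in {1/4, 1/2, 3/4, 1}.

    Gene groups map to reaction classes high/medium/negative/other;
    reactions without a rule get the 'other' weight 1.
    """
    weights = {}
    for rxn_id, rule in rules.items():
        if rule is None:
            weights[rxn_id] = CONFIDENCE_WEIGHTS["other"]
        else:
            group = _rule_group(rule, gene_groups)
            weights[rxn_id] = CONFIDENCE_WEIGHTS[_GROUP_TO_CLASS[group]]
    return weights


def build_gpr_model(
    gpr_strings: dict[str, str],
    expr_stats: dict[str, float] | None = None,
    quantiles: tuple[float, float, float] = (0.25, 0.5, 0.75),
) -> GPRModel:
    """Parse, enumerate, reduce and weight a whole model's GPR rules."""
    rules = {rid: parse_gpr(s) for rid, s in gpr_strings.items()}
    enzymes = enumerate_enzymes(rules)
    feasible, removed = reduce_redundant(enzymes)
    if expr_stats is not None:
        gene_groups = classify_genes(expr_stats, quantiles)
    else:
        known = frozenset().union(
            *(r.genes() for r in rules.values() if r is not None)
        ) if any(rules.values()) else frozenset()
        gene_groups = {g: "not_detected" for g in known}
    weights = weight_reactions(rules, gene_groups)
    return GPRModel(
        rules=rules,
        enzymes=enzymes,
        feasible_enzymes=feasible,
        removed_enzymes=removed,
        isozyme_reactions=_isozyme_reactions(rules, feasible),
        gene_groups=gene_groups,
        weights=weights,
    )
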