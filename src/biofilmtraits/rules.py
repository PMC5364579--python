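"""Declarative gene-set rules and biofilm-group assignment for MAGs.

Traits such as chemotaxis or nitrogen fixation are expressed as small boolean
expression trees over a genome's observed gene symbols, EC numbers and product
descriptions.  Evaluating a rulebook against a genome annotation yields a
:class:`TraitProfile`; the four biofilm traits (chemotaxis, flagellar motility,
EPS production, EPS secretion) then map onto the colonizer groups A/B/C used
to describe which populations can initiate attachment to a mineral surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "RuleExpr",
    "Rulebook",
    "TraitProfile",
    "RulebookError",
    "gene",
    "ec",
    "product_contains",
    "all_of",
    "any_of",
    "at_least",
    "ref",
    "normalize_symbol",
    "evaluate_rule",
    "profile_genome",
    "assign_biofilm_group",
    "default_rulebook",
    "trait_gene_sets",
    "BIOFILM_TRAITS",
    "GROUP_LABELS",
]

#: Trait names required before a biofilm group can be assigned.
BIOFILM_TRAITS = ("chemotaxis", "motility", "eps_production", "eps_secretion")

#: Valid colonizer group labels, in precedence order.
GROUP_LABELS = ("A", "B", "C", "unassigned")


class RulebookError(ValueError):
    """Invalid rule expression or rulebook (bad combinator, cycle, bad REF)."""


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol to annotation-pipeline casing.

    The first character of the symbol is lower-cased and everything else is
    preserved, matching the convention of prokaryotic annotation output:
    ``CheY`` -> ``cheY``, ``NifH`` -> ``nifH``, ``dsv`` -> ``dsv``.
    Idempotent; no fuzzy matching is attempted beyond this.
    """
    s = symbol.strip()
    if not s:
        raise ValueError("empty gene symbol")
    return s[0].lower() + s[1:]


def normalize_ec(number: str) -> str:
    """Strip whitespace and an optional ``EC`` prefix from an EC number."""
    s = number.strip()
    if s.upper().startswith("EC"):
        s = s[2:].lstrip(" :")
    if not s:
        raise ValueError("empty EC number")
    return s


@dataclass(frozen=True)
class RuleExpr:
    """One node of a boolean trait-rule expression tree.

    ``kind`` is one of ``gene``, ``ec``, ``product``, ``all``, ``any``,
    ``at_least``, ``ref``.  Leaves carry ``value`` (a normalized gene symbol,
    an EC number, a product substring, or a referenced trait name);
    ``at_least`` additionally carries the threshold ``k``.
    """

    kind: str
    value: str | None = None
    k: int | None = None
    children: tuple["RuleExpr", ...] = ()

    def __post_init__(self) -> None:
        if self.kind in ("all", "any", "at_least") and not self.children:
            raise RulebookError(f"{self.kind!r} node requires children")
        if self.kind == "at_least":
            if self.k is None or not 1 <= self.k <= len(self.children):
                raise RulebookError(
                    f"at_least threshold k={self.k} outside 1..{len(self.children)}"
                )
        if self.kind in ("gene", "ec", "product", "ref") and not self.value:
            raise RulebookError(f"{self.kind!r} leaf requires a value")

    def leaves(self) -> list["RuleExpr"]:
        """All leaf nodes of the tree, in document order (REFs not expanded)."""
        if not self.children:
            return [self]
        out: list[RuleExpr] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def gene(symbol: str) -> RuleExpr:
    return RuleExpr("gene", value=normalize_symbol(symbol))


def ec(number: str) -> RuleExpr:
    return RuleExpr("ec", value=normalize_ec(number))


def product_contains(text: str) -> RuleExpr:
    return RuleExpr("product", value=text)


def all_of(*children: RuleExpr | str) -> RuleExpr:
    return RuleExpr("all", children=tuple(_coerce(c) for c in children))


def any_of(*children: RuleExpr | str) -> RuleExpr:
    return RuleExpr("any", children=tuple(_coerce(c) for c in children))


def at_least(k: int, *children: RuleExpr | str) -> RuleExpr:
    return RuleExpr("at_least", k=k, children=tuple(_coerce(c) for c in children))


def ref(trait_name: str) -> RuleExpr:
    return RuleExpr("ref", value=trait_name)


def _coerce(node: RuleExpr | str) -> RuleExpr:
    return node if isinstance(node, RuleExpr) else gene(node)


@dataclass
class Rulebook:
    """Named trait rules plus free-text provenance notes.

    ``traits`` maps trait name -> rule expression; ``metadata`` carries an
    optional human-readable note per trait (e.g. the gene-set criterion it
    encodes).  ``validate`` rejects unresolved or cyclic REFs.
    """

    traits: dict[str, RuleExpr]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, rule in self.traits.items():
            for leaf in rule.leaves():
                if leaf.kind == "ref" and leaf.value not in self.traits:
                    raise RulebookError(
                        f"trait {name!r} references unknown trait {leaf.value!r}"
                    )
        # cycle check over the REF graph
        WHITE, GREY, BLACK = 0, 1, 2
        color = {name: WHITE for name in self.traits}

        def visit(name: str, stack: list[str]) -> None:
            color[name] = GREY
            for leaf in self.traits[name].leaves():
                if leaf.kind != "ref":
                    continue
                tgt = leaf.value
                if color[tgt] == GREY:
                    cyc = " -> ".join(stack + [name, tgt])
                    raise RulebookError(f"cyclic trait reference: {cyc}")
                if color[tgt] == WHITE:
                    visit(tgt, stack + [name])
            color[name] = BLACK

        for name in self.traits:
            if color[name] == WHITE:
                visit(name, [])

    def has_biofilm_traits(self) -> bool:
        return all(t in self.traits for t in BIOFILM_TRAITS)


@dataclass
class TraitProfile:
    """Per-genome boolean trait vector with supporting gene evidence."""

    genome_id: str
    trait_values: dict[str, bool]
    evidence: dict[str, frozenset[str]]


def evaluate_rule(rule, annotation, rulebook=None):
    """Evaluate a rule expression against one genome annotation.

    Returns ``(satisfied, evidence)`` where ``evidence`` is the frozenset of
    the genome's gene symbols matched by satisfied GENE leaves anywhere in the
    tree (EC and product matches support the verdict but contribute no gene
    evidence).  Empty annotations never raise; every leaf simply evaluates
    false.  REF leaves require ``rulebook``.
    """
    sat, ev = _eval(rule, annotation, rulebook, ())
    return sat, frozenset(ev)


def _eval(rule, annotation, rulebook, ref_stack):
    kind = rule.kind
    if kind == "gene":
        hit = rule.value in annotation.genes
        return hit, ({rule.value} if hit else set())
    if kind == "ec":
        return rule.value in annotation.ecs, set()
    if kind == "product":
        needle = rule.value.lower()
        hit = any(needle in p.lower() for p in annotation.products)
        return hit, set()
    if kind == "ref":
        if rulebook is None or rule.value not in (rulebook.traits if rulebook else {}):
            raise RulebookError(f"unresolved trait reference {rule.value!r}")
        if rule.value in ref_stack:
            raise RulebookError(f"cyclic trait reference through {rule.value!r}")
        return _eval(
            rulebook.traits[rule.value], annotation, rulebook, ref_stack + (rule.value,)
        )
    # combinators: evaluate every child (no short circuit) so that evidence
    # from satisfied leaves is reported even when the combinator fails
    results = [_eval(c, annotation, rulebook, ref_stack) for c in rule.children]
    evidence: set[str] = set()
    for _, ev in results:
        evidence |= ev
    n_true = sum(1 for sat, _ in results if sat)
    if kind == "all":
        return n_true == len(results), evidence
    if kind == "any":
        return n_true >= 1, evidence
    if kind == "at_least":
        return n_true >= rule.k, evidence
    raise RulebookError(f"unknown rule kind {kind!r}")


def profile_genome(annotation, rulebook: Rulebook) -> TraitProfile:
    """Evaluate every rulebook trait against one genome annotation."""
    values: dict[str, bool] = {}
    evidence: dict[str, frozenset[str]] = {}
    for name, rule in rulebook.traits.items():
        sat, ev = evaluate_rule(rule, annotation, rulebook)
        values[name] = sat
        evidence[name] = ev
    return TraitProfile(annotation.genome_id, values, evidence)


def assign_biofilm_group(profile: TraitProfile) -> str:
    """Assign a colonizer group from the four biofilm traits.

    Precedence A > B > C:

    * ``A``  — chemotaxis, motility, EPS production and EPS secretion all
      present: the genome can sense, swim, attach and build a matrix.
    * ``B``  — EPS production and secretion (matrix builders that cannot swim).
    * ``C``  — chemotaxis and flagellar motility (swimmers without a matrix).
    * ``unassigned`` — anything else.
    """
    missing = [t for t in BIOFILM_TRAITS if t not in profile.trait_values]
    if missing:
        raise RulebookError(f"profile lacks biofilm trait(s): {', '.join(missing)}")
    v = profile.trait_values
    motile = v["chemotaxis"] and v["motility"]
    eps = v["eps_production"] and v["eps_secretion"]
    if motile and eps:
        return "A"
    if eps:
        return "B"
    if motile:
        return "C"
    return "unassigned"


# ---------------------------------------------------------------------------
# default rulebook


def _flagellar_genes() -> list[str]:
    flg = [f"flg{c}" for c in "LKDGHIBCE"]
    fli = [f"fli{c}" for c in "DCEFGMNHIOPQR"]
    flh = ["flhA", "flhB"]
    return flg + fli + flh  # 9 + 13 + 2 = 24 structural genes


def _pathway_config() -> dict:
    """Load the editable fermentation / hydrogenase gene-set configuration."""
    import importlib.resources

    import yaml

    text = (
        importlib.resources.files("biofilmtraits")
        .joinpath("data/fermentation_pathways.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def default_rulebook() -> Rulebook:
    """The built-in trait rulebook for deep-subsurface biofilm MAGs.

    Biofilm-formation traits:

    * chemotaxis — a methyl-accepting chemotaxis protein (detected from the
      product description, as MCPs lack one canonical symbol) plus the full
      cheA/cheB/cheW/cheR/cheY signalling cascade.
    * motility — at least 20 of the 24 flagellar structural genes
      (flgLKDGHIBCE, fliDCEFGMNHIOPQR, flhAB) and both motor genes motAB.
    * eps_production — galU (or both galU and galE; the disjunction keeps the
      stricter variant a one-line config edit).
    * eps_secretion — hlyB+hlyD+tolC (Type I secretion) or eps
      (Sec-dependent secretion).

    Metabolic traits: CBB-cycle CO2 fixation (cbbL or cbbM, or RuBisCO
    EC 4.1.1.39), N2 fixation (at least two of nifKDH, or nitrogenase
    EC 1.18.6.1), anaerobic H2 oxidation (EC 1.12.1.3 or the hydrogenase
    symbols shipped in the config), the Rnf ion-motive-force complex (at least
    four of rnfABCDEG), sulfate reduction (dsv), polysulfide reduction (psrA),
    formate oxidation (fdh), fermentation (all genes of one of eight acetate
    pathways, or two of three genes of one of three ethanol pathways; the
    pathway gene lists are editable config), the four denitrification steps,
    and the autoinducer-2 synthase luxS.
    """
    cfg = _pathway_config()
    acetate = cfg["fermentation"]["acetate_pathways"]
    ethanol = cfg["fermentation"]["ethanol_pathways"]
    hyd_symbols = cfg["hydrogenase_symbols"]

    fermentation = any_of(
        *[all_of(*p["genes"]) for p in acetate],
        *[at_least(2, *p["genes"]) for p in ethanol],
    )

    traits = {
        "chemotaxis": all_of(
            product_contains("methyl-accepting chemotaxis protein"),
            gene("cheA"),
            gene("cheB"),
            gene("cheW"),
            gene("cheR"),
            gene("cheY"),
        ),
        "motility": all_of(
            at_least(20, *_flagellar_genes()),
            gene("motA"),
            gene("motB"),
        ),
        "eps_production": any_of(gene("galU"), all_of(gene("galU"), gene("galE"))),
        "eps_secretion": any_of(
            all_of(gene("hlyB"), gene("hlyD"), gene("tolC")),
            gene("eps"),
        ),
        "co2_fixation_cbb": any_of(gene("cbbL"), gene("cbbM"), ec("4.1.1.39")),
        "n2_fixation": any_of(
            at_least(2, gene("nifK"), gene("nifD"), gene("nifH")),
            ec("1.18.6.1"),
        ),
        "h2_oxidation_anaerobic": any_of(
            ec("1.12.1.3"), *[gene(s) for s in hyd_symbols]
        ),
        "rnf_complex": at_least(4, *[f"rnf{c}" for c in "ABCDEG"]),
        "sulfate_reduction": gene("dsv"),
        "polysulfide_reduction": gene("psrA"),
        "formate_oxidation": gene("fdh"),
        "fermentation": fermentation,
        "nitrate_reduction": any_of(gene("narG"), gene("napA")),
        "nitrite_reduction": any_of(gene("nirK"), gene("nirS")),
        "nitric_oxide_reduction": gene("norB"),
        "nitrous_oxide_reduction": gene("nosZ"),
        "luxS_autoinducer": gene("luxS"),
    }
    metadata = {
        "chemotaxis": "MCP product plus all of cheABWRY",
        "motility": ">=20 of 24 flagellar structural genes and both motAB",
        "eps_production": "galU, or both galU and galE",
        "eps_secretion": "hlyBD+tolC (Type I) or eps (Sec-dependent)",
        "co2_fixation_cbb": "RuBisCO: cbbL or cbbM, or EC 4.1.1.39",
        "n2_fixation": "nitrogenase: >=2 of nifKDH, or EC 1.18.6.1",
        "h2_oxidation_anaerobic": "EC 1.12.1.3 or configured hydrogenase symbols",
        "rnf_complex": ">=4 of rnfABCDEG",
        "sulfate_reduction": "dsv",
        "polysulfide_reduction": "psrA",
        "formate_oxidation": "fdh",
        "fermentation": "one complete acetate pathway or 2/3 of an ethanol pathway",
        "nitrate_reduction": "narG or napA",
        "nitrite_reduction": "nirK or nirS",
        "nitric_oxide_reduction": "norB",
        "nitrous_oxide_reduction": "nosZ",
        "luxS_autoinducer": "luxS (autoinducer-2 synthase)",
    }
    return Rulebook(traits=traits, metadata=metadata)


def trait_gene_sets(rulebook: Rulebook) -> dict[str, set[str]]:
    """Gene symbols (GENE leaves) and EC tags (``EC:`` prefixed) per trait.

    Used to aggregate per-gene coverage frequencies into per-trait
    frequencies; REF leaves are expanded through the rulebook.
    """
    out: dict[str, set[str]] = {}
    for name, rule in rulebook.traits.items():
        symbols: set[str] = set()
        stack = [rule]
        seen_refs: set[str] = set()
        while stack:
            node = stack.pop()
            if node.kind == "gene":
                symbols.add(node.value)
            elif node.kind == "ec":
                symbols.add(f"EC:{node.value}")
            elif node.kind == "ref" and node.value not in seen_refs:
                seen_refs.add(node.value)
                stack.append(rulebook.traits[node.value])
            stack.extend(node.children)
        out[name] = symbols
    return out
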