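"""Rule-engine semantics, the default rulebook, and group assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofilmtraits import (
    RulebookError,
    TraitProfile,
    all_of,
    any_of,
    assign_biofilm_group,
    at_least,
    ec,
    evaluate_rule,
    gene,
    normalize_symbol,
    product_contains,
    profile_genome,
    ref,
    trait_gene_sets,
)
from biofilmtraits.rules import Rulebook

from conftest import make_annotation

MCP = "methyl-accepting chemotaxis protein"
CHE = ["cheA", "cheB", "cheW", "cheR", "cheY"]
FLAGELLAR = (
    [f"flg{c}" for c in "LKDGHIBCE"]
    + [f"fli{c}" for c in "DCEFGMNHIOPQR"]
    + ["flhA", "flhB"]
)


# ---------------------------------------------------------------------------
# symbol normalization


@pytest.mark.parametrize(
    "raw,expected",
    [("CheY", "cheY"), ("NifH", "nifH"), ("dsv", "dsv"), ("FlhA", "flhA")],
)
def test_normalize_symbol_lowercases_first_char_only(raw, expected):
    assert normalize_symbol(raw) == expected
    assert normalize_symbol(expected) == expected  # idempotent


# ---------------------------------------------------------------------------
# leaf and combinator semantics


def test_leaf_semantics():
    ann = make_annotation(
        genes={"cheA"}, ecs={"4.1.1.39"}, products={"Methyl-Accepting Chemotaxis Protein X"}
    )
    assert evaluate_rule(gene("cheA"), ann)[0]
    assert not evaluate_rule(gene("cheB"), ann)[0]
    assert evaluate_rule(ec("4.1.1.39"), ann)[0]
    assert evaluate_rule(product_contains(MCP), ann)[0]  # case-insensitive
    sat, ev = evaluate_rule(gene("cheA"), ann)
    assert ev == {"cheA"}


def test_empty_annotation_is_false_everywhere(rulebook):
    ann = make_annotation()
    for rule in rulebook.traits.values():
        sat, ev = evaluate_rule(rule, ann, rulebook)
        assert not sat and ev == frozenset()


def test_at_least_threshold_boundary(rulebook):
    motility_set = at_least(20, *FLAGELLAR)
    ann19 = make_annotation(genes=set(FLAGELLAR[:19]))
    ann20 = make_annotation(genes=set(FLAGELLAR[:20]))
    assert not evaluate_rule(motility_set, ann19)[0]
    assert evaluate_rule(motility_set, ann20)[0]


def test_chemotaxis_requires_mcp_and_all_che(rulebook):
    rule = rulebook.traits["chemotaxis"]
    full = make_annotation(genes=set(CHE), products={f"some {MCP} homolog"})
    assert evaluate_rule(rule, full, rulebook)[0]
    no_mcp = make_annotation(genes=set(CHE))
    assert not evaluate_rule(rule, no_mcp, rulebook)[0]
    missing_gene = make_annotation(genes=set(CHE[:-1]), products={MCP})
    assert not evaluate_rule(rule, missing_gene, rulebook)[0]


def test_unresolved_ref_raises():
    ann = make_annotation(genes={"galU"})
    with pytest.raises(RulebookError):
        evaluate_rule(ref("nonexistent"), ann, None)


# ---------------------------------------------------------------------------
# default rulebook structure


def test_default_rulebook_trait_inventory(rulebook):
    expected = {
        "chemotaxis", "motility", "eps_production", "eps_secretion",
        "co2_fixation_cbb", "n2_fixation", "h2_oxidation_anaerobic",
        "rnf_complex", "sulfate_reduction", "polysulfide_reduction",
        "formate_oxidation", "fermentation", "nitrate_reduction",
        "nitrite_reduction", "nitric_oxide_reduction",
        "nitrous_oxide_reduction", "luxS_autoinducer",
    }
    assert set(rulebook.traits) == expected


def test_motility_counts_motor_genes_outside_the_20(rulebook):
    """motAB are required in addition to the >=20-of-24 structural set."""
    rule = rulebook.traits["motility"]
    structural = rule.children[0]
    assert structural.kind == "at_least" and structural.k == 20
    assert len(structural.children) == 24
    ann = make_annotation(genes=set(FLAGELLAR))  # 24 structural, no motor
    assert not evaluate_rule(rule, ann, rulebook)[0]
    ann.genes |= {"motA", "motB"}
    assert evaluate_rule(rule, ann, rulebook)[0]


def test_rnf_and_nif_thresholds(rulebook):
    rnf = rulebook.traits["rnf_complex"]
    assert rnf.k == 4 and len(rnf.children) == 6
    three = make_annotation(genes={"rnfA", "rnfB", "rnfC"})
    four = make_annotation(genes={"rnfA", "rnfB", "rnfC", "rnfD"})
    assert not evaluate_rule(rnf, three, rulebook)[0]
    assert evaluate_rule(rnf, four, rulebook)[0]
    nif = rulebook.traits["n2_fixation"]
    two = make_annotation(genes={"nifK", "nifH"})
    one = make_annotation(genes={"nifH"})
    assert evaluate_rule(nif, two, rulebook)[0]
    assert not evaluate_rule(nif, one, rulebook)[0]
    assert evaluate_rule(nif, make_annotation(ecs={"1.18.6.1"}), rulebook)[0]


def test_eps_rules(rulebook):
    prod = rulebook.traits["eps_production"]
    sec = rulebook.traits["eps_secretion"]
    galu_only = make_annotation(genes={"galU"})
    assert evaluate_rule(prod, galu_only, rulebook)[0]
    assert not evaluate_rule(sec, galu_only, rulebook)[0]
    type1 = make_annotation(genes={"hlyB", "hlyD", "tolC"})
    assert evaluate_rule(sec, type1, rulebook)[0]
    assert evaluate_rule(sec, make_annotation(genes={"eps"}), rulebook)[0]
    assert not evaluate_rule(sec, make_annotation(genes={"hlyB", "hlyD"}), rulebook)[0]


def test_trait_gene_sets_include_ec_tags(rulebook):
    sets = trait_gene_sets(rulebook)
    assert "EC:4.1.1.39" in sets["co2_fixation_cbb"]
    assert {"nifK", "nifD", "nifH"} <= sets["n2_fixation"]
    assert sets["sulfate_reduction"] == {"dsv"}


# ---------------------------------------------------------------------------
# group assignment


def _profile(**traits):
    base = {
        "chemotaxis": False,
        "motility": False,
        "eps_production": False,
        "eps_secretion": False,
    }
    base.update(traits)
    return TraitProfile("g", base, {t: frozenset() for t in base})


@pytest.mark.parametrize(
    "traits,label",
    [
        (dict(chemotaxis=True, motility=True, eps_production=True, eps_secretion=True), "A"),
        (dict(eps_production=True, eps_secretion=True), "B"),
        (dict(chemotaxis=True, motility=True), "C"),
        ({}, "unassigned"),
        (dict(eps_production=True), "unassigned"),
        (dict(chemotaxis=True), "unassigned"),
        (dict(chemotaxis=True, motility=True, eps_production=True), "C"),
    ],
)
def test_group_assignment(traits, label):
    assert assign_biofilm_group(_profile(**traits)) == label


def test_group_assignment_is_total_and_exclusive():
    """Every boolean combination of the 4 traits yields exactly one label."""
    for mask in range(16):
        traits = dict(
            chemotaxis=bool(mask & 1),
            motility=bool(mask & 2),
            eps_production=bool(mask & 4),
            eps_secretion=bool(mask & 8),
        )
        label = assign_biofilm_group(_profile(**traits))
        assert label in ("A", "B", "C", "unassigned")


def test_missing_trait_key_raises():
    prof = TraitProfile("g", {"chemotaxis": True}, {})
    with pytest.raises(RulebookError):
        assign_biofilm_group(prof)


def test_saturated_genome_is_group_A_and_all_traits_true(rulebook):
    """A genome carrying every rulebook gene/EC/product satisfies all traits."""
    sets = trait_gene_sets(rulebook)
    genes = {s for gs in sets.values() for s in gs if not s.startswith("EC:")}
    ecs = {s[3:] for gs in sets.values() for s in gs if s.startswith("EC:")}
    ann = make_annotation(genes=genes, ecs=ecs, products={MCP})
    prof = profile_genome(ann, rulebook)
    assert all(prof.trait_values.values())
    assert assign_biofilm_group(prof) == "A"
    for t, ev in prof.evidence.items():
        assert ev <= ann.genes


# ---------------------------------------------------------------------------
# property tests: brute-force oracle and monotonicity


def _oracle_eval(rule, genes, ecs, products):
    """Independent truth-table style evaluator (no evidence tracking)."""
    if rule.kind == "gene":
        return rule.value in genes
    if rule.kind == "ec":
        return rule.value in ecs
    if rule.kind == "product":
        return any(rule.value.lower() in p.lower() for p in products)
    child_truths = [_oracle_eval(c, genes, ecs, products) for c in rule.children]
    table = {"all": all(child_truths), "any": any(child_truths),
             "at_least": sum(child_truths) >= (rule.k or 0)}
    return table[rule.kind]


SYMBOLS = [f"gen{c}" for c in "ABCDEFGHIJKL"]  # 12 symbols


def _random_rule(rng, depth):
    if depth == 0 or rng.random() < 0.4:
        return gene(SYMBOLS[rng.integers(len(SYMBOLS))])
    kind = rng.integers(3)
    n = int(rng.integers(2, 5))
    children = [_random_rule(rng, depth - 1) for _ in range(n)]
    if kind == 0:
        return all_of(*children)
    if kind == 1:
        return any_of(*children)
    return at_least(int(rng.integers(1, n + 1)), *children)


def test_rule_engine_matches_bruteforce_oracle():
    rng = np.random.default_rng(12345)
    for _ in range(1200):
        rule = _random_rule(rng, depth=4)
        present = {s for s in SYMBOLS if rng.random() < 0.5}
        ann = make_annotation(genes=present)
        got, evidence = evaluate_rule(rule, ann)
        assert got == _oracle_eval(rule, present, set(), set())
        assert evidence <= present


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    extra=st.sets(st.sampled_from(SYMBOLS), max_size=6),
)
def test_adding_genes_never_breaks_a_trait(seed, extra):
    """All combinators are monotone: supersets preserve satisfied rules."""
    rng = np.random.default_rng(seed)
    rule = _random_rule(rng, depth=3)
    present = {s for s in SYMBOLS if rng.random() < 0.4}
    before = evaluate_rule(rule, make_annotation(genes=present))[0]
    after = evaluate_rule(rule, make_annotation(genes=present | extra))[0]
    if before:
        assert after


# ---------------------------------------------------------------------------
# rulebook validation


def test_cyclic_refs_rejected_at_load():
    with pytest.raises(RulebookError, match="cyclic"):
        Rulebook(traits={"a": ref("b"), "b": ref("a")})


def test_unknown_ref_rejected_at_load():
    with pytest.raises(RulebookError, match="unknown trait"):
        Rulebook(traits={"a": ref("ghost")})


def test_at_least_bounds_rejected():
    with pytest.raises(RulebookError):
        at_least(4, gene("a"), gene("b"))
    with pytest.raises(RulebookError):
        at_least(0, gene("a"))
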