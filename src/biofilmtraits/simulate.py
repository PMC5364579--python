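"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the real inputs of a surface-colonization
metagenomics experiment:

* annotated genomes with planted biofilm groups / metabolic traits, gene
  dropout (the synthetic analogue of incomplete MAGs: dropout ~ 1 -
  completeness) and decoy genes;
* gene x sample coverage tables with log-normal baselines and planted
  between-group fold changes for chosen traits;
* OTU count tables drawn multinomially from log-normal community profiles.

Every generator is bit-reproducible under a fixed seed and returns a truth
record alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeAnnotation
from .rules import BIOFILM_TRAITS, Rulebook, RuleExpr, trait_gene_sets

__all__ = [
    "GenomeSpec",
    "CoverageSpec",
    "generate_genome",
    "generate_coverage",
    "generate_otu_table",
    "minimal_satisfying_set",
    "DECOY_LEXICON_SIZE",
]

DECOY_LEXICON_SIZE = 5000


def _decoy_lexicon() -> list[str]:
    # fixed symbols disjoint from every plausible rulebook symbol
    return [f"syn{i:04d}" for i in range(DECOY_LEXICON_SIZE)]


@dataclass
class GenomeSpec:
    """Recipe for one synthetic annotated genome."""

    genome_id: str
    planted_group: str = "unassigned"  # A, B, C or unassigned
    planted_metabolic_traits: set[str] = field(default_factory=set)
    dropout: float = 0.0
    decoy_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must lie in [0, 1]")
        if self.planted_group not in ("A", "B", "C", "unassigned"):
            raise ValueError(f"unknown group {self.planted_group!r}")


@dataclass
class CoverageSpec:
    """Recipe for a synthetic gene x sample coverage table.

    ``samples`` maps sample id -> group label; ``effects`` maps trait name ->
    (boosted group, fold change).  Baselines are log-normal with the given
    log-scale parameters; multiplicative noise has coefficient of variation
    ``cv``.
    """

    n_background_genes: int = 50
    samples: dict[str, str] = field(default_factory=dict)
    baseline_mu: float = 0.0
    baseline_sigma: float = 1.0
    effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        for trait, (group, fold) in self.effects.items():
            if fold <= 0:
                raise ValueError(f"fold for {trait!r} must be positive")
            if group not in set(self.samples.values()):
                raise ValueError(f"effect group {group!r} has no samples")


# ---------------------------------------------------------------------------
# genomes


def minimal_satisfying_set(
    rule: RuleExpr, rulebook: Rulebook, rng: np.random.Generator
) -> tuple[set[str], set[str], set[str]]:
    """Sample one minimal (genes, ecs, products) requirement satisfying a rule.

    Disjunctive nodes (ANY, AT_LEAST) choose uniformly among their children,
    so repeated calls explore the alternative minimal satisfying sets.
    """
    kind = rule.kind
    if kind == "gene":
        return {rule.value}, set(), set()
    if kind == "ec":
        return set(), {rule.value}, set()
    if kind == "product":
        return set(), set(), {rule.value}
    if kind == "ref":
        return minimal_satisfying_set(rulebook.traits[rule.value], rulebook, rng)
    if kind == "any":
        child = rule.children[int(rng.integers(len(rule.children)))]
        return minimal_satisfying_set(child, rulebook, rng)
    if kind == "at_least":
        idx = rng.choice(len(rule.children), size=rule.k, replace=False)
        chosen = [rule.children[int(i)] for i in idx]
    else:  # all
        chosen = list(rule.children)
    genes: set[str] = set()
    ecs: set[str] = set()
    products: set[str] = set()
    for c in chosen:
        g, e, p = minimal_satisfying_set(c, rulebook, rng)
        genes |= g
        ecs |= e
        products |= p
    return genes, ecs, products


_GROUP_TRAITS = {
    "A": BIOFILM_TRAITS,
    "B": ("eps_production", "eps_secretion"),
    "C": ("chemotaxis", "motility"),
    "unassigned": (),
}


def generate_genome(
    spec: GenomeSpec, rulebook: Rulebook
) -> tuple[GenomeAnnotation, dict]:
    """Build one synthetic annotation: a minimal satisfying gene set for the
    planted group and metabolic traits, thinned by Bernoulli(dropout)
    deletions and padded with decoy symbols.

    The truth record carries the intended group and traits.
    """
    traits = list(_GROUP_TRAITS[spec.planted_group]) + sorted(
        spec.planted_metabolic_traits
    )
    missing = [t for t in traits if t not in rulebook.traits]
    if missing:
        raise ValueError(f"rulebook lacks planted trait(s): {missing}")
    rng = np.random.default_rng(spec.seed)
    genes: set[str] = set()
    ecs: set[str] = set()
    products: set[str] = set()
    for t in traits:
        g, e, p = minimal_satisfying_set(rulebook.traits[t], rulebook, rng)
        genes |= g
        ecs |= e
        products |= p
    if spec.dropout > 0:
        genes = {g for g in genes if rng.random() >= spec.dropout}
        ecs = {e for e in ecs if rng.random() >= spec.dropout}
        products = {p for p in products if rng.random() >= spec.dropout}
    if spec.decoy_genes:
        lexicon = _decoy_lexicon()
        rulebook_symbols = set().union(*trait_gene_sets(rulebook).values())
        pool = [s for s in lexicon if s not in rulebook_symbols]
        idx = rng.choice(len(pool), size=min(spec.decoy_genes, len(pool)), replace=False)
        genes |= {pool[int(i)] for i in idx}
    ann = GenomeAnnotation(
        genome_id=spec.genome_id, genes=genes, ecs=ecs, products=products
    )
    truth = {
        "genome_id": spec.genome_id,
        "planted_group": spec.planted_group,
        "planted_metabolic_traits": sorted(spec.planted_metabolic_traits),
        "dropout": spec.dropout,
    }
    return ann, truth


# ---------------------------------------------------------------------------
# coverage


def generate_coverage(
    spec: CoverageSpec, rulebook: Rulebook | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate a coverage table with planted between-group fold changes.

    Rows are the gene symbols of every trait named in ``spec.effects``
    (taken from the rulebook; EC-only entries are skipped) plus
    ``n_background_genes`` background genes.  Each gene gets one log-normal
    baseline shared across samples; samples of a boosted group multiply the
    trait's genes by the planted fold; multiplicative log-normal noise with
    the requested CV is applied everywhere.
    """
    if spec.effects and rulebook is None:
        raise ValueError("a rulebook is required when effects name traits")
    if not spec.samples:
        raise ValueError("spec.samples must not be empty")
    rng = np.random.default_rng(spec.seed)
    trait_genes: dict[str, list[str]] = {}
    if spec.effects:
        sets = trait_gene_sets(rulebook)
        for trait in spec.effects:
            if trait not in sets:
                raise ValueError(f"rulebook lacks trait {trait!r}")
            trait_genes[trait] = sorted(
                s for s in sets[trait] if not s.startswith("EC:")
            )
    gene_ids = [g for gl in trait_genes.values() for g in gl]
    gene_ids += [f"bg{i:04d}" for i in range(spec.n_background_genes)]
    gene_ids = list(dict.fromkeys(gene_ids))

    baselines = rng.lognormal(spec.baseline_mu, spec.baseline_sigma, len(gene_ids))
    # log-normal multiplicative noise with unit mean and the requested CV
    noise_sigma = float(np.sqrt(np.log1p(spec.cv**2)))
    samples = list(spec.samples)
    values = np.empty((len(gene_ids), len(samples)))
    fold_by_gene: dict[str, dict[str, float]] = {}
    for trait, (group, fold) in spec.effects.items():
        for g in trait_genes[trait]:
            fold_by_gene.setdefault(g, {})[group] = fold
    for j, s in enumerate(samples):
        group = spec.samples[s]
        noise = rng.lognormal(-0.5 * noise_sigma**2, noise_sigma, len(gene_ids))
        col = baselines * noise
        for i, g in enumerate(gene_ids):
            f = fold_by_gene.get(g, {}).get(group)
            if f is not None:
                col[i] *= f
        values[:, j] = col
    cov = pd.DataFrame(values, index=gene_ids, columns=samples)
    truth = {
        "effects": {t: {"group": g, "fold": f} for t, (g, f) in spec.effects.items()},
        "trait_genes": trait_genes,
        "cv": spec.cv,
        "seed": spec.seed,
    }
    return cov, truth


# ---------------------------------------------------------------------------
# OTU tables


def generate_otu_table(
    n_taxa: int,
    n_samples: int,
    lognormal_mu: float = 0.0,
    lognormal_sigma: float = 1.0,
    depth: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate an OTU count table.

    A single log-normal relative-abundance profile is drawn for the
    community; each sample is an independent multinomial draw of ``depth``
    reads (the default depth matches the common 16S rarefaction depth of
    10,000 sequences).  Truth records the underlying proportions.
    """
    if n_taxa < 1 or n_samples < 1:
        raise ValueError("n_taxa and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(lognormal_mu, lognormal_sigma, n_taxa)
    props = raw / raw.sum()
    counts = rng.multinomial(depth, props, size=n_samples).T
    taxa = [f"OTU_{i + 1:04d}" for i in range(n_taxa)]
    samples = [f"S{j + 1}" for j in range(n_samples)]
    table = pd.DataFrame(counts, index=taxa, columns=samples)
    truth = {"proportions": dict(zip(taxa, props.tolist())), "depth": depth, "seed": seed}
    return table, truth
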