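"""Monte-Carlo validation studies built from the synthetic generators.

These routines quantify how well the pipeline recovers planted ground
truth: group-classification accuracy as a function of gene dropout, and the
type-I error / power of the per-trait frequency ANOVA under the study's
sampling layout (two biofilm metagenomes against four planktonic ones).
"""

from __future__ import annotations

import numpy as np

from .frequency import anova_one_way, normalize_frequencies, trait_frequency
from .rules import Rulebook, assign_biofilm_group, default_rulebook, profile_genome
from .simulate import CoverageSpec, GenomeSpec, generate_coverage, generate_genome

__all__ = [
    "classification_accuracy",
    "anova_rejection_rate",
    "STUDY_DESIGN",
]

#: The study sampling layout: one biofilm metagenome per surface (garnet,
#: glass) versus duplicate metagenomes for each planktonic size fraction.
STUDY_DESIGN = {
    "biofilm_garnet": "biofilm",
    "biofilm_glass": "biofilm",
    "plank_large_1": "planktonic",
    "plank_large_2": "planktonic",
    "plank_small_1": "planktonic",
    "plank_small_2": "planktonic",
}


def classification_accuracy(
    dropout: float,
    n_per_group: int = 50,
    seed: int = 0,
    rulebook: Rulebook | None = None,
    decoy_genes: int = 10,
) -> float:
    """Fraction of synthetic genomes whose biofilm group is recovered.

    Plants ``n_per_group`` genomes for each of the four labels (A, B, C,
    unassigned) at the given dropout, profiles them with the rulebook and
    compares the assigned group to the planted one.
    """
    rulebook = rulebook or default_rulebook()
    rng = np.random.default_rng(seed)
    correct = total = 0
    for group in ("A", "B", "C", "unassigned"):
        for _ in range(n_per_group):
            spec = GenomeSpec(
                genome_id=f"{group}_{total}",
                planted_group=group,
                dropout=dropout,
                decoy_genes=decoy_genes,
                seed=int(rng.integers(2**31 - 1)),
            )
            ann, truth = generate_genome(spec, rulebook)
            got = assign_biofilm_group(profile_genome(ann, rulebook))
            correct += got == truth["planted_group"]
            total += 1
    return correct / total


def anova_rejection_rate(
    fold: float,
    n_reps: int,
    seed: int = 0,
    cv: float = 0.1,
    alpha: float = 0.05,
    trait: str = "co2_fixation_cbb",
    n_background_genes: int = 20,
    rulebook: Rulebook | None = None,
) -> float:
    """Fraction of simulated datasets in which the trait ANOVA rejects.

    With ``fold = 1`` this estimates the type-I error at level ``alpha``;
    with an enriched fold it estimates power.  Each replicate simulates a
    coverage table under :data:`STUDY_DESIGN`, normalizes it, sums the
    trait's gene frequencies and runs the one-way ANOVA.
    """
    rulebook = rulebook or default_rulebook()
    rng = np.random.default_rng(seed)
    from .rules import trait_gene_sets

    gene_set = trait_gene_sets(rulebook)[trait]
    rejections = 0
    for _ in range(n_reps):
        spec = CoverageSpec(
            n_background_genes=n_background_genes,
            samples=STUDY_DESIGN,
            effects={trait: ("biofilm", fold)},
            cv=cv,
            seed=int(rng.integers(2**31 - 1)),
        )
        cov, _ = generate_coverage(spec, rulebook)
        freq = normalize_frequencies(cov)
        vec = trait_frequency(freq, gene_set)
        res = anova_one_way(vec, STUDY_DESIGN, trait_name=trait)
        rejections += res.p < alpha
    return rejections / n_reps
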