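"""Gene-coverage normalization and biofilm-vs-planktonic group comparison.

Raw per-gene coverage (mean read depth) is normalized within each sample by
the sample's total coverage, giving compositional gene frequencies.  Trait
frequencies are sums of the member genes' frequencies, and group differences
(e.g. two biofilm metagenomes against four planktonic ones) are tested per
trait with one-way fixed-effects ANOVA.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "normalize_frequencies",
    "trait_frequency",
    "anova_one_way",
    "compare_traits",
]


@dataclass
class AnovaResult:
    """One-way ANOVA outcome for a single trait's frequency vector."""

    trait_name: str
    F: float
    p: float
    df_between: int
    df_within: int
    group_means: dict[str, float]


def normalize_frequencies(cov: pd.DataFrame) -> pd.DataFrame:
    """Divide each coverage column by its total so columns sum to 1."""
    totals = cov.sum(axis=0)
    dead = totals[totals <= 0]
    if not dead.empty:
        raise ValueError(
            f"sample(s) with zero total coverage: {list(dead.index)}"
        )
    return cov.div(totals, axis=1)


_EC_TAG = re.compile(r"\|EC:([\d.]+)$")


def _row_matches(row_id: str, gene_set: set[str]) -> bool:
    """Match a coverage row id against a trait gene set.

    Row ids are gene symbols, optionally suffixed with an EC tag
    (``cbbL|EC:4.1.1.39``).  Symbols match by exact normalized string; the
    EC tag matches any ``EC:``-prefixed entry of the gene set.
    """
    m = _EC_TAG.search(row_id)
    symbol = _EC_TAG.sub("", row_id)
    if symbol in gene_set:
        return True
    return bool(m) and f"EC:{m.group(1)}" in gene_set


def trait_frequency(freq: pd.DataFrame, gene_set: set[str]) -> pd.Series:
    """Per-sample summed frequency of the genes in ``gene_set``.

    Genes absent from the table contribute zero; a fully disjoint set yields
    an all-zero vector with a logged warning.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    mask = [_row_matches(str(r), gene_set) for r in freq.index]
    if not any(mask):
        logger.warning("no gene of %s found in the frequency table", sorted(gene_set))
        return pd.Series(0.0, index=freq.columns)
    return freq.loc[mask].sum(axis=0)


def anova_one_way(values, design: dict[str, str], trait_name: str = "") -> AnovaResult:
    """One-way fixed-effects ANOVA of per-sample values across groups.

    ``values`` maps sample id -> frequency (a pandas Series or dict); every
    sample must appear in ``design``.  F and p come from the F distribution
    with (k-1, N-k) degrees of freedom.  When the within-group variance is
    exactly zero, unequal group means give ``F = inf, p = 0`` and equal
    means give ``F = 0, p = 1``.
    """
    values = pd.Series(values, dtype=float)
    missing = [s for s in values.index if s not in design]
    if missing:
        raise ValueError(f"samples absent from design: {missing}")
    groups: dict[str, np.ndarray] = {
        g: values[[s for s in values.index if design[s] == g]].to_numpy()
        for g in dict.fromkeys(design[s] for s in values.index)
    }
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA requires at least two groups")
    n_total = int(sum(len(v) for v in groups.values()))
    df_between = k - 1
    df_within = n_total - k
    if df_within == 0:
        raise ValueError("no within-group degrees of freedom (one value per group)")

    grand = values.mean()
    means = {g: float(v.mean()) for g, v in groups.items()}
    ss_between = sum(len(v) * (means[g] - grand) ** 2 for g, v in groups.items())
    ss_within = sum(((v - means[g]) ** 2).sum() for g, v in groups.items())

    if ss_within == 0.0:
        if ss_between == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
    else:
        F = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(trait_name, float(F), float(p), df_between, df_within, means)


def compare_traits(
    freq: pd.DataFrame,
    trait_sets: dict[str, set[str]],
    design: dict[str, str],
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-trait ANOVA battery of grouped frequency comparisons.

    Returns a table ordered by trait name with columns: F, p, degrees of
    freedom, one mean column per group, significance flags at p<0.05 and
    p<0.01, and a status column (``ok`` / ``no data`` / the error message).
    Raw per-trait p-values are reported; a Benjamini-Hochberg column
    (``p_bh``) is appended only on request.
    """
    rows = []
    for trait in sorted(trait_sets):
        gene_set = trait_sets[trait]
        vec = trait_frequency(freq, gene_set) if gene_set else None
        if vec is None or not (vec > 0).any():
            rows.append({"trait": trait, "status": "no data"})
            continue
        try:
            res = anova_one_way(vec, design, trait_name=trait)
        except ValueError as exc:
            rows.append({"trait": trait, "status": str(exc)})
            continue
        row = {
            "trait": trait,
            "F": res.F,
            "p": res.p,
            "df_between": res.df_between,
            "df_within": res.df_within,
            "status": "ok",
        }
        for g, m in res.group_means.items():
            row[f"mean_{g}"] = m
        row["sig_05"] = int(res.p < 0.05)
        row["sig_01"] = int(res.p < 0.01)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("trait")
    if bh_correction and "p" in out.columns:
        from statsmodels.stats.multitest import multipletests

        ok = out["p"].notna()
        padj = pd.Series(np.nan, index=out.index)
        if ok.any():
            padj[ok] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["p_bh"] = padj
    return out
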