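"""Alpha-diversity summaries and OTU-table operations.

Covers the 16S community descriptions of the pipeline: rarefaction to a
common depth, observed richness, the Chao1 and ACE richness estimators, the
Shannon-Weaver (nats, by default) and Inverse Simpson diversity indices,
abundance filtering with a pooled "<1%" remainder row, and the overlap of
abundant taxa between two habitats.

Richness estimation delegates to scikit-bio; Shannon entropy is computed via
``scipy.stats.entropy`` so that relative abundances (not only counts) are
accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import alpha as _alpha

logger = logging.getLogger(__name__)

__all__ = [
    "DiversitySummary",
    "rarefy",
    "shannon",
    "inverse_simpson",
    "chao1",
    "ace",
    "observed_richness",
    "diversity_summary",
    "filter_abundant",
    "abundant_overlap",
]


@dataclass
class DiversitySummary:
    """Richness estimates and diversity indices for one sample."""

    sample_id: str
    s_obs: int
    chao1: float
    ace: float
    shannon: float
    inv_simpson: float


def _counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def rarefy(counts, n: int, seed: int):
    """Subsample a taxon count vector to exactly ``n`` reads without
    replacement (multivariate hypergeometric draw).

    Deterministic for a fixed seed.  Accepts an array or a pandas Series
    and returns the same type with taxon order preserved.
    """
    arr = _counts(counts)
    total = int(arr.sum())
    if not 1 <= n <= total:
        raise ValueError(f"rarefaction depth n={n} outside 1..{total}")
    rng = np.random.default_rng(seed)
    out = rng.multivariate_hypergeometric(arr, n)
    if isinstance(counts, pd.Series):
        return pd.Series(out, index=counts.index)
    return out


def _props(abund) -> np.ndarray:
    p = np.asarray(abund, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    tot = p.sum()
    if tot <= 0:
        raise ValueError("abundances sum to zero")
    return p / tot


def shannon(abund, base: float | None = None) -> float:
    """Shannon-Weaver index H = -sum p_i log p_i (natural log by default)."""
    return float(stats.entropy(_props(abund), base=base))


def inverse_simpson(abund) -> float:
    """Inverse Simpson index 1 / sum p_i^2 (effective species number)."""
    p = _props(abund)
    return float(1.0 / np.sum(p * p))


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness: S_obs + F1(F1-1)/(2(F2+1)) in the bias-corrected
    form (the classic F1^2/(2 F2) form via ``bias_corrected=False``)."""
    return float(_alpha.chao1(_counts(counts), bias_corrected=bias_corrected))


def ace(counts, rare_threshold: int = 10) -> float:
    """ACE richness estimator (rare taxa = counts <= ``rare_threshold``).

    When every rare taxon is a singleton the ACE coverage estimate is zero
    and the estimator is undefined; the bias-corrected Chao1 value is
    returned instead, with a logged note.
    """
    arr = _counts(counts)
    try:
        return float(_alpha.ace(arr, rare_threshold=rare_threshold))
    except ValueError:
        logger.info("ACE undefined (all rare taxa are singletons); using Chao1")
        return chao1(arr)


def observed_richness(counts) -> int:
    """Number of taxa with a positive count."""
    return int((np.asarray(counts) > 0).sum())


def diversity_summary(
    table: pd.DataFrame,
    rarefy_to: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample diversity summary of a count-mode OTU table.

    With ``rarefy_to`` set, each sample is first rarefied to that depth
    (samples with fewer reads raise).  Index: sample id; columns: s_obs,
    chao1, ace, shannon (nats), inv_simpson.
    """
    rows = []
    for sample in table.columns:
        counts = _counts(table[sample])
        if rarefy_to is not None:
            counts = rarefy(counts, rarefy_to, seed=seed)
        counts = counts[counts > 0]
        rows.append(
            {
                "sample_id": sample,
                "s_obs": observed_richness(counts),
                "chao1": chao1(counts),
                "ace": ace(counts),
                "shannon": shannon(counts),
                "inv_simpson": inverse_simpson(counts),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def filter_abundant(
    table: pd.DataFrame,
    threshold_percent: float = 1.0,
    remainder_label: str = "<1%",
) -> pd.DataFrame:
    """Keep taxa reaching ``threshold_percent`` in at least one sample; pool
    everything else into a remainder row.  Column sums are preserved.

    The table must be in percent mode (columns summing to ~100).
    """
    sums = table.sum(axis=0)
    if ((sums - 100.0).abs() > 0.5).any():
        raise ValueError("filter_abundant requires a percent-mode table")
    keep = (table >= threshold_percent).any(axis=1)
    kept = table.loc[keep]
    remainder = table.loc[~keep].sum(axis=0)
    remainder.name = remainder_label
    out = pd.concat([kept, remainder.to_frame().T])
    out.index.name = table.index.name
    return out


def abundant_overlap(
    table: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    threshold_percent: float = 1.0,
    exclude: tuple[str, ...] = (),
) -> set[str]:
    """Taxa at or above ``threshold_percent`` abundance in BOTH samples.

    Rows named in ``exclude`` (e.g. an "Unknown phylum" bucket or a pooled
    remainder row) are ignored.
    """
    for s in (sample_a, sample_b):
        if s not in table.columns:
            raise KeyError(f"unknown sample id {s!r}")
    sub = table.drop(index=[r for r in exclude if r in table.index])
    mask = (sub[sample_a] >= threshold_percent) & (sub[sample_b] >= threshold_percent)
    return set(sub.index[mask])
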