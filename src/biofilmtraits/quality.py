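"""MAG quality gating from single-copy marker gene (SCG) counts.

Genome binning tools evaluate bins against a panel of genes expected exactly
once per genome (36 in the CONCOCT panel used here).  A bin is accepted when
it carries at least 31 distinct panel genes and at most 2 of them in more
than one copy; presence doubles as a completeness estimate (31/36 ~ 86%).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ScgSummary", "accept_bin", "completeness_percent", "quality_table",
           "N_SCG", "MIN_PRESENT", "MAX_DUPLICATED"]

#: Size of the single-copy gene panel.
N_SCG = 36
#: Acceptance floor on distinct SCGs present.
MIN_PRESENT = 31
#: Acceptance ceiling on duplicated SCGs.
MAX_DUPLICATED = 2


@dataclass(frozen=True)
class ScgSummary:
    """Distinct and duplicated single-copy-gene counts for one bin.

    A duplicated gene still counts as present, so
    ``0 <= n_duplicated <= n_present <= total``.
    """

    genome_id: str
    n_present: int
    n_duplicated: int
    total: int = N_SCG

    def __post_init__(self) -> None:
        if not 0 <= self.n_duplicated <= self.n_present <= self.total:
            raise ValueError(
                f"{self.genome_id}: require 0 <= n_duplicated ({self.n_duplicated})"
                f" <= n_present ({self.n_present}) <= {self.total}"
            )


def accept_bin(s: ScgSummary) -> bool:
    """Apply the bin acceptance gate: >=31 SCGs present, <=2 duplicated."""
    return s.n_present >= MIN_PRESENT and s.n_duplicated <= MAX_DUPLICATED


def completeness_percent(s: ScgSummary, total: int | None = None) -> float:
    """Estimated bin completeness: 100 * n_present / total."""
    total = s.total if total is None else total
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * s.n_present / total


def quality_table(scg: pd.DataFrame) -> pd.DataFrame:
    """Add ``accepted`` (0/1) and ``completeness`` columns to an SCG table."""
    out = scg.copy()
    summaries = [
        ScgSummary(str(r.genome_id), int(r.n_present), int(r.n_duplicated))
        for r in scg.itertuples(index=False)
    ]
    out["accepted"] = [int(accept_bin(s)) for s in summaries]
    out["completeness"] = [completeness_percent(s) for s in summaries]
    return out
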