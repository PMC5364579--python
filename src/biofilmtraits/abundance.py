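"""ATP-based cell abundance estimates and biofilm-to-planktonic ratios.

Total ATP extracted from a surface or water sample is converted to a cell
count through an ATP-per-cell factor, normalized by the sampled surface area
(biofilm, cells cm^-2) or water volume (planktonic, cells mL^-1), and the
two densities are compared as a dimensionless fold ratio.  The ratio
deliberately divides a per-cm^2 density by a per-mL density — the standard,
caveated comparison for attached versus suspended communities — and output
records carry a units note saying so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceRecord",
    "atp_to_cells",
    "density",
    "biofilm_fold",
    "summarize_triplicates",
    "FOLD_UNITS_NOTE",
]

FOLD_UNITS_NOTE = "fold ratio compares cells per-cm^2 (biofilm) to per-mL (planktonic)"


@dataclass
class AbundanceRecord:
    """One sample's abundance measurement.

    Exactly one of ``area_cm2`` (surface sample) or ``volume_ml`` (water
    sample) must be set; all set quantities must be positive.
    """

    sample_id: str
    cells_total: float
    atp_amol: float | None = None
    area_cm2: float | None = None
    volume_ml: float | None = None

    def __post_init__(self) -> None:
        if (self.area_cm2 is None) == (self.volume_ml is None):
            raise ValueError(
                f"{self.sample_id}: exactly one of area_cm2 / volume_ml must be set"
            )
        for name in ("cells_total", "atp_amol", "area_cm2", "volume_ml"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.sample_id}: {name} must be non-negative")


def atp_to_cells(atp_amol: float, atp_per_cell_amol: float) -> float:
    """Convert an ATP amount (attomol) to a cell count.

    The ATP-per-cell factor is biology- and protocol-dependent and has no
    universal value; it must be supplied by the caller (the CLI default of
    1 amol/cell is a placeholder to be overridden, never a biological
    constant asserted by this package).
    """
    if atp_amol <= 0 or atp_per_cell_amol <= 0:
        raise ValueError("atp_amol and atp_per_cell_amol must be positive")
    return atp_amol / atp_per_cell_amol


def density(record: AbundanceRecord) -> float:
    """Cell density: cells cm^-2 for surface samples, cells mL^-1 for water."""
    denom = record.area_cm2 if record.area_cm2 is not None else record.volume_ml
    if denom is None or denom <= 0:
        raise ValueError(f"{record.sample_id}: missing or non-positive denominator")
    return record.cells_total / denom


def biofilm_fold(biofilm_density: float, planktonic_density: float) -> float:
    """Fold ratio of a biofilm surface density over a planktonic density.

    Units are heterogeneous by design (see :data:`FOLD_UNITS_NOTE`).
    """
    if biofilm_density <= 0:
        raise ValueError("biofilm density must be positive")
    if planktonic_density <= 0:
        raise ValueError("planktonic density must be positive")
    return biofilm_density / planktonic_density


def summarize_triplicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of replicate ATP measurements per sample.

    Expects columns ``sample_id`` and ``atp_amol`` with one row per
    replicate (typically triplicate); returns per-sample ``atp_mean`` and
    ``atp_sd`` (ddof=1; NaN for a single replicate).
    """
    g = measurements.groupby("sample_id")["atp_amol"]
    out = pd.DataFrame(
        {"atp_mean": g.mean(), "atp_sd": g.std(ddof=1), "n_replicates": g.size()}
    )
    return out
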