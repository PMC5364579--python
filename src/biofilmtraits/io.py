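"""Readers and writers for the pipeline's tabular inputs and outputs.

Formats handled here:

* annotation tables (TSV with ``genome_id``/``gene``/``ec``/``product``
  columns, or one GFF3 file per genome),
* rulebook configuration files (YAML or JSON),
* gene x sample coverage tables, OTU tables, single-copy-gene summaries and
  sample-to-group design files (all TSV),
* generic result-table output (TSV, 4 significant digits).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import rules as _r
from .rules import Rulebook, RuleExpr, RulebookError, normalize_ec, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeAnnotation",
    "FormatError",
    "read_annotations",
    "read_rulebook",
    "rule_from_config",
    "read_coverage",
    "read_otu_table",
    "read_scg_table",
    "read_design",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """Malformed input file (missing column, bad dialect, wrong mode)."""


@dataclass
class GenomeAnnotation:
    """One genome's observed gene symbols, EC numbers and product strings."""

    genome_id: str
    genes: set[str] = field(default_factory=set)
    ecs: set[str] = field(default_factory=set)
    products: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        for s in (self.genes, self.ecs, self.products):
            if "" in s:
                raise ValueError("annotation sets may not contain empty strings")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path, format: str = "tsv") -> list[GenomeAnnotation]:
    """Read per-genome gene annotations from TSV or GFF3.

    TSV dialect: header row with at least ``genome_id`` and ``gene``
    (case-insensitive names), optional ``ec`` and ``product``.  Duplicate
    gene rows collapse into the set; symbols are normalized.

    GFF3 dialect: one file per genome (genome id = file stem); ``gene=``,
    ``ec_number=`` and ``product=`` attributes of CDS features are read.
    """
    if format == "tsv":
        return _read_annotations_tsv(path)
    if format == "gff3":
        return [_read_annotation_gff3(path)]
    raise FormatError(f"unknown annotation format {format!r}")


def _read_annotations_tsv(path) -> list[GenomeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        logger.warning("annotation file %s is empty", path)
        return []
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("genome_id", "gene"):
        if col not in df.columns:
            raise FormatError(f"annotation table {path} lacks mandatory column {col!r}")
    if df.empty:
        logger.warning("annotation file %s has a header but no rows", path)
        return []
    out: list[GenomeAnnotation] = []
    for gid, sub in df.groupby("genome_id", sort=True):
        ann = GenomeAnnotation(genome_id=str(gid))
        for g in sub["gene"].dropna():
            if str(g).strip():
                ann.genes.add(normalize_symbol(str(g)))
        if "ec" in sub.columns:
            for e in sub["ec"].dropna():
                if str(e).strip():
                    ann.ecs.add(normalize_ec(str(e)))
        if "product" in sub.columns:
            for p in sub["product"].dropna():
                if str(p).strip():
                    ann.products.add(str(p).strip())
        out.append(ann)
    return out


def _read_annotation_gff3(path) -> GenomeAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    ann = GenomeAnnotation(genome_id=Path(path).stem)
    for feat in db.features_of_type("CDS"):
        for g in feat.attributes.get("gene", []):
            if g.strip():
                ann.genes.add(normalize_symbol(g))
        for e in feat.attributes.get("ec_number", []):
            if e.strip():
                ann.ecs.add(normalize_ec(e))
        for p in feat.attributes.get("product", []):
            if p.strip():
                ann.products.add(p.strip())
    return ann


# ---------------------------------------------------------------------------
# rulebook configuration

_EXPR_KEYS = {"all", "any", "at_least", "ref", "gene", "ec", "product_contains"}


def rule_from_config(obj) -> RuleExpr:
    """Build a rule expression from its YAML/JSON form.

    A bare string is a gene symbol.  Mappings use exactly one combinator key:
    ``{all: [...]}``, ``{any: [...]}``, ``{at_least: {k: int, of: [...]}}``,
    ``{ref: trait}``, ``{gene: sym}``, ``{ec: number}``,
    ``{product_contains: text}``.
    """
    if isinstance(obj, str):
        return _r.gene(obj)
    if not isinstance(obj, dict) or len(obj) != 1:
        raise RulebookError(f"rule expression must be a string or one-key mapping: {obj!r}")
    key, val = next(iter(obj.items()))
    if key not in _EXPR_KEYS:
        raise RulebookError(f"unknown rule combinator {key!r}")
    if key == "gene":
        return _r.gene(val)
    if key == "ec":
        return _r.ec(str(val))
    if key == "product_contains":
        return _r.product_contains(val)
    if key == "ref":
        return _r.ref(val)
    if key == "at_least":
        if not isinstance(val, dict) or set(val) != {"k", "of"}:
            raise RulebookError("at_least requires {k: int, of: [...]}")
        return _r.at_least(int(val["k"]), *[rule_from_config(c) for c in val["of"]])
    children = [rule_from_config(c) for c in val]
    return _r.all_of(*children) if key == "all" else _r.any_of(*children)


def read_rulebook(path=None) -> Rulebook:
    """Load a rulebook from YAML/JSON, or the built-in default when no path."""
    if path is None:
        return _r.default_rulebook()
    text = Path(path).read_text()
    cfg = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    )
    if not isinstance(cfg, dict):
        raise RulebookError(f"rulebook config {path} must map trait names to rules")
    traits = {}
    metadata = {}
    for name, expr in cfg.items():
        if isinstance(expr, dict) and set(expr) == {"rule", "note"}:
            metadata[name] = str(expr["note"])
            expr = expr["rule"]
        traits[name] = rule_from_config(expr)
    return Rulebook(traits=traits, metadata=metadata)


# ---------------------------------------------------------------------------
# tabular inputs


def read_coverage(path) -> pd.DataFrame:
    """Gene x sample coverage table (first column = gene id, rest numeric)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError(f"coverage table {path} contains negative values")
    dead = [c for c in df.columns if not (df[c] > 0).any()]
    if dead:
        raise FormatError(
            f"coverage table {path}: sample(s) with no positive coverage: {dead}"
        )
    return df


def read_otu_table(path, mode: str = "counts") -> pd.DataFrame:
    """Taxon x sample OTU table in ``counts`` or ``percent`` mode."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if mode == "counts":
        if not (df.values == df.values.astype(int)).all():
            raise FormatError(f"count-mode OTU table {path} has non-integer values")
        df = df.astype(int)
        if (df.values < 0).any():
            raise FormatError(f"OTU table {path} has negative counts")
    elif mode == "percent":
        sums = df.sum(axis=0)
        bad = sums[(sums - 100.0).abs() > 0.5]
        if not bad.empty:
            raise FormatError(
                f"percent-mode OTU table {path}: columns not summing to 100: "
                f"{list(bad.index)}"
            )
    else:
        raise FormatError(f"unknown OTU table mode {mode!r}")
    return df


def read_scg_table(path) -> pd.DataFrame:
    """Single-copy-gene summary (genome_id, n_present, n_duplicated)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("genome_id", "n_present", "n_duplicated"):
        if col not in df.columns:
            raise FormatError(f"SCG table {path} lacks mandatory column {col!r}")
    return df


def read_design(path) -> dict[str, str]:
    """Sample-to-group design file (sample_id, group) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"design file {path} lacks mandatory column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"design file {path} assigns a sample more than once")
    return dict(zip(df["sample_id"], df["group"]))


# ---------------------------------------------------------------------------
# output


def write_table(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV with 4-significant-digit floats.

    Labels containing tab characters are preserved by pandas' quoting, so
    ``read_table(write_table(x))`` round-trips both values (to ~1e-4
    relative) and labels.
    """
    if table is None:
        raise ValueError("table must not be None")
    os.makedirs(os.path.dirname(os.path.abspath(path)) or ".", exist_ok=True)
    table.to_csv(path, sep="\t", float_format="%.4g")


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", index_col=0)
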