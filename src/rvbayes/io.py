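"""Tabular I/O, variant filtering and variant-class assignment.

The pipeline consumes a per-variant allele-count table: one row per
ultra-rare variant carrying its gene symbol, functional annotation
(protein-truncating or missense), an optional missense pathogenicity
score (MPC), and the minor-allele counts observed in cases and in
controls.  No individual-level genotypes are needed anywhere downstream.

Canonical in-memory container is a :class:`pandas.DataFrame` with the
columns of :data:`VARIANT_COLUMNS`; helper dataclasses wrap the sample
composition and named gene sets.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SampleFrame",
    "GeneSet",
    "VARIANT_COLUMNS",
    "read_variant_table",
    "write_variant_table",
    "filter_ultra_rare",
    "classify_variant",
    "assign_variant_classes",
    "read_gene_set",
    "restrict_to_gene_set",
]

logger = logging.getLogger("rvbayes")
if not logger.handlers:  # timestamped key=value lines on stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: Required columns of the variant table, in canonical order.
VARIANT_COLUMNS = ["gene", "variant", "annotation", "mpc", "ac_case", "ac_control"]

#: Recognised functional annotations.
ANNOTATIONS = ("PTV", "missense")


class VariantTableError(ValueError):
    """Malformed or contract-violating variant table."""


@dataclass(frozen=True)
class SampleFrame:
    """Case/control cohort sizes (individuals, not alleles)."""

    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError(
                f"sample sizes must be >= 1, got n_case={self.n_case}, "
                f"n_control={self.n_control}"
            )

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


@dataclass(frozen=True)
class GeneSet:
    """Named, deduplicated, upper-cased collection of gene symbols."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(s.strip().upper() for s in symbols if s.strip()))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated variant table.

    Expects a header with columns ``gene  variant  annotation  mpc
    ac_case  ac_control``; ``mpc`` may be ``NA`` (customary for PTVs).
    Raises :class:`VariantTableError` naming the offending column or
    1-based data-row index on malformed input.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene": str, "variant": str, "annotation": str},
        na_values=["NA"],
        keep_default_na=True,
    )
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[VARIANT_COLUMNS].copy()
    for col in ("ac_case", "ac_control"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise VariantTableError(
                f"{path}: column {col!r} must be a non-negative integer; "
                f"offending data row {row} (value {df[col].iloc[row - 1]!r})"
            )
        df[col] = vals.astype(np.int64)
    unknown = ~df["annotation"].isin(ANNOTATIONS)
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0]) + 1
        raise VariantTableError(
            f"{path}: unknown annotation {df['annotation'].iloc[row - 1]!r} at data row {row}"
        )
    df["mpc"] = pd.to_numeric(df["mpc"], errors="coerce")
    logger.info("read_variant_table path=%s n_records=%d", path, len(df))
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a variant table as TSV (``mpc`` missing values as ``NA``)."""
    cols = [c for c in VARIANT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", index=False, na_rep="NA")


def filter_ultra_rare(df: pd.DataFrame, mac_max: int = 5) -> pd.DataFrame:
    """Keep ultra-rare variants: 1 <= cohort minor-allele count <= ``mac_max``.

    The minor-allele count is taken cohort-wide (cases + controls).
    Order-preserving and idempotent.
    """
    if mac_max < 1:
        raise ValueError(f"mac_max must be >= 1, got {mac_max}")
    total = df["ac_case"] + df["ac_control"]
    out = df.loc[(total >= 1) & (total <= mac_max)].copy()
    logger.info(
        "filter_ultra_rare mac_max=%d n_in=%d n_retained=%d", mac_max, len(df), len(out)
    )
    return out


def classify_variant(
    annotation: str, mpc: float | None, mpc_high: float = 3.0, mpc_low: float = 2.0
) -> str | None:
    """Assign a variant class from annotation and MPC score.

    Protein-truncating variants and missense variants with
    ``mpc >= mpc_high`` form class ``"I"`` (high impact); missense
    variants with ``mpc_low <= mpc < mpc_high`` form class ``"II"``;
    missense below ``mpc_low`` are excluded (returns ``None``).
    """
    if annotation == "PTV":
        return "I"
    if annotation != "missense":
        raise ValueError(f"unknown annotation {annotation!r}")
    if mpc is None or (isinstance(mpc, float) and np.isnan(mpc)):
        raise VariantTableError("missense variant without an MPC score")
    if mpc >= mpc_high:
        return "I"
    if mpc >= mpc_low:
        return "II"
    return None


def assign_variant_classes(
    df: pd.DataFrame, mpc_high: float = 3.0, mpc_low: float = 2.0
) -> pd.DataFrame:
    """Vectorised class assignment; returns only classified records.

    Adds a ``var_class`` column with values ``"I"``/``"II"`` and drops
    missense variants below ``mpc_low``.  Missense records lacking an
    MPC score raise :class:`VariantTableError`.
    """
    is_ptv = df["annotation"] == "PTV"
    is_mis = df["annotation"] == "missense"
    no_mpc = is_mis & df["mpc"].isna()
    if no_mpc.any():
        row = int(np.flatnonzero(no_mpc.to_numpy())[0]) + 1
        raise VariantTableError(f"missense variant without MPC score at data row {row}")
    var_class = pd.Series(pd.NA, index=df.index, dtype="object")
    var_class[is_ptv | (is_mis & (df["mpc"] >= mpc_high))] = "I"
    var_class[is_mis & (df["mpc"] >= mpc_low) & (df["mpc"] < mpc_high)] = "II"
    out = df.copy()
    out["var_class"] = var_class
    out = out.loc[var_class.notna()].copy()
    logger.info(
        "assign_variant_classes mpc_high=%s mpc_low=%s n_in=%d n_classified=%d",
        mpc_high, mpc_low, len(df), len(out),
    )
    return out


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list (one symbol/line, ``#`` comments)."""
    path = Path(path)
    symbols: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line)
    gs = GeneSet.from_symbols(name or path.stem, symbols)
    logger.info("read_gene_set path=%s n_members=%d", path, len(gs))
    return gs


def restrict_to_gene_set(df: pd.DataFrame, constraint_set: GeneSet) -> pd.DataFrame:
    """Keep only variants in genes belonging to ``constraint_set``.

    Symbols are compared upper-cased.  An empty intersection is allowed
    (logged as a warning) so that callers can decide how to proceed.
    """
    keep = df["gene"].str.upper().isin(constraint_set.members)
    out = df.loc[keep].copy()
    n_genes = out["gene"].nunique()
    if len(out) == 0:
        logger.warning(
            "restrict_to_gene_set set=%s empty intersection", constraint_set.name
        )
    logger.info(
        "restrict_to_gene_set set=%s n_in=%d n_retained=%d n_genes=%d",
        constraint_set.name, len(df), len(out), n_genes,
    )
    return out
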