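"""Bundled gene-list fixtures.

Ships the published overlap lists between the genes this analysis
nominates at Bayesian FDR < 5% in the schizophrenia exome cohort and
three reference disorder gene lists: 102 autism genes, 299
developmental-delay/intellectual-disability (DD/ID) genes and 64
schizophrenia GWAS genes.  Only the overlapping genes are published;
the reference list sizes are recorded as constants so overlap
percentages can be recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import GeneSet, read_gene_set

__all__ = [
    "REFERENCE_SET_SIZES",
    "load_overlap_set",
    "disorder_overlap_summary",
]

#: Published sizes of the reference disorder gene lists.
REFERENCE_SET_SIZES = {"autism": 102, "ddid": 299, "scz_gwas": 64}

_FILES = {
    "autism": "fdr_overlap_autism.txt",
    "ddid": "fdr_overlap_ddid.txt",
    "scz_gwas": "fdr_overlap_scz_gwas.txt",
}


def load_overlap_set(name: str) -> GeneSet:
    """Load one bundled overlap gene list (``autism``/``ddid``/``scz_gwas``)."""
    if name not in _FILES:
        raise KeyError(f"unknown gene list {name!r}; choose from {sorted(_FILES)}")
    path = resources.files("rvbayes").joinpath("data", _FILES[name])
    with resources.as_file(path) as p:
        return read_gene_set(p, name=name)


def disorder_overlap_summary() -> pd.DataFrame:
    """Overlap counts and percentages against the reference list sizes.

    Percentage uses the reference list size as denominator (e.g. 13
    autism overlaps out of 102 autism genes -> 12.75%).
    """
    rows = []
    for name, size in REFERENCE_SET_SIZES.items():
        gs = load_overlap_set(name)
        rows.append(
            {
                "reference": name,
                "overlap_count": len(gs),
                "reference_size": size,
                "pct_of_reference": round(100.0 * len(gs) / size, 2),
            }
        )
    return pd.DataFrame(rows)
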