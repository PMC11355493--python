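"""Bayesian FDR gene nomination.

Genes are ranked by posterior risk probability; the Bayesian FDR of the
top-k prefix is the running mean of the local false-discovery
probabilities (1 - posterior) over that prefix.  The nominated set is
the largest prefix with FDR strictly below the requested level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["bayesian_fdr_select"]


def bayesian_fdr_select(gene_posteriors: pd.DataFrame, level: float = 0.05) -> pd.DataFrame:
    """Rank genes by posterior and flag the Bayesian-FDR selection.

    Parameters
    ----------
    gene_posteriors
        DataFrame with columns ``gene`` and ``posterior`` (any extra
        columns, e.g. ``bf``, are carried through).
    level
        FDR level; selection keeps the largest prefix with cumulative
        FDR < level.

    Returns
    -------
    DataFrame sorted by descending posterior (posterior ties broken by
    gene symbol, so output is deterministic) with added columns
    ``rank`` (1-based), ``cum_fdr`` and boolean ``selected``.
    """
    if not 0.0 <= level < 1.0:
        # level 0 is allowed and selects nothing (the comparison is strict)
        raise ValueError(f"level must be in [0, 1), got {level}")
    post = np.asarray(gene_posteriors["posterior"], dtype=float)
    if len(post) and (np.nanmin(post) < 0 or np.nanmax(post) > 1 or np.isnan(post).any()):
        raise ValueError("posteriors must lie in [0, 1]")
    out = gene_posteriors.sort_values(
        ["posterior", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    k = np.arange(1, len(out) + 1)
    out["rank"] = k
    out["cum_fdr"] = np.cumsum(1.0 - out["posterior"].to_numpy()) / k
    # sorted descending by posterior => cum_fdr is non-decreasing, so the
    # strict-threshold rows form a prefix of the ranking
    out["selected"] = out["cum_fdr"] < level
    return out
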