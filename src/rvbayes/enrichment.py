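"""Gene-set overlap and enrichment statistics.

Covers three related questions about a nominated gene list:

* how many of its genes appear on a reference list (overlap counts and
  percentages),
* whether that overlap is larger than chance within a stated gene
  universe (Fisher exact test on the 2x2 membership table), and
* database-agnostic term enrichment (hypergeometric fold change with
  Bonferroni correction) for any gene -> term annotation map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet, logger

__all__ = [
    "OverlapResult",
    "TermEnrichment",
    "overlap",
    "fisher_exact_2x2",
    "set_enrichment",
    "term_fold_enrichment",
]


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of a query set A with a reference set B."""

    set_a_name: str
    set_b_name: str
    overlap_members: tuple[str, ...]
    overlap_count: int
    pct_of_b: float
    universe_size: int | None = None
    fisher_p: float | None = None
    odds_ratio: float | None = None


@dataclass(frozen=True)
class TermEnrichment:
    """Fold-change enrichment of one annotation term."""

    term_id: str
    k: int      # term hits in the query
    n: int      # query size (within reference)
    K: int      # term hits in the reference
    N: int      # reference size
    fold: float
    p: float
    p_adj: float


def overlap(set_a: GeneSet, set_b: GeneSet) -> OverlapResult:
    """Exact intersection of two gene sets; pct uses |B| as denominator."""
    if len(set_b) == 0:
        raise ValueError("reference set B is empty; percentage undefined")
    members = tuple(sorted(set_a.members & set_b.members))
    return OverlapResult(
        set_a_name=set_a.name,
        set_b_name=set_b.name,
        overlap_members=members,
        overlap_count=len(members),
        pct_of_b=100.0 * len(members) / len(set_b),
    )


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "greater"
) -> tuple[float, float]:
    """Fisher exact test for the table [[a, b], [c, d]].

    Returns ``(p_value, odds_ratio)`` with the sample odds ratio
    ``(a*d)/(b*c)`` (inf when b*c = 0 and a*d > 0, nan for 0/0).  The
    one-sided ``greater`` p-value is the upper hypergeometric tail of
    ``a``; ``two-sided`` sums all tables with point probability no
    larger than the observed one (with a 1e-9 relative slack so exact
    ties computed in floating point are included).
    Any zero margin makes the table degenerate: p = 1 with a warning.
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")
    a, b, c, d = (int(x) for x in cells)
    n_row1, n_col1, n_tot = a + b, a + c, a + b + c + d
    if ad := (a * d):
        odds_ratio = np.inf if b * c == 0 else ad / (b * c)
    else:
        odds_ratio = np.nan if b * c == 0 else 0.0
    if min(n_row1, n_col1, c + d, b + d) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0, odds_ratio
    hg = stats.hypergeom(n_tot, n_col1, n_row1)
    if alternative == "greater":
        p = float(hg.sf(a - 1))
    else:
        support = np.arange(max(0, n_row1 + n_col1 - n_tot), min(n_row1, n_col1) + 1)
        pmf = hg.pmf(support)
        p_obs = float(hg.pmf(a))
        p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    if p > 1.0 - 1e-9:  # full-support sums should be exactly 1
        p = 1.0
    return float(p), odds_ratio


def set_enrichment(
    query: GeneSet,
    reference_sets: Sequence[GeneSet],
    universe: GeneSet,
    alternative: str = "greater",
) -> list[OverlapResult]:
    """Fisher enrichment of ``query`` against each reference set.

    All sets are clipped to ``universe`` before building the 2x2 table
    (in-query & in-ref / in-query only / in-ref only / neither).
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    q = query.members & universe.members
    if q != query.members:
        warnings.warn(
            f"{len(query.members - universe.members)} query gene(s) outside "
            "the universe were dropped",
            stacklevel=2,
        )
    results = []
    for ref in reference_sets:
        r = ref.members & universe.members
        inter = q & r
        a = len(inter)
        b = len(q) - a
        c = len(r) - a
        d = len(universe) - a - b - c
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, orat = fisher_exact_2x2(a, b, c, d, alternative)
        results.append(
            OverlapResult(
                set_a_name=query.name,
                set_b_name=ref.name,
                overlap_members=tuple(sorted(inter)),
                overlap_count=a,
                pct_of_b=100.0 * a / len(ref) if len(ref) else float("nan"),
                universe_size=len(universe),
                fisher_p=p,
                odds_ratio=orat,
            )
        )
        logger.info(
            "set_enrichment query=%s ref=%s overlap=%d p=%.3g",
            query.name, ref.name, a, p,
        )
    return results


def term_fold_enrichment(
    query: GeneSet,
    term_map: Mapping[str, set[str]] | pd.DataFrame,
    reference: GeneSet,
) -> list[TermEnrichment]:
    """Per-term fold change and hypergeometric enrichment p-values.

    ``term_map`` maps gene symbol -> set of term ids (or a DataFrame
    with ``gene``/``term`` columns).  Fold change is (k/n)/(K/N) for k
    query hits out of n query genes versus K reference hits out of N
    reference genes; p is the hypergeometric upper tail, Bonferroni-
    corrected over all terms with at least one reference hit.  Sorted
    by descending fold change.
    """
    if isinstance(term_map, pd.DataFrame):
        gmap: dict[str, set[str]] = {}
        for g, t in zip(term_map["gene"], term_map["term"]):
            gmap.setdefault(str(g).upper(), set()).add(str(t))
        term_map = gmap
    else:
        term_map = {g.upper(): set(ts) for g, ts in term_map.items()}
    n_dropped = len(query.members - reference.members)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} query gene(s) absent from the reference were dropped",
            stacklevel=2,
        )
    q = query.members & reference.members
    n, big_n = len(q), len(reference)
    term_ref: dict[str, int] = {}
    term_hits: dict[str, int] = {}
    for g in reference.members:
        for t in term_map.get(g, ()):
            term_ref[t] = term_ref.get(t, 0) + 1
            if g in q:
                term_hits[t] = term_hits.get(t, 0) + 1
    n_terms = len(term_ref)
    out = []
    for t, big_k in term_ref.items():
        k = term_hits.get(t, 0)
        fold = (k / n) / (big_k / big_n) if n else 0.0
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        out.append(
            TermEnrichment(
                term_id=t, k=k, n=n, K=big_k, N=big_n,
                fold=fold, p=p, p_adj=min(1.0, p * n_terms),
            )
        )
    out.sort(key=lambda e: (-e.fold, e.term_id))
    return out
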