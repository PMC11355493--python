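"""Two-level Bayesian mixture model for rare-variant gene association.

Hierarchy
---------
Each gene ``i`` in a universe of ``G`` genes carries a latent risk
indicator ``Z_i ~ Bernoulli(delta)``.  Within a risk gene, each variant
``j`` of class ``c`` carries a latent risk indicator ``U_ij ~
Bernoulli(eta_c)``; in a non-risk gene every variant is null.  A risk
variant's case/control count split follows the tilted binomial of
:mod:`rvbayes.bayes_factor`, a null variant the untilted one.  With
``BF_ij`` the per-variant Bayes factor, the gene-level Bayes factor is

    LR_i = prod_j [ (1 - eta_c(j)) + eta_c(j) * BF_ij ]

and the marginal log-likelihood (up to the constant null likelihood)

    l(delta, eta) = sum_i log[ (1 - delta) + delta * LR_i ].

``(delta, eta)`` are shared across genes and estimated by EM on the
latent indicators; genes are then ranked by the posterior risk
probability ``delta * LR_i / ((1 - delta) + delta * LR_i)``.

The public surface follows the statsmodels convention: build a
:class:`RareVariantMixture` from data, call :meth:`~RareVariantMixture.fit`,
and read estimates, likelihood-ratio tests, per-gene results and a
``summary()`` off the returned :class:`RareVariantMixtureResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .bayes_factor import DEFAULT_PRIORS, GroupPrior, null_case_share, variant_bf_table
from .fdr import bayesian_fdr_select
from .io import SampleFrame

__all__ = [
    "gene_bayes_factor",
    "RareVariantMixture",
    "RareVariantMixtureResults",
    "LRTResult",
]


def gene_bayes_factor(
    bfs: Sequence[float],
    var_classes: Sequence[str],
    eta: Mapping[str, float],
) -> float:
    """Gene Bayes factor: mixture product over the gene's variants.

    ``prod_j [(1 - eta_c) + eta_c * bf_j]``; equals 1 for a gene with no
    variants and collapses to ``prod bf_j`` at eta = 1.
    """
    if len(bfs) != len(var_classes):
        raise ValueError("bfs and var_classes must have equal length")
    lr = 1.0
    for b, c in zip(bfs, var_classes):
        if c not in eta:
            raise ValueError(f"unknown variant class {c!r}")
        e = eta[c]
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"eta[{c!r}] must be in [0, 1], got {e}")
        lr *= (1.0 - e) + e * b
    return lr


@dataclass(frozen=True)
class LRTResult:
    """Boundary-corrected likelihood-ratio test of eta_c = 0."""

    var_class: str
    statistic: float
    pvalue: float
    llf_full: float
    llf_constrained: float


class RareVariantMixture:
    """Rare-variant mixture model over a gene universe.

    Parameters
    ----------
    variants
        Classified variant table (columns ``gene``, ``var_class``,
        ``ac_case``, ``ac_control``; a precomputed ``bf`` column is used
        if present, otherwise Bayes factors are computed from the counts).
    sample
        Cohort sizes; required unless ``bf`` is precomputed.
    priors
        Per-class effect-size priors (default: class I mean relative
        risk 3, class II mean 1, both rate 1).
    gene_universe
        Optional iterable of gene ids defining the full universe.  Genes
        without retained variants contribute a neutral Bayes factor of 1
        but still count in the risk-gene proportion delta.
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        sample: SampleFrame | None = None,
        priors: Mapping[str, GroupPrior] | None = None,
        gene_universe: Iterable[str] | None = None,
        rel_tol: float = 1e-8,
    ) -> None:
        self.priors = dict(DEFAULT_PRIORS if priors is None else priors)
        self.sample = sample
        if "bf" not in variants.columns:
            if sample is None:
                raise ValueError("sample sizes are required to compute Bayes factors")
            variants = variant_bf_table(variants, sample, self.priors, rel_tol)
        self.variants = variants.reset_index(drop=True)
        bad = set(self.variants["var_class"]) - set(self.priors)
        if bad:
            raise ValueError(f"unknown variant class(es) {sorted(bad)}")

        genes_with_var = list(dict.fromkeys(self.variants["gene"]))
        if gene_universe is None:
            universe = genes_with_var
        else:
            universe = list(dict.fromkeys(gene_universe))
            missing = set(genes_with_var) - set(universe)
            if missing:
                raise ValueError(
                    f"{len(missing)} variant gene(s) absent from gene_universe, "
                    f"e.g. {sorted(missing)[:3]}"
                )
        self.gene_ids: list[str] = sorted(universe)
        self.n_genes = len(self.gene_ids)
        if len(self.variants) == 0:
            raise ValueError("model needs at least one variant")

        gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
        self.classes: list[str] = sorted(set(self.variants["var_class"]))
        class_pos = {c: i for i, c in enumerate(self.classes)}

        order = np.argsort(self.variants["gene"].map(gene_pos).to_numpy(), kind="stable")
        v = self.variants.iloc[order]
        self._bf = v["bf"].to_numpy(dtype=float)
        if np.any(~np.isfinite(self._bf)) or np.any(self._bf < 0):
            raise ValueError("variant Bayes factors must be finite and >= 0")
        self._vclass = np.array([class_pos[c] for c in v["var_class"]])
        self._vgene = v["gene"].map(gene_pos).to_numpy()
        self._starts = np.flatnonzero(np.r_[True, np.diff(self._vgene) > 0])
        self._genes_with_var = self._vgene[self._starts]
        self._logbf = np.log(np.maximum(self._bf, 1e-300))

    # ------------------------------------------------------------------
    # alternative constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        n_case: int,
        n_control: int,
        priors: Mapping[str, GroupPrior] | None = None,
        gene_universe: Iterable[str] | None = None,
    ) -> "RareVariantMixture":
        return cls(df, SampleFrame(n_case, n_control), priors, gene_universe)

    @classmethod
    def from_bayes_factors(
        cls,
        gene_bfs: Mapping[str, Sequence[tuple[str, float]]],
        gene_universe: Iterable[str] | None = None,
    ) -> "RareVariantMixture":
        """Build directly from per-gene (class, Bayes factor) pairs."""
        rows = [
            {"gene": g, "variant": f"{g}:{i}", "var_class": c, "bf": b}
            for g, pairs in gene_bfs.items()
            for i, (c, b) in enumerate(pairs)
        ]
        classes = sorted({r["var_class"] for r in rows})
        priors = {c: DEFAULT_PRIORS.get(c, GroupPrior(c, 1.0)) for c in classes}
        universe = gene_universe if gene_universe is not None else list(gene_bfs)
        return cls(pd.DataFrame(rows), priors=priors, gene_universe=universe)

    # ------------------------------------------------------------------
    # likelihood machinery
    # ------------------------------------------------------------------
    def _eta_vec(self, eta: Mapping[str, float]) -> np.ndarray:
        try:
            vec = np.array([eta[c] for c in self.classes], dtype=float)
        except KeyError as exc:
            raise ValueError(f"eta missing class {exc}") from exc
        if np.any((vec < 0) | (vec > 1)):
            raise ValueError(f"eta must be in [0, 1], got {eta}")
        return vec

    def _gene_loglr(self, eta_vec: np.ndarray) -> np.ndarray:
        """log LR_i for every gene in the universe (0 for variant-free genes)."""
        e = eta_vec[self._vclass]
        w = (1.0 - e) + e * self._bf
        loglr = np.zeros(self.n_genes)
        loglr[self._genes_with_var] = np.add.reduceat(
            np.log(np.maximum(w, 1e-300)), self._starts
        )
        return loglr

    def loglike(self, delta: float, eta: Mapping[str, float]) -> float:
        """Marginal log-likelihood relative to the all-null model."""
        if not 0.0 <= delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {delta}")
        loglr = self._gene_loglr(self._eta_vec(eta))
        return float(np.sum(_log_mix(delta, loglr)))

    def _em_update(
        self, delta: float, eta_vec: np.ndarray
    ) -> tuple[float, np.ndarray, float]:
        """One EM sweep; returns (new delta, new eta, loglik at input params)."""
        e = eta_vec[self._vclass]
        w = (1.0 - e) + e * self._bf
        loglr = np.zeros(self.n_genes)
        loglr[self._genes_with_var] = np.add.reduceat(
            np.log(np.maximum(w, 1e-300)), self._starts
        )
        ll = float(np.sum(_log_mix(delta, loglr)))
        # E-step: posterior gene risk T_i and variant risk U_ij
        t_gene = _posterior_mix(delta, loglr)
        u = np.where(w > 0, e * self._bf / np.maximum(w, 1e-300), 1.0)
        tv = t_gene[self._vgene]
        # M-step
        new_delta = float(np.mean(t_gene))
        num = np.bincount(self._vclass, weights=tv * u, minlength=len(self.classes))
        den = np.bincount(self._vclass, weights=tv, minlength=len(self.classes))
        new_eta = np.where(den > 0, num / np.maximum(den, 1e-300), eta_vec)
        return new_delta, np.clip(new_eta, 0.0, 1.0), ll

    def _run_em(
        self,
        delta0: float,
        eta0: np.ndarray,
        tol: float,
        max_iter: int,
        fixed_zero: int | None = None,
    ) -> tuple[float, np.ndarray, np.ndarray, bool, int]:
        delta, eta = delta0, eta0.copy()
        if fixed_zero is not None:
            eta[fixed_zero] = 0.0
        # each _em_update returns the log-likelihood at its *input* params,
        # so iteration t's ll is the likelihood after t parameter updates
        new_delta, new_eta, ll_prev = self._em_update(delta, eta)
        if fixed_zero is not None:
            new_eta[fixed_zero] = 0.0
        trace: list[float] = [ll_prev]
        delta, eta = new_delta, new_eta
        converged = False
        n_iter = 0
        for it in range(1, max_iter + 1):
            new_delta, new_eta, ll = self._em_update(delta, eta)
            if fixed_zero is not None:
                new_eta[fixed_zero] = 0.0
            if not np.isfinite(ll):
                raise FloatingPointError(f"non-finite log-likelihood at iteration {it}")
            trace.append(ll)
            n_iter = it
            if abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1.0):
                converged = True
                break
            ll_prev = ll
            delta, eta = new_delta, new_eta
        return delta, eta, np.asarray(trace), converged, n_iter

    def fit(
        self,
        start_delta: float = 0.1,
        start_eta: float | Mapping[str, float] = 0.1,
        tol: float = 1e-8,
        max_iter: int = 5000,
        n_restarts: int = 5,
        seed: int = 0,
    ) -> "RareVariantMixtureResults":
        """Fit (delta, eta) by EM with jittered multi-start.

        The first start uses ``start_delta``/``start_eta``; the remaining
        ``n_restarts - 1`` draw all parameters uniformly on (0.02, 0.98)
        from ``seed``, guarding against absorbing boundary fixed points
        (eta = 0 exactly is one).  The run with the best final
        log-likelihood is kept.
        """
        if isinstance(start_eta, Mapping):
            eta0 = self._eta_vec(start_eta)
        else:
            eta0 = np.full(len(self.classes), float(start_eta))
        if not (0.0 < start_delta < 1.0) or np.any((eta0 <= 0) | (eta0 >= 1)):
            raise ValueError("start values must lie strictly inside (0, 1)")
        rng = np.random.default_rng(seed)
        starts = [(start_delta, eta0)]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(
                (float(rng.uniform(0.02, 0.98)), rng.uniform(0.02, 0.98, len(self.classes)))
            )
        best = None
        for d0, e0 in starts:
            delta, eta, trace, conv, n_iter = self._run_em(d0, e0, tol, max_iter)
            llf = self.loglike(delta, dict(zip(self.classes, eta)))
            if best is None or llf > best[0]:
                best = (llf, delta, eta, trace, conv, n_iter)
        llf, delta, eta, trace, conv, n_iter = best
        return RareVariantMixtureResults(
            model=self,
            delta=delta,
            eta=dict(zip(self.classes, eta)),
            llf=llf,
            loglik_trace=trace,
            converged=conv,
            n_iter=n_iter,
            tol=tol,
            max_iter=max_iter,
        )


def _log_mix(delta: float, loglr: np.ndarray) -> np.ndarray:
    """log[(1 - delta) + delta * LR] computed stably from log LR."""
    with np.errstate(divide="ignore"):
        a = np.log1p(-delta) if delta < 1.0 else -np.inf
        b = np.log(delta) if delta > 0.0 else -np.inf
    return np.logaddexp(a, b + loglr)


def _posterior_mix(delta: float, loglr: np.ndarray) -> np.ndarray:
    """Posterior P(risk | data) = delta*LR / ((1-delta) + delta*LR)."""
    if delta <= 0.0:
        return np.zeros_like(loglr)
    if delta >= 1.0:
        return np.ones_like(loglr)
    return special.expit(np.log(delta) - np.log1p(-delta) + loglr)


class RareVariantMixtureResults:
    """Fitted mixture estimates, tests and per-gene quantities."""

    def __init__(
        self,
        model: RareVariantMixture,
        delta: float,
        eta: dict[str, float],
        llf: float,
        loglik_trace: np.ndarray,
        converged: bool,
        n_iter: int,
        tol: float,
        max_iter: int,
    ) -> None:
        self.model = model
        self.delta = delta
        self.eta = eta
        self.llf = llf
        self.loglik_trace = loglik_trace
        self.converged = converged
        self.n_iter = n_iter
        self._tol = tol
        self._max_iter = max_iter
        self._lrt_cache: dict[str, LRTResult] = {}

    # -- likelihood-ratio tests ---------------------------------------
    def lrt_eta(self, var_class: str, n_restarts: int = 5, seed: int = 0) -> LRTResult:
        """Test eta_c = 0 with the boundary-corrected chi-square null.

        The constrained model (eta of ``var_class`` pinned at 0, all
        other parameters re-optimised) is refit by the same multi-start
        EM; since 0 is on the parameter boundary the null of the LRT
        statistic is the 50:50 mixture of a point mass at 0 and
        chi-square(1), so p = 0.5 * P(chi2_1 > stat).
        """
        if var_class in self._lrt_cache:
            return self._lrt_cache[var_class]
        m = self.model
        if var_class not in m.classes:
            raise ValueError(f"unknown variant class {var_class!r}")
        fixed = m.classes.index(var_class)
        rng = np.random.default_rng(seed)
        starts = [(0.1, np.full(len(m.classes), 0.1))]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(
                (float(rng.uniform(0.02, 0.98)), rng.uniform(0.02, 0.98, len(m.classes)))
            )
        best_llf = -np.inf
        best_sol = None
        for d0, e0 in starts:
            delta, eta, _, _, _ = m._run_em(
                d0, e0, self._tol, self._max_iter, fixed_zero=fixed
            )
            llf = m.loglike(delta, dict(zip(m.classes, eta)))
            if llf > best_llf:
                best_llf, best_sol = llf, (delta, eta)
        # polish the full fit from the constrained optimum (eta_c nudged off
        # the absorbing boundary) so the full likelihood can never trail the
        # constrained one by more than convergence noise
        d0, e0 = best_sol
        e0 = np.clip(e0, 1e-3, 1.0 - 1e-12)
        delta, eta, _, _, _ = m._run_em(
            max(d0, 1e-3), e0, self._tol * 1e-2, 4 * self._max_iter
        )
        llf_full = max(self.llf, m.loglike(delta, dict(zip(m.classes, eta))))
        stat = 2.0 * (llf_full - best_llf)
        # EM creeps geometrically toward an eta = 0 boundary optimum, so a
        # no-evidence class can leave the full fit short by O(1e-3); such
        # statistics are numerically zero (the p-value moves by < 0.02 at the
        # p ~ 0.5 end) and are clipped to 0.  Larger shortfalls signal a
        # genuine optimizer failure and are raised.
        slack = max(1e-2, 1e-6 * (abs(llf_full) + 1.0))
        if stat < -slack:
            raise FloatingPointError(
                f"constrained fit beat the full fit (stat={stat}); full fit "
                "did not reach the maximum"
            )
        stat = max(stat, 0.0)
        pvalue = 0.5 * float(stats.chi2.sf(stat, df=1))
        res = LRTResult(var_class, stat, pvalue, llf_full, best_llf)
        self._lrt_cache[var_class] = res
        return res

    @property
    def eta_pvalues(self) -> dict[str, float]:
        return {c: self.lrt_eta(c).pvalue for c in self.model.classes}

    # -- per-gene quantities ------------------------------------------
    def gene_results(self) -> pd.DataFrame:
        """Per-gene Bayes factor and posterior risk probability."""
        m = self.model
        loglr = m._gene_loglr(m._eta_vec(self.eta))
        post = _posterior_mix(self.delta, loglr)
        return pd.DataFrame(
            {"gene": m.gene_ids, "bf": np.exp(loglr), "posterior": post}
        )

    def select_genes(self, fdr_level: float = 0.05) -> pd.DataFrame:
        """Rank genes by posterior and nominate at a Bayesian FDR level."""
        return bayesian_fdr_select(self.gene_results(), level=fdr_level)

    # -- reporting -----------------------------------------------------
    def summary(self, fdr_level: float = 0.05) -> str:
        m = self.model
        lines = [
            "Rare-variant mixture model (EM fit)",
            "=" * 55,
            f"Genes in universe:      {m.n_genes}",
            f"Variants:               {len(m.variants)}",
            f"Log-likelihood (rel.):  {self.llf:.4f}",
            f"Converged:              {self.converged} ({self.n_iter} iterations)",
            "-" * 55,
            f"delta (risk-gene prop.): {self.delta:.4f}",
        ]
        for c in m.classes:
            p = self.lrt_eta(c).pvalue
            prior = m.priors.get(c)
            gb = f"{prior.gamma_bar:g}" if prior else "?"
            lines.append(
                f"eta[{c}] (risk-variant prop., gamma_bar={gb}): "
                f"{self.eta[c]:.4f}   LRT p = {p:.3g}"
            )
        sel = self.select_genes(fdr_level)
        lines += [
            "-" * 55,
            f"Genes at Bayesian FDR < {fdr_level:g}: {int(sel['selected'].sum())}",
        ]
        return "\n".join(lines)
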