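"""Synthetic case-control ultra-rare variant counts with known truth.

Emulates a SCHEMA-like exome count dataset over a constraint-gene
universe: ~3000 genes, a fraction ``delta`` of risk genes, two variant
classes with very different risk-variant proportions (class I: PTVs and
high-MPC missense, class II: MPC 2-3 missense), Gamma-distributed
relative risks, ultra-rare totals capped at a minor-allele count of 5,
and a heavily imbalanced case:control cohort (24,248 : 97,322).

The generative process mirrors the fitted likelihood exactly: a risk
variant tilts the binomial split of its fixed carrier-allele total
between cases and controls, so parameter recovery by the model is
well-posed.  Default truth values match the proportions the model
estimates on the real cohort (delta = 0.451, eta_I = 0.6766,
eta_II = 0.081).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_factor import null_case_share, risk_case_share
from .io import SampleFrame, logger

__all__ = ["SimulationConfig", "simulate_dataset", "truth_fdp", "TRUTH_COLUMNS"]

TRUTH_COLUMNS = ["gene", "variant", "z_gene", "u_variant", "gamma"]


def _default_eta() -> dict[str, float]:
    return {"I": 0.6766, "II": 0.081}


def _default_gamma_bar() -> dict[str, float]:
    return {"I": 3.0, "II": 1.0}


def _default_vpg() -> dict[str, float]:
    # mean retained ultra-rare variants per constraint gene, per class;
    # class II (moderate missense) sites outnumber high-impact class I
    # less than proportionally because of the MPC >= 2 restriction
    return {"I": 6.0, "II": 4.0}


def _default_total_dist() -> tuple[float, ...]:
    return (0.2, 0.2, 0.2, 0.2, 0.2)


@dataclass
class SimulationConfig:
    """Ground-truth configuration of one synthetic dataset.

    ``total_count_distribution`` gives the probabilities of cohort
    minor-allele totals 1..mac_max (uniform by default).  ``seed`` is
    mandatory so every dataset is reproducible.
    """

    seed: int
    n_genes: int = 3000
    n_case: int = 24248
    n_control: int = 97322
    delta_true: float = 0.451
    eta_true: dict[str, float] = field(default_factory=_default_eta)
    gamma_bar_true: dict[str, float] = field(default_factory=_default_gamma_bar)
    sigma_true: float = 1.0
    variants_per_gene_mean: dict[str, float] = field(default_factory=_default_vpg)
    mac_max: int = 5
    total_count_distribution: tuple[float, ...] = field(default_factory=_default_total_dist)

    def __post_init__(self) -> None:
        probs = np.asarray(self.total_count_distribution, dtype=float)
        if len(probs) != self.mac_max or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError(
                "total_count_distribution must be mac_max probabilities summing to 1"
            )
        if not 0.0 <= self.delta_true <= 1.0:
            raise ValueError("delta_true must be in [0, 1]")
        for c, e in self.eta_true.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"eta_true[{c!r}] must be in [0, 1]")
        if set(self.eta_true) != set(self.gamma_bar_true) or set(self.eta_true) != set(
            self.variants_per_gene_mean
        ):
            raise ValueError("eta_true, gamma_bar_true, variants_per_gene_mean need equal keys")

    @property
    def sample(self) -> SampleFrame:
        return SampleFrame(self.n_case, self.n_control)


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one dataset; returns ``(variant_table, truth_table)``.

    The variant table has the standard columns (gene, variant,
    annotation, mpc, ac_case, ac_control) and round-trips through
    :mod:`rvbayes.io` — class I variants are emitted as PTVs, class II
    as missense with an MPC drawn uniformly in [2, 3).  The truth table
    records the per-gene risk indicator ``z_gene``, the per-variant risk
    indicator ``u_variant`` and the sampled relative risk ``gamma``
    (1.0 for null variants).
    """
    rng = np.random.default_rng(config.seed)
    p0 = null_case_share(config.sample)
    classes = sorted(config.eta_true)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    z = rng.random(config.n_genes) < config.delta_true

    var_rows: list[dict] = []
    truth_rows: list[dict] = []
    totals_support = np.arange(1, config.mac_max + 1)
    probs = np.asarray(config.total_count_distribution, dtype=float)
    for gi, g in enumerate(genes):
        for c in classes:
            n_var = rng.poisson(config.variants_per_gene_mean[c])
            if n_var == 0:
                continue
            u = (rng.random(n_var) < config.eta_true[c]) & z[gi]
            gamma = np.ones(n_var)
            shape = config.gamma_bar_true[c] * config.sigma_true
            gamma[u] = rng.gamma(shape, 1.0 / config.sigma_true, size=int(u.sum()))
            totals = rng.choice(totals_support, size=n_var, p=probs)
            p_case = np.where(u, risk_case_share(np.maximum(gamma, 1e-12), p0), p0)
            ac_case = rng.binomial(totals, p_case)
            mpc = rng.uniform(2.0, 3.0, size=n_var)
            for vi in range(n_var):
                vid = f"{g}:{c}:{vi}"
                var_rows.append(
                    {
                        "gene": g,
                        "variant": vid,
                        "annotation": "PTV" if c == "I" else "missense",
                        "mpc": np.nan if c == "I" else round(float(mpc[vi]), 4),
                        "ac_case": int(ac_case[vi]),
                        "ac_control": int(totals[vi] - ac_case[vi]),
                    }
                )
                truth_rows.append(
                    {
                        "gene": g,
                        "variant": vid,
                        "z_gene": int(z[gi]),
                        "u_variant": int(u[vi]),
                        "gamma": float(gamma[vi]),
                    }
                )
    variants = pd.DataFrame(
        var_rows, columns=["gene", "variant", "annotation", "mpc", "ac_case", "ac_control"]
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    logger.info(
        "simulate_dataset seed=%d n_genes=%d n_variants=%d n_risk_genes=%d",
        config.seed, config.n_genes, len(variants), int(z.sum()),
    )
    return variants, truth


def truth_fdp(selected_genes, truth: pd.DataFrame) -> float:
    """Realised false-discovery proportion of a selected gene list.

    Fraction of selected genes whose true risk indicator is 0; an empty
    selection returns 0.0 by convention (no discoveries, none false).
    """
    z_by_gene = truth.drop_duplicates("gene").set_index("gene")["z_gene"]
    selected = list(selected_genes)
    if not selected:
        return 0.0
    unknown = [g for g in selected if g not in z_by_gene.index]
    if unknown:
        raise ValueError(f"selected gene(s) not in truth table: {unknown[:3]}")
    return float((z_by_gene.loc[selected] == 0).mean())
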