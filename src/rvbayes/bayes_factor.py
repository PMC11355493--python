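"""Per-variant Bayes factors for a case/control allele-count split.

Model
-----
An ultra-rare variant with cohort minor-allele count ``T`` splits its
``T`` carrier alleles between cases and controls.  Under the null the
count in cases is Binomial(T, p0) with ``p0 = n_case / (n_case +
n_control)``.  A risk variant with relative risk ``gamma`` tilts that
share to

    p(gamma) = gamma * p0 / (gamma * p0 + (1 - p0)),

so the alternative marginal likelihood integrates the binomial over a
Gamma effect-size prior with mean ``gamma_bar``:

    gamma ~ Gamma(shape = gamma_bar * sigma, rate = sigma).

The Bayes factor is the ratio of the marginal alternative likelihood to
the null likelihood.  The binomial coefficients cancel, leaving

    BF(k, T) = E_gamma[ gamma^k * (p0 * gamma + 1 - p0)^(-T) ],

evaluated by adaptive quadrature on the log-relative-risk axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special

from .io import SampleFrame

__all__ = [
    "GroupPrior",
    "DEFAULT_PRIORS",
    "null_case_share",
    "risk_case_share",
    "variant_bayes_factor",
    "variant_bf_table",
]


class QuadratureError(RuntimeError):
    """Numerical quadrature failed to reach the requested accuracy."""


@dataclass(frozen=True)
class GroupPrior:
    """Gamma effect-size prior of one variant class.

    ``gamma_bar`` is the prior mean relative risk; ``sigma`` the rate
    parameter controlling dispersion (shape = gamma_bar * sigma, so the
    mean is gamma_bar for every sigma and the variance gamma_bar/sigma).
    """

    var_class: str
    gamma_bar: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_bar <= 0 or self.sigma <= 0:
            raise ValueError(
                f"gamma_bar and sigma must be > 0, got {self.gamma_bar}, {self.sigma}"
            )

    @property
    def shape(self) -> float:
        return self.gamma_bar * self.sigma

    @property
    def rate(self) -> float:
        return self.sigma


#: Class I (PTV + high-MPC missense) mean relative risk 3; class II
#: (MPC 2-3 missense) mean 1, reflecting its expected low burden.
DEFAULT_PRIORS: dict[str, GroupPrior] = {
    "I": GroupPrior("I", gamma_bar=3.0, sigma=1.0),
    "II": GroupPrior("II", gamma_bar=1.0, sigma=1.0),
}


def null_case_share(sample: SampleFrame) -> float:
    """Probability that a carrier allele falls in a case under the null."""
    return sample.n_case / sample.n_total


def risk_case_share(gamma, p0: float):
    """Case share of carrier alleles for relative risk ``gamma``.

    Strictly increasing in gamma; equals ``p0`` at gamma = 1.  Accepts
    scalar or array gamma.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("gamma must be > 0")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    out = gamma * p0 / (gamma * p0 + (1.0 - p0))
    return out if out.ndim else float(out)


def _bf_integrand(u, k: int, t: int, p0: float, prior: GroupPrior):
    """Integrand on the u = log(gamma) axis, prior density included.

    Everything is assembled in log space so extreme u neither overflow
    (exp(u) in the Gamma tail) nor underflow prematurely.
    """
    u = np.asarray(u, dtype=float)
    a, r = prior.shape, prior.rate
    # log[ gamma^k (p0 gamma + q0)^-T * GammaPdf(gamma) * gamma ],  gamma = e^u
    with np.errstate(over="ignore"):
        logf = (
            k * u
            - t * np.logaddexp(np.log(p0) + u, np.log1p(-p0))
            + a * np.log(r)
            - special.gammaln(a)
            + a * u
            - r * np.exp(np.minimum(u, 700.0))
        )
    return np.exp(logf)


def variant_bayes_factor(
    ac_case: int,
    ac_total: int,
    p0: float,
    prior: GroupPrior,
    rel_tol: float = 1e-8,
) -> float:
    """Bayes factor of risk vs null for one variant's count split.

    Parameters
    ----------
    ac_case, ac_total
        Minor-allele count in cases and in the whole cohort.
    p0
        Null case share from :func:`null_case_share`.
    prior
        Effect-size prior of the variant's class.
    rel_tol
        Target relative accuracy of the quadrature.
    """
    if not 0 <= ac_case <= ac_total:
        raise ValueError(f"need 0 <= ac_case <= ac_total, got {ac_case}, {ac_total}")
    if ac_total == 0:
        return 1.0
    val, abserr = integrate.quad(
        _bf_integrand,
        -np.inf,
        np.inf,
        args=(ac_case, ac_total, p0, prior),
        epsabs=1e-14,
        epsrel=rel_tol,
        limit=200,
    )
    if not np.isfinite(val) or (val > 0 and abserr / val > 100 * rel_tol):
        raise QuadratureError(
            f"quadrature did not converge: value={val}, abserr={abserr}, "
            f"k={ac_case}, T={ac_total}, p0={p0}, prior={prior}"
        )
    return float(max(val, 0.0))


def variant_bf_table(
    variants: pd.DataFrame,
    sample: SampleFrame,
    priors: dict[str, GroupPrior] | None = None,
    rel_tol: float = 1e-8,
) -> pd.DataFrame:
    """Attach a ``bf`` column to a classified variant table.

    Ultra-rare counts make the (class, ac_case, total) combinations few,
    so Bayes factors are computed once per combination and broadcast.
    """
    priors = DEFAULT_PRIORS if priors is None else priors
    unknown = set(variants["var_class"]) - set(priors)
    if unknown:
        raise ValueError(f"no prior configured for variant class(es) {sorted(unknown)}")
    p0 = null_case_share(sample)
    out = variants.copy()
    total = out["ac_case"].to_numpy() + out["ac_control"].to_numpy()
    key = pd.DataFrame(
        {"var_class": out["var_class"].to_numpy(), "k": out["ac_case"].to_numpy(), "t": total}
    )
    cache: dict[tuple[str, int, int], float] = {}
    bf = np.empty(len(out))
    for i, (c, k, t) in enumerate(zip(key["var_class"], key["k"], key["t"])):
        ck = (c, int(k), int(t))
        if ck not in cache:
            cache[ck] = variant_bayes_factor(int(k), int(t), p0, priors[c], rel_tol)
        bf[i] = cache[ck]
    out["bf"] = bf
    return out
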