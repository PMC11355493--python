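"""Independent oracles used across the test suite.

Each oracle recomputes a quantity by a route deliberately different
from the package implementation: dense-grid trapezoid or Monte-Carlo
integration for the variant Bayes factor, exhaustive grid search for
the EM argmax, and exact integer hypergeometric enumeration for the
Fisher test.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats


def bf_grid_oracle(k: int, t: int, p0: float, gamma_bar: float, sigma: float,
                   gmax: float = 200.0, step: float = 1e-3) -> float:
    """Trapezoid integration of the Bayes-factor integrand on a dense
    relative-risk grid (0, gmax]."""
    shape = gamma_bar * sigma
    if shape >= 2.0:
        g = np.arange(0.0, gmax + step / 2, step)
        pdf = stats.gamma.pdf(g, a=shape, scale=1.0 / sigma)
        ratio = g**k / (p0 * g + (1.0 - p0)) ** t
        return float(np.trapezoid(ratio * pdf, g))
    # shape in [0.5, 2): the density (or its derivative) is singular at 0,
    # which caps a plain trapezoid at ~1e-4 accuracy; integrate on the
    # v = sqrt(gamma) axis where the transformed integrand
    # 2 v^(2a-1) sigma^a exp(-sigma v^2) ratio(v^2) / Gamma(a)
    # is bounded down to v = 0 (needs 2a - 1 >= 0)
    assert shape >= 0.5, "trapezoid oracle supports shape >= 0.5"
    from scipy.special import gamma as gamma_fn

    v = np.arange(0.0, np.sqrt(gmax) + step / 2, step)
    g = v**2
    ratio = g**k / (p0 * g + (1.0 - p0)) ** t
    with np.errstate(divide="ignore"):
        f = (
            2.0 * sigma**shape / gamma_fn(shape)
            * np.where(v > 0, v ** (2 * shape - 1), 1.0 if shape == 0.5 else 0.0)
            * np.exp(-sigma * g) * ratio
        )
    return float(np.trapezoid(f, v))


def bf_mc_oracle(k: int, t: int, p0: float, gamma_bar: float, sigma: float,
                 n_draws: int = 10_000_000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, standard error) of the Bayes factor:
    average binomial likelihood ratio over Gamma prior draws."""
    rng = np.random.default_rng(seed)
    g = rng.gamma(gamma_bar * sigma, 1.0 / sigma, n_draws)
    vals = g**k / (p0 * g + (1.0 - p0)) ** t
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_draws))


def mixture_grid_argmax(class1_genes, class2_genes, step: float = 1e-3):
    """Exhaustive grid argmax of the mixture marginal log-likelihood.

    ``class1_genes``/``class2_genes`` are lists of per-gene Bayes-factor
    lists, every gene's variants in a single class.  The log-likelihood
    then separates as A(delta, eta1) + B(delta, eta2), so maximising A
    and B over eta at each delta reproduces the argmax of the full
    (delta, eta1, eta2) grid exactly, without materialising the cube.
    """
    grid = np.linspace(0.0, 1.0, int(round(1.0 / step)) + 1)
    d = grid[:, None]

    def block(genes):
        tot = np.zeros((len(grid), len(grid)))
        for bfs in genes:
            lr = np.ones_like(grid)
            for b in bfs:
                lr = lr * ((1.0 - grid) + grid * b)
            tot += np.log((1.0 - d) + d * lr[None, :])
        return tot

    a, b = block(class1_genes), block(class2_genes)
    best_a, arg_a = a.max(axis=1), a.argmax(axis=1)
    best_b, arg_b = b.max(axis=1), b.argmax(axis=1)
    tot = best_a + best_b
    i = int(np.argmax(tot))
    return float(grid[i]), float(grid[arg_a[i]]), float(grid[arg_b[i]]), float(tot[i])


def fisher_enum_oracle(a: int, b: int, c: int, d: int, alternative: str) -> float:
    """Fisher exact p-value by exact integer enumeration of all tables
    with the observed margins (float division happens once, at the end)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if min(r1, c1, n - r1, n - c1) == 0:
        return 1.0
    num = {x: comb(r1, x) * comb(n - r1, c1 - x) for x in range(lo, hi + 1)}
    denom = comb(n, c1)
    if alternative == "greater":
        total = sum(v for x, v in num.items() if x >= a)
    elif alternative == "two-sided":
        total = sum(v for v in num.values() if v <= num[a])
    else:
        raise ValueError(alternative)
    return total / denom
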