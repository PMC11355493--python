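"""Gene-level mixture: gene Bayes factors, EM estimation and the LRT."""

import numpy as np
import pandas as pd
import pytest

from rvbayes.bayes_factor import GroupPrior
from rvbayes.model import RareVariantMixture, gene_bayes_factor
from rvbayes.simulate import SimulationConfig, simulate_dataset
from rvbayes.io import assign_variant_classes, filter_ultra_rare

from oracles import mixture_grid_argmax


class TestGeneBayesFactor:
    def test_zero_eta_is_neutral(self):
        assert gene_bayes_factor([5.0, 0.1, 7.0], ["I", "I", "II"], {"I": 0, "II": 0}) == 1.0

    def test_hand_value(self):
        # (0.5 + 0.5*2) * (0.5 + 0.5*3) = 1.5 * 2.0
        assert gene_bayes_factor([2.0, 3.0], ["I", "I"], {"I": 0.5, "II": 0.0}) == pytest.approx(3.0)

    def test_eta_one_collapses_to_bf(self):
        assert gene_bayes_factor([7.3], ["I"], {"I": 1.0}) == pytest.approx(7.3)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            gene_bayes_factor([1.0], ["X"], {"I": 0.5})


def _fit_toy(gene_bfs, **kw):
    m = RareVariantMixture.from_bayes_factors(gene_bfs)
    return m, m.fit(**kw)


class TestEMFit:
    def test_flat_likelihood_returns_initial_values(self):
        m, res = _fit_toy(
            {"A": [("I", 1.0), ("II", 1.0)], "B": [("I", 1.0)]}, n_restarts=1
        )
        assert res.converged and res.n_iter == 1
        assert res.delta == pytest.approx(0.1)
        assert res.eta["I"] == pytest.approx(0.1)

    def test_ascent_on_every_iteration(self):
        _, res = _fit_toy({"A": [("I", 8.0), ("I", 1.2)], "B": [("I", 0.5)], "C": [("II", 1.1)]})
        assert np.all(np.diff(res.loglik_trace) >= -1e-10)

    @pytest.mark.parametrize(
        "class1, class2",
        [
            # the boundary toy: argmax has eta at 1
            ([[8.0, 1.2], [0.5]], [[1.1]]),
            # interior optimum: mix of strong and null genes
            ([[9.0, 0.2], [0.3], [1.0]], [[4.0], [0.25]]),
            # <= 4 genes, <= 2 variants each, both classes informative
            ([[6.0], [0.4, 1.5]], [[3.0, 0.2], [0.9]]),
        ],
    )
    def test_grid_oracle_equivalence(self, class1, class2):
        """EM argmax matches an exhaustive 1e-3 grid search of the
        marginal log-likelihood within 2e-3 per parameter."""
        gene_bfs = {}
        for i, bfs in enumerate(class1):
            gene_bfs[f"C1_{i}"] = [("I", b) for b in bfs]
        for i, bfs in enumerate(class2):
            gene_bfs[f"C2_{i}"] = [("II", b) for b in bfs]
        d, e1, e2, ll = mixture_grid_argmax(class1, class2)
        m, res = _fit_toy(gene_bfs, tol=1e-13, max_iter=200_000)
        assert res.delta == pytest.approx(d, abs=2e-3)
        assert res.eta["I"] == pytest.approx(e1, abs=2e-3)
        assert res.eta["II"] == pytest.approx(e2, abs=2e-3)
        # and EM's likelihood is no worse than the grid's best
        assert res.llf >= ll - 1e-6

    def test_permutation_invariance(self):
        genes = {
            "A": [("I", 8.0), ("II", 1.3)],
            "B": [("I", 0.5)],
            "C": [("II", 2.1), ("I", 0.9)],
        }
        perm = {"C": list(reversed(genes["C"])), "A": genes["A"], "B": genes["B"]}
        _, r1 = _fit_toy(genes)
        _, r2 = _fit_toy(perm)
        assert r1.delta == pytest.approx(r2.delta, abs=1e-12)
        for c in ("I", "II"):
            assert r1.eta[c] == pytest.approx(r2.eta[c], abs=1e-12)

    def test_stronger_class1_evidence_never_lowers_eta1(self):
        base = {"A": [("I", 3.0)], "B": [("I", 0.8)], "C": [("II", 1.2)]}
        boosted = {"A": [("I", 6.0)], "B": [("I", 1.6)], "C": [("II", 1.2)]}
        _, r1 = _fit_toy(base, tol=1e-12, max_iter=100_000)
        _, r2 = _fit_toy(boosted, tol=1e-12, max_iter=100_000)
        assert r2.eta["I"] >= r1.eta["I"] - 1e-9

    def test_zero_variant_genes_dilute_delta(self):
        genes = {"A": [("I", 50.0)], "B": [("I", 40.0)]}
        m_small = RareVariantMixture.from_bayes_factors(genes)
        universe = ["A", "B"] + [f"N{i}" for i in range(8)]
        m_big = RareVariantMixture.from_bayes_factors(genes, gene_universe=universe)
        r_small = m_small.fit()
        r_big = m_big.fit()
        assert m_big.n_genes == 10
        assert r_big.delta < r_small.delta

    def test_no_variants_rejected(self):
        with pytest.raises(ValueError):
            RareVariantMixture.from_bayes_factors({})

    def test_requires_interior_start(self):
        m = RareVariantMixture.from_bayes_factors({"A": [("I", 2.0)]})
        with pytest.raises(ValueError):
            m.fit(start_delta=0.0)


class TestParameterRecovery:
    def test_single_replicate_recovery(self):
        """One synthetic dataset at the published-scale truth values:
        estimates land within the documented tolerances."""
        cfg = SimulationConfig(
            seed=1, n_genes=2000, delta_true=0.45,
            eta_true={"I": 0.68, "II": 0.08},
        )
        variants, _ = simulate_dataset(cfg)
        df = assign_variant_classes(filter_ultra_rare(variants))
        model = RareVariantMixture(
            df, cfg.sample, gene_universe=[f"G{i:05d}" for i in range(cfg.n_genes)]
        )
        res = model.fit(seed=1)
        assert res.converged
        assert res.delta == pytest.approx(0.45, abs=0.05)
        assert res.eta["I"] == pytest.approx(0.68, abs=0.05)
        assert res.eta["II"] == pytest.approx(0.08, abs=0.06)


class TestPriorSensitivity:
    def test_delta_and_eta2_robust_to_class1_prior_mean(self):
        """Raising the class-I prior mean relative risk from 3 to 4 or 5
        barely moves the risk-gene proportion delta or the class-II
        risk-variant proportion eta2 (the class-I eta absorbs the prior
        shift)."""
        cfg = SimulationConfig(
            seed=31, n_genes=1000, delta_true=0.45, eta_true={"I": 0.68, "II": 0.08}
        )
        variants, _ = simulate_dataset(cfg)
        df = assign_variant_classes(filter_ultra_rare(variants))
        fits = {}
        for gb in (3.0, 4.0, 5.0):
            priors = {
                "I": GroupPrior("I", gb, 1.0),
                "II": GroupPrior("II", 1.0, 1.0),
            }
            fits[gb] = RareVariantMixture(df, cfg.sample, priors).fit(seed=0)
        for gb in (4.0, 5.0):
            assert fits[gb].delta == pytest.approx(fits[3.0].delta, abs=0.05)
            assert fits[gb].eta["II"] == pytest.approx(fits[3.0].eta["II"], abs=0.05)


class TestLRT:
    def test_flat_evidence_gives_half(self):
        """With every Bayes factor at 1 the LRT statistic is 0 and the
        boundary-corrected p-value is exactly 0.5."""
        _, res = _fit_toy({"A": [("I", 1.0)], "B": [("II", 1.0)]}, n_restarts=1)
        lrt = res.lrt_eta("I")
        assert lrt.statistic == pytest.approx(0.0, abs=1e-8)
        assert lrt.pvalue == pytest.approx(0.5)

    def test_unknown_class_rejected(self):
        _, res = _fit_toy({"A": [("I", 2.0)]})
        with pytest.raises(ValueError):
            res.lrt_eta("X")

    def test_power_at_published_signal_strength(self):
        """Strong class-I signal (eta1 = 0.68, gamma_bar = 3, G = 2000)
        is detected at p < 1e-10, as on the real cohort."""
        for seed in (11, 12):
            cfg = SimulationConfig(
                seed=seed, n_genes=2000, delta_true=0.45,
                eta_true={"I": 0.68, "II": 0.08},
            )
            variants, _ = simulate_dataset(cfg)
            df = assign_variant_classes(filter_ultra_rare(variants))
            res = RareVariantMixture(df, cfg.sample).fit(seed=1)
            assert res.lrt_eta("I").pvalue < 1e-10


class TestResultsSurface:
    def test_gene_results_posterior_identity(self):
        _, res = _fit_toy({"A": [("I", 8.0)], "B": [("I", 0.5)], "C": [("II", 1.1)]})
        gr = res.gene_results()
        d = res.delta
        expected = d * gr["bf"] / ((1 - d) + d * gr["bf"])
        assert np.allclose(gr["posterior"], expected)

    def test_summary_mentions_estimates(self):
        _, res = _fit_toy({"A": [("I", 8.0)], "B": [("I", 0.5)], "C": [("II", 1.1)]})
        text = res.summary()
        assert "delta" in text and "eta[I]" in text and "FDR" in text
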