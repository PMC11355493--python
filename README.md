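# rvbayes

Bayesian mixture-model rare-variant gene association from case–control
allele counts.

Burden tests collapse all rare variants in a gene into one score, which
works only when most collapsed variants are causal.  In disorders such
as schizophrenia the signal is sparse: a risk gene may carry one or two
large-effect ultra-rare variants among many neutral ones.  `rvbayes`
implements a two-level Bayesian mixture model for exactly this regime.
It needs only, per variant, the minor-allele counts in cases and in
controls — no individual-level genotypes — which makes it applicable to
meta-analytic count releases such as the SCHEMA schizophrenia exome
data (24,248 cases, 97,322 controls).

## Model

For a variant with cohort minor-allele count *T*, the count in cases is
Binomial(*T*, *p₀*) under the null, with *p₀ = n_case / (n_case +
n_control)*.  A risk variant with relative risk γ tilts the case share
to γ*p₀* / (γ*p₀* + 1 − *p₀*), and γ is given a Gamma prior with mean
γ̄ per variant class (class I: protein-truncating variants and missense
with MPC ≥ 3, default γ̄ = 3; class II: missense with MPC 2–3, default
γ̄ = 1).  Integrating over the prior gives a per-variant Bayes factor
BF<sub>ij</sub>.

Each gene *i* is a risk gene with probability δ; within a risk gene a
class-*c* variant is a risk variant with probability η<sub>c</sub>.
The gene-level Bayes factor is

&nbsp;&nbsp;LR<sub>i</sub> = ∏<sub>j</sub> [(1 − η<sub>c(j)</sub>) + η<sub>c(j)</sub> · BF<sub>ij</sub>]

and (δ, η₁, η₂) are estimated by EM on the marginal likelihood
∑<sub>i</sub> log[(1 − δ) + δ·LR<sub>i</sub>].  Genes are ranked by the
posterior risk probability δ·LR<sub>i</sub> / ((1 − δ) + δ·LR<sub>i</sub>)
and nominated where the cumulative mean of (1 − posterior) — the
Bayesian FDR — stays below the chosen level (default 5%).  Each
η<sub>c</sub> is tested against 0 with a likelihood-ratio test using
the boundary-corrected ½χ²₁ null.  Overlap of the nominated list with
reference gene sets is quantified by Fisher exact tests and
hypergeometric fold-change term enrichment.

## Worked example

```python
import rvbayes as rv
from rvbayes.simulate import SimulationConfig, simulate_dataset

# synthetic SCHEMA-like cohort with known truth
cfg = SimulationConfig(seed=7, n_genes=2000, delta_true=0.45,
                       eta_true={"I": 0.68, "II": 0.08})
variants, truth = simulate_dataset(cfg)

df = rv.assign_variant_classes(rv.filter_ultra_rare(variants))
model = rv.RareVariantMixture(df, cfg.sample)
res = model.fit(seed=1)
print(res.summary())
```

```
Rare-variant mixture model (EM fit)
=======================================================
Genes in universe:      2000
Variants:               20079
Log-likelihood (rel.):  546.4771
Converged:              True (356 iterations)
-------------------------------------------------------
delta (risk-gene prop.): 0.4581
eta[I] (risk-variant prop., gamma_bar=3): 0.6757   LRT p = 9.53e-240
eta[II] (risk-variant prop., gamma_bar=1): 0.0915   LRT p = 0.145
-------------------------------------------------------
Genes at Bayesian FDR < 0.05: 187
```

The fit recovers the generating truth: about 46% of genes are estimated
to be risk genes (truth 45%), two thirds of class-I variants in risk
genes are risk variants (truth 68%) with overwhelming LRT evidence,
while the class-II proportion is small and not significant — the same
qualitative picture the method produces on the real schizophrenia
cohort.  Of the 187 genes nominated at Bayesian FDR < 5%, the realised
false-discovery proportion against the simulation truth is 0.032.

The same pipeline is scriptable from the shell:

```bash
rvb simulate --seed 7 --n-genes 2000 --out-variants v.tsv --out-truth t.tsv
rvb fit --variants v.tsv --n-case 24248 --n-control 97322 --fdr-level 0.05
rvb run --config run.yaml        # full chain with manifest + provenance
```

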