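# cladediv

Clade-level diversification analysis for comparative biologists: does a
trait (canonically, the proportion of herbivorous species in an insect
clade) predict how fast clades diversify?

The package implements the standard age-and-richness workflow end to end:

* **Net diversification rates** by the method-of-moments estimator for stem
  ages. For a clade with *n* described species and stem age *t* (Myr),
  under a relative extinction fraction ε = μ/λ,

  r̂ = ln(*n*(1 − ε) + ε) / *t*    (lineages/Myr, natural log)

  conventionally evaluated at ε ∈ {0, 0.5, 0.9}.
* **PGLS regression** of rates (or log richness) on clade traits, with the
  error covariance taken from the time-calibrated tree (Brownian motion)
  and phylogenetic signal estimated as Pagel's λ by maximum likelihood over
  [0, 1] (κ and δ fixed at 1). Reported per model: coefficients with SEs
  and t-tests, λ̂, r², the model F-test P, and AIC for model ranking.
* **Sister-clade comparisons**: non-overlapping, least-inclusive sister
  pairs in which herbivory is present (any proportion) in exactly one
  member; because sister clades share a stem age, a richness difference
  implies a rate difference. Pairs are aggregated by an exact one-tailed
  binomial sign test, P = Σᵢ₌ₖⁿ C(n, i)/2ⁿ.
* **A synthetic-data generator** (Yule order-level trees; rates
  rᵢ = a + b·hᵢ plus λ-scaled Brownian noise; richness drawn from the
  survival-conditioned birth–death clade-size law) so every stage can be
  validated against known ground truth.

Trees are read from Newick or NEXUS (TRANSLATE tables supported) via
dendropy; trait tables are plain TSV/CSV.

## Worked example

Simulate a 31-clade dataset with a true herbivory effect
(b = 0.05 lineages/Myr per unit proportion) and run the full battery:

```sh
cladediv simulate --out demo --seed 42
cladediv run --tree sim=demo/tree.nwk --traits demo/traits.tsv \
    --epsilon 0,0.5,0.9 --outdir demo_out --sisters
```

`demo_out/pgls_models.tsv` at ε = 0.9 contains:

```
                                     formula  n  lambda_hat  r_squared  model_P       aic
                       rate ~ herbivory_prop 31         0.0     0.6674   0.0000 -179.1633
                                rate ~ wings 31         0.0     0.0006   0.8958 -145.0591
                         rate ~ holometaboly 31         0.0     0.0012   0.8536 -145.0775
               rate ~ herbivory_prop + wings 31         0.0     0.6838   0.0000 -178.7295
rate ~ herbivory_prop + wings + holometaboly 31         0.0     0.6843   0.0000 -176.7807
```

The herbivory-only model explains 67% of rate variation and carries
essentially all of the AIC weight, while the two binary traits — simulated
with no effect — explain under 1%: the analysis recovers exactly the
structure that was generated. λ̂ = 0 here because rate-estimation noise
(independent across clades) dominates the weak phylogenetic signal of the
simulated rate deviations.

Sister-clade comparison on the same data (clades with more than half their
species herbivorous versus herbivory-poor sisters):

```sh
$ cladediv sisters --tree demo/tree.nwk --traits demo/traits.tsv \
      --threshold 0.5 --out demo_sisters.tsv
pooled: n=8 k=8 ties=0 one-tailed P=0.00390625
```

All eight informative sister pairs are richer on the herbivorous side
(P = 1/2⁸), the qualitative signature of a positive trait effect,
without estimating any rates.

As a library, the same analysis is three calls:

```python
import cladediv as cd

ds = cd.simulate_dataset(cd.SimConfig(seed=42))
cfg = cd.AnalysisConfig(trees={"sim": ds.tree}, traits=ds.table)
models, coefs = cd.run_order_analysis(cfg)
```

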