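# invasion-abc

Inference of invasion routes from multi-locus microsatellite genotypes by
approximate Bayesian computation (ABC), with model choice by random forest
(ABC-RF) and by rejection + discriminant-regression (ABC-LDA).

Reconstructing how an invasive species spread — which native or invasive
population seeded which introduction, whether founders passed through a
demographic bottleneck, and whether genetically distinct sources admixed —
is a model-choice problem: each candidate route is a demographic scenario,
and the genetic data decide between them. The likelihood of such scenarios
is intractable, so inference is simulation-based. This package provides the
whole pipeline for population geneticists working with co-dominant
microsatellite data: GenePop I/O, scenario declaration and enumeration,
a coalescent simulator with a generalized stepwise mutation model,
the one-/two-/three-population summary-statistic catalog, reference-table
construction, both model-choice engines, ABC parameter estimation, and
posterior-predictive model checking. A synthetic-data module generates toy
invasion histories with known truth so every stage is testable end to end.

## The method

For a focal (target) population and k candidate sources, the competing set
contains the k single-source scenarios and the C(k,2) pairwise-admixture
scenarios. Backward in time, an introduction is a divergence without
subsequent gene flow at the first-record date (converted at 12
generations/year), preceded by a founding bottleneck of d_b generations at
effective size N_b; **bottleneck severity** is d_b/N_b. Admixture is a
backward probabilistic merge: each lineage joins source 1 with probability
r and source 2 with probability 1 − r.

A *reference table* is built by drawing parameters θ from priors,
simulating microsatellite data under each scenario (structured coalescent +
generalized stepwise mutations in a bounded allele window), and reducing
each dataset to summary statistics **s** (4 per population, 8 per pair, 3
per triplet; 4P + 8·C(P,2) + 3·C(P,3) in total). Then:

- **ABC-RF** trains a 500-tree classification forest on (**s**, LDA axes) →
  scenario. The observed data's *classification votes* select the scenario;
  the out-of-bag misclassification fraction is the *prior error rate*; a
  secondary regression forest on the error indicator gives the posterior
  probability of the winner.
- **ABC-LDA** keeps the 1% of simulations closest to the observed **s** and
  fits a polychotomous logistic regression of the scenario label on the
  discriminant axes, evaluated at the observed point.
- **Parameter estimation** keeps the closest 0.1% of the winning scenario's
  rows, logit-transforms each parameter to its prior range, and adjusts by
  weighted local linear regression; severity d_b/N_b is summarized from the
  adjusted draws and classified weak (< 0.12) / moderate (0.12–0.22) /
  strong (> 0.3).
- **Model-posterior checking** simulates from the fitted scenario-posterior
  combination and computes tail-area posterior predictive p-values
  (ppp = min(p, 1−p), p = Prob(q_sim < q_obs)) for the held-out statistics
  not used in estimation, with Benjamini–Hochberg FDR control and a
  principal-component projection of simulations around the observed point.

Details, assumptions and numerical choices are in `docs/methods.md`.

## Worked example

```python
import invasion_abc as ia

world = ia.make_toy_invasion("small", rng_seed=1)
print("competing scenarios:", [sc.name for sc in world.competing])

report = ia.end_to_end_smoke(world, budget=600, rng_seed=2,
                             n_trees=300, n_ppc=200)
print("votes:", report["votes"])
print("best scenario:", report["best_scenario"], "(truth:", world.scenario.name + ")")
print(f"posterior probability: {report['posterior_probability']:.3f}")
print(f"prior error rate: {report['prior_error_rate']:.3f}")
r = report["posterior_summaries"]["r_inv1"]
print(f"admixture rate r_inv1: median {r['median']:.3f} "
      f"[q5% {r['q05']:.3f}, q95% {r['q95']:.3f}]  (truth 0.5)")
for pop, s in report["severity"].items():
    print(f"bottleneck severity {pop}: median {s['median']:.3f} -> {s['class']}")
print("test statistics with ppp < 0.05:", report["ppc_n_below_005"],
      "| flagged after FDR:", report["ppc_n_flagged_fdr"])
```

Output (a few minutes on one CPU):

```
competing scenarios: ['inv1<-nat1', 'inv1<-nat2', 'inv1<-nat1+nat2']
votes: {'inv1<-nat1': 13, 'inv1<-nat2': 35, 'inv1<-nat1+nat2': 252}
best scenario: inv1<-nat1+nat2 (truth: inv1<-nat1+nat2)
posterior probability: 0.853
prior error rate: 0.210
admixture rate r_inv1: median 0.425 [q5% 0.236, q95% 0.623]  (truth 0.5)
bottleneck severity inv1: median 0.407 -> strong
bottleneck severity inv2: median 0.034 -> weak
test statistics with ppp < 0.05: 2 | flagged after FDR: 0
```

Reading it: the toy world's true history — the first invasive population is
a balanced admixture of the two natives — wins 252 of 300 classification
votes against both single-source alternatives, with posterior probability
0.85 and a prior error rate of 0.21 on a 600-row-per-scenario table. The
admixture-rate posterior brackets the true 0.5; the strong founding
bottleneck (true severity 0.5) and the weak one (0.005) land in the right
severity classes; and the posterior-predictive check finds nothing to flag
after FDR control, as it should when the fitted model is the generating
one.

The same stages are scriptable from the shell:

```bash
invasion-abc toydata --profile small --seed 1 --out toy/
invasion-abc scenarios --sources Asia,Hawaii --target US-Wat
invasion-abc sumstats --in toy/observed.gen --set full --out stats.csv
invasion-abc reftable --truth toy/truth.yaml --n 600 --seed 2 --out rt/
invasion-abc choose-rf --table rt/ --observed stats.csv --trees 300 \
    --seed 2 --out choice.json
```

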