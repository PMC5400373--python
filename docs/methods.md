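# Methods

`invasion-abc` reconstructs invasion routes from multi-locus microsatellite
genotypes by simulation-based (likelihood-free) inference: competing
demographic scenarios are simulated under parameter values drawn from
priors, each simulated dataset is reduced to a vector of summary
statistics, and scenario choice / parameter estimation / model checking are
carried out by comparing the observed statistic vector to the simulated
ones. This note documents the model, the estimators, the numerical choices,
and what the synthetic test worlds do and do not establish.

## Demographic model

Scenarios are ordered event lists read backward from sampling (time 0, in
generations). Four event types are supported:

- `SAMPLE(pop, n, t=0)` — n diploids sampled at present;
- `DIVERGE(derived → source, t)` — an introduction is modeled as a
  divergence without subsequent gene flow: all lineages of the derived
  population move into its source at t;
- `ADMIX(derived → source1/source2, r, t)` — backward probabilistic merge:
  each lineage of the admixed population independently joins source1 with
  probability r and source2 with probability 1 − r;
- `SIZE_CHANGE(pop, Ne, t)` — the population's diploid effective size
  switches to Ne from t backward.

A founding bottleneck is the motif `SIZE_CHANGE(target, Nb, t_intro − db)`
followed (backward) by the divergence/admixture at `t_intro`: the founded
population sits at the reduced size Nb for db generations immediately after
its foundation, then returns to a stable (large) size. If a drawn db
exceeds t_intro, the size change is clamped to time 0 — the population is
still inside its bottleneck phase when sampled, which is the only coherent
forward-time reading. **Bottleneck severity** is the ratio db/Nb
(generations per effective diploid); larger values mean stronger founding
drift. Introduction times are not free parameters: the date of first record
in the invaded area is converted to generations at a configurable rate
(default 12 generations/year) and fixed. Unsampled "ghost" populations may
be declared to absorb source uncertainty inside a structured native range;
their split times are free prior parameters.

For one target population and k candidate sources, the competing set is
enumerated as the k single-source scenarios plus the C(k, 2) pairwise
admixture scenarios — k + k(k−1)/2 models (3, 6, 10, 21 for k = 2, 3, 4, 6)
— each carrying a founding bottleneck on the target. Sources are tied
together by nested divergences into a common ancestor whose time prior is
bounded below by the latest calendar-fixed introduction, so every scenario
has a single ancestral population.

## Coalescent simulator

Genealogies are simulated per locus under the continuous-time structured
coalescent: within a population with k active lineages and size Ne, the
waiting time to the next coalescence is exponential with rate
k(k−1)/2 · 1/(2Ne) per generation. Populations evolve independently between
scheduled events, so the implementation batch-draws each population's
embedded coalescence chain per inter-event epoch (the chain is truncated at
the epoch end; the construction is exact, not an approximation). The
continuous-time approximation is appropriate for the large effective sizes
used here; a generation-by-generation Wright–Fisher simulation would change
nothing detectable at these sizes. Unlinked loci are independent given the
demography.

The test suite validates the simulator against independent oracles: the
mean pairwise coalescence time 2N; the expectation 4N(1 − 1/n) for larger
samples; and a cross-check of a two-population divergence scenario against
msprime's implementation of the same model (note that msprime requires an
explicit ancestral deme — a sampled population reused as a split ancestor
is inactive before the split).

## Mutation model

Microsatellites mutate under a generalized stepwise model (GSM). Mutations
are placed on branches as Poisson counts (rate × branch length); each
mutation moves the repeat count by ±k where k is geometric,
P(k) = (1 − P) Pᵏ⁻¹ with P = `p_geom` (P = 0 is the strict stepwise model),
sign equiprobable. Alleles live in a contiguous window of allowed repeat
counts with reflecting boundaries (default 40 states, [10, 49]); the root
allele is the window midpoint — arbitrary but range-safe, and stated so
tests can rely on it. Per-locus rates are drawn from a Gamma distribution
with mean μ and shape 2 (rate heterogeneity across loci); both μ and
`p_geom` can be prior parameters, so mutation-model uncertainty propagates
into the reference table. Defaults (μ = 5·10⁻⁴ per locus per generation,
p_geom = 0.22, 40-state window, Gamma shape 2) are editable configuration,
not claims: they are in the range conventional for drosophilid
microsatellite work. Single-nucleotide insertions are not modeled; alleles
are repeat counts throughout (GenePop 3-digit encoding on disk, 0 = missing).

The strict-stepwise equilibrium gene diversity 1 − 1/√(1 + 8Nμ)
(Ohta–Kimura) is used as a closed-form oracle in the tests, with a wide
window so boundary reflection is negligible there.

## Summary statistics

The catalog (computed per locus and averaged over usable loci) is:

- per population (4): mean number of alleles; mean unbiased gene diversity
  ñ/(ñ−1)(1 − Σp²) with ñ non-missing gene copies; mean allele-size
  variance; mean Garza–Williamson M = (number of alleles)/(allele-size
  range + 1);
- per unordered pair (8): the three pooled-sample analogues; the
  Weir–Cockerham (1984) multi-locus ratio estimator of FST (Σa / Σ(a+b+c)
  over alleles and loci, raw value retained — clamping to ≥0 is for
  reports); both directions of an assignment log-likelihood (mean over the
  individuals of one sample of their genotype log-likelihood under the
  other sample's allele frequencies, add-one smoothing over the locus's
  allele support so private alleles never hit log 0); the shared-allele
  distance DAS = 1 − mean proportion of alleles shared between
  across-population individual pairs; and (δμ)², the squared difference in
  mean allele size;
- per unordered triplet (3 arrangements, one per choice of admixed
  target): an admixture coefficient computed per locus by least squares —
  projecting the admixed population's allele frequencies onto the segment
  between the source frequencies, r̂ = Σ(f₁−f₂)(f_adm−f₂) / Σ(f₁−f₂)²,
  clipped to [0, 1] and averaged over informative loci. Indistinguishable
  sources yield 0.5 with a flag.

This 4 / 8 / 3 decomposition gives 4P + 8·C(P,2) + 3·C(P,3) statistics for
P populations — 39, 130, 204, 301, 424 for P = 3, 5, 6, 7, 8 — and is
validated by those totals. The assignment-likelihood and admixture
statistics are documented stand-ins reconstructed from their counting
behaviour and standard definitions; they are validated by the counting
rules, permutation invariance, and estimator-consistency properties, not
against any external implementation.

The reduced "expert" estimation set is: allele count and gene diversity per
population, all pairwise FST, and one admixture coefficient per declared
triplet — 2P + C(P,2) + T statistics (95 for P = 12, T = 5). Declared
triplets are canonicalized so the two sources follow population order
(swapping sources complements the coefficient; as a regression covariate
the orientation is conventional). Missing alleles are excluded locus-wise;
an individual missing either allele at a locus is excluded at that locus;
loci unusable in any member of a pair/triplet are dropped from that
statistic's average.

## Reference tables

A reference table holds, per row, the scenario index, the drawn parameter
vector and the statistic vector. Rows are seeded individually from
(root seed, scenario index, row index, retry counter), making tables
bit-reproducible and independent of the worker count. Rows with non-finite
statistics (e.g., FST undefined under zero polymorphism) are resimulated
with the next retry seed and logged. Storage is parquet plus a JSON
metadata sidecar with a format version; loading verifies the version and
the row count, and CSV export is provided.

## Model choice

**ABC-RF.** Linear-discriminant axes fitted on the table (min(K−1, d)
columns) are appended to the statistics; a 500-tree classification forest
(scikit-learn, default features-per-split and depth, recorded in the
result) is trained to predict the scenario index. The observed vector's
votes are the per-tree predictions; the winner is the vote argmax, ties
broken toward the lowest scenario index with a logged warning. The prior
error rate is the forest's out-of-bag (OOB) misclassification fraction —
the probability of choosing a wrong scenario when scenario and parameters
are drawn from their priors. (A held-out variant is also provided; OOB is
the default as standard forest practice.) The posterior probability of the
winner is 1 minus the prediction of a secondary regression forest fitted to
the OOB misclassification indicator, evaluated at the observed point and
clipped to [0, 1]; its leaves are smoothed (min 5 samples) because at
desk-scale table sizes a fully grown regression forest is dominated by
local noise. Replicate runs retrain on the same table with fresh forest
seeds and report mean ± sd.

**ABC-LDA.** Statistics are standardized by their table-wide median
absolute deviation (falling back to the standard deviation for degenerate
columns; the rejection metric's scaling is a design choice). The closest
fraction of rows under Euclidean distance (default 1%) is kept, and a
multinomial logistic regression of the scenario label on the discriminant
axes over the accepted rows gives the scenario probabilities at the
observed point. Scenarios absent from the accepted set get probability 0
with a warning; the logistic fit carries a mild ridge so complete
separation cannot blow up. The optional confidence interval for the best
probability uses the regression's asymptotic Fisher-information covariance
and the delta method, and is labeled approximate. The prior error rate
holds out pseudo-observed rows from the table and counts how often the
highest-probability scenario differs from the generating one (default 500
draws at full scale).

## Parameter estimation

Under the selected scenario, the nearest fraction of that scenario's rows
(default 0.1% at full scale; desk-scale runs use larger fractions so the
local regression stays overdetermined) is kept under the same MAD-scaled
distance, with Epanechnikov weights 1 − (d/d_max)². Each parameter is
mapped by logit((θ − lo)/(hi − lo)) to its prior range — which guarantees
adjusted draws respect the bounds after back-transformation — regressed
linearly on (simulated − observed) statistics by weighted least squares,
and intercept-adjusted. A rank-deficient design falls back to the
rejection-only posterior with a warning. Summaries are the weighted mean,
midpoint-convention weighted quantiles (median, q5%, q95%), and a mode from
a Gaussian kernel density (Silverman bandwidth) on the adjusted draws.
Bottleneck severity is summarized as the ratio of the adjusted (db, Nb)
draws — a derived quantity, not a sampled parameter — and classified as
weak (< 0.12), moderate (0.12–0.22) or strong (> 0.3); medians in the
uncovered band [0.22, 0.3] or on a boundary are reported as unclassified
with a warning rather than silently assigned.

## Posterior-predictive checking

Datasets are simulated from the chosen scenario with parameter vectors
resampled (with replacement, posterior weights) from the posterior draws.
For each test statistic q, p = Prob(q_sim < q_obs) over the simulations
(ties count one half, since many catalog statistics are discrete), and the
posterior predictive p-value is the tail area ppp = min(p, 1 − p) ∈ [0, 0.5].
Test statistics must be disjoint from the estimation set — checking a model
with the statistics that fitted it is circular, so overlap is an error, not
a warning. The Monte-Carlo resolution 1/(n_ppc + 1) is reported, and the
two-sided equivalents 2·ppp (floored at the resolution) enter a
Benjamini–Hochberg step-up FDR adjustment at level 0.05 (configurable).
Under the true model the folded rule flags ppp < α with probability 2α, the
calibration the tests check. A principal-component projection (constant
columns dropped, columns standardized, components fitted on the simulated
vectors only) maps the observed point through the same transform and
reports a depth rank — the fraction of simulations with smaller
variance-scaled squared distance from the center; a well-specified model
leaves the observed point inside the cloud, a grossly misspecified one
(e.g., a 10× mutation rate) pushes it to rank ≈ 1.

## Synthetic test worlds

The synthetic module generates complete toy studies: a true scenario and
parameter vector, an "observed" dataset, the declared first-record dates,
and the enumerated competing set containing the truth. The `small` profile
(4 populations — a native pair plus two invasive, 10 loci, 20 diploids per
sample) emulates the structure of a multi-site invasion study: a native
pair diverged 4,000 generations ago (Ne 4,000), an invasive population
founded 120 generations ago as a balanced admixture (r = 0.5) of the two
natives through a strong bottleneck (severity 0.5), and a serial
colonization 48 generations ago through a weak bottleneck (severity 0.005).
The balanced admixture and the 100-fold severity contrast are deliberate:
toy effect sizes are chosen large enough that recovery is statistically
comfortable at desk-scale table sizes, and they all live in one file so
tests are auditable. The `paper-like` profile (8 populations, 25 loci,
samples of 15–44 diploids) adds the remaining motifs — an admixture between
a native source and an earlier invasive population, independent continental
introductions, a serial intra-continental colonization — at realistic
sample-size heterogeneity.

What passing these tests shows: the machinery is internally consistent,
seeded-reproducible, calibrated under the true model, and able to recover
well-separated truths at reduced scale. What it does not show: performance
on real data, whose allele-frequency spectra, null alleles, genotyping
error and weak effect sizes the toy worlds make no attempt to emulate.

## Desk-scale problem sizes

Full-scale analyses of this kind use 10⁴ simulated datasets per scenario
for forest-based choice (10⁵ total when more than ten scenarios compete),
5·10⁵ per scenario for rejection-based choice, 500 trees, the closest 1%
for the regression step and the closest 0.1% of 10⁷ rows for estimation.
The package defaults mirror those values where a single number is needed,
and every size is configurable. The test suite and the property checks run
the same code at reduced sizes — hundreds to a couple of thousand rows per
scenario, 10–25 loci, 15–30 diploids per sample, 150–500 trees — chosen as
the smallest sizes at which the checked properties (chance-level behaviour
on identical scenarios, near-zero error on separable ones, the
forest-vs-regression ordering on equally small tables, admixture-rate and
severity-ordering recovery, tail-area calibration) hold with comfortable
Monte-Carlo margins.

## Known limitations

- No continuous migration, overlapping generations, selection, linkage, or
  sequence-level mutation; loci are exchangeable given the demography.
- The assignment-likelihood and admixture statistics are reconstructed
  stand-ins (see above), adequate as covariates but not reference
  implementations of any published estimator.
- Null-allele frequencies are consumed, never estimated; only the
  exclusion rule (drop a locus whose frequency exceeds 10% in any
  population sample, strict inequality) is implemented.
- The prior sets are editable defaults: "set1" rectangular, "set2"
  mid-range truncated normals. They encode ranges, not empirical claims.
- The LDA-regression confidence interval ignores the rejection step's
  sampling variability and is labeled approximate.
- The secondary-forest posterior probability is noisy for small tables even
  with leaf smoothing; replicate spread is reported so users can see it.
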