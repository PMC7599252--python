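# Methods

## Network proximity

Distances are unweighted hop counts on the undirected PPI graph; edge
confidence scores are used only to threshold edges (kept when strictly
greater than `min_score`, default 700) and never as weights or
distances. Analysis runs on the largest connected component, so every
closest-distance query is well defined; a size tie between components
is broken by the lexicographically smallest member node.

The closest-distance statistic d_c(T, S) averages, over drug targets
t ∈ T, the distance to the nearest pathway gene. It is deliberately
asymmetric (averaging over targets only): the question is whether the
*drug's* targets sit near the pathway, not the reverse. A target inside
the pathway contributes 0.

**Degree-matched null.** Nodes are sorted by degree and grouped into
contiguous-degree bins holding at least `min_bin_size` nodes (greedy
merge of adjacent degree values; a final undersized bin merges into its
predecessor). The floor defaults to min(100, max(3, n/10)): 100 on
real-scale interactomes, lowered automatically on small synthetic
graphs, which would otherwise be unbinnable. Each null iteration
replaces every gene of T and of S with a node drawn uniformly from the
gene's bin, without replacement within a set, T and S independently of
each other — matching the published proximity randomization. Null sets
may therefore overlap by chance, exactly as arbitrary gene sets do.
With the null mean μ and population sd σ over `n_iter` draws (default
1000), z = (d_c − μ)/σ; if σ = 0 (e.g. all relevant bins are
singletons) z is defined as 0 and the pathway is not proximal, since
such configurations carry no proximity information. The proximity
cutoff is the lower-tail normal quantile Φ⁻¹(α) rather than a
hard-coded constant, so α is configurable; α = 0.10 reproduces −1.2816.
An exact-empirical-quantile mode was considered and rejected as the
default because the normal approximation is the convention this
statistic is reported with.

On graphs up to 4000 nodes an all-pairs distance matrix is cached
(scipy.sparse.csgraph) and the null is fully vectorized; larger graphs
fall back to per-draw multi-source BFS.

## Pathway activity (ssGSEA)

Per sample, genes are ordered by expression descending (ties broken by
descending gene label, making results reproducible); rank magnitudes
n..1 raised to the weight exponent (default 0.25, the ssGSEA
convention) form the in-set cumulative distribution, the out-of-set
cumulative distribution is uniform, and the enrichment score is the
summed difference down the list. NES divides every ES by the single
max−min ES range of the call (the common implementation's behavior); a
per-sample normalization mode exists behind a flag. Because only ranks
enter, the score is invariant to any strictly monotone per-sample
transform; the optional log2(x+1) step therefore matters only for
interpretability of stored matrices.

Standardization is per feature across samples with the population (1/n)
sd; constant rows are dropped with a warning. Organoid, patient and
isogenic matrices are standardized separately — within-dataset
z-scoring is the framework's batch-effect handling, and the patient
median split is invariant to it.

## Regression and ranking

Ridge is the default model. The penalty is selected by 3-fold
cross-validated mean squared error over α ∈ {0.1, …, 1.0} (folds
shuffled under the caller's seed), then refit on all samples with an
intercept. The ridge solve itself uses the centered closed form
(XᵀX + αI)⁻¹Xᵀy — verified against scikit-learn's `Ridge` in the test
suite — because resampling loops (bootstrap, leave-k-out) perform tens
of thousands of fits. OLS (`linear`) and linear-kernel SVR at C = 1
(`svr_linear`) are available; an OLS request on a singular design is an
error advising ridge. Features are ranked by |β|, ties broken
lexicographically.

IC50 enters untransformed by default; a `log10_ic50` option covers
responses spanning orders of magnitude (the synthetic generator's IC50
is log-normal, so the out-of-sample R² reported by the acceptance
script uses it). The 60/10/30 split evaluation floors the train and
validation sizes and gives the remainder to test (n=20 → 12/2/6), tunes
α by validation RMSE, and reports test R² as the squared Pearson
correlation of observed and predicted response.

The correlation-based gene-selection baseline holds out half the
organoids in each of 10 iterations and selects genes whose mean
Spearman p across iterations is below 0.05. "Mean p < cut" is one
reading of "significant average correlation"; it is conservative on
8-sample halves (the planted-driver selection rate is ~0.82 under the
test fixture), which the tests account for.

## Patient scoring and survival

Score_patient = Σ over the top-N ranked pathways of standardized
activity × β (N = 1 by default). Higher score predicts resistance
because β maps activity to IC50. The median split assigns scores ≤
median to responders (ties at the median go to the predicted-sensitive
side; no patient is dropped); an all-equal score vector is an error
rather than an arbitrary split.

The log-rank test is computed as a vectorized life table
(hypergeometric variance, events before censorings at tied times,
χ²(1)); it is cross-checked against lifelines to 1e-8 on random
censored data in the suite, and Kaplan–Meier curves come from
lifelines directly. Mann–Whitney concordance uses the exact
distribution for combined n ≤ 20 without ties and the tie-corrected
normal approximation otherwise; the alternative direction is
configurable ("greater" for resistance mutations, "less" for
sensitizing ones). Isogenic contrasts are pooled-variance two-sample
two-tailed t-tests on the pathway's activity, reporting which group is
higher so direction can be checked against sign(β).

The bootstrap draws k random pathways (k = the proximal count) per
iteration, retrains, and walks the coefficient ranking for the first
pathway that both separates treated-patient survival (log-rank p <
0.05 on its single-feature median split) and passes the
direction-consistent isogenic contrast; "equal-or-better rank" means
numerically ≤ the observed rank, and iterations with no qualifying
pathway are "absent", never successes. An absent observed rank yields
empirical p = 1; a zero count is reported alongside the "< 1/n_iter"
convention. The survival-only criterion is available behind a flag.

## Synthetic scenarios

Expression follows a latent-factor model: each pathway has a standard
normal activity per sample, and a gene's expression sums the factors of
its pathways plus N(0, noise_sd²) noise (noise_sd = 0.5 by default).
This gives rank-based ssGSEA a realistic but imperfect view of the
latent activity (NES–latent correlation ≈ 0.95 at default sizes). The
generator does not attempt platform noise spectra, batch structure or
count models; what passing tests show is that the chain of estimators
recovers planted structure under this idealized signal model, not that
it would survive microarray/RNA-seq artifacts.

Scenario defaults: a 1000-node preferential-attachment network (m = 3;
an Erdős–Rényi mode exists), 50 pathways of 8–25 genes, 4 drug targets,
the planted pathway's genes within 1 hop of the targets (every target
covered, so d_c ≤ 1 by construction), 20 organoids, activity–IC50
correlation −0.9 (IC50 = exp of a correlated Gaussian, so the rank
correlation carries to the raw scale), 114 treated / 298 untreated
patients, hazard ratio 3 between resistance halves under treatment
only (exponential survival, baseline hazard 1/365 per day), 30%
censoring, and 3 sensitive vs 9 resistant isogenic lines with a 2-sd
shift of the planted pathway's genes. Censored patients are observed
for a uniform fraction of their event time, which realizes the
censoring fraction exactly. Isogenic lines share a common genetic
origin, so their pathway baselines are drawn once and shared across
lines — line-to-line variation is gene-level noise plus the resistance
shift; this is what makes a 3-vs-9 t-test at a 2-sd shift nearly always
significant at the pathway level. The mutation marker is Bernoulli with
a logistic link to the resistance latent.

All generators, the null sampler, fold assignment and the bootstrap are
driven by numpy Generators seeded from a single integer (per-stage
seeds derived by FNV-style hashing of the stage name, kept below 2³¹),
and are bit-reproducible.

## Problem sizes in the checks

The test suite and acceptance script run at desk scale, chosen as
representative rather than exhaustive: 100 scenario seeds for the
planted-recovery rate, 1000 draws for the self-null z moments and the
log-rank type-I simulation, 200 seeds for survival specificity, a
300+120-draw self-null bootstrap (PIT uniformity with a 0.15
discreteness allowance), and 5 scenario replicates (medians reported)
with a 200-iteration bootstrap in the acceptance script. The
10,000-iteration bootstrap of a full-scale analysis is supported by the
same code path via `n_iter`.

## Known limitations

- Pathway activities are treated as independent features; overlapping
  pathways share genes and therefore activity, which ridge shrinks but
  does not model.
- The bootstrap's patient-survival criterion reuses the same treated
  cohort in every iteration, so empirical p-values are conditional on
  that cohort.
- No Cox modeling, covariate adjustment, or competing risks; overall
  survival with a binary median split only.
- Gene identifiers are opaque strings; mapping between platforms is the
  caller's responsibility.
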