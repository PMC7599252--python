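# netbiomark

Network-proximity biomarker discovery from organoid pharmacogenomic
screens, and prediction of patient drug response from the discovered
biomarkers.

## The problem

Patient-derived organoid screens measure drug sensitivity (IC50) with
matched transcriptomes, but translating those screens into clinical
biomarkers is hard: whole-transcriptome models overfit tiny organoid
cohorts, and drug-target expression alone rarely predicts response.
`netbiomark` implements a network-assisted strategy: restrict the
feature space to biological pathways that are *topologically close to
the drug's targets* in a protein–protein interaction (PPI) network,
train a regularized regression of organoid IC50 on the activity of
those pathways, and carry the resulting coefficients into patient
cohorts as a per-patient drug-resistance score.

## The method

**Proximity filter.** For a drug with target set *T* and a pathway with
gene set *S*, the closest distance on the PPI network (edges kept at
STRING confidence score > 700, largest connected component) is

    d_c(T, S) = (1/|T|) Σ_{t∈T} min_{s∈S} d(t, s)

with *d* the unweighted shortest-path length. Significance comes from a
degree-preserving null: both *T* and *S* are replaced by random gene
sets drawn from degree bins (1000 iterations), and z = (d_c − μ)/σ
against that reference. A pathway is *proximal* when z ≤ Φ⁻¹(0.10) =
−1.2816.

**Pathway activity.** Gene expression is converted to per-sample
pathway activity by single-sample GSEA (rank-weighted running sum,
weight 0.25; NES = ES normalized by the global ES range) and z-scored
per pathway within each dataset.

**Biomarker ranking.** Organoid IC50 is regressed on the proximal
pathways' activities (ridge by default; penalty chosen by 3-fold CV
over α ∈ {0.1, …, 1.0}); pathways are ranked by |β|, and the magnitude
is the pathway's predictive performance.

**Patient scoring and validation.** Each patient's predicted resistance
is Score = Σ_p Exp_patient,p × β_p over the top-ranked pathway(s).
Patients are split at the median score into responders and
non-responders; the split is validated by a two-sided log-rank test on
overall survival in drug-treated patients, with untreated patients as a
negative control, plus isogenic sensitive/resistant cell-line t-tests,
one-sided Mann–Whitney concordance with mutation biomarkers, a
leave-up-to-3-organoids-out robustness sweep, and a random-pathway
bootstrap that converts the biomarker's predictive rank into an
empirical p-value.

Every input can be produced by the built-in synthetic-scenario
generator (`netbiomark.simulate`), which plants a pathway near the drug
targets whose activity drives organoid IC50 and treated-patient hazard,
so the whole chain is testable without external data.

## Worked example

Generate a synthetic scenario, then run discovery and validation:

```bash
netbiomark simulate --seed 11 --out-dir fixtures
netbiomark discover --config discover.yaml     # paths as in fixtures/
netbiomark validate --config validate.yaml
```

Discovery prints the selected biomarker:

```
top biomarker: pathway_planted (beta=-1.3547)
```

`results/proximity.tsv` shows why it was selected — the planted pathway
sits half a hop from the drug targets, 4.7 null standard deviations
closer than degree-matched chance:

```
pathway          d_c   mu_null  sigma_null  z        proximal
pathway_planted  0.5   2.11225  0.34327     -4.6967  1
pathway_009      1.25  2.19300  0.35969     -2.6217  1
```

Validation reports the survival pattern expected of a real biomarker —
separation in treated patients, none in the untreated control — plus
the orthogonal checks:

```
treated   log-rank chi2 7.84, p = 0.0051   (57 vs 57 patients)
untreated log-rank chi2 0.70, p = 0.401    (149 vs 149 patients)
isogenic  t = 51.5, p = 1.8e-13, higher in sensitive lines
mutation  one-sided Mann-Whitney p = 4.3e-17
```

The negative β means high pathway activity tracks low IC50
(sensitivity), so the isogenic contrast must find the pathway higher in
sensitive lines — which it does.

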