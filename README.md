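# hallmark-timing

Pan-cancer tumors differ in *when* genome instability arises during their
evolution. Because a mutation's variant allele frequency (VAF) is a proxy
for how clonal — and hence how early — it is, the mean VAF of mutations in
genes of each of the ten canonical cancer hallmarks gives a per-patient
hallmark *timing profile*. Clustering these 10-dimensional profiles splits
a cohort into **EGI** tumors (early genome instability: the
genome-instability hallmark ranks first by VAF) and **LGI** tumors (late
genome instability: immune-evasion and inflammation hallmarks lead
instead). This package implements that analysis for cohort-scale somatic
mutation data, together with the molecular follow-up that characterizes
the two groups:

- **Profiling & clustering** — per-patient mean VAF per hallmark,
  descending-VAF ranks, mean-centred PCA (all components), k-means with
  the cluster count chosen at the elbow of the within-cluster
  sum-of-squares (WSS) curve, silhouette QC, and EGI/LGI naming by the
  cluster-mean rank of the genome-instability hallmark.
- **Mutational signatures** — SBS96 classification of substitutions
  (pyrimidine-strand trinucleotide channels), per-sample signature
  refitting against a reference catalog by greedy golden-section descent
  on the reconstruction SSE (deconstructSigs scheme, trim 0.06), a
  ≥50-mutation sample filter, and dominant-signature calls (argmax) for
  SBS weights and supplied copy-number (CN) exposure matrices.
- **Association statistics** — per-signature 2×2 contingency tests
  (chi-square when all expected cells ≥ 5, Fisher's exact otherwise) with
  Benjamini–Hochberg FDR; a within-cluster patient bootstrap (R = 1000) of
  dominant-signature counts compared between clusters by the two-sample
  Anderson–Darling test with Cohen's *d* effect sizes and 95% CIs;
  univariate logistic odds ratios for immune/stemness features (LGI coded
  1, Bonferroni-corrected); per-hallmark Mann–Whitney VAF comparisons; and
  the substitution-count vs mean-VAF Pearson correlation control.
- **Synthetic cohorts** — a generator that plants all of the above
  (hallmark orderings, signature mixtures, dominant CN signatures,
  feature shifts) with full ground truth, so every stage can be validated
  against known structure.

## Worked example

```python
from hallmark_timing import HallmarkTimingModel, CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=123))   # 200 EGI + 200 LGI patients
model = HallmarkTimingModel.from_cohort(cohort, R=1000)
results = model.fit(seed=123)
print(results.summary())
```

prints (abridged):

```
Hallmark genome-instability timing — fit summary
====================================================
samples clustered        : 400  (EGI 201 / LGI 199)
k (clusters)             : 2
average silhouette width : 0.345
GI mean-rank margin      : 3.51

Per-hallmark VAF comparison (Mann-Whitney, BH):
  genome_instability     dVAF(LGI-EGI)=-0.0482  p_adj=1.66e-59  [EGI]
  immune_evasion         dVAF(LGI-EGI)=+0.0471  p_adj=4.7e-62  [LGI]
  inflammation           dVAF(LGI-EGI)=+0.0496  p_adj=1.71e-61  [LGI]
  ...
CN dominant-signature enrichment (contingency, BH):
  CN1        dfrac(EGI-LGI)=-0.3728  p_adj=5.07e-16  [LGI]
  CN17       dfrac(EGI-LGI)=+0.3125  p_adj=1.59e-12  [EGI]
  ...
Feature enrichment (logistic OR, Bonferroni):
  mast_cells_resting     OR=133 [22.7, 784]  p_adj=4.28e-07  [LGI]
  stemness_mrna_index    OR=0.0079 [0.00181, 0.0344]  p_adj=7.66e-10  [EGI]
  ...
```

Reading the output: the elbow picked k = 2 and the two clusters recover
the planted groups almost perfectly (the GI mean-rank margin of 3.5 says
the genome-instability hallmark ranks ~3.5 positions earlier in the EGI
cluster). The hallmark table shows the planted ordering contrast — genome
instability earlier (higher VAF) in EGI, immune/inflammation earlier in
LGI, with median VAF differences of ~0.05. The CN table flags the planted
enrichments (CN1 dominant more often in LGI, CN17 in EGI), and the forest
table recovers every planted feature shift with the correct direction
(OR > 1 ⇒ LGI-associated, OR < 1 ⇒ EGI-associated).

The same pipeline runs from files via the CLI:

```sh
hallmark-timing simulate --out cohort/ --seed 123
hallmark-timing run --config run.yaml        # all stages + figures + manifest
hallmark-timing cluster --mutations cohort/mutations.tsv \
    --hallmarks cohort/hallmark_map.tsv --out out/
```

Inputs are tab-delimited: a MAF-like mutation table (`sample_id gene chrom
pos ref alt vaf [context3]`), a `gene → hallmark` map, a COSMIC-format
96-row SBS catalog, a patients × CN-signatures exposure matrix, and a
per-patient feature table.

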