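# emtscore

Gene-signature scoring and PD-L1 association analysis for breast-cancer
expression and immunohistochemistry (IHC) cohorts.

Epithelial–mesenchymal transition (EMT) and the claudin-low (CL) molecular
subtype of breast cancer are both linked to elevated expression of the
immune-checkpoint ligand PD-L1 (gene symbol *CD274*). `emtscore` packages
the computational side of that analysis for anyone who wants to run it on
their own cohorts or simulate it:

- **Signature scoring.** For a gene signature with an up-regulated set *U*
  and a down-regulated set *D*, each sample *s* gets the score

  ```
  score(s) = mean_{g in U} x_gs  −  mean_{g in D} x_gs
  ```

  on log-scale normalized expression *x*. Applied to the built-in 17-gene
  EMT signature (12 mesenchymal up-genes ZEB1, ZEB2, SNAI1, SNAI2, TWIST1,
  TWIST2, FOXC2, VIM, FN1, SOX10, MMP2, MMP3; 5 epithelial down-genes CDH1,
  CLDN3, CLDN4, CLDN7, DSP) this is the EMT score; applied to a claudin-low
  signature loaded from a GMT file it is the CL score.
- **Score–gene correlation.** Pearson correlation of a score vector with a
  target gene's expression (default *CD274*), with two-sided p-values from
  the t-distribution and optional subgroup stratification (e.g. TNBC-only).
- **IHC marker association.** Dichotomization of percent-positive IHC
  readouts (E-cadherin down-regulated at ≤ 70% positive tumor cells,
  vimentin up-regulated at > 5%), 2×2 cross-classification against PD-L1
  status, and association testing: χ² on 1 df, switching to Fisher's exact
  test whenever any expected cell frequency is below five, or Fisher forced
  for all rows. Fisher's two-sided p sums hypergeometric point
  probabilities no larger than the observed table's, computed with exact
  integer arithmetic.
- **Synthetic cohorts.** Seed-deterministic generators for expression
  cohorts with a planted claudin-low subpopulation (and CD274 coupled to
  the latent subtype) and for IHC cohorts with a tunable PD-L1–EMT odds
  ratio, so the whole pipeline is testable without any downloads.

## Worked example

```python
from emtscore import (fixture_cohort, builtin_emt_signature, claudin_low_score,
                      correlate_score_with_gene, build_table, association_test)

matrix, metadata, ihc = fixture_cohort()   # 50 genes x 40 samples, 67 IHC patients

sv = claudin_low_score(builtin_emt_signature(), matrix)
res = correlate_score_with_gene(sv, matrix, "CD274")
print(f"EMT score vs CD274: r={res.r:.3f} p={res.p:.2e} n={res.n}")

for marker in ("ecad", "vim", "combined"):
    t = build_table(ihc, marker)
    a = association_test(t, mode="fisher")
    print(f"{marker:8s} ({t.a},{t.b};{t.c},{t.d})  OR={a.odds_ratio:.2f}  p={a.p:.4f}")
```

prints

```
EMT score vs CD274: r=0.549 p=2.43e-04 n=40
ecad     (9,10;10,38)  OR=3.42  p=0.0390
vim      (10,9;9,39)  OR=4.81  p=0.0140
combined (6,2;13,46)  OR=10.62  p=0.0051
```

The EMT score correlates positively with *CD274* because the fixture plants
a claudin-low subpopulation whose CD274 expression is coupled to the latent
subtype; the three marker tables associate PD-L1 protein status with
E-cadherin loss, vimentin gain, and their combination, with the combined
phenotype showing the strongest association (odds ratio ≈ 10.6).

The same analysis runs from the shell:

```sh
emtscore synth --out cohort --seed 7
emtscore score     --config run.yaml --out reports
emtscore correlate --config run.yaml --out reports
emtscore ihc       --config run.yaml --out reports
```

where `run.yaml` names the input files (`matrix`, `metadata`, `ihc_table`),
the target gene, the association mode (`auto`, `fisher` or `chi2`) and an
optional subgroup flag. Reports are deterministic TSVs; a machine-readable
run summary is written alongside.

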