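# Methods

## Signature scores

A signature is an ordered pair of disjoint gene sets: genes up-regulated in
the phenotype and genes down-regulated. The per-sample score is the plain
mean of the up-set's log expression minus the mean of the down-set's, so it
is invariant to adding a constant to the whole matrix and scales linearly
with the matrix. No per-gene standardization is applied by default; a
`standardize` flag z-scores each gene row across samples first, which is
the usual choice when mixing array platforms, and is provided as a clearly
labeled extension rather than the default behaviour.

The built-in EMT signature holds the 17 genes most commonly used to stage
EMT in breast tissue: 12 mesenchymal effectors and transcription factors on
the up side and 5 epithelial/junction genes (E-cadherin, claudins 3/4/7,
desmoplakin) on the down side. The up/down split follows the universally
accepted marker directions — epithelial genes fall during EMT — since any
flat list of these 17 genes implies exactly this partition. Informal
spellings are normalized through a small alias table (`Snai1`→`SNAI1`,
`Snail2`→`SNAI2`, `PD-L1`/`B7-H1`→`CD274`, …), extensible per call, so the
built-in signature matches any reasonably labeled matrix.

Claudin-low scoring uses the identical formula under its own entry point;
CL signatures of any size (the published one has 1,604 genes) are loaded
from standard GMT files as a `<NAME>_UP` / `<NAME>_DN` pair. Signature
matching proceeds with at least one gene per side; coverage below 80% on
either side raises a warning, since the signatures were designed for
genome-wide arrays where coverage is near-total.

"Top-k" subsetting of a signature (for heatmap-style exports) takes the k
genes of largest absolute weight when weights exist, else a deterministic
alphabetical order within up-then-down sets. This is a presentation choice
only; scores never depend on it. Sample ordering by score breaks ties
lexicographically by sample id so exports are bit-identical across runs.

## Input handling

Expression matrices are tab-delimited, genes in rows, already normalized on
a log scale (an optional `log2(x+1)` transform exists but is off by
default). Duplicate gene rows — typically multiple array probes per gene —
are collapsed by mean (configurable to max); mean is the
least-assumption summary. Missing-value tokens `NA`/`nan`/empty are
accepted only for entirely missing rows, which are dropped with a warning;
partial missingness is rejected because the up-minus-down score has no
defined semantics for it.

IHC tables carry one row per patient: dichotomous PD-L1 status and the
percentage of tumor cells staining positive for E-cadherin and vimentin,
each validated to [0, 100].

## Association tests

E-cadherin is called down-regulated at ≤ 70% positive cells (boundary
included) and vimentin up-regulated at strictly > 5%; a reading of exactly
5% is classified not-up, the conservative completion of cutoffs quoted as
"> 5" vs "< 5". The combined EMT phenotype requires both calls. Each
marker is cross-classified against PD-L1 status with the fixed convention
row 1 = marker positive for the EMT direction, column 1 = PD-L1 positive,
so the odds ratio is ad/bc (infinite when bc = 0 with ad > 0).

Mode `auto` applies the classical rule: χ² on 1 df (Yates correction
available but off by default) unless any expected frequency
row·col/N is below five, in which case Fisher's exact test is used. Mode
`fisher` forces Fisher for every row, which is how dichotomized marker
tables of this size are conventionally reported; it is the default for the
IHC pipeline. Fisher's two-sided p-value uses the mainstream convention —
the sum over all tables with the observed margins of hypergeometric point
probabilities no larger than the observed table's — computed with exact
integer weights C(r1,k)·C(r2,c1−k), so ties are decided exactly rather
than through floating-point comparisons; the rational sum is converted to
float only at the end. This is exact and fast for cohort-scale tables
(N up to ~1000).

Pearson correlations report two-sided p-values from the t-statistic
t = r·√((n−2)/(1−r²)) on n−2 df; constant vectors and n < 3 are rejected.
p-values below 1e−300 are clamped to that floor and flagged as an upper
bound rather than returned as zero. When the target gene appears inside
the signature being scored, it is removed and the scores recomputed before
correlating, so the target never contributes to the score it is tested
against. No multiple-testing adjustment is applied anywhere; raw p-values
are reported.

## Synthetic cohorts

The expression generator draws, per gene, a fixed baseline mean from
N(8, 2²) (array-intensity-like log2 units) and i.i.d. Gaussian noise with
SD `sigma` per sample. Each sample is claudin-low with probability
`frac_cl`; CL samples have the signature's up-genes shifted by +`delta_up`
and down-genes by −`delta_down`, and the CD274 row adds
`alpha`·(CL indicator). Under this model the expected score gap between CL
and background samples is exactly `delta_up + delta_down`, which the
recovery checks exploit.

Defaults: `n_samples=200`, `frac_cl=0.15` (a realistic claudin-low
prevalence in unselected breast-tumor cohorts), `delta_up=delta_down=1.0`
(one log2 unit, i.e. two-fold shifts), `sigma=1.0`, `n_noise_genes=100`,
and `alpha=2.0`, sized analytically so the score–CD274 correlation lands
near r ≈ 0.5–0.6, the strength seen in large real cohorts. The IHC
generator draws a latent EMT phenotype (Bernoulli `p_emt`) and PD-L1 status
from phenotype-conditional probabilities; percentages are uniform within
the legal sub-range for the phenotype (e.g. vimentin in (5, 100] when
EMT-positive), so dichotomization recovers the phenotype exactly. Its
defaults (67 patients, `p_emt=8/67`, `p_pdl1_given_emt=0.75`,
`p_pdl1_given_no_emt=0.22`) emulate a strongly associated 67-patient
cohort. Every generator takes one seed and builds a single local
`numpy.random.Generator`; identical seeds give byte-identical outputs.

What the generators deliberately omit: gene–gene correlation, platform and
batch effects, copy-number structure, and the empirical value
distributions of real microarray or RNA-seq cohorts. Passing calibration
and recovery checks on these cohorts therefore demonstrates correctness of
the statistical machinery under the assumed independent-Gaussian model,
not robustness to the correlation structure of real tumors.

The fixture cohort plants its 67 IHC records deterministically (not
sampled) from a fixed joint distribution over (E-cadherin call, vimentin
call, PD-L1 status), chosen so the three marginal 2×2 tables are exact to
the count; the companion 50-gene × 40-sample matrix comes from the
stochastic generator at a fixed seed.

## Verification sizes and numerical choices

The Fisher implementation is checked exhaustively against an
exact-rational enumeration oracle on all 46,375 tables with N ≤ 30, and
against scipy on random larger tables. Score algebra is checked on 200
random small matrices against a brute-force per-sample loop. Calibration
uses 500 null IHC cohorts of 200 patients (the χ² branch of the auto rule;
Fisher is deliberately conservative, so calibration is a property of the
χ² branch), and coupling detection/nulls use 200 simulated expression
cohorts each; these sizes give binomial/standard-error bands tight enough
to be informative while keeping the default test run fast. Report files
format scores and correlation coefficients with 6 significant digits and
p-values in 3-digit scientific notation so reruns are diffable.

## Known limitations

- Per-cell missing expression values are rejected rather than imputed.
- Confidence intervals for r and the odds ratio are not computed.
- No rank-based or single-sample-GSEA scoring variants; the score is the
  plain (optionally z-scored) up-minus-down mean.
- The χ²/Fisher selection threshold (expected frequency < 5) is the
  classical rule of thumb, not a data-driven choice.
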