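"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators: (1) a log-scale expression cohort containing a planted
claudin-low-like subpopulation — mesenchymal signature genes shifted up,
epithelial/claudin genes shifted down, and CD274 coupled to the latent
subtype indicator; (2) an IHC patient cohort in which PD-L1 positivity
depends on a latent EMT phenotype with a tunable odds ratio. Both are fully
determined by their seed (one ``numpy`` Generator per call, no global
state).

A deterministic fixture cohort is also provided whose dichotomized IHC
cross-tabulations are planted exactly (not sampled), so marker-association
outputs on it are reproducible to the count.

Noise is independent Gaussian per gene on the log scale: the simplest model
under which the up-minus-down score has a closed-form expected shift of
``delta_up + delta_down`` between planted-subtype and background samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sigio import (
    ExpressionMatrix,
    GeneSignature,
    IHCRecord,
    SampleMetadata,
    builtin_emt_signature,
)

#: Mean and spread of per-gene baseline log2 expression, array-intensity-like.
_BASELINE_MEAN = 8.0
_BASELINE_SD = 2.0


@dataclass(frozen=True)
class ExpressionSimParams:
    """Parameters of the expression-cohort generator.

    delta_up / delta_down are the mean shifts (log2 units) applied to the
    signature's up- and down-genes in planted claudin-low samples; alpha
    couples CD274 to the latent subtype indicator; sigma is the per-gene
    Gaussian noise SD. Defaults give a subtype prevalence and effect sizes
    typical of claudin-low tumors in bulk breast-cancer cohorts, with alpha
    sized so the score-CD274 correlation lands near the strength observed in
    large real cohorts (r around 0.5-0.6).
    """

    n_samples: int = 200
    frac_cl: float = 0.15
    delta_up: float = 1.0
    delta_down: float = 1.0
    alpha: float = 2.0
    sigma: float = 1.0
    n_noise_genes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not (0.0 < self.frac_cl < 1.0):
            raise ValueError("frac_cl must be in (0, 1)")
        if self.delta_up < 0 or self.delta_down < 0:
            raise ValueError("shifts must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be non-negative")


@dataclass(frozen=True)
class IHCSimParams:
    """Parameters of the IHC-cohort generator.

    The EMT phenotype is Bernoulli(p_emt); PD-L1 positivity is Bernoulli
    with probability conditional on the phenotype. Defaults emulate a
    67-patient cohort in which the combined EMT phenotype carries roughly a
    10-fold odds of PD-L1 positivity.
    """

    n_patients: int = 67
    p_emt: float = 8 / 67
    p_pdl1_given_emt: float = 0.75
    p_pdl1_given_no_emt: float = 0.22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        for name in ("p_emt", "p_pdl1_given_emt", "p_pdl1_given_no_emt"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def generate_expression_cohort(
    params: ExpressionSimParams,
    sig: GeneSignature | None = None,
) -> tuple[ExpressionMatrix, list[SampleMetadata]]:
    """Simulate a cohort with a planted claudin-low subpopulation.

    Returns the matrix (signature genes + CD274 + background genes) and
    per-sample metadata carrying the true subtype label under flag ``CL``.
    """
    if sig is None:
        sig = builtin_emt_signature()
    if len(sig) == 0:
        raise ValueError("empty signature")
    rng = np.random.default_rng(params.seed)

    genes = list(sig.up_genes) + list(sig.down_genes)
    if "CD274" in genes:
        raise ValueError("signature must not contain the target gene CD274")
    noise_genes = [f"BG{i:04d}" for i in range(1, params.n_noise_genes + 1)]
    all_genes = genes + ["CD274"] + noise_genes
    samples = [f"S{i:03d}" for i in range(1, params.n_samples + 1)]

    cl = rng.random(params.n_samples) < params.frac_cl
    mu = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=len(all_genes))
    values = mu[:, None] + rng.normal(
        0.0, params.sigma, size=(len(all_genes), params.n_samples)
    )
    n_up = len(sig.up_genes)
    values[:n_up, cl] += params.delta_up
    values[n_up:len(genes), cl] -= params.delta_down
    values[len(genes), :] += params.alpha * cl  # CD274 coupling

    matrix = ExpressionMatrix(pd.DataFrame(values, index=all_genes, columns=samples))
    metadata = [
        SampleMetadata(s, {"CL": bool(flag)}) for s, flag in zip(samples, cl)
    ]
    return matrix, metadata


def generate_ihc_cohort(params: IHCSimParams) -> list[IHCRecord]:
    """Simulate an IHC cohort with a tunable PD-L1-EMT association.

    EMT-phenotype patients draw ecad_pct uniformly in (0, 70] and vim_pct in
    (5, 100]; background patients draw ecad_pct in (70, 100] and vim_pct in
    [0, 5], so the dichotomization recovers the phenotype exactly.
    """
    rng = np.random.default_rng(params.seed)
    records: list[IHCRecord] = []
    for i in range(1, params.n_patients + 1):
        emt = rng.random() < params.p_emt
        p_pos = params.p_pdl1_given_emt if emt else params.p_pdl1_given_no_emt
        pdl1 = rng.random() < p_pos
        if emt:
            ecad = rng.uniform(0.0, 70.0)
            vim = rng.uniform(5.0, 100.0)
        else:
            ecad = rng.uniform(70.0, 100.0)
            vim = rng.uniform(0.0, 5.0)
        records.append(IHCRecord(f"P{i:03d}", bool(pdl1), float(ecad), float(vim)))
    return records


# Joint (ecad_down, vim_up, PD-L1+) counts planted in the fixture cohort.
# Their three marginal 2x2 cross-tabulations are, by construction:
#   ecad_down vs PD-L1: (9, 10; 10, 38)
#   vim_up    vs PD-L1: (10, 9; 9, 39)
#   combined  vs PD-L1: (6, 2; 13, 46)
_FIXTURE_CELLS = (
    # (ecad_down, vim_up, pdl1_positive, count)
    (True, True, True, 6),
    (True, True, False, 2),
    (True, False, True, 3),
    (True, False, False, 8),
    (False, True, True, 4),
    (False, True, False, 7),
    (False, False, True, 6),
    (False, False, False, 31),
)


def fixture_cohort() -> tuple[ExpressionMatrix, list[SampleMetadata], list[IHCRecord]]:
    """Small deterministic cohort for tests and documentation.

    The expression matrix is 50 genes x 40 samples from the stochastic
    generator at a fixed seed; the 67 IHC records are planted so their
    dichotomized cross-tabulations exactly reproduce the reference marker
    tables. The metadata carries the true ``CL`` flag plus a deterministic
    ``TNBC`` flag usable for subgroup stratification.
    """
    params = ExpressionSimParams(
        n_samples=40, n_noise_genes=32, seed=20240
    )
    matrix, metadata = generate_expression_cohort(params, builtin_emt_signature())
    metadata = [
        SampleMetadata(
            m.sample_id,
            {"CL": m.flags["CL"], "TNBC": m.flags["CL"] or (i % 3 == 0)},
        )
        for i, m in enumerate(metadata)
    ]

    records: list[IHCRecord] = []
    pid = 0
    for ecad_down, vim_up, pdl1, count in _FIXTURE_CELLS:
        for _ in range(count):
            pid += 1
            records.append(
                IHCRecord(
                    f"P{pid:03d}",
                    pdl1,
                    ecad_pct=40.0 if ecad_down else 90.0,
                    vim_pct=30.0 if vim_up else 2.0,
                )
            )
    return matrix, metadata, records
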