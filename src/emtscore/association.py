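"""Statistical layer: Pearson correlation with subgroup stratification, IHC
dichotomization, and 2x2 contingency association tests.

The contingency machinery implements the analysis convention of the study it
supports: categories are compared with the chi-square test unless any
expected cell frequency is below five, in which case Fisher's exact test is
used; the IHC marker table is additionally reproducible with Fisher forced
for every row. Fisher's two-sided p-value follows the mainstream
"sum of point probabilities no larger than the observed table's" convention
and is computed with exact integer arithmetic, so ties are handled without
floating-point ambiguity for cohort-scale tables (N up to ~1000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb, isnan
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .sigio import ExpressionMatrix, GeneSignature, IHCRecord, SampleMetadata
from .scoring import ScoreVector, claudin_low_score

logger = logging.getLogger(__name__)

#: Smallest p-value reported; smaller values are clamped and flagged as an
#: upper bound rather than returned as an exact zero.
P_FLOOR = 1e-300

#: Expected-frequency threshold below which the auto rule switches from
#: chi-square to Fisher's exact test.
EXPECTED_MIN = 5.0

#: E-cadherin is called down-regulated at <= 70% positive tumor cells;
#: vimentin is called up-regulated at > 5%.
ECAD_DOWN_MAX_PCT = 70.0
VIM_UP_MIN_PCT = 5.0


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a two-sided p-value from the t-distribution."""

    r: float
    p: float
    n: int
    x_label: str = "x"
    y_label: str = "y"


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    x_label: str = "x",
    y_label: str = "y",
) -> CorrelationResult:
    """Pearson product-moment correlation, two-sided p via the t-statistic
    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 for a defined p-value, got n={n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    p = float(res.pvalue)
    if p < P_FLOOR:
        logger.warning("correlation p underflow; reporting upper bound %g", P_FLOOR)
        p = P_FLOOR
    return CorrelationResult(float(res.statistic), p, n, x_label, y_label)


def correlate_score_with_gene(
    scores: ScoreVector,
    matrix: ExpressionMatrix,
    gene: str,
    subset: Sequence[str] | None = None,
    signature: GeneSignature | None = None,
) -> CorrelationResult:
    """Correlate per-sample scores with one gene's expression.

    Samples are aligned by id; ``subset`` restricts to a subgroup (e.g. TNBC
    samples). If ``signature`` is supplied and contains the target gene, the
    gene is removed from the signature and the scores recomputed, so the
    target never contributes to the score it is correlated with.
    """
    from .sigio import normalize_symbol

    gene = normalize_symbol(gene)
    if gene not in matrix.data.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    if signature is not None and gene in signature.genes:
        logger.warning(
            "target gene %s is in signature %s; excluding it from the score",
            gene, signature.name,
        )
        reduced = GeneSignature(
            signature.name,
            tuple(g for g in signature.up_genes if g != gene),
            tuple(g for g in signature.down_genes if g != gene),
        )
        scores = claudin_low_score(reduced, matrix)

    ids = list(scores.scores.index)
    if subset is not None:
        wanted = set(subset)
        ids = [s for s in ids if s in wanted]
    ids = [s for s in ids if s in matrix.data.columns]
    if not ids:
        raise ValueError("no samples left after subsetting")
    x = scores.scores.loc[ids].to_numpy()
    y = matrix.data.loc[gene, ids].to_numpy()
    return pearson(x, y, x_label=scores.signature_name, y_label=gene)


def stratify(metadata: Sequence[SampleMetadata], flag: str) -> list[str]:
    """Sample ids whose named boolean flag is true (e.g. the TNBC subgroup)."""
    if not any(flag in m.flags for m in metadata):
        raise KeyError(f"flag {flag!r} not present in metadata")
    return [m.sample_id for m in metadata if m.flags.get(flag, False)]


class IHCStatus(NamedTuple):
    ecad_down: bool
    vim_up: bool
    combined: bool


def dichotomize_ihc(record: IHCRecord) -> IHCStatus:
    """Dichotomize one IHC record.

    E-cadherin down-regulated at <= 70% positive cells (boundary included),
    vimentin up-regulated at strictly > 5%; the combined EMT phenotype
    requires both.
    """
    ecad_down = record.ecad_pct <= ECAD_DOWN_MAX_PCT
    vim_up = record.vim_pct > VIM_UP_MIN_PCT
    return IHCStatus(ecad_down, vim_up, ecad_down and vim_up)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts cross-classifying marker status (rows) vs PD-L1 (columns).

    Convention: row 1 = marker positive for the EMT direction, column 1 =
    PD-L1 positive; so ``a`` counts marker+/PD-L1+ patients.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("counts must be non-negative integers")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def odds_ratio(self) -> float:
        ad, bc = self.a * self.d, self.b * self.c
        if bc == 0:
            return float("inf") if ad > 0 else float("nan")
        return ad / bc


MARKERS = ("ecad", "vim", "combined")


def build_table(records: Sequence[IHCRecord], marker: str) -> ContingencyTable2x2:
    """Cross-classify a cohort on one dichotomized marker vs PD-L1 status."""
    if marker not in MARKERS:
        raise ValueError(f"unknown marker {marker!r}; choose from {MARKERS}")
    if not records:
        raise ValueError("empty IHC cohort")
    field = {"ecad": "ecad_down", "vim": "vim_up", "combined": "combined"}[marker]
    a = b = c = d = 0
    for rec in records:
        status = getattr(dichotomize_ihc(rec), field)
        if status:
            a, b = (a + 1, b) if rec.pdl1_positive else (a, b + 1)
        else:
            c, d = (c + 1, d) if rec.pdl1_positive else (c, d + 1)
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value by exact integer arithmetic.

    Sums, over all tables with the observed margins, the hypergeometric
    point probabilities no larger than the observed table's. Point
    probabilities are compared as integer weights C(r1,k)*C(r2,c1-k), so
    ties are exact; the sum is a Fraction, converted to float at the end.
    """
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = t.total
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = comb(r1, t.a) * comb(r2, c1 - t.a)
    num = sum(
        w for k in range(lo, hi + 1)
        if (w := comb(r1, k) * comb(r2, c1 - k)) <= w_obs
    )
    p = float(Fraction(num, comb(n, c1)))
    return min(max(p, P_FLOOR), 1.0)


def expected_frequencies(t: ContingencyTable2x2) -> tuple[np.ndarray, float]:
    """Expected cell frequencies row_total*col_total/N, and their minimum."""
    obs = t.as_array().astype(float)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / t.total
    return exp, float(exp.min())


def chi_square(t: ContingencyTable2x2, yates: bool = False) -> float:
    """Chi-square test of independence on 1 df; Yates correction optional
    (off by default). Requires all four marginal totals to be positive."""
    obs = t.as_array()
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero marginal total")
    _, p, _, _ = stats.chi2_contingency(obs, correction=yates)
    return min(max(float(p), P_FLOOR), 1.0)


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of a 2x2 association test: method actually used, two-sided p,
    odds ratio ad/bc, and the expected frequencies behind the method choice."""

    method: str
    p: float
    odds_ratio: float
    expected: np.ndarray
    min_expected: float
    table: ContingencyTable2x2


def association_test(
    t: ContingencyTable2x2, mode: str = "auto", yates: bool = False
) -> AssociationResult:
    """Test a 2x2 table for association.

    ``mode="auto"`` applies the expected-frequency rule: chi-square unless
    any expected cell is below five, then Fisher's exact test.
    ``mode="fisher"`` forces Fisher (reproducing marker tables reported with
    Fisher throughout); ``mode="chi2"`` forces chi-square with a warning if
    the rule would have demanded Fisher.
    """
    if mode not in ("auto", "fisher", "chi2"):
        raise ValueError(f"unknown mode {mode!r}")
    exp, min_exp = expected_frequencies(t)
    if mode == "auto":
        method = "fisher" if min_exp < EXPECTED_MIN else "chi2"
    else:
        method = mode
    if method == "chi2" and min_exp < EXPECTED_MIN:
        logger.warning(
            "chi-square forced with min expected frequency %.3g < %g", min_exp,
            EXPECTED_MIN,
        )
    p = fisher_exact(t) if method == "fisher" else chi_square(t, yates=yates)
    return AssociationResult(method, p, t.odds_ratio, exp, min_exp, t)
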