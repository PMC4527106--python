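"""Association layer: Pearson correlation, dichotomization, 2x2 tests."""

import math
from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from emtscore import (
    ContingencyTable2x2,
    ExpressionMatrix,
    GeneSignature,
    IHCRecord,
    SampleMetadata,
    ScoreVector,
    association_test,
    build_table,
    chi_square,
    claudin_low_score,
    correlate_score_with_gene,
    dichotomize_ihc,
    expected_frequencies,
    fisher_exact,
    pearson,
    stratify,
)


def fisher_oracle(a, b, c, d):
    """Exhaustive enumeration oracle with exact rational arithmetic.

    Builds every table with the observed margins, computes each table's
    hypergeometric probability from the factorial formula, and sums those no
    larger than the observed table's.
    """
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    const = Fraction(
        factorial(r1) * factorial(r2) * factorial(c1) * factorial(c2), factorial(n)
    )

    def prob(x):
        return const / (
            factorial(x) * factorial(r1 - x) * factorial(c1 - x)
            * factorial(r2 - c1 + x)
        )

    p_obs = prob(a)
    total = sum(
        (prob(k) for k in range(max(0, c1 - r2), min(r1, c1) + 1)
         if prob(k) <= p_obs),
        Fraction(0),
    )
    return float(min(total, Fraction(1)))


class TestPearson:
    def test_perfect_correlation(self):
        assert pearson([1, 2, 3, 4], [1, 2, 3, 4]).r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson([1, 2, 3, 4], [-1, -2, -3, -4]).r == pytest.approx(-1.0)

    def test_matches_explicit_formula(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([2, 1, 4, 3, 6], dtype=float)
        # explicit covariance / variance computation
        r_hand = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        t = r_hand * math.sqrt(3 / (1 - r_hand**2))
        p_hand = 2 * scipy.stats.t.sf(abs(t), df=3)
        res = pearson(x, y)
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        assert res.p == pytest.approx(p_hand, rel=1e-9)
        assert res.n == 5

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson([1, 2], [3, 4])

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_symmetry_and_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r, abs=1e-12)
        assert pearson(scale * x + shift, y).r == pytest.approx(
            pearson(x, y).r, abs=1e-9
        )


class TestCorrelateScoreWithGene:
    def _cohort(self):
        rng = np.random.default_rng(11)
        genes = ["A", "B", "C", "CD274"]
        samples = [f"S{i}" for i in range(12)]
        data = pd.DataFrame(rng.normal(5, 1, size=(4, 12)), index=genes,
                            columns=samples)
        matrix = ExpressionMatrix(data)
        sig = GeneSignature("T", ("A", "B"), ("C",))
        return sig, matrix, claudin_low_score(sig, matrix)

    def test_constant_gene_propagates_error(self):
        sig, matrix, sv = self._cohort()
        const = matrix.data.copy()
        const.loc["CD274"] = 3.0
        with pytest.raises(ValueError, match="constant"):
            correlate_score_with_gene(sv, ExpressionMatrix(const), "CD274")

    def test_identity_subset_matches_full_cohort(self):
        sig, matrix, sv = self._cohort()
        full = correlate_score_with_gene(sv, matrix, "CD274")
        subset = correlate_score_with_gene(sv, matrix, "CD274",
                                           subset=matrix.sample_ids)
        assert full.r == pytest.approx(subset.r)
        assert full.n == subset.n

    def test_absent_gene_rejected(self):
        sig, matrix, sv = self._cohort()
        with pytest.raises(KeyError):
            correlate_score_with_gene(sv, matrix, "NOPE")

    def test_target_gene_excluded_from_signature(self, caplog):
        sig, matrix, sv = self._cohort()
        sig_with_target = GeneSignature("T", ("A", "B", "CD274"), ("C",))
        with caplog.at_level("WARNING"):
            res = correlate_score_with_gene(
                sv, matrix, "CD274", signature=sig_with_target
            )
        assert "excluding" in caplog.text
        clean = correlate_score_with_gene(sv, matrix, "CD274", signature=sig)
        assert res.r == pytest.approx(clean.r)


class TestStratify:
    meta = [
        SampleMetadata("S1", {"TNBC": True}),
        SampleMetadata("S2", {"TNBC": False}),
        SampleMetadata("S3", {"TNBC": True}),
    ]

    def test_selects_flagged_samples(self):
        assert stratify(self.meta, "TNBC") == ["S1", "S3"]

    def test_unknown_flag_rejected(self):
        with pytest.raises(KeyError):
            stratify(self.meta, "HER2")

    def test_no_sample_flagged_gives_empty(self):
        meta = [SampleMetadata("S1", {"TNBC": False})]
        assert stratify(meta, "TNBC") == []


class TestDichotomize:
    @pytest.mark.parametrize(
        "ecad,vim,expected",
        [
            (70.0, 50.0, (True, True, True)),    # ecad boundary is inclusive
            (60.0, 5.0, (True, False, False)),   # vim boundary is exclusive
            (60.0, 10.0, (True, True, True)),
            (90.0, 10.0, (False, True, False)),
            (71.0, 5.1, (False, True, False)),
        ],
    )
    def test_cutoffs(self, ecad, vim, expected):
        rec = IHCRecord("P", True, ecad_pct=ecad, vim_pct=vim)
        assert tuple(dichotomize_ihc(rec)) == expected


class TestBuildTable:
    def test_fixture_marker_tables(self, cohort):
        _, _, records = cohort
        vim = build_table(records, "vim")
        assert (vim.a, vim.b, vim.c, vim.d) == (10, 9, 9, 39)
        ecad = build_table(records, "ecad")
        assert (ecad.a, ecad.b, ecad.c, ecad.d) == (9, 10, 10, 38)
        comb = build_table(records, "combined")
        assert (comb.a, comb.b, comb.c, comb.d) == (6, 2, 13, 46)

    def test_single_record(self):
        rec = [IHCRecord("P1", True, ecad_pct=90.0, vim_pct=10.0)]
        t = build_table(rec, "vim")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 0)

    def test_cells_sum_to_cohort_size(self, cohort):
        _, _, records = cohort
        for marker in ("ecad", "vim", "combined"):
            assert build_table(records, marker).total == len(records)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_table([], "vim")


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_diagonal_table_exact_third(self):
        # margins (2,2)/(2,2): P(k=0)=P(k=2)=1/6, P(k=1)=4/6; two-sided = 2/6
        assert fisher_exact(ContingencyTable2x2(2, 0, 0, 2)) == pytest.approx(1 / 3)

    @pytest.mark.parametrize(
        "table,printed",
        [((10, 9, 9, 39), 0.014), ((9, 10, 10, 38), 0.039), ((6, 2, 13, 46), 0.005)],
    )
    def test_marker_tables_match_printed_p(self, table, printed):
        p = fisher_exact(ContingencyTable2x2(*table))
        assert p == pytest.approx(printed, abs=5e-4)

    @settings(deadline=None, max_examples=60)
    @given(st.tuples(st.integers(0, 25), st.integers(0, 25),
                     st.integers(0, 25), st.integers(0, 25)).filter(sum))
    def test_transposition_and_swap_invariance(self, cells):
        a, b, c, d = cells
        p = fisher_exact(ContingencyTable2x2(a, b, c, d))
        assert fisher_exact(ContingencyTable2x2(a, c, b, d)) == pytest.approx(p)
        assert fisher_exact(ContingencyTable2x2(d, c, b, a)) == pytest.approx(p)

    @settings(deadline=None, max_examples=60)
    @given(st.tuples(st.integers(0, 20), st.integers(0, 20),
                     st.integers(0, 20), st.integers(0, 20)).filter(sum))
    def test_matches_enumeration_oracle_and_scipy(self, cells):
        t = ContingencyTable2x2(*cells)
        p = fisher_exact(t)
        assert p == pytest.approx(fisher_oracle(*cells), abs=1e-12)
        p_scipy = scipy.stats.fisher_exact(t.as_array())[1]
        assert p == pytest.approx(p_scipy, rel=1e-6, abs=1e-12)
        assert 0 < p <= 1


class TestChiSquare:
    def test_independent_table(self):
        assert chi_square(ContingencyTable2x2(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # chi2 = 60*(20*20-10*10)^2 / (30*30*30*30) = 20/3
        p_hand = float(scipy.stats.chi2.sf(20 / 3, df=1))
        assert chi_square(ContingencyTable2x2(20, 10, 10, 20)) == pytest.approx(
            p_hand, rel=1e-9
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square(ContingencyTable2x2(0, 0, 5, 5))

    def test_yates_is_more_conservative(self):
        t = ContingencyTable2x2(12, 5, 6, 14)
        assert chi_square(t, yates=True) > chi_square(t, yates=False)

    def test_approaches_fisher_for_large_tables(self):
        # same proportions, growing N: chi2 and Fisher p converge
        gaps = []
        for scale in (1, 5, 25):
            t = ContingencyTable2x2(6 * scale, 4 * scale, 4 * scale, 6 * scale)
            gaps.append(abs(chi_square(t) - fisher_exact(t)))
        assert gaps[2] < gaps[0]


class TestExpectedFrequencies:
    def test_hand_arithmetic(self):
        exp, mn = expected_frequencies(ContingencyTable2x2(10, 9, 9, 39))
        assert mn == pytest.approx(19 * 19 / 67)
        assert exp.sum() == pytest.approx(67)

    def test_uniform_table(self):
        exp, mn = expected_frequencies(ContingencyTable2x2(1, 1, 1, 1))
        np.testing.assert_allclose(exp, 1.0)
        assert mn == 1.0


class TestAssociationTest:
    def test_auto_selects_fisher_below_threshold(self):
        res = association_test(ContingencyTable2x2(6, 2, 13, 46), mode="auto")
        assert res.method == "fisher"
        assert res.min_expected == pytest.approx(8 * 19 / 67)
        assert res.p == pytest.approx(0.005, abs=5e-4)

    def test_auto_selects_chi2_above_threshold(self):
        res = association_test(ContingencyTable2x2(10, 9, 9, 39), mode="auto")
        assert res.method == "chi2"

    def test_forced_fisher_reproduces_marker_p(self):
        res = association_test(ContingencyTable2x2(9, 10, 10, 38), mode="fisher")
        assert res.method == "fisher"
        assert res.p == pytest.approx(0.039, abs=5e-4)

    def test_odds_ratio_ad_over_bc(self):
        res = association_test(ContingencyTable2x2(10, 9, 9, 39), mode="fisher")
        assert res.odds_ratio == pytest.approx(10 * 39 / 81)

    def test_infinite_odds_ratio_when_bc_zero(self):
        res = association_test(ContingencyTable2x2(5, 0, 0, 5), mode="fisher")
        assert res.odds_ratio == math.inf

    def test_forced_chi2_warns_below_threshold(self, caplog):
        with caplog.at_level("WARNING"):
            res = association_test(ContingencyTable2x2(6, 2, 13, 46), mode="chi2")
        assert res.method == "chi2"
        assert "forced" in caplog.text

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            association_test(ContingencyTable2x2(1, 1, 1, 1), mode="exact")
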