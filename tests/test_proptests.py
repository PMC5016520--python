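"""Two-proportion tests, Fisher fallback, and p-value adjustment."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from clonostat.proptests import (
    PROCEDURES,
    adjust_pvalues,
    fisher_exact_two_sided,
    rejection_curves,
    run_comparison,
    scatter_table,
    small_count_guard,
    ztest_two_proportions,
)
from clonostat.repertoire import GeneCountTable


def make_table(rows, totals, gene_type="V", level="gene"):
    return GeneCountTable(
        gene_type=gene_type, level=level, mode="diversity",
        rows=rows, several_items={}, totals=totals,
    )


class TestSmallCountGuard:
    @pytest.mark.parametrize(
        "x1,n1,x2,n2,expected",
        [
            (3, 1000, 10, 1000, True),    # n1*p1 = 3 < 5
            (500, 1000, 400, 1000, False),
            (0, 1000, 0, 1000, True),     # zero occurrence
            (998, 1000, 500, 1000, True), # n1*(1-p1) = 2 < 5
            (5, 1000, 5, 1000, False),    # boundary: exactly 5 is allowed
        ],
    )
    def test_rule(self, x1, n1, x2, n2, expected):
        assert small_count_guard(x1, n1, x2, n2) is expected

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            small_count_guard(0, 0, 1, 10)


class TestZTest:
    def test_symmetry_null(self):
        z, rawp, diff, lo, hi = ztest_two_proportions(100, 1000, 100, 1000)
        assert z == 0 and rawp == 1 and diff == 0
        assert lo == pytest.approx(-hi)

    def test_matches_independent_pooled_ztest(self):
        """Cross-check z and p against statsmodels' pooled two-sample test."""
        for x1, n1, x2, n2 in [(100, 1000, 50, 1000), (30, 500, 60, 700), (400, 900, 350, 800)]:
            z, rawp, *_ = ztest_two_proportions(x1, n1, x2, n2)
            z_ref, p_ref = proportions_ztest([x1, x2], [n1, n2])
            assert z == pytest.approx(z_ref, abs=1e-12)
            assert rawp == pytest.approx(p_ref, abs=1e-12)

    def test_wald_ci_formula(self):
        x1, n1, x2, n2 = 100, 1000, 50, 1000
        _, _, diff, lo, hi = ztest_two_proportions(x1, n1, x2, n2, alpha=0.05)
        p1, p2 = x1 / n1, x2 / n2
        se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        assert hi - diff == pytest.approx(1.959963984540054 * se, rel=1e-12)
        assert diff - lo == pytest.approx(1.959963984540054 * se, rel=1e-12)

    def test_guard_violation_raises(self):
        with pytest.raises(ValueError, match="guard"):
            ztest_two_proportions(1, 1000, 2, 1000)

    @given(
        x1=st.integers(50, 450), x2=st.integers(50, 450),
        n=st.integers(500, 2000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_significance_boundary(self, x1, x2, n):
        """|z| > 1.96 exactly when the two-sided p drops below 0.05."""
        z, rawp, *_ = ztest_two_proportions(x1, n, x2, n)
        if abs(abs(z) - 1.959963984540054) > 1e-9:
            assert (abs(z) > 1.959963984540054) == (rawp < 0.05)


def fisher_oracle(x1, n1, x2, n2):
    """Exhaustive probability-mass enumeration over the fixed margins."""
    M, K, N = n1 + n2, x1 + x2, n1  # total, successes, draws from set 1
    obs = hypergeom.pmf(x1, M, K, N)
    total = 0.0
    for k in range(max(0, K - n2), min(K, n1) + 1):
        p = hypergeom.pmf(k, M, K, N)
        if p <= obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisher:
    def test_degenerate_zero_table(self):
        assert fisher_exact_two_sided(0, 10, 0, 10) == 1.0

    def test_symmetric_table_is_mode(self):
        assert fisher_exact_two_sided(5, 10, 5, 10) == 1.0

    def test_matches_enumeration_oracle(self):
        assert fisher_exact_two_sided(1, 10, 9, 10) == pytest.approx(
            fisher_oracle(1, 10, 9, 10), abs=1e-12
        )

    @given(
        n1=st.integers(1, 12), n2=st.integers(1, 12),
        data=st.data(),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_enumeration_property(self, n1, n2, data):
        x1 = data.draw(st.integers(0, n1))
        x2 = data.draw(st.integers(0, n2))
        assert fisher_exact_two_sided(x1, n1, x2, n2) == pytest.approx(
            fisher_oracle(x1, n1, x2, n2), abs=1e-9
        )


class TestFisherZConvergence:
    def test_agreement_at_large_cells(self):
        """Exact and normal-approximation p converge as cells grow.

        The probability-mass two-sided Fisher p is conservative relative
        to the pooled z p; the gap falls below 0.01 once the smallest
        occurrence count reaches several hundred at repertoire-scale
        set sizes.
        """
        n = 20_000
        for x1, x2 in [(500, 550), (700, 760), (1000, 1100), (2000, 1900), (5000, 5200)]:
            _, p, *_ = ztest_two_proportions(x1, n, x2, n)
            assert abs(p - fisher_exact_two_sided(x1, n, x2, n)) < 0.01

    def test_fisher_is_conservative_at_small_cells(self):
        """At counts of tens the exact p sits above the z p."""
        for x1, x2 in [(50, 60), (80, 100), (60, 75)]:
            _, p, *_ = ztest_two_proportions(x1, 20_000, x2, 20_000)
            assert fisher_exact_two_sided(x1, 20_000, x2, 20_000) >= p


SM_EQUIV = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "sidakSS": "sidak",
    "sidakSD": "holm-sidak",
    "BH": "fdr_bh",
    "BY": "fdr_by",
}


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for proc in PROCEDURES:
            assert adjust_pvalues([0.037], proc)[0] == pytest.approx(0.037)

    def test_closed_form_examples(self):
        raw = [0.01, 0.02, 0.03]
        assert adjust_pvalues(raw, "BH") == pytest.approx([0.03, 0.03, 0.03])
        assert adjust_pvalues(raw, "bonferroni") == pytest.approx([0.03, 0.06, 0.09])

    def test_empty(self):
        assert adjust_pvalues([], "BH").size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "BH")

    @pytest.mark.parametrize("proc", PROCEDURES)
    def test_matches_statsmodels_reference(self, proc):
        rng = np.random.default_rng(7)
        for _ in range(50):
            raw = rng.uniform(size=rng.integers(2, 60))
            ours = adjust_pvalues(raw, proc)
            ref = multipletests(raw, alpha=0.05, method=SM_EQUIV[proc])[1]
            assert np.max(np.abs(ours - ref)) < 1e-12

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_dominance_properties(self, raw):
        """bonferroni >= sidakSS >= raw; holm >= BH; BY >= BH, elementwise."""
        bonf = adjust_pvalues(raw, "bonferroni")
        sidak = adjust_pvalues(raw, "sidakSS")
        holm = adjust_pvalues(raw, "holm")
        bh = adjust_pvalues(raw, "BH")
        by = adjust_pvalues(raw, "BY")
        raw = np.asarray(raw)
        eps = 1e-12
        assert np.all(bonf >= sidak - eps)
        assert np.all(sidak >= raw - eps)
        assert np.all(holm >= bh - eps)
        assert np.all(by >= bh - eps)
        for adj in (bonf, sidak, holm, bh, by):
            assert np.all(adj >= raw - eps) and np.all(adj <= 1 + eps)


class TestRunComparison:
    def test_method_choice_and_interpretation(self):
        table = make_table(
            {"IGHV4-34": (300, 150), "IGHV9-99": (2, 1), "IGHV1-2": (100, 100)},
            totals=(2000, 2000),
        )
        rows = {r.item: r for r in run_comparison(table)}
        assert rows["IGHV4-34"].method == "z"
        assert rows["IGHV9-99"].method == "fisher" and rows["IGHV9-99"].z is None
        assert "rawp" in rows["IGHV4-34"].interpretation
        assert rows["IGHV1-2"].interpretation == "NS"

    def test_family_spans_tables(self):
        tv = make_table({f"IGHV1-{i}": (50 + i, 50) for i in range(2, 10)}, (2000, 2000))
        tj = make_table({"IGHJ4": (900, 800), "IGHJ6": (700, 750)}, (2000, 2000),
                        gene_type="J")
        rows = run_comparison([tv, tj])
        assert len(rows) == 10
        # joint family: bonferroni multiplies by 10, not by per-table sizes
        r = min(rows, key=lambda r: r.rawp)
        assert r.adj["bonferroni"] == pytest.approx(min(1, 10 * r.rawp))

    def test_single_item_adjustments_equal_raw(self):
        rows = run_comparison(make_table({"IGHV1-2": (100, 120)}, (2000, 2000)))
        r = rows[0]
        for proc in PROCEDURES:
            assert r.adj[proc] == pytest.approx(r.rawp)

    def test_mixed_levels_rejected(self):
        t1 = make_table({"IGHV1-2": (10, 10)}, (100, 100))
        t2 = make_table({"IGHV1-2*01": (10, 10)}, (100, 100), level="allele")
        with pytest.raises(ValueError):
            run_comparison([t1, t2])

    def test_row_invariants(self, small_sets):
        from clonostat.repertoire import count_by_gene

        tables = [count_by_gene(*small_sets, gt) for gt in ("V", "D", "J")]
        for r in run_comparison(tables):
            assert 0 <= r.p1 <= 1 and 0 <= r.p2 <= 1
            assert r.ci_low <= r.diff <= r.ci_high
            assert 0 <= r.rawp <= 1
            for proc in PROCEDURES:
                assert r.rawp - 1e-12 <= r.adj[proc] <= 1 + 1e-12


class TestRejectionCurves:
    def test_monotone_and_bounded(self):
        table = make_table(
            {f"IGHV1-{i}": (60 + 12 * i, 60) for i in range(2, 20)}, (4000, 4000)
        )
        rows = run_comparison(table)
        for curve in rejection_curves(rows):
            assert np.all(np.diff(curve.n_rejected) >= 0)
            assert curve.n_rejected[0] <= curve.n_rejected[-1] <= len(rows)

    def test_alpha_one_rejects_everything(self):
        table = make_table({"IGHV1-2": (50, 60), "IGHV1-3": (70, 78)}, (1000, 1000))
        rows = run_comparison(table)
        curves = rejection_curves(rows, alpha_grid=np.array([1.0]))
        for c in curves:
            assert c.n_rejected[0] == len(rows)

    def test_counts_match_direct_recount(self):
        table = make_table(
            {f"IGHV1-{i}": (60 + 10 * i, 60) for i in range(2, 12)}, (3000, 3000)
        )
        rows = run_comparison(table)
        grid = np.array([0.01, 0.05, 0.2])
        for curve in rejection_curves(rows, alpha_grid=grid):
            for a, n in zip(curve.alphas, curve.n_rejected):
                if curve.procedure == "rawp":
                    expected = sum(r.rawp < a for r in rows)
                else:
                    expected = sum(r.adj[curve.procedure] < a for r in rows)
                assert n == expected


class TestScatterTable:
    def test_neglog10_and_sign(self):
        table = make_table(
            {"IGHV4-34": (300, 150), "IGHV1-8": (150, 300), "IGHV9-99": (2, 1)},
            totals=(2000, 2000),
        )
        rows = run_comparison(table)
        df = scatter_table(rows).set_index("item")
        raw = {r.item: r.rawp for r in rows}
        assert df.loc["IGHV4-34", "neglog10_rawp"] == pytest.approx(
            -math.log10(raw["IGHV4-34"])
        )
        assert df.loc["IGHV4-34", "sign"] == 1
        assert df.loc["IGHV1-8", "sign"] == -1
        assert math.isnan(df.loc["IGHV9-99", "z"])  # fisher rows carry no z

    def test_zero_p_capped(self):
        table = make_table({"IGHV4-34": (1900, 20), "IGHV1-2": (50, 1800)}, (2000, 2000))
        rows = run_comparison(table)
        df = scatter_table(rows)
        assert np.all(np.isfinite(df["neglog10_rawp"]))

    def test_sign_convention_vs_z(self):
        """diff > 0 with raw significance coincides with z > 1.96."""
        rng = np.random.default_rng(3)
        rows = run_comparison(
            make_table(
                {f"IGHV1-{i}": (int(60 + rng.integers(0, 80)), 60) for i in range(2, 30)},
                (5000, 5000),
            )
        )
        for r in rows:
            if r.method == "z" and r.rawp < 0.05:
                assert (r.diff > 0) == (r.z > 1.959)
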