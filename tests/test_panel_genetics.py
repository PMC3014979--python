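"""Allele calling, contingency tests, trios and the diversity regression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from polyq.datasets import panel_gene_summary
from polyq.panel_genetics import (
    AlleleCallError,
    LocusDef,
    allele_table,
    call_allele,
    diversity_regression,
    fisher_exact_rxc,
    genotype_from_peaks,
    mendelian_check,
)

LOCUS = LocusDef("L", 200, 10)


class TestCallAllele:
    def test_reference_size_is_identity(self):
        assert call_allele(200.0, LOCUS) == (10, False)

    def test_on_grid_offset(self):
        assert call_allele(206.2, LOCUS) == (12, False)  # off-grid by 0.2

    def test_off_grid_sets_warning(self):
        assert call_allele(204.6, LOCUS) == (12, True)  # off-grid by 1.4

    def test_half_rounds_away_from_zero(self):
        assert call_allele(201.5, LOCUS)[0] == 11
        assert call_allele(198.5, LOCUS)[0] == 9

    def test_units_below_one_rejected(self):
        with pytest.raises(AlleleCallError):
            call_allele(160.0, LocusDef("S", 190, 2))

    def test_single_peak_called_homozygous(self):
        assert genotype_from_peaks([206.0], LOCUS) == (12, 12, False)

    def test_two_peaks_sorted(self):
        assert genotype_from_peaks([206.0, 200.0], LOCUS)[:2] == (10, 12)


def _panel(rows):
    return pd.DataFrame(
        rows,
        columns=["animalId", "population", "subtype", "locusId", "allele1Units", "allele2Units"],
    )


class TestAlleleTable:
    def test_copy_counting(self):
        panel = _panel(
            [("a1", "p", "s", "L", 10, 10), ("a2", "p", "s", "L", 10, 12)]
        )
        tab = allele_table(panel, "L")
        assert tab.loc[10, "p"] == 3 and tab.loc[12, "p"] == 1

    def test_column_margins_twice_animals(self):
        panel = _panel(
            [("a1", "p", "s", "L", 10, 11), ("a2", "q", "s", "L", 12, 13), ("a3", "q", "s", "L", 12, 12)]
        )
        tab = allele_table(panel, "L")
        assert tab["p"].sum() == 2 and tab["q"].sum() == 4

    def test_unknown_locus_rejected(self):
        with pytest.raises(ValueError):
            allele_table(_panel([("a1", "p", "s", "L", 10, 10)]), "NOPE")


def exact_2x2_oracle(table):
    """Enumerate every 2x2 table with the observed margins directly."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    logden = gammaln(n + 1)
    lognum = (
        gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c1 + 1) + gammaln(n - c1 + 1)
    )

    def logp(x):
        cells = [x, r1 - x, c1 - x, r2 - (c1 - x)]
        if min(cells) < 0:
            return None
        return lognum - logden - sum(gammaln(v + 1) for v in cells)

    lp_obs = logp(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        lp = logp(x)
        if lp is not None and lp <= lp_obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


class TestFisherExact:
    def test_perfect_homogeneity(self):
        assert fisher_exact_rxc([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle_2x2(self, rng):
        for _ in range(20):
            tab = rng.integers(0, 12, size=(2, 2))
            if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                continue
            res = fisher_exact_rxc(tab)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_2x2_oracle(tab), rel=1e-10)

    def test_matches_scipy_2x2(self, rng):
        for _ in range(10):
            tab = rng.integers(1, 15, size=(2, 2))
            assert fisher_exact_rxc(tab).p_value == pytest.approx(
                stats.fisher_exact(tab)[1], rel=1e-9
            )

    def test_montecarlo_agrees_with_exact(self, rng):
        tab = rng.integers(1, 10, size=(5, 2))
        exact = fisher_exact_rxc(tab, max_tables=10**6)
        reps = 100_000
        mc = fisher_exact_rxc(tab, max_tables=1, reps=reps, seed=5)
        assert mc.method == "montecarlo"
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / reps)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 2 / reps

    def test_zero_row_trimmed_with_warning(self):
        with pytest.warns(UserWarning):
            res = fisher_exact_rxc([[3, 4], [0, 0], [5, 1]])
        assert res.table.shape == (2, 2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[0, 0], [0, 0]])


class TestMendelianCheck:
    def _panel(self, genos):
        return _panel_rows(genos)

    def test_consistent_trio_passes(self):
        panel = _panel_rows({"s": (10, 12), "d": (12, 14), "c": (10, 14)})
        out = mendelian_check([("s", "d", "c")], panel, "L")
        assert list(out["status"]) == ["pass"]

    def test_novel_allele_fails(self):
        panel = _panel_rows({"s": (10, 10), "d": (10, 10), "c": (10, 13)})
        out = mendelian_check([("s", "d", "c")], panel, "L")
        assert list(out["status"]) == ["fail"]

    def test_shared_allele_both_parents(self):
        panel = _panel_rows({"s": (10, 12), "d": (12, 14), "c": (12, 12)})
        assert list(mendelian_check([("s", "d", "c")], panel, "L")["status"]) == ["pass"]

    def test_missing_genotype_untested(self):
        panel = _panel_rows({"s": (10, 12), "d": (12, 14)})
        out = mendelian_check([("s", "d", "c")], panel, "L")
        assert list(out["status"]) == ["untested"]


def _panel_rows(genos):
    return _panel(
        [(a, "p", "s", "L", g[0], g[1]) for a, g in genos.items()]
    )


class TestDiversityRegression:
    def test_collinear_points(self):
        res = diversity_regression([(k, 2 * k + 1) for k in range(1, 6)])
        assert res.slope == pytest.approx(2.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_published_pairs_match_closed_form_ols(self):
        genes = panel_gene_summary()
        poly = genes[genes["alleles"] > 1]
        pairs = list(zip(poly["maxPureCag"], poly["alleles"]))
        assert len(pairs) == 16
        res = diversity_regression(pairs)
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=float)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        assert res.slope == pytest.approx(sxy / sxx)
        assert res.intercept == pytest.approx(y.mean() - (sxy / sxx) * x.mean())
        assert res.pearson_r == pytest.approx(sxy / math.sqrt(sxx * syy))
        assert res.pearson_r > 0  # longer pure runs, more alleles

    def test_constant_response_flagged(self):
        res = diversity_regression([(1, 4), (2, 4), (3, 4)])
        assert (res.slope, res.pearson_r, res.flagged) == (0.0, 0.0, True)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            diversity_regression([(2, 1), (2, 2), (2, 3)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            diversity_regression([(1, 1), (2, 2)])
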