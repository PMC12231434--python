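"""Statistical battery against independent oracles.

Oracles: the Kruskal-Wallis rank formula with tie correction computed by
hand; full 2^n sign-pattern enumeration for the Wilcoxon signed-rank exact
p; Pearson-on-midranks for Spearman; an explicit cell-means sum-of-squares
decomposition (and pingouin's mixed ANOVA) for the split-plot ANOVA.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from usvmap import (
    DataError,
    SucroseRecord,
    holm_bonferroni,
    kruskal_wallis,
    rm_anova_strain_by_measurement,
    spearman,
    sucrose_summary,
    wilcoxon_signed_rank,
)


def kw_oracle(groups):
    """H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), midranks, tie-corrected."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    return h / tie


def wilcoxon_enumeration_oracle(diffs):
    """Two-sided exact p by enumerating all sign patterns of |d| ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    n = len(d)
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    ws = np.asarray(ws, dtype=float)
    p_low = (ws <= w_obs + 1e-12).mean()
    p_high = (ws >= w_obs - 1e-12).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestKruskalWallis:
    def test_worked_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic_value == pytest.approx(3.857, abs=5e-4)
        assert res.df[0] == 1

    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic_value == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_matches_rank_formula_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            groups = [rng.integers(0, 6, rng.integers(3, 10)).astype(float) for _ in range(3)]
            if len(np.unique(np.concatenate(groups))) == 1:
                continue
            res = kruskal_wallis(groups)
            assert res.statistic_value == pytest.approx(kw_oracle(groups), abs=1e-10)

    def test_two_groups_equals_mann_whitney_z_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(size=12)  # continuous, tie-free
        u = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
        n1, n2 = len(a), len(b)
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert kruskal_wallis([a, b]).statistic_value == pytest.approx(z**2, rel=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=8), rng.normal(1, 1, size=9)]
        h1 = kruskal_wallis(groups).statistic_value
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic_value
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(DataError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(DataError):
            kruskal_wallis([[1.0], []])


class TestWilcoxon:
    def test_equal_vectors_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.degenerate and res.p_value == 1.0

    def test_all_positive_n5_exact(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert res.p_value == pytest.approx(1 / 16)
        assert res.extra["method"] == "exact"

    def test_exact_matches_enumeration_n8(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            res = wilcoxon_signed_rank(a, b)
            assert res.p_value == pytest.approx(wilcoxon_enumeration_oracle(a - b), abs=1e-12)

    def test_zero_differences_dropped(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [1.0, 1.0, 1.0, 4.0, 5.0, 6.0]  # three zero diffs
        res = wilcoxon_signed_rank(a, b)
        assert res.extra["n_nonzero"] == 2

    def test_large_or_tied_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 4, 30).astype(float)
        b = rng.integers(0, 4, 30).astype(float)
        if np.all(a == b):  # pragma: no cover - seed-stable guard
            a[0] += 1
        res = wilcoxon_signed_rank(a, b)
        assert res.extra["method"] == "approx"
        assert 0 <= res.p_value <= 1


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2.0, 4.0, 4.5, 100.0]).statistic_value == 1.0
        assert spearman(x, [5.0, 1.0, 0.5, -2.0]).statistic_value == -1.0

    def test_tied_data_matches_midrank_pearson_oracle(self):
        x, y = [1.0, 2.0, 2.0, 3.0], [1.0, 2.0, 3.0, 3.0]
        expect = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert spearman(x, y).statistic_value == pytest.approx(expect, abs=1e-12)

    def test_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=25), rng.normal(size=25)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        assert spearman(x, y).statistic_value == pytest.approx(
            np.corrcoef(rx, ry)[0, 1], abs=1e-12
        )

    def test_zero_variance_flagged(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate and np.isnan(res.statistic_value)


def records_from_matrix(y, strains):
    """subjects x 4 matrix -> SucroseRecord list (measurement order fixed)."""
    cells = (("day", "water"), ("night", "water"), ("day", "sucrose"), ("night", "sucrose"))
    recs = []
    for i, (row, g) in enumerate(zip(y, strains)):
        for (phase, fluid), v in zip(cells, row):
            recs.append(SucroseRecord(f"r{i:02d}", g, phase, fluid, float(v)))
    return recs


def rm_anova_ss_oracle(y, strains):
    """Explicit split-plot decomposition from cell means, by direct sums."""
    y = np.asarray(y, dtype=float)
    strains = np.asarray(strains)
    levels = sorted(set(strains))
    n_subj, m = y.shape
    a = len(levels)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_subj = m * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_strain = sum(m * (strains == g).sum() * (y[strains == g].mean() - grand) ** 2 for g in levels)
    ss_meas = n_subj * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_cells = sum(((y[strains == g] - y[strains == g].mean(axis=0)) ** 2).sum() for g in levels)
    ss_inter = ss_total - ss_cells - ss_meas - ss_strain
    df = {"strain": (a - 1, n_subj - a), "meas": (m - 1, (m - 1) * (n_subj - a)),
          "inter": ((a - 1) * (m - 1), (m - 1) * (n_subj - a))}
    ms_err_b = (ss_subj - ss_strain) / df["strain"][1]
    ms_err_w = (ss_total - ss_meas - ss_subj - ss_inter) / df["meas"][1]
    return {
        "strain": (ss_strain / df["strain"][0]) / ms_err_b,
        "measurement": (ss_meas / df["meas"][0]) / ms_err_w,
        "strain_x_measurement": (ss_inter / df["inter"][0]) / ms_err_w,
    }


class TestRmAnova:
    def test_constant_data_all_f_zero(self):
        y = np.full((8, 4), 5.0)
        recs = records_from_matrix(y, ["a"] * 4 + ["b"] * 4)
        for res in rm_anova_strain_by_measurement(recs):
            assert res.statistic_value == 0.0 and res.p_value == 1.0

    def test_known_cell_means_zero_subject_variance(self):
        """With no subject noise the F ratios must match the SS oracle."""
        rng = np.random.default_rng(6)
        cell = np.array([[1.0, 2.0, 8.0, 30.0], [2.0, 2.0, 20.0, 35.0]])
        strains = np.array(["a"] * 6 + ["b"] * 6)
        y = np.vstack([cell[0]] * 6 + [cell[1]] * 6) + rng.normal(0, 0.5, (12, 4))
        recs = records_from_matrix(y, strains)
        oracle = rm_anova_ss_oracle(y, strains)
        for res in rm_anova_strain_by_measurement(recs):
            assert res.statistic_value == pytest.approx(oracle[res.name], abs=1e-8)

    @pytest.mark.parametrize("ns", [(6, 6), (5, 9)])
    def test_matches_pingouin_mixed_anova(self, ns):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        n = sum(ns)
        y = rng.normal(10, 2, (n, 4)) + rng.normal(0, 1.5, (n, 1))
        strains = np.array(["a"] * ns[0] + ["b"] * ns[1])
        ours = {r.name: r for r in rm_anova_strain_by_measurement(records_from_matrix(y, strains))}
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 4),
                "group": np.repeat(strains, 4),
                "meas": np.tile(np.arange(4), n),
                "y": y.ravel(),
            }
        )
        aov = pg.mixed_anova(data=long, dv="y", within="meas", subject="subject",
                             between="group", correction=False).set_index("Source")
        for label, src in (("strain", "group"), ("measurement", "meas"),
                           ("strain_x_measurement", "Interaction")):
            assert ours[label].statistic_value == pytest.approx(aov.loc[src, "F"], abs=1e-8)
            assert ours[label].p_value == pytest.approx(aov.loc[src, "p_unc"], abs=1e-8)
            assert ours[label].df == (aov.loc[src, "DF1"], aov.loc[src, "DF2"])

    def test_ss_decomposition_identity(self):
        rng = np.random.default_rng(8)
        y = rng.normal(10.0, 2.0, size=(11, 4))
        strains = np.array(["a"] * 5 + ["b"] * 6)
        results = {r.name: r for r in rm_anova_strain_by_measurement(records_from_matrix(y, strains))}
        ss_total = ((y - y.mean()) ** 2).sum()
        parts = (
            results["strain"].extra["ss_effect"]
            + results["strain"].extra["ss_error"]
            + results["measurement"].extra["ss_effect"]
            + results["strain_x_measurement"].extra["ss_effect"]
            + results["measurement"].extra["ss_error"]
        )
        assert parts == pytest.approx(ss_total, abs=1e-8)

    def test_incomplete_rat_excluded(self, caplog):
        y = np.random.default_rng(9).normal(10.0, 2.0, size=(6, 4))
        recs = records_from_matrix(y, ["a"] * 3 + ["b"] * 3)
        recs = [r for r in recs if not (r.rat_id == "r00" and r.fluid == "water" and r.phase == "day")]
        with caplog.at_level("WARNING"):
            results = rm_anova_strain_by_measurement(recs)
        assert "excluded" in caplog.text
        assert results[0].n_per_group == (2, 3)

    def test_greenhouse_geisser_option(self):
        """GG epsilon lies in [1/(m-1), 1] and the corrected p is never
        smaller than the uncorrected one."""
        rng = np.random.default_rng(10)
        y = rng.normal(10, 2, (12, 4)) * np.array([1.0, 1.0, 3.0, 0.3])  # break sphericity
        y = np.abs(y)
        recs = records_from_matrix(y, ["a"] * 6 + ["b"] * 6)
        res = {r.name: r for r in rm_anova_strain_by_measurement(recs, gg=True)}
        eps = res["measurement"].extra["eps_gg"]
        assert 1 / 3 <= eps <= 1.0
        for name in ("measurement", "strain_x_measurement"):
            assert res[name].extra["p_gg"] >= res[name].p_value - 1e-12
        assert "p_gg" not in res["strain"].extra

    def test_pure_subject_offsets_give_zero_measurement_f(self):
        offsets = np.arange(10, dtype=float).reshape(-1, 1)
        y = np.tile(offsets, (1, 4))
        recs = records_from_matrix(y, ["a"] * 5 + ["b"] * 5)
        res = {r.name: r for r in rm_anova_strain_by_measurement(recs)}
        assert res["measurement"].statistic_value == pytest.approx(0.0, abs=1e-10)


class TestSucroseSummary:
    def test_preference_arithmetic(self):
        recs = [
            SucroseRecord("r1", "g", "day", "sucrose", 20.1),
            SucroseRecord("r1", "g", "day", "water", 2.5),
        ]
        row = sucrose_summary(recs).per_rat.iloc[0]
        assert row["preference"] == pytest.approx(20.1 / 22.6, abs=1e-9)

    def test_limit_cases(self):
        even = sucrose_summary(
            [SucroseRecord("r", "g", "day", "sucrose", 3.0), SucroseRecord("r", "g", "day", "water", 3.0)]
        ).per_rat
        assert even["preference"].iloc[0] == 0.5
        full = sucrose_summary(
            [SucroseRecord("r", "g", "day", "sucrose", 3.0), SucroseRecord("r", "g", "day", "water", 0.0)]
        ).per_rat
        assert full["preference"].iloc[0] == 1.0

    def test_zero_total_intake_flagged_nan(self):
        recs = [
            SucroseRecord("r", "g", "day", "sucrose", 0.0),
            SucroseRecord("r", "g", "day", "water", 0.0),
        ]
        assert np.isnan(sucrose_summary(recs).per_rat["preference"].iloc[0])

    def test_group_mean_sem(self):
        recs = [SucroseRecord(f"r{i}", "g", "day", "sucrose", v) for i, v in enumerate([1.0, 2.0, 3.0])]
        g = sucrose_summary(recs).group
        assert g["mean"].iloc[0] == pytest.approx(2.0)
        assert g["sem"].iloc[0] == pytest.approx(1.0 / np.sqrt(3))


def test_holm_adjustment_monotone_and_bounded():
    adj = holm_bonferroni([0.01, 0.04, 0.03, 0.5])
    assert adj == pytest.approx([0.04, 0.09, 0.09, 0.5])
    assert all(0 <= p <= 1 for p in holm_bonferroni([0.9, 0.95, 0.99]))
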