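"""ANOVA, FDR, PCA, conservation classes, and Fisher over-representation."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossmask import (
    ChipLayout,
    ExpressionMatrix,
    ParameterError,
    ProbeMask,
    SampleDesign,
    anova_de,
    classify_conservation,
    fisher_overrep,
    pca_overview,
)


def _expr_from_groups(groups: dict[str, np.ndarray], design: SampleDesign) -> ExpressionMatrix:
    """Build an ExpressionMatrix with per-tissue value blocks (3 reps each)."""
    frame = pd.DataFrame(
        np.column_stack([groups[t] for t in design.tissues()]),
        columns=design.sample_ids,
    )
    frame.index = [f"G{i}" for i in range(len(frame))]
    return ExpressionMatrix(frame, design, pd.Series(11, index=frame.index))


class TestAnovaDE:
    def test_printed_toy_groups_f_three(self, balanced_design):
        """Groups (1,2,3), (2,3,4), (3,4,5): MSB = 3, MSW = 1, F = 3 on (2, 6) df."""
        expr = _expr_from_groups(
            {
                "nodule": np.array([[1.0, 2.0, 3.0]]),
                "leaf": np.array([[2.0, 3.0, 4.0]]),
                "root": np.array([[3.0, 4.0, 5.0]]),
            },
            balanced_design,
        )
        table = anova_de(expr)
        assert table["f_statistic"].iloc[0] == pytest.approx(3.0)
        f_oracle, p_oracle = stats.f_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert table["f_statistic"].iloc[0] == pytest.approx(f_oracle)
        assert table["p_value"].iloc[0] == pytest.approx(p_oracle)

    def test_equal_means_not_significant(self, balanced_design):
        expr = _expr_from_groups(
            {
                "nodule": np.array([[1.0, 2.0, 3.0]]),
                "leaf": np.array([[3.0, 1.0, 2.0]]),
                "root": np.array([[2.0, 3.0, 1.0]]),
            },
            balanced_design,
        )
        table = anova_de(expr)
        assert table["f_statistic"].iloc[0] == pytest.approx(0.0)
        assert not table["significant"].iloc[0]

    def test_shift_invariance_and_tissue_relabeling(self, rng, balanced_design):
        vals = rng.normal(8, 1, size=(30, 9))
        frame = pd.DataFrame(vals, index=[f"G{i}" for i in range(30)],
                             columns=balanced_design.sample_ids)
        expr = ExpressionMatrix(frame, balanced_design, pd.Series(11, index=frame.index))
        base = anova_de(expr)
        shifted = ExpressionMatrix(frame + 5.0, balanced_design,
                                   pd.Series(11, index=frame.index))
        np.testing.assert_allclose(
            anova_de(shifted)["f_statistic"], base["f_statistic"], rtol=1e-9
        )
        relabeled_table = balanced_design.table.copy()
        relabeled_table["tissue"] = relabeled_table["tissue"].map(
            {"nodule": "root", "leaf": "nodule", "root": "leaf"}
        )
        relabeled = ExpressionMatrix(
            frame, SampleDesign(relabeled_table), pd.Series(11, index=frame.index)
        )
        np.testing.assert_allclose(
            anova_de(relabeled)["f_statistic"], base["f_statistic"], rtol=1e-9
        )

    def test_planted_de_matches_reimplementation(self, rng, balanced_design):
        n = 200
        vals = rng.normal(8, 0.3, size=(n, 9))
        de_rows = rng.choice(n, 30, replace=False)
        vals[de_rows, 0:3] += 2.0  # nodule shift
        frame = pd.DataFrame(vals, index=[f"G{i}" for i in range(n)],
                             columns=balanced_design.sample_ids)
        expr = ExpressionMatrix(frame, balanced_design, pd.Series(11, index=frame.index))
        table = anova_de(expr, p_cut=1e-4, fold_cut=2, fdr_cut=0.0015)
        # independent recount with scipy + direct BH + fold filter
        ps, fs = [], []
        for i in range(n):
            f, p = stats.f_oneway(vals[i, 0:3], vals[i, 3:6], vals[i, 6:9])
            ps.append(p)
            fs.append(f)
        ps = np.array(ps)
        order = np.argsort(ps)
        fdr = np.empty(n)
        prev = 1.0
        for rank, idx in enumerate(order[::-1]):
            k = n - rank
            prev = min(prev, ps[idx] * n / k)
            fdr[idx] = prev
        sig_oracle = set()
        for i in range(n):
            means = [vals[i, 0:3].mean(), vals[i, 3:6].mean(), vals[i, 6:9].mean()]
            max_ratio = max(
                abs(means[a] - means[b]) for a in range(3) for b in range(a + 1, 3)
            )
            if ps[i] < 1e-4 and fdr[i] < 0.0015 and max_ratio >= 1.0:
                sig_oracle.add(f"G{i}")
        np.testing.assert_allclose(table["f_statistic"], fs, rtol=1e-8)
        np.testing.assert_allclose(table["fdr"], fdr, rtol=1e-10)
        assert set(table.index[table["significant"]]) == sig_oracle

    def test_pathogen_probe_sets_excluded(self, balanced_design, tiny_layout):
        frame = pd.DataFrame(
            np.random.default_rng(0).normal(8, 1, size=(3, 9)),
            index=["PSA", "PSB", "PSC"],
            columns=balanced_design.sample_ids,
        )
        expr = ExpressionMatrix(frame, balanced_design, pd.Series(3, index=frame.index))
        table = anova_de(expr, layout=tiny_layout)
        assert "PSC" not in table.index  # Phytophthora sojae control
        assert {"PSA", "PSB"} == set(table.index)


class TestPCA:
    def test_explained_fractions_sum_to_one(self, rng, balanced_design):
        frame = pd.DataFrame(rng.normal(8, 2, size=(50, 9)),
                             columns=balanced_design.sample_ids)
        frame.index = [f"G{i}" for i in range(50)]
        expr = ExpressionMatrix(frame, balanced_design, pd.Series(11, index=frame.index))
        res = pca_overview(expr)
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-10)

    def test_two_samples_pc1_explains_all(self, balanced_design):
        design = SampleDesign(balanced_design.table.iloc[:2])
        frame = pd.DataFrame(
            np.random.default_rng(1).normal(8, 2, size=(20, 2)),
            columns=design.sample_ids,
        )
        frame.index = [f"G{i}" for i in range(20)]
        expr = ExpressionMatrix(frame, design, pd.Series(11, index=frame.index))
        res = pca_overview(expr, n_components=1)
        assert res.explained[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng, balanced_design):
        frame = pd.DataFrame(rng.normal(0, 1, size=(50, 9)),
                             columns=balanced_design.sample_ids)
        frame.index = [f"G{i}" for i in range(50)]
        expr = ExpressionMatrix(frame, balanced_design, pd.Series(11, index=frame.index))
        res = pca_overview(expr)
        x = frame.to_numpy().T
        xc = x - x.mean(axis=0)
        eigvals = np.linalg.eigvalsh(xc @ xc.T)[::-1]
        fractions = eigvals[: len(res.explained)] / eigvals.sum()
        np.testing.assert_allclose(res.explained, np.abs(fractions), atol=1e-8)

    def test_scores_orthogonal(self, rng, balanced_design):
        frame = pd.DataFrame(rng.normal(0, 1, size=(40, 9)),
                             columns=balanced_design.sample_ids)
        frame.index = [f"G{i}" for i in range(40)]
        expr = ExpressionMatrix(frame, balanced_design, pd.Series(11, index=frame.index))
        res = pca_overview(expr, n_components=4)
        gram = res.scores.to_numpy().T @ res.scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestClassifyConservation:
    def test_exhaustive_retained_sweep(self):
        """All retained counts 0..11 map to the documented piecewise classes."""
        k = 11
        pm = {f"G{r}": [f"G{r}:{i:02d}" for i in range(1, k + 1)] for r in range(k + 1)}
        layout = ChipLayout(pm)
        masked = set()
        for r in range(k + 1):  # gene G{r} retains exactly r probes
            masked.update(pm[f"G{r}"][: k - r])
        table = classify_conservation(
            ProbeMask(frozenset(masked), 80.0, "Pv", 7 / 9), layout
        )
        expected = {
            0: "all_masked", 1: "hyper_variable", 2: "hyper_variable",
            **{r: "intermediate" for r in range(3, 10)},
            10: "highly_conserved", 11: "highly_conserved",
        }
        for r, group in expected.items():
            assert table.loc[f"G{r}", "group"] == group
            assert table.loc[f"G{r}", "retained"] == r
        active = table[table["group"] != "all_masked"]
        assert set(active["group"]) == {
            "hyper_variable", "intermediate", "highly_conserved"
        }

    def test_invalid_cutoffs_rejected(self, tiny_layout):
        with pytest.raises(ParameterError):
            classify_conservation(ProbeMask.empty(), tiny_layout, hi_min=2, hyper_max=2)


class TestFisherOverrep:
    def test_worked_hypergeometric_tail(self):
        """Universe 20, class 5 fully inside a selection of 10.

        One-sided tail = C(15,5)/C(20,10) = 3003/184756; the two-sided p
        sums point masses no larger than the observed one.
        """
        universe = {f"g{i}" for i in range(20)}
        cls = {f"g{i}" for i in range(5)}
        selection = {f"g{i}" for i in range(10)}
        table = fisher_overrep(selection, {g: ["C1"] for g in cls}, universe)
        row = table.loc["C1"]
        tail = comb(15, 5) / comb(20, 10)
        assert tail == pytest.approx(3003 / 184756)
        # enumeration oracle for the two-sided p: sum of P(X = x) <= P(X = 5)
        rv = stats.hypergeom(20, 5, 10)
        p_obs = rv.pmf(5)
        p_two = sum(rv.pmf(x) for x in range(6) if rv.pmf(x) <= p_obs * (1 + 1e-9))
        assert row["fisher_p"] == pytest.approx(p_two, rel=1e-9)
        assert row["direction"] == "over"
        assert row["z_value"] > 0

    def test_enumeration_over_random_small_tables(self, rng):
        """Two-sided Fisher p equals the hypergeometric point-mass sum."""
        for _ in range(20):
            n_universe = int(rng.integers(10, 50))
            universe = {f"g{i}" for i in range(n_universe)}
            k = int(rng.integers(1, n_universe))
            cls = set(rng.choice(sorted(universe), size=k, replace=False))
            m = int(rng.integers(1, n_universe))
            selection = set(rng.choice(sorted(universe), size=m, replace=False))
            table = fisher_overrep(selection, {g: ["C"] for g in cls}, universe)
            rv = stats.hypergeom(n_universe, len(cls), len(selection))
            p_obs = rv.pmf(len(cls & selection))
            support = range(max(0, len(cls) + len(selection) - n_universe),
                            min(len(cls), len(selection)) + 1)
            p_two = sum(rv.pmf(x) for x in support if rv.pmf(x) <= p_obs * (1 + 1e-9))
            assert table.loc["C", "fisher_p"] == pytest.approx(min(1.0, p_two), rel=1e-7)

    def test_empty_selection_flags_nothing(self):
        universe = {f"g{i}" for i in range(10)}
        table = fisher_overrep(set(), {"g0": ["C"], "g1": ["C"]}, universe)
        assert not table["flagged"].any()

    def test_complement_flips_direction_preserves_p(self, rng):
        universe = {f"g{i}" for i in range(30)}
        cls = {f"g{i}" for i in range(8)}
        selection = {f"g{i}" for i in range(4, 16)}
        a = fisher_overrep(selection, {g: ["C"] for g in cls}, universe)
        b = fisher_overrep(universe - selection, {g: ["C"] for g in cls}, universe)
        assert a.loc["C", "fisher_p"] == pytest.approx(b.loc["C", "fisher_p"])
        assert a.loc["C", "direction"] != b.loc["C", "direction"]

    def test_bonferroni_over_classes(self):
        universe = {f"g{i}" for i in range(40)}
        class_map = {f"g{i}": [f"C{i % 4}"] for i in range(40)}
        selection = {f"g{i}" for i in range(10)}
        table = fisher_overrep(selection, class_map, universe)
        assert len(table) == 4
        np.testing.assert_allclose(
            table["bonferroni_p"], np.minimum(1.0, table["fisher_p"] * 4)
        )
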