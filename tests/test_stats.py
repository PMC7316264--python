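"""ANOVA engine, p-value kernels, FDR and the edge-wise scan."""

import numpy as np
import pandas as pd
import pytest

from rsconn.stats import (
    bh_fdr,
    edgewise_scan,
    mixed_anova_2x2,
    mixed_anova_arrays,
    network_metric_anova,
    p_from_f,
    p_from_t,
    posthoc_edge,
)
from tests.conftest import functional_from, make_labels
from tests.oracles import splitplot_anova_balanced


class TestPValueKernels:
    @pytest.mark.parametrize(
        "t,df,expected",
        [(2.34, 13, 0.036), (2.91, 24, 0.008), (0.0, 10, 1.0)],
    )
    def test_t_kernel(self, t, df, expected):
        assert p_from_t(t, df) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "F,df,expected",
        [(5.93, (1, 24), 0.023), (7.99, (1, 24), 0.009), (0.0, (2, 30), 1.0)],
    )
    def test_f_kernel(self, F, df, expected):
        assert p_from_f(F, *df) == pytest.approx(expected, abs=5e-4)

    def test_f_equals_squared_t_for_df1_one(self):
        for t in np.linspace(0.1, 5.0, 25):
            for df in (2, 5, 13, 24, 100):
                assert p_from_f(t**2, 1, df) == pytest.approx(
                    p_from_t(t, df), abs=1e-10
                )

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            p_from_t(1.0, 0)
        with pytest.raises(ValueError):
            p_from_f(1.0, 0, 10)


def long_format(y1, y2, g1):
    rows = []
    for i in range(len(y1)):
        group = "group1" if g1[i] else "group2"
        rows.append(dict(subject=f"s{i}", group=group, timepoint="tp1", value=y1[i]))
        rows.append(dict(subject=f"s{i}", group=group, timepoint="tp2", value=y2[i]))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_constant_data_gives_zero_f_unit_p(self):
        y = np.full(10, 3.0)
        res = mixed_anova_2x2(long_format(y, y, np.arange(10) < 5))
        assert res.F_group == res.F_time == res.F_interaction == 0.0
        assert res.p_group == res.p_time == res.p_interaction == 1.0

    def test_planted_interaction_dominates(self):
        rng = np.random.default_rng(0)
        g1 = np.arange(12) < 6
        y1 = rng.normal(size=12) * 1e-3
        y2 = y1 + np.where(g1, -0.5, 0.0)
        res = mixed_anova_2x2(long_format(y1, y2, g1))
        assert res.F_interaction > 1e4
        assert res.p_interaction < 1e-10

    def test_interaction_equals_squared_change_score_t(self):
        """Algebraic identity, checked over 100 random unbalanced designs."""
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        for _ in range(100):
            n1, n2 = rng.integers(3, 12, size=2)
            y1 = rng.normal(size=n1 + n2)
            y2 = rng.normal(size=n1 + n2)
            g1 = np.arange(n1 + n2) < n1
            res = mixed_anova_arrays(y1, y2, g1)
            d = y2 - y1
            t, _ = sps.ttest_ind(d[g1], d[~g1], equal_var=True)
            assert float(res["F_interaction"]) == pytest.approx(t**2, abs=1e-8)

    def test_matches_cell_means_oracle_on_balanced_designs(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(3, 10))
            y1 = rng.normal(size=2 * n)
            y2 = rng.normal(size=2 * n)
            g1 = np.arange(2 * n) < n
            res = mixed_anova_arrays(y1, y2, g1)
            Fa, Fb, Fab = splitplot_anova_balanced(y1, y2, g1)
            assert float(res["F_group"]) == pytest.approx(Fa, rel=1e-8)
            assert float(res["F_time"]) == pytest.approx(Fb, rel=1e-8)
            assert float(res["F_interaction"]) == pytest.approx(Fab, rel=1e-8)

    def test_group_and_interaction_match_pingouin_unbalanced(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        for _ in range(10):
            n1, n2 = rng.integers(3, 10, size=2)
            y1 = rng.normal(size=n1 + n2)
            y2 = rng.normal(size=n1 + n2)
            g1 = np.arange(n1 + n2) < n1
            res = mixed_anova_arrays(y1, y2, g1)
            aov = pg.mixed_anova(
                data=long_format(y1, y2, g1),
                dv="value",
                within="timepoint",
                subject="subject",
                between="group",
            ).set_index("Source")
            assert float(res["F_group"]) == pytest.approx(aov.loc["group", "F"], rel=1e-8)
            assert float(res["F_interaction"]) == pytest.approx(
                aov.loc["Interaction", "F"], rel=1e-8
            )

    def test_missing_timepoint_is_an_error(self):
        df = long_format(np.zeros(6), np.zeros(6), np.arange(6) < 3)
        df = df.drop(df[(df.subject == "s2") & (df.timepoint == "tp2")].index)
        with pytest.raises(ValueError, match="incomplete"):
            mixed_anova_2x2(df)

    def test_single_subject_group_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            mixed_anova_arrays(np.zeros(3), np.zeros(3), np.array([True, False, False]))


class TestBhFdr:
    def test_hand_executed_step_up(self):
        flags = bh_fdr([0.001, 0.02, 0.03, 0.04, 0.2], q=0.05)
        assert flags.tolist() == [True, True, True, True, False]

    def test_all_unit_pvalues_reject_nothing(self):
        assert not bh_fdr(np.ones(50), 0.05).any()

    def test_single_pvalue_reduces_to_raw_threshold(self):
        assert bh_fdr([0.04], 0.05).tolist() == [True]
        assert bh_fdr([0.06], 0.05).tolist() == [False]

    def test_contains_bonferroni_rejections(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(0, 0.2, size=40)
            bh = bh_fdr(p, 0.05)
            bonf = p <= 0.05 / len(p)
            assert (bh | ~bonf).all()  # bonferroni set is a subset

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], 0.05)
        with pytest.raises(ValueError):
            bh_fdr([0.5], 0.0)


class TestPosthoc:
    def test_identical_timepoints_give_null_paired_test(self):
        y = np.arange(8.0)
        out = posthoc_edge(y, y, np.arange(8) < 4)
        assert out["paired_group1"]["t"] == 0.0
        assert out["paired_group1"]["p"] == 1.0

    def test_planted_group1_change_detected(self):
        rng = np.random.default_rng(5)
        g1 = np.arange(12) < 6
        y1 = rng.normal(size=12) * 0.01
        y2 = y1 + np.where(g1, -0.4, 0.0) + rng.normal(size=12) * 0.01
        out = posthoc_edge(y1, y2, g1)
        assert out["paired_group1"]["p"] < 0.01
        assert out["paired_group2"]["p"] > 0.05

    def test_paired_t_matches_hand_arithmetic(self):
        """4 subjects in group1 with known differences."""
        y1 = np.array([1.0, 2.0, 3.0, 4.0, 0.0, 0.0])
        diffs = np.array([0.5, 0.1, 0.3, 0.7])
        y2 = y1.copy()
        y2[:4] += diffs
        out = posthoc_edge(y1, y2, np.arange(6) < 4)
        expected_t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(4))
        assert out["paired_group1"]["t"] == pytest.approx(expected_t, abs=1e-10)
        assert out["paired_group1"]["df"] == 3


def cohort_of_matrices(n_rois, n1, n2, rng, planted=None, delta=0.0):
    """Fisher-z matrices with i.i.d. noise and an optional planted change."""
    labels = make_labels(n_rois)
    subjects = {f"s{i}": ("group1" if i < n1 else "group2") for i in range(n1 + n2)}
    functional = {}
    for i, sid in enumerate(subjects):
        for tp in ("tp1", "tp2"):
            z = rng.normal(0, 0.1, size=(n_rois, n_rois))
            if planted and tp == "tp2" and i < n1:
                for a, b in planted:
                    z[a, b] += delta
                    z[b, a] += delta
            functional[(sid, tp)] = functional_from(z)
    return functional, subjects


class TestEdgewiseScan:
    def test_df_matches_cohort_sizes(self):
        rng = np.random.default_rng(6)
        functional, subjects = cohort_of_matrices(6, 14, 12, rng)
        res = edgewise_scan(functional, subjects, q=0.05)
        assert res.df == (1, 24)
        assert res.summary["n_edges_tested"] == 15

    def test_huge_effect_on_one_edge_is_the_only_component(self):
        rng = np.random.default_rng(7)
        functional, subjects = cohort_of_matrices(
            8, 6, 6, rng, planted=[(2, 5)], delta=-3.0
        )
        res = edgewise_scan(functional, subjects, q=0.05)
        flagged = res.table[res.table.fdr_flag]
        assert len(flagged) == 1
        assert {flagged.iloc[0].node1, flagged.iloc[0].node2} == {"roi02", "roi05"}
        assert res.components == [
            {"nodes": ["roi02", "roi05"], "n_nodes": 2, "n_edges": 1}
        ]

    def test_edge_mask_restricts_family(self):
        rng = np.random.default_rng(8)
        functional, subjects = cohort_of_matrices(6, 4, 4, rng)
        mask = np.zeros((6, 6), dtype=int)
        mask[0, 1] = mask[1, 0] = mask[2, 3] = mask[3, 2] = 1
        res = edgewise_scan(functional, subjects, q=0.05, edge_mask=mask)
        assert res.summary["n_edges_tested"] == 2

    def test_posthoc_columns_present_for_flagged_edges(self):
        rng = np.random.default_rng(9)
        functional, subjects = cohort_of_matrices(
            6, 6, 6, rng, planted=[(0, 1)], delta=-2.0
        )
        res = edgewise_scan(functional, subjects, q=0.05)
        row = res.table[res.table.fdr_flag].iloc[0]
        assert row["p_paired_group1"] < 0.05
        assert np.isfinite(row["t_unpaired_tp2"])


class TestNetworkMetricAnova:
    def _table(self, rng, delta=0.0):
        rows = []
        for i in range(12):
            group = "group1" if i < 6 else "group2"
            for tp in ("tp1", "tp2"):
                for net in ("VAN", "DAN"):
                    val = rng.normal() * 0.05
                    if net == "VAN" and group == "group1" and tp == "tp2":
                        val += delta
                    rows.append(
                        dict(
                            subject=f"s{i}",
                            group=group,
                            timepoint=tp,
                            network=net,
                            strength=val,
                            e_glob=val / 2,
                            e_loc=val / 3,
                        )
                    )
        return pd.DataFrame(rows)

    def test_six_analyses_per_run(self):
        rng = np.random.default_rng(10)
        table = self._table(rng)
        results = [
            network_metric_anova(table, metric, net)
            for net in ("VAN", "DAN")
            for metric in ("strength", "e_glob", "e_loc")
        ]
        assert len(results) == 6

    def test_constant_metric_gives_unit_p(self):
        table = self._table(np.random.default_rng(11))
        table["strength"] = 1.0
        res = network_metric_anova(table, "strength", "VAN")
        assert res["anova"].p_interaction == 1.0

    def test_planted_van_decrease_detected(self):
        table = self._table(np.random.default_rng(12), delta=-0.5)
        van = network_metric_anova(table, "strength", "VAN")
        dan = network_metric_anova(table, "strength", "DAN")
        assert van["anova"].p_interaction < 0.001
        assert dan["anova"].p_interaction > 0.05
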