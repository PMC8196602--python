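"""Two-group testing, BH FDR, thresholds, and gene collapse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cnitflow as cf
from cnitflow.differential import (
    apply_thresholds,
    bh_fdr,
    collapse_to_genes,
    probeset_test,
    run_contrast,
)
from cnitflow.types import (
    ContrastResult,
    ExpressionMatrix,
    ProbeAnnotation,
    Thresholds,
    ValidationError,
)


def _matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix("mRNA", pd.DataFrame(values, index=probes, columns=samples))


def bh_oracle(p):
    """Direct min-over-tails evaluation of the BH step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = np.inf
    for i in range(m - 1, -1, -1):
        running_min = min(running_min, m * p[order[i]] / (i + 1))
        q[order[i]] = min(running_min, 1.0)
    return q


class TestProbesetTest:
    def test_identical_groups_null(self):
        m = _matrix([[2, 2, 2, 2]], samples=["a", "b", "c", "d"])
        res = probeset_test(m, ["a", "b"], ["c", "d"])
        row = res.data.iloc[0]
        assert row["p_value"] == 1.0
        assert row["mean_log2_diff"] == 0.0

    def test_four_point_closed_form_matches_scipy(self):
        # group1 = {2, 4}, group2 = {1, 3}
        m = _matrix([[2, 4, 1, 3]], samples=["a", "b", "c", "d"])
        res = probeset_test(m, ["a", "b"], ["c", "d"])
        t_ref, p_ref = stats.ttest_ind([2, 4], [1, 3], equal_var=True)
        assert res.data.iloc[0]["t_statistic"] == pytest.approx(t_ref)
        assert res.data.iloc[0]["p_value"] == pytest.approx(p_ref)
        assert res.data.iloc[0]["mean_log2_diff"] == pytest.approx(1.0)

    def test_vectorised_agrees_with_scipy_across_probes(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(8, 1, size=(50, 10))
        m = _matrix(vals)
        g1, g2 = m.sample_ids[:5], m.sample_ids[5:]
        res = probeset_test(m, g1, g2)
        t_ref, p_ref = stats.ttest_ind(vals[:, :5], vals[:, 5:], axis=1, equal_var=True)
        assert np.allclose(res.data["t_statistic"], t_ref)
        assert np.allclose(res.data["p_value"], p_ref)

    def test_welch_agrees_with_scipy(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(8, 1, size=(20, 9))
        m = _matrix(vals)
        g1, g2 = m.sample_ids[:4], m.sample_ids[4:]
        res = probeset_test(m, g1, g2, welch=True)
        t_ref, p_ref = stats.ttest_ind(vals[:, :4], vals[:, 4:], axis=1, equal_var=False)
        assert np.allclose(res.data["t_statistic"], t_ref)
        assert np.allclose(res.data["p_value"], p_ref)

    def test_zero_variance_unequal_means(self):
        m = _matrix([[1, 1, 2, 2]], samples=["a", "b", "c", "d"])
        res = probeset_test(m, ["a", "b"], ["c", "d"])
        assert res.data.iloc[0]["p_value"] == 0.0

    def test_planted_shift_yields_tiny_p(self):
        # shift 1.0 log2 unit, n = 12 vs 12, sigma = 0.3
        rng = np.random.default_rng(1)
        n_probes = 1000
        base = rng.normal(8, 1.5, size=n_probes)
        g1 = base[:, None] + 1.0 + rng.normal(0, 0.3, size=(n_probes, 12))
        g2 = base[:, None] + rng.normal(0, 0.3, size=(n_probes, 12))
        m = _matrix(np.hstack([g1, g2]))
        res = probeset_test(m, m.sample_ids[:12], m.sample_ids[12:])
        assert np.median(res.data["p_value"]) < 0.001

    @pytest.mark.parametrize(
        "g1,g2,msg",
        [(["a"], ["c", "d"], ">= 2"), (["a", "b"], ["b", "c"], "overlap"), (["a", "x"], ["c", "d"], "not in matrix")],
    )
    def test_bad_groups_rejected(self, g1, g2, msg):
        m = _matrix([[1, 2, 3, 4]], samples=["a", "b", "c", "d"])
        with pytest.raises(ValidationError, match=msg):
            probeset_test(m, g1, g2)

    def test_label_swap_negates_effect_keeps_p(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(8, 1, size=(30, 8)))
        g1, g2 = m.sample_ids[:4], m.sample_ids[4:]
        r12 = probeset_test(m, g1, g2)
        r21 = probeset_test(m, g2, g1)
        assert np.allclose(r12.data["mean_log2_diff"], -r21.data["mean_log2_diff"])
        assert np.allclose(r12.data["p_value"], r21.data["p_value"])
        flipped = r12.data["direction"].map({"up": "down", "down": "up"})
        assert (flipped == r21.data["direction"]).all()


class TestBHFdr:
    def test_all_equal_p(self):
        assert np.allclose(bh_fdr([0.03] * 5), 0.03)

    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_oracle_equivalence_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.integers(0, 10**6))
    def test_permutation_equivariance(self, p, seed):
        p = np.asarray(p)
        perm = np.random.default_rng(seed).permutation(len(p))
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestApplyThresholds:
    def _result(self, p, q, diff):
        df = pd.DataFrame(
            {
                "mean_log2_diff": diff,
                "t_statistic": 0.0,
                "p_value": p,
                "q_value": q,
                "fold_change": np.exp2(diff),
                "direction": np.where(np.asarray(diff) > 0, "up", "down"),
                "passes": False,
            },
            index=[f"p{i}" for i in range(len(p))],
        )
        return ContrastResult("c", "mRNA", df)

    def test_boundary_semantics(self):
        # p strictly below, q and FC at the boundary -> passes
        res = self._result([0.0009], [0.05], [np.log2(1.5)])
        out = apply_thresholds(res, Thresholds.mrna())
        # apply_thresholds recomputes q from p; with one p, q = p < 0.05
        assert bool(out.data.iloc[0]["passes"])

    def test_p_exactly_at_cutoff_fails(self):
        res = self._result([0.001], [0.001], [2.0])
        out = apply_thresholds(res, Thresholds.mrna())
        assert not bool(out.data.iloc[0]["passes"])

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        n = 300
        res = self._result(
            rng.uniform(0, 0.01, n), np.zeros(n), rng.normal(0, 1.2, n)
        )
        tight = apply_thresholds(res, Thresholds(p_cutoff=0.001, fc_cutoff=1.5))
        loose = apply_thresholds(res, Thresholds(p_cutoff=0.005, fc_cutoff=1.2))
        assert set(tight.passing.index) <= set(loose.passing.index)

    def test_planted_recovery_rate(self):
        # 200 planted effects (delta 1.2, sigma 0.3, n 11 vs 12) among 2000 probesets
        cohort = cf.generate_cohort(cf.GeneratorConfig(seed=7))
        rep = cf.qc_report(cohort.matrix, cohort.annotation)
        filtered, _ = cf.apply_qc(cohort.matrix, rep)
        norm = cf.quantile_normalize(filtered)
        g1 = [s for s in cohort.samples.samples("CNIT", "mRNA") if s in norm.data.columns]
        g2 = cohort.samples.samples("Normal", "mRNA")
        assert (len(g1), len(g2)) == (11, 12)
        res = run_contrast(norm, g1, g2, Thresholds.mrna(), "CNIT_vs_Normal")
        planted = cohort.truth.loc[cohort.truth["condition"] == "CNIT", "probeset_id"]
        assert res.data.loc[planted, "passes"].mean() >= 0.95


class TestNullFdrControl:
    def test_bh_false_discovery_fraction_bounded(self):
        # 200 global-null datasets: mean false-discovery proportion <= 0.05 + 3 SE
        rng = np.random.default_rng(123)
        fdps = []
        for _ in range(200):
            vals = rng.normal(8, 1, size=(400, 24))
            m = _matrix(vals)
            res = probeset_test(m, m.sample_ids[:12], m.sample_ids[12:])
            q = bh_fdr(res.data["p_value"].to_numpy())
            n_disc = int((q <= 0.05).sum())
            fdps.append(1.0 if n_disc > 0 else 0.0)  # all discoveries are false
        fdps = np.asarray(fdps)
        mc_err = fdps.std(ddof=1) / np.sqrt(len(fdps))
        assert fdps.mean() <= 0.05 + 3 * mc_err


class TestCollapse:
    def _result(self, rows):
        df = pd.DataFrame(rows).set_index("probeset_id")
        df["t_statistic"] = 0.0
        df["q_value"] = df["p_value"]
        df["fold_change"] = np.exp2(df["mean_log2_diff"])
        return ContrastResult("c", "mRNA", df)

    def _ann(self, mapping):
        rows = [
            {"probe_id": p, "gene_symbol": g, "control_class": "none", "qc_gene": ""}
            for p, g in mapping.items()
        ]
        return ProbeAnnotation(pd.DataFrame(rows))

    def test_two_up_probesets_collapse_up(self):
        res = self._result(
            [
                {"probeset_id": "a", "mean_log2_diff": 1.0, "p_value": 1e-5, "direction": "up", "passes": True},
                {"probeset_id": "b", "mean_log2_diff": 0.8, "p_value": 1e-5, "direction": "up", "passes": True},
            ]
        )
        d = collapse_to_genes(res, self._ann({"a": "G1", "b": "G1"}))
        assert d.directions == {"G1": "up"}

    def test_majority_wins(self):
        res = self._result(
            [
                {"probeset_id": "a", "mean_log2_diff": 0.7, "p_value": 1e-5, "direction": "up", "passes": True},
                {"probeset_id": "b", "mean_log2_diff": 0.8, "p_value": 1e-5, "direction": "up", "passes": True},
                {"probeset_id": "c", "mean_log2_diff": -3.0, "p_value": 1e-5, "direction": "down", "passes": True},
            ]
        )
        d = collapse_to_genes(res, self._ann({"a": "G1", "b": "G1", "c": "G1"}))
        assert d.directions == {"G1": "up"}

    def test_tie_broken_by_largest_effect(self):
        res = self._result(
            [
                {"probeset_id": "a", "mean_log2_diff": 0.7, "p_value": 1e-5, "direction": "up", "passes": True},
                {"probeset_id": "b", "mean_log2_diff": -2.0, "p_value": 1e-5, "direction": "down", "passes": True},
            ]
        )
        d = collapse_to_genes(res, self._ann({"a": "G1", "b": "G1"}))
        assert d.directions == {"G1": "down"}

    def test_unmapped_passing_tracked_not_dropped(self):
        res = self._result(
            [
                {"probeset_id": "a", "mean_log2_diff": 1.0, "p_value": 1e-5, "direction": "up", "passes": True},
                {"probeset_id": "b", "mean_log2_diff": 1.0, "p_value": 1e-5, "direction": "up", "passes": True},
            ]
        )
        d = collapse_to_genes(res, self._ann({"a": "G1", "b": ""}))
        assert d.directions == {"G1": "up"}
        assert d.unmapped_passing == ["b"]

    def test_paper_multiplicity_fixture_collapses_to_1483(self):
        res, ann = cf.generate_collapse_fixture(seed=42)
        assert int(res.data["passes"].sum()) == 1837
        d = collapse_to_genes(res, ann)
        assert len(d) == 1483
        assert sum(1 for v in d.directions.values() if v == "up") == 714
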