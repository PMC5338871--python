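"""Stepwise selection, correlation screen, CV/ROC machinery and the
randomization test."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import reefspawn as rs
from reefspawn.covariates import TermDef


def _builder_from_columns(df, group_col=None):
    """Design builder over plain continuous columns x0, x1, ..."""
    defs = {
        c: TermDef("continuous", c)
        for c in df.columns
        if c not in {"spawning", "set_id", "species", "year"}
    }
    return rs.DesignBuilder(df, term_defs=defs, group_col=group_col)


def _sim_frame(n, coefs, seed, n_noise=0):
    rng = np.random.default_rng(seed)
    data = {f"x{i}": rng.standard_normal(n) for i in range(len(coefs) + n_noise)}
    eta = sum(c * data[f"x{i}"] for i, c in enumerate(coefs))
    data["spawning"] = rng.binomial(1, expit(eta)).astype(float)
    data["set_id"] = [f"S{i}" for i in range(n)]
    data["species"] = "SYN"
    return pd.DataFrame(data)


class TestFilterModelable:
    def _records(self, n_spawn):
        n = n_spawn + 50
        return pd.DataFrame(
            {
                "species": "A",
                "set_id": [f"S{i // 4}" for i in range(n)],
                "spawning": [1] * n_spawn + [0] * 50,
            }
        )

    def test_boundary_exclusion(self):
        tab = rs.filter_modelable(self._records(90))
        assert not tab.loc["A", "modelable"]  # strictly greater than 90

    def test_boundary_inclusion(self):
        tab = rs.filter_modelable(self._records(91))
        assert tab.loc["A", "modelable"]

    def test_valid_sets_threshold(self):
        rec = pd.DataFrame(
            {
                "species": "A",
                "set_id": ["a"] * 3 + ["b"] * 2 + ["c"] * 5,
                "spawning": 0,
            }
        )
        tab = rs.filter_modelable(rec)
        assert tab.loc["A", "n_valid_sets"] == 2  # sets a (3 fish) and c (5)


class TestCorrelationScreen:
    def test_duplicate_blocked(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        vals = pd.DataFrame({"a": x, "b": x})
        scr = rs.correlation_screen(vals, {"a": "num", "b": "num"})
        assert scr.is_blocked("a", "b")

    def test_independent_allowed(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(
            {"a": rng.uniform(size=10000), "b": rng.uniform(size=10000)}
        )
        scr = rs.correlation_screen(vals, {"a": "num", "b": "num"})
        assert abs(scr.matrix.loc["a", "b"]) < 0.05
        assert not scr.is_blocked("a", "b")

    def test_exact_limit_allowed(self):
        # construct |r| == 0.60 exactly: strict > blocks, == does not
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = x.copy()
        # mix with anti-correlated part to reach r = 0.6
        rng = np.random.default_rng(2)
        a = rng.standard_normal(5000)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.standard_normal(5000)
        r = np.corrcoef(a, b)[0, 1]
        vals = pd.DataFrame({"a": a, "b": b})
        scr = rs.correlation_screen(
            vals, {"a": "num", "b": "num"}, limit=abs(r)
        )
        assert not scr.is_blocked("a", "b")

    def test_factor_pair_cramers_v(self):
        rng = np.random.default_rng(3)
        a = rng.choice(["u", "v"], 500)
        vals = pd.DataFrame({"a": a, "b": a})
        scr = rs.correlation_screen(vals, {"a": "cat", "b": "cat"})
        assert scr.matrix.loc["a", "b"] == pytest.approx(1.0)
        assert scr.is_blocked("a", "b")

    def test_zero_variance_excluded(self):
        vals = pd.DataFrame({"a": np.ones(100), "b": np.arange(100.0)})
        scr = rs.correlation_screen(vals, {"a": "num", "b": "num"})
        assert "a" in scr.excluded


class TestROC:
    def test_separable(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        labels = scores.astype(int)
        assert rs.auc_mann_whitney(scores, labels) == pytest.approx(100.0)

    def test_threshold_worked_example(self):
        t = rs.optimal_threshold(
            np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1])
        )
        assert t == pytest.approx(0.8)

    def test_threshold_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            scores = rng.uniform(size=60)
            labels = rng.integers(0, 2, 60)
            if labels.sum() in (0, 60):
                continue
            t = rs.optimal_threshold(scores, labels)
            n1, n0 = labels.sum(), (1 - labels).sum()

            def j(th):
                pred = scores >= th
                return (
                    (pred & (labels == 1)).sum() / n1
                    + (~pred & (labels == 0)).sum() / n0
                )

            best = max(j(th) for th in np.unique(scores))
            assert j(t) == pytest.approx(best)
            # lowest threshold attaining the max
            lower = [th for th in np.unique(scores) if th < t]
            assert all(j(th) < best - 1e-12 for th in lower)

    def test_auc_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.uniform(size=500)
        labels = rng.binomial(1, np.clip(scores, 0.05, 0.95))
        ours = rs.auc_mann_whitney(scores, labels)
        assert ours == pytest.approx(100 * roc_auc_score(labels, scores), abs=1e-9)


class TestGradeAUC:
    @pytest.mark.parametrize(
        "auc,grade",
        [
            (81.93, "good"),
            (90.31, "excellent"),
            (67.99, "poor"),
            (90.0, "excellent"),
            (80.0, "good"),
            (70.0, "fair"),
            (69.999, "poor"),
            (100.0, "excellent"),
        ],
    )
    def test_mapping(self, auc, grade):
        assert rs.grade_auc(auc) == grade

    def test_monotone(self):
        order = ["poor", "fair", "good", "excellent"]
        grades = [order.index(rs.grade_auc(a)) for a in np.linspace(0, 100, 101)]
        assert (np.diff(grades) >= 0).all()

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rs.grade_auc(104.0)


class TestCrossValidate:
    def test_separable_fixture(self):
        df = _sim_frame(400, [5.0], seed=6)
        df["x0"] = np.where(df["spawning"] == 1, 2.0, -2.0)
        b = _builder_from_columns(df)
        cv = rs.crossvalidate(b.build(("x0",)), seed=0)
        assert cv.auc == pytest.approx(100.0)
        assert cv.fpr == 0.0
        assert cv.fnr == 0.0
        assert cv.grade == "excellent"

    def test_fold_partition(self):
        df = _sim_frame(300, [0.5], seed=7)
        b = _builder_from_columns(df)
        cv = rs.crossvalidate(b.build(("x0",)), seed=1)
        assert (cv.fold_assignments >= 0).all()
        assert len(np.unique(cv.fold_assignments)) == 10

    def test_null_auc_near_half(self):
        df = _sim_frame(2000, [0.0], seed=8, n_noise=0)
        b = _builder_from_columns(df)
        cv = rs.crossvalidate(b.build(("x0",)), seed=2)
        assert 45.0 <= cv.auc <= 55.0


class TestForwardStepwise:
    def test_true_predictor_first(self):
        df = _sim_frame(2000, [1.0], seed=9, n_noise=3)
        b = _builder_from_columns(df)
        res = rs.forward_stepwise(b, ("x0", "x1", "x2", "x3"))
        assert res.best_terms[0] == "x0"

    def test_path_aic_nonincreasing(self):
        df = _sim_frame(1500, [0.8, 0.4], seed=10, n_noise=2)
        b = _builder_from_columns(df)
        res = rs.forward_stepwise(b, ("x0", "x1", "x2", "x3"))
        aics = [a for _, a in res.path]
        assert all(a2 < a1 for a1, a2 in zip(aics, aics[1:]))

    def test_hierarchy_rule(self):
        rec = pd.DataFrame(
            {
                "set_id": [f"S{i}" for i in range(600)],
                "year": 2010,
                "month": np.random.default_rng(11).choice([5, 6, 7], 600),
                "lat": np.random.default_rng(12).uniform(30, 34, 600),
                "spawning": np.random.default_rng(13).integers(0, 2, 600).astype(float),
                "species": "SYN",
            }
        )
        b = rs.DesignBuilder(rec, group_col=None)
        res = rs.forward_stepwise(b, ("lat_bin:month",))
        # interaction cannot enter without both margins
        assert res.best_terms == ()
        res2 = rs.forward_stepwise(b, ("lat_bin:month",), hierarchy_override=True)
        assert res2.visited  # evaluated once the override is set

    def test_blocked_candidates_skipped(self):
        rng = np.random.default_rng(14)
        df = _sim_frame(1000, [1.0], seed=14)
        df["x1"] = df["x0"] + 0.01 * rng.standard_normal(1000)  # |r| ~ 1
        b = _builder_from_columns(df)
        vals, kinds = b.screen_values(["x0", "x1"])
        scr = rs.correlation_screen(vals, kinds)
        res = rs.forward_stepwise(b, ("x0", "x1"), screen=scr)
        assert set(res.best_terms) in ({"x0"}, {"x1"})
        assert len(res.best_terms) == 1


class TestRandomizationTest:
    def test_permutation_preserves_marginals(self):
        df = _sim_frame(400, [0.8], seed=15, n_noise=2)
        b = _builder_from_columns(df)
        rep = rs.randomization_test(
            b, base_terms=(), true_term="x0", candidates=("x1", "x2"),
            reps=3, seed=0,
        )
        assert rep.reps == 3
        assert 0 <= rep.spurious_probability <= 1

    def test_reps_validation(self):
        df = _sim_frame(200, [0.5], seed=16, n_noise=1)
        b = _builder_from_columns(df)
        with pytest.raises(ValueError):
            rs.randomization_test(b, (), "x0", ("x1",), reps=0)

    def test_default_reps_is_500(self):
        import inspect

        sig = inspect.signature(rs.randomization_test)
        assert sig.parameters["reps"].default == 500
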