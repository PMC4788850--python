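"""Hybrid cascade, rule extraction, model-selection protocol, grading."""

import warnings

import numpy as np
import pandas as pd
import pytest

from palsykit import classifier as cl, synthetic as syn
from palsykit.errors import StateError, UnresolvedGradeError
from palsykit.features import FEATURE_NAMES

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


def separable_cohort(n=60, threshold=0.95, margin=0.02, seed=0):
    """Healthy above / unhealthy below a planted f10 threshold."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        sick = i % 2 == 0
        if i < 2:
            # boundary samples pin the planted threshold: the gap between
            # them is centered on `threshold`
            base = threshold - margin if sick else threshold + margin
        elif sick:
            base = rng.uniform(0.5, threshold - margin)
        else:
            base = rng.uniform(threshold + margin, 1.0)
        # f1..f9 carry no class information; only f10 separates
        f = rng.uniform(0.5, 1.0, 9)
        row = {f"f{j+1}": f[j] for j in range(9)}
        row["f10"] = base
        row["label"] = "PP" if sick else "healthy"
        rows.append(row)
    return pd.DataFrame(rows)


class TestExtractRules:
    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_planted_threshold(self, seed):
        df = separable_cohort(seed=seed)
        y = (df["label"] != "healthy").astype(int).to_numpy()
        rules = cl.extract_rules(df[list(FEATURE_NAMES)], y)
        assert rules
        thresholds = [
            p.threshold for r in rules for p in r.predicates if p.feature == "f10"
        ]
        assert thresholds and min(abs(t - 0.95) for t in thresholds) <= 0.02

    def test_single_class_gives_empty_ruleset(self):
        df = separable_cohort()
        X = df[list(FEATURE_NAMES)]
        assert cl.extract_rules(X, np.zeros(len(X), dtype=int)) == []

    def test_predicates_reference_known_features(self):
        df = separable_cohort(seed=3)
        y = (df["label"] != "healthy").astype(int).to_numpy()
        for rule in cl.extract_rules(df[list(FEATURE_NAMES)], y):
            for p in rule.predicates:
                assert p.feature in FEATURE_NAMES
                assert np.isfinite(p.threshold)


class _AlwaysHealthy:
    def predict(self, X):
        return np.zeros(len(X), dtype=int)


class _AlwaysPP:
    def predict(self, X):
        return np.zeros(len(X), dtype=int)


def _rule(feature, op, threshold, label=1):
    return cl.Rule(
        predicates=(cl.Predicate(feature, op, threshold),),
        label=label, purity=1.0, support=10,
    )


def _vector(**overrides):
    vals = {name: 0.99 for name in FEATURE_NAMES}
    vals.update(overrides)
    return pd.Series(vals)


class TestHybridCascade:
    def test_rules_bypass_ml_entirely(self):
        model = cl.HybridModel(
            rule1=[_rule("f10", "<=", 0.9)],
            rule2=[_rule("f4", ">", 0.9)],
            clf1=_AlwaysHealthy(), clf2=_AlwaysPP(),
        )
        out = model.classify(_vector(f10=0.85, f4=0.95))
        assert out == {
            "label": "unhealthy", "type": "CP",
            "trace": {"stage1": "rule", "stage2": "rule"},
        }

    def test_stage1_ml_healthy_exits_before_stage2(self):
        model = cl.HybridModel(
            rule1=[_rule("f10", "<=", 0.5)], rule2=[], clf1=_AlwaysHealthy(), clf2=None,
        )
        out = model.classify(_vector())
        assert out["label"] == "healthy" and "stage2" not in out["trace"]

    def test_rule1_dominates_any_fallback(self):
        df = separable_cohort(seed=4)
        rule1 = [_rule("f10", "<=", 0.95)]
        for clf in (_AlwaysHealthy(), _AlwaysPP()):
            model = cl.HybridModel(rule1=rule1, rule2=[], clf1=clf, clf2=_AlwaysPP())
            for _, row in df[df["label"] != "healthy"].iterrows():
                assert model.classify(row)["label"] == "unhealthy"

    def test_untrained_model_raises(self):
        with pytest.raises(StateError):
            cl.HybridModel().classify(_vector())


class TestModelSelection:
    def test_folds_partition_each_sample_once(self):
        y = np.array([0] * 10 + [1] * 35)  # N = 45 as in the worked example
        config = cl.CvConfig(seed=0, folds=9)
        for rep in range(3):
            splitter = cl.make_folds(y, config, rep)
            seen = np.zeros(45, dtype=int)
            sizes = []
            for _, va in splitter.split(np.zeros((45, 1)), y):
                seen[va] += 1
                sizes.append(len(va))
            assert (seen == 1).all()
            assert sizes == [5] * 9  # every fold has exactly 5 samples

    def test_grid_has_ten_parameters(self):
        assert len(cl.CvConfig().grid) == 10

    def test_deterministic_under_fixed_seed(self):
        df = syn.generate_cohort(syn.CohortSpec(seed=3))
        cfg = cl.CvConfig(seed=5, repetitions=2)
        m1, r1 = cl.select_model(df, cfg)
        m2, r2 = cl.select_model(df, cfg)
        assert m1.C == m2.C
        pd.testing.assert_frame_equal(
            r1["stage1"].per_repetition, r2["stage1"].per_repetition
        )
        assert [r.describe() for r in m1.rule1] == [r.describe() for r in m2.rule1]

    def test_harmonic_mean_recomputes_from_sens_spec(self):
        df = syn.generate_cohort(syn.CohortSpec(seed=3))
        _, reports = cl.select_model(df, cl.CvConfig(seed=1, repetitions=3))
        for stage in reports.values():
            for _, row in stage.per_repetition.iterrows():
                s, p = row["sensitivity"], row["specificity"]
                expected = 0.0 if s + p == 0 else 2 * s * p / (s + p)
                assert np.isclose(row["harmonic_mean"], expected)

    def test_holdout_never_touches_training(self):
        df = separable_cohort(n=40, seed=7)
        X = df[list(FEATURE_NAMES)]
        y = (df["label"] != "healthy").to_numpy(dtype=int)
        from sklearn.model_selection import train_test_split

        cfg = cl.CvConfig(seed=2, repetitions=1)
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=cfg.holdout, stratify=y, random_state=cfg.seed
        )
        assert set(idx_train).isdisjoint(idx_test)


class TestGrading:
    @pytest.fixture(scope="class")
    def grading_fit(self):
        df = syn.generate_grading_cohort(n=240, seed=2)
        train = df.iloc[:180].reset_index(drop=True)
        test = df.iloc[180:].reset_index(drop=True)
        graders = {
            r: cl.RegionalGrader(r, seed=0).fit(train, train[f"grade_{r}"].to_numpy())
            for r in cl.REGION_FEATURES
        }
        return graders, test

    def test_regional_holdout_accuracy(self, grading_fit):
        graders, test = grading_fit
        for region, grader in graders.items():
            acc = np.mean(
                [grader.predict(row) == row[f"grade_{region}"] for _, row in test.iterrows()]
            )
            assert acc >= 0.8, region

    def test_symmetric_subject_grades_normal(self, grading_fit):
        graders, _ = grading_fit
        x = _vector()  # all features ~0.99
        for grader in graders.values():
            assert grader.predict(x) == 1

    def test_mouth_grader_ignores_forehead_features(self, grading_fit):
        graders, test = grading_fit
        mouth = graders["mouth"]
        preds = [mouth.predict(row) for _, row in test.iterrows()]
        shuffled = test.copy()
        rng = np.random.default_rng(0)
        for colname in ("f1", "f2", "f3", "f4", "f5", "f6"):
            shuffled[colname] = rng.permutation(shuffled[colname].to_numpy())
        preds2 = [mouth.predict(row) for _, row in shuffled.iterrows()]
        assert preds == preds2

    def test_overall_grade_worked_example(self):
        assert cl.overall_grade_lookup(2, 2, 2) == 3
        assert cl.overall_grade_lookup(1, 1, 1) == 1

    def test_unmatched_triple_uses_mnlr(self):
        df = syn.generate_cohort(syn.CohortSpec(seed=4))
        model = cl.fit_grading(df, seed=0)
        grade, mechanism = cl.overall_grade((1, 6, 1), df.iloc[0], model.overall_fallback)
        assert mechanism == "MNLR" and 1 <= grade <= 6

    def test_unmatched_triple_without_fallback_raises(self):
        with pytest.raises(UnresolvedGradeError):
            cl.overall_grade((1, 6, 1))

    def test_untrained_regional_grader_raises(self):
        with pytest.raises(StateError):
            cl.RegionalGrader("eye").predict(_vector())
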