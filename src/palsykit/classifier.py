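"""Hybrid rule + regularized-regression cascade and House-Brackmann grading.

Two-stage screening cascade:

1. *Healthy vs. unhealthy.*  A high-precision rule set distilled from a
   decision tree fires first; when no rule matches, a regularized
   logistic regression (or another fallback family) decides.  A healthy
   verdict exits the cascade.
2. *Peripheral (PP) vs. central (CP) palsy.*  Same hybrid structure on
   the unhealthy branch.

Rules are extracted by fitting a shallow decision tree and converting
root-to-leaf paths whose leaf purity reaches a threshold (0.95) into
conjunctions of feature/threshold predicates — the rule path is meant to
be high precision, with the regression absorbing the ambiguous cases.

Model selection follows a stratified 70/30 holdout: on the 70% (``D'``)
a 9-fold cross-validation evaluates the hybrid at each of 10 log-spaced
regularization strengths, the strength maximizing the mean fold
performance (harmonic mean of sensitivity and specificity) is selected,
the hybrid is retrained on all of ``D'`` and scored on the hidden 30%.
The whole procedure repeats 20 times (fresh fold shuffles) and the test
metrics are averaged.

Severity grading maps regional feature subsets (forehead: f1..f5, eye:
f1 and f6, mouth: f7..f9) to regional House-Brackmann grades I–VI via
rule + multinomial-regression hybrids; the overall grade comes from a
lookup table over concordant regional triples, with a multinomial
logistic regression fallback for discordant triples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, StateError, UnresolvedGradeError
from .features import FEATURE_NAMES

REGION_FEATURES = {
    "forehead": ("f1", "f2", "f3", "f4", "f5"),
    "eye": ("f1", "f6"),
    "mouth": ("f7", "f8", "f9"),
}


@dataclass(frozen=True)
class Predicate:
    """Single threshold test on one feature."""

    feature: str
    op: str  # "<=" or ">"
    threshold: float

    def __call__(self, x: pd.Series) -> bool:
        v = float(x[self.feature])
        return v <= self.threshold if self.op == "<=" else v > self.threshold

    def describe(self) -> str:
        return f"{self.feature} {self.op} {self.threshold:.4g}"


@dataclass
class Rule:
    """Conjunction of predicates implying a class label."""

    predicates: tuple[Predicate, ...]
    label: int
    purity: float
    support: int

    def matches(self, x: pd.Series) -> bool:
        return all(p(x) for p in self.predicates)

    def describe(self) -> str:
        return " and ".join(p.describe() for p in self.predicates) + f" -> {self.label}"


@dataclass
class CvConfig:
    """Model-selection protocol settings."""

    holdout: float = 0.30
    folds: int = 9
    repetitions: int = 20
    grid: tuple[float, ...] = tuple(np.logspace(-2, 2, 10))
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if not self.grid:
            raise ConfigurationError("parameter grid must be non-empty")
        if not 0.0 < self.holdout < 1.0:
            raise ConfigurationError("holdout fraction must lie in (0, 1)")


_FALLBACKS = {
    # L2 penalty (the estimator's default)
    "logistic": lambda C, seed: LogisticRegression(C=C, max_iter=2000),
    "svm": lambda C, seed: SVC(C=C, random_state=seed),
    "tree": lambda C, seed: DecisionTreeClassifier(
        max_depth=3, min_samples_leaf=3, random_state=seed
    ),
    "naive_bayes": lambda C, seed: GaussianNB(),
}


def extract_rules(
    X: pd.DataFrame,
    y: np.ndarray,
    *,
    positive_label: int = 1,
    max_depth: int = 3,
    min_samples_leaf: int = 3,
    min_purity: float = 0.95,
    seed: int = 0,
) -> list[Rule]:
    """Distill high-precision rules for the positive class from a
    shallow decision tree (Gini impurity).

    Only root-to-leaf paths whose leaf purity for ``positive_label``
    reaches ``min_purity`` become rules; rules are ordered by purity then
    support.  Single-class data yields an empty rule set (the cascade
    then degenerates to the fallback classifier alone).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        return []
    cols = list(X.columns)
    tree = DecisionTreeClassifier(
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        criterion="gini",
        random_state=seed,
    ).fit(X.to_numpy(), y)
    t = tree.tree_
    classes = list(tree.classes_)
    if positive_label not in classes:
        return []
    pos_idx = classes.index(positive_label)
    rules: list[Rule] = []

    def walk(node: int, path: tuple[Predicate, ...]):
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node][0] * t.weighted_n_node_samples[node]
            total = counts.sum()
            purity = counts[pos_idx] / total if total else 0.0
            if purity >= min_purity and path:
                rules.append(
                    Rule(predicates=path, label=positive_label, purity=float(purity),
                         support=int(round(total)))
                )
            return
        feat = cols[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], path + (Predicate(feat, "<=", thr),))
        walk(t.children_right[node], path + (Predicate(feat, ">", thr),))

    walk(0, ())
    rules.sort(key=lambda r: (-r.purity, -r.support))
    return rules


def _rules_match(rules: list[Rule], x: pd.Series) -> bool:
    return any(r.matches(x) for r in rules)


@dataclass
class HybridModel:
    """Two-stage cascade: rules fire first, fallbacks absorb the rest."""

    rule1: list[Rule] = field(default_factory=list)  # unhealthy trigger
    rule2: list[Rule] = field(default_factory=list)  # CP trigger
    clf1: object | None = None  # healthy(0) vs unhealthy(1)
    clf2: object | None = None  # PP(0) vs CP(1)
    C: float | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def classify(self, x: pd.Series) -> dict:
        """Classify one subject; the trace records which mechanism
        (rule or fallback classifier) decided each stage."""
        if self.clf1 is None:
            raise StateError("stage-1 fallback not trained")
        trace = {}
        xv = x[list(self.feature_names)].to_numpy(dtype=float).reshape(1, -1)
        if _rules_match(self.rule1, x):
            unhealthy, trace["stage1"] = True, "rule"
        else:
            unhealthy = bool(self.clf1.predict(xv)[0])
            trace["stage1"] = "ml"
        if not unhealthy:
            return {"label": "healthy", "type": None, "trace": trace}
        if _rules_match(self.rule2, x):
            cp, trace["stage2"] = True, "rule"
        else:
            if self.clf2 is None:
                raise StateError("stage-2 fallback not trained")
            cp = bool(self.clf2.predict(xv)[0])
            trace["stage2"] = "ml"
        return {"label": "unhealthy", "type": "CP" if cp else "PP", "trace": trace}


def hybrid_classify(model: HybridModel, x: pd.Series) -> dict:
    """Functional alias for :meth:`HybridModel.classify`."""
    return model.classify(x)


def performance(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Sensitivity, specificity and their harmonic mean (positive = 1)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    pos, neg = y_true == 1, y_true == 0
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((y_pred[neg] == 0).mean()) if neg.any() else np.nan
    if np.isnan(sens) or np.isnan(spec) or sens + spec == 0:
        hmean = 0.0 if not (np.isnan(sens) or np.isnan(spec)) else np.nan
    else:
        hmean = 2 * sens * spec / (sens + spec)
    return {"sensitivity": sens, "specificity": spec, "harmonic_mean": hmean}


def _predict_stage(rules: list[Rule], clf, X: pd.DataFrame) -> np.ndarray:
    """Stage prediction: rule match forces the positive class."""
    out = np.asarray(clf.predict(X.to_numpy(dtype=float)), dtype=int)
    for i, (_, row) in enumerate(X.iterrows()):
        if _rules_match(rules, row):
            out[i] = 1
    return out


def make_folds(y: np.ndarray, config: CvConfig, repetition: int):
    """Cross-validation splitter for one repetition.

    Stratified when every class is at least as populous as the fold
    count; otherwise plain shuffled folds (the per-fold class check then
    excludes degenerate validation splits).  Seeded per repetition.
    """
    min_class = int(np.bincount(np.asarray(y, dtype=int)).min())
    cls = StratifiedKFold if min_class >= config.folds else KFold
    return cls(n_splits=config.folds, shuffle=True, random_state=config.seed + repetition)


@dataclass
class StageReport:
    per_repetition: pd.DataFrame
    selected_C: list[float]

    def summary(self) -> dict[str, float]:
        return self.per_repetition[["sensitivity", "specificity", "harmonic_mean"]].mean().to_dict()


def select_stage_model(
    X: pd.DataFrame,
    y: np.ndarray,
    config: CvConfig,
    *,
    fallback: str = "logistic",
) -> tuple[list[Rule], object, float, StageReport]:
    """Full model-selection protocol for one binary stage.

    Stratified 70/30 holdout; per repetition a fresh stratified k-fold
    shuffle of ``D'``: rules + fallback are fit on the training folds at
    every grid value, scored on the validation fold (harmonic mean),
    fold-averaged per grid value, and the maximizing value selected.  The
    hybrid is then retrained on all of ``D'`` and scored on the holdout.
    Folds whose validation split lacks a class are excluded from the
    average.  Returns the final refit (last repetition) and the
    per-repetition holdout report.
    """
    if fallback not in _FALLBACKS:
        raise ConfigurationError(f"unknown fallback family {fallback!r}")
    y = np.asarray(y, dtype=int)
    X = X.reset_index(drop=True)
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=config.holdout, stratify=y,
        random_state=config.seed,
    )
    Xp, yp = X.iloc[idx_train].reset_index(drop=True), y[idx_train]
    Xt, yt = X.iloc[idx_test].reset_index(drop=True), y[idx_test]
    rows, selected = [], []
    rules_final, clf_final, c_final = [], None, np.nan
    for rep in range(config.repetitions):
        skf = make_folds(yp, config, rep)
        scores = np.full((config.folds, len(config.grid)), np.nan)
        for k, (tr, va) in enumerate(skf.split(Xp, yp)):
            if len(np.unique(yp[va])) < 2 or len(np.unique(yp[tr])) < 2:
                continue  # fold measure flagged and excluded
            rules = extract_rules(Xp.iloc[tr], yp[tr], seed=config.seed)
            for j, C in enumerate(config.grid):
                clf = _FALLBACKS[fallback](C, config.seed).fit(
                    Xp.iloc[tr].to_numpy(dtype=float), yp[tr]
                )
                pred = _predict_stage(rules, clf, Xp.iloc[va])
                scores[k, j] = performance(yp[va], pred)["harmonic_mean"]
        mean_scores = np.nanmean(scores, axis=0)
        best_j = int(np.nanargmax(mean_scores))
        C = float(config.grid[best_j])
        rules_final = extract_rules(Xp, yp, seed=config.seed)
        clf_final = _FALLBACKS[fallback](C, config.seed).fit(
            Xp.to_numpy(dtype=float), yp
        )
        c_final = C
        pred_t = _predict_stage(rules_final, clf_final, Xt)
        row = performance(yt, pred_t)
        row["repetition"] = rep
        row["C"] = C
        rows.append(row)
        selected.append(C)
    report = StageReport(per_repetition=pd.DataFrame(rows), selected_C=selected)
    return rules_final, clf_final, c_final, report


def select_model(
    table: pd.DataFrame,
    config: CvConfig | None = None,
    *,
    fallback: str = "logistic",
) -> tuple[HybridModel, dict[str, StageReport]]:
    """Train the full two-stage cascade from a labeled feature table.

    ``table`` needs columns ``f1..f10`` and ``label`` in
    {healthy, PP, CP}.  Stage 1 screens healthy (0) vs unhealthy (1) on
    all subjects; stage 2 separates PP (0) from CP (1) on the unhealthy
    subset.
    """
    config = config or CvConfig()
    X = table[list(FEATURE_NAMES)]
    y1 = (table["label"] != "healthy").to_numpy(dtype=int)
    rule1, clf1, c1, rep1 = select_stage_model(X, y1, config, fallback=fallback)
    sick = table[table["label"] != "healthy"]
    y2 = (sick["label"] == "CP").to_numpy(dtype=int)
    rule2, clf2, c2, rep2 = select_stage_model(
        sick[list(FEATURE_NAMES)], y2, config, fallback=fallback
    )
    model = HybridModel(rule1=rule1, rule2=rule2, clf1=clf1, clf2=clf2, C=c1)
    return model, {"stage1": rep1, "stage2": rep2}


# ---------------------------------------------------------------------------
# House-Brackmann grading


class RegionalGrader:
    """Rule + multinomial-regression hybrid for one facial region."""

    def __init__(
        self, region: str, *, seed: int = 0, min_purity: float = 0.98,
        C: float = 1000.0,
    ):
        # six-way grade boundaries make mildly impure depth-3 leaves
        # unreliable, so grading rules demand near-certain leaves; the
        # binary screening cascade keeps the looser 0.95 bar
        if region not in REGION_FEATURES:
            raise ConfigurationError(f"unknown region {region!r}")
        self.region = region
        self.features = list(REGION_FEATURES[region])
        self.seed = seed
        self.min_purity = min_purity
        # grade boundaries are steep steps of features living on [0, 1],
        # so useful coefficients are O(100): keep the penalty weak
        self.C = C
        self.rules: list[Rule] = []
        self.mnlr: LogisticRegression | None = None

    def fit(self, table: pd.DataFrame, grades: np.ndarray) -> "RegionalGrader":
        X = table[self.features]
        grades = np.asarray(grades, dtype=int)
        self.rules = []
        for g in np.unique(grades):
            for rule in extract_rules(
                X, (grades == g).astype(int), seed=self.seed,
                min_purity=self.min_purity,
            ):
                rule.label = int(g)
                self.rules.append(rule)
        self.rules.sort(key=lambda r: (-r.purity, -r.support))
        self.mnlr = LogisticRegression(max_iter=5000, C=self.C).fit(
            X.to_numpy(dtype=float), grades
        )
        return self

    def predict(self, x: pd.Series) -> int:
        if self.mnlr is None:
            raise StateError(f"regional grader for {self.region!r} not trained")
        for rule in self.rules:
            if rule.matches(x[self.features]):
                return int(rule.label)
        xv = x[self.features].to_numpy(dtype=float).reshape(1, -1)
        return int(self.mnlr.predict(xv)[0])


def regional_grade(x: pd.Series, region: str, model: RegionalGrader) -> int:
    """Grade one region (1 = normal .. 6 = total paralysis)."""
    if model.region != region:
        raise ConfigurationError(f"model trained for {model.region!r}, not {region!r}")
    return model.predict(x)


def load_hb_table() -> dict[tuple[int, int, int], int]:
    """Shipped lookup table: concordant regional-grade triples to overall
    grade.  Editable data, an interpretation of the regional scale."""
    raw = json.loads(
        resources.files("palsykit.data").joinpath("hb_overall.json").read_text()
    )
    return {
        (r["forehead"], r["eye"], r["mouth"]): r["overall"] for r in raw["rows"]
    }


_HB_TABLE: dict[tuple[int, int, int], int] | None = None


def overall_grade_lookup(
    forehead: int, eye: int, mouth: int, *, fallback: str = "error"
) -> int | None:
    """Table-only overall grade; ``fallback`` handles unmatched triples:
    ``"error"`` raises, ``"max"`` returns the worst regional grade,
    ``"none"`` returns None."""
    global _HB_TABLE
    if _HB_TABLE is None:
        _HB_TABLE = load_hb_table()
    key = (int(forehead), int(eye), int(mouth))
    if key in _HB_TABLE:
        return _HB_TABLE[key]
    if fallback == "max":
        return max(key)
    if fallback == "none":
        return None
    raise UnresolvedGradeError(f"no table row for regional triple {key}")


def overall_grade(
    regional: tuple[int, int, int],
    x: pd.Series | None = None,
    fallback_model: LogisticRegression | None = None,
) -> tuple[int, str]:
    """Overall House-Brackmann grade from the regional triple.

    Returns ``(grade, mechanism)`` where mechanism is ``"table"`` or
    ``"MNLR"``.  A triple absent from the table requires the multinomial
    fallback (trained on f1..f10) and the subject's feature vector.
    """
    grade = overall_grade_lookup(*regional, fallback="none")
    if grade is not None:
        return grade, "table"
    if fallback_model is None or x is None:
        raise UnresolvedGradeError(
            f"triple {tuple(regional)} unmatched and no MNLR fallback supplied"
        )
    xv = x[list(FEATURE_NAMES)].to_numpy(dtype=float).reshape(1, -1)
    return int(fallback_model.predict(xv)[0]), "MNLR"


@dataclass
class GradingModel:
    """Regional graders plus the overall-grade fallback."""

    regional: dict[str, RegionalGrader]
    overall_fallback: LogisticRegression | None = None

    def grade(self, x: pd.Series) -> dict:
        grades = {r: g.predict(x) for r, g in self.regional.items()}
        triple = (grades["forehead"], grades["eye"], grades["mouth"])
        overall, mechanism = overall_grade(triple, x, self.overall_fallback)
        return {"regional": grades, "overall": overall, "mechanism": mechanism}


def fit_grading(table: pd.DataFrame, *, seed: int = 0) -> GradingModel:
    """Train the three regional graders and the overall MNLR fallback.

    ``table`` needs ``f1..f10`` plus ``grade_forehead``, ``grade_eye``,
    ``grade_mouth`` and ``grade_overall`` columns.
    """
    regional = {
        r: RegionalGrader(r, seed=seed).fit(table, table[f"grade_{r}"].to_numpy())
        for r in REGION_FEATURES
    }
    fb = LogisticRegression(max_iter=5000, C=1000.0).fit(
        table[list(FEATURE_NAMES)].to_numpy(dtype=float),
        table["grade_overall"].to_numpy(dtype=int),
    )
    return GradingModel(regional=regional, overall_fallback=fb)
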