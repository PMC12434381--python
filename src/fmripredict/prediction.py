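"""Family-aware behavior prediction with nested hyperparameter selection.

Evaluation protocol: 10 random family-respecting train/test partitions
(test ~15% of the cohort, rounded to whole families so siblings never
straddle the boundary), three inner folds on the training set to pick
hyperparameters, features standardized with statistics computed on training
data only. Continuous targets are scored with the coefficient of
determination R^2, the binary target with accuracy.

Significance is assessed with a permutation null: targets are reshuffled
``n_permutations`` times for each outer split and the whole pipeline refit,
giving (splits x permutations) null scores; a feature predicts above chance
iff the mean real score exceeds the null's 95th percentile.

The public surface follows the statsmodels idiom: build a
:class:`BehaviorPrediction` model from data, call ``fit()``, and read the
estimates off the returned :class:`BehaviorPredictionResults` (which knows
how to ``summary()`` itself). The module-level functions beneath it are the
reusable primitives.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.svm import SVC

from ._seeds import derive_seed

REGRESSION_MODELS = ("elasticnet_reg", "krr")
CLASSIFICATION_MODELS = ("elasticnet_clf", "svm")
MODEL_NAMES = REGRESSION_MODELS + CLASSIFICATION_MODELS


def default_grid(name: str) -> dict[str, list]:
    """Small standard hyperparameter grids (linear kernels throughout)."""
    if name == "elasticnet_reg":
        return {
            "alpha": list(np.logspace(-3, 3, 7)),
            "l1_ratio": [0.1, 0.5, 0.9],
        }
    if name == "krr":
        return {"alpha": list(np.logspace(-3, 3, 7))}
    if name == "elasticnet_clf":
        return {
            "C": list(np.logspace(-3, 3, 7)),
            "l1_ratio": [0.1, 0.5, 0.9],
        }
    if name == "svm":
        return {"C": list(np.logspace(-2, 2, 5))}
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


@dataclass
class ModelSpec:
    """A model family plus its hyperparameter candidate grid."""

    name: str
    grid: dict[str, list] = field(default_factory=dict)
    kernel: str = "linear"

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")
        if not self.grid:
            self.grid = default_grid(self.name)
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    @property
    def is_classifier(self) -> bool:
        return self.name in CLASSIFICATION_MODELS

    def candidates(self) -> list[dict]:
        keys = sorted(self.grid)
        return [
            dict(zip(keys, vals))
            for vals in itertools.product(*(self.grid[k] for k in keys))
        ]

    def make_estimator(self, params: dict):
        if self.name == "elasticnet_reg":
            return ElasticNet(max_iter=3000, tol=1e-3, **params)
        if self.name == "krr":
            return KernelRidge(kernel=self.kernel, **params)
        if self.name == "elasticnet_clf":
            return LogisticRegression(
                penalty="elasticnet", solver="saga", max_iter=2000, tol=1e-3, **params
            )
        return SVC(kernel=self.kernel, **params)


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; may be negative."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.square(y_true - y_true.mean()).sum())
    if ss_tot == 0:
        raise ValueError("zero variance in y_true; R^2 undefined")
    ss_res = float(np.square(y_true - y_pred).sum())
    return 1.0 - ss_res / ss_tot


def accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitScheme:
    """Family-preserving outer train/test partitions plus inner-fold count."""

    n_outer_splits: int
    test_fraction: float
    n_inner_folds: int
    seed: int
    subject_ids: list
    family_ids: list
    splits: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)

    def train_ids(self, k: int) -> list:
        return [self.subject_ids[i] for i in self.splits[k][0]]

    def test_ids(self, k: int) -> list:
        return [self.subject_ids[i] for i in self.splits[k][1]]


def make_family_splits(
    subject_ids: list,
    family_ids: list,
    n_outer_splits: int = 10,
    test_fraction: float = 0.15,
    n_inner_folds: int = 3,
    seed: int = 0,
) -> SplitScheme:
    """Random family-respecting train/test partitions.

    For each split, families are shuffled and added to the test set until it
    reaches ``test_fraction`` of the cohort; test sizes therefore vary with
    family granularity but never split a family.
    """
    if len(subject_ids) != len(family_ids):
        raise ValueError("subject_ids and family_ids must align")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    families: dict = {}
    for idx, fam in enumerate(family_ids):
        families.setdefault(fam, []).append(idx)
    fam_names = list(families)
    n = len(subject_ids)
    target = test_fraction * n
    splits = []
    for k in range(n_outer_splits):
        rng = np.random.default_rng(derive_seed(seed, "outer-split", k))
        order = rng.permutation(len(fam_names))
        test_idx: list[int] = []
        for fi in order:
            if len(test_idx) >= target:
                break
            test_idx.extend(families[fam_names[fi]])
        test_set = set(test_idx)
        train_idx = [i for i in range(n) if i not in test_set]
        if not train_idx or not test_idx:
            raise ValueError(
                "family structure leaves an empty train or test set; "
                "cannot form a family-respecting partition"
            )
        splits.append((np.asarray(train_idx), np.asarray(sorted(test_idx))))
    return SplitScheme(
        n_outer_splits=n_outer_splits,
        test_fraction=test_fraction,
        n_inner_folds=n_inner_folds,
        seed=seed,
        subject_ids=list(subject_ids),
        family_ids=list(family_ids),
        splits=splits,
    )


# ---------------------------------------------------------------------------
# one split: scale on train, pick hyperparameters on inner folds, score test


@dataclass
class SplitFit:
    """Outcome of one outer split, with leakage-audit diagnostics."""

    score: float
    best_params: dict
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    y_pred: np.ndarray


def _scaler_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


def _inner_folds(y: np.ndarray, n_folds: int, classifier: bool) -> list[np.ndarray]:
    """Deterministic inner-fold test indices (stratified-ish for classifiers)."""
    n = len(y)
    n_folds = min(n_folds, n)
    if classifier:
        order = np.argsort(y, kind="stable")
        assignment = np.empty(n, dtype=int)
        assignment[order] = np.arange(n) % n_folds
        return [np.flatnonzero(assignment == f) for f in range(n_folds)]
    return [fold for fold in np.array_split(np.arange(n), n_folds) if fold.size]


def _safe_score(y_true, y_pred, classifier: bool) -> float:
    if classifier:
        return accuracy(y_true, y_pred)
    try:
        return r_squared(y_true, y_pred)
    except ValueError:
        return -np.inf


def fit_predict_one_split(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    model: ModelSpec,
    n_inner_folds: int = 3,
) -> SplitFit:
    """Nested evaluation of one outer split.

    Standardization statistics and hyperparameter selection use training data
    only; the winning candidate (inner-fold mean score, first-in-grid on
    ties) is refit on the full training set and scored on the test set.
    """
    x_train = np.asarray(x_train, dtype=float)
    x_test = np.asarray(x_test, dtype=float)
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if not model.is_classifier and np.std(y_train.astype(float)) == 0:
        raise ValueError("constant target in training data; model selection undefined")
    if model.is_classifier and len(np.unique(y_train)) < 2:
        raise ValueError("single-class target in training data")

    folds = _inner_folds(y_train, n_inner_folds, model.is_classifier)
    candidates = model.candidates()
    inner_means = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for params in candidates:
            scores = []
            for test_fold in folds:
                mask = np.ones(len(y_train), dtype=bool)
                mask[test_fold] = False
                mean, scale = _scaler_stats(x_train[mask])
                est = model.make_estimator(params)
                est.fit((x_train[mask] - mean) / scale, y_train[mask])
                pred = est.predict((x_train[test_fold] - mean) / scale)
                scores.append(_safe_score(y_train[test_fold], pred, model.is_classifier))
            inner_means.append(float(np.mean(scores)))
        best = int(np.argmax(inner_means))
        mean, scale = _scaler_stats(x_train)
        est = model.make_estimator(candidates[best])
        est.fit((x_train - mean) / scale, y_train)
        y_pred = est.predict((x_test - mean) / scale)
    score = (
        accuracy(y_test, y_pred)
        if model.is_classifier
        else r_squared(y_test, y_pred)
    )
    return SplitFit(
        score=score,
        best_params=candidates[best],
        scaler_mean=mean,
        scaler_scale=scale,
        y_pred=np.asarray(y_pred),
    )


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationNull:
    """Null scores from target reshuffling: one entry per (split, permutation)."""

    null_scores: np.ndarray

    def percentile(self, q: float = 95.0) -> float:
        return float(np.percentile(self.null_scores, q))


@dataclass
class EvalResult:
    """Per-split scores with the summary statistics reported alongside them."""

    per_split_scores: np.ndarray
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    p_value: float | None = None
    significant: bool | None = None

    @classmethod
    def from_scores(
        cls,
        scores: np.ndarray,
        p_value: float | None = None,
        significant: bool | None = None,
    ) -> "EvalResult":
        scores = np.asarray(scores, dtype=float)
        return cls(
            per_split_scores=scores,
            mean=float(scores.mean()),
            sd=float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
            median=float(np.median(scores)),
            q1=float(np.percentile(scores, 25)),
            q3=float(np.percentile(scores, 75)),
            p_value=p_value,
            significant=significant,
        )


def evaluate_splits(
    x: np.ndarray,
    y: np.ndarray,
    scheme: SplitScheme,
    model: ModelSpec,
) -> list[SplitFit]:
    """Fit/score every outer split of a fixed feature matrix."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    return [
        fit_predict_one_split(
            x[tr], y[tr], x[te], y[te], model, scheme.n_inner_folds
        )
        for tr, te in scheme.splits
    ]


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    scheme: SplitScheme,
    model: ModelSpec,
    n_permutations: int = 100,
    seed: int = 0,
) -> tuple[EvalResult, PermutationNull]:
    """Real evaluation plus a reshuffled-target null distribution.

    Targets are freely permuted across the whole cohort before each refit,
    independently for every (split, permutation) pair, giving
    ``n_outer_splits * n_permutations`` null scores. The p-value is the
    +1-smoothed proportion of null scores at or above the mean real score;
    the significance flag compares the mean real score against the null's
    95th percentile (strict inequality).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    fits = evaluate_splits(x, y, scheme, model)
    real_scores = np.array([f.score for f in fits])
    null = []
    for k, (tr, te) in enumerate(scheme.splits):
        for p in range(n_permutations):
            rng = np.random.default_rng(derive_seed(scheme.seed, "perm", seed, k, p))
            y_perm = y[rng.permutation(len(y))]
            fit = fit_predict_one_split(
                x[tr], y_perm[tr], x[te], y_perm[te], model, scheme.n_inner_folds
            )
            null.append(fit.score)
    null_arr = np.asarray(null)
    mean_real = float(real_scores.mean())
    p_value = (1.0 + float((null_arr >= mean_real).sum())) / (1.0 + null_arr.size)
    significant = mean_real > np.percentile(null_arr, 95)
    result = EvalResult.from_scores(real_scores, p_value=p_value, significant=significant)
    return result, PermutationNull(null_scores=null_arr)


# ---------------------------------------------------------------------------
# statsmodels-style surface


class BehaviorPrediction:
    """Predict one behavioral target from one feature matrix.

    Parameters
    ----------
    x : (n_subjects, dim) array
        Feature matrix for one feature subtype.
    y : (n_subjects,) array
        Continuous target (R^2 scoring) or binary target (accuracy scoring).
    family_ids : sequence
        Family membership per subject; families are never split across
        train and test.
    model : str or ModelSpec
        One of ``elasticnet_reg``, ``krr``, ``elasticnet_clf``, ``svm``.
    """

    def __init__(
        self,
        x: np.ndarray,
        y: np.ndarray,
        family_ids,
        model: str | ModelSpec = "krr",
        n_outer_splits: int = 10,
        test_fraction: float = 0.15,
        n_inner_folds: int = 3,
        seed: int = 0,
        subject_ids=None,
        feature_name: str = "feature",
        target_name: str = "target",
    ) -> None:
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y)
        if self.x.shape[0] != len(self.y) or self.x.shape[0] != len(family_ids):
            raise ValueError("x, y and family_ids must agree on subject count")
        self.model_spec = ModelSpec(model) if isinstance(model, str) else model
        self.feature_name = feature_name
        self.target_name = target_name
        ids = list(subject_ids) if subject_ids is not None else list(range(len(self.y)))
        self.scheme = make_family_splits(
            ids,
            list(family_ids),
            n_outer_splits=n_outer_splits,
            test_fraction=test_fraction,
            n_inner_folds=n_inner_folds,
            seed=seed,
        )

    @classmethod
    def from_dataframe(
        cls,
        features: pd.DataFrame,
        subjects: pd.DataFrame,
        target: str,
        family_col: str = "family_id",
        **kwargs,
    ) -> "BehaviorPrediction":
        """Build from a feature table and a subject table indexed by subject ID."""
        subjects = subjects.set_index("subject_id") if "subject_id" in subjects else subjects
        aligned = subjects.loc[features.index]
        return cls(
            features.to_numpy(),
            aligned[target].to_numpy(),
            aligned[family_col].tolist(),
            subject_ids=list(features.index),
            target_name=target,
            **kwargs,
        )

    def fit(self, n_permutations: int = 0) -> "BehaviorPredictionResults":
        """Run the split evaluation (and the permutation test if requested)."""
        if n_permutations > 0:
            result, null = permutation_test(
                self.x, self.y, self.scheme, self.model_spec, n_permutations
            )
            fits = None
        else:
            fits = evaluate_splits(self.x, self.y, self.scheme, self.model_spec)
            result = EvalResult.from_scores(np.array([f.score for f in fits]))
            null = None
        return BehaviorPredictionResults(self, result, null, fits)


class BehaviorPredictionResults:
    """Results of a fitted :class:`BehaviorPrediction`."""

    def __init__(
        self,
        model: BehaviorPrediction,
        result: EvalResult,
        null: PermutationNull | None,
        fits: list[SplitFit] | None = None,
    ) -> None:
        self.model = model
        self.result = result
        self.null = null
        self.fits = fits

    @property
    def per_split_scores(self) -> np.ndarray:
        return self.result.per_split_scores

    @property
    def mean_score(self) -> float:
        return self.result.mean

    @property
    def p_value(self) -> float | None:
        return self.result.p_value

    def summary_frame(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame(
            [
                {
                    "target": self.model.target_name,
                    "feature": self.model.feature_name,
                    "model": self.model.model_spec.name,
                    "mean": r.mean,
                    "sd": r.sd,
                    "median": r.median,
                    "q1": r.q1,
                    "q3": r.q3,
                    "p_value": r.p_value,
                }
            ]
        )

    def summary(self) -> str:
        metric = "accuracy" if self.model.model_spec.is_classifier else "R^2"
        lines = [
            "Behavior prediction results",
            "===========================",
            f"target:  {self.model.target_name}",
            f"feature: {self.model.feature_name} (dim {self.model.x.shape[1]})",
            f"model:   {self.model.model_spec.name}   metric: {metric}",
            f"splits:  {self.model.scheme.n_outer_splits} "
            f"(test fraction {self.model.scheme.test_fraction}, "
            f"{self.model.scheme.n_inner_folds} inner folds)",
            "",
            self.summary_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        if self.null is not None:
            lines.append(
                f"null: {self.null.null_scores.size} permuted scores, "
                f"95th percentile {self.null.percentile():.3f} -> "
                f"{'significant' if self.result.significant else 'not significant'}"
            )
        return "\n".join(lines)
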