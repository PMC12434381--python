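"""End-to-end orchestration: cohort -> features -> prediction -> tables.

The consensus connectome (and hence the harmonic basis behind the GSP
features) depends on which subjects are in the *training* set, so for the
four GSP features the feature matrix is rebuilt per outer split from the
training subjects' SCs; the non-GSP features are computed once per cohort.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from ._seeds import derive_seed
from .connectome import basis_from_subjects
from .prediction import (
    EvalResult,
    ModelSpec,
    PermutationNull,
    SplitScheme,
    fit_predict_one_split,
    make_family_splits,
)
from .preprocess import PreprocessConfig, preprocess_session
from .synthetic import BINARY_TARGET, SubjectRecord

logger = logging.getLogger("fmripredict")


def target_vector(cohort: list[SubjectRecord], target: str) -> np.ndarray:
    if target == BINARY_TARGET:
        return np.array([r.target_binary for r in cohort])
    return np.array([r.targets_continuous[target] for r in cohort])


def preprocess_cohort(
    cohort: list[SubjectRecord],
    config: PreprocessConfig | None,
    tr_seconds: float,
) -> dict[str, list[np.ndarray]]:
    """Denoise every session of every subject once; keyed by subject ID."""
    out: dict[str, list[np.ndarray]] = {}
    for rec in cohort:
        if config is None:
            out[rec.subject_id] = rec.sessions
        else:
            out[rec.subject_id] = [
                preprocess_session(ts, conf, config, tr_seconds)
                for ts, conf in zip(rec.sessions, rec.confounds)
            ]
    return out


def split_feature_matrix(
    cohort: list[SubjectRecord],
    feature_name: str,
    sessions_by_id: dict[str, list[np.ndarray]],
    train_idx: np.ndarray | None = None,
    session_amount: float | None = None,
    tr_seconds: float = 0.72,
) -> np.ndarray:
    """Feature matrix for all subjects; GSP basis built from train subjects only."""
    basis = None
    if feature_name in feat.GSP_FEATURES:
        if train_idx is None:
            raise ValueError(f"{feature_name} needs the training subjects for its basis")
        _, basis = basis_from_subjects(
            [cohort[i].sc for i in train_idx],
            [cohort[i].subject_id for i in train_idx],
        )
    rows = []
    for rec in cohort:
        ts = feat.concat_sessions(sessions_by_id[rec.subject_id], session_amount)
        rows.append(feat.compute_feature(ts, feature_name, basis, tr_seconds))
    return np.vstack(rows)


def evaluate_feature_target(
    cohort: list[SubjectRecord],
    feature_name: str,
    target: str,
    model: str | ModelSpec,
    n_outer_splits: int = 10,
    test_fraction: float = 0.15,
    n_inner_folds: int = 3,
    n_permutations: int = 0,
    seed: int = 0,
    preprocess_config: PreprocessConfig | None = None,
    tr_seconds: float = 0.72,
    session_amount: float | None = None,
    scheme: SplitScheme | None = None,
    sessions_by_id: dict[str, list[np.ndarray]] | None = None,
) -> tuple[EvalResult, PermutationNull | None]:
    """Family-aware nested-CV evaluation of one (feature, target, model) triple.

    Rebuilds the consensus harmonic basis from each split's training subjects
    for GSP features; permutations reshuffle the target over the whole cohort
    for every (split, permutation) pair, reusing that split's feature matrix.
    """
    model_spec = ModelSpec(model) if isinstance(model, str) else model
    ids = [r.subject_id for r in cohort]
    fams = [r.family_id for r in cohort]
    if scheme is None:
        scheme = make_family_splits(
            ids, fams, n_outer_splits, test_fraction, n_inner_folds,
            seed=derive_seed(seed, "splits"),
        )
    y = target_vector(cohort, target)
    if sessions_by_id is None:
        sessions_by_id = preprocess_cohort(cohort, preprocess_config, tr_seconds)

    is_gsp = feature_name in feat.GSP_FEATURES
    x_global = None
    if not is_gsp:
        x_global = split_feature_matrix(
            cohort, feature_name, sessions_by_id, None, session_amount, tr_seconds
        )

    real_scores = []
    null_scores = []
    for k, (tr, te) in enumerate(scheme.splits):
        t0 = time.perf_counter()
        x = x_global if x_global is not None else split_feature_matrix(
            cohort, feature_name, sessions_by_id, tr, session_amount, tr_seconds
        )
        fit = fit_predict_one_split(
            x[tr], y[tr], x[te], y[te], model_spec, scheme.n_inner_folds
        )
        real_scores.append(fit.score)
        for p in range(n_permutations):
            rng = np.random.default_rng(derive_seed(seed, "perm", k, p))
            y_perm = y[rng.permutation(len(y))]
            nfit = fit_predict_one_split(
                x[tr], y_perm[tr], x[te], y_perm[te], model_spec, scheme.n_inner_folds
            )
            null_scores.append(nfit.score)
        logger.info(
            "feature=%s target=%s model=%s split=%d score=%.4f (%.2fs)",
            feature_name, target, model_spec.name, k, fit.score,
            time.perf_counter() - t0,
        )

    real = np.asarray(real_scores)
    if n_permutations > 0:
        null_arr = np.asarray(null_scores)
        mean_real = float(real.mean())
        p_value = (1.0 + float((null_arr >= mean_real).sum())) / (1.0 + null_arr.size)
        significant = mean_real > np.percentile(null_arr, 95)
        return (
            EvalResult.from_scores(real, p_value=p_value, significant=significant),
            PermutationNull(null_scores=null_arr),
        )
    return EvalResult.from_scores(real), None


def models_for_target(target: str, model_names: list[str]) -> list[str]:
    from .prediction import CLASSIFICATION_MODELS, REGRESSION_MODELS

    if target == BINARY_TARGET:
        return [m for m in model_names if m in CLASSIFICATION_MODELS]
    return [m for m in model_names if m in REGRESSION_MODELS]


def run_all(config, out_dir: str | Path | None = None):
    """Run the configured feature x target x model comparison end to end.

    Emits ``results.csv`` (one summary row per combination, mirroring the
    published table layout), ``per_split_scores.csv``, the scaling grid CSV
    and plots when enabled, and a ``manifest.json`` recording versions and
    the master seed.
    """
    from . import __version__
    from .config import RunConfig
    from .plots import plot_score_distributions, plot_scaling_heatmap, plot_scan_time_curves
    from .scaling import run_scaling
    from .synthetic import generate_cohort, read_cohort, write_cohort

    assert isinstance(config, RunConfig)
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort_dir = Path(config.cohort_dir)
    if (cohort_dir / "subjects.tsv").exists():
        cohort = read_cohort(cohort_dir)
    elif config.cohort is not None:
        cohort = generate_cohort(config.cohort_config())
        write_cohort(cohort, cohort_dir)
    else:
        raise FileNotFoundError(
            f"no cohort at {cohort_dir} and no cohort section in the config"
        )
    tr = config.cohort.tr_seconds if config.cohort else 0.72
    prep = config.preprocess_config()
    sessions_by_id = preprocess_cohort(cohort, prep, tr)

    rows = []
    split_rows = []
    null_frames = []
    for target in config.targets:
        for feature_name in config.features:
            for model_name in models_for_target(target, config.models):
                result, null = evaluate_feature_target(
                    cohort,
                    feature_name,
                    target,
                    model_name,
                    n_outer_splits=config.scheme.n_outer_splits,
                    test_fraction=config.scheme.test_fraction,
                    n_inner_folds=config.scheme.n_inner_folds,
                    n_permutations=config.permutations,
                    seed=derive_seed(config.master_seed, "predict", feature_name, target, model_name),
                    preprocess_config=prep,
                    tr_seconds=tr,
                    sessions_by_id=sessions_by_id,
                )
                rows.append(
                    {
                        "target": target,
                        "feature": feature_name,
                        "model": model_name,
                        "mean": result.mean,
                        "sd": result.sd,
                        "median": result.median,
                        "q1": result.q1,
                        "q3": result.q3,
                        "p_value": result.p_value,
                        "significant": result.significant,
                    }
                )
                for k, s in enumerate(result.per_split_scores):
                    split_rows.append(
                        {
                            "target": target,
                            "feature": feature_name,
                            "model": model_name,
                            "split": k,
                            "score": s,
                        }
                    )
                if null is not None:
                    null_frames.append(
                        pd.DataFrame(
                            {
                                "target": target,
                                "feature": feature_name,
                                "model": model_name,
                                "null_score": null.null_scores,
                            }
                        )
                    )
    results = pd.DataFrame(rows)
    results.to_csv(out / "results.csv", index=False)
    per_split = pd.DataFrame(split_rows)
    per_split.to_csv(out / "per_split_scores.csv", index=False)
    if null_frames:
        pd.concat(null_frames).to_csv(out / "null_scores.csv", index=False)
    if len(per_split):
        plot_score_distributions(per_split, out / "score_distributions.png")

    scaling_grid = None
    if config.scaling is not None and config.scaling.enabled:
        sc = config.scaling
        scaling_grid = run_scaling(
            cohort,
            sc.feature,
            sc.target,
            sc.model,
            train_fractions=tuple(sc.train_fractions),
            session_amounts=tuple(sc.session_amounts),
            n_outer_splits=config.scheme.n_outer_splits,
            test_fraction=config.scheme.test_fraction,
            n_inner_folds=config.scheme.n_inner_folds,
            seed=derive_seed(config.master_seed, "scaling"),
            preprocess_config=prep,
            tr_seconds=tr,
        )
        scaling_grid.to_frame().to_csv(out / "scaling.csv", index=False)
        plot_scaling_heatmap(scaling_grid, out / "scaling_heatmap.png")
        plot_scan_time_curves(scaling_grid, out / "scan_time_curves.png")

    import sklearn

    manifest = {
        "fmripredict": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit_learn": sklearn.__version__,
        "master_seed": config.master_seed,
        "n_subjects": len(cohort),
        "targets": list(config.targets),
        "features": list(config.features),
        "models": list(config.models),
        "permutations": config.permutations,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results, scaling_grid
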