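"""Sample-size x scan-time scaling experiments.

The prediction pipeline is repeated over a grid of training-set fractions
(0.2 .. 1.0 in steps of 0.2) and scanning-session amounts (0.25 sessions,
doubling to 4). Test sets stay fixed across training fractions within a
split; scan-time truncation always keeps a prefix of frames starting at the
beginning of session one, so every frame used at a smaller amount is also
used at every larger one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .features import concat_sessions
from .prediction import ModelSpec, fit_predict_one_split, make_family_splits
from .pipeline import preprocess_cohort, split_feature_matrix, target_vector

DEFAULT_TRAIN_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)
DEFAULT_SESSION_AMOUNTS = (0.25, 0.5, 1.0, 2.0, 4.0)

#: scan minutes per quarter session (1200-frame session at TR 0.72 s = 14.4 min)
MINUTES_PER_QUARTER_SESSION = 3.6


def scan_time_axis(
    session_amount: float | np.ndarray,
    minutes_per_quarter_session: float = MINUTES_PER_QUARTER_SESSION,
) -> float | np.ndarray:
    """Convert a session amount to cumulative scan minutes (0.25 -> 3.6, 4 -> 57.6)."""
    amount = np.asarray(session_amount, dtype=float)
    if (amount <= 0).any():
        raise ValueError("session amounts must be positive")
    minutes = amount * 4.0 * minutes_per_quarter_session
    return float(minutes) if np.isscalar(session_amount) else minutes


def subsample_train(
    train_ids: list,
    family_ids: dict | list,
    fraction: float,
    seed: int = 0,
) -> list:
    """Family-respecting subset of the training ids, nested across fractions.

    Families are shuffled once per seed and a prefix is taken until the
    subset reaches ``fraction`` of the training size, so the subset at 0.2 is
    contained in the subset at 0.4, and so on. The test set is untouched by
    construction (it is simply not passed in).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if isinstance(family_ids, dict):
        fam_of = family_ids
    else:
        fam_of = dict(zip(train_ids, family_ids))
    if fraction == 1.0:
        return list(train_ids)
    families: dict = {}
    for sid in train_ids:
        families.setdefault(fam_of[sid], []).append(sid)
    fam_names = list(families)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(fam_names))
    target = fraction * len(train_ids)
    subset: list = []
    for fi in order:
        if len(subset) >= target:
            break
        subset.extend(families[fam_names[fi]])
    return subset


def truncate_scan(
    sessions: list[np.ndarray], session_amount: float
) -> np.ndarray:
    """Concatenate a prefix of the (preprocessed) sessions worth ``session_amount``.

    Fractional amounts take the leading floor(frac * frames) frames of the
    next session; the result always starts at the beginning of session one.
    """
    return concat_sessions(sessions, session_amount)


@dataclass
class ScalingGrid:
    """Per-split scores indexed by (train_fraction, session_amount)."""

    train_fractions: tuple[float, ...]
    session_amounts: tuple[float, ...]
    cells: dict[tuple[float, float], np.ndarray] = field(default_factory=dict)
    feature_name: str = ""
    target_name: str = ""
    model_name: str = ""

    def mean_table(self) -> pd.DataFrame:
        """Heatmap table: rows = train fractions, columns = session amounts."""
        data = {
            amount: [float(np.mean(self.cells[(f, amount)])) for f in self.train_fractions]
            for amount in self.session_amounts
        }
        return pd.DataFrame(data, index=list(self.train_fractions))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (frac, amount), scores in self.cells.items():
            for k, s in enumerate(scores):
                rows.append(
                    {
                        "feature": self.feature_name,
                        "target": self.target_name,
                        "model": self.model_name,
                        "train_fraction": frac,
                        "sessions": amount,
                        "split": k,
                        "score": s,
                    }
                )
        return pd.DataFrame(rows)


def run_scaling(
    cohort,
    feature_name: str,
    target: str,
    model: str | ModelSpec,
    train_fractions: tuple[float, ...] = DEFAULT_TRAIN_FRACTIONS,
    session_amounts: tuple[float, ...] = DEFAULT_SESSION_AMOUNTS,
    n_outer_splits: int = 10,
    test_fraction: float = 0.15,
    n_inner_folds: int = 3,
    seed: int = 0,
    preprocess_config=None,
    tr_seconds: float = 0.72,
) -> ScalingGrid:
    """Fill the scaling grid: one array of per-split scores per cell.

    Features are recomputed per cell from the truncated scans; for GSP
    features the consensus connectome is additionally recomputed from each
    cell's (possibly subsampled) training subjects.
    """
    from .features import GSP_FEATURES

    model_spec = ModelSpec(model) if isinstance(model, str) else model
    ids = [r.subject_id for r in cohort]
    fams = [r.family_id for r in cohort]
    fam_of = dict(zip(ids, fams))
    idx_of = {sid: i for i, sid in enumerate(ids)}
    scheme = make_family_splits(
        ids, fams, n_outer_splits, test_fraction, n_inner_folds,
        seed=derive_seed(seed, "splits"),
    )
    y = target_vector(cohort, target)
    sessions_by_id = preprocess_cohort(cohort, preprocess_config, tr_seconds)
    is_gsp = feature_name in GSP_FEATURES

    grid = ScalingGrid(
        train_fractions=tuple(train_fractions),
        session_amounts=tuple(session_amounts),
        feature_name=feature_name,
        target_name=target,
        model_name=model_spec.name,
    )
    for amount in session_amounts:
        x_amount = None
        if not is_gsp:
            x_amount = split_feature_matrix(
                cohort, feature_name, sessions_by_id, None, amount, tr_seconds
            )
        for frac in train_fractions:
            scores = []
            for k in range(scheme.n_outer_splits):
                train_ids = scheme.train_ids(k)
                sub_ids = subsample_train(
                    train_ids, fam_of, frac, seed=derive_seed(seed, "subsample", k)
                )
                tr_idx = np.array([idx_of[s] for s in sub_ids])
                te_idx = scheme.splits[k][1]
                x = x_amount if x_amount is not None else split_feature_matrix(
                    cohort, feature_name, sessions_by_id, tr_idx, amount, tr_seconds
                )
                fit = fit_predict_one_split(
                    x[tr_idx], y[tr_idx], x[te_idx], y[te_idx],
                    model_spec, n_inner_folds,
                )
                scores.append(fit.score)
            grid.cells[(frac, amount)] = np.asarray(scores)
    return grid
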