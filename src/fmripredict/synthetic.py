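"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the analysis assumes, so every downstream
stage is testable without restricted neuroimaging data:

* one base community-structured weighted graph stands in for the group-level
  structural connectome; each subject's SC is a noisy perturbation of it
  (multiplicative lognormal edge jitter plus random edge addition/deletion),
  which makes consensus construction nontrivial;
* BOLD for a subject is generated *on that subject's own harmonics*:
  x(t) = U diag(g(lambda)) w(t) + eps(t), with g(lambda) =
  exp(-spectral_decay * lambda) and white w, eps — so graph-spectral energy
  is concentrated on low harmonics by construction;
* continuous targets are noisy linear functions of a designated ground-truth
  feature (FC edges, regional SD, or low-harmonic graph PSD), scaled so a
  requested fraction of target variance is explained by the features;
* the binary target (sex) thresholds a latent built from the regional-SD
  ground truth plus noise;
* subjects belong to families of size 1-5; motion confounds are smooth
  random walks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .connectome import harmonic_basis, normalized_laplacian
from .matrixio import read_matrix, write_matrix

CONTINUOUS_TARGETS = (
    "mental_health",
    "cognition",
    "processing_speed",
    "substance_use",
    "age",
)
BINARY_TARGET = "sex"


def _default_effects() -> dict[str, float]:
    # cognition and age carry signal by default (the two continuous targets
    # found predictable); sex loads on regional variability; the rest are noise.
    return {
        "mental_health": 0.0,
        "cognition": 0.3,
        "processing_speed": 0.0,
        "substance_use": 0.0,
        "age": 0.3,
        "sex": 0.5,
    }


def _default_informative() -> dict[str, str]:
    return {
        "mental_health": "none",
        "cognition": "fc_edges",
        "processing_speed": "none",
        "substance_use": "none",
        "age": "graph_psd_low",
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the acquisition the pipeline targets: R=274 regions,
    four ~14.4 min sessions of 1200 frames at TR=0.72 s.
    """

    n_subjects: int = 40
    n_regions: int = 274
    n_sessions: int = 4
    frames_per_session: int = 1200
    tr_seconds: float = 0.72
    n_communities: int = 5
    family_size_probs: tuple[float, ...] = (0.40, 0.35, 0.15, 0.07, 0.03)
    effect_size_per_target: dict[str, float] = field(default_factory=_default_effects)
    informative_feature: dict[str, str] = field(default_factory=_default_informative)
    spectral_decay: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_regions", "n_sessions", "frames_per_session", "n_communities"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        probs = np.asarray(self.family_size_probs, dtype=float)
        if probs.ndim != 1 or len(probs) != 5 or (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("family_size_probs must be 5 non-negative values summing to 1")
        for tgt, e in self.effect_size_per_target.items():
            if not 0 <= e <= 1:
                raise ValueError(f"effect size for {tgt} must be in [0, 1]")
        for tgt, kind in self.informative_feature.items():
            if kind not in ("fc_edges", "regional_sd", "graph_psd_low", "none"):
                raise ValueError(f"unknown informative feature {kind!r} for {tgt}")
        if self.spectral_decay <= 0:
            raise ValueError("spectral_decay must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SubjectRecord:
    """One synthetic subject: SC, sessions, confounds, targets, family."""

    subject_id: str
    family_id: str
    sc: np.ndarray
    sessions: list[np.ndarray]
    confounds: list[np.ndarray]
    targets_continuous: dict[str, float]
    target_binary: int


def _base_graph(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Community-structured weighted base SC (stochastic-block-model-like)."""
    n = config.n_regions
    labels = np.arange(n) % config.n_communities
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    p_edge = np.where(same, 0.8, 0.15)
    present = rng.random(iu.size) < p_edge
    weights = rng.lognormal(mean=0.0, sigma=0.5, size=iu.size)
    weights *= np.where(same, 1.0, 0.4)
    w = np.zeros((n, n))
    w[iu[present], ju[present]] = weights[present]
    w = w + w.T
    _fix_isolated(w, rng)
    return w


def _fix_isolated(w: np.ndarray, rng: np.random.Generator) -> None:
    """Connect any isolated node to a random other node (in place)."""
    n = w.shape[0]
    for i in np.flatnonzero(w.sum(axis=1) == 0):
        j = int(rng.integers(n - 1))
        j = j if j < i else j + 1
        val = float(rng.lognormal(0.0, 0.5)) * 0.4
        w[i, j] = w[j, i] = val


def _subject_sc(base: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Perturb the base graph: lognormal jitter + 2% edge deletion/addition."""
    n = base.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = base[iu, ju].copy()
    present = vals > 0
    vals[present] *= rng.lognormal(0.0, 0.2, size=int(present.sum()))
    drop = present & (rng.random(iu.size) < 0.02)
    vals[drop] = 0.0
    add = (~present) & (rng.random(iu.size) < 0.02)
    vals[add] = rng.lognormal(0.0, 0.5, size=int(add.sum())) * 0.2
    sc = np.zeros((n, n))
    sc[iu, ju] = vals
    sc = sc + sc.T
    _fix_isolated(sc, rng)
    return sc


def _subject_bold(
    sc: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Sessions of graph-spectrally low-concentrated BOLD on the subject's harmonics."""
    basis = harmonic_basis(normalized_laplacian(sc))
    g = np.exp(-config.spectral_decay * basis.eigenvalues)
    # scale so the signal part has unit average per-region variance
    scale = np.sqrt(config.n_regions / np.square(g).sum())
    sessions = []
    for _ in range(config.n_sessions):
        w = rng.standard_normal((config.n_regions, config.frames_per_session))
        x = basis.eigenvectors @ (g[:, None] * w) * scale
        if config.noise_sd > 0:
            x = x + config.noise_sd * rng.standard_normal(x.shape)
        sessions.append(x)
    return sessions


def _session_confounds(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Six smooth random-walk motion regressors, frame x 6."""
    steps = rng.normal(0.0, 0.05, size=(config.frames_per_session, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    smooth = np.column_stack(
        [np.convolve(walk[:, j], kernel, mode="same") for j in range(6)]
    )
    return smooth


def _ground_truth_features(
    records: list[SubjectRecord], config: CohortConfig
) -> dict[str, np.ndarray]:
    """Per-kind ground-truth feature matrices from the generated raw BOLD."""
    out: dict[str, np.ndarray] = {}
    kinds = set(config.informative_feature.values()) | {"regional_sd"}
    kinds.discard("none")
    concat = [feat.concat_sessions(r.sessions) for r in records]
    if "fc_edges" in kinds:
        out["fc_edges"] = np.vstack([feat.fc(ts) for ts in concat])
    if "regional_sd" in kinds:
        out["regional_sd"] = np.vstack([feat.regional_sd(ts) for ts in concat])
    if "graph_psd_low" in kinds:
        rows = []
        for r, ts in zip(records, concat):
            basis = harmonic_basis(normalized_laplacian(r.sc))
            psd = feat.graph_psd(feat.gft(ts, basis))
            rows.append(psd[: config.n_regions // 2])
        out["graph_psd_low"] = np.vstack(rows)
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _make_targets(
    records: list[SubjectRecord],
    config: CohortConfig,
    rng: np.random.Generator,
) -> None:
    n = len(records)
    gt = _ground_truth_features(records, config)
    for name in CONTINUOUS_TARGETS:
        effect = config.effect_size_per_target.get(name, 0.0)
        kind = config.informative_feature.get(name, "none")
        noise = rng.standard_normal(n)
        if effect > 0 and kind != "none":
            w = rng.standard_normal(gt[kind].shape[1])
            signal = _standardize(gt[kind] @ w)
            y = np.sqrt(effect) * signal + np.sqrt(1.0 - effect) * noise
        else:
            y = noise
        if name == "age":
            # narrow adult range, mean ~28.7, sd ~3.7
            y = np.clip(28.68 + 3.71 * y, 22.0, 37.0)
        for rec, val in zip(records, y):
            rec.targets_continuous[name] = float(val)
    # binary target: logistic threshold on a regional-SD latent + noise
    e_sex = config.effect_size_per_target.get("sex", 0.5)
    w = rng.standard_normal(gt["regional_sd"].shape[1])
    latent = np.sqrt(e_sex) * _standardize(gt["regional_sd"] @ w)
    latent = latent + np.sqrt(max(1.0 - e_sex, 0.0)) * rng.standard_normal(n)
    for rec, val in zip(records, latent):
        rec.target_binary = int(val > 0)


def _assign_families(
    n_subjects: int, probs: tuple[float, ...], rng: np.random.Generator
) -> list[str]:
    sizes = []
    total = 0
    while total < n_subjects:
        size = int(rng.choice(np.arange(1, 6), p=np.asarray(probs)))
        size = min(size, n_subjects - total)
        sizes.append(size)
        total += size
    ids = []
    for k, size in enumerate(sizes):
        ids.extend([f"fam-{k:04d}"] * size)
    return ids


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate the full synthetic cohort, deterministically given the seed."""
    rng = np.random.default_rng(config.seed)
    base = _base_graph(config, rng)
    family_ids = _assign_families(config.n_subjects, config.family_size_probs, rng)
    records = []
    for s in range(config.n_subjects):
        sc = _subject_sc(base, rng)
        sessions = _subject_bold(sc, config, rng)
        confounds = [_session_confounds(config, rng) for _ in range(config.n_sessions)]
        # motion bleeds weakly into the signal so confound regression matters
        for ts, conf in zip(sessions, confounds):
            ts += 0.1 * conf.sum(axis=1)[None, :]
        records.append(
            SubjectRecord(
                subject_id=f"sub-{s:04d}",
                family_id=family_ids[s],
                sc=sc,
                sessions=sessions,
                confounds=confounds,
                targets_continuous={},
                target_binary=0,
            )
        )
    _make_targets(records, config, rng)
    return records


def partition_factor_subset(
    cohort: list[SubjectRecord], n_holdout: int
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Split off a family-respecting holdout of the smallest size >= n_holdout.

    Mirrors reserving a subset of subjects for deriving behavioral factor
    scores while the remainder forms the main analysis cohort. Families are
    never separated; the holdout size is the smallest achievable total of
    whole families that reaches ``n_holdout`` (found by subset-sum over
    family sizes, deterministic in cohort order).
    """
    if n_holdout < 0:
        raise ValueError("n_holdout must be >= 0")
    if n_holdout >= len(cohort):
        raise ValueError("n_holdout must be smaller than the cohort")
    if n_holdout == 0:
        return [], list(cohort)

    fam_order: list[str] = []
    fam_members: dict[str, list[SubjectRecord]] = {}
    for rec in cohort:
        if rec.family_id not in fam_members:
            fam_order.append(rec.family_id)
            fam_members[rec.family_id] = []
        fam_members[rec.family_id].append(rec)
    sizes = [len(fam_members[f]) for f in fam_order]
    max_size = max(sizes)

    # subset-sum DP over totals up to n_holdout + max_size - 1
    cap = n_holdout + max_size - 1
    reachable = np.zeros(cap + 1, dtype=bool)
    reachable[0] = True
    used = np.full((len(sizes), cap + 1), False)
    for k, size in enumerate(sizes):
        newly = reachable.copy()
        shifted = np.zeros_like(reachable)
        shifted[size:] = reachable[:-size] if size > 0 else reachable
        newly |= shifted
        used[k] = shifted & ~reachable
        reachable = newly
    candidates = np.flatnonzero(reachable[n_holdout:])
    target = n_holdout + int(candidates[0])

    chosen: set[str] = set()
    total = target
    for k in range(len(sizes) - 1, -1, -1):
        if used[k][total]:
            chosen.add(fam_order[k])
            total -= sizes[k]
    assert total == 0
    holdout = [r for r in cohort if r.family_id in chosen]
    main = [r for r in cohort if r.family_id not in chosen]
    return holdout, main


# ---------------------------------------------------------------------------
# directory layout I/O


def write_cohort(cohort: list[SubjectRecord], out_dir: str | Path) -> None:
    """Write subjects.tsv plus per-subject SC/session/confound TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        row = {"subject_id": rec.subject_id, "family_id": rec.family_id}
        row.update(rec.targets_continuous)
        row["sex"] = rec.target_binary
        rows.append(row)
        sub = out / rec.subject_id
        write_matrix(sub / "sc.tsv", rec.sc)
        for k, (ts, conf) in enumerate(zip(rec.sessions, rec.confounds), start=1):
            write_matrix(sub / f"sess-{k}_bold.tsv", ts)
            write_matrix(sub / f"sess-{k}_confounds.tsv", conf)
    # %.17g round-trips float64 exactly, so a written cohort reloads bit-identically
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False, float_format="%.17g")


def read_cohort(in_dir: str | Path) -> list[SubjectRecord]:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = Path(in_dir)
    table = pd.read_csv(root / "subjects.tsv", sep="\t", float_precision="round_trip")
    target_cols = [
        c for c in table.columns if c not in ("subject_id", "family_id", "sex")
    ]
    cohort = []
    for _, row in table.iterrows():
        sub = root / str(row["subject_id"])
        sessions = []
        confounds = []
        k = 1
        while (sub / f"sess-{k}_bold.tsv").exists():
            sessions.append(read_matrix(sub / f"sess-{k}_bold.tsv"))
            confounds.append(read_matrix(sub / f"sess-{k}_confounds.tsv"))
            k += 1
        cohort.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                family_id=str(row["family_id"]),
                sc=read_matrix(sub / "sc.tsv"),
                sessions=sessions,
                confounds=confounds,
                targets_continuous={c: float(row[c]) for c in target_cols},
                target_binary=int(row["sex"]),
            )
        )
    return cohort
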