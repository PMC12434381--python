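"""The nine fMRI feature subtypes.

Three families are computed per subject from preprocessed region x frame
time series:

* functional connectivity (``fc``): vectorized upper triangle of the Pearson
  correlation matrix, dimension R(R-1)/2;
* region-wise statistics (``mean``, ``sd``, ``mssd``, ``falff``), dimension R;
* graph-signal-processing features on the connectome harmonic basis
  (``psd``, ``sdi``, ``coupled_fc``, ``decoupled_fc``): the graph Fourier
  transform x_hat = U^T x expresses each frame in harmonics of the consensus
  structural connectome; a cutoff at half the harmonic count splits the
  signal into a structure-coupled (low) and decoupled (high) part.

Sessions are concatenated along time (after per-session preprocessing)
before any feature is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import HarmonicBasis

#: canonical names of the nine feature subtypes
FEATURE_NAMES = (
    "fc",
    "mean",
    "sd",
    "mssd",
    "falff",
    "psd",
    "sdi",
    "coupled_fc",
    "decoupled_fc",
)

#: features whose dimension is R(R-1)/2 rather than R
EDGE_FEATURES = frozenset({"fc", "coupled_fc", "decoupled_fc"})

#: features that require a harmonic basis
GSP_FEATURES = frozenset({"psd", "sdi", "coupled_fc", "decoupled_fc"})


@dataclass
class GraphSignal:
    """Graph-domain representation of a time series: x_hat = U^T x per frame."""

    coefficients: np.ndarray  # harmonic x frame

    @property
    def n_frames(self) -> int:
        return self.coefficients.shape[1]


@dataclass(frozen=True)
class FilterSpec:
    """Ideal graph filter keeping harmonics [0, cutoff) (low) or [cutoff, R) (high)."""

    cutoff_index: int
    mode: str  # "low" | "high"

    def __post_init__(self) -> None:
        if self.mode not in ("low", "high"):
            raise ValueError("mode must be 'low' or 'high'")


@dataclass
class FeatureMatrix:
    """subjects x dimension matrix for one feature subtype."""

    values: np.ndarray
    feature_name: str
    subject_ids: list

    def __post_init__(self) -> None:
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def _as_ts(ts: np.ndarray, min_frames: int = 1) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be region x frame")
    if ts.shape[1] < min_frames:
        raise ValueError(f"need at least {min_frames} frames, got {ts.shape[1]}")
    return ts


def _check_variance(ts: np.ndarray, reference: np.ndarray | None = None) -> None:
    """Raise if any region's series is (numerically) constant.

    ``reference`` sets the scale against which "zero" variance is judged;
    this catches filtered signals that vanished relative to their source.
    """
    sd = ts.std(axis=1)
    scale = np.sqrt(np.mean(np.square(reference if reference is not None else ts)))
    tol = 1e-10 * max(scale, np.finfo(float).tiny)
    if (sd <= tol).any():
        bad = int(np.flatnonzero(sd <= tol)[0])
        raise ValueError(f"region {bad} has zero variance; correlation undefined")


def fc(ts: np.ndarray, _reference: np.ndarray | None = None) -> np.ndarray:
    """Pearson-correlation edge vector: strict upper triangle, row-major."""
    ts = _as_ts(ts, min_frames=3)
    _check_variance(ts, _reference)
    corr = np.corrcoef(ts)
    iu, ju = np.triu_indices(ts.shape[0], k=1)
    return np.clip(corr[iu, ju], -1.0, 1.0)


def regional_mean(ts: np.ndarray) -> np.ndarray:
    """Per-region sample mean over frames."""
    return _as_ts(ts, min_frames=2).mean(axis=1)


def regional_sd(ts: np.ndarray) -> np.ndarray:
    """Per-region sample standard deviation (denominator N-1)."""
    return _as_ts(ts, min_frames=2).std(axis=1, ddof=1)


def mssd(ts: np.ndarray) -> np.ndarray:
    """Mean squared successive difference: (1/(N-1)) * sum (x_{i+1}-x_i)^2.

    Known as BOLD variability; quantifies moment-to-moment signal change.
    """
    ts = _as_ts(ts, min_frames=2)
    diffs = np.diff(ts, axis=1)
    return np.square(diffs).sum(axis=1) / (ts.shape[1] - 1)


def falff(
    ts: np.ndarray,
    tr_seconds: float,
    band: tuple[float, float] = (0.01, 0.08),
) -> np.ndarray:
    """Fractional amplitude of low-frequency fluctuations.

    Ratio of the amplitude spectrum summed over ``band`` (endpoints
    inclusive) to the sum over all positive frequencies; DC is excluded from
    the denominator. Computed from a plain (untapered) periodogram.
    """
    ts = _as_ts(ts, min_frames=8)
    lo, hi = band
    nyquist = 0.5 / tr_seconds
    if not (0 < lo < hi <= nyquist):
        raise ValueError(f"band {band} must lie inside (0, Nyquist={nyquist:g}] Hz")
    freqs = np.fft.rfftfreq(ts.shape[1], d=tr_seconds)
    amp = np.abs(np.fft.rfft(ts, axis=1))
    positive = freqs > 0
    in_band = positive & (freqs >= lo) & (freqs <= hi)
    denom = amp[:, positive].sum(axis=1)
    if (denom <= 0).any():
        raise ValueError("zero total spectral amplitude in a region")
    return amp[:, in_band].sum(axis=1) / denom


def gft(ts: np.ndarray, basis: HarmonicBasis) -> GraphSignal:
    """Graph Fourier transform: project each frame onto the harmonics."""
    ts = _as_ts(ts)
    if ts.shape[0] != basis.n_regions:
        raise ValueError(
            f"time series has {ts.shape[0]} regions, basis has {basis.n_regions}"
        )
    return GraphSignal(coefficients=basis.eigenvectors.T @ ts)


def igft(gs: GraphSignal, basis: HarmonicBasis) -> np.ndarray:
    """Inverse graph Fourier transform back to the region domain."""
    coeff = np.asarray(gs.coefficients, dtype=float)
    if coeff.shape[0] != basis.n_regions:
        raise ValueError("coefficient count does not match basis size")
    return basis.eigenvectors @ coeff


def graph_psd(gs: GraphSignal) -> np.ndarray:
    """Graph power spectral density: l2 norm over time of each coefficient.

    PSD_k = sqrt(sum_t x_hat_k(t)^2), so sum_k PSD_k^2 equals the total
    signal energy (Parseval over harmonics and time).
    """
    coeff = np.asarray(gs.coefficients, dtype=float)
    if coeff.shape[1] < 1:
        raise ValueError("graph signal has no frames")
    return np.sqrt(np.square(coeff).sum(axis=1))


def default_cutoff(n_regions: int) -> int:
    """Half the harmonic count, floor(R/2): the coupled/decoupled boundary."""
    return n_regions // 2


def graph_filter(
    ts: np.ndarray, basis: HarmonicBasis, spec: FilterSpec
) -> np.ndarray:
    """Ideal graph low-/high-pass: zero the complementary band, transform back.

    ``low`` keeps harmonic indices [0, cutoff), ``high`` keeps [cutoff, R);
    low(x) + high(x) = x for any cutoff.
    """
    n = basis.n_regions
    if not 0 < spec.cutoff_index <= n:
        raise ValueError(f"cutoff_index must be in (0, {n}], got {spec.cutoff_index}")
    gs = gft(ts, basis)
    coeff = gs.coefficients.copy()
    if spec.mode == "low":
        coeff[spec.cutoff_index :, :] = 0.0
    else:
        coeff[: spec.cutoff_index, :] = 0.0
    return igft(GraphSignal(coeff), basis)


def coupled_fc(
    ts: np.ndarray, basis: HarmonicBasis, cutoff_index: int | None = None
) -> np.ndarray:
    """FC of the graph low-pass (structure-coupled) signal."""
    cut = default_cutoff(basis.n_regions) if cutoff_index is None else cutoff_index
    low = graph_filter(ts, basis, FilterSpec(cut, "low"))
    return fc(low, _reference=np.asarray(ts, dtype=float))


def decoupled_fc(
    ts: np.ndarray, basis: HarmonicBasis, cutoff_index: int | None = None
) -> np.ndarray:
    """FC of the graph high-pass (structure-decoupled) signal."""
    cut = default_cutoff(basis.n_regions) if cutoff_index is None else cutoff_index
    high = graph_filter(ts, basis, FilterSpec(cut, "high"))
    return fc(high, _reference=np.asarray(ts, dtype=float))


def sdi(
    ts: np.ndarray, basis: HarmonicBasis, cutoff_index: int | None = None
) -> np.ndarray:
    """Structural decoupling index: per-region ||high(x)|| / ||low(x)|| over time."""
    ts = _as_ts(ts)
    cut = default_cutoff(basis.n_regions) if cutoff_index is None else cutoff_index
    low = graph_filter(ts, basis, FilterSpec(cut, "low"))
    high = graph_filter(ts, basis, FilterSpec(cut, "high"))
    low_norm = np.linalg.norm(low, axis=1)
    high_norm = np.linalg.norm(high, axis=1)
    scale = np.linalg.norm(ts) / np.sqrt(ts.shape[0])
    tol = 1e-10 * max(scale, np.finfo(float).tiny)
    if (low_norm <= tol).any():
        bad = int(np.flatnonzero(low_norm <= tol)[0])
        raise ValueError(f"zero low-pass norm in region {bad}; SDI undefined")
    return high_norm / low_norm


def concat_sessions(
    sessions: list[np.ndarray], session_amount: float | None = None
) -> np.ndarray:
    """Concatenate sessions along time, optionally truncated to an amount.

    ``session_amount`` counts sessions (0.25, 0.5, 1, 2, 4, ...): the frames
    are always a prefix starting at the beginning of session one; a
    fractional amount takes the leading floor(frac * frames) of the next
    session. ``None`` keeps everything.
    """
    if len(sessions) == 0:
        raise ValueError("no sessions")
    mats = [np.asarray(s, dtype=float) for s in sessions]
    if session_amount is None:
        return np.concatenate(mats, axis=1)
    amount = float(session_amount)
    if amount <= 0:
        raise ValueError("session_amount must be positive")
    if amount > len(mats):
        raise ValueError(
            f"session_amount {amount} exceeds the {len(mats)} available sessions"
        )
    n_full = int(amount)
    frac = amount - n_full
    parts = mats[:n_full]
    if frac > 0:
        nxt = mats[n_full]
        n_frames = int(frac * nxt.shape[1])
        if n_frames < 1:
            raise ValueError("fractional session amount selects no frames")
        parts = parts + [nxt[:, :n_frames]]
    return np.concatenate(parts, axis=1)


def compute_feature(
    ts: np.ndarray,
    feature_name: str,
    basis: HarmonicBasis | None = None,
    tr_seconds: float = 0.72,
) -> np.ndarray:
    """One subject's feature vector from a concatenated region x frame array."""
    if feature_name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature_name!r}; expected one of {FEATURE_NAMES}")
    if feature_name in GSP_FEATURES and basis is None:
        raise ValueError(f"feature {feature_name!r} requires a harmonic basis")
    if feature_name == "fc":
        return fc(ts)
    if feature_name == "mean":
        return regional_mean(ts)
    if feature_name == "sd":
        return regional_sd(ts)
    if feature_name == "mssd":
        return mssd(ts)
    if feature_name == "falff":
        return falff(ts, tr_seconds)
    if feature_name == "psd":
        return graph_psd(gft(ts, basis))
    if feature_name == "sdi":
        return sdi(ts, basis)
    if feature_name == "coupled_fc":
        return coupled_fc(ts, basis)
    return decoupled_fc(ts, basis)


def build_feature_matrix(
    cohort,
    feature_name: str,
    basis: HarmonicBasis | None = None,
    session_amount: float | None = None,
    preprocess_config=None,
    tr_seconds: float = 0.72,
) -> FeatureMatrix:
    """Stack one feature vector per subject, in cohort order.

    Each subject's sessions are preprocessed individually (when a config is
    given), concatenated along time — truncated to ``session_amount`` if set —
    and reduced to one feature vector. GSP features need the harmonic
    ``basis`` of the relevant training set's consensus connectome.
    """
    from .preprocess import preprocess_session  # local import: avoid cycle at module load

    rows = []
    ids = []
    for rec in cohort:
        if preprocess_config is not None:
            sessions = [
                preprocess_session(ts, conf, preprocess_config, tr_seconds)
                for ts, conf in zip(rec.sessions, rec.confounds)
            ]
        else:
            sessions = rec.sessions
        ts = concat_sessions(sessions, session_amount)
        rows.append(compute_feature(ts, feature_name, basis, tr_seconds))
        ids.append(rec.subject_id)
    return FeatureMatrix(
        values=np.vstack(rows), feature_name=feature_name, subject_ids=ids
    )
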