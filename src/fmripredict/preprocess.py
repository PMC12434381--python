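"""Parcel-level BOLD denoising.

The chain mirrors the standard resting-state cleanup applied to minimally
preprocessed, parcellated time series: drop the initial frames affected by
scanner drift, regress out motion confounds (with their first-order
derivatives) together with a linear trend, and temporally high-pass filter.
The fixed order is discard -> confound regression (incl. detrend) ->
high-pass; spatial operations (realignment, distortion correction) are out of
scope because the input is already parcel-level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class PreprocessConfig:
    """Denoising parameters.

    Parameters
    ----------
    n_discard : int
        Initial frames dropped from every session (default 6).
    highpass_hz : float
        High-pass cutoff in Hz (default 0.01). Must lie below Nyquist for the
        sampling interval in use.
    motion, motion_derivatives, linear_trend : bool
        Which columns enter the confound design matrix, besides an intercept
        which is always included.
    """

    n_discard: int = 6
    highpass_hz: float = 0.01
    motion: bool = True
    motion_derivatives: bool = True
    linear_trend: bool = True

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.highpass_hz <= 0:
            raise ValueError("highpass_hz must be positive")


def discard_frames(ts: np.ndarray, n_discard: int) -> np.ndarray:
    """Drop the first ``n_discard`` frames (columns) of a region x frame array."""
    ts = np.asarray(ts, dtype=float)
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= ts.shape[1]:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.shape[1]} frames: output would be empty"
        )
    return ts[:, n_discard:]


def build_confound_design(
    confounds: np.ndarray | None,
    n_frames: int,
    config: PreprocessConfig,
) -> np.ndarray:
    """Assemble the confound design matrix: intercept, motion, derivatives, trend.

    Derivatives are backward differences with the first element set to 0, so
    the series length is preserved.
    """
    cols = [np.ones(n_frames)]
    if confounds is not None and config.motion:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.shape[0] != n_frames:
            raise ValueError(
                f"confounds have {confounds.shape[0]} frames, time series has {n_frames}"
            )
        cols.append(confounds)
        if config.motion_derivatives:
            deriv = np.diff(confounds, axis=0, prepend=confounds[:1])
            deriv[0] = 0.0
            cols.append(deriv)
    if config.linear_trend:
        trend = np.linspace(-1.0, 1.0, n_frames)
        cols.append(trend[:, None])
    design = np.column_stack(cols)
    return design


def regress_confounds(
    ts: np.ndarray,
    confounds: np.ndarray | None,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Return residuals of each region's series after OLS on the confound design.

    Residuals are orthogonal to every design column. Raises if the design is
    rank deficient (e.g. an all-zero confound column duplicating the
    intercept's span, or duplicated regressors).
    """
    config = config or PreprocessConfig()
    ts = np.asarray(ts, dtype=float)
    n_frames = ts.shape[1]
    design = build_confound_design(confounds, n_frames, config)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"confound design is rank deficient (rank {rank} < {design.shape[1]} columns)"
        )
    beta, *_ = np.linalg.lstsq(design, ts.T, rcond=None)
    return ts - (design @ beta).T


def highpass(ts: np.ndarray, tr_seconds: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase high-pass filter along time (order-2 Butterworth, filtfilt).

    Forward-backward application squares the magnitude response (order-4
    equivalent) and avoids phase distortion that would corrupt successive-
    difference statistics.
    """
    ts = np.asarray(ts, dtype=float)
    nyquist = 0.5 / tr_seconds
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:g}) Hz")
    sos = signal.butter(2, cutoff_hz / nyquist, btype="highpass", output="sos")
    return signal.sosfiltfilt(sos, ts, axis=1)


def preprocess_session(
    ts: np.ndarray,
    confounds: np.ndarray | None,
    config: PreprocessConfig,
    tr_seconds: float,
) -> np.ndarray:
    """Apply the full chain to one session: discard, regress, high-pass."""
    out = discard_frames(ts, config.n_discard)
    conf = None
    if confounds is not None:
        conf = np.asarray(confounds, dtype=float)[config.n_discard :]
    out = regress_confounds(out, conf, config)
    out = highpass(out, tr_seconds, config.highpass_hz)
    return out
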