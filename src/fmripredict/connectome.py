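"""Consensus structural connectome and its harmonic basis.

A group-level structural connectivity (SC) matrix is built from the SCs of
the *training* subjects only: a binary consensus mask (edges ranked by
across-subject occurrence) is Hadamard-multiplied with the element-wise mean
weight matrix. The connectome harmonics are the eigenvectors of the symmetric
normalized Laplacian of that consensus matrix; they form the orthonormal
basis of the graph Fourier transform used by all graph-signal features.

The consensus is recomputed per training set by the caller — nothing in this
module may see test subjects (see the leakage tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConsensusSC:
    """Group consensus SC: masked mean of subject weight matrices."""

    weights: np.ndarray
    mask: np.ndarray
    subject_ids_used: list = field(default_factory=list)


@dataclass
class HarmonicBasis:
    """Eigenpairs of the symmetric normalized Laplacian.

    ``eigenvalues`` ascend in [0, 2]; column k of ``eigenvectors`` belongs to
    eigenvalue k. Low eigenvalues correspond to spatially smooth harmonics
    (signal coupled to structure), high eigenvalues to rough ones.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.eigenvectors.shape[0]


def _check_sc_stack(scs: list[np.ndarray]) -> np.ndarray:
    if len(scs) == 0:
        raise ValueError("need at least one subject SC")
    stack = np.asarray(scs, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("subject SCs must share one square shape")
    return stack


def consensus_mask(
    scs: list[np.ndarray], target_density: float | str = "auto"
) -> np.ndarray:
    """Binary consensus mask by occurrence-ranked edge selection.

    Edges (upper-triangle pairs) are ranked by descending across-subject
    occurrence frequency, ties broken by descending mean weight then by
    edge index, and kept until the requested edge density is reached.
    ``target_density='auto'`` uses the mean subject edge density, so the
    consensus preserves the typical individual sparsity.
    """
    stack = _check_sc_stack(scs)
    n = stack.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    occurrence = (stack[:, iu, ju] > 0).mean(axis=0)
    mean_w = stack[:, iu, ju].mean(axis=0)

    n_pairs = iu.size
    if target_density == "auto":
        density = float((stack[:, iu, ju] > 0).mean())
    else:
        density = float(target_density)
        if not 0 < density <= 1:
            raise ValueError("target_density must be in (0, 1]")
    n_keep = int(round(density * n_pairs))
    # never keep edges absent in every subject
    n_keep = min(n_keep, int((occurrence > 0).sum()))

    order = np.lexsort((np.arange(n_pairs), -mean_w, -occurrence))
    keep = order[:n_keep]
    mask = np.zeros((n, n))
    mask[iu[keep], ju[keep]] = 1.0
    return mask + mask.T


def consensus_sc(
    scs: list[np.ndarray],
    subject_ids: list | None = None,
    target_density: float | str = "auto",
) -> ConsensusSC:
    """Masked mean SC: Hadamard product of consensus mask and mean weights."""
    stack = _check_sc_stack(scs)
    mask = consensus_mask(list(stack), target_density)
    weights = mask * stack.mean(axis=0)
    return ConsensusSC(
        weights=weights, mask=mask, subject_ids_used=list(subject_ids or [])
    )


def normalized_laplacian(sc: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian L = I - D^{-1/2} A D^{-1/2}.

    Requires a symmetric non-negative matrix with zero diagonal and no
    isolated node; the spectrum then lies in [0, 2] with a zero eigenvalue
    for each connected component.
    """
    a = np.asarray(sc, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("SC must be square")
    if not np.allclose(a, a.T):
        raise ValueError("SC must be symmetric")
    if (a < 0).any():
        raise ValueError("SC weights must be non-negative")
    deg = a.sum(axis=1)
    if (deg <= 0).any():
        bad = int(np.flatnonzero(deg <= 0)[0])
        raise ValueError(f"isolated node (zero degree) at index {bad}")
    d_isqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(a.shape[0]) - d_isqrt[:, None] * a * d_isqrt[None, :]
    return (lap + lap.T) / 2.0


def harmonic_basis(lap: np.ndarray) -> HarmonicBasis:
    """Eigendecompose a symmetric Laplacian into an ordered, sign-fixed basis.

    Eigenvalues ascend; each eigenvector's sign is fixed so that its
    largest-magnitude entry (first such index on ties) is positive, making
    graph Fourier coefficients reproducible across runs and platforms.
    """
    lap = np.asarray(lap, dtype=float)
    if not np.allclose(lap, lap.T, atol=1e-10):
        raise ValueError("Laplacian must be symmetric")
    evals, evecs = np.linalg.eigh(lap)
    for k in range(evecs.shape[1]):
        col = evecs[:, k]
        lead = int(np.argmax(np.abs(col)))
        if col[lead] < 0:
            evecs[:, k] = -col
    return HarmonicBasis(eigenvalues=evals, eigenvectors=evecs)


def basis_from_subjects(
    scs: list[np.ndarray],
    subject_ids: list | None = None,
    target_density: float | str = "auto",
) -> tuple[ConsensusSC, HarmonicBasis]:
    """Consensus SC and its harmonic basis from a set of (training) subjects."""
    cons = consensus_sc(scs, subject_ids, target_density)
    basis = harmonic_basis(normalized_laplacian(cons.weights))
    return cons, basis
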