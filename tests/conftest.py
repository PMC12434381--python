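"""Shared fixtures: small synthetic cohorts and harmonic bases.

Everything is generated at test time; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from fmripredict import CohortConfig, generate_cohort, harmonic_basis, normalized_laplacian
from fmripredict.synthetic import SubjectRecord


def random_connected_graph(n: int, seed: int) -> np.ndarray:
    """Random weighted graph guaranteed connected (ring + random extra edges)."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        w[i, j] = w[j, i] = rng.uniform(0.5, 1.5)
    iu, ju = np.triu_indices(n, k=1)
    extra = rng.random(iu.size) < 0.3
    vals = rng.uniform(0.1, 1.0, iu.size)
    w[iu[extra], ju[extra]] = np.maximum(w[iu[extra], ju[extra]], vals[extra])
    w[ju[extra], iu[extra]] = w[iu[extra], ju[extra]]
    return w


def make_stub_subjects(family_sizes: list[int]) -> list[SubjectRecord]:
    """Minimal records (no imaging data) for split/partition logic tests."""
    records = []
    s = 0
    for f, size in enumerate(family_sizes):
        for _ in range(size):
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{s:04d}",
                    family_id=f"fam-{f:04d}",
                    sc=np.zeros((2, 2)),
                    sessions=[],
                    confounds=[],
                    targets_continuous={},
                    target_binary=0,
                )
            )
            s += 1
    return records


@pytest.fixture(scope="session")
def basis12():
    return harmonic_basis(normalized_laplacian(random_connected_graph(12, seed=3)))


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(
        n_subjects=24,
        n_regions=12,
        n_sessions=2,
        frames_per_session=60,
        n_communities=3,
        seed=7,
    )
    return generate_cohort(cfg)
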