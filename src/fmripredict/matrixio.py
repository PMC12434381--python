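"""Delimited-text matrix I/O.

All matrices (SC, BOLD sessions, confounds, eigenvectors, feature matrices)
are exchanged as plain TSV with a one-line ``# rows cols`` header so files are
diffable and self-describing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_matrix(path: str | Path, arr: np.ndarray) -> None:
    """Write a 2-D array as TSV with a ``# rows cols`` sidecar header line."""
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {arr.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, arr, delimiter="\t", header=f"{arr.shape[0]} {arr.shape[1]}")


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a matrix written by :func:`write_matrix`, validating the header."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    if header.startswith("#"):
        try:
            rows, cols = (int(t) for t in header[1:].split())
        except ValueError:
            return arr
        if arr.shape != (rows, cols):
            raise ValueError(
                f"{path}: header promises {rows}x{cols}, file holds {arr.shape}"
            )
    return arr
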