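"""Edge vectorization: fixed row-major upper-triangle convention.

A symmetric n x n matrix with zero diagonal maps to a length
n*(n-1)/2 vector taken over the strict upper triangle (i < j), rows
first. For n = 68 this gives 2278 edges. Every module in the package
uses this one convention.
"""

from __future__ import annotations

import numpy as np

N_REGIONS_DEFAULT = 68


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def triu_indices(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle, row-major."""
    return np.triu_indices(n_regions, k=1)


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Upper-triangle vector of a square matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    i, j = triu_indices(m.shape[0])
    return m[i, j]


def unvectorize(edges: np.ndarray, n_regions: int) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from an edge vector."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (n_edges(n_regions),):
        raise ValueError(
            f"edge vector has length {edges.shape}, expected {n_edges(n_regions)} "
            f"for {n_regions} regions"
        )
    m = np.zeros((n_regions, n_regions))
    i, j = triu_indices(n_regions)
    m[i, j] = edges
    m[j, i] = edges
    return m
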