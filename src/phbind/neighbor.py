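"""Minimum-image distances and cell-list neighbour search.

The cell list only *prunes* candidate pairs; distances for surviving
candidates are computed with exactly the same minimum-image formula as a
brute-force all-pairs search, so the result sets are bit-identical to the
O(N^2) oracle whenever ``cutoff <= min(box)/2``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["min_image_vectors", "min_image_distance", "pairs_within_cutoff"]


def min_image_vectors(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Pairwise minimum-image distance matrix between point sets a and b."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    delta = min_image_vectors(a[:, None, :] - b[None, :, :], box)
    return np.sqrt(np.sum(delta * delta, axis=-1))


def pairs_within_cutoff(a, b, box, cutoff: float):
    """Index pairs ``(i, j)`` with minimum-image ``|a_i - b_j| <= cutoff``.

    Uses a cell list over ``b`` with cell edge >= cutoff. Falls back to
    brute force when the box supports fewer than 3 cells along any axis
    (the cell decomposition then offers no pruning).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    box = np.asarray(box, dtype=float)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff > np.min(box) / 2:
        raise ValueError("cutoff exceeds half the smallest box edge")
    if a.size == 0 or b.size == 0:
        return np.empty((0, 2), dtype=int)

    n_cells = np.maximum(np.floor(box / cutoff).astype(int), 1)
    if np.any(n_cells < 3):
        d = min_image_distance(a, b, box)
        ii, jj = np.nonzero(d <= cutoff)
        return np.column_stack([ii, jj])

    cell_edge = box / n_cells
    b_wrapped = np.mod(b, box)
    b_cells = np.minimum((b_wrapped / cell_edge).astype(int), n_cells - 1)
    b_flat = (b_cells[:, 0] * n_cells[1] + b_cells[:, 1]) * n_cells[2] + b_cells[:, 2]
    order = np.argsort(b_flat, kind="stable")
    sorted_flat = b_flat[order]
    starts = np.searchsorted(sorted_flat, np.arange(np.prod(n_cells)))
    ends = np.searchsorted(sorted_flat, np.arange(np.prod(n_cells)), side="right")

    a_wrapped = np.mod(a, box)
    a_cells = np.minimum((a_wrapped / cell_edge).astype(int), n_cells - 1)
    offsets = np.array(
        [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    )
    out = []
    for i, ac in enumerate(a_cells):
        neigh = np.mod(ac + offsets, n_cells)
        flat = (neigh[:, 0] * n_cells[1] + neigh[:, 1]) * n_cells[2] + neigh[:, 2]
        cand = np.concatenate([order[starts[f]:ends[f]] for f in np.unique(flat)])
        if cand.size == 0:
            continue
        d = min_image_distance(a[i], b[cand], box)[0]
        hits = cand[d <= cutoff]
        out.extend((i, int(j)) for j in np.sort(hits))
    if not out:
        return np.empty((0, 2), dtype=int)
    return np.asarray(out, dtype=int)
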