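"""Fixed team grid and nearest-colleague resolution.

Workers are laid out row-major on a rectangular grid (the default crew is
200 workers on a 20x10 grid).  The colleague effect for a worker is the mean
risk acceptance of their k nearest co-workers (default k=20) by Euclidean
distance on grid coordinates, with ties broken by ascending worker id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TeamLayout", "build_layout", "nearest_colleagues", "colleague_acceptance"]

DEFAULT_K = 20


@dataclass
class TeamLayout:
    """Row-major grid placement plus the cached nearest-colleague table."""

    n_cols: int
    n_rows: int
    positions: np.ndarray  # shape (N, 2), columns (col, row)
    neighbor_table: np.ndarray  # shape (N, k), neighbor ids sorted by (distance, id)

    @property
    def n_workers(self) -> int:
        return self.positions.shape[0]

    @property
    def k(self) -> int:
        return self.neighbor_table.shape[1]


def _neighbor_table(positions: np.ndarray, k: int) -> np.ndarray:
    n = positions.shape[0]
    k_eff = min(k, n - 1)
    if k_eff <= 0:
        return np.empty((n, 0), dtype=np.intp)
    diff = positions[:, None, :] - positions[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    # exclude self; ties broken by ascending id via stable sort on ids first
    np.fill_diagonal(dist2, np.iinfo(np.int64).max)
    order = np.argsort(dist2, axis=1, kind="stable")  # ids are the tie-break
    return order[:, :k_eff].astype(np.intp)


def build_layout(
    n_workers: int, n_cols: int = 20, n_rows: int = 10, k: int = DEFAULT_K
) -> TeamLayout:
    """Place ``n_workers`` row-major on an ``n_cols`` x ``n_rows`` grid.

    Worker 0 sits at (0, 0), worker ``n_cols - 1`` at (n_cols-1, 0), worker
    ``n_cols`` at (0, 1), and so on.  Raises ``ValueError`` when the grid does
    not hold exactly ``n_workers``.
    """
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    if n_cols * n_rows != n_workers:
        raise ValueError(
            f"grid {n_cols}x{n_rows} holds {n_cols * n_rows} workers, "
            f"not n_workers={n_workers}"
        )
    ids = np.arange(n_workers)
    positions = np.column_stack([ids % n_cols, ids // n_cols]).astype(np.int64)
    return TeamLayout(n_cols, n_rows, positions, _neighbor_table(positions, k))


def nearest_colleagues(layout: TeamLayout, worker: int, k: int = DEFAULT_K) -> np.ndarray:
    """The ``min(k, N-1)`` workers nearest to ``worker``, nearest first.

    Served from the cached table when it is wide enough; ties are always
    broken by ascending id.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not 0 <= worker < layout.n_workers:
        raise ValueError(f"unknown worker id {worker}")
    if k <= layout.k:
        return layout.neighbor_table[worker, : min(k, layout.n_workers - 1)].copy()
    return _neighbor_table(layout.positions, k)[worker]


def colleague_acceptance(neighbor_ras, own_ra: float | None = None) -> float:
    """Colleague effect: mean of the neighbors' previous-day risk acceptance.

    A degenerate one-worker team has no colleagues; the worker's own
    acceptance is returned instead.
    """
    arr = np.asarray(neighbor_ras, dtype=float)
    if arr.size == 0:
        if own_ra is None:
            raise ValueError("empty neighbor list requires own_ra fallback")
        return float(own_ra)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("neighbor risk acceptances must lie in [0, 1]")
    return float(arr.mean())
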