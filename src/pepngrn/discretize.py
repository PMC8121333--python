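"""Per-gene discretization of continuous expression into k levels.

All three methods operate row-wise on the concatenation of every time
series for a gene, so a gene gets one set of thresholds across experiments:

* equal-width (``ewd``): bin width ``(max - min) / k``, half-open bins with
  the global maximum clamped into the top bin;
* equal-frequency (``efd``): stable sort, then split into k bins whose
  sizes differ by at most one (remainder assigned to the lowest bins);
* 1-D k-means (``kmeans``): Lloyd iterations from deterministic quantile
  initial centres, clusters relabelled by ascending centre.

Constant rows map wholly to level 0 under every method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import DiscretizedDataset, TimeSeriesDataset

METHODS = ("ewd", "efd", "kmeans")


@dataclass(frozen=True)
class DiscretizationConfig:
    method: str = "efd"
    n_bins: int = 2
    seed: int = 0  # documentation only: all methods below are deterministic

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def discretize(data: TimeSeriesDataset, config: DiscretizationConfig) -> DiscretizedDataset:
    fn = {"ewd": discretize_ewd, "efd": discretize_efd, "kmeans": discretize_kmeans}
    return fn[config.method](data, config.n_bins)


def _apply_rowwise(data: TimeSeriesDataset, k: int, row_fn) -> DiscretizedDataset:
    if k < 2:
        raise ValueError("k must be >= 2")
    concat = data.concatenated()
    levels = np.vstack([row_fn(concat[g], k) for g in range(data.n_genes)])
    # split back into the original per-series blocks
    out, start = [], 0
    for mat in data.series:
        n = mat.shape[1]
        out.append(levels[:, start:start + n])
        start += n
    return DiscretizedDataset(gene_names=list(data.gene_names), series=out, n_bins=k)


def discretize_ewd(data: TimeSeriesDataset, k: int) -> DiscretizedDataset:
    return _apply_rowwise(data, k, _ewd_row)


def discretize_efd(data: TimeSeriesDataset, k: int) -> DiscretizedDataset:
    return _apply_rowwise(data, k, _efd_row)


def discretize_kmeans(data: TimeSeriesDataset, k: int) -> DiscretizedDataset:
    return _apply_rowwise(data, k, _kmeans_row)


def _ewd_row(row: np.ndarray, k: int) -> np.ndarray:
    lo, hi = row.min(), row.max()
    if hi == lo:
        return np.zeros(row.shape, dtype=np.int64)
    thresh = (hi - lo) / k
    return np.minimum(np.floor((row - lo) / thresh).astype(np.int64), k - 1)


def _efd_row(row: np.ndarray, k: int) -> np.ndarray:
    n = row.size
    if row.min() == row.max():
        return np.zeros(n, dtype=np.int64)
    base, rem = divmod(n, k)
    # remainder spread over the lowest bins, so bin sizes differ by <= 1
    sizes = [base + (1 if b < rem else 0) for b in range(k)]
    order = np.argsort(row, kind="stable")
    levels = np.empty(n, dtype=np.int64)
    start = 0
    for b, size in enumerate(sizes):
        levels[order[start:start + size]] = b
        start += size
    return levels


def _kmeans_row(row: np.ndarray, k: int, tol: float = 1e-9, max_iter: int = 300) -> np.ndarray:
    distinct = np.unique(row)
    if distinct.size == 1:
        return np.zeros(row.shape, dtype=np.int64)
    if distinct.size < k:
        # fewer distinct values than clusters: each value is its own cluster
        return np.searchsorted(distinct, row).astype(np.int64)
    centres = np.quantile(row, [(2 * i + 1) / (2 * k) for i in range(k)])
    centres = _split_duplicate_centres(centres, distinct)
    for _ in range(max_iter):
        assign = np.argmin(np.abs(row[:, None] - centres[None, :]), axis=1)
        # reseed any emptied cluster at the point farthest from its centre,
        # so k distinct values always yield k non-empty clusters
        for c in range(k):
            if not np.any(assign == c):
                far = int(np.argmax(np.abs(row - centres[assign])))
                centres[c] = row[far]
                assign = np.argmin(np.abs(row[:, None] - centres[None, :]), axis=1)
        new = centres.copy()
        for c in range(k):
            members = row[assign == c]
            if members.size:
                new[c] = members.mean()
        if np.max(np.abs(new - centres)) < tol:
            centres = new
            break
        centres = new
    assign = np.argmin(np.abs(row[:, None] - centres[None, :]), axis=1)
    # relabel clusters 0..k-1 by ascending centre, dropping empty clusters
    used = np.unique(assign)
    order = used[np.argsort(centres[used], kind="stable")]
    relabel = np.empty(centres.size, dtype=np.int64)
    relabel[order] = np.arange(order.size)
    return relabel[assign]


def _split_duplicate_centres(centres: np.ndarray, distinct: np.ndarray) -> np.ndarray:
    """Quantile init can collide on skewed rows; nudge duplicates apart."""
    centres = np.sort(centres)
    if np.unique(centres).size == centres.size:
        return centres
    out, taken = [], set()
    for c in centres:
        if c not in taken:
            out.append(c)
            taken.add(c)
        else:
            free = [v for v in distinct if v not in taken]
            if free:
                pick = free[int(np.argmin(np.abs(np.array(free) - c)))]
                out.append(pick)
                taken.add(pick)
            else:
                out.append(c)
    return np.sort(np.array(out, dtype=float))
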