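"""Core in-memory containers shared by every stage of the pipeline.

The method operates on one or more time series measured over the same set
of ``p`` genes.  Continuous expression is held in :class:`TimeSeriesDataset`,
its discrete counterpart (levels ``0..k-1``) in :class:`DiscretizedDataset`.
Inferred interactions are ``(regulator, target, sign)`` triplets with a
score in ``[0, 1]`` (:class:`ScoredEdge`); reference networks are
:class:`GoldStandard` objects, optionally carrying regulation signs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

Pair = Tuple[str, str]

ACTIVATION = 1
INHIBITION = -1


def _check_gene_names(gene_names: Sequence[str]) -> List[str]:
    names = list(gene_names)
    if len(names) < 2:
        raise ValueError("a dataset needs at least 2 genes")
    if len(set(names)) != len(names):
        dupes = sorted({g for g in names if names.count(g) > 1})
        raise ValueError(f"duplicate gene name(s): {', '.join(dupes)}")
    return names


@dataclass
class TimeSeriesDataset:
    """Continuous expression for ``p`` genes over one or more time series.

    Each entry of ``series`` is a ``p x n_s`` float matrix (genes in rows,
    time points in columns); all series share ``gene_names`` ordering.
    ``time_labels`` is informational only.
    """

    gene_names: List[str]
    series: List[np.ndarray]
    time_labels: Optional[List[List[float]]] = None

    def __post_init__(self) -> None:
        self.gene_names = _check_gene_names(self.gene_names)
        p = len(self.gene_names)
        mats = []
        for i, mat in enumerate(self.series):
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != p:
                raise ValueError(
                    f"series {i} has shape {mat.shape}, expected {p} gene rows"
                )
            if mat.shape[1] < 2:
                raise ValueError(f"series {i} has fewer than 2 time points")
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"series {i} contains missing/non-finite values")
            mats.append(mat)
        if not mats:
            raise ValueError("dataset must contain at least one series")
        self.series = mats

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_series(self) -> int:
        return len(self.series)

    def concatenated(self) -> np.ndarray:
        """All series stacked along the time axis, one ``p x n_total`` matrix."""
        return np.concatenate(self.series, axis=1)


@dataclass
class DiscretizedDataset:
    """Integer-level expression with levels in ``{0..n_bins-1}``."""

    gene_names: List[str]
    series: List[np.ndarray]
    n_bins: int

    def __post_init__(self) -> None:
        self.gene_names = _check_gene_names(self.gene_names)
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        p = len(self.gene_names)
        mats = []
        for i, mat in enumerate(self.series):
            mat = np.asarray(mat)
            if not np.issubdtype(mat.dtype, np.integer):
                as_int = mat.astype(int)
                if not np.array_equal(as_int, mat):
                    raise ValueError(f"series {i} has non-integer levels")
                mat = as_int
            if mat.ndim != 2 or mat.shape[0] != p:
                raise ValueError(
                    f"series {i} has shape {mat.shape}, expected {p} gene rows"
                )
            if mat.min() < 0 or mat.max() > self.n_bins - 1:
                raise ValueError(
                    f"series {i} has levels outside [0, {self.n_bins - 1}]"
                )
            mats.append(mat.astype(np.int64))
        if not mats:
            raise ValueError("dataset must contain at least one series")
        self.series = mats

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.series, axis=1)


@dataclass
class GoldStandard:
    """A reference network: directed edges, optionally signed.

    ``signs`` maps ``(regulator, target)`` to +1 (activation) or -1
    (inhibition) and must cover every edge exactly when ``signed`` is True.
    """

    edges: Set[Pair]
    signs: Optional[Dict[Pair, int]] = None
    signed: bool = False

    def __post_init__(self) -> None:
        for reg, tgt in self.edges:
            if reg == tgt:
                raise ValueError(f"self edge not allowed: {reg}")
        if self.signed:
            if self.signs is None or set(self.signs) != self.edges:
                raise ValueError("signed gold standard must map every edge to a sign")
            bad = [e for e, s in self.signs.items() if s not in (ACTIVATION, INHIBITION)]
            if bad:
                raise ValueError(f"invalid sign for edge(s) {bad}")
        elif self.signs:
            raise ValueError("signs given but signed flag is False")

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for reg, tgt in self.edges:
            out.add(reg)
            out.add(tgt)
        return out

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.edges


@dataclass(frozen=True, order=True)
class ScoredEdge:
    """One ranked interaction.

    ``sign`` is +1 for activation, -1 for inhibition, 0 when the run carries
    no sign information (unsigned supervised mode).  Field order makes the
    natural sort lexicographic (regulator, target); ranked output instead
    sorts by descending score with that order as tie-break.
    """

    regulator: str
    target: str
    sign: int
    score: float

    def __post_init__(self) -> None:
        if self.regulator == self.target:
            raise ValueError(f"self edge not allowed: {self.regulator}")
        if self.sign not in (ACTIVATION, INHIBITION, 0):
            raise ValueError(f"sign must be +1, -1 or 0, got {self.sign}")
        if not (0.0 <= self.score <= 1.0) or not np.isfinite(self.score):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def pair(self) -> Pair:
        return (self.regulator, self.target)


def rank_edges(edges: Sequence[ScoredEdge]) -> List[ScoredEdge]:
    """Total order: score non-increasing, ties broken lexicographically."""
    return sorted(edges, key=lambda e: (-e.score, e.regulator, e.target))
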