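"""Score aggregation, sign selection, decay estimation and thresholding.

Two unsupervised aggregation variants turn an evidence table into edge
scores:

* ``v1`` — unweighted: the mean of the four evidence probabilities,
  ``Score(r,t,s) = (1/4) Σ_e Pr_e(r,t,s)``, missing evidence contributing 0;
* ``v2`` — count-weighted: ``Σ_e C_e(r,t,s) / Σ_e C_e(t)``, so evidence
  types that occur more often weigh more.

A v1/v2 score is a *conditional* sign probability: assuming the edge
exists, how strongly the data favour that regulation sign.  Hence for a
target showing all four evidence types the two signs of a pair sum to 1
under v1 (and whenever any evidence exists under v2), and pairs whose two
signs tie exactly are discarded as clear false positives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, NamedTuple

import numpy as np

from .datatypes import (
    ACTIVATION,
    INHIBITION,
    DiscretizedDataset,
    GoldStandard,
    Pair,
    ScoredEdge,
    rank_edges,
)
from .evidence import EvidenceTable


def score_v1(table: EvidenceTable) -> List[ScoredEdge]:
    """Unweighted aggregation: mean of the four evidence probabilities."""
    scores = table.probabilities.mean(axis=0)  # 2 x n_reg x p
    return _edges_from_matrix(table, scores)


def score_v2(table: EvidenceTable) -> List[ScoredEdge]:
    """Count-weighted aggregation: summed counts over summed target totals."""
    num = table.counts.sum(axis=0)              # 2 x n_reg x p
    den = table.target_totals.sum(axis=0)       # p
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den[None, None, :] > 0,
                          num / np.maximum(den[None, None, :], 1), 0.0)
    return _edges_from_matrix(table, scores)


def _edges_from_matrix(table: EvidenceTable, scores: np.ndarray) -> List[ScoredEdge]:
    out = []
    for s, sign in ((0, ACTIVATION), (1, INHIBITION)):
        for ri, reg in enumerate(table.regulators):
            for ti, tgt in enumerate(table.gene_names):
                if reg == tgt:
                    continue
                out.append(ScoredEdge(reg, tgt, sign, float(scores[s, ri, ti])))
    return out


def select_signs(edges: Iterable[ScoredEdge], tolerance: float = 1e-12) -> List[ScoredEdge]:
    """Keep the higher-scoring sign per pair; discard exact ties entirely.

    A regulator either activates or inhibits a target, never both, so equal
    scores across the two signs flag a spurious pair.  Pairs present with a
    single sign keep it.
    """
    by_pair: Dict[Pair, Dict[int, ScoredEdge]] = {}
    for e in edges:
        slot = by_pair.setdefault(e.pair, {})
        if e.sign in slot:
            raise ValueError(f"duplicate entry for {e.pair} sign {e.sign}")
        slot[e.sign] = e
    kept = []
    for pair in by_pair:
        slot = by_pair[pair]
        if len(slot) == 1:
            kept.append(next(iter(slot.values())))
            continue
        plus, minus = slot[ACTIVATION], slot[INHIBITION]
        if abs(plus.score - minus.score) <= tolerance:
            continue
        kept.append(plus if plus.score > minus.score else minus)
    return rank_edges(kept)


@dataclass
class DecayProfile:
    """Per-gene decay frequency: how often the gene steps down when expressed."""

    gene_names: List[str]
    decay_count: np.ndarray
    occurrence_count: np.ndarray

    @property
    def decay_prob(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.occurrence_count > 0,
                            self.decay_count / np.maximum(self.occurrence_count, 1), 0.0)

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.gene_names, self.decay_prob.tolist()))

    def to_tsv(self, path) -> None:
        from pathlib import Path
        lines = ["gene\tdecay_count\toccurrence_count\tdecay_prob"]
        for g, d, o, pr in zip(self.gene_names, self.decay_count,
                               self.occurrence_count, self.decay_prob):
            lines.append(f"{g}\t{int(d)}\t{int(o)}\t{pr:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")


def decay_probability(data: DiscretizedDataset) -> DecayProfile:
    """DecayProb(g) = (# negative within-series level steps) / (# time points with level > 0)."""
    decay = np.zeros(data.n_genes, dtype=np.int64)
    occ = np.zeros(data.n_genes, dtype=np.int64)
    for mat in data.series:
        diff = np.diff(mat, axis=1)
        decay += (diff < 0).sum(axis=1)
        occ += (mat > 0).sum(axis=1)
    return DecayProfile(gene_names=list(data.gene_names),
                        decay_count=decay, occurrence_count=occ)


@dataclass(frozen=True)
class ThresholdConfig:
    n_reg: int = 3
    th: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reg < 1:
            raise ValueError("n_reg must be >= 1")
        if not (0.0 <= self.th <= 1.0):
            raise ValueError("th must lie in [0, 1]")


def threshold_edges(edges: Iterable[ScoredEdge], cfg: ThresholdConfig) -> List[ScoredEdge]:
    """Per target keep the top ``n_reg`` regulators, then drop scores below ``th``.

    The filter order is fixed: the regulator cap applies first, the score
    floor second.  Ties within a target are broken lexicographically.
    """
    by_target: Dict[str, List[ScoredEdge]] = {}
    for e in edges:
        by_target.setdefault(e.target, []).append(e)
    kept = []
    for tgt in by_target:
        ranked = sorted(by_target[tgt], key=lambda e: (-e.score, e.regulator, e.target))
        kept.extend(e for e in ranked[: cfg.n_reg] if e.score >= cfg.th)
    return rank_edges(kept)


class NetworkLikelihood(NamedTuple):
    likelihood: float
    log10_likelihood: float


def network_likelihood(edge_probs: Mapping[Pair, float], gold: GoldStandard,
                       mode: str = "full") -> NetworkLikelihood:
    """Probability of the reference network under per-pair edge probabilities.

    ``edges_only`` multiplies P(edge) over the reference edges; ``full``
    additionally multiplies (1 - P(edge)) over every candidate non-edge.
    Returned with its log10 to avoid underflow; a reference edge at
    probability 0 yields -inf, reported rather than raised.
    """
    if mode not in ("full", "edges_only"):
        raise ValueError(f"mode must be 'full' or 'edges_only', got {mode!r}")
    for pair, p in edge_probs.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability for {pair} outside [0, 1]: {p}")
    log10 = 0.0
    for pair, p in edge_probs.items():
        if pair in gold.edges:
            log10 += math.log10(p) if p > 0 else -math.inf
        elif mode == "full":
            log10 += math.log10(1.0 - p) if p < 1 else -math.inf
    missing = [pair for pair in gold.edges if pair not in edge_probs]
    if missing:
        raise ValueError(f"no probability supplied for reference edge(s) {missing[:3]}")
    return NetworkLikelihood(likelihood=10.0 ** log10 if log10 > -math.inf else 0.0,
                             log10_likelihood=log10)
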