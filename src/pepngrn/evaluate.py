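"""Ranking evaluation against a reference network.

AUROC is computed rank-based (the probability that a true edge outranks a
false one, ties counted one half — the Mann-Whitney form, identical to
trapezoidal ROC integration).  AUPR is the non-interpolated step sum
``Σ (R_i - R_{i-1}) P_i``; interpolation conventions change the number, so
the choice is fixed and documented here.  The candidate universe for a
whole-network evaluation is every ordered non-self pair: pairs the method
discarded (e.g. sign ties) re-enter with score 0 so rankings of different
methods stay comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .datatypes import GoldStandard, Pair, ScoredEdge


def candidate_pairs(genes: Sequence[str],
                    regulators: Optional[Sequence[str]] = None) -> List[Pair]:
    """All ordered non-self (regulator, target) pairs over a gene universe."""
    regs = list(regulators) if regulators is not None else list(genes)
    return [(r, t) for r in regs for t in genes if r != t]


def scores_from_edges(edges: Iterable[ScoredEdge]) -> Dict[Pair, float]:
    out: Dict[Pair, float] = {}
    for e in edges:
        if e.pair in out:
            raise ValueError(f"duplicate scored pair {e.pair}")
        out[e.pair] = e.score
    return out


def _vectors(scores: Mapping[Pair, float], gold: GoldStandard,
             candidates: Sequence[Pair]) -> Tuple[np.ndarray, np.ndarray]:
    y = np.array([1 if pair in gold.edges else 0 for pair in candidates])
    s = np.array([scores.get(pair, 0.0) for pair in candidates], dtype=float)
    return y, s


def auroc(scores: Mapping[Pair, float], gold: GoldStandard,
          candidates: Sequence[Pair]) -> float:
    """Rank-based AUROC; NaN when either class is absent (undefined)."""
    y, s = _vectors(scores, gold, candidates)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(s)  # average ranks handle ties as half-concordant
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(scores: Mapping[Pair, float], gold: GoldStandard,
         candidates: Sequence[Pair]) -> float:
    """Non-interpolated area under the precision-recall curve."""
    y, s = _vectors(scores, gold, candidates)
    if y.sum() == 0 or y.sum() == y.size:
        return math.nan
    return float(average_precision_score(y, s))


def average_rank(scores: Mapping[Pair, float], gold: GoldStandard,
                 candidates: Sequence[Pair], n_random: int = 100,
                 seed: int = 0) -> Tuple[float, float]:
    """Mean rank (1 = best) of true edges and of a random pair sample.

    A ranking is good when true edges sit near the top (low mean rank) and
    random pairs near the bottom (high mean rank).  Ties are broken
    lexicographically so the ranking is total.
    """
    ordered = sorted(candidates,
                     key=lambda pair: (-scores.get(pair, 0.0), pair[0], pair[1]))
    rank_of = {pair: i + 1 for i, pair in enumerate(ordered)}
    true_ranks = [rank_of[pair] for pair in ordered if pair in gold.edges]
    rank_true = float(np.mean(true_ranks)) if true_ranks else math.nan
    rng = np.random.default_rng(seed)
    n = len(ordered)
    take = min(n_random, n)
    sample = rng.choice(n, size=take, replace=False)
    rank_random = float(np.mean(sample + 1))
    return rank_true, rank_random


@dataclass
class EvaluationResult:
    auroc: float
    aupr: float
    baseline_aupr: float
    average_rank_true: float
    average_rank_random: float
    n_candidates: int
    n_positives: int

    def as_dict(self) -> Dict[str, float]:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "baseline_aupr": self.baseline_aupr,
            "average_rank_true": self.average_rank_true,
            "average_rank_random": self.average_rank_random,
            "n_candidates": self.n_candidates,
            "n_positives": self.n_positives,
        }


def evaluate(scores: Mapping[Pair, float], gold: GoldStandard,
             candidates: Sequence[Pair], n_random: int = 100,
             seed: int = 0) -> EvaluationResult:
    y, _ = _vectors(scores, gold, candidates)
    n_pos = int(y.sum())
    rank_true, rank_random = average_rank(scores, gold, candidates,
                                          n_random=n_random, seed=seed)
    return EvaluationResult(
        auroc=auroc(scores, gold, candidates),
        aupr=aupr(scores, gold, candidates),
        baseline_aupr=n_pos / len(candidates) if candidates else math.nan,
        average_rank_true=rank_true,
        average_rank_random=rank_random,
        n_candidates=len(candidates),
        n_positives=n_pos,
    )


def dream_overall_score(p_auroc: Sequence[float],
                        p_aupr: Sequence[float]) -> Tuple[float, float, float]:
    """Challenge-style overall score from per-network p-values.

    Each metric's score is ``-(1/n) Σ log10(p_i)``; the overall score is the
    mean of the two.  Computing the p-values themselves (null distributions)
    is outside this package's scope — they are inputs.
    """
    for ps in (p_auroc, p_aupr):
        for p in ps:
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p-values must lie in (0, 1], got {p}")
    s_roc = -float(np.mean(np.log10(p_auroc)))
    s_pr = -float(np.mean(np.log10(p_aupr)))
    return s_roc, s_pr, (s_roc + s_pr) / 2.0
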