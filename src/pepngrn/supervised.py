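"""Supervised score aggregation (variant v3).

Instead of fixed evidence weights, v3 learns one logistic-regression model
per regulation sign from a reference network: each candidate signed edge
becomes a row of four features (its evidence probabilities), labelled 1
when the reference contains that edge with that sign.  Training folds are
balanced with SMOTE before fitting because true edges are rare.  At test
time every pair is scored by both sign models and the larger probability
wins, carrying that model's sign; the score is an edge-presence
probability, unlike the conditional sign probabilities of v1/v2.

When the reference network is unsigned a single model is trained on the
activation-sign feature vectors (the inhibition features are their
complements, hence carry no independent information).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression

from .datatypes import ACTIVATION, INHIBITION, GoldStandard, Pair, ScoredEdge, rank_edges
from .evidence import EVIDENCE_TYPES, EvidenceTable

_SIGN_AXIS = {ACTIVATION: 0, INHIBITION: 1}


@dataclass
class FeatureMatrix:
    """One row per candidate (signed) edge: the four evidence probabilities."""

    features: np.ndarray          # m x 4
    labels: np.ndarray            # m, in {0,1}
    pairs: List[Pair]             # m entries
    signs: np.ndarray             # m, in {+1,-1} (signed mode) or 0 (unsigned)

    def __post_init__(self) -> None:
        m = self.features.shape[0]
        if self.features.shape != (m, 4):
            raise ValueError("feature matrix must have 4 columns")
        if not (len(self.labels) == len(self.pairs) == len(self.signs) == m):
            raise ValueError("feature matrix components disagree in length")
        if self.features.size and (self.features.min() < 0 or self.features.max() > 1):
            raise ValueError("evidence probabilities must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        idx = np.flatnonzero(mask)
        return FeatureMatrix(self.features[idx], self.labels[idx],
                             [self.pairs[i] for i in idx], self.signs[idx])


def build_features(table: EvidenceTable, gold: GoldStandard,
                   mode: str = "signed") -> FeatureMatrix:
    """Assemble the per-edge feature matrix for one network.

    Signed mode emits a row per (regulator, target, sign): for a 10-gene
    network that is 90 ordered pairs and 180 rows.  Unsigned mode emits one
    row per pair using the activation-sign feature vector.
    """
    if mode not in ("signed", "unsigned"):
        raise ValueError(f"mode must be 'signed' or 'unsigned', got {mode!r}")
    if mode == "signed" and not gold.signed:
        raise ValueError("signed mode requires a signed gold standard")
    pr = table.probabilities  # 4 x 2 x n_reg x p
    pairs = table.candidate_pairs()
    reg_idx = {g: i for i, g in enumerate(table.regulators)}
    tgt_idx = {g: i for i, g in enumerate(table.gene_names)}

    rows, labels, out_pairs, signs = [], [], [], []
    sign_list = (ACTIVATION, INHIBITION) if mode == "signed" else (ACTIVATION,)
    for sign in sign_list:
        s = _SIGN_AXIS[sign]
        for (r, t) in pairs:
            rows.append(pr[:, s, reg_idx[r], tgt_idx[t]])
            if mode == "signed":
                labels.append(int((r, t) in gold.edges and gold.signs[(r, t)] == sign))
                signs.append(sign)
            else:
                labels.append(int((r, t) in gold.edges))
                signs.append(0)
            out_pairs.append((r, t))
    return FeatureMatrix(np.array(rows, dtype=float).reshape(-1, 4),
                         np.array(labels, dtype=int), out_pairs,
                         np.array(signs, dtype=int))


def stack_features(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    return FeatureMatrix(
        np.vstack([m.features for m in matrices]),
        np.concatenate([m.labels for m in matrices]),
        [p for m in matrices for p in m.pairs],
        np.concatenate([m.signs for m in matrices]),
    )


def smote_upsample(features: np.ndarray, labels: np.ndarray,
                   k_neighbors: int = 5, seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Balance a binary training set by synthetic minority oversampling.

    New minority points are drawn on the segment between a random minority
    point and one of its ``k_neighbors`` nearest minority neighbours, with
    a uniform interpolation factor.  The minority class is upsampled to the
    majority size exactly.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("SMOTE needs both classes present in the training data")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = n_maj - n_min
    if n_new == 0:
        return features.copy(), labels.copy()
    minority_x = features[labels == minority]
    rng = np.random.default_rng(seed)
    if n_min == 1:
        warnings.warn("minority class has a single example; duplicating it instead "
                      "of interpolating", RuntimeWarning, stacklevel=2)
        synth = np.repeat(minority_x, n_new, axis=0)
    else:
        k = min(k_neighbors, n_min - 1)
        # pairwise distances within the minority class; exclude self
        d = np.linalg.norm(minority_x[:, None, :] - minority_x[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        neighbours = np.argsort(d, axis=1, kind="stable")[:, :k]
        base = rng.integers(0, n_min, size=n_new)
        pick = rng.integers(0, k, size=n_new)
        gap = rng.uniform(0.0, 1.0, size=n_new)
        nb = neighbours[base, pick]
        synth = minority_x[base] + gap[:, None] * (minority_x[nb] - minority_x[base])
    out_x = np.vstack([features, synth])
    out_y = np.concatenate([labels, np.full(n_new, minority, dtype=int)])
    return out_x, out_y


@dataclass
class LogisticModel:
    """Bias plus one weight per evidence type: W = [w0, w_PE, w_DE, w_SPE, w_SDE]."""

    weights: np.ndarray  # length 5

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (5,):
            raise ValueError("expected 5 weights (bias + 4 evidence types)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite model weights")

    @property
    def bias(self) -> float:
        return float(self.weights[0])

    def evidence_weight(self, evidence: str) -> float:
        return float(self.weights[1 + EVIDENCE_TYPES.index(evidence)])


def fit_logistic(features: np.ndarray, labels: np.ndarray,
                 regularization: float = 100.0) -> LogisticModel:
    """Penalised maximum-likelihood fit; ``regularization`` is the inverse L2
    strength (weak by default so weights stay finite on separable data)."""
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite feature value")
    clf = LogisticRegression(C=regularization, solver="lbfgs",
                             max_iter=5000, tol=1e-10)
    clf.fit(features, np.asarray(labels, dtype=int))
    return LogisticModel(np.concatenate([clf.intercept_, clf.coef_.ravel()]))


def predict(model: LogisticModel, features: np.ndarray) -> np.ndarray:
    """Rowwise sigmoid of the linear score; P > 0.5 classifies as edge-present."""
    features = np.asarray(features, dtype=float)
    z = model.bias + features @ model.weights[1:]
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 5
    grouping: str = "by_network"
    seed: int = 0
    k_neighbors: int = 5
    regularization: float = 100.0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.grouping not in ("by_network", "by_edge"):
            raise ValueError("grouping must be 'by_network' or 'by_edge'")


@dataclass
class FoldResult:
    fold: int
    test_networks: List[int]
    edges: List[ScoredEdge]
    models: Dict[int, LogisticModel]


def run_v3(tables: Sequence[EvidenceTable], golds: Sequence[GoldStandard],
           cv: CVConfig = CVConfig(), mode: str = "signed") -> List[FoldResult]:
    """Cross-validated supervised scoring over one or more networks.

    ``by_network`` grouping holds out whole networks (with 5 networks and
    k=5 each network is scored exactly once as test); ``by_edge`` is for a
    single network and partitions its pairs at random per the seed.
    """
    if len(tables) != len(golds):
        raise ValueError("need one gold standard per evidence table")
    mats = [build_features(t, g, mode=mode) for t, g in zip(tables, golds)]

    results = []
    if cv.grouping == "by_network":
        if len(tables) < cv.k_folds:
            raise ValueError(
                f"by_network grouping needs >= {cv.k_folds} networks, got {len(tables)}"
            )
        assignment = [i % cv.k_folds for i in range(len(tables))]
        for fold in range(cv.k_folds):
            test_ids = [i for i, f in enumerate(assignment) if f == fold]
            train_ids = [i for i in range(len(tables)) if i not in test_ids]
            train = stack_features([mats[i] for i in train_ids])
            test = stack_features([mats[i] for i in test_ids])
            models = _fit_fold(train, cv, mode, fold)
            edges = _score_fold(test, models, mode)
            results.append(FoldResult(fold, test_ids, edges, models))
    else:
        if len(tables) != 1:
            raise ValueError("by_edge grouping expects a single network")
        mat = mats[0]
        pairs = sorted(set(mat.pairs))
        rng = np.random.default_rng(cv.seed)
        order = rng.permutation(len(pairs))
        fold_of_pair = {pairs[j]: i % cv.k_folds for i, j in enumerate(order)}
        row_folds = np.array([fold_of_pair[p] for p in mat.pairs])
        for fold in range(cv.k_folds):
            train = mat.subset(row_folds != fold)
            test = mat.subset(row_folds == fold)
            models = _fit_fold(train, cv, mode, fold)
            edges = _score_fold(test, models, mode)
            results.append(FoldResult(fold, [0], edges, models))
    return results


def _fit_fold(train: FeatureMatrix, cv: CVConfig, mode: str, fold: int) -> Dict[int, LogisticModel]:
    models: Dict[int, LogisticModel] = {}
    sign_list = (ACTIVATION, INHIBITION) if mode == "signed" else (0,)
    for sign in sign_list:
        sub = train.subset(train.signs == sign)
        if np.unique(sub.labels).size < 2:
            raise ValueError(
                f"fold {fold}: training rows for sign {sign:+d} contain a single class"
                if mode == "signed" else
                f"fold {fold}: training rows contain a single class"
            )
        # one seed per fold (not per sign) keeps the activation/inhibition
        # roles exchangeable, which the sign-symmetry invariant relies on
        x, y = smote_upsample(sub.features, sub.labels,
                              k_neighbors=cv.k_neighbors,
                              seed=(cv.seed * 1009 + fold * 13) % (2**31))
        models[sign] = fit_logistic(x, y, regularization=cv.regularization)
    return models


def _score_fold(test: FeatureMatrix, models: Dict[int, LogisticModel], mode: str) -> List[ScoredEdge]:
    if mode == "unsigned":
        probs = predict(models[0], test.features)
        return rank_edges([ScoredEdge(r, t, 0, float(p))
                           for (r, t), p in zip(test.pairs, probs)])
    # score each pair with both sign models; the larger probability wins and
    # the reported edge carries the winning model's sign (activation on ties)
    act_rows = test.subset(test.signs == ACTIVATION)
    inh_rows = test.subset(test.signs == INHIBITION)
    p_act = dict(zip(act_rows.pairs, predict(models[ACTIVATION], act_rows.features)))
    p_inh = dict(zip(inh_rows.pairs, predict(models[INHIBITION], inh_rows.features)))
    edges = []
    for pair in sorted(set(test.pairs)):
        pa = p_act.get(pair)
        pi = p_inh.get(pair)
        if pa is not None and (pi is None or pa >= pi):
            edges.append(ScoredEdge(pair[0], pair[1], ACTIVATION, float(pa)))
        else:
            edges.append(ScoredEdge(pair[0], pair[1], INHIBITION, float(pi)))
    return rank_edges(edges)
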