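"""Transition-evidence extraction from adjacent state pairs.

Between two adjacent time points a target gene can exhibit one of four
events, each an *evidence type* about its regulators:

===================  ==========================  ==========================
evidence             2-bin target transition     3-bin target transition
===================  ==========================  ==========================
production (PE)      0 -> 1                      {0,1} -> 2
decay (DE)           1 -> 0                      {2,1} -> 0
sustained prod (SPE) 1 -> 1                      2 -> 2
sustained decay(SDE) 0 -> 0                      0 -> 0
===================  ==========================  ==========================

(Other 3-bin transitions carry no evidence.)  For each event, every
candidate regulator's level at the *earlier* time point implies a sign:
for production-side evidence (PE, SPE) a high regulator pre-state counts
toward activation and a low one toward inhibition; for decay-side evidence
(DE, SDE) the roles are swapped — the target falling or sitting low while
a regulator is low is what an activator left idle looks like, whereas an
inhibitor would have been high.  Counts are normalised per target and
evidence type into probabilities ``Pr_e = C_e(r,t,sign) / C_e(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import ACTIVATION, INHIBITION, DiscretizedDataset

EVIDENCE_TYPES = ("PE", "DE", "SPE", "SDE")
_E_INDEX = {e: i for i, e in enumerate(EVIDENCE_TYPES)}
_SIGNS = (ACTIVATION, INHIBITION)


@dataclass(frozen=True)
class RuleSet:
    """Admissible regulator pre-states and target transitions per evidence type."""

    n_bins: int

    def __post_init__(self) -> None:
        if self.n_bins not in (2, 3):
            raise ValueError("rule tables are defined for 2 or 3 bins only")

    def activation_pre_states(self, evidence: str) -> frozenset:
        """Regulator pre-levels counted toward activation for this evidence."""
        high = frozenset({1} if self.n_bins == 2 else {1, 2})
        low = frozenset({0})
        return high if evidence in ("PE", "SPE") else low

    def inhibition_pre_states(self, evidence: str) -> frozenset:
        high = frozenset({1} if self.n_bins == 2 else {1, 2})
        low = frozenset({0})
        return low if evidence in ("PE", "SPE") else high

    def target_event(self, pre: int, post: int) -> Optional[str]:
        return classify_target_event(pre, post, self.n_bins)


def classify_target_event(pre_level: int, post_level: int, n_bins: int) -> Optional[str]:
    """Map one target transition to its evidence type, or None for 3-bin
    transitions that match no rule (0->1, 2->1, 1->1, plateaus at 1)."""
    top = n_bins - 1
    for lvl in (pre_level, post_level):
        if not (0 <= lvl <= top):
            raise ValueError(f"level {lvl} out of range for {n_bins} bins")
    if n_bins == 2:
        return {(0, 1): "PE", (1, 0): "DE", (1, 1): "SPE", (0, 0): "SDE"}[
            (pre_level, post_level)
        ]
    if post_level == 2 and pre_level in (0, 1):
        return "PE"
    if post_level == 0 and pre_level in (1, 2):
        return "DE"
    if pre_level == 2 and post_level == 2:
        return "SPE"
    if pre_level == 0 and post_level == 0:
        return "SDE"
    return None


@dataclass
class StatePairSet:
    """Adjacent (pre, post) network states, never spanning a series boundary."""

    gene_names: List[str]
    pre: np.ndarray   # p x n_pairs
    post: np.ndarray  # p x n_pairs
    n_bins: int

    @property
    def n_pairs(self) -> int:
        return self.pre.shape[1]


def build_state_pairs(data: DiscretizedDataset) -> StatePairSet:
    pres = [mat[:, :-1] for mat in data.series]
    posts = [mat[:, 1:] for mat in data.series]
    return StatePairSet(
        gene_names=list(data.gene_names),
        pre=np.concatenate(pres, axis=1),
        post=np.concatenate(posts, axis=1),
        n_bins=data.n_bins,
    )


@dataclass
class EvidenceTable:
    """Signed edge counts and probabilities per evidence type.

    ``counts`` has shape (4 evidence types, 2 signs, n_regulators, p);
    ``target_totals`` has shape (4, p).  Sign axis index 0 is activation,
    1 is inhibition.  Self pairs are structurally zero.
    """

    gene_names: List[str]
    regulators: List[str]
    counts: np.ndarray
    target_totals: np.ndarray
    n_bins: int

    _gene_idx: Dict[str, int] = field(default_factory=dict, repr=False)
    _reg_idx: Dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._gene_idx = {g: i for i, g in enumerate(self.gene_names)}
        self._reg_idx = {g: i for i, g in enumerate(self.regulators)}

    @property
    def probabilities(self) -> np.ndarray:
        """Pr_e(r, t, sign) = C_e(r,t,sign) / C_e(t); 0 where the total is 0."""
        totals = self.target_totals[:, None, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            pr = np.where(totals > 0, self.counts / np.maximum(totals, 1), 0.0)
        return pr

    def count(self, regulator: str, target: str, sign: int, evidence: str) -> int:
        s = 0 if sign == ACTIVATION else 1
        return int(self.counts[_E_INDEX[evidence], s,
                               self._reg_idx[regulator], self._gene_idx[target]])

    def target_total(self, target: str, evidence: str) -> int:
        return int(self.target_totals[_E_INDEX[evidence], self._gene_idx[target]])

    def probability(self, regulator: str, target: str, sign: int, evidence: str) -> float:
        e, t = _E_INDEX[evidence], self._gene_idx[target]
        total = self.target_totals[e, t]
        if total == 0:
            return 0.0
        return self.count(regulator, target, sign, evidence) / total

    def candidate_pairs(self) -> List[Tuple[str, str]]:
        return [(r, t) for r in self.regulators for t in self.gene_names if r != t]

    def to_tsv(self, path) -> None:
        lines = ["regulator\ttarget\tsign\tevidence\tcount\tprobability"]
        pr = self.probabilities
        for e, ev in enumerate(EVIDENCE_TYPES):
            for s, sign in enumerate(("+", "-")):
                for ri, reg in enumerate(self.regulators):
                    for ti, tgt in enumerate(self.gene_names):
                        if reg == tgt:
                            continue
                        lines.append(
                            f"{reg}\t{tgt}\t{sign}\t{ev}\t"
                            f"{int(self.counts[e, s, ri, ti])}\t{pr[e, s, ri, ti]:.6g}"
                        )
        Path(path).write_text("\n".join(lines) + "\n")


def extract_evidence(pairs: StatePairSet, rules: Optional[RuleSet] = None,
                     regulators: Optional[Sequence[str]] = None) -> EvidenceTable:
    """Apply the rule tables to every (state pair, target, candidate regulator).

    ``regulators`` restricts candidates (e.g. a known TF list); default is
    every gene.  Each (pair, target) with a recognised event contributes
    exactly one signed count per candidate regulator other than the target,
    and increments the target's total for that evidence type once.
    """
    rules = rules or RuleSet(n_bins=pairs.n_bins)
    if rules.n_bins != pairs.n_bins:
        raise ValueError("rule table bin count does not match the data")
    genes = pairs.gene_names
    if regulators is None:
        regulators = list(genes)
    else:
        regulators = list(regulators)
        missing = [r for r in regulators if r not in genes]
        if missing:
            raise ValueError(f"regulator(s) not in dataset: {', '.join(missing)}")
    gene_pos = {g: i for i, g in enumerate(genes)}
    reg_rows = np.array([gene_pos[r] for r in regulators], dtype=int)
    p, n_reg = len(genes), len(regulators)

    counts = np.zeros((4, 2, n_reg, p), dtype=np.int64)
    totals = np.zeros((4, p), dtype=np.int64)

    # event[e] is a p x n_pairs indicator of targets exhibiting evidence e
    event = np.zeros((4, p, pairs.n_pairs), dtype=bool)
    for e, ev in enumerate(EVIDENCE_TYPES):
        table = _transition_indicator(pairs, ev)
        event[e] = table
        totals[e] = table.sum(axis=1)

    pre_reg = pairs.pre[reg_rows]  # n_reg x n_pairs
    for e, ev in enumerate(EVIDENCE_TYPES):
        act_set = rules.activation_pre_states(ev)
        act = np.isin(pre_reg, list(act_set))
        m = event[e]  # p x n_pairs
        counts[e, 0] = act.astype(np.int64) @ m.T.astype(np.int64)
        counts[e, 1] = (~act).astype(np.int64) @ m.T.astype(np.int64)

    # regulator == target pairs are never emitted
    for ri, reg in enumerate(regulators):
        counts[:, :, ri, gene_pos[reg]] = 0

    return EvidenceTable(gene_names=list(genes), regulators=regulators,
                         counts=counts, target_totals=totals, n_bins=pairs.n_bins)


def _transition_indicator(pairs: StatePairSet, evidence: str) -> np.ndarray:
    pre, post, k = pairs.pre, pairs.post, pairs.n_bins
    top = k - 1
    if evidence == "PE":
        return (post == top) & (pre < top)
    if evidence == "DE":
        return (post == 0) & (pre > 0)
    if evidence == "SPE":
        return (pre == top) & (post == top)
    if evidence == "SDE":
        return (pre == 0) & (post == 0)
    raise ValueError(f"unknown evidence type {evidence!r}")
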