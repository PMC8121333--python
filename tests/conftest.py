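"""Shared fixtures and the independent brute-force evidence oracle.

The oracle re-reads the logical rule tables literally and loops over every
(state pair, target, regulator) triple with plain dict arithmetic.  It
shares no code with the package's vectorised extraction, so agreement is a
genuine cross-check.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest

from pepngrn import DiscretizedDataset

# --- literal transcription of the rule tables -------------------------------

_EVENT_2BIN = {(0, 1): "PE", (1, 0): "DE", (1, 1): "SPE", (0, 0): "SDE"}
_EVENT_3BIN = {(0, 2): "PE", (1, 2): "PE", (2, 0): "DE", (1, 0): "DE",
               (2, 2): "SPE", (0, 0): "SDE"}

# regulator pre-states counted toward activation, per evidence type
_ACT_PRE = {
    2: {"PE": {1}, "SPE": {1}, "DE": {0}, "SDE": {0}},
    3: {"PE": {1, 2}, "SPE": {1, 2}, "DE": {0}, "SDE": {0}},
}


def brute_force_evidence(data: DiscretizedDataset,
                         regulators: Optional[List[str]] = None):
    """Dict-based evidence counts: (reg, tgt, sign, evidence) -> count,
    plus (tgt, evidence) -> total.  Signs are +1 / -1."""
    genes = data.gene_names
    regulators = regulators if regulators is not None else list(genes)
    k = data.n_bins
    event_of = _EVENT_2BIN if k == 2 else _EVENT_3BIN
    counts: Dict[Tuple[str, str, int, str], int] = {}
    totals: Dict[Tuple[str, str], int] = {}
    for mat in data.series:
        for t in range(mat.shape[1] - 1):
            pre, post = mat[:, t], mat[:, t + 1]
            for j, tgt in enumerate(genes):
                ev = event_of.get((int(pre[j]), int(post[j])))
                if ev is None:
                    continue
                totals[(tgt, ev)] = totals.get((tgt, ev), 0) + 1
                for r in regulators:
                    if r == tgt:
                        continue
                    ri = genes.index(r)
                    sign = 1 if int(pre[ri]) in _ACT_PRE[k][ev] else -1
                    key = (r, tgt, sign, ev)
                    counts[key] = counts.get(key, 0) + 1
    return counts, totals


def random_micro_dataset(rng: np.random.Generator, n_bins: int) -> DiscretizedDataset:
    """Tiny random discretized dataset: p <= 5 genes, series of <= 8 points."""
    p = int(rng.integers(2, 6))
    n_series = int(rng.integers(1, 3))
    series = [rng.integers(0, n_bins, size=(p, int(rng.integers(2, 9))))
              for _ in range(n_series)]
    return DiscretizedDataset(gene_names=[f"G{i+1}" for i in range(p)],
                              series=series, n_bins=n_bins)


# --- worked micro example used across modules -------------------------------

@pytest.fixture
def two_gene_dataset() -> DiscretizedDataset:
    """g1 = [1,1,0,0], g2 = [0,1,1,0]: g2 produces, sustains and decays while
    g1 is successively on and off; hand-checkable against the rule tables."""
    return DiscretizedDataset(
        gene_names=["g1", "g2"],
        series=[np.array([[1, 1, 0, 0], [0, 1, 1, 0]])],
        n_bins=2,
    )
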