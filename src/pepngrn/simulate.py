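"""Synthetic regulatory networks and noisy multi-level time-series expression.

The generator produces the kind of data the inference method assumes:
first-order Markov regulation with a one-step lag, threshold activation,
stochastic synthesis/decay, and optional measurement noise.  Each gene
holds a discrete level in ``{0..k-1}``; at every step a target responds to
its regulators' levels at the previous time point: an inhibitor at top
level actively represses (the target falls one level), otherwise an
activator at top level drives synthesis (the target rises one level).  A
target with only inhibitors is constitutively synthesised while its
repressors are off, the classic derepression picture.  Unregulated genes —
and regulated ones with no active regulator — drift: a small basal
probability of rising and a per-step decay probability of falling.
Observed continuous
expression is the level plus uniform jitter; flip noise independently
replaces a fraction of discrete observations with a uniform random level
before the jitter is added.

The mechanism is deliberately *not* the inference rule tables: recovery of
the generating network from simulated data is therefore a genuine test of
the method, not a tautology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .datatypes import (
    ACTIVATION,
    INHIBITION,
    DiscretizedDataset,
    GoldStandard,
    Pair,
    TimeSeriesDataset,
)

JITTER = 0.3  # uniform jitter half-width; keeps levels separable under EWD


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated data set.

    Defaults describe a sparse TF-restricted network observed over ten
    independent series of 21 time points, mirroring common in-silico
    benchmark designs at desk scale.
    """

    n_genes: int = 20
    n_tfs: int = 5
    max_regulators_per_target: int = 2
    n_series: int = 10
    n_timepoints: int = 21
    levels: int = 2
    flip_noise: float = 0.0
    basal_synthesis_prob: float = 0.1
    decay_prob_per_step: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must not exceed n_genes")
        if self.max_regulators_per_target < 1:
            raise ValueError("max_regulators_per_target must be >= 1")
        if not (0.0 <= self.flip_noise < 1.0):
            raise ValueError("flip_noise must lie in [0, 1)")
        for name in ("basal_synthesis_prob", "decay_prob_per_step"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.n_timepoints < 2 or self.n_series < 1:
            raise ValueError("need at least one series of >= 2 time points")

    @property
    def gene_names(self) -> List[str]:
        return [f"G{i + 1}" for i in range(self.n_genes)]

    @property
    def tf_names(self) -> List[str]:
        return self.gene_names[: self.n_tfs]


def generate_network(cfg: SimulationConfig) -> GoldStandard:
    """Draw a sparse signed network: every target gets 1..max regulators
    sampled from the TF pool, each independently an activator or inhibitor."""
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_names
    tfs = cfg.tf_names
    # TFs stay autonomous (independent telegraph dynamics) so that regulator
    # attribution is identifiable; when every gene is a TF, all genes become
    # targets so the generator still emits a network.
    targets = [g for g in genes if g not in tfs] or list(genes)
    edges = set()
    signs: Dict[Pair, int] = {}
    for tgt in targets:
        pool = [tf for tf in tfs if tf != tgt]
        if not pool:
            continue
        n_reg = int(rng.integers(1, cfg.max_regulators_per_target + 1))
        n_reg = min(n_reg, len(pool))
        chosen = rng.choice(len(pool), size=n_reg, replace=False)
        for c in chosen:
            reg = pool[int(c)]
            edges.add((reg, tgt))
            signs[(reg, tgt)] = ACTIVATION if rng.random() < 0.5 else INHIBITION
    return GoldStandard(edges=edges, signs=signs, signed=True)


def simulate_expression(net: GoldStandard, cfg: SimulationConfig
                        ) -> Tuple[TimeSeriesDataset, DiscretizedDataset]:
    """Simulate the network forward and return (continuous data, noiseless levels).

    The second element holds the true generating levels before flip noise
    and jitter, for round-trip checks of the discretizers.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes = cfg.gene_names
    idx = {g: i for i, g in enumerate(genes)}
    top = cfg.levels - 1
    activators: List[List[int]] = [[] for _ in genes]
    inhibitors: List[List[int]] = [[] for _ in genes]
    for (reg, tgt) in net.edges:
        if reg not in idx or tgt not in idx:
            raise ValueError(f"network gene {reg!r}/{tgt!r} missing from config universe")
        (activators if net.signs[(reg, tgt)] == ACTIVATION else inhibitors)[
            idx[tgt]].append(idx[reg])

    cont_series, true_series = [], []
    for _ in range(cfg.n_series):
        levels = np.empty((cfg.n_genes, cfg.n_timepoints), dtype=np.int64)
        levels[:, 0] = rng.integers(0, cfg.levels, size=cfg.n_genes)
        for t in range(1, cfg.n_timepoints):
            prev = levels[:, t - 1]
            for g in range(cfg.n_genes):
                veto = any(prev[i] == top for i in inhibitors[g])
                if activators[g]:
                    drive = any(prev[a] == top for a in activators[g])
                else:
                    # inhibitor-only targets are constitutively synthesised
                    # while their repressors are off (derepression)
                    drive = bool(inhibitors[g]) and not veto
                lvl = prev[g]
                if veto:
                    lvl = max(lvl - 1, 0)  # active repression accelerates decay
                elif drive:
                    lvl = min(lvl + 1, top)
                elif rng.random() < cfg.basal_synthesis_prob:
                    lvl = min(lvl + 1, top)
                elif rng.random() < cfg.decay_prob_per_step:
                    lvl = max(lvl - 1, 0)
                levels[g, t] = lvl
        observed = levels.copy()
        if cfg.flip_noise > 0:
            flips = rng.random(observed.shape) < cfg.flip_noise
            observed[flips] = rng.integers(0, cfg.levels, size=int(flips.sum()))
        cont = observed + rng.uniform(-JITTER, JITTER, size=observed.shape)
        cont_series.append(cont)
        true_series.append(levels)

    continuous = TimeSeriesDataset(gene_names=genes, series=cont_series)
    noiseless = DiscretizedDataset(gene_names=genes, series=true_series,
                                   n_bins=cfg.levels)
    return continuous, noiseless
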