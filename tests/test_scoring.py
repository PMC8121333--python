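"""Score aggregation (v1/v2), sign selection, decay, thresholding, likelihood."""

import math

import numpy as np
import pytest

from pepngrn import (
    DiscretizedDataset,
    GoldStandard,
    ScoredEdge,
    ThresholdConfig,
    build_state_pairs,
    decay_probability,
    extract_evidence,
    network_likelihood,
    score_v1,
    score_v2,
    select_signs,
    threshold_edges,
)
from conftest import random_micro_dataset


def _score_map(edges):
    return {(e.pair, e.sign): e.score for e in edges}


def test_v1_is_mean_of_probabilities(two_gene_dataset):
    table = extract_evidence(build_state_pairs(two_gene_dataset))
    v1 = _score_map(score_v1(table))
    # Pr(+) over (PE, DE, SPE, SDE) for g1->g2 is (1, 1, 1, 0)
    assert v1[(("g1", "g2"), 1)] == pytest.approx(0.75)
    assert v1[(("g1", "g2"), -1)] == pytest.approx(0.0)
    assert v1[(("g2", "g1"), -1)] == pytest.approx(0.75)


def test_v2_is_count_ratio(two_gene_dataset):
    table = extract_evidence(build_state_pairs(two_gene_dataset))
    v2 = _score_map(score_v2(table))
    # counts for (g1,g2,+) = 1+1+1+0 = 3 of 3 total target events
    assert v2[(("g1", "g2"), 1)] == pytest.approx(1.0)
    assert v2[(("g1", "g2"), -1)] == pytest.approx(0.0)


def test_v2_partial_sign_ratio():
    # regulator matches + for 7 of the target's 10 evidence occurrences
    reg = [1, 1, 1, 1, 1, 1, 1, 0, 1, 0, 1]
    tgt = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
    ds = DiscretizedDataset(gene_names=["R", "T"],
                            series=[np.array([reg, tgt])], n_bins=2)
    table = extract_evidence(build_state_pairs(ds))
    assert sum(table.target_total("T", e) for e in ("PE", "DE", "SPE", "SDE")) == 10
    v2 = _score_map(score_v2(table))
    assert v2[(("R", "T"), 1)] == pytest.approx(0.7)
    assert v2[(("R", "T"), -1)] == pytest.approx(0.3)


def test_all_scores_within_unit_interval():
    rng = np.random.default_rng(42)
    for n_bins in (2, 3):
        ds = random_micro_dataset(rng, n_bins)
        table = extract_evidence(build_state_pairs(ds))
        for edges in (score_v1(table), score_v2(table)):
            assert all(0.0 <= e.score <= 1.0 for e in edges)


def test_v2_sign_sum_is_one_when_evidence_exists():
    rng = np.random.default_rng(9)
    ds = random_micro_dataset(rng, 2)
    table = extract_evidence(build_state_pairs(ds))
    v2 = _score_map(score_v2(table))
    total_by_target = {t: sum(table.target_total(t, e)
                              for e in ("PE", "DE", "SPE", "SDE"))
                       for t in ds.gene_names}
    for (pair, sign), s in v2.items():
        if sign == 1 and total_by_target[pair[1]] > 0:
            assert s + v2[(pair, -1)] == pytest.approx(1.0, abs=1e-12)


def test_v1_sign_sum_counts_evidence_types_present():
    """v1 sign-sum equals (number of evidence types with events)/4."""
    rng = np.random.default_rng(10)
    for _ in range(5):
        ds = random_micro_dataset(rng, 2)
        table = extract_evidence(build_state_pairs(ds))
        v1 = _score_map(score_v1(table))
        for tgt in ds.gene_names:
            n_present = sum(table.target_total(tgt, e) > 0
                            for e in ("PE", "DE", "SPE", "SDE"))
            for reg in ds.gene_names:
                if reg == tgt:
                    continue
                s = v1[((reg, tgt), 1)] + v1[((reg, tgt), -1)]
                assert s == pytest.approx(n_present / 4, abs=1e-12)


def test_select_signs_keeps_winner_discards_ties():
    edges = [
        ScoredEdge("A", "B", 1, 0.75), ScoredEdge("A", "B", -1, 0.25),
        ScoredEdge("A", "C", 1, 0.5), ScoredEdge("A", "C", -1, 0.5),
        ScoredEdge("B", "C", 1, 0.3),
    ]
    kept = select_signs(edges)
    by_pair = {e.pair: e for e in kept}
    assert by_pair[("A", "B")].sign == 1 and by_pair[("A", "B")].score == 0.75
    assert ("A", "C") not in by_pair          # exact tie discarded
    assert by_pair[("B", "C")].score == 0.3   # single sign kept


def test_decay_probability_hand_examples():
    ds = DiscretizedDataset(
        gene_names=["g1", "zero", "rise"],
        series=[np.array([[1, 1, 0, 0], [0, 0, 0, 0], [0, 1, 1, 1]])],
        n_bins=2,
    )
    prof = decay_probability(ds)
    d = prof.as_dict()
    assert d["g1"] == pytest.approx(0.5)    # 1 decay / 2 expressed points
    assert d["zero"] == 0.0                  # never expressed
    assert d["rise"] == 0.0                  # never decays


def test_decay_diff_respects_series_boundaries():
    ds = DiscretizedDataset(gene_names=["g", "pad"],
                            series=[np.array([[1, 1], [0, 0]]),
                                    np.array([[0, 0], [0, 0]])],
                            n_bins=2)
    # junction 1 -> 0 between series must not count as a decay
    assert decay_probability(ds).as_dict()["g"] == 0.0


def test_threshold_edges_sequential_filters():
    edges = [ScoredEdge(f"R{i}", "T", 1, s)
             for i, s in enumerate([0.9, 0.8, 0.7, 0.6, 0.5])]
    assert len(threshold_edges(edges, ThresholdConfig(n_reg=3, th=0.0))) == 3
    assert len(threshold_edges(edges, ThresholdConfig(n_reg=3, th=0.75))) == 2
    assert len(threshold_edges(edges, ThresholdConfig(n_reg=10, th=0.0))) == 5


def test_threshold_output_is_subset_of_input():
    rng = np.random.default_rng(3)
    edges = [ScoredEdge(f"R{i}", f"T{j}", 1, float(rng.random()))
             for i in range(4) for j in range(3)]
    out = threshold_edges(edges, ThresholdConfig(n_reg=2, th=0.3))
    assert set(out) <= set(edges)


def test_network_likelihood_products():
    gold = GoldStandard(edges={("A", "B"), ("A", "C"), ("B", "C")})
    probs = {("A", "B"): 0.9, ("A", "C"): 0.8, ("B", "C"): 0.5, ("C", "A"): 0.3}
    full = network_likelihood(probs, gold, mode="full")
    assert full.likelihood == pytest.approx(0.9 * 0.8 * 0.5 * 0.7)
    only = network_likelihood(probs, gold, mode="edges_only")
    assert only.likelihood == pytest.approx(0.9 * 0.8 * 0.5)
    assert only.log10_likelihood == pytest.approx(math.log10(0.36))


def test_network_likelihood_perfect_and_zero_cases():
    gold = GoldStandard(edges={("A", "B")})
    perfect = network_likelihood({("A", "B"): 1.0, ("B", "A"): 0.0}, gold, "full")
    assert perfect.likelihood == 1.0
    zero = network_likelihood({("A", "B"): 0.0}, gold, "edges_only")
    assert zero.likelihood == 0.0 and zero.log10_likelihood == -math.inf
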