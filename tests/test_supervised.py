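"""Feature construction, SMOTE balancing, logistic fits and cross-validated v3."""

import numpy as np
import pytest

from pepngrn import (
    CVConfig,
    DiscretizedDataset,
    GoldStandard,
    LogisticModel,
    build_features,
    build_state_pairs,
    extract_evidence,
    fit_logistic,
    predict,
    run_v3,
    smote_upsample,
)


def _random_table(rng, p=10, n_bins=2, n_points=20):
    ds = DiscretizedDataset(gene_names=[f"G{i+1}" for i in range(p)],
                            series=[rng.integers(0, n_bins, size=(p, n_points))],
                            n_bins=n_bins)
    return extract_evidence(build_state_pairs(ds))


def _random_signed_gold(rng, genes, n_edges=12):
    pairs = [(r, t) for r in genes for t in genes if r != t]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = {pairs[i] for i in chosen}
    # alternate signs so both classes are always represented
    signs = {e: (1 if i % 2 == 0 else -1) for i, e in enumerate(sorted(edges))}
    return GoldStandard(edges=edges, signs=signs, signed=True)


def test_feature_matrix_row_counts():
    rng = np.random.default_rng(0)
    table = _random_table(rng)
    gold = _random_signed_gold(rng, table.gene_names)
    fm = build_features(table, gold, mode="signed")
    assert fm.n_rows == 180  # 90 ordered pairs x 2 signs
    assert len(set(fm.pairs)) == 90
    unsigned = build_features(table, GoldStandard(edges=gold.edges), mode="unsigned")
    assert unsigned.n_rows == 90


def test_unsigned_mode_small_universe():
    rng = np.random.default_rng(1)
    table = _random_table(rng, p=3)
    gold = GoldStandard(edges={("G1", "G2")})
    fm = build_features(table, gold, mode="unsigned")
    assert fm.n_rows == 6  # 3 x 2 ordered pairs
    assert fm.labels.sum() == 1


def test_signed_mode_requires_signed_gold():
    rng = np.random.default_rng(2)
    table = _random_table(rng, p=3)
    with pytest.raises(ValueError, match="signed"):
        build_features(table, GoldStandard(edges={("G1", "G2")}), mode="signed")


def test_labels_match_gold_signs():
    rng = np.random.default_rng(3)
    table = _random_table(rng, p=4)
    gold = GoldStandard(edges={("G1", "G2")}, signs={("G1", "G2"): -1}, signed=True)
    fm = build_features(table, gold, mode="signed")
    for pair, sign, label in zip(fm.pairs, fm.signs, fm.labels):
        assert label == int(pair == ("G1", "G2") and sign == -1)


def test_smote_balances_and_interpolates():
    rng = np.random.default_rng(4)
    majority = rng.random((90, 4))
    minority = rng.random((10, 4))
    x = np.vstack([majority, minority])
    y = np.array([0] * 90 + [1] * 10)
    xb, yb = smote_upsample(x, y, seed=11)
    assert (yb == 1).sum() == 90 and (yb == 0).sum() == 90
    # synthetic points stay inside the minority bounding box (convexity)
    synth = xb[100:]
    assert synth.min() >= minority.min() - 1e-12
    assert synth.max() <= minority.max() + 1e-12


def test_smote_on_degenerate_segment():
    # two minority points: every synthetic point lies on their segment
    x = np.vstack([np.zeros((4, 4)), [[0, 0, 0, 0], [1, 1, 1, 1]]])
    y = np.array([0, 0, 0, 0, 1, 1])
    xb, yb = smote_upsample(x, y, seed=0)
    synth = xb[6:]
    for row in synth:
        assert np.allclose(row, row[0])  # all coordinates equal on the diagonal
        assert 0.0 <= row[0] <= 1.0


def test_smote_determinism_and_errors():
    rng = np.random.default_rng(5)
    x = rng.random((30, 4))
    y = np.array([0] * 25 + [1] * 5)
    a = smote_upsample(x, y, seed=7)
    b = smote_upsample(x, y, seed=7)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    with pytest.raises(ValueError, match="both classes"):
        smote_upsample(x, np.zeros(30, dtype=int))
    with pytest.warns(RuntimeWarning, match="single example"):
        smote_upsample(x, np.array([0] * 29 + [1]), seed=1)


def test_logistic_no_signal_limit():
    rng = np.random.default_rng(6)
    x = rng.random((2000, 4))
    y = rng.integers(0, 2, size=2000)
    model = fit_logistic(x, y)
    assert np.all(np.abs(model.weights[1:]) < 0.3)
    assert np.allclose(predict(model, x).mean(), 0.5, atol=0.05)


def test_logistic_separated_single_feature():
    x = np.zeros((40, 4))
    x[:20, 0] = 1.0
    y = np.array([1] * 20 + [0] * 20)
    model = fit_logistic(x, y)
    assert model.weights[1] > 0
    preds = predict(model, x) > 0.5
    assert np.array_equal(preds, y.astype(bool))


def test_logistic_recovers_planted_weights():
    rng = np.random.default_rng(7)
    x = rng.random((5000, 4))
    true_w = np.array([0.0, 2.0, 0.0, 0.0, 0.0])
    p = 1 / (1 + np.exp(-(true_w[0] + x @ true_w[1:])))
    y = (rng.random(5000) < p).astype(int)
    model = fit_logistic(x, y)
    assert np.all(np.abs(model.weights - true_w) <= 0.3)


@pytest.mark.parametrize("features, weights, expected", [
    ((0, 0, 0, 0), [0, 0, 0, 0, 0], 0.5),
    ((1, 0, 0, 0), [0, 1, 0, 0, 0], 1 / (1 + np.exp(-1.0))),
    ((0, 0, 0, 0), [2, 1, 1, 1, 1], 1 / (1 + np.exp(-2.0))),
])
def test_predict_closed_form(features, weights, expected):
    model = LogisticModel(np.array(weights, dtype=float))
    assert predict(model, np.array([features], dtype=float))[0] == pytest.approx(expected)


def _separable_setup(rng, n_networks=5, p=6, n_edges=5):
    """Evidence tables whose SDE(+) probability perfectly marks true edges."""
    tables, golds = [], []
    for _ in range(n_networks):
        genes = [f"G{i+1}" for i in range(p)]
        # craft a table via a dataset, then overwrite counts for separability
        ds = DiscretizedDataset(gene_names=genes,
                                series=[rng.integers(0, 2, size=(p, 8))], n_bins=2)
        table = extract_evidence(build_state_pairs(ds))
        gold = _random_signed_gold(rng, genes, n_edges=n_edges)
        table.target_totals[:] = 10
        table.counts[:] = 0
        gi = {g: i for i, g in enumerate(genes)}
        for r in genes:
            for t in genes:
                if r == t:
                    continue
                true_sign = gold.signs.get((r, t))
                for s, sign in ((0, 1), (1, -1)):
                    table.counts[3, s, gi[r], gi[t]] = 10 if sign == true_sign else 0
        tables.append(table)
        golds.append(gold)
    return tables, golds


def test_run_v3_each_network_tested_once():
    rng = np.random.default_rng(8)
    tables, golds = _separable_setup(rng)
    results = run_v3(tables, golds, cv=CVConfig(k_folds=5, seed=0), mode="signed")
    tested = sorted(i for fr in results for i in fr.test_networks)
    assert tested == [0, 1, 2, 3, 4]


def test_run_v3_separable_scores_true_edges_higher():
    rng = np.random.default_rng(9)
    tables, golds = _separable_setup(rng)
    results = run_v3(tables, golds, cv=CVConfig(k_folds=5, seed=1), mode="signed")
    for fr in results:
        gold = golds[fr.test_networks[0]]
        true_scores = [e.score for e in fr.edges if e.pair in gold.edges]
        false_scores = [e.score for e in fr.edges if e.pair not in gold.edges]
        assert min(true_scores) > max(false_scores)
        # winning model's sign matches the planted sign on true edges
        for e in fr.edges:
            if e.pair in gold.edges:
                assert e.sign == gold.signs[e.pair]
        assert all(0.0 < e.score < 1.0 for e in fr.edges)


def test_run_v3_unsigned_mode_single_model():
    rng = np.random.default_rng(10)
    tables, golds = _separable_setup(rng)
    unsigned = [GoldStandard(edges=g.edges) for g in golds]
    results = run_v3(tables, unsigned, cv=CVConfig(k_folds=5, seed=2), mode="unsigned")
    for fr in results:
        assert set(fr.models) == {0}
        assert all(e.sign == 0 for e in fr.edges)


def test_run_v3_by_edge_grouping_single_network():
    rng = np.random.default_rng(11)
    tables, golds = _separable_setup(rng, n_networks=1, p=8, n_edges=12)
    results = run_v3(tables, golds,
                     cv=CVConfig(k_folds=4, grouping="by_edge", seed=3), mode="signed")
    seen = [p for fr in results for p in {e.pair for e in fr.edges}]
    assert sorted(seen) == sorted({(r, t) for r in tables[0].gene_names
                                  for t in tables[0].gene_names if r != t})


def test_run_v3_errors():
    rng = np.random.default_rng(12)
    tables, golds = _separable_setup(rng, n_networks=3)
    with pytest.raises(ValueError, match="by_network grouping needs"):
        run_v3(tables, golds, cv=CVConfig(k_folds=5), mode="signed")
    # a fold whose training labels are single-class is reported by fold id
    empty_gold = [GoldStandard(edges=set(), signs={}, signed=True)
                  for _ in range(3)]
    with pytest.raises(ValueError, match="fold 0"):
        run_v3(tables, empty_gold, cv=CVConfig(k_folds=3), mode="signed")


def test_sign_model_symmetry_with_complementary_features():
    """Swapping every gold sign and the two models' roles leaves max-scores
    unchanged when the sign features are complements of each other."""
    rng = np.random.default_rng(13)
    tables, golds = _separable_setup(rng)
    # make features complementary explicitly: counts(-) = total - counts(+)
    for t in tables:
        t.counts[:, 1] = t.target_totals[:, None, :] - t.counts[:, 0]
        for gi, g in enumerate(t.gene_names):
            t.counts[:, :, gi, gi] = 0
    flipped = [GoldStandard(edges=g.edges,
                            signs={e: -s for e, s in g.signs.items()}, signed=True)
               for g in golds]
    res_a = run_v3(tables, golds, cv=CVConfig(k_folds=5, seed=4), mode="signed")
    res_b = run_v3(tables, flipped, cv=CVConfig(k_folds=5, seed=4), mode="signed")
    for fa, fb in zip(res_a, res_b):
        sa = {e.pair: e.score for e in fa.edges}
        sb = {e.pair: e.score for e in fb.edges}
        for pair in sa:
            assert sa[pair] == pytest.approx(sb[pair], abs=1e-6)
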