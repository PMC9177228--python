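"""Greedy accuracy-preserving pruning: correctness against independent
step-by-step simulations, structural equivalence, and fixed-point audits."""

import numpy as np
import pytest

from kfselm.data_io import FeatureDataset
from kfselm.elm_core import (
    ELMModel,
    PruneMasks,
    accuracy,
    correct_count,
    fit_output_weights,
    hidden_output,
    init_random_elm,
    predict_scores,
    train_elm,
)
from kfselm.pruning import (
    masked_accuracy,
    prune_classifier,
    prune_hidden_pass,
    prune_input_pass,
    prune_input_to_fixed_point,
)
from kfselm.synthetic import SyntheticSpec, generate_dataset


def make_instance(seed=0, n=6, L=10, N=30, informative=2):
    """Small fitted instance: `informative` features carry a mean shift."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 0.3, size=(N, n))
    labels = ["a"] * (N // 2) + ["b"] * (N - N // 2)
    X[N // 2 :, :informative] += 1.2
    ds = FeatureDataset.from_features(np.tanh(X), labels)
    model = train_elm(ds, L, seed=seed + 1)
    return model, ds


# ---------------------------------------------------------------------------
# masked evaluation


def structural_scores(model, masks, X):
    """Oracle: physically delete masked feature columns and hidden nodes,
    then evaluate the reduced network from scratch."""
    keep_in = np.flatnonzero(masks.input_mask)
    keep_hid = np.flatnonzero(masks.hidden_mask)
    reduced = ELMModel(
        model.input_weights[np.ix_(keep_hid, keep_in)],
        model.biases[keep_hid],
        model.output_weights[keep_hid, :],
        model.activation,
    )
    return hidden_output(reduced, X[:, keep_in]) @ reduced.output_weights


def test_masked_equals_structurally_reduced():
    rng = np.random.default_rng(1)
    model, ds = make_instance(seed=3)
    for _ in range(10):
        masks = PruneMasks(
            rng.integers(0, 2, model.n_features),
            rng.integers(0, 2, model.n_hidden),
        )
        if masks.n_active_hidden == 0:
            masks.hidden_mask[0] = 1
        O_masked = predict_scores(model, ds.X, masks)
        O_reduced = structural_scores(model, masks, ds.X)
        assert np.allclose(O_masked, O_reduced, atol=1e-10)
        assert masked_accuracy(model, masks, ds) == accuracy(O_reduced, ds.T)


def test_masked_accuracy_identity_masks():
    model, ds = make_instance(seed=4)
    masks = PruneMasks.full(model.n_features, model.n_hidden)
    assert masked_accuracy(model, masks, ds) == accuracy(
        predict_scores(model, ds.X), ds.T
    )


def test_masked_accuracy_size_mismatch():
    model, ds = make_instance(seed=5)
    bad = PruneMasks(np.ones(3, np.int8), np.ones(model.n_hidden, np.int8))
    with pytest.raises(ValueError):
        masked_accuracy(model, bad, ds)


# ---------------------------------------------------------------------------
# greedy oracle: an independent, from-scratch simulation of the sweep rule


def greedy_input_sim(model, masks, ds):
    masks = masks.copy()
    best = correct_count(predict_scores(model, ds.X, masks), ds.T)
    removed = 0
    for k in np.flatnonzero(masks.input_mask):
        trial = masks.copy()
        trial.input_mask[k] = 0
        c = correct_count(predict_scores(model, ds.X, trial), ds.T)
        if c >= best:
            masks, best, removed = trial, c, removed + 1
    return masks, removed


def greedy_hidden_sim(model, masks, ds):
    masks = masks.copy()
    best = correct_count(predict_scores(model, ds.X, masks), ds.T)
    removed = 0
    for j in np.flatnonzero(masks.hidden_mask):
        trial = masks.copy()
        trial.hidden_mask[j] = 0
        c = correct_count(predict_scores(model, ds.X, trial), ds.T)
        if c >= best:
            masks, best, removed = trial, c, removed + 1
    return masks, removed


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_input_pass_matches_greedy_simulation(seed):
    model, ds = make_instance(seed=seed, n=5, L=8)
    full = PruneMasks.full(5, 8)
    got, n_got = prune_input_pass(model, full, ds)
    want, n_want = greedy_input_sim(model, full, ds)
    assert n_got == n_want
    assert np.array_equal(got.input_mask, want.input_mask)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_hidden_pass_matches_greedy_simulation(seed):
    model, ds = make_instance(seed=seed, n=5, L=8)
    full = PruneMasks.full(5, 8)
    got, n_got = prune_hidden_pass(model, full, ds)
    want, n_want = greedy_hidden_sim(model, full, ds)
    assert n_got == n_want
    assert np.array_equal(got.hidden_mask, want.hidden_mask)


# ---------------------------------------------------------------------------
# structural removals that must always succeed


def test_all_zero_feature_columns_pruned_in_one_pass():
    model, ds = make_instance(seed=6, n=6)
    ds.X[:, 3] = 0.0
    ds.X[:, 4] = 0.0
    masks, removed = prune_input_pass(
        model, PruneMasks.full(6, model.n_hidden), ds
    )
    assert masks.input_mask[3] == 0 and masks.input_mask[4] == 0
    assert removed >= 2


def test_duplicated_feature_column_removable_on_fixture():
    """On this seeded fixture one copy of an exactly duplicated informative
    feature is pruned without accuracy loss.  This is fixture-specific, not
    a guarantee: β is never refit, so removing one duplicate halves the
    signal's effective input weight and can change the scores enough to
    flip examples on other draws."""
    rng = np.random.default_rng(6)
    N, n = 60, 8
    X = rng.normal(0, 0.3, size=(N, n))
    labels = ["a"] * 30 + ["b"] * 30
    X[30:, 0] += 1.5
    X[:, 1] = X[:, 0]  # exact duplicate of the informative feature
    ds = FeatureDataset.from_features(np.tanh(X), labels)
    model = train_elm(ds, L=300, seed=7)
    masks = prune_input_to_fixed_point(model, PruneMasks.full(n, 300), ds)
    assert masks.input_mask[0] == 0 or masks.input_mask[1] == 0


def test_zero_output_row_hidden_node_always_pruned():
    model, ds = make_instance(seed=9, L=8)
    beta = model.output_weights.copy()
    beta[2, :] = 0.0
    model = model.with_output_weights(beta)
    masks, _ = prune_hidden_pass(model, PruneMasks.full(model.n_features, 8), ds)
    assert masks.hidden_mask[2] == 0


def test_single_predictive_feature_retained():
    """A feature identical to the label separation survives pruning: removing
    it provably drops accuracy to chance."""
    rng = np.random.default_rng(10)
    N, n = 40, 10
    X = rng.normal(0, 1.0, size=(N, n))
    labels = ["a"] * 20 + ["b"] * 20
    X[:20, 0] = -0.9
    X[20:, 0] = 0.9  # the only signal
    ds = FeatureDataset.from_features(np.tanh(X), labels)
    model = train_elm(ds, L=40, seed=11)
    if accuracy(predict_scores(model, ds.X), ds.T) == 1.0:
        masks = prune_classifier(model, ds)
        assert masks.input_mask[0] == 1


# ---------------------------------------------------------------------------
# fixed points and the full alternation


def exhaustive_local_minimality(model, masks, ds):
    """Audit: no single active node is removable without a strict accuracy
    decrease."""
    best = correct_count(predict_scores(model, ds.X, masks), ds.T)
    for k in np.flatnonzero(masks.input_mask):
        trial = masks.copy()
        trial.input_mask[k] = 0
        assert correct_count(predict_scores(model, ds.X, trial), ds.T) < best
    for j in np.flatnonzero(masks.hidden_mask):
        trial = masks.copy()
        trial.hidden_mask[j] = 0
        assert correct_count(predict_scores(model, ds.X, trial), ds.T) < best


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_prune_classifier_fixed_point_properties(seed):
    model, ds = make_instance(seed=seed, n=8, L=12, N=40)
    before = masked_accuracy(model, PruneMasks.full(8, 12), ds)
    log = []
    masks = prune_classifier(model, ds, log=log)
    after = masked_accuracy(model, masks, ds)
    # monotone accuracy across every kept removal
    incumbents = [e.correct_after for e in log if e.action == "kept"]
    assert all(b <= a for b, a in zip(incumbents, incumbents[1:]))
    assert after >= before
    exhaustive_local_minimality(model, masks, ds)
    # idempotence: pruning an already-pruned classifier changes nothing
    again = prune_classifier(model, ds, masks=masks)
    assert np.array_equal(again.input_mask, masks.input_mask)
    assert np.array_equal(again.hidden_mask, masks.hidden_mask)


def test_input_fixed_point_idempotent():
    model, ds = make_instance(seed=12)
    masks = prune_input_to_fixed_point(
        model, PruneMasks.full(model.n_features, model.n_hidden), ds
    )
    again, removed = prune_input_pass(model, masks, ds)
    assert removed == 0
    assert np.array_equal(again.input_mask, masks.input_mask)


def test_noise_features_are_screened_out():
    """With >= 50% pure-noise features, pruning shrinks the input layer in
    every seeded run."""
    for seed in range(20):
        spec = SyntheticSpec(
            n_regions=7, n_per_class=20, informative_edges=4,
            effect_size=2.0, seed=100 + seed,
        )
        ds, _ = generate_dataset(spec)  # 21 features, 4 informative
        model = train_elm(ds, L=100, seed=seed)
        masks = prune_classifier(model, ds)
        assert masks.n_active_inputs < ds.n_features


def test_incremental_cache_matches_full_recompute():
    """Masked accuracy computed after a pass equals a fresh evaluation of the
    returned mask (the rank-1 cache introduces no drift)."""
    model, ds = make_instance(seed=13, n=10, L=16, N=50)
    masks = prune_classifier(model, ds)
    fresh = accuracy(predict_scores(model, ds.X, masks), ds.T)
    assert masked_accuracy(model, masks, ds) == fresh
    O_masked = predict_scores(model, ds.X, masks)
    from_scratch = (
        hidden_output(model, ds.X, masks.input_mask)
        * masks.hidden_mask[None, :]
    ) @ model.output_weights
    assert np.allclose(O_masked, from_scratch, atol=1e-10)
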