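"""Contrastive probe loss anchors and conv-probe mechanics."""

import numpy as np
import pytest

from bioseqlm.nn import Tensor
from bioseqlm.probes import (AttentionStack, ConvContactProbe,
                             EmbeddingPairSet, clip_loss, evaluate_conv_probe,
                             train_conv_probe, train_probe)


def test_clip_loss_single_pair_is_zero():
    X = np.array([[1.0, 0.0, 0.0, 0.0]])
    W = Tensor(np.eye(4)[:1], requires_grad=True)
    assert clip_loss(X, X, W, tau=1.0).item() == pytest.approx(0.0, abs=1e-7)


def test_clip_loss_infinite_temperature_limit_is_log_n():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(8, 12)).astype(np.float32)
    Y = rng.normal(size=(8, 12)).astype(np.float32)
    W = Tensor(rng.normal(size=(2, 12)), requires_grad=True)
    assert clip_loss(X, Y, W, tau=1e6).item() == pytest.approx(np.log(8),
                                                               abs=1e-3)


def test_clip_loss_two_pair_hand_value():
    # projected embeddings equal to the identity rows: S = I / tau, tau = 1;
    # per-row loss = -ln(e / (e + 1)) ~= 0.3133
    X = np.eye(2, dtype=np.float32)
    W = Tensor(np.eye(2), requires_grad=True)
    expected = -np.log(np.e / (np.e + 1.0))
    assert clip_loss(X, X, W, tau=1.0).item() == pytest.approx(expected,
                                                               abs=1e-4)


def test_clip_loss_nonnegative_and_log_n_for_constant_similarity():
    # all projected rows identical -> S constant -> loss = ln N exactly
    X = np.tile(np.array([[2.0, 0.0, 0.0]], dtype=np.float32), (5, 1))
    W = Tensor(np.eye(3), requires_grad=True)
    assert clip_loss(X, X, W, tau=0.07).item() == pytest.approx(np.log(5),
                                                                abs=1e-5)


def test_clip_loss_rejects_zero_norm_projection():
    X = np.array([[0.0, 1.0]], dtype=np.float32)
    W = Tensor(np.array([[1.0, 0.0]]), requires_grad=True)
    with pytest.raises(ValueError):
        clip_loss(X, X, W)


def _aligned_pairs(n=120, d=80, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d)).astype(np.float32)
    Y = X + noise * rng.normal(size=(n, d)).astype(np.float32)
    return EmbeddingPairSet(X, Y)


def test_probe_on_identical_embeddings_is_perfect():
    pairs = _aligned_pairs(noise=0.0)
    result = train_probe(pairs, steps=300, seed=1)
    assert result.auroc > 0.99
    assert result.matched.mean() > 0.99


def test_probe_on_independent_embeddings_is_chance():
    rng = np.random.default_rng(2)
    pairs = EmbeddingPairSet(rng.normal(size=(150, 80)),
                             rng.normal(size=(150, 80)))
    result = train_probe(pairs, steps=300, seed=2)
    assert abs(result.auroc - 0.5) < 0.1


def test_probe_never_mutates_embeddings():
    pairs = _aligned_pairs(seed=3)
    before = (pairs.X.copy(), pairs.Y.copy())
    train_probe(pairs, steps=100, seed=3)
    assert np.array_equal(pairs.X, before[0])
    assert np.array_equal(pairs.Y, before[1])


def test_probe_generalization_gap_shrinks_with_training_fraction():
    pairs = _aligned_pairs(n=200, noise=0.6, seed=4)
    gaps = []
    for frac in (0.05, 0.5):
        r = train_probe(pairs, train_frac=frac, steps=400, seed=4)
        gaps.append(r.train_auroc - r.auroc)
    assert gaps[1] < gaps[0] + 0.02


def test_probe_rank_constraint_enforced():
    with pytest.raises(ValueError):
        train_probe(_aligned_pairs(d=40), rank=16)


def test_probe_requires_enough_pairs():
    with pytest.raises(ValueError):
        train_probe(EmbeddingPairSet(np.ones((3, 80)), np.ones((3, 80))))


# ------------------------------------------------------------------ conv probe
def _random_stacks(n, C=4, L=10, seed=0):
    rng = np.random.default_rng(seed)
    logits = rng.normal(size=(n, C, L, L))
    maps = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
    return [AttentionStack(m) for m in maps]


def test_conv_probe_zero_final_layer_gives_half():
    rng = np.random.default_rng(0)
    probe = ConvContactProbe(4, rng, hidden=8)
    probe.convs[-1].data[:] = 0.0
    stack = _random_stacks(1)[0]
    assert np.allclose(probe.predict(stack), 0.5)


@pytest.mark.parametrize("L", [3, 7, 12])
def test_conv_probe_output_length_matches_input(L):
    probe = ConvContactProbe(4, np.random.default_rng(1), hidden=8)
    stack = _random_stacks(1, L=L, seed=L)[0]
    assert probe.predict(stack).shape == (L,)


def test_conv_probe_channel_permutation_symmetry():
    """Permuting input channels together with the first-layer kernels leaves
    the output unchanged."""
    rng = np.random.default_rng(2)
    probe = ConvContactProbe(4, rng, hidden=8)
    stack = _random_stacks(1, seed=5)[0]
    base = probe.predict(stack)
    perm = np.array([2, 0, 3, 1])
    probe.convs[0].data = probe.convs[0].data[:, perm]
    probe.input_mean = probe.input_mean[perm]
    probe.input_std = probe.input_std[perm]
    permuted = probe.predict(AttentionStack(stack.channels[perm]))
    assert np.allclose(base, permuted, atol=1e-5)


def test_conv_probe_training_is_deterministic():
    stacks = _random_stacks(12, seed=6)
    rng = np.random.default_rng(7)
    labels = [rng.random(10) < 0.3 for _ in stacks]
    f1s = []
    for _ in range(2):
        probe = train_conv_probe(stacks, labels, steps=20, batch=4, hidden=8,
                                 seed=9)
        f1s.append(evaluate_conv_probe(probe, stacks, labels))
    assert f1s[0] == f1s[1]


def test_conv_probe_all_negative_fold_reports_zero(caplog):
    stacks = _random_stacks(4, seed=8)
    labels = [np.zeros(10, dtype=bool) for _ in stacks]
    probe = train_conv_probe(stacks, labels, steps=5, batch=2, hidden=8, seed=0)
    assert evaluate_conv_probe(probe, stacks, labels, threshold=0.0) == 0.0
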