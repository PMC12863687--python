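"""MLM batching, corruption statistics, schedule anchors, muP transfer."""

import numpy as np
import pytest

from bioseqlm.encoder import Encoder, EncoderConfig
from bioseqlm.pretraining import (OptimizerPlan, lr_schedule, make_mlm_batch,
                                  pretrain)
from bioseqlm.synthetic import gen_gene_protein_pairs
from bioseqlm.tokenization import Modality, encode, train_vocabulary_pair


@pytest.fixture(scope="module")
def pool_and_vocabs():
    pairs = gen_gene_protein_pairs(30, seed=5)
    genes = [p.gene for p in pairs]
    prots = [p.protein for p in pairs]
    nuc, prot = train_vocabulary_pair(genes, prots, algorithm="single_char")
    pool = [encode(g, nuc) for g in genes] + [encode(p, prot) for p in prots]
    return pool, {Modality.NUCLEIC: nuc, Modality.PROTEIN: prot}


def test_zero_mask_rate_leaves_batch_clean(pool_and_vocabs):
    pool, vocabs = pool_and_vocabs
    batch = make_mlm_batch(pool, vocabs, 64, 4, mask_rate=0.0,
                           rng=np.random.default_rng(0))
    assert (batch.input_ids == batch.target_ids).all()
    assert not batch.loss_mask.any()


def test_full_mask_rate_all_mask_token(pool_and_vocabs):
    pool, vocabs = pool_and_vocabs
    batch = make_mlm_batch(pool, vocabs, 64, 4, mask_rate=1.0,
                           rng=np.random.default_rng(0), mix=(1.0, 0.0, 0.0))
    for row, ids, mod in zip(batch.loss_mask, batch.input_ids, batch.modalities):
        mask_id = vocabs[mod].special_ids["mask"]
        specials = set(vocabs[mod].special_ids.values())
        non_special = ~np.isin(batch.target_ids[0], list(specials))
        assert (ids[row] == mask_id).all()
        # every non-special position must be selected
        assert row.sum() > 0


def test_corruption_rate_concentrates_at_mask_rate(pool_and_vocabs):
    pool, vocabs = pool_and_vocabs
    rng = np.random.default_rng(1)
    selected, total = 0, 0
    while total < 10_000:
        batch = make_mlm_batch(pool, vocabs, 64, 4, mask_rate=0.15, rng=rng)
        selected += batch.loss_mask.sum()
        total += batch.pad_mask.sum()
    assert abs(selected / total - 0.15) < 0.02


def test_modality_purity_across_many_batches(pool_and_vocabs):
    pool, vocabs = pool_and_vocabs
    rng = np.random.default_rng(2)
    nuc_range = set(vocabs[Modality.NUCLEIC].id_range) \
        | set(vocabs[Modality.NUCLEIC].special_ids.values())
    prot_range = set(vocabs[Modality.PROTEIN].id_range) \
        | set(vocabs[Modality.PROTEIN].special_ids.values())
    for _ in range(1500):
        batch = make_mlm_batch(pool, vocabs, 32, 8, rng=rng)
        for row in batch.input_ids:
            ids = set(row.tolist())
            assert not (ids & nuc_range and ids & prot_range)


def test_empty_pool_rejected(pool_and_vocabs):
    _, vocabs = pool_and_vocabs
    with pytest.raises(ValueError):
        make_mlm_batch([], vocabs, 64, 4)


def test_lr_schedule_anchors():
    assert lr_schedule(0, 100, 10) == pytest.approx(1e-5)
    assert lr_schedule(10, 100, 10) == pytest.approx(1.0)
    assert lr_schedule(100, 100, 10) == pytest.approx(1e-5)


def test_lr_schedule_monotone_up_then_down():
    scales = [lr_schedule(s, 200, 20) for s in range(201)]
    assert all(a <= b + 1e-12 for a, b in zip(scales[:20], scales[1:21]))
    assert all(a >= b - 1e-12 for a, b in zip(scales[20:-1], scales[21:]))


def test_lr_schedule_clamps_out_of_range(caplog):
    assert lr_schedule(500, 100, 10) == pytest.approx(1e-5)
    assert any("clamping" in r.message for r in caplog.records)


def test_pretrain_zero_steps_leaves_parameters(pool_and_vocabs):
    pool, vocabs = pool_and_vocabs
    vmax = max(v.max_id for v in vocabs.values()) + 1
    enc = Encoder(EncoderConfig(d=16, n_layers=1, n_heads=2, vocab_size=vmax,
                                context_length=32), np.random.default_rng(0))
    before = enc.state_dict()
    pretrain(pool, enc, vocabs, n_steps=0, n_rows=2, context_length=32, seed=0)
    after = enc.state_dict()
    assert all(np.array_equal(before[k], after[k]) for k in before)


def test_pretrain_deterministic_traces(pool_and_vocabs):
    pool, vocabs = pool_and_vocabs
    vmax = max(v.max_id for v in vocabs.values()) + 1
    cfg = EncoderConfig(d=16, n_layers=1, n_heads=2, vocab_size=vmax,
                        context_length=32)
    traces = []
    for _ in range(2):
        enc = Encoder(cfg, np.random.default_rng(0))
        traces.append(pretrain(pool, enc, vocabs, n_steps=8, n_rows=2,
                               context_length=32, seed=3))
    assert traces[0] == traces[1]


def test_toy_corpus_mlm_loss_falls_below_half_uniform(pool_and_vocabs):
    pool, vocabs = pool_and_vocabs
    vmax = max(v.max_id for v in vocabs.values()) + 1
    enc = Encoder(EncoderConfig(d=48, n_layers=2, n_heads=4, vocab_size=vmax,
                                context_length=64), np.random.default_rng(0))
    trace = pretrain(pool[:20], enc, vocabs, n_steps=800, n_rows=4,
                     context_length=64, seed=0)
    final = np.mean([x[2] for x in trace[-20:]])
    assert final < 0.5 * np.log(vmax)


def test_mup_optimal_base_lr_transfers_across_width(pool_and_vocabs):
    """The loss-minimising base learning rate should not shift by more than
    one grid step between a narrow and a wide model."""
    pool, vocabs = pool_and_vocabs
    vmax = max(v.max_id for v in vocabs.values()) + 1
    grid = [0.0125, 0.05, 0.2]
    best = {}
    for width in (32, 128):
        losses = []
        for base in grid:
            enc = Encoder(EncoderConfig(d=width, n_layers=2, n_heads=4,
                                        vocab_size=vmax, context_length=64),
                          np.random.default_rng(0))
            plan = OptimizerPlan(hidden_lr_base=base)
            trace = pretrain(pool, enc, vocabs, n_steps=80, n_rows=4,
                             context_length=64, plan=plan, seed=1)
            losses.append(np.mean([x[2] for x in trace[-10:]]))
        best[width] = int(np.argmin(losses))
    assert abs(best[32] - best[128]) <= 1
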