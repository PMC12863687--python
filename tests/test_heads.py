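"""Task heads: joint input layout, DG regression, contact tagging, pair maps."""

import numpy as np
import pytest

from bioseqlm.encoder import Encoder, EncoderConfig
from bioseqlm.heads import (ComplexRecord, ContactTaggingModel, DGModel,
                            DualEncoderDGModel, FinetuneLRs,
                            PairwiseContactHead, _fit_regression,
                            build_multiomic_input, evaluate_dG,
                            finetune_contacts, predict_contact_map)
from bioseqlm.tokenization import encode


@pytest.fixture(scope="module")
def vocabs():
    from bioseqlm.tokenization import train_vocabulary_pair

    return train_vocabulary_pair(["ACGTU", "ACGT"], ["ACDEFGHIKLMNPQRSTVWY"],
                                 algorithm="single_char")


def _encoder(vocabs, d=32, seed=0, ctx=64):
    nuc, prot = vocabs
    cfg = EncoderConfig(d=d, n_layers=2, n_heads=4,
                        vocab_size=max(nuc.max_id, prot.max_id) + 1,
                        context_length=ctx)
    return Encoder(cfg, np.random.default_rng(seed))


def test_single_strand_layout(vocabs):
    nuc, prot = vocabs
    record = ComplexRecord("MKV", ("ACGT",))
    inp = build_multiomic_input(record, prot, nuc)
    ids = inp.ids.tolist()
    assert ids[0] == prot.special_ids["cls"]
    assert ids.count(prot.special_ids["sep"]) == 1
    assert len(ids) == 1 + 3 + 1 + 4


def test_double_strand_layout_token_count(vocabs):
    nuc, prot = vocabs
    record = ComplexRecord("MKVL", ("ACGT", "TGCA"))
    inp = build_multiomic_input(record, prot, nuc)
    assert len(inp.ids) == 1 + 4 + 1 + 4 + 1 + 4


def test_modality_ranges_partition_at_separators(vocabs):
    nuc, prot = vocabs
    record = ComplexRecord("MKVLW", ("ACGT", "GG"))
    inp = build_multiomic_input(record, prot, nuc)
    specials = set(prot.special_ids.values()) | set(nuc.special_ids.values())
    segments, current = [], []
    for i in inp.ids.tolist():
        if i in specials:
            if current:
                segments.append(current)
            current = []
        else:
            current.append(i)
    segments.append(current)
    assert all(i in prot.id_range for i in segments[0])
    for seg in segments[1:]:
        assert all(i in nuc.id_range for i in seg)


def test_overlength_truncates_nucleic_tail_only(vocabs, caplog):
    nuc, prot = vocabs
    record = ComplexRecord("MKVLW", ("ACGT" * 10,))
    inp = build_multiomic_input(record, prot, nuc, context_length=16)
    assert len(inp.ids) == 16
    assert inp.protein_token_slice == slice(1, 6)  # protein intact
    assert any("truncating" in r.message for r in caplog.records)
    with pytest.raises(ValueError):
        build_multiomic_input(ComplexRecord("M" * 30, ("A",)), prot, nuc,
                              context_length=16)


def test_empty_chains_rejected(vocabs):
    with pytest.raises(ValueError):
        ComplexRecord("", ("ACGT",))
    with pytest.raises(ValueError):
        ComplexRecord("MKV", ())


def test_zero_weight_head_predicts_bias(vocabs):
    nuc, prot = vocabs
    model = DGModel(_encoder(vocabs), prot, nuc, np.random.default_rng(0))
    model.head.proj.weight.data[:] = 0.0
    model.head.proj.bias.data[:] = -7.25
    for record in (ComplexRecord("MKV", ("ACGT",)),
                   ComplexRecord("WYACD", ("GG", "CC"))):
        assert model.predict_dG(record) == pytest.approx(-7.25, abs=1e-5)


def test_dg_memorization_capacity(vocabs):
    """With test == train (leakage deliberately allowed), a toy joint model
    must drive the MAE on 20 records close to zero."""
    from bioseqlm.synthetic import gen_binding_dataset

    records, _ = gen_binding_dataset(proteins_per_family=2, seqs_per_protein=5,
                                     seed=3)
    records = records[:20]
    nv, pv = _vocabs_for(records)
    cfg = EncoderConfig(d=64, n_layers=2, n_heads=4,
                        vocab_size=max(nv.max_id, pv.max_id) + 1,
                        context_length=48)
    model = DGModel(Encoder(cfg, np.random.default_rng(0)), pv, nv,
                    np.random.default_rng(0))
    _fit_regression(model, records, epochs=250, batch=8, lrs=FinetuneLRs(),
                    seed=0)
    assert evaluate_dG(model, records)["mae"] < 0.1


def _vocabs_for(records):
    from bioseqlm.tokenization import train_vocabulary_pair

    prot = sorted({r.protein_seq for r in records})
    nuc = sorted({s for r in records for s in r.nucleic_seqs})
    return train_vocabulary_pair(nuc, prot, algorithm="single_char")


def test_dual_encoder_prediction_is_additive(vocabs):
    """The single-omic control's prediction decomposes into a protein term
    plus a nucleic term: swapping partners leaves the sum structure intact."""
    nuc, prot = vocabs
    dual = DualEncoderDGModel(_encoder(vocabs, seed=1), _encoder(vocabs, seed=2),
                              prot, nuc, np.random.default_rng(3))
    p = ["MKV", "WYACD"]
    n = ["ACGT", "GGCC"]
    f = {(i, j): dual.predict_dG(ComplexRecord(p[i], (n[j],)))
         for i in range(2) for j in range(2)}
    assert f[(0, 0)] + f[(1, 1)] == pytest.approx(f[(0, 1)] + f[(1, 0)], abs=1e-4)


def test_contact_tagger_zero_head_gives_half_probability(vocabs):
    nuc, prot = vocabs
    model = ContactTaggingModel(_encoder(vocabs), prot, nuc,
                                np.random.default_rng(0))
    model.head.weight.data[:] = 0.0
    model.head.bias.data[:] = 0.0
    record = ComplexRecord("MKVLW", ("ACGT",),
                           contact_labels=np.zeros(5, dtype=bool))
    probs = model.predict_contacts_per_residue(record)
    assert probs.shape == (5,)
    assert np.allclose(probs, 0.5)


def test_contact_tagger_requires_labels(vocabs):
    nuc, prot = vocabs
    model = ContactTaggingModel(_encoder(vocabs), prot, nuc,
                                np.random.default_rng(0))
    with pytest.raises(ValueError):
        finetune_contacts(model, [ComplexRecord("MKV", ("ACGT",))], epochs=1)


def test_contact_tagger_beats_all_positive_baseline():
    from bioseqlm.evaluation import max_random_f1, metrics
    from bioseqlm.synthetic import gen_contact_dataset

    fixtures = gen_contact_dataset(48, protein_length=16, seed=4)
    records = [f.record for f in fixtures]
    nv, pv = _vocabs_for(records)
    cfg = EncoderConfig(d=48, n_layers=2, n_heads=4,
                        vocab_size=max(nv.max_id, pv.max_id) + 1,
                        context_length=48)
    model = ContactTaggingModel(Encoder(cfg, np.random.default_rng(1)), pv, nv,
                                np.random.default_rng(1))
    finetune_contacts(model, records[:40], epochs=15, batch=8, seed=1)
    preds = np.concatenate([model.predict_contacts_per_residue(r)
                            for r in records[40:]])
    truth = np.concatenate([r.contact_labels for r in records[40:]])
    ratio = truth.mean() / (1 - truth.mean())
    assert metrics(preds, truth, "f1") > max_random_f1(ratio) + 0.1


def test_pairwise_head_mask_combinatorics():
    head = PairwiseContactHead(32, np.random.default_rng(0))
    mask = head.loss_mask(24)
    # pairs with |i-j| >= 12 among 24 positions: 2 * (13*12/2) = 156
    assert mask.sum() == 2 * (13 * 12 // 2)
    with pytest.raises(ValueError):
        head.loss_mask(12)


def test_pairwise_head_output_bounded_and_p_at_L(vocabs):
    from bioseqlm.evaluation import precision_at_L

    nuc, prot = vocabs
    enc = _encoder(vocabs)
    head = PairwiseContactHead(enc.config.d, np.random.default_rng(1),
                               proj_dim=16, channels=8)
    tokens = encode("MKVLWACDEFGHIKLMN", prot)
    probs = predict_contact_map(enc, head, tokens)
    L = len(tokens.ids)
    assert probs.shape == (L, L)
    assert (probs > 0).all() and (probs < 1).all()
    # P@L is exactly 1 when the true contacts are the top-L predicted pairs
    flat = np.argsort(-probs.ravel())[:L]
    truth = np.zeros_like(probs, dtype=bool)
    truth.ravel()[flat] = True
    assert precision_at_L(probs, truth, top=L) == 1.0


def test_pcc_of_constant_predictions_reports_zero(vocabs):
    from bioseqlm.evaluation import metrics

    assert metrics(np.full(5, 1.7), np.arange(5.0), "pcc") == 0.0
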