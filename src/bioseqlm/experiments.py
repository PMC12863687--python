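"""Reference desk-scale experiments.

These are the package's end-to-end study conditions: parameter recovery of
the synthetic binding energetics with a jointly pretrained encoder, the
joint-vs-single-omic contrast for both the regression task and the
contrastive modality-invariance probe, and the planted-signal check for the
frozen-attention contact probe.  Problem sizes are chosen so each experiment
runs in minutes on one CPU; docs/methods.md records the choices.

Every function is deterministic given its ``seed``; derived seeds stay below
2^31.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import Encoder, EncoderConfig, pooled_embedding
from .evaluation import audit_leakage, build_folds, max_random_f1, metrics
from .heads import (ComplexRecord, DGModel, DualEncoderDGModel, FinetuneLRs,
                    _fit_regression, build_multiomic_input, evaluate_dG)
from .pretraining import pretrain
from .probes import (EmbeddingPairSet, evaluate_conv_probe,
                     stack_from_encoder_output, train_conv_probe, train_probe)
from .synthetic import (gen_binding_dataset, gen_contact_dataset,
                        gen_gene_protein_pairs)
from .tokenization import Modality, encode, train_vocabulary_pair


def _sub_seed(seed: int, offset: int) -> int:
    return int((seed + offset) % (2 ** 31 - 1))


def _vocabs_for_records(records):
    prot = sorted({r.protein_seq for r in records})
    nuc = sorted({s for r in records for s in r.nucleic_seqs})
    return train_vocabulary_pair(nuc, prot, algorithm="single_char")


def _binding_setup(seed: int, width: int):
    records, model = gen_binding_dataset(seed=_sub_seed(seed, 0))
    nv, pv = _vocabs_for_records(records)
    cfg = EncoderConfig(d=width, n_layers=2, n_heads=8,
                        vocab_size=max(nv.max_id, pv.max_id) + 1,
                        context_length=48)
    folds = build_folds(records, n_folds=10,
                        rng=np.random.default_rng(_sub_seed(seed, 1)))
    return records, model, nv, pv, cfg, folds


def run_dg_recovery(
    seed: int = 0,
    width: int = 256,
    pretrain_steps: int = 300,
    epochs: int = 32,
    batch: int = 16,
    eval_fold: int = 0,
    audit: bool = True,
) -> dict:
    """MLM-pretrain a 2-layer joint encoder, fine-tune on the synthetic
    binding dataset (sigma = 0.5 kcal/mol), and score one held-out fold.

    The pretraining pool mixes a gene/protein pair corpus with the binding
    sequences, mirroring the generalist-pretrain / task-fine-tune split."""
    records, model, nv, pv, cfg, folds = _binding_setup(seed, width)
    vocabs = {Modality.NUCLEIC: nv, Modality.PROTEIN: pv}
    corpus = gen_gene_protein_pairs(150, seed=_sub_seed(seed, 7))
    pool = ([encode(p.protein, pv) for p in corpus]
            + [encode(p.gene, nv) for p in corpus]
            + [encode(s, nv) for s in sorted({r.nucleic_seqs[0] for r in records})]
            + [encode(s, pv) for s in sorted({r.protein_seq for r in records})])
    enc = Encoder(cfg, np.random.default_rng(_sub_seed(seed, 2)))
    pretrain(pool, enc, vocabs, n_steps=pretrain_steps, n_rows=8,
             context_length=48, seed=_sub_seed(seed, 3))

    test_groups = folds.test_groups(eval_fold)
    train = [r for r in records if r.protein_seq not in test_groups]
    test = [r for r in records if r.protein_seq in test_groups]
    dg = DGModel(enc, pv, nv, np.random.default_rng(_sub_seed(seed, 4)))
    _fit_regression(dg, train, epochs=epochs, batch=batch, lrs=FinetuneLRs(),
                    seed=_sub_seed(seed, 5))
    result = evaluate_dG(dg, test)
    result["n_test"] = len(test)
    result["noise_sigma"] = model.noise_sigma
    if audit:
        result["leakage_violations"] = audit_leakage(folds)
    result["model"] = dg
    result["binding_model"] = model
    return result


def run_dg_direction(
    seed: int = 0,
    n_reps: int = 5,
    width: int = 64,
    epochs: int = 24,
    batch: int = 16,
) -> dict:
    """Paired comparison: joint multi-omic regressor vs the dual-encoder
    single-omic control, fine-tuned on matched data and budget."""
    joint_pccs, dual_pccs = [], []
    for rep in range(n_reps):
        rep_seed = _sub_seed(seed, 37 * rep + 11)
        records, _, nv, pv, cfg_, folds = _binding_setup(rep_seed, width)
        cfg = EncoderConfig(d=width, n_layers=2, n_heads=8,
                            vocab_size=cfg_.vocab_size, context_length=48)
        test_groups = folds.test_groups(0)
        train = [r for r in records if r.protein_seq not in test_groups]
        test = [r for r in records if r.protein_seq in test_groups]
        rng = np.random.default_rng(rep_seed)
        joint = DGModel(Encoder(cfg, rng), pv, nv, rng)
        _fit_regression(joint, train, epochs=epochs, batch=batch,
                        lrs=FinetuneLRs(), seed=rep_seed)
        joint_pccs.append(evaluate_dG(joint, test)["pcc"])
        rng = np.random.default_rng(_sub_seed(rep_seed, 1))
        dual = DualEncoderDGModel(
            Encoder(cfg, rng),
            Encoder(cfg, np.random.default_rng(_sub_seed(rep_seed, 2))),
            pv, nv, rng)
        _fit_regression(dual, train, epochs=epochs, batch=batch,
                        lrs=FinetuneLRs(), seed=rep_seed)
        dual_pccs.append(evaluate_dG(dual, test)["pcc"])
    return {"joint_pccs": joint_pccs, "dual_pccs": dual_pccs,
            "mean_gap": float(np.mean(joint_pccs) - np.mean(dual_pccs))}


def run_modality_alignment(
    seed: int = 0,
    n_pairs: int = 600,
    width: int = 72,
    pretrain_steps: int = 1500,
    probe_steps: int = 3000,
    n_probe_seeds: int = 5,
) -> dict:
    """Emergent gene-protein alignment: a single low-rank probe on a jointly
    pretrained encoder vs dual probes on two single-omic encoders.

    All three encoders get the same step budget; embeddings are the pooled
    first-token states, frozen before probing.
    """
    pairs = gen_gene_protein_pairs(n_pairs, seed=_sub_seed(seed, 0))
    genes = [p.gene for p in pairs]
    prots = [p.protein for p in pairs]
    nv, pv = train_vocabulary_pair(genes, prots, algorithm="single_char")
    vocabs = {Modality.NUCLEIC: nv, Modality.PROTEIN: pv}
    cfg = EncoderConfig(d=width, n_layers=2, n_heads=4,
                        vocab_size=max(nv.max_id, pv.max_id) + 1,
                        context_length=128)
    gene_toks = [encode(g, nv) for g in genes]
    prot_toks = [encode(p, pv) for p in prots]

    def embed_all(enc, toks, vocab):
        cls = vocab.special_ids["cls"]
        rows = []
        for t in toks:
            ids = np.asarray([cls] + t.ids[:cfg.context_length - 1])
            rows.append(pooled_embedding(enc.forward(ids)).data[0])
        return np.asarray(rows)

    joint = Encoder(cfg, np.random.default_rng(_sub_seed(seed, 1)))
    pretrain(gene_toks + prot_toks, joint, vocabs, n_steps=pretrain_steps,
             n_rows=8, context_length=128, seed=_sub_seed(seed, 2))
    gene_only = Encoder(cfg, np.random.default_rng(_sub_seed(seed, 3)))
    pretrain(gene_toks, gene_only, vocabs, n_steps=pretrain_steps, n_rows=8,
             context_length=128, seed=_sub_seed(seed, 4))
    prot_only = Encoder(cfg, np.random.default_rng(_sub_seed(seed, 5)))
    pretrain(prot_toks, prot_only, vocabs, n_steps=pretrain_steps, n_rows=8,
             context_length=128, seed=_sub_seed(seed, 6))

    joint_set = EmbeddingPairSet(embed_all(joint, gene_toks, nv),
                                 embed_all(joint, prot_toks, pv))
    single_set = EmbeddingPairSet(embed_all(gene_only, gene_toks, nv),
                                  embed_all(prot_only, prot_toks, pv))
    joint_aurocs, dual_aurocs = [], []
    for k in range(n_probe_seeds):
        probe_seed = _sub_seed(seed, 100 + k)
        joint_aurocs.append(train_probe(joint_set, mode="joint_single_W",
                                        steps=probe_steps,
                                        seed=probe_seed).auroc)
        dual_aurocs.append(train_probe(single_set, mode="dual_W_control",
                                       steps=probe_steps,
                                       seed=probe_seed).auroc)
    return {"joint_aurocs": joint_aurocs, "dual_aurocs": dual_aurocs,
            "mean_gap": float(np.mean(joint_aurocs) - np.mean(dual_aurocs))}


def run_attention_probe(
    seed: int = 0,
    n_complexes: int = 100,
    n_train: int = 80,
    protein_length: int = 16,
    width: int = 64,
    pretrain_steps: int = 300,
    probe_steps: int = 500,
    positive_ratio: float = 0.29,
    planted_channel: int = 3,
) -> dict:
    """Planted-signal recovery for the frozen-attention conv probe.

    Attention stacks come from a briefly pretrained toy encoder run on
    synthetic complexes; one channel is overwritten with a row pattern in
    which positive residues attend strongly to the first position, and labels
    are that pattern — a deterministic, margin-separated function of a single
    channel.  A label-shuffled control trained identically should fall to the
    all-positive baseline 2p/(1+p).
    """
    fixtures = gen_contact_dataset(n_complexes, protein_length=protein_length,
                                   seed=_sub_seed(seed, 0))
    records = [f.record for f in fixtures]
    nv, pv = _vocabs_for_records(records)
    vocabs = {Modality.NUCLEIC: nv, Modality.PROTEIN: pv}
    cfg = EncoderConfig(d=width, n_layers=2, n_heads=4,
                        vocab_size=max(nv.max_id, pv.max_id) + 1,
                        context_length=48)
    enc = Encoder(cfg, np.random.default_rng(_sub_seed(seed, 1)))
    pool = ([encode(s, pv) for s in sorted({r.protein_seq for r in records})]
            + [encode(s, nv) for s in sorted({r.nucleic_seqs[0] for r in records})])
    pretrain(pool, enc, vocabs, n_steps=pretrain_steps, n_rows=8,
             context_length=48, seed=_sub_seed(seed, 2))

    stacks = []
    for r in records:
        inp = build_multiomic_input(r, pv, nv, cfg.context_length)
        out = enc.forward(inp.ids)
        stacks.append(stack_from_encoder_output(
            out.attentions, token_slice=inp.protein_token_slice))

    p = positive_ratio / (1.0 + positive_ratio)
    rng = np.random.default_rng(_sub_seed(seed, 3))
    L = stacks[0].channels.shape[1]
    planted = []
    for s in stacks:
        labels = rng.random(L) < p
        channel = np.full((L, L), 1.0 / L, dtype=np.float32)
        channel[labels] = 0.5 / (L - 1)
        channel[labels, 0] = 0.5  # positives attend to the first position
        s.channels[planted_channel] = channel
        planted.append(labels)

    probe = train_conv_probe(stacks[:n_train], planted[:n_train],
                             steps=probe_steps, batch=8,
                             seed=_sub_seed(seed, 4))
    planted_f1 = evaluate_conv_probe(probe, stacks[n_train:], planted[n_train:])

    shuffle_rng = np.random.default_rng(_sub_seed(seed, 5))
    shuffled = [shuffle_rng.permutation(l) for l in planted]
    control = train_conv_probe(stacks[:n_train], shuffled[:n_train],
                               steps=probe_steps, batch=8,
                               seed=_sub_seed(seed, 4))
    shuffled_f1 = evaluate_conv_probe(control, stacks[n_train:],
                                      shuffled[n_train:])
    rate = np.mean([l.mean() for l in shuffled])
    return {
        "planted_f1": planted_f1,
        "shuffled_f1": shuffled_f1,
        "uninformative_ceiling": max_random_f1(rate / (1.0 - rate)),
        "n_eval": len(stacks) - n_train,
    }


def run_leakage_audit(seed: int = 0, planted_near_duplicates: int = 2) -> dict:
    """Fold construction on family-structured proteins with planted
    near-duplicates; verifies pinning and the absence of homologous
    train/test pairs."""
    from .evaluation import PINNED_TRAIN, normalized_alignment_score

    records, _ = gen_binding_dataset(
        planted_near_duplicates=planted_near_duplicates, seed=_sub_seed(seed, 0))
    folds = build_folds(records, n_folds=10,
                        rng=np.random.default_rng(_sub_seed(seed, 1)))
    proteins = sorted({r.protein_seq for r in records})
    planted_pairs = [
        (a, b)
        for i, a in enumerate(proteins) for b in proteins[i + 1:]
        if normalized_alignment_score(a, b).normalized > 1.5
    ]
    pinned_ok = all(
        folds.fold_of_group[a] == PINNED_TRAIN
        or folds.fold_of_group[b] == PINNED_TRAIN
        for a, b in planted_pairs)
    return {
        "n_planted_pairs": len(planted_pairs),
        "all_planted_pairs_pinned": bool(pinned_ok),
        "leakage_violations": audit_leakage(folds),
        "n_groups": len(folds.fold_of_group),
    }
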