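# bioseqlm

Desk-scale multi-omic biosequence language models: one transformer encoder,
jointly pretrained on protein and nucleic-acid sequences with the masked
language modeling (MLM) objective, then fine-tuned and probed on
protein–nucleic-acid interaction tasks.

Most biosequence models are single-omic — they see either proteins or
nucleic acids.  Interactions that matter pharmacologically (transcription
factor binding, aptamer–protein recognition) live *between* the modalities.
This package implements, small enough to run on a laptop CPU, the complete
machinery of a multi-omic model study:

* **Modality-disjoint tokenization** — separate BPE or single-character
  vocabularies for protein and nucleic sequences with globally disjoint id
  ranges and exact per-token character spans (`bioseqlm.tokenization`),
  plus the four residue↔token transforms for per-residue tasks
  (`bioseqlm.transforms`).
* **muP transformer encoder** — bidirectional, RoPE positions, RMSNorm +
  SwiGLU, attention scores scaled 1/head_dim, embeddings at fixed learning
  rate 0.05 and hidden groups at 32/width, full attention-map export
  (`bioseqlm.encoder`, `bioseqlm.pretraining`).  Everything differentiable
  runs on a compact NumPy reverse-mode autodiff engine (`bioseqlm.nn`).
* **Task heads** — binding free energy ΔG (kcal/mol) regressed from the
  first-token embedding of the joint `[cls] protein [sep] nucleic` context;
  a dual-encoder single-omic control; per-residue contact tagging; a
  TAPE-style pairwise ResNet contact head; generic classification
  (`bioseqlm.heads`).
* **Homology-aware evaluation** — BLOSUM62 global alignment normalised by
  alignment length, 10-fold protein-disjoint splits with pinning of any
  protein scoring > 1.5 against another, distance-threshold contact
  labeling from PDB structures, and the analytic random-guessing F1 ceiling
  2p/(1+p) (`bioseqlm.evaluation`).
* **Specificity scans** — JASPAR-style PFM consensus extraction, 5%
  mutation scans (8 unique mutants) and ΔΔG aggregation
  (`bioseqlm.specificity`).
* **Interpretability probes** — the rank-16, τ = 0.07 contrastive
  modality-invariance probe (5%/95% split) and the 4-layer convolutional
  probe over frozen attention stacks (`bioseqlm.probes`).
* **Synthetic data with known ground truth** — translated gene/protein
  pairs with introns, a recoverable binding-energy model, and contact
  fixtures whose minimal 3-D coordinates reproduce the planted labels
  (`bioseqlm.synthetic`); reference experiments in `bioseqlm.experiments`.

See `docs/methods.md` for the model details, the synthetic study
conditions, and known limitations.

## Worked example

Recover the synthetic binding energetics with a width-256 joint encoder
(about two minutes of pretraining + fine-tuning on one CPU):

```python
from bioseqlm.experiments import run_dg_recovery, run_dg_direction

result = run_dg_recovery(seed=0)
print(f"held-out PCC  {result['pcc']:.3f}")
print(f"held-out MAE  {result['mae']:.2f} kcal/mol")
print(f"leakage violations  {result['leakage_violations']}")
```

prints

```
held-out PCC  0.931
held-out MAE  1.10 kcal/mol
leakage violations  0
```

i.e. the fine-tuned joint model explains most of the held-out variance of
the generative energies (noise floor σ = 0.5 kcal/mol) on proteins it never
saw, and no test protein has a homolog (normalised BLOSUM62 score > 1.5) in
its training fold.  The single-omic contrast:

```python
print(run_dg_direction(seed=0))
```

```
{'joint_pccs': [0.949, 0.902, 0.962, 0.760, 0.906],
 'dual_pccs':  [0.187, 0.189, 0.185, 0.191, 0.086],
 'mean_gap': 0.728}
```

The dual-encoder control collapses to near-zero correlation: its additive
head cannot represent the protein-family × nucleic-site interaction that
carries the signal in this dataset — the same qualitative contrast a joint
multi-omic model shows against single-omic controls on real binding data.

A command-line interface wraps the library for file-based workflows:

```bash
bioseqlm gen-synthetic --what binding --seed 1 --out data/
bioseqlm pretrain --nucleic-fasta genes.fasta --protein-fasta prots.fasta --out ckpt/
bioseqlm finetune-dg --checkpoint ckpt/ --table data/binding.tsv --fold 0 --out dg/
bioseqlm scan-jaspar --pfm data/families.pfm --proteins dbps.fasta --checkpoint dg/ --out scan/
```

Every command writes a config snapshot and log into `--out`.

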