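# Methods

`bioseqlm` implements, at desk scale, a complete multi-omic biosequence
modelling pipeline: modality-disjoint tokenization, masked-language-model
(MLM) pretraining of a non-causal transformer under maximal update
parameterization (muP), fine-tuning heads for protein–nucleic-acid binding
free energy (ΔG), binding specificity and contact prediction, and two
interpretability probes over frozen model internals.  This note records the
models, the synthetic study conditions, the numerical choices, and what the
package's tests do and do not establish.

## Tokenization

Protein and nucleic-acid sequences use separate vocabularies with globally
disjoint id ranges, so a string such as `ACGT` — a valid oligonucleotide and
a valid tetrapeptide — has a different tokenized form per modality.  Two
schemes are provided: byte-pair encoding (BPE; iterative merging of the most
frequent adjacent pair, ties broken lexicographically so training is
deterministic) and single-character vocabularies.  The canonical alphabets
are the 20 standard amino acids and the 5 standard bases (A, C, G, T, U);
sequences containing anything else are rejected with a logged warning.
Encoding uses greedy longest-match segmentation and records, for every
token, the half-open character span it covers.  Those spans are the
foundation of all per-residue↔per-token transforms: aggregation to token
space uses the per-span mode (classification; ties resolve to the lowest
class id) or mean (regression), and predictions are broadcast back by
duplicating a token's value over its span.  Contact maps transform
analogously: a token pair is a contact if *any* residue pair across the two
spans is, and the short-range loss mask is positive when some residue pair
across the spans is at least 12 residues apart (|r−s| ≥ 12).

Each modality carries its own `cls`, `sep`, `mask`, `pad` specials, with ids
outside both piece ranges.  A dedicated leading `cls` token provides the
pooled ("first token") embedding; without it, pooling would depend
uncontrollably on the first sequence token's identity.

## Encoder and muP

The backbone is a pre-norm transformer in the LLaMA style — RMSNorm, rotary
positional embeddings (RoPE, base 10000) applied to queries and keys, gated
SwiGLU feed-forward of width round(8/3·d) — with full bidirectional
attention.  Following muP:

* pre-softmax attention scores are scaled by 1/head_dim (not 1/√head_dim);
* token embeddings are initialised with O(1) variance, all hidden linear
  maps with variance ∝ 1/fan_in;
* the embedding/unembedding group trains at a fixed learning rate (0.05)
  while every other group's rate scales as 32/width.

"Width" in the attention scaling is read as the per-head width (head_dim),
the standard muP prescription.  The tests verify the two observable
consequences at this scale: hidden-activation RMS at initialisation varies
by less than 2× across widths 64–256, and the loss-minimising base learning
rate on a small MLM task does not shift by more than one grid step between
width 32 and width 128.

Every forward pass can export the complete attention stack
(n_layers × n_heads row-stochastic L×L maps), which the interpretability
probes consume; attention is materialised exactly for this reason (no
fused/implicit attention).

All differentiable components run on a small reverse-mode automatic
differentiation engine over float32 NumPy arrays (`bioseqlm.nn`), with
AdamW (β = (0.9, 0.95), ε = 1e−8, weight decay 1e−2) and a one-cycle
schedule (cosine ramp and decay; scale exactly 1e−5 at the first and last
step and 1.0 at the warmup peak).  Gradient correctness is tested against
finite differences for every op family.

## Pretraining

MLM batches are packed greedily: each batch row holds one or more sequences
of a *single* modality joined by that modality's separator, so protein and
nucleic ids never share a context window.  Corruption selects each
non-special position with probability 0.15 and applies the standard
80/10/10 mix (mask token / random same-modality piece / unchanged); the
loss is computed only at selected positions.  Sequence order is a seeded
shuffle; runs are bitwise reproducible given the seed.

## Binding free-energy head and the single-omic control

A complex is presented as `[cls] protein [sep] nucleic ([sep] nucleic₂)`,
mixing the two vocabularies in one context; ΔG (kcal/mol) is a linear map
of the pooled first-token embedding.  Over-length inputs are truncated from
the nucleic tail only.  Fine-tuning minimises MSE with three muP-style
learning-rate groups — head 1e−2, embeddings 1e−3, remaining encoder
parameters 1e−4·1024/width — on the one-cycle schedule (defaults: 64
epochs, batch 256; the desk-scale experiments below use smaller values).

The single-omic control embeds protein and nucleic chains with two separate
encoders and regresses ΔG from the concatenated pooled embeddings, trained
end-to-end with the same learning-rate structure.  Its final head is
additive in the two embeddings, so it can represent each side's marginal
effect but not protein-specific nucleic preferences.  Per-residue contact
tagging applies a linear+sigmoid head at every protein token position
(labels aggregated to token space for BPE models); the pairwise
residue–residue head projects embeddings to 128 dimensions, builds the
256-channel pair grid by concatenation, and reduces it with an 8-layer
residual 3×3 conv stack, with the loss masked to |i−j| ≥ 12.

## Homology-aware evaluation

Cross-validation groups records by exact protein sequence and splits groups
into 10 protein-disjoint folds.  Homology is measured by global BLOSUM62
alignment (gap open 11 / extend 1, the BLAST convention; the identical-pair
statistic is gap-free and insensitive to this choice) normalised by
alignment length, so an identical pair of typical composition scores ≈ 5.2
and unrelated sequences score below 0.  Arguments are ordered canonically
before aligning, making the score exactly symmetric under tied optima.
Every protein scoring above 1.5 with any other protein is pinned to the
train side of all folds; an audit scans every test/train pair and must find
no pair above the threshold.  Free groups are assigned greedily to the
currently smallest fold (by record count) after a seeded shuffle.

Contact labels come from 3-D structures containing exactly one protein
chain and one or two nucleic chains: a residue is a contact when its
minimum heavy-atom distance to any nucleotide heavy atom is within the
threshold (4/6/8 Å).  The analytic ceiling for label-independent guessing,
used as a floor in probe evaluations, is F1* = 2p/(1+p) at prevalence
p = r/(1+r); at the 8 Å positive:negative ratio r = 0.29 this is 0.37.

## Specificity scan

The consensus of a position-frequency matrix is the per-column argmax base
(ties → alphabetical).  The scan draws 8 unique mutants by substituting
each position with probability 5% (uniform over the three other bases),
rejection-sampling until each mutant differs from the consensus and from
the others — which biases the per-mutant substitution count slightly above
the unconditional binomial mean p·W; both the raw and the conditional
distributions are tested.  ΔΔG_j = ΔG(mutant_j) − ΔG(consensus); on the
synthetic energy model the oracle ΔΔG is strictly positive for every PFM
with strict per-column maxima, which grounds the sign expectation.

## Synthetic study conditions

The generators are first-class, seeded, and carry their own ground truth.

**Gene–protein pairs.**  Proteins (16–32 residues) carry one of 8 conserved
N-terminal 4-residue family signatures over a background drawn from a
per-pair Dirichlet(0.3) residue composition; genes are built by uniform
synonymous codon choice (standard genetic code) plus a stop codon, with
GT…AG introns inserted at rate 0.1 per codon boundary.  Family motifs,
composition and length are thus latent factors visible on both sides of the
translation map, giving MLM something real to learn; splicing and
re-translating every gene must reproduce its protein exactly (checked
against an independent translator).

**Binding energetics.**  ΔG(protein of family f, site s) = baseline_f +
Σ_w penalty_f[s_w, w] + N(0, σ).  Families come in pairs with *opposing*
specificities — the partner family's penalty matrix is the column
complement — and baselines are drawn from a narrow realistic range
(−10 … −8 kcal/mol), so the family-averaged nucleic preference is exactly
constant and the learnable signal is almost entirely the protein-family ×
nucleic-sequence interaction.  Probe sites are noisy copies (25%
substitution) of the consensus of a *uniformly random* family, independent
of the record's protein, so the nucleic marginal also carries no family
information.  Both properties exist to make the single-omic control's
ceiling explicit: an additive predictor can learn nothing beyond the
(nearly constant) baselines.  Protein backgrounds are resampled until all
pairwise normalised alignment scores stay below 1.4, so folds are never
starved by accidental homology; planted near-duplicates (single-residue
changes, score ≫ 1.5) are available to exercise the pinning rule.
Penalties are uniform on [0.5, 2.5] kcal/mol before column-min subtraction;
with motif width 8 this yields label standard deviations near 2 kcal/mol
against σ = 0.5 noise.

**Contacts.**  Contacting residues are the positions covered by planted
`RKR` motif copies (± 0–1 residue jitter), with copy count targeting a
0.29 positive:negative ratio.  In coordinate mode each fixture also gets a
minimal PDB — one Cα per residue, contacts placed 5 Å from a two-atom
nucleic chain, non-contacts ≥ 20 Å away — constructed so that 8 Å
distance labelling reproduces the planted labels exactly.

What the generators deliberately do not model: codon-usage bias, realistic
secondary structure, indel homology, database-scale composition.  Passing
tests therefore demonstrate that the machinery recovers known signal under
controlled conditions, not that it attains any particular accuracy on real
ProNAB/JASPAR/PDB data.

## Interpretability probes

**Contrastive modality-invariance probe.**  Pooled gene and protein
embeddings are projected by a rank-16 matrix W (k ≪ d enforced as
k < d/4), rows normalised, and trained with the symmetric InfoNCE loss at
τ = 0.07 (AdamW, lr 0.01 linearly decayed to 0) on 5% of the pairs;
held-out quality is the AUROC of matched vs mismatched cosine similarity.
The dual-probe control trains separate W_x, W_y (twice the parameters) and
is applied to two single-omic encoders trained with the same step budget.

**Frozen-attention conv probe.**  The attention stack is treated as image
channels through a 4-layer 3×3 conv net (C→64→64→64→1, zero same-padding);
the L×L output is averaged over its last axis into L logits.  Inputs are
standardised per channel with statistics frozen from the training stacks:
at this scale attention weights sit near 1/L, and without the affine
rescaling the probe spends its entire budget re-scaling its own weights.
Fold F1 is evaluated at the F1-maximising threshold, so an uninformative
probe degrades to the all-positive ceiling 2p/(1+p) rather than to zero.
A comparison harness trains identical probes on stacks from a base and a
ΔG-fine-tuned model and reports ΔF1.

## Reference experiments and problem sizes

`bioseqlm.experiments` pins the desk-scale study conditions (all on one
CPU, minutes each):

* **ΔG recovery** — width-256, 2-layer joint encoder; 300 MLM steps on a
  mixed corpus (150 gene/protein pairs + the binding sequences); 32
  fine-tuning epochs, batch 16, on 9 of 10 folds of the 320-record binding
  set at σ = 0.5; held-out Pearson correlation on fold 0 (32 records, 2
  unseen proteins) with a full leakage audit.
* **Joint vs single-omic (regression)** — 5 paired repetitions at width 64,
  24 epochs each, fresh data per repetition; the joint model's held-out PCC
  is compared with the dual-encoder control's on identical splits.
* **Modality alignment** — 600 gene/protein pairs; width-72 joint encoder
  and two single-omic encoders, 1500 MLM steps each; probes trained for
  3000 steps on 30 pairs (5%), scored on the remaining 570, over multiple
  probe seeds.
* **Attention probe** — 100 complexes (protein length 16), stacks from a
  300-step-pretrained width-64 encoder, probes trained 500 steps, batch 8.

A brief MLM phase at these corpus sizes is not automatically beneficial for
downstream regression — with very small pools the embeddings drift toward
unigram statistics — which is why the recovery experiment pretrains on the
mixed corpus rather than the task sequences alone.

## Known limitations

* The emergent gene↔protein alignment contrast is weak at desk scale.  The
  joint-model advantage over the dual-probe single-omic control is large
  and stable for the ΔG task (where it is structural: the control's head is
  additive), but for the contrastive probe the measured AUROC gap is small
  and run-dependent; see the experiment output rather than assuming the
  effect size.  Mechanistically, the toy joint encoder has little capacity
  pressure to reuse representation directions across modalities, which is
  the hypothesised driver of alignment in large models.
* Attention-probe and alignment results depend on briefly trained toy
  encoders; their attention structure is far weaker than in converged
  large models.
* The engine is single-threaded float32 NumPy; it is meant for desk-scale
  experiments, not production training.
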