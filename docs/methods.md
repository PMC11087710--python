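# Methods

## Overview

`rxnbind` predicts enzyme binding-site residues without supervision by
mining the attention matrices of a masked language model (MLM) trained on
joint text representations of bio-catalyzed reactions: substrate and
product SMILES plus the enzyme's amino-acid sequence. The premise is that
to predict masked enzyme tokens the model must exploit whatever
statistical coupling exists between substrate identity and particular
sequence regions — and that this coupling surfaces as attention mass
between reactant tokens and the substrate-interacting part of the
sequence.

## Data model and preparation

A corpus is plain text, one `reactants|enzyme>>products` record per line,
molecules separated by `.`. The enzyme field is an EC number (1–4
dot-separated positive integers) or a sequence over the 20 canonical
residues plus X; the EC grammar match decides, which is unambiguous since
digits and dots never occur in sequences. SMILES are opaque text at this
layer: no chemistry validation, and product-group keys are plain string
equality (a chemistry-aware canonicalizer hook backed by rdkit is
available but off by default, keeping preparation deterministic and
dependency-light).

Preparation steps, each a pure function:

* **EC→sequence augmentation** expands each EC-bearing reaction into one
  record per mapped sequence, sampling exactly `cap` sequences
  (default 10,000) per over-represented EC with a seeded uniform draw.
  Records whose EC is absent from the user-supplied map are dropped and
  counted in a report, never silently.
* **Deduplication** collapses exact duplicate serialized records only;
  the same reaction with two different enzyme sequences is two records.
* **Product-stratified splitting** groups reactions by product key and
  assigns whole groups to train/validation/test by seeded shuffle with
  largest-remainder rounding on group counts, so no product appears in
  two splits.

## Tokenization

SMILES are tokenized with the standard atom/bond-level regular expression
(bracket atoms, `Cl`/`Br`, ring-bond digits, `%nn` ring bonds and stereo
markers are single tokens); concatenating the tokens reproduces the input
exactly, and unmatched characters raise with their position.

Amino-acid sequences are compressed with a Byte-Pair Encoding tokenizer
implemented here: the vocabulary is seeded with every single residue
character (so any sequence encodes — losslessness is structural, merges
only ever concatenate), then grown by merging the most frequent adjacent
pair, ties broken toward the lexicographically smallest id pair, making
training deterministic. Every token carries its half-open residue interval
`[start, end)`; the offsets partition `[0, len(seq))`, which is what lets
token-level votes be mapped back to residue coordinates. Compression is
monotone in vocabulary size on the training corpus (asserted empirically,
non-strict).

A joint vocabulary holds six special tokens, the SMILES token inventory
and the BPE tokens in disjoint id ranges (the SMILES atom `C` is not the
residue `C`). One encoded reaction is

```
[CLS] r reactant tokens [SEP] m enzyme tokens [SEP] p product tokens [EOS]
```

with `r`, `m`, `p` and the special positions recorded; organic reactions
omit the enzyme block (m = 0). Over-length inputs raise (carrying the
attained length) rather than truncate: the attention analysis requires the
entire sequence, and silent truncation would corrupt residue offsets.

## Masking

SMILES regions get single-token MLM at rate 0.15 (exactly
`round(0.15 · region length)` unique positions). The enzyme region gets
n-gram MLM: disjoint spans with lengths uniform in [2, 5], placed until
coverage reaches the enzyme rate, overshooting by at most max-n − 1;
regions shorter than the minimum n fall back to single-token masking. The
enzyme ("dense") rate defaults to 0.30 — a package choice, config-exposed,
chosen so that planted motifs are frequently hidden in full and must be
reconstructed from substrate context. Rates apply per region and special
tokens are never maskable by construction (plans are drawn over content
positions only). Replacement follows the usual 80/10/10
mask/random/keep convention, also config-exposed.

## Model and training

The encoder is a standard pre-LayerNorm bidirectional transformer
(token + position embeddings; per layer: multi-head self-attention and a
GELU MLP, both residual; final LayerNorm and a vocabulary projection),
implemented directly in numpy with analytic gradients. The contract the
rest of the package relies on is only: token ids in, per-layer per-head
row-stochastic attention matrices out. Correctness of the hand-derived
backprop is enforced by a finite-difference gradient test over every
parameter tensor.

Training samples each example from the enzymatic corpus with probability
0.9 and the organic corpus with 0.1 (per-example sampling rather than loss
re-weighting, keeping the loss a plain masked-token cross-entropy), pads
batches with attention suppressed at padded keys, and optimizes with Adam
(lr 1e-3, β = 0.9/0.999). Everything — initialization, batch sampling,
masking — is seed-reproducible, and a non-finite loss aborts with a
diagnostic. The desk-scale default is 2 layers, 4 heads, width 64,
batch 16, 2,500 steps (a few minutes on one CPU); the full-scale
configuration (BERT-base shape, 50,000 steps, vocabularies up to 75K) is
expressible through the same `ModelConfig` but is not exercised by tests.

## Attention mining

For one reaction, the attention tensor has shape (layers, heads, l, l)
with every row a distribution over key positions. The interaction matrix
of a chosen layer and head is

```
P[i, j] = A[reactant_i, enzyme_j] + A[enzyme_j, reactant_i]
```

(shape r × m, entries in [0, 2]), with special-token rows and columns
excluded via the recorded layout. This is the reactant-rows × enzyme-cols
block plus the transposed enzyme-rows × reactant-cols block — the only
pairing that has shape r × m and links the two regions; source
descriptions of this slice print an inconsistent column range, which we
treat as a typographical slip.

Each reactant token casts k votes for its k highest-valued enzyme columns
(ties toward the lower index, via a stable sort; k clamps to m). Votes are
cast by *all* reactant tokens by default, including bond and ring symbols —
the literal reading of the consensus scheme; `atoms_only=True` restricts
the consensus to atom tokens. The union of voted
tokens is mapped through the residue offsets and merged into a
`SegmentSet`. The predicted token set is monotone in k, hence so is
residue coverage.

The (layer, head, k) configuration is selected by exhaustive grid search
maximizing mean overlap score on held-out data, ties toward the lowest
layer, then head, then k. Published full-scale analyses of this method
report a single best head/layer and both "top 6" and "top 5" for k; the
discrepancy is preserved rather than resolved — the default is k = 5 and
every k is reachable by flag. All indices here are 0-based; no
correspondence to any 1-based numbering elsewhere is claimed.

## Evaluation

Binding sites are `SegmentSet`s: sorted, non-overlapping, *merged*
half-open integer intervals. Merging is enforced upstream because the
interval-arithmetic overlap score can exceed 1 on unmerged input; on
merged sets it is exactly `|predicted ∩ truth| / |truth|` (asserted
against a residue-set oracle on 1,000 random pairs).

The false-positive rate uses a per-whole-segment indicator — a predicted
segment contributes its full length iff it intersects no ground-truth
segment — following the printed formula literally; the per-residue variant
is available as `false_positive_rate_residues`. Empty ground truth makes
OS undefined (error), empty predictions make FPR undefined (error); the
report aggregator counts such examples separately and emits both
per-example means and pooled ratios, since aggregate percentages can be
read either way.

The random baseline places a requested number of non-overlapping segments
totalling `round(coverage · length)` residues: sizes as even as possible,
positions uniform over all separated arrangements (stars-and-bars gap
composition with one residue reserved between segments when feasible).
Construction of random baselines is underdetermined in general; this
coverage- and count-matched model is the documented interpretation, and
both knobs are caller-supplied.

For structural use, `grid_box` centers a cube (default side 50 Å) on the
arithmetic mean of binding-site atom coordinates — translation-equivariant
and permutation-invariant — and `barycenter_distance` is the Euclidean
distance between box centers. PDB coordinates are read with biopython
using author residue numbering, verbatim.

## Synthetic study conditions

The generator emulates the structure the method exploits, not enzyme
chemistry. Defaults: 4 substrate classes realized as disjoint pools of
small SMILES fragments (alcohols, aromatics, carbonyls, halides/amines);
one fixed random 10-residue motif per class; sequences uniform 60–120
residues of i.i.d. uniform background; 20,000 enzymatic and 2,000 organic
reactions; association strength ρ = 1 (each enzyme carries its class motif
at a uniform random position; with probability 1 − ρ a same-length random
decoy is planted instead, so the recorded truth segment is always
defined). Everything is reproducible from one seed, including byte-
identical fixture files.

What passing tests show: the pipeline end-to-end can discover a
substrate-conditioned sequence region from masked-token training alone,
at effect sizes chosen to be unambiguous. What they do not show: recovery
under real-data conditions — homologous redundancy, non-contiguous 3D
binding sites, motif variability, class imbalance, sequences far longer
than 120 residues — none of which the generator models.

## Benchmark protocol and problem sizes

The end-to-end benchmark (`rxnbind.experiment.planted_motif_benchmark`,
also what `scripts/acceptance.py` runs) uses the default conditions above,
holds out the last 100 records (the synthetic fragment pools admit only
~15 distinct product keys, so a product-stratified split would starve
entire classes; the product split remains the tool for real corpora),
trains a 260-token BPE vocabulary (≈300 joint tokens) on at most 2,000
training sequences, trains the default encoder for 2,500 steps, and
grid-searches all layers × heads × k ∈ {1, 3, 5}. The random baseline is
matched per example to the prediction's coverage and segment count. At
seed 1 this yields mean OS 0.973 against a baseline of 0.353 (ratio 2.76)
with held-out masked loss falling from 5.66 to 4.21.

## Numerical choices

* float64 throughout the encoder; LayerNorm ε = 1e-5; attention rows sum
  to 1 within 1e-5 (asserted on every extracted tensor).
* Attention-key padding uses an additive −1e9 bias before the softmax.
* Top-k and grid-search ties break deterministically (lowest index /
  lowest layer-head-k).
* `round(rate · n)` is floor(x + 0.5), avoiding banker's rounding.
* BPE merge ties break toward the smallest id pair; training on a capped
  seeded subsample of the corpus.
* Half-open 0-based intervals everywhere; degenerate inputs (empty
  corpus splits, empty mask plans, k > m, regions shorter than the
  minimum n-gram) are defined behaviors, not errors, whereas undefined
  metrics and infeasible specs raise.

## Known limitations

* The encoder is a reference implementation tuned for clarity and desk
  scale, not throughput; full-scale corpora would need a GPU stack.
* Voting by all reactant tokens lets punctuation-like SMILES tokens vote;
  on short reactants this adds noise to P.
* The per-segment FPR is coarse for long predicted segments (one residue
  of overlap zeroes the whole segment's contribution); the residue-level
  variant quantifies the difference.
* The synthetic benchmark's contiguous single-motif truth is easier than
  real, spatially assembled binding sites; scores here bound what the
  machinery can do when its assumptions hold, not field performance.
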