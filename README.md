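# rxnbind

Unsupervised prediction of enzyme binding-site residues from the attention
maps of a masked language model trained on text representations of
bio-catalyzed reactions.

## The problem

An enzyme's binding site — the handful of residues that hold the substrate
in place — is conserved, functionally critical, and expensive to determine
experimentally. `rxnbind` targets the setting where all that is known about
an enzyme is its amino-acid sequence and a reaction it catalyzes, written
as

```
reactants|enzyme>>products
```

with reactants/products in SMILES and the enzyme as an amino-acid sequence
(or an EC number to be expanded into sequences). A bidirectional
transformer encoder is trained with masked language modeling on such
records — single-token masking on the SMILES regions, n-gram masking on
the enzyme region, mixing an organic (enzyme-free) reaction corpus at
weight 0.1 with the enzymatic corpus at weight 0.9. No binding-site labels
are ever seen.

At inference, for a reaction of r reactant tokens, m enzyme tokens and p
product tokens, the attention matrix A ∈ R^(l×l) (l = r + m + p) of a
chosen layer and head yields the reactant–enzyme interaction matrix

```
P = A[reactants, enzyme] + A[enzyme, reactants]^T   ∈ R^(r×m)
```

Each reactant token casts k votes for its highest-scoring enzyme tokens;
the union of voted tokens, mapped through the BPE tokenizer's residue
offsets, is the predicted binding region. Predictions are scored against
ground-truth segments B_s with the overlap score

```
OS(B, B_s) = Σ_i Σ_j max(0, min(b_i, b_j) − max(a_i, a_j)) / Σ_j (b_j − a_j)
```

and a per-segment false-positive rate (fraction of predicted length in
segments that intersect no ground-truth segment). The (layer, head, k)
configuration is chosen by exhaustive grid search on held-out data.

Because real ground truth requires co-crystal structures, the package
ships a synthetic corpus generator that plants a class-specific sequence
motif tied to the substrate class of each reaction, with exact recorded
truth — so the entire pipeline (data prep, tokenizer and model training,
attention mining, evaluation) runs and is tested at desk scale with no
downloads.

## Worked example

```python
import rxnbind as rb

rxn = rb.parse_reaction("CCO.O|MKTAYIAKQR>>CC(=O)O")
print(rxn.reactants, rxn.enzyme.value, rxn.products)
# ('CCO', 'O') MKTAYIAKQR ('CC(=O)O',)

print(rb.tokenize_smiles("O=C(Cl)c1ccccc1"))
# ['O', '=', 'C', '(', 'Cl', ')', 'c', '1', 'c', 'c', 'c', 'c', 'c', '1']

pred  = rb.SegmentSet(((15, 25),))       # predicted residues [15, 25)
truth = rb.SegmentSet(((10, 20),))       # ground truth       [10, 20)
print(rb.overlap_score(pred, truth), rb.false_positive_rate(pred, truth))
# 0.5 0.0

box = rb.grid_box([(0, 0, 0), (2, 2, 2)])      # docking grid box, side 50 Å
print(box.center, box.side)
# (1.0, 1.0, 1.0) 50.0
```

The end-to-end pipeline on the default synthetic conditions (4 substrate
classes, 10-residue motifs, 20,000 enzymatic + 2,000 organic reactions):

```python
from rxnbind.experiment import planted_motif_benchmark
res = planted_motif_benchmark(seed=1, steps=2500)
print(res.to_dict())
```

yields, at seed 1:

```
best (layer, head, k):        (0, 3, 5)
mean overlap score:           0.973
baseline overlap score:       0.353
overlap vs baseline ratio:    2.756
held-out masked loss:         5.655 -> 4.207
```

i.e. the best attention head recovers 97.3% of the planted motif residues,
2.8× the coverage-matched random baseline — the motif location was never a
training signal, only masked-token prediction was.

A `rxnbind` console script exposes the same steps as subcommands
(`synth`, `prepare`, `tokenizer-train`, `train`, `predict`, `gridsearch`,
`evaluate`); run `rxnbind --help`.

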