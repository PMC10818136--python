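# sagdti

Attention-derived prediction of drug–target interactions (DTI) from three
information sources at once: the drug's SMILES string with relative
inter-atom distances, the target's binding-pocket structure as an atom
graph, and the pair's place in a heterogeneous biological network.

## Who this is for

Computational drug-discovery researchers who want a transparent, CPU-only,
fully reproducible reference implementation of an atom-level +
node-level attention DTI classifier — complete with a synthetic benchmark
generator that plants a known interaction rule, so every architectural claim
is testable without downloading BindingDB-scale data or training on a GPU.

## The model in brief

For a drug–target pair (D, P) the score is

    score = sigmoid( FNN( Pool( Conv( [X_Mol ; X_Bio] ))))

with the two attribute vectors computed as follows.

**Molecular attributes `X_Mol`.** The SMILES of D is tokenized
(character-level, Cl/Br as single tokens) and embedded as token + position
vectors `X_D`. One relative-position attention block biases logits with
`A_R[i,j] = (X_D[i] W_Q) · W_R[min(clip, |i−j|)]` (zero at non-atom tokens),
then a stack of multi-head self-attention encoders produces `D_R`. Binding
sites of P, extracted from PDB structures by bounding boxes or
ligand proximity, become atom graphs with a 38-dim node schema, are
flattened into a token sequence and encoded by a parallel stack with an
adjacency attention bias, giving `P_R`. The interaction pairing map
`IM[i,j] = sigmoid(D_R[i]·P_R[j] / √d)` scores every drug-token /
pocket-atom pair in [0, 1]; a zero-padded convolution with pooling reads it
out into `X_Mol`.

**Biological attributes `X_Bio`.** Drugs and targets form one undirected
graph mixing interaction edges and thresholded similarity edges. Two masked
multi-head GAT layers (`e_ij = LeakyReLU(a·[W h_i ‖ W h_j])`, softmax over
first-order neighbors, non-neighbors exactly 0) produce node embeddings;
`X_Bio` is the element-wise max of the two endpoint embeddings.

Training is Adam on binary cross-entropy with early stopping on validation
AUPR. Metrics: AUROC, AUPR, MCC, F1, balanced accuracy. Splits: new-target,
new-drug, pairwise k-fold, and a cold-start protocol that removes every
entity of a test pair from training. Structural ablations are first-class
switches: `no_gat` (drop `X_Bio`), `no_3d` (residue tokens instead of pocket
graphs), `no_rel` (`A_R = 0`).

Everything — attention, GAT, convolutions, Adam, backprop — runs on a small
NumPy reverse-mode autodiff core shipped in the package
(`sagdti.autodiff`), single-threaded float64, bit-reproducible per seed.

## Worked example

```bash
sagdti simulate --out bench --n-drugs 100 --n-targets 30 --n-pairs 800 --seed 7
sagdti train --data bench --out model.npz --epochs 15 --seed 0
```

`simulate` prints:

```
wrote 100 drugs / 30 targets / 800 pairs (positive fraction 0.529) to bench
```

and writes `smiles.csv`, `proteins/*.pdb`, `sites.json`, `edges.csv`,
`pairs.csv`, `spec.yaml`. `train` holds out fold 0 of a pairwise split,
logs one line per epoch and ends with a validation report:

```
epoch 13: train_loss=0.4143 val_auroc=0.865 val_aupr=0.863
...
{
  "variant": "full",
  "seed": 0,
  "best_epoch": 13,
  "validation": {
    "auroc": 0.8652282676672921,
    "aupr": 0.8633779765291983,
    "mcc": 0.5805908012956227,
    "f1": 0.7951807228915663,
    "b_acc": 0.7889305816135084,
    "n_pos": 78,
    "n_neg": 82
  }
}
```

Read: on 160 held-out pairs the model ranks a random interacting pair above
a random non-interacting one 87% of the time; at the 0.5 threshold it keeps
F1 0.80. The planted rule's Bayes ceiling is ≈ 0.94, so the small model has
recovered most of the available signal in 15 epochs. Score new pairs with

```bash
sagdti predict --data bench --checkpoint model.npz --pairs query.csv --out scores.csv
sagdti ablate  --data bench --variant no_gat --epochs 15   # branch contribution
```

The same flows are available as library calls (`generate_dataset`, `fit`,
`DTIModel.predict`); the CLI is a thin wrapper.

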