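# adrgraph

Drug / side-effect association prediction from heterogeneous graphs.

The model scores every (drug, side effect) pair by fusing two branches:

1. **Topology branch** — two drug–side-effect heterogeneous graphs (one per
   drug-similarity view: chemical substructures and treated diseases) are
   each encoded by a graph-convolutional autoencoder trained adversarially
   against an MLP discriminator. The per-view node embeddings are fused by
   representation-level attention (per-feature softmax weights with residual
   connections); a pair's two fused rows are stacked and passed through two
   conv-pool stages (16 then 32 filters).
2. **Attribute branch** — each pair's raw profile rows
   (`[M_i ‖ O_i]` over `[Oᵀ_j ‖ S_j]`, one channel per similarity view) are
   encoded with self-calibrated convolution: a down-pooled latent path gates
   a same-padded convolution of the original tensor through a sigmoid
   calibration weight, and is concatenated with an unpadded original-path
   stack (16 then 32 filters).

Each branch ends in a dense softmax head; the final score is
`λ·p_topo + (1−λ)·p_att`.

Because the original SIDER/CTD matrices are not redistributable, the package
ships a seed-controlled synthetic generator: drugs and side effects are
partitioned into planted blocks, associations are Bernoulli(p_in) within /
Bernoulli(p_out) across blocks, and block-signature substructure /
disease features produce the similarity matrices via cosine and Jaccard
measures.

All differentiable components are implemented on numpy +
[autograd](https://github.com/HIPS/autograd) with a hand-rolled Adam
(no GPU or deep-learning framework required).

## CLI

```bash
# generate a synthetic dataset (TSV matrices + meta.json)
adrgraph simulate --n-drugs 60 --n-side-effects 120 --n-blocks 3 \
    --p-in 0.5 --p-out 0.02 --seed 0 --out data/

# train one cross-validation fold; writes (drug, side_effect, score, label, fold)
adrgraph train --data data/ --fold 0 --seed 0 --out scores.tsv

# metrics: per-fold AUC/AUPR, averages, recall@k, per-drug table
adrgraph evaluate --scores scores.tsv --out metrics.json --per-drug per_drug.csv

# the full five-fold protocol in one go
adrgraph crossval --data data/ --seed 0 --out results/
```

`train`/`crossval` accept `--config cfg.yaml` with any `TrainConfig` field,
e.g.:

```yaml
head_epochs: 15
batch_size: 64
lam: 0.5
use_tga: true      # false = attribute-branch-only ablation
use_scpa: true     # false = topology-branch-only ablation
use_rla: true      # false = residual-sum fusion (no attention)
gan:
  encoder_dims: [64, 32]   # last entry is the embedding width N_f
  epochs: 200
  gamma: 10.0
```

## Library use

```python
from adrgraph import (SyntheticConfig, generate_dataset, make_folds,
                      mask_test_positives, TrainConfig, train_model)

ds = generate_dataset(SyntheticConfig(seed=0))
fold = make_folds(ds.o.values, seed=0).folds[0]
o_train = mask_test_positives(ds.o.values, fold)
model = train_model(ds.m_chem.values, ds.m_dise.values, ds.s.values,
                    o_train, fold.train_pairs, fold.train_labels,
                    TrainConfig(seed=0))
scores = model.score_pairs(fold.test_pairs)
```

## Layout

```
src/adrgraph/
  graphs.py      similarity/association matrices, heterogeneous graphs,
                 symmetric Laplacian normalisation
  synthetic.py   planted-block dataset generator
  io.py          TSV persistence for dataset directories
  nn.py          autograd building blocks (conv2d, pooling, bilinear
                 resize, Adam, ...)
  gan.py         GCN autoencoder generator + MLP discriminator, adversarial
                 training per graph view
  fusion.py      representation-level attention, pair stacking, conv head
  attributes.py  pairwise attribute tensors, self-calibrated convolution
  model.py       scoring heads, losses, joint training, λ-weighted fusion
  evaluation.py  five-fold CV splits, AUC/AUPR, recall@k, per-drug metrics
  cli.py         simulate / train / evaluate / crossval
```
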