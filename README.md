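# swgcn

Link prediction on sparse piRNA–disease association networks with a
**supplementarily weighted graph convolutional network**.

PIWI-interacting RNAs (piRNAs) are ~23–36 nt small non-coding RNAs with
documented roles in disease, but experimentally validated piRNA–disease
associations cover only about 5% of possible pairs. Graph learners
starve on such a sparse bipartite network. This package implements a
two-stage remedy for computational biologists prioritising candidate
associations:

1. **Supplementary weighting.** An ensemble of 15 basic classifiers
   (Random Forest, SVM, GBDT × five negative resamples) scores every
   unknown cell of the association matrix A_PD, producing a weighted
   adjacency A′ ∈ [0,1]^{m×n} that is 1 on known training positives and
   the ensemble-averaged confidence elsewhere.
2. **Graph convolution.** A GCN propagates over the heterogeneous block
   graph A_all = [[P_seq, A′], [A′ᵀ, D_sem]] — Smith-Waterman sequence
   similarity between piRNAs, ontology (Wang-style, θ = 0.5) semantic
   similarity between diseases — using the self-looped symmetric
   normalisation D̃^{-1/2}(I + A_all)D̃^{-1/2}. Node inputs are
   random-walk-with-restart features of the similarity networks; pair
   scores are inner products of the reduced embeddings, trained with a
   β-enhanced masked MSE loss ‖Â − U‖²_F + μ‖W‖².

Everything runs on synthetic data shaped like the curated corpora
(tall-thin matrix, ~6% density, short sequences whose similarity tracks
shared associations, small disease ontology), so the full method is
exercisable and testable without any download. See `docs/methods.md`
for the model details and design choices.

## Worked example

```python
import numpy as np
from swgcn import RunConfig, generate, run_study

world = generate(m=300, n=15, rank=4, density=0.06, seed=0)
result = run_study(world.seqs, world.dag, world.a,
                   RunConfig(seed=0, weighting_mode="weighted"))
r = result.report
print(f"held-out AUC={r.auc:.4f} AUPR={r.aupr:.4f} "
      f"({r.n_pos} positives vs {r.n_neg} negatives)")
```

prints

```
held-out AUC=0.8163 AUPR=0.8512 (56 positives vs 56 negatives)
```

— the model's ranking quality on a balanced set of held-out validated
associations versus sampled unknown pairs (0.5 would be chance). Running
the same study with `weighting_mode="none"` (the raw Boolean network)
drops the AUC to 0.62, which is the point of the supplementary
weighting: filling unknown cells with ensemble confidences gives the
graph convolution enough connectivity to learn from.

The same pipeline is scriptable from the shell:

```bash
swgcn simulate --m 300 --n 15 --rank 4 --density 0.06 --seed 0 --out world/
swgcn run --fasta world/sequences.fasta --assoc world/associations.tsv \
          --dag world/dag.tsv --seed 0 --mode weighted --out run/
```

which writes every stage output (similarity matrices, RWR features,
weighted adjacency, score matrix) as diffable TSV plus a JSON manifest
and evaluation report under `run/`. Short narrative scripts for each
capability live in `examples/`.

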