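"""Fill the unknown cells of a sparse association matrix with ensemble
confidence weights.

Generates a small synthetic world, trains the 15 basic classifiers on
the phase-1 splits and prints how the resulting weights separate
held-out true associations from true negatives.
"""

import numpy as np

from swgcn import (
    generate,
    make_splits,
    rwr_features,
    semantic_similarity,
    sequence_similarity,
    supplementary_weighted_adjacency,
    train_basic_ensemble,
)

world = generate(m=120, n=10, rank=3, density=0.08, seed=5)
print(f"world: {world.a.shape[0]} piRNAs x {world.a.shape[1]} diseases, "
      f"{int(world.a.sum())} positives "
      f"({world.a.mean():.1%} density)")

fp = rwr_features(sequence_similarity(world.seqs))
fd = rwr_features(semantic_similarity(world.dag))
splits = make_splits(world.a, seed=5)
ensemble = train_basic_ensemble(splits, fp, fd)
print(f"trained {len(ensemble)} basic scorers "
      "(RF, SVM, GBDT x 5 negative resamples)")

weighted = supplementary_weighted_adjacency(
    world.a, ensemble, splits.ben2_pos, fp, fd
)
pos, neg = splits.ind2_pos, splits.ind2_neg
w_pos = weighted[pos[:, 0], pos[:, 1]].mean()
w_neg = weighted[neg[:, 0], neg[:, 1]].mean()
print(f"mean weight on held-out true associations: {w_pos:.3f}")
print(f"mean weight on held-out true negatives:    {w_neg:.3f}")
print("-> the ensemble assigns higher confidence to cells that hide real\n"
      "   associations, which is exactly the structure the GCN then exploits.")
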