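"""Run the full pipeline in all three weighting modes on one world.

Compares held-out ranking quality of the supplementarily weighted
network against the Boolean top-20% promotion and the raw sparse
network.  The mode-independent stages (similarities, features, splits,
basic ensemble) are computed once and shared, so the comparison
isolates the weighting strategy.  Uses the default benchmark world
(300 piRNAs x 15 diseases at 6% density); takes a minute or two.
"""

from swgcn import (
    RunConfig,
    generate,
    make_splits,
    run_study,
    rwr_features,
    semantic_similarity,
    sequence_similarity,
    train_basic_ensemble,
)

world = generate(m=300, n=15, rank=4, density=0.06, seed=0)
print(f"world: 300 piRNAs x 15 diseases, {int(world.a.sum())} positives\n")

p_seq = sequence_similarity(world.seqs)
d_sem = semantic_similarity(world.dag)
fp, fd = rwr_features(p_seq), rwr_features(d_sem)
splits = make_splits(world.a, seed=0)
shared = dict(
    p_seq=p_seq,
    d_sem=d_sem,
    fp=fp,
    fd=fd,
    splits=splits,
    ensemble=train_basic_ensemble(splits, fp, fd),
)

for mode in ("weighted", "boolean:20", "none"):
    cfg = RunConfig(seed=0, weighting_mode=mode)
    result = run_study(world.seqs, world.dag, world.a, cfg, precomputed=shared)
    r = result.report
    print(f"{mode:>10}: AUC={r.auc:.4f} AUPR={r.aupr:.4f}")
print(
    "\n-> the weighted network usually ranks held-out associations best:\n"
    "   fractional confidences both densify the graph and tell the GCN\n"
    "   how much to trust each supplemented edge."
)
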