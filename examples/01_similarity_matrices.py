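"""Compute the two homogeneous similarity matrices on a toy input.

Builds four short piRNA sequences and a five-term disease ontology,
then prints the normalised Smith-Waterman sequence similarity and the
Wang-style semantic similarity.
"""

import numpy as np

from swgcn import DiseaseDAG, SequenceSet, semantic_similarity, sequence_similarity

seqs = SequenceSet(
    ids=("piR-1", "piR-2", "piR-3", "piR-4"),
    seqs=(
        "TGCATTTGAGGATGCCAGTGAAGAGTTA",
        "TGCATTTGAGGATGCCTGTGAAGAGTTA",  # one substitution vs piR-1
        "AACCGGTTACGTACGTAACCGGTTACGT",
        "GGGGTTTTCCCCAAAAGGGGTTTTCCCC",
    ),
)
p_seq = sequence_similarity(seqs)
print("sequence similarity (normalised local alignment):")
print(np.round(p_seq, 3))
print("-> piR-1 vs piR-2 differ by one base, so their similarity is near 1;")
print("   unrelated sequences fall toward the chance level of short matches.\n")

# melanoma and basal cell carcinoma share the skin-cancer lineage.
dag = DiseaseDAG(
    terms=("disease", "cancer", "skin cancer", "melanoma", "basal cell carcinoma"),
    edges=(
        ("cancer", "disease"),
        ("skin cancer", "cancer"),
        ("melanoma", "skin cancer"),
        ("basal cell carcinoma", "skin cancer"),
    ),
    theta=0.5,
)
d_sem = semantic_similarity(dag)
ix = dag.index()
print("semantic similarity (shared-ancestor contributions, theta=0.5):")
print(np.round(d_sem, 3))
print(
    "-> melanoma vs basal cell carcinoma:",
    round(d_sem[ix["melanoma"], ix["basal cell carcinoma"]], 3),
    "(siblings under 'skin cancer'); melanoma vs the root is",
    round(d_sem[ix["melanoma"], ix["disease"]], 3),
)
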