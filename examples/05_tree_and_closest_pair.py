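"""Neighbor-joining tree from an alignment and the closest cross-group pair.

JTT maximum-likelihood distances are computed for every sequence pair of a
small aligned family, a neighbor-joining tree is built, and the
thermophile-mesophile leaf pair with the smallest patristic (path-length)
distance is selected — the pair most worth a detailed structural
comparison.
"""

from thermofold import closest_cross_pair, distance_matrix_from_msa, neighbor_joining
from thermofold.phylo import serialize_newick
from thermofold.synthetic import make_related_family

_, seqs = make_related_family(5, length=60, sub_rate=0.12, seed=21)
ids = ["t1", "t2", "t3", "m1", "m2"]
labels = {"t1": "thermophile", "t2": "thermophile", "t3": "thermophile",
          "m1": "mesophile", "m2": "mesophile"}
msa = dict(zip(ids, seqs))

dm = distance_matrix_from_msa(msa)
print("JTT ML distances (substitutions/site):")
print(dm.to_phylip())
tree = neighbor_joining(dm)
print("newick:", serialize_newick(tree))
t, m = closest_cross_pair(tree, labels)
print(f"closest thermophile-mesophile pair: {t} / {m}")
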