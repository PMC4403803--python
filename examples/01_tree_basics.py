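"""Patristic distances and Faith's PD on a small dated tree.

Builds a toy ultrametric tree (branch lengths in millions of years, Ma),
prints the patristic distance matrix between its species and the
phylogenetic diversity of a subset.
"""

import spacephylo as sp

# three taxa: A and B diverged 1 Ma ago, their ancestor split from C 2 Ma ago
tree = sp.read_tree("((A:1,B:1):1,C:2);")
print(f"root age: {tree.root_age} Ma")

m = sp.patristic_matrix(tree, ["A", "B", "C"])
print("patristic distances (Ma):")
for i, a in enumerate(m.labels):
    print(" ", a, [f"{v:.0f}" for v in m.values[i]])

pd_ab = sp.faith_pd(tree, {"A", "B"})
pd_all = sp.faith_pd(tree, {"A", "B", "C"})
print(f"Faith's PD of {{A,B}}: {pd_ab} Ma  (edges A + B + their stem to the root)")
print(f"Faith's PD of all taxa: {pd_all} Ma  (= total branch length)")
# Each patristic entry is twice the age of the pair's common ancestor on an
# ultrametric tree; PD is the branch length their assemblage spans.
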