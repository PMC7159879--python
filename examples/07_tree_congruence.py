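"""Congruence of core-component phylogenies via Robinson-Foulds distance.

Trees are consumed as newick (built externally), pruned to their shared
leaves and compared as unrooted topologies; normalized RF of 0 means
identical histories -- the signature of components co-evolving as one
ternary complex -- and 1 means maximally conflicting trees.
"""

from conflictscan import rf_congruence
from conflictscan.io import read_newick

# toy trees for the three core components over five shared organisms
vmap = read_newick("((Org1,Org2),(Org3,(Org4,Org5)));")
moxr = read_newick("((Org1,Org2),(Org3,(Org4,Org5)));")
vwa = read_newick("((Org1,Org3),(Org2,(Org4,Org5)));")

for name, tree in [("MoxR", moxr), ("vWA", vwa)]:
    res = rf_congruence(vmap, tree, "VMAP", name)
    print(f"VMAP vs {name}: shared leaves={res.n_shared_leaves} "
          f"RF={res.rf_distance} normalized={res.normalized_rf:.2f}")
# VMAP and MoxR agree perfectly (RF 0); the rearranged vWA tree pays two
# conflicting bipartitions, i.e. partial incongruence.
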