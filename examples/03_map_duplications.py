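"""Root a gene tree and map its duplications to species-tree nodes.

The gene tree below carries two parallel seed-plant clades — the signature
of a duplication in the seed-plant ancestor. After rooting on the
chlorophyte outgroup, the species-overlap criterion calls one duplication
and maps it to Spermatophyta; counting events at designated nodes gives
the per-node expansion calls.
"""

from phylomode import (
    backbone_tree,
    expansions_at_nodes,
    load_gene_tree,
    map_duplications,
    root_by_outgroup,
)

tree = backbone_tree()

newick = (
    "((CON|a1,(AMB|b1,EUD|c1)),((CON|a2,(AMB|b2,EUD|c2)),CHL|out));"
)
gtree = load_gene_tree(newick)
rooted = root_by_outgroup(gtree, tree.outgroup_rank())

events = map_duplications(rooted, tree)
print(f"duplication events: {len(events)}")
for ev in events:
    print(f"  mapped to {ev.mapped_label} "
          f"({len(ev.leafset)} descendant gene copies)")

counts = expansions_at_nodes(events, ["Euphyllophyta", "Spermatophyta"], tree)
print(f"expansions at nodes of interest: {counts}")
print("An expansion call requires an event mapped exactly to the listed "
      "ancestor, not to one of its descendants.")
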