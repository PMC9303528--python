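"""Place gene-family origins on the species tree by single-gain parsimony.

Uses the packaged 14-taxon plant backbone. Each presence/absence row is
explained by one gain (at the LCA of all species with evidence) plus the
minimum number of heritable losses; the printed losses count the maximal
all-absent subtrees below the origin.
"""

from phylomode import backbone_tree, infer_origin_node

tree = backbone_tree()

patterns = {
    # mosses + hornworts + vascular plants, liverwort lost
    "stomatal-development-like": {
        "MOS": 2, "HORN": 1, "LYC": 2, "FERN": 1, "CON": 2,
        "AMB": 2, "MON1": 2, "MON2": 2, "EUD": 2,
    },
    # green algae + land plants, lycophyte lost
    "guard-cell-channel-like": {
        "CHL": 2, "CHA": 1, "LIV": 2, "MOS": 2, "HORN": 1, "FERN": 1,
        "CON": 2, "AMB": 2, "MON1": 2, "MON2": 2, "EUD": 2,
    },
    # vascular plants only
    "stomatal-density-like": {
        "LYC": 2, "FERN": 1, "CON": 2, "AMB": 2, "MON1": 2, "MON2": 2, "EUD": 2,
    },
}

for name, partial_row in patterns.items():
    row = {t: partial_row.get(t, 0) for t in tree.tips}
    call = infer_origin_node(row, tree, hg_id=name)
    print(f"{name}:")
    print(f"  origin node     : {call.origin_label}")
    print(f"  implied losses  : {call.implied_losses}")
    print(f"  presence tips   : {len(call.presence_tips)}")
print("The origin is the last common ancestor of every species with "
      "evidence; losses are the absent subtrees that single gain implies.")
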