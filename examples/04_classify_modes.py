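"""Classify the packaged worked example: novel, coopted, expanded.

Four archetypal families on the 14-taxon backbone are classified against
two traits (stomatal development at Embryophyta, vascular tissue at
Tracheophyta). The labels read: novel = origin coincides with the trait
origin; coopted = older origin retained by every genome of the trait
clade; expanded = a duplication at a designated node; post_origin =
younger than the trait.
"""

from phylomode import classify_worked_example, summarize_modes, worked_example

example = worked_example()
calls = classify_worked_example(example)

for c in sorted(calls, key=lambda c: (c.trait, c.hg_id)):
    labels = "+".join(sorted(c.labels)) or "none"
    extra = f" at {','.join(c.expanded_at)}" if c.expanded_at else ""
    print(f"{c.trait:22s} {c.hg_id:12s} origin={c.origin_label:13s} "
          f"losses={c.implied_losses} -> {labels}{extra}")

print()
print(summarize_modes(calls, list(example.traits), example.tree).to_string(index=False))
print("\nEach trait row counts labels independently; predates_or_at_origin "
      "counts families whose origin is the trait node or older.")
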