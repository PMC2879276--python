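"""Infer a single gene's relocation from its Muller-element states.

CG5029 carries its intron-bearing (parental) copy on Muller B in nine
species and an intronless retrocopy on Muller A — the X — in the three
virilis-clade species: a rare movement onto the X, localized to the stem
of that clade.
"""

from retromove import (
    classify_movement,
    infer_event,
    load_default_muller_map,
    load_default_tree,
    load_table1,
)

table1 = load_table1()
tree = load_default_tree()
muller = load_default_muller_map()

ev = infer_event(table1, "CG5029", tree, muller)
print(f"gene          : {ev.gene}")
print(f"source element: {ev.source}  (parental copy)")
print(f"target element: {ev.target}  (retroposed copy)")
print(f"event branch  : {ev.event_branch}")
print(f"single origin : {ev.single_origin}")
print(f"movement class: {classify_movement(ev, muller)}")
print(f"derived copy in: {', '.join(ev.context_species)}")
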