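"""Infer the minimum synteny events separating two opsin neighbourhoods.

The block is the classic 6+n sliding window: the opsin run plus three
flanking genes on each side.  The search explains a child block set from a
parent with the fewest gene losses, tandem duplications, inversions and
translocations.
"""

from opsinevo.synteny import infer_branch_events

parent = [(
    ("hcfc1", 1, False), ("tmem187", 1, False), ("irak1", 1, False),
    ("SWS2", 1, True), ("LWS", 1, True),
    ("gnl3l", 1, False), ("fgd1", 1, False), ("tfe3", 1, False),
)]

# the child lost one flank gene and tandem-duplicated SWS2
child = [(
    ("hcfc1", 1, False), ("tmem187", 1, False),
    ("SWS2", 1, True), ("SWS2", 1, True), ("LWS", 1, True),
    ("gnl3l", 1, False), ("fgd1", 1, False), ("tfe3", 1, False),
)]

events = infer_branch_events(parent, child)
print("minimum event explanation:")
for e in events:
    print(f"  {e.event}({e.payload})")
print(
    f"\n{len(events)} events: the smallest set of rearrangements that turns"
    "\nthe parental neighbourhood into the observed one (parsimony)."
)

# an opsin appearing with entirely new flanking genes implies a translocation
moved = [(("zic1", 1, False), ("LWS", 1, True), ("pls3", 1, False))]
kept = [(
    ("hcfc1", 1, False), ("tmem187", 1, False), ("irak1", 1, False),
    ("SWS2", 1, True),
    ("gnl3l", 1, False), ("fgd1", 1, False), ("tfe3", 1, False),
)]
events2 = infer_branch_events(parent, kept + moved)
print("\nLWS with brand-new flanks:", [e.event for e in events2])
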