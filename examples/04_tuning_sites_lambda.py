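"""Spectral tuning sites: ancestral residues and lambda-max prediction.

Sites are numbered by bovine rhodopsin.  The LWS lambda-max follows the
additive five-sites rule (sites 164/181/261/269/292; ancestral genotype
S/H/Y/T/A = 560 nm with a vitamin-A1 chromophore); other families use the
shipped table of measured per-substitution shifts.
"""

from opsinevo.io_formats import SpeciesTree
from opsinevo.tuning import (
    asr_sites,
    label_substitutions,
    predict_lws_lambda,
    predict_shift,
)

# five-sites rule
ancestral = {164: "S", 181: "H", 261: "Y", 269: "T", 292: "A"}
print("ancestral teleost LWS lambda-max:", predict_lws_lambda(ancestral), "nm")
blue_shifted = {164: "A", 181: "H", 261: "F", 269: "T", 292: "A"}
print("S164A + Y261F genotype:        ", predict_lws_lambda(blue_shifted), "nm")

# single-substitution shifts
print("Rh2 E122Q shift:", predict_shift("Rh2", ["E122Q"]), "nm (blue)")
print("SWS2 A94C+W265Y (interacting pair):",
      predict_shift("SWS2", ["A94C", "W265Y"]), "nm")

# ancestral residues at one site by ML on a species tree
tree = SpeciesTree.from_newick("(((carp:60,tetra:60):40,pike:100):50,gar:150);")
residues = {"carp": "Q", "tetra": "Q", "pike": "E", "gar": "E"}
states = asr_sites(tree, residues, site=122, rate=0.001)
root = tree.root_id
print(f"\nroot residue at site 122: {states.map_residue[root]} "
      f"(posterior {states.map_prob[root]:.3f})")
for branch, labels in label_substitutions({122: states}, tree).items():
    for l in labels:
        print(f"  branch {branch}: {l['label']}")
print("The labelled branch is where the blue-shifting E122Q change occurred.")
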