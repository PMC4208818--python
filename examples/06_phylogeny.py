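"""NJ tree with bootstrap support and sister-pair extraction.

Builds a small protein alignment containing two near-identical paralogs
among diverged relatives, reconstructs the NJ tree from p-distances,
bootstraps 200 replicates and extracts the supported cherries — the
tree-based definition of a paralogous pair.
"""

from iqdfam.io import SeqRecord
from iqdfam.phylo import bootstrap_support, sister_pairs

aln = [
    SeqRecord("GmA1", "MKVLIDEQRSTPLWNA" * 4, "protein"),
    SeqRecord("GmA2", "MKVLIDEQRSTPLWNS" * 4, "protein"),  # 1 residue off A1
    SeqRecord("GmB1", "MKVHGDEQRATPYWNA" * 4, "protein"),
    SeqRecord("GmB2", "MKVHGDEARATPYWGA" * 4, "protein"),
    SeqRecord("GmC1", "MPTSSSWEDFKKYHNA" * 4, "protein"),
]

tree = bootstrap_support(aln, n_reps=200, seed=11)
print(tree.ascii_art())
for pair in sister_pairs(tree, min_support=0.5):
    print(f"sister pair: {pair[0]}-{pair[1]}")
print("newick:", str(tree).strip())
# Internal labels are bootstrap proportions; a cherry with high support is
# the operational definition of a coparalog pair in a one-species tree.
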