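"""Classify six-OTU topologies into duplication-timing scenarios.

Rooting each candidate on the outgroup, a topology supports a
duplication *after* the lineage split when both within-lineage paralog
pairs form clades, and a duplication *before* the split when a
cross-lineage orthology pair forms a clade.
"""

from dupsplit import classify_topology, parse_newick

examples = [
    "(((Ost-2,Ost-1),(Cho-1,Cho-2)),Cyc,OG);",
    "((((Cho-1,Ost-1),Ost-2),Cho-2),Cyc,OG);",
    "((((Cho-1,Ost-2),Ost-1),Cho-2),Cyc,OG);",
]
for nwk in examples:
    print(f"{classify_topology(parse_newick(nwk)):11s}  {nwk}")
print()
print("The first tree pairs paralogs within each lineage (duplication after")
print("the split); the second contains the Cho-1+Ost-1 orthology clade")
print("(duplication before the split); the third matches neither rule.")
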