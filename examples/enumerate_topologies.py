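"""Enumerate every unrooted topology over the six constrained OTUs.

With within-OTU relationships fixed, the hypothesis space of the
gene-family analysis is the set of unrooted binary trees over the six
OTU labels: (2k-5)!! = 105 topologies for k = 6.  Canonical forms prove
the enumeration is duplicate-free.
"""

from dupsplit import classify_topology, enumerate_topologies

otus = ["Ost-1", "Ost-2", "Cho-1", "Cho-2", "Cyc", "OG"]
tops = enumerate_topologies(otus)
canon = {t.canonical_form() for t in tops}
print(f"{len(tops)} topologies over {len(otus)} OTUs "
      f"({len(canon)} distinct canonical forms)")

by_scenario = {}
for t in tops:
    by_scenario.setdefault(classify_topology(t), []).append(t)
for name, group in sorted(by_scenario.items()):
    print(f"  {name:11s}: {len(group)} topologies, e.g. "
          f"{group[0].to_newick(lengths=False)}")
print()
print("post_split trees pair each lineage's paralogs; pre_split trees pair")
print("orthologs across lineages; 'other' trees match neither fingerprint.")
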