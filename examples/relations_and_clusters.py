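"""The ontology layer: labels, inter-label relations and gene clusters.

Prints the prototype label-set sizes (24/10/8 at unit level, 27/13/11 with
the gene label and UTRs), classifies a few interval pairs with the
12-relation algebra, and maps prototype combinations to gene-cluster labels
with their Sequence Ontology accessions.
"""

from ligmotif import Interval, default_ontology, relation_between

onto = default_ontology()

print("label vocabulary:", len(onto.labels), "labels")
for g in "VDJ":
    print(f"  {g}: unit {onto.label_count(g, 'unit'):2d} labels,"
          f" gene {onto.label_count(g, 'gene'):2d} labels")

print("\ninterval relations (gene-orientation coordinates):")
pairs = [
    (Interval(0, 10), Interval(19, 30)),   # disjoint, A upstream
    (Interval(0, 10), Interval(10, 30)),   # abutting
    (Interval(4, 15), Interval(4, 40)),    # nested, same 5' end
    (Interval(4, 20), Interval(10, 40)),   # partial overlap
]
for a, b in pairs:
    print(f"  A={tuple(a)} B={tuple(b)}: A {relation_between(a, b)} B"
          f"  /  B {relation_between(b, a)} A")

print("\ngene clusters:")
for present in [{"V"}, {"D", "J"}, {"V", "D"}, {"V", "D", "J"}]:
    cluster = onto.cluster_label_for(present)
    print(f"  {sorted(present)} -> {cluster.name} ({cluster.so_id or 'no SO term'})")
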