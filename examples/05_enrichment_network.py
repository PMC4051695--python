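"""GO enrichment ratios per severity class and the interaction network.

Builds a screen fixture with hit genes biased toward sarcomeric GO terms,
computes term-by-class enrichment ratios, and assembles the
severity-coloured interaction multigraph.
"""

from sarcotrack import enrichment as enr, synthetic as syn

fixture = syn.gen_screen_fixture((5, 13, 28, 86), seed=3)
universe = tuple(g.gene for g in fixture.genes)
ann = enr.AnnotationSet(annotations=fixture.go_annotations, universe=universe)

classes: dict[str, list[str]] = {}
for g in fixture.genes:
    classes.setdefault(g.severity, []).append(g.gene)

terms = ["sarcomere", "actin cytoskeleton", "myosin complex", "microtubule"]
table = enr.enrichment_table(terms, classes, ann)
print("enrichment ratios (term frequency in class / frequency in screen):")
print(table.round(2).to_string())

severities = {g.gene: g.severity for g in fixture.genes}
graph = enr.build_network(severities, fixture.edges)
loops = sum(1 for u, v in graph.edges() if u == v)
print(f"\nnetwork: {graph.number_of_nodes()} genes, {graph.number_of_edges()} "
      f"interactions ({loops} reflexive)")
print("Ratios above 1 mean over-representation: sarcomeric terms concentrate "
      "in the hit classes, microtubule terms in the no-phenotype class.")
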