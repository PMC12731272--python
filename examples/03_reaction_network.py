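"""Reaction-network views of the example model.

The full network writes each taxon as a replicator consuming its required
resources; the reduced taxa-only network needs the minimal producing sets
of every taxon (a minimal-hitting-set problem, NP-hard in general), one
replication dependency per minimal set.
"""

from cotox import (
    fixture,
    minimal_producing_sets_exact,
    reduced_taxa_network,
    to_reaction_network,
)

model = fixture("fig1")
print("full reaction network:")
for r in to_reaction_network(model):
    print(f"  [{r.kind:10s}] {r.text()}")

print("\nminimal producing sets of taxon b (requires f1, f2, f4):")
for ps in minimal_producing_sets_exact(model, "b"):
    print("  suppliers {" + ",".join(sorted(ps.suppliers)) + "}")

net = reduced_taxa_network(model, method="exact")
print("\nreduced taxa-only network:")
for consumer, suppliers in net.dependencies:
    print(f"  {consumer} <- {{{','.join(sorted(suppliers))}}}")
for producer, victim in net.toxin_edges:
    print(f"  {producer} -x-> {victim}   (toxin kill)")
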