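"""Infer minimal toxin and food tables back from measured compositions.

Starting from the six toxin-aware organizations of the example model, the
non-persistent unions of the measured hierarchy witness the taxa
impairing ({a},{c}); each orientation gives one single-toxin table.  The
food-table heuristic then reconstructs a four-resource table whose
implied organization set matches the measurements exactly.
"""

from cotox import (
    build_extended_hierarchy,
    enumerate_organizations_bruteforce,
    find_impairings,
    fixture,
    impairings_to_toxin_tables,
    implied_organizations,
    infer_food_table,
    minimal_impairing_cover,
    sort_taxa_sets,
    write_model,
)

model = fixture("fig1")
orgs = enumerate_organizations_bruteforce(model, apply_toxins=True)
h = build_extended_hierarchy(orgs, model, apply_toxins=True)
fmt = lambda s: "{" + ",".join(sorted(s)) + "}"

print("measured organizations:",
      [fmt(o) for o in sort_taxa_sets(orgs)])
print("non-persistent unions:",
      [fmt(u) for u in sort_taxa_sets(h.non_persistent_unions)])

imps = find_impairings(orgs, h.non_persistent_unions)
print("taxa impairings:",
      [f"({fmt(i.side_a)},{fmt(i.side_b)})" for i in imps])
covers = minimal_impairing_cover(imps, h.non_persistent_unions)
alts = impairings_to_toxin_tables(list(covers[0]), orgs,
                                  h.non_persistent_unions)
print(f"{len(alts)} minimal toxin tables:")
for alt in alts:
    for toxin, producers, sensitives in alt.rows:
        print(f"  {toxin}: produced by {fmt(producers)}, "
              f"kills {fmt(sensitives)}")

print("\ninferred minimal food table(s):")
for result in infer_food_table(orgs, imps, seed=0):
    print(f"  exact={result.exact}, "
          f"{result.model.n_resources} resources "
          f"({result.n_seed_requirements} from requirement assignment)")
    print("\n".join("  " + line for line in
                    write_model(result.model).splitlines()))
    assert implied_organizations(result.model, imps) == orgs
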