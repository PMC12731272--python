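"""Load the five-taxon example model and enumerate its organizations.

An organization is a taxa set in which every required food resource is
produced by some member and nobody is killed by a toxin made inside the
set.  The toxin (c produces t1, a is sensitive) removes three of the ten
toxin-free organizations.
"""

from cotox import (
    enumerate_organizations_bruteforce,
    fixture,
    sort_taxa_sets,
    taxon_profile,
)

model = fixture("fig1")
print(model)
for taxon in model.taxa:
    p = taxon_profile(model, taxon)
    print(f"  {taxon}: requires {sorted(p.required_resources)}, "
          f"produces {sorted(p.produced_resources)}, "
          f"toxins out {sorted(p.produced_toxins)}, "
          f"sensitive to {sorted(p.sensitive_toxins)}")

for toxins in (False, True):
    orgs = enumerate_organizations_bruteforce(model, apply_toxins=toxins)
    label = "with" if toxins else "without"
    print(f"\n{len(orgs)} organizations {label} toxins "
          "(empty set included):")
    for o in sort_taxa_sets(orgs):
        print("  {" + ",".join(sorted(o)) + "}")
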