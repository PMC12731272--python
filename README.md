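# cotox

Coexistence hierarchies of microbial communities from
consumer-resource-toxin models.

## The problem

Microbial communities persist through cross-feeding: taxa consume
resources that other taxa produce. Which sub-communities can persist at
all is a structural question that can be answered without kinetics.
`cotox` models a community as two sign tables over `S` taxa:

* a **food resource table** `R ∈ {−1,0,1}^{S×M}` — `ρ_{iα} = +1` when
  taxon *i* produces resource *α*, `−1` when it requires it;
* a **toxin table** `T ∈ {−1,0,1}^{S×T}` — `τ_{iβ} = +1` when taxon *i*
  produces toxin *β*, `−1` when the toxin kills it.

A taxa set `O ⊆ {1,…,S}` is an **organization** when

1. every required resource is produced within the set:
   `∀i∈O ∀α∈δ_i ∃j∈O : α∈ε_j`, and
2. no member is sensitive to a toxin produced within the set:
   `∀i∈O ∀β∈η_i ∄j∈O : β∈ζ_j`,

where `δ_i/ε_i` are the required/produced resources and `η_i/ζ_i` the
sensitive/produced toxins of taxon *i*. Organizations are the candidate
persistent sub-communities; the empty set always qualifies and is counted.

The package is aimed at theoretical ecologists and microbiome researchers
who want to

* enumerate all organizations of a model (exhaustively or
  constructively through minimal producing sets),
* build the **extended hierarchy**: the Hasse diagram of organizations
  plus their pairwise non-persistent unions (red) and intersections
  (yellow), and decompose it into interaction clusters and elementary
  organizations,
* derive full or reduced (taxa-only) **reaction networks**, including
  the NP-hard minimal-producing-set reduction with exact and greedy
  paths,
* simulate **measurement experiments** (novel / neutral / random
  encounter) that reconstruct the hierarchy from observed compositions,
  with recovery curves and false discovery rates,
* **infer minimal models** back from measurements: taxa impairings and
  minimal toxin tables from non-persistent unions, and a minimal food
  table whose implied organizations match the measurements exactly.

## Worked example

The built-in `fig1` fixture is a five-taxon community: `a` feeds `b`
(f2, f4), `b` feeds `d` and `e` (f3), `d`/`e` close the loop (f1, f4),
and `c` produces toxin `t1` that kills `a`.

```python
from cotox import enumerate_organizations_bruteforce, fixture, sort_taxa_sets

model = fixture("fig1")
for toxins in (False, True):
    orgs = enumerate_organizations_bruteforce(model, apply_toxins=toxins)
    print(len(orgs), [",".join(sorted(o)) for o in sort_taxa_sets(orgs)])
```

prints

```
10 ['', 'a', 'a,b,d', 'a,b,e', 'b,c,d', 'a,b,c,d', 'a,b,c,e', 'a,b,d,e', 'b,c,d,e', 'a,b,c,d,e']
7 ['', 'a', 'a,b,d', 'a,b,e', 'b,c,d', 'a,b,d,e', 'b,c,d,e']
```

— the toxin removes the three organizations containing both `a` and `c`.
Two of the removed sets ({a,b,c,d} and {a,b,c,d,e}) are still unions of
surviving organizations, so they appear as red nodes in the extended
hierarchy. Running the inference the other way around
(`examples/05_model_inference.py`):

```
taxa impairings: ['({a},{c})']
2 minimal toxin tables:
  t1: produced by {a}, kills {c}
  t1: produced by {c}, kills {a}
inferred minimal food table(s):
  exact=True, 4 resources (4 from requirement assignment)
```

The impairing says `a` and `c` never co-occur in any measured
organization; a single toxin in either orientation explains both red
nodes, and the reconstructed four-resource food table implies exactly the
six measured organizations (plus the empty one), matching the resource
count of the generating model even though the individual cross-feeding
links differ.

The `examples/` directory holds one short script per capability; each
prints the quantities it computes with a note on what they mean. A thin
CLI mirrors the library:

```sh
cotox enumerate --fixture fig1
cotox hierarchy --fixture fig1 --format dot
cotox random --S 10 --M 10 --T 5 --seed 1 --out model.tsv
```

## Model file format

TSV with one header row (resource labels, a `|` marker, toxin labels) and
one row per taxon with cells `+`, `-`, `0` — see
`src/cotox/data/fig1.tsv`. A JSON schema mirroring the in-memory fields
is also supported by `read_model`/`write_model`.
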