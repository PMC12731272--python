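"""The extended hierarchy of organizations.

The Hasse diagram over all organizations of a model plus their pairwise
unions and intersections.  Nodes are colour-coded in exports the way the
diagrams of this framework are usually drawn:

* green — organization,
* red — non-persistent union (union of two organizations that is not an
  organization; arises only when toxins are present),
* yellow — non-persistent intersection.

A set that is simultaneously a pairwise union and a pairwise intersection
of organizations is itself an organization (it is self-maintaining as a
union and toxin-compatible as a subset of an organization), so the three
statuses are mutually exclusive and classification precedence is green.

The module also decomposes organizations into *interaction clusters* (the
taxa not present in any strictly contained organization) and derives the
*elementary organizations* — the minimal units from which all other
organizations arise as unions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Literal

import networkx as nx

from . import _bits
from .errors import IntegrityError, ParameterError
from .model import CRTModel
from .organizations import _compiled, _mask, is_organization, sort_taxa_sets

Status = Literal["organization", "non_persistent_union",
                 "non_persistent_intersection"]

_COLOR = {
    "organization": "green",
    "non_persistent_union": "red",
    "non_persistent_intersection": "yellow",
}


@dataclass(frozen=True)
class HierarchyNode:
    taxa: frozenset[str]
    status: Status


@dataclass(frozen=True)
class ExtendedHierarchy:
    """Nodes plus the cover relation (lower, upper) of strict inclusion."""

    nodes: tuple[HierarchyNode, ...]
    edges: frozenset[tuple[frozenset[str], frozenset[str]]]

    def by_status(self, status: Status) -> list[frozenset[str]]:
        return [n.taxa for n in self.nodes if n.status == status]

    @property
    def organizations(self) -> list[frozenset[str]]:
        return self.by_status("organization")

    @property
    def non_persistent_unions(self) -> list[frozenset[str]]:
        return self.by_status("non_persistent_union")

    @property
    def non_persistent_intersections(self) -> list[frozenset[str]]:
        return self.by_status("non_persistent_intersection")


@dataclass(frozen=True)
class InteractionCluster:
    """The taxa an organization introduces over everything below it."""

    organization: frozenset[str]
    cluster: frozenset[str]
    kind: Literal["context_free", "context_dependent"]


def build_extended_hierarchy(
    organizations: Iterable[frozenset[str]],
    model: CRTModel,
    apply_toxins: bool = True,
) -> ExtendedHierarchy:
    """Extended hierarchy from a complete organization set.

    ``organizations`` must be exactly the enumeration output for
    ``(model, apply_toxins)``; each listed set is re-checked against the
    organization predicate.  Unions/intersections are taken pairwise over
    organizations only (not iterated over derived sets).
    """
    cm = _compiled(model)
    orgs = [_mask(s, model) for s in organizations]
    for m, s in zip(orgs, organizations):
        if not cm.is_organization(m, apply_toxins):
            raise IntegrityError(
                f"input set {sorted(s)} is not an organization under "
                f"apply_toxins={apply_toxins}")
    org_set = set(orgs)
    unions, inters = set(), set()
    for i in range(len(orgs)):
        for j in range(i + 1, len(orgs)):
            u = orgs[i] | orgs[j]
            if u not in org_set:
                unions.add(u)
            v = orgs[i] & orgs[j]
            if v not in org_set:
                inters.add(v)
    # a set that is both a derived union and intersection must satisfy the
    # organization predicate (see module docstring); flag violations
    both = unions & inters
    if both:
        raise IntegrityError(
            "derived sets classify as both union and intersection but fail "
            f"the organization predicate: {sorted(map(bin, both))}")
    nodes = (
        [HierarchyNode(_bits.labels_of(m, model.taxa), "organization")
         for m in orgs]
        + [HierarchyNode(_bits.labels_of(m, model.taxa),
                         "non_persistent_union") for m in unions]
        + [HierarchyNode(_bits.labels_of(m, model.taxa),
                         "non_persistent_intersection") for m in inters]
    )
    nodes.sort(key=lambda n: (len(n.taxa), tuple(sorted(n.taxa))))
    all_masks = orgs + list(unions) + list(inters)
    edges = _cover_edges(all_masks)
    label = {m: _bits.labels_of(m, model.taxa) for m in all_masks}
    return ExtendedHierarchy(
        nodes=tuple(nodes),
        edges=frozenset((label[a], label[b]) for a, b in edges),
    )


def _cover_edges(masks: list[int]) -> list[tuple[int, int]]:
    """Cover pairs (lower, upper) of the inclusion order on distinct masks."""
    uniq = sorted(set(masks), key=_bits.popcount)
    edges = []
    for y in uniq:
        covers: list[int] = []
        # scan strictly smaller sets in decreasing cardinality: x is a cover
        # of y iff x < y and no already-kept cover lies between them
        below = [x for x in uniq if x != y and x & ~y == 0]
        for x in sorted(below, key=_bits.popcount, reverse=True):
            if not any(x & ~c == 0 for c in covers):
                covers.append(x)
        edges.extend((x, y) for x in covers)
    return edges


def interaction_clusters(
    organizations: Iterable[frozenset[str]],
    model: CRTModel,
    apply_toxins: bool = True,
) -> list[InteractionCluster]:
    """One cluster record per organization.

    The cluster of O is O minus the union of all organizations strictly
    contained in O; it is context-free iff it is itself an organization
    (hence self-sustaining), context-dependent otherwise.
    """
    cm = _compiled(model)
    orgs = sorted({_mask(s, model) for s in organizations},
                  key=lambda m: (_bits.popcount(m), m))
    out = []
    for o in orgs:
        below = 0
        for p in orgs:
            if p != o and p & ~o == 0:
                below |= p
        cluster = o & ~below
        kind = ("context_free"
                if cluster and cm.is_organization(cluster, apply_toxins)
                else "context_dependent")
        out.append(InteractionCluster(
            organization=_bits.labels_of(o, model.taxa),
            cluster=_bits.labels_of(cluster, model.taxa),
            kind=kind,
        ))
    return out


def elementary_organizations(
    organizations: Iterable[frozenset[str]],
    model: CRTModel,
    apply_toxins: bool = True,
) -> frozenset[frozenset[str]]:
    """Organizations that introduce a non-empty interaction cluster.

    Every other organization is verified to equal the union of the
    elementary organizations it contains (the modular-buildup property).
    """
    clusters = interaction_clusters(organizations, model, apply_toxins)
    elem = {c.organization for c in clusters if c.cluster}
    for c in clusters:
        if c.cluster or not c.organization:
            continue
        union: frozenset[str] = frozenset()
        for e in elem:
            if e <= c.organization:
                union |= e
        if union != c.organization:
            raise IntegrityError(
                f"organization {sorted(c.organization)} is not a union of "
                "elementary organizations")
    return frozenset(elem)


def cluster_dependency_graph(
    cluster: InteractionCluster, model: CRTModel
) -> nx.Graph:
    """Undirected resource-dependency graph restricted to cluster taxa.

    Edge u–v iff one produces a food resource the other requires.  Every
    interaction cluster is connected through such dependencies.
    """
    g = nx.Graph()
    members = sorted(cluster.cluster)
    g.add_nodes_from(members)
    cm = _compiled(model)
    for i, u in enumerate(members):
        iu = model.taxon_index(u)
        for v in members[i + 1:]:
            iv = model.taxon_index(v)
            if (cm.eps[iu] & cm.delta[iv]) or (cm.eps[iv] & cm.delta[iu]):
                g.add_edge(u, v)
    return g


# -- export ----------------------------------------------------------------

def _node_id(taxa: frozenset[str]) -> str:
    return "{" + ",".join(sorted(taxa)) + "}"


def export_hierarchy(h: ExtendedHierarchy, format: str = "dot") -> str:
    """Render the hierarchy as DOT, GraphML or JSON text.

    DOT/GraphML nodes carry a ``color`` attribute (green/red/yellow) and
    DOT ranks nodes by cardinality; the JSON form round-trips through
    :func:`hierarchy_from_json`.
    """
    nodes = sorted(h.nodes, key=lambda n: (len(n.taxa), tuple(sorted(n.taxa))))
    edges = sorted(h.edges, key=lambda e: (_node_id(e[0]), _node_id(e[1])))
    if format == "json":
        return json.dumps(
            {
                "nodes": [
                    {"taxa": sorted(n.taxa), "status": n.status}
                    for n in nodes
                ],
                "edges": [[sorted(a), sorted(b)] for a, b in edges],
            },
            indent=1,
        )
    if format == "dot":
        lines = ["digraph hierarchy {", "  rankdir=BT;"]
        by_card: dict[int, list[str]] = {}
        for n in nodes:
            nid = _node_id(n.taxa)
            lines.append(
                f'  "{nid}" [style=filled, fillcolor={_COLOR[n.status]}, '
                f'label="{nid}"];'
            )
            by_card.setdefault(len(n.taxa), []).append(nid)
        for card in sorted(by_card):
            ids = " ".join(f'"{i}"' for i in by_card[card])
            lines.append(f"  {{ rank=same; {ids} }}")
        for a, b in edges:
            lines.append(f'  "{_node_id(a)}" -> "{_node_id(b)}";')
        lines.append("}")
        return "\n".join(lines) + "\n"
    if format == "graphml":
        g = nx.DiGraph()
        for n in nodes:
            g.add_node(_node_id(n.taxa), status=n.status,
                       color=_COLOR[n.status], size=len(n.taxa))
        for a, b in edges:
            g.add_edge(_node_id(a), _node_id(b))
        return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"
    raise ParameterError(f"unknown hierarchy format {format!r}")


def hierarchy_from_json(text: str) -> ExtendedHierarchy:
    doc = json.loads(text)
    nodes = tuple(
        HierarchyNode(frozenset(n["taxa"]), n["status"])
        for n in doc["nodes"]
    )
    edges = frozenset(
        (frozenset(a), frozenset(b)) for a, b in doc["edges"]
    )
    return ExtendedHierarchy(nodes=nodes, edges=edges)
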