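"""Reaction-network views of a CRT model.

A model can be written as an explicit reaction network over taxa,
resources and toxins (replicator, outflow and toxin-kill reactions), or
reduced to a taxa-only network in which each taxon carries one replication
dependency per *minimal producing set* — an inclusion-minimal set of taxa
whose joint production covers the taxon's requirements.  Enumerating all
minimal producing sets is the minimal-hitting-set problem and NP-hard, so
the reduction offers an exact path (small candidate pools) and a seeded
greedy heuristic (near-minimal, locally pruned).

Stoichiometric coefficients on the product side are "sufficiently high";
they are kept as the symbolic token ``n`` unless a numeric value is
requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

from . import _bits
from .errors import CapacityError, InfeasibleError
from .model import CRTModel
from .organizations import _compiled

Coefficient = Union[int, str]  # positive int or the symbolic token "n"

#: default cap on candidate-supplier pool size for the exact search
EXACT_CAP = 20


@dataclass(frozen=True)
class Reaction:
    educts: tuple[tuple[Coefficient, str], ...]
    products: tuple[tuple[Coefficient, str], ...]
    kind: Literal["replicator", "outflow", "toxin_kill"]

    def text(self) -> str:
        return f"{_side(self.educts)} -> {_side(self.products)}"


def _side(terms: tuple[tuple[Coefficient, str], ...]) -> str:
    if not terms:
        return ""
    parts = []
    for coeff, species in terms:
        parts.append(species if coeff == 1 else f"{coeff} {species}")
    return " + ".join(parts)


@dataclass(frozen=True)
class ProducingSet:
    """Suppliers whose joint production covers a consumer's requirements."""

    consumer: str
    suppliers: frozenset[str]
    covered: frozenset[str]


@dataclass(frozen=True)
class ReducedNetwork:
    """Taxa-only view: replication dependencies plus toxin kill edges."""

    dependencies: tuple[tuple[str, frozenset[str]], ...]
    toxin_edges: tuple[tuple[str, str], ...]  # (producer, victim)


def to_reaction_network(
    model: CRTModel, n: Coefficient = "n"
) -> list[Reaction]:
    """The explicit reaction network of a model.

    One replicator per taxon (consume delta_i, produce 2x itself plus
    epsilon_i and zeta_i at coefficient ``n``), one outflow per taxon
    (spontaneous death), and one kill reaction per (sensitive taxon, toxin)
    pair.
    """
    out: list[Reaction] = []
    for i, taxon in enumerate(model.taxa):
        required = [r for r, v in zip(model.resources, model.food_table[i])
                    if v == -1]
        produced = [r for r, v in zip(model.resources, model.food_table[i])
                    if v == 1]
        toxins = [t for t, v in zip(model.toxins, model.toxin_table[i])
                  if v == 1]
        out.append(Reaction(
            educts=tuple([(1, taxon)] + [(1, r) for r in required]),
            products=tuple([(2, taxon)] + [(n, r) for r in produced]
                           + [(n, t) for t in toxins]),
            kind="replicator",
        ))
    for taxon in model.taxa:
        out.append(Reaction(educts=((1, taxon),), products=(),
                            kind="outflow"))
    for i, taxon in enumerate(model.taxa):
        for t, v in zip(model.toxins, model.toxin_table[i]):
            if v == -1:
                out.append(Reaction(
                    educts=((1, taxon), (1, t)),
                    products=((1, t),),
                    kind="toxin_kill",
                ))
    return out


def minimal_producing_sets_exact(
    model: CRTModel, taxon: str, cap: int = EXACT_CAP
) -> list[ProducingSet]:
    """All inclusion-minimal supplier sets covering ``taxon``'s requirements.

    Subset enumeration by ascending cardinality with superset pruning over
    the pool of candidate suppliers (taxa producing at least one required
    resource).  Returns ``[ProducingSet(taxon, {}, {})]`` when the taxon
    requires nothing, and ``[]`` when some requirement has no producer at
    all.  Raises :class:`CapacityError` above ``cap`` candidates.
    """
    cm = _compiled(model)
    i = model.taxon_index(taxon)
    delta = cm.delta[i]
    required = _bits.labels_of(delta, model.resources)
    if not delta:
        return [ProducingSet(taxon, frozenset(), frozenset())]
    families = [1 << a for a in _bits.bits(delta)]
    try:
        covers = _bits.minimal_hitting_sets(families, cm.eps, cap=cap)
    except _bits._CapacitySignal as sig:
        raise CapacityError(
            f"{sig.n} candidate suppliers exceed the exact-search cap of "
            f"{cap}; use minimal_producing_set_greedy") from None
    out = [
        ProducingSet(taxon, _bits.labels_of(mask, model.taxa), required)
        for mask in covers
    ]
    out.sort(key=lambda p: (len(p.suppliers), tuple(sorted(p.suppliers))))
    return out


def minimal_producing_set_greedy(
    model: CRTModel, taxon: str, seed: int = 0
) -> ProducingSet:
    """A near-minimal producing set by greedy maximum coverage.

    Iteratively adds the supplier resolving the most remaining requirements
    (ties broken by seeded uniform choice), then prunes element-wise so the
    result is locally minimal: no single supplier can be dropped.
    """
    cm = _compiled(model)
    i = model.taxon_index(taxon)
    delta = cm.delta[i]
    if not delta:
        return ProducingSet(taxon, frozenset(), frozenset())
    producible = 0
    for j in range(cm.S):
        producible |= cm.eps[j]
    missing = delta & ~producible
    if missing:
        labels = sorted(_bits.labels_of(missing, model.resources))
        raise InfeasibleError(
            f"no producer exists for required resource(s) {labels}")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    covered = 0
    while delta & ~covered:
        gains = [_bits.popcount(cm.eps[j] & delta & ~covered)
                 for j in range(cm.S)]
        best = max(gains)
        ties = [j for j, g in enumerate(gains) if g == best]
        j = int(rng.choice(ties))
        chosen.append(j)
        covered |= cm.eps[j]
    # pruning pass: drop suppliers made redundant by later picks
    pruned = list(chosen)
    for j in list(pruned):
        rest = 0
        for k in pruned:
            if k != j:
                rest |= cm.eps[k]
        if delta & ~rest == 0:
            pruned.remove(j)
    suppliers = frozenset(model.taxa[j] for j in pruned)
    return ProducingSet(taxon, suppliers,
                        _bits.labels_of(delta, model.resources))


def reduced_taxa_network(
    model: CRTModel,
    method: Literal["exact", "greedy"] = "exact",
    seed: int = 0,
    cap: int = EXACT_CAP,
) -> ReducedNetwork:
    """Taxa-only interaction network.

    One (consumer, supplier-set) dependency per minimal producing set
    (``exact``) or one near-minimal set per taxon (``greedy``); a toxin
    edge producer→victim for every producer of a toxin some taxon is
    sensitive to.  Taxa with an uncoverable requirement contribute no
    dependency entry: they cannot replicate in any community.
    """
    deps: list[tuple[str, frozenset[str]]] = []
    for taxon in model.taxa:
        if method == "exact":
            for ps in minimal_producing_sets_exact(model, taxon, cap=cap):
                deps.append((taxon, ps.suppliers))
        else:
            try:
                ps = minimal_producing_set_greedy(model, taxon, seed=seed)
            except InfeasibleError:
                continue
            deps.append((taxon, ps.suppliers))
    cm = _compiled(model)
    edges = []
    for b in range(model.n_toxins):
        producers = [model.taxa[j] for j in range(model.n_taxa)
                     if cm.zeta[j] >> b & 1]
        victims = [model.taxa[i] for i in range(model.n_taxa)
                   if cm.eta[i] >> b & 1]
        edges.extend((p, v) for p in producers for v in victims)
    return ReducedNetwork(dependencies=tuple(deps),
                          toxin_edges=tuple(sorted(set(edges))))


def reduced_is_self_maintaining(
    s: frozenset[str], network: ReducedNetwork
) -> bool:
    """Self-maintenance evaluated on the reduced network: every member has
    some replication dependency whose suppliers all belong to ``s``."""
    members = frozenset(s)
    for taxon in members:
        entries = [sup for t, sup in network.dependencies if t == taxon]
        if not any(sup <= members for sup in entries):
            return False
    return True
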