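"""Organizations: self-maintaining, toxin-compatible taxa sets.

An *organization* is a set of taxa in which (1) every required food
resource of every member is produced by some member, and (2) no member is
sensitive to a toxin produced within the set.  Closure, the second half of
the chemical-organization-theory definition, is vacuous here because taxa
are self-replicators that never create new taxa.

Taxa sets are plain ``frozenset[str]`` at the API surface; sorted-label
order is the canonical serialization.  The empty set is always an
organization (both conditions hold vacuously) and is counted as one
throughout the package.
"""

from __future__ import annotations

from typing import Iterable

from . import _bits
from .errors import CapacityError, UnknownLabelError
from .model import CRTModel

TaxaSet = frozenset  # canonical immutable taxa set (of str labels)

#: refuse exhaustive power-set scans above this many taxa by default
BRUTEFORCE_CAP = 20


def _compiled(model: CRTModel) -> _bits.CompiledModel:
    cm = getattr(model, "_compiled_cache", None)
    if cm is None:
        cm = _bits.CompiledModel(model.food_table, model.toxin_table)
        model._compiled_cache = cm
    return cm


def _mask(s: Iterable[str], model: CRTModel) -> int:
    m = 0
    for lab in s:
        m |= 1 << model.taxon_index(lab)
    return m


def _sets(masks: Iterable[int], model: CRTModel) -> frozenset[frozenset[str]]:
    return frozenset(_bits.labels_of(m, model.taxa) for m in masks)


def sort_taxa_sets(sets: Iterable[frozenset[str]]) -> list[frozenset[str]]:
    """Deterministic order: ascending cardinality, then lexicographic."""
    return sorted(sets, key=lambda s: (len(s), tuple(sorted(s))))


def is_self_maintaining(s: Iterable[str], model: CRTModel) -> bool:
    """True iff every member's every required resource is produced by some
    member of ``s`` (vacuously true for the empty set)."""
    return _compiled(model).is_self_maintaining(_mask(s, model))


def toxin_conflicts(
    s: Iterable[str], model: CRTModel
) -> frozenset[tuple[str, str, str]]:
    """All (producer, toxin, victim) triples violating toxin compatibility
    within ``s``.  Empty iff no member is hit by a toxin made inside ``s``."""
    cm = _compiled(model)
    triples = cm.toxin_conflicts(_mask(s, model))
    return frozenset(
        (model.taxa[j], model.toxins[t], model.taxa[i]) for j, t, i in triples
    )


def is_organization(
    s: Iterable[str], model: CRTModel, apply_toxins: bool = True
) -> bool:
    """The organization predicate: self-maintaining and, when
    ``apply_toxins``, free of internal toxin conflicts."""
    cm = _compiled(model)
    return cm.is_organization(_mask(s, model), apply_toxins)


def enumerate_organizations_bruteforce(
    model: CRTModel, apply_toxins: bool = True, cap: int = BRUTEFORCE_CAP
) -> frozenset[frozenset[str]]:
    """All organizations by exhaustive power-set scan.

    Refuses models with more than ``cap`` taxa (the scan is ``2^S``); use
    :func:`enumerate_organizations_constructive` beyond that.
    """
    if model.n_taxa > cap:
        raise CapacityError(
            f"S={model.n_taxa} exceeds the brute-force cap of {cap}; "
            "use the constructive enumeration"
        )
    masks = _bits.enumerate_organization_masks(
        model.food_table, model.toxin_table, apply_toxins
    )
    return _sets(masks, model)


def enumerate_organizations_constructive(
    model: CRTModel, apply_toxins: bool = True
) -> frozenset[frozenset[str]]:
    """All organizations without scanning the full power set.

    For each taxon, minimal self-maintaining closures are grown by
    repeatedly resolving unmet requirements through minimal producing sets
    (branching over the alternatives); the collected closures are then
    closed under pairwise union, which generates every toxin-free
    organization.  Toxin filtering is a final removal pass.
    """
    cm = _compiled(model)
    base = _closure_seeds(cm)
    # close under pairwise union to a fixed point (union of self-maintaining
    # sets is self-maintaining when toxins are ignored)
    orgs: set[int] = {0} | base
    frontier = set(orgs)
    while frontier:
        new: set[int] = set()
        for u in frontier:
            for v in orgs:
                w = u | v
                if w not in orgs and w not in new:
                    new.add(w)
        orgs |= new
        frontier = new
    if apply_toxins:
        orgs = {m for m in orgs if not cm.has_toxin_conflict(m)}
    return _sets(orgs, model)


def _minimal_cover_masks(cm: _bits.CompiledModel, resource_mask: int,
                         memo: dict[int, list[int]]) -> list[int]:
    """Minimal taxa masks whose joint production covers ``resource_mask``."""
    hit = memo.get(resource_mask)
    if hit is not None:
        return hit
    families = [1 << a for a in _bits.bits(resource_mask)]
    candidates = cm.eps
    idx_masks = _bits.minimal_hitting_sets(families, candidates)
    # translate candidate-index masks to taxa masks (identity here: the
    # candidate list is exactly the taxa in order)
    memo[resource_mask] = idx_masks
    return idx_masks


def _closure_seeds(cm: _bits.CompiledModel) -> set[int]:
    """All minimal per-taxon self-maintaining closures (toxin-free)."""
    memo: dict[int, list[int]] = {}
    closed: set[int] = set()
    for i in range(cm.S):
        stack = [1 << i]
        seen: set[int] = set()
        while stack:
            state = stack.pop()
            if state in seen:
                continue
            seen.add(state)
            prod = cm.produced_resources(state)
            unmet = 0
            for j in _bits.bits(state):
                unmet |= cm.delta[j] & ~prod
            if unmet == 0:
                closed.add(state)
                continue
            for cover in _minimal_cover_masks(cm, unmet, memo):
                stack.append(state | cover)
    return closed


def generate_organization(
    initial: Iterable[str], model: CRTModel
) -> frozenset[str]:
    """The organization generated by an arbitrary taxa set.

    Models the fast action of toxins followed by starvation: taxa sensitive
    to any toxin produced within the *initial* set are removed in one pass
    (they are never re-added, even if the producer later starves), then taxa
    whose required resources are unsupplied are removed simultaneously per
    round until a fixed point.  The result is always an organization and a
    subset of the input; the map is idempotent.
    """
    cm = _compiled(model)
    state = _mask(initial, model)
    tox = cm.produced_toxins(state)
    if tox:
        for i in _bits.bits(state):
            if cm.eta[i] & tox:
                state &= ~(1 << i)
    while True:
        prod = cm.produced_resources(state)
        removed = 0
        for i in _bits.bits(state):
            if cm.delta[i] & ~prod:
                removed |= 1 << i
        if not removed:
            break
        state &= ~removed
    return _bits.labels_of(state, model.taxa)
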