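"""Model inference from measured community compositions.

Two inverse problems are solved, both under a parsimony principle:

* **Toxin tables from non-persistent unions.**  Each non-persistent union
  of measured organizations witnesses a *taxa impairing* — a minimal pair
  of disjoint taxa sets that never co-occur in any organization.  A
  minimum set of impairings explaining every non-persistent union is then
  translated into candidate toxin tables (one toxin per impairing, two
  orientations each).

* **Food tables from measured organizations.**  Starting from one private
  requirement per taxon whose monoculture was never observed, the
  algorithm synthesizes supply conditions (minimal hitting sets of the
  co-occurrence patterns), selects a small producer-set cover that rules
  out every unobserved composition, and shares resources between taxa with
  identical supplier sets.  The hard constraint is exactness: the returned
  table must imply precisely the measured organizations under the given
  impairing constraints.  Resource count is minimized heuristically, as a
  globally optimal table is not guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _bits
from .errors import CapacityError, InconsistencyError, ParameterError
from .model import CRTModel


@dataclass(frozen=True)
class Impairing:
    """Minimal pair of disjoint taxa sets unable to coexist.

    The pair is unordered; sides are canonicalized so ``side_a`` sorts
    before ``side_b``.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self):
        a, b = self.side_a, self.side_b
        if not a or not b:
            raise ParameterError("impairing sides must be non-empty")
        if a & b:
            raise ParameterError("impairing sides must be disjoint")
        if tuple(sorted(b)) < tuple(sorted(a)):
            object.__setattr__(self, "side_a", b)
            object.__setattr__(self, "side_b", a)

    @property
    def union(self) -> frozenset[str]:
        return self.side_a | self.side_b


@dataclass(frozen=True)
class ToxinTableAlternative:
    """A candidate toxin table: (toxin label, producers, sensitives) rows.

    ``extrapolated`` flags alternatives derived from impairings with a
    multi-taxon side; the translation (all of one side produces, all of
    the other is sensitive) is then a modelling choice rather than forced.
    """

    rows: tuple[tuple[str, frozenset[str], frozenset[str]], ...]
    extrapolated: bool = False


def find_impairings(
    organizations: Iterable[frozenset[str]],
    non_persistent_unions: Iterable[frozenset[str]],
) -> frozenset[Impairing]:
    """All minimal taxa impairings witnessing the non-persistent unions.

    Candidates are generated from every decomposition of a non-persistent
    union into two organizations (starting from the pair's set
    differences), minimized side-wise, and kept only when consistent with
    the *entire* organization set: no organization may contain both sides.
    Raises :class:`InconsistencyError` if some union admits no impairing
    (a signal of measurement error or a model-class violation).
    """
    orgs = [frozenset(o) for o in organizations]
    unions = [frozenset(u) for u in non_persistent_unions]

    def coexists(a: frozenset[str], b: frozenset[str]) -> bool:
        ab = a | b
        return any(ab <= o for o in orgs)

    found: set[Impairing] = set()
    for u in unions:
        decomps = [
            (o1, o2) for o1, o2 in combinations(orgs, 2) if o1 | o2 == u
        ]
        for o1, o2 in decomps:
            a0, b0 = o1 - o2, o2 - o1
            for imp in _minimal_subpairs(a0, b0, coexists):
                found.add(imp)
    # cross-candidate minimization: drop any impairing dominated by a
    # smaller one found elsewhere
    minimal = {
        imp for imp in found
        if not any(other != imp and _dominates(other, imp) for other in found)
    }
    for u in unions:
        if not any(imp.union <= u for imp in minimal):
            raise InconsistencyError(
                f"non-persistent union {sorted(u)} is explained by no "
                "taxa impairing")
    return frozenset(minimal)


def _minimal_subpairs(a0, b0, coexists) -> list[Impairing]:
    out: list[Impairing] = []
    pairs = sorted(
        ((frozenset(a), frozenset(b))
         for a in _nonempty_subsets(a0) for b in _nonempty_subsets(b0)),
        key=lambda p: len(p[0]) + len(p[1]),
    )
    for a, b in pairs:
        if coexists(a, b):
            continue
        imp = Impairing(a, b)
        if not any(_dominates(got, imp) for got in out):
            out.append(imp)
    return out


def _nonempty_subsets(s: frozenset):
    items = sorted(s)
    for r in range(1, len(items) + 1):
        yield from (frozenset(c) for c in combinations(items, r))


def _dominates(small: Impairing, big: Impairing) -> bool:
    return ((small.side_a <= big.side_a and small.side_b <= big.side_b)
            or (small.side_a <= big.side_b and small.side_b <= big.side_a))


def is_minimal_impairing(
    imp: Impairing, organizations: Iterable[frozenset[str]]
) -> bool:
    """Verify minimality by checking every one-element-smaller variant."""
    orgs = [frozenset(o) for o in organizations]

    def impairs(a, b):
        return a and b and not any((a | b) <= o for o in orgs)

    if not impairs(imp.side_a, imp.side_b):
        return False
    for x in imp.side_a:
        if impairs(imp.side_a - {x}, imp.side_b):
            return False
    for x in imp.side_b:
        if impairs(imp.side_a, imp.side_b - {x}):
            return False
    return True


def minimal_impairing_cover(
    impairings: Iterable[Impairing],
    non_persistent_unions: Iterable[frozenset[str]],
    cap: int = 20,
) -> list[frozenset[Impairing]]:
    """All minimum-cardinality impairing subsets explaining every union.

    An impairing explains a union when the union contains both its sides.
    Exact search over subsets by ascending size; refuses more than ``cap``
    impairings.
    """
    imps = sorted(set(impairings),
                  key=lambda i: (tuple(sorted(i.side_a)),
                                 tuple(sorted(i.side_b))))
    unions = [frozenset(u) for u in non_persistent_unions]
    if not unions:
        return [frozenset()]
    for u in unions:
        if not any(imp.union <= u for imp in imps):
            raise InconsistencyError(
                f"non-persistent union {sorted(u)} is explained by no "
                "given impairing")
    if len(imps) > cap:
        raise CapacityError(
            f"{len(imps)} impairings exceed the exact set-cover cap {cap}")
    for size in range(1, len(imps) + 1):
        solutions = [
            frozenset(combo)
            for combo in combinations(imps, size)
            if all(any(imp.union <= u for imp in combo) for u in unions)
        ]
        if solutions:
            return solutions
    return []  # unreachable: the full set always covers


def impairings_to_toxin_tables(
    cover: Iterable[Impairing],
    organizations: Optional[Iterable[frozenset[str]]] = None,
    non_persistent_unions: Optional[Iterable[frozenset[str]]] = None,
) -> list[ToxinTableAlternative]:
    """Translate an impairing cover into candidate toxin tables.

    One fresh toxin per impairing; per impairing two orientations (side A
    produces and side B is sensitive, or vice versa), so a cover of k
    impairings yields ``2^k`` alternatives.  When the measured
    classification is supplied, each alternative is verified to reproduce
    it exactly (organizations conflict-free, non-persistent unions
    conflicted).
    """
    imps = sorted(set(cover),
                  key=lambda i: (tuple(sorted(i.side_a)),
                                 tuple(sorted(i.side_b))))
    alternatives = []
    extrapolated = any(
        len(i.side_a) > 1 or len(i.side_b) > 1 for i in imps)
    for orientation in product((0, 1), repeat=len(imps)):
        rows = []
        for k, (imp, o) in enumerate(zip(imps, orientation), start=1):
            producers = imp.side_a if o == 0 else imp.side_b
            sensitives = imp.side_b if o == 0 else imp.side_a
            rows.append((f"t{k}", producers, sensitives))
        alternatives.append(
            ToxinTableAlternative(rows=tuple(rows),
                                  extrapolated=extrapolated))
    if organizations is not None and non_persistent_unions is not None:
        orgs = [frozenset(o) for o in organizations]
        unions = [frozenset(u) for u in non_persistent_unions]
        for alt in alternatives:
            bad_green = [o for o in orgs if _conflicted(o, alt)]
            bad_red = [u for u in unions if not _conflicted(u, alt)]
            if bad_green or bad_red:
                raise InconsistencyError(
                    "toxin table alternative fails to reproduce the "
                    f"classification: conflicted organizations {bad_green}, "
                    f"unconflicted unions {bad_red}")
    return alternatives


def _conflicted(s: frozenset[str], alt: ToxinTableAlternative) -> bool:
    return any(s & prod and s & sens for _, prod, sens in alt.rows)


# -- food table inference --------------------------------------------------

@dataclass(frozen=True)
class InferredFoodTable:
    """Result of the food-table search.

    ``model`` is a toxin-free CRT model over the taxa universe whose
    implied organization set (under the impairing constraints) is compared
    against the measurements; ``exact`` states whether they agree,
    ``residual`` lists the symmetric difference otherwise.
    ``n_seed_requirements`` is the number of resources introduced by the
    initial requirement-assignment step (one per taxon whose monoculture
    was not measured).
    """

    model: CRTModel
    exact: bool
    residual: frozenset[frozenset[str]]
    n_seed_requirements: int


def implied_organizations(
    food_model: CRTModel, impairings: Iterable[Impairing] = ()
) -> frozenset[frozenset[str]]:
    """All taxa sets implied persistent by a food table: self-maintaining
    and containing no impairing pair."""
    from .organizations import enumerate_organizations_bruteforce
    imps = list(impairings)
    orgs = enumerate_organizations_bruteforce(food_model, apply_toxins=False)
    return frozenset(
        o for o in orgs if not any(imp.union <= o for imp in imps)
    )


def infer_food_table(
    measured_organizations: Iterable[frozenset[str]],
    impairings: Iterable[Impairing] = (),
    taxa: Optional[Sequence[str]] = None,
    seed: int = 0,
    n_alternatives: int = 3,
    cap: int = 16,
) -> list[InferredFoodTable]:
    """Minimal food tables implying exactly the measured organizations.

    The search proceeds in three steps mirroring how such tables are built
    by hand:

    1. *Requirement assignment* — every taxon whose monoculture was not
       measured receives a requirement (taxa with a measured monoculture
       can require nothing at all, since a requirement can never be
       satisfied in isolation).
    2. *Supply synthesis* — for each such taxon the admissible supplier
       sets are the minimal hitting sets of its co-occurrence witnesses
       (the measured sets containing it, minus itself); a seeded greedy
       cover selects supplier sets that jointly rule out every unobserved
       composition.
    3. *Resource sharing* — requirements backed by the same supplier set
       share one resource column.

    Exactness of the implied organization set is the hard constraint; when
    the model class cannot express the measurements (some unobserved
    composition survives even the strongest admissible table), the
    strongest table is returned flagged ``exact=False`` with the residual.
    Several seeded tie-break variants are explored; the returned list
    holds the distinct best tables by (resource count, entry count).
    """
    measured = {frozenset(m) for m in measured_organizations}
    if frozenset() not in measured:
        raise ParameterError(
            "measured organizations must include the empty set")
    universe: set[str] = set()
    for m in measured:
        universe |= m
    imps = list(impairings)
    for imp in imps:
        universe |= imp.union
    if taxa is not None:
        universe |= set(taxa)
    order = sorted(universe)
    S = len(order)
    if S > cap:
        raise CapacityError(
            f"{S} taxa exceed the food-table inference cap of {cap}")
    idx = {t: i for i, t in enumerate(order)}
    meas_masks = {_bits.mask_of(m, idx) for m in measured}
    imp_masks = [(_bits.mask_of(i.union, idx)) for i in imps]

    def blocked(x: int) -> bool:
        return any(u & x == u for u in imp_masks)

    for m in meas_masks:
        if blocked(m):
            raise InconsistencyError(
                "a measured organization contains both sides of an "
                "impairing")

    free = {i for i in range(S) if (1 << i) in meas_masks}
    nonfree = [i for i in range(S) if i not in free]
    n_seed = len(nonfree)

    # admissible supplier sets per taxon: minimal hitting sets of the
    # witness family {X \ {t} : t in X, X measured}
    conjuncts: dict[int, list[int]] = {}
    for t in nonfree:
        witnesses = [m & ~(1 << t) for m in meas_masks if m >> t & 1]
        cands = [1 << j for j in range(S) if j != t]
        sols = _bits.minimal_hitting_sets(witnesses, cands)
        taxa_masks = []
        for sol in sols:
            m = 0
            for k in _bits.bits(sol):
                m |= cands[k]
            taxa_masks.append(m)
        conjuncts[t] = taxa_masks or [0]
        if not witnesses:
            conjuncts[t] = [0]  # taxon never observed: unsupportable

    def supported(t: int, x: int, chosen: dict[int, list[int]]) -> bool:
        return all(d & x for d in chosen.get(t, []))

    def implied_masks(chosen: dict[int, list[int]]) -> set[int]:
        out = set()
        for x in range(1 << S):
            if blocked(x):
                continue
            if all(supported(t, x, chosen)
                   for t in _bits.bits(x) if t not in free):
                out.add(x)
        return out

    # feasibility under the strongest admissible table
    strongest = {t: list(conjuncts[t]) for t in nonfree}
    implied_strong = implied_masks(strongest)
    if implied_strong != meas_masks:
        residual = implied_strong ^ meas_masks
        model = _table_from_pairs(
            [(t, d) for t in nonfree for d in conjuncts[t]], order)
        return [InferredFoodTable(
            model=model, exact=False,
            residual=frozenset(_bits.labels_of(m, order) for m in residual),
            n_seed_requirements=n_seed)]

    # exclusion targets: unobserved, unblocked compositions
    to_exclude = [x for x in range(1 << S)
                  if not blocked(x) and x not in meas_masks]
    # coverage of each candidate (taxon, supplier-set) pair
    pair_cover: dict[tuple[int, int], set[int]] = {}
    for t in nonfree:
        for d in conjuncts[t]:
            cov = {x for x in to_exclude if x >> t & 1 and not d & x}
            if cov:
                pair_cover[(t, d)] = cov

    results: list[InferredFoodTable] = []
    seen_tables: set[tuple] = set()
    for variant in range(max(1, n_alternatives)):
        rng = np.random.default_rng((seed + variant) % (2**31))
        chosen_pairs = _greedy_group_cover(pair_cover, set(to_exclude), rng)
        table = _table_from_pairs(chosen_pairs, order)
        key = _canonical_key(table)
        if key in seen_tables:
            continue
        seen_tables.add(key)
        implied = implied_organizations(table, imps)
        meas_sets = frozenset(_bits.labels_of(m, order) for m in meas_masks)
        exact = implied == meas_sets
        results.append(InferredFoodTable(
            model=table, exact=exact,
            residual=frozenset(implied ^ meas_sets),
            n_seed_requirements=n_seed))
    best = min((r.model.n_resources,
                int(np.count_nonzero(r.model.food_table)))
               for r in results)
    return [r for r in results
            if (r.model.n_resources,
                int(np.count_nonzero(r.model.food_table))) == best]


def _greedy_group_cover(
    pair_cover: dict[tuple[int, int], set[int]],
    targets: set[int],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Cover ``targets`` with (taxon, supplier-set) pairs, greedily adding
    whole supplier-set groups (one group = one future resource column),
    then pruning redundant pairs."""
    by_d: dict[int, list[tuple[int, int]]] = {}
    for (t, d), cov in pair_cover.items():
        by_d.setdefault(d, []).append((t, d))
    chosen_groups: list[int] = []
    chosen_pairs: list[tuple[int, int]] = []
    remaining = set(targets)
    while remaining:
        scores = []
        for d, pairs in by_d.items():
            if d in chosen_groups:
                continue
            gain = len(set().union(*(pair_cover[p] for p in pairs))
                       & remaining)
            if gain:
                scores.append((gain, d))
        if not scores:
            break  # feasibility was pre-checked; leftover means inexact
        best_gain = max(g for g, _ in scores)
        ties = sorted(d for g, d in scores if g == best_gain)
        d = ties[int(rng.integers(len(ties)))]
        chosen_groups.append(d)
        chosen_pairs.extend(by_d[d])
        for p in by_d[d]:
            remaining -= pair_cover[p]
    # prune pairs (entry reduction), then empty groups fall away
    for p in sorted(chosen_pairs,
                    key=lambda q: len(pair_cover[q])):
        rest = [q for q in chosen_pairs if q != p]
        covered = set().union(*(pair_cover[q] for q in rest)) if rest else set()
        if targets <= covered:
            chosen_pairs = rest
    return chosen_pairs


def _table_from_pairs(
    pairs: list[tuple[int, int]], order: Sequence[str]
) -> CRTModel:
    """Build the food table: one resource per distinct supplier set."""
    groups: dict[int, list[int]] = {}
    for t, d in pairs:
        groups.setdefault(d, []).append(t)
    columns = sorted(groups.items(),
                     key=lambda kv: (sorted(kv[1]), kv[0]))
    S = len(order)
    M = len(columns)
    food = np.zeros((S, M), dtype=np.int8)
    for a, (d, taxa_reqs) in enumerate(columns):
        for t in taxa_reqs:
            food[t, a] = -1
        for j in _bits.bits(d):
            food[j, a] = 1
    resources = [f"r{a+1}" for a in range(M)]
    return CRTModel(list(order), resources, [], food,
                    np.zeros((S, 0), dtype=np.int8))


def _canonical_key(model: CRTModel) -> tuple:
    cols = sorted(
        tuple(int(v) for v in model.food_table[:, a])
        for a in range(model.n_resources)
    )
    return tuple(cols)
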