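"""Internal bitmask machinery.

Taxa sets are manipulated as Python integers (bit i = taxon at index i in the
model's taxon order).  All public modules convert to/from frozensets of labels
at their boundaries; everything combinatorial happens here.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np


def mask_of(labels: Iterable[str], index: dict[str, int]) -> int:
    m = 0
    for lab in labels:
        m |= 1 << index[lab]
    return m


def labels_of(mask: int, order: Sequence[str]) -> frozenset[str]:
    return frozenset(order[i] for i in range(len(order)) if mask >> i & 1)


def bits(mask: int) -> list[int]:
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return out


def popcount(mask: int) -> int:
    return bin(mask).count("1")


class CompiledModel:
    """Per-taxon requirement/production bitmasks of a CRT model.

    ``delta``/``eps`` are resource masks, ``zeta``/``eta`` toxin masks, one per
    taxon.  ``producers_of[r]`` is the taxa mask producing resource bit r.
    """

    def __init__(self, food: np.ndarray, toxin: np.ndarray):
        S, M = food.shape
        T = toxin.shape[1]
        self.S, self.M, self.T = S, M, T
        self.delta = [mask_from_row(food[i], -1) for i in range(S)]
        self.eps = [mask_from_row(food[i], +1) for i in range(S)]
        self.eta = [mask_from_row(toxin[i], -1) for i in range(S)]
        self.zeta = [mask_from_row(toxin[i], +1) for i in range(S)]
        self.producers_of = [
            mask_from_row(food[:, a], +1) for a in range(M)
        ]

    def produced_resources(self, taxa_mask: int) -> int:
        out = 0
        for i in bits(taxa_mask):
            out |= self.eps[i]
        return out

    def produced_toxins(self, taxa_mask: int) -> int:
        out = 0
        for i in bits(taxa_mask):
            out |= self.zeta[i]
        return out

    def is_self_maintaining(self, taxa_mask: int) -> bool:
        prod = self.produced_resources(taxa_mask)
        return all(self.delta[i] & ~prod == 0 for i in bits(taxa_mask))

    def toxin_conflicts(self, taxa_mask: int) -> list[tuple[int, int, int]]:
        """(producer, toxin, victim) index triples within ``taxa_mask``."""
        out = []
        members = bits(taxa_mask)
        for j in members:
            z = self.zeta[j]
            if not z:
                continue
            for i in members:
                hit = self.eta[i] & z
                for t in bits(hit):
                    out.append((j, t, i))
        return out

    def has_toxin_conflict(self, taxa_mask: int) -> bool:
        tox = self.produced_toxins(taxa_mask)
        if not tox:
            return False
        return any(self.eta[i] & tox for i in bits(taxa_mask))

    def is_organization(self, taxa_mask: int, apply_toxins: bool = True) -> bool:
        if not self.is_self_maintaining(taxa_mask):
            return False
        return not (apply_toxins and self.has_toxin_conflict(taxa_mask))


def mask_from_row(row: np.ndarray, sign: int) -> int:
    m = 0
    for j in np.flatnonzero(row == sign):
        m |= 1 << int(j)
    return m


def enumerate_organization_masks(
    food: np.ndarray, toxin: np.ndarray, apply_toxins: bool
) -> list[int]:
    """All organization bitmasks of the model, by exhaustive subset scan.

    Vectorized over chunks of the power set; suitable up to S ~ 20.
    """
    S = food.shape[0]
    produces = (food == 1)
    requires = (food == -1)
    tox_produces = (toxin == 1)
    tox_hits = (toxin == -1)
    n = 1 << S
    chunk = min(n, 1 << 16)
    out: list[int] = []
    taxa_bits = np.arange(S, dtype=np.int64)
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n), dtype=np.int64)
        A = ((idx[:, None] >> taxa_bits) & 1).astype(bool)  # subsets × taxa
        prod = A @ produces  # counts of producers per resource
        unmet = (requires @ (prod == 0).T).T > 0  # subset × taxon
        bad = (A & unmet).any(axis=1)
        if apply_toxins and toxin.shape[1] > 0:
            tox = A @ tox_produces
            hit = (tox_hits @ (tox > 0).T).T > 0
            bad |= (A & hit).any(axis=1)
        out.extend(int(v) for v in idx[~bad])
    return out


def minimal_hitting_sets(
    families: Sequence[int], candidates: Sequence[int], cap: int | None = None
) -> list[int]:
    """Inclusion-minimal subsets of ``candidates`` hitting every family mask.

    ``families`` are bitmasks over an arbitrary ground set; candidate ``i``
    hits family ``f`` when ``candidates[i] & f`` is nonzero.  Returns masks
    over the *candidate index* space.  Empty ``families`` yields ``[0]`` (the
    empty set hits vacuously).  Returns ``[]`` if some family is unhittable.
    """
    if not families:
        return [0]
    if any(f == 0 for f in families):
        return []
    useful = [k for k, c in enumerate(candidates)
              if any(c & f for f in families)]
    for f in families:
        if not any(candidates[k] & f for k in useful):
            return []
    if cap is not None and len(useful) > cap:
        raise _CapacitySignal(len(useful))
    found: list[int] = []
    for size in range(1, len(useful) + 1):
        for combo in combinations(useful, size):
            m = 0
            for k in combo:
                m |= 1 << k
            if any(found_m & m == found_m for found_m in found):
                continue  # superset of a known minimal set
            cover = 0
            for k in combo:
                cover |= candidates[k]
            if all(cover & f for f in families):
                found.append(m)
    return found


class _CapacitySignal(Exception):
    def __init__(self, n: int):
        self.n = n
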