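"""Simulated measurement experiments and hierarchy reconstruction.

A *measurement* is a taxa set observed as a stable community composition;
under the persistence assumption every measurement is an organization of
the (unknown) underlying model.  Reconstruction tracks, next to the
measured sets, their pairwise unions and intersections:

* additional unions / additional intersections — derived sets not
  themselves measured; candidates for unobserved organizations,
* additional organizations — sets that are simultaneously a pairwise
  union and a pairwise intersection of measurements; such a set is
  provably a true organization.

Three encounter experiments are provided: ``novel`` (uniform draws without
replacement), ``neutral`` (uniform with replacement) and ``random`` (a
random taxa set collapsed to the organization it generates: toxin
casualties removed first, then iterative starvation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .model import CRTModel, GenerationParams, random_model
from .organizations import (
    enumerate_organizations_bruteforce,
    generate_organization,
    sort_taxa_sets,
)

CountPolicy = Literal["measured_only", "plus_additional_orgs",
                      "plus_all_candidates"]


@dataclass(frozen=True)
class EncounterConfig:
    """How measurements are drawn.

    ``inclusion_p`` is the per-taxon inclusion probability of the random
    encounter mode (default 0.5); it is ignored by the other modes.
    """

    mode: Literal["novel", "neutral", "random"]
    n_draws: int
    inclusion_p: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("novel", "neutral", "random"):
            raise ParameterError(f"unknown encounter mode {self.mode!r}")
        if self.n_draws < 0:
            raise ParameterError("n_draws must be >= 0")
        if not 0.0 <= self.inclusion_p <= 1.0:
            raise ParameterError("inclusion_p outside [0, 1]")


@dataclass(frozen=True)
class ReconstructionState:
    """Measured sets plus everything derivable from their pairwise algebra."""

    measured: frozenset[frozenset[str]] = frozenset()
    _unions: frozenset[frozenset[str]] = frozenset()
    _intersections: frozenset[frozenset[str]] = frozenset()

    @property
    def additional_unions(self) -> frozenset[frozenset[str]]:
        return self._unions - self.measured

    @property
    def additional_intersections(self) -> frozenset[frozenset[str]]:
        return self._intersections - self.measured

    @property
    def additional_organizations(self) -> frozenset[frozenset[str]]:
        return self.additional_unions & self.additional_intersections

    def recovered(self, policy: CountPolicy) -> frozenset[frozenset[str]]:
        if policy == "measured_only":
            return self.measured
        if policy == "plus_additional_orgs":
            return self.measured | self.additional_organizations
        if policy == "plus_all_candidates":
            return (self.measured | self.additional_unions
                    | self.additional_intersections)
        raise ParameterError(f"unknown count policy {policy!r}")


def update_reconstruction(
    state: ReconstructionState, new_measurement: Iterable[str]
) -> ReconstructionState:
    """Fold one measurement into the state (no-op on repeats).

    Derived collections are maintained over *pairwise* unions and
    intersections of distinct measured sets.
    """
    new = frozenset(new_measurement)
    if new in state.measured:
        return state
    unions = set(state._unions)
    inters = set(state._intersections)
    for m in state.measured:
        unions.add(m | new)
        inters.add(m & new)
    return ReconstructionState(
        measured=state.measured | {new},
        _unions=frozenset(unions),
        _intersections=frozenset(inters),
    )


def draw_measurements(
    model: CRTModel,
    organizations: Iterable[frozenset[str]],
    config: EncounterConfig,
) -> list[frozenset[str]]:
    """Simulate an ordered series of measurements.

    ``organizations`` must be the toxin-aware enumeration of ``model``.
    ``novel`` permutes the organizations uniformly (capped at their count);
    ``neutral`` draws uniformly with replacement; ``random`` draws a taxa
    set with per-taxon probability ``inclusion_p`` and records the
    organization it generates (possibly the empty one).
    """
    config.validate()
    orgs = sort_taxa_sets(set(organizations))
    rng = np.random.default_rng(config.seed)
    if config.mode == "novel":
        n = config.n_draws
        if n > len(orgs):
            warnings.warn(
                f"novel mode: n_draws={n} exceeds the {len(orgs)} "
                "organizations; capping", stacklevel=2)
            n = len(orgs)
        perm = rng.permutation(len(orgs))
        return [orgs[int(k)] for k in perm[:n]]
    if config.mode == "neutral":
        if not orgs and config.n_draws:
            raise ParameterError("cannot draw from an empty organization set")
        idx = rng.integers(0, len(orgs), size=config.n_draws)
        return [orgs[int(k)] for k in idx]
    out = []
    for _ in range(config.n_draws):
        keep = rng.random(model.n_taxa) < config.inclusion_p
        initial = [t for t, k in zip(model.taxa, keep) if k]
        out.append(generate_organization(initial, model))
    return out


@dataclass(frozen=True)
class RecoveryPoint:
    n_measurements: int
    fraction_recovered: float
    n_additional_unions: int
    n_additional_intersections: int
    n_additional_organizations: int


def recovery_curve(
    model: CRTModel,
    config: EncounterConfig,
    count_policy: CountPolicy = "plus_additional_orgs",
    organizations: Optional[Iterable[frozenset[str]]] = None,
) -> list[RecoveryPoint]:
    """Recovered fraction of true organizations after each measurement.

    The fraction counts recovered sets that are true organizations of the
    model, over the total organization count; under the
    ``plus_additional_orgs`` policy every counted set is provably true, so
    the curve carries no false discoveries.
    """
    if organizations is None:
        organizations = enumerate_organizations_bruteforce(model)
    true_orgs = frozenset(frozenset(o) for o in organizations)
    series = draw_measurements(model, true_orgs, config)
    state = ReconstructionState()
    points = []
    for k, meas in enumerate(series, start=1):
        state = update_reconstruction(state, meas)
        recovered = state.recovered(count_policy)
        points.append(RecoveryPoint(
            n_measurements=k,
            fraction_recovered=len(recovered & true_orgs) / len(true_orgs),
            n_additional_unions=len(state.additional_unions),
            n_additional_intersections=len(state.additional_intersections),
            n_additional_organizations=len(state.additional_organizations),
        ))
    return points


def false_discovery_rate(
    state: ReconstructionState,
    true_orgs: Iterable[frozenset[str]],
    category: Literal["unions", "intersections"],
) -> Optional[float]:
    """Fraction of derived candidates in a category that are not true
    organizations; ``None`` (undefined) when the category is empty."""
    if category == "unions":
        cand = state.additional_unions
    elif category == "intersections":
        cand = state.additional_intersections
    else:
        raise ParameterError(f"unknown FDR category {category!r}")
    if not cand:
        return None
    truth = frozenset(frozenset(o) for o in true_orgs)
    return len([c for c in cand if c not in truth]) / len(cand)


def hierarchy_counts(model: CRTModel) -> tuple[int, int, int]:
    """(organizations, non-persistent unions, non-persistent intersections)
    of the toxin-aware extended hierarchy, counted as distinct sets."""
    orgs = list(enumerate_organizations_bruteforce(model))
    s = set(orgs)
    red, yellow = set(), set()
    for i in range(len(orgs)):
        for j in range(i + 1, len(orgs)):
            u = orgs[i] | orgs[j]
            if u not in s:
                red.add(u)
            v = orgs[i] & orgs[j]
            if v not in s:
                yellow.add(v)
    return len(orgs), len(red), len(yellow)


def run_parameter_study(
    grid: Sequence[GenerationParams],
    replicates: int,
    seed: int = 0,
    recovery_draws_factor: Optional[float] = None,
) -> pd.DataFrame:
    """Hierarchy statistics over an ensemble of random models.

    One row per (grid point, replicate); replicate ``r`` of a grid point
    with base seed ``s`` uses seed ``seed + s + r``.  When
    ``recovery_draws_factor`` is given, a neutral-encounter run with
    ``factor * n_organizations`` draws is added per model, reporting the
    recovered fraction (measured plus additional organizations) and the
    union/intersection FDR at the end of the run.
    """
    rows = []
    for params in grid:
        for r in range(replicates):
            p = GenerationParams(
                S=params.S, M=params.M, T=params.T,
                p_food_produce=params.p_food_produce,
                p_food_require=params.p_food_require,
                p_toxin_produce=params.p_toxin_produce,
                p_toxin_sensitive=params.p_toxin_sensitive,
                seed=seed + params.seed + r,
            )
            model = random_model(p)
            n_green, n_red, n_yellow = hierarchy_counts(model)
            row = {
                "S": p.S, "M": p.M, "T": p.T,
                "p_food_produce": p.p_food_produce,
                "p_food_require": p.p_food_require,
                "p_toxin_produce": p.p_toxin_produce,
                "p_toxin_sensitive": p.p_toxin_sensitive,
                "replicate": r, "seed": p.seed,
                "n_organizations": n_green,
                "n_non_persistent_unions": n_red,
                "n_non_persistent_intersections": n_yellow,
            }
            if recovery_draws_factor is not None:
                orgs = enumerate_organizations_bruteforce(model)
                cfg = EncounterConfig(
                    mode="neutral",
                    n_draws=int(round(recovery_draws_factor * len(orgs))),
                    seed=p.seed,
                )
                state = ReconstructionState()
                for m in draw_measurements(model, orgs, cfg):
                    state = update_reconstruction(state, m)
                recovered = state.recovered("plus_additional_orgs")
                row["recovered_fraction"] = (
                    len(recovered & orgs) / len(orgs) if orgs else 1.0)
                row["union_fdr"] = false_discovery_rate(state, orgs, "unions")
                row["intersection_fdr"] = false_discovery_rate(
                    state, orgs, "intersections")
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_study(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of the mean per grid point."""
    keys = ["S", "M", "T", "p_food_produce", "p_food_require",
            "p_toxin_produce", "p_toxin_sensitive"]
    metrics = [c for c in df.columns
               if c not in keys + ["replicate", "seed"]]
    grouped = df.groupby(keys)[metrics]
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem().add_suffix("_sem")
    return pd.concat([mean, sem], axis=1).reset_index()
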