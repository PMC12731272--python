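"""Simulate neutral-encounter measurements and reconstruct the hierarchy.

Measurements are organizations drawn uniformly with replacement.  The
reconstruction also tracks pairwise unions/intersections of measurements;
a set that is both at once (an "additional organization") is provably a
true organization, so counting those accelerates recovery without false
discoveries.
"""

from cotox import (
    EncounterConfig,
    GenerationParams,
    enumerate_organizations_bruteforce,
    false_discovery_rate,
    random_model,
    recovery_curve,
)

model = random_model(GenerationParams(S=10, M=10, T=5, seed=5))
orgs = enumerate_organizations_bruteforce(model)
n_draws = int(round(2.5 * len(orgs)))
cfg = EncounterConfig(mode="neutral", n_draws=n_draws, seed=5)
points = recovery_curve(model, cfg, "plus_additional_orgs",
                        organizations=orgs)

print(f"model with {len(orgs)} organizations; {n_draws} neutral draws")
for p in points[:: max(1, len(points) // 8)] + [points[-1]]:
    print(f"  after {p.n_measurements:3d} measurements: "
          f"{100 * p.fraction_recovered:5.1f}% recovered, "
          f"{p.n_additional_organizations} additional organizations")

from cotox import ReconstructionState, draw_measurements, \
    update_reconstruction

state = ReconstructionState()
for meas in draw_measurements(model, orgs, cfg):
    state = update_reconstruction(state, meas)
for cat in ("unions", "intersections"):
    fdr = false_discovery_rate(state, orgs, cat)
    shown = "undefined" if fdr is None else f"{fdr:.2f}"
    print(f"additional-{cat} false discovery rate: {shown}")
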