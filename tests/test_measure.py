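import itertools

import numpy as np
import pytest

from cotox import (
    EncounterConfig,
    GenerationParams,
    ReconstructionState,
    draw_measurements,
    enumerate_organizations_bruteforce,
    false_discovery_rate,
    hierarchy_counts,
    is_organization,
    recovery_curve,
    run_parameter_study,
    summarize_study,
    update_reconstruction,
)

from conftest import make_random_model


def fold(measurements):
    state = ReconstructionState()
    for m in measurements:
        state = update_reconstruction(state, m)
    return state


class TestDrawMeasurements:
    def test_zero_draws(self, fig1):
        cfg = EncounterConfig(mode="neutral", n_draws=0, seed=0)
        orgs = enumerate_organizations_bruteforce(fig1)
        assert draw_measurements(fig1, orgs, cfg) == []

    def test_novel_full_run_is_permutation(self, fig1):
        orgs = enumerate_organizations_bruteforce(fig1)
        cfg = EncounterConfig(mode="novel", n_draws=7, seed=3)
        series = draw_measurements(fig1, orgs, cfg)
        assert len(series) == 7 and set(series) == set(orgs)

    def test_novel_overdraw_caps_with_warning(self, fig1):
        orgs = enumerate_organizations_bruteforce(fig1)
        cfg = EncounterConfig(mode="novel", n_draws=99, seed=0)
        with pytest.warns(UserWarning, match="capping"):
            series = draw_measurements(fig1, orgs, cfg)
        assert len(series) == len(orgs)

    def test_random_mode_yields_generated_organizations(self, fig1):
        orgs = enumerate_organizations_bruteforce(fig1)
        cfg = EncounterConfig(mode="random", n_draws=50, inclusion_p=0.5,
                              seed=11)
        for meas in draw_measurements(fig1, orgs, cfg):
            assert is_organization(meas, fig1, apply_toxins=True)

    def test_random_mode_full_initial_set_collapses(self, fig1):
        # inclusion probability 1 forces the initial set {a..e}, whose
        # generated organization is {b,c,d,e}
        orgs = enumerate_organizations_bruteforce(fig1)
        cfg = EncounterConfig(mode="random", n_draws=3, inclusion_p=1.0,
                              seed=0)
        assert draw_measurements(fig1, orgs, cfg) == \
            [frozenset("bcde")] * 3

    def test_seed_reproducibility(self, fig1):
        orgs = enumerate_organizations_bruteforce(fig1)
        cfg = EncounterConfig(mode="neutral", n_draws=20, seed=5)
        assert draw_measurements(fig1, orgs, cfg) == \
            draw_measurements(fig1, orgs, cfg)


class TestReconstructionState:
    def test_pairwise_example(self):
        state = fold([frozenset("abd"), frozenset("bcd")])
        assert state.additional_unions == {frozenset("abcd")}
        assert state.additional_intersections == {frozenset("bd")}
        assert state.additional_organizations == frozenset()

    def test_duplicate_measurement_is_noop(self):
        state = fold([frozenset("abd"), frozenset("bcd")])
        assert update_reconstruction(state, frozenset("abd")) is state

    def test_all_fig1_measurements_reveal_both_red_unions(self, fig1):
        orgs = enumerate_organizations_bruteforce(fig1)
        state = fold(orgs)
        assert frozenset("abcd") in state.additional_unions
        assert frozenset("abcde") in state.additional_unions

    def test_additional_collections_disjoint_from_measured(self):
        for seed in range(10):
            m = make_random_model(seed, S=6, M=4, T=2)
            orgs = sorted(enumerate_organizations_bruteforce(m),
                          key=sorted)[:5]
            state = fold(orgs)
            assert not state.additional_unions & state.measured
            assert not state.additional_intersections & state.measured
            assert state.additional_organizations <= (
                state.additional_unions & state.additional_intersections)

    def test_additional_organization_theorem_fig1_exhaustive(self, fig1):
        # over all 2^7 measurement subsets, every additional organization
        # is a true organization
        orgs = sorted(enumerate_organizations_bruteforce(fig1), key=sorted)
        for r in range(len(orgs) + 1):
            for subset in itertools.combinations(orgs, r):
                state = fold(subset)
                for s in state.additional_organizations:
                    assert is_organization(s, fig1, apply_toxins=True)

    def test_additional_organization_theorem_random_models(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            m = make_random_model(seed, S=7, M=5, T=2,
                                  p_toxin_produce=0.2,
                                  p_toxin_sensitive=0.2)
            orgs = sorted(enumerate_organizations_bruteforce(m), key=sorted)
            k = min(len(orgs), 6)
            idx = rng.choice(len(orgs), size=k, replace=False)
            state = fold([orgs[i] for i in idx])
            for s in state.additional_organizations:
                assert is_organization(s, m, apply_toxins=True)


class TestRecoveryCurve:
    def test_saturation_at_full_measurement(self, fig1):
        cfg = EncounterConfig(mode="novel", n_draws=7, seed=0)
        points = recovery_curve(fig1, cfg, "measured_only")
        assert points[-1].fraction_recovered == 1.0

    def test_monotone_recovery(self, fig1):
        for policy in ("measured_only", "plus_additional_orgs",
                       "plus_all_candidates"):
            cfg = EncounterConfig(mode="neutral", n_draws=30, seed=2)
            points = recovery_curve(fig1, cfg, policy)
            fracs = [p.fraction_recovered for p in points]
            assert fracs == sorted(fracs)

    def test_novel_mode_fraction_is_k_over_n(self, fig1):
        cfg = EncounterConfig(mode="novel", n_draws=7, seed=4)
        points = recovery_curve(fig1, cfg, "measured_only")
        assert [p.fraction_recovered for p in points] == \
            pytest.approx([k / 7 for k in range(1, 8)])

    def test_plus_additional_orgs_counts_only_true_organizations(self, fig1):
        cfg = EncounterConfig(mode="neutral", n_draws=25, seed=9)
        pts = recovery_curve(fig1, cfg, "plus_additional_orgs")
        # fractions under this policy never exceed 1 and carry no FDR
        assert all(0 <= p.fraction_recovered <= 1 for p in pts)

    def test_neutral_coupon_collector(self, fig1):
        # expected unique fraction after k of N draws ~ 1-(1-1/N)^k
        orgs = enumerate_organizations_bruteforce(fig1)
        N = len(orgs)
        k = 10
        runs = 200
        seen = []
        for s in range(runs):
            cfg = EncounterConfig(mode="neutral", n_draws=k, seed=s)
            series = draw_measurements(fig1, orgs, cfg)
            seen.append(len(set(series)) / N)
        expected = 1 - (1 - 1 / N) ** k
        se = np.std(seen) / np.sqrt(runs)
        assert abs(np.mean(seen) - expected) < 3 * se + 1e-9


class TestFalseDiscoveryRate:
    def test_union_fdr_zero_without_toxins(self):
        for seed in range(30):
            m = make_random_model(seed, S=6, M=4, T=0)
            orgs = sorted(enumerate_organizations_bruteforce(m), key=sorted)
            state = fold(orgs[: max(2, len(orgs) // 2)])
            fdr = false_discovery_rate(state, orgs, "unions")
            assert fdr in (None, 0.0)

    def test_fig1_single_pair_union_fdr_one(self, fig1):
        orgs = enumerate_organizations_bruteforce(fig1)
        state = fold([frozenset("abd"), frozenset("bcd")])
        assert false_discovery_rate(state, orgs, "unions") == 1.0

    def test_empty_category_undefined(self, fig1):
        orgs = enumerate_organizations_bruteforce(fig1)
        assert false_discovery_rate(ReconstructionState(), orgs,
                                    "unions") is None


class TestParameterStudy:
    def test_toxin_free_grid_has_no_red_nodes(self):
        grid = [GenerationParams(S=5, M=4, T=0, seed=0)]
        df = run_parameter_study(grid, replicates=5, seed=100)
        assert (df["n_non_persistent_unions"] == 0).all()

    def test_tiny_model_counts_match_hand_enumeration(self):
        # S=2, M=1: organization counts verified against the brute force
        grid = [GenerationParams(S=2, M=1, T=0, seed=0)]
        df = run_parameter_study(grid, replicates=10, seed=0)
        for _, row in df.iterrows():
            m = make_random_model(int(row["seed"]), S=2, M=1, T=0)
            assert row["n_organizations"] == len(
                enumerate_organizations_bruteforce(m))

    def test_summary_has_mean_and_sem(self):
        grid = [GenerationParams(S=4, M=3, T=1, seed=0)]
        df = run_parameter_study(grid, replicates=4, seed=0,
                                 recovery_draws_factor=2.5)
        summary = summarize_study(df)
        assert "n_organizations_mean" in summary.columns
        assert "n_organizations_sem" in summary.columns
        assert "recovered_fraction_mean" in summary.columns
        assert len(summary) == 1

    def test_hierarchy_counts_against_direct_computation(self, fig1):
        assert hierarchy_counts(fig1) == (7, 2, 5)
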