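import pytest

from cotox import (
    Impairing,
    InconsistencyError,
    ParameterError,
    build_extended_hierarchy,
    enumerate_organizations_bruteforce,
    find_impairings,
    impairings_to_toxin_tables,
    implied_organizations,
    infer_food_table,
    is_minimal_impairing,
    minimal_impairing_cover,
)

from conftest import make_random_model


@pytest.fixture(scope="module")
def fig1_hierarchy(fig1):
    orgs = enumerate_organizations_bruteforce(fig1, True)
    h = build_extended_hierarchy(orgs, fig1, True)
    return orgs, h


class TestImpairing:
    def test_sides_canonicalized(self):
        imp = Impairing(frozenset("c"), frozenset("a"))
        assert imp.side_a == frozenset("a")

    def test_invalid_sides_rejected(self):
        with pytest.raises(ParameterError):
            Impairing(frozenset(), frozenset("a"))
        with pytest.raises(ParameterError):
            Impairing(frozenset("ab"), frozenset("b"))


class TestFindImpairings:
    def test_fig1_yields_a_c(self, fig1_hierarchy):
        orgs, h = fig1_hierarchy
        imps = find_impairings(orgs, h.non_persistent_unions)
        assert imps == {Impairing(frozenset("a"), frozenset("c"))}

    def test_toxin_free_hierarchy_yields_none(self, fig1):
        orgs = enumerate_organizations_bruteforce(fig1, False)
        assert find_impairings(orgs, set()) == frozenset()

    def test_bars_c_yields_a_s(self, bars):
        m = bars["bars_c"]
        orgs = enumerate_organizations_bruteforce(m, True)
        h = build_extended_hierarchy(orgs, m, True)
        imps = find_impairings(orgs, h.non_persistent_unions)
        assert imps == {Impairing(frozenset(["A"]), frozenset(["S"]))}

    def test_unexplainable_union_raises(self, fig1_hierarchy):
        orgs, _ = fig1_hierarchy
        # {a,b,d,e} is itself an organization: nothing can impair it
        with pytest.raises(InconsistencyError):
            find_impairings(orgs, {frozenset("abde")})

    def test_outputs_verified_minimal(self):
        for seed in range(30):
            m = make_random_model(seed, S=6, M=4, T=2,
                                  p_toxin_produce=0.25,
                                  p_toxin_sensitive=0.25)
            orgs = enumerate_organizations_bruteforce(m, True)
            h = build_extended_hierarchy(orgs, m, True)
            for imp in find_impairings(orgs, h.non_persistent_unions):
                assert is_minimal_impairing(imp, orgs)


class TestImpairingCover:
    def test_fig1_single_cover(self, fig1_hierarchy):
        orgs, h = fig1_hierarchy
        imps = find_impairings(orgs, h.non_persistent_unions)
        covers = minimal_impairing_cover(imps, h.non_persistent_unions)
        assert covers == [frozenset(
            {Impairing(frozenset("a"), frozenset("c"))})]

    def test_empty_union_set_gives_empty_cover(self):
        assert minimal_impairing_cover([], []) == [frozenset()]

    def test_two_independent_impairings_needed(self):
        # two unions, each explained by a different singleton impairing
        i1 = Impairing(frozenset("a"), frozenset("b"))
        i2 = Impairing(frozenset("c"), frozenset("d"))
        unions = [frozenset("ab"), frozenset("cd")]
        covers = minimal_impairing_cover([i1, i2], unions)
        assert covers == [frozenset({i1, i2})]


class TestToxinTables:
    def test_fig1_two_alternatives(self, fig1_hierarchy):
        orgs, h = fig1_hierarchy
        cover = [Impairing(frozenset("a"), frozenset("c"))]
        alts = impairings_to_toxin_tables(cover, orgs,
                                          h.non_persistent_unions)
        assert len(alts) == 2
        orientations = {(tuple(sorted(p)), tuple(sorted(s)))
                        for alt in alts for _, p, s in alt.rows}
        assert orientations == {(("a",), ("c",)), (("c",), ("a",))}
        assert not any(a.extrapolated for a in alts)

    def test_empty_cover_single_empty_table(self):
        alts = impairings_to_toxin_tables([])
        assert len(alts) == 1 and alts[0].rows == ()

    def test_two_impairings_four_alternatives(self):
        cover = [Impairing(frozenset("a"), frozenset("b")),
                 Impairing(frozenset("c"), frozenset("d"))]
        assert len(impairings_to_toxin_tables(cover)) == 4

    def test_multi_taxon_side_flagged_extrapolated(self):
        cover = [Impairing(frozenset("ab"), frozenset("c"))]
        alts = impairings_to_toxin_tables(cover)
        assert all(a.extrapolated for a in alts)

    def test_roundtrip_on_random_models(self):
        # enumerate organizations of a known model, infer impairings and
        # toxin tables; some alternative reproduces the red/green split
        tested = 0
        for seed in range(60):
            m = make_random_model(seed, S=6, M=4, T=2,
                                  p_toxin_produce=0.25,
                                  p_toxin_sensitive=0.25)
            orgs = enumerate_organizations_bruteforce(m, True)
            h = build_extended_hierarchy(orgs, m, True)
            reds = h.non_persistent_unions
            if not reds:
                continue
            try:
                imps = find_impairings(orgs, reds)
                covers = minimal_impairing_cover(imps, reds, cap=20)
            except InconsistencyError:
                continue
            ok = False
            for cover in covers:
                try:
                    impairings_to_toxin_tables(cover, orgs, reds)
                except InconsistencyError:
                    continue
                ok = True
                break
            if ok:
                tested += 1
        assert tested >= 10  # enough toxin-bearing models exercised


class TestFoodTableInference:
    def test_fig1_roundtrip_four_resources(self, fig1_hierarchy):
        orgs, _ = fig1_hierarchy
        imps = {Impairing(frozenset("a"), frozenset("c"))}
        results = infer_food_table(orgs, imps, seed=0)
        assert results
        for r in results:
            assert r.exact
            assert r.n_seed_requirements == 4
            assert r.model.n_resources == 4
            assert implied_organizations(r.model, imps) == orgs

    def test_full_power_set_needs_no_resources(self):
        import itertools
        taxa = ["a", "b"]
        measured = {frozenset(c) for r in range(3)
                    for c in itertools.combinations(taxa, r)}
        [r] = infer_food_table(measured)
        assert r.exact and r.model.n_resources == 0

    def test_two_taxa_one_resource(self):
        measured = {frozenset(), frozenset("a")}
        results = infer_food_table(measured, taxa=["a", "b"])
        for r in results:
            assert r.exact
            assert r.model.n_resources == 1
            col = r.model.food_table[:, 0]
            b = r.model.taxa.index("b")
            assert col[b] == -1 and (col == 1).sum() == 0

    def test_missing_empty_set_rejected(self):
        with pytest.raises(ParameterError):
            infer_food_table({frozenset("a")})

    def test_roundtrip_on_random_toxin_free_models(self):
        # every returned table re-implies exactly the measured set
        exact_count = 0
        for seed in range(25):
            m = make_random_model(seed, S=5, M=4, T=0)
            orgs = enumerate_organizations_bruteforce(m, False)
            for r in infer_food_table(orgs, seed=seed):
                if r.exact:
                    assert implied_organizations(r.model) == orgs
                    assert not r.residual
                    exact_count += 1
                else:
                    assert r.residual  # flagged best effort is honest
        assert exact_count >= 20

    def test_roundtrip_with_impairings(self):
        # toxin-bearing models: organizations + inferred impairings
        for seed in range(15):
            m = make_random_model(seed, S=5, M=4, T=1,
                                  p_toxin_produce=0.3,
                                  p_toxin_sensitive=0.3)
            orgs = enumerate_organizations_bruteforce(m, True)
            h = build_extended_hierarchy(orgs, m, True)
            try:
                imps = find_impairings(orgs, h.non_persistent_unions)
            except InconsistencyError:
                continue
            for r in infer_food_table(orgs, imps, seed=seed):
                if r.exact:
                    assert implied_organizations(r.model, imps) == orgs
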