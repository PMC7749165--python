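"""Crosslink mapping, distance classification, null distribution, regions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlstruct import (
    AnalysisConfig,
    Atom,
    Chain,
    Crosslink,
    CrosslinkSet,
    MappedCrosslink,
    RegionDef,
    Residue,
    StructureModel,
    SubunitMap,
    ToyComplexSpec,
    classify,
    compare_complexes,
    make_toy_complex,
    map_crosslinks,
    overlength_fraction,
    random_pair_null,
    region_pair_counts,
    simulate_crosslinks,
)


def ca_residue(num, xyz, name="ALA"):
    return Residue(name=name, number=num, atoms=[Atom(name="CA", element="C", coord=xyz)])


def homodimer_model():
    """Two α chains at 10 Å and 40 Å from a β site — ambiguity fixture."""
    chains = [
        Chain("A", [ca_residue(1, [10.0, 0, 0])]),
        Chain("B", [ca_residue(1, [40.0, 0, 0])]),
        Chain("C", [ca_residue(5, [0.0, 0, 0])]),
    ]
    model = StructureModel(id="dimer-toy", chains=chains)
    submap = SubunitMap({"alpha": ["A", "B"], "beta": ["C"]})
    return model, submap


class TestMapCrosslinks:
    def test_minimum_distance_over_homodimer_chains(self):
        model, submap = homodimer_model()
        xset = CrosslinkSet("", [Crosslink("alpha", 1, "beta", 5)])
        [m] = map_crosslinks(xset, model, submap, AnalysisConfig())
        # brute force over both assignments: min(10, 40) = 10
        assert m.distance == pytest.approx(10.0)
        assert m.chain_a == "A"

    def test_absent_residue_unmapped(self):
        model, submap = homodimer_model()
        xset = CrosslinkSet("", [Crosslink("alpha", 99, "beta", 5)])
        [m] = map_crosslinks(xset, model, submap, AnalysisConfig())
        assert m.klass == "unmapped" and m.distance is None

    def test_unknown_protein_unmapped_with_reason(self):
        model, submap = homodimer_model()
        xset = CrosslinkSet("", [Crosslink("sigma", 1, "beta", 5)])
        [m] = map_crosslinks(xset, model, submap, AnalysisConfig())
        assert m.klass == "unmapped" and "sigma" in m.reason

    def test_conservation_of_counts(self, toy_complex):
        model, submap = toy_complex
        sim = simulate_crosslinks(model, submap, n=200, violation_fraction=0.2, seed=1)
        bad = CrosslinkSet(
            sim.xset.complex_label,
            sim.xset.links + [Crosslink("omega", 1, "beta", 1, complex_label=sim.xset.complex_label)],
        )
        mapped = map_crosslinks(bad, model, submap, AnalysisConfig())
        counts = {"within": 0, "over_length": 0, "unmapped": 0}
        for m in mapped:
            counts[m.klass] += 1
        assert sum(counts.values()) == len(bad)
        assert counts["unmapped"] == 1

    def test_rigid_motion_leaves_distances_unchanged(self, toy_complex):
        model, submap = toy_complex
        sim = simulate_crosslinks(model, submap, n=50, violation_fraction=0.3, seed=2)
        cfg = AnalysisConfig()
        before = [m.distance for m in map_crosslinks(sim.xset, model, submap, cfg)]
        ang = np.deg2rad(73.0)
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        moved = StructureModel(
            id="moved",
            chains=[
                Chain(
                    c.chain_id,
                    [
                        Residue(
                            r.name,
                            r.number,
                            atoms=[
                                Atom(a.name, a.element, R @ a.coord + np.array([5.0, -3.0, 11.0]))
                                for a in r.atoms
                            ],
                        )
                        for r in c.residues
                    ],
                )
                for c in model.chains
            ],
        )
        after = [m.distance for m in map_crosslinks(sim.xset, moved, submap, cfg)]
        assert np.allclose(before, after, atol=1e-6)


class TestClassify:
    @pytest.mark.parametrize(
        "distance,expected",
        [(24.9, "within"), (25.1, "over_length"), (25.0, "within")],
    )
    def test_boundary_convention(self, distance, expected):
        m = MappedCrosslink(
            Crosslink("beta", 1, "delta", 2), "A", "B", distance, "within"
        )
        assert classify(m, AnalysisConfig(distance_limit=25.0)) == expected

    def test_unmapped_rejected(self):
        m = MappedCrosslink(Crosslink("beta", 1, "delta", 2), None, None, None, "unmapped")
        with pytest.raises(ValueError):
            classify(m, AnalysisConfig())

    @given(st.floats(0.1, 100.0), st.floats(0.1, 100.0))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_distance(self, d1, d2):
        lo, hi = sorted([d1, d2])
        cfg = AnalysisConfig(distance_limit=25.0)
        link = Crosslink("beta", 1, "delta", 2)
        k_lo = classify(MappedCrosslink(link, "A", "B", lo, "within"), cfg)
        k_hi = classify(MappedCrosslink(link, "A", "B", hi, "within"), cfg)
        assert not (k_lo == "over_length" and k_hi == "within")


class TestOverlengthFraction:
    def test_all_within(self):
        link = Crosslink("beta", 1, "delta", 2)
        mapped = [MappedCrosslink(link, "A", "B", 5.0, "within") for _ in range(4)]
        assert overlength_fraction(mapped) == 0.0

    def test_three_of_ten(self):
        link = Crosslink("beta", 1, "delta", 2)
        mapped = [
            MappedCrosslink(link, "A", "B", 30.0, "over_length") for _ in range(3)
        ] + [MappedCrosslink(link, "A", "B", 5.0, "within") for _ in range(7)]
        assert overlength_fraction(mapped) == pytest.approx(0.3)

    def test_zero_mapped_undefined(self):
        link = Crosslink("beta", 1, "delta", 2)
        with pytest.raises(ValueError):
            overlength_fraction([MappedCrosslink(link, None, None, None, "unmapped")])

    def test_matches_brute_force_on_synthetic(self, toy_complex):
        model, submap = toy_complex
        sim = simulate_crosslinks(model, submap, n=200, violation_fraction=0.25, seed=9)
        mapped = map_crosslinks(sim.xset, model, submap, AnalysisConfig())
        n_over = 0
        n_tot = 0
        for m in mapped:  # independent loop over links
            if m.klass == "unmapped":
                continue
            n_tot += 1
            if m.distance > 25.0:
                n_over += 1
        assert overlength_fraction(mapped) == pytest.approx(n_over / n_tot)


class TestRandomPairNull:
    def test_three_residue_hand_enumeration(self):
        coords = {1: [0.0, 0, 0], 2: [3.0, 0, 0], 3: [3.0, 4.0, 0]}
        model = StructureModel(
            id="t", chains=[Chain("A", [ca_residue(i, c) for i, c in coords.items()])]
        )
        null = random_pair_null(model, None, AnalysisConfig())
        expected = sorted([3.0, 5.0, 4.0])  # pairs (1,2), (1,3), (2,3) by hand
        assert sorted(null.distances.tolist()) == pytest.approx(expected)

    def test_single_residue_error(self):
        model = StructureModel(id="t", chains=[Chain("A", [ca_residue(1, [0, 0, 0])])])
        with pytest.raises(ValueError):
            random_pair_null(model, None, AnalysisConfig())

    def test_exhaustive_pair_count(self):
        model, submap = make_toy_complex(
            ToyComplexSpec(chains=(("beta", 30, "straight_strand"),), seed=0)
        )
        null = random_pair_null(model, submap, AnalysisConfig())
        assert null.n_pairs == 30 * 29 // 2

    def test_sampled_reproducible_and_close_to_exhaustive(self, toy_complex):
        model, submap = toy_complex
        exact = random_pair_null(model, submap, AnalysisConfig())
        cfg = AnalysisConfig(null_mode="sampled", null_sample_size=10_000, seed=5)
        s1 = random_pair_null(model, submap, cfg)
        s2 = random_pair_null(model, submap, cfg)
        assert np.array_equal(s1.distances, s2.distances)  # bit-reproducible
        # max CDF deviation against the exhaustive oracle
        grid = np.linspace(0, exact.distances.max(), 200)
        cdf_e = np.searchsorted(np.sort(exact.distances), grid) / exact.n_pairs
        cdf_s = np.searchsorted(np.sort(s1.distances), grid) / s1.n_pairs
        assert np.abs(cdf_e - cdf_s).max() < 0.02

    def test_sampled_mean_converges(self, toy_complex):
        model, submap = toy_complex
        exact = random_pair_null(model, submap, AnalysisConfig())
        cfg = AnalysisConfig(null_mode="sampled", null_sample_size=10_000, seed=17)
        s = random_pair_null(model, submap, cfg)
        se = exact.distances.std() / np.sqrt(s.n_pairs)
        assert abs(s.distances.mean() - exact.distances.mean()) < 3 * se

    def test_reactivity_restriction_shrinks_universe(self, toy_complex):
        model, submap = toy_complex
        full = random_pair_null(model, submap, AnalysisConfig())
        restricted = random_pair_null(
            model, submap, AnalysisConfig(reactivity_restricted_null=True)
        )
        assert 0 < restricted.n_pairs < full.n_pairs


REGIONS = [
    RegionDef("beta_lobes", "beta", ((146, 248),)),
    RegionDef("bp_shelf_jaw", "beta_prime", ((794, 1141),)),
]


class TestRegionPairCounts:
    def _model(self):
        chains = [
            Chain("B", [ca_residue(n, [float(n), 0, 0]) for n in (150, 200, 300)]),
            Chain("P", [ca_residue(n, [float(n), 1, 0]) for n in (800, 900, 1200)]),
        ]
        model = StructureModel(id="r", chains=chains)
        return model, SubunitMap({"beta": ["B"], "beta_prime": ["P"]})

    def test_no_links_zero_matrix(self):
        _, submap = self._model()
        rc = region_pair_counts([], REGIONS, submap)
        assert rc.matrix.sum() == 0 and rc.n_other == 0

    def test_lobe_to_shelf_link_counted(self):
        model, submap = self._model()
        xset = CrosslinkSet("", [Crosslink("beta", 200, "beta_prime", 900)])
        mapped = map_crosslinks(xset, model, submap, AnalysisConfig(distance_limit=5000))
        rc = region_pair_counts(mapped, REGIONS, submap)
        assert rc.count("beta_lobes", "bp_shelf_jaw") == 1

    def test_outside_regions_goes_to_other(self):
        model, submap = self._model()
        xset = CrosslinkSet("", [Crosslink("beta", 300, "beta_prime", 1200)])
        mapped = map_crosslinks(xset, model, submap, AnalysisConfig(distance_limit=5000))
        rc = region_pair_counts(mapped, REGIONS, submap)
        assert rc.matrix.sum() == 0 and rc.n_other == 1

    def test_overlapping_regions_rejected(self):
        _, submap = self._model()
        bad = REGIONS + [RegionDef("dup", "beta", ((200, 260),))]
        with pytest.raises(ValueError):
            region_pair_counts([], bad, submap)

    def test_matrix_equals_brute_force_double_loop(self, toy_complex):
        model, submap = toy_complex
        regions = [
            RegionDef("bp_lo", "beta_prime", ((1, 30),)),
            RegionDef("bp_hi", "beta_prime", ((31, 60),)),
            RegionDef("b_all", "beta", ((1, 60),)),
        ]
        sim = simulate_crosslinks(model, submap, n=50, violation_fraction=0.2, seed=13)
        mapped = map_crosslinks(sim.xset, model, submap, AnalysisConfig())
        rc = region_pair_counts(mapped, regions, submap)

        expected = np.zeros((3, 3), dtype=int)
        other = 0
        for m in mapped:  # independent double loop
            ia = ib = None
            for i, r in enumerate(regions):
                role_a = submap.role_of(m.chain_a)
                role_b = submap.role_of(m.chain_b)
                if r.role == role_a and any(lo <= m.link.resnum_a <= hi for lo, hi in r.ranges):
                    ia = i
                if r.role == role_b and any(lo <= m.link.resnum_b <= hi for lo, hi in r.ranges):
                    ib = i
            if ia is None or ib is None:
                other += 1
                continue
            expected[ia, ib] += 1
            if ia != ib:
                expected[ib, ia] += 1
        assert np.array_equal(rc.matrix, expected)
        assert rc.n_other == other


class TestCompareComplexes:
    def test_empty_set_gives_zero_row(self, toy_complex):
        model, submap = toy_complex
        empty = CrosslinkSet("empty", [])
        comp = compare_complexes([empty], model, submap, [], AnalysisConfig())
        row = comp.table.iloc[0]
        assert row["n_total"] == 0 and row["n_mapped"] == 0

    def test_designed_fractions_within_binomial_ci(self, toy_complex):
        model, submap = toy_complex
        sets = []
        for f, seed in ((0.1, 21), (0.5, 22)):
            sim = simulate_crosslinks(
                model, submap, n=400, violation_fraction=f, seed=seed,
                complex_label=f"f{f}",
            )
            sets.append(sim.xset)
        comp = compare_complexes(sets, model, submap, [], AnalysisConfig())
        for f, (_, row) in zip((0.1, 0.5), comp.table.iterrows()):
            n = row["n_mapped"]
            half = 2.576 * np.sqrt(f * (1 - f) / n)
            assert abs(row["over_fraction"] - f) <= half + 1e-9

    def test_contrast_between_complexes(self, hinged_pair):
        """Links absent from one region block in one complex stay absent."""
        (closed_model, closed_map), (open_model, open_map) = hinged_pair
        regions = [
            RegionDef("bp_distal", "beta_prime", ((31, 60),)),
            RegionDef("b_all", "beta", ((1, 60),)),
        ]
        # complex A: links everywhere; complex B: only within beta
        sim_a = simulate_crosslinks(
            closed_model, closed_map, n=150, violation_fraction=0.0, seed=31,
            complex_label="A",
        )
        only_beta = [
            l for l in sim_a.xset.links if l.protein_a == "beta" and l.protein_b == "beta"
        ]
        set_b = CrosslinkSet("B", [
            Crosslink(l.protein_a, l.resnum_a, l.protein_b, l.resnum_b,
                      score=l.score, fdr=l.fdr, complex_label="B")
            for l in only_beta
        ])
        comp = compare_complexes(
            [sim_a.xset, set_b], closed_model, closed_map, regions, AnalysisConfig()
        )
        rc_b = comp.region_counts["B"]
        assert rc_b.count("bp_distal", "b_all") == 0
        rc_a = comp.region_counts["A"]
        assert rc_a.matrix.sum() > 0

    def test_no_sets_rejected(self, toy_complex):
        model, submap = toy_complex
        with pytest.raises(ValueError):
            compare_complexes([], model, submap, [], AnalysisConfig())


class TestAnalysisConfig:
    def test_invalid_limit(self):
        with pytest.raises(ValueError):
            AnalysisConfig(distance_limit=0)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            AnalysisConfig(null_mode="bogus")
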