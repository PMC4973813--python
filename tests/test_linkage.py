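import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fabmap.linkage import (
    PairwiseLinkage,
    build_map,
    estimate_rf,
    group_markers,
    haldane,
    kosambi,
    map_trait_locus,
    order_markers,
    pairwise_linkages,
    segregation_check,
    space_markers,
)
from fabmap.simulate import simulate_population


def f2_class_probs(r):
    """Closed-form 9-class F2 joint genotype probabilities (coupling)."""
    n, c = (1 - r) / 2, r / 2  # non-recombinant / recombinant gamete prob
    p = {}
    p[(0, 0)] = n * n
    p[(0, 1)] = 2 * n * c
    p[(0, 2)] = c * c
    p[(1, 0)] = 2 * n * c
    p[(1, 1)] = 2 * (n * n + c * c)
    p[(1, 2)] = 2 * n * c
    p[(2, 0)] = c * c
    p[(2, 1)] = 2 * n * c
    p[(2, 2)] = n * n
    return p


def grid_ml(counts9, step=1e-4):
    """Grid-search ML over r and both phase orientations (oracle)."""
    grid = np.arange(step, 0.5 + step / 2, step)
    best = (-math.inf, 0.5)
    for flip in (False, True):
        c = {
            (i, 2 - j if flip else j): v for (i, j), v in counts9.items()
        }
        for r in grid:
            p = f2_class_probs(r)
            ll = sum(
                n * math.log(p[k]) for k, n in c.items() if n > 0 and p[k] > 0
            )
            if all(p[k] > 0 for k, n in c.items() if n > 0) and ll > best[0]:
                best = (ll, r)
    return best[1]


def calls_from_counts(counts9):
    names = {0: "AA", 1: "AB", 2: "BB"}
    a, b = [], []
    for (i, j), n in counts9.items():
        a.extend([names[i]] * n)
        b.extend([names[j]] * n)
    return a, b


class TestEstimateRf:
    def test_zero_recombinants(self):
        a = ["AA"] * 15 + ["AB"] * 20 + ["BB"] * 15
        pl = estimate_rf(a, a)
        assert pl.r_hat < 1e-3
        assert pl.lod > 10

    def test_independent_markers_null(self):
        tm = {"c1": [("m1", 0.0)], "c2": [("m2", 0.0)]}
        gm = simulate_population(tm, "f2", 200, seed=5)
        pl = estimate_rf(list(gm.marker_calls("m1")), list(gm.marker_calls("m2")))
        assert pl.r_hat > 0.4
        assert pl.lod < 1.5

    def test_lod_zero_at_half(self):
        rng = np.random.default_rng(3)
        a = list(rng.choice(["AA", "AB", "BB"], p=[0.25, 0.5, 0.25], size=100))
        b = list(rng.choice(["AA", "AB", "BB"], p=[0.25, 0.5, 0.25], size=100))
        pl = estimate_rf(a, b)
        assert pl.lod >= 0

    def test_symmetric_in_arguments(self):
        tm = {"c1": [("m1", 0.0), ("m2", 15.0)]}
        gm = simulate_population(tm, "f2", 150, seed=8)
        a, b = list(gm.marker_calls("m1")), list(gm.marker_calls("m2"))
        assert estimate_rf(a, b).r_hat == pytest.approx(estimate_rf(b, a).r_hat, abs=1e-9)

    def test_too_few_individuals(self):
        with pytest.raises(ValueError, match="need >= 10"):
            estimate_rf(["AA"] * 5, ["AA"] * 5)

    def test_em_matches_grid_search(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            r_true = rng.uniform(0.02, 0.48)
            p = f2_class_probs(r_true)
            keys = list(p)
            draws = rng.multinomial(60, [p[k] for k in keys])
            counts = dict(zip(keys, draws))
            a, b = calls_from_counts(counts)
            r_em = estimate_rf(a, b).r_hat
            r_grid = grid_ml(counts)
            assert r_em == pytest.approx(r_grid, abs=1e-3)

    def test_inbred_design(self):
        tm = {"c1": [("m1", 0.0), ("m2", 10.0)]}
        gm = simulate_population(tm, "ril", 400, seed=11)
        pl = estimate_rf(list(gm.marker_calls("m1")), list(gm.marker_calls("m2")), "inbred")
        # RIL-by-selfing inflates the observed recombinant fraction;
        # the correction maps it back near the meiotic r
        assert pl.r_hat == pytest.approx(0.0906, abs=0.035)

    def test_dominant_pair_design(self):
        tm = {"c1": [("t", 0.0), ("m", 10.0)]}
        gm = simulate_population(tm, "f2", 400, seed=13)
        trait = ["D" if c in ("AB", "BB") else "R" for c in gm.marker_calls("t")]
        pl = estimate_rf(trait, list(gm.marker_calls("m")), "f2_dominant_pair")
        assert pl.r_hat == pytest.approx(0.0906, abs=0.05)


class TestGroupMarkers:
    def edge(self, a, b, lod=10.0, r=0.1):
        return PairwiseLinkage(a, b, r, lod, 100)

    def test_two_simulated_clusters(self):
        tm = {
            "c1": [(f"a{i}", i * 10.0) for i in range(5)],
            "c2": [(f"b{i}", i * 10.0) for i in range(5)],
        }
        gm = simulate_population(tm, "f2", 150, seed=21)
        calls = {m: list(gm.marker_calls(m)) for m in gm.markers}
        table = pairwise_linkages(calls)
        groups = group_markers(table.values(), markers=list(calls))
        assert len(groups) == 2
        assert {frozenset(g) for g in groups} == {
            frozenset(f"a{i}" for i in range(5)),
            frozenset(f"b{i}" for i in range(5)),
        }

    def test_lod_boundary_inclusive(self):
        groups = group_markers([self.edge("x", "y", lod=5.0)], min_lod=5.0)
        assert groups == [["x", "y"]]

    def test_below_boundary_excluded(self):
        groups = group_markers([self.edge("x", "y", lod=4.99)], min_lod=5.0)
        assert groups == [["x"], ["y"]]

    def test_max_r_excludes(self):
        groups = group_markers([self.edge("x", "y", r=0.35)], max_r=0.3)
        assert groups == [["x"], ["y"]]

    def test_all_unlinked_singletons(self):
        groups = group_markers([], markers=["a", "b", "c"])
        assert groups == [["a"], ["b"], ["c"]]


def linkages_from_matrix(markers, dist):
    out = []
    for i, a in enumerate(markers):
        for j in range(i + 1, len(markers)):
            out.append(PairwiseLinkage(a, markers[j], dist[i][j], 20.0, 100))
    return out


class TestOrderMarkers:
    def test_two_loci(self):
        links = linkages_from_matrix(["a", "b"], [[0, 0.1], [0.1, 0]])
        assert order_markers(["a", "b"], links) == [["a"], ["b"]]

    def test_cosegregating_binned(self):
        links = [
            PairwiseLinkage("a", "b", 0.0, 30.0, 100),
            PairwiseLinkage("a", "c", 0.1, 20.0, 100),
            PairwiseLinkage("b", "c", 0.1, 20.0, 100),
        ]
        ordered = order_markers(["a", "b", "c"], links)
        assert [sorted(b) for b in ordered] == [["a", "b"], ["c"]]

    def test_matches_bruteforce_sarf(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            k = int(rng.integers(3, 7))
            markers = [f"m{i}" for i in range(k)]
            d = np.round(rng.uniform(0.02, 0.45, size=(k, k)), 3)
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            links = linkages_from_matrix(markers, d)
            ordered = order_markers(markers, links)
            got = [b[0] for b in ordered]
            idx = {m: i for i, m in enumerate(markers)}

            def sarf_of(perm):
                return sum(d[idx[x], idx[y]] for x, y in zip(perm, perm[1:]))

            best = min(sarf_of(p) for p in itertools.permutations(markers))
            assert sarf_of(got) == pytest.approx(best, abs=1e-9)

    def test_true_order_recovered_from_simulation(self):
        tm = {"c1": [(f"m{i:02d}", i * 5.0) for i in range(8)]}
        gm = simulate_population(tm, "f2", 200, seed=41)
        calls = {m: list(gm.marker_calls(m)) for m in gm.markers}
        table = pairwise_linkages(calls)
        ordered = order_markers(list(calls), table.values())
        got = [b[0] for b in ordered]
        truth = [f"m{i:02d}" for i in range(8)]
        assert got == truth or got == truth[::-1]

    def test_orientation_normalised(self):
        links = linkages_from_matrix(
            ["z", "m", "a"], [[0, 0.1, 0.3], [0.1, 0, 0.1], [0.3, 0.1, 0]]
        )
        ordered = order_markers(["z", "m", "a"], links)
        assert ordered[0] == ["a"]


class TestSpaceMarkers:
    def test_zero_r_zero_cm(self):
        assert kosambi(0.0) == 0.0
        assert haldane(0.0) == 0.0

    def test_kosambi_closed_form(self):
        assert kosambi(0.2) == pytest.approx(21.18, abs=0.01)

    def test_haldane_closed_form(self):
        assert haldane(0.2) == pytest.approx(25.54, abs=0.01)

    def test_cumulative_positions(self):
        links = linkages_from_matrix(
            ["a", "b", "c"], [[0, 0.1, 0.2], [0.1, 0, 0.1], [0.2, 0.1, 0]]
        )
        lg = space_markers([["a"], ["b"], ["c"]], links, map_function="haldane")
        assert lg.loci[0].position == 0.0
        assert lg.loci[1].position == pytest.approx(haldane(0.1))
        assert lg.loci[2].position == pytest.approx(2 * haldane(0.1))

    @given(st.floats(0.001, 0.49))
    @settings(max_examples=100, deadline=None)
    def test_map_functions_increasing_and_agree_small_r(self, r):
        assert kosambi(r) > 0
        assert haldane(r) >= kosambi(r)
        if r < 0.01:
            assert abs(kosambi(r) - haldane(r)) / kosambi(r) < 0.01


class TestBuildMap:
    def test_full_pipeline_two_groups(self):
        tm = {
            "c1": [(f"a{i}", i * 8.0) for i in range(5)],
            "c2": [(f"b{i}", i * 8.0) for i in range(4)],
        }
        gm = simulate_population(tm, "f2", 180, seed=51)
        calls = {m: list(gm.marker_calls(m)) for m in gm.markers}
        gmap, _ = build_map(calls)
        assert len(gmap.groups) == 2
        assert not gmap.unplaced
        for lg in gmap.groups:
            positions = [l.position for l in lg.loci]
            assert positions == sorted(positions)
            assert positions[0] == 0.0


class TestTraitMapping:
    def test_three_to_one_check(self):
        passes = 0
        for seed in range(50):
            tm = {"c1": [("t", 0.0)]}
            gm = simulate_population(tm, "f2", 136, seed=seed)
            trait = ["D" if c in ("AB", "BB") else "R" for c in gm.marker_calls("t")]
            if segregation_check(trait) >= 0.05:
                passes += 1
        assert passes >= 47  # >= 94% of seeds

    def test_trait_flanked_by_true_neighbours(self):
        tm = {"c1": [(f"m{i:02d}", i * 6.0) for i in range(8)]}
        # plant the trait locus between m03 and m04
        full = {"c1": tm["c1"] + [("trait", 21.0)]}
        gm = simulate_population(full, "f2", 250, seed=61)
        trait = ["D" if c in ("AB", "BB") else "R" for c in gm.marker_calls("trait")]
        calls = {m: list(gm.marker_calls(m)) for m in gm.markers if m != "trait"}
        gmap, _ = build_map(calls)
        group, idx, (left, right) = map_trait_locus(trait, calls, gmap)
        assert {left, right} <= {"m03", "m04"}

    def test_trait_duplicating_marker(self):
        tm = {"c1": [(f"m{i}", i * 10.0) for i in range(4)]}
        gm = simulate_population(tm, "f2", 200, seed=71)
        trait = ["D" if c in ("AB", "BB") else "R" for c in gm.marker_calls("m2")]
        calls = {m: list(gm.marker_calls(m)) for m in gm.markers}
        gmap, _ = build_map(calls)
        group, idx, (left, right) = map_trait_locus(trait, calls, gmap)
        assert "m2" in (left, right)

    def test_monomorphic_trait_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            segregation_check(["D"] * 50)
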