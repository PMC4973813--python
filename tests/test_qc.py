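import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fabmap.qc import (
    GenotypeMatrix,
    allele_stats,
    classify_quality,
    concordance_audit,
    concordance_fraction,
    distance_and_upgma,
    distortion_filter,
    iterative_no_call_filter,
    line_heterozygosity,
)
from fabmap.simulate import simulate_fluorescence


def gm_from(rows, lines=None, markers=None):
    lines = lines or [f"L{i}" for i in range(len(rows))]
    markers = markers or [f"m{j}" for j in range(len(rows[0]))]
    return GenotypeMatrix(pd.DataFrame(rows, index=lines, columns=markers))


class TestGenotypeMatrix:
    def test_call_domain_enforced(self):
        with pytest.raises(ValueError, match="invalid"):
            gm_from([["AA", "XY"]])

    def test_csv_roundtrip(self, tmp_path):
        gm = gm_from([["AA", "AB"], ["BB", "NC"]])
        gm.to_csv(tmp_path / "g.csv")
        back = GenotypeMatrix.from_csv(tmp_path / "g.csv")
        assert back.calls.equals(gm.calls)


class TestClassifyQuality:
    def test_tight_clusters_class_one(self):
        pts = pd.DataFrame(
            {
                "x": [0.9, 0.91, 0.1, 0.11, 0.55, 0.56],
                "y": [0.1, 0.11, 0.9, 0.89, 0.55, 0.54],
                "call": ["AA", "AA", "BB", "BB", "AB", "AB"],
            }
        )
        assert classify_quality(pts).quality_class == "I"

    def test_merged_cloud_class_four(self):
        rng = np.random.default_rng(0)
        pts = pd.DataFrame(
            {
                "x": rng.normal(0.5, 0.3, 30),
                "y": rng.normal(0.5, 0.3, 30),
                "call": ["AA", "AB", "BB"] * 10,
            }
        )
        assert classify_quality(pts).quality_class in ("III", "IV")

    def test_single_class_is_iv(self):
        pts = pd.DataFrame({"x": [0.9] * 6, "y": [0.1] * 6, "call": ["AA"] * 6})
        assert classify_quality(pts).quality_class == "IV"

    def test_too_few_samples(self):
        pts = pd.DataFrame({"x": [0.9] * 5, "y": [0.1] * 5, "call": ["AA"] * 5})
        with pytest.raises(ValueError, match="6 samples"):
            classify_quality(pts)

    @pytest.mark.parametrize("archetype,expected", [("I", "I"), ("II", "II"), ("IV", "IV")])
    def test_archetype_closed_loop(self, archetype, expected):
        calls = ["AA"] * 10 + ["AB"] * 20 + ["BB"] * 10
        agree = sum(
            classify_quality(simulate_fluorescence(calls, archetype, seed=s)).quality_class
            == expected
            for s in range(100)
        )
        assert agree >= 90


class TestIterativeNoCallFilter:
    def test_complete_matrix_unchanged(self):
        gm = gm_from([["AA", "AB"], ["BB", "AA"]])
        out, log = iterative_no_call_filter(gm)
        assert out.calls.equals(gm.calls)
        assert log == []

    def test_bad_line_removed(self):
        rows = [["NC"] * 5 + ["AA"] * 15] + [["AA"] * 20 for _ in range(9)]
        gm = gm_from(rows)
        out, log = iterative_no_call_filter(gm)
        assert log == [("line", "L0", 0.25)]
        assert "L0" not in out.lines

    def test_marker_preferred_on_tie(self):
        # one marker and one line both at 50% NC
        gm = gm_from([["NC", "AA"], ["AA", "NC"]])
        # line L0: 50%, L1: 50%; markers m0: 50%, m1: 50% -> marker m0 first
        out, log = iterative_no_call_filter(gm, max_nc=0.4)
        assert log[0][0] == "marker"
        assert log[0][1] == "m0"

    def test_idempotent_and_clean(self):
        rng = np.random.default_rng(42)
        rows = rng.choice(["AA", "AB", "BB", "NC"], p=[0.4, 0.2, 0.3, 0.1], size=(20, 50))
        gm = gm_from(rows.tolist())
        out, _ = iterative_no_call_filter(gm)
        assert (out.nc_rate_by_line() <= 0.06).all()
        assert (out.nc_rate_by_marker() <= 0.06).all()
        again, log2 = iterative_no_call_filter(out)
        assert again.calls.equals(out.calls)
        assert log2 == []

    def test_exhausted_matrix_raises(self):
        gm = gm_from([["NC", "NC"], ["NC", "NC"]])
        with pytest.raises(ValueError, match="exhausted"):
            iterative_no_call_filter(gm)


class TestAlleleStats:
    def test_half_frequency(self):
        gm = gm_from([["AA"], ["BB"]])
        s = allele_stats(gm, "m0")
        assert s.p == 0.5
        assert s.gene_diversity == pytest.approx(0.5)
        assert s.pic == pytest.approx(0.375)

    def test_monomorphic(self):
        gm = gm_from([["AA"], ["AA"]])
        s = allele_stats(gm, "m0")
        assert s.gene_diversity == 0.0
        assert s.pic == 0.0

    def test_quarter_frequency(self):
        gm = gm_from([["AA"], ["BB"], ["BB"], ["BB"]])
        assert allele_stats(gm, "m0").gene_diversity == pytest.approx(0.375)

    def test_het_counts_one_of_each(self):
        gm = gm_from([["AB"], ["AB"]])
        assert allele_stats(gm, "m0").p == 0.5

    def test_all_nc_raises(self):
        gm = gm_from([["NC"], ["NC"]])
        with pytest.raises(ValueError, match="no called"):
            allele_stats(gm, "m0")

    def test_private_to_discovery_line(self):
        gm = gm_from([["BB"], ["AA"], ["AA"], ["AA"]], lines=["d1", "d2", "x", "y"])
        s = allele_stats(gm, "m0", discovery_lines=("d1", "d2"))
        assert s.private_to == "d1"

    def test_not_private_when_shared(self):
        gm = gm_from([["BB"], ["AA"], ["BB"], ["AA"]], lines=["d1", "d2", "x", "y"])
        s = allele_stats(gm, "m0", discovery_lines=("d1", "d2"))
        assert s.private_to is None

    @given(st.integers(1, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=50, deadline=None)
    def test_diversity_bounds_and_symmetry(self, n_aa, n_ab, n_bb):
        rows = [["AA"]] * n_aa + [["AB"]] * n_ab + [["BB"]] * n_bb
        gm = gm_from(rows)
        swapped = gm_from([["BB"]] * n_aa + [["AB"]] * n_ab + [["AA"]] * n_bb)
        s, t = allele_stats(gm, "m0"), allele_stats(swapped, "m0")
        assert 0 <= s.gene_diversity <= 0.5
        assert s.pic <= s.gene_diversity + 1e-12
        assert s.gene_diversity == pytest.approx(t.gene_diversity)


class TestLineHeterozygosity:
    def test_all_homozygous(self):
        gm = gm_from([["AA", "BB", "AA"]])
        het, hom = line_heterozygosity(gm, "L0")
        assert het == 0.0
        assert hom == 100.0

    def test_one_percent(self):
        gm = gm_from([["AB"] + ["AA"] * 99])
        het, _ = line_heterozygosity(gm, "L0")
        assert het == pytest.approx(1.0)

    def test_complementarity_random(self):
        rng = np.random.default_rng(9)
        rows = rng.choice(["AA", "AB", "BB", "NC"], size=(5, 40)).tolist()
        rows = [r if any(c != "NC" for c in r) else ["AA"] * 40 for r in rows]
        gm = gm_from(rows)
        for line in gm.lines:
            het, hom = line_heterozygosity(gm, line)
            assert het + hom == pytest.approx(100.0)

    def test_all_nc_raises(self):
        gm = gm_from([["NC", "NC"]])
        with pytest.raises(ValueError):
            line_heterozygosity(gm, "L0")


class TestConcordance:
    def test_all_match(self):
        gm = gm_from([["AA", "BB"], ["BB", "AA"]], lines=["d1", "d2"])
        predicted = {
            "m0": {"d1": "AA", "d2": "BB"},
            "m1": {"d1": "BB", "d2": "AA"},
        }
        _, summary, excluded = concordance_audit(gm, predicted)
        assert summary == 1.0
        assert excluded == []

    def test_printed_counts_fraction(self):
        assert concordance_fraction(512, 757) == pytest.approx(0.676, abs=5e-4)

    def test_nc_excluded_from_denominator(self):
        gm = gm_from([["NC", "AA"], ["BB", "BB"]], lines=["d1", "d2"])
        predicted = {"m0": {"d1": "AA", "d2": "BB"}, "m1": {"d1": "AA", "d2": "BB"}}
        flags, summary, excluded = concordance_audit(gm, predicted)
        assert excluded == ["m0"]
        assert list(flags) == ["m1"]

    def test_mismatch_detected(self):
        gm = gm_from([["BB"], ["BB"]], lines=["d1", "d2"])
        flags, summary, _ = concordance_audit(gm, {"m0": {"d1": "AA", "d2": "BB"}})
        assert flags == {"m0": False}
        assert summary == 0.0


class TestDistortionFilter:
    def test_ideal_f2_kept(self):
        calls = ["AA"] * 30 + ["AB"] * 60 + ["BB"] * 30
        v = distortion_filter(calls, "f2")
        assert v.ratio == pytest.approx(1.0)
        assert v.verdict == "keep"

    def test_f2_excess_homozygotes_removed(self):
        calls = ["AA"] * 35 + ["BB"] * 35 + ["AB"] * 30
        v = distortion_filter(calls, "f2")
        assert v.ratio == pytest.approx(70 / 30)
        assert v.verdict == "remove"
        assert v.reason == "skew"

    def test_missing_parental_allele_removed(self):
        calls = ["AA"] * 50 + ["AB"] * 50
        v = distortion_filter(calls, "f2")
        assert v.reason == "missing_parental_allele"

    def test_inbred_inside_bounds_kept(self):
        calls = ["AB"] * 9 + ["AA"] * 46 + ["BB"] * 45
        v = distortion_filter(calls, "inbred")
        assert v.ratio == pytest.approx(9 / 91)
        assert v.verdict == "keep"

    def test_inbred_excess_het_removed(self):
        calls = ["AB"] * 30 + ["AA"] * 35 + ["BB"] * 35
        assert distortion_filter(calls, "inbred").verdict == "remove"

    def test_zero_denominator_infinite_ratio(self):
        calls = ["AA"] * 50 + ["BB"] * 50  # no hets in f2
        v = distortion_filter(calls, "f2")
        assert v.ratio == float("inf")
        assert v.verdict == "remove"


class TestUpgma:
    def test_duplicate_lines_zero_distance(self):
        gm = gm_from([["AA", "AB", "BB"], ["AA", "AB", "BB"], ["BB", "AA", "AA"]])
        dist, newick = distance_and_upgma(gm)
        assert dist.iloc[0, 1] == 0.0
        assert "L0:0" in newick

    def test_hand_computed_three_lines(self):
        # engineered distances: d(A,B)=0.1, d(A,C)=0.4
        calls = {
            "A": ["AA"] * 10,
            "B": ["AA"] * 9 + ["BB"] * 1,
            "C": ["AA"] * 6 + ["BB"] * 4,
        }
        gm = GenotypeMatrix(pd.DataFrame(calls).T)
        dist, newick = distance_and_upgma(gm)
        assert dist.loc["A", "B"] == pytest.approx(0.1)
        assert dist.loc["A", "C"] == pytest.approx(0.4)
        # UPGMA joins (A,B) at height 0.05
        assert "(A:0.05,B:0.05)" in newick

    def test_ultrametric(self):
        rng = np.random.default_rng(13)
        rows = rng.choice(["AA", "AB", "BB"], size=(8, 60)).tolist()
        gm = gm_from(rows)
        _, newick = distance_and_upgma(gm)
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(newick), "newick")
        depths = tree.depths()
        leaf_depths = [d for cl, d in depths.items() if cl.is_terminal()]
        assert max(leaf_depths) - min(leaf_depths) < 1e-9

    def test_no_shared_markers_raises(self):
        gm = gm_from([["AA", "NC"], ["NC", "AA"]])
        with pytest.raises(ValueError, match="co-called"):
            distance_and_upgma(gm)
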