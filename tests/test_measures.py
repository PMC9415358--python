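"""Biodiversity measures: formula oracles and invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecotransfer import measures


def pie_by_enumeration(counts):
    """Brute-force PIE: enumerate all unordered pairs of individuals and
    count the fraction that are interspecific."""
    individuals = []
    for species, n in enumerate(counts):
        individuals.extend([species] * n)
    pairs = list(itertools.combinations(range(len(individuals)), 2))
    if not pairs:
        return 0.0
    inter = sum(individuals[i] != individuals[j] for i, j in pairs)
    return inter / len(pairs)


class TestPIE:
    @given(st.lists(st.integers(min_value=0, max_value=6), min_size=1,
                    max_size=5).filter(lambda c: 2 <= sum(c) <= 12))
    @settings(max_examples=200, deadline=None)
    def test_matches_pairwise_enumeration(self, counts):
        expected = pie_by_enumeration(counts)
        assert measures.hurlbert_pie(np.array(counts)) == pytest.approx(
            expected, abs=1e-12)

    def test_single_species_and_degenerate(self):
        assert measures.hurlbert_pie(np.array([5])) == 0.0
        assert measures.hurlbert_pie(np.array([1])) == 0.0
        assert measures.hurlbert_pie(np.array([])) == 0.0

    def test_two_even_species(self):
        # 4 individuals, C(4,2)=6 pairs, 4 interspecific -> 2/3
        assert measures.hurlbert_pie(np.array([2, 2])) == pytest.approx(2 / 3)


class TestGreatCircle:
    def test_analytic_distances(self):
        assert measures.great_circle_km(0, 0, 0, 0) == pytest.approx(0.0)
        assert measures.great_circle_km(0, 0, 0, 1) == pytest.approx(
            6371 * np.pi / 180, rel=1e-6)
        assert measures.great_circle_km(0, 0, 90, 0) == pytest.approx(
            6371 * np.pi / 2, rel=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            measures.great_circle_km(91, 0, 0, 0)
        with pytest.raises(ValueError):
            measures.great_circle_km(0, 181, 0, 0)

    @given(st.lists(st.tuples(st.floats(-90, 90), st.floats(-180, 180)),
                    min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_triangle_inequality(self, pts):
        (a, b, c) = pts
        dab = measures.great_circle_km(a[0], a[1], b[0], b[1])
        dba = measures.great_circle_km(b[0], b[1], a[0], a[1])
        dac = measures.great_circle_km(a[0], a[1], c[0], c[1])
        dcb = measures.great_circle_km(c[0], c[1], b[0], b[1])
        assert dab == pytest.approx(dba, abs=1e-9)
        assert dab <= dac + dcb + 1e-6


class TestSorensen:
    def test_overlap_counting(self):
        assert measures.sorensen({"A", "B", "C"}, {"A", "B", "C"}) == 1.0
        assert measures.sorensen({"A"}, {"B"}) == 0.0
        # a=1, b=1, c=1 -> 2/(2+1+1) = 0.5
        assert measures.sorensen({"A", "B"}, {"B", "C"}) == pytest.approx(0.5)

    @given(st.sets(st.integers(0, 8)), st.sets(st.integers(0, 8)))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, s1, s2):
        v = measures.sorensen(s1, s2)
        assert v == measures.sorensen(s2, s1)
        assert 0.0 <= v <= 1.0
        if s1 and s1 == s2:
            assert v == 1.0
        if s1 and s2 and not (s1 & s2):
            assert v == 0.0


class TestSiteMeasures:
    def test_known_assemblages(self, toy_tables):
        studies, sites, assemblage = toy_tables
        out = measures.site_measures(assemblage, assemblage, sites, studies)
        a1 = out.set_index("site_id").loc["A1"]
        # {sp1:10, sp2:10}: S=2, A=20, PIE=(20/19)(1-0.5)
        assert a1["S"] == 2
        assert a1["logA"] == pytest.approx(np.log10(21))
        assert a1["evenness"] == pytest.approx(
            np.arcsin(np.sqrt(20 / 19 * 0.5)))
        a2 = out.set_index("site_id").loc["A2"]
        assert a2["S"] == 1 and a2["evenness"] == 0.0
        # occurrence study: abundance/evenness invalid
        b1 = out.set_index("site_id").loc["B1"]
        assert not b1["valid_abundance"] and np.isnan(b1["logA"])

    def test_single_species_example(self):
        studies = pd.DataFrame({"study_id": ["A"], "is_abundance": [True]})
        sites = pd.DataFrame({"site_id": ["A1"], "study_id": ["A"]})
        asm = pd.DataFrame({"site_id": ["A1"], "taxon_id": ["spA"],
                            "measurement": [5.0]})
        out = measures.site_measures(asm, asm, sites, studies)
        assert out.loc[0, "S"] == 1
        assert out.loc[0, "logA"] == pytest.approx(np.log10(6))
        assert out.loc[0, "evenness"] == 0.0

    def test_empty_site_convention(self):
        studies = pd.DataFrame({"study_id": ["A"], "is_abundance": [True]})
        sites = pd.DataFrame({"site_id": ["A1"], "study_id": ["A"]})
        asm = pd.DataFrame(columns=["site_id", "taxon_id", "measurement"])
        out = measures.site_measures(asm, asm, sites, studies)
        assert out.loc[0, "S"] == 0
        assert out.loc[0, "logA"] == 0.0
        assert not out.loc[0, "valid_evenness"]

    def test_negative_measurement_rejected(self, toy_tables):
        studies, sites, assemblage = toy_tables
        bad = assemblage.copy()
        bad.loc[0, "measurement"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            measures.site_measures(bad, bad, sites, studies)


class TestEffortCorrection:
    def test_divide_by_rescaled_effort(self, toy_tables):
        studies, sites, assemblage = toy_tables
        out = measures.effort_correct(assemblage, sites, studies)
        # study A: efforts 1 and 2 -> rescaled 0.5, 1.0
        a1 = out[out["site_id"] == "A1"]["measurement"]
        a2 = out[out["site_id"] == "A2"]["measurement"]
        assert (a1 == 20.0).all()
        assert (a2 == 10.0).all()

    def test_occurrence_study_passthrough(self, toy_tables):
        studies, sites, assemblage = toy_tables
        out = measures.effort_correct(assemblage, sites, studies)
        b = out[out["site_id"].str.startswith("B")]["measurement"]
        assert (b == 1.0).all()

    def test_equal_effort_identity(self, toy_tables):
        studies, sites, assemblage = toy_tables
        sites = sites.copy()
        sites["sampling_effort"] = 2
        out = measures.effort_correct(assemblage, sites, studies)
        pd.testing.assert_frame_equal(out, assemblage)

    def test_nonpositive_effort_names_site(self, toy_tables):
        studies, sites, assemblage = toy_tables
        sites = sites.copy()
        sites.loc[0, "sampling_effort"] = 0
        with pytest.raises(ValueError, match="A1"):
            measures.effort_correct(assemblage, sites, studies)

    def test_richness_invariant_under_correction(self, toy_tables):
        studies, sites, assemblage = toy_tables
        out = measures.effort_correct(assemblage, sites, studies)
        before = measures.site_measures(assemblage, assemblage, sites, studies)
        after = measures.site_measures(out, assemblage, sites, studies)
        assert (before["S"] == after["S"]).all()


class TestFillExtents:
    def _studies(self):
        return pd.DataFrame({
            "study_id": ["A", "B", "C", "D"],
            "sampling_method": ["pc", "pc", "pc", "tr"],
            "taxon_group": ["birds", "birds", "birds", "fungi"],
        })

    def _sites(self, extents):
        return pd.DataFrame({
            "site_id": [f"s{i}" for i in range(4)],
            "study_id": ["A", "B", "C", "D"],
            "extent_m": extents,
        })

    def test_method_taxon_mean(self):
        out = measures.fill_missing_extents(
            self._sites([10.0, 30.0, np.nan, 7.0]), self._studies())
        assert out.loc[2, "extent_m"] == pytest.approx(20.0)
        assert out.loc[2, "extent_fill_level"] == "method+taxon"

    def test_no_missing_is_identity(self):
        out = measures.fill_missing_extents(
            self._sites([10.0, 30.0, 20.0, 7.0]), self._studies())
        assert (out["extent_fill_level"] == "observed").all()
        assert out["extent_m"].tolist() == [10.0, 30.0, 20.0, 7.0]

    def test_global_fallback(self):
        studies = self._studies()
        studies.loc[3, ["sampling_method", "taxon_group"]] = ["xx", "yy"]
        out = measures.fill_missing_extents(
            self._sites([10.0, 30.0, 20.0, np.nan]), studies)
        assert out.loc[3, "extent_m"] == pytest.approx(20.0)
        assert out.loc[3, "extent_fill_level"] == "global"

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="nothing to average"):
            measures.fill_missing_extents(
                self._sites([np.nan] * 4), self._studies())


class TestPairwiseComposition:
    def test_identity_disjoint_and_partial(self):
        studies = pd.DataFrame({"study_id": ["A"], "is_abundance": [True]})
        sites = pd.DataFrame({
            "site_id": ["s1", "s2", "s3"], "study_id": ["A"] * 3,
            "lat": [0.0, 0.0, 0.0], "lon": [0.0, 0.0, 0.0]})
        asm = pd.DataFrame({
            "site_id": ["s1", "s1", "s2", "s2", "s3"],
            "taxon_id": ["A", "B", "B", "C", "Z"],
            "measurement": [1.0] * 5})
        out = measures.pairwise_composition(asm, sites).set_index(
            ["site_i", "site_j"])
        # {A,B} vs {B,C}: 0.5 -> logit 0; co-located -> log10(0.05)
        p12 = out.loc[("s1", "s2")]
        assert p12["sim_logit"] == pytest.approx(0.0, abs=1e-12)
        assert p12["log_dist"] == pytest.approx(np.log10(0.05))
        # disjoint -> clamped at 0.001
        p13 = out.loc[("s1", "s3")]
        assert p13["sim_logit"] == pytest.approx(np.log(0.001 / 0.999))

    def test_identical_pair_clamped(self):
        studies = pd.DataFrame({"study_id": ["A"], "is_abundance": [True]})
        sites = pd.DataFrame({
            "site_id": ["s1", "s2"], "study_id": ["A"] * 2,
            "lat": [0.0, 1.0], "lon": [0.0, 0.0]})
        asm = pd.DataFrame({
            "site_id": ["s1"] * 3 + ["s2"] * 3,
            "taxon_id": ["A", "B", "C"] * 2,
            "measurement": [1.0] * 6})
        out = measures.pairwise_composition(asm, sites)
        assert out.loc[0, "sim_logit"] == pytest.approx(np.log(0.999 / 0.001))

    def test_single_site_study_yields_empty_table(self):
        sites = pd.DataFrame({"site_id": ["s1"], "study_id": ["A"],
                              "lat": [0.0], "lon": [0.0]})
        asm = pd.DataFrame({"site_id": ["s1"], "taxon_id": ["A"],
                            "measurement": [1.0]})
        assert len(measures.pairwise_composition(asm, sites)) == 0
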