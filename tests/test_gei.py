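"""GEI scan, slope mapping, three-way classification and AP-degree statistics."""

import numpy as np
import pandas as pd
import pytest

from apmap import gei, synthio, tradeoff
from apmap.gei import (
    GEILocusRecord,
    classify_gei_locus,
    gei_scan,
    map_gei_pair,
    mapping_degree_of_antagonism,
    reaction_norm,
    significant_gei_loci,
    slope_gei_overlap,
    slope_phenotype,
    slope_scan,
    t_test_alpha,
)
from apmap.io_formats import PhenotypeMatrix
from apmap.qtl import QTLPeak
from apmap.synthio import QTLSpec, TruthTable, simulate_phenotypes


@pytest.fixture(scope="module")
def planted(cross_1000):
    """One strong locus of each class, standardized phenotypes."""
    qtls = (
        QTLSpec("chr01_m010", {"E1": 0.5, "E2": 0.0}, "env_specific"),
        QTLSpec("chr02_m010", {"E1": 1.0, "E2": 0.5}, "scale"),
        QTLSpec("chr03_m010", {"E1": 0.5, "E2": -0.5}, "antagonistic"),
    )
    ph, truth = simulate_phenotypes(
        cross_1000, TruthTable(qtls, (), 1.0, seed=21), ["E1", "E2"]
    )
    return cross_1000, tradeoff.standardize_columns(ph), truth


def zpair(vals1, vals2, ids=None):
    df = pd.DataFrame({"E1": vals1, "E2": vals2})
    if ids is not None:
        df.index = ids
    m = PhenotypeMatrix(df)
    m.standardized = True
    return m


class TestThresholdDerivation:
    def test_bonferroni_family_of_ten(self):
        assert t_test_alpha(0.05, 10) == 0.005

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            t_test_alpha(0.0, 10)


class TestSlope:
    def test_identical_environments_zero(self):
        z = zpair([0.3, -0.2, 1.1], [0.3, -0.2, 1.1])
        assert (slope_phenotype(z, ("E1", "E2")).values == 0).all()

    def test_definition(self):
        z = zpair([0.5], [-0.5])
        assert slope_phenotype(z, ("E1", "E2")).values.iloc[0] == pytest.approx(-1.0)

    def test_antisymmetry(self):
        z = zpair([0.5, -1.0], [0.25, 0.75])
        fwd = slope_phenotype(z, ("E1", "E2")).values
        rev = slope_phenotype(z, ("E2", "E1")).values
        np.testing.assert_allclose(fwd, -rev)

    def test_missing_entities_dropped_and_counted(self):
        z = zpair([0.5, np.nan, 1.0], [0.25, 0.5, np.nan])
        sl = slope_phenotype(z, ("E1", "E2"))
        assert len(sl.values) == 1 and sl.n_dropped == 2

    def test_requires_standardized(self):
        with pytest.raises(ValueError, match="standardized"):
            slope_phenotype(PhenotypeMatrix(pd.DataFrame({"E1": [1.0], "E2": [2.0]})), ("E1", "E2"))


class TestGeiScan:
    def test_identical_phenotypes_zero_lod(self, cross_1000):
        rng = np.random.default_rng(22)
        y = rng.normal(size=1000)
        z = zpair(y, y, ids=cross_1000.segregant_ids)
        z.values[:] = (z.values - z.values.mean()) / z.values.std(ddof=1)
        scan = gei_scan(cross_1000, z, ("E1", "E2"), 100, 23)
        np.testing.assert_allclose(scan["lod"], 0.0, atol=1e-8)

    def test_environment_order_symmetry(self, planted):
        g, z, _ = planted
        a = gei_scan(g, z, ("E1", "E2"), 100, 24)
        b = gei_scan(g, z, ("E2", "E1"), 100, 24)
        np.testing.assert_allclose(a["lod"], b["lod"], atol=1e-9)

    def test_antagonistic_locus_detected(self, planted):
        g, z, _ = planted
        scan = gei_scan(g, z, ("E1", "E2"), 100, 25)
        assert scan.loc["chr03_m010", "p"] < 0.1
        assert scan.loc["chr03_m010", "lod"] == scan["lod"].max()


class TestSlopeScan:
    def test_antagonistic_slope_lod_exceeds_single_env(self, planted):
        from apmap.qtl import lod_scan

        g, z, _ = planted
        sl = slope_phenotype(z, ("E1", "E2"))
        s_scan, _ = slope_scan(g, sl, 100, 26)
        m = "chr03_m010"
        lod_e1 = lod_scan(g, z.values["E1"]).loc[m, "lod"]
        lod_e2 = lod_scan(g, z.values["E2"]).loc[m, "lod"]
        assert s_scan.loc[m, "lod"] > max(lod_e1, lod_e2)

    def test_equal_effect_locus_cancels_in_slope(self, cross_1000):
        qtls = (QTLSpec("chr04_m010", {"E1": 1.0, "E2": 1.0}),)
        ph, _ = simulate_phenotypes(cross_1000, TruthTable(qtls, (), 1.0, 27), ["E1", "E2"])
        z = tradeoff.standardize_columns(ph)
        sl = slope_phenotype(z, ("E1", "E2"))
        s_scan, _ = slope_scan(cross_1000, sl, 100, 28)
        assert s_scan.loc["chr04_m010", "p"] > 0.1


class TestJointFilter:
    @pytest.mark.parametrize(
        "p_gei, p_slope, kept",
        [(0.05, 0.01, True), (0.2, 0.01, False), (0.05, 0.06, False), (0.1, 0.05, False)],
    )
    def test_threshold_rules(self, p_gei, p_slope, kept):
        idx = ["m1"]
        gdf = pd.DataFrame({"p": [p_gei]}, index=idx)
        sdf = pd.DataFrame({"p": [p_slope]}, index=idx)
        assert (significant_gei_loci(gdf, sdf) == ["m1"]) == kept

    def test_mismatched_markers_rejected(self):
        gdf = pd.DataFrame({"p": [0.01]}, index=["m1"])
        sdf = pd.DataFrame({"p": [0.01]}, index=["m2"])
        with pytest.raises(ValueError, match="different markers"):
            significant_gei_loci(gdf, sdf)


class TestClassification:
    def test_planted_classes_recovered(self, planted):
        g, z, truth = planted
        for q in truth.qtls:
            rec = classify_gei_locus(g, z, ("E1", "E2"), q.marker_id)
            assert rec.gei_class == q.gei_class

    def test_allele_relabel_invariance(self, planted):
        g, z, truth = planted
        flipped = synthio.GenotypeMatrix(1.0 - g.calls, g.markers)
        for q in truth.qtls:
            a = classify_gei_locus(g, z, ("E1", "E2"), q.marker_id)
            b = classify_gei_locus(flipped, z, ("E1", "E2"), q.marker_id)
            assert a.gei_class == b.gei_class
            assert a.mean_by_e1 == pytest.approx(b.mean_rm_e1)

    def test_antagonistic_implies_crossing_norms(self, planted):
        g, z, truth = planted
        for q in truth.qtls:
            rn = reaction_norm(g, z, ("E1", "E2"), q.marker_id)
            assert rn.crossing == (q.gei_class == "antagonistic")

    def test_small_allele_class_rejected(self):
        mm = synthio.grid_marker_map(1, 1)
        calls = pd.DataFrame(
            {"chr01_m000": [0.0] * 11 + [1.0]}, index=[f"s{i}" for i in range(12)]
        )
        g = synthio.GenotypeMatrix(calls, mm)
        z = zpair(np.random.default_rng(0).normal(size=12),
                  np.random.default_rng(1).normal(size=12), ids=calls.index)
        with pytest.raises(ValueError, match="< 2 entities"):
            classify_gei_locus(g, z, ("E1", "E2"), "chr01_m000")


class TestPipeline:
    def test_classes_recovered_end_to_end(self, planted):
        g, z, truth = planted
        recs = map_gei_pair(g, z, ("E1", "E2"), 100, 29)
        by_marker = {r.marker_id: r for r in recs}
        for q in truth.qtls:
            rec = by_marker[q.marker_id]
            assert rec.gei_class == q.gei_class
            assert rec.p_gei < 0.1 and rec.p_slope < 0.05


def make_record(marker, chrom, pos, cls, pair=("E1", "E2")):
    return GEILocusRecord(
        marker, chrom, pos, pair[0], pair[1], 0.01, 0.01, 0.001, 0.001,
        0, 0, 0, 0, 0, 0, 0, 0, cls,
    )


class TestMappingDegree:
    def test_definition_arithmetic(self):
        recs = [make_record(f"s{i}", "c1", 1_000_000 * (i + 1), "scale") for i in range(10)]
        # crossovers from another pair near the first five scale loci
        recs += [
            make_record(f"a{i}", "c1", 1_000_000 * (i + 1) + 50_000, "antagonistic", ("E1", "E3"))
            for i in range(5)
        ]
        assert mapping_degree_of_antagonism(recs) == pytest.approx(50.0)

    def test_no_antagonistic_loci(self):
        recs = [make_record("s1", "c1", 100, "scale")]
        assert mapping_degree_of_antagonism(recs) == 0.0

    def test_zero_distance_counts(self):
        recs = [
            make_record("s1", "c1", 100, "env_specific"),
            make_record("a1", "c1", 100, "antagonistic", ("E1", "E3")),
        ]
        assert mapping_degree_of_antagonism(recs) == pytest.approx(100.0)

    def test_same_pair_crossover_ignored(self):
        recs = [
            make_record("s1", "c1", 100, "scale"),
            make_record("a1", "c1", 200, "antagonistic"),  # same pair
        ]
        assert mapping_degree_of_antagonism(recs) == 0.0


class TestOverlap:
    def peak(self, marker, chrom, pos):
        return QTLPeak(marker, chrom, pos, 5.0, 0.01, "E1")

    def test_identical_lists(self):
        peaks = [self.peak("m1", "c1", 100), self.peak("m2", "c2", 5_000)]
        assert slope_gei_overlap(peaks, peaks) == (100.0, 100.0)

    def test_disjoint_chromosomes(self):
        a = [self.peak("m1", "c1", 100)]
        b = [self.peak("m2", "c2", 100)]
        assert slope_gei_overlap(a, b) == (0.0, 0.0)

    def test_window_boundary_inclusive(self):
        a = [self.peak("m1", "c1", 100)]
        b = [self.peak("m2", "c1", 60_100)]
        assert slope_gei_overlap(a, b) == (100.0, 100.0)
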