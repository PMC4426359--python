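"""Two-locus interaction scan, crossover flags, Fisher's exact test."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from apmap import gei, synthio, tradeoff
from apmap.epistasis import (
    COMBOS,
    ContingencyTable,
    TwoLocusRecord,
    collate_candidate_markers,
    fisher_exact,
    genotype_class_means,
    resolution_flags,
    resolution_test,
    two_locus_interaction_scan,
)
from apmap.synthio import EpistasisSpec, TruthTable, simulate_phenotypes


def fisher_enumeration_oracle(a, b, c, d, side="two_sided"):
    """Exact-rational hypergeometric enumeration, independent of the package."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    pmf = {x: Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom) for x in range(lo, hi + 1)}
    if side == "greater":
        return float(sum(p for x, p in pmf.items() if x >= a))
    if side == "less":
        return float(sum(p for x, p in pmf.items() if x <= a))
    pobs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= pobs))


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact(ContingencyTable(((5, 5), (5, 5)))) == pytest.approx(1.0)

    def test_crossover_resolution_table(self):
        # 18/25 mixed-combination crossovers vs 9/25 parental crossovers
        t = ContingencyTable(((18, 7), (9, 16)))
        assert fisher_exact(t) == pytest.approx(0.022241295691722483, abs=1e-12)
        assert fisher_exact(t, "greater") == pytest.approx(0.011120647845861241, abs=1e-12)

    def test_perfect_association_closed_form(self):
        t = ContingencyTable(((10, 0), (0, 10)))
        assert fisher_exact(t) == pytest.approx(2 / comb(20, 10), abs=1e-15)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 16, size=4)
        t = ContingencyTable(((int(a), int(b)), (int(c), int(d))))
        for side in ("two_sided", "greater", "less"):
            assert fisher_exact(t, side) == pytest.approx(
                fisher_enumeration_oracle(a, b, c, d, side), abs=1e-12
            )

    def test_matches_scipy_cross_check(self):
        from scipy.stats import fisher_exact as scipy_fisher

        for tbl in [((18, 7), (9, 16)), ((3, 12), (7, 2)), ((0, 5), (5, 0))]:
            t = ContingencyTable(tbl)
            assert fisher_exact(t) == pytest.approx(
                scipy_fisher(np.array(tbl)).pvalue, rel=1e-9
            )

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ContingencyTable(((1, -1), (0, 2)))


class TestCollation:
    def test_p_below_one_included(self, grid_map):
        p = pd.Series(1.0, index=grid_map.marker_ids)
        p.iloc[0] = 0.9
        cands = collate_candidate_markers({"E1": p}, [], grid_map)
        assert cands == [grid_map.marker_ids[0]]

    def test_nearby_candidates_collapse_to_best(self, grid_map):
        p = pd.Series(1.0, index=grid_map.marker_ids)
        p.iloc[0] = 0.5  # chr01_m000, pos 1
        p.iloc[3] = 0.1  # chr01_m003, pos 30001 -> within 60 kb, better p
        cands = collate_candidate_markers({"E1": p}, [], grid_map)
        assert cands == ["chr01_m003"]

    def test_empty_inputs(self, grid_map):
        assert collate_candidate_markers({}, [], grid_map) == []


@pytest.fixture(scope="module")
def compensatory(cross_1000, grid_map):
    truth = synthio.compensatory_pair_truth(grid_map, ["E1", "E2"], n_pairs=5, seed=31)
    ph, _ = simulate_phenotypes(cross_1000, truth, ["E1", "E2"])
    z = tradeoff.standardize_columns(ph)
    return cross_1000, z, truth


class TestInteractionScan:
    def test_planted_interaction_detected_single_pair(self, cross_1000):
        # direct slope-scale interaction: power example at 0.5 SD, n = 1000
        # (analytic power ~0.97 at the permutation threshold)
        n_hit = 0
        reps = 20
        for rep in range(reps):
            g1 = cross_1000.calls["chr01_m010"].to_numpy()
            g2 = cross_1000.calls["chr02_m010"].to_numpy()
            rng = np.random.default_rng(40 + rep)
            slope_vals = 0.5 * g1 * g2 + rng.normal(size=1000)
            sl = gei.SlopeVector(
                pd.Series(slope_vals, index=cross_1000.segregant_ids), "E1", "E2"
            )
            recs = two_locus_interaction_scan(
                cross_1000, sl, ["chr01_m010", "chr02_m010"], 100, 50 + rep
            )
            if recs[0].interaction_p < 0.05:
                n_hit += 1
        assert n_hit >= 0.9 * reps

    def test_additive_only_null_rate(self, cross_1000):
        # additive main effects alone must not trigger the interaction test
        # (nominal rate 0.05; bound leaves binomial slack at 20 replicates)
        n_sig = 0
        reps = 20
        for rep in range(reps):
            g1 = cross_1000.calls["chr01_m010"].to_numpy()
            g2 = cross_1000.calls["chr02_m010"].to_numpy()
            rng = np.random.default_rng(60 + rep)
            slope_vals = 0.5 * g1 + 0.5 * g2 + rng.normal(size=1000)
            sl = gei.SlopeVector(
                pd.Series(slope_vals, index=cross_1000.segregant_ids), "E1", "E2"
            )
            recs = two_locus_interaction_scan(
                cross_1000, sl, ["chr01_m010", "chr02_m010"], 100, 70 + rep
            )
            if recs[0].interaction_p < 0.05:
                n_sig += 1
        assert n_sig <= 4

    def test_marker_order_symmetry(self, compensatory):
        g, z, truth = compensatory
        sl = gei.slope_phenotype(z, ("E1", "E2"))
        pair = truth.epistasis[0]
        a = two_locus_interaction_scan(g, sl, [pair.marker_a, pair.marker_b], 100, 80)
        b = two_locus_interaction_scan(g, sl, [pair.marker_b, pair.marker_a], 100, 80)
        assert a[0].interaction_lod == pytest.approx(b[0].interaction_lod, abs=1e-9)

    def test_linked_pairs_excluded(self, cross_1000):
        sl = gei.SlopeVector(
            pd.Series(np.zeros(1000) + np.arange(1000) * 1e-3, index=cross_1000.segregant_ids),
            "E1", "E2",
        )
        recs = two_locus_interaction_scan(
            cross_1000, sl, ["chr01_m000", "chr01_m003", "chr02_m000"], 100, 81
        )
        tested = {(r.marker_a, r.marker_b) for r in recs}
        assert ("chr01_m000", "chr01_m003") not in tested


class TestClassMeans:
    def test_counts_and_marginal_consistency(self, compensatory):
        g, z, truth = compensatory
        pair = truth.epistasis[0]
        cm = genotype_class_means(g, z, ("E1", "E2"), (pair.marker_a, pair.marker_b))
        assert cm[("E1", "n")].sum() == 1000
        # marginalizing over marker 2 reproduces the single-locus reaction norm
        rn = gei.reaction_norm(g, z, ("E1", "E2"), pair.marker_a)
        w = cm[("E1", "n")]
        by_mean = (cm.loc["BB", ("E1", "mean")] * w["BB"] + cm.loc["BR", ("E1", "mean")] * w["BR"]) / (
            w["BB"] + w["BR"]
        )
        assert by_mean == pytest.approx(rn.mean_by_e1, abs=1e-9)

    def test_planted_means_recovered(self, cross_1000, grid_map):
        spec = EpistasisSpec("chr01_m010", "chr02_m010", {"E1": 0.0, "E2": 1.0})
        truth = TruthTable((), (spec,), 0.5, seed=32)
        ph, _ = simulate_phenotypes(cross_1000, truth, ["E1", "E2"])
        cm = genotype_class_means(cross_1000, ph, ("E1", "E2"), ("chr01_m010", "chr02_m010"))
        # only the RR class has the interaction mean in E2
        assert cm.loc["RR", ("E2", "mean")] == pytest.approx(1.0, abs=2 * cm.loc["RR", ("E2", "se")] + 0.01)
        assert abs(cm.loc["BR", ("E2", "mean")]) < 3 * cm.loc["BR", ("E2", "se")] + 0.01


def constructed_record(means_e1, means_e2):
    cm = pd.DataFrame(
        {("E1", "mean"): means_e1, ("E2", "mean"): means_e2,
         ("E1", "se"): [0.01] * 4, ("E2", "se"): [0.01] * 4,
         ("E1", "n"): [25] * 4, ("E2", "n"): [25] * 4},
        index=list(COMBOS),
    )
    cm.columns = pd.MultiIndex.from_tuples(cm.columns)
    return TwoLocusRecord("a", "b", "E1", "E2", 0.01, 3.0, {}, cm)


class TestResolutionFlags:
    def test_mixed_crossover_parental_parallel(self):
        # BB/RR keep their order; BR and RB contrasts flip between envs
        rec = constructed_record([0.0, -0.5, 0.5, 1.0], [1.0, 1.5, 0.5, 2.0])
        het, par = resolution_flags(rec)
        assert het and not par

    def test_all_parallel(self):
        rec = constructed_record([0.0, 0.2, 0.4, 0.6], [1.0, 1.2, 1.4, 1.6])
        assert resolution_flags(rec) == (False, False)

    def test_parental_order_flip(self):
        rec = constructed_record([0.0, 0.1, 0.2, 1.0], [1.0, 0.6, 0.7, 0.5])
        _, par = resolution_flags(rec)
        assert par

    def test_flags_pure_function_of_means(self, compensatory):
        g, z, truth = compensatory
        sl = gei.slope_phenotype(z, ("E1", "E2"))
        pair = truth.epistasis[0]
        recs = two_locus_interaction_scan(
            g, sl, [pair.marker_a, pair.marker_b], 100, 83, phenotypes=z
        )
        f1 = resolution_flags(recs[0])
        cm = genotype_class_means(g, z, ("E1", "E2"), (pair.marker_a, pair.marker_b))
        rec2 = TwoLocusRecord(pair.marker_a, pair.marker_b, "E1", "E2", 1.0, 0.0, {}, cm)
        assert resolution_flags(rec2) == f1


class TestResolutionTest:
    def test_all_mixed_crossovers(self):
        recs = [constructed_record([0.0, -0.5, 0.5, 1.0], [1.0, 1.5, 0.5, 2.0]) for _ in range(6)]
        table, p = resolution_test(recs)
        assert table.counts == ((6, 0), (0, 6))
        assert p == pytest.approx(fisher_enumeration_oracle(6, 0, 0, 6), abs=1e-12)

    def test_no_crossovers_p_one(self):
        recs = [constructed_record([0.0, 0.2, 0.4, 0.6], [1.0, 1.2, 1.4, 1.6]) for _ in range(5)]
        table, p = resolution_test(recs)
        assert table.counts == ((0, 5), (0, 5)) and p == pytest.approx(1.0)

    def test_compensatory_scenario_asymmetry(self, compensatory):
        g, z, truth = compensatory
        recs = []
        for pair in truth.epistasis:
            cm = genotype_class_means(g, z, ("E1", "E2"), (pair.marker_a, pair.marker_b))
            recs.append(TwoLocusRecord(pair.marker_a, pair.marker_b, "E1", "E2", 1.0, 0.0, {}, cm))
        table, p = resolution_test(recs)
        het, par = table.counts[0][0], table.counts[1][0]
        assert het > par
        assert p == pytest.approx(
            fisher_enumeration_oracle(het, len(recs) - het, par, len(recs) - par), abs=1e-12
        )
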