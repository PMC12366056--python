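"""Haplotype calling, subtype assignment, cross-layer enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

import cadomics as cd
from cadomics.cluster import ClusterSolution
from cadomics.integrate import HAPLOTYPE_PANEL, classify_panel_genotypes, pearson_chi_square
from cadomics.io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix


def _panel_matrix(rows: list[list[int]]):
    df = pd.DataFrame(rows, columns=list(HAPLOTYPE_PANEL), dtype=np.int8)
    df.index = pd.Index([f"s{i}" for i in range(len(rows))])
    snps = pd.DataFrame(
        {"chrom": "5", "pos": range(100, 100 + 5), "ref": "A", "alt": "G"},
        index=df.columns,
    )
    return GenotypeMatrix(df, snps)


def _solution(labels: pd.Series, k: int) -> ClusterSolution:
    return ClusterSolution(
        k=k, assignments=labels, centroids=np.zeros((k, 1)), inertia=0.0,
        silhouette_mean=0.0, silhouette=pd.Series(0.0, index=labels.index),
    )


class TestHaplotypeRules:
    def test_all_hom_alt_is_haplotype3(self):
        g = _panel_matrix([[HOM_ALT] * 5])
        assert cd.call_haplotypes(g).haplotype.iloc[0] == 3

    def test_haplotype2_pattern(self):
        """Hom-ref at the four SNPs plus hom-alt at rs36993."""
        row = [HOM_REF] * 5
        row[list(HAPLOTYPE_PANEL).index("rs36993")] = HOM_ALT
        g = _panel_matrix([row])
        assert cd.call_haplotypes(g).haplotype.iloc[0] == 2

    def test_exhaustive_243_combinations(self):
        """All 3^5 complete genotype combinations: exactly one hap2, one hap3."""
        combos = list(itertools.product([HOM_REF, HET, HOM_ALT], repeat=5))
        g = _panel_matrix([list(c) for c in combos])
        calls = cd.call_haplotypes(g).haplotype
        counts = calls.value_counts().to_dict()
        assert counts == {1: 241, 2: 1, 3: 1}
        # the vectorized caller agrees with the scalar rule on every combination
        for row, hap in zip(combos, calls):
            assert classify_panel_genotypes(np.array(row, dtype=np.int8),
                                            HAPLOTYPE_PANEL) == hap

    def test_missing_call_defaults_to_wild_type_with_flag(self):
        row = [HOM_ALT] * 5
        row[2] = MISSING
        g = _panel_matrix([row])
        res = cd.call_haplotypes(g)
        assert res.haplotype.iloc[0] == 1
        assert bool(res.missing_flag.iloc[0])

    def test_absent_panel_snp_rejected(self, small_cohort):
        g = small_cohort.genotypes
        trimmed = g.subset([c for c in g.calls.columns if c != "rs36993"])
        with pytest.raises(ValueError, match="rs36993"):
            cd.call_haplotypes(trimmed)


class TestSubtypes:
    def _pair(self, n=60):
        idx = pd.Index([f"s{i}" for i in range(n)])
        rng = np.random.default_rng(0)
        met = pd.Series(rng.integers(1, 6, n), index=idx)
        gen = pd.Series(rng.integers(1, 6, n), index=idx)
        return _solution(met, 5), _solution(gen, 5)

    def test_rule_assignment_and_partition(self):
        met, gen = self._pair()
        rules = {"Subtype-I": (2, (4, 5)), "Subtype-II": (4, (2, 3))}
        sub = cd.assign_subtypes(met, gen, rules)
        t = sub.table
        in_one = (t["metabolomic_cluster"] == 2) & t["genetic_cluster"].isin((4, 5))
        assert (t.loc[in_one, "subtype"] == "Subtype-I").all()
        assert (t.loc[~in_one & (t["subtype"] == "Subtype-I")]).empty
        counts = sub.counts()
        assert counts.sum() == len(t)  # subtype labels partition the cohort

    def test_unmatched_pair_stays_unassigned(self):
        met, gen = self._pair()
        rules = {"Subtype-I": (2, (4,))}
        sub = cd.assign_subtypes(met, gen, rules)
        t = sub.table
        row = t[(t["metabolomic_cluster"] == 2) & (t["genetic_cluster"] == 1)]
        assert (row["subtype"] == "unassigned").all()

    def test_overlapping_rules_rejected(self):
        met, gen = self._pair()
        rules = {"Subtype-I": (2, (4,)), "Subtype-II": (2, (4, 5))}
        with pytest.raises(ValueError, match="overlap"):
            cd.assign_subtypes(met, gen, rules)


class TestEnrichment:
    def test_hand_computed_2x2_collapse(self):
        """Counts 60/40 vs 40/60 → chi-square 8.0, p 0.00468."""
        idx = pd.Index([f"s{i}" for i in range(200)])
        a = pd.Series([1] * 100 + [2] * 100, index=idx)
        b = pd.Series([1] * 60 + [2] * 40 + [1] * 40 + [2] * 60, index=idx)
        res = cd.crosstab_enrichment(_solution(a, 2), _solution(b, 2))
        row = res.pair_tests.query("cluster_a == 1 and clusters_b == '1'").iloc[0]
        assert row["chi2"] == pytest.approx(8.0, abs=1e-10)
        assert row["p"] == pytest.approx(0.004678, rel=1e-3)

    def test_identical_partitions_strongly_associated(self):
        rng = np.random.default_rng(1)
        idx = pd.Index([f"s{i}" for i in range(500)])
        lab = pd.Series(rng.integers(1, 6, 500), index=idx)
        relabel = lab.map({1: 3, 2: 5, 3: 1, 4: 2, 5: 4})
        res = cd.crosstab_enrichment(_solution(lab, 5), _solution(relabel, 5))
        matched = res.pair_tests.loc[res.pair_tests["n11"] > 0]
        diag = matched.loc[matched.groupby("cluster_a")["n11"].idxmax()]
        assert (diag["p"] < 1e-10).all()

    def test_independent_partitions_not_significant(self):
        ok = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            idx = pd.Index([f"s{i}" for i in range(500)])
            a = pd.Series(rng.integers(1, 6, 500), index=idx)
            b = pd.Series(rng.integers(1, 6, 500), index=idx)
            res = cd.crosstab_enrichment(_solution(a, 5), _solution(b, 5))
            ok += res.pair_tests["p"].min() > 1e-4
        assert ok >= 4

    @pytest.mark.parametrize("shape", [(2, 2), (3, 4), (5, 5), (6, 6)])
    def test_full_table_chi2_matches_independent_formula(self, shape):
        rng = np.random.default_rng(shape[0] * 10 + shape[1])
        table = rng.integers(1, 40, size=shape)
        chi2, p, df = pearson_chi_square(table)
        n = table.sum()
        ref = 0.0
        for i in range(shape[0]):
            for j in range(shape[1]):
                e = table[i].sum() * table[:, j].sum() / n
                ref += (table[i, j] - e) ** 2 / e
        assert chi2 == pytest.approx(ref, rel=1e-12)
        from scipy import stats
        assert p == pytest.approx(stats.chi2.sf(ref, df), abs=1e-12)

    def test_derive_rules_finds_planted_pairing(self):
        """Residual rule recovers which genetic clusters enrich a metabolomic one."""
        rng = np.random.default_rng(7)
        idx = pd.Index([f"s{i}" for i in range(600)])
        met = pd.Series(rng.integers(1, 6, 600), index=idx)
        gen = met.copy()
        # metabolomic cluster 2 ties to genetic 4 and 5
        two = met == 2
        gen[two] = rng.choice([4, 5], two.sum())
        # add noise
        flip = rng.random(600) < 0.1
        gen[flip] = rng.integers(1, 6, flip.sum())
        rules = cd.derive_subtype_rules(_solution(met, 5), _solution(gen, 5),
                                        target_clusters=(2, 4))
        assert set(rules["Subtype-I"][1]) >= {4, 5}


class TestHaplotypeGroupFrequencies:
    def test_all_wild_type_degenerate(self):
        idx = pd.Index([f"s{i}" for i in range(30)])
        cohort = pd.DataFrame(
            {"group": ["control"] * 10 + ["high-risk"] * 10 + ["CAD"] * 10,
             "sex": "male", "age": 50.0},
            index=idx,
        )
        calls = cd.HaplotypeCall(
            pd.Series(1, index=idx), pd.DataFrame(index=idx),
            pd.Series(False, index=idx),
        )
        out = cd.haplotype_group_frequencies(calls, cohort)
        assert out["p"] == 1.0
        np.testing.assert_allclose(out["frequency_by_group"].loc[1], 1.0)

    def test_group_shares_sum_to_one(self, small_cohort):
        calls = cd.call_haplotypes(small_cohort.genotypes)
        out = cd.haplotype_group_frequencies(calls, small_cohort.cohort)
        shares = out["group_share_by_haplotype"]
        np.testing.assert_allclose(shares.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(out["frequency_by_group"].sum(axis=0), 1.0,
                                   atol=1e-12)

    def test_planted_trend_detected(self):
        cfg = cd.SimulationConfig(n_per_group=(800, 800, 800), n_snps=60,
                                  n_metabolites=5, n_informative_features=0, seed=9)
        co = cd.generate_cohort(cfg)
        calls = cd.call_haplotypes(co.genotypes)
        out = cd.haplotype_group_frequencies(calls, co.cohort)
        freqs = out["frequency_by_group"].loc[3]
        assert freqs["control"] < freqs["high-risk"] < freqs["CAD"]
        assert out["p"] < 0.05
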