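"""Ubiquity filtering, correlation screening, and cluster assignment."""

import numpy as np
import pandas as pd
import pytest

from domthermo import community as comm
from domthermo import phylotype_classifier as pc
from domthermo.synthetic_data import (
    SynthesisConfig,
    generate_community,
    generate_soil_and_thermo_structure,
)


def community_table(counts, sites):
    df = pd.DataFrame(
        counts, index=[f"t{i}" for i in range(len(counts))],
        columns=[f"s{j}" for j in range(len(counts[0]))],
    )
    return comm.CommunityTable(counts=df, sample_sites=pd.Series(sites, index=df.columns))


class TestUbiquityFilter:
    def setup_method(self):
        # 6 sites x 2 samples; taxon occupancy by construction
        sites = [f"S{j // 2}" for j in range(12)]
        counts = np.zeros((3, 12), dtype=int)
        counts[0, :10] = 1          # 5 sites
        counts[1, :8] = 1           # 4 sites
        counts[2, 0] = 1            # 1 site
        self.table = community_table(counts, sites)

    def test_default_five_of_six(self):
        assert pc.ubiquity_filter(self.table, min_sites=5) == ["t0"]

    def test_four_site_taxon_dropped_at_five(self):
        assert "t1" not in pc.ubiquity_filter(self.table, min_sites=5)

    def test_min_sites_one_keeps_all_detected(self):
        assert pc.ubiquity_filter(self.table, min_sites=1) == ["t0", "t1", "t2"]


class TestSpearman:
    def test_monotone_increasing(self):
        x = np.arange(10.0)
        rho, p = pc.spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p < 0.001

    def test_monotone_decreasing(self):
        x = np.arange(10.0)
        rho, _ = pc.spearman(x, -x**3)
        assert rho == pytest.approx(-1.0)

    def test_midrank_ties_match_brute_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        rho, _ = pc.spearman(x, y)
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_small_n_exact_permutation_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho, p = pc.spearman(x, y)
        k = round(p * 120)
        assert abs(p * 120 - k) < 1e-9  # p is a multiple of 1/5!

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            pc.spearman(np.ones(6), np.arange(6.0))


def record(rho_dg, p_dg, rho_som, p_som, taxon="t"):
    return pc.AssociationRecord(
        taxon_id=taxon, occupancy_sites=6,
        rho_dg=rho_dg, p_dg=p_dg, r_dg=rho_dg, pr_dg=p_dg,
        rho_som=rho_som, p_som=p_som, r_som=rho_som, pr_som=p_som,
    )


class TestClassify:
    def test_both_significant_cluster_one_core(self):
        rec = pc.classify_phylotypes([record(-0.6, 0.01, +0.5, 0.02)])[0]
        assert rec.cluster == pc.CLUSTER_I and rec.core

    def test_single_variable_cluster_two_not_core(self):
        rec = pc.classify_phylotypes([record(+0.4, 0.03, +0.1, 0.40)])[0]
        assert rec.cluster == pc.CLUSTER_II and not rec.core

    def test_nonsignificant_excluded(self):
        rec = pc.classify_phylotypes([record(0.2, 0.3, -0.2, 0.2)])[0]
        assert rec.cluster == pc.UNCLASSIFIED and not rec.conflict

    def test_conflicting_signs_flagged(self):
        rec = pc.classify_phylotypes([record(-0.5, 0.01, -0.5, 0.01)])[0]
        assert rec.cluster == pc.UNCLASSIFIED and rec.conflict

    def test_inclusion_exclusion_audit(self):
        rng = np.random.default_rng(0)
        recs = [
            record(rng.uniform(-1, 1), rng.uniform(0, 1), rng.uniform(-1, 1),
                   rng.uniform(0, 1), taxon=f"t{i}")
            for i in range(200)
        ]
        out = pc.classify_phylotypes(recs, alpha=0.05)
        n_sig = sum(r.cluster != pc.UNCLASSIFIED or r.conflict for r in out)
        a = sum(r.pr_dg < 0.05 for r in out)
        b = sum(r.pr_som < 0.05 for r in out)
        both = sum(r.pr_dg < 0.05 and r.pr_som < 0.05 for r in out)
        assert n_sig == a + b - both

    def test_label_symmetry_under_dg_negation(self):
        """Negating the dG variable swaps clusters I and II exactly."""
        cfg = SynthesisConfig(seed=5, n_taxa=60, n_cluster1=15, n_cluster2=15)
        soil = generate_soil_and_thermo_structure(cfg)
        table, _, _ = generate_community(cfg, soil["target_median_dg"], soil["som"])
        dg = soil["target_median_dg"]
        som = soil["som"]
        recs = pc.classify_phylotypes(pc.screen_taxa(table, dg, som))
        swap = {pc.CLUSTER_I: pc.CLUSTER_II, pc.CLUSTER_II: pc.CLUSTER_I,
                pc.UNCLASSIFIED: pc.UNCLASSIFIED}
        # dG-only-significant taxa swap labels when dG flips sign; core taxa
        # become sign conflicts because their SOM association is unchanged.
        recs_neg = pc.classify_phylotypes(pc.screen_taxa(table, -dg, som))
        for r, rn in zip(recs, recs_neg):
            assert r.taxon_id == rn.taxon_id
            if r.pr_dg < 0.05 and r.pr_som >= 0.05:
                assert rn.cluster == swap[r.cluster]
            elif r.core and r.cluster != pc.UNCLASSIFIED:
                assert rn.conflict
        # negating both variables is the full mirror: every label swaps.
        recs_mirror = pc.classify_phylotypes(pc.screen_taxa(table, -dg, -som))
        for r, rm in zip(recs, recs_mirror):
            assert rm.cluster == swap[r.cluster]
            assert rm.core == r.core


class TestPlantedRecovery:
    def test_planted_clusters_recovered(self):
        cfg = SynthesisConfig(seed=1, n_taxa=200, n_cluster1=40, n_cluster2=40)
        soil = generate_soil_and_thermo_structure(cfg)
        table, _, planted = generate_community(cfg, soil["target_median_dg"], soil["som"])
        rare = comm.rarefy(table, 7000, seed=1)
        recs = pc.classify_phylotypes(
            pc.screen_taxa(rare, soil["target_median_dg"], soil["som"])
        )
        label = {r.taxon_id: r.cluster for r in recs}
        planted_taxa = planted[planted.isin(["I", "II"])]
        hit = np.mean([label[t] == planted_taxa[t] for t in planted_taxa.index])
        null_taxa = planted[planted == "null"]
        false = np.mean([label[t] != pc.UNCLASSIFIED for t in null_taxa.index])
        assert hit >= 0.9
        assert false <= 0.15


class TestGroupRegression:
    def _setup(self, seed=2):
        cfg = SynthesisConfig(seed=seed, n_taxa=120, n_cluster1=30, n_cluster2=30)
        soil = generate_soil_and_thermo_structure(cfg)
        table, _, planted = generate_community(cfg, soil["target_median_dg"], soil["som"])
        recs = pc.classify_phylotypes(
            pc.screen_taxa(table, soil["target_median_dg"], soil["som"])
        )
        return cfg, soil, table, recs

    def test_planted_groups_show_opposite_slopes(self):
        _, soil, table, recs = self._setup()
        fits = pc.group_abundance_regression(recs, table, soil["target_median_dg"], soil["som"])
        assert fits[pc.CLUSTER_I]["dg"].slope < 0 < fits[pc.CLUSTER_II]["dg"].slope
        assert fits[pc.CLUSTER_I]["dg"].p_value < 0.05

    def test_single_taxon_group_equals_own_regression(self):
        _, soil, table, recs = self._setup()
        member = next(r for r in recs if r.cluster == pc.CLUSTER_I)
        one = [r if r is member else record(0, 1, 0, 1, taxon=r.taxon_id) for r in recs]
        for r in one:
            if r is not member:
                r.cluster = pc.UNCLASSIFIED
        fits = pc.group_abundance_regression(one, table, soil["target_median_dg"], soil["som"])
        rel = table.relative_abundance().loc[member.taxon_id]
        from domthermo.soilstats import ols_fit

        direct = ols_fit(soil["target_median_dg"], rel)
        assert fits[pc.CLUSTER_I]["dg"].slope == pytest.approx(direct.slope, rel=1e-9)

    def test_groups_partition_significant_set(self):
        _, _, _, recs = self._setup()
        members_i = {r.taxon_id for r in recs if r.cluster == pc.CLUSTER_I}
        members_ii = {r.taxon_id for r in recs if r.cluster == pc.CLUSTER_II}
        assert not members_i & members_ii
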