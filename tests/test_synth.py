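import numpy as np
import pandas as pd
import pytest

from ribodelim.cbc import cbc_matrix, delineate_species
from ribodelim.kmer import distance_matrix
from ribodelim.structures import encode12
from ribodelim.synth import (InfeasibleCBCError, SynthConfig,
                             decompose_cbc_matrix, default_cbc_matrix,
                             gen_community_series, gen_coverage_table,
                             gen_host_phenotype_tables, gen_kmer_profiles,
                             gen_ribotype_sequences)


from ribodelim.alignment import SeqStructAlignment


def gapless_alignment(records):
    rows = np.vstack([encode12(r).codes for r in records])
    return SeqStructAlignment([r.id for r in records], rows)


def reconstruct(cols, n):
    d = np.zeros((n, n), dtype=int)
    for assign in cols:
        for i in range(n):
            for j in range(i + 1, n):
                if assign[i] != assign[j]:
                    d[i, j] += 1
                    d[j, i] += 1
    return d


class TestCBCDecomposition:
    def test_default_matrix_spans_one_to_nine(self):
        d = default_cbc_matrix(8)
        off = d[np.triu_indices(8, 1)]
        assert set(range(1, 10)) <= set(off.tolist())
        assert (np.diag(d) == 0).all()

    def test_star_matrix_reconstructs_exactly(self):
        d = default_cbc_matrix(8)
        cols = decompose_cbc_matrix(d)
        assert np.array_equal(reconstruct(cols, 8), d)

    def test_two_taxon_case(self):
        d = np.array([[0, 2], [2, 0]])
        cols = decompose_cbc_matrix(d)
        assert len(cols) == 2 and np.array_equal(reconstruct(cols, 2), d)

    def test_non_additive_matrix_via_search(self):
        # equilateral triangle: not star-additive with integer weights
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        cols = decompose_cbc_matrix(d)
        assert np.array_equal(reconstruct(cols, 3), d)

    def test_infeasible_zero_pattern_raises(self):
        # a~b share zero CBCs but disagree about c: no partition family
        # can serve c against a without also separating b
        d = np.array([[0, 0, 3], [0, 0, 0], [3, 0, 0]])
        with pytest.raises(InfeasibleCBCError):
            decompose_cbc_matrix(d)


class TestRibotypeSequences:
    def test_round_trip_r2(self):
        cfg = SynthConfig(n_ribotypes=2, strains_per_ribotype=1,
                          planted_cbc=np.array([[0, 2], [2, 0]]), seed=0)
        records, truth = gen_ribotype_sequences(cfg)
        m = cbc_matrix(gapless_alignment(records))
        assert np.array_equal(m.counts, truth.cbc_matrix)

    def test_eight_ribotypes_recovered_exactly(self, small_config):
        records, truth = gen_ribotype_sequences(small_config)
        m = cbc_matrix(gapless_alignment(records))
        rib = truth.ribotype_of_strain
        for i, a in enumerate(m.taxa):
            for j, b in enumerate(m.taxa):
                ra = int(rib[a][3:]) - 1
                rb = int(rib[b][3:]) - 1
                assert m.counts[i, j] == truth.cbc_matrix[ra, rb]

    def test_within_ribotype_cbc_zero(self, small_config):
        records, truth = gen_ribotype_sequences(small_config)
        m = cbc_matrix(gapless_alignment(records))
        partition, conflicts = delineate_species(m)
        assert len(partition) == 8 and not conflicts

    def test_determinism(self):
        cfg = SynthConfig(strains_per_ribotype=2, seed=42)
        r1, _ = gen_ribotype_sequences(cfg)
        r2, _ = gen_ribotype_sequences(SynthConfig(strains_per_ribotype=2, seed=42))
        assert [(r.id, r.nucleotides, r.structure) for r in r1] == \
            [(r.id, r.nucleotides, r.structure) for r in r2]

    def test_overfull_request_names_pair(self):
        d = np.full((8, 8), 9)
        np.fill_diagonal(d, 0)
        with pytest.raises(InfeasibleCBCError):
            gen_ribotype_sequences(SynthConfig(planted_cbc=d, seed=0))

    def test_config_validation(self):
        bad = np.array([[0, 10], [10, 0]])
        with pytest.raises(ValueError, match=r"\[0, 9\]"):
            SynthConfig(n_ribotypes=2, planted_cbc=bad)


class TestKmerProfiles:
    def test_full_core_fraction_identical_within_ribotype(self):
        cfg = SynthConfig(n_ribotypes=2, strains_per_ribotype=3,
                          kmer_core_fraction=1.0, kmer_profile_size=500,
                          kmer_core_pool_size=800,
                          kmer_background_pool_size=2000, seed=1)
        profiles, truth = gen_kmer_profiles(cfg)
        d = distance_matrix(profiles, "kulczynski")
        for i, a in enumerate(d.ids):
            for j, b in enumerate(d.ids):
                if i < j and truth.ribotype_of_strain[a] == truth.ribotype_of_strain[b]:
                    assert d.values[i, j] == 0.0

    def test_planted_partition_recovered_at_core_08(self, rng):
        from scipy.cluster.hierarchy import fcluster, linkage

        cfg = SynthConfig(kmer_profile_size=1000, kmer_core_pool_size=1500,
                          kmer_background_pool_size=20000, seed=5)
        profiles, truth = gen_kmer_profiles(cfg)
        d = distance_matrix(profiles, "kulczynski")
        labels = fcluster(linkage(d.condensed(), "average"), t=8, criterion="maxclust")
        mapping = {}
        for sid, lab in zip(d.ids, labels):
            mapping.setdefault(lab, set()).add(truth.ribotype_of_strain[sid])
        assert len(mapping) == 8 and all(len(v) == 1 for v in mapping.values())

    def test_zero_core_no_better_than_chance(self, rng):
        from scipy.cluster.hierarchy import fcluster, linkage

        cfg = SynthConfig(n_ribotypes=4, strains_per_ribotype=4,
                          kmer_core_fraction=0.0, kmer_profile_size=400,
                          kmer_core_pool_size=500,
                          kmer_background_pool_size=5000, seed=6)
        profiles, truth = gen_kmer_profiles(cfg)
        d = distance_matrix(profiles, "kulczynski")
        labels = fcluster(linkage(d.condensed(), "average"), t=4, criterion="maxclust")
        truth_labels = np.array([int(truth.ribotype_of_strain[s][3:])
                                 for s in d.ids])

        def agreement(a, b):
            same_a = a[:, None] == a[None, :]
            same_b = b[:, None] == b[None, :]
            iu = np.triu_indices(len(a), 1)
            return float((same_a[iu] == same_b[iu]).mean())

        obs = agreement(labels, truth_labels)
        null = [agreement(labels, rng.permutation(truth_labels)) for _ in range(200)]
        # observed pair agreement inside the null permutation band
        assert obs <= np.quantile(null, 0.99)

    def test_within_between_ratio_grows_as_core_shrinks(self):
        ratios = []
        for frac in (0.9, 0.6, 0.3):
            cfg = SynthConfig(n_ribotypes=3, strains_per_ribotype=4,
                              kmer_core_fraction=frac, kmer_profile_size=400,
                              kmer_core_pool_size=600,
                              kmer_background_pool_size=6000, seed=7)
            profiles, truth = gen_kmer_profiles(cfg)
            d = distance_matrix(profiles, "kulczynski")
            within, between = [], []
            for i in range(len(d.ids)):
                for j in range(i + 1, len(d.ids)):
                    same = truth.ribotype_of_strain[d.ids[i]] == \
                        truth.ribotype_of_strain[d.ids[j]]
                    (within if same else between).append(d.values[i, j])
            ratios.append(np.mean(within) / np.mean(between))
        assert ratios[0] < ratios[1] < ratios[2]

    def test_pool_exhaustion_raises(self):
        with pytest.raises(ValueError, match="pool"):
            gen_kmer_profiles(SynthConfig(kmer_profile_size=1000,
                                          kmer_core_pool_size=500, seed=0))


class TestCoverageTable:
    def test_noise_free_construction_exact(self):
        cfg = SynthConfig(n_ribotypes=1, strains_per_ribotype=1,
                          planted_copies={"A1": 100}, coverage_depth=10.0, seed=0)
        table, truth = gen_coverage_table(cfg, noise=False)
        from ribodelim.operons import estimate_operon_copies
        e = estimate_operon_copies(table, "A1")
        assert e.copies == pytest.approx(100.0)
        assert table.operon_coverage("A1") == pytest.approx(1000.0)

    def test_flagged_genes_not_in_panel(self):
        cfg = SynthConfig(n_ribotypes=1, strains_per_ribotype=2, seed=2)
        table, _ = gen_coverage_table(cfg, flagged_fraction=0.5)
        from ribodelim.operons import select_reference_genes
        for s in table.strains:
            genes = select_reference_genes(table, s)
            flags = table.genes_of(s).set_index("feature")["flag"]
            assert all(flags[g] == "ok" for g in genes)
            assert 7 <= len(genes) <= 55

    def test_planted_copies_recovered_within_5pct(self, small_config):
        from ribodelim.operons import estimate_operon_copies
        table, truth = gen_coverage_table(small_config)
        for s in table.strains:
            e = estimate_operon_copies(table, s)
            true = truth.copies_of_strain[s]
            assert 58 <= true <= 270
            assert abs(e.copies - true) / true < 0.05


class TestCommunitySeries:
    def test_shapes_dates_and_descriptors(self, small_config):
        community, env, years, truth = gen_community_series(small_config)
        assert community.shape == (48, 16)
        assert list(env.columns) == ["temperature", "salinity", "precipitation",
                                     "tide_coefficient", "NO3", "PO4", "SiOH4"]
        assert len(set(years)) == 3
        for _, block in community.groupby(years):
            assert block.index.is_monotonic_increasing

    def test_flat_niche_taxon_has_negligible_omi(self):
        cfg = SynthConfig(n_taxa=6, niche_breadth=1e6, seed=9)
        community, env, years, truth = gen_community_series(cfg)
        from ribodelim.niche import hellinger, omi_analysis
        res = omi_analysis(hellinger(community), env)
        # an effectively infinite breadth makes every taxon's profile flat
        assert np.max(res.omi) < 0.01 * np.mean(res.inertia)

    def test_identical_optima_give_full_overlap(self):
        cfg = SynthConfig(n_taxa=4, seed=10)
        optima = np.tile(np.full(7, 0.5), (4, 1))
        cfg2 = SynthConfig(n_taxa=4, niche_optima=optima, seed=10)
        community, env, years, truth = gen_community_series(cfg2)
        from ribodelim.niche import (hellinger, kernel_niche, niche_grid,
                                     omi_analysis, schoener_d)
        res = omi_analysis(hellinger(community), env)
        grid = niche_grid(res.sample_scores, g=60)
        taxa = list(community.columns[:2])
        n1 = kernel_niche(res.sample_scores, community[taxa[0]].to_numpy(float), grid)
        n2 = kernel_niche(res.sample_scores, community[taxa[1]].to_numpy(float), grid)
        assert schoener_d(n1, n2) > 0.9

    def test_optima_recovered_on_first_axis(self, small_config):
        from scipy.stats import spearmanr
        from ribodelim.niche import hellinger, omi_analysis
        community, env, years, truth = gen_community_series(small_config)
        res = omi_analysis(hellinger(community), env)
        well = community.sum().to_numpy() >= 500
        m1 = res.marginality @ res.axes[:, 0]
        planted = (truth.optima - truth.optima.mean(0)) @ res.axes[:, 0]
        rho = spearmanr(m1[well], planted[well]).statistic
        assert abs(rho) > 0.9


class TestHostPhenotypeTables:
    def test_universal_host_column_all_ones(self, small_config):
        phen, hosts, species_of_host, truth = gen_host_phenotype_tables(small_config)
        universal = [h for h in hosts.columns
                     if species_of_host[h] == "S_acuminata_STR1"]
        assert (hosts[universal] == 1).all().all()

    def test_single_host_class_rows(self, small_config):
        phen, hosts, species_of_host, truth = gen_host_phenotype_tables(small_config)
        for strain, rib in truth.ribotype_of_strain.items():
            n_species = len({species_of_host[h]
                             for h in hosts.columns if hosts.loc[strain, h] == 1})
            assert n_species == int(truth.host_class_of_ribotype[rib])

    def test_matrix_binary_and_deterministic(self, small_config):
        _, h1, _, _ = gen_host_phenotype_tables(small_config)
        _, h2, _, _ = gen_host_phenotype_tables(small_config)
        assert h1.isin([0, 1]).all().all()
        pd.testing.assert_frame_equal(h1, h2)
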