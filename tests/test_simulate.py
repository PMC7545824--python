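"""Simulator laws: strain construction, tetrad meiosis, breeding schemes,
and pooled-sequencing noise."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from tetramap.genome import build_genome_model, synthesize_reference
from tetramap.simulate import (
    SimConfig,
    SimulationError,
    StrainGenome,
    meiosis_tetrad,
    mutagenize,
    position_at_recombination_fraction,
    run_backcross_scheme,
    run_outcross_pools,
    segregating_sites,
    sequence_strain,
    simulate_pool_sequencing,
    spawn_strains,
)
from tetramap.variants import parse_site_key, site_key


def _het_sites(a: StrainGenome, b: StrainGenome) -> set[str]:
    return set(a.alleles) ^ set(b.alleles)


class TestSpawnStrains:
    def test_divergence_is_exact(self, small_cfg, small_model, small_reference,
                                 small_strains):
        background, outcross = small_strains
        assert len(_het_sites(background, outcross)) == small_cfg.n_outcross_snps
        assert background.mating_type != outcross.mating_type
        # background SNPs are shared ancestry, carried by both strains
        assert set(background.alleles) <= set(outcross.alleles)

    def test_zero_outcross_snps_gives_isogenic_pair(self, small_model,
                                                    small_reference):
        bg, oc = spawn_strains(small_model, small_reference, 0, 25, seed=5)
        assert set(bg.alleles) == set(oc.alleles)

    def test_overfull_genome_rejected(self, small_reference):
        model = build_genome_model(
            SimConfig(n_chromosomes=1, chromosome_length=100_000, n_genes=1)
        )
        ref = synthesize_reference(model, 0)
        with pytest.raises(SimulationError):
            spawn_strains(model, ref, 200_000, 0, seed=0)

    def test_snp_spacing_is_exponential(self):
        # uniform placement at 100 SNPs/Mbp: inter-SNP spacings across 10
        # independent panels should match an exponential with mean 10 kbp
        model = build_genome_model(
            SimConfig(n_chromosomes=1, chromosome_length=10_000_000, n_genes=2)
        )
        ref = synthesize_reference(model, 1)
        spacings = []
        for seed in range(10):
            _, oc = spawn_strains(model, ref, 1000, 0, seed=seed)
            pos = np.sort([parse_site_key(k)[1] for k in oc.alleles])
            spacings.append(np.diff(pos))
        pooled = np.concatenate(spacings)
        result = stats.kstest(pooled, "expon", args=(0, 10_000))
        assert result.pvalue > 0.005


class TestMutagenize:
    def test_mutation_count_and_causative(self, small_cfg, small_model,
                                          small_mutant, small_strains):
        background, _ = small_strains
        novel = set(small_mutant.alleles) - set(background.alleles)
        assert len(novel) == small_cfg.n_mutations
        assert small_mutant.causative_site in novel
        gene = small_model.gene(small_cfg.causative_gene)
        _, pos, _, _ = parse_site_key(small_mutant.causative_site)
        assert gene.contains(pos)

    def test_single_mutation_is_causative_only(self, small_model,
                                               small_reference, small_strains):
        background, _ = small_strains
        mutant = mutagenize(background, small_model, small_reference, 1, "g01",
                            seed=3)
        assert set(mutant.alleles) - set(background.alleles) == {
            mutant.causative_site
        }

    def test_seed_moves_silent_mutations_not_gene(self, small_model,
                                                  small_reference, small_strains):
        background, _ = small_strains
        m1 = mutagenize(background, small_model, small_reference, 20, "g02", seed=1)
        m2 = mutagenize(background, small_model, small_reference, 20, "g02", seed=2)
        assert set(m1.alleles) != set(m2.alleles)
        gene = small_model.gene("g02")
        for m in (m1, m2):
            _, pos, _, _ = parse_site_key(m.causative_site)
            assert gene.contains(pos)

    def test_unknown_gene_rejected(self, small_model, small_reference,
                                   small_strains):
        background, _ = small_strains
        with pytest.raises(SimulationError):
            mutagenize(background, small_model, small_reference, 5, "nope", seed=0)


class TestMeiosis:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("map_rate", [0.0, 6.0, 50.0])
    def test_two_to_two_law(self, small_cfg, small_reference, seed, map_rate,
                            small_strains, small_mutant):
        """Every inter-parental heterozygous site segregates exactly 2:2,
        for all seeds and map rates."""
        model = dataclasses.replace(
            build_genome_model(small_cfg), genetic_map_rate=map_rate
        )
        _, outcross = small_strains
        tet = meiosis_tetrad(small_mutant, outcross, model, seed=seed)
        for key in _het_sites(small_mutant, outcross):
            assert sum(p.carries(key) for p in tet.products) == 2
        assert sorted(p.mating_type for p in tet.products) == ["+", "+", "-", "-"]

    def test_homozygous_site_segregates_4_0(self, small_model, small_strains,
                                            small_mutant):
        _, outcross = small_strains
        shared = set(small_mutant.alleles) & set(outcross.alleles)
        tet = meiosis_tetrad(small_mutant, outcross, small_model, seed=9)
        key = sorted(shared)[0]
        assert sum(p.carries(key) for p in tet.products) == 4

    def test_same_mating_type_rejected(self, small_model, small_strains):
        background, _ = small_strains
        with pytest.raises(SimulationError):
            meiosis_tetrad(background, background, small_model, seed=0)

    def test_recombinant_frequency_matches_haldane(self):
        """Two loci at map distance d recombine at c = (1 - e^(-2d))/2."""
        cfg = SimConfig(n_chromosomes=1, chromosome_length=4_000_000, n_genes=2,
                        seed=13)
        model = build_genome_model(cfg)
        ref = synthesize_reference(model, 13)
        bg, _ = spawn_strains(model, ref, 0, 0, seed=13)
        mutant = mutagenize(bg, model, ref, 1, "g01", seed=13)
        ckey = mutant.causative_site
        chrom, pos, _, _ = parse_site_key(ckey)
        c_expected = 0.12
        lpos = position_at_recombination_fraction(model, chrom, pos, c_expected)
        lref = ref[chrom][lpos - 1]
        lkey = site_key(chrom, lpos, lref, "ACGT".replace(lref, "")[0])
        mutant.alleles[lkey] = 1
        partner = dataclasses.replace(bg, mating_type="-")
        rng = np.random.default_rng(13)
        n_rec = n_tot = 0
        for _ in range(2500):
            tet = meiosis_tetrad(mutant, partner, model, seed=rng)
            for p in tet.products:
                n_rec += p.carries(ckey) != p.carries(lkey)
                n_tot += 1
        assert n_tot == 10_000
        assert abs(n_rec / n_tot - c_expected) < 0.015


class TestBackcross:
    def test_zero_generations_is_identity(self, small_model, small_strains,
                                          small_mutant):
        background, _ = small_strains
        out = run_backcross_scheme(small_mutant, background, 0, small_model,
                                   seed=0)
        assert out is small_mutant

    def test_negative_generations_rejected(self, small_model, small_strains,
                                           small_mutant):
        background, _ = small_strains
        with pytest.raises(SimulationError):
            run_backcross_scheme(small_mutant, background, -1, small_model, seed=0)

    def test_causative_always_retained(self, small_model, small_strains,
                                       small_mutant):
        background, _ = small_strains
        rng = np.random.default_rng(4)
        for _ in range(30):
            out = run_backcross_scheme(small_mutant, background, 3, small_model,
                                       seed=rng)
            assert out.causative_site == small_mutant.causative_site


class TestOutcrossPools:
    def test_pool_sizes_and_partition(self, small_model, small_strains,
                                      small_mutant):
        _, outcross = small_strains
        tsp, wt, tetrads = run_outcross_pools(small_mutant, outcross, 15,
                                              small_model, seed=0)
        assert len(tsp) == len(wt) == 30  # 60 progenies from 15 tetrads
        assert all(p.has_phenotype for p in tsp)
        assert not any(p.has_phenotype for p in wt)
        assert len(tetrads) == 15


class TestPoolSequencing:
    def test_single_strain_zero_error_reports_100(self, small_cfg, small_mutant):
        cfg = dataclasses.replace(small_cfg, base_error_rate=0.0,
                                  mean_coverage=30.0)
        sites = segregating_sites(small_mutant)
        table = sequence_strain(small_mutant, sites, cfg, seed=5)
        assert len(table) > 0
        assert all(r.frequency == 100.0 for r in table.records)
        assert table.keys() <= set(sites)

    def test_half_carrier_pool_converges_to_50(self, small_cfg, small_model,
                                               small_reference):
        carrier = StrainGenome("c", "+", {"chr01:100:A:T": 1})
        non_carrier = StrainGenome("n", "-", {})
        cfg = dataclasses.replace(small_cfg, base_error_rate=0.0,
                                  mean_coverage=400.0)
        table = simulate_pool_sequencing([carrier, non_carrier],
                                         ["chr01:100:A:T"], cfg, seed=8)
        freq = table.records[0].frequency
        se = 100 * np.sqrt(0.25 / 400)
        assert abs(freq - 50.0) < 3 * se

    def test_empty_pool_rejected(self, small_cfg):
        with pytest.raises(SimulationError):
            simulate_pool_sequencing([], ["chr01:1:A:T"], small_cfg)

    def test_seed_fixes_every_record(self, small_cfg, small_model,
                                     small_reference, small_mutant):
        sites = segregating_sites(small_mutant)
        t1 = sequence_strain(small_mutant, sites, small_cfg, seed=11,
                             reference=small_reference, model=small_model)
        t2 = sequence_strain(small_mutant, sites, small_cfg, seed=11,
                             reference=small_reference, model=small_model)
        assert t1.records == t2.records
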