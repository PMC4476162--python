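"""The synthetic generator: constructed validity, determinism, recovery."""

import numpy as np
import pytest

from splicecis.gene_models import extract_internal_exon_features
from splicecis.ese_constraint import mask_ese_and_density
from splicecis.genetics import ks_ng86
from splicecis.synthetic_data import (SimulationConfig, simulate_codon_trend_pool,
                                      simulate_ortholog_pair,
                                      simulate_phylo_traits,
                                      simulate_polymorphism,
                                      simulate_species_genes)


class TestGeneGeneration:
    def test_constructed_genes_pass_all_filters(self, small_bundle_paths):
        from splicecis.gene_models import load_and_filter_genes

        genes, rejections = load_and_filter_genes(*small_bundle_paths)
        assert rejections == []
        assert len(genes) == 60

    def test_deterministic_under_seed(self, motifs):
        cfg = SimulationConfig(seed=3, n_genes=5)
        g1, genome1 = simulate_species_genes(cfg, motifs)
        g2, genome2 = simulate_species_genes(cfg, motifs)
        assert [g.cds_sequence for g in g1] == [g.cds_sequence for g in g2]
        assert genome1 == genome2

    def test_density_slope_recovery(self, motifs):
        # planted +0.05 density per log10 intron size; OLS slope within 20%
        cfg = SimulationConfig(seed=8, n_genes=850,
                               density_slope_log_size=0.05,
                               density_slope_intron_count=0.0)
        genes, _ = simulate_species_genes(cfg, motifs)
        dens, logsize = [], []
        for g in genes:
            for f in extract_internal_exon_features(g):
                if f.flank5_seq is None:
                    continue
                dens.append(mask_ese_and_density(f.flank5_seq,
                                                 motifs).density)
                logsize.append(np.log10(f.intron5))
        assert len(dens) > 4000
        slope = np.polyfit(logsize, dens, 1)[0]
        assert slope == pytest.approx(0.05, rel=0.20)

    def test_zero_slope_gives_no_dependence(self, motifs):
        from splicecis.stats_core import spearman

        cfg = SimulationConfig(seed=9, n_genes=350,
                               density_slope_log_size=0.0,
                               density_slope_intron_count=0.0)
        genes, _ = simulate_species_genes(cfg, motifs)
        dens, logsize = [], []
        for g in genes:
            for f in extract_internal_exon_features(g):
                if f.flank5_seq is not None:
                    dens.append(mask_ese_and_density(f.flank5_seq,
                                                     motifs).density)
                    logsize.append(np.log10(f.intron5))
        rho, p = spearman(np.array(dens), np.array(logsize))
        assert abs(rho) < 0.05


class TestOrthologSimulation:
    def test_full_constraint_silences_ese_columns(self, small_gene_set,
                                                  motifs):
        from splicecis.ese_constraint import (_codon_ese_flags, _encode,
                                              _window_ints,
                                              align_gene_features,
                                              coverage_from_windows)
        from splicecis.gene_models import FLANK_LEN
        from splicecis.genetics import ks_from_codons

        genes, _ = small_gene_set
        ese_a, ese_b = [], []
        for g in genes[:15]:
            a, b = simulate_ortholog_pair(g, motifs, 0.08, 1.0, seed=2)
            for af in align_gene_features(
                    g, extract_internal_exon_features(g), a, b):
                for region, seq in ((af.flank5, af.feature.flank5_seq),
                                    (af.flank3, af.feature.flank3_seq)):
                    if region is None:
                        continue
                    cov = coverage_from_windows(
                        _window_ints(_encode(seq)[None, :]),
                        motifs.motif_ints, FLANK_LEN)[0]
                    flags = _codon_ese_flags(region, cov)
                    ese_a.append(region.a[flags])
                    ese_b.append(region.b[flags])
        est = ks_from_codons(np.concatenate(ese_a), np.concatenate(ese_b))
        assert est.syn_diffs == 0
        assert est.ks == 0.0

    def test_no_constraint_matches_core_rate(self, small_gene_set, motifs):
        genes, _ = small_gene_set
        rng = np.random.default_rng(5)
        ks_vals = []
        for g in genes:
            a, b = simulate_ortholog_pair(g, motifs, 0.06, 0.0,
                                          seed=int(rng.integers(2 ** 31)))
            ks_vals.append(ks_ng86(a, b).ks)
        assert np.mean(ks_vals) == pytest.approx(0.06, abs=0.005)

    def test_nonsynonymous_sites_frozen(self, small_gene_set, motifs):
        from Bio.Seq import Seq

        genes, _ = small_gene_set
        a, b = simulate_ortholog_pair(genes[0], motifs, 0.2, 0.0, seed=1)
        assert str(Seq(a).translate()) == str(Seq(b).translate())

    def test_invalid_constraint_rejected(self, small_gene_set, motifs):
        with pytest.raises(ValueError):
            simulate_ortholog_pair(small_gene_set[0][0], motifs, 0.06, 1.5)

    def test_deterministic(self, small_gene_set, motifs):
        g = small_gene_set[0][0]
        assert simulate_ortholog_pair(g, motifs, 0.06, 0.3, seed=7) == \
            simulate_ortholog_pair(g, motifs, 0.06, 0.3, seed=7)


class TestTrendPool:
    def test_null_pool_uniform(self):
        pool = simulate_codon_trend_pool(2000, n_planted=0, seed=0)
        allc = np.concatenate([e.codons for e in pool])
        freqs = np.bincount(allc, minlength=61) / len(allc)
        assert np.max(np.abs(freqs - 1 / 61)) < 0.005

    def test_odd_planted_rejected(self):
        with pytest.raises(ValueError):
            simulate_codon_trend_pool(100, n_planted=3)

    def test_short_exons_rejected(self):
        with pytest.raises(ValueError):
            simulate_codon_trend_pool(100, min_len=30)


class TestPhyloTraits:
    def test_zero_branch_lengths_keep_root_state(self):
        import dendropy

        t = dendropy.Tree.get(data="((A:0,B:0):0,(C:0,D:0):0);",
                              schema="newick")
        tab = simulate_phylo_traits(t, np.eye(2), seed=0, root=(2.0, -1.0))
        assert np.allclose(tab["trait_x"], 2.0)
        assert np.allclose(tab["trait_y"], -1.0)

    def test_rate_scale_invariance_of_correlation(self):
        from splicecis.phylo_comparative import independent_contrasts
        from splicecis.synthetic_data import random_tree

        tree = random_tree(20, seed=4)
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        t1 = simulate_phylo_traits(tree, R, seed=9)
        t2 = simulate_phylo_traits(tree, 4.0 * R, seed=9)
        # same seed: doubling the rate matrix scales traits by 2 exactly
        assert np.allclose(2.0 * t1.to_numpy(), t2.to_numpy())

    def test_non_psd_rejected(self):
        import dendropy

        t = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        with pytest.raises(ValueError):
            simulate_phylo_traits(t, np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestPolymorphismDeterminism:
    def test_same_seed_same_sample(self):
        s1 = simulate_polymorphism(0.01, 4, 1000, seed=3)
        s2 = simulate_polymorphism(0.01, 4, 1000, seed=3)
        assert s1.sequences == s2.sequences

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            simulate_polymorphism(0.01, 1, 100, seed=0)
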