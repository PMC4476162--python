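"""ESE masking, pseudo-ESE nulls, binned and gene-level constraint."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicecis.ese_constraint import (HexamerSet, binned_flank_constraint,
                                      gene_level_constraint,
                                      generate_pseudo_hexamers,
                                      load_hexamer_set, mask_ese_and_density,
                                      selection_proportion_per_exon)
from splicecis.gene_models import FLANK_LEN


def flank(seq: str) -> str:
    assert len(seq) <= FLANK_LEN
    return seq + "C" * (FLANK_LEN - len(seq))


class TestMasking:
    def test_no_hits(self):
        m = mask_ese_and_density(flank("A" * 20), HexamerSet("s",
                                                             frozenset({"GGGGGG"})))
        assert m.covered_sites == frozenset()
        assert m.density == 0.0

    def test_overlapping_hits_unioned(self):
        # GAAGAA at offsets 0 and 3 covers positions 0..8
        m = mask_ese_and_density(flank("GAAGAAGAA"),
                                 HexamerSet("s", frozenset({"GAAGAA"})))
        assert m.covered_sites == frozenset(range(9))
        assert m.density == pytest.approx(9 / FLANK_LEN)

    def test_density_arithmetic(self):
        m = mask_ese_and_density(flank("GAAGAATTTTTTGAAGAA"),
                                 HexamerSet("s", frozenset({"GAAGAA"})))
        assert len(m.covered_sites) == 12
        assert m.density == pytest.approx(12 / 69)

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            mask_ese_and_density(flank("GAANAA"),
                                 HexamerSet("s", frozenset({"GAAGAA"})))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            mask_ese_and_density("GAAGAA", HexamerSet("s",
                                                      frozenset({"GAAGAA"})))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_density_complement_identity(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, FLANK_LEN)])
        motifs = HexamerSet("s", frozenset(
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 6)])
            for _ in range(10)))
        m = mask_ese_and_density(seq, motifs)
        uncovered = FLANK_LEN - len(m.covered_sites)
        assert m.density == pytest.approx(1.0 - uncovered / FLANK_LEN)


class TestHexamerSets:
    def test_packaged_sets_have_reported_cardinalities(self, motifs):
        from splicecis.synthetic_data import default_ese_set

        assert len(motifs) == 84
        assert len(default_ese_set("int3_400")) == 54

    def test_invalid_hexamer_rejected(self):
        with pytest.raises(ValueError):
            HexamerSet("bad", frozenset({"GGG"}))

    def test_duplicate_file_rejected(self, tmp_path):
        p = tmp_path / "dup.txt"
        p.write_text("GAAGAA\nGAAGAA\n")
        with pytest.raises(ValueError):
            load_hexamer_set(str(p))

    def test_pseudo_sets_match_size_and_composition(self, motifs):
        rng = np.random.default_rng(0)
        sets = [generate_pseudo_hexamers(motifs, rng) for _ in range(100)]
        assert all(len(s) == len(motifs) for s in sets)
        pooled = np.mean([s.base_frequencies for s in sets], axis=0)
        assert np.max(np.abs(pooled - motifs.base_frequencies)) < 0.02


class TestBinnedConstraint:
    def test_equal_count_bins(self, aligned_features, motifs):
        res = binned_flank_constraint(aligned_features, motifs, n_bins=20,
                                      pseudo_reps=0, seed=0)
        for end in ("5prime", "3prime"):
            counts = res[end]["n_ends"]
            assert counts.max() - counts.min() <= 1
            assert res[end]["upper_limit"].is_monotonic_increasing

    def test_constraint_formula(self, aligned_features, motifs):
        res = binned_flank_constraint(aligned_features, motifs, n_bins=10,
                                      pseudo_reps=0, seed=0)
        t = res["5prime"]
        expect = (t["ks_core"] - t["ks_ese"]) / t["ks_core"]
        assert np.allclose(t["constraint"], expect, equal_nan=True)

    def test_planted_constraint_detected(self, aligned_features, motifs):
        # fixture planted c = 0.5: ESE flank Ks well below core Ks overall
        res = binned_flank_constraint(aligned_features, motifs, n_bins=5,
                                      pseudo_reps=0, seed=0)
        pooled = np.mean([1 - res[e]["ks_ese"].mean() / res[e]["ks_core"].mean()
                          for e in res])
        assert 0.3 < pooled < 0.7

    def test_pseudo_columns_not_constrained(self, aligned_features, motifs):
        # pseudo-ESE sets mostly miss the planted motifs, so their Ks sits
        # near core Ks rather than near the constrained ESE Ks
        res = binned_flank_constraint(aligned_features, motifs, n_bins=5,
                                      pseudo_reps=20, seed=0)
        t = res["5prime"]
        assert t["ks_pseudo_mean"].mean() > t["ks_ese"].mean()

    def test_too_many_bins_rejected(self, aligned_features, motifs):
        with pytest.raises(ValueError):
            binned_flank_constraint(aligned_features, motifs, n_bins=10 ** 6)


class TestSelectionProportion:
    def test_interpolation_and_product(self, aligned_features, motifs):
        res = selection_proportion_per_exon(aligned_features, motifs)
        for end in ("5prime", "3prime"):
            t = res[end]["table"]
            expect = res[end]["intercept"] + res[end]["slope"] * t["log10_intron"]
            assert np.allclose(t["constraint_interp"], expect)
            assert np.allclose(t["selection"],
                               t["density"] * t["constraint_interp"])
            # zero-density ends give zero selection regardless of constraint
            zero = t[t["density"] == 0]
            if len(zero):
                assert (zero["selection"] == 0).all()

    def test_negative_products_unfloored(self, aligned_features, motifs):
        res = selection_proportion_per_exon(aligned_features, motifs)
        t = res["5prime"]["table"]
        neg = t[t["constraint_interp"] < 0]
        if len(neg):
            assert (neg.loc[neg["density"] > 0, "selection"] < 0).all()


@pytest.fixture(scope="module")
def gl(small_gene_set, aligned_features, motifs):
    genes, _ = small_gene_set
    return gene_level_constraint(genes, aligned_features, motifs,
                                 cutoff=102, resample_reps=50,
                                 perm_m=100, seed=0)


class TestGeneLevel:
    def test_cutoff_enforced(self, gl):
        t = gl["table"]
        assert (t["ese_len"] > 102).all()
        assert (t["core_len"] > 102).all()

    def test_zero_ese_divergence_gives_unit_constraint(self, small_gene_set,
                                                       motifs):
        # c = 1: no synonymous change in any ESE column, so every retained
        # gene has constraint exactly 1
        from splicecis.ese_constraint import align_gene_features
        from splicecis.gene_models import extract_internal_exon_features
        from splicecis.synthetic_data import simulate_ortholog_pair

        genes, _ = small_gene_set
        afs = []
        for g in genes[:20]:
            a, b = simulate_ortholog_pair(g, motifs, 0.06, 1.0, seed=4)
            afs += align_gene_features(
                g, extract_internal_exon_features(g), a, b)
        res = gene_level_constraint(genes[:20], afs, motifs, cutoff=102,
                                    resample_reps=0, perm_m=50, seed=0)
        assert (res["table"]["constraint"] == 1.0).all()

    def test_correlation_report_complete(self, gl):
        for dim in ("mean_intron_size", "intron_density", "intron_number"):
            rec = gl["correlations"][dim]
            assert -1 <= rec["rho"] <= 1
            assert -1 <= rec["gamma"] <= 1
            assert 0 < rec["gamma_p_perm"] <= 1

    def test_nonstandard_cutoff_warns(self, small_gene_set, aligned_features,
                                      motifs):
        genes, _ = small_gene_set
        with pytest.warns(UserWarning, match="cutoff"):
            gene_level_constraint(genes, aligned_features, motifs, cutoff=120,
                                  resample_reps=0, perm_m=50, seed=0)

    def test_resampling_at_full_pool_reproduces_decision(self, small_gene_set,
                                                         aligned_features,
                                                         motifs):
        # when the 150-bp group equals the retained pool, every resample
        # reproduces the full-pool significance decision
        genes, _ = small_gene_set
        res = gene_level_constraint(genes, aligned_features, motifs,
                                    cutoff=102, resample_reps=30, perm_m=50,
                                    seed=1)
        if res["n_resample"] == len(res["table"]):
            from splicecis.stats_core import spearman

            frac = res["resampling_significant_fraction"]
            t = res["table"]
            for dim, f in frac.items():
                p = spearman(t["constraint"], t[dim])[1]
                assert f == (1.0 if p < 0.05 else 0.0)
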