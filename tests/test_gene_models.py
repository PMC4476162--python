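"""Gene-model loading, filtering, feature extraction and genomic traits."""

import numpy as np
import pytest

from splicecis.gene_models import (GeneModel, compute_genomic_traits,
                                   extract_internal_exon_features,
                                   load_and_filter_genes, write_gff3)
from splicecis.synthetic_data import simulate_invalid_genes


def _write(tmp_path, gff_text, fasta_text):
    gff = tmp_path / "a.gff3"
    fasta = tmp_path / "g.fasta"
    gff.write_text(gff_text)
    fasta.write_text(fasta_text)
    return str(gff), str(fasta)


@pytest.fixture(scope="module")
def invalid_loaded(tmp_path_factory):
    gff_text, fasta_text = simulate_invalid_genes()
    gff, fasta = _write(tmp_path_factory.mktemp("invalid"),
                        gff_text, fasta_text)
    return load_and_filter_genes(gff, fasta)


class TestFiltering:
    def test_valid_multi_exon_gene_retained(self, invalid_loaded):
        genes, _ = invalid_loaded
        assert [g.gene_id for g in genes] == ["ok_gene"]
        assert genes[0].cds_sequence.startswith("ATG")
        assert genes[0].cds_sequence.endswith("TAA")

    @pytest.mark.parametrize("gene_id,reason", [
        ("internal_stop", "internal stop"),
        ("intronless", "intronless"),
        ("ambiguous_base", "ambiguous nucleotide"),
        ("bad_start", "missing start codon"),
        ("bad_stop", "missing stop codon"),
        ("bad_frame", "CDS length not a multiple of 3"),
    ])
    def test_rejection_reasons(self, invalid_loaded, gene_id, reason):
        _, rejections = invalid_loaded
        assert (gene_id, reason) in rejections

    def test_malformed_gff_raises(self, tmp_path):
        gff, fasta = _write(
            tmp_path,
            "##gff-version 3\nchrI\tx\tgene\tfoo\tbar\t.\t+\t.\tID=g\n",
            ">chrI\nACGT\n")
        with pytest.raises(ValueError, match="malformed GFF3"):
            load_and_filter_genes(gff, fasta)

    def test_missing_chromosome_raises(self, tmp_path):
        gff, fasta = _write(
            tmp_path,
            "##gff-version 3\n"
            "chrZ\tx\tgene\t1\t9\t.\t+\t.\tID=g\n"
            "chrZ\tx\tmRNA\t1\t9\t.\t+\t.\tID=g.t;Parent=g\n"
            "chrZ\tx\tCDS\t1\t9\t.\t+\t0\tID=g.c;Parent=g.t\n",
            ">chrI\nACGT\n")
        with pytest.raises(ValueError, match="chrZ"):
            load_and_filter_genes(gff, fasta)


class TestRoundTrip:
    def test_write_reload_identity(self, small_gene_set, tmp_path):
        genes, genome = small_gene_set
        gff = tmp_path / "rt.gff3"
        fasta = tmp_path / "rt.fasta"
        write_gff3(genes, str(gff))
        with open(fasta, "w") as fh:
            for sid, seq in genome.items():
                fh.write(f">{sid}\n{seq}\n")
        loaded, rejections = load_and_filter_genes(str(gff), str(fasta))
        assert rejections == []
        assert len(loaded) == len(genes)
        by_id = {g.gene_id: g for g in loaded}
        for g in genes:
            assert by_id[g.gene_id].cds_sequence == g.cds_sequence
            assert by_id[g.gene_id].intron_sizes == g.intron_sizes
            assert by_id[g.gene_id].strand == g.strand

    def test_span_identity(self, small_gene_set):
        for g in small_gene_set[0]:
            assert sum(g.exon_lengths) + sum(g.intron_sizes) == g.gene_span


class TestStrandSymmetry:
    def test_minus_strand_gene_yields_same_features(self, tmp_path):
        from splicecis.genetics import revcomp

        # 3-exon gene, exons 150/150/150 bp, introns 100 bp with gt..ag
        rng = np.random.default_rng(7)
        sense = [c for c in
                 ("".join(p) for p in __import__("itertools").product(
                     "ACGT", repeat=3))
                 if c not in ("TAA", "TAG", "TGA")]
        cods = [sense[i] for i in rng.integers(0, 61, 150)]
        cods[0] = "ATG"
        cds = "".join(cods)[:-3] + "TAA"
        exon_seqs = [cds[:150], cds[150:300], cds[300:450]]
        intron = "GT" + "".join(rng.choice(list("ACGT"), 96)) + "AG"
        region = exon_seqs[0] + intron + exon_seqs[1] + intron + exon_seqs[2]

        plus_chrom = "AAAA" + region + "TTTT"
        minus_chrom = "AAAA" + revcomp(region).upper() + "TTTT"
        rows_plus, rows_minus = [], []
        for rows, strand, chrom_len in ((rows_plus, "+", len(plus_chrom)),
                                        (rows_minus, "-", len(minus_chrom))):
            coords = []
            for i in range(3):
                s = 4 + i * 250
                coords.append((s, s + 150))
            if strand == "-":
                coords = [(chrom_len - e, chrom_len - s) for s, e in coords]
                coords.sort()
            lo, hi = coords[0][0] + 1, coords[-1][1]
            rows.append(f"chrI\tt\tgene\t{lo}\t{hi}\t.\t{strand}\t.\tID=g")
            rows.append(f"chrI\tt\tmRNA\t{lo}\t{hi}\t.\t{strand}\t.\t"
                        f"ID=g.t;Parent=g")
            for k, (s, e) in enumerate(coords, 1):
                rows.append(f"chrI\tt\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                            f"ID=g.c{k};Parent=g.t")
        feats = {}
        for name, chrom, rows in (("plus", plus_chrom, rows_plus),
                                  ("minus", minus_chrom, rows_minus)):
            gff, fasta = (tmp_path / f"{name}.gff3", tmp_path / f"{name}.fa")
            gff.write_text("##gff-version 3\n" + "\n".join(rows) + "\n")
            fasta.write_text(f">chrI\n{chrom}\n")
            genes, rej = load_and_filter_genes(str(gff), str(fasta))
            assert rej == []
            assert genes[0].cds_sequence == cds
            feats[name] = extract_internal_exon_features(genes[0])
        for fp, fm in zip(feats["plus"], feats["minus"]):
            assert fp.flank5_seq == fm.flank5_seq
            assert fp.donor_string == fm.donor_string
            assert fp.acceptor_string == fm.acceptor_string
            assert fp.intron5 == fm.intron5


class TestExonFeatures:
    def _gene(self, exon_lengths, cds=None):
        rng = np.random.default_rng(1)
        total = sum(exon_lengths)
        if cds is None:
            sense = ["GCT", "GAA", "CTG", "TCC"]
            n = total // 3
            cds = "ATG" + "".join(sense[i % 4] for i in range(n - 2)) + "TAA"
        exons, pos = [], 0
        for length in exon_lengths:
            exons.append((pos, pos + length))
            pos += length + 100
        return GeneModel("g", "chrI", "+", exons, cds,
                         [100] * (len(exon_lengths) - 1),
                         [("gt", "ag")] * (len(exon_lengths) - 1))

    def test_internal_exons_only(self):
        g = self._gene([150, 150, 150, 150, 150])
        feats = extract_internal_exon_features(g)
        assert [f.exon_index for f in feats] == [2, 3, 4]

    def test_two_exon_gene_gives_empty_list(self):
        assert extract_internal_exon_features(self._gene([150, 150])) == []

    def test_short_exon_has_no_flanks(self):
        g = self._gene([150, 138, 150])
        (feat,) = extract_internal_exon_features(g)
        assert feat.length == 138
        assert feat.flank5_seq is None
        assert feat.core_seq is None

    def test_139bp_exon_has_flanks_and_centered_core(self):
        g = self._gene([150, 139, 150])
        (feat,) = extract_internal_exon_features(g)
        exon_seq = g.cds_sequence[150:289]
        assert feat.flank5_seq == exon_seq[:69]
        assert feat.flank3_seq == exon_seq[-69:]
        assert feat.core_seq == exon_seq[35:35 + 69]

    def test_donor_acceptor_case_coding(self):
        g = self._gene([150, 150, 150])
        (feat,) = extract_internal_exon_features(g)
        exon_seq = g.cds_sequence[150:300]
        assert feat.donor_string == exon_seq[-2:] + "gt"
        assert feat.acceptor_string == "ag" + exon_seq[:2]

    def test_aggt_donor_string(self):
        # exon ending ...CAG with canonical downstream intron -> "AGgt"
        g = self._gene([150, 150, 150])
        cds = list(g.cds_sequence)
        cds[298:300] = "AG"
        g.cds_sequence = "".join(cds)
        (feat,) = extract_internal_exon_features(g)
        assert feat.donor_string == "AGgt"


class TestGenomicTraits:
    def test_trait_arithmetic(self):
        g1 = GeneModel("a", "c", "+", [(0, 300), (1000, 1300), (2700, 3000)],
                       "A" * 900, [700, 1400], [("gt", "ag")] * 2)
        tr = compute_genomic_traits([g1])
        assert tr.X == pytest.approx(900 / 3000)      # CDS over span
        assert tr.N == pytest.approx(2 / 0.9)         # introns per CDS kb
        assert tr.M == pytest.approx((700 + 1400) / 2)

    def test_three_intron_density_example(self):
        g = GeneModel("a", "c", "+",
                      [(0, 375), (475, 850), (950, 1325), (1425, 1800)],
                      "A" * 1500, [100, 200, 300], [("gt", "ag")] * 3)
        tr = compute_genomic_traits([g])
        assert tr.N == pytest.approx(2.0)
        assert tr.M == pytest.approx(200.0)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            compute_genomic_traits([])
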