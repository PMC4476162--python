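"""Gene-model parsing, filtering and per-exon feature extraction.

A gene model here is one protein-coding transcript per gene (the longest-CDS
transcript when several are annotated): ordered coding exons, the introns
between them, and the spliced CDS on the coding strand. Genes are filtered to
a clean analysable set — ATG start, canonical stop, no internal stop, no
ambiguous bases, at least one intron — and internal exons longer than
2 x 69 bp expose their 69-nt end flanks and a central 69-nt core, the units
of all downstream ESE analyses. GFF3 input is 1-based inclusive; internally
all intervals are 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

from .genetics import STOP_CODONS, revcomp

FLANK_LEN = 69
MIN_FLANKED_EXON = 2 * FLANK_LEN  # exon must exceed this to have flanks/core

_VALID = frozenset("ACGT")


@dataclass
class GeneModel:
    """One protein-coding gene reduced to a single transcript."""

    gene_id: str
    seqid: str
    strand: str                       # '+' or '-'
    exons: list                       # (start, end) 0-based half-open, genomic,
                                      # listed in transcription (5'->3') order
    cds_sequence: str                 # spliced CDS, coding strand, incl. stop
    intron_sizes: list                # bp, transcription order
    intron_boundaries: list = field(default_factory=list)
                                      # (first2, last2) of each intron on the
                                      # coding strand, lower case
    @property
    def gene_span(self) -> int:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return max(ends) - min(starts)

    @property
    def exon_lengths(self) -> list:
        return [e - s for s, e in self.exons]

    @property
    def cds_offsets(self) -> list:
        """Start offset of each exon within the spliced CDS."""
        offs, cum = [], 0
        for length in self.exon_lengths:
            offs.append(cum)
            cum += length
        return offs


@dataclass
class ExonFeature:
    """An internal exon with its splice-relevant attributes.

    flank5_seq/flank3_seq/core_seq are populated only when the exon exceeds
    138 bp; donor/acceptor strings are 4-letter case-coded splice sites
    (exon upper case, intron lower case), e.g. "AGgt".
    """

    gene_id: str
    exon_index: int           # 1-based ordinal within the gene
    length: int
    intron5: int              # upstream intron size, bp
    intron3: int              # downstream intron size, bp
    donor_string: str
    acceptor_string: str
    frame_offset: int         # CDS offset of the exon start modulo 3
    cds_offset: int           # exon start within the spliced CDS
    flank5_seq: str | None = None
    flank3_seq: str | None = None
    core_seq: str | None = None


@dataclass
class GenomicTraits:
    """Species-level splice-related genomic traits."""

    species: str
    X: float    # mean CDS length / gene length
    N: float    # introns per kb of mature CDS
    M: float    # mean intron size, bp


def _check_cds(cds: str, n_exons: int) -> str | None:
    """First failing filter rule for a candidate gene, or None if clean."""
    if len(cds) % 3 != 0:
        return "CDS length not a multiple of 3"
    if n_exons < 2:
        return "intronless"
    if not set(cds) <= _VALID:
        return "ambiguous nucleotide"
    if cds[:3] != "ATG":
        return "missing start codon"
    if cds[-3:] not in STOP_CODONS:
        return "missing stop codon"
    for i in range(0, len(cds) - 3, 3):
        if cds[i:i + 3] in STOP_CODONS:
            return "internal stop"
    return None


def load_genome(fasta_path: str) -> dict:
    """Genome FASTA as {seqid: upper-case sequence string}."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(fasta_path, "fasta")}


def load_and_filter_genes(gff_path: str, fasta_path: str):
    """Parse a GFF3 + genome FASTA into filtered GeneModels.

    One transcript per gene is used (longest total CDS). Returns
    (genes, rejections) where rejections is a list of (gene_id, reason) for
    every gene failing a filter. Raises ValueError on malformed GFF3.
    """
    genome = load_genome(fasta_path)
    try:
        db = gffutils.create_db(gff_path, ":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
    except Exception as err:  # gffutils errors carry the offending line
        raise ValueError(f"malformed GFF3 record in {gff_path}: {err}") from err

    genes, rejections = [], []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in genome:
            raise ValueError(
                f"annotation references sequence {gene.seqid!r} absent "
                f"from {os.path.basename(fasta_path)}")
        best = None
        for mrna in db.children(gene, featuretype="mRNA"):
            segs = sorted((c.start - 1, c.end)
                          for c in db.children(mrna, featuretype="CDS"))
            if not segs:
                continue
            total = sum(e - s for s, e in segs)
            if best is None or total > best[0]:
                best = (total, segs)
        if best is None:
            rejections.append((gene.id, "no CDS"))
            continue
        _, segs = best
        model = _build_model(gene.id, gene.seqid, gene.strand, segs, genome)
        reason = _check_cds(model.cds_sequence, len(model.exons))
        if reason is not None:
            rejections.append((gene.id, reason))
        else:
            genes.append(model)
    return genes, rejections


def _build_model(gene_id, seqid, strand, segs, genome) -> GeneModel:
    """Assemble a GeneModel from sorted genomic CDS segments."""
    chrom = genome[seqid]
    if strand == "-":
        order = segs[::-1]  # transcription order
    else:
        order = segs
    pieces = []
    for s, e in order:
        seg = chrom[s:e]
        pieces.append(revcomp(seg) if strand == "-" else seg)
    cds = "".join(pieces)

    sizes, bounds = [], []
    for (s1, e1), (s2, e2) in zip(order, order[1:]):
        a, b = (e1, s2) if strand == "+" else (e2, s1)
        sizes.append(b - a)
        iseq2 = chrom[a:a + 2], chrom[b - 2:b]
        if strand == "-":
            first2, last2 = revcomp(iseq2[1]), revcomp(iseq2[0])
        else:
            first2, last2 = iseq2
        bounds.append((first2.lower(), last2.lower()))
    return GeneModel(gene_id, seqid, strand, list(order), cds, sizes, bounds)


def extract_internal_exon_features(gene: GeneModel) -> list:
    """ExonFeatures for internal exons (first and last excluded).

    Flank and core sequences are set only for exons longer than 138 bp; the
    core is the central 69 nt (start offset floor((length - 69)/2)).
    """
    feats = []
    offs = gene.cds_offsets
    lens = gene.exon_lengths
    n = len(gene.exons)
    for i in range(1, n - 1):
        off, length = offs[i], lens[i]
        exon_seq = gene.cds_sequence[off:off + length]
        donor = exon_seq[-2:].upper() + gene.intron_boundaries[i][0]
        acceptor = gene.intron_boundaries[i - 1][1] + exon_seq[:2].upper()
        feat = ExonFeature(
            gene_id=gene.gene_id, exon_index=i + 1, length=length,
            intron5=gene.intron_sizes[i - 1], intron3=gene.intron_sizes[i],
            donor_string=donor, acceptor_string=acceptor,
            frame_offset=off % 3, cds_offset=off)
        if length > MIN_FLANKED_EXON:
            feat.flank5_seq = exon_seq[:FLANK_LEN]
            feat.flank3_seq = exon_seq[-FLANK_LEN:]
            mid = (length - FLANK_LEN) // 2
            feat.core_seq = exon_seq[mid:mid + FLANK_LEN]
        feats.append(feat)
    return feats


def compute_genomic_traits(genes, species: str = "species") -> GenomicTraits:
    """Species-level traits X, N, M pooled over a gene set."""
    if not genes:
        raise ValueError("empty gene list")
    x = sum(len(g.cds_sequence) / g.gene_span for g in genes) / len(genes)
    total_introns = sum(len(g.intron_sizes) for g in genes)
    total_cds_kb = sum(len(g.cds_sequence) for g in genes) / 1000.0
    all_introns = [s for g in genes for s in g.intron_sizes]
    m = sum(all_introns) / len(all_introns) if all_introns else 0.0
    return GenomicTraits(species, x, total_introns / total_cds_kb, m)


def write_gff3(genes, path: str) -> None:
    """Write GeneModels as GFF3 (gene/mRNA/exon/CDS; coding exons only)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo = min(s for s, _ in g.exons) + 1
            hi = max(e for _, e in g.exons)
            fh.write(f"{g.seqid}\tsplicecis\tgene\t{lo}\t{hi}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{g.seqid}\tsplicecis\tmRNA\t{lo}\t{hi}\t.\t"
                     f"{g.strand}\t.\tID={mid};Parent={g.gene_id}\n")
            phases = {tuple(seg): (3 - off % 3) % 3
                      for seg, off in zip(g.exons, g.cds_offsets)}
            for k, (s, e) in enumerate(sorted(g.exons), 1):
                for ftype in ("exon", "CDS"):
                    phase = str(phases[(s, e)]) if ftype == "CDS" else "."
                    fh.write(f"{g.seqid}\tsplicecis\t{ftype}\t{s + 1}\t{e}\t.\t"
                             f"{g.strand}\t{phase}\t"
                             f"ID={mid}.{ftype}{k};Parent={mid}\n")


def features_to_table(features):
    """ExonFeatures as a pandas DataFrame (one row per internal exon)."""
    import pandas as pd

    return pd.DataFrame([{
        "gene_id": f.gene_id, "exon_index": f.exon_index, "length": f.length,
        "intron5": f.intron5, "intron3": f.intron3,
        "donor": f.donor_string, "acceptor": f.acceptor_string,
        "frame_offset": f.frame_offset, "cds_offset": f.cds_offset,
    } for f in features])
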