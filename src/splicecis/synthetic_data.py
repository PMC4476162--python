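"""Synthetic data generation for every pipeline stage.

The generator emulates the statistical structure the analyses assume, so that
each stage has a parameter-recovery test with no external downloads:

* multi-exon gene architectures (exon count 3 + Poisson, log-normal intron
  sizes) with valid ORFs by construction, ESE hexamers planted in the 69-bp
  flanks of internal exons at a coverage density that is a linear function of
  log10 flanking-intron size and downstream intron count;
* ortholog pairs diverged at synonymous sites only, at per-site rate d_core
  outside ESE coverage and d_core·(1 - c) inside, nonsynonymous positions
  held fixed (the analyses consume Ks only);
* infinite-sites-style polymorphism samples from a neutral coalescent
  genealogy (msprime) at a stated per-site θ;
* correlated bivariate Brownian traits on a phylogeny;
* codon pools with positional usage gradients planted in a chosen number of
  codons (paired up/down so all other codons stay exactly flat).

Every output is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import asdict, dataclass

import dendropy
import msprime
import numpy as np
import pandas as pd

from .genetics import (CODON_INDEX, CODONS, CODON_AA, STOP_CODONS,
                       SENSE_CODONS, revcomp)
from .gene_models import GeneModel, FLANK_LEN
from .ese_constraint import HexamerSet, _encode, _window_ints, \
    coverage_from_windows, load_hexamer_set
from .junction_trends import ExonCodons, MIN_DIST, MAX_DIST
from .popgen_theta import PolymorphismSample

_SENSE64 = np.array([CODON_INDEX[c] for c in SENSE_CODONS])
_STOP64 = np.array([CODON_INDEX[c] for c in sorted(STOP_CODONS)])
_BASES = np.array(list("ACGT"))


def _syn_alt_tables():
    """Per codon x position: synonymous alternative bases (NG86 convention)."""
    n_alt = np.zeros((64, 3), dtype=np.int64)
    alts = np.full((64, 3, 3), -1, dtype=np.int64)
    for ci, cod in enumerate(CODONS):
        if cod in STOP_CODONS:
            continue
        for pos in range(3):
            k = 0
            for bi, b in enumerate("ACGT"):
                if b == cod[pos]:
                    continue
                alt = cod[:pos] + b + cod[pos + 1:]
                if alt not in STOP_CODONS and CODON_AA[alt] == CODON_AA[cod]:
                    alts[ci, pos, k] = bi
                    k += 1
            n_alt[ci, pos] = k
    return n_alt, alts


_N_ALT, _ALTS = _syn_alt_tables()


def default_ese_set(name: str = "int3") -> HexamerSet:
    """The packaged synthetic stand-in ESE hexamer sets.

    These are purine-rich random hexamers of the cardinalities of the
    published INT3 (84) and INT3_400 (54) consensus ESE sets; they are
    synthetic stand-ins, not the published motif lists, which are not
    redistributable here. Any hexamer file can be supplied instead.
    """
    fname = {"int3": "int3_synthetic.txt",
             "int3_400": "int3_400_synthetic.txt"}[name]
    path = os.path.join(os.path.dirname(__file__), "data", fname)
    return load_hexamer_set(path, name=f"{name}_synthetic")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Divergence (d_core = 0.06) matches the primate-scale synonymous
    divergence the constraint analysis is designed around; θ = 0.005 and
    n = 10 haplotypes are typical published polymorphism panels; intron sizes
    are log-normal around e^7 ≈ 1.1 kb.
    """

    seed: int = 0
    n_genes: int = 300
    exon_count_lambda: float = 5.0     # exon count = 3 + Poisson(lambda)
    min_exon_len: int = 150            # bp; keeps flanks/cores defined
    max_exon_len: int = 300
    intron_mu_ln: float = 7.0
    intron_sigma_ln: float = 1.2
    min_intron: int = 70
    base_density: float = 0.12         # ESE coverage at log10 size 3, 3 downstream introns
    density_slope_log_size: float = 0.03
    density_slope_intron_count: float = 0.005
    p_exon_end_AG: float = 0.35        # donor "AGgt" usage
    p_exon_start_GT: float = 0.20      # acceptor "agGT" usage
    minus_strand_frac: float = 0.3
    d_core: float = 0.06               # core synonymous branch length
    ese_constraint: float = 0.3        # c; ESE synonymous rate = d_core*(1-c)
    theta: float = 0.005
    n_haplotypes: int = 10
    polymorphism_length: int = 100_000
    n_tips: int = 30
    rho_true: float = 0.8
    bm_rate: float = 1.0
    ese_set_name: str = "int3"


def _force_bases(cods: np.ndarray, assignments: list, rng) -> None:
    """Redraw codons so given (cds_position, base) constraints hold.

    Constrained codons are redrawn uniformly from sense codons matching the
    pattern; the initial ATG and terminal stop are never touched.
    """
    by_codon = {}
    for pos, base in assignments:
        by_codon.setdefault(pos // 3, []).append((pos % 3, base))
    last = len(cods) - 1
    for ci, pat in by_codon.items():
        if ci in (0, last):
            continue
        cands = [CODON_INDEX[c] for c in SENSE_CODONS
                 if all(c[o] == b for o, b in pat)]
        if cands:
            cods[ci] = cands[rng.integers(len(cands))]


def _plantable_motifs(motifs: HexamerSet) -> list:
    """Motifs whose two in-frame codons are both sense codons."""
    out = [m for m in sorted(motifs.motifs)
           if m[:3] not in STOP_CODONS and m[3:] not in STOP_CODONS]
    if not out:
        raise ValueError("no motif in the set can be planted in frame")
    return out


def _scrub_flank(cods: np.ndarray, lo: int, hi: int, forbidden: set,
                 motif_ints: np.ndarray, rng, max_iter: int = 25) -> None:
    """Redraw codons until the CDS window [lo, hi) has no chance motif hit.

    Hexamer hits arising from the random codon background would otherwise put
    a ~0.1 coverage floor under the planted density model. Hits that only
    touch protected codons (boundaries, start/stop) may survive.
    """
    c_lo, c_hi = lo // 3, (hi - 1) // 3 + 1
    for _ in range(max_iter):
        seq = "".join(CODONS[c] for c in cods[c_lo:c_hi])
        sub = seq[lo - 3 * c_lo:hi - 3 * c_lo]
        wins = _window_ints(_encode(sub)[None, :])[0]
        hits = np.flatnonzero(np.isin(wins, motif_ints))
        if hits.size == 0:
            return
        changed = False
        for o in hits:
            cands = [j for j in range((lo + o) // 3, (lo + o + 5) // 3 + 1)
                     if j not in forbidden]
            if cands:
                j = cands[rng.integers(len(cands))]
                cods[j] = _SENSE64[rng.integers(len(_SENSE64))]
                changed = True
        if not changed:
            return


def simulate_species_genes(config: SimulationConfig,
                           motifs: HexamerSet | None = None):
    """Generate gene models plus the genome they live on.

    Returns (genes, genome) with genome = {"chr1": sequence}. Genes satisfy
    every gene-model filter by construction; ESE hexamers are planted
    codon-aligned in internal-exon flanks at the density model's target
    coverage; exon-boundary dinucleotides controlling donor ("AGgt") and
    acceptor ("agGT") usage are drawn at the configured probabilities;
    introns are canonical gt..ag.
    """
    rng = np.random.default_rng(config.seed)
    motifs = motifs or default_ese_set(config.ese_set_name)
    plantable = _plantable_motifs(motifs)
    genes, chrom_parts = [], []
    cursor = 0
    stop64 = _STOP64

    for gidx in range(config.n_genes):
        k = 3 + rng.poisson(config.exon_count_lambda)
        lens = rng.integers(config.min_exon_len, config.max_exon_len + 1,
                            size=k)
        lens[-1] += (3 - lens.sum() % 3) % 3
        total = int(lens.sum())
        offs = np.concatenate([[0], np.cumsum(lens)[:-1]])
        n_cod = total // 3
        cods = _SENSE64[rng.integers(0, len(_SENSE64), n_cod)]
        cods[0] = CODON_INDEX["ATG"]
        cods[-1] = stop64[rng.integers(3)]

        # splice-site-proximal exon dinucleotides, then motif planting
        assignments = []
        forbidden = {0, n_cod - 1}
        for i in range(k):
            off, length = int(offs[i]), int(lens[i])
            if i < k - 1 and rng.random() < config.p_exon_end_AG:
                assignments += [(off + length - 2, "A"),
                                (off + length - 1, "G")]
            if i > 0 and rng.random() < config.p_exon_start_GT:
                assignments += [(off, "G"), (off + 1, "T")]
            forbidden |= {off // 3, (off + 1) // 3,
                          (off + length - 2) // 3, (off + length - 1) // 3}
        _force_bases(cods, assignments, rng)

        sizes = rng.lognormal(config.intron_mu_ln, config.intron_sigma_ln,
                              size=k - 1)
        sizes = np.maximum(sizes.astype(np.int64), config.min_intron)

        motif_ints = motifs.motif_ints
        for i in range(1, k - 1):
            off, length = int(offs[i]), int(lens[i])
            n_down = (k - 1) - i
            for intron_size, lo, hi in (
                    (int(sizes[i - 1]), off, off + FLANK_LEN),
                    (int(sizes[i]), off + length - FLANK_LEN, off + length)):
                target = (config.base_density
                          + config.density_slope_log_size
                          * (np.log10(intron_size) - 3.0)
                          + config.density_slope_intron_count * (n_down - 3))
                target = float(np.clip(target, 0.0, 0.55))
                # scrub chance hits so realized coverage tracks the target
                _scrub_flank(cods, lo, hi, forbidden, motif_ints, rng)
                slots = [j for j in range((lo + 2) // 3, (hi - 6) // 3 + 1)
                         if 3 * j >= lo and 3 * j + 6 <= hi
                         and j not in forbidden and j + 1 not in forbidden]
                # stochastic rounding keeps E[coverage] linear in the target
                x = target * FLANK_LEN / 6
                n_plant = int(x) + (1 if rng.random() < x - int(x) else 0)
                rng.shuffle(slots)
                taken = set()
                planted = 0
                for j in slots:
                    if planted >= n_plant:
                        break
                    if {j - 1, j, j + 1} & taken:
                        continue
                    m = plantable[rng.integers(len(plantable))]
                    cods[j] = CODON_INDEX[m[:3]]
                    cods[j + 1] = CODON_INDEX[m[3:]]
                    taken |= {j, j + 1}
                    planted += 1

        cds = "".join(CODONS[c] for c in cods)
        strand = "-" if rng.random() < config.minus_strand_frac else "+"

        # assemble the gene region on the coding strand
        region_parts, region_offs = [], []
        pos = 0
        for i in range(k):
            region_offs.append(pos)
            region_parts.append(cds[int(offs[i]):int(offs[i] + lens[i])])
            pos += int(lens[i])
            if i < k - 1:
                filler = "".join(_BASES[rng.integers(0, 4,
                                                     int(sizes[i]) - 4)])
                region_parts.append("GT" + filler + "AG")
                pos += int(sizes[i])
        region = "".join(region_parts)

        spacer = "".join(_BASES[rng.integers(0, 4, 200)])
        base = cursor + 200
        chrom_parts.append(spacer)
        chrom_parts.append(region if strand == "+" else revcomp(region).upper())
        cursor = base + len(region)

        exons = []
        for i in range(k):
            ro, ln = region_offs[i], int(lens[i])
            if strand == "+":
                exons.append((base + ro, base + ro + ln))
            else:
                exons.append((base + len(region) - (ro + ln),
                              base + len(region) - ro))
        genes.append(GeneModel(
            gene_id=f"g{gidx:05d}", seqid="chr1", strand=strand,
            exons=exons, cds_sequence=cds,
            intron_sizes=[int(s) for s in sizes],
            intron_boundaries=[("gt", "ag")] * (k - 1)))
    tail = "".join(_BASES[rng.integers(0, 4, 200)])
    genome = {"chr1": "".join(chrom_parts) + tail}
    return genes, genome


def _jc_ps(d: float) -> float:
    """Expected proportion of differing sites at JC branch length d."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def simulate_ortholog_pair(gene: GeneModel, motifs: HexamerSet,
                           d_core: float, c: float, seed=None):
    """A gap-free codon-aligned ortholog pair for one gene.

    Synonymous sites substitute with per-site probability implied by JC
    branch length d_core outside ESE coverage and d_core·(1 - c) inside.
    ESE coverage is what the analysis masks: hexamer hits within the 69-nt
    flanks of internal exons, a codon counting as covered when >= 2 of its 3
    sites are hit (so flank ESE columns evolve at exactly d_core·(1 - c) and
    cores at d_core). Nonsynonymous positions are held fixed.
    """
    from .gene_models import extract_internal_exon_features

    if not 0.0 <= c <= 1.0:
        raise ValueError("constraint c must be in [0, 1]")
    if _jc_ps(d_core) >= 0.74:
        import warnings
        warnings.warn("d_core near Jukes-Cantor saturation")
    rng = np.random.default_rng(seed)
    cds = gene.cds_sequence
    enc = _encode(cds)
    n_cod = len(cds) // 3
    codon_ese = np.zeros(n_cod, dtype=bool)
    for f in extract_internal_exon_features(gene):
        if f.flank5_seq is None:
            continue
        for lo in (f.cds_offset, f.cds_offset + f.length - FLANK_LEN):
            cov = coverage_from_windows(
                _window_ints(enc[None, lo:lo + FLANK_LEN]),
                motifs.motif_ints, FLANK_LEN)[0]
            first = lo + (3 - lo % 3) % 3
            for p in range(first, lo + FLANK_LEN - 2, 3):
                if cov[p - lo:p - lo + 3].sum() >= 2:
                    codon_ese[p // 3] = True
    ps = np.where(codon_ese, _jc_ps(d_core * (1.0 - c)), _jc_ps(d_core))

    d0 = enc[0::3].astype(np.int64)
    d1 = enc[1::3].astype(np.int64)
    d2 = enc[2::3].astype(np.int64)
    digits = [d0.copy(), d1.copy(), d2.copy()]
    for pos in range(3):
        cur = digits[0] * 16 + digits[1] * 4 + digits[2]
        nalt = _N_ALT[cur, pos]
        p = (nalt / 3.0) * ps
        hit = rng.random(len(cur)) < p
        if hit.any():
            pick = (rng.random(hit.sum()) * nalt[hit]).astype(np.int64)
            digits[pos][hit] = _ALTS[cur[hit], pos, pick]
    b_cods = digits[0] * 16 + digits[1] * 4 + digits[2]
    seq_b = "".join(CODONS[i] for i in b_cods)
    return cds, seq_b


def simulate_polymorphism(theta: float, n: int, L: int, seed=None,
                          species: str = "species") -> PolymorphismSample:
    """Coalescent infinite-sites-style polymorphism sample at per-site θ.

    A neutral genealogy of n haploid samples is simulated with msprime and
    nucleotide mutations dropped at per-site rate θ/2 on a haploid population
    of size 0.5 coalescent units, so that E[π] = θ per site. Mutations use a
    strict Jukes–Cantor state change (no silent transitions); rare recurrent
    hits at one site yield η > S.
    """
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    rng = np.random.default_rng(seed)
    ancestral = _BASES[rng.integers(0, 4, L)]
    mat = np.tile(ancestral, (n, 1))
    if theta > 0:
        ms_seed = int(rng.integers(1, 2 ** 31 - 1))
        ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=0.5,
                                  sequence_length=L,
                                  random_seed=ms_seed)
        third = 1.0 / 3.0
        strict_jc = msprime.MatrixMutationModel(
            ["A", "C", "G", "T"],
            root_distribution=[0.25] * 4,
            transition_matrix=[[0, third, third, third],
                               [third, 0, third, third],
                               [third, third, 0, third],
                               [third, third, third, 0]])
        mts = msprime.sim_mutations(ts, rate=theta, model=strict_jc,
                                    random_seed=ms_seed + 1)
        for var in mts.variants():
            j = int(var.site.position)
            alleles = np.array([a if a else "N" for a in var.alleles])
            mat[:, j] = alleles[var.genotypes]
    seqs = ["".join(row) for row in mat]
    return PolymorphismSample(species, seqs, "intron")


def random_tree(n_tips: int, seed=None) -> dendropy.Tree:
    """A random Kingman coalescent tree with n_tips leaves.

    Coalescent waiting times give strictly positive internal branch lengths,
    which keeps standardized contrasts finite for any trait values.
    """
    r = random.Random(seed)
    taxa = dendropy.TaxonNamespace([f"sp{i:02d}" for i in range(n_tips)])
    return dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=taxa, pop_size=1.0, rng=r)


def simulate_phylo_traits(tree: dendropy.Tree, rate_matrix, seed=None,
                          root=(0.0, 0.0)) -> pd.DataFrame:
    """Bivariate Brownian motion along a tree; returns tip trait values.

    rate_matrix is the 2x2 per-unit-branch-length covariance; it must be
    positive semidefinite.
    """
    R = np.asarray(rate_matrix, dtype=float)
    if R.shape != (2, 2) or not np.allclose(R, R.T):
        raise ValueError("rate matrix must be symmetric 2x2")
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-12:
        raise ValueError("rate matrix must be positive semidefinite")
    rng = np.random.default_rng(seed)
    # PSD square root (Cholesky fails on singular matrices)
    w, V = np.linalg.eigh(R)
    root_mat = V @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ V.T
    values = {}
    rows = {}
    for node in tree.preorder_node_iter():
        bl = node.edge.length or 0.0
        if node.parent_node is None:
            values[node] = np.array(root, dtype=float)
        else:
            step = root_mat @ rng.standard_normal(2) * np.sqrt(bl)
            values[node] = values[node.parent_node] + step
        if node.is_leaf():
            rows[node.taxon.label] = values[node]
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["trait_x", "trait_y"])
    out.index.name = "species"
    return out.sort_index()


def simulate_codon_trend_pool(n_exons: int, n_planted: int = 6,
                              effect: float = 0.5, min_len: int = 68,
                              max_len: int = 100, seed=None):
    """Exon codon pool with positional gradients planted in n_planted codons.

    Planted codons are paired: half decrease in proportional usage with
    distance from the junction (preferred near ends, negative rho), half
    increase, with equal and opposite linear slopes of relative magnitude
    `effect`, so every unplanted codon keeps exactly uniform usage at every
    distance. Distance is min(d5', d3'); min_len >= 2*MAX_DIST keeps the two
    ends' windows disjoint. effect = 0 gives a fully uniform null pool.
    """
    if n_planted % 2:
        raise ValueError("n_planted must be even (paired up/down gradients)")
    if min_len < 2 * MAX_DIST:
        raise ValueError("min_len must be >= twice the trend window")
    rng = np.random.default_rng(seed)
    lens = rng.integers(min_len, max_len + 1, n_exons)
    starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
    total = int(lens.sum())
    codons = rng.integers(0, 61, total)

    if n_planted and effect:
        j = np.concatenate([np.arange(n) for n in lens])
        exon_len = np.repeat(lens, lens)
        d = np.minimum(j + 1, exon_len - j)
        half = n_planted // 2
        for dist in range(MIN_DIST, MAX_DIST + 1):
            idx = np.flatnonzero(d == dist)
            if idx.size == 0:
                continue
            frac = (dist - MIN_DIST) / (MAX_DIST - MIN_DIST)
            delta = effect * (1.0 - 2.0 * frac) / 61.0
            p = np.full(61, 1.0 / 61.0)
            p[:half] += delta          # decreasing usage with distance
            p[half:n_planted] -= delta
            codons[idx] = rng.choice(61, size=idx.size, p=p)
    return [ExonCodons(codons[s:s + n], phase5=False, phase3=False)
            for s, n in zip(starts, lens)]


def simulate_invalid_genes():
    """A tiny GFF3+FASTA bundle exercising every gene-filter rejection path.

    Returns (gff_text, fasta_text); gene ids name the violated rule.
    """
    # hand-built single-chromosome toy cases
    records = []
    chrom = []
    cursor = 0

    def add(gene_id, exon_seqs, intron="GTAAGCATTTTCCAG"):
        nonlocal cursor
        parts, coords = [], []
        pos = cursor
        for i, ex in enumerate(exon_seqs):
            coords.append((pos, pos + len(ex)))
            parts.append(ex)
            pos += len(ex)
            if i < len(exon_seqs) - 1:
                parts.append(intron)
                pos += len(intron)
        chrom.append("".join(parts))
        cursor = pos
        records.append((gene_id, coords))

    add("ok_gene", ["ATGAAAGGG", "CCCGAATAA"])
    add("internal_stop", ["ATGTGACCC", "AAAGGGTAA"])
    add("intronless", ["ATGAAACCCGGGTAA"])
    add("ambiguous_base", ["ATGAANGGG", "CCCGAATAA"])
    add("bad_start", ["TTGAAAGGG", "CCCGAATAA"])
    add("bad_stop", ["ATGAAAGGG", "CCCGAAGCA"])
    add("bad_frame", ["ATGAAAGG", "CCCGAATAA"])

    lines = ["##gff-version 3"]
    for gid, coords in records:
        lo, hi = coords[0][0] + 1, coords[-1][1]
        lines.append(f"chrI\ttoy\tgene\t{lo}\t{hi}\t.\t+\t.\tID={gid}")
        lines.append(f"chrI\ttoy\tmRNA\t{lo}\t{hi}\t.\t+\t.\t"
                     f"ID={gid}.t1;Parent={gid}")
        for k, (s, e) in enumerate(coords, 1):
            lines.append(f"chrI\ttoy\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                         f"ID={gid}.e{k};Parent={gid}.t1")
            lines.append(f"chrI\ttoy\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                         f"ID={gid}.c{k};Parent={gid}.t1")
    gff = "\n".join(lines) + "\n"
    fasta = ">chrI\n" + "".join(chrom) + "\n"
    return gff, fasta


def write_bundle(config: SimulationConfig, out_dir: str) -> dict:
    """Write a full fixture bundle and its manifest; returns the manifest."""
    from .gene_models import write_gff3

    os.makedirs(out_dir, exist_ok=True)
    motifs = default_ese_set(config.ese_set_name)
    genes, genome = simulate_species_genes(config, motifs)
    with open(os.path.join(out_dir, "genome.fasta"), "w") as fh:
        for sid, seq in genome.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_gff3(genes, os.path.join(out_dir, "annotation.gff3"))

    orth_dir = os.path.join(out_dir, "orthologs")
    os.makedirs(orth_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    for g in genes:
        a, b = simulate_ortholog_pair(g, motifs, config.d_core,
                                      config.ese_constraint,
                                      seed=int(rng.integers(2 ** 31)))
        with open(os.path.join(orth_dir, f"{g.gene_id}.fasta"), "w") as fh:
            fh.write(f">{g.gene_id}_ingroup\n{a}\n>{g.gene_id}_outgroup\n{b}\n")

    poly_dir = os.path.join(out_dir, "polymorphism")
    os.makedirs(poly_dir, exist_ok=True)
    sample = simulate_polymorphism(config.theta, config.n_haplotypes,
                                   config.polymorphism_length,
                                   seed=config.seed + 2)
    with open(os.path.join(poly_dir, "locus1.fasta"), "w") as fh:
        for i, s in enumerate(sample.sequences):
            fh.write(f">hap{i}\n{s}\n")

    tree = random_tree(config.n_tips, seed=config.seed + 3)
    tree.write(path=os.path.join(out_dir, "tree.nwk"), schema="newick")
    r = config.bm_rate
    R = np.array([[r, config.rho_true * r], [config.rho_true * r, r]])
    traits = simulate_phylo_traits(tree, R, seed=config.seed + 4)
    traits.to_csv(os.path.join(out_dir, "traits.tsv"), sep="\t")

    with open(os.path.join(out_dir, "ese_hexamers.txt"), "w") as fh:
        fh.write("\n".join(sorted(motifs.motifs)) + "\n")

    manifest = {"seed": config.seed, "config": asdict(config),
                "n_genes": len(genes)}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
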