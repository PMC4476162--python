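"""Positional codon/amino-acid usage trends near exon–intron junctions.

Many genomes show systematic skews in codon usage toward exon ends, driven by
the nucleotide composition of exonic splice enhancers. The trend statistic
here follows that logic: for each codon (61 sense codons) or amino acid (20),
proportional usage is computed at codon distances 2..34 from the junction
(the boundary codon itself is excluded, as are first and last exons) and a
two-tailed Spearman correlation of proportion against distance is taken.
Negative rho means preferred near exon ends. The species-level cis-motif
usage metric Y is the proportion of k-mers whose trend is significant after
Bonferroni correction within the k-mer family, optionally averaged over
repeated subsamples of 5,000 exons to control for exon-count differences
between species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genetics import (AA_INDEX, AMINO_ACIDS, CODON_AA, SENSE_CODONS,
                       SENSE_INDEX, encode_codons)

MIN_DIST = 2
MAX_DIST = 34
N_POS = MAX_DIST - MIN_DIST + 1  # 33 positions

#: amino-acid index of each sense codon, for aggregating codon counts
_AA_OF_SENSE = np.array([AA_INDEX[CODON_AA[c]] for c in SENSE_CODONS])


@dataclass
class TrendProfile:
    kmer: str
    end: str            # "5prime" or "3prime"
    rho: float
    p_raw: float
    significant: bool


@dataclass
class CisMotifUsage:
    species: str
    Y_codon: float
    Y_aa: float
    Y_codon_sub: float
    Y_aa_sub: float


@dataclass
class SpliceSiteUsage:
    species: str
    P1: float   # proportion of donor sites "AGgt"
    P2: float   # proportion of acceptor sites "agGT"


@dataclass
class ExonCodons:
    """Complete in-frame codons of one internal exon, as sense-codon indices.

    phase5/phase3 flag a partial boundary codon at the respective end; the
    partial codon occupies distance position 1 there (and position 1 is always
    dropped from the trend test).
    """

    codons: np.ndarray
    phase5: bool
    phase3: bool


def exon_codon_records(gene) -> list:
    """ExonCodons for every internal exon of a filtered GeneModel."""
    out = []
    offs = gene.cds_offsets
    lens = gene.exon_lengths
    for i in range(1, len(gene.exons) - 1):
        off, length = offs[i], lens[i]
        start = off + (3 - off % 3) % 3            # first complete codon
        stop = off + length - (off + length) % 3   # end of last complete codon
        if stop - start < 3:
            continue
        cod = encode_codons(gene.cds_sequence[start:stop])
        out.append(ExonCodons(_to_sense(cod), phase5=off % 3 != 0,
                              phase3=(off + length) % 3 != 0))
    return out


def _build_sense_map() -> np.ndarray:
    from .genetics import CODON_INDEX

    m = np.full(64, -1, dtype=np.int64)
    for c, i in SENSE_INDEX.items():
        m[CODON_INDEX[c]] = i
    return m


_SENSE_MAP = _build_sense_map()


def _to_sense(cod64: np.ndarray) -> np.ndarray:
    """Map 64-codon indices to sense-codon indices, dropping stops/invalid."""
    out = _SENSE_MAP[cod64]
    return out[out >= 0]


def occurrence_table(exons: list) -> tuple[np.ndarray, np.ndarray]:
    """Flatten an exon pool into (exon_id, cell) occurrence arrays.

    cell = ((end * 61) + codon) * N_POS + (d - MIN_DIST) with end 0 = 5prime,
    1 = 3prime. Used for fast full-pool and subsampled counting.
    """
    exon_ids, cells = [], []
    for eid, ex in enumerate(exons):
        n = len(ex.codons)
        if n == 0:
            continue
        # 5' distances
        d5 = np.arange(n) + (2 if ex.phase5 else 1)
        m5 = (d5 >= MIN_DIST) & (d5 <= MAX_DIST)
        # 3' distances
        d3 = np.arange(n)[::-1] + (2 if ex.phase3 else 1)
        m3 = (d3 >= MIN_DIST) & (d3 <= MAX_DIST)
        c5 = (0 * 61 + ex.codons[m5]) * N_POS + (d5[m5] - MIN_DIST)
        c3 = (1 * 61 + ex.codons[m3]) * N_POS + (d3[m3] - MIN_DIST)
        cell = np.concatenate([c5, c3])
        cells.append(cell)
        exon_ids.append(np.full(len(cell), eid, dtype=np.int64))
    if not cells:
        raise ValueError("empty exon pool")
    return np.concatenate(exon_ids), np.concatenate(cells)


def counts_from_occurrences(exon_ids, cells, weights=None) -> np.ndarray:
    """(2, 61, N_POS) count array, optionally weighted per exon."""
    w = None if weights is None else weights[exon_ids]
    flat = np.bincount(cells, weights=w, minlength=2 * 61 * N_POS)
    return flat.reshape(2, 61, N_POS)


def spearman_by_column(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-tailed Spearman of each column of P against row order.

    Average ranks for ties; t-approximation for p (n = number of rows).
    Constant columns yield rho = 0, p = 1.
    """
    n, k = P.shape
    rp = stats.rankdata(P, axis=0)
    rd = np.arange(1, n + 1, dtype=float)[:, None]
    rp_c = rp - rp.mean(axis=0)
    rd_c = rd - rd.mean()
    denom = np.sqrt((rp_c ** 2).sum(axis=0) * (rd_c ** 2).sum())
    rho = np.zeros(k)
    ok = denom > 0
    num = (rp_c * rd_c).sum(axis=0)
    rho[ok] = num[ok] / denom[ok]
    rho = np.clip(rho, -1.0, 1.0)
    p = np.ones(k)
    sub = ok & (np.abs(rho) < 1.0)
    t = rho[sub] * np.sqrt((n - 2) / (1.0 - rho[sub] ** 2))
    p[sub] = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[ok & (np.abs(rho) >= 1.0)] = 0.0
    return rho, p


def trend_from_counts(counts: np.ndarray, family: str = "codon",
                      alpha: float = 0.05):
    """Trend test from a (61, N_POS) codon count matrix for one end.

    Returns (rho, p_raw, significant) arrays over the k-mer family; the
    Bonferroni threshold is alpha / family size (61 codons or 20 amino
    acids), applied within family and per end.
    """
    if family == "amino_acid":
        mat = np.zeros((len(AMINO_ACIDS), counts.shape[1]))
        np.add.at(mat, _AA_OF_SENSE, counts)
        counts = mat
    elif family != "codon":
        raise ValueError("family must be 'codon' or 'amino_acid'")
    totals = counts.sum(axis=0)
    used = totals > 0
    if used.sum() < 2:
        raise ValueError("fewer than 2 positions with nonzero totals")
    P = (counts[:, used] / totals[used]).T
    rho, p = spearman_by_column(P)
    thresh = alpha / counts.shape[0]
    return rho, p, p < thresh


def positional_trend_test(exons: list, family: str = "codon",
                          end: str = "5prime", alpha: float = 0.05):
    """TrendProfiles for each k-mer of a family at one exon end."""
    eids, cells = occurrence_table(exons)
    counts = counts_from_occurrences(eids, cells)
    eidx = 0 if end == "5prime" else 1
    rho, p, sig = trend_from_counts(counts[eidx], family, alpha)
    names = SENSE_CODONS if family == "codon" else AMINO_ACIDS
    return [TrendProfile(k, end, float(r), float(pv), bool(s))
            for k, r, pv, s in zip(names, rho, p, sig)]


def _y_from_counts(counts: np.ndarray, alpha: float, both_ends: bool):
    """(Y_codon, Y_aa) from a (2, 61, N_POS) count array."""
    ys = []
    for family, size in (("codon", 61), ("amino_acid", len(AMINO_ACIDS))):
        sig = np.zeros((2, size), dtype=bool)
        for e in range(2):
            _, _, sig[e] = trend_from_counts(counts[e], family, alpha)
        hit = sig.all(axis=0) if both_ends else sig.any(axis=0)
        ys.append(hit.mean())
    return ys


def cis_motif_usage_metric(exons: list, subsample_size: int = 5000,
                           repetitions: int = 100, seed=None,
                           alpha: float = 0.05, both_ends: bool = False,
                           species: str = "species") -> CisMotifUsage:
    """Full-pool and subsample-averaged cis-motif usage metric Y.

    The subsampled metric draws `subsample_size` exons with replacement
    `repetitions` times and averages the proportion of significant k-mers;
    deterministic given the seed.
    """
    if subsample_size <= 0:
        raise ValueError("subsample_size must be positive")
    eids, cells = occurrence_table(exons)
    n_pool = len(exons)
    counts = counts_from_occurrences(eids, cells)
    y_codon, y_aa = _y_from_counts(counts, alpha, both_ends)

    rng = np.random.default_rng(seed)
    subs = np.zeros((repetitions, 2))
    for r in range(repetitions):
        draw = rng.integers(0, n_pool, size=subsample_size)
        mult = np.bincount(draw, minlength=n_pool).astype(float)
        c = counts_from_occurrences(eids, cells, weights=mult)
        subs[r] = _y_from_counts(c, alpha, both_ends)
    return CisMotifUsage(species, float(y_codon), float(y_aa),
                         float(subs[:, 0].mean()), float(subs[:, 1].mean()))


def splice_site_usage(features, species: str = "species") -> SpliceSiteUsage:
    """P1 = proportion of donors "AGgt"; P2 = proportion of acceptors "agGT"."""
    donors = [f.donor_string for f in features if f.donor_string]
    acceptors = [f.acceptor_string for f in features if f.acceptor_string]
    if not donors or not acceptors:
        raise ValueError("no donor/acceptor strings available")
    p1 = sum(d == "AGgt" for d in donors) / len(donors)
    p2 = sum(a == "agGT" for a in acceptors) / len(acceptors)
    return SpliceSiteUsage(species, p1, p2)
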