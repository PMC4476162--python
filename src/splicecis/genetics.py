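"""Codon-level machinery shared across the package.

Provides the standard genetic code, integer codon encoding, synonymous-site
counting and the Nei–Gojobori (1986) pairwise tables used by the Ks engine.
Changes to or from stop codons are treated as nonsynonymous in site counting,
and mutational pathways passing through a stop codon are excluded from the
multiple-hit averaging (falling back to all pathways only when every pathway
is blocked by a stop).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations, product

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: all 64 codons in lexicographic ACGT order; codon i decodes base-4 digits of i
CODONS = ["".join(c) for c in product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

#: one-letter amino acid per codon, '*' for stop
CODON_AA = {c: str(Seq(c).translate()) for c in CODONS}
STOP_CODONS = frozenset(c for c, a in CODON_AA.items() if a == "*")
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

AMINO_ACIDS = sorted({a for a in CODON_AA.values() if a != "*"})
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string, preserving case."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_codons(seq: str) -> np.ndarray:
    """Encode an in-frame nucleotide string as an int array of codon indices.

    Codons containing characters outside ACGT (gaps, ambiguity codes) encode
    as -1 so callers can mask them out.
    """
    if len(seq) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        idx[arr == ord(b)] = i
    cod = idx.reshape(-1, 3)
    bad = (cod < 0).any(axis=1)
    out = cod[:, 0] * 16 + cod[:, 1] * 4 + cod[:, 2]
    out[bad] = -1
    return out


def synonymous_site_fraction(codon: str) -> float:
    """NG86 synonymous site count of one codon (0..3).

    Each position contributes (number of synonymous single-base changes)/3;
    changes to stop codons count as nonsynonymous.
    """
    if codon in STOP_CODONS:
        return 0.0
    aa = CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_AA[alt] == aa:
                s += 1.0
    return s / 3.0


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between two codons.

    Averages over all orderings of the differing positions; orderings whose
    intermediate codons are stops are excluded, unless every ordering is
    blocked, in which case all orderings are used (steps to/from stops counted
    nonsynonymous).
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order):
        cur, sd, nd, blocked = a, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != b:
                blocked = True
            if (cur not in STOP_CODONS and nxt not in STOP_CODONS
                    and CODON_AA[cur] == CODON_AA[nxt]):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd, blocked

    paths = [walk(order) for order in permutations(diff)]
    open_paths = [(s, n) for s, n, blocked in paths if not blocked]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd


@lru_cache(maxsize=1)
def ng86_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precomputed NG86 lookup tables over all 64x64 codon pairs.

    Returns (syn_sites[64], syn_diff[64,64], nonsyn_diff[64,64], valid[64,64])
    where valid is False when either codon is a stop.
    """
    s_sites = np.array([synonymous_site_fraction(c) for c in CODONS])
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    valid = np.ones((64, 64), dtype=bool)
    for i, a in enumerate(CODONS):
        for j, b in enumerate(CODONS):
            if a in STOP_CODONS or b in STOP_CODONS:
                valid[i, j] = False
                continue
            sd[i, j], nd[i, j] = _pathway_counts(a, b)
    return s_sites, sd, nd, valid


@dataclass
class KsEstimate:
    """NG86 synonymous divergence between two aligned coding sequences."""

    ks: float                 # JC-corrected synonymous substitutions per site
    syn_sites: float          # synonymous sites, averaged over both sequences
    syn_diffs: float          # pathway-averaged synonymous differences
    nonsyn_sites: float
    nonsyn_diffs: float
    n_codons: int             # codon columns actually used
    saturated: bool = False   # ps >= 3/4, log correction undefined

    @property
    def ps(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites > 0 else np.nan


def ks_from_codons(a: np.ndarray, b: np.ndarray) -> KsEstimate:
    """NG86 Ks from two equal-length arrays of 64-space codon indices.

    Entries that are negative (gap/ambiguity) or stop codons in either
    sequence are skipped. Raises ValueError when no usable codon column or no
    synonymous site remains.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    s_sites, sd_tab, nd_tab, valid_tab = ng86_tables()
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    ok2 = valid_tab[a, b]
    a, b = a[ok2], b[ok2]
    n_cod = len(a)
    if n_cod == 0:
        raise ValueError("no usable codon columns")
    s = 0.5 * (s_sites[a].sum() + s_sites[b].sum())
    n = 3.0 * n_cod - s
    sd = sd_tab[a, b].sum()
    nd = nd_tab[a, b].sum()
    if s <= 0:
        raise ValueError("zero synonymous sites; Ks undefined")
    ps = sd / s
    if ps >= 0.75:
        return KsEstimate(np.nan, s, sd, n, nd, n_cod, saturated=True)
    ks = -0.75 * np.log(1.0 - (4.0 / 3.0) * ps)
    return KsEstimate(ks, s, sd, n, nd, n_cod, saturated=False)


def ks_ng86(seq_a: str, seq_b: str) -> KsEstimate:
    """Nei–Gojobori (1986) Ks with Jukes–Cantor correction.

    Sequences must be equal-length, in-frame codon alignments; codon columns
    containing gaps, ambiguity codes or stop codons are skipped.
    """
    return ks_from_codons(encode_codons(seq_a), encode_codons(seq_b))
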