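"""Independent brute-force oracles used only by the test suite.

These re-derive expected values from first principles with naive string
manipulation and exhaustive enumeration, deliberately sharing no code with
the package implementation.
"""

from itertools import permutations

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def syn_sites_oracle(codon: str) -> float:
    """Synonymous sites of one codon; changes to stops are nonsynonymous."""
    if codon in STOPS:
        return 0.0
    total = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOPS and _aa(alt) == _aa(codon):
                total += 1
    return total / 3.0


def pair_diffs_oracle(a: str, b: str):
    """Pathway-averaged (syn, nonsyn) differences between two codons.

    All orderings of the differing positions are listed explicitly; orderings
    visiting a stop intermediate are discarded unless all are.
    """
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in permutations(positions):
        cur = a
        steps = []
        stop_hit = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOPS and nxt != b:
                stop_hit = True
            steps.append((cur, nxt))
            cur = nxt
        sd = sum(1 for x, y in steps
                 if x not in STOPS and y not in STOPS and _aa(x) == _aa(y))
        nd = len(steps) - sd
        results.append((sd, nd, stop_hit))
    usable = [(s, n) for s, n, hit in results if not hit]
    if not usable:
        usable = [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def ks_oracle(seq_a: str, seq_b: str):
    """NG86 + Jukes-Cantor Ks by direct accumulation over codons.

    Returns (ks, ps); np.nan ks when saturated.
    """
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = sd = n_used = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if set(ca + cb) - set("ACGT") or ca in STOPS or cb in STOPS:
            continue
        S += (syn_sites_oracle(ca) + syn_sites_oracle(cb)) / 2.0
        sd += pair_diffs_oracle(ca, cb)[0]
        n_used += 1
    if n_used == 0 or S == 0:
        raise ValueError("no usable synonymous sites")
    ps = sd / S
    if ps >= 0.75:
        return np.nan, ps
    return -0.75 * np.log(1 - 4.0 * ps / 3.0), ps


def gamma_oracle(x, y) -> float:
    """Goodman-Kruskal gamma by O(n^2) pair enumeration."""
    c = d = 0
    n = len(x)
    for i in range(n - 1):
        for j in range(i + 1, n):
            sx = np.sign(x[j] - x[i])
            sy = np.sign(y[j] - y[i])
            if sx == 0 or sy == 0:
                continue
            if sx == sy:
                c += 1
            else:
                d += 1
    if c + d == 0:
        raise ValueError("all pairs tied")
    return (c - d) / (c + d)


def spearman_oracle(x, y) -> float:
    """Rank-then-Pearson Spearman rho with average ranks."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
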