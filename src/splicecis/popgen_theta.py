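"""Per-site N_e·μ estimation from polymorphism alignments.

Three standard estimators of the population-scaled mutation rate θ are
computed per site from n aligned haplotypes: nucleotide diversity π (mean
pairwise differences), Watterson's θ_S from the number of segregating sites
S / a_n with a_n = Σ_{i=1}^{n-1} 1/i, and θ_η from the minimum mutation count
η (a site with k distinct bases contributes k − 1). Under the neutral model
θ = 4·N_e·μ for diploid autosomes, so N_e·μ = θ / 4 by default (the ploidy
factor is configurable). A synonymous-sites-only mode restricts S, η and π to
synonymous variation in coding input, with L the NG86 synonymous site count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .genetics import CODON_AA, CODONS, ng86_tables

_ORD = {b: i for i, b in enumerate("ACGT")}


@dataclass
class PolymorphismSample:
    """n aligned haplotypes over L sites from one species/locus."""

    species: str
    sequences: list
    locus_class: str = "intron"   # "intron" or "cds_synonymous"

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise ValueError("need at least 2 haplotypes")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("haplotypes must be aligned to equal length")


@dataclass
class ThetaEstimates:
    species: str
    n: int
    L: float
    pi: float
    S: int
    eta: int
    theta_pi: float
    theta_S: float
    theta_eta: float
    ne_mu_pi: float
    ne_mu_S: float
    ne_mu_eta: float


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def _site_matrix(sample: PolymorphismSample) -> np.ndarray:
    """(n, L) base-index matrix; columns with any gap/ambiguity dropped."""
    mat = np.full((len(sample.sequences), len(sample.sequences[0])), -1,
                  dtype=np.int8)
    for i, s in enumerate(sample.sequences):
        arr = np.frombuffer(s.upper().encode(), dtype=np.uint8)
        for b, j in _ORD.items():
            mat[i, arr == ord(b)] = j
    keep = (mat >= 0).all(axis=0)
    return mat[:, keep]


def _pairwise_diffs(mat: np.ndarray) -> float:
    """Mean pairwise difference count over all haplotype pairs."""
    n = mat.shape[0]
    total = 0
    for i in range(n - 1):
        total += (mat[i + 1:] != mat[i]).sum()
    return total / (n * (n - 1) / 2)


def _synonymous_partition(mat: np.ndarray):
    """(is_syn_segregating per site, synonymous site count L_syn).

    A segregating nucleotide site is synonymous when every haplotype codon
    containing it encodes the same amino acid; L_syn is the NG86 synonymous
    site count averaged over haplotypes.
    """
    n, L = mat.shape
    L3 = L - L % 3
    mat = mat[:, :L3]
    s_sites, *_ = ng86_tables()
    cod = (mat[:, 0::3].astype(np.int64) * 16
           + mat[:, 1::3] * 4 + mat[:, 2::3])
    aa = np.array([CODON_AA[c] for c in CODONS])
    sense = np.array([CODON_AA[c] != "*" for c in CODONS])
    cod_ok = sense[cod].all(axis=0)          # codon columns with no stop
    aa_uniform = np.array([
        len(set(aa[cod[:, j]])) == 1 for j in range(cod.shape[1])])
    syn_codon = cod_ok & aa_uniform
    seg = np.array([len(np.unique(mat[:, j])) > 1 for j in range(L3)])
    syn_site = np.repeat(syn_codon, 3) & seg
    L_syn = float(s_sites[cod[:, cod_ok]].sum(axis=1).mean()) if cod_ok.any() else 0.0
    return syn_site, L_syn, mat


def theta_estimates(sample: PolymorphismSample,
                    ploidy_factor: float = 4.0) -> ThetaEstimates:
    """π, Watterson and η estimates of θ per site, plus N_e·μ = θ/ploidy.

    In cds_synonymous mode only synonymous segregating sites enter S, η and
    π, and L is the synonymous site count.
    """
    mat = _site_matrix(sample)
    n, L = mat.shape
    if L == 0:
        raise ValueError("no usable sites after filtering")
    a_n = harmonic_number(n - 1)

    if sample.locus_class == "cds_synonymous":
        syn_site, L_eff, mat3 = _synonymous_partition(mat)
        sub = mat3[:, syn_site]
        if L_eff <= 0:
            raise ValueError("zero synonymous sites")
        S = sub.shape[1]
        eta = int(sum(len(np.unique(sub[:, j])) - 1
                      for j in range(sub.shape[1])))
        pi = _pairwise_diffs(sub) if S else 0.0
    else:
        L_eff = float(L)
        seg_counts = np.array([len(np.unique(mat[:, j])) for j in range(L)])
        S = int((seg_counts > 1).sum())
        eta = int((seg_counts - 1).sum())
        pi = _pairwise_diffs(mat)

    theta_pi = pi / L_eff
    theta_S = S / (a_n * L_eff)
    theta_eta = eta / (a_n * L_eff)
    return ThetaEstimates(
        sample.species, n, L_eff, pi, S, eta, theta_pi, theta_S, theta_eta,
        ne_mu_from_theta(theta_pi, ploidy_factor),
        ne_mu_from_theta(theta_S, ploidy_factor),
        ne_mu_from_theta(theta_eta, ploidy_factor))


def ne_mu_from_theta(theta: float, ploidy_factor: float = 4.0) -> float:
    """N_e·μ per site from θ; ploidy_factor 4 (diploid) or 2 (haploid)."""
    if ploidy_factor <= 0:
        raise ValueError("ploidy_factor must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return theta / ploidy_factor


def load_polymorphism_fasta(path: str, species: str = "species",
                            locus_class: str = "intron") -> PolymorphismSample:
    """Read one locus of aligned haplotypes from a FASTA file."""
    seqs = [str(r.seq).upper() for r in SeqIO.parse(path, "fasta")]
    return PolymorphismSample(species, seqs, locus_class)


def combined_estimates(samples, ploidy_factor: float = 4.0) -> ThetaEstimates:
    """L-weighted average of per-locus estimates for one species."""
    ests = [theta_estimates(s, ploidy_factor) for s in samples]
    w = np.array([e.L for e in ests])
    wsum = w.sum()

    def avg(attr):
        return float(sum(getattr(e, attr) * wi for e, wi in zip(ests, w))
                     / wsum)

    first = ests[0]
    return ThetaEstimates(
        first.species, first.n, float(wsum),
        avg("pi"), int(sum(e.S for e in ests)), int(sum(e.eta for e in ests)),
        avg("theta_pi"), avg("theta_S"), avg("theta_eta"),
        avg("ne_mu_pi"), avg("ne_mu_S"), avg("ne_mu_eta"))
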