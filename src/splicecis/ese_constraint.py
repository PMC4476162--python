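"""ESE masking, Ks partitioning and the flank-constraint selection metrics.

Exonic splice enhancers (ESEs) are hexamer motifs concentrated in the 69-bp
flanks of internal exons. Masking a flank with a hexamer set partitions its
sites into ESE (covered by at least one exact motif hit) and non-ESE; a codon
column counts as ESE when at least two of its three sites are covered. The
synonymous divergence (NG86 Ks) of ESE flank sequence is compared with the
Ks of 69-bp exon cores, giving the flank ESE constraint

    constraint = (Ks_core - Ks_ESE_flank) / Ks_core,

the fraction of synonymous divergence removed by selection on ESEs. Because
individual flanks carry very few synonymous sites, exon ends are pooled into
20 equal-occupancy flanking-intron-size bins and each partition concatenated
before estimating Ks. Pseudo-ESE hexamer sets of matched size and nucleotide
composition provide a mutational-bias null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import encode_codons, ks_from_codons
from .gene_models import FLANK_LEN
from . import stats_core

HEXLEN = 6
_POW4 = 4 ** np.arange(HEXLEN - 1, -1, -1)
_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_LUT[ord(_b)] = _i


@dataclass(frozen=True)
class HexamerSet:
    """A named set of 6-mer motifs (ESE or pseudo-ESE)."""

    name: str
    motifs: frozenset

    def __post_init__(self):
        for m in self.motifs:
            if len(m) != HEXLEN or not set(m) <= set("ACGT"):
                raise ValueError(f"invalid hexamer {m!r}")

    def __len__(self):
        return len(self.motifs)

    @property
    def motif_ints(self) -> np.ndarray:
        return np.sort(np.array([_encode(m) @ _POW4 for m in self.motifs]))

    @property
    def base_frequencies(self) -> np.ndarray:
        """Pooled A,C,G,T frequencies over all motifs."""
        counts = np.zeros(4)
        for m in self.motifs:
            np.add.at(counts, _encode(m), 1)
        return counts / counts.sum()


@dataclass
class ESEMask:
    """Positions of a flank covered by at least one hexamer hit."""

    covered_sites: frozenset
    density: float


def load_hexamer_set(path: str, name: str | None = None) -> HexamerSet:
    """Read a hexamer set from a plain-text file, one 6-mer per line."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            m = line.strip().upper()
            if m:
                motifs.append(m)
    if len(set(motifs)) != len(motifs):
        raise ValueError(f"duplicate motifs in {path}")
    return HexamerSet(name or path, frozenset(motifs))


def _encode(seq: str) -> np.ndarray:
    arr = _BASE_LUT[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError(f"sequence contains non-ACGT characters: {seq!r}")
    return arr


def _window_ints(mat: np.ndarray) -> np.ndarray:
    """Base-4 integer of every 6-mer window; mat is (n, L) base indices."""
    win = np.lib.stride_tricks.sliding_window_view(mat, HEXLEN, axis=-1)
    return win @ _POW4


def coverage_from_windows(wins: np.ndarray, motif_ints: np.ndarray,
                          length: int) -> np.ndarray:
    """Boolean coverage matrix (n, length) from per-window integers."""
    hits = np.isin(wins, motif_ints)
    cov = np.zeros(wins.shape[:-1] + (length,), dtype=bool)
    for s in range(HEXLEN):
        cov[..., s:s + wins.shape[-1]] |= hits
    return cov


def mask_ese_and_density(flank_seq: str, motifs: HexamerSet) -> ESEMask:
    """Mask one 69-nt flank: union of all exact hexamer hits.

    density = covered positions / 69.
    """
    if len(flank_seq) != FLANK_LEN:
        raise ValueError(f"flank must be {FLANK_LEN} nt")
    enc = _encode(flank_seq)[None, :]
    cov = coverage_from_windows(_window_ints(enc), motifs.motif_ints,
                                FLANK_LEN)[0]
    covered = frozenset(np.flatnonzero(cov).tolist())
    return ESEMask(covered, len(covered) / FLANK_LEN)


def generate_pseudo_hexamers(motifs: HexamerSet, rng,
                             name: str = "pseudo") -> HexamerSet:
    """A pseudo-ESE set: same cardinality, bases drawn i.i.d. per position
    from the true set's pooled base frequencies; duplicates redrawn.
    Coincidental matches to true motifs are not excluded.
    """
    freqs = motifs.base_frequencies
    bases = np.array(list("ACGT"))
    out = set()
    while len(out) < len(motifs):
        h = "".join(bases[rng.choice(4, HEXLEN, p=freqs)])
        out.add(h)
    return HexamerSet(name, frozenset(out))


# ---------------------------------------------------------------------------
# alignment plumbing

@dataclass
class RegionCodons:
    """In-frame codon columns of one flank or core region of an alignment.

    a/b are 64-space codon indices for ingroup/outgroup; pos (n, 3) carries
    each codon's site positions local to the 69-nt region (flanks only).
    """

    a: np.ndarray
    b: np.ndarray
    pos: np.ndarray | None = None


@dataclass
class AlignedFeature:
    """An internal-exon feature joined to its ortholog alignment regions."""

    feature: object            # ExonFeature
    flank5: RegionCodons | None = None
    flank3: RegionCodons | None = None
    core: RegionCodons | None = None


def _region_codons(aln_a: str, aln_b: str, pos_to_col: np.ndarray,
                   cds_start: int, cds_stop: int, local_origin: int | None):
    """Codon columns for CDS interval [cds_start, cds_stop)."""
    first = cds_start + (3 - cds_start % 3) % 3
    a_cods, b_cods, pos_rows = [], [], []
    for p in range(first, cds_stop - 2, 3):
        cols = pos_to_col[p:p + 3]
        a_cod = "".join(aln_a[c] for c in cols)
        b_cod = "".join(aln_b[c] for c in cols)
        if "-" in b_cod or "-" in a_cod:
            continue
        a_cods.append(a_cod)
        b_cods.append(b_cod)
        if local_origin is not None:
            pos_rows.append([p - local_origin, p + 1 - local_origin,
                             p + 2 - local_origin])
    if not a_cods:
        return None
    a = encode_codons("".join(a_cods))
    b = encode_codons("".join(b_cods))
    pos = np.array(pos_rows) if local_origin is not None else None
    return RegionCodons(a, b, pos)


def align_gene_features(gene, features, aln_a: str, aln_b: str):
    """Join ExonFeatures to regions of a codon-aligned ortholog pair.

    aln_a is the ingroup CDS with gaps '-' (ungapped it must equal the gene's
    CDS), aln_b the aligned outgroup sequence.
    """
    ungapped = aln_a.replace("-", "")
    if ungapped != gene.cds_sequence:
        raise ValueError(f"alignment does not match CDS of {gene.gene_id}")
    pos_to_col = np.flatnonzero(np.frombuffer(aln_a.encode(), dtype=np.uint8)
                                != ord("-"))
    out = []
    for f in features:
        af = AlignedFeature(feature=f)
        if f.flank5_seq is not None:
            off = f.cds_offset
            af.flank5 = _region_codons(aln_a, aln_b, pos_to_col,
                                       off, off + FLANK_LEN, off)
            end3 = off + f.length
            af.flank3 = _region_codons(aln_a, aln_b, pos_to_col,
                                       end3 - FLANK_LEN, end3,
                                       end3 - FLANK_LEN)
            mid = off + (f.length - FLANK_LEN) // 2
            af.core = _region_codons(aln_a, aln_b, pos_to_col,
                                     mid, mid + FLANK_LEN, None)
        out.append(af)
    return out


# ---------------------------------------------------------------------------
# binned constraint

def _safe_ks(a_list, b_list) -> float:
    if not a_list:
        return np.nan
    a = np.concatenate(a_list)
    b = np.concatenate(b_list)
    try:
        est = ks_from_codons(a, b)
    except ValueError:
        return np.nan
    return est.ks


def _end_records(aligned_features, end: str):
    """(feature, flank_region, intron_size, flank_seq) for one end."""
    recs = []
    for af in aligned_features:
        f = af.feature
        if end == "5prime" and af.flank5 is not None:
            recs.append((f, af.flank5, af.core, f.intron5, f.flank5_seq))
        elif end == "3prime" and af.flank3 is not None:
            recs.append((f, af.flank3, af.core, f.intron3, f.flank3_seq))
    recs.sort(key=lambda r: (r[3], r[0].gene_id, r[0].exon_index))
    return recs


def _codon_ese_flags(region: RegionCodons, cov: np.ndarray) -> np.ndarray:
    """A codon column is ESE when >= 2 of its 3 sites are covered."""
    return cov[region.pos].sum(axis=1) >= 2


def binned_flank_constraint(aligned_features, motifs: HexamerSet,
                            n_bins: int = 20, pseudo_reps: int = 100,
                            seed=None) -> dict:
    """Per-bin Ks of ESE / non-ESE / core partitions and flank constraint.

    Exon ends are apportioned into n_bins equal-occupancy bins by flanking
    intron size (5' and 3' ends against their own flanking intron,
    separately); each partition is concatenated within a bin before a single
    Ks estimate. Pseudo-ESE columns are re-masked with `pseudo_reps`
    composition-matched random hexamer sets. Returns {"5prime": DataFrame,
    "3prime": DataFrame} with columns bin, upper_limit, n_ends, ks_ese,
    ks_non_ese, ks_core, ks_pseudo_mean, ks_pseudo_se, constraint.
    """
    rng = np.random.default_rng(seed)
    pseudo_sets = [generate_pseudo_hexamers(motifs, rng, name=f"pseudo{k}")
                   for k in range(pseudo_reps)]
    out = {}
    for end in ("5prime", "3prime"):
        recs = _end_records(aligned_features, end)
        if n_bins > len(recs):
            raise ValueError(
                f"n_bins={n_bins} exceeds {len(recs)} exon ends at {end}")
        flank_mat = np.stack([_encode(r[4]) for r in recs])
        wins = _window_ints(flank_mat)
        cov_true = coverage_from_windows(wins, motifs.motif_ints, FLANK_LEN)
        groups = np.array_split(np.arange(len(recs)), n_bins)
        rows = []
        for b, idx in enumerate(groups):
            ese_a, ese_b, non_a, non_b, core_a, core_b = ([] for _ in range(6))
            for i in idx:
                _, region, core, _, _ = recs[i]
                flags = _codon_ese_flags(region, cov_true[i])
                ese_a.append(region.a[flags]); ese_b.append(region.b[flags])
                non_a.append(region.a[~flags]); non_b.append(region.b[~flags])
                if core is not None:
                    core_a.append(core.a); core_b.append(core.b)
            ks_ese = _safe_ks(ese_a, ese_b)
            ks_non = _safe_ks(non_a, non_b)
            ks_core = _safe_ks(core_a, core_b)
            pseudo_ks = []
            for pset in pseudo_sets:
                cov_p = coverage_from_windows(wins[idx], pset.motif_ints,
                                              FLANK_LEN)
                pa, pb = [], []
                for j, i in enumerate(idx):
                    _, region, _, _, _ = recs[i]
                    flags = _codon_ese_flags(region, cov_p[j])
                    pa.append(region.a[flags]); pb.append(region.b[flags])
                pseudo_ks.append(_safe_ks(pa, pb))
            pseudo_ks = np.array(pseudo_ks, dtype=float)
            ok = np.isfinite(pseudo_ks)
            p_mean = pseudo_ks[ok].mean() if ok.any() else np.nan
            p_se = (pseudo_ks[ok].std(ddof=1) / np.sqrt(ok.sum())
                    if ok.sum() > 1 else np.nan)
            constraint = ((ks_core - ks_ese) / ks_core
                          if np.isfinite(ks_core) and ks_core > 0
                          and np.isfinite(ks_ese) else np.nan)
            rows.append({
                "bin": b, "upper_limit": recs[idx[-1]][3], "n_ends": len(idx),
                "ks_ese": ks_ese, "ks_non_ese": ks_non, "ks_core": ks_core,
                "ks_pseudo_mean": p_mean, "ks_pseudo_se": p_se,
                "constraint": constraint,
            })
        out[end] = pd.DataFrame(rows)
    return out


def selection_proportion_per_exon(aligned_features, motifs: HexamerSet) -> dict:
    """Per-exon-end ESE density x regression-interpolated constraint.

    For each end an OLS line of unbinned per-end constraint against
    log10(flanking intron size) is fitted (ends with undefined Ks excluded);
    each exon end then gets selection = density x line(log10 size), with
    negative interpolated constraints retained unfloored. Returns per end a
    dict with the per-end table, the fitted (slope, intercept) and the
    Spearman rho/p of selection vs log10 intron size.
    """
    out = {}
    for end in ("5prime", "3prime"):
        recs = _end_records(aligned_features, end)
        if not recs:
            raise ValueError(f"no exon ends with flanks at {end}")
        flank_mat = np.stack([_encode(r[4]) for r in recs])
        cov = coverage_from_windows(_window_ints(flank_mat),
                                    motifs.motif_ints, FLANK_LEN)
        rows = []
        for i, (f, region, core, intron, _) in enumerate(recs):
            flags = _codon_ese_flags(region, cov[i])
            ks_ese = _safe_ks([region.a[flags]], [region.b[flags]])
            ks_core = (_safe_ks([core.a], [core.b])
                       if core is not None else np.nan)
            constraint = ((ks_core - ks_ese) / ks_core
                          if np.isfinite(ks_core) and ks_core > 0
                          and np.isfinite(ks_ese) else np.nan)
            rows.append({
                "gene_id": f.gene_id, "exon_index": f.exon_index,
                "intron_size": intron, "log10_intron": np.log10(intron),
                "density": cov[i].mean(), "constraint_raw": constraint,
            })
        tab = pd.DataFrame(rows)
        fit_ok = tab["constraint_raw"].notna()
        if fit_ok.sum() < 3:
            raise ValueError("fewer than 3 points for constraint regression")
        slope, intercept = np.polyfit(tab.loc[fit_ok, "log10_intron"],
                                      tab.loc[fit_ok, "constraint_raw"], 1)
        tab["constraint_interp"] = intercept + slope * tab["log10_intron"]
        tab["selection"] = tab["density"] * tab["constraint_interp"]
        rho, p = stats_core.spearman(tab["selection"], tab["log10_intron"])
        out[end] = {"table": tab, "slope": float(slope),
                    "intercept": float(intercept), "rho": rho, "p": p}
    return out


def gene_level_constraint(genes, aligned_features, motifs: HexamerSet,
                          cutoff: int = 102, resample_reps: int = 1000,
                          perm_m: int = 1000, seed=None,
                          alpha: float = 0.05) -> dict:
    """Gene-level flank ESE constraint vs the three intronic dimensions.

    All flank ESE codon columns of a gene (both ends) and all core columns
    are concatenated; genes whose concatenations exceed `cutoff` bp are
    retained and a single constraint computed per gene. Association of
    constraint with mean intron size, intron density (introns/kb CDS) and
    intron number is assessed by Spearman, partial Spearman (controlling the
    other two) and Goodman–Kruskal gamma with a permutation p-value.
    The resampling report draws (without replacement) as many genes as pass
    the 150-bp cutoff from the retained pool, `resample_reps` times, and
    records the fraction of draws with Spearman p < alpha per dimension.
    """
    if cutoff not in (102, 150, 201):
        warnings.warn(f"non-standard cutoff {cutoff} bp; proceeding")
    rng = np.random.default_rng(seed)
    by_gene = {}
    for af in aligned_features:
        by_gene.setdefault(af.feature.gene_id, []).append(af)
    gene_map = {g.gene_id: g for g in genes}

    rows = []
    for gid, afs in by_gene.items():
        gene = gene_map.get(gid)
        if gene is None:
            continue
        flanks, regions = [], []
        for af in afs:
            for region, seq in ((af.flank5, af.feature.flank5_seq),
                                (af.flank3, af.feature.flank3_seq)):
                if region is not None and seq is not None:
                    flanks.append(seq)
                    regions.append(region)
        core_a = [af.core.a for af in afs if af.core is not None]
        core_b = [af.core.b for af in afs if af.core is not None]
        if not regions or not core_a:
            continue
        mat = np.stack([_encode(s) for s in flanks])
        cov = coverage_from_windows(_window_ints(mat), motifs.motif_ints,
                                    FLANK_LEN)
        ese_a, ese_b = [], []
        for region, c in zip(regions, cov):
            flags = _codon_ese_flags(region, c)
            ese_a.append(region.a[flags]); ese_b.append(region.b[flags])
        ese_len = 3 * sum(len(x) for x in ese_a)
        core_len = 3 * sum(len(x) for x in core_a)
        ks_ese = _safe_ks(ese_a, ese_b)
        ks_core = _safe_ks(core_a, core_b)
        constraint = ((ks_core - ks_ese) / ks_core
                      if np.isfinite(ks_core) and ks_core > 0
                      and np.isfinite(ks_ese) else np.nan)
        rows.append({
            "gene_id": gid, "ese_len": ese_len, "core_len": core_len,
            "constraint": constraint,
            "mean_intron_size": float(np.mean(gene.intron_sizes)),
            "intron_density": len(gene.intron_sizes)
            / (len(gene.cds_sequence) / 1000.0),
            "intron_number": len(gene.intron_sizes),
        })
    full = pd.DataFrame(rows)
    kept = full[(full.ese_len > cutoff) & (full.core_len > cutoff)
                & full.constraint.notna()].reset_index(drop=True)

    dims = ["mean_intron_size", "intron_density", "intron_number"]
    correlations = {}
    for dim in dims:
        others = [d for d in dims if d != dim]
        rho, p = stats_core.spearman(kept["constraint"], kept[dim])
        try:
            prho, pp = stats_core.partial_spearman(
                kept["constraint"], kept[dim], [kept[o] for o in others])
        except ValueError:  # constant constraint (e.g. all genes at unity)
            prho, pp = np.nan, np.nan
        try:
            gam = stats_core.goodman_kruskal_gamma_perm(
                kept[dim].to_numpy(), kept["constraint"].to_numpy(),
                m=perm_m, seed=rng.integers(2 ** 31))
            gamma, gamma_p = gam.gamma, gam.p_perm
        except ValueError:
            gamma, gamma_p = np.nan, np.nan
        correlations[dim] = {
            "rho": rho, "p": p, "partial_rho": prho, "partial_p": pp,
            "gamma": gamma, "gamma_p_perm": gamma_p,
        }

    n150 = int(((full.ese_len > 150) & (full.core_len > 150)
                & full.constraint.notna()).sum())
    resampling = {}
    if 3 <= n150 <= len(kept) and resample_reps > 0:
        hits = {dim: 0 for dim in dims}
        for _ in range(resample_reps):
            take = rng.choice(len(kept), size=n150, replace=False)
            sub = kept.iloc[take]
            for dim in dims:
                _, p = stats_core.spearman(sub["constraint"], sub[dim])
                if p < alpha:
                    hits[dim] += 1
        resampling = {dim: hits[dim] / resample_reps for dim in dims}
    return {"table": kept, "full_table": full, "correlations": correlations,
            "resampling_significant_fraction": resampling,
            "n_resample": n150}
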