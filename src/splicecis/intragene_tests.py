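"""Within-gene tests of the decoy-splice-site model.

If missplicing risk grows with the number of downstream splice sites, early
exons should carry denser ESE coverage than late ones. The primary contrast
is the 5'-flank ESE density of the second exon against the last-but-one exon
in genes with at least four exons (the terminal exon is never used, to avoid
nucleotide constraints near the stop codon). A loess regression of density on
log10 upstream-intron size controls for the confounding effect of proximal
intron size, with Mann–Whitney and paired sign tests on the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stats_core
from .ese_constraint import HexamerSet, mask_ese_and_density
from .gene_models import extract_internal_exon_features


@dataclass
class PairedDensityRecord:
    """5'-flank ESE densities of exon 2 and the last-but-one exon."""

    gene_id: str
    density_second: float
    density_penultimate: float
    intron5_second: int
    intron5_penultimate: int


def paired_density_records(genes, motifs: HexamerSet) -> list:
    """Build PairedDensityRecords from filtered genes with >= 4 exons.

    Both target exons must exceed 138 bp (flanks defined).
    """
    out = []
    for gene in genes:
        if len(gene.exons) < 4:
            continue
        feats = {f.exon_index: f for f in extract_internal_exon_features(gene)}
        second = feats.get(2)
        penult = feats.get(len(gene.exons) - 1)
        if (second is None or penult is None
                or second.flank5_seq is None or penult.flank5_seq is None):
            continue
        out.append(PairedDensityRecord(
            gene.gene_id,
            mask_ese_and_density(second.flank5_seq, motifs).density,
            mask_ese_and_density(penult.flank5_seq, motifs).density,
            second.intron5, penult.intron5))
    return out


def second_vs_penultimate_test(records) -> dict:
    """Paired binomial test of second-exon vs penultimate-exon ESE density.

    Counts genes where the second exon is denser vs sparser (ties ignored);
    two-sided exact binomial with p = 0.5. Reports medians of both classes.
    """
    diffs = [r.density_second - r.density_penultimate for r in records]
    higher = sum(d > 0 for d in diffs)
    lower = sum(d < 0 for d in diffs)
    tied = sum(d == 0 for d in diffs)
    n = higher + lower
    if n == 0:
        raise ValueError("no informative pairs (all ties)")
    p = stats_core.exact_binomial_p(higher, n, 0.5, "two-sided")
    return {
        "higher": higher, "lower": lower, "tied": tied,
        "binomial_p": p,
        "median_second": float(np.median([r.density_second for r in records])),
        "median_penultimate": float(
            np.median([r.density_penultimate for r in records])),
    }


def loess_residual_test(records, span: float = 0.75) -> dict:
    """Density comparison controlling proximal (5') intron size via loess.

    A single loess of density on log10 intron size is fitted on the pooled
    records of both exon classes; the classes' residuals are compared by
    Mann–Whitney U, and a within-gene paired sign test on residuals gives a
    binomial p.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if len(records) < 30:
        raise ValueError("need at least 30 records for a stable loess")
    x = np.concatenate([
        np.log10([r.intron5_second for r in records]),
        np.log10([r.intron5_penultimate for r in records])])
    y = np.concatenate([
        [r.density_second for r in records],
        [r.density_penultimate for r in records]])
    fitted, resid = stats_core.loess_fit(x, y, span=span, degree=1)
    n = len(records)
    res_second, res_penult = resid[:n], resid[n:]
    u, p_mwu = stats_core.mann_whitney_u(res_second, res_penult, "two-sided")
    d = res_second - res_penult
    higher = int((d > 0).sum())
    lower = int((d < 0).sum())
    informative = higher + lower
    p_paired = (stats_core.exact_binomial_p(higher, informative, 0.5)
                if informative else 1.0)
    return {
        "mwu_u": u, "mwu_p": p_mwu,
        "residual_higher": higher, "residual_lower": lower,
        "paired_binomial_p": p_paired,
        "mean_residual_second": float(res_second.mean()),
        "mean_residual_penultimate": float(res_penult.mean()),
    }


def splice_site_intron_size_test(features) -> dict:
    """Do AGgt-donor exons sit next to larger downstream introns?

    One-sided Mann–Whitney U (AGgt group greater) on the flanking (3')
    intron size of AGgt-donor exons vs all other donors.
    """
    aggt = [f.intron3 for f in features if f.donor_string == "AGgt"]
    other = [f.intron3 for f in features if f.donor_string != "AGgt"]
    if not aggt or not other:
        raise ValueError("a donor group is empty")
    if len(aggt) == 1 or len(other) == 1:
        import warnings
        warnings.warn("single observation in a group; test is degenerate")
    u, p = stats_core.mann_whitney_u(aggt, other, alternative="greater")
    return {
        "u": u, "p": p,
        "median_aggt": float(np.median(aggt)),
        "median_other": float(np.median(other)),
        "n_aggt": len(aggt), "n_other": len(other),
    }
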