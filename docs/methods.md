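# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Gene models and features

A gene model is one protein-coding transcript per gene — the longest-CDS
transcript when several are annotated, since annotation sources rarely say
which isoform analyses should use. Input GFF3 is 1-based inclusive;
internally every interval is 0-based half-open, converted once at the parse
boundary. Coding exons (CDS segments) are the "exons" of all analyses; UTRs
are out of scope. Filters retain genes that start with ATG, end with
TAA/TAG/TGA, contain no in-frame internal stop in the *spliced* CDS, contain
no ambiguous base, and have at least one intron; each rejected gene is logged
with the first rule it failed.

Internal exons (first and last excluded — the last to avoid stop-codon
-proximal composition effects) expose features only when longer than
2 × 69 = 138 bp: the 5′ and 3′ 69-nt flanks, and a central 69-nt core whose
start offset is floor((length − 69)/2), maximizing distance from both
junctions. Splice sites are 4-letter case-coded strings (last two exon nt in
upper case + first two intron nt in lower case for donors, mirrored for
acceptors), so canonical-intron donors read e.g. `AGgt`.

Species traits: X = mean over genes of CDS length / gene span (first exon
start to last exon end); N = total introns / total CDS kb; M = mean intron
size pooled over genes.

## NG86 Ks engine

Synonymous divergence uses Nei–Gojobori (1986) counting with a Jukes–Cantor
correction, ks = −(3/4)·ln(1 − (4/3)·ps). Synonymous sites per codon are
counted per position as (synonymous single-base alternatives)/3, with
changes to stop codons counted as nonsynonymous; pairwise differences for
multi-hit codons are averaged over all orderings of the differing positions,
excluding orderings that pass through a stop codon (all orderings are used
in the rare case every one is blocked). Site counts are averaged over the
two sequences. Codon columns containing gaps, ambiguity codes or stop
codons are skipped. ps ≥ 3/4 is reported as saturated with no numeric ks;
zero synonymous sites is an error. All 64×64 codon-pair counts are
precomputed once; concatenated-partition Ks is then a table lookup over
codon index arrays. The test suite checks the engine against an independent
brute-force pathway-enumeration oracle on 1,000 random pairs to 1e-10.

## ESE masking and the constraint metrics

A flank is masked by exact hexamer matching; the union of all hit windows is
the covered (ESE) site set, and ESE density = covered/69 — the definition
consistent with per-nucleotide flank coverage. In-frame codon columns of a
region enter the analysis only when complete and gap-free in both sequences
of the ortholog alignment; a codon column is assigned to the ESE partition
when ≥ 2 of its 3 sites are covered (majority rule), else non-ESE. Masking
is performed on the ingroup flank and projected onto alignment columns; the
outgroup is not independently scanned.

Exon ends are assigned to 20 equal-occupancy bins by flanking intron size
(5′ and 3′ ends separately, each against its own flanking intron; ties at
bin boundaries broken by stable sort on size, gene id, exon ordinal; bins
may differ by one when the count is not divisible by 20). Within each bin
the ESE, non-ESE and core codon columns are concatenated before a single Ks
estimate per partition, and

    constraint = (Ks_core − Ks_ESE_flank) / Ks_core.

Pseudo-ESE sets — same cardinality, hexamer bases drawn i.i.d. per position
from the true set's pooled base frequencies, duplicates redrawn, coincidental
matches to true motifs retained — are re-masked `pseudo_reps` times per bin
and summarized as mean ± se of Ks. Negative constraints are never floored;
downstream rank statistics are unaffected by monotone truncation.

The per-exon selection metric fits one OLS line per end of unbinned per-end
constraint against log10 flanking intron size (ends with undefined Ks
excluded) and reports, per exon end, ESE density × line-interpolated
constraint, plus the Spearman correlation of that product with log intron
size. The gene-level analysis concatenates all flank ESE columns and all
core columns of a gene (both ends pooled), retains genes whose
concatenations exceed the length cutoff (102, 150 or 201 bp; other values
warn and proceed), and correlates per-gene constraint with mean intron
size, intron density and intron number by Spearman, partial Spearman
(controlling the other two dimensions on ranks) and Goodman–Kruskal gamma
with a permutation p. A resampling report draws, without replacement, as
many genes as pass the 150-bp cutoff from the retained pool 1,000 times and
records how often each Spearman correlation stays significant. Degenerate
inputs (e.g. every retained gene at constraint exactly 1, which happens when
no ESE column diverged) yield NaN partial/gamma statistics rather than an
error.

## Junction usage trends and Y

For each internal exon the complete in-frame codons are indexed by distance
from each junction; a partial boundary codon (phase ≠ 0) occupies distance
position 1, which is always dropped, so complete codons start at position 2
in phase-shifted exons and position 1 (dropped) otherwise. Proportional
usage of each of the 61 sense codons (or 20 amino acids) is computed at
distances 2–34, and a two-tailed Spearman correlation against distance gives
rho (negative = preferred near exon ends) and a t-approximate p (n = 33
positions; average ranks; constant profiles return rho 0, p 1). Bonferroni
correction is applied within k-mer family and per end (α/61 or α/20). A
k-mer counts toward Y when significant at either end by default; a
`both_ends` switch requires the conjunction, since the source phrasing of
the metric is ambiguous. The subsampled Y draws 5,000 exons with
replacement 100 times (both configurable) and averages the proportion
significant; it is deterministic given a seed. P1 and P2 are simple
proportions of donor `AGgt` and acceptor `agGT` strings.

## Intragene decoy tests

Genes with ≥ 4 exons contribute one record when both the second and the
last-but-one exon exceed 138 bp: their 5′-flank ESE densities and 5′ intron
sizes. The sign test counts genes with a denser second exon versus a denser
penultimate exon (ties dropped) under an exact two-sided binomial at p = 0.5.
The size-controlled variant fits a single loess (span 0.75, degree 1,
tricube weights via statsmodels lowess, no robustness iterations) of density
on log10 5′-intron size over the pooled records of both classes, compares
class residuals by Mann–Whitney U (exact for small tie-free samples, normal
approximation with tie correction otherwise) and repeats the within-gene
sign test on residual differences. A separate test asks whether `AGgt`-donor
exons sit next to larger downstream introns (one-sided MWU).

## θ and N_e·μ

From n aligned haplotypes (gap/ambiguity columns dropped listwise):
π = mean pairwise differences; S = segregating sites; η = Σ(distinct bases
− 1) per site, so η ≥ S with equality absent recurrent mutation. Per-site
estimators divide by L and, for S and η, by a_n = Σ_{i=1}^{n−1} 1/i.
N_e·μ = θ/4 by default (diploid autosomes); the divisor is configurable
because the appropriate ploidy factor depends on the locus. In
synonymous-sites mode, only sites whose observed codon variation is
amino-acid-invariant count as segregating, and L is the NG86 synonymous site
count averaged over haplotypes. Multi-locus input is averaged weighted by L.

## Phylogenetic correlation

Standardized Felsenstein contrasts are computed by post-order pruning
(polytomies resolved arbitrarily with zero-length branches; a zero-variance
contrast between unequal values is reported as ±inf). The correlation of two
traits' contrast series is taken through the origin, as contrasts have
expectation zero. The primary evidence statistic is the likelihood-ratio
statistic of correlated versus independent bivariate Brownian motion,
−k·ln(1 − ρ̂²), asymptotically χ²(1) under independence (so ~15.7% of null
replicates exceed 2 — the classes weak/positive/strong/very strong at
2/5/10 are an evidence convention, not a calibrated test). An MCMC mode
mirrors the harmonic-mean marginal-likelihood convention: a seeded
Metropolis chain over (log σ₁², log σ₂², atanh ρ) with flat priors on those
transformed scales, statistic = 2·(log harmonic-mean likelihood correlated −
independent). Harmonic-mean estimators are high-variance; the ML mode is the
deterministic primary path and the MCMC mode exists to reproduce the
evidence scale. |ρ̂| = 1 reports +inf with a flag.

## Synthetic generator

The generator's defaults are the package's study conditions:

* gene architectures: exon count 3 + Poisson(5); exon lengths uniform
  150–300 bp (so flanks and cores are always defined; the last exon absorbs
  the mod-3 remainder); intron sizes log-normal(μ_ln = 7, σ_ln = 1.2,
  min 70 bp), i.e. median ≈ 1.1 kb — a human-like scale; 30% of genes on the
  minus strand; canonical gt..ag introns.
* ESE planting: per flank, a target coverage density = 0.12 + 0.03·(log10
  intron size − 3) + 0.005·(downstream introns − 3), clipped to [0, 0.55].
  Chance hexamer hits in the flank are first scrubbed by redrawing codons
  (a random 84-hexamer set otherwise floors coverage near 0.11), then
  motifs are planted codon-aligned and non-overlapping, with stochastic
  rounding of the motif count so expected coverage is linear in the target.
  Realized mean density ≈ 0.14, matching the order of published human flank
  densities. Exon-boundary dinucleotides are drawn so that ~35% of donors
  read `AGgt` and ~20% of acceptors `agGT`.
* ortholog divergence: synonymous sites substitute with the probability
  implied by Jukes–Cantor branch length d_core = 0.06 (primate-scale)
  outside ESE coverage and d_core·(1 − c) inside, where coverage uses
  exactly the flank-masking majority rule the analysis applies — so planted
  c is the estimand, ESE columns evolve at exactly d_core·(1 − c), and c = 1
  silences them completely. Nonsynonymous positions are frozen: the analyses
  consume Ks only, so simulating amino-acid evolution would add noise
  without adding coverage (documented limitation).
* polymorphism: a neutral coalescent genealogy (msprime, no recombination)
  with strict Jukes–Cantor state changes at per-site rate θ (default 0.005,
  n = 10, L = 1e5), so E[π] = θ and E[S] = θ·a_n·L; rare recurrent hits give
  η > S, as in real data.
* traits: bivariate Brownian motion (default ρ_true = 0.8) on a Kingman
  coalescent tree (default 30 tips); the coalescent guarantees strictly
  positive internal branches, keeping contrasts finite.
* codon-trend pools: planted gradients are paired (half enriched near
  junctions, half depleted, equal and opposite linear slopes), so all
  unplanted codons keep exactly uniform usage at every distance and the
  planted count is the exact expectation of recovered trends. Distance is
  min(d5′, d3′) with exon lengths ≥ 68 codons, keeping the two 34-codon
  windows disjoint.

What the generator does *not* emulate: real intron-size distributions beyond
a log-normal, alternative splicing, recombination, selection at
nonsynonymous sites, alignment error or indels (ortholog pairs are
gap-free), regional mutation-rate variation, and real ESE motif identity —
the packaged hexamer files are synthetic purine-rich stand-ins of the
published set sizes (84 and 54), clearly labelled as such. Passing
parameter-recovery tests therefore demonstrates the estimators are correct
under the stated model, not that real genomes satisfy the model.

## Problem sizes and numerical choices

Validation runs use ~2,000 internal exon ends per end for constraint
recovery (tolerance ±0.08 around planted c ∈ {0, 0.3, 0.6}, averaged over
the two ends and 20 bins), 20,000 exons for exact planted-trend recovery,
200 replicates for family-wise-error and θ-unbiasedness checks, and 500
replicates for ρ recovery — sizes chosen so each check's Monte-Carlo error
is comfortably inside its tolerance. Permutation p-values are one-sided
greater-or-equal with ties counted conservatively, p = (n+1)/(m+1).
Spearman uses average ranks and the t approximation (trend windows have a
fixed n = 33). Bin Ks estimates on empty or saturated partitions propagate
as NaN and are excluded from summaries. Loess supports degree 1 only;
requesting another degree is an error rather than a silent fallback.

## Known limitations

* The harmonic-mean MCMC statistic inherits the estimator's instability;
  it is seeded and reproducible but its numeric value should not be
  over-interpreted — only its evidence class is used.
* The per-exon constraint regression uses individual exon-end Ks estimates,
  which are extremely noisy (few synonymous sites each); the interpolated
  product smooths but also correlates the product with intron size by
  construction, which is why the binned and gene-level analyses are the
  primary quantities.
* CDS-synonymous θ mode classifies a segregating site as synonymous only
  when all observed codons agree in amino acid, a conservative rule that
  drops mixed synonymous/nonsynonymous columns.
* Real-data GFF3 handling assumes gene → mRNA → CDS hierarchies with
  `Parent` links; pathological annotations (trans-splicing, shared CDS)
  are out of scope.
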