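# Methods

This note documents the models behind `fibermap`, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## The mapping design being emulated

A single partially dominant locus controls fiber color in an F2
population from a brown × white cross. Homozygous mutants are brown,
heterozygotes cream/tan, homozygous wild types white, so carriers:white
segregate 3:1. Two 77-plant bulks with contrasting phenotypes are
sequenced; variants called identically in both bulks carry no mapping
information, and the residual (symmetric difference) piles up around the
locus because the white bulk — all wild-type homozygotes — lacks the
mutant-parent alleles only where linkage keeps recombinants out. A
dominant-marker walk then narrows the interval, and the candidate
regulatory lesion is the presence/absence of an upstream LTR
retrotransposon whose absence de-represses the adjacent pigment gene.

## F2 simulation

- **Recombination.** No interference (Haldane): crossovers per gamete
  and chromosome are Poisson with mean = map length in Morgans;
  positions uniform on the physical length (constant cM/bp). Each F2
  plant is two independent gametes from heterozygous F1s; the genotype
  at any coordinate derives from the stored breakpoints, so marker
  calls, bulk variant presence and the causal genotype are all
  consistent by construction.
- **Default genome.** Five 50-Mb chromosomes at 50 cM each (1 cM/Mb, a
  typical plant euchromatic rate) and one parental difference per kb —
  a desk-scale stand-in for a 26-chromosome tetraploid genome,
  configurable upward. The causal locus sits at 22.5 Mb on the middle
  chromosome: the centre of a default 5-Mb scan window. Deliberately
  not the exact mid-chromosome (25 Mb), which coincides with a window
  boundary and would split the differential-variant signal between two
  windows — a geometric pathology, not a property of the method.
- **Color model.** CIELab means per causal genotype: the measured
  parental values for 0 and 2 copies, the arithmetic midpoint for
  heterozygotes (the design source says only "intermediate"). Gaussian
  noise per channel and technical replicate, default sd 1.0 — inside
  the 0.18–1.36 range of the parental replicate SDs. Three replicates
  per plant, averaged before classification.
- **Bulk variant calls.** Presence/absence at the called-variant level,
  not allele frequencies: a site is truly present in a bulk iff any
  member carries the mutant-parent allele. `dropout` (default 0.05)
  drops truly present calls; `genotyping_error` (default 0.02) flips
  calls. With 77-plant bulks an unlinked site is present in both bulks
  with probability 1 − 0.25⁷⁷ ≈ 1, so the subtraction background is
  almost entirely call noise (≈ 2·p·(1−p) ≈ 13% of sites per window at
  the defaults), while near the locus the white bulk truly lacks the
  mutant allele out to the nearest contaminating recombinant — an
  exponentially distributed depletion zone with mean ≈ 0.65 Mb per side
  at the defaults. That zone's width, not the call noise, dominates
  replicate-to-replicate variation in peak height.
- **Bulk membership.** Uniform random within phenotype group (the
  design source does not state how bulk members were chosen from the
  phenotyped plants).

## Scan conventions

Windows are 0-based half-open, tile each chromosome from 0 in
`bin_width` steps (default 5 Mb), and a 1-based variant position p falls
in window ⌊(p−1)/w⌋. The peak is the global maximum window (ties:
lowest chromosome name, then start); the reported region extends over
adjacent windows with counts ≥ `extend_fraction` × peak (default 0.5).
Raw counts only — no smoothing or confidence band; note that with a
noisy background whose level exceeds half the peak, the extension rule
spans the background run, so the *peak window* is the localization
statement. All user-facing output converts to the usual conventions
(VCF/GFF3 1-based inclusive, BED 0-based half-open).

## Markers

Dominant mutant-specific assays cannot distinguish heterozygous from
homozygous carriers, so no recombination fraction is estimated — only
discordance counts between call (P/N) and phenotype group (brown and
cream are carriers). The interval is the span between the nearest
markers with ≥ 1 recombinant on each side of the zero-recombinant set;
panels with no zero-recombinant marker (or no recombinant flank on one
side) are flagged open, with ties for the minimum all reported.

## LTR annotation

Seed-and-extend with exact 15-mer seeds grouped by diagonal (clusters
merged within the band), banded gapped extension (match +1, mismatch −2,
gap −3, band 50, X-drop 50) from the densest cluster. Linear gap costs
let each DP row be solved with a running maximum, so extension is a few
vector operations per row. The two aligned spans are the LTRs; the gap
between them is the internal region; identity is matches over aligned
columns. On an element presented alone, both outer alignment ends are
hard sequence boundaries and the copies are phase-locked, so the three
lengths are recovered exactly; embedded in a flanked region, boundaries
can shift a base or two where flank sequence continues the repeat by
chance. Presence requires identity ≥ 0.85 over ≥ 0.8 of the element
(both strands scanned; coordinates reported on the forward strand).
Remnant evidence on absent calls: solo LTR (either LTR aligning at ≥ 0.8
of its length), then a 4–6 bp duplicated motif adjacent to the
insertion point (default: the site midpoint), then a partial-element
match, else none. The 4–6 bp range is typical for Ty3/Gypsy target-site
duplications; the chance rate of a spurious TSD at a fixed point is
1 − Π(1 − 4⁻ᵏ) ≈ 0.5%, which the property tests verify.

The bundled element fixture is built to the reported structure of the
locus element — 2877 bp 5′ LTR, 4687 bp internal region, 3′ LTR equal to
the 5′ LTR with a 2-bp insertion (2879 bp) — noting that the reported
"~10.7 kb" missing region slightly exceeds the 10,443-bp component sum;
the component lengths are taken as authoritative for fixtures.

## Differential expression

CPM normalization (column sums), pseudocount 1 before logs and ratios,
fold change = ratio of pseudocounted mean CPM. Testing is a per-gene
one-way ANOVA on log2(CPM+1) — with two lines, exactly the pooled
t-test — with one important default: **empirical-Bayes variance
moderation**. With two replicates per line a gene-wise test has two
error degrees of freedom, and no effect, however large, can clear a BH
threshold across thousands of genes (a 179-fold change reaches only
p ≈ 2×10⁻³). The moderated test shrinks each gene's variance toward a
mean–variance trend (lowess of log s² on mean log2 expression, prior
df estimated by moment-matching on log variances) and adds the prior
df to the test — the standard small-n RNA-seq remedy. The unmoderated
ANOVA is available via `moderation=False`. Significance requires both
q < 0.05 and a two-fold change; genes constant across all samples are
reported untested with q = 1.

The count generator draws gene baselines LogNormal(ln 50, 1) on a CPM
scale, library sizes LogNormal(ln 10⁶, 0.1), and negative-binomial
counts with dispersion 0.05 (Poisson at 0). Planted genes take the
median baseline (50) rather than a random draw: with a desk-scale
library a randomly high baseline times a 756× fold can become a large
fraction of the library, and CPM normalization then compresses every
fold — a composition artifact of the scaled-down world. Even with the
anchored baseline, a 2,000-gene library shows visible compression
(≈ 139× recovered for a planted 179×); fold-recovery validation is
therefore done at a 20,000-gene transcriptome scale, where the planted
share is < 3% and recovery is unbiased. DEG *counts* on real data are
not expected to match any published tally — the upstream normalization
and test stack there is different and the data external.

## What a green test establishes — and what it does not

The generator reproduces the design's statistical skeleton: Mendelian
segregation, linkage decay of bulk enrichment, dominant-marker
information loss, element structure, planted expression effects. It does
not model read-level error, tetraploid homoeolog confusion, allele
frequencies within pools (presence/absence only), mapping bias, or real
LD structure. Green tests therefore establish that the *analysis logic*
is correct and calibrated on its stated assumptions, not that any
particular biological dataset would reproduce published values.

## Numerical details

- One seeded `numpy.random.Generator` per run; the pipeline spawns
  independent child streams per stage from the master seed, and reruns
  are byte-identical.
- Pearson χ² without Yates correction (with it, the canonical 3:1
  statistic would not reproduce).
- Tukey HSD uses the studentized range (Tukey–Kramer for unbalanced
  groups) via `scipy.stats.tukey_hsd`.
- Multi-allelic VCF records are split per alternate allele before set
  keying; variant identity ignores zygosity.
- Peak ties break deterministically (lowest chromosome name, then
  start); classification ties sit inside the cream band by construction.
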