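# Methods

This note documents the models, parameter choices and numerical
conventions behind `sdrscan`, and what the synthetic study conditions do
and do not establish about real data.

## Coordinate convention

All coordinates are 1-based and inclusive on both ends
(length = end − start + 1), the convention in which genomic positions
are printed; BED files are converted to 0-based half-open only at the
file boundary. Kb figures use 1 Kb = 1000 bp with
round-half-away-from-zero, to one decimal for components and to an
integer for the SDR headline.

## Genotype QC

Per-call thresholds (GQ ≥ 20, DP ≥ 7) *mask individual calls* rather
than dropping sites, because they are defined per individual per site;
masked calls then feed the call-rate criteria naturally. Site criteria:
biallelic SNP, site quality Q ≥ 30, call rate ≥ 0.90 overall and ≥ 12
called individuals in each sex, and global MAF ≥ 0.05 with a rescue for
sites at per-sex MAF ≥ 0.20 in either sex. MAF is computed on allele
counts of called genotypes only. Multi-allelic records and indels are
dropped at load, not split. The per-sex called-individual count is
evaluated after masking — the cascade reading of the rule; this is an
assumption, and the threshold is exposed (`min_called_per_sex`).
Filtering is idempotent and order-independent in the retained set;
drop counts are attributed to the first failing criterion in cascade
order for reporting.

## Association statistics

*Fisher's exact test* is two-sided by the minimum-likelihood rule: all
tables with the observed margins whose hypergeometric point probability
is ≤ the observed one (within 1e-12 relative tolerance, so exact ties
stay together) contribute to p. Monomorphic tables return p = 1 and are
flagged. The test operates on allele counts (2 × called genotypes),
oriented to the global minor allele.

*Allele-frequency LRT*: G = 2[ℓ(p̂_F) + ℓ(p̂_M) − ℓ(p̂_pooled)] with
binomial log-likelihoods at the closed-form MLEs, clipped at 0 and
referred to χ² with 1 df. This is a deliberate count-based surrogate for
genotype-likelihood differentiation tests: it shares the null (one
common allele frequency) without requiring GL fields, which the
pipeline does not model.

*BH-FDR* is the standard step-up procedure (statsmodels backend),
order-preserving; `fdr_threshold` returns the largest raw p with
q ≤ α, always an element of the input.

*Weir–Cockerham (1984)* two-population components a, b, c are computed
from called sample size n, allele frequency p and observed heterozygote
proportion h per sex, with r = 2. Negative per-site values are reported
as-is — truncating them would bias the genome-wide figure, which is the
ratio of sums Σa / Σ(a+b+c) over polymorphic sites (not a mean of
ratios) and can legitimately be slightly negative in a panmictic cohort.
The canonical fully sex-linked configuration (24 heterozygous females at
p = 0.5, 20 homozygous males at p = 0) gives F_ST = 11/23 ≈ 0.478.

## Sex-specific SNP detector

A site is sex-specific for focal sex S when: heterozygote count in S ≥
`min_het_count`, H_O in S ≥ 0.75, zero heterozygotes in the other sex,
and every called genotype of the other sex is the same homozygote.
`min_het_count` defaults to 18, the value implied by the 0.75 floor at
24 focal-sex samples; when unset it is derived as ⌈min_ho × n_focal⌉, a
generalisation for other cohort sizes (the appropriate male-focal
threshold for 20 males, for instance, is 15). "Homozygous for one
allele" is enforced on called genotypes only, so other-sex missingness
does not disqualify a site.

Heterozygote excess alone cannot separate ZW from XY-with-a-deletion:
all-female heterozygosity also arises at segregating sites over a
W-deleted region. `classify_system` therefore requires corroboration for
a definitive call — either uniform depth between sexes at the hit sites,
or a co-locating sex-limited coverage region of the matching sex —
and otherwise returns a provisional label; conflicting focal sexes
(> 10% minority) or contradictory coverage give `ambiguous`.

LD between hits is the squared Pearson correlation of unphased genotype
dosage (0/1/2) over samples called at both sites (no haplotype EM);
pairs sharing < 4 called samples are undefined.

## Coverage scan

Welch's unequal-variance t-test runs per position (optionally per fixed
window on window means). A position is a female-specific candidate when
p < 1e-4, the mean over females of each individual's depth ratio to *its
own* genome-wide mean lies in [0.35, 0.65], and mean male depth ≤ 2X
(the ceiling that distinguishes hemizygosity from a copy-number
difference; exactly zero is not required, absorbing mismapping noise).
The per-individual ratio makes the half-depth band robust to the 20–41X
between-individual spread. Degenerate positions (both sexes constant)
get p = 1 when equal and p = 0 (flagged) when not. Candidate runs merge
across gaps ≤ 200 bp and regions < 1000 bp are dropped; both merge
parameters are explicit guesses exposed in `CoverageCallConfig`, since
no standard exists for how contiguous significant loci are joined.

## Region assembly

Sex-specific SNPs within 10 kb of each other cluster; each cluster span
gains 5 kb flanks, clipped to the chromosome; flanked clusters that
overlap merge (flanks are annotation, not evidence). The SDR spans the
sex-linked regions plus any hemizygous region between or overlapping
them; hemizygous regions outside that span are listed but excluded.
Repeat content is |union(repeats) ∩ region| / |region|.

## Annotation

Category precedence within a transcript is CDS > UTR > intron; across
overlapping genes the highest-precedence category wins, ties broken by
smallest gene id (deterministic). Coding effects translate the affected
codon on the coding strand (honouring CDS phase) with the standard
genetic code: synonymous, nonsense (stop gained), else missense; only
single-base substitutions get effect calls. Upstream/downstream is
measured from the *gene span* boundary (not the TSS), resolved by
strand, within a 5 kb flank; beyond that, intergenic. Exonic positions
outside annotated CDS/UTR are assigned to the nearest UTR side with a
warning. Exon identity uses a global pairwise alignment per exon pair
(paired by order from the 3' end when no pairing is given), identity =
matches / alignment columns with gap columns counting against, averaged
unweighted across pairs.

## Marker design

The paralog scan seeds with exact 15-mers, chains seeds per diagonal
band (tolerance 150, accommodating ~100 bp of cumulative indel), and
refines each band with an affine-gap *fit* alignment: the query aligned
end-to-end against a free-ended subject window (match +1, mismatch −2,
gap open −5, gap extend −2; a length-L gap costs open + L·extend). The
fit shape is deliberate: a purely local alignment stops at the largest
gap-free block when an internal gap costs more than the remaining tail
recovers, whereas the paralog comparison must cross internal indels to
measure them. `total_gap_bp` is the net aligned-span difference, which
equals |subject length − query length| for end-to-end alignments.
Self-hits are excluded by overlap with the query locus. Scores are
verified against an independent full-DP oracle.

Marker candidates need exactly one copy inside a sex-limited haploid
region and a length difference ≥ 20 bp (gel-resolvable on 2% agarose);
ranked by length difference then identity, with exact-match runs ≥ 20 bp
reported as shared-primer flanks. In-silico PCR matches primers exactly
by default (`max_mismatch = 0`; when tolerance is allowed, the 3'
terminus must still match), in both primer-assignment orientations;
product length is the inclusive span between the two primers' outer 5'
ends, products > 3 kb are dropped, and > 100 products aborts as
non-specific. Band patterns assign copy number per sex from the template
locus (haploid region: 1 in its sex, 0 in the other; elsewhere 2/2);
a single-copy band is annotated as reduced-dosage, matching its fainter
gel intensity.

## Synthetic cohort (the study conditions)

Defaults emulate a two-lake resequencing design: 24 females + 20 males,
ZW, per-individual genome-wide mean depth uniform on 20–41X, genotype
error 0.5%, missingness 2%, 10,000 autosomal SNPs on a 500 kb autosome
and 20 fully sex-linked SNPs in two clusters on an 80 kb sex chromosome,
a 21,326 bp hemizygous insertion between the clusters (females at half
depth, males at mean 0.25X), and a 590 bp source segment copied to a
diploid locus with three inserted gaps of 40 + 30 + 27 = 97 bp.

Modelling choices:

* **Depth** is negative-binomial around the individual's mean with
  dispersion k = 20 (variance μ + μ²/k) — overdispersed relative to
  Poisson, as short-read coverage is. The depth matrix covers the sex
  chromosome; per-individual mean-depth recovery is therefore checked
  outside the hemizygous interval, where on a whole genome the
  insertion's contribution would be negligible.
* **Hemizygosity lives in depth, not genotypes**: no VCF records are
  emitted inside the insertion, since a single-copy region has no
  diploid biallelic genotypes — it is found by coverage, not SNPs.
* **Autosomal allele frequencies** draw from a Beta(0.8, 0.8) rescaled
  to [0.05, 0.95] — a U-shaped spectrum loosely resembling a site
  frequency spectrum after a MAF floor; genotypes are Hardy–Weinberg
  at the site frequency. The spectrum is a free modelling choice, not
  an empirical claim.
* **Error and quality**: an erroneous call is replaced by one of the
  other two genotypes uniformly; correct calls draw GQ ~ N(65, 18) and
  erroneous calls GQ ~ N(12, 6), both clipped to [3, 99], so GQ
  decreases with error probability and the GQ ≥ 20 mask removes most
  injected errors — calibration realism is not attempted, only the
  ordering that makes the thresholds meaningful. Site QUAL is 0.7 ×
  total depth, floored at 30.
* **XY mode** swaps which sex is heterogametic; one code path.
* The reference genome is the heterogametic individual's assembly, so
  it contains the hemizygous insertion — required for the half-depth
  signature to be observable.

What passing on these conditions does **not** show: the generator has no
linkage disequilibrium between autosomal sites, no population structure
between sampling sites, no recombination gradient at the SDR boundary,
no GC/mappability bias in depth, and read-level artefacts (duplicates,
mismapping into the paralog) are absent. Sensitivity and false-positive
results transfer to real cohorts only to the extent those factors are
second-order at desk scale.

## Problem sizes

The shipped tests and the acceptance script run the generator at the
default sizes above (10 replicate cohorts for detector recovery, 10 for
hemizygous-region recovery, 1000 random tables for the exact-test
oracle, 200 codons × 9 substitutions for the effect-call oracle); the
full suite completes in well under a minute of compute per replicate on
one CPU.
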