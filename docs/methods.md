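# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, the assumptions of the synthetic-data generator, and
the known limitations.

## Coordinates, genotypes and naming

All user-facing coordinates are 1-based inclusive (VCF convention); any
half-open intervals are internal and never serialized. Markers are named
`S<chrom>_<pos>` (chromosome prefix stripped), matching the convention on
grape linkage maps. Genotypes are stored as integer codes that double as
alt-allele dosage — 0 hom-ref, 1 het, 2 hom-alt, −1 missing — and a cell
with zero read depth is always missing. Undefined statistics print the
literal token `NaN` (no association detectable), never an empty cell.

## Haploblock definition and LD retrieval

Marker effects in a biparental pseudo-testcross are estimated by splitting
progeny into the two parental-haplotype classes (in a testcross
configuration, a heterozygous progeny received the informative parent's alt
allele) and differencing the class phenotype means; classes smaller than
two progeny leave the effect undefined and the marker excluded downstream.
The haploblock is the maximal contiguous run of markers around the anchor
whose |effect| ≥ τ·|effect(anchor)|. τ defaults to 0.8: "similar effect"
needs a number, and 0.8 keeps markers whose effect is within 20 % of the
anchor's while excluding clearly unlinked flanks; it is exposed in the API
for other populations.

Linkage disequilibrium between dosage vectors is the squared Pearson
correlation over pairwise-complete samples (missing excluded pairwise, the
behavior of the standard genotype-r² tools). The P-value uses the
asymptotic χ² = n·r² test with 1 df; for n < 30 an exact permutation P
(10 000 permutations) is available via `exact=True`, since the χ²
approximation thins out in small families. Candidate retrieval keeps sites
inside the haploblock with ≤5 % missing data and anchor-LD P ≤ 1e−25 —
the platform's working defaults; both are parameters. Monomorphic input
yields r² = NaN rather than an arbitrary 0, because no association is
estimable.

## Template extraction

Primer templates come from the GBS reads themselves, not the reference
genome, so primers match the alleles they must amplify. Reads covering a
candidate SNP are grouped by the base observed there (reads with a deletion
or N at the site are discarded); `num_tags` counts distinct read sequences.
Per allele, each flank column up to 30 bp from the SNP takes the strict
majority base of covering reads, truncating at the first uncovered column;
ties break to the lexicographically smallest base so that identical read
sets in any order give identical templates. The agreement percent is the
mean per-column majority fraction × 100.

Rejection codes are assigned in priority order:

| code | rule |
|------|------|
| 1 | ≠ 2 alleles among the reads |
| 2 | any flank consensus < 10 bp |
| 3 | inter-allele flank identity < 90 % over ≤ 20 bp next to the SNP |
| 4 | site depth above the outlier cutoff (putative repeat) |
| 0 | design-eligible |

The depth-outlier cutoff (code 4) is the larger of mean + 4·SD and the
99th percentile of candidate-site depths — "extremely high depth" needs an
operational definition and this flags roughly the top percent of sites
while being robust to a heavy tail. Allele 1 is the allele with the higher
read count (ties: reference allele first), making the 18-parameter vector
deterministic. The 30-bp maximum flank leaves a 22-bp primer room to spare
over the 10-bp coverage minimum. The coverage rule is applied to the
consensus stack (any read may contribute to a column), the laxer of the
two possible readings; requiring a single read to span the whole flank
would only shrink the candidate set.

## Primer design and curation

With the default 22-bp primer length, the forward primer is the 22
template bases immediately 5′ of the SNP and the reverse primer the
reverse complement of the 22 bases immediately 3′, so the SNP is the
center base of a 45-bp amplicon and neither primer overlaps it (no allele
bias by design). This fixed-position picking is fully determined by the
template; an optional ±N slack search maximizing closeness to 60 °C is a
config extension, not the default.

Melting temperatures are computed in-package by nearest-neighbor
thermodynamics (Biopython's NN engine with the unified SantaLucia
parameter table, 50 mM Na⁺, 25 nM each strand, entropy salt correction),
rather than by shelling out to an external design binary: it keeps the
47–79 °C retention and 52–70 °C recommendation filters reproducible and
dependency-free, and the tests pin it against an independent hand
summation of the same published table to ±0.1 °C. Curation drops pairs
with either Tm outside 47–79 °C, flags (keeps) pairs outside 52–70 °C, and
among transitively overlapping amplicons keeps the one with the smallest
anchor-LD P — a deterministic stand-in for manual curation, recorded
decision by decision in the curation log. Linker tails are the constant
33-nt forward / 34-nt reverse sequences used for dual-index PCR, giving
55/56-nt oligos at the default primer length.

## Primer-efficiency classifier

Templates are described by the canonical 18-parameter vector
(`num_tags, pvalue, phase, reject_code, a1, a1_count, a1_lseq_pct,
a1_rseq_pct, a2, a2_count, a2_lseq_pct, a2_rseq_pct, ltemp, rtemp,
a1_lseq_len, a1_rseq_len, a2_lseq_len, a2_rseq_len`); allele bases are
coded A=1…T=4 and categorical-ish fields (reject_code, phase) enter as
numbers. Labels (efficient vs non-efficient) are user-supplied; the helper
`label_templates` applies the ≥50× depth and ≤10 % missing working
thresholds. Four families are evaluated — L2 logistic regression,
RBF-kernel SVM (Platt-calibrated so all models score on a probability
scale), an unpruned decision tree, and a 500-tree random forest — by
repeated stratified holdout (default 50 repeats at 70/30, seeded) rather
than a single split, which makes the reported AUC stable at panel-sized
n. AUC is computed as the Mann–Whitney probability that a random positive
outscores a random negative (midranks for ties) and interpreted on the
conventional bands: <0.60 poor, 0.60–0.74 moderate, 0.75–0.89 good,
≥0.90 very good.

## Genotyping

The default batch is four 96-well plates on a 16 × 24 dual-index grid
(384 combinations): 380 sample wells and 4 blanks, each plate carrying two
duplicated individuals and one blank as QC. The shipped index sets are
synthetic 8-mers generated once with pairwise Hamming distance ≥ 3, so the
one-mismatch demultiplexing rule can never be ambiguous; real index sets
can be substituted. A read is assigned when each of its two indexes
matches exactly one layout index within one mismatch; assigned + blank +
unassigned partitions the input exactly.

Reads are assigned to amplicons by forward-primer prefix match (≤1
substitution, unique); the base at the primer-length offset is tallied
against the template's two alleles. Genotypes are called from
d = reads_a1 + reads_a2 with minor fraction f = min/d: d < 5 → missing;
f ≤ 0.1 → majority homozygote; f ≥ 0.2 → heterozygote; the 0.1–0.2 band
is ambiguous and left missing. This transparent allele-fraction caller
replaces a general-purpose variant caller deliberately: each amplicon has
one known SNP at a known offset, so haplotype assembly adds nothing, and
the thresholds are auditable. A site monomorphic across all samples is
flagged "no polymorphism" and excluded from VCF output.

Per-amplicon QC reports mean depth over all assigned samples (blanks
excluded, missing included — the denominator is the batch's sample count),
CV as sample SD/mean, missing individuals and rate, with pass flags at the
>50× and <10 % working thresholds. On-target accounting tiles the genome
in 500-bp windows (non-overlapping by default; the step is configurable
for true sliding windows) and reports the fraction of reads falling in
windows that overlap panel amplicons.

## MAS analysis

Association is a one-way ANOVA of phenotype across genotype classes:
P from the F distribution, marker R² = SS_between/SS_total. Binary and
ordinal phenotypes (sex M/H/f coded 2/1/0; 1–5 field ratings) enter as
numeric class codes. Fewer than two classes, or zero total sum of squares,
yields NaN with R² = 0; perfect separation yields R² = 1 with P printed
as 0. Pooled analysis concatenates families sharing a segregation pattern
with no family covariate (a covariate option exists), so pooling never
alters the per-family results.

MAF is the lesser allele's frequency among non-missing calls; the
segregation-distortion flag is a two-sided exact binomial test of the
minor-allele count against the 0.25 testcross expectation at α = 0.05 —
a descriptive observation in routine use, made testable here.

Phasing resolves, per marker, which allele travels with the favorable
trait state: the candidate is the allele the donor parent carries at
higher dosage than the other parent, confirmed (or contradicted →
`out_of_phase`) by the carrier-class phenotype mean in progeny;
configurations with neither signal are `unphasable` and excluded from
decisions. Transferability dendrograms cluster markers by average linkage
on 1 − r² (undefined pairs get distance 1, the agnostic maximum). Marker
density is span/count in kb, rounded half-up. The decision table scores
each seedling by the R²-weighted mean favorable-allele dosage across
phased markers and keeps it above a configurable vote threshold; per-trait
tables join into a pyramiding view that selects seedlings kept for every
trait.

## The synthetic-data generator

The simulator emulates the study designs end to end. Families are F1
pseudo-testcrosses: the donor parent heterozygous at every marker with alt
alleles on haplotype 1, the other parent homozygous reference, so markers
segregate 1:1 het:hom-ref (expected MAF 0.25). Gametes undergo Poisson
crossovers at a configurable cM/Mb rate (default 3, a typical plant
genome-wide figure). The sex locus has three alleles with dominance
M > H > f and parent genotypes given as strings (e.g. HH × Mf segregates
1:1 M:H); the phenotype, not the genotype, is observed, coded M=2, H=1,
f=0 after resolving dominance. Quantitative loci add Gaussian noise scaled
as σ² = var(genetic)·(1−R²)/R², so the realized single-marker ANOVA R²
approximates the target (0.54 by default, a major-QTL regime; 0.93 and
0.13 regimes are reached the same way).

GBS stacks are 64-bp fully aligned reads over a SNP with shared planted
flanks (optionally diverged at chosen offsets to trip the mismatch rule)
and iid substitution errors. Amplicon runs draw per-(well, amplicon) depth
from a negative binomial (default dispersion 8, giving the depth CVs of a
few tenths to ~1 seen in real runs, which a Poisson cannot produce),
sample the read allele from the well's genotype, prefix the forward
primer, and carry the dual index pair in the FASTQ header; blanks draw
Poisson(0.2) stray reads. Everything is deterministic under a seed, to the
byte for FASTQ output.

What the simulator does not model: PCR chimeras and index hopping,
base-quality variation, indels, paralog cross-amplification, polyploidy.
Passing recovery tests therefore demonstrates the pipeline's correctness
under clean assumptions, not robustness to those artifacts.

## Published-panel summaries

The package ships the per-amplicon summary tables of three published
grapevine panels (flower sex, Ren2 powdery-mildew resistance, acylated
anthocyanins) as TSVs and derives marker densities (55/218/133 kb per
marker) and experiment-level QC from them. Percentage summaries use the
number of amplicons tested in an experiment as the denominator, counting
an amplicon that failed SNP calling (hence absent from the summary) as
failing every threshold; coverage medians are over amplicons with data,
reported to the nearest fold. Under this single rule, experiment 1 shows
87 % of amplicons under 10 % missing data with 220× median coverage, and
experiment 2 shows 83 % of amplicons above 50× — the QC regime the
platform targets.

## Problem sizes and numerical notes

Tests and the acceptance script run simulations at moderate sizes chosen
to make the statistical assertions stable: 400 progeny for segregation and
R²-recovery checks (R² tolerance ±0.08 ≈ 3 SE), 80-progeny × ~10-marker
runs for genotyping concordance, 200 samples for null-AUC calibration, 50
holdout repeats for classifier evaluation. Permutation P-values use
10 000 permutations. Floating-point ties in AUC use midranks; consensus
and allele ordering ties break lexicographically / toward the reference
allele, so every pipeline output is reproducible bit for bit under a
fixed seed.

## Known limitations

- The allele-fraction caller assumes biallelic SNPs at known offsets; it
  is not a general variant caller and ignores base qualities.
- Primer thermodynamics cover duplex Tm only — no hairpin/dimer screening
  or multiplex cross-dimer checks; multiplex compatibility is assumed.
- Effect estimation and phasing assume an informative-parent testcross
  configuration; both-parent-heterozygous markers are not fully exploited.
- Pooled association uses plain concatenation; families with different
  phenotype scales should be standardized upstream or pooled with the
  covariate option.
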