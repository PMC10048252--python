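# Methods

This note documents the models, defaults and numerical conventions behind
`inpp5d_iso`, and what the synthetic-data generator does and does not
emulate.

## Study design being modelled

A bulk-brain cohort of 56 subjects (28 AD, 28 non-AD; high NIARI
neuropathology coinciding with AD status) genotyped at two AD-associated
*INPP5D* SNPs — rs35349669 (minor allele T, MAF 0.498) and rs10933431
(minor allele G, MAF 0.220), in weak LD (r² = 0.18) — and at a transcribed
5'UTR reporter SNP, rs1141328 (G/A), which is not co-inherited with either
AD SNP.  Isoform expression is measured by qPCR against standard curves;
allele-specific expression is measured by amplicon sequencing of the
reporter SNP in the 26 reporter heterozygotes, in both cDNA and genomic
DNA.  A separate genotyping table covers 61 samples; the fixture keeps the
61-sample genotype table and the 56-subject cohort table as distinct
artifacts because their sources do not reconcile to a single roster.

## Haplotype and cohort simulation

Two-locus haplotype frequencies are solved from (MAF_A, MAF_B, r²) via
D = ±√(r²·p_A q_A p_B q_B); r² carries no sign, so a coupling convention is
required.  The default couples the minor alleles (D > 0), switchable with
`d_sign=-1`.  Requests beyond the Lewontin bound raise an error that names
the maximum achievable r².  Genotypes are two independent haplotype draws
(HWE); the reporter SNP is drawn independently (default allele-A frequency
0.45, chosen as "high MAF" appropriate for a useful reporter).  The AD/non-AD
split is exact (`round(n·fraction)`), not binomial, to mirror a designed
28/28 cohort; NIARI is high exactly for AD cases, and NIARI assignment is
independent of genotype.  Ages and post-mortem intervals are drawn around
the cohort means (82 ± 6 / 82 ± 9 years; 3.4 ± 0.6 / 2.8 ± 0.9 h).

## Expression states

Per-assay copies are log10-normal: a shared per-sample microglial abundance
factor (SD 0.5 log10 units) scales every assay, tracked by the reference
gene *ITGAM* with small measurement noise (SD 0.05), plus per-assay noise
(SD 0.15).  High-NIARI subjects' means are multiplied by per-assay fold
effects (default 1.5 for all *INPP5D* assays — a generator knob, not an
estimate).  With these settings the fitted models on n = 56 show adj R²
≈ 0.9 and a standardized reference β ≈ 0.95, the regime the analysis is
meant for.  The D47 fraction is Normal(0.13, 0.03) clipped to [0.01, 0.9] —
mean 13 % of exon-12-containing transcripts — and D47 copies are that
fraction of the ex11–ex12 assay.  The ex26-present baseline sits ~105×
above the ex15–ex16 baseline, the scale of the exon-26-retention
comparator.

For reporter heterozygotes that are also heterozygous at the designated
effect SNP (default rs35349669), the true G:A transcription ratio is
`aei_effect` or `1/aei_effect` with equal probability — the reporter is
unlinked, so which reporter allele rides the risk haplotype is random
phase.  Effect-SNP homozygotes and the null (`aei_effect = 1`) give ratio
exactly 1.  The default direction (minor allele increases expression)
follows public expression-QTL annotation; the magnitude is a knob with no
asserted literature value.

## Amplicon reads and allele counting

Reads are barcode + fixed left flank + allele 16-mer + fixed right flank,
truncated to 250 nt (2×250 chemistry; only read-level substitution errors
are modelled — no indels, adapters, quality decay, PCR duplicates or
chimeras).  Allele-1 read counts are Binomial(depth, p) with p from the
true ratio (cDNA), 0.5 (gDNA heterozygote) or 0/1 (homozygote).  A fast
path draws the binomial counts directly for calibration studies; it is
distributionally identical to counting error-free reads.

Counting policy: a read is assigned to an allele when any window of the
read (or its reverse complement — on by default, since reads come in both
orientations) matches that allele's k-mer within `max_mismatch` ∈ {0, 1},
with the variant base itself always required to match.  Default is exact
matching; the 1-mismatch mode exists because error handling in the original
counting scripts of such assays is typically unstated.  Reads matching both
k-mers count as ambiguous (never double-counted); with exact matching this
requires a sequence repeat and does not occur for this amplicon.  Samples
with fewer than 100 informative reads (configurable) are flagged and
excluded downstream; a zero allele-2 count raises an explicit
undefined-ratio error rather than returning infinity.

## AEI statistic and conditional test

cDNA G:A ratios are normalized to genomic DNA either by the cohort mean of
gDNA ratios (default — the natural choice when a single gDNA control mean
is reported) or by each sample's own gDNA ratio (`paired`).  The imbalance
magnitude is |normalized ratio − mean over included heterozygotes|; an
`anchor=1.0` option measures deviation from perfect balance instead.  The
deviation is computed across all included samples, not within genotype
groups.

Each AD SNP's effect on AEI magnitude is tested only among subjects
homozygous at the other SNP; double heterozygotes are thereby excluded
(phase unknown).  Test-SNP homozygotes (both classes pooled) are compared
with heterozygotes by a two-sided Mann–Whitney U test: exact enumeration of
the permutation null (Streitberg–Røhmel shift algorithm on doubled
midranks, valid under ties) whenever min(n₁,n₂) ≤ 10 and n₁+n₂ ≤ 30,
otherwise the normal approximation with tie and continuity corrections.
No multiple-testing correction is applied; p values are nominal.

Calibration (recomputed by the test suite): under the null the conditional
test rejects at 4–5 % at α = 0.05 over 1,000 simulated cohorts of n = 56 at
10,000 reads/sample; power rises monotonically across true ratios 1.01 /
1.03 / 1.06, chosen inside the responsive range implied by the binomial
ratio noise at that depth (SE ≈ 0.02).

## qPCR quantitation and models

Standard curves are least-squares fits of Cq on log10(copies); curves with
non-negative slope are flagged rejected.  Replicate Cq values are averaged
before quantitation; sub-single-copy inversions are flagged `below_range`
but returned.  Copy numbers are log10-transformed (the base is irrelevant
to standardized coefficients).  The reference gene enters as a covariate on
the right-hand side rather than by pre-dividing; ratio-based analyses
(isoform vs full-length) use `relative_expression`.  All model variables
are z-scored (ddof = 1), so coefficients are standardized βs and a sole
predictor's β equals its Pearson r.  Genotype is coded additively by
minor-allele count; the coding is a parameter.  The CHX trend is the OLS
slope of D47 fraction on hours within the CHX arm, with the arm contrast as
a treatment-by-time interaction and a Spearman rank correlation as a
distribution-free companion.

## Isoform catalog conventions

Coordinates are 1-based closed intervals in spliced-transcript space; exon
labels follow the gene's global numbering with the retained intron-14
segment (`in14`) ordered between ex14 and ex15.  A primer pair captures an
isoform iff both anchors are present and no exon between them (in global
numbering) is absent.  Deletions are recorded per exon in
application-time coordinates, so primer positions given on the reference
map through them; a deletion overlapping a primer footprint, or an absent
anchor exon, yields no product, and a deletion between the primers
shortens the product by exactly the deleted overlap.

The packaged catalog is synthetic: deterministic sequences with the real
topology.  Exon 12 (150 nt) starts on a codon boundary, so deleting its
first 47 nt shifts frame (47 mod 3 = 2) and the downstream sequence
produces a premature stop; exon 26 is 44 nt (44 mod 3 = 2) and exon 27 is
engineered so the exon-26 skip reads the +1 frame as the 17-residue tail
SEALSELPLSREPRGTA followed by a stop, while the reference frame continues
past the junction to a later stop.  The ex9–ex12 and ex11–ex12 primer
pairs are placed to give 458/411 and 224/177 nt products on the reference
and D47 variant.  Real sequences are not shipped; any catalog with real
sequences can be supplied as JSON in the documented schema.

NMD candidacy uses the standard last-exon-junction heuristic: a PTC whose
stop codon ends more than 50 nt (strict inequality, configurable) upstream
of the final exon–exon junction is a candidate; a PTC in the last exon, or
any stop in a single-exon transcript, is not.  The rule is a configurable
convention, not a measured property.

Two notational ambiguities in the source material were resolved as: the
phosphatase-domain TSS-C isoform is 213 throughout, and its leader is
intron 14 (not intron 15).

## Reproducibility and problem sizes

All generators accept integer seeds; one run seed derives per-stage
substreams keyed by a CRC32 hash of the stage name, so stages are
independently reproducible and full-pipeline outputs are byte-identical
under a fixed seed.  The analysis drivers use 56-subject cohorts; read
simulation uses 10,000 reads/sample for the calibration and acceptance
studies and 2,000 reads/sample in the pooled-FASTQ demonstration driver.
The repeated-cohort calibrations (1,000 null cohorts; 150 cohorts per
power level; 500 seeds for effect-recovery) use the binomial fast path.

## What passing tests do and do not show

The simulator reproduces the statistical structure the analysis assumes —
HWE genotypes with the stated LD, exact design splits, log-linear qPCR,
binomial allele sampling, linear CHX accumulation.  It does not emulate
real amplicon artefacts (PCR bias beyond a constant factor cancelled by
gDNA normalization, strand imbalance, indels, contamination), genuine
biological covariance between isoforms beyond a shared microglial factor,
or genotype–pathology dependence.  Green tests therefore validate the
pipeline's correctness and calibration under its stated model, not the
biological conclusions on real tissue; the published subject-level
regression statistics are not recomputable without the original data and
are used only to set plausible generator defaults.
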