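# Methods

This note records the models, parameter choices and numerical decisions
behind `allelemeth`, and what the synthetic-data tests do and do not
establish about real data.

## Coordinate system and the amplicon model

Coordinates are 1-based inclusive genomic positions throughout (BED export
converts to 0-based half-open). Only plus-strand cytosines are enumerated;
minus-strand CpG symmetry is assumed rather than modelled, which is how OB
reads inform a CpG site: the G at coord+1 carries the complementary strand's
C, taken to share the methylation state of the plus-strand C. Site names are
`context_dddd` from the last four digits of the coordinate; a collision
appends the full coordinate. A CpG-SNP is a CpG site linked to a C>T
polymorphism; its methylation exists only on C alleles, and every haplotype
in the catalogue declares which base it carries there.

The bundled reference sequence is synthetic (a seeded random 1418-mer pinned
to the locus coordinates, with the marker SNPs, the CpG-SNP and the four
named CpGs placed at their genomic positions); the pipeline accepts any real
FASTA + JSON annotation with the same schema.

## Read processing

**Quality filter.** Mean-Phred ≥ 30, the conventional CCS threshold.

**Strand space.** Bisulfite PCR yields two distinguishable template spaces.
We classify by edit distance after collapsing C→T (OT) or G→A (OB) in both
read and reference; ties or best identity < 0.8 mark a read unalignable. The
0.8 identity floor and the 50%-of-amplicon length floor are repository
choices (the source protocol does not state them); both are configurable.

**Alignment.** Two engines behind one interface. The default is edlib's
edit-distance path — amplicon reads are substitution-dominated and locus
identity is guaranteed by the PCR design, so a unit-cost global alignment is
both sufficient and ~50× faster. An affine-gap engine (Biopython's global
aligner; match +1, mismatch −1, gap open −3, extend −1; a gap of length L
costs open + (L−1)·extend) is available for indel-heavy stress tests and is
the engine checked against a quadratic-time Gotoh oracle in the tests.
Identity is matches over the longer sequence length, so gaps depress it.

**Calling.** At a cytosine site, the read base in the site's informative
space maps C→M / T→U (OT) or G→M / A→U at the partner G (OB); any other base
is NA, not U — counting sequencing errors as converted would bias
methylation downward. OB reads cannot inform plus-strand CpH sites (no
partner G), so conversion QC draws on OT reads; efficiency is estimated as
1 − pooled CpH methylation, and any CpH site above 0.2 is flagged (0.2
mirrors the VMS lower bound; an unmethylated site above it is no longer
"hypomethylated").

**Phasing.** A SNP allele is called per read from the conversion images of
its two alleles in the read's space (OT: C→{C,T}; OB: G→{G,A}); overlapping
images mask the SNP for that read. With the catalogue TGT/GAG/TGG over
alleles T/G, G/A, T/G, markers 1+3 are informative in OB space and all three
in OT space, so both spaces phase. The C/T CpG-SNP is readable only in OB
space, which is also the only space where its methylation is called — and
only on reads carrying C. A read is assigned when its unmasked calls fit
exactly one catalogue haplotype. The subject's diplotype is inferred from
read-label frequencies (second label needs ≥ 20% of assigned reads);
per-allele profiles below 5× depth are excluded from statistics but logged,
and a heterozygote left with one passing allele falls back to it with a
warning. "Coverage", used as a covariate downstream, is the subject's total
haplotype-assigned passing reads (the source never defines it; per-subject
was chosen over per-site).

**Subject averages.** Mean of the two allele fractions; at the CpG-SNP a T
allele contributes a structural 0, so C/T subjects get half the C-allele
fraction and T/T subjects 0. This reproduces the near-bimodal subject-level
distribution such sites show; `t_allele_zero=False` treats T alleles as
missing instead.

## Scores

PERS = Σ ln(OR) over present exposures, OR 1.04/1.84/2.87 for winter birth
(December–February), obstetric complications, adverse childhood experiences.
The weights are literature constants by design and never re-estimated. VMS
bounds [0.20, 0.80] are inclusive and applied to the pooled (patients +
controls) mean; per-group means are emitted for inspection.

## Bootstrap inference

Case-resampling bootstrap of whole rows, B = 1000 by default. BCa intervals
use the median-bias correction z0 = Φ⁻¹(fraction of replicates below the
estimate, half-weight on ties, clipped away from 0/1) and jackknife
acceleration a; BC (mediation) sets a = 0. The bootstrap p-value is the
smallest α at which the (1−α) interval excludes 0, searched on an α-grid of
0.001 — the "bootstrap p" of point-and-click statistics packages is not
defined anywhere we know of, so this CI-inversion definition is ours and is
stated wherever the p is reported. Degenerate bootstrap distributions (all
replicates equal) fall back to percentile with a warning.

Calibration, measured by the test suite: BCa 95% slope intervals at n = 80
cover ≈ 93.5% — the known small-sample narrowness of percentile-type
intervals (bootstrap SD underestimates the sampling SD by a few percent and
there is no t-correction). The tail is relatively worse: at α = 0.0125 the
realized two-sided level is ~2–3× nominal at n ≈ 130 rows regardless of B,
resampling unit (rows vs subject clusters) or quantile rule, and our
endpoints match R's `boot::boot.ci(type="bca")` on shared data. Consequently
a Bonferroni family of four bootstrap tests realizes a family-wise error
near 7%, not ≤ 5%; the family-wise null suite asserts the nominal bound and
documents this as a property of BCa at this design size, not of the
implementation. Exact-distribution routes (Kruskal–Wallis) are calibrated
(1.0% at nominal 1.25%).

Stepwise selection is forward-backward on Wald p-values (enter 0.05, remove
0.10 — the defaults of common GUI statistics software; an AIC criterion is
available and is the one checked against exhaustive best-subset search).
Forced covariates and the intercept are never removed. Dunn post hoc z tests
use tie-adjusted rank variances and are left unadjusted internally; the
caller applies the Bonferroni family. The conditional Spearman is the
partial correlation of rank-transformed variables. The normality gate is a
plain KS test against a fitted normal (no Lilliefors correction — the source
software's variant is unstated) with the cube transform applied on rejection
with left skew. LD is computed on gamete counts with χ² = N_gametes · r².

Haplotype effects are encoded per the analysis they serve: allele-level rows
with GAG/TGG-vs-TGT dummies for the per-site models, subject-level
risk-allele count 0/1/2 for phenotype and mediation models.

## Mediation

Product of coefficients from two linear fits (mediator ~ treatment +
confounders; outcome ~ treatment + mediator + confounders), indirect = a·b,
total = c′ + a·b (equal to the reduced-model coefficient exactly, by
linearity). Intervals are bias-corrected bootstrap (BCa behind a flag), p by
CI inversion. With a near-deterministic genotype→methylation link the
direct and indirect paths are close to collinear and their intervals widen
accordingly; the total effect remains well estimated. Null calibration
(a = 0, n = 500, B = 199): the BC interval covers 0 in ≈ 94.7% of seeds;
recovery of a·b = 0.20 at n = 500 is unbiased to within ±0.05 (median).

## The synthetic cohort

Defaults are the study conditions where stated: 66 patients + 63 controls;
exposure prevalences 23/36/55% (patients), tertiary education 71%, VNTR V2
allele frequency 0.41; per-allele depth mean 30 (the source states only a 5×
floor; 30× is a realistic CCS amplicon depth), conversion efficiency 0.99,
inappropriate conversion 0.01, substitution error 0.005, constant Q40 bases.
Site models place the four VMS at their published pooled means (≈ 0.28,
0.74, 0.8, with the CpG-SNP C-allele mean 0.90 giving a subject-level mean
set by the C-allele frequency): one stochastic, one additive (logit-scale
haplotype offsets + PERS slope), one allele-specific, one CpG-SNP
structural. Haplotype frequencies (TGT 0.45 / GAG 0.40 / TGG 0.15) are not
published and were chosen once as realistic for a common risk haplotype.

Choices that simplify reality, hence limits on what green tests show:
CpG-SNP linkage is deterministic (D′ = r² = 1; the population estimate is
r² ≈ 0.92), so phasing never meets a recombinant allele. Exposures couple
through a sequential logistic factorisation (education | sex → ACE |
education → SOB → OC | SOB, sex) with intercepts calibrated so marginals hit
their targets exactly — it reproduces the reported pairwise association
signs with minimal parameters but is not a causal model of obstetric risk.
Reads are full-length with substitutions only (an indel rate exists for
aligner stress tests); there is no instrument noise model, no chimeras, no
within-molecule conversion gradients. Phenotypes are linear in covariates
with Gaussian noise on an arbitrary scale (T-score standardisation is out of
scope); power at n = 66 for the mediation path is accordingly low and the
generator makes no attempt to inflate it. The VNTR couples to the risk
haplotype at the allele level with target correlation r (feasibility bound
reported on violation); r = 0.7 default sits near the bound implied by the
frequencies.

## Pipeline routing and eligibility

Per-site genetic/environmental models follow the distribution of the data:
sites passing the normality gate (raw or cubed) go to allele-level
BootstrapOLS with haplotype dummies, PERS and the risk×PERS interaction;
sites failing it (the near-bimodal CpG-SNP in practice) go to
Kruskal–Wallis + Dunn with a conditional Spearman for PERS. Bonferroni
families: 4 across the VMS, 6 across phenotypes. Depression is analysed only
when at least 10 subjects score PANSS G6 ≥ 4 (the eligibility rule the
source applies qualitatively; 10 is our configurable floor). Stages log
record counts at every filter so attrition is auditable, and the report
embeds seed, B and a config hash.

## Problem sizes in the test suite

The suite runs at desk scale: shared cohorts of 6–24 subjects for
read-level checks, 100 subjects for methylation recovery, 500 replicate
cohorts for family-wise error, 1000 datasets (n = 80, B = 399) for slope
coverage, 500 seeds (n = 500, B = 199) for mediation null coverage. These
sizes give Monte-Carlo standard errors comfortably below the asserted
margins while keeping the default run in minutes.

## Known limitations

No statistical phasing across subjects (read-backed only); no genome-scale
alignment or liftover; no FDR procedures or mixed models; LD/HWE assume
autosomal biallelic counts; the bootstrap p is a CI-inversion construct with
the tail behaviour described above; plotting is left to the caller.
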