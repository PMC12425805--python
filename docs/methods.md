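# Methods

`pancistrome` implements a haplotype-specific analysis of transcription-factor
(TF) footprint occupancy for a panel of F1 hybrids that share one reference
mother. This note records the models, the numerical choices, and what the
synthetic data generator does and does not emulate.

## The measurement model

Each variant site in each line carries footprint coverage for the two
haplotypes, expressed in RPGC units (reads per genome coverage; scale =
effective genome size / mapped reads). The **binding frequency** toward the
reference allele is

    f = RPGC_ref / (RPGC_ref + RPGC_pat),

missing (NA) when both alleles have zero reads. Fragment-center tracks
collapse each read to a 20-bp window centred on its middle base; for
even-length reads one of the two central bases is chosen at random, for odd
lengths the window is `[m-10, m+10)`. One read therefore contributes exactly
`20 x scale` mass to the track.

**MP (MOA polymorphism):** a variant inside a footprint peak whose
better-covered allele exceeds 7 RPGC (~25 reads at the default scale of 0.3)
while the other allele has at least one read. We read the threshold's "at
least one read in the corresponding allele" as applying to the *other*
allele, which is what makes the allelic test well defined; the alternative
reading (same allele) is implied by the RPGC cut-off anyway.

**AMP (allele-specific MP):** an MP whose reference read count deviates from
Binomial(n, 1/2) by an exact two-sided binomial test — on read counts, never
on normalised values — with Benjamini–Hochberg control at 1% FDR within each
line x condition. The two-sided p-value is the "minlike" sum of outcome
probabilities not exceeding the observed one, with R's `1 + 1e-7` relative
tolerance, so it reproduces `binom.test` exactly. AMPs whose
whole-genome-sequencing control ratio falls outside the 5th–95th percentile
(linear interpolation) of all MP control ratios are discarded as likely
mapping artifacts.

**INDELs** (2–50 bp, non-reference allele in >=2 lines): the allele carrying
the inserted sequence is scored as the mean RPGC over the insertion span; the
allele lacking it as the mean over the 3 bp before plus 3 bp after the
deletion point (zero-coverage bases count). RPGC means are back-converted to
reads by `round(rpgc / scale)`, half away from zero.

## bQTL mapping

At every site that is an MP in at least two lines, five ordinary
least-squares models are fitted across lines:

    f ~ mCHH      f ~ mCG      f ~ mCHG      f ~ GT      f ~ GT + mCG + mCHG + mCHH

with `GT` in {0, 1} (paternal allele identical to / different from the
reference) and `mC*` the paternal-minus-reference difference of the ±20 bp
window methylation means. The response is an allelic ratio, so the allelic
methylation *difference* is the natural per-line predictor; using one
allele's level instead would conflate line-to-line methylation variation with
allelic contrast. p-values are two-sided t-tests on the slope; predictors
with zero variance or zero residual variance give missing p-values.

Selection applies BH per model across sites at 5% FDR (not pooled across the
five models, keeping per-feature error control interpretable). A site is
genotype-associated when the GT model passes and methylation-associated when
any single-context model passes; the full model is available as a
configurable tie-informer (`meth_rule="any"`). Significant sites within 65 bp
chain transitively into linkage groups; the lead is the member with the
lowest p among its *significant* models, ties broken leftmost.

## Methylation classes

Window means use a closed ±20 bp window (the boundary convention is a
choice; the window is stated without one). Differential methylation: one
allele <10% and the other >70%. Strict equality: both <10% or both >70%.
The two classes are mutually exclusive by construction. CG and CHG drive the
differential analysis (they carry effectively all allelic differences); CHH
is kept only as a covariate in the association models. When CG and CHG
disagree on direction the pair is treated as not differential.

## Condition response

Footprint regions are tested for a drought response by a two-sided Welch
t-test on replicate coverages (significant at p < 0.05). Sites with an AMP
call in at least one condition are grouped: (I) detected in exactly one
condition; (II)/(III) >=60% bias toward the same/opposite allele in both;
(IV) significant bias in one condition with the other frequency strictly
inside (40%, 60%). The 60% rule deliberately replaces a second statistical
cut-off in the second condition; a pair with bias >=60% there falls to II/III
whether or not it was separately significant. High-confidence drought
candidates are bQTL within 65 bp of AMPs inside significantly responsive
regions in >=2 lines, lying within 5 kb upstream of the TSS or 1 kb
downstream of the TTS (strand-aware, gene body included) of a gene whose
transcripts are both haplotype-specific and drought-responsive.

## Variance-component partitioning (VCAP)

Kinships are centred cross-products `K = ZZ'/c` scaled to mean diagonal 1
(the centred-IBS analogue; the original analysis names a tool, not a
formula). Background SNPs are matched to bQTL by allele-frequency bin (0.1)
and distance-to-gene bin (intragenic, 0–1 kb, ..., 9–10 kb, >10 kb; distance
to the nearest gene edge, 0 inside), one non-bQTL site per bQTL without
replacement within a permutation; an empty cell falls back to the nearest
non-empty distance bin at the same allele-frequency bin with a warning.
Across permutations the bQTL kinship is fixed and only the background (and
hence rest-of-genome) sets are resampled.

REML fits `y = 1b + sum_k u_k + e`, `u_k ~ N(0, s2_k K_k)`, with
average-information updates, an EM warm-up step, step rejection to EM
whenever the likelihood would decrease, components clamped at a floor of
`1e-8 x var(y)`, and convergence on a relative log-likelihood change below
`1e-8` (tight enough that proportions are stable to ~1e-5 under trait
rescaling). Individuals with missing trait values are dropped and the
kinships subset. Estimates agree with a derivative-free maximisation of the
same restricted likelihood to better than 1e-3 in proportions on small
problems.

Trait simulation follows the validation design: each trait is a sum of
zero-mean multivariate normals with covariances `h2_k K_k` plus
`h2_e I`, heritabilities summing to 1. Kinships that are PSD only to machine
precision are square-rooted via eigenvalue clipping (silently); genuinely
indefinite inputs warn.

## The synthetic world

`SimConfig` defaults state the emulated design once: 25 F1 lines, variants
retained with the non-reference allele in >=2 lines (minimum allele
frequency 0.08), footprint peaks covering 2% of a 1-Mb linear chromosome,
three replicates at mean depth 50 with gamma-Poisson overdispersion
(`var = mu + 0.3 mu^2`; the count model is a choice, the original states
none), RPGC = reads x 0.3 so ~25 reads ≈ 7.5 RPGC, methylation modes at
0.02/0.85 (Beta, concentration 150) so the <10%/>70% rule separates them
cleanly, and well-watered vs drought conditions.

Occupancy truth is a logistic effect model: `f = expit(b_G GT + b_M dM)`
with both slopes set so a full effect moves the frequency from 0.5 to
`0.5 + delta` (default delta 0.25). Genotype effects act in lines carrying
the non-reference allele; methylation effects act through the scaled allelic
methylation difference, so the hypomethylated allele never has lower
expected occupancy — the generator encodes the direction the analysis is
meant to detect, which is exactly why a green directionality test validates
the caller's sign conventions rather than discovering biology. Causal sites
are labelled geno/meth/both/null; the spec'd configuration has no field for
the "both" class, so `frac_both_effect` (default 0.05) was added. Drought
rescales total occupancy at a configured fraction of sites (x2 or x0.05,
the latter dropping below the detection limit) while preserving allelic
bias, which is the regime the condition-group analysis distinguishes.

Half of the variant sites are placed inside peaks (`frac_sites_in_peak`):
the analysis only concerns variants at occupied loci, and a uniform layout
would leave ~2% of sites past the in-peak filter.

For variance-component validation, genotypes come from a Balding–Nichols
model with 25 clusters (the family count of a nested association mapping
panel) and Fst 0.15, drawn independently per marker component. This matters:
with i.i.d. markers all kinships collapse toward the identity and the
three-way partition is not identifiable at n = 400; with structured markers
the components separate and 20 simulated traits recover heritabilities of
(0.4, 0.2, 0.2, 0.2) to within ±0.05 in the mean.

What the generator does **not** emulate: read-level reference-mapping bias
(counts are drawn symmetrically), linkage disequilibrium between variant
sites (genotypes are independent across sites), trans-acting variation,
real methylation spatial autocorrelation, and multi-chromosome genomes
(a single linear chromosome; a `chrom` column carries through). Green tests
therefore establish correctness of the statistical machinery under the
stated model, not robustness to those artefacts.

## Determinism

All randomness flows from one seed through named substreams
(`SimConfig.rng("genotypes")`, ...), so an identical configuration produces
byte-identical fixture files; the pipeline manifest records the config
snapshot, seed, per-stage record counts and SHA-256 digests of every output.

## Known limitations

- The REML solver is dense (O(n^3) per iteration); it is meant for panels of
  hundreds to a few thousand individuals, not biobank scale.
- The matched-background fallback (nearest distance bin) breaks exact
  histogram equality when a cell has too few non-bQTL sites; it warns when
  it does.
- Attribution of a bQTL to methylation uses marginal single-context models;
  with strongly correlated genotype and methylation the geno/meth/both split
  is identifiable only to the extent the predictors decorrelate across lines.
- `fragment_center_track` loops over reads in Python; it is a fixture-scale
  utility, not a BAM-scale one.
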