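# Methods

This note documents the models behind `ffnmap`, the defaults and why they
were chosen, the numerical decisions that matter, and what the synthetic
data can and cannot tell you about real experiments.

## F2 simulation

**Genome frame.** Twelve chromosomes of 230 Mb with parent-informative SNPs
on a jittered grid (default mean spacing 500 kb, jitter up to ±45% of the
spacing).  These sizes are representative of the pepper genome at the marker
density a pooled RNA-seq experiment typically yields; both are
configuration, not biology.

**Meiosis.** Crossovers follow a Haldane (no-interference) process: the
count per chromosome is Poisson with mean equal to the map length in
Morgans, positions are uniform (constant cM/Mb), and each gamete starts on a
random parental strand.  The model is deliberately minimal because it has a
closed-form oracle — the recombination fraction between loci d Morgans
apart is r = ½(1 − e^(−2d)), and the F2 genotype correlation is 1 − 2r —
which the test suite checks directly.  Pepper's recombination landscape is
not published at this resolution; the rate defaults to 2 cM/Mb and is
configurable.  Crossover interference, recombination hot/cold spots and
segregation distortion are *not* modelled.

**Trait model.** One biallelic locus, placed by default at 97.5% of
chromosome 2 (the distal end).  FFN is drawn per plant as
round(N(μ_g, σ_g)) clipped to ≥ 1, with genotype means (2.3, 8.5, 14.0) —
the early-parent, F1 and late-parent averages — and standard deviations
(0.7, 1.0, 0.6).  The means are observed quantities; the standard
deviations are a calibration chosen so simulated parental ranges match the
observed 1–4 and 13–15 leaf counts, since within-genotype variances were
not reported.  The early allele is fully recessive by construction
(μ_het ≈ μ_F1 sits with the late class).  Minor loci, epistasis and
genotype-by-environment effects are out of scope.

**Pooling and sequencing.** The two bulks are the k = 30 lowest- and
highest-FFN plants, ties broken by individual index so pool membership is
deterministic.  At each SNP the true late-allele frequency of a pool is
mean(genotype)/2 over members; the observed alt count is
Binomial(D, f(1−e) + (1−f)e) with D ~ Poisson(depth), zero depths
resampled.  Defaults: depth 100, allele-flip error e = 0.01.  Depth varies
per SNP (Poisson) rather than being fixed because RNA-seq coverage is
overdispersed; expression-level variation between genes, allele-specific
expression and mapping bias are *not* emulated, so real pool-seq data will
be noisier than the generator at equal nominal depth.

## Delta-SNP index and windowing

Frequencies are f = alt/(ref+alt) per pool, masked where a pool's depth is
below `min_depth` (default 10).  The index is **signed**, delta = f_early −
f_late, preserving which parent contributes the allele; peak calling uses
|delta|.  Windows are anchored at position 1 on every chromosome, half-open
[start, start + 3 Mb), advanced in 1 Mb steps, truncated at the chromosome
end; a window needs `min_snps` (default 5) SNPs for a mean, and the mean is
the unweighted mean of member SNP deltas in genomic order (the test oracle
recomputes it naively with the same summation order, so agreement is
exact).  Coordinates are 1-based throughout, matching VCF convention.

**Peak calling.** A window is flagged when |mean delta| ≥ genome-wide
mean + z·SD (default z = 3; a median/MAD variant and a plain quantile cut
are selectable).  If the spread degenerates to zero the rule falls back to
flagging any non-zero window.  Contiguous flagged windows merge into one
peak spanning their union, ranked by maximum |mean delta| with ties going
to the leftmost.  Because linkage makes window deltas long-range correlated
along a chromosome, the genome-wide z-rule is *not* a familywise error
control: under a phenotype-blind null it flags occasional weak runs
(|mean delta| ≲ 0.4 in the default design).  What identifies a real
single-locus signal is the magnitude of the top peak (≈ 0.95–1.0) and its
stability; in the default design the rank-1 peak contains the true locus in
essentially every replicate.  Users who need genome-wide calibrated peak
probabilities should raise z or permute pool labels.

## Segregation genetics

**Antimode.** The early/late threshold is the "low point" of the FFN
histogram.  The histogram of a 297-plant F2 is sparse, so the raw deepest
bin is noisy; the implementation (i) smooths the integer histogram with a
width-3 moving average, (ii) takes interior local minima between the
outermost modes as candidates, and (iii) returns the candidate with the
least raw count mass in a width-5 neighbourhood — a valley is a sparse
*region*, not one empty bin — with ties resolved to the smaller value.
With the default trait model this yields 5, the value separating the
early (2–4) and late (6–14) classes.  In an independent 2000-replicate
check the rule lands in the correct valley 99.7% of the time; the residual
failures pick the shallower dip between the heterozygote and late-parent
clusters, which the trait model leaves genuinely trimodal.  Plants exactly
at the threshold are "ambiguous" and excluded from ratio tests, mirroring
class definitions that omit the valley value.

**Ratio test.** Pearson chi-square without continuity correction,
df = classes − 1, upper-tail p.  No correction is applied because none was
stated for the original analysis and the plain statistic reproduces its
printed p-value (χ² = 1.08, df 1 → p = 0.30).

**CAPS prediction.** Recognition sites are IUPAC strings scanned
case-insensitively with overlaps allowed; ambiguity codes expand in the
site but never match in the sequence.  Cut coordinates are match start +
offset (reverse-complement scanning optional, cuts mapped back to forward
coordinates); fragments are consecutive differences including both ends,
so they always sum to the amplicon length.  The enzyme catalog (TaiI =
ACGT cut after the site, plus a few common enzymes) is an editable table,
not hard-coded chemistry.

## Relative expression (2^−ΔΔCT)

Technical replicates are averaged to one Ct per (sample, gene, biological
replicate) *before* any normalization; ΔCt = Ct_target − Ct_reference per
biological replicate; ΔΔCt subtracts the calibrator sample's mean ΔCt; fold
change is 2^−ΔΔCt, assuming perfect doubling per cycle (no efficiency
correction, single reference gene).  Biological-replicate dispersion is
summarized as the standard error of fold changes.  Group comparisons use
the Welch (unequal-variance) t test — chosen over the pooled-variance form
because equal variances were never established — or the
Wilcoxon–Mann–Whitney test, exact when the combined sample is ≤ 20 and
tie-free, otherwise the normal approximation with tie correction.

## Mixed-model association

The model is y = μ + Qα + x_vβ + u + ε with u ~ N(0, σ²g·K),
ε ~ N(0, σ²e·I).  Variants are filtered at MAF ≥ 5% (computed on
non-missing calls).  K is the centered cross-product (VanRaden) kinship
ZZᵀ/Σ2p(1−p) with mean-imputed missing dosages; Q defaults to the two
leading principal components of the centered genotype matrix, standing in
for an externally estimated structure matrix.  The variance ratio
δ = σ²e/σ²g is estimated **once under the null** by REML profiled over the
eigen-spectrum of K (grid on log δ ∈ [−10, 10] plus bounded refinement) —
the EMMAX shortcut; compression of individuals is not reimplemented, as it
is a speed device rather than a different estimand.  Each variant is then
tested by weighted least squares on the eigenvector-rotated system with the
residual scale re-estimated per variant, giving a Wald t statistic with
n − p degrees of freedom; with K = I and no Q this reduces *exactly* to
OLS, which the tests verify to 1e-8 against an independent implementation.
Individuals missing a variant's call are excluded casewise from that test
(the rotation is recomputed on the subset at the fixed δ̂).  PVE is defined
as β̂²·Var(x)/Var(y) on the observed scale, clipped to [0, 1].  Because the
tested variants also build K, null p-values are mildly conservative
(empirical 5%-level size ≈ 0.042 in a 50-variant panel) — the familiar
proximal-contamination effect; leave-one-out kinship would remove it but is
unnecessary at candidate-gene scale.

## Divergence dating

T = Ks/(2R) with R = 1.5×10⁻⁸ synonymous substitutions per site per year,
reported in Mya (rounded to 2 d.p. in tables).  Ks values are inputs; no
saturation correction or filtering is applied.  For a duplicated block the
mean Ks over gene pairs is dated — by linearity this equals the mean of the
per-pair times.

## Problem sizes in the tests and acceptance script

The suite exercises the study design at its native scale (n = 297, pools of
30, 12 × 230 Mb, 500 kb SNP spacing) and uses replicate counts chosen to
keep the whole suite at a few minutes on one CPU: 200 replicates for the
segregation-ratio study, 50 for peak recovery, 1,000 null replicates
(n = 200, 50 variants) for mixed-model calibration, and 200 replicates at
n = 164 for PVE recovery.  All simulations derive their randomness from
explicit seeds and are byte-reproducible.

## Known limitations

- The generator emulates DNA-like allele sampling of pooled RNA-seq; it does
  not model expression variation, allele-specific expression, mapping bias
  or index hopping, so passing tests demonstrate the statistical machinery,
  not robustness to every RNA-seq artifact.
- The peak caller's z-threshold is descriptive, not a calibrated genome-wide
  error rate (see above).
- The mixed model assumes a single random effect with known-form kinship;
  dominance, epistasis and environment are absent.
- The trait model's within-genotype standard deviations are a calibration;
  real F2 phenotype dispersion (and hence antimode sharpness) may differ.
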