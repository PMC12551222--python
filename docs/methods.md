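# Methods

`hapintro` reimplements, as a reusable library, an ancestry-aware analysis of
donor introgression in admixed livestock genomes: detecting gene flow,
localizing it on the genome, asking whether it was selected, and connecting
it to phenotypes, expression, and regulatory context. Everything is
exercised on synthetic data with known ground truth; this note records the
models, the defaults and why they were chosen, and what the synthetic
experiments do and do not demonstrate.

## Coordinate conventions

Internally all intervals are 0-based half-open. VCF positions (1-based) are
converted at the I/O boundary. Two deliberate exceptions: (i) window
membership of a variant compares its 1-based position directly against the
half-open window bounds, matching the windowing of the common VCF tools (a
variant at 50,000 falls in [25k, 75k) and [50k, 100k), not [0, 50k));
(ii) spans quoted from 1-based inclusive coordinates (browser style) are
`end − start + 1` bp, so Chr7:30,297,170−30,364,571 spans 67,402 bp ≈
67.40 kb.

## Synthetic data

**Source panels.** Three panels — a recipient (EUR-like) and two donors —
are drawn from a Balding–Nichols model: ancestral frequencies
Uniform(0.05, 0.95), panel frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with
F = `panel_fst` (default 0.3), haplotypes sampled site-independently.
Empirically the realized two-population Weir–Cockerham F_ST matches the
Beta parameter closely (0.294 realized at F = 0.3), so no extra calibration
is applied.

**Admixed cohorts.** Each admixed haplotype is a tract mosaic: breakpoints
are a Poisson process at rate `generations × recomb_rate` per bp
(exponential tract lengths); each tract copies a uniformly chosen haplotype
from the recipient (probability 1 − α) or a donor panel (total probability
α = `admix_fraction`, default 0.2, split by `donor_weights`). The default
map is a constant 1 cM/Mb. The admixture age default is 30 generations;
association-scale experiments use 60 generations and a 150 Mb chromosome so
the cohort carries enough independent tracts for variance-component
estimation (see below). True per-site and per-block labels are returned
beside the data, so every downstream stage has an accuracy oracle.

**Traits and expression.** A trait is
`y = Σ_k d_k β_k + u + covariates + e` where `d_k` is the 0/1/2 donor-
ancestry dosage at causal block k, the polygenic term `u` is built from
*centered, unstandardized* block dosages (its covariance is then
proportional to the VanRaden method-1 GRM used by the estimator — a
standardized-weight polygenic term would be a misspecified pairing and
biases REML), orthogonalized against the causal dosages so that each
declared variance fraction is marginal, and rescaled so the realized
genetic fraction equals the declared h². Two discrete covariates (year,
parity) and two quantitative ones (start/end test weights) are generated
with recorded coefficients. Expression is exp-Gaussian (TPM-like) with one
cis causal block per gene acting on the log scale.

**Sweep generator.** Site-independent panels carry no LD, so EHH statistics
are undefined on them. A dedicated generator produces hard-sweep-like
structure: a fraction of haplotypes (default 0.4) copies a single core
haplotype contiguously around the core site until a geometric break
(default probability 0.02 per site per side, i.e. a mean shared flank of
50 sites ≈ 50 kb at the default density). The derived core allele marks
carriers. These defaults give a concentrated sweep signature: a much wider
one spreads the signal over many hitchhiking sites and no single site
stands out — real sweep scans face the same trade-off, which is why
practice summarizes at the window level.

**What the generator does not emulate.** Background LD outside sweeps,
allele-frequency spectra under drift/selection, genotyping error, phasing
switch errors, and missingness (inputs are assumed imputed). Passing tests
therefore demonstrate correctness of the estimators and calibrated behavior
under the stated generative model, not robustness to real-data artifacts.

## Local-ancestry painting

Haplotypes are recoded in non-overlapping 5-SNP blocks anchored at each
chromosome's first retained SNP. The per-block panel score is the mean of
`exp(−Hamming distance)` to the panel's reference haplotypes. A bare
per-block score is too weak at F_ST 0.3 (≈0.81 block accuracy): ancestry
tracts span tens to hundreds of blocks, so the classifier combines
log-scores over a centered context window (default 11 blocks), renormalizes
across panels, and assigns the argmax panel only when its combined score
exceeds 0.5, falling back to the recipient code otherwise. The fallback is
deliberately conservative — it under-calls introgression. With defaults,
block accuracy on matched simulations is ≈0.99 and the recovered
genome-mean donor frequency tracks the simulated admixture fraction.
`context_blocks=1` recovers the bare score. An ingestion path
(`read_ancestry_paint`) re-segments externally produced MSP-style ancestry
tracks onto the 5-SNP grid by majority bp overlap, ties toward the
recipient code.

Donor channels are kept separate (DONOR1, DONOR2) with a derived pooled
channel `DONOR_ALL`, since analyses both pool and separate donors.
Introgressed regions are maximal runs of blocks whose donor frequency
exceeds 0.5. Profile similarity uses Pearson r (NaN on a constant track)
and KLD with a 1e-9 pseudo-count before normalization.

## Introgression statistics

**D-statistic.** Frequency-weighted ABBA/BABA over shared biallelic sites
polarized by the outgroup major allele (outgroup ties drop the site):
`n_ABBA = Σ (1−p₁)p₂p₃(1−p₄)`, `n_BABA = Σ p₁(1−p₂)p₃(1−p₄)`,
`D = (n_ABBA − n_BABA)/(n_ABBA + n_BABA)`. Significance is a delete-one
jackknife over contiguous equal-SNP blocks (default 20; Z = D/SE, two-sided
normal p). With few blocks the normal reference for Z is anti-conservative
(t-like tails: ≈8% exceedance at |Z| > 2 with 20 blocks); calibration
studies therefore use 50 blocks, where the null exceedance is ≈5–6%.
A pattern-count mode covers the four-haploid-genome worked example.

**F_ST and LSBL.** Per-site Weir & Cockerham (1984) components a, b, c for
two diploid populations; windowed weighted estimator Σa/Σ(a+b+c); per-site
ratio for LSBL, `(d_hl + d_hc − d_lc)/2`, negatives retained. Estimates are
not clamped. **Duncan's multiple range test** compares sorted group means
against critical ranges from the studentized range at protection level
1−(1−α)^(p−1), harmonic-mean group size, emitting a compact letter display.

## Selection scans

EHH at flanking site j is the probability that two haplotypes drawn from
the set are identical over the stretch from the core to j
(Σ C(n_h,2)/C(n,2)). The curve extends outward from the core *excluding*
the core allele itself, so EHH at the core is 1 in every mode by
definition; for the cross-population statistic this is a documented
convention choice (including the core allele would make the core value the
site's homozygosity). Truncation: EHH < 0.05 or an inter-site gap > 200 kb;
cores whose curve reaches a chromosome edge first are skipped. iHS is
ln(iHH_derived/iHH_ancestral) with trapezoidal integration over genetic
distance (constant map; any linear map cancels in the ratio), standardized
within derived-allele-frequency bins — 50 bins by default, fewer on small
simulated scans so each bin holds enough sites for a stable mean and sd.
XP-EHH integrates both populations to a common stopping point defined on
the pooled sample and standardizes genome-wide.

Bin summaries per 50-kb window record the % of |iHS| > 2, min/max XP-EHH
and SNP counts; a bin is called under positive selection when its minimum
XP-EHH exceeds 2 AND its iHS summary is in the genome-wide top 1% (ties
included; fewer than 100 bins is an error). The cross-breed enrichment test
is a chi-squared homogeneity test on the 2×k overlap/non-overlap table
(df = k−1), reporting overlap percentages at one decimal.

## Mixed-model association

The GRM is VanRaden method-1 on ancestry-block dosages (centered by 2p,
scaled by 2Σp(1−p); monomorphic markers dropped). REML profiles the
restricted likelihood over the variance ratio via the eigendecomposition of
G (grid plus Brent refinement). The scan reuses the null variance
components per candidate (EMMAX approximation), whitening by V^(−1/2) and
testing each candidate by GLS/Wald; candidates collinear with covariates
are flagged missing. FDR is Benjamini–Hochberg by default; an
empirical-null local-fdr mode (central-matching null plus KDE marginal) is
exposed for fidelity with tail-area-vs-local ambiguity in the original
tooling. QTL intervals are maximal runs of significant blocks.

Two structural findings from the simulations are worth recording. First,
variance-component precision is governed by the number of independent
ancestry tracts, not the marker count: on a short chromosome the ±0.1
recovery band for h² = 0.5 is unattainable at n = 500, while a 150 Mb
chromosome at 60 generations gives sd(ĥ²) ≈ 0.04. Second, with
tract-structured dosages an EMMAX scan whose GRM contains the scanned
blocks suffers strong proximal contamination (the candidate's tract
direction is absorbed by the polygenic term; z shrinks from ≈4.5 to ≈2.7 at
2% explained variance). Power experiments therefore build the GRM from a
background chromosome — the leave-one-chromosome-out practice of standard
GWAS tools — and then reach essentially full power at n = 1000.

GBLUP computes ĝ = σ̂g² G V⁻¹(y − Xb̂) in the eigenbasis; the top/bottom-k
GEBV split sorts by (gebv, sample id) so ties are deterministic and the two
sets are disjoint. GEBV bins (default 325 individuals, remainder bin kept
and flagged) report the target-haplotype frequency per bin with the
least-squares trend.

## eGWAS and colocalization

The cis window is TSS ± 2 Mb. The default association/permutation mode is
plain linear regression on covariate-adjusted residuals — matching the
permutation tool the analysis emulates — with an LMM mode exposed. The
gene-level adjusted p uses adaptive permutations (batches of 250, stop
after 100 exceedances once 1000 permutations are reached, cap 10,000) and a
Beta(a, b) MLE fit to the permutation minima; the tissue-level threshold is
α/n_genes. TSS distances are signed, strand-flipped for minus-strand genes.

Colocalization uses Wakefield log-ABFs, `½ln(1−r) + z²r/2` with
r = W/(V+W), prior effect sd 0.15, priors p1 = p2 = 1e-4, p12 = 1e-5, and
log-space sums over configurations for PP.H0..PP.H4. The LD-iterated merge
partitions markers into the lead's high-LD set H (r² > 0.9, lead included)
and the rest R, runs coloc on R and on R ∪ {h} for each h ∈ H, and keeps
each marker's maximum run-level PP.H4 — order-free by construction. SMR is
T = z_g²z_e²/(z_g²+z_e²) against χ²₁; no heterogeneity test is performed.

## Regulatory integration

Peaks with inter-peak gaps ≤ 12.5 kb are stitched (signal summed; the
operation is idempotent). Stitched regions are ranked by signal, both axes
rescaled to [0,1], the curve lightly smoothed (window 3), and the cutoff
placed where the tangent slope first exceeds 1; super-enhancers are the
regions whose scaled signal exceeds the curve's value at the cutoff point
(a signal threshold, not a rank threshold — with a rank rule the smoothing
window would drag in neighbors of a jump). Fewer than three stitched
regions degenerates the rule: all regions are reported, none called. TAD
co-membership asks whether one non-overlapping domain contains both
interval midpoints.

## Numerical choices and degenerate inputs

Hardy–Weinberg filtering uses a mid-p exact test on diploid genotype counts
(no installed library exposes one). Monomorphic sites/windows are NaN, not
dropped; zero-variance vectors make Pearson r and LD r² NaN; a D-statistic
with no informative sites, an SMR test with both z = 0, and a gene with no
cis marker are all flagged missing rather than zeroed. All simulations are
reproducible from (config, seed); test and acceptance problem sizes
(replicate counts, chromosome lengths, site counts) are fixed in the code
as the package's chosen desk-scale study conditions.

## Known limitations

The painter is a window classifier, not a CRF: it has no explicit switch
model and its posterior is a renormalized score, not a calibrated
probability. The D-statistic normal reference needs enough jackknife
blocks. EHH statistics on the stylized sweep generator demonstrate
detection, not selection-coefficient calibration. The empirical-null fdr
mode is a simple central-matching implementation, adequate for mode
comparison, not a full local-fdr machinery. Real-data concerns — reference
panel misspecification, phasing errors, relatedness beyond the GRM — are
out of scope of the synthetic validation.
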