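# hapintro

Ancestry-aware introgression analysis for admixed genomes, built as a
library with worked example scripts. The motivating setting is historical
gene flow from Chinese domestic pigs into European commercial breeds:
centuries-old admixture left donor haplotypes segregating in modern
cohorts, some of them under positive selection and some associated with
production traits and gene expression. `hapintro` provides the full chain
of analyses for that question — and validates every stage on synthetic
admixed cohorts with known ground truth.

**Who it is for.** Population/quantitative geneticists who want a
transparent, tested reference implementation of this analysis chain on
phased diploid genotypes, and a generator of realistic admixed fixtures to
benchmark such pipelines.

## What it computes

- **Gene flow**: the four-taxon ABBA–BABA statistic
  `D = (n_ABBA − n_BABA)/(n_ABBA + n_BABA)` with frequency-weighted counts,
  outgroup polarization, and block-jackknife Z-scores.
- **Local ancestry**: recoding of phased haplotypes into non-overlapping
  5-SNP blocks labeled {recipient, donor1, donor2} by a reference-panel
  window classifier; donor-haplotype frequency tracks; introgressed regions
  as runs of blocks with donor frequency > 0.5; Pearson/KLD profile
  comparisons.
- **Differentiation**: per-site and windowed Weir–Cockerham F_ST,
  locus-specific branch lengths `LSBL = (d_hl + d_hc − d_lc)/2`, Duncan's
  multiple range test.
- **Selection**: EHH, iHS (frequency-bin standardized) and XP-EHH
  (genome-wide standardized), 50-kb bin summaries, positive-selection calls
  (min XP-EHH > 2 and top-1% iHS), chi-squared enrichment across breeds.
- **Association**: VanRaden GRM on ancestry dosages, eigendecomposition
  REML, EMMAX-style mixed-model block scans with BH FDR, GBLUP breeding
  values, extreme-GEBV group selection, GEBV-bin haplotype-frequency trends,
  10-SNP top-LSBL haplotypes and minimum spanning networks.
- **Expression**: cis eGWAS with adaptive permutations and Beta-fit
  adjusted p-values, per-gene Bonferroni thresholds, TSS-distance profiles,
  Wakefield-ABF colocalization (PP.H0..PP.H4) with an LD-iterated
  max-PP.H4 merge, and the SMR test `T = z_g²z_e²/(z_g²+z_e²) ~ χ²₁`.
- **Regulatory context**: ROSE-style super-enhancer stitching (12.5 kb gap,
  hockey-stick slope rule) and TAD co-membership.
- **Synthetic data**: Balding–Nichols source panels at configurable F_ST,
  tract-mosaic admixed cohorts with truth labels, phenotypes with
  block-level ancestry effects plus polygenic background, cis-driven
  expression, and a hard-sweep haplotype generator for the EHH statistics.

See `docs/methods.md` for models, defaults, and limitations.

## Worked example

`examples/introgression_scan.py` simulates a recipient and two donor panels
at F_ST 0.3, admixes 20% donor ancestry into 100 individuals, then runs the
D-statistic and the local-ancestry painter:

```
D = 0.0282, Z = 5.56, p = 2.76e-08
block-level painting accuracy vs truth: 0.995
genome-mean donor haplotype frequency: 0.211 (simulated admixture fraction 0.2)
```

A positive D with Z > 2 is the classic signature of gene flow between the
cohort and the donor panel; the painter then localizes it, recovering both
the per-block labels (99.5% accuracy) and the genome-wide donor fraction
(0.211 vs the simulated 0.2). The other scripts in `examples/` cover the
selection scans, the haplotype-block GWAS/GBLUP, the eGWAS/colocalization
chain, and the super-enhancer/TAD module, each printing the quantities it
computes with a closing note on how to read them.

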