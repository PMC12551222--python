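"""Haplotype-block mixed-model GWAS and GBLUP on a simulated cohort.

One ancestry block explains 2% of a trait with h2 = 0.5; the scan uses a
GRM built from a background chromosome (leave-scan-chromosome-out) to avoid
proximal contamination, then computes breeding values and relates
introgressed-haplotype frequency to GEBV bins.
"""

import numpy as np
import pandas as pd

import hapintro as hi
from hapintro.simulate import SimulationConfig, TraitSpec


def admixed_blocks(seed, chrom, m_snps, length):
    cfg = SimulationConfig(seed=seed, m_snps=m_snps, n_per_panel=30,
                           admix_fraction=0.2, chrom_length_bp=length,
                           generations=60, chrom=chrom)
    panels = hi.simulate_panels(cfg)
    _, truth = hi.simulate_admixed_cohort(
        cfg, panels["EUR"], {"DONOR1": panels["DONOR1"], "DONOR2": panels["DONOR2"]},
        n_samples=800)
    return hi.truth_block_labels(truth)


tb_scan = admixed_blocks(11, "1", 2500, 40_000_000)
tb_bg = admixed_blocks(12, "2", 5000, 80_000_000)
tb = np.concatenate([tb_scan, tb_bg], axis=1)
n1 = tb_scan.shape[1]

cfg = SimulationConfig(seed=11, trait_specs=[TraitSpec(250, 0.02, 0.5)])
pheno, info = hi.simulate_traits(cfg, tb, [f"s{i:04d}" for i in range(800)])
carrier = tb > 0
D = carrier.reshape(800, 2, tb.shape[1]).sum(1).astype(float)

cov = pheno[["year", "parity", "weight_start", "weight_end"]].astype(
    {"year": "category", "parity": "category"})
grm = hi.build_grm(D[:, n1:])
reml = hi.reml_fit(pheno["trait"].to_numpy(), cov, grm)
print(f"REML heritability estimate: {reml.h2:.3f} "
      f"(background-genome GRM captures its share of the simulated 0.5)")

assoc = hi.block_scan(D[:, :n1], pheno["trait"].to_numpy(), cov, grm, reml)
print(f"causal block q-value: {assoc.loc[250, 'q']:.3g} "
      f"(best block: {int(assoc['q'].idxmin())})")

gebv = hi.gblup(pheno["trait"].to_numpy(), cov, grm, reml,
                pheno["sample_id"].tolist())
r = np.corrcoef(gebv["gebv"], info["genetic_values"])[0, 1]
print(f"GEBV vs true genetic value correlation: {r:.3f}")

high, low = hi.select_extreme_gebv(gebv, k=100)
print(f"top/bottom-100 GEBV gap: "
      f"{gebv.set_index('sample_id').loc[high, 'gebv'].mean() - gebv.set_index('sample_id').loc[low, 'gebv'].mean():.3f}")

# carriers of the causal donor block, binned by GEBV rank
counts = dict(zip(pheno["sample_id"], D[:, 250].astype(int)))
bins = hi.gebv_frequency_bins(gebv, counts, bin_size=200)
print(f"haplotype-frequency trend across GEBV bins: slope = "
      f"{bins.attrs['slope']:.4f}, r = {bins.attrs['pearson_r']:.3f}")

# q < 0.05 at the planted block recovers the QTL; a positive trend slope
# means the donor haplotype is enriched among high-breeding-value animals.
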