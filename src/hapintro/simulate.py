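"""Synthetic-data generator with known ground truth.

The generator emulates the study design every downstream stage assumes:

* three differentiated source panels — a European-wild-boar-like recipient
  and two Chinese-donor-like panels — drawn from a Balding–Nichols model at
  a configurable F_ST (the Beta parameter; realized two-population
  Weir–Cockerham F_ST matches it closely);
* admixed cohorts whose haplotypes are tract mosaics of the panels, with
  exponential tract lengths at rate ``generations x recomb_rate`` per bp and
  a configurable total donor fraction, returning the true per-site and
  per-block ancestry labels;
* phenotypes with block-level ancestry effects plus a polygenic background
  and recorded covariate coefficients, and expression with one cis causal
  block per gene near its TSS;
* a dedicated hard-sweep-like haplotype generator (a core haplotype copied
  with geometric decay) for the EHH statistics, because site-independent
  panels carry no LD.

Everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .vcfio import HaplotypeMatrix, VariantTable

EUR, DONOR1, DONOR2 = 0, 1, 2
ANCESTRY_NAMES = ("EUR", "DONOR1", "DONOR2")


@dataclass
class TraitSpec:
    """One causal ancestry block: index, variance fraction, and the trait h2."""

    causal_block: int
    variance_fraction: float
    h2: float = 0.5


@dataclass
class ExpressionSpec:
    """One gene: TSS position, cis causal block index, variance fraction."""

    gene_id: str
    tss: int
    cis_block: int
    variance_fraction: float
    strand: str = "+"


@dataclass
class SimulationConfig:
    n_per_panel: int = 50
    m_snps: int = 5000
    chrom_length_bp: int = 10_000_000
    chrom: str = "1"
    panel_fst: float = 0.3
    admix_fraction: float = 0.2
    donor_weights: tuple[float, float] = (0.5, 0.5)
    generations: int = 30
    recomb_rate: float = 1e-8  # Morgans per bp (1 cM/Mb)
    seed: int = 0
    block_size_snps: int = 5
    trait_specs: list[TraitSpec] = field(default_factory=list)
    expression_specs: list[ExpressionSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.panel_fst < 1.0):
            raise ValueError("panel_fst must be in (0, 1)")
        if not (0.0 <= self.admix_fraction < 1.0):
            raise ValueError("admix_fraction must be in [0, 1)")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        traits = [TraitSpec(**t) for t in raw.pop("trait_specs", [])]
        exprs = [ExpressionSpec(**e) for e in raw.pop("expression_specs", [])]
        return cls(trait_specs=traits, expression_specs=exprs, **raw)


def _variant_table(cfg: SimulationConfig, rng: np.random.Generator) -> VariantTable:
    pos = np.sort(rng.choice(cfg.chrom_length_bp - 1, cfg.m_snps, replace=False)) + 1
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, cfg.m_snps)
    alt_i = (ref_i + rng.integers(1, 4, cfg.m_snps)) % 4
    frame = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": pos,
            "id": [f"{cfg.chrom}:{p}" for p in pos],
            "ref": bases[ref_i],
            "alt": bases[alt_i],
        }
    )
    return VariantTable(frame)


def simulate_panels(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, HaplotypeMatrix]:
    """Draw the three source panels under a Balding–Nichols model.

    Ancestral frequencies are Uniform(0.05, 0.95); each panel's per-site
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F); haplotypes are sampled
    site-independently given the panel frequency.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    vt = _variant_table(cfg, rng)
    p = rng.uniform(0.05, 0.95, cfg.m_snps)
    F = cfg.panel_fst
    out = {}
    for name in ANCESTRY_NAMES:
        q = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        alleles = (rng.random((2 * cfg.n_per_panel, cfg.m_snps)) < q).astype(np.int8)
        out[name] = HaplotypeMatrix(
            vt, alleles, [f"{name}_{i}" for i in range(cfg.n_per_panel)]
        )
    return out


def simulate_outgroup(
    cfg: SimulationConfig,
    panels: dict[str, HaplotypeMatrix],
    n: int = 10,
    drift: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> HaplotypeMatrix:
    """An outgroup panel close to the ancestral frequencies (for polarization)."""
    rng = np.random.default_rng(cfg.seed + 97) if rng is None else rng
    vt = next(iter(panels.values())).variants
    # mildly drifted from a low-frequency ancestral state so the major allele
    # usually marks the ancestral allele
    p = np.clip(rng.beta(1, 9, cfg.m_snps), 0.01, 0.4)
    q = rng.beta(p * (1 - drift) / drift, (1 - p) * (1 - drift) / drift)
    alleles = (rng.random((2 * n, cfg.m_snps)) < q).astype(np.int8)
    return HaplotypeMatrix(vt, alleles, [f"OUT_{i}" for i in range(n)])


def simulate_admixed_cohort(
    cfg: SimulationConfig,
    recipient: HaplotypeMatrix,
    donors: dict[str, HaplotypeMatrix],
    n_samples: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Build admixed haplotypes as tract mosaics with known ancestry truth.

    Tract breakpoints follow a Poisson process at rate
    ``generations x recomb_rate`` per bp; each tract copies a uniformly
    chosen haplotype from the recipient panel (probability ``1 - alpha``) or
    from a donor panel (total probability ``alpha``, split by
    ``donor_weights``).

    Returns the cohort and the per-site truth labels (0 = recipient,
    1/2 = donors), one row per haplotype.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    vt = recipient.variants
    pos = vt.pos
    m = len(vt)
    donor_names = list(donors)
    src = [recipient] + [donors[d] for d in donor_names]
    w = np.array(cfg.donor_weights, dtype=float)[: len(donor_names)]
    w = w / w.sum() if w.sum() > 0 else np.full(len(donor_names), 1 / len(donor_names))
    probs = np.concatenate([[1 - cfg.admix_fraction], cfg.admix_fraction * w])
    rate = cfg.generations * cfg.recomb_rate
    n_hap = 2 * n_samples
    alleles = np.zeros((n_hap, m), dtype=np.int8)
    truth = np.zeros((n_hap, m), dtype=np.int8)
    L = cfg.chrom_length_bp
    pos0 = pos - 1  # sorted 0-based positions
    for h in range(n_hap):
        x = 0.0
        while x < L:
            seg = rng.exponential(1.0 / rate) if rate > 0 else L
            anc = rng.choice(len(probs), p=probs)
            hap = src[anc].alleles[rng.integers(src[anc].n_haplotypes)]
            i0 = np.searchsorted(pos0, x, side="left")
            i1 = np.searchsorted(pos0, x + seg, side="left")
            alleles[h, i0:i1] = hap[i0:i1]
            truth[h, i0:i1] = anc
            x += seg
    hm = HaplotypeMatrix(vt, alleles, [f"ADM_{i}" for i in range(n_samples)])
    return hm, truth


def truth_block_labels(truth_sites: np.ndarray, block_size: int = 5) -> np.ndarray:
    """Majority per-block ancestry label from per-site truth labels."""
    n_hap, m = truth_sites.shape
    n_blocks = (m + block_size - 1) // block_size
    out = np.zeros((n_hap, n_blocks), dtype=np.int8)
    for b in range(n_blocks):
        chunk = truth_sites[:, b * block_size : (b + 1) * block_size]
        counts = np.stack([(chunk == k).sum(1) for k in range(3)])
        out[:, b] = counts.argmax(0)
    return out


def ancestry_dosage(
    truth_blocks: np.ndarray, block: int, combined: bool = True
) -> np.ndarray:
    """Per-sample donor-ancestry dosage (0/1/2) at one block."""
    lab = truth_blocks[:, block]
    carrier = (lab > 0) if combined else (lab == DONOR1)
    return carrier.reshape(-1, 2).sum(1).astype(float)


def simulate_traits(
    cfg: SimulationConfig,
    truth_blocks: np.ndarray,
    sample_ids: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict]:
    """Phenotypes: causal-block ancestry effects + polygenic term + noise.

    ``y = sum_k dosage_k * beta_k + u + covariate effects + e`` where the
    polygenic term ``u`` is built from all block dosages with i.i.d. weights
    (a GRM-covariant Gaussian), and the noise variance is scaled so the
    genetic fraction of variance matches the trait h2.  Two discrete and two
    quantitative covariates are generated; their true coefficients are
    returned in the truth dict.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    n = len(sample_ids)
    n_blocks = truth_blocks.shape[1]
    D = np.stack(
        [ancestry_dosage(truth_blocks, b) for b in range(n_blocks)], axis=1
    )  # n x B
    h2 = cfg.trait_specs[0].h2 if cfg.trait_specs else 0.5
    causal = np.zeros(n)
    betas = {}
    frac_causal = 0.0
    for spec in cfg.trait_specs:
        d = D[:, spec.causal_block]
        v = d.var()
        beta = np.sqrt(spec.variance_fraction / v) if v > 0 else 0.0
        causal += d * beta
        betas[spec.causal_block] = beta
        frac_causal += spec.variance_fraction
    # polygenic background fills the remaining genetic variance; weights act
    # on centered (not standardized) dosages so the implied covariance is
    # proportional to the VanRaden method-1 relationship matrix
    Dc = D - D.mean(0)
    ok = Dc.std(0) > 0
    u = Dc[:, ok] @ rng.normal(0, 1, ok.sum()) / np.sqrt(ok.sum())
    # orthogonalize against the causal dosages (tract structure correlates
    # neighbouring blocks) so each causal variance fraction stays marginal
    if betas:
        C = np.column_stack([np.ones(n)] + [D[:, b] for b in betas])
        coef, *_ = np.linalg.lstsq(C, u, rcond=None)
        u = u - C @ coef
    h2_poly = max(h2 - frac_causal, 0.0)
    if u.std() > 0:
        u = u / u.std() * np.sqrt(h2_poly)
    e = rng.normal(0, np.sqrt(max(1.0 - h2, 1e-12)), n)
    # covariates: two discrete, two quantitative, with recorded coefficients
    year = rng.integers(0, 3, n)
    parity = rng.integers(0, 3, n)
    w_start = rng.normal(30, 3, n)
    w_end = rng.normal(100, 6, n)
    cov_coef = {"year": [0.0, 0.3, -0.2], "parity": [0.0, 0.15, 0.35],
                "weight_start": 0.02, "weight_end": 0.01}
    cov_part = (
        np.array(cov_coef["year"])[year]
        + np.array(cov_coef["parity"])[parity]
        + cov_coef["weight_start"] * (w_start - 30)
        + cov_coef["weight_end"] * (w_end - 100)
    )
    y = causal + u + e + cov_part
    pheno = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "trait": y,
            "year": year,
            "parity": parity,
            "weight_start": w_start,
            "weight_end": w_end,
        }
    )
    truth = {
        "block_effects": betas,
        "covariate_coefficients": cov_coef,
        "h2": h2,
        "genetic_values": causal + u,
    }
    return pheno, truth


def simulate_expression(
    cfg: SimulationConfig,
    truth_blocks: np.ndarray,
    sample_ids: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """TPM-like expression with one cis causal ancestry block per gene.

    Returns (expression genes x samples, TSS table, truth dict).  Values are
    exp-Gaussian so they behave like TPMs (positive, right-skewed); the cis
    effect acts on the log scale.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    n = len(sample_ids)
    rows, tss_rows, effects = [], [], {}
    for spec in cfg.expression_specs:
        d = ancestry_dosage(truth_blocks, spec.cis_block)
        v = d.var()
        beta = np.sqrt(spec.variance_fraction / v) if v > 0 else 0.0
        log_expr = 1.0 + d * beta + rng.normal(
            0, np.sqrt(max(1 - spec.variance_fraction, 1e-12)), n
        )
        rows.append(pd.Series(np.exp(log_expr), name=spec.gene_id))
        tss_rows.append((spec.gene_id, cfg.chrom, spec.tss, spec.strand))
        effects[spec.gene_id] = {"cis_block": spec.cis_block, "beta": beta}
    expr = pd.DataFrame(rows)
    expr.columns = list(sample_ids)
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "tss", "strand"])
    return expr, tss, {"cis_effects": effects}


def simulate_sweep_panel(
    m_snps: int = 2000,
    n_hap: int = 100,
    core_index: Optional[int] = None,
    carrier_fraction: float = 0.4,
    break_prob: float = 0.02,
    chrom_length_bp: int = 2_000_000,
    seed: int = 0,
) -> tuple[HaplotypeMatrix, int]:
    """Hard-sweep-like haplotypes: carriers copy a core haplotype outward.

    Each carrier shares the core haplotype contiguously around the core site
    until a geometric break (probability ``break_prob`` per site per side),
    after which it reverts to its own background.  This creates the extended
    haplotype homozygosity that iHS/XP-EHH detect; site-independent panels
    have none.  The derived allele at the core marks the carriers.
    """
    rng = np.random.default_rng(seed)
    core = m_snps // 2 if core_index is None else core_index
    pos = np.sort(rng.choice(chrom_length_bp - 1, m_snps, replace=False)) + 1
    freqs = rng.uniform(0.05, 0.95, m_snps)
    alleles = (rng.random((n_hap, m_snps)) < freqs).astype(np.int8)
    core_hap = (rng.random(m_snps) < freqs).astype(np.int8)
    n_car = int(round(carrier_fraction * n_hap))
    carriers = rng.choice(n_hap, n_car, replace=False)
    alleles[:, core] = 0
    for h in carriers:
        left = rng.geometric(break_prob)
        right = rng.geometric(break_prob)
        lo, hi = max(0, core - left), min(m_snps, core + right + 1)
        alleles[h, lo:hi] = core_hap[lo:hi]
        alleles[h, core] = 1
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, m_snps)
    vt = VariantTable(
        pd.DataFrame(
            {
                "chrom": "1",
                "pos": pos,
                "id": [f"1:{p}" for p in pos],
                "ref": bases[ref_i],
                "alt": bases[(ref_i + 1) % 4],
            }
        )
    )
    hm = HaplotypeMatrix(vt, alleles, [f"S_{i}" for i in range(n_hap // 2)])
    return hm, core


def neutral_panel(
    m_snps: int = 1000,
    n_hap: int = 100,
    chrom_length_bp: int = 1_000_000,
    seed: int = 0,
) -> HaplotypeMatrix:
    """Site-independent neutral haplotypes (no LD, no sweep)."""
    hm, _ = simulate_sweep_panel(
        m_snps, n_hap, carrier_fraction=0.0, chrom_length_bp=chrom_length_bp, seed=seed
    )
    return hm
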