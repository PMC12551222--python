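"""Four-taxon D-statistics, Weir–Cockerham F_ST, LSBL, and Duncan's test.

The D-statistic follows the frequency-weighted (population-level)
ABBA/BABA formulation: with derived-allele frequencies p1..p3 in the three
in-group populations and p4 in the outgroup,

    n_ABBA += (1-p1) p2 p3 (1-p4),   n_BABA += p1 (1-p2) p3 (1-p4)

summed over biallelic sites, D = (n_ABBA - n_BABA) / (n_ABBA + n_BABA).
Significance comes from a delete-one block jackknife over contiguous
equal-SNP blocks, Z = D / SE, two-sided normal p.  Sites are polarized by
the outgroup major allele (ties drop the site).  A pure pattern-count mode
is provided for the single-genome worked example.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, WindowStatTrack, assign_sites_to_windows
from .vcfio import HaplotypeMatrix


@dataclass
class DStatResult:
    n_abba: float
    n_baba: float
    D: float
    jackknife_se: float
    Z: float
    p_value: float
    block_count: int
    n_sites: int


def _polarize(outgroup: HaplotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(keep mask, derived-is-alt flags) from the outgroup major allele."""
    f = outgroup.allele_freq()
    keep = f != 0.5  # outgroup tie: drop the site
    derived_is_alt = f < 0.5  # ancestral = outgroup major allele
    return keep, derived_is_alt


def d_statistic(
    p1: HaplotypeMatrix,
    p2: HaplotypeMatrix,
    p3: HaplotypeMatrix,
    outgroup: HaplotypeMatrix,
    n_jackknife_blocks: int = 20,
) -> DStatResult:
    """Frequency-weighted ABBA/BABA D with block-jackknife significance."""
    m = p1.n_variants
    if not (p2.n_variants == p3.n_variants == outgroup.n_variants == m):
        raise ValueError("populations do not share a variant set")
    keep, derived_is_alt = _polarize(outgroup)
    freqs = []
    for pop in (p1, p2, p3, outgroup):
        f = pop.allele_freq()
        freqs.append(np.where(derived_is_alt, f, 1.0 - f))
    q1, q2, q3, q4 = (f[keep] for f in freqs)
    abba = (1 - q1) * q2 * q3 * (1 - q4)
    baba = q1 * (1 - q2) * q3 * (1 - q4)
    tot_a, tot_b = abba.sum(), baba.sum()
    denom = tot_a + tot_b
    if denom == 0:
        return DStatResult(0.0, 0.0, np.nan, np.nan, np.nan, np.nan, 0, int(keep.sum()))
    D = (tot_a - tot_b) / denom
    # delete-one jackknife over contiguous equal-SNP blocks
    n = len(abba)
    B = min(n_jackknife_blocks, n)
    edges = np.linspace(0, n, B + 1).astype(int)
    d_del = np.empty(B)
    for j in range(B):
        sl = slice(edges[j], edges[j + 1])
        a_j = tot_a - abba[sl].sum()
        b_j = tot_b - baba[sl].sum()
        d_del[j] = (a_j - b_j) / (a_j + b_j) if (a_j + b_j) > 0 else D
    se = float(np.sqrt((B - 1) / B * np.sum((d_del - d_del.mean()) ** 2)))
    z = D / se if se > 0 else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return DStatResult(float(tot_a), float(tot_b), float(D), se, float(z), p, B, n)


def d_statistic_counts(
    h1: np.ndarray, h2: np.ndarray, h3: np.ndarray, hout: np.ndarray
) -> DStatResult:
    """Pattern-count D for four single (haploid) genomes of 0/1 alleles.

    A site is ABBA when h1 matches the outgroup and h2 matches h3 (and the
    shared allele differs from the outgroup's); BABA swaps h1 and h2.
    """
    h1, h2, h3, hout = (np.asarray(x) for x in (h1, h2, h3, hout))
    der1, der2, der3 = (x != hout for x in (h1, h2, h3))
    abba = int((~der1 & der2 & der3).sum())
    baba = int((der1 & ~der2 & der3).sum())
    denom = abba + baba
    D = (abba - baba) / denom if denom else np.nan
    return DStatResult(abba, baba, D, np.nan, np.nan, np.nan, 0, len(h1))


def wc_fst_components(
    popA: HaplotypeMatrix, popB: HaplotypeMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components a, b, c.

    Two-population, diploid form: `a` is the among-population component,
    `b` among individuals within populations, `c` within individuals
    (heterozygosity).  The per-site estimator is a/(a+b+c); the windowed
    weighted estimator is sum(a)/sum(a+b+c).
    """
    if popA.n_samples < 2 or popB.n_samples < 2:
        raise ValueError("need >= 2 diploid samples per population")
    gA, gB = popA.dosages(), popB.dosages()
    n1, n2 = popA.n_samples, popB.n_samples
    r = 2
    p1, p2 = gA.mean(0) / 2, gB.mean(0) / 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * (gA == 1).mean(0) + n2 * (gB == 1).mean(0)) / (r * nbar)
    a = (
        nbar
        / nc
        * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    )
    b = (
        nbar
        / (nbar - 1)
        * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    )
    c = hbar / 2
    return a, b, c


def wc_fst(
    popA: HaplotypeMatrix,
    popB: HaplotypeMatrix,
    windows: list[GenomicInterval] | None = None,
) -> tuple[np.ndarray, WindowStatTrack | None]:
    """Per-site W&C F_ST ratios and, optionally, windowed weighted values.

    Monomorphic sites (zero denominator) are NaN; a window with no
    polymorphic sites is flagged missing (NaN), not dropped.  Values are not
    clamped: slightly negative estimates are informative.
    """
    a, b, c = wc_fst_components(popA, popB)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(denom != 0, a / denom, np.nan)
    track = None
    if windows is not None:
        vt = popA.variants
        idxs = assign_sites_to_windows(windows, vt.chrom, vt.pos)
        vals = np.full(len(windows), np.nan)
        for i, idx in enumerate(idxs):
            if len(idx) == 0:
                continue
            d = denom[idx].sum()
            if d != 0:
                vals[i] = a[idx].sum() / d
        track = WindowStatTrack(windows)
        track.add("fst", vals)
    return per_site, track


def lsbl(
    fst_high_low: np.ndarray, fst_high_cdp: np.ndarray, fst_low_cdp: np.ndarray
) -> np.ndarray:
    """Locus-specific branch length of the 'high' group per site.

    LSBL = (d(high,low) + d(high,CDP) - d(low,CDP)) / 2.  Negative values
    are retained.  The three tracks must be site-aligned.
    """
    arrs = [np.asarray(x, dtype=float) for x in (fst_high_low, fst_high_cdp, fst_low_cdp)]
    if not (len(arrs[0]) == len(arrs[1]) == len(arrs[2])):
        raise ValueError("site-set mismatch between pairwise F_ST tracks")
    return (arrs[0] + arrs[1] - arrs[2]) / 2.0


def duncan_mrt(groups: dict[str, np.ndarray], alpha: float = 0.05) -> "pd.DataFrame":
    """Duncan's multiple range test with a compact letter display.

    One-way ANOVA supplies the error mean square; means are compared
    against critical ranges built from the studentized range at protection
    level ``1 - (1 - alpha)^(p-1)`` for a span of p means.  Group sizes may
    differ; the harmonic mean of the sizes is used in the standard error.
    Returns a frame with group, n, mean, and letters (groups sharing a
    letter do not differ significantly).
    """
    import pandas as pd

    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = list(groups)
    vals = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(v) < 2 for v in vals):
        raise ValueError("need >= 2 values per group")
    ns = np.array([len(v) for v in vals])
    means = np.array([v.mean() for v in vals])
    df_err = int(ns.sum() - len(labels))
    sse = sum(((v - v.mean()) ** 2).sum() for v in vals)
    mse = sse / df_err
    if mse == 0:
        raise ValueError("zero within-group variance across all groups")
    n_h = len(ns) / np.sum(1.0 / ns)
    se = np.sqrt(mse / n_h)
    order = np.argsort(-means)  # descending
    k = len(labels)
    crit = {
        p: stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df_err) * se
        for p in range(2, k + 1)
    }

    def differ(i: int, j: int) -> bool:
        """Significance of the comparison between sorted ranks i < j."""
        span = j - i + 1
        return means[order[i]] - means[order[j]] > crit[span]

    # compact letter display: maximal non-significant stretches of sorted means
    segments = []
    for i in range(k):
        j = i
        while j + 1 < k and not differ(i, j + 1):
            j += 1
        segments.append((i, j))
    # keep only maximal segments
    maximal = [
        (a, b)
        for a, b in segments
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in segments)
    ]
    letters = {lab: "" for lab in labels}
    for si, (a, b) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + si)
        for r in range(a, b + 1):
            letters[labels[order[r]]] += ch
    return pd.DataFrame(
        {
            "group": labels,
            "n": ns,
            "mean": means,
            "letters": [letters[g] for g in labels],
        }
    )
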