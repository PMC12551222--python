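"""Extended-haplotype-homozygosity statistics and sweep-region calling.

EHH at a flanking site j, for a haplotype set of size n, is the probability
that two randomly drawn haplotypes are identical over the stretch from the
core to j:  sum_h C(n_h, 2) / C(n, 2) over distinct extended haplotypes h.
iHS is the log-ratio of the integrated EHH (iHH, trapezoidal over genetic
distance) of derived versus ancestral carriers at a core site, standardized
within derived-allele-frequency bins.  XP-EHH is the log-ratio of iHH
between two populations at the same core, integrated to a common stopping
point defined on the pooled sample, standardized genome-wide.

Curves are truncated where EHH drops below ``cutoff`` (default 0.05) or an
inter-site gap exceeds ``max_gap_bp`` (default 200 kb); cores whose curve
reaches a chromosome edge before the cutoff are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, assign_sites_to_windows
from .vcfio import HaplotypeMatrix

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP_BP = 200_000


@dataclass
class EhhCurve:
    """EHH values per flanking site, for one or more haplotype sets.

    ``index`` is the site indices ordered from the leftmost reached site to
    the rightmost (the core is included); ``ehh`` maps a set name to the
    matching EHH values.  EHH is 1 at the core and non-increasing outward.
    """

    core_index: int
    index: np.ndarray
    ehh: dict[str, np.ndarray]


def _side_ehh(
    alleles: np.ndarray,
    subsets: dict[str, np.ndarray],
    core: int,
    step: int,
    pos: np.ndarray,
    cutoff: float,
    max_gap_bp: int,
    stop_on: str,
) -> tuple[list[int], dict[str, list[float]], bool]:
    """EHH decay on one side of the core for several haplotype subsets.

    ``stop_on`` names the subset whose EHH controls truncation.  Returns
    (site indices outward, per-subset EHH lists, hit_edge) where hit_edge is
    True when the chromosome ended before the controlling EHH fell below
    the cutoff.
    """
    m = alleles.shape[1]
    n_tot = alleles.shape[0]
    labels = np.zeros(n_tot, dtype=np.int64)
    sizes = {k: len(v) for k, v in subsets.items()}
    idx = [core]
    curves: dict[str, list[float]] = {k: [1.0] for k in subsets}
    j = core
    while True:
        jn = j + step
        if jn < 0 or jn >= m:
            return idx, curves, True
        if abs(int(pos[jn]) - int(pos[j])) > max_gap_bp:
            return idx, curves, False
        comb = labels * 2 + alleles[:, jn]
        _, labels = np.unique(comb, return_inverse=True)
        vals = {}
        for k, rows in subsets.items():
            n = sizes[k]
            cnt = np.bincount(labels[rows])
            vals[k] = float((cnt * (cnt - 1)).sum() / (n * (n - 1)))
        idx.append(jn)
        for k in subsets:
            curves[k].append(vals[k])
        if vals[stop_on] < cutoff:
            return idx, curves, False
        j = jn


def ehh_curve(
    hm: HaplotypeMatrix,
    core_index: int,
    mode: str = "allele-split",
    cutoff: float = DEFAULT_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> EhhCurve:
    """EHH decay curve around a core site.

    ``mode='allele-split'`` computes separate curves for carriers of the
    derived (allele 1) and ancestral (allele 0) core alleles; the core must
    be polymorphic with >= 2 haplotypes per class.  ``mode='whole-pop'``
    computes a single curve over all haplotypes.
    """
    a = hm.alleles
    pos = hm.variants.pos
    if mode == "allele-split":
        der = np.flatnonzero(a[:, core_index] == 1)
        anc = np.flatnonzero(a[:, core_index] == 0)
        if len(der) < 2 or len(anc) < 2:
            raise ValueError("core site monomorphic (or singleton) in allele-split mode")
        subsets = {"derived": der, "ancestral": anc}
        stop_on = "derived"
    elif mode == "whole-pop":
        subsets = {"all": np.arange(a.shape[0])}
        stop_on = "all"
    else:
        raise ValueError("mode must be 'allele-split' or 'whole-pop'")
    # each subset truncates on its own decay: run per subset per side
    per_set: dict[str, dict[int, tuple[list[int], list[float]]]] = {}
    all_idx: set[int] = {core_index}
    for name, rows in subsets.items():
        per_set[name] = {}
        for step in (-1, 1):
            si, curves, _ = _side_ehh(
                a, {name: rows}, core_index, step, pos, cutoff, max_gap_bp, name
            )
            per_set[name][step] = (si, curves[name])
            all_idx.update(si)
    index = np.array(sorted(all_idx))
    ehh = {}
    for name in subsets:
        vals = np.full(len(index), np.nan)
        for step in (-1, 1):
            si, cv = per_set[name][step]
            vals[np.searchsorted(index, si)] = cv
        ehh[name] = vals
    return EhhCurve(core_index, index, ehh)


def _ihh_side(
    alleles: np.ndarray,
    rows: np.ndarray,
    core: int,
    step: int,
    gpos: np.ndarray,
    pos: np.ndarray,
    cutoff: float,
    max_gap_bp: int,
) -> tuple[float, bool]:
    """Integrated EHH on one side; (iHH, hit_edge)."""
    idx, curves, edge = _side_ehh(
        alleles, {"s": rows}, core, step, pos, cutoff, max_gap_bp, "s"
    )
    if edge:
        return np.nan, True
    x = gpos[idx]
    y = np.array(curves["s"])
    return float(abs(np.trapezoid(y, x))), False


def ihs_scan(
    hm: HaplotypeMatrix,
    maf_min: float = 0.05,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    recomb_rate: float = 1e-8,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Per-site iHS: ln(iHH_derived / iHH_ancestral), bin-standardized.

    Alleles must be polarized (1 = derived).  Genetic positions come from a
    constant map (``recomb_rate`` Morgans/bp); any linear map leaves the
    log-ratio unchanged.  Sites whose curves reach a chromosome edge, or
    with a zero iHH on either allele, are skipped (NaN).  Standardization is
    to mean 0, sd 1 within derived-allele-frequency bins.
    """
    a = hm.alleles
    pos = hm.variants.pos.astype(float)
    gpos = pos * recomb_rate * 100.0  # cM
    m = hm.n_variants
    freq = a.mean(0)
    unstd = np.full(m, np.nan)
    for j in range(m):
        f = freq[j]
        if min(f, 1 - f) < maf_min:
            continue
        der = np.flatnonzero(a[:, j] == 1)
        anc = np.flatnonzero(a[:, j] == 0)
        if len(der) < 2 or len(anc) < 2:
            continue
        vals = []
        skip = False
        for rows in (der, anc):
            ihh = 0.0
            for step in (-1, 1):
                v, edge = _ihh_side(a, rows, j, step, gpos, pos, cutoff, max_gap_bp)
                if edge:
                    skip = True
                    break
                ihh += v
            if skip or ihh == 0.0:
                skip = True
                break
            vals.append(ihh)
        if not skip:
            unstd[j] = np.log(vals[0] / vals[1])
    std = standardize_by_freq_bin(unstd, freq, n_bins)
    return pd.DataFrame(
        {
            "chrom": hm.variants.chrom,
            "pos": hm.variants.pos,
            "freq": freq,
            "ihs_unstd": unstd,
            "ihs_std": std,
        }
    )


def standardize_by_freq_bin(
    values: np.ndarray, freq: np.ndarray, n_bins: int = 50
) -> np.ndarray:
    """Zero-mean unit-sd within derived-allele-frequency bins."""
    out = np.full_like(values, np.nan, dtype=float)
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.digitize(freq, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = (which == b) & np.isfinite(values)
        if sel.sum() < 2:
            continue
        v = values[sel]
        s = v.std()
        if s > 0:
            out[sel] = (v - v.mean()) / s
    return out


def xpehh_scan(
    popA: HaplotypeMatrix,
    popB: HaplotypeMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    recomb_rate: float = 1e-8,
) -> pd.DataFrame:
    """Per-site XP-EHH: ln(iHH_A / iHH_B), standardized genome-wide.

    Both populations share the truncation point, defined by the EHH decay
    of the pooled haplotype sample (combined-EHH stopping).
    """
    if popA.n_variants != popB.n_variants:
        raise ValueError("populations do not share a variant set")
    stacked = np.vstack([popA.alleles, popB.alleles])
    nA = popA.n_haplotypes
    rowsA = np.arange(nA)
    rowsB = np.arange(nA, nA + popB.n_haplotypes)
    rows_all = np.arange(stacked.shape[0])
    pos = popA.variants.pos.astype(float)
    gpos = pos * recomb_rate * 100.0
    m = popA.n_variants
    unstd = np.full(m, np.nan)
    for j in range(m):
        ihhA = ihhB = 0.0
        skip = False
        for step in (-1, 1):
            idx, curves, edge = _side_ehh(
                stacked,
                {"A": rowsA, "B": rowsB, "all": rows_all},
                j,
                step,
                pos,
                cutoff,
                max_gap_bp,
                "all",
            )
            if edge:
                skip = True
                break
            x = gpos[idx]
            ihhA += abs(np.trapezoid(curves["A"], x))
            ihhB += abs(np.trapezoid(curves["B"], x))
        if skip or ihhA == 0.0 or ihhB == 0.0:
            continue
        unstd[j] = np.log(ihhA / ihhB)
    fin = np.isfinite(unstd)
    std = np.full(m, np.nan)
    if fin.sum() >= 2 and unstd[fin].std() > 0:
        std[fin] = (unstd[fin] - unstd[fin].mean()) / unstd[fin].std()
    return pd.DataFrame(
        {
            "chrom": popA.variants.chrom,
            "pos": popA.variants.pos,
            "xpehh_unstd": unstd,
            "xpehh_std": std,
        }
    )


def sweep_bin_summaries(
    ihs: pd.DataFrame,
    xpehh: pd.DataFrame,
    windows: list[GenomicInterval],
    top_fraction: float = 0.01,
    min_bins: int = 100,
) -> pd.DataFrame:
    """Per-bin sweep summaries and the positive-selection call.

    Per window: % of variants with |iHS| > 2, min and max XP-EHH, and a
    positive-selection flag set when the bin's minimum XP-EHH exceeds 2 AND
    its |iHS|>2 percentage is in the genome-wide top ``top_fraction`` (ties
    at the boundary all included).  Fewer than ``min_bins`` bins makes the
    top-1% rule degenerate and raises an error.
    """
    if len(windows) < min_bins:
        raise ValueError(f"need >= {min_bins} bins for the top-1% rule")
    idx_i = assign_sites_to_windows(windows, ihs["chrom"].to_numpy(), ihs["pos"].to_numpy())
    idx_x = assign_sites_to_windows(
        windows, xpehh["chrom"].to_numpy(), xpehh["pos"].to_numpy()
    )
    ihs_std = ihs["ihs_std"].to_numpy()
    xp_std = xpehh["xpehh_std"].to_numpy()
    rows = []
    for w, ii, xi in zip(windows, idx_i, idx_x):
        iv = ihs_std[ii]
        iv = iv[np.isfinite(iv)]
        xv = xp_std[xi]
        xv = xv[np.isfinite(xv)]
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "n_snps": len(ii),
                "pct_abs_ihs_gt2": 100.0 * (np.abs(iv) > 2).mean() if len(iv) else np.nan,
                "min_xpehh": xv.min() if len(xv) else np.nan,
                "max_xpehh": xv.max() if len(xv) else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    scored = df["pct_abs_ihs_gt2"].dropna()
    thr = np.quantile(scored, 1 - top_fraction) if len(scored) else np.inf
    df["ihs_top1pct"] = df["pct_abs_ihs_gt2"] >= thr
    df["is_positive_selection"] = (df["min_xpehh"] > 2) & df["ihs_top1pct"]
    return df


def positive_regions(summaries: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]), "positive")
        for _, r in summaries[summaries["is_positive_selection"]].iterrows()
    ]


def count_overlaps(
    regions: list[GenomicInterval], targets: list[GenomicInterval]
) -> int:
    """Number of regions overlapping at least one target interval."""
    n = 0
    for r in regions:
        for t in targets:
            if r.chrom == t.chrom and r.start < t.end and t.start < r.end:
                n += 1
                break
    return n


def enrichment_chisq(counts: dict[str, tuple[int, int]]) -> dict:
    """Chi-squared homogeneity test of overlap proportions across breeds.

    ``counts`` maps a breed label to (n_overlapping, n_total) positive-
    selection regions.  Builds the 2 x k overlap/non-overlap table, tests
    homogeneity with df = k - 1, and reports each breed's overlap
    percentage at one decimal.
    """
    labels = list(counts)
    table = np.array([[counts[b][0], counts[b][1] - counts[b][0]] for b in labels]).T
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    pct = {
        b: round(100.0 * counts[b][0] / counts[b][1], 1) if counts[b][1] else np.nan
        for b in labels
    }
    return {
        "chi2": float(chi2),
        "df": int(dof),
        "p_value": float(p),
        "overlap_pct": pct,
        "table": table,
    }


def chisq_upper_tail(statistic: float, df: int) -> float:
    """Upper-tail probability of a chi-squared statistic."""
    return float(stats.chi2.sf(statistic, df))
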