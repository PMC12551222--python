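"""Bayesian colocalization (Wakefield ABFs) and the SMR test.

For each variant, the Wakefield approximate Bayes factor against the null
is  log ABF = 0.5 * ln(1 - r) + 0.5 * z^2 * r  with r = W / (V + W), V the
squared standard error and W the prior effect variance (default sd 0.15 for
quantitative traits).  The five posterior hypothesis probabilities PP.H0 ..
PP.H4 (no signal / trait-only / expression-only / two distinct causal
variants / one shared causal variant) follow from summing ABFs over
configurations under per-variant priors p1, p2, p12.

The LD-iterated merge re-runs colocalization once per high-LD companion of
the lead marker, added one at a time to the non-redundant set, and keeps
each marker's maximum PP.H4 across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .egwas import ld_r2


@dataclass
class ColocResult:
    labf_trait: np.ndarray
    labf_expr: np.ndarray
    pp: dict[str, float]  # PP.H0 .. PP.H4
    priors: tuple[float, float, float]

    @property
    def pp_h4(self) -> float:
        return self.pp["PP.H4"]


def wakefield_labf(
    beta: np.ndarray | None = None,
    se: np.ndarray | None = None,
    z: np.ndarray | None = None,
    prior_sd: float = 0.15,
) -> np.ndarray:
    """Per-variant log approximate Bayes factor.

    Accepts either (beta, se) or z together with se; ``prior_sd`` is the
    prior standard deviation of the effect (W = prior_sd^2).
    """
    if se is None:
        raise ValueError("standard errors are required")
    se = np.asarray(se, dtype=float)
    if np.all(se == 0):
        raise ValueError("all standard errors are zero")
    if z is None:
        if beta is None:
            raise ValueError("provide beta or z")
        z = np.asarray(beta, dtype=float) / se
    else:
        z = np.asarray(z, dtype=float)
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    return 0.5 * np.log(1 - r) + 0.5 * z**2 * r


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    trait: dict[str, np.ndarray],
    expr: dict[str, np.ndarray],
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd_trait: float = 0.15,
    prior_sd_expr: float = 0.15,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    ``trait`` and ``expr`` each carry per-variant summary statistics over a
    shared variant list: keys 'beta' and 'se', or 'z' and 'se'.
    """
    l1 = wakefield_labf(
        trait.get("beta"), trait.get("se"), trait.get("z"), prior_sd_trait
    )
    l2 = wakefield_labf(expr.get("beta"), expr.get("se"), expr.get("z"), prior_sd_expr)
    if len(l1) != len(l2):
        raise ValueError("trait and expression must share the variant list")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lH0 = 0.0
    lH1 = np.log(p1) + s1
    lH2 = np.log(p2) + s2
    # sum_{i != j} ABF1_i ABF2_j = (sum ABF1)(sum ABF2) - sum ABF1_i ABF2_i
    lH3 = np.log(p1) + np.log(p2) + _log_diff_exp(s1 + s2, s12)
    lH4 = np.log(p12) + s12
    ls = np.array([lH0, lH1, lH2, lH3, lH4])
    post = np.exp(ls - logsumexp(ls))
    pp = {f"PP.H{i}": float(post[i]) for i in range(5)}
    return ColocResult(l1, l2, pp, (p1, p2, p12))


def iterative_coloc(
    trait: dict[str, np.ndarray],
    expr: dict[str, np.ndarray],
    dosages: np.ndarray,
    lead_index: int,
    r2_threshold: float = 0.9,
    **coloc_kwargs,
) -> np.ndarray:
    """LD-iterated colocalization with the max-PP.H4-per-marker merge.

    Markers in high LD (r^2 > threshold) with the lead form the set H; the
    rest form R.  One run is done on R alone and one on R plus each member
    of H in turn; every marker's final value is the maximum run-level PP.H4
    over the runs that contained it.  ``dosages`` is samples x markers.
    """
    D = np.asarray(dosages, dtype=float)
    m = D.shape[1]
    r2 = np.array([ld_r2(D[:, j], D[:, lead_index]) for j in range(m)])
    H = np.flatnonzero(r2 > r2_threshold)
    R = np.flatnonzero(~(r2 > r2_threshold))
    if len(H) == 0 and len(R) == 0:
        raise ValueError("no markers to colocalize")

    def run(idx: np.ndarray) -> float:
        t = {k: np.asarray(v)[idx] for k, v in trait.items() if v is not None}
        e = {k: np.asarray(v)[idx] for k, v in expr.items() if v is not None}
        return coloc_abf(t, e, **coloc_kwargs).pp_h4

    best = np.full(m, -np.inf)
    if len(R):
        pp = run(R)
        best[R] = np.maximum(best[R], pp)
    for h in H:
        idx = np.sort(np.append(R, h))
        pp = run(idx)
        best[idx] = np.maximum(best[idx], pp)
    best[~np.isfinite(best)] = np.nan
    return best


def smr_test(z_gwas: float, z_eqtl: float) -> tuple[float, float]:
    """Summary-data Mendelian randomization test.

    T = z_gwas^2 z_eqtl^2 / (z_gwas^2 + z_eqtl^2), compared to chi-squared
    with 1 df.  T is bounded by min(z_gwas^2, z_eqtl^2).  Returns (T, p);
    both z zero is undefined (NaN, NaN).
    """
    zg2 = float(z_gwas) ** 2
    ze2 = float(z_eqtl) ** 2
    if zg2 + ze2 == 0:
        return float("nan"), float("nan")
    T = zg2 * ze2 / (zg2 + ze2)
    return T, float(stats.chi2.sf(T, 1))
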