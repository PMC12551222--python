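"""GRM construction, REML, mixed-model block scan, GBLUP, and FDR.

The model is  y = X b + a m + g + e  with g ~ N(0, sigma_g^2 G) built from
recoded ancestry-block dosages and e ~ N(0, sigma_e^2 I).  REML uses the
eigendecomposition of G and a one-dimensional search over the variance
ratio; the per-marker scan reuses the null-model variance components
(EMMAX-style), testing each candidate by generalized least squares with a
Wald statistic.  GBLUP breeding values follow
ghat = sigma_g^2 G V^{-1} (y - X bhat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class GRM:
    values: np.ndarray  # n x n
    n_markers: int
    freqs: np.ndarray  # centering frequencies

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


@dataclass
class RemlResult:
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    beta: np.ndarray


def build_grm(dosages: np.ndarray) -> GRM:
    """VanRaden method-1 GRM on 0/1/2 (ancestry or allele) dosages.

    Markers are centered by twice their frequency and the cross-product is
    scaled by 2 * sum p_k (1 - p_k); monomorphic markers are dropped.
    """
    D = np.asarray(dosages, dtype=float)
    p = D.mean(0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("all markers monomorphic")
    D = D[:, keep]
    p = p[keep]
    Z = D - 2 * p
    denom = 2 * np.sum(p * (1 - p))
    G = Z @ Z.T / denom
    return GRM(G, int(keep.sum()), p)


def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    """Fixed-effect design: intercept + covariates.

    Discrete (non-numeric or categorical) columns of a DataFrame become
    indicator contrasts dropping one reference level.
    """
    cols = [np.ones(n)]
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            for c in covariates.columns:
                col = covariates[c]
                if col.dtype.kind in "OUSb" or str(col.dtype) == "category":
                    dummies = pd.get_dummies(col, drop_first=True)
                    for dc in dummies.columns:
                        cols.append(dummies[dc].to_numpy(dtype=float))
                else:
                    cols.append(col.to_numpy(dtype=float))
        else:
            arr = np.atleast_2d(np.asarray(covariates, dtype=float))
            if arr.shape[0] != n:
                arr = arr.T
            cols.extend(arr.T)
    return np.column_stack(cols)


def reml_fit(
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    grm: GRM,
    log_delta_bounds: tuple[float, float] = (-10.0, 10.0),
) -> RemlResult:
    """Single-component REML via eigendecomposition of G.

    Profiles the restricted likelihood over delta = sigma_e^2 / sigma_g^2
    on a grid plus Brent refinement; h2 = 1 / (1 + delta).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = _design(covariates, n)
    if n <= X.shape[1]:
        raise ValueError("n must exceed the number of fixed effects")
    S, U = np.linalg.eigh(grm.values)
    if S.min() < -1e-6 * max(1.0, S.max()):
        raise ValueError("GRM is not positive semidefinite within tolerance")
    S = np.maximum(S, 0.0)
    yr = U.T @ y
    Xr = U.T @ X
    p = X.shape[1]

    def neg_rll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = S + delta
        Xw = Xr / np.sqrt(w)[:, None]
        yw = yr / np.sqrt(w)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        rss = float(r @ r)
        sg2 = rss / (n - p)
        _, logdet_xtx = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * (
            (n - p) * (np.log(2 * np.pi * sg2) + 1)
            + np.sum(np.log(w))
            + logdet_xtx
        )
        return -ll

    grid = np.linspace(log_delta_bounds[0], log_delta_bounds[1], 41)
    vals = [neg_rll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_rll, bounds=(lo, hi), method="bounded")
    delta = float(np.exp(res.x))
    w = S + delta
    Xw = Xr / np.sqrt(w)[:, None]
    yw = yr / np.sqrt(w)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    sg2 = float(r @ r) / (n - p)
    se2 = delta * sg2
    return RemlResult(
        sigma2_g=sg2,
        sigma2_e=se2,
        h2=sg2 / (sg2 + se2),
        loglik=-float(res.fun),
        eigvals=S,
        eigvecs=U,
        beta=np.asarray(beta),
    )


def block_scan(
    markers: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    grm: GRM,
    reml: RemlResult | None = None,
    marker_meta: pd.DataFrame | None = None,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Per-marker mixed-model association scan (EMMAX approximation).

    The null REML variance ratio is reused for every candidate: the data
    are whitened by V^{-1/2} = diag(sigma_g^2 s_i + sigma_e^2)^{-1/2} in the
    eigenbasis of G, candidates are residualized against the fixed effects,
    and a Wald test yields beta, SE, z, and p.  Candidates collinear with
    the covariates (zero residual variance) are flagged missing.  FDR
    q-values use Benjamini-Hochberg by default, or an empirical-null local
    fdr (``fdr_method='empirical_null'``).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    M = np.asarray(markers, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    X = _design(covariates, n)
    if reml is None:
        reml = reml_fit(y, covariates, grm)
    w = reml.sigma2_g * reml.eigvals + reml.sigma2_e
    U = reml.eigvecs
    sw = np.sqrt(w)
    yw = (U.T @ y) / sw
    Xw = (U.T @ X) / sw[:, None]
    Mw = (U.T @ M) / sw[:, None]
    Q, _ = np.linalg.qr(Xw)
    y_perp = yw - Q @ (Q.T @ yw)
    M_perp = Mw - Q @ (Q.T @ Mw)
    mm = np.einsum("ij,ij->j", M_perp, M_perp)
    my = M_perp.T @ y_perp
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(mm > 1e-10, my / mm, np.nan)
        se = np.where(mm > 1e-10, 1.0 / np.sqrt(mm), np.nan)
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "marker": (
                marker_meta["marker"]
                if marker_meta is not None and "marker" in marker_meta
                else np.arange(M.shape[1])
            ),
            "beta": beta,
            "se": se,
            "z": z,
            "p": pvals,
        }
    )
    if marker_meta is not None:
        for c in ("chrom", "start", "end"):
            if c in marker_meta:
                out[c] = marker_meta[c].to_numpy()
    ok = np.isfinite(pvals)
    q = np.full_like(pvals, np.nan)
    if ok.any():
        if fdr_method == "bh":
            from statsmodels.stats.multitest import multipletests

            q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        elif fdr_method == "empirical_null":
            q[ok] = empirical_null_lfdr(z[ok])
        else:
            raise ValueError(f"unknown fdr_method: {fdr_method}")
    out["q"] = q
    return out


def empirical_null_lfdr(z: np.ndarray) -> np.ndarray:
    """Local fdr against an empirical central-matching null.

    The null is N(0, s0^2) with s0 from the central half of the z
    distribution (robust to a small non-null fraction); the marginal
    density comes from a Gaussian KDE.  lfdr = pi0 f0(z) / f(z), capped at 1.
    """
    z = np.asarray(z, dtype=float)
    med = np.median(z)
    s0 = stats.iqr(z) / 1.349 if len(z) > 10 else z.std()
    s0 = max(s0, 1e-8)
    f0 = stats.norm.pdf(z, med, s0)
    kde = stats.gaussian_kde(z)
    f = np.maximum(kde(z), 1e-300)
    return np.minimum(f0 / f, 1.0)


def qtl_intervals(
    assoc: pd.DataFrame, q_threshold: float = 0.05
) -> list[tuple[str, int, int]]:
    """Maximal runs of consecutive significant blocks, merged to intervals."""
    need = {"chrom", "start", "end", "q"}
    if not need.issubset(assoc.columns):
        raise ValueError("assoc frame needs chrom/start/end/q columns")
    out = []
    cur = None
    prev_idx = None
    for idx, row in assoc.iterrows():
        sig = np.isfinite(row["q"]) and row["q"] < q_threshold
        if sig:
            if cur is not None and row["chrom"] == cur[0] and prev_idx == idx - 1:
                cur = (cur[0], cur[1], int(row["end"]))
            else:
                if cur is not None:
                    out.append(cur)
                cur = (row["chrom"], int(row["start"]), int(row["end"]))
            prev_idx = idx
    if cur is not None:
        out.append(cur)
    return out


def gblup(
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    grm: GRM,
    reml: RemlResult | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """GBLUP breeding values: ghat = sigma_g^2 G V^{-1} (y - X bhat).

    V = sigma_g^2 G + sigma_e^2 I; bhat is the GLS fixed-effect solution
    under V.  Returns a GebvTable frame (sample_id, gebv).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if reml is None:
        reml = reml_fit(y, covariates, grm)
    X = _design(covariates, n)
    U, S = reml.eigvecs, reml.eigvals
    w = reml.sigma2_g * S + reml.sigma2_e
    if np.any(w <= 0):
        raise ValueError("singular V")
    yr = U.T @ y
    Xr = U.T @ X
    Xw = Xr / np.sqrt(w)[:, None]
    yw = yr / np.sqrt(w)
    bhat, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r_rot = yr - Xr @ bhat
    ghat = reml.sigma2_g * (U @ (S / w * r_rot))
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    return pd.DataFrame({"sample_id": ids, "gebv": ghat})


def select_extreme_gebv(
    gebv: pd.DataFrame, k: int = 100
) -> tuple[list[str], list[str]]:
    """Disjoint top-k and bottom-k sample sets by GEBV.

    Ties are broken by sample-id lexicographic order so the split is
    deterministic.
    """
    n = len(gebv)
    if n < 2 * k:
        raise ValueError(f"need n >= 2k samples (n={n}, k={k})")
    asc = gebv.sort_values(["gebv", "sample_id"], ascending=[True, True])
    ids = asc["sample_id"].tolist()
    low = ids[:k]
    high = ids[-k:][::-1]
    return high, low
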