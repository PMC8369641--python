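"""Single-SNP mixed-linear-model GWAS with a genomic-kinship polygenic term.

The model for trait y is

    y = X b + x_j a_j + u + e,     u ~ N(0, sigma2_g K),   e ~ N(0, sigma2_e I)

with fixed covariates X (intercept plus, by default, the first three
principal components of the dosage matrix) and the candidate marker
dosage x_j tested one at a time.  Variance components are estimated by
REML once under the null (no marker) via a one-dimensional search over
delta = sigma2_e / sigma2_g on the eigenbasis of K, and reused for every
marker (the P3D approximation); ``exact=True`` re-optimises per marker.
Marker tests are Wald chi-square(1) on the GLS coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .structure_ld import KinshipMatrix


class MlmError(ValueError):
    pass


@dataclass
class MlmNullFit:
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray            # fixed effects (intercept + covariates)
    delta: float                # sigma2_e / sigma2_g
    loglik: float               # REML log-likelihood at the optimum
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n: int

    @property
    def heritability(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None and covariates.size:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])
    return X


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, Uy: np.ndarray,
                     UX: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Profile REML negative log-likelihood at delta (returns -ll, s2g, beta)."""
    delta = np.exp(log_delta)
    w = lam + delta
    n, p = UX.shape
    Xw = UX / w[:, None]
    XtWX = UX.T @ Xw
    XtWy = Xw.T @ Uy
    beta = np.linalg.solve(XtWX, XtWy)
    r = Uy - UX @ beta
    rss = float(np.sum(r * r / w))
    s2g = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    _, logdet_xx = np.linalg.slogdet(UX.T @ UX)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * s2g) + 1.0)
                 + np.sum(np.log(w)) + logdet_xwx - logdet_xx)
    return -ll, s2g, beta


def fit_null_mlm(y: np.ndarray, covariates: np.ndarray | None,
                 K: KinshipMatrix | np.ndarray,
                 log_delta_bounds: tuple[float, float] = (-11.5, 11.5),
                 n_grid: int = 100) -> MlmNullFit:
    """REML variance components of the null (no-marker) mixed model.

    Grid search over log delta followed by bounded scalar refinement;
    tolerance 1e-8 on the log-likelihood scale.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise MlmError("y must be complete; drop missing individuals first")
    if float(np.var(y)) == 0.0:
        raise MlmError("y is constant")
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    n = len(y)
    if Kv.shape != (n, n):
        raise MlmError("kinship dimension mismatch")
    lam, U = np.linalg.eigh(Kv)
    if lam.min() < -1e-6:
        raise MlmError("kinship is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    X = _design(n, covariates)
    Uy = U.T @ y
    UX = U.T @ X

    grid = np.linspace(*log_delta_bounds, n_grid)
    vals = [(_reml_neg_loglik(g, lam, Uy, UX)[0], g) for g in grid]
    best = min(vals)[1]
    span = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        lambda g: _reml_neg_loglik(g, lam, Uy, UX)[0],
        bounds=(best - span, best + span), method="bounded",
        options={"xatol": 1e-10})
    nll, s2g, beta = _reml_neg_loglik(res.x, lam, Uy, UX)
    delta = float(np.exp(res.x))
    return MlmNullFit(sigma2_g=s2g, sigma2_e=s2g * delta, beta=beta,
                      delta=delta, loglik=-nll, eigenvalues=lam,
                      eigenvectors=U, n=n)


def mlm_scan(y: np.ndarray, dosage: np.ndarray,
             covariates: np.ndarray | None, K: KinshipMatrix | np.ndarray,
             null_fit: MlmNullFit | None = None, exact: bool = False
             ) -> pd.DataFrame:
    """Wald chi-square(1) association test per marker under V-hat fixed.

    Columns: effect, se, wald, p, neglog10p.  Monomorphic markers get
    missing p.  ``exact`` re-estimates variance components per marker.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if null_fit is None:
        null_fit = fit_null_mlm(y, covariates, K)
    lam, U = null_fit.eigenvalues, null_fit.eigenvectors
    n = null_fit.n
    X = _design(n, covariates)
    m = dosage.shape[1]

    if exact:
        eff = np.full(m, np.nan)
        se = np.full(m, np.nan)
        for j in range(m):
            x = dosage[:, j]
            if np.var(x) == 0:
                continue
            Xa = np.hstack([X, x[:, None]])
            fit_j = fit_null_mlm(y, Xa[:, 1:], K)
            w = lam + fit_j.delta
            UXa = U.T @ Xa
            XtWX = (UXa / w[:, None]).T @ UXa
            cov = np.linalg.inv(XtWX) * fit_j.sigma2_g
            eff[j] = fit_j.beta[-1]
            se[j] = np.sqrt(cov[-1, -1])
    else:
        w = lam + null_fit.delta
        sw = np.sqrt(w)
        ys = (U.T @ y) / sw
        Xs = (U.T @ X) / sw[:, None]
        Gs = (U.T @ dosage) / sw[:, None]
        Q, _ = np.linalg.qr(Xs)
        yP = ys - Q @ (Q.T @ ys)
        GP = Gs - Q @ (Q.T @ Gs)
        xtx = np.einsum("ij,ij->j", GP, GP)
        xty = GP.T @ yP
        mono = np.var(dosage, axis=0) == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            eff = xty / xtx
            se = np.sqrt(null_fit.sigma2_g / xtx)
        eff[mono] = np.nan
        se[mono] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (eff / se) ** 2
        p = stats.chi2.sf(wald, df=1)
        neglog = -np.log10(np.clip(p, 1e-300, None))
    out = pd.DataFrame({"effect": eff, "se": se, "wald": wald, "p": p,
                        "neglog10p": neglog})
    return out


def bh_fdr(pvalues: np.ndarray, q: float = 0.05
           ) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level q.

    Returns (rejection flags, threshold) where the threshold is the
    largest rejected p-value (the line drawn on a Manhattan plot); nan
    when nothing is rejected.  Missing p-values are never rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), float("nan")
    ok = ~np.isnan(p)
    flags = np.zeros(p.shape, dtype=bool)
    if ok.sum():
        rej, _, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")[:4]
        flags[ok] = rej
    thr = float(p[flags].max()) if flags.any() else float("nan")
    return flags, thr


def gwas_mlm_results(scan: pd.DataFrame, markers: pd.DataFrame,
                     y: np.ndarray, dosage: np.ndarray,
                     fdr_q: float = 0.05) -> pd.DataFrame:
    """Assemble the full per-marker result table (effect, p, FDR flag, PVE)."""
    from .qtl_effects import snp_pve

    flags, thr = bh_fdr(scan["p"].to_numpy(), q=fdr_q)
    pve = np.full(len(scan), np.nan)
    vy = float(np.var(y))
    for j in range(len(scan)):
        e = scan["effect"].iloc[j]
        if np.isfinite(e) and vy > 0:
            pve[j] = snp_pve(y, dosage[:, j], e)
    out = markers[["chrom", "pos"]].copy().reset_index(drop=True)
    out["effect"] = scan["effect"].to_numpy()
    out["se"] = scan["se"].to_numpy()
    out["p"] = scan["p"].to_numpy()
    out["neglog10p"] = scan["neglog10p"].to_numpy()
    out["significant"] = flags
    out["pve"] = pve
    out.attrs["fdr_threshold"] = thr
    return out
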