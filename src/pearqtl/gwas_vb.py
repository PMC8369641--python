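"""Variational-Bayes multiple-QTL regression (vBayesB).

All markers are fitted simultaneously:

    y_i = mu + sum_j x_ij delta_j a_j + f_fam(i) + e_i

with delta_j ~ Bernoulli(pi), a_j | s2_aj ~ N(0, s2_aj), s2_aj ~
scaled-inv-chi2(nu, S2), family (progeny) effects f_k ~ N(0, s2_f) and
e_i ~ N(0, s2_e).  The posterior is approximated by mean-field
coordinate ascent: each marker's spike-and-slab factor q(delta_j, a_j)
is updated against the current residual, followed immediately by the
conjugate update of q(s2_aj); family factors are Gaussian; mu, s2_e and
s2_f are point parameters maximised in the same free energy
(variational EM), so every update is an exact coordinate maximisation
and the ELBO is non-decreasing.  The posterior inclusion probability
gamma_j is the marker's "SNP weight"; the model-averaged effect is
gamma_j * atilde_j.

The sequential residual-update sweep is compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import digamma, gammaln

from .geno_io import FamilyStructure, GenotypeMatrix


class VBError(ValueError):
    pass


@dataclass
class VBHyper:
    """Priors and fitting controls.

    ``pi`` defaults to 10/m (about ten QTLs expected genome-wide); ``s2``
    defaults to the standard BayesB scaling: prior mean of the per-SNP
    effect variance equals 0.5 * Var(y) / (pi * sum_k 2 p_k (1 - p_k)).
    """

    pi: float | None = None
    nu: float = 4.2
    s2: float | None = None
    max_iter: int = 1000
    tol: float = 1e-6
    n_restarts: int = 1
    seed: int = 0
    shuffle: bool = False

    def validate(self) -> None:
        if self.pi is not None and not (0.0 < self.pi < 1.0):
            raise VBError("pi must be in (0,1)")
        if self.nu <= 0 or (self.s2 is not None and self.s2 <= 0):
            raise VBError("nu and s2 must be positive")
        if self.tol <= 0:
            raise VBError("tol must be positive")


@dataclass
class VBFit:
    mu: float
    gamma: np.ndarray          # posterior inclusion probability per marker
    a_mean: np.ndarray         # slab posterior mean
    a_var: np.ndarray          # slab posterior variance
    s2a_mean: np.ndarray       # E[s2_aj]
    family_effects: dict       # family label -> posterior mean progeny effect
    sigma2_e: float
    sigma2_f: float
    elbo_trace: np.ndarray
    converged: bool
    hyper: VBHyper = field(repr=False, default=None)

    @property
    def weights(self) -> np.ndarray:
        """Model-averaged marker effects gamma_j * atilde_j."""
        return self.gamma * self.a_mean


@njit(cache=True)
def _digamma(x: float) -> float:
    res = 0.0
    while x < 6.0:
        res -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    return (res + math.log(x) - 0.5 * inv
            - inv2 * (1.0 / 12.0 - inv2 * (1.0 / 120.0 - inv2 / 252.0)))


@njit(cache=True)
def _sweep(Xt, r, xtx, gamma, a_mean, a_var, einv, elog,
           nu, nuS2, sigma2e, logit_pi, order):
    m, n = Xt.shape
    for t in range(len(order)):
        j = order[t]
        if xtx[j] <= 0.0:
            continue
        b_old = gamma[j] * a_mean[j]
        xtr = 0.0
        for i in range(n):
            xtr += Xt[j, i] * r[i]
        xtr += b_old * xtx[j]
        v = 1.0 / (xtx[j] / sigma2e + einv[j])
        a = v * xtr / sigma2e
        lam = logit_pi + 0.5 * (math.log(v) - elog[j]) + 0.5 * a * a / v
        if lam > 35.0:
            g = 1.0
        elif lam < -35.0:
            g = 0.0
        else:
            g = 1.0 / (1.0 + math.exp(-lam))
        shift = b_old - g * a
        if shift != 0.0:
            for i in range(n):
                r[i] += Xt[j, i] * shift
        gamma[j] = g
        a_mean[j] = a
        a_var[j] = v
        # conjugate scaled-inv-chi2 update of q(s2_aj)
        A = nuS2 + g * (a * a + v)
        ndf = nu + g
        einv[j] = ndf / A
        elog[j] = math.log(A / 2.0) - _digamma(ndf / 2.0)


def _elbo(r, xtx, gamma, a_mean, a_var, einv, elog, fam_mean, fam_var,
          fam_sizes, nu, S2, sigma2e, sigma2f, pi, n) -> float:
    g = np.clip(gamma, 1e-12, 1.0 - 1e-12)
    a2v = a_mean ** 2 + a_var
    e_rss = (float(r @ r)
             + float(np.sum(xtx * (gamma * a2v - (gamma * a_mean) ** 2)))
             + float(np.sum(fam_sizes * fam_var)))
    ll = -0.5 * n * np.log(2 * np.pi * sigma2e) - e_rss / (2 * sigma2e)

    spike = np.sum(g * (np.log(pi) - 0.5 * (np.log(2 * np.pi) + elog)
                        - 0.5 * einv * a2v)
                   + (1 - g) * np.log(1 - pi))
    entropy = np.sum(-g * np.log(g) - (1 - g) * np.log(1 - g)
                     + g * 0.5 * np.log(2 * np.pi * np.e * a_var))

    nuS2 = nu * S2
    ndf = nu + gamma
    A = nuS2 + gamma * a2v
    log_p = (0.5 * nu * np.log(nuS2 / 2) - gammaln(nu / 2)
             - (1 + nu / 2) * elog - 0.5 * nuS2 * einv)
    log_q = (0.5 * ndf * np.log(A / 2) - gammaln(ndf / 2)
             - (1 + ndf / 2) * elog - 0.5 * A * einv)
    s2a_term = float(np.sum(log_p - log_q))

    fam_term = 0.0
    if len(fam_mean):
        fam_term = float(np.sum(
            -0.5 * np.log(2 * np.pi * sigma2f)
            - (fam_mean ** 2 + fam_var) / (2 * sigma2f)
            + 0.5 * np.log(2 * np.pi * np.e * fam_var)))
    return float(ll + spike + entropy + s2a_term + fam_term)


def fit_vbayesb(y: np.ndarray, g: GenotypeMatrix | np.ndarray,
                families: FamilyStructure | np.ndarray | None = None,
                hyper: VBHyper | None = None,
                fix_sigma2e: float | None = None,
                fit_intercept: bool = True) -> VBFit:
    """Fit the spike-and-slab multiple-QTL model by coordinate-ascent VB.

    ``families`` may be a FamilyStructure (codes derived from the
    genotype IDs), an integer code array, or None (no progeny effects;
    also disabled automatically when only one class is present).
    Deterministic given ``hyper.seed``, which controls update-order
    shuffling and restarts.
    """
    hyper = hyper or VBHyper()
    hyper.validate()
    y = np.asarray(y, dtype=float)
    if isinstance(g, GenotypeMatrix):
        X = g.dosage
        ids = g.ids
    else:
        X = np.asarray(g, dtype=float)
        ids = None
    if np.isnan(X).any():
        raise VBError("complete dosages required (impute first)")
    if np.isnan(y).any():
        raise VBError("y must be complete")
    n, m = X.shape
    if len(y) != n:
        raise VBError("y length does not match genotypes")

    if isinstance(families, FamilyStructure):
        if ids is None:
            raise VBError("FamilyStructure requires a GenotypeMatrix")
        codes = families.codes_for(ids)
        fam_labels = sorted(pd.unique(families.labels.reindex(ids)))
    elif families is not None:
        codes = np.asarray(families, dtype=np.int64)
        fam_labels = [str(k) for k in range(codes.max() + 1)]
    else:
        codes, fam_labels = None, []
    if codes is not None and len(np.unique(codes)) < 2:
        codes, fam_labels = None, []

    pi = hyper.pi if hyper.pi is not None else min(10.0 / m, 0.5)
    p = X.mean(axis=0) / 2.0
    sum2pq = float(np.sum(2 * p * (1 - p)))
    if hyper.s2 is not None:
        S2 = hyper.s2
    else:
        prior_mean = 0.5 * float(np.var(y)) / max(pi * sum2pq, 1e-12)
        S2 = prior_mean * (hyper.nu - 2) / hyper.nu if hyper.nu > 2 else prior_mean
        S2 = max(S2, 1e-12)
    nuS2 = hyper.nu * S2

    Xt = np.ascontiguousarray(X.T)
    xtx = np.einsum("ij,ij->j", X, X)
    rng = np.random.default_rng(hyper.seed)

    best = None
    for restart in range(max(hyper.n_restarts, 1)):
        gamma = np.zeros(m)
        a_mean = np.zeros(m)
        a_var = np.full(m, S2)
        einv = np.full(m, hyper.nu / nuS2)
        elog = np.full(m, math.log(nuS2 / 2.0) - digamma(hyper.nu / 2.0))
        if codes is not None:
            K = codes.max() + 1
            fam_sizes = np.bincount(codes, minlength=K).astype(float)
            fam_mean = np.zeros(K)
            fam_var = np.full(K, 1e-3)
        else:
            fam_sizes = np.zeros(0)
            fam_mean = np.zeros(0)
            fam_var = np.zeros(0)
        mu = float(np.mean(y)) if fit_intercept else 0.0
        sigma2e = fix_sigma2e if fix_sigma2e is not None else max(float(np.var(y)), 1e-8)
        sigma2f = max(0.05 * float(np.var(y)), 1e-8)
        r = y - mu
        order0 = np.arange(m, dtype=np.int64)

        trace: list[float] = []
        converged = False
        for it in range(hyper.max_iter):
            order = rng.permutation(m).astype(np.int64) if hyper.shuffle else order0
            if fit_intercept:
                r += mu
                mu = float(np.mean(r))
                r -= mu
            _sweep(Xt, r, xtx, gamma, a_mean, a_var, einv, elog,
                   hyper.nu, nuS2, sigma2e, math.log(pi / (1 - pi)), order)
            if codes is not None:
                for k in range(len(fam_mean)):
                    sel = codes == k
                    r[sel] += fam_mean[k]
                    v = 1.0 / (fam_sizes[k] / sigma2e + 1.0 / sigma2f)
                    fam_mean[k] = v * float(np.sum(r[sel])) / sigma2e
                    fam_var[k] = v
                    r[sel] -= fam_mean[k]
                sigma2f = max(float(np.mean(fam_mean ** 2 + fam_var)), 1e-10)
            if fix_sigma2e is None:
                a2v = a_mean ** 2 + a_var
                e_rss = (float(r @ r)
                         + float(np.sum(xtx * (gamma * a2v - (gamma * a_mean) ** 2)))
                         + float(np.sum(fam_sizes * fam_var)))
                sigma2e = max(e_rss / n, 1e-10)
            elbo = _elbo(r, xtx, gamma, a_mean, a_var, einv, elog,
                         fam_mean, fam_var, fam_sizes, hyper.nu, S2,
                         sigma2e, sigma2f, pi, n)
            if trace and elbo < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
                raise RuntimeError(
                    f"ELBO decreased at iteration {it}: {trace[-1]} -> {elbo}")
            if trace and abs(elbo - trace[-1]) < hyper.tol * max(1.0, abs(elbo)):
                trace.append(elbo)
                converged = True
                break
            trace.append(elbo)

        fit = VBFit(
            mu=mu, gamma=gamma.copy(), a_mean=a_mean.copy(),
            a_var=a_var.copy(),
            s2a_mean=np.where(hyper.nu + gamma > 2,
                              (nuS2 + gamma * (a_mean ** 2 + a_var))
                              / np.maximum(hyper.nu + gamma - 2, 1e-9),
                              np.inf),
            family_effects={lab: float(v) for lab, v in zip(fam_labels, fam_mean)},
            sigma2_e=sigma2e, sigma2_f=sigma2f,
            elbo_trace=np.array(trace), converged=converged, hyper=hyper)
        if best is None or fit.elbo_trace[-1] > best.elbo_trace[-1]:
            best = fit
    if not best.converged:
        import warnings
        warnings.warn("vBayesB did not converge within max_iter; returning "
                      "best state", RuntimeWarning, stacklevel=2)
    return best


def significant_snps(fit: VBFit, g: GenotypeMatrix | None = None,
                     threshold: float = 0.85) -> np.ndarray:
    """Markers with inclusion probability >= threshold (inclusive).

    Sorted by chromosome then position when a GenotypeMatrix is given,
    else by index.
    """
    idx = np.flatnonzero(fit.gamma >= threshold)
    if g is None or len(idx) == 0:
        return idx
    chrom = g.markers["chrom"].to_numpy()[idx]
    pos = g.markers["pos"].to_numpy()[idx]

    def key(c):
        s = str(c)
        return (0, int(s)) if s.isdigit() else (1, s)

    order = sorted(range(len(idx)), key=lambda t: (key(chrom[t]), pos[t]))
    return idx[order]


def vb_effect_summary(fit: VBFit, y: np.ndarray, g: GenotypeMatrix,
                      threshold: float = 0.85) -> pd.DataFrame:
    """Per-significant-marker table: gamma, model-averaged effect, PVE (%)."""
    from .qtl_effects import snp_pve

    idx = significant_snps(fit, g, threshold)
    rows = []
    for j in idx:
        b = fit.gamma[j] * fit.a_mean[j]
        rows.append({
            "marker": g.marker_names()[j],
            "chrom": g.markers["chrom"].iloc[j],
            "pos": int(g.markers["pos"].iloc[j]),
            "gamma": fit.gamma[j],
            "effect": fit.a_mean[j],
            "effect_avg": b,
            "pve": snp_pve(np.asarray(y, float), g.dosage[:, j], b),
        })
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos", "gamma",
                                       "effect", "effect_avg", "pve"])
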