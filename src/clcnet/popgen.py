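"""Linkage-disequilibrium statistics, kinship, heritability and a GWAS scan.

r² is the squared Pearson correlation of alt-allele dosages with pairwise
deletion of missing calls. The genomic relationship matrix follows the
classical VanRaden construction (centred dosages, normalised by 2Σp(1−p));
narrow-sense heritability is estimated by single-component REML on the
eigendecomposition of that matrix. The GWAS scan is ordinary least squares
per SNP with genotype principal components as covariates — a deliberately
simple marginal scan used here only as a feature filter and for comparing
against model-based SNP attributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geno import (
    MISSING_CODE,
    GenotypeMatrix,
    allele_frequencies,
    imputed_dosages,
)

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_r2",
    "r2_matrix",
    "LDDecayCurve",
    "ld_decay",
    "GRM",
    "compute_grm",
    "H2Estimate",
    "reml_h2",
    "GWASResult",
    "gwas_scan",
]


def pairwise_r2(x, y) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing calls (code 3) are excluded pairwise. Returns NaN when fewer
    than two jointly observed samples remain or either vector is constant
    after missing removal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING_CODE) & (y != MISSING_CODE)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        return float("nan")
    vx = x - x.mean()
    vy = y - y.mean()
    sxx, syy = float(vx @ vx), float(vy @ vy)
    if sxx <= 0 or syy <= 0:
        return float("nan")
    sxy = float(vx @ vy)
    return sxy * sxy / (sxx * syy)


def r2_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs r² for an n×m dosage block with pairwise deletion.

    Vectorised via masked cross-products; agrees with :func:`pairwise_r2`
    entry by entry. Undefined entries (too few joint samples or constant
    columns) are NaN; the diagonal is 1 for non-constant columns.
    """
    V = np.asarray(values, dtype=float)
    M = (V != MISSING_CODE).astype(float)
    Z = np.where(M > 0, V, 0.0)
    n = M.T @ M
    sx = Z.T @ M
    sy = sx.T
    sxy = Z.T @ Z
    sxx = (Z * Z).T @ M
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = (cov * cov) / (varx * vary)
    r2[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2


@dataclass
class LDDecayCurve:
    """Mean pairwise r² by physical-distance bin (equal-width bp bins)."""

    bin_edges: np.ndarray   # length n_bins+1, covering (0, max_dist]
    mean_r2: np.ndarray     # NaN where a bin holds no pair
    pair_counts: np.ndarray


def ld_decay(G: GenotypeMatrix, max_dist: int = 100_000, n_bins: int = 20) -> LDDecayCurve:
    """LD decay: same-chromosome SNP pairs within *max_dist* bp, binned."""
    edges = np.linspace(0.0, float(max_dist), n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in G.chromosomes:
        idx = G.chrom_indices(c)
        if len(idx) < 2:
            continue
        pos = G.pos[idx].astype(float)
        r2 = r2_matrix(G.values[:, idx])
        iu, ju = np.triu_indices(len(idx), k=1)
        dist = pos[ju] - pos[iu]
        ok = (dist > 0) & (dist <= max_dist) & np.isfinite(r2[iu, ju])
        if not ok.any():
            continue
        b = np.clip(np.ceil(dist[ok] / (max_dist / n_bins)).astype(int) - 1, 0, n_bins - 1)
        np.add.at(sums, b, r2[iu, ju][ok])
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(edges, mean, counts)


@dataclass
class GRM:
    """Genomic relationship matrix with its sample ids."""

    matrix: np.ndarray
    sample_ids: np.ndarray
    n_snps_used: int = 0
    n_snps_dropped: int = 0


def compute_grm(G: GenotypeMatrix) -> GRM:
    """VanRaden (method 1) GRM: (M−2P)(M−2P)ᵀ / 2Σp(1−p).

    Missing calls are mean-imputed per SNP for this computation only.
    Monomorphic SNPs are dropped (count logged and recorded).
    """
    X = imputed_dosages(G.values)
    p = allele_frequencies(G.values)
    poly = np.isfinite(p) & (p > 0) & (p < 1) & (X.std(axis=0) > 0)
    n_drop = int((~poly).sum())
    if n_drop:
        logger.info("compute_grm: dropped %d monomorphic SNPs", n_drop)
    if poly.sum() == 0:
        raise ValueError("no polymorphic SNPs; cannot build GRM")
    W = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0
    return GRM(K, G.sample_ids.copy(), int(poly.sum()), n_drop)


@dataclass
class H2Estimate:
    """Single-component REML heritability estimate."""

    h2: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    n_evals: int = 0
    eval_history: np.ndarray | None = None


def _reml_profile(h2: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> tuple:
    """Profiled REML log-likelihood at heritability *h2* (K eigenvalues d)."""
    lam = h2 / (1.0 - h2)
    w = lam * d + 1.0
    wi = 1.0 / w
    XtWX = Xt.T @ (wi[:, None] * Xt)
    XtWy = Xt.T @ (wi * yt)
    beta = np.linalg.solve(XtWX, XtWy)
    r = yt - Xt @ beta
    n, p = len(yt), Xt.shape[1]
    rss = float(r @ (wi * r))
    sigma_e2 = rss / (n - p)
    sign, logdet = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        np.sum(np.log(w))
        + (n - p) * np.log(sigma_e2)
        + logdet
        + (n - p) * (1.0 + np.log(2.0 * np.pi))
    )
    return float(ll), sigma_e2, lam


def reml_h2(K: GRM | np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-6) -> H2Estimate:
    """REML heritability under y ~ N(μ1, σg²K + σe²I).

    K is eigendecomposed once and the profiled restricted likelihood is
    maximised over the variance ratio by bounded 1-D search. The estimate
    is clipped to [0,1] by the parameterisation itself.
    """
    Km = K.matrix if isinstance(K, GRM) else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if Km.shape != (n, n):
        raise ValueError("GRM / phenotype dimension mismatch")
    if np.std(y, ddof=1) <= 0 or not np.isfinite(y).all():
        raise ValueError("phenotype is constant or non-finite")
    d, U = np.linalg.eigh(Km)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Xt = U.T @ np.ones((n, 1))
    history: list[tuple[float, float]] = []

    def neg(h2: float) -> float:
        ll, _, _ = _reml_profile(h2, d, yt, Xt)
        history.append((h2, ll))
        return -ll

    eps = 1e-6
    res = optimize.minimize_scalar(
        neg, bounds=(eps, 1.0 - eps), method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    if not res.success:
        raise RuntimeError(
            f"REML did not converge after {max_iter} iterations (last h2={res.x:.4f})"
        )
    h2 = float(res.x)
    ll, sigma_e2, lam = _reml_profile(h2, d, yt, Xt)
    sigma_g2 = lam * sigma_e2
    h2_hat = sigma_g2 / (sigma_g2 + sigma_e2)
    if h2 < 2 * eps:   # boundary: effectively zero genetic variance
        h2_hat, sigma_g2 = 0.0, 0.0
    return H2Estimate(
        h2=float(np.clip(h2_hat, 0.0, 1.0)),
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        loglik=float(ll),
        n_evals=len(history),
        eval_history=np.asarray(history),
    )


@dataclass
class GWASResult:
    """Marginal per-SNP association scan results."""

    table: pd.DataFrame      # snp_id, chrom, pos, beta, se, p
    covariates: str

    def __len__(self) -> int:
        return len(self.table)


def gwas_scan(G: GenotypeMatrix, y: np.ndarray, n_pcs: int = 5) -> GWASResult:
    """Per-SNP OLS of y on dosage + intercept + top genotype PCs.

    Missing dosages are mean-imputed for this scan. Two-sided p-values come
    from the t statistic with n − n_pcs − 2 degrees of freedom. Constant
    SNPs get NaN beta/se/p.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if G.n_samples != n:
        raise ValueError("genotype and phenotype rows are not aligned")
    if n <= n_pcs + 2:
        raise ValueError("too few samples for the requested number of PCs")
    X = imputed_dosages(G.values)
    C = np.ones((n, 1))
    if n_pcs > 0:
        from sklearn.decomposition import PCA

        Xc = X - X.mean(axis=0)
        pcs = PCA(n_components=min(n_pcs, min(Xc.shape) - 1), svd_solver="randomized",
                  random_state=0).fit_transform(Xc)
        C = np.hstack([C, pcs])
    Q, _ = np.linalg.qr(C)
    yr = y - Q @ (Q.T @ y)
    Xr = X - Q @ (Q.T @ X)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    sxy = Xr.T @ yr
    df = n - C.shape[1] - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
        rss = float(yr @ yr) - beta * sxy
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
        t = beta / se
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    bad = ~np.isfinite(sxx) | (sxx <= 1e-12)
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[bad] = np.nan
    table = pd.DataFrame(
        {"snp_id": G.snp_ids, "chrom": G.chrom, "pos": G.pos,
         "beta": beta, "se": se, "p": p}
    )
    return GWASResult(table, covariates=f"intercept + {C.shape[1] - 1} genotype PCs")
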