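"""Candidate-gene association of sequence variants with a quantitative trait.

The model is the standard single-random-effect mixed linear model used for
structured association panels:

    y = mu + Q a + x_v b + u + e,   u ~ N(0, sg2 K),  e ~ N(0, se2 I)

with population-structure covariates Q as fixed effects and a genomic
kinship K as the covariance of the polygenic random effect.  Variance
components are estimated once by REML under the null model over the
eigen-spectrum of K (the EMMAX shortcut); each variant is then tested by
weighted least squares on the decorrelated system, re-estimating the
residual scale per variant so that with K = I and no Q the procedure reduces
exactly to ordinary least squares.  The proportion of phenotypic variance
explained by a variant is b^2 Var(x_v) / Var(y) on the observed scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "minor_allele_frequency",
    "filter_maf",
    "kinship_matrix",
    "structure_covariates",
    "mlm_association",
    "significant_variants",
    "haplotype_expression_split",
]


def minor_allele_frequency(gmat: pd.DataFrame) -> pd.Series:
    """Per-variant MAF from a 0/1/2 dosage matrix, ignoring missing calls."""
    freq = gmat.mean(axis=0, skipna=True) / 2.0
    return pd.concat([freq, 1.0 - freq], axis=1).min(axis=1)


def filter_maf(gmat: pd.DataFrame, maf_min: float = 0.05) -> pd.DataFrame:
    """Drop variants with minor-allele frequency below ``maf_min``.

    MAF is computed on non-missing calls; monomorphic variants (MAF 0) are
    always removed.  Idempotent.  An empty result is returned with a warning
    rather than raised.
    """
    if gmat.shape[0] < 2:
        raise ValueError("need at least two individuals")
    maf = minor_allele_frequency(gmat)
    keep = (maf >= maf_min) & (maf > 0)
    out = gmat.loc[:, keep.to_numpy()]
    if out.shape[1] == 0:
        warnings.warn("all variants removed by the MAF filter")
    return out


def _impute_mean(gmat: pd.DataFrame) -> np.ndarray:
    # copy=True: to_numpy may otherwise return a view of the caller's frame
    g = gmat.to_numpy(dtype=float, copy=True)
    col_mean = np.nanmean(g, axis=0)
    idx = np.where(np.isnan(g))
    g[idx] = col_mean[idx[1]]
    return g


def kinship_matrix(gmat: pd.DataFrame) -> np.ndarray:
    """Centered cross-product (VanRaden) kinship: K = Z Z' / sum(2 p (1-p)).

    Z is the mean-imputed dosage matrix with twice the allele frequency
    subtracted from each variant column.
    """
    if gmat.shape[1] < 2:
        raise ValueError("need at least two variants for a kinship matrix")
    g = _impute_mean(gmat)
    p = g.mean(axis=0) / 2.0
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom == 0:
        raise ValueError("all variants monomorphic; kinship undefined")
    z = g - 2.0 * p
    return z @ z.T / denom


def structure_covariates(gmat: pd.DataFrame, n_components: int = 2) -> np.ndarray:
    """Leading principal components of the centered genotype matrix.

    Used as fixed-effect structure covariates (a stand-in for an externally
    estimated Q matrix).  Columns are centered by construction.
    """
    g = _impute_mean(gmat)
    g = g - g.mean(axis=0)
    u, s, _ = np.linalg.svd(g, full_matrices=False)
    return u[:, :n_components] * s[:n_components]


def _reml_delta(lam: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> float:
    """REML estimate of delta = se2/sg2 on the rotated null system.

    ``lam`` are the (clipped) eigenvalues of K and ``yr``/``xr`` the
    eigenvector-rotated phenotype and null fixed-effect design.  The profile
    restricted likelihood is maximized over log(delta) on [-10, 10] by a grid
    pass followed by bounded refinement.
    """
    n, q = xr.shape

    def negll(log_delta: float) -> float:
        d = lam + np.exp(log_delta)
        w = 1.0 / d
        xw = xr * np.sqrt(w)[:, None]
        yw = yr * np.sqrt(w)
        beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
        resid = yw - xw @ beta
        rss = float(resid @ resid)
        xtx = xw.T @ xw
        sign, logdet_x = np.linalg.slogdet(xtx)
        if sign <= 0 or rss <= 0:
            return np.inf
        return 0.5 * (
            (n - q) * np.log(rss / (n - q)) + float(np.sum(np.log(d))) + logdet_x
        )

    grid = np.linspace(-10.0, 10.0, 41)
    values = [negll(g) for g in grid]
    i = int(np.argmin(values))
    lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded")
    best = res.x if res.fun <= values[i] else grid[i]
    return float(np.exp(best))


def _wls_test(xr: np.ndarray, yr: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Weighted LS fit; returns (beta, se, rss, dof) with per-fit scale."""
    sw = np.sqrt(w)
    xw = xr * sw[:, None]
    yw = yr * sw
    n, p = xw.shape
    beta, _, rank, _ = np.linalg.lstsq(xw, yw, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("singular fixed-effect design")
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(xw.T @ xw)
    se = np.sqrt(np.diag(cov))
    return beta, se, rss, dof


def mlm_association(
    gmat: pd.DataFrame,
    phenotype,
    Q: np.ndarray | None = None,
    K: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mixed-linear-model association scan over the variants of ``gmat``.

    Returns a DataFrame indexed by variant id with the allele-substitution
    effect, its standard error, the Wald (t) p-value, the proportion of
    phenotypic variance explained, and the sample size used.  Individuals
    with a missing call at a variant are excluded casewise from that
    variant's test (the kinship rotation is recomputed on the subset, keeping
    the null-model variance ratio).  Variants whose design is singular are
    skipped with a warning.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if gmat.shape[0] != n:
        raise ValueError("genotype matrix and phenotype dimensions disagree")
    if Q is not None:
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        if Q.shape[0] != n:
            Q = Q.T
        if Q.shape[0] != n:
            raise ValueError("Q dimensions disagree with phenotype")
    x0 = np.ones((n, 1)) if Q is None else np.column_stack([np.ones(n), Q])

    if K is None:
        lam = np.ones(n)
        u_eig = np.eye(n)
        delta = 1.0  # weights constant; value irrelevant
    else:
        K = np.asarray(K, dtype=float)
        if K.shape != (n, n):
            raise ValueError("K dimensions disagree with phenotype")
        lam, u_eig = np.linalg.eigh((K + K.T) / 2.0)
        lam = np.clip(lam, 0.0, None)
        yr0 = u_eig.T @ y
        xr0 = u_eig.T @ x0
        delta = _reml_delta(lam, yr0, xr0)

    yr = u_eig.T @ y
    xr0_full = u_eig.T @ x0
    w_full = 1.0 / (lam + delta)
    var_y = float(np.var(y, ddof=1))

    rows = []
    for vid in gmat.columns:
        x = gmat[vid].to_numpy(dtype=float)
        mask = ~np.isnan(x)
        try:
            if mask.all():
                design = np.column_stack([xr0_full, u_eig.T @ x])
                beta, se, _, dof = _wls_test(design, yr, w_full)
                n_used = n
                var_x = float(np.var(x, ddof=1))
            else:
                ys, xs = y[mask], x[mask]
                x0s = x0[mask]
                if K is None:
                    lam_s, u_s = np.ones(int(mask.sum())), np.eye(int(mask.sum()))
                else:
                    lam_s, u_s = np.linalg.eigh(
                        (K[np.ix_(mask, mask)] + K[np.ix_(mask, mask)].T) / 2.0
                    )
                    lam_s = np.clip(lam_s, 0.0, None)
                design = np.column_stack([u_s.T @ x0s, u_s.T @ xs])
                beta, se, _, dof = _wls_test(design, u_s.T @ ys, 1.0 / (lam_s + delta))
                n_used = int(mask.sum())
                var_x = float(np.var(xs, ddof=1))
        except np.linalg.LinAlgError:
            warnings.warn(f"variant {vid!r} skipped: singular design")
            continue
        b = float(beta[-1])
        se_b = float(se[-1])
        tstat = b / se_b if se_b > 0 else np.inf
        p = float(2.0 * stats.t.sf(abs(tstat), dof)) if dof > 0 else np.nan
        pve = min(1.0, b * b * var_x / var_y) if var_y > 0 else np.nan
        rows.append((vid, b, se_b, p, pve, n_used))
    return pd.DataFrame(
        rows, columns=["variant", "beta", "se", "p_value", "pve", "n_used"]
    ).set_index("variant")


def significant_variants(results: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Variants with p below the fixed significance level, sorted by p."""
    if results.empty:
        raise ValueError("empty association results")
    return results[results["p_value"] < alpha].sort_values("p_value")


def haplotype_expression_split(genotypes, expression, het_policy: str = "exclude"):
    """Split accessions into the two homozygous haplotype classes of one
    biallelic variant and compare expression with a rank-sum test.

    Returns ``(groups, n_het_excluded, p_value)`` where ``groups`` maps the
    genotype code (0, 2) to the expression values of its carriers.
    Heterozygotes are excluded by default (inbred-panel convention).
    """
    from .qpcr import compare_groups

    g = np.asarray(genotypes, dtype=float)
    ex = np.asarray(expression, dtype=float)
    if g.shape != ex.shape:
        raise ValueError("genotypes and expression must align")
    if het_policy != "exclude":
        raise ValueError("only het_policy='exclude' is supported")
    groups = {0: ex[g == 0], 2: ex[g == 2]}
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("one haplotype group is empty")
    p = compare_groups(groups[0], groups[2], test="wmw")
    return groups, int(np.sum(g == 1)), p
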