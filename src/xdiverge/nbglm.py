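"""Negative-binomial generalized linear models for count data.

The model for gene g, sample i is

    y_gi ~ NB(mu_gi, phi_g),      Var(y) = mu + phi * mu^2,
    log mu_gi = offset_i + x_i' beta_g,

with a log link, per-sample offsets carrying the (effective) library
sizes, and a gene-wise overdispersion phi >= 0 (phi = 0 is the Poisson
limit). Coefficients are maximum-likelihood at fixed phi, obtained by
iteratively reweighted least squares with step-halving; all genes are fit
simultaneously with vectorized linear algebra.

Dispersion is estimated by maximizing the Cox-Reid adjusted profile
likelihood (APL), either as a single value shared by all genes
("common") or gene-wise shrunk toward the common value by a weighted
likelihood with a configurable prior ("tagwise").

Inference on a coefficient contrast c'beta uses the likelihood-ratio
test: the reduced model is the full design restricted to the null space
of the contrast, and the deviance difference is referred to chi-square
with 1 degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special, stats

__all__ = [
    "NBFit",
    "nb_loglik",
    "nb_deviance",
    "fit_nb_glm",
    "lrt_contrast",
    "adjusted_profile_loglik",
    "estimate_dispersion",
]

_ETA_CAP = 40.0  # linear-predictor clamp; exp(40) dwarfs any real count
_MAX_ITER = 50
_TOL = 1e-8


def _as_gene_matrix(y: np.ndarray) -> tuple[np.ndarray, bool]:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        return y[None, :], True
    return y, False


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray | float) -> np.ndarray:
    """Per-observation NB(mu, phi) log-likelihood (Poisson when phi=0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    phi = np.asarray(phi, dtype=float)
    phi_b = np.broadcast_to(phi, np.broadcast_shapes(y.shape, phi.shape))
    out = np.empty(np.broadcast_shapes(y.shape, mu.shape, phi_b.shape))
    pois = phi_b == 0
    yb = np.broadcast_to(y, out.shape)
    mub = np.broadcast_to(mu, out.shape)
    if np.any(pois):
        out[pois] = stats.poisson.logpmf(yb[pois], mub[pois])
    nb = ~pois
    if np.any(nb):
        r = 1.0 / phi_b[nb]
        yy, mm = yb[nb], mub[nb]
        out[nb] = (
            special.gammaln(yy + r)
            - special.gammaln(r)
            - special.gammaln(yy + 1.0)
            + r * np.log(r / (r + mm))
            + yy * np.log(mm / (r + mm))
        )
    return out


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray | float) -> np.ndarray:
    """Per-gene residual deviance, 2*(ll_saturated - ll_fitted).

    ``y`` may be (n,) or (genes, n); the sum is over the last axis.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim and y.ndim == 2:
        phi = phi[:, None]
    ylogy = np.where(y > 0, y * np.log(np.maximum(y, 1.0) / mu), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(phi > 0, 1.0 / np.where(phi > 0, phi, 1.0), np.inf)
        nb_term = np.where(
            phi > 0,
            (y + r) * np.log((y + r) / (mu + r)),
            y - mu,  # Poisson limit of (y+r) log((y+r)/(mu+r)) as r->inf
        )
    unit = 2.0 * (ylogy - nb_term)
    return unit.sum(axis=-1)


@dataclass
class NBFit:
    """Fitted NB-GLM for a block of genes sharing one design.

    Attributes
    ----------
    beta : (genes, p) coefficients on the natural-log scale.
    mu : (genes, n) fitted means.
    dispersion : (genes,) phi used in the fit.
    deviance : (genes,) residual deviance.
    converged : (genes,) IRLS convergence flags.
    ok : (genes,) False for degenerate genes (all-zero counts) that are
        excluded from testing.
    """

    beta: np.ndarray
    mu: np.ndarray
    dispersion: np.ndarray
    deviance: np.ndarray
    converged: np.ndarray
    ok: np.ndarray
    design: np.ndarray
    offsets: np.ndarray
    y: np.ndarray = field(repr=False, default=None)

    def coef_cov(self) -> np.ndarray:
        """(genes, p, p) asymptotic covariance, inverse Fisher information."""
        w = self.mu / (1.0 + self.dispersion[:, None] * self.mu)
        xtwx = np.einsum("ni,gn,nj->gij", self.design, w, self.design)
        return np.linalg.inv(xtwx)

    def contrast_estimate(self, contrast: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(estimate, SE) of c'beta per gene, natural-log scale."""
        c = np.asarray(contrast, dtype=float)
        est = self.beta @ c
        se = np.sqrt(np.einsum("i,gij,j->g", c, self.coef_cov(), c))
        return est, se


def _irls(y, design, offsets, phi, beta0=None):
    g, n = y.shape
    p = design.shape[1]
    phi_col = phi[:, None]
    if beta0 is None:
        # unweighted LS on shifted log counts for a starting point
        z0 = np.log(y + 0.5) - offsets
        beta = np.linalg.lstsq(design, z0.T, rcond=None)[0].T
    else:
        beta = beta0.copy()
    eta = np.clip(offsets + beta @ design.T, -_ETA_CAP, _ETA_CAP)
    mu = np.exp(eta)
    dev = nb_deviance(y, mu, phi)
    converged = np.zeros(g, dtype=bool)
    active = np.ones(g, dtype=bool)
    for _ in range(_MAX_ITER):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        mu_a = mu[idx]
        w = mu_a / (1.0 + phi_col[idx] * mu_a)
        z = (eta[idx] - offsets) + (y[idx] - mu_a) / mu_a
        xtwx = np.einsum("ni,gn,nj->gij", design, w, design)
        xtwx += 1e-10 * np.eye(p)
        xtwz = np.einsum("ni,gn->gi", design, w * z)
        beta_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        step = beta_new - beta[idx]
        # step-halving keeps the deviance monotone non-increasing
        dev_old = dev[idx]
        scale = np.ones(idx.size)
        for _half in range(12):
            cand = beta[idx] + scale[:, None] * step
            eta_c = np.clip(offsets + cand @ design.T, -_ETA_CAP, _ETA_CAP)
            dev_c = nb_deviance(y[idx], np.exp(eta_c), phi[idx])
            worse = dev_c > dev_old + 1e-12
            if not np.any(worse):
                break
            scale[worse] *= 0.5
        beta[idx] = beta[idx] + scale[:, None] * step
        eta[idx] = np.clip(offsets + beta[idx] @ design.T, -_ETA_CAP, _ETA_CAP)
        mu[idx] = np.exp(eta[idx])
        dev_new = nb_deviance(y[idx], mu[idx], phi[idx])
        done = np.abs(dev_old - dev_new) < _TOL * (np.abs(dev_new) + 1.0)
        dev[idx] = dev_new
        converged[idx[done]] = True
        active[idx[done]] = False
    return beta, mu, dev, converged


def fit_nb_glm(
    y: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray | None = None,
    dispersion: np.ndarray | float = 0.0,
) -> NBFit:
    """Fit NB-GLMs for one gene (1-D ``y``) or a block of genes (2-D).

    All genes share ``design`` (n x p, full rank) and ``offsets`` (n,);
    ``dispersion`` is a scalar or per-gene vector. Genes whose counts are
    all zero are returned flagged (``ok=False``) and skipped by testing.
    """
    y, squeeze = _as_gene_matrix(y)
    if np.any(~np.isfinite(y)) or np.any(y < 0):
        raise ValueError("counts must be finite and nonnegative")
    design = np.asarray(design, dtype=float)
    n = y.shape[1]
    if design.shape[0] != n:
        raise ValueError("design rows must match number of samples")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is not full rank")
    if offsets is None:
        offsets = np.zeros(n)
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (n,):
        raise ValueError("offsets must be one per sample")
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],)).copy()
    if np.any(phi < 0):
        raise ValueError("dispersion must be nonnegative")

    ok = y.sum(axis=1) > 0
    g, p = y.shape[0], design.shape[1]
    beta = np.full((g, p), np.nan)
    mu = np.full((g, n), np.nan)
    dev = np.full(g, np.nan)
    conv = np.zeros(g, dtype=bool)
    if np.any(ok):
        b, m, d, c = _irls(y[ok], design, offsets, phi[ok])
        beta[ok], mu[ok], dev[ok], conv[ok] = b, m, d, c
    fit = NBFit(
        beta=beta, mu=mu, dispersion=phi, deviance=dev, converged=conv, ok=ok,
        design=design, offsets=offsets, y=y,
    )
    return fit


def lrt_contrast(fit_full: NBFit, contrast: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio test of H0: c'beta = 0 against the full model.

    Returns (statistic, pvalue), each per gene; df = 1. Genes flagged not
    ok carry NaN.
    """
    c = np.asarray(contrast, dtype=float)
    p = fit_full.design.shape[1]
    if c.shape != (p,):
        raise ValueError(f"contrast must have length {p}")
    if np.all(c == 0):
        raise ValueError("contrast must be nonzero")
    nullspace = linalg.null_space(c[None, :])  # p x (p-1)
    reduced_design = fit_full.design @ nullspace
    g = fit_full.y.shape[0]
    stat = np.full(g, np.nan)
    pval = np.full(g, np.nan)
    ok = fit_full.ok
    if np.any(ok):
        red = fit_nb_glm(
            fit_full.y[ok], reduced_design, fit_full.offsets, fit_full.dispersion[ok]
        )
        s = np.maximum(red.deviance - fit_full.deviance[ok], 0.0)
        stat[ok] = s
        pval[ok] = stats.chi2.sf(s, df=1)
    return stat, pval


# ----------------------------------------------------------------------
# dispersion estimation


def adjusted_profile_loglik(
    phi: float,
    y: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray | None = None,
) -> np.ndarray:
    """Per-gene Cox-Reid adjusted profile log-likelihood at one phi.

    APL_g(phi) = ll_g(beta_hat(phi); phi) - 0.5 * log det(X' W X),
    the adjustment removing first-order bias from estimating beta.
    """
    fit = fit_nb_glm(y, design, offsets, dispersion=phi)
    yk = fit.y
    ll = np.where(
        fit.ok,
        nb_loglik(yk, np.where(fit.ok[:, None], fit.mu, 1.0), fit.dispersion[:, None]).sum(axis=1),
        np.nan,
    )
    w = np.where(fit.ok[:, None], fit.mu, 1.0)
    w = w / (1.0 + fit.dispersion[:, None] * w)
    xtwx = np.einsum("ni,gn,nj->gij", fit.design, w, fit.design)
    sign, logdet = np.linalg.slogdet(xtwx + 1e-12 * np.eye(fit.design.shape[1]))
    return np.where(fit.ok, ll - 0.5 * logdet, np.nan)


def estimate_dispersion(
    y: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray | None = None,
    method: str = "common",
    prior_df: float = 10.0,
    phi_bounds: tuple[float, float] = (1e-6, 10.0),
    grid_size: int = 21,
) -> float | np.ndarray:
    """Estimate NB dispersion over a design by Cox-Reid APL maximization.

    method "common" returns the single phi maximizing the summed APL of
    all (non-all-zero) genes; "tagwise" returns per-gene phi maximizing a
    weighted likelihood APL_g + (prior_df / residual_df) * mean-APL,
    shrinking gene-wise estimates toward the common value.
    """
    y2, _ = _as_gene_matrix(y)
    design = np.asarray(design, dtype=float)
    n, p = design.shape
    if n - p < 1:
        raise ValueError("at least one residual degree of freedom is required")
    expressed = y2.sum(axis=1) > 0
    if not np.any(expressed):
        raise ValueError("no expressed genes to estimate dispersion from")
    yk = y2[expressed]

    def neg_sum_apl(log_phi: float) -> float:
        apl = adjusted_profile_loglik(np.exp(log_phi), yk, design, offsets)
        return -np.nansum(apl)

    res = optimize.minimize_scalar(
        neg_sum_apl,
        bounds=(np.log(phi_bounds[0]), np.log(phi_bounds[1])),
        method="bounded",
        options={"xatol": 1e-4},
    )
    common = float(np.exp(res.x))
    if common <= phi_bounds[0] * 1.5:
        common_out = 0.0 if neg_sum_apl(np.log(phi_bounds[0])) <= res.fun + 1e-9 else common
    else:
        common_out = common
    if method == "common":
        return common_out

    if method != "tagwise":
        raise ValueError(f"unknown dispersion method {method!r}")
    center = max(common, 10 * phi_bounds[0])
    grid = np.exp(np.linspace(np.log(center / 16), np.log(center * 16), grid_size))
    apl = np.vstack([
        adjusted_profile_loglik(g_phi, yk, design, offsets) for g_phi in grid
    ])  # grid x genes
    prior_weight = prior_df / (n - p)
    objective = apl + prior_weight * np.nanmean(apl, axis=1, keepdims=True)
    best = np.argmax(objective, axis=0)
    # quadratic interpolation of the maximum on the log-phi grid
    log_grid = np.log(grid)
    phi_g = np.empty(yk.shape[0])
    for j, b in enumerate(best):
        if b == 0 or b == grid_size - 1:
            phi_g[j] = grid[b]
            continue
        x0, x1, x2 = log_grid[b - 1], log_grid[b], log_grid[b + 1]
        f0, f1, f2 = objective[b - 1, j], objective[b, j], objective[b + 1, j]
        denom = f0 - 2 * f1 + f2
        if denom >= -1e-12:
            phi_g[j] = grid[b]
        else:
            h = x1 - x0
            phi_g[j] = np.exp(x1 + 0.5 * h * (f0 - f2) / denom)
    out = np.full(y2.shape[0], common_out)
    out[expressed] = phi_g
    return out
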