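"""Generalized linear mixed models with a single (donor) random intercept.

The fitter is batched: many features (genes, peaks, or cluster-membership
indicators) sharing one design matrix are fitted simultaneously with
vectorized penalized iteratively reweighted least squares (PIRLS). The
random-intercept variance is updated by an EM-type fixed-point step and the
negative-binomial dispersion by per-feature Newton steps on the profile
likelihood. Wald tests use the fixed-effect block of the joint (beta, u)
information matrix with a t reference whose degrees of freedom equal the
number of donors minus the number of fixed effects (the donor level is
where the diagnosis contrast lives, so it sets the effective sample size);
likelihood-ratio tests evaluate the Laplace-approximated marginal
likelihood at the converged fit.

Families: ``"nb"`` (negative binomial, log link, NB2 parameterization
Var = mu + phi * mu^2) and ``"binomial"`` (logit link, Bernoulli).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

PHI_MIN = 1e-4
PHI_MAX = 1e4
SIGMA2_MIN = 1e-8
MU_EPS = 1e-10


@dataclass
class GlmmFit:
    """Batched fit result; arrays are indexed by feature."""

    beta: np.ndarray            # (G, p) fixed-effect coefficients
    se: np.ndarray              # (G, p) Wald standard errors
    wald_p: np.ndarray          # (G, p) two-sided Wald p-values (t reference)
    sigma2: np.ndarray          # (G,) donor random-intercept variance
    phi: np.ndarray             # (G,) NB dispersion (NaN for binomial)
    u: np.ndarray               # (G, D) posterior-mode donor intercepts
    converged: np.ndarray       # (G,) bool
    loglik: np.ndarray          # (G,) Laplace marginal log-likelihood
    df: int = 0                 # t degrees of freedom used for Wald p
    columns: list = field(default_factory=list)


def _nb_loglik(Y, mu, phi):
    """NB2 log-likelihood, summed over cells. Y, mu: (G, n); phi: (G, 1)."""
    a = 1.0 / phi
    return np.sum(
        special.gammaln(Y + a) - special.gammaln(a) - special.gammaln(Y + 1.0)
        + a * np.log(a / (a + mu))
        + Y * np.log(np.maximum(mu, MU_EPS) / (a + mu)),
        axis=1,
    )


def _nb_dispersion_newton(Y, mu, log_a, n_steps=2):
    """Newton steps on t = log(1/phi) for the NB profile likelihood."""
    for _ in range(n_steps):
        a = np.exp(log_a)[:, None]
        am = a + mu
        grad_a = np.sum(
            special.digamma(Y + a) - special.digamma(a)
            + np.log(a / am) + 1.0 - (a + Y) / am,
            axis=1,
        )
        curv_a = np.sum(
            special.polygamma(1, Y + a) - special.polygamma(1, a)
            + 1.0 / a - 2.0 / am + (a + Y) / am**2,
            axis=1,
        )
        a1 = a[:, 0]
        g_t = a1 * grad_a
        h_t = a1 * grad_a + a1**2 * curv_a
        step = np.where(h_t < 0, -g_t / np.minimum(h_t, -1e-8), np.sign(g_t) * 0.5)
        log_a = np.clip(log_a + np.clip(step, -2.0, 2.0),
                        np.log(1.0 / PHI_MAX), np.log(1.0 / PHI_MIN))
    return log_a


def _phi_moment_init(Y, offset):
    """Method-of-moments NB dispersion from depth-adjusted counts.

    The offset is centered first so the init (and hence the whole iteration
    path) is invariant to a constant depth shift."""
    r = Y / np.exp(offset - offset.mean())[None, :]
    m = np.maximum(r.mean(axis=1), 1e-8)
    v = r.var(axis=1)
    phi = (v - m) / m**2
    return np.clip(np.nan_to_num(phi, nan=1.0), 0.01, 100.0)


def fit_glmm(
    Y: np.ndarray,
    X: np.ndarray,
    donor_idx: np.ndarray,
    offset: np.ndarray | None = None,
    family: str = "nb",
    max_iter: int = 50,
    tol: float = 1e-4,
    columns: list | None = None,
) -> GlmmFit:
    """Fit per-feature GLMMs with one random intercept, batched over rows of Y.

    Parameters
    ----------
    Y : (G, n) response matrix (counts for NB, 0/1 for binomial).
    X : (n, p) fixed-effect design including the intercept column.
    donor_idx : (n,) grouping labels (any hashable dtype).
    offset : (n,) linear-predictor offset (log relative depth for NB).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)

    donors, d_idx = np.unique(np.asarray(donor_idx), return_inverse=True)
    D = len(donors)
    # sort cells by donor so per-donor sums are contiguous segment reductions
    order = np.argsort(d_idx, kind="stable")
    Y = np.ascontiguousarray(Y[:, order])
    X = np.ascontiguousarray(X[order])
    offset = offset[order]
    d_sorted = d_idx[order]
    starts = np.searchsorted(d_sorted, np.arange(D))

    def seg(a):  # (G, n) -> (G, D) per-donor sums
        return np.add.reduceat(a, starts, axis=1)

    beta = np.zeros((G, p))
    if family == "nb":
        base = np.maximum(Y.mean(axis=1) / np.mean(np.exp(offset)), 1e-8)
        beta[:, 0] = np.log(base)
        phi = _phi_moment_init(Y, offset)
        log_a = np.log(1.0 / phi)
    elif family == "binomial":
        pbar = np.clip(Y.mean(axis=1), 1e-4, 1 - 1e-4)
        beta[:, 0] = np.log(pbar / (1 - pbar))
        phi = np.full(G, np.nan)
        log_a = None
    else:
        raise ValueError(f"unknown family {family!r}")
    sigma2 = np.full(G, 0.1)
    u = np.zeros((G, D))
    delta = np.full(G, np.inf)
    Xt = X.T.copy()

    def pirls_step(beta, u, sigma2, phi):
        eta = beta @ Xt + u[:, d_sorted]
        eta += offset[None, :]
        np.clip(eta, -30.0, 30.0, out=eta)
        if family == "nb":
            mu = np.exp(eta)
            w = mu / (1.0 + phi[:, None] * mu)
            z = (eta - offset[None, :]) + (Y - mu) / np.maximum(mu, MU_EPS)
        else:
            mu = special.expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-6, None)
            z = (eta - offset[None, :]) + (Y - mu) / w
        wz = w * z
        A_xx = np.empty((G, p, p))
        A_xz = np.empty((G, p, D))
        for j in range(p):
            wxj = w * Xt[j]
            A_xz[:, j, :] = seg(wxj)
            for k in range(j, p):
                A_xx[:, j, k] = A_xx[:, k, j] = wxj @ X[:, k]
        A_zz = seg(w)
        r_x = wz @ X
        r_z = seg(wz)
        dinv = 1.0 / (A_zz + 1.0 / sigma2[:, None])
        Ad = A_xz * dinv[:, None, :]
        S_b = A_xx - Ad @ A_xz.transpose(0, 2, 1) + 1e-10 * np.eye(p)[None]
        rhs = r_x - np.einsum("gpd,gd->gp", Ad, r_z)
        beta_new = np.linalg.solve(S_b, rhs[:, :, None])[:, :, 0]
        u_new = dinv * (r_z - np.einsum("gpd,gp->gd", A_xz, beta_new))
        return beta_new, u_new, dinv, A_zz, S_b

    for it in range(max_iter):
        beta_new, u_new, dinv, A_zz, _ = pirls_step(beta, u, sigma2, phi)
        delta = np.max(np.abs(beta_new - beta), axis=1)
        beta, u = beta_new, u_new
        # EM-type variance update with conditional-variance correction
        sigma2 = np.maximum(np.mean(u**2 + dinv, axis=1), SIGMA2_MIN)
        if family == "nb" and it % 2 == 1 and it < max_iter - 6:
            eta = np.clip(beta @ Xt + u[:, d_sorted] + offset[None, :], -30, 30)
            log_a = _nb_dispersion_newton(Y, np.exp(eta), log_a)
            phi = np.clip(1.0 / np.exp(log_a), PHI_MIN, PHI_MAX)
        if np.max(delta) < tol and it >= 6:
            break
    # stabilization sweeps with variance/dispersion frozen
    for _ in range(3):
        beta_new, u_new, dinv, A_zz, S_b = pirls_step(beta, u, sigma2, phi)
        delta = np.max(np.abs(beta_new - beta), axis=1)
        beta, u = beta_new, u_new
    converged = delta < 10 * tol

    cov_beta = np.linalg.inv(S_b)
    se = np.sqrt(np.clip(np.einsum("gpp->gp", cov_beta), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    df = max(D - p, 1)
    wald_p = 2.0 * stats.t.sf(np.abs(tstat), df)

    eta = np.clip(beta @ Xt + u[:, d_sorted] + offset[None, :], -30, 30)
    if family == "nb":
        data_ll = _nb_loglik(Y, np.exp(eta), phi[:, None])
    else:
        mu = special.expit(eta)
        data_ll = np.sum(
            Y * np.log(np.clip(mu, 1e-12, None))
            + (1 - Y) * np.log(np.clip(1 - mu, 1e-12, None)),
            axis=1,
        )
    loglik = (
        data_ll
        - 0.5 * np.sum(u**2, axis=1) / sigma2
        - 0.5 * np.sum(np.log1p(sigma2[:, None] * A_zz), axis=1)
    )

    return GlmmFit(
        beta=beta, se=se, wald_p=wald_p, sigma2=sigma2, phi=phi, u=u,
        converged=converged, loglik=loglik, df=df,
        columns=list(columns) if columns is not None else [],
    )


def lrt_pvalue(full: GlmmFit, reduced: GlmmFit, df: int = 1) -> np.ndarray:
    """Likelihood-ratio p-values from Laplace marginal log-likelihoods."""
    lr = 2.0 * (full.loglik - reduced.loglik)
    return stats.chi2.sf(np.maximum(lr, 0.0), df)
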