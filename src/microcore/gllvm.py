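"""Generalised linear latent variable models for taxon count matrices.

Each taxon j gets a log-link count GLM whose linear predictor combines
observed covariates and a shared low-dimensional latent score per sample:

    g(mu_ij) = eta_ij = beta_0j + x_i' beta_j + u_i' theta_j

with u_i ~ N(0, I_d) capturing unmeasured sample-level covariation
(sequencing batch, micro-environment) that would otherwise inflate
apparent taxon-covariate associations.  Estimation alternates penalised
per-taxon GLM fits (our own iteratively reweighted least squares, Poisson
or negative-binomial with per-taxon moment-estimated dispersion) with
Newton updates of the latent scores under their standard-normal prior —
a joint-mode (penalised quasi-likelihood) scheme.  Standard errors are
conditional on the estimated latent scores.

With ``n_latent = 0`` the model collapses exactly to independent
per-taxon GLMs, which provides an external correctness oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import CountTable
from .design import build_design

logger = logging.getLogger(__name__)

__all__ = ["build_design", "fit_gllvm", "directional_associations", "GllvmFit"]

_ETA_CLIP = 30.0


def _irls(
    y: np.ndarray,
    x: np.ndarray,
    alpha: float | np.ndarray = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
    offset: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Log-link count GLM by iteratively reweighted least squares.

    ``alpha`` is the negative-binomial dispersion (variance mu + alpha
    mu^2), scalar or per-observation; zero gives Poisson.  Returns
    (coefficients, covariance, converged); covariance is the inverse
    Fisher information.
    """
    n, k = x.shape
    if offset is None:
        offset = np.zeros(n)
    # initialise from log of smoothed response
    beta = np.linalg.lstsq(x, np.log(y + 0.5) - offset, rcond=None)[0]
    ridge = 1e-10 * np.eye(k)
    for _ in range(max_iter):
        eta = np.clip(x @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.maximum(np.exp(eta), 1e-10)
        w = mu / (1.0 + alpha * mu)
        z = eta - offset + (y - mu) / mu
        xw = x * w[:, None]
        xtwx = x.T @ xw + ridge
        try:
            beta_new = np.linalg.solve(xtwx, xw.T @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(xtwx, xw.T @ z, rcond=None)[0]
        delta = beta_new - beta
        step = np.max(np.abs(delta))
        if step > 10.0:  # damp: separation can explode the working response
            delta *= 10.0 / step
        beta = beta + delta
        if step < tol:
            converged = True
            break
    else:
        converged = False
    eta = np.clip(x @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    xtwx = x.T @ (x * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(xtwx)
    return beta, cov, converged


def _moment_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion: solve sum((y-mu)^2 - mu) = alpha sum(mu^2)."""
    denom = np.sum(mu**2)
    if denom <= 0:
        return 0.0
    return float(max(0.0, np.sum((y - mu) ** 2 - mu) / denom))


def _ml_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile maximum-likelihood NB dispersion given fitted means.

    The moment estimator is biased low when the means vary widely (it is
    dominated by high-mean observations), which deflates Wald standard
    errors; the profile MLE does not share that bias.
    """
    mu = np.maximum(mu, 1e-12)

    def nll(log_a: float) -> float:
        r = np.exp(-log_a)  # size parameter 1/alpha
        return -float(
            np.sum(
                special.gammaln(y + r)
                - special.gammaln(r)
                + r * np.log(r / (r + mu))
                + y * np.log(mu / (r + mu))
            )
        )

    res = optimize.minimize_scalar(nll, bounds=(np.log(1e-4), np.log(1e2)), method="bounded")
    alpha = float(np.exp(res.x))
    # a near-boundary solution means the data are effectively Poisson
    return 0.0 if alpha <= 1.2e-4 else alpha


@dataclass
class GllvmFit:
    """Fitted latent-variable count model."""

    coefficients: pd.DataFrame  # taxa x design columns (incl. intercept)
    std_errors: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    loadings: pd.DataFrame  # taxa x latent dims
    scores: pd.DataFrame  # samples x latent dims
    dispersion: pd.Series  # per-taxon NB dispersion (0 for Poisson)
    family: str
    n_latent: int
    converged: bool
    n_iter: int
    seed: int
    ci_level: float = 0.95
    excluded_taxa: list[str] = field(default_factory=list)

    def coefficient_table(self) -> pd.DataFrame:
        """Long-format per-taxon, per-covariate coefficient summary."""
        rows = []
        for taxon in self.coefficients.index:
            for col in self.coefficients.columns:
                rows.append(
                    {
                        "taxon": taxon,
                        "covariate": col,
                        "estimate": self.coefficients.at[taxon, col],
                        "se": self.std_errors.at[taxon, col],
                        "ci_low": self.ci_low.at[taxon, col],
                        "ci_high": self.ci_high.at[taxon, col],
                    }
                )
        return pd.DataFrame(rows)


def fit_gllvm(
    table: CountTable,
    design: pd.DataFrame,
    family: str = "nb",
    n_latent: int = 2,
    seed: int = 0,
    max_iter: int = 30,
    tol: float = 1e-4,
    max_zero_fraction: float = 0.95,
    ci_level: float = 0.95,
) -> GllvmFit:
    """Fit the latent-variable count model by alternating optimisation.

    Parameters
    ----------
    table
        OTU x sample counts (the response).
    design
        Sample x covariate model matrix from :func:`build_design`
        (without intercept; one is added internally).
    family
        ``"nb"`` (negative binomial, default) or ``"poisson"``.
    n_latent
        Latent dimension d; ``0`` reduces to independent per-taxon GLMs.
    max_zero_fraction
        Taxa with a higher fraction of zero counts are excluded (too
        sparse to stabilise a per-taxon GLM) with a warning.
    """
    if family not in ("nb", "poisson"):
        raise ValueError(f"unknown family {family!r}")
    if list(design.index) != table.sample_ids:
        design = design.loc[table.sample_ids]
    n = table.n_samples
    x = np.hstack([np.ones((n, 1)), design.to_numpy(dtype=float)])
    col_names = ["(Intercept)"] + list(design.columns)
    k = x.shape[1]
    if n_latent >= n:
        raise ValueError("latent dimension must be smaller than the number of samples")
    if n <= k + n_latent:
        raise ValueError(
            f"need more samples ({n}) than design columns + latent dims ({k + n_latent})"
        )

    y_all = table.counts.T.astype(float)  # samples x taxa
    zero_frac = (y_all == 0).mean(axis=0)
    keep = zero_frac <= max_zero_fraction
    excluded = [t for t, k_ in zip(table.otu_ids, keep) if not k_]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} taxa with > {max_zero_fraction:.0%} zeros",
            stacklevel=2,
        )
    taxa = [t for t, k_ in zip(table.otu_ids, keep) if k_]
    y = y_all[:, keep]
    p = y.shape[1]

    rng = np.random.default_rng(seed)
    alphas = np.zeros(p)
    is_nb = family == "nb"

    def fit_taxa(
        x_aug: np.ndarray, update_alpha: bool
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        betas = np.zeros((p, x_aug.shape[1]))
        covs = np.zeros((p, x_aug.shape[1], x_aug.shape[1]))
        ok = np.ones(p, dtype=bool)
        for j in range(p):
            b, c, conv = _irls(y[:, j], x_aug, alpha=alphas[j])
            betas[j], covs[j], ok[j] = b, c, conv
            if is_nb and update_alpha:
                mu = np.exp(np.clip(x_aug @ b, -_ETA_CLIP, _ETA_CLIP))
                alphas[j] = _moment_dispersion(y[:, j], mu)
        return betas, covs, ok

    def newton_scores(
        u0: np.ndarray,
        theta_m: np.ndarray,
        alpha_m: np.ndarray,
        fixed_m: np.ndarray,
        y_m: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Mode of the latent scores under the N(0, I) prior; returns
        (scores, per-sample inverse Hessians = score covariances)."""
        u_cur = u0.copy()
        d = u_cur.shape[1]
        hess = np.broadcast_to(np.eye(d), (u_cur.shape[0], d, d)).copy()
        for _ in range(50):
            eta_m = np.clip(fixed_m + u_cur @ theta_m.T, -_ETA_CLIP, _ETA_CLIP)
            mu_m = np.exp(eta_m)
            grad = ((y_m - mu_m) / (1.0 + alpha_m * mu_m)) @ theta_m - u_cur
            w_m = mu_m / (1.0 + alpha_m * mu_m)
            hess = np.einsum("ij,jk,jl->ikl", w_m, theta_m, theta_m)
            hess += np.eye(d)[None, :, :]
            bad = ~np.isfinite(hess).all(axis=(1, 2)) | ~np.isfinite(grad).all(axis=1)
            if bad.any():  # defensive: freeze pathological samples this step
                hess[bad] = np.eye(d)
                grad[bad] = 0.0
            delta = np.linalg.solve(hess, grad[:, :, None])[:, :, 0]
            # damp large steps to keep eta in range
            scale = np.maximum(1.0, np.abs(delta).max(axis=1, keepdims=True) / 4.0)
            u_cur = u_cur + delta / scale
            if np.max(np.abs(delta)) < 1e-9:
                break
        return u_cur, np.linalg.inv(hess)

    def penalized_loglik(u_cur: np.ndarray, betas: np.ndarray) -> float:
        eta = np.clip(
            np.hstack([x, u_cur]) @ betas.T, -_ETA_CLIP, _ETA_CLIP
        )
        mu = np.exp(eta)
        if is_nb:
            a = np.maximum(alphas, 1e-10)
            r = 1.0 / a
            ll = np.sum(
                special.gammaln(y + r)
                - special.gammaln(r)
                + r * np.log(r / (r + mu))
                + y * np.log(np.maximum(mu, 1e-300) / (r + mu))
            )
        else:
            ll = np.sum(y * eta - mu)
        return float(ll - 0.5 * np.sum(u_cur**2))

    if n_latent == 0:
        betas, covs, ok = fit_taxa(x, update_alpha=is_nb)
        if is_nb:  # ML dispersion, then one refit for final inference
            for j in range(p):
                mu = np.exp(np.clip(x @ betas[j], -_ETA_CLIP, _ETA_CLIP))
                alphas[j] = _ml_dispersion(y[:, j], mu)
            betas, covs, ok = fit_taxa(x, update_alpha=False)
        u = np.zeros((n, 0))
        theta = np.zeros((p, 0))
        converged, n_iter = bool(ok.all()), 1
        se = np.sqrt(np.maximum(np.einsum("jkk->jk", covs), 0.0))[:, :k]
    else:
        # initialise scores from Pearson residuals of the covariate-only fit
        betas, covs, ok = fit_taxa(x, update_alpha=is_nb)
        eta0 = np.clip(x @ betas.T, -_ETA_CLIP, _ETA_CLIP)
        mu0 = np.exp(eta0)
        resid = (y - mu0) / np.sqrt(mu0 + alphas * mu0**2 + 1e-12)
        uu, _, _ = np.linalg.svd(resid, full_matrices=False)
        u = uu[:, :n_latent] * np.sqrt(n)
        u += 0.01 * rng.standard_normal(u.shape)

        # block-coordinate ascent; dispersions are re-estimated only during
        # the first sweeps, then frozen so the objective is fixed and the
        # penalised log-likelihood convergence test is meaningful.  Scores
        # are kept orthogonal to the design span during estimation
        # (identifiability); the inference pass below re-estimates them
        # without that restriction.
        qx, _ = np.linalg.qr(x)
        freeze_after = 3
        converged = False
        n_iter = 0
        prev_ll = -np.inf
        theta = np.zeros((p, n_latent))
        u = u - qx @ (qx.T @ u)
        for it in range(max_iter):
            n_iter = it + 1
            x_aug = np.hstack([x, u])
            betas, covs, ok = fit_taxa(x_aug, update_alpha=is_nb and it < freeze_after)
            theta = betas[:, k:]
            fixed = x @ betas[:, :k].T  # samples x taxa
            u, _ = newton_scores(u, theta, alphas, fixed, y)
            u = u - qx @ (qx.T @ u)
            ll = penalized_loglik(u, betas)
            if it >= freeze_after and abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
                converged = True
                break
            prev_ll = ll

        # rotate to the identifiable form: upper-triangular-zero loadings
        # with positive diagonal (orthogonal rotation leaves the N(0,I)
        # prior and the fitted predictor unchanged)
        if n_latent > 1 and p >= n_latent:
            q, r = np.linalg.qr(theta[:n_latent].T)
            signs = np.sign(np.diag(r))
            signs[signs == 0] = 1.0
            q = q * signs
            theta = theta @ q
            u = u @ q
        elif n_latent == 1:
            sign = np.sign(theta[0, 0]) or 1.0
            theta *= sign
            u *= sign
        if not converged:
            logger.warning("GLLVM did not converge in %d iterations", max_iter)

        # Inference pass with cross-fitted scores: taxon j's scores are
        # re-estimated from the other taxa only, so its own noise cannot
        # leak into them, then re-projected off the design span.  Three
        # variance components supplement the conditional Fisher
        # information: (i) score-estimation uncertainty theta' Sigma_i
        # theta as extra per-sample dispersion, (ii) the marginal
        # random-effect variance of the *in-span* latent realisation
        # (formally unidentifiable from covariate effects per taxon, so it
        # must be priced into the coefficient SEs), and (iii) a Pearson
        # factor guarding residual overdispersion.  Dispersion is profiled
        # by ML at this stage.
        est_b = np.zeros((p, k))
        se = np.zeros((p, k))
        theta_out = np.zeros((p, n_latent))
        ok = np.ones(p, dtype=bool)
        fixed_all = x @ betas[:, :k].T
        for j in range(p):
            if p > 1:
                mask = np.ones(p, dtype=bool)
                mask[j] = False
                u_j, sig_j = newton_scores(
                    u, theta[mask], alphas[mask], fixed_all[:, mask], y[:, mask]
                )
            else:
                u_j, sig_j = u, np.zeros((n, n_latent, n_latent))
            u_j = u_j - qx @ (qx.T @ u_j)
            x_aug = np.hstack([x, u_j])
            b, c, conv = _irls(y[:, j], x_aug, alpha=alphas[j])
            mu = np.exp(np.clip(x_aug @ b, -_ETA_CLIP, _ETA_CLIP))
            th_j = b[k:]
            vu = np.einsum("m,iml,l->i", th_j, sig_j, th_j)
            a_j = _ml_dispersion(y[:, j], mu) if is_nb else 0.0
            alphas[j] = a_j
            b, c, conv = _irls(y[:, j], x_aug, alpha=a_j + vu)
            mu = np.exp(np.clip(x_aug @ b, -_ETA_CLIP, _ETA_CLIP))
            th_j = b[k:]
            w_j = mu / (1.0 + (a_j + vu) * mu)
            a_mat = x_aug.T @ (x_aug * w_j[:, None])
            try:
                a_inv = np.linalg.inv(a_mat)
            except np.linalg.LinAlgError:
                a_inv = np.linalg.pinv(a_mat)
            m_mat = qx.T @ (x_aug * w_j[:, None])
            v_extra = float(th_j @ th_j) * (a_inv @ (m_mat.T @ m_mat) @ a_inv)
            var = mu + (a_j + vu) * mu**2
            df = n - x_aug.shape[1]
            phi = max(1.0, float(np.sum((y[:, j] - mu) ** 2 / var)) / max(df, 1))
            cov_full = c * phi + v_extra
            est_b[j] = b[:k]
            se[j] = np.sqrt(np.maximum(np.diag(cov_full)[:k], 0.0))
            theta_out[j] = th_j
            ok[j] = conv
        betas = np.hstack([est_b, theta_out])
        # keep the estimation-stage loadings: they carry the identifiability
        # structure (upper-triangular zeros, positive diagonal)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    est = betas[:, :k]
    latent_cols = [f"LV{j + 1}" for j in range(n_latent)]
    fit = GllvmFit(
        coefficients=pd.DataFrame(est, index=taxa, columns=col_names),
        std_errors=pd.DataFrame(se, index=taxa, columns=col_names),
        ci_low=pd.DataFrame(est - z * se, index=taxa, columns=col_names),
        ci_high=pd.DataFrame(est + z * se, index=taxa, columns=col_names),
        loadings=pd.DataFrame(theta, index=taxa, columns=latent_cols),
        scores=pd.DataFrame(u, index=table.sample_ids, columns=latent_cols),
        dispersion=pd.Series(alphas if family == "nb" else np.zeros(p), index=taxa),
        family=family,
        n_latent=n_latent,
        converged=converged,
        n_iter=n_iter,
        seed=seed,
        ci_level=ci_level,
        excluded_taxa=excluded,
    )
    return fit


def directional_associations(fit: GllvmFit, level: float = 0.95) -> pd.DataFrame:
    """Classify each taxon-covariate coefficient by its confidence interval.

    ``positive`` if the CI lies entirely above zero, ``negative`` if
    entirely below, else ``none``.  ``level`` may differ from the fit's
    stored level; intervals are recomputed from the standard errors.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = fit.coefficients - z * fit.std_errors
    hi = fit.coefficients + z * fit.std_errors
    out = pd.DataFrame("none", index=fit.coefficients.index, columns=fit.coefficients.columns)
    out = out.mask(lo > 0, "positive").mask(hi < 0, "negative")
    return out.drop(columns=["(Intercept)"], errors="ignore")
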