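"""Sparse log-contrast regression with a zero-sum coefficient constraint.

A compositional (CODA) regression links a response — a continuous soil
property or a binary management split — to log-transformed taxon
proportions with coefficients constrained to sum to zero, so only
log-*ratios* of taxa matter and predictions are invariant to per-sample
rescaling of counts.  Sparsity comes from an elastic-net penalty
(LASSO + ridge); the solver is pairwise coordinate descent, which moves
coefficient mass between pairs of taxa and therefore preserves the
zero-sum constraint exactly at every step.  The penalty weight is chosen
by seeded k-fold cross-validation at the minimum mean validation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountTable

__all__ = ["fit_coda_lasso", "predict_coda", "CodaLassoFit"]


def _log_features(table: CountTable, pseudocount: float) -> np.ndarray:
    """Samples x taxa matrix of log(TSS proportion + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = table.counts.astype(float)
    sizes = x.sum(axis=0)
    if np.any(sizes == 0):
        raise ValueError("all-zero sample; log-contrast features undefined")
    return np.log(x / sizes + pseudocount).T


def _sweep_kernel(
    gram: np.ndarray,
    diag: np.ndarray,
    c: np.ndarray,
    beta: np.ndarray,
    zsum: np.ndarray,
    wsum: float,
    ysum: float,
    beta0: float,
    n: int,
    lam_l1: float,
    lam_l2: float,
    max_sweeps: int,
    tol: float,
) -> float:
    """Pairwise coordinate-descent sweeps on the Gram system (in place).

    Each pair update moves mass t from taxon k to taxon j — the exact
    minimiser of 0.5*A*t^2 - B*t + lam_l1*(|b_j + t| + |b_k - t|), a
    piecewise quadratic with breakpoints at -b_j and b_k — so sum(beta)
    is invariant.  Returns the updated intercept.
    """
    p = beta.shape[0]
    for _ in range(max_sweeps):
        # intercept (unpenalised)
        num = ysum - beta0 * wsum
        for m in range(p):
            num -= zsum[m] * beta[m]
        shift = num / wsum
        beta0 += shift
        for m in range(p):
            c[m] -= shift * zsum[m]
        max_step = abs(shift)
        for j in range(p - 1):
            for k in range(j + 1, p):
                a = (diag[j] + diag[k] - 2.0 * gram[j, k]) / n + 2.0 * lam_l2
                if a <= 0.0:
                    continue
                b = (c[j] - c[k]) / n - lam_l2 * (beta[j] - beta[k])
                bj = beta[j]
                bk = beta[k]
                best_t = 0.0
                best_obj = lam_l1 * (abs(bj) + abs(bk))
                for s1 in (-1.0, 1.0):
                    for s2 in (-1.0, 1.0):
                        t = (b - lam_l1 * (s1 - s2)) / a
                        if s1 * (bj + t) >= 0.0 and s2 * (bk - t) >= 0.0:
                            obj = 0.5 * a * t * t - b * t + lam_l1 * (abs(bj + t) + abs(bk - t))
                            if obj < best_obj - 1e-15:
                                best_obj = obj
                                best_t = t
                for t in (-bj, bk):
                    obj = 0.5 * a * t * t - b * t + lam_l1 * (abs(bj + t) + abs(bk - t))
                    if obj < best_obj - 1e-15:
                        best_obj = obj
                        best_t = t
                if best_t != 0.0:
                    beta[j] += best_t
                    beta[k] -= best_t
                    for m in range(p):
                        c[m] -= best_t * (gram[j, m] - gram[k, m])
                    if abs(best_t) > max_step:
                        max_step = abs(best_t)
        if max_step < tol:
            break
    return beta0


try:  # JIT the sweep loop when numba is present; the pure-Python path is identical
    from numba import njit as _njit

    _sweep_kernel = _njit(cache=False)(_sweep_kernel)  # type: ignore[assignment]
except ImportError:  # pragma: no cover
    pass


def _zero_sum_enet(
    z: np.ndarray,
    y: np.ndarray,
    lam: float,
    mixing: float,
    weights: np.ndarray | None = None,
    beta0: float = 0.0,
    beta: np.ndarray | None = None,
    max_sweeps: int = 1000,
    tol: float = 1e-7,
) -> tuple[float, np.ndarray]:
    """Weighted-least-squares elastic net under the zero-sum constraint.

    Pairwise coordinate descent: each update shifts mass t from taxon k to
    taxon j, leaving sum(beta) unchanged (it starts, and stays, at 0).
    All inner products are maintained on the Gram matrix, so one pair
    update costs O(p) regardless of sample size.
    """
    n, p = z.shape
    w = np.ones(n) if weights is None else weights
    beta = np.zeros(p) if beta is None else beta.copy()
    lam_l1 = lam * mixing
    lam_l2 = lam * (1.0 - mixing)
    wsum = float(w.sum())

    zw = z * w[:, None]
    gram = np.ascontiguousarray(zw.T @ z)  # Z' W Z
    zsum = zw.sum(axis=0)  # Z' W 1
    # c[m] = z_m' W r  with  r = y - beta0 - Z beta
    c = zw.T @ y - beta0 * zsum - gram @ beta
    ysum = float((w * y).sum())
    diag = np.ascontiguousarray(np.diag(gram))

    beta0 = _sweep_kernel(
        gram, diag, c, beta, zsum, wsum, ysum, float(beta0),
        n, lam_l1, lam_l2, max_sweeps, tol,
    )
    # snap numerically-dead coefficients to exact zero
    beta[np.abs(beta) < 1e-12] = 0.0
    return float(beta0), beta


def _fit_path_gaussian(
    z: np.ndarray, y: np.ndarray, lambdas: np.ndarray, mixing: float
) -> list[tuple[float, np.ndarray]]:
    fits = []
    beta0, beta = float(y.mean()), np.zeros(z.shape[1])
    for lam in lambdas:
        beta0, beta = _zero_sum_enet(z, y, lam, mixing, beta0=beta0, beta=beta)
        fits.append((beta0, beta.copy()))
    return fits


def _relaxed_gaussian(
    z: np.ndarray, y: np.ndarray, support: np.ndarray
) -> tuple[float, np.ndarray]:
    """Unpenalised least squares on a support, subject to sum(beta) = 0.

    Solved through the KKT system of the equality-constrained problem;
    removes the L1 shrinkage bias so that the penalty only selects the
    support (relaxed / debiased fit).
    """
    s = np.where(support)[0]
    p = z.shape[1]
    if len(s) == 0:
        return float(y.mean()), np.zeros(p)
    zs = z[:, s]
    n, q = zs.shape
    x = np.column_stack([np.ones(n), zs])
    kkt = np.zeros((q + 2, q + 2))
    kkt[: q + 1, : q + 1] = x.T @ x
    kkt[1 : q + 1, q + 1] = 1.0
    kkt[q + 1, 1 : q + 1] = 1.0
    rhs = np.zeros(q + 2)
    rhs[: q + 1] = x.T @ y
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    beta = np.zeros(p)
    beta[s] = sol[1 : q + 1]
    beta[s] -= beta[s].sum() / max(q, 1)  # exact zero-sum despite round-off
    return float(sol[0]), beta


def _relaxed_logistic(
    z: np.ndarray, y: np.ndarray, support: np.ndarray, max_iter: int = 50
) -> tuple[float, np.ndarray]:
    """Unpenalised logistic fit on a support with sum(beta) = 0 (IRLS + KKT)."""
    s = np.where(support)[0]
    p = z.shape[1]
    pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    beta0 = float(np.log(pbar / (1 - pbar)))
    if len(s) == 0:
        return beta0, np.zeros(p)
    zs = z[:, s]
    n, q = zs.shape
    x = np.column_stack([np.ones(n), zs])
    coef = np.zeros(q + 1)
    coef[0] = beta0
    for _ in range(max_iter):
        eta = np.clip(x @ coef, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-6)
        work = eta + (y - mu) / w
        xw = x * w[:, None]
        kkt = np.zeros((q + 2, q + 2))
        kkt[: q + 1, : q + 1] = x.T @ xw
        kkt[1 : q + 1, q + 1] = 1.0
        kkt[q + 1, 1 : q + 1] = 1.0
        rhs = np.zeros(q + 2)
        rhs[: q + 1] = xw.T @ work
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        new = sol[: q + 1]
        step = np.max(np.abs(new - coef))
        coef = new
        if step < 1e-8:
            break
    beta = np.zeros(p)
    beta[s] = coef[1:]
    beta[s] -= beta[s].sum() / max(q, 1)
    return float(coef[0]), beta


def _fit_logistic(
    z: np.ndarray,
    y: np.ndarray,
    lam: float,
    mixing: float,
    beta0: float,
    beta: np.ndarray,
    max_outer: int = 25,
    tol: float = 1e-6,
) -> tuple[float, np.ndarray]:
    """Penalised logistic regression by IRLS around the zero-sum ENet solver."""
    for _ in range(max_outer):
        eta = np.clip(beta0 + z @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-5)
        work = eta + (y - mu) / w
        b0_new, b_new = _zero_sum_enet(
            z, work, lam, mixing, weights=w, beta0=beta0, beta=beta
        )
        step = max(abs(b0_new - beta0), float(np.max(np.abs(b_new - beta))))
        beta0, beta = b0_new, b_new
        if step < tol:
            break
    return beta0, beta


def _loss(y: np.ndarray, pred: np.ndarray, loss: str) -> float:
    if loss == "gaussian":
        return float(np.mean((y - pred) ** 2))
    p = np.clip(1.0 / (1.0 + np.exp(-pred)), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class CodaLassoFit:
    """Zero-sum sparse log-contrast model at the CV-chosen penalty."""

    response_name: str
    loss: str  # "gaussian" or "logistic"
    intercept: float
    coefficients: pd.Series  # per-taxon, sums to zero
    mixing: float
    pseudocount: float
    lambda_path: np.ndarray
    lambda_chosen: float
    cv_errors: pd.DataFrame  # columns: lambda, mean_error, se_error
    seed: int
    relaxed: bool = True
    path_coefficients: np.ndarray | None = None  # penalised betas, path x taxa

    @property
    def selected(self) -> dict[str, list[str]]:
        """Nonzero-coefficient taxa split by sign of association."""
        nz = self.coefficients[self.coefficients != 0]
        return {
            "positive": list(nz[nz > 0].index),
            "negative": list(nz[nz < 0].index),
        }

    def predict(self, table: CountTable) -> pd.Series:
        return predict_coda(self, table)


def _path_fits(
    z: np.ndarray, y: np.ndarray, lambdas: np.ndarray, mixing: float, loss: str
) -> list[tuple[float, np.ndarray]]:
    if loss == "gaussian":
        return _fit_path_gaussian(z, y, lambdas, mixing)
    pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
    b0, b = float(np.log(pbar / (1 - pbar))), np.zeros(z.shape[1])
    fits = []
    for lam in lambdas:
        b0, b = _fit_logistic(z, y, lam, mixing, b0, b)
        fits.append((b0, b.copy()))
    return fits


def fit_coda_lasso(
    table: CountTable,
    y,
    response_name: str = "response",
    mixing: float = 1.0,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 30,
    cv_folds: int = 5,
    pseudocount: float = 1e-6,
    seed: int = 0,
    relax: bool = True,
    lambda_rule: str = "1se",
) -> CodaLassoFit:
    """Fit the zero-sum elastic-net log-contrast model with CV penalty choice.

    Parameters
    ----------
    table
        OTU x sample counts; features are log(TSS proportion + pseudocount).
    y
        Continuous response (squared-error loss) or binary 0/1 group
        labels (logistic deviance) aligned with the table's samples.
    mixing
        Elastic-net mixing in [0, 1]: 1 = pure LASSO, 0 = pure ridge.
    lambdas
        Penalty grid (descending).  Defaults to ``n_lambdas`` log-spaced
        values from the smallest all-zero lambda down three decades.
    relax
        Refit each candidate support by unpenalised zero-sum regression
        (relaxed fit) both inside cross-validation and for the returned
        model, so the penalty only chooses the support and the reported
        coefficients are unshrunk.  With shrinkage bias removed the CV
        curve is flat across supersets of the true support, which is why
        the default selection rule is parsimonious (``"1se"``).
    lambda_rule
        ``"1se"``: largest lambda whose mean CV error is within one
        standard error of the minimum; ``"min"``: the minimiser itself.
    """
    y = np.asarray(pd.Series(y).loc[table.sample_ids] if isinstance(y, pd.Series) else y, dtype=float)
    if len(y) != table.n_samples:
        raise ValueError("response length does not match the number of samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must lie in [0, 1]")
    if table.n_samples < cv_folds:
        raise ValueError("need at least cv_folds samples")
    if lambda_rule not in ("1se", "min"):
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
    binary = set(np.unique(y)) <= {0.0, 1.0}
    loss = "logistic" if binary else "gaussian"
    if loss == "gaussian" and np.var(y) == 0:
        raise ValueError("constant response")
    z = _log_features(table, pseudocount)
    n, p = z.shape

    if lambdas is None:
        # smallest lambda at which beta = 0 is optimal for the zero-sum L1
        # problem: all pairwise gradient gaps within the penalty
        grad = z.T @ (y - y.mean()) / n
        span = float(grad.max() - grad.min())
        lam_max = span / (2.0 * max(mixing, 1e-3)) * 1.05
        lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)
    else:
        lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    if len(lambdas) == 0:
        raise ValueError("empty lambda grid")

    relaxer = _relaxed_gaussian if loss == "gaussian" else _relaxed_logistic

    rng = np.random.default_rng(seed)
    fold_of = np.arange(n) % cv_folds  # balanced: every fold non-empty
    rng.shuffle(fold_of)

    errors = np.zeros((len(lambdas), cv_folds))
    for f in range(cv_folds):
        train, test = fold_of != f, fold_of == f
        fits = _path_fits(z[train], y[train], lambdas, mixing, loss)
        for li, (b0, b) in enumerate(fits):
            if relax:
                b0, b = relaxer(z[train], y[train], b != 0)
            errors[li, f] = _loss(y[test], b0 + z[test] @ b, loss)

    mean_err = errors.mean(axis=1)
    se_err = errors.std(axis=1, ddof=1) / np.sqrt(cv_folds)
    finite = np.isfinite(mean_err)
    if not finite.any():
        raise ValueError("cross-validation produced no finite errors")
    best = int(np.nanargmin(np.where(finite, mean_err, np.inf)))
    if lambda_rule == "1se":
        threshold = mean_err[best] + (se_err[best] if np.isfinite(se_err[best]) else 0.0)
        candidates = np.nonzero(finite & (mean_err <= threshold))[0]
        if len(candidates):
            best = int(candidates.min())
    lam_chosen = float(lambdas[best])

    full_path = _path_fits(z, y, lambdas, mixing, loss)
    beta0, beta = full_path[best]
    if relax:
        beta0, beta = relaxer(z, y, beta != 0)

    cv = pd.DataFrame({"lambda": lambdas, "mean_error": mean_err, "se_error": se_err})
    return CodaLassoFit(
        response_name=response_name,
        loss=loss,
        intercept=float(beta0),
        coefficients=pd.Series(beta, index=table.otu_ids, name="coefficient"),
        mixing=mixing,
        pseudocount=pseudocount,
        lambda_path=np.asarray(lambdas),
        lambda_chosen=lam_chosen,
        cv_errors=cv,
        seed=seed,
        relaxed=relax,
        path_coefficients=np.array([b for _, b in full_path]),
    )


def predict_coda(fit: CodaLassoFit, table: CountTable) -> pd.Series:
    """Linear predictor (gaussian) or probability (logistic) per sample."""
    missing = [t for t in fit.coefficients.index if t not in set(table.otu_ids)]
    if missing:
        raise ValueError(f"taxa missing from table: {missing[:5]}")
    sub = table.select_otus(list(fit.coefficients.index))
    z = _log_features(sub, fit.pseudocount)
    eta = fit.intercept + z @ fit.coefficients.to_numpy()
    if fit.loss == "logistic":
        eta = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    return pd.Series(eta, index=table.sample_ids, name="prediction")
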