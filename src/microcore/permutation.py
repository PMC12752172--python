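"""Permutation tests on distance matrices: PERMANOVA and db-RDA selection.

PERMANOVA partitions the squared inter-sample distances sequentially
(Type I) over an ordered term list, with pseudo-F statistics tested by
free permutation of sample labels.  Stepwise distance-based RDA performs
forward selection with a backward pass, testing each candidate's partial
pseudo-F on principal-coordinate axes by permutation.  A simple OLS of
one distance matrix's pairs on another's quantifies how strongly a
secondary (e.g. functional) distance tracks taxonomic turnover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy import stats
from skbio import DistanceMatrix

from .containers import SampleMetadata
from .design import build_design
from .diversity import pcoa

logger = logging.getLogger(__name__)

__all__ = [
    "permanova",
    "PermanovaResult",
    "stepwise_dbrda_select",
    "StepwiseResult",
    "distance_regression",
    "DistanceRegression",
]


@dataclass
class PermanovaResult:
    """Sequential decomposition of a distance matrix over model terms."""

    table: pd.DataFrame  # rows: terms + Residual + Total; cols: df, SumOfSqs, R2, F, p
    n_permutations: int
    seed: int

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4f}")


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def _hat(x: np.ndarray) -> np.ndarray:
    """Projection onto the column space of x (rank-safe via QR)."""
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def _align(dm: DistanceMatrix, meta: SampleMetadata) -> tuple[DistanceMatrix, SampleMetadata]:
    have = [s for s in dm.ids if s in set(meta.sample_ids)]
    missing = [s for s in dm.ids if s not in set(meta.sample_ids)]
    if missing:
        logger.warning("dropping %d samples without metadata: %s", len(missing), missing[:5])
    if len(have) < 3:
        raise ValueError("fewer than 3 samples with metadata")
    return dm.filter(have), meta.subset(have)


def permanova(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type I) PERMANOVA over an ordered term list.

    Each term's sum of squares is the gain in explained (Gower-centred)
    trace when it joins the model after the preceding terms.  Pseudo-F
    uses the full-model residual; p-values come from free permutation of
    sample labels, with the (1 + count) / (1 + n_perm) estimator.
    """
    if not terms:
        raise ValueError("no terms supplied")
    dm, meta = _align(dm, meta)
    n = len(dm.ids)
    for t in terms:
        col = meta.data[t]
        if col.nunique() < 2:
            raise ValueError(f"term {t!r} is constant among retained samples")

    g = _gower_center(dm.data)
    ss_total = np.trace(g)

    # cumulative hat matrices (intercept first)
    designs = []
    x = np.ones((n, 1))
    designs.append(_hat(x))
    dfs = []
    for t in terms:
        xt = build_design(meta, [t]).to_numpy()
        x = np.hstack([x, xt])
        h = _hat(x)
        dfs.append(int(round(np.trace(h) - np.trace(designs[-1]))))
        designs.append(h)
    h_full = designs[-1]
    df_res = n - int(round(np.trace(h_full)))
    if df_res < 1:
        raise ValueError("model saturates the samples; no residual degrees of freedom")

    def term_ss(gmat: np.ndarray) -> np.ndarray:
        traces = np.array([np.sum(h * gmat) for h in designs])
        return np.diff(traces)

    ss_terms = term_ss(g)
    ss_res = ss_total - np.sum(h_full * g)
    f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p = term_ss(gp)
        ss_res_p = ss_total - np.sum(h_full * gp)
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
        # tolerance so exact ties (label symmetries) count as exceedances
        exceed += f_p >= f_obs - 1e-10 * np.maximum(1.0, np.abs(f_obs))
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = {}
    for i, t in enumerate(terms):
        rows[t] = {
            "df": dfs[i],
            "SumOfSqs": ss_terms[i],
            "R2": ss_terms[i] / ss_total,
            "F": f_obs[i],
            "p": pvals[i],
        }
    rows["Residual"] = {
        "df": df_res,
        "SumOfSqs": ss_res,
        "R2": ss_res / ss_total,
        "F": np.nan,
        "p": np.nan,
    }
    rows["Total"] = {"df": n - 1, "SumOfSqs": ss_total, "R2": 1.0, "F": np.nan, "p": np.nan}
    return PermanovaResult(pd.DataFrame.from_dict(rows, orient="index"), n_perm, seed)


@dataclass
class StepwiseResult:
    """Forward/backward db-RDA selection outcome with its step trace."""

    selected: list[str]
    trace: list[dict] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)


def _pcoa_scores(dm: DistanceMatrix, inertia: float = 0.95) -> np.ndarray:
    """PCoA axes retaining >= ``inertia`` of the positive eigenvalue mass."""
    ord_res = pcoa(dm)
    pos = ord_res.eigenvalues[ord_res.eigenvalues > 0]
    cum = np.cumsum(pos) / pos.sum()
    k = int(np.searchsorted(cum, inertia) + 1)
    return ord_res.coordinates[:, : min(k, ord_res.coordinates.shape[1])]


def _partial_f(y: np.ndarray, x_base: np.ndarray, x_add: np.ndarray) -> tuple[float, int, int]:
    """Partial pseudo-F of x_add conditioned on x_base for response scores y."""
    h0 = _hat(x_base)
    h1 = _hat(np.hstack([x_base, x_add]))
    rank0 = int(round(np.trace(h0)))
    rank1 = int(round(np.trace(h1)))
    df_add = rank1 - rank0
    n = y.shape[0]
    df_res = n - rank1
    if df_add < 1 or df_res < 1:
        return np.nan, df_add, df_res
    rss0 = np.sum((y - h0 @ y) ** 2)
    rss1 = np.sum((y - h1 @ y) ** 2)
    f = ((rss0 - rss1) / df_add) / (rss1 / df_res)
    return f, df_add, df_res


def _perm_p(
    y: np.ndarray,
    x_base: np.ndarray,
    x_add: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    f_obs, df_add, df_res = _partial_f(y, x_base, x_add)
    if not np.isfinite(f_obs):
        return np.nan, np.nan
    count = 0
    n = y.shape[0]
    tol = 1e-10 * max(1.0, abs(f_obs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_p, _, _ = _partial_f(y[perm], x_base, x_add)
        if f_p >= f_obs - tol:
            count += 1
    return f_obs, (1.0 + count) / (1.0 + n_perm)


def stepwise_dbrda_select(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    candidates: list[str],
    alpha_enter: float = 0.05,
    alpha_drop: float = 0.10,
    n_perm: int = 199,
    seed: int = 0,
) -> StepwiseResult:
    """Forward selection with backward elimination on db-RDA pseudo-F.

    At each forward step the candidate with the smallest permutation
    p-value (conditioned on the current model) enters if p <= alpha_enter;
    after each entry, terms whose conditional p-value exceeds alpha_drop
    are removed.  Terminates when neither pass changes the model.
    Constant or collinear candidates are skipped with a warning.
    """
    if not candidates:
        raise ValueError("no candidate covariates supplied")
    dm, meta = _align(dm, meta)
    n = len(dm.ids)
    y = _pcoa_scores(dm)
    rng = np.random.default_rng(seed)

    usable = []
    for c in candidates:
        try:
            build_design(meta, [c])
        except ValueError as exc:
            logger.warning("skipping candidate %r: %s", c, exc)
            continue
        usable.append(c)

    selected: list[str] = []
    trace: list[dict] = []
    intercept = np.ones((n, 1))

    def design_for(names: list[str]) -> np.ndarray:
        if not names:
            return intercept
        return np.hstack([intercept, build_design(meta, names).to_numpy()])

    changed = True
    while changed:
        changed = False
        # forward pass
        best = None
        x_base = design_for(selected)
        for c in usable:
            if c in selected:
                continue
            x_add = build_design(meta, [c]).to_numpy()
            f, p = _perm_p(y, x_base, x_add, n_perm, rng)
            trace.append({"step": "try_add", "term": c, "F": f, "p": p, "model": list(selected)})
            if np.isfinite(p) and (best is None or p < best[1] or (p == best[1] and f > best[2])):
                best = (c, p, f)
        if best is not None and best[1] <= alpha_enter:
            selected.append(best[0])
            trace.append({"step": "add", "term": best[0], "F": best[2], "p": best[1], "model": list(selected)})
            changed = True
            # backward pass
            dropped = True
            while dropped and len(selected) > 1:
                dropped = False
                worst = None
                for c in selected:
                    others = [s for s in selected if s != c]
                    f, p = _perm_p(y, design_for(others), build_design(meta, [c]).to_numpy(), n_perm, rng)
                    trace.append({"step": "try_drop", "term": c, "F": f, "p": p, "model": list(selected)})
                    if np.isfinite(p) and (worst is None or p > worst[1]):
                        worst = (c, p)
                if worst is not None and worst[1] > alpha_drop:
                    selected.remove(worst[0])
                    trace.append({"step": "drop", "term": worst[0], "p": worst[1], "model": list(selected)})
                    dropped = True
    return StepwiseResult(selected, trace)


@dataclass
class DistanceRegression:
    """OLS of secondary-distance pairs on taxonomic-distance pairs.

    ``slope`` is the resilience proxy: a lower slope means the secondary
    (e.g. functional) distance responds less to taxonomic turnover.  The
    n(n-1)/2 pair values are not independent, so the standard errors are
    descriptive, not inferential.
    """

    slope: float
    intercept: float
    r_squared: float
    stderr: float
    n_pairs: int


def distance_regression(
    d_taxonomic: DistanceMatrix, d_secondary: DistanceMatrix
) -> DistanceRegression:
    """Regress secondary distances on taxonomic distances over unique pairs."""
    if list(d_taxonomic.ids) != list(d_secondary.ids):
        d_secondary = d_secondary.filter(d_taxonomic.ids)
    n = len(d_taxonomic.ids)
    if n < 3:
        raise ValueError("need at least 3 samples for a distance regression")
    x = squareform(d_taxonomic.data, checks=False)
    y = squareform(d_secondary.data, checks=False)
    res = stats.linregress(x, y)
    return DistanceRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr),
        n_pairs=len(x),
    )
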