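"""Samejima graded response model: marginal-ML EM estimation, information
curves, threshold comparison, and the threshold-overlap response-consistency
check.

Model: for an item with ``m`` ordered categories, discrimination ``a`` and
strictly increasing thresholds ``b_1 < ... < b_{m-1}``,

    P(X >= k | theta) = logistic(a * (theta - b_{k-1})),   k = 2..m,

with the latent trait fixed to N(0, 1) for identification.  Estimation is
marginal maximum likelihood via EM on a fixed quadrature grid (default 61
equally spaced nodes on [-6, 6], weighted by the standard-normal density);
the M-step maximizes each item's expected complete-data log-likelihood with
a smooth unconstrained parametrization (log-discrimination, first threshold,
log threshold gaps).  Standard errors come from the observed information
matrix, obtained by central finite differences of the marginal
log-likelihood; confidence intervals are Wald.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "GrmItemParams",
    "GrmFit",
    "InformationCurve",
    "ConsistencyReport",
    "fit_grm",
    "information_curves",
    "threshold_correlation",
    "response_consistency_check",
]


# ---------------------------------------------------------------------------
# parameters and containers

@dataclass
class GrmItemParams:
    item_id: str
    a: float
    b: np.ndarray                     # (m-1,) strictly increasing
    se_a: float | None = None
    se_b: np.ndarray | None = None
    n_categories: int = 0
    category_map: dict | None = None  # observed code -> collapsed 1..m_obs

    def ci(self, level: float = 0.95) -> tuple[tuple[float, float], np.ndarray]:
        """Wald CIs for (a, b); requires standard errors."""
        if self.se_a is None or self.se_b is None:
            raise ValueError("standard errors were not computed for this fit")
        zc = norm.ppf(0.5 + level / 2)
        ci_a = (self.a - zc * self.se_a, self.a + zc * self.se_a)
        ci_b = np.column_stack([self.b - zc * self.se_b, self.b + zc * self.se_b])
        return ci_a, ci_b


@dataclass
class GrmFit:
    items: list[GrmItemParams]
    log_likelihood: float
    ll_path: list[float]
    nodes: np.ndarray
    weights: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    excluded_items: list[str] = field(default_factory=list)

    def thresholds_matrix(self) -> pd.DataFrame:
        """Items x thresholds (NaN-padded when category counts differ)."""
        width = max(len(it.b) for it in self.items)
        rows = {it.item_id: np.pad(it.b.astype(float), (0, width - len(it.b)),
                                   constant_values=np.nan)
                for it in self.items}
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=[f"b{k+1}" for k in range(width)])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_obs": self.n_obs,
            "excluded_items": self.excluded_items,
            "items": [
                {"id": it.item_id, "a": it.a, "b": list(map(float, it.b)),
                 "se_a": it.se_a,
                 "se_b": None if it.se_b is None else list(map(float, it.se_b))}
                for it in self.items
            ],
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


# ---------------------------------------------------------------------------
# probability machinery

def category_probs(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P(X = k | theta) for k = 1..m; shape (m, len(theta))."""
    cum = expit(a * (theta[None, :] - b[:, None]))       # P(X >= k+1)
    upper = np.vstack([np.ones_like(theta), cum])
    lower = np.vstack([cum, np.zeros_like(theta)])
    return upper - lower


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    gaps = np.diff(b)
    return np.concatenate([[np.log(a), b[0]], np.log(np.maximum(gaps, 1e-8))])


def _unpack(x: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(np.clip(x[0], -5, 5)))
    b = x[1] + np.concatenate([[0.0], np.cumsum(np.exp(np.clip(x[2:], -12, 5)))])
    return a, b


def _item_neg_q(x: np.ndarray, counts: np.ndarray, nodes: np.ndarray) -> float:
    """Negative expected complete-data log-likelihood for one item.

    ``counts``: (m, q) expected number of responses in category k at node q.
    """
    a, b = _unpack(x)
    p = np.maximum(category_probs(a, b, nodes), 1e-300)
    return -float((counts * np.log(p)).sum())


# ---------------------------------------------------------------------------
# estimation

def _prepare(x: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame, list[str]]:
    df = pd.DataFrame(x).copy()
    df.columns = [str(c) for c in df.columns]
    df = df.astype("Float64")
    df = df[df.notna().any(axis=1)]       # drop all-missing rows
    excluded = [c for c in df.columns if df[c].dropna().nunique() < 2]
    return df.drop(columns=excluded), excluded


def fit_grm(
    responses: pd.DataFrame | np.ndarray,
    n_quadrature: int = 61,
    theta_range: tuple[float, float] = (-6.0, 6.0),
    tol: float = 1e-4,
    max_iter: int = 200,
    compute_se: bool = True,
) -> GrmFit:
    """Fit a unidimensional graded response model by marginal ML (EM).

    ``responses``: respondents x items, integer category codes (1-based) with
    missing allowed.  Per-item observed categories are collapsed onto
    consecutive codes before fitting; items with fewer than two observed
    categories are excluded with a warning flag on the fit.  Convergence:
    successive marginal log-likelihood gain below ``tol``.  Non-convergence
    is flagged, not raised.
    """
    df, excluded = _prepare(responses)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 items with >= 2 observed categories")

    nodes = np.linspace(*theta_range, n_quadrature)
    weights = norm.pdf(nodes)
    weights = weights / weights.sum()

    # collapse observed categories to consecutive 1..m_obs
    items: list[str] = list(df.columns)
    cat_maps: dict[str, dict] = {}
    resp: dict[str, np.ndarray] = {}
    for c in items:
        observed = sorted(int(v) for v in df[c].dropna().unique())
        cat_maps[c] = {orig: i + 1 for i, orig in enumerate(observed)}
        col = df[c].map(lambda v: cat_maps[c].get(int(v)) if pd.notna(v) else np.nan)
        resp[c] = col.to_numpy(dtype=float)

    n = len(df)
    # starting values: a = 1, thresholds at normal quantiles of cumulative
    # category frequencies
    params: dict[str, tuple[float, np.ndarray]] = {}
    for c in items:
        r = resp[c][~np.isnan(resp[c])].astype(int)
        m = len(cat_maps[c])
        freq = np.bincount(r, minlength=m + 1)[1:] / len(r)
        cum = np.clip(np.cumsum(freq)[:-1], 1e-3, 1 - 1e-3)
        b0 = norm.ppf(cum)
        b0 = np.maximum.accumulate(b0 + 1e-6 * np.arange(m - 1))
        params[c] = (1.0, b0)

    def log_lik_matrix() -> np.ndarray:
        """(n, q) log joint likelihood of each row at each node."""
        ll = np.zeros((n, len(nodes)))
        for c in items:
            a, b = params[c]
            logp = np.log(np.maximum(category_probs(a, b, nodes), 1e-300))
            obs = ~np.isnan(resp[c])
            ll[obs] += logp[resp[c][obs].astype(int) - 1]
        return ll

    ll_path: list[float] = []
    converged = False
    for it_no in range(1, max_iter + 1):
        ll = log_lik_matrix() + np.log(weights)[None, :]
        mx = ll.max(axis=1, keepdims=True)
        lik = np.exp(ll - mx)
        marg = lik.sum(axis=1)
        total_ll = float((np.log(marg) + mx[:, 0]).sum())
        ll_path.append(total_ll)
        if len(ll_path) > 1 and abs(ll_path[-1] - ll_path[-2]) < tol:
            converged = True
            break
        post = lik / marg[:, None]                    # (n, q)
        for c in items:
            obs = ~np.isnan(resp[c])
            r = resp[c][obs].astype(int)
            m = len(cat_maps[c])
            counts = np.zeros((m, len(nodes)))
            np.add.at(counts, r - 1, post[obs])
            a, b = params[c]
            sol = minimize(_item_neg_q, _pack(a, b), args=(counts, nodes),
                           method="L-BFGS-B")
            params[c] = _unpack(sol.x)

    fit_items = [
        GrmItemParams(item_id=c, a=params[c][0], b=params[c][1],
                      n_categories=len(cat_maps[c]),
                      category_map=cat_maps[c])
        for c in items
    ]
    fit = GrmFit(items=fit_items, log_likelihood=ll_path[-1], ll_path=ll_path,
                 nodes=nodes, weights=weights, converged=converged,
                 n_iter=len(ll_path), n_obs=n, excluded_items=excluded)
    if compute_se:
        _attach_standard_errors(fit, resp, items, cat_maps)
    return fit


def _marginal_ll(x: np.ndarray, layout, resp, items, cat_maps, nodes, weights) -> float:
    n = len(next(iter(resp.values())))
    ll = np.zeros((n, len(nodes)))
    for c in items:
        lo, hi = layout[c]
        a, b = _unpack(x[lo:hi])
        logp = np.log(np.maximum(category_probs(a, b, nodes), 1e-300))
        obs = ~np.isnan(resp[c])
        ll[obs] += logp[resp[c][obs].astype(int) - 1]
    ll += np.log(weights)[None, :]
    mx = ll.max(axis=1, keepdims=True)
    return float((np.log(np.exp(ll - mx).sum(axis=1)) + mx[:, 0]).sum())


def _attach_standard_errors(fit: GrmFit, resp, items, cat_maps) -> None:
    """Observed-information SEs via central FD Hessian of the marginal LL.

    The Hessian is computed in the unconstrained parametrization and mapped
    to (a, b) by the delta method.
    """
    layout: dict[str, tuple[int, int]] = {}
    x_parts = []
    pos = 0
    for it in fit.items:
        xi = _pack(it.a, it.b)
        layout[it.item_id] = (pos, pos + len(xi))
        x_parts.append(xi)
        pos += len(xi)
    x0 = np.concatenate(x_parts)
    p = len(x0)
    h = 1e-4
    args = (layout, resp, items, cat_maps, fit.nodes, fit.weights)

    f0 = _marginal_ll(x0, *args)
    hess = np.empty((p, p))
    f_plus = np.empty(p)
    f_minus = np.empty(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h
        f_plus[i] = _marginal_ll(x0 + e, *args)
        f_minus[i] = _marginal_ll(x0 - e, *args)
        hess[i, i] = (f_plus[i] - 2 * f0 + f_minus[i]) / h**2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            fpp = _marginal_ll(x0 + ei + ej, *args)
            fmm = _marginal_ll(x0 - ei - ej, *args)
            hess[i, j] = hess[j, i] = (
                fpp - f_plus[i] - f_plus[j] + 2 * f0 - f_minus[i] - f_minus[j] + fmm
            ) / (2 * h**2)

    info = -hess
    try:
        cov_x = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_x = np.linalg.pinv(info)

    for it in fit.items:
        lo, hi = layout[it.item_id]
        xi = x0[lo:hi]
        sub = cov_x[lo:hi, lo:hi]
        # Jacobian of (a, b_1..b_{m-1}) wrt (log a, b_1, log gaps)
        m1 = len(it.b)
        jac = np.zeros((m1 + 1, m1 + 1))
        jac[0, 0] = np.exp(xi[0])                     # da/dlog a
        jac[1:, 1] = 1.0                              # db_k/db_1
        gaps = np.exp(xi[2:])
        for k in range(1, m1):                        # b_{k+1} includes gaps 1..k
            jac[k + 1, 2:2 + k] = gaps[:k]
        cov_ab = jac @ sub @ jac.T
        se = np.sqrt(np.maximum(np.diag(cov_ab), 0.0))
        it.se_a = float(se[0])
        it.se_b = se[1:]


# ---------------------------------------------------------------------------
# information

@dataclass
class InformationCurve:
    theta: np.ndarray
    item_information: pd.DataFrame     # items x theta
    test_information: np.ndarray
    standard_error: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        df = self.item_information.T.copy()
        df["test_information"] = self.test_information
        df["standard_error"] = self.standard_error
        df.index = pd.Index(self.theta, name="theta")
        df.to_csv(path)


def item_information(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Graded-response item information sum_k (P_k')^2 / P_k at each theta."""
    cum = expit(a * (theta[None, :] - b[:, None]))
    upper = np.vstack([np.ones_like(theta), cum])
    lower = np.vstack([cum, np.zeros_like(theta)])
    p = np.maximum(upper - lower, 1e-300)
    d_upper = a * upper * (1 - upper)
    d_lower = a * lower * (1 - lower)
    dp = d_upper - d_lower
    return (dp**2 / p).sum(axis=0)


def information_curves(fit: GrmFit, theta: Sequence[float] | None = None) -> InformationCurve:
    """Item and test information over a theta grid (default the fit's grid);
    the latent-score standard error is ``1/sqrt(I)``."""
    grid = fit.nodes if theta is None else np.asarray(theta, dtype=float)
    if grid.size == 0:
        raise ValueError("empty theta grid")
    rows = {it.item_id: item_information(it.a, it.b, grid) for it in fit.items}
    info = pd.DataFrame.from_dict(rows, orient="index", columns=range(len(grid)))
    total = info.sum(axis=0).to_numpy()
    return InformationCurve(theta=grid, item_information=info,
                            test_information=total,
                            standard_error=1.0 / np.sqrt(np.maximum(total, 1e-300)))


def threshold_correlation(fit_original: GrmFit, fit_adjusted: GrmFit) -> pd.DataFrame:
    """Pearson correlations, across items, of original vs adjusted threshold
    vectors (rows: original ``b_k``; columns: adjusted ``b_k``)."""
    b_o = fit_original.thresholds_matrix()
    b_a = fit_adjusted.thresholds_matrix()
    # adjusted columns conventionally carry an "_adj" suffix; pair by stem
    b_o.index = [i.removesuffix("_adj") for i in b_o.index]
    b_a.index = [i.removesuffix("_adj") for i in b_a.index]
    common = b_o.index.intersection(b_a.index)
    if len(common) < 3:
        raise ValueError("threshold correlation needs at least 3 shared items")
    b_o, b_a = b_o.loc[common], b_a.loc[common]
    out = pd.DataFrame(index=b_o.columns, columns=b_a.columns, dtype=float)
    for ko in b_o.columns:
        for ka in b_a.columns:
            out.loc[ko, ka] = b_o[ko].corr(b_a[ka])
    out.index = [f"orig_{c}" for c in b_o.columns]
    out.columns = [f"adj_{c}" for c in b_a.columns]
    return out


# ---------------------------------------------------------------------------
# response consistency

@dataclass
class ConsistencyReport:
    per_threshold: pd.DataFrame   # index k; pooled CIs for each instrument + overlap
    fraction_overlapping: float
    verdict: str                  # "met" | "violated"
    level: float
    cutoff: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "fraction_overlapping": self.fraction_overlapping,
            "verdict": self.verdict, "level": self.level, "cutoff": self.cutoff,
            "per_threshold": json.loads(self.per_threshold.to_json(orient="index")),
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _pooled_threshold(fit: GrmFit, k: int) -> tuple[float, float] | None:
    """Inverse-variance weighted mean and SE of threshold ``b_{k+1}`` over
    items; ``None`` when no item provides a finite positive SE for it."""
    est, var = [], []
    for it in fit.items:
        if len(it.b) > k and it.se_b is not None \
                and np.isfinite(it.se_b[k]) and it.se_b[k] > 0:
            est.append(it.b[k])
            var.append(it.se_b[k] ** 2)
    if not est:
        return None
    w = 1.0 / np.asarray(var)
    mean = float((w * np.asarray(est)).sum() / w.sum())
    return mean, float(np.sqrt(1.0 / w.sum()))


def response_consistency_check(
    vignette_fit: GrmFit,
    self_fit: GrmFit,
    level: float = 0.95,
    overlap_cutoff: float = 0.75,
) -> ConsistencyReport:
    """Do vignette and self-report items share response thresholds?

    For each threshold index the item-level estimates are pooled within each
    instrument (inverse-variance weighting) and the two pooled Wald CIs are
    tested for overlap; the consistency requirement is judged met when the
    fraction of overlapping threshold indices reaches ``overlap_cutoff``.
    """
    n_v = max(len(it.b) for it in vignette_fit.items)
    n_s = max(len(it.b) for it in self_fit.items)
    if n_v != n_s:
        raise ValueError(f"instruments have different threshold counts ({n_v} vs {n_s}); "
                         "the check requires a shared category scale")
    zc = norm.ppf(0.5 + level / 2)
    rows = []
    for k in range(n_v):
        pooled_v = _pooled_threshold(vignette_fit, k)
        pooled_s = _pooled_threshold(self_fit, k)
        if pooled_v is None or pooled_s is None:
            continue    # threshold not estimable in one instrument
        (mv, sev), (ms, ses) = pooled_v, pooled_s
        lo_v, hi_v = mv - zc * sev, mv + zc * sev
        lo_s, hi_s = ms - zc * ses, ms + zc * ses
        rows.append({
            "threshold": k + 1,
            "vignette_lo": lo_v, "vignette_hi": hi_v,
            "self_lo": lo_s, "self_hi": hi_s,
            "overlap": bool(max(lo_v, lo_s) <= min(hi_v, hi_s)),
        })
    if not rows:
        raise ValueError("no threshold index was estimable in both instruments")
    df = pd.DataFrame(rows).set_index("threshold")
    frac = float(df["overlap"].mean())
    return ConsistencyReport(per_threshold=df, fraction_overlapping=frac,
                             verdict="met" if frac >= overlap_cutoff else "violated",
                             level=level, cutoff=overlap_cutoff)
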