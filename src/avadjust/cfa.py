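"""Correlated-factors confirmatory factor analysis by maximum likelihood.

Simple-structure model: each item loads on exactly one factor, factor
variances are fixed at 1 (so loadings are directly standardized against the
factors), factor correlations and uniquenesses are free.  The fit minimizes
the ML discrepancy

    F = log|Sigma(theta)| + tr(S Sigma(theta)^{-1}) - log|S| - p

by L-BFGS from a deterministic start (loadings from item-scale-score
correlations, uniquenesses at half the item variance, factor correlations at
zero).  Fit indices follow the usual covariance-structure definitions:
``chi2 = (n-1) F``, CFI against the independence baseline, and
``RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1)))``.

Ordinal item scores are treated as numeric (Pearson covariances);
polychoric estimation is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = ["CfaModel", "CfaFit", "fit_cfa", "configural_fit", "prune_items"]


@dataclass(frozen=True)
class CfaModel:
    """Item -> factor assignment (simple structure)."""

    pattern: dict[str, str]
    factors: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = {f for f in self.pattern.values() if f not in self.factors}
        if unknown:
            raise ValueError(f"pattern references undeclared factors: {sorted(unknown)}")

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.pattern)

    def items_of(self, factor: str) -> list[str]:
        return [i for i, f in self.pattern.items() if f == factor]

    def drop(self, item: str) -> "CfaModel":
        return CfaModel({i: f for i, f in self.pattern.items() if i != item}, self.factors)

    def n_free_parameters(self) -> int:
        p, q = len(self.pattern), len(self.factors)
        return p + p + q * (q - 1) // 2      # loadings + uniquenesses + correlations

    def degrees_of_freedom(self) -> int:
        p = len(self.pattern)
        return p * (p + 1) // 2 - self.n_free_parameters()

    @classmethod
    def from_codebook(cls, codebook, suffix: str = "") -> "CfaModel":
        pattern = {it.item_id + suffix: it.construct for it in codebook.items}
        return cls(pattern, tuple(codebook.constructs))


@dataclass
class CfaFit:
    model: CfaModel
    loadings: pd.Series
    phi: pd.DataFrame
    uniquenesses: pd.Series
    discrepancy: float
    chi2: float
    df: int
    cfi: float
    rmsea: float
    n: int
    converged: bool
    baseline_chi2: float = 0.0
    baseline_df: int = 0

    def standardized_loadings(self) -> pd.Series:
        """Loadings standardized by model-implied item SDs."""
        lam = self.loadings
        sigma_jj = lam**2 + self.uniquenesses
        return lam / np.sqrt(sigma_jj)

    def summary_row(self, label: str = "") -> dict:
        return {"model": label, "CFI": self.cfi, "RMSEA": self.rmsea,
                "chi2": self.chi2, "df": self.df, "n": self.n}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "chi2": self.chi2, "df": self.df, "cfi": self.cfi, "rmsea": self.rmsea,
            "discrepancy": self.discrepancy, "n": self.n, "converged": self.converged,
            "loadings": self.loadings.round(6).to_dict(),
            "uniquenesses": self.uniquenesses.round(6).to_dict(),
            "factor_correlations": json.loads(self.phi.round(6).to_json()),
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


# ---------------------------------------------------------------------------
# parametrization helpers

def _phi_from_params(x: np.ndarray, q: int) -> np.ndarray:
    """Unit-diagonal PD correlation matrix from q(q-1)/2 unconstrained
    parameters via a row-normalized Cholesky factor."""
    L = np.eye(q)
    idx = 0
    for i in range(1, q):
        L[i, :i] = x[idx:idx + i]
        idx += i
        L[i] /= np.linalg.norm(L[i])
    return L @ L.T


def _implied(lam_vec, psi_vec, phi, item_factor: np.ndarray) -> np.ndarray:
    lam = np.zeros((len(lam_vec), phi.shape[0]))
    lam[np.arange(len(lam_vec)), item_factor] = lam_vec
    return lam @ phi @ lam.T + np.diag(psi_vec)


def fit_cfa(
    data: pd.DataFrame | np.ndarray,
    model: CfaModel,
    n: int | None = None,
    max_iter: int = 2000,
) -> CfaFit:
    """Fit the correlated-factors model to raw data or a covariance matrix.

    Pass raw respondents-x-items data (``n`` inferred) or a covariance
    matrix with explicit ``n``.  Raises on a non-positive-definite sample
    covariance (consider a small ridge repair, ``S + eps I``, upstream).
    """
    items = list(model.items)
    if isinstance(data, pd.DataFrame) and set(items) <= set(map(str, data.columns)):
        df = data[items].astype("Float64").astype(float).dropna()
        if n is None:
            n = len(df)
        s = np.cov(df.to_numpy().T, ddof=1)
        raw = df
    else:
        s = np.asarray(data, dtype=float)
        raw = None
        if n is None:
            raise ValueError("n must be given when fitting from a covariance matrix")
    p = len(items)
    if s.shape != (p, p):
        raise ValueError(f"covariance shape {s.shape} does not match {p} model items")
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    sign, logdet_s = np.linalg.slogdet(s)
    if sign <= 0 or np.any(np.linalg.eigvalsh(s) <= 0):
        raise ValueError("sample covariance is not positive definite; "
                         "consider a ridge repair (S + eps*I) before fitting")

    q = len(model.factors)
    f_idx = {f: i for i, f in enumerate(model.factors)}
    item_factor = np.array([f_idx[model.pattern[i]] for i in items])

    # start values: loading = cov(item, unit-weighted factor score) scaled,
    # psi = half the item variance, phi = identity
    diag = np.diag(s)
    lam0 = np.empty(p)
    for fi, f in enumerate(model.factors):
        members = np.flatnonzero(item_factor == fi)
        w = np.zeros(p); w[members] = 1.0
        sc_var = float(w @ s @ w)
        for j in members:
            c = float(s[j] @ w)
            lam0[j] = c / np.sqrt(max(sc_var, 1e-12))
    lam0 = np.clip(lam0, -0.95 * np.sqrt(diag), 0.95 * np.sqrt(diag))
    psi0 = diag * 0.5

    def unpack(x):
        lam = x[:p]
        psi = np.exp(np.clip(x[p:2 * p], -12, 12))
        phi = _phi_from_params(x[2 * p:], q)
        return lam, psi, phi

    def objective(x) -> float:
        lam, psi, phi = unpack(x)
        sigma = _implied(lam, psi, phi, item_factor)
        sign_m, logdet_m = np.linalg.slogdet(sigma)
        if sign_m <= 0:
            return 1e10
        try:
            solve = np.linalg.solve(sigma, s)
        except np.linalg.LinAlgError:
            return 1e10
        return logdet_m + np.trace(solve) - logdet_s - p

    x0 = np.concatenate([lam0, np.log(np.maximum(psi0, 1e-8)), np.zeros(q * (q - 1) // 2)])
    res = minimize(objective, x0, method="L-BFGS-B",
                   options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": 1e-12,
                            "gtol": 1e-8})
    lam, psi, phi = unpack(res.x)
    f_min = max(float(res.fun), 0.0)

    chi2 = (n - 1) * f_min
    df = model.degrees_of_freedom()
    # independence baseline
    f_base = float(np.sum(np.log(diag)) - logdet_s)
    chi2_b = (n - 1) * f_base
    df_b = p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))) if df > 0 else 0.0

    return CfaFit(
        model=model,
        loadings=pd.Series(lam, index=items),
        phi=pd.DataFrame(phi, index=model.factors, columns=model.factors),
        uniquenesses=pd.Series(psi, index=items),
        discrepancy=f_min, chi2=float(chi2), df=df, cfi=float(cfi), rmsea=rmsea,
        n=int(n), converged=bool(res.success),
        baseline_chi2=float(chi2_b), baseline_df=df_b,
    )


def configural_fit(
    tables: dict[str, pd.DataFrame],
    model: CfaModel,
) -> tuple[CfaFit, dict[str, CfaFit]]:
    """Multigroup configural fit: same pattern, all parameters free per group.

    Implemented as independent per-group fits; the combined chi-square and
    degrees of freedom are sums, and combined CFI/RMSEA are computed from
    the summed model and baseline statistics with the total n.  Groups with
    ``n <= p`` are excluded with a warning entry.
    """
    if len(tables) < 2:
        raise ValueError("configural fit needs at least 2 groups")
    p = len(model.items)
    fits: dict[str, CfaFit] = {}
    for g, df in tables.items():
        if len(pd.DataFrame(df).dropna()) <= p:
            continue
        fits[g] = fit_cfa(df, model)
    if len(fits) < 2:
        raise ValueError("fewer than 2 groups had n > p")
    chi2 = sum(f.chi2 for f in fits.values())
    df_tot = sum(f.df for f in fits.values())
    chi2_b = sum(f.baseline_chi2 for f in fits.values())
    df_b = sum(f.baseline_df for f in fits.values())
    n_tot = sum(f.n for f in fits.values())
    num = max(chi2 - df_tot, 0.0)
    den = max(chi2_b - df_b, chi2 - df_tot, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    rmsea = float(np.sqrt(max(chi2 - df_tot, 0.0) / (df_tot * (n_tot - 1))))
    any_g = next(iter(fits.values()))
    combined = CfaFit(
        model=model,
        loadings=pd.concat({g: f.loadings for g, f in fits.items()}),
        phi=any_g.phi,      # per-group matrices available in `fits`
        uniquenesses=pd.concat({g: f.uniquenesses for g, f in fits.items()}),
        discrepancy=sum(f.discrepancy for f in fits.values()),
        chi2=float(chi2), df=df_tot, cfi=float(cfi), rmsea=rmsea,
        n=n_tot, converged=all(f.converged for f in fits.values()),
        baseline_chi2=float(chi2_b), baseline_df=df_b,
    )
    return combined, fits


@dataclass
class PruneStep:
    item: str
    loading: float


def prune_items(
    data: pd.DataFrame,
    model: CfaModel,
    loading_threshold: float = 0.20,
    min_items_per_factor: int = 3,
) -> tuple[CfaModel, CfaFit, list[PruneStep]]:
    """Iteratively drop the worst misfitting item and refit.

    At each step the item with the smallest standardized loading, provided
    it is below ``loading_threshold`` (or negative), is removed — ties are
    broken by item order — and the model is refit.  Pruning stops when no
    item qualifies or when removing one would leave its factor with fewer
    than ``min_items_per_factor`` items.  Returns the final model, its fit,
    and the audit trail of removals.
    """
    audit: list[PruneStep] = []
    current = model
    fit = fit_cfa(data, current)
    while True:
        std = fit.standardized_loadings()
        order = np.argsort(std.to_numpy(), kind="stable")
        candidate = None
        for pos in order:
            item = std.index[pos]
            if std.iloc[pos] >= loading_threshold:
                break
            if len(current.items_of(current.pattern[item])) <= min_items_per_factor:
                continue     # would strip the factor too far
            candidate = item
            break
        if candidate is None:
            return current, fit, audit
        audit.append(PruneStep(item=candidate, loading=float(std[candidate])))
        current = current.drop(candidate)
        fit = fit_cfa(data, current)
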