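"""McDonald's omega with bootstrap confidence intervals.

Omega-total from a single-factor maximum-likelihood model of the item
covariance matrix:

    omega = (sum lambda_i)^2 / [ (sum lambda_i)^2 + sum psi_i ]

with loadings ``lambda`` and unique variances ``psi`` — the proportion of
scale-score variance attributable to the general factor ("factor
saturation").  The one-factor ML fit uses the concentrated likelihood: for
fixed uniquenesses the optimal loading is the leading eigenvector of the
psi-standardized covariance, so only ``log psi`` is optimized.

Confidence intervals are percentile bootstrap over respondents (default
B = 1000, seeded).  Heywood cases (negative uniquenesses) are clamped at
zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = ["OmegaEstimate", "OmegaComparison", "one_factor_ml",
           "omega_from_cov", "mcdonald_omega", "compare_omegas"]

_PSI_FLOOR = 1e-6


def one_factor_ml(cov: np.ndarray, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, bool]:
    """ML one-factor solution ``(loadings, uniquenesses, heywood_flag)``.

    Minimizes the ML discrepancy via the eigenvalue form: with
    ``S* = Psi^{-1/2} S Psi^{-1/2}`` and eigenvalues ``t_1 >= t_2 >= ...``,
    the concentrated discrepancy is ``sum_{j>=2} (t_j - log t_j - 1)``.
    """
    s = np.asarray(cov, dtype=float)
    p = s.shape[0]
    diag = np.diag(s)

    def objective(log_psi: np.ndarray) -> float:
        psi = np.exp(log_psi)
        d = 1.0 / np.sqrt(psi)
        t = np.linalg.eigvalsh(d[:, None] * s * d[None, :])[::-1]
        t = np.maximum(t, 1e-12)
        return float(np.sum(t[1:] - np.log(t[1:]) - 1.0))

    x0 = np.log(np.maximum(diag * 0.5, _PSI_FLOOR))
    # explicit FD step: near-Heywood solutions make the default step sit in
    # eigenvalue round-off noise
    res = minimize(objective, x0, method="L-BFGS-B",
                   bounds=[(np.log(_PSI_FLOOR), None)] * p,
                   options={"maxiter": max_iter, "eps": 1e-5})
    psi = np.exp(res.x)
    heywood = bool(np.any(res.x <= np.log(_PSI_FLOOR) + 1e-9))
    d = 1.0 / np.sqrt(psi)
    vals, vecs = np.linalg.eigh(d[:, None] * s * d[None, :])
    t1, v1 = vals[-1], vecs[:, -1]
    lam = np.sqrt(psi) * v1 * np.sqrt(max(t1 - 1.0, 0.0))
    if lam.sum() < 0:
        lam = -lam
    return lam, psi, heywood


def omega_from_cov(cov: np.ndarray) -> float:
    """Point estimate of omega-total from a covariance matrix."""
    lam, psi, _ = one_factor_ml(cov)
    s = lam.sum()
    return float(s**2 / (s**2 + psi.sum()))


@dataclass(frozen=True)
class OmegaEstimate:
    omega: float
    ci: tuple[float, float]
    level: float
    n_bootstrap: int
    seed: int
    n: int
    heywood: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.omega <= 1.0):
            raise ValueError(f"omega out of (0, 1]: {self.omega}")
        if not (self.ci[0] <= self.omega <= self.ci[1]):
            raise ValueError("CI must contain the point estimate")

    def __str__(self) -> str:
        return f"{self.omega:.2f} [{self.ci[0]:.2f}, {self.ci[1]:.2f}]"


def mcdonald_omega(
    items: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> OmegaEstimate:
    """Omega-total for one scale with a percentile-bootstrap CI.

    ``items``: respondents x items of one scale.  Missing data enter through
    the pairwise-complete covariance; bootstrap resamples respondents.
    Requires >= 3 items and more respondents than items.
    """
    df = pd.DataFrame(items).astype("Float64").astype(float)
    df = df[df.notna().any(axis=1)]
    p = df.shape[1]
    if p < 3:
        raise ValueError("omega needs at least 3 items")
    if len(df) <= p:
        raise ValueError("omega needs more respondents than items")
    zero_var = [c for c in df.columns if df[c].std(skipna=True) == 0]
    if zero_var:
        raise ValueError(f"zero-variance items: {zero_var}")

    cov = df.cov(min_periods=2).to_numpy()
    lam, psi, heywood = one_factor_ml(cov)
    s = lam.sum()
    omega = float(s**2 / (s**2 + psi.sum()))

    rng = np.random.default_rng(seed)
    arr = df.to_numpy()
    n = len(arr)
    reps = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        boot = pd.DataFrame(arr[idx])
        c = boot.cov(min_periods=2).to_numpy()
        if np.any(~np.isfinite(c)):
            continue
        try:
            reps.append(omega_from_cov(c))
        except np.linalg.LinAlgError:
            continue
    alpha = (1.0 - level) / 2
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    lo, hi = min(lo, omega), max(hi, omega)
    return OmegaEstimate(omega=omega, ci=(float(lo), float(hi)), level=level,
                         n_bootstrap=n_bootstrap, seed=seed, n=n, heywood=heywood)


@dataclass(frozen=True)
class OmegaComparison:
    significant: bool
    direction: str          # "increase" | "decrease" | "none"
    before: tuple[float, float]
    after: tuple[float, float]

    def __str__(self) -> str:
        verdict = "significant difference" if self.significant else "no significant difference"
        return f"{verdict} ({self.direction})"


def compare_omegas(before: OmegaEstimate, after: OmegaEstimate) -> OmegaComparison:
    """CI-overlap comparison: a significant difference iff the two
    confidence intervals are disjoint."""
    if before.level != after.level:
        raise ValueError("confidence levels differ between the two estimates")
    disjoint = before.ci[1] < after.ci[0] or after.ci[1] < before.ci[0]
    if not disjoint:
        direction = "none"
    else:
        direction = "increase" if after.omega > before.omega else "decrease"
    return OmegaComparison(significant=disjoint, direction=direction,
                           before=before.ci, after=after.ci)
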