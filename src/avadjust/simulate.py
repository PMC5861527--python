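"""Two-group synthetic survey generator with known measurement truth.

Emulates the measurement structure the pipeline assumes: five correlated
latent traits (Big Five, with neuroticism generated in its emotional-
stability orientation to match the vignette wording), 8-10 five-point items
per trait, three vignettes per trait with fixed latent locations, two
outcome scales, and — crucially — group-level differential item functioning
(DIF) implemented as a response-*threshold* shift that leaves the latent
traits untouched, plus person-level acquiescent and extreme response styles.

Every respondent draws one set of person thresholds

    tau_k = alpha + gamma * (b_k + delta_g)

(acquiescence shift ``alpha``, extremity scale ``gamma``, group shift
``delta_g``) and uses the *same* thresholds to rate self-report items,
vignettes and outcome items, so response consistency holds by construction.
Self responses follow a graded-response mechanism: the response is one plus
the number of person thresholds below ``a_i * theta + eps`` with standard
logistic ``eps``; vignette responses apply the same mechanism to the
vignette's latent location plus a small perception noise.

Because the threshold shift moves self and vignette ratings together, the
vignette-relative recoding can remove this DIF — which is exactly the
property the generator exists to test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (LikertScale, ItemSpec, OutcomeScale, ResponseTable,
                        SurveyCodebook, VignetteSet, from_dataframe)

__all__ = ["SimConfig", "SimResult", "simulate", "recovery_report", "default_codebook"]

CONSTRUCTS = ("extraversion", "agreeableness", "conscientiousness",
              "neuroticism", "openness")
# item counts mirror the 44-item Big Five inventory layout
ITEMS_PER_CONSTRUCT = {"extraversion": 8, "agreeableness": 9,
                       "conscientiousness": 9, "neuroticism": 8, "openness": 10}


def _default_phi() -> np.ndarray:
    """Weakly positive trait correlations; stability positive with all
    (equivalently neuroticism negative), per the Big Five structure."""
    phi = np.full((5, 5), 0.20)
    np.fill_diagonal(phi, 1.0)
    return phi


@dataclass
class SimConfig:
    group_names: tuple[str, str] = ("G1", "G2")
    group_sizes: tuple[int, int] = (423, 143)
    constructs: tuple[str, ...] = CONSTRUCTS
    items_per_construct: dict = field(default_factory=lambda: dict(ITEMS_PER_CONSTRUCT))
    n_categories: int = 5
    k_vignettes: int = 3
    # latent structure
    mu: np.ndarray | None = None            # (groups, constructs); zeros = no trait DIF
    phi: np.ndarray | None = None           # trait correlation matrix
    # items
    a_range: tuple[float, float] = (1.2, 2.2)
    base_thresholds: tuple[float, ...] = (-1.8, -0.6, 0.6, 1.8)
    reverse_every: int = 3                  # every reverse_every-th item is reverse keyed
    # DIF and response styles
    delta: tuple[float, float] = (0.0, 0.8)  # group threshold shift
    sigma_acquiescence: float = 0.3
    sigma_extremity: float = 0.25            # sd of log(gamma)
    # vignettes
    vignette_locations: tuple[float, ...] = (-1.5, 0.0, 1.5)
    vignette_discrimination: float = 2.5
    perception_sd: float = 0.2
    vignette_rating_noise: float = 1.0   # logistic scale of the rating act; 0 = deterministic
    misorder_rate: float = 0.0
    # outcomes
    outcome_thresholds_7: tuple[float, ...] = (-2.0, -1.2, -0.4, 0.4, 1.2, 2.0)
    ls_loadings: dict = field(default_factory=lambda: {
        "extraversion": 0.30, "conscientiousness": 0.20, "neuroticism": 0.30})
    cb_loadings: dict = field(default_factory=lambda: {
        "conscientiousness": -0.35, "agreeableness": -0.30, "neuroticism": -0.20})
    outcome_noise_sd: float = 0.8
    # when False, outcome items are discretized with the *base* thresholds
    # (no person styles, no group shift): outcomes depend on latent traits only
    outcome_styles: bool = True

    def resolved_mu(self) -> np.ndarray:
        if self.mu is not None:
            return np.asarray(self.mu, dtype=float)
        return np.zeros((len(self.group_names), len(self.constructs)))

    def resolved_phi(self) -> np.ndarray:
        phi = _default_phi() if self.phi is None else np.asarray(self.phi, dtype=float)
        if np.any(np.linalg.eigvalsh(phi) <= 0):
            raise ValueError("trait correlation matrix must be positive definite")
        return phi


def default_codebook(config: SimConfig | None = None) -> SurveyCodebook:
    """Codebook matching the generator's layout (items ``<construct>_<j>``)."""
    config = config or SimConfig()
    items = []
    for c in config.constructs:
        for j in range(1, config.items_per_construct[c] + 1):
            items.append(ItemSpec(
                item_id=f"{c}_{j}", construct=c,
                reverse_keyed=(j % config.reverse_every == 0),
                scale=LikertScale(config.n_categories)))
    vsets = {
        c: VignetteSet(c, tuple(f"{c}_v{j}" for j in range(1, config.k_vignettes + 1)),
                       LikertScale(config.n_categories))
        for c in config.constructs
    }
    outcomes = (
        OutcomeScale("life_satisfaction", tuple(f"ls_{j}" for j in range(1, 6)),
                     LikertScale(5)),
        OutcomeScale("counterproductive", tuple(f"cb_{j}" for j in range(1, 8)),
                     LikertScale(7)),
    )
    return SurveyCodebook(
        constructs=config.constructs, items=tuple(items), vignette_sets=vsets,
        outcomes=outcomes, group_column="group",
        score_reversed_constructs=frozenset({"neuroticism"}),
    )


@dataclass
class SimResult:
    table: ResponseTable          # raw, unkeyed responses
    codebook: SurveyCodebook
    truth: pd.DataFrame           # per-respondent latent traits, styles, thresholds

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "responses.csv")
        self.codebook.to_yaml(outdir / "codebook.yaml")
        self.truth.to_csv(outdir / "truth.csv", index_label="respondent")


def _graded_response(u: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Response = 1 + number of person thresholds strictly below the utility.

    ``u``: (n,) utilities; ``tau``: (n, m-1) strictly increasing thresholds.
    """
    return 1 + (tau < u[:, None]).sum(axis=1)


def simulate(config: SimConfig | None = None, seed: int = 0) -> SimResult:
    """Draw one synthetic two-group cohort; bit-reproducible from ``seed``."""
    config = config or SimConfig()
    codebook = default_codebook(config)
    q = len(config.constructs)
    mu, phi = config.resolved_mu(), config.resolved_phi()

    ss = np.random.SeedSequence(seed)
    r_traits, r_items, r_styles, r_noise, r_misorder = (
        np.random.default_rng(s) for s in ss.spawn(5))

    n_total = sum(config.group_sizes)
    group_idx = np.repeat(np.arange(len(config.group_names)), config.group_sizes)
    groups = np.array(config.group_names)[group_idx]

    # latent traits
    chol = np.linalg.cholesky(phi)
    theta = r_traits.standard_normal((n_total, q)) @ chol.T + mu[group_idx]

    # person styles and thresholds (shared across instruments: response
    # consistency true by construction)
    alpha = r_styles.normal(0.0, config.sigma_acquiescence, n_total)
    # unit-mean lognormal: sigma_extremity is a mean-preserving spread, so
    # raising it adds extreme responders without shifting the average
    # threshold scale
    sg = config.sigma_extremity
    gamma = np.exp(r_styles.normal(-sg**2 / 2, sg, n_total))
    delta = np.asarray(config.delta)[group_idx]
    b = np.asarray(config.base_thresholds)
    tau = alpha[:, None] + gamma[:, None] * (b[None, :] + delta[:, None])
    b7 = np.asarray(config.outcome_thresholds_7)
    tau7 = alpha[:, None] + gamma[:, None] * (b7[None, :] + delta[:, None])
    assert np.all(np.diff(tau, axis=1) > 0) and np.all(np.diff(tau7, axis=1) > 0)

    data: dict[str, np.ndarray] = {}
    truth_a: dict[str, float] = {}
    for ci, c in enumerate(config.constructs):
        # self-report items
        for j in range(1, config.items_per_construct[c] + 1):
            a_i = r_items.uniform(*config.a_range)
            truth_a[f"{c}_{j}"] = a_i
            u = a_i * theta[:, ci] + r_noise.logistic(0.0, 1.0, n_total)
            resp = _graded_response(u, tau)
            if j % config.reverse_every == 0:   # stored in reversed wording
                resp = config.n_categories + 1 - resp
            data[f"{c}_{j}"] = resp
        # vignettes: same thresholds, location + perception noise
        zcols = []
        for vj, loc in enumerate(config.vignette_locations, start=1):
            perceived = loc + (r_noise.normal(0.0, config.perception_sd, n_total)
                               if config.perception_sd > 0 else np.zeros(n_total))
            u = config.vignette_discrimination * perceived
            if config.vignette_rating_noise > 0:
                u = u + r_noise.logistic(0.0, config.vignette_rating_noise, n_total)
            zcols.append(_graded_response(u, tau))
        z = np.column_stack(zcols)
        if config.misorder_rate > 0:
            hit = r_misorder.random(n_total) < config.misorder_rate
            for i in np.flatnonzero(hit):
                z[i] = r_misorder.permutation(z[i])
        for vj in range(config.k_vignettes):
            data[f"{c}_v{vj + 1}"] = z[:, vj]

    # outcomes: linear in latent traits, discretized with the person's own
    # thresholds (outcome items remain DIF-affected, as in a real survey)
    cidx = {c: i for i, c in enumerate(config.constructs)}
    if not config.outcome_styles:
        tau_ls = np.broadcast_to(b, (n_total, len(b)))
        tau_cb = np.broadcast_to(b7, (n_total, len(b7)))
    else:
        tau_ls, tau_cb = tau, tau7
    for prefix, loadings, n_items, tau_o in (
        ("ls", config.ls_loadings, 5, tau_ls),
        ("cb", config.cb_loadings, 7, tau_cb),
    ):
        eta = sum(w * theta[:, cidx[c]] for c, w in loadings.items())
        for j in range(1, n_items + 1):
            u = eta + r_noise.normal(0.0, config.outcome_noise_sd, n_total) \
                + r_noise.logistic(0.0, 1.0, n_total)
            data[f"{prefix}_{j}"] = _graded_response(u, tau_o)

    df = pd.DataFrame(data, index=pd.Index(range(n_total), name="respondent"))
    df.insert(0, "group", groups)
    table = from_dataframe(df, codebook)

    truth = pd.DataFrame(
        {"group": groups, "alpha": alpha, "gamma": gamma,
         **{f"theta_{c}": theta[:, i] for i, c in enumerate(config.constructs)},
         **{f"tau_{k + 1}": tau[:, k] for k in range(tau.shape[1])}},
        index=df.index,
    )
    truth.attrs["item_discriminations"] = truth_a
    return SimResult(table=table, codebook=codebook, truth=truth)


def _cohens_d(x: pd.Series, g: pd.Series, names: tuple[str, str]) -> float:
    a = x[g == names[0]].dropna().to_numpy(dtype=float)
    b = x[g == names[1]].dropna().to_numpy(dtype=float)
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((a.mean() - b.mean()) / sp)


def recovery_report(
    raw_scores: pd.DataFrame,
    adj_scores: pd.DataFrame,
    truth: pd.DataFrame,
    constructs: tuple[str, ...] = CONSTRUCTS,
) -> pd.DataFrame:
    """Score-vs-truth summary: validity correlations and between-group bias.

    For each construct: the correlation of raw and adjusted scale scores
    with the generating trait, the standardized between-group difference
    (Cohen's d) of raw scores, adjusted scores and the latent truth, and the
    bias of each score's difference relative to the latent difference.
    Scores must be in the generator's (vignette) orientation.
    """
    g = truth["group"]
    names = tuple(pd.unique(g))[:2]
    rows = []
    for c in constructs:
        th = truth[f"theta_{c}"]
        d_lat = _cohens_d(th, g, names)
        d_raw = _cohens_d(raw_scores[c], g, names)
        d_adj = _cohens_d(adj_scores[c], g, names)
        rows.append({
            "construct": c,
            "corr_raw": float(raw_scores[c].astype(float).corr(th)),
            "corr_adjusted": float(adj_scores[c].astype(float).corr(th)),
            "d_latent": d_lat, "d_raw": d_raw, "d_adjusted": d_adj,
            "bias_raw": d_raw - d_lat, "bias_adjusted": d_adj - d_lat,
        })
    return pd.DataFrame(rows).set_index("construct")
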