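"""Deleterious-pleiotropy battery: line-level fitness genetics and its
(non-)covariation with wing shape.

Isofemale lines reared in a common garden are assayed for five fitness
components (adult longevity with right-censoring, developmental rate,
juvenile survival, body size, early reproductive success). The battery
asks whether standing genetic variation in wing shape carries deleterious
pleiotropic side effects: heritable line variation per trait (REML mixed
model with heteroscedastic residuals by treatment), a genetic-quality PC1
from line BLUPs with two randomization nulls, a shape-fitness two-block
PLS, and a stabilizing-selection distance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .morphometrics import PLSResult, two_block_pls

__all__ = [
    "VarianceComponents",
    "variance_components",
    "survival_blups",
    "quality_pca",
    "residualize_shapes",
    "shape_fitness_pls",
    "stabilizing_test",
]

FITNESS_TRAITS = [
    "longevity",
    "developmental_rate",
    "juvenile_survival",
    "body_size",
    "early_repro",
]


# ---------------------------------------------------------------------------
# One-random-effect REML with heteroscedastic residuals by treatment
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    V_line: float
    V_resid: dict  # treatment level -> residual variance
    chi2_LRT: float
    p_boundary: float  # 0.5*chi2_0 + 0.5*chi2_1 mixture
    p_plain: float  # plain chi2_1 (as conventionally reported)
    blups: pd.Series  # line-level shrinkage predictions
    loglik: float
    loglik_null: float


def _design_matrix(df: pd.DataFrame, treatment: str, population: str) -> np.ndarray:
    """Cell-means fixed-effect design: one column per observed
    treatment x population cell (spans main effects + interaction)."""
    cell = df[treatment].astype(str) + "||" + df[population].astype(str)
    return pd.get_dummies(cell).to_numpy(dtype=float)


def _reml_negll(y, X, line_codes, n_lines, treat_codes, n_treat, theta):
    """Negative REML log-likelihood; theta = (log V_line, log V_t ...).

    Lines are independent blocks; each block covariance is
    diag(V_treat) + V_line * 11', inverted by rank-one Woodbury.
    """
    V_line = np.exp(theta[0])
    V_t = np.exp(theta[1:])
    r = V_t[treat_codes]  # per-observation residual variance
    ri = 1.0 / r

    # accumulate per-line Woodbury pieces
    logdet = float(np.sum(np.log(r)))
    s_l = np.bincount(line_codes, weights=ri, minlength=n_lines)
    denom = 1.0 + V_line * s_l
    logdet += float(np.sum(np.log(denom)))

    def Vinv_mul(B):
        # V^{-1} B for stacked observations (B: (n, q))
        RB = B * ri[:, None]
        sums = np.zeros((n_lines, B.shape[1]))
        np.add.at(sums, line_codes, RB)
        corr = (V_line / denom)[:, None] * sums
        return RB - ri[:, None] * corr[line_codes]

    yv = y[:, None]
    Vy = Vinv_mul(yv)
    XtVX = X.T @ Vinv_mul(X)
    XtVy = X.T @ Vy
    try:
        c = np.linalg.cholesky(XtVX)
    except np.linalg.LinAlgError:
        return 1e300
    logdet_X = 2 * float(np.sum(np.log(np.diag(c))))
    beta = np.linalg.solve(XtVX, XtVy)
    yPy = float((yv.T @ Vy).item()) - float((XtVy.T @ beta).item())
    return 0.5 * (logdet + logdet_X + yPy)


def variance_components(
    table: pd.DataFrame,
    trait: str,
    line: str = "line",
    treatment: str = "treatment",
    population: str = "population",
) -> VarianceComponents:
    """REML variance components for one fitness trait.

    Model: trait ~ treatment*population (fixed) + line (random intercept),
    residual variances free per treatment. The line effect is tested by a
    likelihood-ratio test against the no-line model; because the null puts
    the variance on the boundary, the mixture p (half a chi-square on one
    df) is reported alongside the plain chi-square p.
    """
    df = table.dropna(subset=[trait]).copy()
    y = df[trait].to_numpy(dtype=float)
    if y.std() == 0:
        raise ValueError(f"trait {trait!r} is constant")
    line_codes, line_levels = pd.factorize(df[line])
    treat_codes, treat_levels = pd.factorize(df[treatment])
    n_lines, n_treat = len(line_levels), len(treat_levels)
    per_line = np.bincount(line_codes, minlength=n_lines)
    if np.mean(per_line >= 2) < 0.8:
        raise ValueError("need >= 2 observations for >= 80% of lines "
                         "(line variance otherwise confounded with residual)")
    X = _design_matrix(df, treatment, population)
    # drop collinear columns
    q, rmat = np.linalg.qr(X)
    keep = np.abs(np.diag(rmat)) > 1e-8 * np.abs(np.diag(rmat)).max()
    X = X[:, keep]

    v0 = y.var()
    x0 = np.log(np.concatenate([[v0 / 4], np.full(n_treat, v0 / 2)]))

    def obj(theta):
        return _reml_negll(y, X, line_codes, n_lines, treat_codes, n_treat, theta)

    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"REML did not converge for {trait}: {res.message}")
    theta = res.x
    ll_full = -res.fun

    # null model: V_line -> 0 (drop the random effect)
    def obj0(eta):
        th = np.concatenate([[-60.0], eta])
        return _reml_negll(y, X, line_codes, n_lines, treat_codes, n_treat, th)

    res0 = optimize.minimize(obj0, x0[1:], method="Nelder-Mead",
                             options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    ll_null = -res0.fun
    chi2 = max(0.0, 2 * (ll_full - ll_null))
    p_plain = float(stats.chi2.sf(chi2, 1))
    p_boundary = 0.5 * p_plain if chi2 > 0 else 1.0

    # BLUPs at the REML estimates
    V_line = float(np.exp(theta[0]))
    V_t = np.exp(theta[1:])
    r = V_t[treat_codes]
    ri = 1.0 / r
    s_l = np.bincount(line_codes, weights=ri, minlength=n_lines)
    denom = 1.0 + V_line * s_l

    def Vinv_mul(B):
        RB = B * ri[:, None]
        sums = np.zeros((n_lines, B.shape[1]))
        np.add.at(sums, line_codes, RB)
        corr = (V_line / denom)[:, None] * sums
        return RB - ri[:, None] * corr[line_codes]

    XtVX = X.T @ Vinv_mul(X)
    beta = np.linalg.solve(XtVX, X.T @ Vinv_mul(y[:, None]))
    resid = y - (X @ beta).ravel()
    Vr = Vinv_mul(resid[:, None]).ravel()
    u = V_line * np.bincount(line_codes, weights=Vr, minlength=n_lines)

    return VarianceComponents(
        V_line=V_line,
        V_resid={str(lev): float(v) for lev, v in zip(treat_levels, V_t)},
        chi2_LRT=float(chi2),
        p_boundary=float(p_boundary),
        p_plain=p_plain,
        blups=pd.Series(u, index=line_levels, name=trait),
        loglik=float(ll_full),
        loglik_null=float(ll_null),
    )


# ---------------------------------------------------------------------------
# Censored longevity: rank-based line scores
# ---------------------------------------------------------------------------

def survival_blups(
    table: pd.DataFrame,
    time: str = "longevity",
    censored: str = "censored",
    line: str = "line",
    shrinkage: float = 5.0,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Line-level longevity scores from censored lifetimes.

    Each observation receives a martingale-type residual under the pooled
    Nelson-Aalen cumulative hazard (death indicator minus cumulative hazard
    at the observed time); a line's score is the negated residual sum
    shrunk toward zero by line sample size, so higher scores mean
    longer-lived lines. The line effect is tested by permuting line labels
    (statistic: variance of the line scores).
    """
    from lifelines import NelsonAalenFitter

    df = table.dropna(subset=[time]).copy()
    event = ~df[censored].astype(bool).to_numpy()
    if not event.any():
        raise ValueError("all observations censored: no deaths to rank")
    t = df[time].to_numpy(dtype=float)
    naf = NelsonAalenFitter()
    naf.fit(t, event_observed=event)
    H = naf.cumulative_hazard_at_times(t).to_numpy()
    resid = event.astype(float) - H  # martingale residual (null model)

    codes, levels = pd.factorize(df[line])
    n_lines = len(levels)

    def scores_for(c):
        sums = np.bincount(c, weights=resid, minlength=n_lines)
        counts = np.bincount(c, minlength=n_lines)
        return -sums / (counts + shrinkage)

    obs = scores_for(codes)
    stat_obs = obs.var()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if scores_for(rng.permutation(codes)).var() >= stat_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"scores": pd.Series(obs, index=levels, name="longevity_score"),
            "p_perm": float(p), "n_events": int(event.sum()),
            "censor_rate": float(1 - event.mean())}


# ---------------------------------------------------------------------------
# Genetic-quality PC1 with two randomization nulls
# ---------------------------------------------------------------------------

def quality_pca(blups: pd.DataFrame, n_rand: int = 1000,
                seed: int | None = None) -> dict:
    """PCA of the trait correlation matrix of line BLUPs.

    pct_var is the share of the leading eigenvalue. Two nulls for "is PC1
    bigger than chance": (1) iid standard-normal matrices of the same
    shape; (2) independently permuting each trait's BLUPs across lines
    (destroys trait correlations, keeps marginals). PC1 is oriented so its
    loading sum is positive.
    """
    B = blups.to_numpy(dtype=float)
    n, p = B.shape
    if p < 3 or n < 10:
        raise ValueError("need >= 3 traits and >= 10 lines")
    if np.any(B.std(axis=0) == 0):
        raise ValueError("constant trait column")

    def pc1_share(M):
        C = np.corrcoef(M, rowvar=False)
        vals = np.linalg.eigvalsh(C)
        return vals[-1] / vals.sum()

    C = np.corrcoef(B, rowvar=False)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    loadings = vecs[:, 0]
    if loadings.sum() < 0:
        loadings = -loadings
    pct = float(vals[0] / vals.sum())
    scores = (B - B.mean(axis=0)) / B.std(axis=0, ddof=1) @ loadings

    rng = np.random.default_rng(seed)
    null_matrix = np.empty(n_rand)
    null_perm = np.empty(n_rand)
    for b in range(n_rand):
        null_matrix[b] = pc1_share(rng.standard_normal((n, p)))
        P = np.column_stack([B[rng.permutation(n), j] for j in range(p)])
        null_perm[b] = pc1_share(P)
    p_matrix = (np.sum(null_matrix >= pct) + 1) / (n_rand + 1)
    p_perm = (np.sum(null_perm >= pct) + 1) / (n_rand + 1)
    return {
        "loadings": pd.Series(loadings, index=blups.columns),
        "pct_var": pct,
        "scores": pd.Series(scores, index=blups.index, name="PC1"),
        "p_rand_matrix": float(p_matrix),
        "p_rand_perm": float(p_perm),
        "null_matrix": null_matrix,
        "null_perm": null_perm,
        "eigenvalues": vals,
    }


# ---------------------------------------------------------------------------
# Shape-fitness covariation
# ---------------------------------------------------------------------------

def residualize_shapes(line_shapes: np.ndarray, sizes: np.ndarray,
                       populations: np.ndarray) -> np.ndarray:
    """Residuals of line mean shapes on centroid size and population
    (accounts for allometry and local adaptation before fitness tests)."""
    Y = np.asarray(line_shapes, dtype=float)
    X = np.column_stack([
        np.asarray(sizes, dtype=float),
        pd.get_dummies(pd.Series(populations)).to_numpy(dtype=float),
    ])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def shape_fitness_pls(
    line_shapes: np.ndarray,
    block2: np.ndarray | pd.Series | pd.DataFrame,
    sizes: np.ndarray | None = None,
    populations: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> PLSResult:
    """Two-block PLS of line mean shapes against fitness.

    Block 1 is shape residualized on size and population when those are
    supplied; block 2 is PC1 scores or the 5-trait BLUP matrix.
    """
    Y = np.asarray(line_shapes, dtype=float)
    if sizes is not None and populations is not None:
        Y = residualize_shapes(Y, sizes, populations)
    B2 = block2.to_numpy() if hasattr(block2, "to_numpy") else np.asarray(block2)
    if B2.ndim == 1:
        B2 = B2[:, None]
    return two_block_pls(Y, B2.astype(float), n_perm=n_perm, seed=seed)


def stabilizing_test(
    line_shapes: np.ndarray,
    fitness: pd.DataFrame,
    sizes: np.ndarray | None = None,
    populations: np.ndarray | None = None,
) -> dict:
    """Correlation between line fitness and distance from the mean shape.

    Stabilizing selection on wing shape predicts fitness to decline with a
    line's multivariate (Procrustes) distance from the average wing. The
    per-trait Pearson correlation and two-sided t-test are reported, plus
    an outlier-robust rerun excluding the most distant line.
    """
    Y = np.asarray(line_shapes, dtype=float)
    if sizes is not None and populations is not None:
        Y = residualize_shapes(Y, sizes, populations)
    dist = np.linalg.norm(Y - Y.mean(axis=0), axis=1)
    if dist.std() == 0:
        raise ValueError("zero variance in shape distances")
    if len(dist) < 10:
        raise ValueError("need >= 10 lines")

    def corr_table(mask):
        rows = []
        for col in fitness.columns:
            f = fitness[col].to_numpy(dtype=float)
            r, p = stats.pearsonr(dist[mask], f[mask])
            rows.append({"trait": col, "r": r, "p": p})
        return pd.DataFrame(rows).set_index("trait")

    full = np.ones(len(dist), dtype=bool)
    no_outlier = full.copy()
    no_outlier[np.argmax(dist)] = False
    return {"correlations": corr_table(full),
            "correlations_no_outlier": corr_table(no_outlier),
            "distances": dist}
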