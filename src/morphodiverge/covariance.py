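"""Covariance-matrix estimation and common-subspace comparison.

The pipeline works with several 22x22 shape covariance matrices:

* ``D`` — covariance of left-right fluctuating-asymmetry vectors
  (developmental variability),
* ``G`` — among-isofemale-line covariance (standing genetic variation),
* ``P`` — pooled phenotypic covariance,
* ``M`` — mutational covariance (external input),
* ``R`` — evolutionary rate matrix (see :mod:`morphodiverge.phylo`).

Matrices are compared by the variances each expresses along a shared
orthonormal basis — the eigenvectors of an independently estimated
reference matrix (Krzanowski-style common subspace) — summarized by the
OLS slope and Pearson correlation of the log variances, with parametric
(Wishart) resampling for confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .morphometrics import N_COORDS, AlignedShapeTable, gpa, LandmarkConfig, N_LANDMARKS

MAX_SHAPE_RANK = 18  # 22 coordinates minus translation/rotation/scale

__all__ = [
    "CovMatrix",
    "ReferenceBasis",
    "SubspaceComparison",
    "estimate_P",
    "estimate_G",
    "estimate_D",
    "scale_by_trace",
    "effective_rank",
    "subspace_variances",
    "subspace_regression",
    "resample_comparison",
    "read_matrix_csv",
    "write_matrix_csv",
]


@dataclass
class CovMatrix:
    """Labelled symmetric PSD matrix with sample-size provenance."""

    values: np.ndarray
    role: str = "other"  # one of D, M, G, P, R, other
    n_units: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("covariance matrix must be square")
        asym = np.abs(V - V.T).max()
        tol = 1e-10 * max(1.0, np.abs(V).max())
        if asym > tol:
            raise ValueError(f"matrix is not symmetric (max asymmetry {asym:g})")
        self.values = (V + V.T) / 2
        ev = np.linalg.eigvalsh(self.values)
        if ev.min() < -1e-8 * max(self.trace, 1e-300):
            raise ValueError(f"matrix is not PSD (min eigenvalue {ev.min():g})")

    @property
    def trace(self) -> float:
        return float(np.trace(self.values))

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (descending) and matching eigenvector columns."""
        vals, vecs = np.linalg.eigh(self.values)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]


@dataclass
class ReferenceBasis:
    """Orthonormal columns (eigenvectors of a reference matrix, descending)."""

    vectors: np.ndarray  # (p, k)
    source_role: str = "P"

    def __post_init__(self) -> None:
        V = np.asarray(self.vectors, dtype=float)
        gram = V.T @ V
        if np.abs(gram - np.eye(V.shape[1])).max() > 1e-10:
            raise ValueError("basis columns are not orthonormal")
        self.vectors = V

    @classmethod
    def from_matrix(cls, C: CovMatrix, k: int | None = None) -> "ReferenceBasis":
        _, vecs = C.eigen()
        if k is not None:
            vecs = vecs[:, :k]
        return cls(vectors=vecs, source_role=C.role)


@dataclass
class SubspaceComparison:
    log_var_x: np.ndarray
    log_var_y: np.ndarray
    slope_beta: float
    intercept: float
    pearson_r: float
    ci_slope: tuple[float, float] | None = None
    ci_r: tuple[float, float] | None = None
    n_resamples: int = 0

    @property
    def k(self) -> int:
        return len(self.log_var_x)


# ---------------------------------------------------------------------------
# Estimation from structured shape samples
# ---------------------------------------------------------------------------

def estimate_P(table: AlignedShapeTable, grouping: str = "population") -> CovMatrix:
    """Pooled within-group phenotypic covariance of Procrustes coordinates."""
    labels = table.metadata[grouping].to_numpy()
    codes, uniques = pd.factorize(labels)
    n, g = len(table), len(uniques)
    if n <= g:
        raise ValueError(f"n={n} observations do not exceed {g} groups")
    S = np.zeros((table.shapes.shape[1],) * 2)
    for j in range(g):
        sel = table.shapes[codes == j]
        if len(sel) < 2:
            continue
        d = sel - sel.mean(axis=0)
        S += d.T @ d
    return CovMatrix(S / (n - g), role="P", n_units=n - g,
                     provenance=f"pooled within-{grouping}")


def estimate_G(table: AlignedShapeTable, line: str = "line",
               population: str = "population") -> CovMatrix:
    """Among-line covariance of line mean shapes, centred by population.

    Isofemale-line means act as breeding-value proxies; the estimate
    includes a within-line attenuation term of order Sigma_within/m for m
    individuals per line (reported, not corrected).
    """
    md = table.metadata
    if md[line].nunique() < 3:
        raise ValueError("need at least 3 lines to estimate G")
    df = pd.DataFrame(table.shapes)
    df["_line"] = md[line].to_numpy()
    df["_pop"] = md[population].to_numpy()
    line_means = df.groupby(["_pop", "_line"], observed=True).mean()
    pops = line_means.index.get_level_values(0)
    n_pops = pops.nunique()
    centred = line_means.groupby(level=0, observed=True).transform(lambda x: x - x.mean())
    X = centred.to_numpy()
    n_lines = len(X)
    if n_lines <= n_pops:
        raise ValueError("need more lines than populations")
    G = X.T @ X / (n_lines - n_pops)
    return CovMatrix(G, role="G", n_units=n_lines - n_pops,
                     provenance=f"{n_lines} line means, {n_pops} populations")


def estimate_D(
    configs_or_table,
    individual: str = "specimen_id",
    side: str = "side",
    reference: np.ndarray | None = None,
) -> CovMatrix:
    """Covariance of left-right fluctuating-asymmetry vectors.

    Right-side configurations are reflected, all sides superimposed jointly
    (reflection allowed in the fit), and the per-individual L-R coordinate
    difference vectors are collected. The mean asymmetry (directional
    asymmetry) is removed, leaving fluctuating asymmetry only.

    Pass ``reference`` (a consensus configuration) to fix the coordinate
    frame when D will be compared against matrices estimated elsewhere —
    superimpositions are otherwise only defined up to rotation.
    """
    if isinstance(configs_or_table, AlignedShapeTable):
        table = configs_or_table
    else:
        configs = list(configs_or_table)
        reflected = []
        for c in configs:
            coords = c.coords.copy()
            if c.side == "R":
                coords[:, 0] = -coords[:, 0]
            reflected.append(LandmarkConfig(coords=coords, specimen_id=c.specimen_id,
                                            species=c.species, family=c.family,
                                            line=c.line, population=c.population,
                                            side=c.side, source=c.source))
        table = gpa(reflected, allow_reflection=True, reference=reference)

    md = table.metadata
    diffs = []
    for ind, grp in md.groupby(individual):
        sides = grp[side].to_numpy()
        if "L" in sides and "R" in sides:
            li = grp.index[sides == "L"][0]
            ri = grp.index[sides == "R"][0]
            diffs.append(table.shapes[li] - table.shapes[ri])
    if len(diffs) < 3:
        raise ValueError(f"only {len(diffs)} complete L/R pairs; need >= 3")
    A = np.array(diffs)
    A -= A.mean(axis=0)
    D = A.T @ A / (len(A) - 1)
    return CovMatrix(D, role="D", n_units=len(A),
                     provenance=f"{len(A)} L/R pairs, directional asymmetry removed")


# ---------------------------------------------------------------------------
# Scaling, rank, subspace comparison
# ---------------------------------------------------------------------------

def scale_by_trace(C: CovMatrix) -> CovMatrix:
    """Return C / trace(C), preserving role and provenance."""
    t = C.trace
    if t <= 0:
        raise ValueError("cannot trace-scale a zero-trace matrix")
    return CovMatrix(C.values / t, role=C.role, n_units=C.n_units,
                     provenance=(C.provenance + " [trace-scaled]").strip())


def effective_rank(C: CovMatrix, n_units: int | None = None,
                   max_rank: int = MAX_SHAPE_RANK) -> int:
    """Effective rank by AIC over factor-analytic approximations.

    For each candidate rank k the estimate is modelled as Wishart with a
    rank-k-plus-isotropic scale (leading k eigenpairs kept, the remaining
    spectrum replaced by its mean); the k minimising AIC is returned,
    capped at the shape-space dimension. This stands in for reduced-rank
    factor-analytic REML model selection.
    """
    n = n_units if n_units is not None else C.n_units
    if n is None or n < 5:
        raise ValueError("effective_rank needs n_units >= 5")
    p = C.dim
    vals, vecs = C.eigen()
    vals = np.maximum(vals, 0.0)
    S = C.values
    max_rank = min(max_rank, p)
    best_k, best_aic = 1, np.inf
    floor = 1e-12 * max(C.trace, 1e-300)
    for k in range(1, max_rank + 1):
        resid = vals[k:]
        sigma2 = max(resid.mean() if len(resid) else 0.0, floor)
        model_vals = np.concatenate([np.maximum(vals[:k], sigma2),
                                     np.full(p - k, sigma2)])
        Sigma = (vecs * model_vals) @ vecs.T
        sign, logdet = np.linalg.slogdet(Sigma)
        tr = float(np.trace(np.linalg.solve(Sigma, S)))
        ll = -0.5 * n * (logdet + tr)
        n_par = k * p - k * (k - 1) // 2 + 1
        aic = -2 * ll + 2 * n_par
        if aic < best_aic - 1e-9:
            best_aic, best_k = aic, k
    return best_k


def subspace_variances(X: CovMatrix | np.ndarray,
                       basis: ReferenceBasis | np.ndarray,
                       k: int | None = None) -> np.ndarray:
    """Variances of X along the basis columns: diag(B^T X B), first k."""
    Xv = X.values if isinstance(X, CovMatrix) else np.asarray(X, dtype=float)
    B = basis.vectors if isinstance(basis, ReferenceBasis) else np.asarray(basis, dtype=float)
    if B.shape[0] != Xv.shape[0]:
        raise ValueError(f"basis dimension {B.shape[0]} != matrix dimension {Xv.shape[0]}")
    if k is not None:
        if k > B.shape[1]:
            raise ValueError(f"k={k} exceeds {B.shape[1]} basis vectors")
        B = B[:, :k]
    return np.einsum("ij,jk,ki->i", B.T, Xv, B)


def subspace_regression(X: CovMatrix, Y: CovMatrix,
                        basis: ReferenceBasis | np.ndarray,
                        k: int = 10) -> SubspaceComparison:
    """Regress log variances of Y on log variances of X along a common basis.

    X is the predictor (developmental/mutational variance), Y the response
    (macroevolutionary variance). Natural logs; slope and r are invariant
    to trace-scaling of either matrix (intercept shifts).
    """
    vx = subspace_variances(X, basis, k)
    vy = subspace_variances(Y, basis, k)
    for name, v in (("X", vx), ("Y", vy)):
        bad = np.where(v <= 0)[0]
        if len(bad):
            raise ValueError(f"nonpositive variance along dimension {bad[0]} of {name}")
    lx, ly = np.log(vx), np.log(vy)
    fit = stats.linregress(lx, ly)
    return SubspaceComparison(
        log_var_x=lx, log_var_y=ly,
        slope_beta=float(fit.slope), intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
    )


def _wishart_draw(rng: np.ndarray, C: CovMatrix) -> CovMatrix:
    """One Wishart(df=n_units, scale=C/df) draw via the PSD square root.

    Realized as L Z Z^T L^T / df so rank-deficient estimates resample
    without jitter.
    """
    df = C.n_units
    vals, vecs = C.eigen()
    L = vecs * np.sqrt(np.maximum(vals, 0.0))
    Z = rng.standard_normal((C.dim, df))
    W = L @ Z @ Z.T @ L.T / df
    return CovMatrix((W + W.T) / 2, role=C.role, n_units=df)


def resample_comparison(
    X: CovMatrix,
    Y: CovMatrix,
    basis: ReferenceBasis | np.ndarray,
    k: int = 10,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> SubspaceComparison:
    """Subspace regression with parametric-resampling confidence intervals.

    Each matrix is resampled from a Wishart distribution with df = its
    n_units and scale = estimate/df (normal-theory sampling error of a
    REML estimate), the slope and correlation recomputed per draw, and the
    2.5/97.5 percentiles reported.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    for C, name in ((X, "X"), (Y, "Y")):
        if C.n_units is None:
            raise ValueError(f"matrix {name} has no n_units for resampling")
    point = subspace_regression(X, Y, basis, k)
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_resamples)
    rs = np.empty(n_resamples)
    done = 0
    attempts = 0
    while done < n_resamples and attempts < 20 * n_resamples:
        attempts += 1
        try:
            cmp_b = subspace_regression(_wishart_draw(rng, X), _wishart_draw(rng, Y),
                                        basis, k)
        except ValueError:  # nonpositive variance in a draw: redraw
            continue
        slopes[done] = cmp_b.slope_beta
        rs[done] = cmp_b.pearson_r
        done += 1
    if done < n_resamples:
        raise RuntimeError("resampling failed to produce valid draws")
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    rlo, rhi = np.percentile(rs, [2.5, 97.5])
    point.ci_slope = (float(lo), float(hi))
    point.ci_r = (float(rlo), float(rhi))
    point.n_resamples = n_resamples
    return point


# ---------------------------------------------------------------------------
# Matrix file I/O
# ---------------------------------------------------------------------------

def write_matrix_csv(path, C: CovMatrix) -> None:
    """Plain CSV with a one-line '# role=... n_units=...' header comment."""
    with open(path, "w") as fh:
        fh.write(f"# role={C.role} n_units={C.n_units if C.n_units is not None else ''}\n")
        np.savetxt(fh, C.values, delimiter=",")


def read_matrix_csv(path, role: str | None = None) -> CovMatrix:
    """Read a matrix CSV (also accepts whitespace-delimited plain matrices)."""
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        key, val = tok.split("=", 1)
                        meta[key] = val
                continue
            rows.append([float(x) for x in line.replace(",", " ").split()])
    V = np.array(rows)
    n_units = int(meta["n_units"]) if meta.get("n_units") else None
    return CovMatrix(V, role=role or meta.get("role", "other"), n_units=n_units,
                     provenance=f"read from {path}")
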