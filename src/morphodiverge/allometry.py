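"""Evolutionary allometry: shape-on-size regression, alignment tests, and
allometry-free residual shapes.

Allometry — systematic covariation of shape with size — is a candidate
common cause for the alignment between developmental variability and
macroevolutionary divergence: correlational selection for allometric
scaling could shape both. The module estimates the multivariate allometric
vector (regression of the 22 Procrustes coordinates on log centroid size),
tests its alignment with covariance matrices against a random-direction
null, and residualizes shapes on a common allometric slope so the rate
matrix can be re-estimated allometry-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .covariance import CovMatrix, scale_by_trace, ReferenceBasis
from .morphometrics import AlignedShapeTable

__all__ = [
    "AllometryFit",
    "fit_allometry",
    "fit_allometry_gls",
    "vector_correlation",
    "expected_abs_cos",
    "alignment_null",
    "remove_allometry",
]


@dataclass
class AllometryFit:
    b_allom: np.ndarray  # regression slope of shape on log size (22-vector)
    unit_vector: np.ndarray  # normalized copy
    R2: float
    F: float
    p_perm: float
    df: tuple[int, int]


def _shape_size_arrays(shapes, sizes):
    Y = shapes.shapes if isinstance(shapes, AlignedShapeTable) else np.asarray(shapes, float)
    s = np.asarray(sizes, dtype=float)
    if np.any(s <= 0):
        raise ValueError("centroid sizes must be strictly positive")
    if s.std() == 0:
        raise ValueError("constant size: allometry is unidentifiable")
    return Y, np.log(s)


def fit_allometry(shapes, sizes, n_perm: int = 999,
                  seed: int | None = None) -> AllometryFit:
    """Multivariate regression of shape on log centroid size.

    Per-coordinate OLS gives the allometric shape-change vector; R^2 is the
    model sum of squares over the total (summed across coordinates), F uses
    the (1, n-2) single-predictor structure, and significance comes from
    permuting sizes across rows.
    """
    Y, x = _shape_size_arrays(shapes, sizes)
    n = len(x)
    if n < 10:
        raise ValueError("allometry fit needs n >= 10")
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sxx = float(xc @ xc)

    def stats_for(xcv):
        b = Yc.T @ xcv / sxx
        ss_model = sxx * float(b @ b)
        ss_total = float(np.sum(Yc**2))
        R2 = min(ss_model / ss_total, 1.0)
        ss_resid = max(ss_total - ss_model, 0.0)
        F = np.inf if ss_resid == 0 else (ss_model / 1) / (ss_resid / (n - 2))
        return b, R2, F

    b, R2, F = stats_for(xc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        Fp = stats_for(xc[rng.permutation(n)])[2]
        if Fp >= F:
            count += 1
    p = (count + 1) / (n_perm + 1)
    nrm = np.linalg.norm(b)
    return AllometryFit(b_allom=b, unit_vector=b / nrm if nrm > 0 else b,
                        R2=float(R2), F=float(F), p_perm=float(p), df=(1, n - 2))


def fit_allometry_gls(shapes, sizes, S: np.ndarray) -> np.ndarray:
    """Phylogenetic allometry: GLS slope of family mean shape on log size.

    ``S`` is the phylogenetic relationship matrix of the families (shared
    branch lengths); the returned 22-vector is the GLS regression slope,
    for comparison (vector correlation) with the ordinary estimate.
    """
    Y, x = _shape_size_arrays(shapes, sizes)
    Si = np.linalg.inv(S)
    one = np.ones(len(x))
    # GLS-centre x and Y by the phylogenetic mean
    w = Si @ one / (one @ Si @ one)
    xc = x - w @ x
    Yc = Y - np.outer(one, w @ Y)
    denom = float(xc @ Si @ xc)
    if denom <= 0:
        raise ValueError("degenerate size variation under the phylogeny")
    return (Yc.T @ (Si @ xc)) / denom


def expected_abs_cos(d: int) -> float:
    """E|cos angle| between two independent uniform unit vectors in R^d."""
    return float(special.gamma(d / 2) / (np.sqrt(np.pi) * special.gamma((d + 1) / 2)))


def vector_correlation(v1: np.ndarray, v2: np.ndarray, n_perm: int = 9999,
                       seed: int | None = None) -> dict:
    """Absolute cosine between two direction vectors, with a random-direction
    null: p = fraction of uniformly random unit-vector pairs of the same
    dimension whose |cos| meets or exceeds the observed."""
    v1 = np.asarray(v1, dtype=float).ravel()
    v2 = np.asarray(v2, dtype=float).ravel()
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal dimension")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero vector has no direction")
    r = abs(float(v1 @ v2) / (n1 * n2))
    d = len(v1)
    rng = np.random.default_rng(seed)
    # |cos| between two uniform directions == |cos| between one fixed and one
    # uniform direction (rotation invariance): simulate the cheap version
    g = rng.standard_normal((n_perm, d))
    cos = np.abs(g[:, 0]) / np.linalg.norm(g, axis=1)
    p = (np.sum(cos >= r) + 1) / (n_perm + 1)
    return {"r": r, "p": float(p)}


def alignment_null(vector: np.ndarray, C: CovMatrix, n_rand: int = 1000,
                   seed: int | None = None,
                   subspace: np.ndarray | None = None) -> dict:
    """Variance of a trace-scaled matrix captured by a direction, against a
    uniform random-direction null.

    captured = v' C' v for the unit-normalized vector (e_beta with |beta|=1).
    The null draws uniformly random unit vectors inside the shape subspace
    (columns of ``subspace`` if given, else the leading 18 eigenvectors of
    C) and reports P_RAND = fraction of random vectors capturing at least
    as much. A flag marks the degenerate isotropic case where the null has
    zero spread.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be >= 100")
    v = np.asarray(vector, dtype=float).ravel()
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("zero vector")
    v = v / nrm
    Cs = scale_by_trace(C).values
    captured = float(v @ Cs @ v)

    if subspace is None:
        _, vecs = C.eigen()
        k = min(18, C.dim)
        B = vecs[:, :k]
    else:
        B = np.asarray(subspace, dtype=float)
        k = B.shape[1]
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n_rand, k))
    G /= np.linalg.norm(G, axis=1, keepdims=True)
    dirs = G @ B.T  # (n_rand, p) unit vectors in the subspace
    null = np.einsum("ij,jk,ik->i", dirs, Cs, dirs)
    degenerate = bool(null.std() < 1e-12)
    p = (np.sum(null >= captured) + 1) / (n_rand + 1)
    return {"captured_fraction": captured, "P_RAND": float(p),
            "null": null, "degenerate": degenerate}


def remove_allometry(shapes, sizes) -> AlignedShapeTable | np.ndarray:
    """Residual shapes after removing a common allometric slope.

    The common (pooled) slope of shape on log centroid size is regressed
    out and the grand mean re-added, so residual rows remain interpretable
    shape configurations. Idempotent: residualizing twice equals once.
    """
    Y, x = _shape_size_arrays(shapes, sizes)
    xc = x - x.mean()
    mean = Y.mean(axis=0)
    Yc = Y - mean
    b = Yc.T @ xc / float(xc @ xc)
    resid = Yc - np.outer(xc, b) + mean
    if isinstance(shapes, AlignedShapeTable):
        return AlignedShapeTable(shapes=resid,
                                 centroid_sizes=shapes.centroid_sizes,
                                 metadata=shapes.metadata,
                                 consensus=shapes.consensus)
    return resid
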