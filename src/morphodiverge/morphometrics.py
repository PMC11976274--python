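"""Landmark geometric morphometrics: TPS I/O, Procrustes superimposition,
and the generic multivariate tests used throughout the pipeline.

Shapes are 11 two-dimensional landmarks per wing. After generalized
Procrustes analysis (GPA) each configuration is centred at the origin,
scaled to unit centroid size and rotated to the consensus, so the 22
Procrustes coordinates live in an (at most) 18-dimensional shape space
(4 dimensions are consumed by translation, rotation and scaling).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

N_LANDMARKS = 11
N_COORDS = 2 * N_LANDMARKS

__all__ = [
    "LandmarkConfig",
    "AlignedShapeTable",
    "PLSResult",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "read_landmark_csv",
    "write_landmark_csv",
    "centroid_size",
    "gpa",
    "procrustes_distance",
    "procrustes_anova",
    "cva_loo",
    "two_block_pls",
]


class TPSParseError(ValueError):
    """Raised for malformed TPS records; carries the offending line number."""


@dataclass
class LandmarkConfig:
    """One digitized landmark configuration plus its nesting metadata."""

    coords: np.ndarray  # (11, 2), raw digitized units (scale applied if known)
    specimen_id: str = ""
    species: str = ""
    family: str = ""
    line: str = ""
    population: str = ""
    side: str = "unknown"  # 'L', 'R' or 'unknown'
    source: str = ""  # 'photo' or 'illustration'
    has_scale: bool = False
    scale_factor: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"expected {N_LANDMARKS} two-dimensional landmarks, "
                f"got array of shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark configuration contains missing coordinates")


@dataclass
class AlignedShapeTable:
    """Procrustes-aligned coordinate vectors with nesting metadata.

    ``shapes`` rows are flattened (x1, y1, ..., x11, y11) Procrustes
    coordinates; ``centroid_sizes`` are recorded before unit scaling.
    """

    shapes: np.ndarray  # (n, 22)
    centroid_sizes: np.ndarray  # (n,)
    metadata: pd.DataFrame
    consensus: np.ndarray  # (22,)

    def __len__(self) -> int:
        return self.shapes.shape[0]

    def configs(self) -> np.ndarray:
        """Aligned configurations as an (n, 11, 2) array."""
        return self.shapes.reshape(-1, N_LANDMARKS, 2)


@dataclass
class PLSResult:
    r_pls: float
    Z: float
    p_perm: float
    left_vector: np.ndarray
    right_vector: np.ndarray
    scores: np.ndarray  # (n, 2)


# ---------------------------------------------------------------------------
# TPS dialect I/O (tpsDig2 flavour)
# ---------------------------------------------------------------------------

_LM_RE = re.compile(r"^LM3?\s*=\s*(\d+)\s*$", re.IGNORECASE)
_KV_RE = re.compile(r"^(ID|IMAGE|SCALE)\s*=\s*(.*)$", re.IGNORECASE)


def read_tps(path, n_landmarks: int = N_LANDMARKS,
             strict: bool = False) -> tuple[list[LandmarkConfig], list[str]]:
    """Parse a TPS file into landmark configurations.

    Returns ``(configs, rejected)`` where ``rejected`` lists human-readable
    reports for records whose landmark count differs from ``n_landmarks``
    (those are never silently dropped). ``SCALE=`` records multiply the raw
    coordinates into physical units. With ``strict=True`` a rejected record
    raises instead.
    """
    with open(path) as fh:
        lines = fh.readlines()

    configs: list[LandmarkConfig] = []
    rejected: list[str] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _LM_RE.match(line)
        if m is None:
            raise TPSParseError(f"line {i + 1}: expected LM= record, got {line!r}")
        if "lm3" in line.lower():
            raise TPSParseError(f"line {i + 1}: 3D TPS records are not supported")
        n_lm = int(m.group(1))
        start = i + 1
        coords = []
        i += 1
        for _ in range(n_lm):
            if i >= n:
                raise TPSParseError(f"line {i + 1}: truncated record ({n_lm} landmarks declared)")
            raw = lines[i].strip().replace(",", " ")
            parts = raw.split()
            if len(parts) != 2:
                raise TPSParseError(f"line {i + 1}: expected 'x y' coordinate pair, got {lines[i].strip()!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(f"line {i + 1}: non-numeric coordinate") from exc
            i += 1
        meta: dict[str, str] = {}
        while i < n:
            kv = _KV_RE.match(lines[i].strip())
            if kv is None:
                break
            meta[kv.group(1).upper()] = kv.group(2).strip()
            i += 1
        if n_lm != n_landmarks:
            msg = (f"record starting line {start - 1 + 1}: LM={n_lm}, "
                   f"expected {n_landmarks}; record rejected")
            if strict:
                raise TPSParseError(msg)
            rejected.append(msg)
            continue
        arr = np.array(coords, dtype=float)
        scale = None
        if "SCALE" in meta:
            scale = float(meta["SCALE"])
            arr = arr * scale
        configs.append(
            LandmarkConfig(
                coords=arr,
                specimen_id=meta.get("ID", ""),
                has_scale=scale is not None,
                scale_factor=scale,
            )
        )
    return configs, rejected


def write_tps(path, configs: Sequence[LandmarkConfig]) -> None:
    """Write configurations in the TPS dialect (coordinates in stored units).

    Scale factors are not re-divided out: a read/write round trip preserves
    the in-memory coordinates exactly.
    """
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.coords.shape[0]}\n")
            for x, y in c.coords:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            if c.specimen_id:
                fh.write(f"ID={c.specimen_id}\n")


_CSV_META = ["specimen_id", "species", "family", "line", "population", "side", "source"]


def write_landmark_csv(path, configs: Sequence[LandmarkConfig]) -> None:
    rows = []
    for c in configs:
        row = {k: getattr(c, k) for k in _CSV_META}
        for j in range(N_LANDMARKS):
            row[f"x{j + 1}"] = c.coords[j, 0]
            row[f"y{j + 1}"] = c.coords[j, 1]
        row["scale"] = c.scale_factor if c.has_scale else np.nan
        rows.append(row)
    # %.17g is lossless for float64, so tables round-trip bit-exact
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_landmark_csv(path) -> list[LandmarkConfig]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""],
                     float_precision="round_trip")
    configs = []
    xcols = [f"x{j + 1}" for j in range(N_LANDMARKS)]
    ycols = [f"y{j + 1}" for j in range(N_LANDMARKS)]
    for _, row in df.iterrows():
        coords = np.column_stack([row[xcols].to_numpy(float), row[ycols].to_numpy(float)])
        scale = row.get("scale", np.nan)
        has_scale = np.isfinite(scale) if isinstance(scale, float) else False
        configs.append(
            LandmarkConfig(
                coords=coords,
                **{k: str(row[k]) if k in row else "" for k in _CSV_META},
                has_scale=bool(has_scale),
                scale_factor=float(scale) if has_scale else None,
            )
        )
    return configs


# ---------------------------------------------------------------------------
# Procrustes geometry
# ---------------------------------------------------------------------------

def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark deviations from their centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords.reshape(-1, 2)
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred**2)))
    if cs <= 0.0:
        raise ValueError("degenerate configuration: all landmarks coincident")
    return cs


def _optimal_rotation(A: np.ndarray, B: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Rotation matrix Q minimising ||A Q - B||_F for centred configurations."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    Q = U @ Vt
    if not allow_reflection and np.linalg.det(Q) < 0:
        U[:, -1] *= -1
        Q = U @ Vt
    return Q


def _center_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    cs = centroid_size(coords)
    return (coords - coords.mean(axis=0)) / cs, cs


def gpa(
    configs: Sequence[LandmarkConfig] | np.ndarray,
    metadata: pd.DataFrame | None = None,
    reference: np.ndarray | None = None,
    allow_reflection: bool = False,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> AlignedShapeTable:
    """Generalized Procrustes analysis.

    Each configuration is centred, scaled to unit centroid size, and rotated
    to the running consensus; the consensus is re-estimated until it changes
    by less than ``tol``. If ``reference`` is given (a flattened 22-vector or
    an 11x2 configuration), alignment is to that fixed consensus instead of
    the sample mean.
    """
    if isinstance(configs, np.ndarray):
        raw = [np.asarray(c, dtype=float) for c in configs.reshape(-1, N_LANDMARKS, 2)]
        if metadata is None:
            metadata = pd.DataFrame(index=range(len(raw)))
    else:
        raw = [c.coords for c in configs]
        if metadata is None:
            metadata = pd.DataFrame(
                {k: [getattr(c, k) for c in configs] for k in _CSV_META}
            )
    if len(raw) < 2:
        raise ValueError("GPA needs at least two configurations")

    mats = []
    sizes = []
    for c in raw:
        m, cs = _center_scale(c)
        mats.append(m)
        sizes.append(cs)
    mats = np.array(mats)  # (n, 11, 2)

    if reference is not None:
        ref = np.asarray(reference, dtype=float).reshape(N_LANDMARKS, 2)
        ref, _ = _center_scale(ref)
        for i in range(len(mats)):
            mats[i] = mats[i] @ _optimal_rotation(mats[i], ref, allow_reflection)
        consensus = ref
    else:
        consensus = mats[0].copy()
        for _ in range(max_iter):
            for i in range(len(mats)):
                mats[i] = mats[i] @ _optimal_rotation(mats[i], consensus, allow_reflection)
            new = mats.mean(axis=0)
            new, _ = _center_scale(new)
            delta = np.linalg.norm(new - consensus)
            consensus = new
            if delta < tol:
                break

    return AlignedShapeTable(
        shapes=mats.reshape(len(mats), N_COORDS),
        centroid_sizes=np.asarray(sizes, dtype=float),
        metadata=metadata.reset_index(drop=True),
        consensus=consensus.reshape(N_COORDS),
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance: Euclidean norm between aligned
    coordinate vectors in a common superimposition."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# Procrustes ANOVA (Goodall-style, permutation inference)
# ---------------------------------------------------------------------------

def _factor_ss(Y: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    grand = Y.mean(axis=0)
    ss_total = float(np.sum((Y - grand) ** 2))
    ss_factor = 0.0
    for g in range(n_groups):
        sel = Y[codes == g]
        if len(sel):
            ss_factor += len(sel) * float(np.sum((sel.mean(axis=0) - grand) ** 2))
    return ss_factor, ss_total


def procrustes_anova(
    table: AlignedShapeTable,
    factor: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Goodall-style Procrustes ANOVA for one grouping factor.

    Sums of squares of the Procrustes coordinates are partitioned into
    among- and within-group components; R^2 = SS_factor / SS_total. The
    F ratio uses (g-1, n-g) degrees of freedom; significance and the Z
    effect size come from permutation of rows (raw F standardized).
    """
    labels = table.metadata[factor].to_numpy()
    codes, uniques = pd.factorize(labels)
    g = len(uniques)
    n = len(table)
    if g < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: permutation p-value is coarse")
    Y = table.shapes

    def f_stat(Yp):
        ss_f, ss_t = _factor_ss(Yp, codes, g)
        ss_w = ss_t - ss_f
        return (ss_f / (g - 1)) / (ss_w / (n - g)), ss_f / ss_t

    F_obs, R2 = f_stat(Y)
    rng = np.random.default_rng(seed)
    perm_F = np.empty(n_perm)
    for b in range(n_perm):
        perm_F[b] = f_stat(Y[rng.permutation(n)])[0]
    p = (np.sum(perm_F >= F_obs) + 1) / (n_perm + 1)
    sd = perm_F.std(ddof=1)
    Z = (F_obs - perm_F.mean()) / sd if sd > 0 else np.inf
    return {
        "F": float(F_obs),
        "R2": float(R2),
        "Z": float(Z),
        "p": float(p),
        "df": (g - 1, n - g),
    }


# ---------------------------------------------------------------------------
# Canonical variate analysis with leave-one-out cross-validation
# ---------------------------------------------------------------------------

def _cva_axes(Y: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Canonical axes maximizing among/within variance ratio (W^-1 B eigh)."""
    from scipy.linalg import eigh

    grand = Y.mean(axis=0)
    p = Y.shape[1]
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for g in range(n_groups):
        sel = Y[codes == g]
        d = sel.mean(axis=0) - grand
        B += len(sel) * np.outer(d, d)
        W += (sel - sel.mean(axis=0)).T @ (sel - sel.mean(axis=0))
    W += 1e-12 * np.trace(W) / p * np.eye(p)  # guards exact singularity
    vals, vecs = eigh(B, W)
    order = np.argsort(vals)[::-1]
    k = min(n_groups - 1, p)
    return vecs[:, order[:k]]


def cva_loo(
    table: AlignedShapeTable,
    groups: str,
    min_group_size: int = 5,
    pc_var: float = 0.99,
) -> dict:
    """Canonical variate analysis with leave-one-out classification.

    Groups with fewer than ``min_group_size`` observations are dropped
    (mirroring the requirement of at least five observations per family).
    Because within-group covariance inversion needs n > p, shapes are first
    projected onto the principal components explaining ``pc_var`` of the
    variance. Each held-out row is classified to the nearest group centroid
    in the CV space refit without it.
    """
    labels = table.metadata[groups].to_numpy()
    counts = pd.Series(labels).value_counts()
    keep_levels = set(counts[counts >= min_group_size].index)
    keep = np.array([lab in keep_levels for lab in labels])
    if keep.sum() == 0:
        raise ValueError("no group meets the minimum size requirement")
    Y = table.shapes[keep]
    labs = labels[keep]
    codes, uniques = pd.factorize(labs)
    if len(uniques) < 2:
        raise ValueError("fewer than two groups retained")
    if pd.Series(codes).value_counts().min() < 2:
        raise ValueError("a retained group has fewer than 2 observations")

    # PC projection for rank control
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    npc = int(np.searchsorted(frac, pc_var) + 1)
    npc = min(npc, Yc.shape[0] - len(uniques) - 1) or 1
    X = Yc @ Vt[:npc].T

    n = len(X)
    correct = 0
    cv_scores = np.zeros((n, min(len(uniques) - 1, npc)))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        A = _cva_axes(X[mask], codes[mask], len(uniques))
        Z = X[mask] @ A
        cents = np.array([Z[codes[mask] == g].mean(axis=0) for g in range(len(uniques))])
        zi = X[i] @ A
        pred = int(np.argmin(np.sum((cents - zi) ** 2, axis=1)))
        if pred == codes[i]:
            correct += 1
        cv_scores[i, : A.shape[1]] = zi[: cv_scores.shape[1]]
    return {
        "classification_rate": correct / n,
        "cv_scores": cv_scores,
        "n_retained": n,
        "groups_retained": list(uniques),
    }


# ---------------------------------------------------------------------------
# Two-block partial least squares
# ---------------------------------------------------------------------------

def two_block_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> PLSResult:
    """Two-block PLS: SVD of the cross-covariance of column-centred blocks.

    ``r_pls`` is the Pearson correlation of the first pair of latent scores;
    significance is by permuting the rows of Y (``(b+1)/(m+1)`` smoothing)
    and the effect size Z standardizes the observed r against the permuted
    distribution.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("blocks must have the same number of rows")
    if n < 4:
        raise ValueError("two-block PLS needs n >= 4")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if not (Xc.any() and Yc.any()):
        raise ValueError("zero-variance block")

    def first_r(Yp):
        C = Xc.T @ Yp / (n - 1)
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        u, v = U[:, 0], Vt[0]
        sx, sy = Xc @ u, Yp @ v
        denom = sx.std() * sy.std()
        if denom == 0:
            return 0.0, u, v, sx, sy
        return float(np.corrcoef(sx, sy)[0, 1]), u, v, sx, sy

    r_obs, u, v, sx, sy = first_r(Yc)
    rng = np.random.default_rng(seed)
    perm_r = np.empty(n_perm)
    for b in range(n_perm):
        perm_r[b] = first_r(Yc[rng.permutation(n)])[0]
    p = (np.sum(perm_r >= r_obs) + 1) / (n_perm + 1)
    sd = perm_r.std(ddof=1)
    Z = (r_obs - perm_r.mean()) / sd if sd > 0 else np.inf
    return PLSResult(
        r_pls=abs(r_obs),
        Z=float(Z),
        p_perm=float(p),
        left_vector=u,
        right_vector=v,
        scores=np.column_stack([sx, sy]),
    )
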