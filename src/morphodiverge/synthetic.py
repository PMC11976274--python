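"""Synthetic-data generation with known ground truth.

Every input the pipeline consumes can be generated here: a calibrated
ultrametric family tree, species-replicated tip shapes evolved by
Brownian motion, an individual-level left/right landmark table with
isofemale-line and population structure, and a five-trait fitness table
with a shared genetic-quality axis and optional shape-fitness pleiotropy.

The default configuration mirrors the empirical study design: 11
two-dimensional landmarks per wing, 43 family-level tips on a 185-Myr
tree, 71 isofemale lines in 7 populations, 17% right-censoring of
longevity. All shape covariance inputs are constructed inside the
18-dimensional tangent subspace of the consensus configuration, so
generated variation never excites the four Procrustes null directions
(translation x/y, rotation, scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .morphometrics import (
    N_COORDS,
    N_LANDMARKS,
    AlignedShapeTable,
    LandmarkConfig,
    centroid_size,
)
from .fitness import FITNESS_TRAITS
from .phylo import Phylogeny

__all__ = [
    "BASE_CONFIGURATION",
    "SynthConfig",
    "consensus_shape",
    "tangent_projector",
    "tangent_basis",
    "structured_cov",
    "gen_tree",
    "gen_macro_shapes",
    "gen_lines",
    "gen_fitness",
    "table_from_shapes",
]

# A fixed wing-like 11-landmark reference configuration (arbitrary units;
# vein junctions roughly along a leading edge, wing tip, and trailing edge).
BASE_CONFIGURATION = np.array([
    [0.0, 0.0],
    [1.8, 0.55],
    [3.6, 0.80],
    [5.6, 0.85],
    [7.6, 0.55],
    [8.8, 0.05],
    [7.2, -0.40],
    [5.2, -0.62],
    [3.2, -0.58],
    [1.4, -0.35],
    [4.6, 0.10],
])


def consensus_shape() -> np.ndarray:
    """Centred, unit-centroid-size reference configuration (22-vector)."""
    c = BASE_CONFIGURATION - BASE_CONFIGURATION.mean(axis=0)
    return (c / centroid_size(c)).reshape(N_COORDS)


def tangent_projector(consensus: np.ndarray | None = None) -> np.ndarray:
    """Projector onto the 18-dim shape tangent space at the consensus.

    Removes the four Procrustes null directions: x/y translation, scaling
    (the consensus itself) and infinitesimal rotation.
    """
    z = consensus_shape() if consensus is None else np.asarray(consensus, float).ravel()
    xy = z.reshape(N_LANDMARKS, 2)
    tx = np.zeros(N_COORDS)
    tx[0::2] = 1.0
    ty = np.zeros(N_COORDS)
    ty[1::2] = 1.0
    rot = np.empty(N_COORDS)
    rot[0::2] = -xy[:, 1]
    rot[1::2] = xy[:, 0]
    Q = np.column_stack([tx, ty, z, rot])
    Q, _ = np.linalg.qr(Q)
    return np.eye(N_COORDS) - Q @ Q.T


def tangent_basis(consensus: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal 22x18 basis of the shape tangent space."""
    P = tangent_projector(consensus)
    vals, vecs = np.linalg.eigh(P)
    return vecs[:, vals > 0.5]


def structured_cov(trace: float, decay: float = 0.5, rng=None,
                   basis: np.ndarray | None = None,
                   rotate: bool = True) -> np.ndarray:
    """A 22x22 PSD matrix with geometrically decaying spectrum living in
    the tangent subspace; with ``rotate`` a random (seeded) orthogonal
    rotation within the subspace sets the eigenvectors."""
    B = tangent_basis() if basis is None else basis
    k = B.shape[1]
    lam = decay ** np.arange(k)
    lam = lam / lam.sum() * trace
    if rotate:
        rng = np.random.default_rng(rng)
        Q, _ = np.linalg.qr(rng.standard_normal((k, k)))
        B = B @ Q
    return (B * lam) @ B.T


@dataclass
class SynthConfig:
    """Ground-truth parameters for all generators.

    Defaults reproduce the empirical design sizes: 43 families over 185
    Myr of divergence, 71 isofemale lines across 7 populations, 17%
    longevity censoring. Covariance magnitudes are in squared Procrustes
    units: developmental (asymmetry) noise trace 2e-4, among-line genetic
    trace 1e-4, species-level scatter trace 1e-3, and a per-Myr BM rate
    trace of 2e-5 (so family divergence over the tree depth is of the same
    order as, but larger than, within-family scatter).
    """

    seed: int = 0
    # macroevolution
    n_families: int = 43
    species_per_family: int = 10
    tree_depth_myr: float = 185.0
    Sigma_true: np.ndarray | None = None  # per-Myr BM rate
    Sigma_species: np.ndarray | None = None  # within-family species scatter
    rate_trace: float = 2e-5
    species_trace: float = 1e-3
    # microevolution (lines)
    n_populations: int = 7
    n_lines: int = 71
    inds_per_line: int = 6
    Sigma_dev: np.ndarray | None = None  # L-R asymmetry covariance
    Sigma_line: np.ndarray | None = None  # between-line covariance
    Sigma_pop: np.ndarray | None = None
    Sigma_ind: np.ndarray | None = None
    dev_trace: float = 2e-4
    line_trace: float = 1e-4
    spectrum_decay: float = 0.5  # geometric eigenvalue decay of shape covs
    directional_asymmetry: float = 0.0
    # allometry
    allometry_vector: np.ndarray | None = None
    allometry_strength: float = 0.06
    log_size_sd: float = 0.4
    # fitness
    quality_loadings: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 1.0, 1.0, 1.0, 1.0]))
    quality_var_share: float = 0.25
    shape_pleiotropy_vector: np.ndarray | None = None
    pleiotropy_strength: float = 0.0
    censor_rate: float = 0.17
    n_treatments: int = 3
    reps_per_treatment: int = 4

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        if self.Sigma_dev is None:
            self.Sigma_dev = structured_cov(self.dev_trace, decay=self.spectrum_decay,
                                            rng=rng.integers(2**31))
        if self.Sigma_line is None:
            # standing genetic variation aligned with developmental bias
            self.Sigma_line = self.Sigma_dev * (self.line_trace / np.trace(self.Sigma_dev))
        if self.Sigma_pop is None:
            self.Sigma_pop = self.Sigma_line * 0.3
        if self.Sigma_ind is None:
            self.Sigma_ind = self.Sigma_dev * 0.5
        if self.Sigma_true is None:
            # macroevolution along the developmental line of least resistance
            self.Sigma_true = self.Sigma_dev * (self.rate_trace / np.trace(self.Sigma_dev))
        if self.Sigma_species is None:
            self.Sigma_species = self.Sigma_dev * (self.species_trace / np.trace(self.Sigma_dev))
        if self.allometry_vector is None:
            vals, vecs = np.linalg.eigh(self.Sigma_dev)
            self.allometry_vector = vecs[:, -1]
        for name in ("Sigma_dev", "Sigma_line", "Sigma_pop", "Sigma_ind",
                     "Sigma_true", "Sigma_species"):
            M = getattr(self, name)
            if np.abs(M - M.T).max() > 1e-10 or np.linalg.eigvalsh(M).min() < -1e-12:
                raise ValueError(f"{name} must be symmetric PSD")
        if not 0 <= self.quality_var_share <= 1:
            raise ValueError("quality_var_share must be in [0, 1]")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def gen_tree(config: SynthConfig, seed: int | None = None) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_families`` tips rescaled to
    ``tree_depth_myr``; tips are labelled fam01, fam02, ...."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_families
    if n < 2:
        raise ValueError("need at least two families")
    taxa = dendropy.TaxonNamespace([f"fam{i + 1:02d}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    # forward Yule: start with two lineages, split a random one at each event
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child(edge_length=0.0)
        active.append(child)
    t = 0.0
    while len(active) < n:
        k = len(active)
        wait = rng.exponential(1.0 / k)
        t += wait
        for nd in active:
            nd.edge.length += wait
        idx = rng.integers(k)
        parent = active.pop(idx)
        for _ in range(2):
            active.append(parent.new_child(edge_length=0.0))
    # final stretch to the present
    wait = rng.exponential(1.0 / n)
    t += wait
    for nd in active:
        nd.edge.length += wait
    # rescale to exact depth and attach taxa
    scale = config.tree_depth_myr / t
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length *= scale
    labels = list(taxa)
    rng.shuffle(labels)
    for leaf, taxon in zip(tree.leaf_node_iter(), labels):
        leaf.taxon = taxon
    return Phylogeny(tree=tree)


# ---------------------------------------------------------------------------
# Macroevolutionary tip shapes
# ---------------------------------------------------------------------------

def _chol_psd(M: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((M + M.T) / 2)
    return vecs * np.sqrt(np.maximum(vals, 0.0))


def gen_macro_shapes(config: SynthConfig, phy: Phylogeny,
                     seed: int | None = None) -> pd.DataFrame:
    """Species-level tip shapes: family means evolve by BM with
    ``Sigma_true``; species add N(0, Sigma_species) scatter and (optionally)
    allometric shape-size coupling. Returns a tidy table with family,
    species, log size and the 22 shape columns, centred on the consensus.
    Side effect: fills ``phy.tip_data`` with the per-family species arrays.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    L_true = _chol_psd(config.Sigma_true)
    L_sp = _chol_psd(config.Sigma_species)
    mu = consensus_shape()

    # BM along the tree
    states: dict = {}
    tree = phy.tree
    states[id(tree.seed_node)] = mu.copy()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        l = node.edge.length or 0.0
        step = np.sqrt(l) * (L_true @ rng.standard_normal(N_COORDS))
        states[id(node)] = states[id(node.parent_node)] + step

    rows = []
    shape_cols = [f"s{j + 1}" for j in range(N_COORDS)]
    v = config.allometry_vector / np.linalg.norm(config.allometry_vector)
    tip_data: dict[str, np.ndarray] = {}
    for leaf in tree.leaf_node_iter():
        fam = leaf.taxon.label
        fam_mean = states[id(leaf)]
        shapes = fam_mean + (L_sp @ rng.standard_normal(
            (N_COORDS, config.species_per_family))).T
        logsize = rng.normal(0.0, config.log_size_sd, config.species_per_family)
        shapes = shapes + np.outer(logsize, v) * config.allometry_strength
        tip_data[fam] = shapes
        for s in range(config.species_per_family):
            row = {"family": fam, "species": f"{fam}_sp{s + 1}",
                   "log_size": logsize[s]}
            row.update(dict(zip(shape_cols, shapes[s])))
            rows.append(row)
    phy.tip_data = tip_data
    return pd.DataFrame(rows)


def table_from_shapes(shapes: np.ndarray, metadata: pd.DataFrame,
                      centroid_sizes: np.ndarray | None = None) -> AlignedShapeTable:
    """Wrap already-aligned shape vectors as an AlignedShapeTable."""
    shapes = np.asarray(shapes, dtype=float)
    n = len(shapes)
    return AlignedShapeTable(
        shapes=shapes,
        centroid_sizes=(np.ones(n) if centroid_sizes is None
                        else np.asarray(centroid_sizes, float)),
        metadata=metadata.reset_index(drop=True),
        consensus=shapes.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# Isofemale-line individual-level data
# ---------------------------------------------------------------------------

def gen_lines(config: SynthConfig, seed: int | None = None,
              ) -> tuple[list[LandmarkConfig], pd.DataFrame]:
    """Individual-level left/right landmark data with line/population
    nesting.

    Each individual's mean shape = population effect + line effect +
    individual effect around the consensus; each side adds independent
    developmental noise N(0, Sigma_dev / 2), so the L-R difference has
    covariance Sigma_dev. Configurations are exported raw — randomly
    rotated, translated and scaled, with the right side mirrored — so
    the Procrustes machinery is fully exercised downstream. Returns the
    configuration list and a table of per-line true genetic shape effects.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    mu = consensus_shape()
    L_pop = _chol_psd(config.Sigma_pop)
    L_line = _chol_psd(config.Sigma_line)
    L_ind = _chol_psd(config.Sigma_ind)
    L_dev = _chol_psd(config.Sigma_dev / 2.0)
    da = config.directional_asymmetry * (config.allometry_vector /
                                         np.linalg.norm(config.allometry_vector))

    # distribute lines across populations as evenly as possible
    base = config.n_lines // config.n_populations
    counts = np.full(config.n_populations, base)
    counts[: config.n_lines - base * config.n_populations] += 1

    configs: list[LandmarkConfig] = []
    line_rows = []
    for pop_i, n_lines_pop in enumerate(counts):
        pop = f"pop{pop_i + 1}"
        pop_eff = L_pop @ rng.standard_normal(N_COORDS)
        for li in range(n_lines_pop):
            line = f"{pop}_line{li + 1}"
            line_eff = L_line @ rng.standard_normal(N_COORDS)
            line_rows.append({"line": line, "population": pop,
                              **{f"g{j + 1}": line_eff[j] for j in range(N_COORDS)}})
            for ind in range(config.inds_per_line):
                spec = f"{line}_ind{ind + 1}"
                ind_eff = L_ind @ rng.standard_normal(N_COORDS)
                ind_mean = mu + pop_eff + line_eff + ind_eff
                logsize = rng.normal(0.0, config.log_size_sd)
                ind_mean = ind_mean + config.allometry_strength * logsize * (
                    config.allometry_vector / np.linalg.norm(config.allometry_vector))
                for side in ("L", "R"):
                    noise = L_dev @ rng.standard_normal(N_COORDS)
                    vec = ind_mean + noise + (da if side == "L" else -da)
                    coords = vec.reshape(N_LANDMARKS, 2)
                    # random rigid motion + digitizing scale
                    theta = rng.uniform(0, 2 * np.pi)
                    Rm = np.array([[np.cos(theta), -np.sin(theta)],
                                   [np.sin(theta), np.cos(theta)]])
                    scale = np.exp(logsize) * 100.0  # "pixels"
                    coords = coords @ Rm.T * scale + rng.uniform(-50, 50, 2)
                    if side == "R":
                        coords = coords.copy()
                        coords[:, 0] = -coords[:, 0]
                    configs.append(LandmarkConfig(
                        coords=coords, specimen_id=spec, line=line,
                        population=pop, side=side, species="focal_sp",
                        family="focal_family",
                    ))
    return configs, pd.DataFrame(line_rows)


# ---------------------------------------------------------------------------
# Fitness table
# ---------------------------------------------------------------------------

_TRAIT_SCALES = {
    # trait: (grand mean, line sd on natural scale, residual sd)
    "longevity": (35.0, 4.0, 10.0),
    "developmental_rate": (0.050, 0.004, 0.008),
    "juvenile_survival": (0.70, 0.06, 0.12),
    "body_size": (2.00, 0.08, 0.12),
    "early_repro": (90.0, 10.0, 35.0),
}


def gen_fitness(config: SynthConfig, line_effects: pd.DataFrame,
                seed: int | None = None) -> pd.DataFrame:
    """Five fitness traits for every line x treatment x replicate.

    A latent line "quality" loads on all five traits with share
    ``quality_var_share`` of the line-level variance; optional pleiotropy
    adds a readout of the line's true shape effect along
    ``shape_pleiotropy_vector``. Longevity is right-censored at the
    empirical (1 - censor_rate) quantile. Juvenile survival is clipped to
    [0, 1]; early reproductive success drops females that died before day
    15 and zero-layers (both flagged).
    """
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    lines = line_effects["line"].tolist()
    pops = line_effects["population"].tolist()
    n_lines = len(lines)
    gcols = [c for c in line_effects.columns if c.startswith("g")]
    Gmat = line_effects[gcols].to_numpy(dtype=float)

    quality = rng.standard_normal(n_lines)
    if config.shape_pleiotropy_vector is not None and config.pleiotropy_strength > 0:
        w = np.asarray(config.shape_pleiotropy_vector, float)
        w = w / np.linalg.norm(w)
        readout = Gmat @ w
        sd = readout.std()
        if sd > 0:
            readout = readout / sd
        a = config.pleiotropy_strength
        quality = np.sqrt(1 - a**2) * quality + a * readout

    share = config.quality_var_share
    loadings = np.sign(config.quality_loadings)
    traits = FITNESS_TRAITS
    line_vals = {}
    for tname, load in zip(traits, loadings):
        specific = rng.standard_normal(n_lines)
        latent = np.sqrt(share) * load * quality + np.sqrt(1 - share) * specific
        line_vals[tname] = latent

    t_effects = {t: rng.normal(0, 0.5, config.n_treatments) for t in traits}
    rows = []
    for li, (line, pop) in enumerate(zip(lines, pops)):
        for tr in range(config.n_treatments):
            for rep in range(config.reps_per_treatment):
                row = {"line": line, "population": pop,
                       "treatment": f"T{tr + 1}", "replicate": rep + 1}
                for tname in traits:
                    mu, sd_line, sd_res = _TRAIT_SCALES[tname]
                    res_scale = sd_res * (0.8 + 0.2 * tr)  # heteroscedastic
                    val = (mu + sd_line * (line_vals[tname][li] + t_effects[tname][tr])
                           + res_scale * rng.standard_normal())
                    row[tname] = val
                rows.append(row)
    df = pd.DataFrame(rows)
    df["juvenile_survival"] = df["juvenile_survival"].clip(0.0, 1.0)
    df["longevity"] = df["longevity"].clip(lower=1.0)
    df["early_repro"] = df["early_repro"].clip(lower=0.0).round()
    # right-censor longevity at the (1 - censor_rate) quantile
    if config.censor_rate > 0:
        cutoff = df["longevity"].quantile(1.0 - config.censor_rate)
        df["censored"] = df["longevity"] > cutoff
        df.loc[df["censored"], "longevity"] = cutoff
    else:
        df["censored"] = False
    # early-reproduction filters: dead before day 15, and zero-layers
    died_early = (~df["censored"]) & (df["longevity"] < 15)
    zero_layer = df["early_repro"] <= 0
    df["early_repro_excluded"] = died_early | zero_layer
    df.loc[df["early_repro_excluded"], "early_repro"] = np.nan
    return df
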