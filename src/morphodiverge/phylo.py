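"""Phylogenetic rate estimation and branch-wise alignment analysis.

Family-level tip taxa sit on a calibrated ultrametric tree (branch lengths
in millions of years); the species sampled within each family act as
replicated measurements of the family's wing shape. From these the module
estimates:

* the evolutionary rate matrix ``R`` (per-Myr Brownian-motion rate of the
  22 Procrustes coordinates) together with per-dimension phylogenetic
  heritability,
* maximum-likelihood ancestral shapes at every node,
* per-branch shape-change vectors ``beta`` with their evolutionary rate
  (Procrustes distance per Myr) and the alignment statistic

      e_beta = beta' C' beta / |beta|^2

  where ``C'`` is a developmental (D) or mutational (M) covariance matrix
  scaled by its trace — the fraction of developmental variance captured by
  that direction of evolutionary change,
* a Brownian-motion null for the correlation between rate and alignment,
* the neutral-drift divergence expectation (2 x mutational variance per
  generation), and
* divergence-versus-time profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covariance import CovMatrix, scale_by_trace
from .morphometrics import N_COORDS

__all__ = [
    "Phylogeny",
    "RateModel",
    "BranchChange",
    "read_newick",
    "write_newick",
    "phylo_covariance",
    "estimate_R",
    "ReconstructionOperators",
    "ancestral_states",
    "branch_changes",
    "rate_alignment_test",
    "drift_expectation",
    "divergence_profile",
    "simulate_bm_tips",
]


@dataclass
class Phylogeny:
    """Rooted ultrametric tree plus per-family species-level tip data."""

    tree: dendropy.Tree
    tip_data: dict[str, np.ndarray] = field(default_factory=dict)
    # tip_data: family name -> (n_species, 22) array of species mean shapes

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def depth(self) -> float:
        return max(self.tree.calc_node_root_distances(return_leaf_distances_only=True))

    def check_ultrametric(self, rtol: float = 0.01) -> bool:
        d = np.array(self.tree.calc_node_root_distances(return_leaf_distances_only=True))
        return bool((d.max() - d.min()) <= rtol * d.max())

    def family_means(self, labels: list[str] | None = None) -> np.ndarray:
        labels = labels or self.tip_labels
        return np.array([self.tip_data[lab].mean(axis=0) for lab in labels])

    def filter_families(self, min_species: int = 5) -> "Phylogeny":
        """Drop tips with fewer than ``min_species`` sampled species."""
        keep = [lab for lab, arr in self.tip_data.items() if len(arr) >= min_species]
        taxa = [t for t in self.tree.taxon_namespace if t.label in keep]
        tree = self.tree.extract_tree_with_taxa(taxa=taxa)
        return Phylogeny(tree=tree, tip_data={k: self.tip_data[k] for k in keep})


def read_newick(path, tip_data: dict[str, np.ndarray] | None = None,
                require_ultrametric: bool = False) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths in Myr."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            raise ValueError(
                f"edge above {edge.head_node.taxon.label if edge.head_node.taxon else 'internal node'} "
                f"has missing or nonpositive length"
            )
    phy = Phylogeny(tree=tree, tip_data=tip_data or {})
    if require_ultrametric and not phy.check_ultrametric():
        raise ValueError("tree is not ultrametric within 1% tolerance")
    return phy


def write_newick(path, phy: Phylogeny) -> None:
    phy.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def phylo_covariance(phy: Phylogeny,
                     labels: list[str] | None = None) -> np.ndarray:
    """Phylogenetic relationship matrix S: S[i, j] = shared root-path length
    (Myr) of tips i and j; diagonal = root-to-tip depth."""
    tree = phy.tree
    labels = labels or phy.tip_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    S = np.zeros((n, n))
    # depth of each node from root
    depth: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
    # for each internal node, tips descending from each child subtree share it
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            S[i, i] = depth[node]
            node._tipset = [i]
        else:
            children = [c._tipset for c in node.child_nodes()]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            S[i, j] = S[j, i] = depth[node]
            node._tipset = [i for c in children for i in c]
    return S


# ---------------------------------------------------------------------------
# Rate-matrix estimation (phylogenetic mixed model, family tips with
# replicated species observations)
# ---------------------------------------------------------------------------

@dataclass
class RateModel:
    R: CovMatrix
    V_species: CovMatrix
    h2_phylo: np.ndarray  # per-dimension phylogenetic heritability
    h2_weighted: float
    sigma2_phylo: np.ndarray = field(default=None)
    sigma2_species: np.ndarray = field(default=None)


def _psd_project(V: np.ndarray) -> np.ndarray:
    V = (V + V.T) / 2
    vals, vecs = np.linalg.eigh(V)
    return (vecs * np.maximum(vals, 0.0)) @ vecs.T


def estimate_R(phy: Phylogeny, min_species: int = 5,
               min_families: int = 5) -> RateModel:
    """Estimate the per-Myr Brownian rate matrix R and phylogenetic
    heritability from species-replicated family tips.

    Per dimension the model is  y_fs = mu + u_f + e_fs  with
    cov(u) = sigma2_phylo * S (S the Myr relationship matrix) and e iid.
    The species variance is estimated from pooled within-family scatter;
    per-dimension sigma2_phylo by REML in the contrast space obtained from
    the generalized eigendecomposition of (S, diag(1/n_f)). The full R is
    a GLS-rotated method-of-moments estimator (unshrunken), symmetrized
    and projected onto the PSD cone.
    """
    phy = phy.filter_families(min_species=min_species)
    labels = phy.tip_labels
    F = len(labels)
    if F < min_families:
        raise ValueError(f"only {F} families with >= {min_species} species")
    S = phylo_covariance(phy, labels)
    ev = np.linalg.eigvalsh(S)
    if ev.min() <= 0:
        raise ValueError("phylogenetic relationship matrix is not positive definite")

    n_f = np.array([len(phy.tip_data[lab]) for lab in labels])
    ybar = phy.family_means(labels)  # (F, p)
    p = ybar.shape[1]

    # pooled within-family (species) covariance
    W = np.zeros((p, p))
    for lab in labels:
        arr = phy.tip_data[lab]
        d = arr - arr.mean(axis=0)
        W += d.T @ d
    df_w = int(n_f.sum() - F)
    V_species = W / df_w

    # transform family means: D^{-1/2} with D = diag(1/n_f), then contrasts
    Dh = np.sqrt(n_f)  # D^{-1/2} = diag(sqrt(n_f))
    Wmat = (Dh[:, None] * S) * Dh[None, :]
    lam, Q = np.linalg.eigh(Wmat)
    # mean direction in transformed space
    t = Q.T @ Dh  # Q' D^{-1/2} 1
    # orthonormal contrast basis K orthogonal to t
    t_unit = t / np.linalg.norm(t)
    Kfull = np.eye(F) - np.outer(t_unit, t_unit)
    # eigendecomposition of the contrast-projected Lambda
    A = Kfull @ np.diag(lam) @ Kfull
    lam2, Q2 = np.linalg.eigh(A)
    order = np.argsort(lam2)[::-1]
    lam2, Q2 = lam2[order][: F - 1], Q2[:, order][:, : F - 1]

    Z = Q.T @ (Dh[:, None] * ybar)  # (F, p) transformed means
    U = Q2.T @ Z  # (F-1, p) contrasts: cov(U_d, U_e) = R_de*diag(lam2) + V_de*I

    # method-of-moments full R
    sum_lam2 = lam2.sum()
    cross = U.T @ U  # (p, p): sum_i u_id u_ie
    R_mom = (cross - (F - 1) * V_species) / sum_lam2
    R_hat = _psd_project(R_mom)

    # per-dimension REML for sigma2_phylo given sigma2_species; the
    # optimization runs on log(sigma2_phylo) because the variance scale is
    # unknown a priori, with an explicit boundary check at zero
    s2_species = np.maximum(np.diag(V_species), 1e-300)
    s2_phylo = np.empty(p)
    for d in range(p):
        v2 = U[:, d] ** 2
        s2s = s2_species[d]

        def negll(s2p, v2=v2, s2s=s2s):
            w = s2p * lam2 + s2s
            return 0.5 * np.sum(np.log(w) + v2 / w)

        upper = max(v2.max() / max(lam2.min(), 1e-12), 1e-300)
        res = optimize.minimize_scalar(
            lambda phi: negll(np.exp(phi)),
            bounds=(np.log(upper) - 60.0, np.log(upper)), method="bounded",
            options={"xatol": 1e-8})
        cand = float(np.exp(res.x))
        s2_phylo[d] = cand if negll(cand) < negll(0.0) else 0.0

    diag_S = np.diag(S)
    h2 = np.array([
        np.mean(s2_phylo[d] * diag_S / (s2_phylo[d] * diag_S + s2_species[d]))
        for d in range(p)
    ])
    tip_var = s2_phylo * diag_S.mean() + s2_species  # total species-level variance
    h2_weighted = float(np.average(h2, weights=tip_var))

    return RateModel(
        R=CovMatrix(R_hat, role="R", n_units=F - 1,
                    provenance=f"{F} families, {int(n_f.sum())} species"),
        V_species=CovMatrix(_psd_project(V_species), role="other", n_units=df_w,
                            provenance="pooled within-family"),
        h2_phylo=h2,
        h2_weighted=h2_weighted,
        sigma2_phylo=s2_phylo,
        sigma2_species=s2_species,
    )


# ---------------------------------------------------------------------------
# Ancestral reconstruction and branch changes
# ---------------------------------------------------------------------------

class ReconstructionOperators:
    """Precomputed linear operators for BM ancestral reconstruction.

    The ML states under Brownian motion minimise the sum over edges of
    squared change / branch length; the solution is linear in the tip
    values and independent of the rate matrix, so node states and per-edge
    change vectors are matrix products with the tip matrix.
    """

    def __init__(self, phy: Phylogeny):
        tree = phy.tree
        nodes = list(tree.preorder_node_iter())
        self.node_index = {id(nd): i for i, nd in enumerate(nodes)}
        self.nodes = nodes
        n = len(nodes)
        tips = [i for i, nd in enumerate(nodes) if nd.is_leaf()]
        internal = [i for i, nd in enumerate(nodes) if not nd.is_leaf()]
        self.tip_labels = [nodes[i].taxon.label for i in tips]
        L = np.zeros((n, n))
        edges = []  # (parent_idx, child_idx, length)
        for nd in nodes:
            for child in nd.child_nodes():
                l = child.edge.length
                if l is None or l <= 0:
                    raise ValueError("zero or missing branch length")
                pi = self.node_index[id(nd)]
                ci = self.node_index[id(child)]
                w = 1.0 / l
                L[pi, pi] += w
                L[ci, ci] += w
                L[pi, ci] -= w
                L[ci, pi] -= w
                edges.append((pi, ci, l))
        self.edges = edges
        # internal states = A @ tip states
        A = -np.linalg.solve(L[np.ix_(internal, internal)], L[np.ix_(internal, tips)])
        M = np.zeros((n, len(tips)))
        for j, i in enumerate(tips):
            M[i, j] = 1.0
        M[internal] = A
        self.node_operator = M  # (n_nodes, n_tips)
        E = np.array([M[ci] - M[pi] for pi, ci, _ in edges])
        self.edge_operator = E  # (n_edges, n_tips)
        self.edge_lengths = np.array([l for _, _, l in edges])
        self.root_index = self.node_index[id(tree.seed_node)]
        # tip x edge incidence: 1 when the edge lies on the root-to-tip path
        tip_idx = {i: j for j, i in enumerate(tips)}
        path = np.zeros((len(tips), len(edges)))
        on_path: dict[int, list[int]] = {self.root_index: []}
        for e, (pi, ci, _) in enumerate(edges):  # edges are in preorder
            on_path[ci] = on_path[pi] + [e]
        for i, j in tip_idx.items():
            path[j, on_path[i]] = 1.0
        self.tip_path_matrix = path

    def node_states(self, tip_matrix: np.ndarray) -> np.ndarray:
        return self.node_operator @ tip_matrix

    def betas(self, tip_matrix: np.ndarray) -> np.ndarray:
        """Per-edge shape-change vectors (child minus parent state)."""
        return self.edge_operator @ tip_matrix


def ancestral_states(phy: Phylogeny, tip_matrix: np.ndarray | None = None,
                     ops: ReconstructionOperators | None = None) -> dict:
    """GLS/ML ancestral reconstruction under BM from family mean tips.

    Returns ``{"states": (n_nodes, p) array, "nodes": node list,
    "root": root state, "ops": operators}``.
    """
    ops = ops or ReconstructionOperators(phy)
    if tip_matrix is None:
        missing = [lab for lab in ops.tip_labels if lab not in phy.tip_data]
        if missing:
            raise ValueError(f"missing tip data for {missing[:5]}")
        tip_matrix = phy.family_means(ops.tip_labels)
    states = ops.node_states(np.asarray(tip_matrix, dtype=float))
    return {"states": states, "nodes": ops.nodes, "root": states[ops.root_index],
            "ops": ops}


@dataclass
class BranchChange:
    edge_id: int
    beta: np.ndarray
    length_myr: float
    rate: float  # Procrustes distance per Myr
    e_beta: float


def e_beta_stat(beta: np.ndarray, C_scaled: np.ndarray) -> float:
    """Fraction of a trace-scaled covariance matrix captured by beta."""
    beta = np.asarray(beta, dtype=float)
    nrm2 = float(beta @ beta)
    if nrm2 == 0:
        raise ValueError("zero-length change vector: e_beta undefined")
    return float(beta @ C_scaled @ beta) / nrm2


def branch_changes(phy: Phylogeny, C_ref: CovMatrix,
                   tip_matrix: np.ndarray | None = None,
                   ops: ReconstructionOperators | None = None,
                   ) -> tuple[list[BranchChange], int]:
    """Per-edge shape change, rate and alignment with a reference matrix.

    ``C_ref`` (D or M) is trace-scaled internally. Edges with a zero-length
    change vector have no defined direction; they are excluded and counted
    in the returned ``n_excluded``.
    """
    ops = ops or ReconstructionOperators(phy)
    if tip_matrix is None:
        tip_matrix = phy.family_means(ops.tip_labels)
    Cs = scale_by_trace(C_ref).values
    B = ops.betas(np.asarray(tip_matrix, dtype=float))
    out: list[BranchChange] = []
    n_excluded = 0
    for e, (beta, l) in enumerate(zip(B, ops.edge_lengths)):
        nrm = np.linalg.norm(beta)
        if nrm == 0:
            n_excluded += 1
            continue
        out.append(BranchChange(
            edge_id=e, beta=beta, length_myr=float(l),
            rate=float(nrm / l), e_beta=float(beta @ Cs @ beta) / float(nrm**2),
        ))
    return out, n_excluded


def _branch_correlation(B: np.ndarray, lengths: np.ndarray, Cs: np.ndarray) -> float:
    """corr(e_beta, rate) across edges for a tip->beta matrix already built."""
    nrm2 = np.einsum("ij,ij->i", B, B)
    ok = nrm2 > 0
    if ok.sum() < 3:
        return np.nan
    eb = np.einsum("ij,jk,ik->i", B[ok], Cs, B[ok]) / nrm2[ok]
    rate = np.sqrt(nrm2[ok]) / lengths[ok]
    if eb.std() == 0 or rate.std() == 0:
        return np.nan
    return float(np.corrcoef(eb, rate)[0, 1])


def simulate_bm_tips(ops: ReconstructionOperators, Sigma: np.ndarray,
                     rng: np.random.Generator, root: np.ndarray | None = None,
                     ) -> np.ndarray:
    """Simulate tip values under BM: independent per-edge increments
    N(0, length * Sigma) summed root-to-tip."""
    vals, vecs = np.linalg.eigh((Sigma + Sigma.T) / 2)
    Lc = vecs * np.sqrt(np.maximum(vals, 0.0))
    p = Sigma.shape[0]
    increments = np.sqrt(ops.edge_lengths)[:, None] * (
        rng.standard_normal((len(ops.edges), p)) @ Lc.T)
    tips = ops.tip_path_matrix @ increments
    if root is not None:
        tips = tips + root
    return tips


def rate_alignment_test(
    phy: Phylogeny,
    C_ref: CovMatrix,
    rate_model: RateModel | None = None,
    tip_matrix: np.ndarray | None = None,
    n_sim: int = 1000,
    seed: int | None = None,
    trace_target: float | None = None,
    ops: ReconstructionOperators | None = None,
) -> dict:
    """Observed correlation between branch rate and e_beta alignment, with a
    Brownian-motion null.

    The null simulates tip shapes by BM with Sigma = C_ref scaled to the
    same total size as R (trace matched; the correlation itself is
    invariant to that overall scale), reruns the identical ancestral-
    reconstruction -> branch-change pipeline, and reports
    P_RAND = fraction of simulated correlations <= the observed one
    (lower tail: the constraint hypothesis predicts *higher* correlation
    under aligned BM, so a low observed r is the interesting departure).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    ops = ops or ReconstructionOperators(phy)
    if len(ops.edges) < 10:
        raise ValueError(f"only {len(ops.edges)} edges; need >= 10")
    if tip_matrix is None:
        tip_matrix = phy.family_means(ops.tip_labels)
    tip_matrix = np.asarray(tip_matrix, dtype=float)
    Cs = scale_by_trace(C_ref).values

    B_obs = ops.betas(tip_matrix)
    r_obs = _branch_correlation(B_obs, ops.edge_lengths, Cs)

    if trace_target is None:
        trace_target = rate_model.R.trace if rate_model is not None else C_ref.trace
    Sigma_null = C_ref.values * (trace_target / C_ref.trace)

    rng = np.random.default_rng(seed)
    null_r = np.empty(n_sim)
    for b in range(n_sim):
        tips = simulate_bm_tips(ops, Sigma_null, rng)
        null_r[b] = _branch_correlation(ops.betas(tips), ops.edge_lengths, Cs)
    valid = np.isfinite(null_r)
    p_rand = (np.sum(null_r[valid] <= r_obs) + 1) / (valid.sum() + 1)
    return {"r_obs": r_obs, "null_r": null_r, "P_RAND": float(p_rand),
            "n_edges": len(ops.edges)}


# ---------------------------------------------------------------------------
# Drift expectation and divergence profile
# ---------------------------------------------------------------------------

def drift_expectation(vm: np.ndarray, generations: float,
                      observed_variances: np.ndarray) -> pd.DataFrame:
    """Neutral-drift divergence expectation per dimension.

    Under pure drift the among-lineage variance accumulates at twice the
    mutational variance per generation: expected_i = 2 * V_m,i * t. The
    ratio observed/expected measures how far below (or above) the neutral
    expectation the realized divergence sits.
    """
    vm = np.asarray(vm, dtype=float)
    obs = np.asarray(observed_variances, dtype=float)
    if np.any(vm <= 0):
        raise ValueError("mutational variances must be positive")
    if generations <= 0:
        raise ValueError("generations must be positive")
    expected = 2.0 * vm * generations
    return pd.DataFrame({
        "V_m": vm,
        "expected": expected,
        "observed": obs,
        "ratio": obs / expected,
    })


def divergence_profile(
    phy: Phylogeny,
    n_bins: int = 10,
    species_shapes: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Pairwise shape divergence versus phylogenetic distance.

    Every cross-family species pair contributes (divergence time in Myr,
    Procrustes distance between species shapes); pairs are binned by time
    and summarized by the mean distance per bin. Under BM the mean
    *squared* distance grows linearly with divergence time with slope
    2 x trace of the rate matrix.
    """
    labels = phy.tip_labels
    S = phylo_covariance(phy, labels)
    depth = np.diag(S)
    data = species_shapes or phy.tip_data
    times = []
    dists = []
    for i, la in enumerate(labels):
        for j in range(i + 1, len(labels)):
            lb = labels[j]
            # divergence time = depth - shared path
            t = 0.5 * (depth[i] + depth[j]) - S[i, j]
            Xa, Xb = data[la], data[lb]
            diff = Xa[:, None, :] - Xb[None, :, :]
            d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)).ravel()
            times.extend([t] * len(d))
            dists.extend(d.tolist())
    df = pd.DataFrame({"time_myr": times, "procrustes_distance": dists})
    df["sq_distance"] = df["procrustes_distance"] ** 2
    edges = np.linspace(0, df["time_myr"].max() * (1 + 1e-9), n_bins + 1)
    df["bin"] = pd.cut(df["time_myr"], edges, include_lowest=True)
    prof = df.groupby("bin", observed=True).agg(
        time_myr=("time_myr", "mean"),
        mean_distance=("procrustes_distance", "mean"),
        mean_sq_distance=("sq_distance", "mean"),
        n_pairs=("time_myr", "size"),
    ).reset_index(drop=True)
    prof.attrs["pairs"] = df[["time_myr", "procrustes_distance", "sq_distance"]]
    return prof
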