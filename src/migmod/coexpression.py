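"""Consensus weighted co-expression network construction and module detection.

The stage follows the standard WGCNA recipe for an unsigned network:
connectivity-based gene selection, soft-threshold power chosen against a
scale-free topology fit, topological overlap dissimilarity, and
average-linkage clustering cut with an adaptive branch-pruning (dynamic
tree cut) algorithm. Network stability is addressed by a resampled
consensus: the TOM dissimilarity is recomputed on repeated random
leave-out subsets of samples and averaged element-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .io_formats import ExpressionMatrix

__all__ = [
    "GeneNetwork",
    "ModuleAssignment",
    "SoftThresholdFit",
    "MODULE_COLOR_SEQUENCE",
    "select_top_connected",
    "pick_soft_threshold",
    "adjacency_matrix",
    "tom_dissimilarity",
    "consensus_tom",
    "detect_modules",
]

#: Conventional module colour sequence, in decreasing-size assignment order.
MODULE_COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

GREY = "grey"


@dataclass
class GeneNetwork:
    """Soft-thresholded adjacency plus consensus TOM dissimilarity."""

    gene_ids: list[str]
    beta: int
    adjacency: np.ndarray
    consensus_dissimilarity: np.ndarray
    n_resamples: int
    leave_out_fraction: float

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name, mat in (
            ("adjacency", self.adjacency),
            ("consensus_dissimilarity", self.consensus_dissimilarity),
        ):
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {mat.shape}")
            if np.abs(mat - mat.T).max(initial=0.0) > 1e-10:
                raise ValueError(f"{name} is not symmetric within 1e-10")
            if mat.min(initial=0.0) < -1e-12 or mat.max(initial=0.0) > 1 + 1e-12:
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.adjacency), 1.0):
            raise ValueError("adjacency diagonal must be 1")
        if not np.allclose(np.diag(self.consensus_dissimilarity), 0.0):
            raise ValueError("dissimilarity diagonal must be 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ModuleAssignment:
    """Gene -> module label map; "grey" marks unassigned genes."""

    labels: dict[str, str]

    def module_names(self, include_grey: bool = False) -> list[str]:
        sizes = self.module_sizes()
        names = [m for m in sizes if m != GREY or include_grey]
        return names

    def module_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for label in self.labels.values():
            sizes[label] = sizes.get(label, 0) + 1
        return sizes

    def genes_in(self, module: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.labels), "module": list(self.labels.values())}
        )


@dataclass
class SoftThresholdFit:
    """Scale-free topology fit across candidate soft-threshold powers."""

    fit_table: pd.DataFrame  # columns: power, signed_r2, mean_connectivity
    chosen_power: int
    r2_target: float
    target_reached: bool = True


def _safe_abs_correlation(values: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between rows; zero-variance rows correlate 0."""
    sd = values.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance gene(s); correlations set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(values)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    cor[zero_var, :] = 0.0
    cor[:, zero_var] = 0.0
    return np.clip(np.abs(cor), 0.0, 1.0)


def select_top_connected(expr: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the k genes with the largest whole-network connectivity.

    Connectivity of gene i is the sum over all other genes of the absolute
    Pearson correlation. Ties (at the fourth decimal) are broken by input
    order; the surviving genes keep their original order.
    """
    if k > expr.n_genes:
        raise ValueError(f"k={k} exceeds the number of genes ({expr.n_genes})")
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples for correlations")
    cor = _safe_abs_correlation(expr.values)
    connectivity = cor.sum(axis=1) - np.diag(cor)
    order = np.argsort(-np.round(connectivity, 4), kind="stable")
    keep = np.sort(order[:k])
    return ExpressionMatrix(
        gene_ids=[expr.gene_ids[i] for i in keep],
        sample_ids=list(expr.sample_ids),
        values=expr.values[keep],
    )


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology R^2 of a connectivity vector.

    Connectivities are discretised into ``n_bins`` equal-width bins;
    log10(bin frequency) is regressed on log10(bin mean connectivity) and
    the R^2 is given the flipped sign of the slope, so a decreasing
    (power-law-like) relationship scores positive.
    """
    k = np.asarray(connectivity, dtype=float)
    if np.ptp(k) == 0:
        raise ValueError("degenerate fit: all connectivities are identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_mean_k = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        log_freq.append(np.log10(mask.mean()))
        log_mean_k.append(np.log10(mean_k))
    if len(log_freq) < 3:
        raise ValueError("degenerate fit: too few populated connectivity bins")
    fit = linregress(log_mean_k, log_freq)
    r2 = fit.rvalue**2
    return float(-np.sign(fit.slope) * r2)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    candidate_powers: list[int] | None = None,
    r2_target: float = 0.8,
) -> SoftThresholdFit:
    """Choose the smallest power whose signed scale-free R^2 meets the target.

    If no candidate reaches the target, the power maximising the signed R^2
    is chosen and a warning emitted.
    """
    powers = list(candidate_powers) if candidate_powers else list(range(1, 21))
    if not powers:
        raise ValueError("candidate_powers must be non-empty")
    abs_cor = _safe_abs_correlation(expr.values)
    rows = []
    for beta in powers:
        adj = abs_cor**beta
        connectivity = adj.sum(axis=1) - np.diag(adj)
        rows.append(
            {
                "power": beta,
                "signed_r2": _scale_free_fit(connectivity),
                "mean_connectivity": float(connectivity.mean()),
            }
        )
    table = pd.DataFrame(rows)
    reaching = table[table["signed_r2"] >= r2_target]
    if len(reaching):
        chosen = int(reaching["power"].iloc[0])
        reached = True
    else:
        chosen = int(table.loc[table["signed_r2"].idxmax(), "power"])
        reached = False
        warnings.warn(
            f"no candidate power reaches signed R^2 >= {r2_target}; "
            f"using the best fit (power {chosen})"
        )
    return SoftThresholdFit(
        fit_table=table, chosen_power=chosen, r2_target=r2_target, target_reached=reached
    )


def adjacency_matrix(expr: ExpressionMatrix, beta: int) -> np.ndarray:
    """Unsigned adjacency a_ij = |cor(x_i, x_j)|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    adj = _safe_abs_correlation(expr.values) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def tom_dissimilarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap dissimilarity 1 - w_ij.

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj (u != i, j) and k_i the connectivity of i.
    Pairs with a non-positive denominator (fully disconnected) get
    dissimilarity 1 by convention.
    """
    a = np.asarray(adjacency, dtype=float)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0
    k = a0.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (l + a0) / denom
    w[denom <= 0] = 0.0
    d = 1.0 - w
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def consensus_tom(
    expr: ExpressionMatrix,
    beta: int,
    n_resamples: int = 100,
    leave_out_fraction: float = 0.1,
    seed: int = 0,
) -> GeneNetwork:
    """Resampled consensus TOM dissimilarity at a fixed power.

    For each resample a uniformly random subset of
    ceil((1 - leave_out_fraction) * n_samples) samples is drawn without
    replacement, the adjacency and TOM dissimilarity recomputed, and the
    consensus taken as the element-wise mean. The full-data adjacency is
    stored alongside. The power is frozen across resamples so the
    per-resample networks remain comparable.
    """
    if not 0.0 <= leave_out_fraction < 1.0:
        raise ValueError(f"leave_out_fraction must be in [0, 1), got {leave_out_fraction}")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    n_keep = ceil((1.0 - leave_out_fraction) * expr.n_samples)
    if n_keep < 3:
        raise ValueError(
            f"leave_out_fraction {leave_out_fraction} leaves only {n_keep} samples (< 3)"
        )
    rng = np.random.default_rng(seed)
    full_adjacency = adjacency_matrix(expr, beta)
    if n_keep == expr.n_samples:
        consensus = tom_dissimilarity(full_adjacency)
    else:
        consensus = np.zeros((expr.n_genes, expr.n_genes))
        for _ in range(n_resamples):
            subset = np.sort(rng.choice(expr.n_samples, size=n_keep, replace=False))
            adj = adjacency_matrix(expr.subset_samples(subset), beta)
            consensus += tom_dissimilarity(adj)
        consensus /= n_resamples
        consensus = np.clip((consensus + consensus.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(consensus, 0.0)
    return GeneNetwork(
        gene_ids=list(expr.gene_ids),
        beta=beta,
        adjacency=full_adjacency,
        consensus_dissimilarity=consensus,
        n_resamples=n_resamples,
        leave_out_fraction=leave_out_fraction,
    )


def _adaptive_branch_clusters(
    Z: np.ndarray,
    n_leaves: int,
    min_module_size: int,
    min_gap: float,
    min_rank_gap: float,
) -> list[list[int]]:
    """Adaptive branch pruning of a dendrogram.

    A branch is declared a module candidate when it holds at least
    ``min_module_size`` leaves and is internally coherent relative to where
    it attaches: it joins the rest of the tree at a height exceeding its
    own top merge by at least ``min_gap`` (as a fraction of the
    dendrogram's merge-height range) OR with at least ``min_rank_gap``
    (as a fraction of all merges) other merges in between. The height
    criterion resolves well-separated branches; the rank criterion is
    invariant to the height compression that large soft-threshold powers
    cause. The tree is walked from the root; inside an already-declared
    branch a sub-branch is split out only when both it and the remainder
    keep ``min_module_size`` leaves, so genuine modules are not shaved
    apart. Leaves under no declared branch remain unassigned.
    """
    root, _nodes = to_tree(Z, rd=True)
    heights = np.sort(Z[:, 2])
    height_range = float(heights[-1] - heights[0])
    if height_range <= 0:
        return [list(range(n_leaves))]
    gap_threshold = min_gap * height_range
    rank_threshold = min_rank_gap * (n_leaves - 1)

    def height(node) -> float:
        return 0.0 if node.is_leaf() else node.dist

    def rank(h: float) -> int:
        return int(np.searchsorted(heights, h, side="left"))

    def leaves(node) -> list[int]:
        out, stack = [], [node]
        while stack:
            nd = stack.pop()
            if nd.is_leaf():
                out.append(nd.id)
            else:
                stack.extend((nd.left, nd.right))
        return out

    # innermost declared-cluster id per leaf; -1 = unassigned
    assignment = np.full(n_leaves, -1, dtype=int)
    next_cluster = 0
    # stack of (node, enclosing_cluster_id, enclosing_cluster_size)
    stack = [(root, -1, n_leaves)]
    while stack:
        node, enclosing, enclosing_size = stack.pop()
        if node.is_leaf():
            continue
        for child in (node.left, node.right):
            if child.count < min_module_size:
                stack.append((child, enclosing, enclosing_size))
                continue
            height_gap = node.dist - height(child)
            rank_gap = rank(node.dist) - rank(height(child))
            is_root_candidate = (
                height_gap >= gap_threshold or rank_gap >= rank_threshold
            )
            if is_root_candidate and enclosing >= 0:
                # carving a sub-branch must leave a viable remainder
                if enclosing_size - child.count < min_module_size:
                    is_root_candidate = False
            if is_root_candidate:
                cid = next_cluster
                next_cluster += 1
                for leaf in leaves(child):
                    assignment[leaf] = cid
                stack.append((child, cid, child.count))
            else:
                stack.append((child, enclosing, enclosing_size))
    clusters: dict[int, list[int]] = {}
    for leaf, cid in enumerate(assignment):
        if cid >= 0:
            clusters.setdefault(cid, []).append(leaf)
    return list(clusters.values())


def detect_modules(
    network: GeneNetwork,
    min_module_size: int = 30,
    min_gap: float = 0.01,
    min_rank_gap: float = 0.07,
) -> ModuleAssignment:
    """Cluster the consensus dissimilarity into size-ranked colour modules.

    Average-linkage hierarchical clustering of the consensus TOM
    dissimilarity followed by adaptive branch pruning (``min_gap`` and
    ``min_rank_gap`` are the branch join-gap thresholds on the height and
    merge-rank scales); clusters smaller than ``min_module_size`` fall
    into "grey". Surviving modules are
    labelled with the conventional colour sequence in decreasing size
    order (size ties broken by the smallest member index).
    """
    n = network.n_genes
    if n < min_module_size:
        warnings.warn(
            f"{n} genes is fewer than min_module_size={min_module_size}; "
            "all genes assigned to grey"
        )
        return ModuleAssignment(labels={g: GREY for g in network.gene_ids})
    d = network.consensus_dissimilarity
    Z = linkage(squareform(d, checks=False), method="average")
    clusters = _adaptive_branch_clusters(Z, n, min_module_size, min_gap, min_rank_gap)
    surviving = [c for c in clusters if len(c) >= min_module_size]
    surviving.sort(key=lambda c: (-len(c), min(c)))
    labels = {g: GREY for g in network.gene_ids}
    for rank, cluster in enumerate(surviving):
        if rank < len(MODULE_COLOR_SEQUENCE):
            name = MODULE_COLOR_SEQUENCE[rank]
        else:
            name = f"module{rank + 1}"
        for idx in cluster:
            labels[network.gene_ids[idx]] = name
    return ModuleAssignment(labels=labels)
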