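"""Permutation validation of detected modules.

A module is considered statistically meaningful when its mean pairwise
topological overlap exceeds that of random gene sets of the same size
drawn from the network. The empirical p-value uses add-one smoothing so it
is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression import GeneNetwork, ModuleAssignment

__all__ = ["ModuleValidityResult", "validate_modules", "mean_topological_overlap"]


@dataclass
class ModuleValidityResult:
    """Per-module observed overlap, permutation null and empirical p."""

    table: pd.DataFrame  # columns: module, size, observed, perm_mean, perm_sd, p
    n_permutations: int

    def p_value(self, module: str) -> float:
        row = self.table[self.table["module"] == module]
        if row.empty:
            raise KeyError(f"module {module!r} not in validation result")
        return float(row["p"].iloc[0])


def mean_topological_overlap(similarity: np.ndarray, idx: np.ndarray) -> float:
    """Mean over unordered within-set gene pairs of the overlap similarity."""
    s = len(idx)
    sub = similarity[np.ix_(idx, idx)]
    return float((sub.sum() - np.trace(sub)) / (s * (s - 1)))


def validate_modules(
    network: GeneNetwork,
    modules: ModuleAssignment,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ModuleValidityResult:
    """Permutation test of within-module topological overlap.

    For each module of size s, the observed statistic is the mean pairwise
    overlap (1 - consensus dissimilarity). The null draws s genes without
    replacement from all network genes, n_permutations times; the one-sided
    p is (1 + #{perm >= observed}) / (1 + n_permutations). The grey module
    is tested like any other and reported.
    """
    if n_permutations < 100:
        raise ValueError(f"n_permutations must be >= 100, got {n_permutations}")
    rng = np.random.default_rng(seed)
    similarity = 1.0 - network.consensus_dissimilarity
    gene_index = {g: i for i, g in enumerate(network.gene_ids)}
    n = network.n_genes
    rows = []
    for module, size in modules.module_sizes().items():
        member_idx = np.sort(
            [gene_index[g] for g in modules.genes_in(module) if g in gene_index]
        )
        if len(member_idx) < 2:
            warnings.warn(f"module {module!r} has < 2 network genes; skipped")
            continue
        s = len(member_idx)
        observed = mean_topological_overlap(similarity, member_idx)
        perm = np.empty(n_permutations)
        for p_idx in range(n_permutations):
            # sorted draws make the degenerate whole-network module exact
            draw = np.sort(rng.choice(n, size=s, replace=False))
            perm[p_idx] = mean_topological_overlap(similarity, draw)
        p = (1.0 + np.sum(perm >= observed)) / (1.0 + n_permutations)
        rows.append(
            {
                "module": module,
                "size": s,
                "observed": observed,
                "perm_mean": float(perm.mean()),
                "perm_sd": float(perm.std(ddof=1)),
                "p": float(p),
            }
        )
    return ModuleValidityResult(
        table=pd.DataFrame(rows), n_permutations=n_permutations
    )
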