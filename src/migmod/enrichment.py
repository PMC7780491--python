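"""Functional annotation: cell-type specificity bootstrap and pathway
over-representation.

The cell-type test follows the expression-weighted cell-type enrichment
(EWCE) idea: the summed cell-type specificity of a target gene set is
compared against bootstrap sets of the same size drawn uniformly from the
specificity matrix. Pathway over-representation uses a binomial upper-tail
test against the network gene universe. Both families of p-values are
adjusted with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpecificityMatrix",
    "EnrichmentResult",
    "specificity_from_means",
    "ewce_test",
    "pathway_overrepresentation",
]


@dataclass
class SpecificityMatrix:
    """Row-normalised genes x cell-types specificity.

    Entry (g, c) is gene g's mean expression in type c divided by the sum
    of its mean expression over all types; rows sum to one.
    """

    values: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class EnrichmentResult:
    """Per-unit enrichment statistics (cell types or pathways)."""

    table: pd.DataFrame
    # cell types: unit, observed, null_mean, null_sd, fold, p, p_adjusted, significant
    # pathways:   unit, n_reference, n_overlap, p, p_adjusted, significant

    def p_adjusted(self, unit: str) -> float:
        row = self.table[self.table["unit"] == unit]
        if row.empty:
            raise KeyError(f"unit {unit!r} not in result")
        return float(row["p_adjusted"].iloc[0])


def specificity_from_means(cell_mean_expression: pd.DataFrame) -> SpecificityMatrix:
    """Row-normalise a genes x cell-types mean-expression matrix.

    All-zero rows carry no specificity information and are excluded with a
    warning; negative entries are an error.
    """
    values = cell_mean_expression.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative entry in cell-mean expression matrix")
    totals = values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero gene row(s) excluded from specificity")
    keep = ~zero
    spec = values[keep] / totals[keep, None]
    return SpecificityMatrix(
        values=pd.DataFrame(
            spec,
            index=cell_mean_expression.index[keep],
            columns=cell_mean_expression.columns,
        )
    )


def ewce_test(
    spec: SpecificityMatrix,
    target_genes: set[str],
    n_bootstrap: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Bootstrap cell-type enrichment of a gene set.

    Observed statistic per cell type: summed specificity over the target
    genes. Each bootstrap draws |target| genes uniformly without
    replacement from all specificity genes. p = (1 + #{boot >= observed})
    / (1 + n_bootstrap); fold change = observed / bootstrap mean; BH-FDR
    across cell types.
    """
    gene_index = {g: i for i, g in enumerate(spec.genes)}
    inside = sorted(g for g in target_genes if g in gene_index)
    dropped = len(target_genes) - len(inside)
    if dropped:
        warnings.warn(f"{dropped} target gene(s) absent from the specificity matrix")
    if len(inside) < 2:
        raise ValueError("need >= 2 target genes present in the specificity matrix")
    rng = np.random.default_rng(seed)
    values = spec.values.to_numpy()
    n_genes, n_types = values.shape
    target_idx = np.array([gene_index[g] for g in inside])
    observed = values[target_idx].sum(axis=0)
    s = len(target_idx)
    boot = np.empty((n_bootstrap, n_types))
    # without-replacement draws, vectorised in blocks to bound memory
    block = max(1, int(2e7 // max(n_genes, 1)))
    for start in range(0, n_bootstrap, block):
        stop = min(start + block, n_bootstrap)
        keys = rng.random((stop - start, n_genes))
        draws = np.argpartition(keys, s - 1, axis=1)[:, :s]
        boot[start:stop] = values[draws].sum(axis=1)
    p = (1.0 + (boot >= observed[None, :]).sum(axis=0)) / (1.0 + n_bootstrap)
    null_mean = boot.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(null_mean > 0, observed / null_mean, np.nan)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return EnrichmentResult(
        table=pd.DataFrame(
            {
                "unit": spec.cell_types,
                "observed": observed,
                "null_mean": null_mean,
                "null_sd": boot.std(axis=0, ddof=1),
                "fold": fold,
                "p": p,
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    )


def pathway_overrepresentation(
    query: set[str],
    reference: set[str],
    pathways: dict[str, set[str]],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Binomial over-representation of a query gene set in each pathway.

    For a pathway with K genes in the reference universe of size N and a
    query of size n with k overlapping genes, p = P(X >= k) with
    X ~ Binomial(n, K / N); BH-FDR across pathways.
    """
    if not reference:
        raise ValueError("empty reference gene universe")
    outside = query - reference
    if outside:
        raise ValueError(
            f"{len(outside)} query gene(s) outside the reference universe"
        )
    n = len(query)
    n_ref = len(reference)
    rows = []
    for name, genes in pathways.items():
        in_ref = genes & reference
        if not in_ref:
            continue
        k_over = len(query & in_ref)
        rate = len(in_ref) / n_ref
        p = float(stats.binom.sf(k_over - 1, n, rate)) if k_over > 0 else 1.0
        p = min(1.0, p)
        rows.append(
            {"unit": name, "n_reference": len(in_ref), "n_overlap": k_over, "p": p}
        )
    table = pd.DataFrame(rows)
    if len(table):
        _, p_adj, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
        table["p_adjusted"] = p_adj
        table["significant"] = p_adj < alpha
    return EnrichmentResult(table=table)
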