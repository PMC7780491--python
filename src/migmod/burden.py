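"""Module-level mutation-burden testing and replication.

Pipeline: modules whose mutated genes are unusually mutation-tolerant
(higher mean RVIS) are excluded; the remaining modules are tested for an
excess of mutated genes with a one-tailed Fisher's exact test
(module vs rest of the network, mutated vs non-mutated, undetected genes
excluded), Bonferroni-corrected over the tested modules. A module
replicates when it is significant in an independent case cohort but not in
a population control cohort, each cohort tested separately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ModuleAssignment
from .variant_filters import MutationStatusTable

__all__ = [
    "RvisFilterResult",
    "ModuleBurdenResult",
    "rvis_module_filter",
    "fisher_one_tailed",
    "module_burden_test",
    "replication_decision",
]


@dataclass
class RvisFilterResult:
    """Per-module intolerance comparison of mutated vs non-mutated genes."""

    table: pd.DataFrame  # module, n_mutated, n_non_mutated, mean_mutated,
    #                      mean_non_mutated, t_stat, p, excluded
    alpha: float

    @property
    def retained_modules(self) -> list[str]:
        return list(self.table.loc[~self.table["excluded"], "module"])

    @property
    def excluded_modules(self) -> list[str]:
        return list(self.table.loc[self.table["excluded"], "module"])


@dataclass
class ModuleBurdenResult:
    """One module's 2x2 burden test: counts, OR with CI, p and adjusted p."""

    module: str
    mutated_in: int
    nonmutated_in: int
    mutated_out: int
    nonmutated_out: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    p_adjusted: float
    significant: bool


def rvis_module_filter(
    modules: ModuleAssignment,
    status: MutationStatusTable,
    scores: dict[str, float],
    alpha: float = 0.05,
) -> RvisFilterResult:
    """Exclude modules whose mutated genes are significantly more tolerant.

    Welch's one-sided t-test of H1: mean score of mutated genes > mean
    score of non-mutated genes, per non-grey module; a module is excluded
    when p < alpha. Undetected genes and genes without a score are
    ignored; a module with fewer than two scored genes in either group is
    retained with a warning. If both groups have zero variance the test
    falls back to a direct mean comparison.
    """
    if not scores:
        raise ValueError("empty score table")
    rows = []
    for module in modules.module_names(include_grey=False):
        genes = modules.genes_in(module)
        mut = [scores[g] for g in genes if status.status.get(g) == "mutated" and g in scores]
        non = [scores[g] for g in genes if status.status.get(g) == "non_mutated" and g in scores]
        if len(mut) < 2 or len(non) < 2:
            warnings.warn(
                f"module {module!r}: fewer than 2 scored genes in a group; retained"
            )
            rows.append(
                {
                    "module": module,
                    "n_mutated": len(mut),
                    "n_non_mutated": len(non),
                    "mean_mutated": float(np.mean(mut)) if mut else math.nan,
                    "mean_non_mutated": float(np.mean(non)) if non else math.nan,
                    "t_stat": math.nan,
                    "p": math.nan,
                    "excluded": False,
                }
            )
            continue
        mut_a, non_a = np.asarray(mut), np.asarray(non)
        if mut_a.std() == 0 and non_a.std() == 0:
            # degenerate separation: decide on the means directly
            excluded = mut_a.mean() > non_a.mean()
            t_stat, p = math.nan, 0.0 if excluded else 1.0
        else:
            t_stat, p = stats.ttest_ind(
                mut_a, non_a, equal_var=False, alternative="greater"
            )
            excluded = p < alpha and mut_a.mean() > non_a.mean()
        rows.append(
            {
                "module": module,
                "n_mutated": len(mut),
                "n_non_mutated": len(non),
                "mean_mutated": float(mut_a.mean()),
                "mean_non_mutated": float(non_a.mean()),
                "t_stat": float(t_stat) if not math.isnan(float(t_stat)) else math.nan,
                "p": float(p),
                "excluded": bool(excluded),
            }
        )
    return RvisFilterResult(table=pd.DataFrame(rows), alpha=alpha)


def fisher_one_tailed(table: list[list[int]] | np.ndarray) -> tuple[float, float]:
    """One-tailed (enrichment) Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``. p is the upper-tail hypergeometric
    probability P(X >= a) under fixed margins. The odds ratio is the
    cross-product ratio, with the Haldane-Anscombe +0.5 correction applied
    to every cell when any cell is zero; the exact p never uses the
    correction.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    a, b, c, d = (int(x) for x in t.ravel())
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("at least one margin must be non-zero")
    # upper tail of X ~ Hypergeometric(N=n_total, K=a+c successes, n=a+b draws)
    p = float(stats.hypergeom.sf(a - 1, n_total, a + b, a + c))
    p = min(1.0, p)
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = float(a), float(b), float(c), float(d)
    odds_ratio = (a_ * d_) / (b_ * c_)
    return odds_ratio, p


def _or_confidence_interval(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Log-normal (Woolf) 95% CI on counts already +0.5-corrected if needed."""
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se)


def module_burden_test(
    modules: ModuleAssignment,
    status: MutationStatusTable,
    tested_modules: list[str],
    alpha: float = 0.05,
) -> list[ModuleBurdenResult]:
    """Per-module one-tailed Fisher burden test with Bonferroni correction.

    For module m: a = mutated genes in m, b = non-mutated in m,
    c = mutated among all other network genes (grey included),
    d = non-mutated among the rest. Undetected genes never enter any
    count. Adjusted p = min(1, p * number of tested modules).
    """
    n_tested = len(tested_modules)
    results: list[ModuleBurdenResult] = []
    mutated = status.mutated
    non_mutated = status.non_mutated
    for module in tested_modules:
        genes = set(modules.genes_in(module))
        a = len(genes & mutated)
        b = len(genes & non_mutated)
        c = len(mutated - genes)
        d = len(non_mutated - genes)
        if a + b == 0:
            warnings.warn(f"module {module!r} has no detectable genes; skipped")
            continue
        odds_ratio, p = fisher_one_tailed([[a, b], [c, d]])
        if min(a, b, c, d) == 0:
            ci = _or_confidence_interval(a + 0.5, b + 0.5, c + 0.5, d + 0.5)
        else:
            ci = _or_confidence_interval(a, b, c, d)
        p_adj = min(1.0, p * n_tested)
        results.append(
            ModuleBurdenResult(
                module=module,
                mutated_in=a,
                nonmutated_in=b,
                mutated_out=c,
                nonmutated_out=d,
                odds_ratio=odds_ratio,
                ci_low=ci[0],
                ci_high=ci[1],
                p=p,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return results


def burden_results_frame(results: list[ModuleBurdenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module": [r.module for r in results],
            "mutated_in": [r.mutated_in for r in results],
            "nonmutated_in": [r.nonmutated_in for r in results],
            "mutated_out": [r.mutated_out for r in results],
            "nonmutated_out": [r.nonmutated_out for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.significant for r in results],
        }
    )


def replication_decision(
    case_results: list[ModuleBurdenResult],
    control_results: list[ModuleBurdenResult],
) -> dict[str, bool]:
    """A module replicates iff significant in cases and not in controls.

    Each arm carries its own Bonferroni-adjusted significance flag; the
    arms are never pooled. A module present in only one arm is an error.
    """
    case_by_module = {r.module: r for r in case_results}
    control_by_module = {r.module: r for r in control_results}
    if set(case_by_module) != set(control_by_module):
        only = set(case_by_module) ^ set(control_by_module)
        raise ValueError(f"modules present in one arm only: {sorted(only)}")
    return {
        m: case_by_module[m].significant and not control_by_module[m].significant
        for m in case_by_module
    }
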