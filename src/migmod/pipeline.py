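"""End-to-end orchestration: discovery and replication from one config.

Discovery: connectivity selection -> soft-threshold fit -> consensus TOM ->
module detection -> permutation validation -> familial mutated-gene calling
-> intolerance (RVIS) module filter -> module burden test. Replication:
cohort mutated-gene calling on cases and controls separately -> burden
tests restricted to candidate modules -> replication decision. All
randomness fans out from a single seed through stable per-stage child
seeds, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .burden import (
    ModuleBurdenResult,
    RvisFilterResult,
    burden_results_frame,
    module_burden_test,
    replication_decision,
    rvis_module_filter,
)
from .coexpression import (
    ModuleAssignment,
    consensus_tom,
    detect_modules,
    pick_soft_threshold,
    select_top_connected,
)
from .io_formats import ExpressionMatrix, Pedigree, VariantTable
from .module_validation import ModuleValidityResult, validate_modules
from .variant_filters import (
    MutationStatusTable,
    SegregationModel,
    gene_status_cohort,
    gene_status_familial,
)

logger = logging.getLogger("migmod")

__all__ = ["RunConfig", "DiscoveryResult", "run_discovery", "run_replication", "stage_seed"]


@dataclass
class RunConfig:
    """All tunable parameters of a run, with the pipeline's defaults."""

    k_top_genes: int = 5000
    candidate_powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_target: float = 0.8
    n_resamples: int = 100
    leave_out_fraction: float = 0.1
    min_module_size: int = 30
    maf_threshold: float = 0.05
    penetrance_min: float = 0.9
    alpha: float = 0.05
    n_permutations: int = 1000
    n_bootstrap: int = 10_000
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed derived from the run seed."""
    return (zlib.crc32(stage.encode()) ^ (seed * 2654435761)) % (2**31 - 1)


@dataclass
class DiscoveryResult:
    modules: ModuleAssignment
    validity: ModuleValidityResult
    rvis_filter: RvisFilterResult
    burden: list[ModuleBurdenResult]
    status: MutationStatusTable
    chosen_power: int
    scale_free_r2: float
    summary: dict


def run_discovery(
    config: RunConfig,
    expression: ExpressionMatrix,
    variants: VariantTable,
    pedigrees: dict[str, Pedigree],
    scores: dict[str, float],
    out_dir: str | Path | None = None,
) -> DiscoveryResult:
    """Run the full discovery arm on in-memory inputs.

    When ``out_dir`` is given, stage outputs (module assignment, fit table,
    validation table, burden table, JSON run summary) are written there as
    tab-separated text.
    """
    summary: dict = {"config": config.to_dict(), "config_hash": config.config_hash()}

    k = min(config.k_top_genes, expression.n_genes)
    logger.info("selecting %d most connected of %d genes", k, expression.n_genes)
    expr_top = select_top_connected(expression, k)
    summary["n_genes_input"] = expression.n_genes
    summary["n_genes_network"] = expr_top.n_genes

    fit = pick_soft_threshold(expr_top, config.candidate_powers, config.r2_target)
    chosen_row = fit.fit_table[fit.fit_table["power"] == fit.chosen_power].iloc[0]
    summary["chosen_power"] = fit.chosen_power
    summary["scale_free_r2"] = float(chosen_row["signed_r2"])
    logger.info("chose power %d (signed R^2 = %.3f)", fit.chosen_power, chosen_row["signed_r2"])

    network = consensus_tom(
        expr_top,
        beta=fit.chosen_power,
        n_resamples=config.n_resamples,
        leave_out_fraction=config.leave_out_fraction,
        seed=stage_seed(config.seed, "consensus_tom"),
    )
    modules = detect_modules(network, min_module_size=config.min_module_size)
    sizes = modules.module_sizes()
    summary["module_sizes"] = dict(sorted(sizes.items(), key=lambda kv: (-kv[1], kv[0])))
    logger.info("detected %d modules (+grey)", len([m for m in sizes if m != "grey"]))

    validity = validate_modules(
        network,
        modules,
        n_permutations=config.n_permutations,
        seed=stage_seed(config.seed, "validate_modules"),
    )

    model = SegregationModel(penetrance_min=config.penetrance_min)
    status = gene_status_familial(
        variants, pedigrees, network.gene_ids, model, config.maf_threshold
    )
    summary["n_genes_detectable"] = len(status.mutated) + len(status.non_mutated)
    summary["n_genes_mutated"] = len(status.mutated)
    logger.info(
        "%d detectable genes, %d mutated",
        summary["n_genes_detectable"],
        summary["n_genes_mutated"],
    )

    rvis = rvis_module_filter(modules, status, scores, alpha=config.alpha)
    tested = rvis.retained_modules
    summary["n_modules_tested"] = len(tested)
    summary["modules_excluded_by_rvis"] = rvis.excluded_modules

    burden = module_burden_test(modules, status, tested, alpha=config.alpha)
    summary["significant_modules"] = [r.module for r in burden if r.significant]

    result = DiscoveryResult(
        modules=modules,
        validity=validity,
        rvis_filter=rvis,
        burden=burden,
        status=status,
        chosen_power=fit.chosen_power,
        scale_free_r2=float(chosen_row["signed_r2"]),
        summary=summary,
    )
    if out_dir is not None:
        _write_discovery(result, fit.fit_table, Path(out_dir))
    return result


def _write_discovery(result: DiscoveryResult, fit_table: pd.DataFrame, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.modules.to_frame().to_csv(out_dir / "modules.tsv", sep="\t", index=False)
    fit_table.to_csv(out_dir / "soft_threshold_fit.tsv", sep="\t", index=False)
    result.validity.table.to_csv(out_dir / "module_validation.tsv", sep="\t", index=False)
    result.rvis_filter.table.to_csv(out_dir / "rvis_filter.tsv", sep="\t", index=False)
    burden_results_frame(result.burden).to_csv(out_dir / "burden.tsv", sep="\t", index=False)
    status_frame = pd.DataFrame(
        {
            "gene": list(result.status.status),
            "status": list(result.status.status.values()),
            "n_families": [
                result.status.family_counts.get(g, 0) for g in result.status.status
            ],
        }
    )
    status_frame.to_csv(out_dir / "gene_status.tsv", sep="\t", index=False)
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_replication(
    config: RunConfig,
    modules: ModuleAssignment,
    network_genes: list[str],
    case_variants: VariantTable,
    control_variants: VariantTable,
    candidate_modules: list[str],
    out_dir: str | Path | None = None,
) -> dict:
    """Replication arm: separate case and control burden tests.

    Returns a dict with per-arm burden results and the replicated flags.
    """
    case_status = gene_status_cohort(case_variants, network_genes, config.maf_threshold)
    control_status = gene_status_cohort(
        control_variants, network_genes, config.maf_threshold
    )
    case_burden = module_burden_test(modules, case_status, candidate_modules, config.alpha)
    control_burden = module_burden_test(
        modules, control_status, candidate_modules, config.alpha
    )
    replicated = replication_decision(case_burden, control_burden)
    out = {
        "case_burden": case_burden,
        "control_burden": control_burden,
        "replicated": replicated,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        burden_results_frame(case_burden).to_csv(
            out_dir / "replication_cases.tsv", sep="\t", index=False
        )
        burden_results_frame(control_burden).to_csv(
            out_dir / "replication_controls.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"module": list(replicated), "replicated": list(replicated.values())}
        ).to_csv(out_dir / "replication.tsv", sep="\t", index=False)
    return out
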