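"""Synthetic fixtures with known ground truth.

Three generators emulate the data the pipeline consumes: (a) expression
matrices with latent-factor-driven co-expressed gene blocks on a background
of independent noise genes, (b) multi-generation pedigrees in which a
single-copy causal allele drops through the family and carriers are
affected with incomplete penetrance, and (c) cohort variant tables with a
rare-MAF spectrum and a configurable excess of qualifying variants in one
gene module. Every generator is a pure function of its parameters and seed,
and returns a :class:`SimulationTruth` sufficient to score downstream
recovery without inspecting generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    Pedigree,
    PedigreeMember,
    VariantRecord,
    VariantTable,
)
from .variant_filters import SegregationModel, segregates_in_family

__all__ = [
    "SimulationTruth",
    "simulate_modular_expression",
    "simulate_family",
    "simulate_families",
    "simulate_variant_table",
    "simulate_cohort_variant_table",
    "simulate_specificity_data",
]

#: Relative draw weights of the functional consequence classes, reflecting
#: that the bulk of rare coding variation is missense.
_FUNCTIONAL_WEIGHTS = {
    "nonsynonymous_SNV": 0.88,
    "frameshift_deletion": 0.02,
    "frameshift_insertion": 0.02,
    "nonframeshift_deletion": 0.02,
    "nonframeshift_insertion": 0.02,
    "splice_site": 0.02,
    "stopgain": 0.015,
    "stoploss": 0.005,
}


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run.

    ``true_module_labels`` maps each gene to its planted block (background
    genes map to ``"background"``); ``causal_genes`` are the genes given a
    qualifying segregating variant; ``causal_variants`` are (gene, family)
    pairs; ``generator_config`` records every parameter and the seed.
    """

    true_module_labels: dict[str, str] = field(default_factory=dict)
    causal_genes: set[str] = field(default_factory=set)
    causal_variants: set[tuple[str, str]] = field(default_factory=set)
    generator_config: dict = field(default_factory=dict)


def simulate_modular_expression(
    n_background: int,
    module_sizes: Sequence[int],
    n_samples: int,
    within_module_cor: float,
    seed: int,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Latent-factor expression with planted co-expressed blocks.

    For each block a latent standard-normal sample vector ``e`` is drawn;
    each member gene is ``sqrt(r) * e + sqrt(1 - r) * noise`` so the
    expected pairwise correlation inside the block is exactly ``r``.
    Background genes are independent standard normal.
    """
    if not 0.0 < within_module_cor < 1.0:
        raise ValueError(f"within_module_cor must be in (0, 1), got {within_module_cor}")
    if any(s < 2 for s in module_sizes):
        raise ValueError("each module size must be >= 2")
    if n_samples < 10:
        raise ValueError(f"n_samples must be >= 10, got {n_samples}")
    rng = np.random.default_rng(seed)
    r = within_module_cor
    blocks: list[np.ndarray] = []
    labels: dict[str, str] = {}
    gene_ids: list[str] = []
    for m_idx, size in enumerate(module_sizes, start=1):
        latent = rng.standard_normal(n_samples)
        noise = rng.standard_normal((size, n_samples))
        blocks.append(np.sqrt(r) * latent[None, :] + np.sqrt(1.0 - r) * noise)
        for g_idx in range(size):
            gid = f"M{m_idx}_G{g_idx + 1:04d}"
            gene_ids.append(gid)
            labels[gid] = f"block{m_idx}"
    if n_background:
        blocks.append(rng.standard_normal((n_background, n_samples)))
        for g_idx in range(n_background):
            gid = f"BG_G{g_idx + 1:04d}"
            gene_ids.append(gid)
            labels[gid] = "background"
    values = np.vstack(blocks)
    expr = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"S{i + 1:04d}" for i in range(n_samples)],
        values=values,
    )
    truth = SimulationTruth(
        true_module_labels=labels,
        generator_config={
            "n_background": n_background,
            "module_sizes": list(module_sizes),
            "n_samples": n_samples,
            "within_module_cor": r,
            "seed": seed,
        },
    )
    return expr, truth


def simulate_family(
    n_generations: int,
    children_per_couple: int,
    penetrance: float,
    phenocopy_rate: float,
    seed: int,
    family_id: str = "FAM1",
) -> tuple[Pedigree, dict[str, bool]]:
    """Gene-drop a single-copy causal allele through a pedigree.

    One founder in the first couple carries the allele heterozygously; each
    child inherits it with probability 1/2. Couples are monogamous and
    married-in spouses are unrelated non-carriers. Carriers are affected
    with probability ``penetrance``, non-carriers with probability
    ``phenocopy_rate``.
    """
    if n_generations < 2:
        raise ValueError(f"n_generations must be >= 2, got {n_generations}")
    if children_per_couple < 1:
        raise ValueError("children_per_couple must be >= 1")
    if not 0.0 < penetrance <= 1.0:
        raise ValueError(f"penetrance must be in (0, 1], got {penetrance}")
    if not 0.0 <= phenocopy_rate < 1.0:
        raise ValueError(f"phenocopy_rate must be in [0, 1), got {phenocopy_rate}")
    rng = np.random.default_rng(seed)
    members: list[PedigreeMember] = []
    carriers: dict[str, bool] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{family_id}_I{counter:03d}"

    def affection(is_carrier: bool) -> str:
        p = penetrance if is_carrier else phenocopy_rate
        return "yes" if rng.random() < p else "no"

    def add(founder_parents: tuple[str | None, str | None], sex: int, carrier: bool) -> str:
        iid = new_id()
        members.append(
            PedigreeMember(
                individual_id=iid,
                father_id=founder_parents[0],
                mother_id=founder_parents[1],
                sex=sex,
                affected=affection(carrier),
            )
        )
        carriers[iid] = carrier
        return iid

    father = add((None, None), 1, True)  # founding carrier
    mother = add((None, None), 2, False)
    couples = [(father, mother)]
    for _gen in range(1, n_generations):
        next_couples: list[tuple[str, str]] = []
        for f_id, m_id in couples:
            for _ in range(children_per_couple):
                inherits = carriers[f_id] or carriers[m_id]
                child_carrier = bool(inherits and rng.random() < 0.5)
                sex = 1 if rng.random() < 0.5 else 2
                child = add((f_id, m_id), sex, child_carrier)
                if _gen < n_generations - 1:
                    spouse_sex = 2 if sex == 1 else 1
                    spouse = add((None, None), spouse_sex, False)
                    couple = (child, spouse) if sex == 1 else (spouse, child)
                    next_couples.append(couple)
        couples = next_couples
    ped = Pedigree(family_id=family_id, members=members)
    return ped, carriers


def simulate_families(
    n_families: int,
    n_generations: int = 3,
    children_per_couple: int = 3,
    penetrance: float = 0.9,
    phenocopy_rate: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, Pedigree], dict[str, dict[str, bool]]]:
    """Simulate a cohort of independent families with per-family child seeds."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_families)
    pedigrees: dict[str, Pedigree] = {}
    carrier_maps: dict[str, dict[str, bool]] = {}
    for i in range(n_families):
        fam_id = f"FAM{i + 1:03d}"
        ped, carriers = simulate_family(
            n_generations,
            children_per_couple,
            penetrance,
            phenocopy_rate,
            seed=int(child_seeds[i]),
            family_id=fam_id,
        )
        pedigrees[fam_id] = ped
        carrier_maps[fam_id] = carriers
    return pedigrees, carrier_maps


def _draw_consequence(rng: np.random.Generator) -> str:
    classes = list(_FUNCTIONAL_WEIGHTS)
    weights = np.array([_FUNCTIONAL_WEIGHTS[c] for c in classes])
    return classes[rng.choice(len(classes), p=weights / weights.sum())]


def _carrier_variant(
    chrom: str, pos: int, gene: str, maf: float, consequence: str, carriers: set[str]
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="T",
        gene=gene,
        consequence=consequence,
        population_maf=maf,
        genotypes={iid: 1 for iid in carriers},
    )


def simulate_variant_table(
    gene_universe: Sequence[str],
    modules: Mapping[str, str],
    enriched_module: str | None,
    families: dict[str, Pedigree],
    carrier_maps: dict[str, dict[str, bool]],
    qualifying_rate_base: float,
    qualifying_rate_enriched: float,
    seed: int,
    model: SegregationModel | None = None,
) -> tuple[VariantTable, SimulationTruth]:
    """Plant rare functional segregating variants on a family cohort.

    Every gene receives one common non-qualifying variant so it is
    detectable. Independently, with probability ``qualifying_rate_base``
    (or ``qualifying_rate_enriched`` for genes of ``enriched_module``) a
    gene receives a rare functional variant (MAF uniform on
    [0.0001, 0.04]) placed on the carrier genotypes of one family whose
    carrier/affection pattern satisfies the segregation rule, so planted
    variants segregate by construction.
    """
    for name, rate in (
        ("qualifying_rate_base", qualifying_rate_base),
        ("qualifying_rate_enriched", qualifying_rate_enriched),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    if enriched_module is not None and enriched_module not in set(modules.values()):
        raise ValueError(f"enriched module {enriched_module!r} absent from assignment")
    model = model or SegregationModel()
    rng = np.random.default_rng(seed)
    all_individuals = sorted(
        iid for ped in families.values() for iid in ped.individual_ids()
    )
    # families in which the planted carrier set satisfies the segregation rule
    compatible: list[str] = []
    for fam_id in sorted(families):
        carrier_set = {iid for iid, c in carrier_maps[fam_id].items() if c}
        probe = _carrier_variant("1", 1, "probe", 0.001, "nonsynonymous_SNV", carrier_set)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            if carrier_set and segregates_in_family(probe, families[fam_id], model):
                compatible.append(fam_id)
    if (qualifying_rate_base > 0 or qualifying_rate_enriched > 0) and not compatible:
        raise ValueError(
            "no simulated family is compatible with the segregation rule; "
            "raise penetrance or lower the phenocopy rate"
        )
    records: list[VariantRecord] = []
    truth = SimulationTruth(
        true_module_labels=dict(modules),
        generator_config={
            "enriched_module": enriched_module,
            "qualifying_rate_base": qualifying_rate_base,
            "qualifying_rate_enriched": qualifying_rate_enriched,
            "seed": seed,
        },
    )
    pos = 0
    n_ind = len(all_individuals)
    for gene in gene_universe:
        pos += 10
        # common non-qualifying variant: every gene stays detectable
        common_maf = float(rng.uniform(0.06, 0.5))
        n_carr = max(1, int(rng.binomial(min(n_ind, 40), common_maf)))
        carr_idx = rng.choice(n_ind, size=min(n_carr, n_ind), replace=False)
        records.append(
            _carrier_variant(
                "1",
                pos,
                gene,
                common_maf,
                "other",
                {all_individuals[i] for i in carr_idx},
            )
        )
        label = modules.get(gene)
        rate = (
            qualifying_rate_enriched
            if enriched_module is not None and label == enriched_module
            else qualifying_rate_base
        )
        if rate > 0 and rng.random() < rate:
            fam_id = compatible[rng.integers(len(compatible))]
            carrier_set = {iid for iid, c in carrier_maps[fam_id].items() if c}
            pos += 1
            records.append(
                _carrier_variant(
                    "1",
                    pos,
                    gene,
                    float(rng.uniform(0.0001, 0.04)),
                    _draw_consequence(rng),
                    carrier_set,
                )
            )
            truth.causal_genes.add(gene)
            truth.causal_variants.add((gene, fam_id))
    return VariantTable(records=records), truth


def simulate_cohort_variant_table(
    gene_universe: Sequence[str],
    modules: Mapping[str, str],
    enriched_module: str | None,
    individuals: Sequence[str],
    qualifying_rate_base: float,
    qualifying_rate_enriched: float,
    seed: int,
) -> tuple[VariantTable, SimulationTruth]:
    """Variant table for an unrelated cohort (sporadic cases or controls).

    Same per-gene qualifying scheme as :func:`simulate_variant_table` but a
    qualifying variant is simply carried by one random cohort member; no
    pedigree structure is involved.
    """
    if enriched_module is not None and enriched_module not in set(modules.values()):
        raise ValueError(f"enriched module {enriched_module!r} absent from assignment")
    rng = np.random.default_rng(seed)
    individuals = list(individuals)
    n_ind = len(individuals)
    records: list[VariantRecord] = []
    truth = SimulationTruth(
        true_module_labels=dict(modules),
        generator_config={
            "enriched_module": enriched_module,
            "qualifying_rate_base": qualifying_rate_base,
            "qualifying_rate_enriched": qualifying_rate_enriched,
            "seed": seed,
        },
    )
    pos = 0
    for gene in gene_universe:
        pos += 10
        common_maf = float(rng.uniform(0.06, 0.5))
        n_carr = max(1, int(rng.binomial(min(n_ind, 40), common_maf)))
        carr_idx = rng.choice(n_ind, size=min(n_carr, n_ind), replace=False)
        records.append(
            _carrier_variant(
                "1", pos, gene, common_maf, "other", {individuals[i] for i in carr_idx}
            )
        )
        label = modules.get(gene)
        rate = (
            qualifying_rate_enriched
            if enriched_module is not None and label == enriched_module
            else qualifying_rate_base
        )
        if rate > 0 and rng.random() < rate:
            pos += 1
            records.append(
                _carrier_variant(
                    "1",
                    pos,
                    gene,
                    float(rng.uniform(0.0001, 0.04)),
                    _draw_consequence(rng),
                    {individuals[rng.integers(n_ind)]},
                )
            )
            truth.causal_genes.add(gene)
    return VariantTable(records=records), truth


def simulate_specificity_data(
    n_genes: int,
    cell_types: Sequence[str],
    n_marker_per_type: int,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Cell-type mean-expression matrix with planted marker genes.

    Marker genes are expressed 10x higher in their own cell type; the
    remaining genes are near-uniform across types (multiplicative jitter
    with 2% coefficient of variation). Rows carry a random overall scale,
    which specificity normalisation removes.
    """
    cell_types = list(cell_types)
    if n_marker_per_type * len(cell_types) > n_genes:
        raise ValueError("more marker genes requested than genes available")
    rng = np.random.default_rng(seed)
    base = np.ones((n_genes, len(cell_types)))
    markers: dict[str, set[str]] = {ct: set() for ct in cell_types}
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    g = 0
    for t_idx, ct in enumerate(cell_types):
        for _ in range(n_marker_per_type):
            base[g, t_idx] = 10.0
            markers[ct].add(gene_ids[g])
            g += 1
    scale = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    jitter = np.clip(rng.normal(1.0, 0.02, size=base.shape), 0.5, 1.5)
    values = base * jitter * scale[:, None]
    frame = pd.DataFrame(values, index=gene_ids, columns=cell_types)
    return frame, markers
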