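"""Mutated-gene calling: functional class, rarity, and pedigree segregation.

A gene is "mutated" when it carries at least one rare functional variant
that (in familial mode) segregates with affection status in at least one
family under a dominant model with a penetrance floor, or (in cohort mode)
is simply carried by at least one individual. Genes with variants but no
qualifying one are "non-mutated"; genes with no variants at all are
"undetected" and excluded from burden testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .io_formats import (
    FUNCTIONAL_CONSEQUENCES,
    MISSING,
    Pedigree,
    VariantRecord,
    VariantTable,
)

__all__ = [
    "SegregationModel",
    "MutationStatusTable",
    "is_functional",
    "passes_maf",
    "max_credible_af",
    "segregates_in_family",
    "gene_status_familial",
    "gene_status_cohort",
]


@dataclass
class SegregationModel:
    """Dominant-model segregation with a penetrance window.

    Penetrance here is the fraction of variant carriers that are affected;
    a variant segregates when every genotyped affected member carries it
    and the affected fraction among carriers is at least
    ``penetrance_min``. Only the lower bound enters the rule.
    """

    penetrance_min: float = 0.9
    penetrance_max: float = 1.0
    inheritance: str = "dominant"

    def __post_init__(self) -> None:
        if not 0.0 < self.penetrance_min <= self.penetrance_max <= 1.0:
            raise ValueError(
                f"need 0 < penetrance_min <= penetrance_max <= 1, got "
                f"({self.penetrance_min}, {self.penetrance_max})"
            )
        if self.inheritance != "dominant":
            raise ValueError("only the dominant model is supported")


@dataclass
class MutationStatusTable:
    """Per-gene mutated / non-mutated / undetected calls.

    ``family_counts`` gives, per gene, the number of distinct families in
    which a qualifying variant segregates (familial mode only).
    ``qualifying_variants`` lists each gene's qualifying records.
    """

    status: dict[str, str]
    family_counts: dict[str, int] = field(default_factory=dict)
    qualifying_variants: dict[str, list[VariantRecord]] = field(default_factory=dict)

    def genes_with_status(self, which: str) -> set[str]:
        return {g for g, s in self.status.items() if s == which}

    @property
    def mutated(self) -> set[str]:
        return self.genes_with_status("mutated")

    @property
    def non_mutated(self) -> set[str]:
        return self.genes_with_status("non_mutated")

    @property
    def undetected(self) -> set[str]:
        return self.genes_with_status("undetected")


def is_functional(variant: VariantRecord) -> bool:
    """True iff the consequence is one of the eight coding-impact classes."""
    return variant.consequence in FUNCTIONAL_CONSEQUENCES


def passes_maf(variant: VariantRecord, threshold: float = 0.05) -> bool:
    """Strict rarity filter: population MAF < threshold.

    A missing MAF passes: absence from the reference database implies the
    allele is rarer than anything the database reports.
    """
    if variant.population_maf is None:
        return True
    return variant.population_maf < threshold


def max_credible_af(
    prevalence: float,
    inheritance: str,
    genetic_heterogeneity: float,
    allelic_heterogeneity: float,
    penetrance: float,
) -> float:
    """Maximum credible population allele frequency for a causal allele.

    monoallelic:  q = prevalence * G * A / (2 * penetrance)
    biallelic:    q = sqrt(prevalence * G / penetrance) * A

    where G is the genetic and A the allelic heterogeneity. Used to justify
    the rarity cut-off from disease prevalence.
    """
    for name, val in (
        ("prevalence", prevalence),
        ("genetic_heterogeneity", genetic_heterogeneity),
        ("allelic_heterogeneity", allelic_heterogeneity),
        ("penetrance", penetrance),
    ):
        if not 0.0 < val <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {val}")
    if inheritance == "monoallelic":
        return prevalence * genetic_heterogeneity * allelic_heterogeneity / (2.0 * penetrance)
    if inheritance == "biallelic":
        return math.sqrt(prevalence * genetic_heterogeneity / penetrance) * allelic_heterogeneity
    raise ValueError(f"inheritance must be 'monoallelic' or 'biallelic', got {inheritance!r}")


def segregates_in_family(
    variant: VariantRecord,
    family: Pedigree,
    model: SegregationModel | None = None,
) -> bool:
    """Dominant-model segregation of a variant with affection status.

    True iff (a) every affected member with a non-missing genotype carries
    at least one alt allele, and (b) among members with non-missing
    genotypes, affected carriers / carriers >= penetrance_min. Members with
    unknown affection status are excluded from both counts. Individuals
    absent from the genotype map are homozygous reference.
    """
    model = model or SegregationModel()
    n_genotyped_affected = 0
    n_carriers = 0
    n_affected_carriers = 0
    for member in family.members:
        if member.affected == "unknown":
            continue
        dose = variant.dosage(member.individual_id)
        if dose == MISSING:
            continue
        carrier = dose in (1, 2)
        if member.affected == "yes":
            n_genotyped_affected += 1
            if not carrier:
                return False
            n_affected_carriers += 1
        if carrier:
            n_carriers += 1
    if n_genotyped_affected == 0:
        warnings.warn(
            f"family {family.family_id}: no genotyped affected members for "
            f"{variant.chrom}:{variant.pos}"
        )
        return False
    if n_carriers == 0:
        return False
    return n_affected_carriers / n_carriers >= model.penetrance_min


def _qualifies(variant: VariantRecord, maf_threshold: float) -> bool:
    return is_functional(variant) and passes_maf(variant, maf_threshold)


def gene_status_familial(
    variants: VariantTable,
    families: dict[str, Pedigree],
    genes: list[str],
    model: SegregationModel | None = None,
    maf_threshold: float = 0.05,
) -> MutationStatusTable:
    """Call gene status against a family cohort.

    mutated: some rare functional variant segregates in >= 1 family;
    non_mutated: variants exist but none qualifies;
    undetected: no variant of any kind was observed for the gene.
    """
    model = model or SegregationModel()
    by_gene = variants.by_gene()
    gene_set = set(genes)
    status: dict[str, str] = {}
    family_counts: dict[str, int] = {}
    qualifying: dict[str, list[VariantRecord]] = {}
    for gene in genes:
        recs = by_gene.get(gene, [])
        if not recs:
            status[gene] = "undetected"
            family_counts[gene] = 0
            continue
        seg_families: set[str] = set()
        qual_recs: list[VariantRecord] = []
        for rec in recs:
            if not _qualifies(rec, maf_threshold):
                continue
            hit = False
            for fam_id, ped in families.items():
                if segregates_in_family(rec, ped, model):
                    seg_families.add(fam_id)
                    hit = True
            if hit:
                qual_recs.append(rec)
        if seg_families:
            status[gene] = "mutated"
            qualifying[gene] = qual_recs
        else:
            status[gene] = "non_mutated"
        family_counts[gene] = len(seg_families)
    # genes present in the VCF but outside the tested gene list are ignored
    _ = set(by_gene) - gene_set
    return MutationStatusTable(
        status=status, family_counts=family_counts, qualifying_variants=qualifying
    )


def gene_status_cohort(
    variants: VariantTable,
    genes: list[str],
    maf_threshold: float = 0.05,
) -> MutationStatusTable:
    """Call gene status in an unrelated cohort (no segregation requirement).

    mutated: some rare functional variant is carried by >= 1 individual.
    """
    by_gene = variants.by_gene()
    status: dict[str, str] = {}
    qualifying: dict[str, list[VariantRecord]] = {}
    for gene in genes:
        recs = by_gene.get(gene, [])
        if not recs:
            status[gene] = "undetected"
            continue
        qual = [r for r in recs if _qualifies(r, maf_threshold) and r.carriers()]
        if qual:
            status[gene] = "mutated"
            qualifying[gene] = qual
        else:
            status[gene] = "non_mutated"
    return MutationStatusTable(status=status, qualifying_variants=qualifying)
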