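"""Mutated-gene calling: class filter, rarity filter, segregation rule."""

import math
import warnings

import pytest

from migmod.io_formats import (
    FUNCTIONAL_CONSEQUENCES,
    MISSING,
    Pedigree,
    PedigreeMember,
    VariantRecord,
    VariantTable,
)
from migmod.synthetic import simulate_families, simulate_variant_table
from migmod.variant_filters import (
    SegregationModel,
    gene_status_cohort,
    gene_status_familial,
    is_functional,
    max_credible_af,
    passes_maf,
    segregates_in_family,
)


def make_variant(consequence="nonsynonymous_SNV", maf=0.001, genotypes=None, gene="G1"):
    return VariantRecord(
        chrom="1",
        pos=100,
        ref="A",
        alt="T",
        gene=gene,
        consequence=consequence,
        population_maf=maf,
        genotypes=genotypes or {},
    )


def make_family(members, family_id="F1"):
    """members: list of (id, affected, dosage); all founders for simplicity."""
    ped = Pedigree(
        family_id=family_id,
        members=[
            PedigreeMember(iid, None, None, 1, affected) for iid, affected, _ in members
        ],
    )
    genotypes = {iid: dose for iid, _, dose in members if dose != 0}
    return ped, genotypes


class TestFunctionalAndRarity:
    @pytest.mark.parametrize("consequence", sorted(FUNCTIONAL_CONSEQUENCES))
    def test_all_eight_classes_functional(self, consequence):
        assert is_functional(make_variant(consequence=consequence))

    def test_other_not_functional(self):
        assert not is_functional(make_variant(consequence="other"))

    def test_unknown_strings_collapse_to_other(self):
        assert make_variant(consequence="synonymous_SNV").consequence == "other"

    @pytest.mark.parametrize(
        "maf,expected",
        [(0.049, True), (0.05, False), (None, True), (0.0, True), (0.2, False)],
    )
    def test_maf_threshold_strict(self, maf, expected):
        assert passes_maf(make_variant(maf=maf), 0.05) is expected


class TestMaxCredibleAf:
    def test_monoallelic_closed_form(self):
        assert max_credible_af(1.0, "monoallelic", 1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_biallelic_closed_form(self):
        assert max_credible_af(1.0, "biallelic", 1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_biallelic_worked_example(self):
        q = max_credible_af(0.2, "biallelic", 1.0, 0.05, 0.9)
        assert q == pytest.approx(math.sqrt(0.2 / 0.9) * 0.05, abs=1e-12)
        assert q == pytest.approx(0.0236, abs=5e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="penetrance"):
            max_credible_af(0.2, "monoallelic", 1.0, 0.05, 0.0)


class TestSegregation:
    def test_fully_penetrant_dominant(self):
        members = [(f"a{i}", "yes", 1) for i in range(4)] + [
            (f"u{i}", "no", 0) for i in range(3)
        ]
        ped, genotypes = make_family(members)
        assert segregates_in_family(make_variant(genotypes=genotypes), ped)

    def test_affected_non_carrier_fails(self):
        members = [("a1", "yes", 1), ("a2", "yes", 0), ("u1", "no", 0)]
        ped, genotypes = make_family(members)
        assert not segregates_in_family(make_variant(genotypes=genotypes), ped)

    def test_penetrance_floor_arithmetic(self):
        # 9 affected carriers + 1 unaffected carrier: 0.9 >= 0.9 passes
        members = [(f"a{i}", "yes", 1) for i in range(9)] + [("u1", "no", 1)]
        ped, genotypes = make_family(members)
        assert segregates_in_family(make_variant(genotypes=genotypes), ped)
        # 8 affected + 2 unaffected carriers: 0.8 < 0.9 fails
        members = [(f"a{i}", "yes", 1) for i in range(8)] + [
            ("u1", "no", 1),
            ("u2", "no", 1),
        ]
        ped, genotypes = make_family(members)
        assert not segregates_in_family(make_variant(genotypes=genotypes), ped)

    def test_unknown_phenotype_excluded_from_counts(self):
        # the unknown-status carrier must not drag the penetrance below 0.9
        members = [(f"a{i}", "yes", 1) for i in range(9)] + [("x1", "unknown", 1)]
        ped, genotypes = make_family(members)
        assert segregates_in_family(make_variant(genotypes=genotypes), ped)

    def test_missing_genotype_affected_excluded(self):
        members = [("a1", "yes", 1), ("a2", "yes", 0), ("u1", "no", 0)]
        ped, genotypes = make_family(members)
        genotypes["a2"] = MISSING
        assert segregates_in_family(make_variant(genotypes=genotypes), ped)

    def test_no_genotyped_affected_warns_false(self):
        members = [("a1", "yes", 0), ("u1", "no", 1)]
        ped, genotypes = make_family(members)
        genotypes["a1"] = MISSING
        with pytest.warns(UserWarning, match="no genotyped affected"):
            assert not segregates_in_family(make_variant(genotypes=genotypes), ped)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            SegregationModel(penetrance_min=0.95, penetrance_max=0.9)


class TestGeneStatus:
    def test_common_variant_only_is_non_mutated(self):
        ped, _ = make_family([("a1", "yes", 0), ("u1", "no", 0)])
        table = VariantTable(
            records=[make_variant(consequence="other", maf=0.3, genotypes={"a1": 1})]
        )
        status = gene_status_familial(table, {"F1": ped}, ["G1"])
        assert status.status["G1"] == "non_mutated"

    def test_zero_variants_is_undetected(self):
        ped, _ = make_family([("a1", "yes", 0)])
        status = gene_status_familial(VariantTable(records=[]), {"F1": ped}, ["G1"])
        assert status.status["G1"] == "undetected"
        assert status.family_counts["G1"] == 0

    def test_rare_functional_common_maf_not_qualifying(self):
        ped, genotypes = make_family([("a1", "yes", 1), ("u1", "no", 0)])
        table = VariantTable(records=[make_variant(maf=0.2, genotypes=genotypes)])
        status = gene_status_familial(table, {"F1": ped}, ["G1"])
        assert status.status["G1"] == "non_mutated"

    def test_family_count_counts_families_not_variants(self):
        ped_a, gt_a = make_family([("a1", "yes", 1), ("u1", "no", 0)], "FA")
        ped_b, gt_b = make_family([("b1", "yes", 1), ("v1", "no", 0)], "FB")
        v1 = make_variant(maf=0.001, genotypes=gt_a)
        v2 = VariantRecord(
            chrom="1", pos=101, ref="A", alt="G", gene="G1",
            consequence="stopgain", population_maf=0.002, genotypes=dict(gt_a),
        )
        v3 = VariantRecord(
            chrom="1", pos=102, ref="C", alt="G", gene="G1",
            consequence="splice_site", population_maf=0.002, genotypes=dict(gt_b),
        )
        status = gene_status_familial(
            VariantTable(records=[v1, v2, v3]), {"FA": ped_a, "FB": ped_b}, ["G1"]
        )
        assert status.status["G1"] == "mutated"
        assert status.family_counts["G1"] == 2
        assert len(status.qualifying_variants["G1"]) == 3

    def test_generator_truth_recall_is_perfect(self):
        peds, carriers = simulate_families(20, seed=31)
        genes = [f"G{i:03d}" for i in range(300)]
        labels = {g: "m1" for g in genes}
        table, truth = simulate_variant_table(
            genes, labels, None, peds, carriers, 0.10, 0.10, seed=32
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            status = gene_status_familial(table, peds, genes)
        assert truth.causal_genes <= status.mutated  # recall 1.0
        false_rate = len(status.mutated - truth.causal_genes) / len(genes)
        assert false_rate == 0.0  # non-planted variants are common/non-functional

    def test_status_partition_exhaustive(self):
        peds, carriers = simulate_families(10, seed=33)
        genes = [f"G{i}" for i in range(100)]
        labels = {g: "m1" for g in genes}
        table, _ = simulate_variant_table(genes, labels, None, peds, carriers, 0.2, 0.2, seed=34)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            status = gene_status_familial(table, peds, genes)
        assert status.mutated | status.non_mutated | status.undetected == set(genes)
        assert not status.mutated & status.non_mutated

    def test_maf_threshold_monotonicity(self):
        peds, carriers = simulate_families(10, seed=35)
        genes = [f"G{i}" for i in range(100)]
        labels = {g: "m1" for g in genes}
        table, _ = simulate_variant_table(genes, labels, None, peds, carriers, 0.3, 0.3, seed=36)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strict = gene_status_familial(table, peds, genes, maf_threshold=0.01)
            loose = gene_status_familial(table, peds, genes, maf_threshold=0.10)
        assert strict.mutated <= loose.mutated

    def test_familial_subset_of_cohort(self):
        peds, carriers = simulate_families(10, seed=37)
        genes = [f"G{i}" for i in range(100)]
        labels = {g: "m1" for g in genes}
        table, _ = simulate_variant_table(genes, labels, None, peds, carriers, 0.3, 0.3, seed=38)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            familial = gene_status_familial(table, peds, genes)
        cohort = gene_status_cohort(table, genes)
        assert familial.mutated <= cohort.mutated


class TestGeneStatusCohort:
    def test_no_carrier_not_mutated(self):
        table = VariantTable(records=[make_variant(genotypes={})])
        status = gene_status_cohort(table, ["G1"])
        assert status.status["G1"] == "non_mutated"

    def test_single_heterozygote_mutated(self):
        table = VariantTable(records=[make_variant(genotypes={"I1": 1})])
        status = gene_status_cohort(table, ["G1"])
        assert status.status["G1"] == "mutated"
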