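"""Readers and writers for every external format the pipeline touches.

Formats: tab-separated expression matrices (genes x samples), VCF v4.x with
per-gene consequence and population-frequency INFO annotations, 6-column
pre-makeped PED pedigrees, GMT pathway collections, and 2-column gene score
tables. All readers validate strictly and never coerce missing values to
numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "VariantRecord",
    "VariantTable",
    "PedigreeMember",
    "Pedigree",
    "FormatError",
    "FUNCTIONAL_CONSEQUENCES",
    "KNOWN_CONSEQUENCES",
    "MISSING",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_variant_table",
    "write_variant_table",
    "read_pedigrees",
    "write_pedigrees",
    "read_score_table",
    "write_score_table",
    "read_gmt",
    "write_gmt",
    "read_cell_means",
    "write_cell_means",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


#: Sentinel for a missing genotype dosage.
MISSING = "missing"

#: The eight coding-impact consequence classes treated as functional.
FUNCTIONAL_CONSEQUENCES = frozenset(
    {
        "frameshift_deletion",
        "frameshift_insertion",
        "nonframeshift_deletion",
        "nonframeshift_insertion",
        "nonsynonymous_SNV",
        "splice_site",
        "stopgain",
        "stoploss",
    }
)

KNOWN_CONSEQUENCES = FUNCTIONAL_CONSEQUENCES | {"other"}


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix.

    Gene and sample identifiers are ordered and unique; every value is
    finite. Correlation-based stages additionally require >= 3 samples,
    which is checked by those stages rather than here.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dupes):
                raise FormatError(f"duplicate {name} identifier: {dupes[0]!r}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx],
        )

    def subset_samples(self, sample_index: np.ndarray) -> "ExpressionMatrix":
        sample_index = np.asarray(sample_index, dtype=int)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in sample_index],
            values=self.values[:, sample_index],
        )


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First column holds gene identifiers, the header row sample identifiers.
    Duplicate identifiers and non-numeric cells raise :class:`FormatError`
    naming the offending entry.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate gene identifier: {dup!r}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell at gene {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}: {frame.iat[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"missing cell at gene {frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    return ExpressionMatrix.from_frame(numeric)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Variant table
# ---------------------------------------------------------------------------


@dataclass
class VariantRecord:
    """One biallelic variant annotated to exactly one gene.

    ``genotypes`` maps individual id to alt-allele dosage (0, 1, 2) or the
    :data:`MISSING` sentinel. Individuals absent from the mapping are
    homozygous reference; half-missing calls are missing. ``population_maf``
    is ``None`` when the variant is absent from the reference database.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    population_maf: float | None
    genotypes: dict[str, int | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if self.consequence not in KNOWN_CONSEQUENCES:
            self.consequence = "other"
        if self.population_maf is not None and not 0.0 <= self.population_maf <= 1.0:
            raise FormatError(f"population MAF {self.population_maf} outside [0,1]")
        for ind, dose in self.genotypes.items():
            if dose not in (0, 1, 2, MISSING):
                raise FormatError(f"invalid dosage {dose!r} for individual {ind!r}")

    def dosage(self, individual: str) -> int | str:
        return self.genotypes.get(individual, 0)

    def carriers(self) -> set[str]:
        return {i for i, d in self.genotypes.items() if d in (1, 2)}


@dataclass
class VariantTable:
    """A cohort variant call set, one record per (variant, gene)."""

    records: list[VariantRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def genes(self) -> set[str]:
        return {r.gene for r in self.records}

    def by_gene(self) -> dict[str, list[VariantRecord]]:
        out: dict[str, list[VariantRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.gene, []).append(rec)
        return out


def _parse_gt_dosage(gt_types_entry: int) -> int | str:
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    return {0: 0, 1: 1, 2: MISSING, 3: 2}[gt_types_entry]


def read_variant_table(
    path,
    maf_field: str = "MAF",
    consequence_field: str = "CSQ_CLASS",
    gene_field: str = "GENE",
) -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    ``maf_field``, ``consequence_field`` and ``gene_field`` name the INFO
    keys holding the population allele frequency, the consequence class and
    the annotated gene(s). Multi-gene annotations (comma separated) are
    expanded to one record per gene; unknown consequence strings map to
    ``"other"``; a missing MAF is recorded as missing, never as 0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError("VCF has no sample columns (GT required)")
    records: list[VariantRecord] = []
    for var in vcf:
        if var.format("GT") is None and var.gt_types is None:
            raise FormatError(f"variant {var.CHROM}:{var.POS} lacks GT")
        genotypes: dict[str, int | str] = {}
        # phased and unphased are identical as dosage; half-missing -> missing
        for sample, gt in zip(samples, var.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                genotypes[sample] = MISSING
            else:
                dose = sum(1 for a in alleles if a > 0)
                if dose:
                    genotypes[sample] = dose
        if len(var.ALT) != 1:
            raise FormatError(
                f"multi-allelic site at {var.CHROM}:{var.POS}; split to "
                "biallelic records first (e.g. bcftools norm -m-)"
            )
        try:
            raw_maf = var.INFO.get(maf_field)
            maf = None if raw_maf is None else float(raw_maf)
        except (TypeError, ValueError):
            warnings.warn(
                f"unparsable {maf_field} at {var.CHROM}:{var.POS}; treated as missing"
            )
            maf = None
        raw_csq = var.INFO.get(consequence_field)
        if raw_csq is None:
            warnings.warn(
                f"missing {consequence_field} at {var.CHROM}:{var.POS}; "
                "consequence set to 'other'"
            )
        consequence = str(raw_csq) if raw_csq is not None else "other"
        if consequence not in KNOWN_CONSEQUENCES:
            consequence = "other"
        raw_gene = var.INFO.get(gene_field)
        gene_list = str(raw_gene).split(",") if raw_gene is not None else ["."]
        for gene in gene_list:
            records.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=var.ALT[0],
                    gene=gene,
                    consequence=consequence,
                    population_maf=maf,
                    genotypes=dict(genotypes),
                )
            )
    return VariantTable(records=records)


def write_variant_table(
    table: VariantTable,
    path,
    individuals: list[str],
    maf_field: str = "MAF",
    consequence_field: str = "CSQ_CLASS",
    gene_field: str = "GENE",
) -> None:
    """Write a VariantTable as an uncompressed VCF v4.2 text file.

    Records sharing (chrom, pos, ref, alt) but annotated to several genes
    are re-merged into one VCF line with a comma-separated gene list.
    """
    merged: dict[tuple, tuple[VariantRecord, list[str]]] = {}
    order: list[tuple] = []
    for rec in table:
        key = (rec.chrom, rec.pos, rec.ref, rec.alt)
        if key not in merged:
            merged[key] = (rec, [])
            order.append(key)
        merged[key][1].append(rec.gene)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##INFO=<ID={maf_field},Number=1,Type=Float,'
            'Description="Population minor allele frequency">\n'
        )
        fh.write(
            f'##INFO=<ID={consequence_field},Number=1,Type=String,'
            'Description="Consequence class">\n'
        )
        fh.write(
            f'##INFO=<ID={gene_field},Number=1,Type=String,'
            'Description="Annotated gene(s)">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for key in order:
            if key[0] not in chroms:
                chroms.append(key[0])
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individuals)
            + "\n"
        )
        for key in order:
            rec, genes = merged[key]
            info = []
            if rec.population_maf is not None:
                info.append(f"{maf_field}={rec.population_maf:.8g}")
            info.append(f"{consequence_field}={rec.consequence}")
            info.append(f"{gene_field}={','.join(genes)}")
            gts = []
            for ind in individuals:
                dose = rec.dosage(ind)
                gts.append(
                    {"0": "0/0", "1": "0/1", "2": "1/1", MISSING: "./."}[str(dose)]
                )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
                + ";".join(info)
                + "\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


@dataclass
class PedigreeMember:
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: int | str  # 1=male, 2=female, "unknown"
    affected: str  # "yes" | "no" | "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family: structure plus affection status.

    Parent identifiers must resolve within the family and no individual may
    be its own ancestor.
    """

    family_id: str
    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        ids = {m.individual_id for m in self.members}
        if len(ids) != len(self.members):
            raise FormatError(f"duplicate individual id in family {self.family_id}")
        parents = {}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise FormatError(
                        f"family {self.family_id}: unknown parent {pid!r} "
                        f"of {m.individual_id!r}"
                    )
            parents[m.individual_id] = [
                p for p in (m.father_id, m.mother_id) if p is not None
            ]
        # cycle check by DFS over the parent relation
        state: dict[str, int] = {}

        def visit(node: str, stack: list[str]) -> None:
            state[node] = 1
            for parent in parents[node]:
                if state.get(parent) == 1:
                    cycle = stack[stack.index(parent):] if parent in stack else stack
                    raise FormatError(
                        f"family {self.family_id}: cyclic parentage involving "
                        + " -> ".join(cycle + [parent])
                    )
                if state.get(parent, 0) == 0:
                    visit(parent, stack + [parent])
            state[node] = 2

        for m in self.members:
            if state.get(m.individual_id, 0) == 0:
                visit(m.individual_id, [m.individual_id])

    def individual_ids(self) -> list[str]:
        return [m.individual_id for m in self.members]

    def affected_ids(self) -> list[str]:
        return [m.individual_id for m in self.members if m.affected == "yes"]

    def founders(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.is_founder]


_PHENO_CODES = {"2": "yes", "1": "no", "0": "unknown", "-9": "unknown"}
_SEX_CODES = {"1": 1, "2": 2}


def read_pedigrees(path) -> dict[str, Pedigree]:
    """Read a 6-column pre-makeped PED file into Pedigrees keyed by family.

    Columns: family, individual, father, mother, sex, phenotype
    (2=affected, 1=unaffected, 0/-9=unknown). A parent field of "0" means
    founder.
    """
    families: dict[str, list[PedigreeMember]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(f"PED line {lineno}: expected 6 columns, got {len(fields)}")
            fam, ind, father, mother, sex, pheno = fields
            if pheno not in _PHENO_CODES:
                raise FormatError(f"PED line {lineno}: unknown phenotype code {pheno!r}")
            families.setdefault(fam, []).append(
                PedigreeMember(
                    individual_id=ind,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES.get(sex, "unknown"),
                    affected=_PHENO_CODES[pheno],
                )
            )
    return {fam: Pedigree(family_id=fam, members=members) for fam, members in families.items()}


def write_pedigrees(pedigrees: Mapping[str, Pedigree] | Iterable[Pedigree], path) -> None:
    peds = pedigrees.values() if isinstance(pedigrees, Mapping) else pedigrees
    pheno_back = {"yes": "2", "no": "1", "unknown": "0"}
    with open(path, "w") as fh:
        for ped in peds:
            for m in ped.members:
                sex = str(m.sex) if m.sex in (1, 2) else "0"
                fh.write(
                    f"{ped.family_id}\t{m.individual_id}\t{m.father_id or 0}\t"
                    f"{m.mother_id or 0}\t{sex}\t{pheno_back[m.affected]}\n"
                )


# ---------------------------------------------------------------------------
# Score tables, GMT, cell means
# ---------------------------------------------------------------------------


def read_score_table(path) -> dict[str, float]:
    """Read a 2-column TSV of gene -> score (e.g. RVIS)."""
    frame = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if frame.shape[1] != 2:
        raise FormatError(f"score table must have 2 columns, got {frame.shape[1]}")
    genes = frame.iloc[:, 0].astype(str)
    if genes.duplicated().any():
        raise FormatError(f"duplicate gene in score table: {genes[genes.duplicated()].iloc[0]!r}")
    scores = pd.to_numeric(frame.iloc[:, 1], errors="raise").astype(float)
    if not np.isfinite(scores).all():
        raise FormatError("non-finite score in score table")
    return dict(zip(genes, scores))


def write_score_table(scores: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"gene": list(scores.keys()), "score": list(scores.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file (pathway, description, genes...)."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"GMT line {lineno}: pathway {name!r} has no genes")
            if name in pathways:
                raise FormatError(f"duplicate pathway name {name!r}")
            pathways[name] = set(genes)
    return pathways


def write_gmt(pathways: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(genes)) + "\n")


def read_cell_means(path) -> pd.DataFrame:
    """Read a genes x cell-types mean-expression TSV."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        raise FormatError("duplicate gene in cell-mean matrix")
    if (frame.to_numpy() < 0).any():
        raise FormatError("negative entry in cell-mean matrix")
    return frame


def write_cell_means(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="gene")
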