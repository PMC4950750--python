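"""Rarity/effect filtering and Mendelian segregation testing of SNVs/indels.

Variants surviving allele-frequency and predicted-effect filters are tested
for co-segregation with disease under explicit inheritance models: homozygous
recessive, de novo, X-linked hemizygous, and compound heterozygous (two
variants of one gene in trans).  A separate detector flags the genotype
pattern of an SNV uncovered by a deletion on the other haplotype: a proband
called homozygous-alternate while exactly one parent is heterozygous and the
other is homozygous-reference, which is Mendelian-inconsistent for a true
homozygote and instead suggests a deletion inherited from the apparently
wild-type parent; an overlapping CNV call in that parent (or the proband)
corroborates the hypothesis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .intervals import GenomicInterval, normalize_chrom

__all__ = [
    "Genotype",
    "Status",
    "VariantRecord",
    "Pedigree",
    "SegregationResult",
    "CompoundSnvCnvFlag",
    "rarity_filter",
    "effect_filter",
    "segregation_test",
    "test_compound_het",
    "find_compound_het_pairs",
    "flag_snv_cnv_compound",
    "read_annotated_vcf",
]

MODELS = ("homozygous_recessive", "compound_het", "de_novo", "x_linked_hemizygous")


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"  # single-copy alternate (male X)
    HEMI_REF = "hemi_ref"  # single-copy reference (male X)
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI)


class Status(enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_TESTABLE = "not_testable"


@dataclass
class VariantRecord:
    """One biallelic variant with per-sample genotypes and annotations."""

    interval: GenomicInterval
    ref: str
    alt: str
    gene: str
    genotypes: dict[str, Genotype]
    depths: dict[str, int] = field(default_factory=dict)
    population_af: dict[str, float] = field(default_factory=dict)
    effect_class: str = "other"  # lof | missense | splice | synonymous | other
    n_damaging_predictions: int = 0
    quality_flags: tuple[str, ...] = ()

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def pos(self) -> int:
        return self.interval.start


@dataclass
class Pedigree:
    """Sample metadata from a 6-column PED file."""

    table: pd.DataFrame  # family_id, sample_id, father_id, mother_id, sex, affected

    @classmethod
    def from_ped(cls, path) -> "Pedigree":
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["family_id", "sample_id", "father_id", "mother_id", "sex_code", "pheno"],
            dtype=str,
        )
        df["sex"] = df["sex_code"].map({"1": "male", "2": "female"}).fillna("unknown")
        df["affected"] = df["pheno"] == "2"
        return cls(df.drop(columns=["sex_code", "pheno"]))

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    def families(self) -> list[str]:
        return list(dict.fromkeys(self.table["family_id"]))

    def members(self, family_id: str) -> pd.DataFrame:
        return self.table[self.table["family_id"] == family_id]

    def is_male(self, sample_id: str) -> bool:
        row = self.table[self.table["sample_id"] == sample_id]
        return bool(len(row)) and row["sex"].iloc[0] == "male"

    def trio(self, family_id: str) -> tuple[str, str | None, str | None] | None:
        """(proband, father, mother) for the family's first affected child."""
        fam = self.members(family_id)
        ids = set(fam["sample_id"])
        for r in fam.itertuples(index=False):
            if r.affected and (r.father_id in ids or r.mother_id in ids):
                return (
                    r.sample_id,
                    r.father_id if r.father_id in ids else None,
                    r.mother_id if r.mother_id in ids else None,
                )
        aff = fam[fam["affected"]]
        return (aff["sample_id"].iloc[0], None, None) if len(aff) else None


@dataclass(frozen=True)
class SegregationResult:
    status: Status
    model: str
    family_id: str
    explanations: tuple[str, ...] = ()


@dataclass(frozen=True)
class CompoundSnvCnvFlag:
    """Proband hom-alt with one het and one hom-ref parent: possible SNV
    exposed by a deletion inherited from the non-carrier parent."""

    variant: VariantRecord
    family_id: str
    transmitting_parent_het: str
    apparent_wildtype_parent: str
    corroborating_cnv: object | None  # DeletionCall or external-CNV row


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def rarity_filter(
    variants: list[VariantRecord],
    max_af: float,
    databases: list[str] | None = None,
) -> list[VariantRecord]:
    """Keep variants with AF <= ``max_af`` in every configured database
    (missing annotations count as 0, i.e. novel)."""
    out = []
    for v in variants:
        dbs = databases if databases is not None else list(v.population_af)
        if all(v.population_af.get(db, 0.0) <= max_af for db in dbs):
            out.append(v)
    return out


def effect_filter(
    variants: list[VariantRecord],
    keep_classes: tuple[str, ...] = ("lof", "missense", "splice"),
    min_damaging: int = 2,
) -> list[VariantRecord]:
    """Keep predicted-deleterious variants: loss-of-function always, other
    retained classes when called damaging by >= ``min_damaging`` programs."""
    out = []
    for v in variants:
        if v.effect_class not in keep_classes:
            continue
        if v.effect_class != "lof" and v.n_damaging_predictions < min_damaging:
            continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# segregation models
# ---------------------------------------------------------------------------


def _gt(variant: VariantRecord, sample: str) -> Genotype:
    return variant.genotypes.get(sample, Genotype.MISSING)


def segregation_test(
    variant: VariantRecord,
    pedigree: Pedigree,
    model: str,
    family_id: str,
    min_parent_depth: int = 10,
) -> SegregationResult:
    """Test one variant under one inheritance model in one family.

    Missing genotypes in required members yield NOT_TESTABLE (never FAIL), as
    does a pedigree lacking the structure the model needs.  ``compound_het``
    requires two variants; use :func:`test_compound_het`.
    """
    if model == "compound_het":
        raise ValueError("compound_het takes a pair of variants; use test_compound_het")
    if model not in MODELS:
        raise ValueError(f"unknown inheritance model {model!r}")
    fam = pedigree.members(family_id)
    if fam.empty:
        return SegregationResult(Status.NOT_TESTABLE, model, family_id, ("family not in pedigree",))
    notes: list[str] = []

    if model == "homozygous_recessive":
        status = _test_hom_recessive(variant, fam, notes)
    elif model == "de_novo":
        status = _test_de_novo(variant, pedigree, family_id, min_parent_depth, notes)
    else:
        status = _test_x_linked(variant, fam, notes)
    return SegregationResult(status, model, family_id, tuple(notes))


def _test_hom_recessive(variant, fam, notes) -> Status:
    affected = fam[fam["affected"]]["sample_id"]
    parents = set(fam["father_id"]) | set(fam["mother_id"])
    parents = [p for p in parents if p in set(fam["sample_id"])]
    unaffected_kids = fam[~fam["affected"] & (fam["father_id"] != "0")]["sample_id"]
    saw_genotype = False
    for s in affected:
        g = _gt(variant, s)
        if g is Genotype.MISSING:
            notes.append(f"{s}: missing genotype")
            continue
        saw_genotype = True
        if g not in (Genotype.HOM_ALT, Genotype.HEMI):
            notes.append(f"{s}: affected not homozygous ({g.value})")
            return Status.FAIL
    if not saw_genotype:
        return Status.NOT_TESTABLE
    for s in parents:
        g = _gt(variant, s)
        if g is Genotype.MISSING:
            notes.append(f"{s}: parent genotype missing")
        elif g not in (Genotype.HET, Genotype.HEMI_REF, Genotype.HEMI):
            notes.append(f"{s}: parent not heterozygous carrier ({g.value})")
            return Status.FAIL
    for s in unaffected_kids:
        g = _gt(variant, s)
        if g in (Genotype.HOM_ALT, Genotype.HEMI):
            notes.append(f"{s}: unaffected sibling homozygous")
            return Status.FAIL
    return Status.PASS


def _test_de_novo(variant, pedigree, family_id, min_parent_depth, notes) -> Status:
    trio = pedigree.trio(family_id)
    if trio is None or trio[1] is None or trio[2] is None:
        notes.append("no genotyped parents: de novo not testable")
        return Status.NOT_TESTABLE
    proband, father, mother = trio
    g = _gt(variant, proband)
    if g is Genotype.MISSING:
        return Status.NOT_TESTABLE
    if not g.carries_alt:
        notes.append(f"{proband}: proband does not carry the allele")
        return Status.FAIL
    for parent in (father, mother):
        pg = _gt(variant, parent)
        if pg is Genotype.MISSING:
            notes.append(f"{parent}: parent genotype missing")
            return Status.NOT_TESTABLE
        if pg.carries_alt:
            notes.append(f"{parent}: parent carries the allele (inherited)")
            return Status.FAIL
        depth = variant.depths.get(parent)
        if depth is not None and depth < min_parent_depth:
            notes.append(f"{parent}: parent depth {depth} < {min_parent_depth}")
            return Status.NOT_TESTABLE
    return Status.PASS


def _test_x_linked(variant, fam, notes) -> Status:
    if variant.chrom != "chrX":
        notes.append("variant not on chrX")
        return Status.NOT_TESTABLE
    affected = fam[fam["affected"]]
    males = affected[affected["sex"] == "male"]
    if males.empty:
        notes.append("no affected males")
        return Status.NOT_TESTABLE
    saw = False
    for r in males.itertuples(index=False):
        g = _gt(variant, r.sample_id)
        if g is Genotype.MISSING:
            continue
        saw = True
        if g not in (Genotype.HEMI, Genotype.HOM_ALT):
            notes.append(f"{r.sample_id}: affected male not hemizygous ({g.value})")
            return Status.FAIL
        mother = r.mother_id
        mg = _gt(variant, mother)
        if mg is Genotype.MISSING:
            notes.append(f"{mother}: carrier mother genotype missing")
        elif mg is not Genotype.HET:
            notes.append(f"{mother}: mother not a heterozygous carrier ({mg.value})")
            return Status.FAIL
    return Status.PASS if saw else Status.NOT_TESTABLE


def test_compound_het(
    v1: VariantRecord,
    v2: VariantRecord,
    pedigree: Pedigree,
    family_id: str,
) -> SegregationResult:
    """Compound heterozygosity: two variants of one gene in trans — the
    proband is het for both while each parent transmits exactly one."""
    notes: list[str] = []
    if v1.gene != v2.gene or not v1.gene:
        return SegregationResult(Status.FAIL, "compound_het", family_id, ("different genes",))
    trio = pedigree.trio(family_id)
    if trio is None or trio[1] is None or trio[2] is None:
        return SegregationResult(
            Status.NOT_TESTABLE, "compound_het", family_id, ("trio unavailable",)
        )
    proband, father, mother = trio
    for v in (v1, v2):
        if _gt(v, proband) is Genotype.MISSING:
            return SegregationResult(Status.NOT_TESTABLE, "compound_het", family_id, ("proband genotype missing",))
        if _gt(v, proband) is not Genotype.HET:
            notes.append(f"proband not het at {v.interval}")
            return SegregationResult(Status.FAIL, "compound_het", family_id, tuple(notes))
    pat = (_gt(v1, father).carries_alt, _gt(v2, father).carries_alt)
    mat = (_gt(v1, mother).carries_alt, _gt(v2, mother).carries_alt)
    in_trans = (pat == (True, False) and mat == (False, True)) or (
        pat == (False, True) and mat == (True, False)
    )
    if not in_trans:
        notes.append("variants not in trans (each parent must transmit exactly one)")
        return SegregationResult(Status.FAIL, "compound_het", family_id, tuple(notes))
    return SegregationResult(Status.PASS, "compound_het", family_id, tuple(notes))


def find_compound_het_pairs(
    variants: list[VariantRecord],
    pedigree: Pedigree,
    family_id: str,
) -> list[tuple[VariantRecord, VariantRecord, SegregationResult]]:
    """All passing in-trans pairs among the given variants, grouped by gene."""
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.gene:
            by_gene.setdefault(v.gene, []).append(v)
    out = []
    for gene, vs in sorted(by_gene.items()):
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                res = test_compound_het(vs[i], vs[j], pedigree, family_id)
                if res.status is Status.PASS:
                    out.append((vs[i], vs[j], res))
    return out


# ---------------------------------------------------------------------------
# SNV + CNV compound heterozygotes
# ---------------------------------------------------------------------------


def flag_snv_cnv_compound(
    variant: VariantRecord,
    pedigree: Pedigree,
    family_id: str,
    cnv_calls: list = (),
) -> CompoundSnvCnvFlag | None:
    """Raise a flag on the hom-alt proband / het parent / hom-ref parent
    pattern; attach an overlapping CNV of the hom-ref parent or proband when
    one is supplied.  Returns None when the pattern is absent."""
    trio = pedigree.trio(family_id)
    if trio is None or trio[1] is None or trio[2] is None:
        return None
    proband, father, mother = trio
    if _gt(variant, proband) is not Genotype.HOM_ALT:
        return None
    gf, gm = _gt(variant, father), _gt(variant, mother)
    if gf is Genotype.HET and gm is Genotype.HOM_REF:
        het_parent, wt_parent = father, mother
    elif gm is Genotype.HET and gf is Genotype.HOM_REF:
        het_parent, wt_parent = mother, father
    else:
        return None
    cnv = None
    for call in cnv_calls:
        sample = getattr(call, "sample_id", None)
        iv = getattr(call, "interval", None)
        if iv is None:  # external-CNV table row (dict-like)
            sample = call["sample_id"]
            iv = GenomicInterval(call["chrom"], int(call["start"]), int(call["end"]))
        if sample in (wt_parent, proband) and iv.chrom == variant.chrom and (
            iv.start <= variant.pos <= iv.end
        ):
            cnv = call
            break
    return CompoundSnvCnvFlag(variant, family_id, het_parent, wt_parent, cnv)


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def read_annotated_vcf(
    vcf_path,
    pedigree: Pedigree,
    af_keys: tuple[str, ...] = ("AF_DB1", "AF_DB2"),
    gene_key: str = "GENE",
    effect_key: str = "EFFECT",
    damaging_key: str = "NDMG",
    max_af_keep: float | None = None,
) -> list[VariantRecord]:
    """Parse an annotated multi-sample VCF into VariantRecords.

    Diploid hom calls on the male X are re-coded as hemizygous using the
    pedigree sex.  Multi-allelic records are skipped.  ``max_af_keep`` drops
    records whose annotated frequency exceeds the bound in any database
    before genotypes are materialised (a fast path for rarity filtering).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = vcf.samples
    male = {s: pedigree.is_male(s) for s in samples}
    out: list[VariantRecord] = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        if max_af_keep is not None and any(
            (var.INFO.get(key) or 0.0) > max_af_keep for key in af_keys
        ):
            continue
        chrom = normalize_chrom(var.CHROM)
        gts: dict[str, Genotype] = {}
        depths: dict[str, int] = {}
        ad = var.format("AD")
        gt_types = var.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        for i, s in enumerate(samples):
            code = gt_types[i]
            if code == 0:
                g = Genotype.HOM_REF
            elif code == 1:
                g = Genotype.HET
            elif code == 2:
                g = Genotype.HOM_ALT
            else:
                g = Genotype.MISSING
            if chrom == "chrX" and male.get(s) and g is not Genotype.MISSING:
                g = {Genotype.HOM_REF: Genotype.HEMI_REF, Genotype.HOM_ALT: Genotype.HEMI}.get(g, g)
            gts[s] = g
            if ad is not None and ad[i, 0] >= 0:
                depths[s] = int(ad[i, 0]) + int(ad[i, 1])
        afs = {}
        for key in af_keys:
            val = var.INFO.get(key)
            if val is not None:
                afs[key] = float(val)
        out.append(
            VariantRecord(
                interval=GenomicInterval(chrom, var.POS, var.POS),
                ref=var.REF,
                alt=var.ALT[0],
                gene=str(var.INFO.get(gene_key) or ""),
                genotypes=gts,
                depths=depths,
                population_af=afs,
                effect_class=str(var.INFO.get(effect_key) or "other"),
                n_damaging_predictions=int(var.INFO.get(damaging_key) or 0),
            )
        )
    return out
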