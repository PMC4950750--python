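import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conswes.hmzdel import DeletionCall
from conswes.intervals import GenomicInterval
from conswes.segregation import (
    Genotype,
    Pedigree,
    Status,
    VariantRecord,
    effect_filter,
    flag_snv_cnv_compound,
    find_compound_het_pairs,
    rarity_filter,
    segregation_test,
)
from conswes.segregation import test_compound_het as check_compound_het

G = Genotype


def trio_pedigree(proband_sex="female", with_sib=False):
    rows = [
        ("FAM", "DAD", "0", "0", "male", False),
        ("FAM", "MOM", "0", "0", "female", False),
        ("FAM", "KID", "DAD", "MOM", proband_sex, True),
    ]
    if with_sib:
        rows.append(("FAM", "SIB", "DAD", "MOM", "male", False))
    return Pedigree(
        pd.DataFrame(
            rows,
            columns=["family_id", "sample_id", "father_id", "mother_id", "sex", "affected"],
        ).astype({"affected": bool})
    )


def variant(genotypes, chrom="chr1", gene="GENE1", af=0.0, effect="missense", ndmg=3):
    return VariantRecord(
        interval=GenomicInterval(chrom, 1000, 1000),
        ref="G",
        alt="A",
        gene=gene,
        genotypes=genotypes,
        depths={s: 40 for s in genotypes},
        population_af={"db1": af, "db2": af},
        effect_class=effect,
        n_damaging_predictions=ndmg,
    )


# --- filters ----------------------------------------------------------------


def test_rarity_filter_counts():
    variants = [variant({"KID": G.HET}, af=af) for af in
                [0.0, 0.0005, 0.02, 0.001, 0.5, 0.0, 0.0009, 0.0002, 0.0, 0.011]]
    kept = rarity_filter(variants, max_af=0.001)
    assert len(kept) == 7
    assert rarity_filter([variant({"KID": G.HET}, af=0.0)], 0.001)  # AF 0: retained
    # missing AF annotation is treated as novel
    v = variant({"KID": G.HET})
    v.population_af = {}
    assert rarity_filter([v], 0.0) == [v]


def test_filter_order_invariance():
    variants = []
    for af in (0.0, 0.002):
        for effect, ndmg in (("lof", 0), ("missense", 3), ("missense", 1), ("synonymous", 3)):
            variants.append(variant({"KID": G.HET}, af=af, effect=effect, ndmg=ndmg))
    a = effect_filter(rarity_filter(variants, 0.001))
    b = rarity_filter(effect_filter(variants), 0.001)
    assert a == b
    assert {(v.effect_class, v.n_damaging_predictions) for v in a} == {("lof", 0), ("missense", 3)}


# --- single-variant models ---------------------------------------------------


@pytest.mark.parametrize(
    "genotypes, expected",
    [
        # textbook recessive: affected hom, parents het, sib het
        ({"KID": G.HOM_ALT, "DAD": G.HET, "MOM": G.HET, "SIB": G.HET}, Status.PASS),
        # unaffected sibling homozygous breaks segregation
        ({"KID": G.HOM_ALT, "DAD": G.HET, "MOM": G.HET, "SIB": G.HOM_ALT}, Status.FAIL),
        ({"KID": G.HET, "DAD": G.HET, "MOM": G.HET, "SIB": G.HET}, Status.FAIL),
        ({"KID": G.HOM_ALT, "DAD": G.HOM_REF, "MOM": G.HET, "SIB": G.HET}, Status.FAIL),
        # missing proband genotype: not testable, never a fail
        ({"KID": G.MISSING, "DAD": G.HET, "MOM": G.HET, "SIB": G.HET}, Status.NOT_TESTABLE),
    ],
)
def test_homozygous_recessive_patterns(genotypes, expected):
    ped = trio_pedigree(with_sib=True)
    res = segregation_test(variant(genotypes), ped, "homozygous_recessive", "FAM")
    assert res.status is expected


@pytest.mark.parametrize(
    "genotypes, expected",
    [
        ({"KID": G.HET, "DAD": G.HOM_REF, "MOM": G.HOM_REF}, Status.PASS),
        ({"KID": G.HET, "DAD": G.HET, "MOM": G.HOM_REF}, Status.FAIL),
        ({"KID": G.HOM_REF, "DAD": G.HOM_REF, "MOM": G.HOM_REF}, Status.FAIL),
        ({"KID": G.HET, "DAD": G.MISSING, "MOM": G.HOM_REF}, Status.NOT_TESTABLE),
    ],
)
def test_de_novo_patterns(genotypes, expected):
    ped = trio_pedigree()
    res = segregation_test(variant(genotypes), ped, "de_novo", "FAM")
    assert res.status is expected


def test_de_novo_without_parents_not_testable():
    ped = Pedigree(
        pd.DataFrame(
            [("FAM", "KID", "0", "0", "male", True)],
            columns=["family_id", "sample_id", "father_id", "mother_id", "sex", "affected"],
        )
    )
    res = segregation_test(
        variant({"KID": G.HET}), ped, "de_novo", "FAM"
    )
    assert res.status is Status.NOT_TESTABLE


def test_de_novo_shallow_parent_depth_not_testable():
    ped = trio_pedigree()
    v = variant({"KID": G.HET, "DAD": G.HOM_REF, "MOM": G.HOM_REF})
    v.depths["DAD"] = 4
    res = segregation_test(v, ped, "de_novo", "FAM")
    assert res.status is Status.NOT_TESTABLE


@pytest.mark.parametrize(
    "genotypes, expected",
    [
        ({"KID": G.HEMI, "DAD": G.HEMI_REF, "MOM": G.HET}, Status.PASS),
        ({"KID": G.HEMI, "DAD": G.HEMI_REF, "MOM": G.HOM_REF}, Status.FAIL),
        ({"KID": G.HET, "DAD": G.HEMI_REF, "MOM": G.HET}, Status.FAIL),
    ],
)
def test_x_linked_patterns(genotypes, expected):
    ped = trio_pedigree(proband_sex="male")
    res = segregation_test(
        variant(genotypes, chrom="chrX"), ped, "x_linked_hemizygous", "FAM"
    )
    assert res.status is expected


def test_x_linked_requires_chrx_and_affected_male():
    ped = trio_pedigree(proband_sex="male")
    res = segregation_test(
        variant({"KID": G.HEMI, "MOM": G.HET}), ped, "x_linked_hemizygous", "FAM"
    )
    assert res.status is Status.NOT_TESTABLE  # autosomal variant
    ped_f = trio_pedigree(proband_sex="female")
    res = segregation_test(
        variant({"KID": G.HOM_ALT, "MOM": G.HET}, chrom="chrX"),
        ped_f, "x_linked_hemizygous", "FAM",
    )
    assert res.status is Status.NOT_TESTABLE  # no affected male


# --- compound heterozygotes ---------------------------------------------------


def _pair(pat_gt, mat_gt):
    v1 = variant({"KID": G.HET, "DAD": pat_gt[0], "MOM": mat_gt[0]})
    v2 = variant({"KID": G.HET, "DAD": pat_gt[1], "MOM": mat_gt[1]})
    v2.interval = GenomicInterval("chr1", 2000, 2000)
    return v1, v2


def test_compound_het_trans_passes_cis_fails():
    ped = trio_pedigree()
    v1, v2 = _pair((G.HET, G.HOM_REF), (G.HOM_REF, G.HET))
    assert check_compound_het(v1, v2, ped, "FAM").status is Status.PASS
    # cis: both variants on the paternal haplotype
    v1, v2 = _pair((G.HET, G.HET), (G.HOM_REF, G.HOM_REF))
    assert check_compound_het(v1, v2, ped, "FAM").status is Status.FAIL
    # different genes never pair
    v1, v2 = _pair((G.HET, G.HOM_REF), (G.HOM_REF, G.HET))
    v2.gene = "OTHER"
    assert check_compound_het(v1, v2, ped, "FAM").status is Status.FAIL


def test_find_compound_het_pairs():
    ped = trio_pedigree()
    v1, v2 = _pair((G.HET, G.HOM_REF), (G.HOM_REF, G.HET))
    pairs = find_compound_het_pairs([v1, v2], ped, "FAM")
    assert len(pairs) == 1 and pairs[0][2].status is Status.PASS


def test_segregation_test_rejects_compound_het_model():
    with pytest.raises(ValueError):
        segregation_test(variant({"KID": G.HET}), trio_pedigree(), "compound_het", "FAM")


# --- SNV + CNV compound -------------------------------------------------------


def _paternal_del(sample):
    return DeletionCall(
        sample_id=sample,
        interval=GenomicInterval("chr1", 500, 5000),
        gene="GENE1",
        exon_ids=("GENE1|1",),
        mean_rpkm=20.0,
        cohort_frequency=0.001,
        supporting_aoh=None,
        zygosity_label="homozygous",
    )


def test_snv_cnv_flag_on_uncovered_snv_pattern():
    """Proband hom-alt, het mother, wild-type father, plus a paternal deletion
    spanning the site: the classic deletion-uncovered-SNV signature."""
    ped = trio_pedigree()
    v = variant({"KID": G.HOM_ALT, "DAD": G.HOM_REF, "MOM": G.HET})
    flag = flag_snv_cnv_compound(v, ped, "FAM", [_paternal_del("DAD")])
    assert flag is not None
    assert flag.transmitting_parent_het == "MOM"
    assert flag.apparent_wildtype_parent == "DAD"
    assert flag.corroborating_cnv is not None


def test_snv_cnv_flag_without_cnv_still_raises_hypothesis():
    ped = trio_pedigree()
    v = variant({"KID": G.HOM_ALT, "DAD": G.HOM_REF, "MOM": G.HET})
    flag = flag_snv_cnv_compound(v, ped, "FAM", [])
    assert flag is not None and flag.corroborating_cnv is None


def test_snv_cnv_flag_accepts_external_cnv_rows():
    ped = trio_pedigree()
    v = variant({"KID": G.HOM_ALT, "DAD": G.HET, "MOM": G.HOM_REF})
    row = {"sample_id": "MOM", "chrom": "chr1", "start": 500, "end": 5000}
    flag = flag_snv_cnv_compound(v, ped, "FAM", [row])
    assert flag is not None and flag.corroborating_cnv == row
    assert flag.apparent_wildtype_parent == "MOM"


def test_no_flag_for_ordinary_recessive():
    ped = trio_pedigree()
    v = variant({"KID": G.HOM_ALT, "DAD": G.HET, "MOM": G.HET})
    assert flag_snv_cnv_compound(v, ped, "FAM", [_paternal_del("DAD")]) is None


gt_st = st.sampled_from([G.HOM_REF, G.HET, G.HOM_ALT, G.MISSING])


@given(gt_st, gt_st, gt_st)
def test_flag_never_fires_when_both_parents_carry(kid, dad, mom):
    ped = trio_pedigree()
    v = variant({"KID": kid, "DAD": dad, "MOM": mom})
    flag = flag_snv_cnv_compound(v, ped, "FAM", [_paternal_del("DAD")])
    if dad.carries_alt and mom.carries_alt:
        assert flag is None
    if flag is not None:
        assert kid is G.HOM_ALT
        assert {v.genotypes[flag.transmitting_parent_het], v.genotypes[flag.apparent_wildtype_parent]} == {G.HET, G.HOM_REF}
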