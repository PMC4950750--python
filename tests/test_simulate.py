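import hashlib

import numpy as np
import pandas as pd
import pytest

from conswes.intervals import GenomicInterval
from conswes.simulate import (
    SimulationConfig,
    emit_site_allele_fractions,
    sample_autozygous_tracts,
    simulate_cohort,
)


def _sha(path):
    return hashlib.sha256(path.read_bytes()).hexdigest()


def test_same_seed_byte_identical_outputs(tmp_path, cohort8):
    other = simulate_cohort(SimulationConfig(n_families=8, seed=5), tmp_path / "again")
    for attr in ("vcf", "ped", "exon_bed", "counts_tsv", "panel_tsv"):
        assert _sha(getattr(cohort8, attr)) == _sha(getattr(other, attr))


def test_consanguineous_fraction(cohort31):
    fams = cohort31.samples.drop_duplicates("family_id")
    assert len(fams) == 31
    assert int(fams["consanguineous"].sum()) == 28
    probands = cohort31.samples[cohort31.samples["role"] == "proband"]
    assert (probands["sex"] == "male").sum() == 13


def test_planted_total_autozygosity_in_configured_range(cohort31):
    cfg = cohort31.config
    totals = cohort31.aoh_truth.groupby("sample_id")["length"].sum() / 1e6
    consang = set(
        cohort31.samples.loc[
            (cohort31.samples["role"] == "proband") & cohort31.samples["consanguineous"],
            "sample_id",
        ]
    )
    for sample, total in totals.items():
        lo, hi = (
            cfg.target_total_aoh_mb_range_consang
            if sample in consang
            else cfg.target_total_aoh_mb_range_outbred
        )
        assert lo <= total <= hi, sample


def test_tracts_are_disjoint_and_long_enough(cohort31):
    for sample, sub in cohort31.aoh_truth.groupby("sample_id"):
        assert (sub["length"] >= 500_000).all()
        for chrom, tracks in sub.groupby("chrom"):
            t = tracks.sort_values("start")
            assert (t["start"].to_numpy()[1:] > t["end"].to_numpy()[:-1]).all()


class TestTractSampler:
    sizes = {"chr1": 1_000_000_000, "chr2": 1_000_000_000, "chr3": 1_000_000_000}

    def test_zero_target_empty(self):
        assert sample_autozygous_tracts(0, self.sizes, np.random.default_rng(0)) == []

    def test_target_sum_within_tolerance(self):
        tracts = sample_autozygous_tracts(
            100_000_000, self.sizes, np.random.default_rng(1)
        )
        total = sum(t.length for t in tracts)
        assert 95_000_000 <= total <= 105_000_000

    def test_determinism(self):
        a = sample_autozygous_tracts(20_000_000, self.sizes, np.random.default_rng(3))
        b = sample_autozygous_tracts(20_000_000, self.sizes, np.random.default_rng(3))
        assert a == b

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError):
            sample_autozygous_tracts(
                2_000_000_000, {"chr1": 3_000_000_000}, np.random.default_rng(0)
            )

    def test_anchor_covered(self):
        anchor = GenomicInterval("chr1", 500_000_000, 500_050_000)
        tracts = sample_autozygous_tracts(
            5_000_000, self.sizes, np.random.default_rng(4), anchors=[anchor]
        )
        from conswes.intervals import contained_in

        assert any(contained_in(anchor, t) for t in tracts)


class TestAlleleFractions:
    def test_noise_free_values_exact(self):
        rng = np.random.default_rng(0)
        frac = emit_site_allele_fractions([2, 1, 0, 1], [2, 2, 2, 1], 0.0, rng)
        assert frac == pytest.approx([1.0, 0.5, 0.0, 1.0])

    def test_het_mean_near_half(self):
        rng = np.random.default_rng(1)
        frac = emit_site_allele_fractions(
            np.ones(1000), np.full(1000, 2), 0.05, rng
        )
        assert abs(frac.mean() - 0.5) < 0.01
        assert (frac >= 0).all() and (frac <= 1).all()


def _trio_genotypes(vcf_path, fam):
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    idx = {s: i for i, s in enumerate(vcf.samples)}
    trio = [f"{fam}_P", f"{fam}_F", f"{fam}_M"]
    rows = []
    for var in vcf:
        g = var.gt_types
        rows.append((var.CHROM, var.POS, *[int(g[idx[s]]) for s in trio]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "proband", "father", "mother"])


def test_mendelian_consistency_of_truth_genotypes(cohort8):
    """Outside planted de novo sites every trio genotype is Mendelian-possible
    (0 hom-ref, 1 het, 2 hom-alt; male X ignored: hemizygous calls are written
    as diploid)."""
    fam = "F008"  # no planted de novo in this family
    df = _trio_genotypes(cohort8.vcf, fam)
    dn = cohort8.variant_truth.query("family_id == @fam and model == 'de_novo'")
    assert dn.empty
    auto = df[(df["chrom"] != "chrX") & (df[["proband", "father", "mother"]] != 3).all(axis=1)]

    def possible(c, f, m):
        half = lambda g: {0: {0}, 1: {0, 1}, 2: {1}}[g]
        return any(a + b == c for a in half(f) for b in half(m))

    bad = [
        r for r in auto.itertuples(index=False)
        if not possible(r.proband, r.father, r.mother)
    ]
    assert bad == []


def test_aoh_tracts_contain_no_het_proband_genotypes(cohort8):
    for fam in ("F001", "F004"):
        df = _trio_genotypes(cohort8.vcf, fam)
        tracts = cohort8.aoh_truth[cohort8.aoh_truth["sample_id"] == f"{fam}_P"]
        for t in tracts.itertuples(index=False):
            inside = df[(df["chrom"] == t.chrom) & df["pos"].between(t.start, t.end)]
            assert not (inside["proband"] == 1).any()


def test_planted_deletions_reflected_in_read_counts(cohort8):
    counts = pd.read_csv(cohort8.counts_tsv, sep="\t", index_col="exon_id")
    exons = cohort8.exons.set_index("exon_id")
    for d in cohort8.deletion_truth.itertuples(index=False):
        proband = f"{d.family_id}_P"
        member = exons[
            (exons["gene"] == d.gene)
            & exons["exon_index"].between(d.exon_first, d.exon_last)
        ].index
        if d.zygosity in ("homozygous", "hemizygous"):
            assert (counts.loc[member, proband] <= 5).all()
            baseline = counts.loc[member].drop(
                columns=[proband, f"{d.family_id}_F", f"{d.family_id}_M"]
            )
            assert (baseline.median(axis=1) > 50).all()
        else:  # heterozygous: roughly halved, nowhere near zero
            ratio = counts.loc[member, proband] / counts.loc[member].median(axis=1)
            assert ((ratio > 0.3) & (ratio < 0.75)).all()


def test_infeasible_planted_deletion_rejected(tmp_path):
    from conswes.simulate import PlantedDeletion

    cfg = SimulationConfig(
        n_families=2,
        seed=0,
        plant_defaults=False,
        planted_deletions=[PlantedDeletion(0, "NOT_A_GENE", 1, 2, "homozygous")],
    )
    with pytest.raises(ValueError):
        simulate_cohort(cfg, tmp_path / "bad")
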