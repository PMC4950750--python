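"""Synthetic consanguineous exome cohort generator.

Emulates the data a consanguinity-aware WES pipeline consumes — a jointly
called multi-sample VCF with allelic depths, a pedigree, an exon target BED, a
per-exon read-count matrix, and a reference-panel RPKM matrix — on a miniature
genome (three autosomes plus chrX, a few Mb each) so that desk-scale tests run
in seconds.

What is emulated
----------------
* Trio families (father, mother, affected proband), a configurable fraction of
  them consanguineous.  Consanguineous probands carry autozygous tracts whose
  per-genome total is drawn from a range scaled down from the 86.5-507.5 Mb
  observed in consanguineous exomes (97.1-118.8 Mb for outbred ones) by the
  ratio of the miniature autosome size to the ~2,881 Mb hg19 autosome total.
* Per-site allele fractions: homozygous sites ~1, heterozygous ~0.5, with
  configurable Gaussian noise, emitted as integer allelic depths around a mean
  coverage of 80 reads.
* Per-exon read counts drawn negative-binomially around depth x length, with
  planted homozygous/hemizygous deletions (counts ~0) and heterozygous
  deletions (counts halved), plus a reference-panel RPKM matrix standing in
  for a large exome database.
* Planted variants with known inheritance: homozygous-by-descent inside a
  tract, de novo, compound heterozygous, X-linked hemizygous, and one
  SNV-plus-paternal-deletion compound that makes a maternally inherited SNV
  look homozygous in the proband.

Every random draw flows from one seed through named substreams, so identical
configurations produce byte-identical output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, write_bed

__all__ = [
    "GenomeModel",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "sample_autozygous_tracts",
    "emit_site_allele_fractions",
]

HG19_AUTOSOME_MB = 2881.0  # approximate hg19 autosome total, scaling anchor
PAPER_CONSANG_AOH_MB = (86.5, 507.5)
PAPER_OUTBRED_AOH_MB = (97.1, 118.8)

DIAGNOSTIC_CATEGORIES = (
    "known_variant_known_gene",
    "novel_variant_known_gene",
    "known_gene_phenotypic_expansion",
    "novel_candidate_gene",
    "unsolved",
)


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode()) & 0x7FFFFFFF])


@dataclass(frozen=True)
class GenomeModel:
    """Miniature genome: chromosome sizes and a regular gene/exon layout."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 8_000_000,
            "chr2": 6_000_000,
            "chr3": 5_000_000,
            "chrX": 4_000_000,
        }
    )
    gene_spacing_bp: int = 400_000
    exon_length_bp: int = 150
    intron_length_bp: int = 2_000
    # exon counts cycle through this pattern; 15-exon genes anchor planted CNVs
    exon_count_cycle: tuple[int, ...] = (15, 8, 5, 10, 6, 12, 4, 9)

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_sizes if c != "chrX"]

    @property
    def autosome_total_bp(self) -> int:
        return sum(self.chrom_sizes[c] for c in self.autosomes)

    @property
    def aoh_scale(self) -> float:
        """Ratio of the miniature autosome total to the hg19 autosome total."""
        return self.autosome_total_bp / (HG19_AUTOSOME_MB * 1e6)

    def exon_table(self) -> pd.DataFrame:
        """Deterministic exon layout: chrom, start, end, gene, exon_index."""
        rows = []
        for chrom, size in self.chrom_sizes.items():
            gi = 0
            pos = 150_000
            while True:
                n_exons = self.exon_count_cycle[gi % len(self.exon_count_cycle)]
                span = n_exons * self.exon_length_bp + (n_exons - 1) * self.intron_length_bp
                if pos + span > size - 150_000:
                    break
                gene = f"G{chrom[3:]}_{gi:02d}"
                for e in range(n_exons):
                    start = pos + e * (self.exon_length_bp + self.intron_length_bp)
                    rows.append(
                        (chrom, start, start + self.exon_length_bp - 1, gene, e + 1)
                    )
                gi += 1
                pos += self.gene_spacing_bp
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "exon_index"])
        df["exon_id"] = df["gene"] + "|" + df["exon_index"].astype(str)
        df["length"] = df["end"] - df["start"] + 1
        return df


@dataclass
class PlantedDeletion:
    """A deletion planted over a run of exons of one gene."""

    family_index: int  # 0-based family index
    gene: str
    exon_first: int  # 1-based, inclusive
    exon_last: int
    zygosity: str  # homozygous | hemizygous | het_paternal
    carriers: tuple[str, ...] = ("proband",)  # roles with a deleted haplotype


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort; all randomness from ``seed``."""

    n_families: int = 31
    fraction_consanguineous: float = 28 / 31
    fraction_male_probands: float = 13 / 31
    genome: GenomeModel = field(default_factory=GenomeModel)
    # AOH totals, Mb; None -> printed WES ranges scaled to the miniature genome
    target_total_aoh_mb_range_consang: tuple[float, float] | None = None
    target_total_aoh_mb_range_outbred: tuple[float, float] | None = None
    aoh_target_margin: float = 0.12  # per-sample targets drawn this far inside the range
    min_tract_bp: int = 600_000
    mean_depth: float = 80.0
    het_baf_sd: float = 0.05
    site_spacing_bp: float = 2_500.0
    library_size: int = 20_000_000
    read_length: int = 100
    count_dispersion: float = 60.0
    hom_del_residual: float = 0.0005
    panel_size: int = 1000
    panel_del_rate: float = 0.0005
    panel_rpkm_cv: float = 0.2
    plant_defaults: bool = True
    planted_deletions: list[PlantedDeletion] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_consanguineous <= 1.0):
            raise ValueError("fraction_consanguineous must be in [0, 1]")
        if self.n_families < 1:
            raise ValueError("need at least one family")
        scale = self.genome.aoh_scale
        if self.target_total_aoh_mb_range_consang is None:
            self.target_total_aoh_mb_range_consang = (
                PAPER_CONSANG_AOH_MB[0] * scale,
                PAPER_CONSANG_AOH_MB[1] * scale,
            )
        if self.target_total_aoh_mb_range_outbred is None:
            self.target_total_aoh_mb_range_outbred = (
                PAPER_OUTBRED_AOH_MB[0] * scale,
                PAPER_OUTBRED_AOH_MB[1] * scale,
            )
        for rng_ in (self.target_total_aoh_mb_range_consang, self.target_total_aoh_mb_range_outbred):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid AOH target range {rng_}")


@dataclass
class SimulatedCohort:
    """Paths and in-memory tables for one simulated cohort."""

    config: SimulationConfig
    outdir: Path
    vcf: Path
    ped: Path
    exon_bed: Path
    counts_tsv: Path
    library_tsv: Path
    panel_tsv: Path
    samples: pd.DataFrame
    exons: pd.DataFrame
    aoh_truth: pd.DataFrame
    deletion_truth: pd.DataFrame
    variant_truth: pd.DataFrame
    external_cnv: pd.DataFrame
    outcomes: pd.DataFrame

    @property
    def probands(self) -> list[str]:
        return list(self.samples.loc[self.samples["role"] == "proband", "sample_id"])


def sample_autozygous_tracts(
    total_target_bp: int,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
    min_tract_bp: int = 600_000,
    max_tract_bp: int = 2_500_000,
    anchors: list[GenomicInterval] = (),
    edge_buffer_bp: int = 50_000,
    min_gap_bp: int = 200_000,
) -> list[GenomicInterval]:
    """Place non-overlapping autozygous tracts summing (near-)exactly to target.

    ``anchors`` are intervals (e.g. a causal gene) that must each be covered by
    one tract.  Raises when the target exceeds half the genome model or cannot
    be placed.
    """
    total_target_bp = int(total_target_bp)
    if total_target_bp <= 0:
        return []
    genome = sum(chrom_sizes.values())
    if total_target_bp > 0.5 * genome:
        raise ValueError("AOH target exceeds half the genome model")
    if total_target_bp < min_tract_bp:
        raise ValueError("AOH target smaller than the minimum tract length")

    # draw tract lengths summing exactly to the target
    lengths: list[int] = []
    rem = total_target_bp
    for anchor in anchors:
        need = max(anchor.length + 2 * edge_buffer_bp, min_tract_bp)
        hi = min(max_tract_bp, rem)
        length = need if hi <= need else int(rng.uniform(need, hi))
        lengths.append(length)
        rem -= length
    while rem >= min_tract_bp:
        if rem < 2 * min_tract_bp:
            length = rem
        else:
            length = int(rng.uniform(min_tract_bp, min(max_tract_bp, rem - min_tract_bp)))
            if rem - length < min_tract_bp:
                length = rem
        lengths.append(length)
        rem -= length
    if 0 < rem and lengths:
        lengths[-1] += rem  # absorb the remainder so the sum is exact

    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: list[GenomicInterval] = []

    def conflicts(chrom: str, start: int, end: int) -> bool:
        for t in placed:
            if t.chrom == chrom and not (end + min_gap_bp < t.start or start - min_gap_bp > t.end):
                return True
        return False

    for idx, length in enumerate(lengths):
        if idx < len(anchors):
            anchor = anchors[idx]
            slack = length - anchor.length
            for _ in range(200):
                off = int(rng.uniform(edge_buffer_bp, max(edge_buffer_bp + 1, slack - edge_buffer_bp)))
                start = max(1, anchor.start - off)
                end = start + length - 1
                if end > chrom_sizes[anchor.chrom] - edge_buffer_bp:
                    end = chrom_sizes[anchor.chrom] - edge_buffer_bp
                    start = end - length + 1
                if start >= 1 and not conflicts(anchor.chrom, start, end):
                    placed.append(GenomicInterval(anchor.chrom, start, end))
                    break
            else:
                raise ValueError("could not place anchored autozygous tract")
        else:
            for _ in range(200):
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                size = chrom_sizes[chrom]
                if size < length + 2 * edge_buffer_bp:
                    continue
                start = int(rng.uniform(edge_buffer_bp, size - length - edge_buffer_bp))
                end = start + length - 1
                if not conflicts(chrom, start, end):
                    placed.append(GenomicInterval(chrom, start, end))
                    break
            else:
                raise ValueError("could not place autozygous tracts for the requested total")
    return placed


def emit_site_allele_fractions(
    alt_dosage: np.ndarray,
    ploidy: np.ndarray,
    het_baf_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Variant-read fractions for sites with given alt-allele dosage/ploidy.

    The noiseless fraction is ``dosage / ploidy`` (1.0 for homozygous or
    hemizygous alt, 0.5 for het, 0.0 for reference); Gaussian noise with sd
    ``het_baf_sd`` is added and the result clipped to [0, 1].  With sd 0 the
    fractions are exact.
    """
    alt_dosage = np.asarray(alt_dosage, dtype=float)
    ploidy = np.asarray(ploidy, dtype=float)
    frac = np.divide(alt_dosage, ploidy, out=np.zeros_like(alt_dosage), where=ploidy > 0)
    if het_baf_sd > 0:
        frac = frac + rng.normal(0.0, het_baf_sd, size=frac.shape)
    return np.clip(frac, 0.0, 1.0)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _default_planted_deletions(config: SimulationConfig, exons: pd.DataFrame) -> list[PlantedDeletion]:
    """Default CNV plant: one multi-exon and one single-exon homozygous
    deletion, one paternal heterozygous deletion (SNV+CNV family), and one
    hemizygous chrX deletion in a male proband."""
    if not config.plant_defaults:
        return list(config.planted_deletions or [])
    dels: list[PlantedDeletion] = []
    auto15 = exons[(exons["chrom"] != "chrX")].groupby("gene")["exon_index"].max()
    big_genes = sorted(auto15[auto15 == 15].index)
    x_genes = sorted(exons.loc[exons["chrom"] == "chrX", "gene"].unique())
    n = config.n_families
    if n >= 1 and big_genes:
        # exons 3-4 of a 15-exon gene, homozygous in a consanguineous proband
        dels.append(PlantedDeletion(0, big_genes[0], 3, 4, "homozygous"))
    if n >= 2 and len(big_genes) > 1:
        dels.append(PlantedDeletion(1, big_genes[1], 5, 5, "homozygous"))
    if n >= 3 and len(big_genes) > 2:
        # paternally inherited het deletion over the last 7 exons; the SNV+CNV
        # compound family (maternal SNV planted inside the deleted span)
        dels.append(
            PlantedDeletion(2, big_genes[2], 9, 15, "het_paternal", ("proband", "father"))
        )
    n_male = int(round(config.fraction_male_probands * n))
    if n >= 5 and x_genes and n_male >= 5:
        # hemizygous single-exon X deletion in a male proband
        dels.append(PlantedDeletion(4, x_genes[0], 2, 2, "hemizygous"))
    if config.planted_deletions:
        dels.extend(config.planted_deletions)
    return dels


def _assign_categories(n: int) -> list[str]:
    """Deterministic diagnostic-category truth mirroring the cohort accounting
    proportions (2:9:6:11:3 at n=31); unsolved families come last."""
    base = np.array([2, 9, 6, 11, 3], dtype=float)
    counts = np.floor(base / base.sum() * n).astype(int)
    while counts.sum() < n:
        counts[np.argmax(base / base.sum() * n - counts)] += 1
    out: list[str] = []
    for cat, k in zip(DIAGNOSTIC_CATEGORIES, counts):
        out.extend([cat] * int(k))
    return out[:n]


_STRUCT_GROUPS = (
    "corpus_callosum",
    "cortical_dysgenesis",
    "microcephaly",
    "hindbrain",
    "white_matter",
)


def _assign_phenotypes(n: int) -> list[list[str]]:
    """Phenotype-group truth: ~61 % structural, ~39 % DD/ID-only, with
    overlapping structural subgroups."""
    n_struct = int(round(n * 19 / 31))
    groups: list[list[str]] = []
    for i in range(n):
        if i < n_struct:
            base = "syndromic_brain_malformation" if i % 3 == 0 else "nonsyndromic_brain_malformation"
            g = [base, _STRUCT_GROUPS[i % 5]]
            if i % 4 == 0:
                g.append(_STRUCT_GROUPS[(i + 2) % 5])
        else:
            g = ["syndromic_DD_ID" if i % 2 == 0 else "nonsyndromic_DD_ID"]
        groups.append(g)
    return groups


def _genotype_family(
    p: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    proband_male: bool,
    tracts: list[GenomicInterval],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw Mendelian-consistent allele matrices for one trio.

    Returns arrays of shape (n_sites, 2) of alleles (0/1; -1 = absent second
    allele on the male X) for father, mother, proband.
    """
    n = len(p)
    fa = (rng.random((n, 2)) < p[:, None]).astype(np.int8)
    mo = (rng.random((n, 2)) < p[:, None]).astype(np.int8)
    is_x = chroms == "chrX"
    fa[is_x, 1] = -1  # father is hemizygous on X

    # transmitted-allele indices
    t_fa = (rng.random(n) < 0.5).astype(np.int8)
    t_fa[is_x] = 0
    t_mo = (rng.random(n) < 0.5).astype(np.int8)

    # autozygous tracts: proband homozygous for an ancestral allele carried by
    # both parents (keeps the trio Mendelian-consistent)
    in_tract = np.zeros(n, dtype=bool)
    for t in tracts:
        in_tract |= (chroms == t.chrom) & (positions >= t.start) & (positions <= t.end)
    anc = (rng.random(n) < p).astype(np.int8)
    for parent in (fa, mo):
        fix = in_tract & (parent[:, 0] != anc) & (parent[:, 1] != anc)
        parent[fix, 0] = anc[fix]
    # parents transmit the ancestral allele inside the tract
    for parent, t_idx in ((fa, t_fa), (mo, t_mo)):
        has0 = parent[:, 0] == anc
        t_idx[in_tract] = np.where(has0[in_tract], 0, 1).astype(np.int8)

    pr = np.empty((n, 2), dtype=np.int8)
    pr[:, 0] = fa[np.arange(n), t_fa]
    pr[:, 1] = mo[np.arange(n), t_mo]
    if proband_male:
        # male proband: single maternally inherited X allele
        pr[is_x, 0] = mo[is_x][np.arange(int(is_x.sum())), t_mo[is_x]]
        pr[is_x, 1] = -1
    return {"father": fa, "mother": mo, "proband": pr}


def _gt_string(alleles: np.ndarray) -> np.ndarray:
    """Diploid genotype strings from an (n, 2) allele matrix (male-X hemizygous
    calls are written as homozygous diploid genotypes; ploidy is recovered
    downstream from the pedigree sex)."""
    a, b = alleles[:, 0].astype(int), alleles[:, 1].astype(int)
    b = np.where(b < 0, a, b)
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    out = np.where(
        (a < 0),
        "./.",
        np.char.add(np.char.add(lo.astype(str), "/"), hi.astype(str)),
    )
    return out


def simulate_cohort(config: SimulationConfig, outdir) -> SimulatedCohort:
    """Generate a full cohort bundle under ``outdir``.

    Writes VCF v4.2 (GT/AD/DP), 6-column PED, exon BED (name = gene|index),
    read-count TSV, library-size TSV, panel RPKM TSV and truth tables; returns
    a :class:`SimulatedCohort` handle.  Identical configs (same seed) produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = config.genome
    exons = genome.exon_table()
    n_fam = config.n_families

    # --- pedigree -----------------------------------------------------------
    n_consang = int(round(config.fraction_consanguineous * n_fam))
    n_male = int(round(config.fraction_male_probands * n_fam))
    fam_rows = []
    for i in range(n_fam):
        fam = f"F{i + 1:03d}"
        consang = i < n_consang
        male = i < n_male
        fam_rows.append((fam, f"{fam}_F", "0", "0", "male", False, consang, "father"))
        fam_rows.append((fam, f"{fam}_M", "0", "0", "female", False, consang, "mother"))
        fam_rows.append(
            (fam, f"{fam}_P", f"{fam}_F", f"{fam}_M", "male" if male else "female", True, consang, "proband")
        )
    samples = pd.DataFrame(
        fam_rows,
        columns=["family_id", "sample_id", "father_id", "mother_id", "sex", "affected", "consanguineous", "role"],
    )

    # --- planted CNVs and causal variants -----------------------------------
    planted_dels = _default_planted_deletions(config, exons)
    del_rows = []
    for pd_ in planted_dels:
        sub = exons[(exons["gene"] == pd_.gene) & exons["exon_index"].between(pd_.exon_first, pd_.exon_last)]
        if sub.empty:
            raise ValueError(f"planted deletion outside exon model: {pd_}")
        if pd_.family_index >= n_fam:
            raise ValueError(f"planted deletion references family {pd_.family_index} >= n_families")
        del_rows.append(
            {
                "family_id": f"F{pd_.family_index + 1:03d}",
                "gene": pd_.gene,
                "exon_first": pd_.exon_first,
                "exon_last": pd_.exon_last,
                "zygosity": pd_.zygosity,
                "carriers": ",".join(pd_.carriers),
                "chrom": sub["chrom"].iloc[0],
                "start": int(sub["start"].min()),
                "end": int(sub["end"].max()),
            }
        )
    deletion_truth = pd.DataFrame(
        del_rows,
        columns=["family_id", "gene", "exon_first", "exon_last", "zygosity", "carriers", "chrom", "start", "end"],
    )

    # --- background variant sites -------------------------------------------
    site_rng = _substream(config.seed, "sites")
    site_chroms: list[str] = []
    site_pos: list[int] = []
    for chrom, size in genome.chrom_sizes.items():
        pos = 0
        while True:
            pos += int(site_rng.exponential(config.site_spacing_bp)) + 1
            if pos >= size:
                break
            site_chroms.append(chrom)
            site_pos.append(pos)
    af_rng = _substream(config.seed, "afs")
    n_bg = len(site_pos)
    p_pop = af_rng.uniform(0.05, 0.95, size=n_bg)

    sites = pd.DataFrame(
        {
            "chrom": site_chroms,
            "pos": site_pos,
            "p": p_pop,
            "gene": "",
            "effect": "other",
            "ndmg": 0,
            "af_db1": np.round(p_pop * af_rng.uniform(0.9, 1.1, n_bg), 5).clip(0, 1),
            "af_db2": np.round(p_pop * af_rng.uniform(0.9, 1.1, n_bg), 5).clip(0, 1),
            "planted_id": "",
        }
    )

    # --- planted variant plan -----------------------------------------------
    categories = _assign_categories(n_fam)
    n_unsolved = categories.count("unsolved")
    plant_rng = _substream(config.seed, "plant")
    variant_plan: list[dict] = []  # one causal planted variant spec per solved family
    if config.plant_defaults:
        auto_genes = sorted(exons.loc[exons["chrom"] != "chrX", "gene"].unique())
        x_genes = sorted(exons.loc[exons["chrom"] == "chrX", "gene"].unique())
        used: set[str] = {d["gene"] for d in del_rows}
        free_genes = [g for g in auto_genes if g not in used]
        de_novo_fams = set()
        comphet_fam = None
        xl_fam = None
        snvcnv_fam = 2 if any(d["zygosity"] == "het_paternal" and d["family_id"] == "F003" for d in del_rows) else None
        solved = [i for i in range(n_fam) if categories[i] != "unsolved"]
        pool = [i for i in solved if i not in (0, 1, 2)]
        male_pool = [i for i in pool if i < int(round(config.fraction_male_probands * n_fam))]
        if male_pool:
            xl_fam = male_pool[0]
        dn_candidates = [i for i in pool if i != xl_fam]
        de_novo_fams = set(dn_candidates[:4])
        ch_candidates = [i for i in dn_candidates[4:]]
        if ch_candidates:
            comphet_fam = ch_candidates[0]
        for i in solved:
            fam = f"F{i + 1:03d}"
            if i == snvcnv_fam:
                hetdel = next(
                    d for d in del_rows
                    if d["zygosity"] == "het_paternal" and d["family_id"] == fam
                )
                gene = hetdel["gene"]
                sub = exons[(exons["gene"] == gene) & (exons["exon_index"] == 10)]
                variant_plan.append(
                    {"family_id": fam, "gene": gene, "chrom": sub["chrom"].iloc[0],
                     "pos": int(sub["start"].iloc[0]) + 40, "model": "snv_cnv_compound",
                     "effect": "missense", "ndmg": 3}
                )
            elif i in de_novo_fams:
                gene = free_genes.pop(0)
                sub = exons[(exons["gene"] == gene) & (exons["exon_index"] == 1)]
                variant_plan.append(
                    {"family_id": fam, "gene": gene, "chrom": sub["chrom"].iloc[0],
                     "pos": int(sub["start"].iloc[0]) + 10, "model": "de_novo",
                     "effect": "missense", "ndmg": 2}
                )
            elif i == comphet_fam:
                gene = free_genes.pop(0)
                sub = exons[exons["gene"] == gene].sort_values("exon_index")
                for which, exrow in zip(("paternal", "maternal"), (sub.iloc[0], sub.iloc[-1])):
                    variant_plan.append(
                        {"family_id": fam, "gene": gene, "chrom": exrow["chrom"],
                         "pos": int(exrow["start"]) + 20, "model": f"compound_het_{which}",
                         "effect": "missense", "ndmg": 2}
                    )
            elif i == xl_fam:
                gene = x_genes[1 % len(x_genes)]
                sub = exons[(exons["gene"] == gene) & (exons["exon_index"] == 1)]
                variant_plan.append(
                    {"family_id": fam, "gene": gene, "chrom": "chrX",
                     "pos": int(sub["start"].iloc[0]) + 15, "model": "x_linked_hemizygous",
                     "effect": "missense", "ndmg": 2}
                )
            elif i in (0, 1, 2) and i != 2:
                # families with planted homozygous deletions: the CNV is causal
                continue
            else:
                gene = free_genes.pop(int(plant_rng.integers(len(free_genes))))
                sub = exons[(exons["gene"] == gene) & (exons["exon_index"] == 2)]
                if sub.empty:
                    sub = exons[exons["gene"] == gene].iloc[:1]
                variant_plan.append(
                    {"family_id": fam, "gene": gene, "chrom": sub["chrom"].iloc[0],
                     "pos": int(sub["start"].iloc[0]) + 25, "model": "homozygous_recessive",
                     "effect": "lof" if i % 3 == 0 else "missense", "ndmg": 3}
                )

    planted_sites = pd.DataFrame(
        [
            {
                "chrom": v["chrom"],
                "pos": v["pos"],
                "p": 0.0,
                "gene": v["gene"],
                "effect": v["effect"],
                "ndmg": v["ndmg"],
                "af_db1": 0.0,
                "af_db2": 0.0,
                "planted_id": f"{v['family_id']}:{v['model']}",
            }
            for v in variant_plan
        ],
        columns=sites.columns,
    )
    sites = pd.concat([sites, planted_sites], ignore_index=True).drop_duplicates(
        subset=["chrom", "pos"], keep="last"
    )
    sites["_ck"] = sites["chrom"].map(_chrom_key)
    sites = sites.sort_values(["_ck", "pos"], kind="mergesort").drop(columns="_ck").reset_index(drop=True)
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    p_arr = sites["p"].to_numpy()
    n_sites = len(sites)

    # --- autozygous tracts ---------------------------------------------------
    auto_sizes = {c: genome.chrom_sizes[c] for c in genome.autosomes}
    aoh_rows = []
    tracts_by_family: dict[str, list[GenomicInterval]] = {}
    lo_c, hi_c = config.target_total_aoh_mb_range_consang
    lo_o, hi_o = config.target_total_aoh_mb_range_outbred
    mar = config.aoh_target_margin
    causal_anchor: dict[str, GenomicInterval] = {}
    for v in variant_plan:
        if v["model"] == "homozygous_recessive":
            causal_anchor[v["family_id"]] = GenomicInterval(v["chrom"], v["pos"], v["pos"])
    for d in del_rows:
        if d["zygosity"] == "homozygous":
            causal_anchor[d["family_id"]] = GenomicInterval(d["chrom"], d["start"], d["end"])
    for i in range(n_fam):
        fam = f"F{i + 1:03d}"
        consang = bool(samples.loc[samples["family_id"] == fam, "consanguineous"].iloc[0])
        lo, hi = (lo_c, hi_c) if consang else (lo_o, hi_o)
        width = hi - lo
        t_rng = _substream(config.seed, f"tracts:{fam}")
        target_mb = t_rng.uniform(lo + mar * width, hi - mar * width)
        anchors = [causal_anchor[fam]] if fam in causal_anchor else []
        tracts = sample_autozygous_tracts(
            int(target_mb * 1e6),
            auto_sizes,
            t_rng,
            min_tract_bp=config.min_tract_bp,
            anchors=anchors,
        )
        tracts_by_family[fam] = tracts
        for t in tracts:
            aoh_rows.append((f"{fam}_P", t.chrom, t.start, t.end, t.length))
    aoh_truth = pd.DataFrame(aoh_rows, columns=["sample_id", "chrom", "start", "end", "length"])

    # --- genotypes ------------------------------------------------------------
    sample_ids = list(samples["sample_id"])
    male = dict(zip(samples["sample_id"], samples["sex"] == "male"))
    alleles: dict[str, np.ndarray] = {}
    variant_truth_rows = []
    for i in range(n_fam):
        fam = f"F{i + 1:03d}"
        g_rng = _substream(config.seed, f"geno:{fam}")
        trio = _genotype_family(
            p_arr, chrom_arr, pos_arr, male[f"{fam}_P"], tracts_by_family[fam], g_rng
        )
        alleles[f"{fam}_F"] = trio["father"]
        alleles[f"{fam}_M"] = trio["mother"]
        alleles[f"{fam}_P"] = trio["proband"]

    site_index = {(c, int(pp)): k for k, (c, pp) in enumerate(zip(chrom_arr, pos_arr))}
    for v in variant_plan:
        fam = v["family_id"]
        k = site_index[(v["chrom"], v["pos"])]
        fa, mo, pr = alleles[f"{fam}_F"], alleles[f"{fam}_M"], alleles[f"{fam}_P"]
        model = v["model"]
        if model == "homozygous_recessive":
            fa[k] = (0, 1) if not (v["chrom"] == "chrX") else (1, -1)
            mo[k] = (0, 1)
            pr[k] = (1, 1) if pr[k, 1] >= 0 else (1, -1)
        elif model == "de_novo":
            fa[k] = (0, 0) if fa[k, 1] >= 0 else (0, -1)
            mo[k] = (0, 0)
            pr[k] = (0, 1) if pr[k, 1] >= 0 else (1, -1)
        elif model == "compound_het_paternal":
            fa[k] = (0, 1)
            mo[k] = (0, 0)
            pr[k] = (1, 0)
        elif model == "compound_het_maternal":
            fa[k] = (0, 0)
            mo[k] = (0, 1)
            pr[k] = (0, 1)
        elif model == "x_linked_hemizygous":
            fa[k] = (0, -1)
            mo[k] = (0, 1)
            pr[k] = (1, -1)
        elif model == "snv_cnv_compound":
            fa[k] = (0, 0)
            mo[k] = (0, 1)
            pr[k] = (0, 1)  # maternal alt + paternal (deleted) ref haplotype
        variant_truth_rows.append(
            {
                "family_id": fam,
                "gene": v["gene"],
                "chrom": v["chrom"],
                "pos": v["pos"],
                "model": model,
                "effect": v["effect"],
                "ndmg": v["ndmg"],
            }
        )
    variant_truth = pd.DataFrame(
        variant_truth_rows,
        columns=["family_id", "gene", "chrom", "pos", "model", "effect", "ndmg"],
    )

    # --- deletion spans per sample (affect depths and observed genotypes) ----
    hom_del_mask = {s: np.zeros(n_sites, dtype=bool) for s in sample_ids}
    het_del_mask = {s: np.zeros(n_sites, dtype=bool) for s in sample_ids}
    external_rows = []
    for d in del_rows:
        fam = d["family_id"]
        span = (chrom_arr == d["chrom"]) & (pos_arr >= d["start"]) & (pos_arr <= d["end"])
        if d["zygosity"] in ("homozygous", "hemizygous"):
            hom_del_mask[f"{fam}_P"] |= span
            if d["zygosity"] == "homozygous":
                # consanguineous parents are obligate heterozygous carriers
                het_del_mask[f"{fam}_F"] |= span
                het_del_mask[f"{fam}_M"] |= span
        else:  # het_paternal
            for role in d["carriers"].split(","):
                suffix = {"proband": "_P", "father": "_F", "mother": "_M"}[role]
                het_del_mask[fam + suffix] |= span
            external_rows.append(
                {
                    "sample_id": f"{fam}_P",
                    "family_id": fam,
                    "chrom": d["chrom"],
                    "start": d["start"],
                    "end": d["end"],
                    "type": "heterozygous_deletion",
                    "source": "external_caller",
                }
            )
            external_rows.append({**external_rows[-1], "sample_id": f"{fam}_F"})
    external_cnv = pd.DataFrame(
        external_rows,
        columns=["sample_id", "family_id", "chrom", "start", "end", "type", "source"],
    )

    # --- allelic depths and VCF ----------------------------------------------
    is_x_site = chrom_arr == "chrX"
    gt_cols: dict[str, np.ndarray] = {}
    ad_cols: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in sample_ids:
        d_rng = _substream(config.seed, f"depth:{s}")
        al = alleles[s].copy()
        ploidy = np.where(al[:, 1] >= 0, 2.0, 1.0)
        dosage = np.where(al[:, 1] >= 0, al[:, 0] + al[:, 1], np.maximum(al[:, 0], 0)).astype(float)
        # heterozygous deletion: only one haplotype remains; the observed call
        # collapses to a homozygous-looking genotype from the surviving allele
        hetm = het_del_mask[s]
        if hetm.any():
            if s.endswith("_P"):
                surviving = al[:, 1]  # maternal allele (paternal hap deleted)
            else:
                surviving = al[:, 0]
            surviving = np.maximum(surviving, 0)
            ploidy = np.where(hetm, 1.0, ploidy)
            dosage = np.where(hetm, surviving, dosage)
            al = al.copy()
            al[hetm, 0] = surviving[hetm]
            al[hetm, 1] = np.where(al[hetm, 1] >= 0, surviving[hetm], al[hetm, 1])
        depth_scale = np.where(ploidy < 2, 0.5, 1.0)
        homm = hom_del_mask[s]
        depth_scale = np.where(homm, config.hom_del_residual, depth_scale)
        dp = d_rng.poisson(config.mean_depth * depth_scale).astype(np.int64)
        frac = emit_site_allele_fractions(dosage, ploidy, config.het_baf_sd, d_rng)
        altd = np.rint(frac * dp).astype(np.int64)
        refd = dp - altd
        gts = _gt_string(al)
        gts = np.where(dp == 0, "./.", gts)
        gts = np.where(homm, "./.", gts)
        gt_cols[s] = gts
        ad_cols[s] = (refd, altd)

    # drop sites called in no sample (all hom-ref or missing)
    any_called = np.zeros(n_sites, dtype=bool)
    for s in sample_ids:
        g = gt_cols[s]
        any_called |= (g != "0/0") & (g != "./.")
    keep = np.flatnonzero(any_called)

    bases = np.array(["A", "C", "G", "T"])
    b_rng = _substream(config.seed, "bases")
    ref_b = bases[b_rng.integers(0, 4, n_sites)]
    alt_b = np.array([bases[(list(bases).index(r) + 1 + k) % 4] for r, k in zip(ref_b, b_rng.integers(0, 3, n_sites))])

    vcf_path = outdir / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=conswes-simulate\n")
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Predicted effect class">\n')
        fh.write('##INFO=<ID=NDMG,Number=1,Type=Integer,Description="Number of damaging predictions">\n')
        fh.write('##INFO=<ID=AF_DB1,Number=1,Type=Float,Description="Population AF, database 1">\n')
        fh.write('##INFO=<ID=AF_DB2,Number=1,Type=Float,Description="Population AF, database 2">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "\t".join(["FORMAT"] + sample_ids) + "\n")
        gene_arr = sites["gene"].to_numpy()
        eff_arr = sites["effect"].to_numpy()
        ndmg_arr = sites["ndmg"].to_numpy()
        af1_arr = sites["af_db1"].to_numpy()
        af2_arr = sites["af_db2"].to_numpy()
        cols = [(gt_cols[s], *ad_cols[s]) for s in sample_ids]
        for k in keep:
            info = f"AF_DB1={af1_arr[k]:.5f};AF_DB2={af2_arr[k]:.5f};EFFECT={eff_arr[k]};NDMG={int(ndmg_arr[k])}"
            if gene_arr[k]:
                info = f"GENE={gene_arr[k]};" + info
            fields = [
                chrom_arr[k], str(int(pos_arr[k])), ".", ref_b[k], alt_b[k], ".", "PASS", info, "GT:AD:DP",
            ]
            for g, refd, altd in cols:
                fields.append(f"{g[k]}:{refd[k]},{altd[k]}:{refd[k] + altd[k]}")
            fh.write("\t".join(fields) + "\n")

    # --- PED ------------------------------------------------------------------
    ped_path = outdir / "cohort.ped"
    with open(ped_path, "w") as fh:
        for r in samples.itertuples(index=False):
            sex = "1" if r.sex == "male" else "2"
            pheno = "2" if r.affected else "1"
            fh.write("\t".join([r.family_id, r.sample_id, r.father_id, r.mother_id, sex, pheno]) + "\n")

    # --- exon BED -------------------------------------------------------------
    bed_path = outdir / "exons.bed"
    bed = exons[["chrom", "start", "end", "exon_id"]].rename(columns={"exon_id": "name"})
    write_bed(bed, bed_path)

    # --- read counts ----------------------------------------------------------
    ex_rng = _substream(config.seed, "exonbase")
    base_mean = (
        config.mean_depth * exons["length"].to_numpy() / config.read_length
    ) * np.exp(ex_rng.normal(0.0, 0.15, len(exons)))
    count_mat = np.zeros((len(exons), len(sample_ids)), dtype=np.int64)
    ex_chrom = exons["chrom"].to_numpy()
    ex_start = exons["start"].to_numpy()
    ex_end = exons["end"].to_numpy()
    del_factor = {s: np.ones(len(exons)) for s in sample_ids}
    for d in del_rows:
        fam = d["family_id"]
        span = (ex_chrom == d["chrom"]) & (ex_start >= d["start"]) & (ex_end <= d["end"])
        if d["zygosity"] in ("homozygous", "hemizygous"):
            del_factor[f"{fam}_P"][span] = config.hom_del_residual
            if d["zygosity"] == "homozygous":
                del_factor[f"{fam}_F"][span] = 0.5
                del_factor[f"{fam}_M"][span] = 0.5
        else:
            for role in d["carriers"].split(","):
                suffix = {"proband": "_P", "father": "_F", "mother": "_M"}[role]
                del_factor[fam + suffix][span] = 0.5
    theta = config.count_dispersion
    lib_rows = []
    for j, s in enumerate(sample_ids):
        c_rng = _substream(config.seed, f"counts:{s}")
        sf = float(np.exp(c_rng.normal(0.0, 0.05)))
        mean = base_mean * sf * del_factor[s]
        if male[s]:
            mean = np.where(ex_chrom == "chrX", mean * 0.5, mean)
        mean = np.maximum(mean, 1e-9)
        count_mat[:, j] = c_rng.negative_binomial(theta, theta / (theta + mean))
        lib_rows.append((s, int(round(config.library_size * np.exp(c_rng.normal(0.0, 0.05))))))
    counts = pd.DataFrame(count_mat, index=exons["exon_id"], columns=sample_ids)
    counts_path = outdir / "counts.tsv"
    counts.to_csv(counts_path, sep="\t", index_label="exon_id")
    library = pd.DataFrame(lib_rows, columns=["sample_id", "total_reads"])
    library_path = outdir / "library_sizes.tsv"
    library.to_csv(library_path, sep="\t", index=False)

    # --- panel RPKM -----------------------------------------------------------
    p_rng = _substream(config.seed, "panel")
    lib_m = config.library_size / 1e6
    base_rpkm = base_mean / (exons["length"].to_numpy() / 1000.0) / lib_m
    panel_vals = base_rpkm[:, None] * np.exp(
        p_rng.normal(0.0, config.panel_rpkm_cv, size=(len(exons), config.panel_size))
    )
    panel_dels = p_rng.random((len(exons), config.panel_size)) < config.panel_del_rate
    panel_vals = np.where(panel_dels, panel_vals * 0.005, panel_vals)
    panel = pd.DataFrame(
        np.round(panel_vals, 4),
        index=exons["exon_id"],
        columns=[f"PANEL{j + 1:04d}" for j in range(config.panel_size)],
    )
    panel_path = outdir / "panel_rpkm.tsv"
    panel.to_csv(panel_path, sep="\t", index_label="exon_id")

    # --- truth tables and outcomes -------------------------------------------
    phen = _assign_phenotypes(n_fam)
    outcomes = pd.DataFrame(
        {
            "family_id": [f"F{i + 1:03d}" for i in range(n_fam)],
            "category": categories,
            "phenotype_groups": ["|".join(g) for g in phen],
        }
    )
    aoh_truth.to_csv(outdir / "truth_aoh.tsv", sep="\t", index=False)
    deletion_truth.to_csv(outdir / "truth_deletions.tsv", sep="\t", index=False)
    variant_truth.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    external_cnv.to_csv(outdir / "external_cnv.tsv", sep="\t", index=False)
    outcomes.to_csv(outdir / "outcomes.tsv", sep="\t", index=False)
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)

    return SimulatedCohort(
        config=config,
        outdir=outdir,
        vcf=vcf_path,
        ped=ped_path,
        exon_bed=bed_path,
        counts_tsv=counts_path,
        library_tsv=library_path,
        panel_tsv=panel_path,
        samples=samples,
        exons=exons,
        aoh_truth=aoh_truth,
        deletion_truth=deletion_truth,
        variant_truth=variant_truth,
        external_cnv=external_cnv,
        outcomes=outcomes,
    )


def _chrom_key(c: str):
    tail = c[3:]
    return (0, int(tail)) if tail.isdigit() else (1, tail)
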