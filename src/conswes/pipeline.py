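"""End-to-end pipeline configuration and orchestration.

``PipelineConfig`` holds every input path and stage threshold (each threshold
defaulting to the published value), serialises losslessly to/from YAML, and
``run_pipeline`` composes the stages — AOH segmentation, exon-deletion
calling, segregation filtering, candidate ranking, cohort reporting — writing
one artifact bundle plus a manifest with the config hash, seed, and per-stage
record counts.  Identical config and inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import aoh as aoh_mod
from . import hmzdel, ranking, report, segregation
from .intervals import read_bed

__all__ = ["PipelineConfig", "run_pipeline", "stage_aoh", "stage_hmzdel", "stage_segregate"]


@dataclass
class PipelineConfig:
    # inputs
    vcf: str = ""
    ped: str = ""
    exon_bed: str = ""
    counts: str = ""
    library_sizes: str = ""
    panel_rpkm: str = ""
    external_cnv: str = ""  # optional BED-like table from external CNV callers
    outcomes: str = ""  # optional per-family outcome TSV for the report stage
    curation: str = ""  # optional per-gene curated ranking evidence TSV
    outdir: str = "conswes_out"
    # AOH stage
    aoh_min_mean: float = 0.45
    aoh_min_size_bp: int = 1000
    aoh_report_bp: int = 500_000
    min_total_reads: int = 10
    cbs_alpha: float = 0.01
    cbs_permutations: int = 1000
    cbs_min_markers: int = 10
    # deletion stage
    rpkm_threshold: float = 0.5
    frequency_threshold: float = 0.005
    aoh_support_bp: int = 1000
    # segregation stage
    max_af_recessive: float = 0.001
    max_af_de_novo: float = 0.0001
    min_damaging: int = 2
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (the output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def require(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if not path:
                raise FileNotFoundError(f"pipeline input {name!r} not configured")
            if not Path(path).exists():
                raise FileNotFoundError(f"pipeline input {name} does not exist: {path}")


def _probands(ped: segregation.Pedigree) -> list[str]:
    out = []
    for fam in ped.families():
        trio = ped.trio(fam)
        if trio is not None:
            out.append(trio[0])
    return out


def stage_aoh(config: PipelineConfig, samples: list[str] | None = None):
    """AOH calls and summaries for the given samples (default: all probands).

    Returns (aoh_by_sample, summaries); summaries cover autosomes only, since
    the male X is uninformative for autozygosity.
    """
    config.require("vcf", "ped")
    ped = segregation.Pedigree.from_ped(config.ped)
    if samples is None:
        samples = _probands(ped)
    params = aoh_mod.SegmentationParams(
        alpha=config.cbs_alpha,
        n_permutations=config.cbs_permutations,
        min_markers=config.cbs_min_markers,
    )
    aoh_by_sample: dict[str, list[aoh_mod.AohSegment]] = {}
    summaries = []
    for sample in samples:
        tracks = aoh_mod.build_baf_tracks(config.vcf, sample, config.min_total_reads)
        calls: list[aoh_mod.AohSegment] = []
        for chrom in sorted(tracks):
            track = tracks[chrom]
            segs = aoh_mod.segment_track(track, params, base_seed=config.seed)
            calls.extend(
                aoh_mod.call_aoh(track, segs, config.aoh_min_mean, config.aoh_min_size_bp)
            )
        aoh_by_sample[sample] = calls
        autosomal = [c for c in calls if c.interval.chrom != "chrX"]
        summaries.append(aoh_mod.summarize_aoh(sample, autosomal, config.aoh_report_bp))
    return aoh_by_sample, summaries


def _aoh_frames(aoh_by_sample, summaries):
    rows = []
    for sample, calls in aoh_by_sample.items():
        for c in calls:
            rows.append(
                (sample, c.interval.chrom, c.interval.start, c.interval.end,
                 round(c.mean_signal, 4), c.n_sites)
            )
    calls_df = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "mean_signal", "n_sites"]
    )
    summary_df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "n_regions": s.n_regions,
                "max_length": s.max_length,
                "min_length": s.min_length,
                "median_length": s.median_length,
                "mean_length": s.mean_length,
                "total_length": s.total_length,
            }
            for s in summaries
        ]
    )
    return calls_df, summary_df


def _load_rpkm(config: PipelineConfig):
    exons = read_bed(config.exon_bed)
    name = exons["name"].str.split("|", expand=True)
    exons = exons.assign(
        gene=name[0], exon_index=name[1].astype(int), exon_id=exons["name"]
    ).drop(columns="name")
    exons["length"] = exons["end"] - exons["start"] + 1
    counts = pd.read_csv(config.counts, sep="\t", index_col="exon_id")
    counts = counts.reindex(exons["exon_id"])
    library = pd.read_csv(config.library_sizes, sep="\t").set_index("sample_id")["total_reads"]
    rpkm = hmzdel.compute_rpkm(counts, exons["length"].to_numpy(), library)
    cohort = hmzdel.RpkmMatrix(exons, rpkm)
    panel_vals = pd.read_csv(config.panel_rpkm, sep="\t", index_col="exon_id").reindex(exons["exon_id"])
    panel = hmzdel.RpkmMatrix(exons, panel_vals)
    return cohort, panel


def stage_hmzdel(config: PipelineConfig, aoh_by_sample) -> list[hmzdel.DeletionCall]:
    """Exon-deletion calls for every sample with AOH results."""
    config.require("exon_bed", "counts", "library_sizes", "panel_rpkm", "ped")
    cohort, panel = _load_rpkm(config)
    ped = segregation.Pedigree.from_ped(config.ped)
    thresholds = hmzdel.DeletionThresholds(
        max_rpkm=config.rpkm_threshold,
        max_frequency=config.frequency_threshold,
        min_aoh_bp=config.aoh_support_bp,
    )
    calls: list[hmzdel.DeletionCall] = []
    for sample, aoh_calls in aoh_by_sample.items():
        if sample not in cohort.values.columns:
            continue
        flags = hmzdel.exon_deletion_flags(cohort, panel, sample, aoh_calls, thresholds)
        calls.extend(
            hmzdel.call_deletions(flags, sample, ped.is_male(sample), aoh_calls)
        )
    return calls


def _deletion_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "gene": c.gene,
                "n_exons": len(c.exon_ids),
                "exon_ids": ",".join(c.exon_ids),
                "mean_rpkm": round(c.mean_rpkm, 4),
                "cohort_frequency": round(c.cohort_frequency, 5),
                "zygosity": c.zygosity_label,
                "supporting_aoh": str(c.supporting_aoh.interval) if c.supporting_aoh else "",
            }
            for c in calls
        ],
        columns=[
            "sample_id", "chrom", "start", "end", "gene", "n_exons", "exon_ids",
            "mean_rpkm", "cohort_frequency", "zygosity", "supporting_aoh",
        ],
    )


def stage_segregate(config: PipelineConfig, deletion_calls=()) -> pd.DataFrame:
    """Rarity/effect filtering plus per-family segregation tests and SNV+CNV
    compound-heterozygote flags."""
    config.require("vcf", "ped")
    ped = segregation.Pedigree.from_ped(config.ped)
    variants = segregation.read_annotated_vcf(
        config.vcf, ped, max_af_keep=config.max_af_recessive
    )
    rare = segregation.rarity_filter(variants, config.max_af_recessive)
    damaging = segregation.effect_filter(rare, min_damaging=config.min_damaging)
    cnvs: list = list(deletion_calls)
    if config.external_cnv and Path(config.external_cnv).exists():
        ext = hmzdel.read_external_cnv(config.external_cnv)
        cnvs.extend(ext.to_dict("records"))

    rows = []
    for fam in ped.families():
        trio = ped.trio(fam)
        if trio is None:
            continue
        proband = trio[0]
        fam_vars = [
            v
            for v in damaging
            if v.genotypes.get(proband, segregation.Genotype.MISSING).carries_alt
        ]
        for v in fam_vars:
            for model in ("homozygous_recessive", "de_novo", "x_linked_hemizygous"):
                if model == "de_novo":
                    ok_af = all(af <= config.max_af_de_novo for af in v.population_af.values())
                    if not ok_af:
                        continue
                res = segregation.segregation_test(v, ped, model, fam)
                if res.status is segregation.Status.NOT_TESTABLE and model != "homozygous_recessive":
                    continue
                rows.append(
                    {
                        "family_id": fam,
                        "gene": v.gene,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "model": model,
                        "status": res.status.value,
                        "notes": "; ".join(res.explanations),
                    }
                )
            flag = segregation.flag_snv_cnv_compound(v, ped, fam, cnvs)
            if flag is not None:
                rows.append(
                    {
                        "family_id": fam,
                        "gene": v.gene,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "model": "snv_cnv_compound",
                        "status": "flag",
                        "notes": (
                            f"het parent {flag.transmitting_parent_het}; "
                            f"wild-type parent {flag.apparent_wildtype_parent}; "
                            + ("corroborated by overlapping CNV" if flag.corroborating_cnv is not None
                               else "no corroborating CNV")
                        ),
                    }
                )
        for v1, v2, res in segregation.find_compound_het_pairs(fam_vars, ped, fam):
            rows.append(
                {
                    "family_id": fam,
                    "gene": v1.gene,
                    "chrom": v1.chrom,
                    "pos": v1.pos,
                    "model": "compound_het",
                    "status": res.status.value,
                    "notes": f"in trans with {v2.interval}",
                }
            )
    return pd.DataFrame(
        rows, columns=["family_id", "gene", "chrom", "pos", "model", "status", "notes"]
    )


def stage_rank(config: PipelineConfig, seg_df: pd.DataFrame, deletion_calls=()) -> pd.DataFrame:
    """Rank candidate genes, auto-filling the pipeline-derivable criteria.

    ``multiple_families``, ``lof_variant``, ``multi_program_deleterious`` and
    ``rare_in_multiple_databases`` come from pipeline outputs; the curated
    criteria (human interactors/paralogs, animal models, region association,
    tissue expression) come from the optional curation TSV and default False.
    """
    curated = {}
    if config.curation and Path(config.curation).exists():
        cdf = pd.read_csv(config.curation, sep="\t").set_index("gene")
        curated = cdf.to_dict("index")
    ped = segregation.Pedigree.from_ped(config.ped) if config.ped else None
    variants = []
    if config.vcf and ped is not None:
        variants = segregation.read_annotated_vcf(
            config.vcf, ped, max_af_keep=config.max_af_recessive
        )
    by_pos = {(v.chrom, v.pos): v for v in variants}

    passing = seg_df[seg_df["status"].isin(["pass", "flag"])]
    gene_fams: dict[str, set] = {}
    gene_lof: dict[str, bool] = {}
    gene_dmg: dict[str, bool] = {}
    gene_rare: dict[str, bool] = {}
    for r in passing.itertuples(index=False):
        if not r.gene:
            continue
        gene_fams.setdefault(r.gene, set()).add(r.family_id)
        v = by_pos.get((r.chrom, r.pos))
        if v is not None:
            gene_lof[r.gene] = gene_lof.get(r.gene, False) or v.effect_class == "lof"
            gene_dmg[r.gene] = gene_dmg.get(r.gene, False) or (
                v.n_damaging_predictions >= config.min_damaging
            )
            n_rare_dbs = sum(af <= config.max_af_recessive for af in v.population_af.values())
            gene_rare[r.gene] = gene_rare.get(r.gene, False) or n_rare_dbs >= 2
    for c in deletion_calls:
        gene_fams.setdefault(c.gene, set()).add(c.sample_id.rsplit("_", 1)[0])
        gene_lof[c.gene] = True  # a homozygous exon deletion is loss of function
        gene_rare[c.gene] = gene_rare.get(c.gene, False) or c.cohort_frequency < config.frequency_threshold

    scores = []
    for gene in sorted(gene_fams):
        cur = curated.get(gene, {})
        cv = ranking.CriterionVector(
            multiple_families=len(gene_fams[gene]) >= 2,
            human_interactor_paralog_phenotype=bool(cur.get("human_interactor_paralog_phenotype", False)),
            animal_model_phenotype=bool(cur.get("animal_model_phenotype", False)),
            genomic_region_association=bool(cur.get("genomic_region_association", False)),
            lof_variant=gene_lof.get(gene, False),
            multi_program_deleterious=gene_dmg.get(gene, False),
            rare_in_multiple_databases=gene_rare.get(gene, False),
            expressed_in_affected_tissue=bool(cur.get("expressed_in_affected_tissue", False)),
        )
        scores.append(ranking.score_candidate(gene, cv))
    ranked = ranking.rank_cohort(scores)
    return pd.DataFrame(
        [
            {"gene": s.gene, "total_points": s.total_points, "rank_band": s.rank_band,
             **{k: int(v) for k, v in s.criteria.as_dict().items()}}
            for s in ranked
        ]
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing the artifact bundle under ``config.outdir``.

    Returns a dict of output paths and key in-memory results.  Any stage
    failure propagates with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    results: dict = {"outdir": outdir}

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    aoh_by_sample, summaries = run_stage("aoh", lambda: stage_aoh(config))
    calls_df, summary_df = _aoh_frames(aoh_by_sample, summaries)
    calls_df.to_csv(outdir / "aoh_calls.tsv", sep="\t", index=False)
    summary_df.to_csv(outdir / "aoh_summary.tsv", sep="\t", index=False)
    with open(outdir / "aoh_calls.bed", "w") as fh:
        for r in calls_df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.sample_id}|{r.mean_signal}\n")
    manifest["stages"]["aoh"] = {"n_calls": len(calls_df), "n_samples": len(summary_df)}

    deletions = run_stage("hmzdel", lambda: stage_hmzdel(config, aoh_by_sample))
    del_df = _deletion_frame(deletions)
    del_df.to_csv(outdir / "deletion_calls.tsv", sep="\t", index=False)
    with open(outdir / "deletion_calls.bed", "w") as fh:
        for r in del_df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.sample_id}|{r.gene}|{r.zygosity}\n")
    manifest["stages"]["hmzdel"] = {"n_calls": len(del_df)}

    seg_df = run_stage("segregate", lambda: stage_segregate(config, deletions))
    seg_df.to_csv(outdir / "segregation.tsv", sep="\t", index=False)
    manifest["stages"]["segregate"] = {
        "n_rows": len(seg_df),
        "n_pass": int((seg_df["status"] == "pass").sum()) if len(seg_df) else 0,
    }

    ranked = run_stage("rank", lambda: stage_rank(config, seg_df, deletions))
    ranked.to_csv(outdir / "candidates_ranked.tsv", sep="\t", index=False)
    manifest["stages"]["rank"] = {"n_genes": len(ranked)}

    if config.outcomes and Path(config.outcomes).exists():
        outcomes = report.read_outcomes(config.outcomes)
        rates = report.diagnostic_rates(outcomes)
        tallies = report.phenotype_tallies(outcomes)
        rates.to_csv(outdir / "diagnostic_rates.tsv", sep="\t", index=False)
        tallies.to_csv(outdir / "phenotype_tallies.tsv", sep="\t", index=False)
        (outdir / "cohort_summary.txt").write_text(report.summary_text(outcomes))
        manifest["stages"]["report"] = {"n_families": len(outcomes)}

    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results.update(
        aoh=aoh_by_sample, summaries=summaries, deletions=deletions,
        segregation=seg_df, ranked=ranked, manifest=manifest,
    )
    return results
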