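"""Homozygous/hemizygous exon-deletion calling from normalized exome depth.

Whole-exome read depth is summarised per exon as RPKM (reads per kilobase of
exon per million mapped reads).  An exon is flagged as deleted in a sample
when three criteria hold simultaneously:

1. the sample's RPKM for the exon is below 0.5 (strict),
2. the exon is rarely that low across a large sample set — the fraction of
   cohort-plus-reference-panel samples with RPKM < 0.5 at the exon is below
   0.5 % (strict), and
3. the exon lies fully within an AOH region longer than 1 kb (strict),
   i.e. the candidate deletion is exposed on both haplotypes.

Runs of consecutively flagged exons of the same gene merge into one call;
calls on the male X are labelled hemizygous, otherwise homozygous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aoh import AohSegment
from .intervals import GenomicInterval, contained_in

__all__ = [
    "RpkmMatrix",
    "DeletionCall",
    "DeletionThresholds",
    "compute_rpkm",
    "exon_deletion_flags",
    "call_deletions",
    "read_external_cnv",
]


@dataclass(frozen=True)
class DeletionThresholds:
    """Printed calling thresholds: RPKM < 0.5, frequency < 0.5 %, AOH > 1 kb."""

    max_rpkm: float = 0.5
    max_frequency: float = 0.005
    min_aoh_bp: int = 1000


@dataclass
class RpkmMatrix:
    """Samples x exons RPKM with the exon layout alongside.

    ``values`` is a DataFrame indexed by exon_id with one column per sample;
    ``exons`` carries chrom/start/end/gene/exon_index per exon_id in the same
    row order.
    """

    exons: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.exons["exon_id"]) != list(self.values.index):
            raise ValueError("exon table and RPKM matrix rows do not match")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class DeletionCall:
    """A merged run of deleted exons in one sample."""

    sample_id: str
    interval: GenomicInterval
    gene: str
    exon_ids: tuple[str, ...]
    mean_rpkm: float
    cohort_frequency: float  # max over member exons
    supporting_aoh: AohSegment | None
    zygosity_label: str  # homozygous | hemizygous


def compute_rpkm(
    counts: pd.DataFrame,
    exon_lengths: np.ndarray | pd.Series,
    total_reads: pd.Series | dict,
) -> pd.DataFrame:
    """RPKM per (exon, sample): ``(count / (len/1000)) / (total/1e6)``.

    ``counts`` is exons x samples; ``total_reads`` gives each sample's total
    mapped reads (must be > 0).
    """
    lengths = np.asarray(exon_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("exon lengths must be positive")
    totals = pd.Series(total_reads).reindex(counts.columns)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise KeyError(f"total reads missing for samples: {missing}")
    if (totals <= 0).any():
        raise ValueError("total mapped reads must be positive")
    per_kb = counts.to_numpy(dtype=float) / (lengths[:, None] / 1000.0)
    rpkm = per_kb / (totals.to_numpy(dtype=float)[None, :] / 1e6)
    return pd.DataFrame(rpkm, index=counts.index, columns=counts.columns)


def low_depth_frequency(
    cohort: RpkmMatrix,
    panel: RpkmMatrix,
    max_rpkm: float = 0.5,
) -> pd.Series:
    """Per-exon fraction of cohort-plus-panel samples with RPKM < ``max_rpkm``.

    The reference panel stands in for the large exome database the cohort is
    called together with; it must share the cohort's exon set.
    """
    if list(cohort.values.index) != list(panel.values.index):
        raise ValueError("cohort and panel exon sets differ")
    low = (cohort.values.to_numpy() < max_rpkm).sum(axis=1) + (
        panel.values.to_numpy() < max_rpkm
    ).sum(axis=1)
    n = cohort.values.shape[1] + panel.values.shape[1]
    return pd.Series(low / n, index=cohort.values.index, name="low_frequency")


def exon_deletion_flags(
    rpkm: RpkmMatrix,
    panel: RpkmMatrix,
    sample_id: str,
    aoh: list[AohSegment],
    thresholds: DeletionThresholds = DeletionThresholds(),
) -> pd.DataFrame:
    """Per-exon criterion flags (low_rpkm, rare, in_aoh) for one sample.

    ``in_aoh`` requires full containment of the exon in an AOH region whose
    span exceeds ``min_aoh_bp``.
    """
    if sample_id not in rpkm.values.columns:
        raise KeyError(f"sample {sample_id!r} absent from RPKM matrix")
    vals = rpkm.values[sample_id].to_numpy()
    low = vals < thresholds.max_rpkm
    freq = low_depth_frequency(rpkm, panel, thresholds.max_rpkm)
    rare = freq.to_numpy() < thresholds.max_frequency
    big_aoh = [s for s in aoh if s.interval.length > thresholds.min_aoh_bp]
    in_aoh = np.zeros(len(vals), dtype=bool)
    for k, row in enumerate(rpkm.exons.itertuples(index=False)):
        ex_iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        in_aoh[k] = any(contained_in(ex_iv, s.interval) for s in big_aoh)
    out = rpkm.exons[["exon_id", "gene", "exon_index", "chrom", "start", "end"]].copy()
    out["rpkm"] = vals
    out["low_frequency"] = freq.to_numpy()
    out["low_rpkm"] = low
    out["rare"] = rare
    out["in_aoh"] = in_aoh
    out["flagged"] = low & rare & in_aoh
    return out


def call_deletions(
    flags: pd.DataFrame,
    sample_id: str,
    sample_is_male: bool,
    aoh: list[AohSegment] = (),
) -> list[DeletionCall]:
    """Merge consecutively flagged exons (per gene) into deletion calls.

    A gap of one unflagged exon splits a run.  Calls on the male X are
    labelled hemizygous.
    """
    calls: list[DeletionCall] = []
    flagged = flags[flags["flagged"]]
    for gene, sub in flagged.groupby("gene", sort=True):
        sub = sub.sort_values("exon_index")
        run: list[pd.Series] = []
        prev_idx = None
        for _, row in sub.iterrows():
            if prev_idx is not None and row["exon_index"] != prev_idx + 1:
                calls.append(_emit_call(run, sample_id, sample_is_male, aoh))
                run = []
            run.append(row)
            prev_idx = row["exon_index"]
        if run:
            calls.append(_emit_call(run, sample_id, sample_is_male, aoh))
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return calls


def _emit_call(
    run: list[pd.Series],
    sample_id: str,
    sample_is_male: bool,
    aoh: list[AohSegment],
) -> DeletionCall:
    iv = GenomicInterval(run[0]["chrom"], int(run[0]["start"]), int(run[-1]["end"]))
    zyg = "hemizygous" if (sample_is_male and iv.chrom == "chrX") else "homozygous"
    support = next((s for s in aoh if contained_in(iv, s.interval)), None)
    return DeletionCall(
        sample_id=sample_id,
        interval=iv,
        gene=run[0]["gene"],
        exon_ids=tuple(r["exon_id"] for r in run),
        mean_rpkm=float(np.mean([r["rpkm"] for r in run])),
        cohort_frequency=float(np.max([r["low_frequency"] for r in run])),
        supporting_aoh=support,
        zygosity_label=zyg,
    )


def read_external_cnv(path) -> pd.DataFrame:
    """Adapter for BED-like CNV tables from external exome CNV callers.

    Expects a TSV with at least sample_id, chrom, start, end (1-based closed)
    and optional type/source columns; used for corroborating SNV+CNV compound
    heterozygotes and for comparison tables, never as this caller's output.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"external CNV table must have columns {sorted(required)}")
    from .intervals import normalize_chrom

    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df
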