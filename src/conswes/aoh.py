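"""Absence-of-heterozygosity (AOH) detection from exome allelic depths.

For one sample, each called variant site contributes a B-allele frequency
(BAF): the fraction of reads supporting the alternate allele.  Subtracting 0.5
gives a signed deviation that is ~0 at heterozygous sites and ~+0.5 at
homozygous-alternate sites (homozygous-reference sites are not called variants
for the sample and carry no signal).  Circular binary segmentation of that
deviation track yields mean-signal segments; segments whose mean exceeds 0.45
and whose genomic span exceeds 1 kb are reported as AOH — effectively runs
free of heterozygous calls, the hallmark of autozygosity in consanguineous
individuals.  Per-sample summary statistics (count, min/max/median/mean/total
length) are computed over AOH regions of at least 0.5 Mb.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .cbs import Segment, cbs_segment
from .intervals import GenomicInterval, normalize_chrom

__all__ = [
    "BafTrack",
    "AohSegment",
    "AohSummary",
    "SegmentationParams",
    "build_baf_tracks",
    "segment_track",
    "call_aoh",
    "summarize_aoh",
]


@dataclass
class BafTrack:
    """Signed BAF deviations for one sample on one chromosome.

    ``signal[k] = alt_reads/total_reads - 0.5`` at ``positions[k]`` (1-based,
    strictly increasing).
    """

    sample_id: str
    chrom: str
    positions: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.positions) != len(self.signal):
            raise ValueError("positions and signal lengths differ")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class AohSegment:
    """A called AOH region with its mean deviation signal."""

    interval: GenomicInterval
    mean_signal: float
    n_sites: int


@dataclass(frozen=True)
class AohSummary:
    """Per-sample AOH length statistics over regions >= the reporting floor."""

    sample_id: str
    n_regions: int
    max_length: int | None
    min_length: int | None
    median_length: float | None
    mean_length: float | None
    total_length: int


@dataclass(frozen=True)
class SegmentationParams:
    """CBS tuning for BAF tracks (permutation alpha, count, marker floor)."""

    alpha: float = 0.01
    n_permutations: int = 1000
    min_markers: int = 10


def track_seed(sample_id: str, chrom: str, base_seed: int = 0) -> int:
    """Deterministic permutation seed derived from (sample, chromosome)."""
    return (zlib.crc32(f"{sample_id}:{chrom}".encode()) ^ (base_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def build_baf_tracks(
    vcf_path,
    sample_id: str,
    min_total_reads: int = 10,
    exclude_indels: bool = True,
) -> dict[str, BafTrack]:
    """Build per-chromosome BAF deviation tracks for one sample from a VCF.

    Sites are retained when the sample has a called non-reference genotype at a
    biallelic site with at least ``min_total_reads`` reads in its allelic
    depths.  Returns a dict keyed by chromosome; a sample with no usable sites
    yields an empty dict.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    try:
        idx = vcf.samples.index(sample_id)
    except ValueError:
        raise KeyError(f"sample {sample_id!r} not present in {vcf_path}") from None

    per_chrom: dict[str, tuple[list[int], list[float]]] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # multi-allelic sites are skipped, not decomposed
        if exclude_indels and (len(var.REF) != 1 or len(var.ALT[0]) != 1):
            continue
        gt = var.gt_types[idx]  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        if gt not in (1, 2):
            continue
        ad = var.format("AD")
        if ad is None:
            continue
        ref_d, alt_d = int(ad[idx, 0]), int(ad[idx, 1])
        if ref_d < 0 or alt_d < 0:
            continue
        total = ref_d + alt_d
        if total < min_total_reads:
            continue
        chrom = normalize_chrom(var.CHROM)
        pos_list, sig_list = per_chrom.setdefault(chrom, ([], []))
        pos_list.append(var.POS)
        sig_list.append(alt_d / total - 0.5)
    return {
        chrom: BafTrack(sample_id, chrom, np.array(pos), np.array(sig))
        for chrom, (pos, sig) in per_chrom.items()
    }


def segment_track(
    track: BafTrack,
    params: SegmentationParams = SegmentationParams(),
    base_seed: int = 0,
) -> list[Segment]:
    """Run CBS on one BAF track; segments partition its sites."""
    if track.n_sites == 0:
        return []
    rng = np.random.default_rng(track_seed(track.sample_id, track.chrom, base_seed))
    return cbs_segment(
        track.signal,
        alpha=params.alpha,
        n_perm=params.n_permutations,
        min_markers=params.min_markers,
        rng=rng,
    )


def call_aoh(
    track: BafTrack,
    segments: list[Segment],
    min_mean: float = 0.45,
    min_size_bp: int = 1000,
) -> list[AohSegment]:
    """Retain segments with mean signal > ``min_mean`` (strict) and genomic
    span > ``min_size_bp`` (strict); span runs first to last member site."""
    calls = []
    for seg in segments:
        if seg.mean <= min_mean:
            continue
        start = int(track.positions[seg.start])
        end = int(track.positions[seg.end - 1])
        iv = GenomicInterval(track.chrom, start, end)
        if iv.length <= min_size_bp:
            continue
        calls.append(AohSegment(iv, seg.mean, seg.n_markers))
    return calls


def summarize_aoh(
    sample_id: str,
    segments: list[AohSegment],
    min_report_bp: int = 500_000,
) -> AohSummary:
    """Length statistics over AOH regions >= ``min_report_bp`` (inclusive)."""
    lengths = sorted(s.interval.length for s in segments if s.interval.length >= min_report_bp)
    if not lengths:
        return AohSummary(sample_id, 0, None, None, None, None, 0)
    arr = np.array(lengths)
    return AohSummary(
        sample_id=sample_id,
        n_regions=len(lengths),
        max_length=int(arr.max()),
        min_length=int(arr.min()),
        median_length=float(np.median(arr)),
        mean_length=float(arr.mean()),
        total_length=int(arr.sum()),
    )
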