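import numpy as np
import pytest

from conswes.aoh import (
    AohSegment,
    BafTrack,
    build_baf_tracks,
    call_aoh,
    segment_track,
    summarize_aoh,
)
from conswes.cbs import Segment
from conswes.intervals import GenomicInterval

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


@pytest.fixture
def small_vcf(tmp_path):
    records = [
        ("chr1", 100, "A", "G", "1/1", "0,30"),  # pure hom-alt -> +0.5
        ("chr1", 200, "C", "T", "0/1", "15,15"),  # balanced het -> 0.0
        ("chr1", 300, "G", "A", "0/1", "12,28"),  # 28/40 - 0.5 = 0.2
        ("chr1", 400, "T", "C", "0/1", "3,4"),  # total 7 < 10: dropped
        ("chr1", 500, "A", "T", "0/0", "30,0"),  # hom-ref: not a called variant
        ("chr1", 600, "AT", "A", "0/1", "10,10"),  # indel: excluded by default
    ]
    path = tmp_path / "s.vcf"
    lines = [
        f"{c}\t{p}\t.\t{r}\t{a}\t.\tPASS\t.\tGT:AD\t{gt}:{ad}"
        for c, p, r, a, gt, ad in records
    ]
    path.write_text(VCF_HEADER + "\n".join(lines) + "\n")
    return path


def test_build_baf_track_signal_values(small_vcf):
    tracks = build_baf_tracks(small_vcf, "S1", min_total_reads=10)
    track = tracks["chr1"]
    assert list(track.positions) == [100, 200, 300]
    assert track.signal == pytest.approx([0.5, 0.0, 0.2])


def test_build_baf_track_missing_sample(small_vcf):
    with pytest.raises(KeyError):
        build_baf_tracks(small_vcf, "NOPE")


def test_track_invariants():
    with pytest.raises(ValueError):
        BafTrack("s", "chr1", [100, 90], [0.1, 0.2])
    with pytest.raises(ValueError):
        BafTrack("s", "chr1", [100], [0.1, 0.2])


def _track(positions, signal):
    return BafTrack("s", "chr1", np.asarray(positions), np.asarray(signal))


def test_call_aoh_thresholds_are_strict():
    # 50 kb span, 20 sites
    pos = np.linspace(10_000, 60_001, 20).astype(int)
    track = _track(pos, np.full(20, 0.49))
    seg_at_045 = [Segment(0, 20, 0.45)]
    seg_at_049 = [Segment(0, 20, 0.49)]
    assert call_aoh(track, seg_at_045) == []  # mean exactly 0.45: rejected
    calls = call_aoh(track, seg_at_049)
    assert len(calls) == 1
    assert calls[0].interval == GenomicInterval("chr1", int(pos[0]), int(pos[-1]))
    # 900 bp span fails the strict >1 kb size threshold
    tight = _track(np.linspace(1000, 1900, 20).astype(int), np.full(20, 0.49))
    assert call_aoh(tight, seg_at_049) == []
    # exactly 1000 bp span (length 1001 > 1000) is retained
    edge = _track(np.linspace(1000, 2000, 20).astype(int), np.full(20, 0.49))
    assert len(call_aoh(edge, seg_at_049)) == 1


def test_summarize_aoh_statistics():
    def seg(start, length, mean=0.5):
        return AohSegment(GenomicInterval("chr1", start, start + length - 1), mean, 50)

    s = summarize_aoh("s", [seg(1, 1_000_000), seg(5_000_000, 3_000_000)])
    assert s.n_regions == 2
    assert s.total_length == 4_000_000
    assert s.mean_length == pytest.approx(2_000_000)
    assert s.median_length == pytest.approx(2_000_000)
    assert (s.min_length, s.max_length) == (1_000_000, 3_000_000)

    single = summarize_aoh("s", [seg(1, 2_000_000)])
    assert (
        single.max_length
        == single.min_length
        == single.median_length
        == single.mean_length
        == single.total_length
        == 2_000_000
    )

    # the 0.5 Mb reporting floor is inclusive; shorter regions are ignored
    empty = summarize_aoh("s", [seg(1, 400_000)])
    assert empty.n_regions == 0 and empty.total_length == 0
    assert empty.max_length is None
    at_floor = summarize_aoh("s", [seg(1, 500_000)])
    assert at_floor.n_regions == 1


def test_segment_track_recovers_planted_aoh_block():
    """An elevated-signal block inside noisy het background is segmented out
    and called as AOH spanning (close to) the planted sites."""
    rng = np.random.default_rng(9)
    n1, n2, n3 = 150, 100, 150
    sig = np.concatenate(
        [
            rng.choice([0.0, 0.5], n1, p=[0.7, 0.3]),
            np.full(n2, 0.5) - np.abs(rng.normal(0, 0.02, n2)),
            rng.choice([0.0, 0.5], n3, p=[0.7, 0.3]),
        ]
    )
    pos = np.arange(1, n1 + n2 + n3 + 1) * 5_000
    track = _track(pos, sig)
    segs = segment_track(track)
    calls = call_aoh(track, segs)
    assert len(calls) == 1
    call = calls[0]
    planted = GenomicInterval("chr1", int(pos[n1]), int(pos[n1 + n2 - 1]))
    from conswes.intervals import overlap_bp

    ro = overlap_bp(call.interval, planted) / max(call.interval.length, planted.length)
    assert ro >= 0.95
    assert call.mean_signal > 0.45


def test_empty_track_segments():
    track = _track([], [])
    assert segment_track(track) == []
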