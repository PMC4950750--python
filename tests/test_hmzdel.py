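import numpy as np
import pandas as pd
import pytest

from conswes.aoh import AohSegment
from conswes.hmzdel import (
    DeletionThresholds,
    RpkmMatrix,
    call_deletions,
    compute_rpkm,
    exon_deletion_flags,
    low_depth_frequency,
)
from conswes.intervals import GenomicInterval


@pytest.mark.parametrize(
    "count, length, total, expected",
    [
        (100, 1000, 1_000_000, 100.0),
        (0, 1000, 1_000_000, 0.0),
        (50, 500, 2_000_000, 50.0),
    ],
)
def test_compute_rpkm_values(count, length, total, expected):
    counts = pd.DataFrame({"S1": [count]}, index=["g|1"])
    rpkm = compute_rpkm(counts, np.array([length]), {"S1": total})
    assert rpkm.loc["g|1", "S1"] == pytest.approx(expected)


def test_compute_rpkm_rejects_bad_totals():
    counts = pd.DataFrame({"S1": [1]}, index=["g|1"])
    with pytest.raises(ValueError):
        compute_rpkm(counts, np.array([100]), {"S1": 0})
    with pytest.raises(KeyError):
        compute_rpkm(counts, np.array([100]), {"S2": 10})


def _matrix(values: dict, chrom="chr1"):
    n_exons = len(next(iter(values.values())))
    exons = pd.DataFrame(
        {
            "chrom": chrom,
            "start": [10_000 + 2000 * i for i in range(n_exons)],
            "end": [10_150 + 2000 * i for i in range(n_exons)],
            "gene": "G",
            "exon_index": range(1, n_exons + 1),
        }
    )
    exons["exon_id"] = "G|" + exons["exon_index"].astype(str)
    vals = pd.DataFrame(values, index=exons["exon_id"])
    return RpkmMatrix(exons, vals)


def _panel(n_samples, n_exons, low_counts=None):
    vals = {f"P{j}": np.full(n_exons, 50.0) for j in range(n_samples)}
    panel = _matrix(vals)
    if low_counts:
        for exon_row, k in low_counts.items():
            for j in range(k):
                panel.values.iloc[exon_row, j] = 0.1
    return panel


AOH = [AohSegment(GenomicInterval("chr1", 1, 1_000_000), 0.5, 100)]


def test_three_criteria_boundaries_are_strict():
    cohort = _matrix({"S1": [0.5, 0.1, 50.0], "S2": [50.0, 50.0, 50.0]})
    panel = _panel(1029, 3)
    flags = exon_deletion_flags(cohort, panel, "S1", AOH)
    # RPKM exactly 0.5 is NOT low (strict <)
    assert not flags.loc[0, "low_rpkm"]
    assert flags.loc[1, "low_rpkm"]
    assert flags["in_aoh"].all()
    assert flags["flagged"].tolist() == [False, True, False]


def test_frequency_strictly_below_half_percent():
    # 4 extra low panel samples + the test sample = 5/1031 = 0.00485 < 0.005
    cohort = _matrix({"S1": [0.1], "S2": [50.0]})
    rare_panel = _panel(1029, 1, low_counts={0: 4})
    freq = low_depth_frequency(cohort, rare_panel)
    assert freq.iloc[0] == pytest.approx(5 / 1031)
    flags = exon_deletion_flags(cohort, rare_panel, "S1", AOH)
    assert flags.loc[0, "rare"] and flags.loc[0, "flagged"]
    # one more low sample: 6/1031 = 0.00582 >= 0.005 -> common, not called
    common_panel = _panel(1029, 1, low_counts={0: 5})
    flags = exon_deletion_flags(cohort, common_panel, "S1", AOH)
    assert not flags.loc[0, "rare"] and not flags.loc[0, "flagged"]


def test_exon_outside_aoh_never_called():
    cohort = _matrix({"S1": [0.0, 0.0], "S2": [50.0, 50.0]})
    panel = _panel(100, 2)
    flags = exon_deletion_flags(cohort, panel, "S1", aoh=[])
    assert not flags["in_aoh"].any()
    assert not flags["flagged"].any()
    assert call_deletions(flags, "S1", False) == []
    # partial overlap with the AOH region does not count as "located within"
    partial = [AohSegment(GenomicInterval("chr1", 1, 10_100), 0.5, 50)]
    flags = exon_deletion_flags(cohort, panel, "S1", partial)
    assert not flags["in_aoh"].any()


def test_aoh_region_must_exceed_1kb():
    cohort = _matrix({"S1": [0.0], "S2": [50.0]})
    panel = _panel(100, 1)
    tiny = [AohSegment(GenomicInterval("chr1", 10_000, 10_999), 0.5, 20)]  # 1000 bp
    flags = exon_deletion_flags(cohort, panel, "S1", tiny)
    assert not flags["in_aoh"].any()


def test_merging_rules():
    cohort = _matrix({"S1": [50.0, 0.1, 0.1, 50.0, 0.1], "S2": [50.0] * 5})
    panel = _panel(1029, 5)
    flags = exon_deletion_flags(cohort, panel, "S1", AOH)
    calls = call_deletions(flags, "S1", False, AOH)
    # exons 2-3 merge into one call; exon 5 (separated by unflagged 4) is its own
    assert [c.exon_ids for c in calls] == [("G|2", "G|3"), ("G|5",)]
    assert calls[0].interval.start == 12_000 and calls[0].interval.end == 14_150
    assert all(c.zygosity_label == "homozygous" for c in calls)
    assert calls[0].supporting_aoh is AOH[0]


def test_male_chrx_calls_are_hemizygous():
    cohort = _matrix({"S1": [0.1], "S2": [25.0]}, chrom="chrX")
    panel_vals = {f"P{j}": np.full(1, 25.0) for j in range(1029)}
    panel = _matrix(panel_vals, chrom="chrX")
    aoh_x = [AohSegment(GenomicInterval("chrX", 1, 1_000_000), 0.5, 100)]
    flags = exon_deletion_flags(cohort, panel, "S1", aoh_x)
    calls = call_deletions(flags, "S1", True, aoh_x)
    assert len(calls) == 1 and calls[0].zygosity_label == "hemizygous"


def test_threshold_monotonicity():
    """Raising the RPKM threshold never removes a flagged exon; removing AOH
    support never adds one."""
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 2, 12)
    cohort = _matrix({"S1": vals, "S2": np.full(12, 50.0)})
    panel = _panel(1029, 12)
    loose = exon_deletion_flags(cohort, panel, "S1", AOH, DeletionThresholds(max_rpkm=1.0))
    tight = exon_deletion_flags(cohort, panel, "S1", AOH, DeletionThresholds(max_rpkm=0.5))
    assert (tight["flagged"] <= loose["flagged"]).all()
    none = exon_deletion_flags(cohort, panel, "S1", [], DeletionThresholds(max_rpkm=1.0))
    assert (none["flagged"] <= loose["flagged"]).all()


def test_exon_set_mismatch_rejected():
    cohort = _matrix({"S1": [0.1, 0.1]})
    panel = _panel(10, 1)
    with pytest.raises(ValueError):
        exon_deletion_flags(cohort, panel, "S1", AOH)
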