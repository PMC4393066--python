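"""Domain class labels and coverage summaries."""

import numpy as np
import pandas as pd
import pytest

from isoseg.classify import ClassificationThresholds, classify, coverage_summary


def record(source="chr1", start=1, length=1000, gc=0.4, homogeneity="1", n_seg=False):
    return {
        "source_id": source, "start": start, "end": start + length - 1,
        "length": length, "gc": gc, "gc_std": 0.01,
        "homogeneity": homogeneity, "is_n_segment": n_seg,
    }


def frame(rows):
    return pd.DataFrame(rows)


class TestClassify:
    def test_isochoric_low_band_poor(self):
        out = classify(frame([record(length=300_001, gc=0.35)]))
        row = out.iloc[0]
        assert row["size_class"] == "isochoric"
        assert row["gc_band"] == "low"
        assert row["rich_class"] == "GC-poor"

    def test_isochoric_cut_is_strict(self):
        out = classify(frame([record(length=300_000, gc=0.35)]))
        assert out.iloc[0]["size_class"] == "short"

    def test_long_but_nonhomogeneous_is_not_isochoric(self):
        out = classify(frame([record(length=500_000, homogeneity="0")]))
        assert out.iloc[0]["size_class"] == "short"

    @pytest.mark.parametrize(
        "gc,band", [(0.19, "other"), (0.20, "low"), (0.399, "low"), (0.40, "high"),
                    (0.599, "high"), (0.61, "other")],
    )
    def test_band_edges_half_open(self, gc, band):
        assert classify(frame([record(gc=gc)])).iloc[0]["gc_band"] == band

    @pytest.mark.parametrize("gc,rich", [(0.3762, "GC-poor"), (0.3763, "GC-rich")])
    def test_rich_cut(self, gc, rich):
        assert classify(frame([record(gc=gc)])).iloc[0]["rich_class"] == rich

    def test_n_segment_stratum(self):
        out = classify(frame([record(n_seg=True, gc=0.0, homogeneity="NA")]))
        row = out.iloc[0]
        assert row["size_class"] == "n_island"
        assert row["gc_band"] == "NA"
        assert row["rich_class"] == "NA"

    def test_custom_thresholds(self):
        thr = ClassificationThresholds(isochoric_min=1000, rich_cut=0.5)
        out = classify(frame([record(length=2000, gc=0.45)]), thr)
        assert out.iloc[0]["size_class"] == "isochoric"
        assert out.iloc[0]["rich_class"] == "GC-poor"

    def test_raising_isochoric_min_never_increases_isochoric_coverage(self, rng):
        rows, start = [], 1
        for _ in range(30):
            length = int(rng.integers(50_000, 600_000))
            rows.append(record(start=start, length=length, gc=float(rng.uniform(0.2, 0.6))))
            start += length
        prev = None
        for cut in (100_000, 300_000, 500_000):
            out = classify(frame(rows), ClassificationThresholds(isochoric_min=cut))
            cov = out.loc[out["size_class"] == "isochoric", "length"].sum()
            if prev is not None:
                assert cov <= prev
            prev = cov


class TestCoverageSummary:
    def test_single_domain_full_fraction(self):
        out = coverage_summary(classify(frame([record()])))
        assert out.iloc[0]["fraction"] == 1.0

    def test_two_equal_domains_split_evenly(self):
        rows = [record(length=1000, gc=0.35), record(start=1001, length=1000, gc=0.55, homogeneity="0")]
        out = coverage_summary(classify(frame(rows)), by="rich_class")
        by_class = out[out["source_id"] == "chr1"].set_index("rich_class")["fraction"]
        assert by_class["GC-poor"] == 0.5
        assert by_class["GC-rich"] == 0.5

    def test_fractions_sum_to_one_per_source(self, rng):
        rows = []
        for source in ("chr1", "chr2"):
            start = 1
            for _ in range(10):
                length = int(rng.integers(1000, 400_000))
                rows.append(record(source=source, start=start, length=length,
                                   gc=float(rng.uniform(0.15, 0.65)),
                                   homogeneity=str(int(rng.integers(0, 2)))))
                start += length
        out = coverage_summary(classify(frame(rows)))
        for source, grp in out.groupby("source_id"):
            assert grp["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_known_truth_fractions(self):
        # 10 blocks: 4 of class low / 6 of class high by construction
        rows, start = [], 1
        for i in range(10):
            gc = 0.3 if i < 4 else 0.5
            rows.append(record(start=start, length=10_000, gc=gc))
            start += 10_000
        out = coverage_summary(classify(frame(rows)), by="gc_band")
        tot = out[out["source_id"] == "TOTAL"].set_index("gc_band")["fraction"]
        assert tot["low"] == pytest.approx(0.4)
        assert tot["high"] == pytest.approx(0.6)

    def test_non_tiling_errors(self):
        rows = [record(), record(start=1500, length=1000)]
        with pytest.raises(ValueError, match="tile"):
            coverage_summary(classify(frame(rows)))
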