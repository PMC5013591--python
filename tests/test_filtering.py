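"""Mass-defect / RT / inclusion filtering rules and the stage report."""

import numpy as np
import pandas as pd
import pytest

from mzdefect.chem import mass_defect
from mzdefect.filtering import (
    InclusionList,
    build_report,
    filter_full,
    filter_md,
    filter_md_rt,
    match_inclusion,
)
from mzdefect.threshold import PUBLISHED_LINE


def table(rows):
    return pd.DataFrame(rows, columns=["mz", "rt"])


class TestFilterMd:
    def test_salt_cluster_removed(self):
        kept, removed = filter_md(table([(80.94784, 5.0)]))
        assert len(kept) == 0 and len(removed) == 1

    def test_sodiated_glucose_kept(self):
        kept, removed = filter_md(table([(203.05261, 5.0)]))
        assert len(kept) == 1 and len(removed) == 0

    def test_feature_exactly_on_the_line_is_kept(self):
        # dyadic slope/intercept so threshold(100.5) == defect(100.5) == 0.5
        # exactly in floating point; strict ">" must keep the feature
        from mzdefect.threshold import ThresholdLine

        exact_line = ThresholdLine(2.0**-9, 0.3037109375, (50.0, 750.0))
        mz = 100.5
        assert exact_line.threshold_at(mz) == mass_defect(mz) == 0.5
        kept, removed = filter_md(table([(mz, 1.0)]), line=exact_line)
        assert len(kept) == 1 and len(removed) == 0

    def test_empty_table(self):
        kept, removed = filter_md(table([]))
        assert len(kept) == 0 and len(removed) == 0

    def test_rejects_nan_mz(self):
        with pytest.raises(ValueError):
            filter_md(table([(np.nan, 1.0)]))


class TestFilterMdRt:
    def test_early_above_line_removed(self):
        _, removed = filter_md_rt(table([(80.94784, 0.5)]), rt_cutoff=1.5)
        assert len(removed) == 1

    def test_late_above_line_kept(self):
        # a retained multiply charged peptide survives the RT-aware filter
        kept, _ = filter_md_rt(table([(80.94784, 8.0)]), rt_cutoff=1.5)
        assert len(kept) == 1

    def test_early_below_line_kept(self):
        kept, _ = filter_md_rt(table([(203.05261, 0.5)]), rt_cutoff=1.5)
        assert len(kept) == 1

    def test_cutoff_required_and_positive(self):
        with pytest.raises(ValueError):
            filter_md_rt(table([(100.0, 1.0)]), rt_cutoff=0.0)
        with pytest.raises(ValueError):
            filter_md_rt(table([(100.0, 1.0)]), rt_cutoff=None)


class TestInclusion:
    def test_match_within_ppm(self):
        inc = InclusionList((500.0,), tolerance_ppm=5.0)
        assert match_inclusion([500.0 * (1 + 3e-6)], inc)[0]  # 3 ppm away
        assert not match_inclusion([500.0 * (1 + 8e-6)], inc)[0]  # 8 ppm away

    def test_override_keeps_matching_feature(self):
        mz = 80.94784
        inc = InclusionList((mz * (1 + 3e-6),), tolerance_ppm=5.0)
        kept, removed, _ = filter_full(table([(mz, 0.5)]), rt_cutoff=1.5, inclusion=inc)
        assert len(kept) == 1 and len(removed) == 0

    def test_without_inclusion_same_feature_removed(self):
        kept, removed, _ = filter_full(table([(80.94784, 0.5)]), rt_cutoff=1.5, inclusion=None)
        assert len(kept) == 0 and len(removed) == 1

    def test_invalid_inclusion_rejected(self):
        with pytest.raises(ValueError):
            InclusionList((500.0,), tolerance_ppm=-1.0)
        with pytest.raises(ValueError):
            InclusionList((-10.0,))


class TestPartitionProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_preserves_every_feature(self, seed):
        from mzdefect.synth import SyntheticSpec, generate

        ds = generate(SyntheticSpec(60, 25, 15, n_inclusion_metabolites=5, seed=seed))
        inc = ds.inclusion
        kept, removed, _ = filter_full(ds.table, rt_cutoff=1.35, inclusion=inc)
        assert len(kept) + len(removed) == len(ds.table)
        recombined = pd.concat([kept, removed]).sort_index()
        pd.testing.assert_frame_equal(recombined, ds.table)

    def test_order_preserved(self, small_dataset):
        kept, removed = filter_md(small_dataset.table)
        assert list(kept.index) == sorted(kept.index)
        assert list(removed.index) == sorted(removed.index)

    def test_idempotent(self, small_dataset):
        kept1, _ = filter_md(small_dataset.table)
        kept2, removed2 = filter_md(kept1)
        assert len(removed2) == 0
        pd.testing.assert_frame_equal(kept1, kept2)

    def test_monotone_leniency_of_stages(self, plasma_positive):
        ds = plasma_positive
        kept_md, _ = filter_md(ds.table)
        kept_rt, _ = filter_md_rt(ds.table, rt_cutoff=1.35)
        kept_full, _, _ = filter_full(ds.table, rt_cutoff=1.35, inclusion=ds.inclusion)
        assert set(kept_md.index) <= set(kept_rt.index) <= set(kept_full.index)

    def test_matches_per_feature_predicate_brute_force(self, small_dataset):
        ds = small_dataset
        line = PUBLISHED_LINE
        cutoff = 1.35
        kept, removed, _ = filter_full(ds.table, rt_cutoff=cutoff, inclusion=ds.inclusion)
        for i, row in ds.table.iterrows():
            above = mass_defect(row.mz) > line.threshold_at(row.mz, warn_outside=False)
            early = row.rt <= cutoff
            included = False
            if ds.inclusion is not None:
                included = any(
                    abs(row.mz - t) <= 5e-6 * row.mz for t in ds.inclusion.mz
                )
            expect_removed = above and early and not included
            assert (i in removed.index) == expect_removed


class TestReport:
    @pytest.mark.parametrize(
        "initial,remaining,pct",
        [(2227, 1730, 22.32), (1742, 1107, 36.45), (100, 100, 0.00)],
    )
    def test_percent_removed(self, initial, remaining, pct):
        report = build_report(initial, {"md": remaining})
        assert report.stages[0].percent_removed == pct

    def test_none_stage_always_zero(self):
        frame = build_report(50, {"md": 40}).to_frame()
        assert frame.iloc[0]["filter"] == "None"
        assert frame.iloc[0]["percent_removed"] == 0.00

    def test_mismatched_counts_error(self):
        with pytest.raises(ValueError):
            build_report(10, {"md": 11})

    def test_full_filter_report_stages(self, small_dataset):
        _, _, report = filter_full(
            small_dataset.table, rt_cutoff=1.35, inclusion=small_dataset.inclusion
        )
        names = [s.name for s in report.stages]
        assert names == ["md", "md + RT", "md + RT + inclusion"]
        remaining = [s.remaining for s in report.stages]
        assert remaining == sorted(remaining)  # monotone leniency
        assert report.initial == 100

    def test_report_text_layout(self, small_dataset):
        _, _, report = filter_full(small_dataset.table, rt_cutoff=1.35)
        text = str(report)
        assert "None" in text and "md + RT + inclusion" in text
        assert "0.00" in text
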