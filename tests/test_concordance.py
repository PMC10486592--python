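"""Confusion tables, diagnostics, metric-row reconstruction, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import icrcall as ic
from icrcall.concordance import round_half_up
from icrcall.datasets import (
    planted_cohort_calls,
    published_cohort_counts,
    published_platform_metrics,
)
from icrcall.exceptions import InputError
from icrcall.regions import BinaryStatus


def binary_map(pattern: str) -> dict:
    """'AANN' → {'s0': ALTERED, 's1': ALTERED, 's2': NOT_ALTERED, ...}"""
    m = {"A": BinaryStatus.ALTERED, "N": BinaryStatus.NOT_ALTERED}
    return {f"s{i}": m[c] for i, c in enumerate(pattern)}


class TestConfusion:
    def test_identical_call_sets(self):
        calls = binary_map("AAANNNNNNN")
        t = ic.confusion(calls, dict(calls))
        assert (t.tp, t.fn, t.fp, t.tn) == (3, 0, 0, 7)

    def test_complete_disagreement(self):
        t = ic.confusion(binary_map("AAAAA"), binary_map("NNNNN"))
        assert (t.tp, t.fn, t.fp, t.tn) == (0, 5, 0, 0)

    def test_planted_mixed_table(self):
        ref = binary_map("A" * 15 + "N" * 14)
        test = binary_map("A" * 13 + "N" * 2 + "A" * 5 + "N" * 9)
        t = ic.confusion(ref, test)
        assert (t.tp, t.fn, t.fp, t.tn) == (13, 2, 5, 9)

    def test_mismatched_sample_sets_listed(self):
        with pytest.raises(InputError, match="s2"):
            ic.confusion(binary_map("AA"), {"s0": BinaryStatus.ALTERED,
                                            "s2": BinaryStatus.ALTERED})


class TestDiagnostics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((14, 1, 1, 13), (93.3, 92.9, 93.3, 92.9)),
            ((7, 4, 2, 16), (63.6, 88.9, 77.8, 80.0)),
            ((13, 2, 5, 9), (86.7, 64.3, 72.2, 81.8)),
        ],
    )
    def test_metric_rows_hand_checked(self, counts, expected):
        mets = ic.diagnostics(ic.ConfusionTable(*counts)).rounded(1)
        assert (mets.sensitivity, mets.specificity, mets.ppv, mets.npv) == expected

    def test_agreement_is_overall_accuracy(self):
        mets = ic.diagnostics(ic.ConfusionTable(13, 2, 5, 9))
        assert mets.agreement == pytest.approx(100 * 22 / 29)
        assert round_half_up(mets.agreement, 1) == 75.9

    def test_undefined_ratio_reported_absent(self):
        mets = ic.diagnostics(ic.ConfusionTable(0, 0, 2, 3))
        assert mets.sensitivity is None and mets.npv is not None

    @given(
        tp=st.integers(0, 30), fn=st.integers(0, 30),
        fp=st.integers(0, 30), tn=st.integers(0, 30),
    )
    def test_metric_identities_on_random_tables(self, tp, fn, fp, tn):
        """The five metrics satisfy their defining ratios exactly."""
        if tp + fn + fp + tn == 0:
            return
        t = ic.ConfusionTable(tp, fn, fp, tn)
        m = ic.diagnostics(t)
        if tp + fn:
            assert m.sensitivity == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert m.specificity == pytest.approx(100 * tn / (tn + fp))
        if tp + fp:
            assert m.ppv == pytest.approx(100 * tp / (tp + fp))
        if tn + fn:
            assert m.npv == pytest.approx(100 * tn / (tn + fn))
        assert m.agreement == pytest.approx(100 * (tp + tn) / t.n)


class TestReconstructConfusion:
    @pytest.mark.parametrize(
        "metrics, expected",
        [
            ({"sensitivity": 93.3, "specificity": 92.9, "ppv": 93.3,
              "npv": 92.9}, (14, 1, 1, 13)),
            ({"sensitivity": 63.6, "specificity": 88.9, "ppv": 77.8,
              "npv": 80.0}, (7, 4, 2, 16)),
            ({"sensitivity": 86.7, "specificity": 64.3, "ppv": 72.2,
              "npv": 81.8}, (13, 2, 5, 9)),
        ],
    )
    def test_published_rows_invert_uniquely(self, metrics, expected):
        candidates = ic.reconstruct_confusion(29, metrics)
        assert len(candidates) == 1
        assert candidates[0].counts() == expected

    def test_forced_tiny_table(self):
        got = ic.reconstruct_confusion(2, {"sensitivity": 100, "specificity": 100})
        assert len(got) == 1 and got[0].counts() == (1, 0, 0, 1)

    def test_empty_result_is_valid(self):
        # sensitivity 50 requires an even split of at least 2 positives
        assert ic.reconstruct_confusion(1, {"sensitivity": 50.0,
                                            "specificity": 100.0}) == []

    def test_candidates_round_trip_through_diagnostics(self):
        metrics = {"sensitivity": 86.7, "specificity": 64.3}
        for cand in ic.reconstruct_confusion(29, metrics):
            m = ic.diagnostics(cand)
            assert round_half_up(m.sensitivity, 1) == 86.7
            assert round_half_up(m.specificity, 1) == 64.3

    def test_matches_independent_enumeration(self):
        """Cross-check against a directly coded brute-force search."""
        import itertools

        metrics = {"sensitivity": 63.6, "specificity": 88.9}
        n = 29
        expected = []
        for tp, fn, fp in itertools.product(range(n + 1), repeat=3):
            tn = n - tp - fn - fp
            if tn < 0 or tp + fn == 0 or tn + fp == 0:
                continue
            if (round_half_up(100 * tp / (tp + fn), 1) == 63.6
                    and round_half_up(100 * tn / (tn + fp), 1) == 88.9):
                expected.append((tp, fn, fp, tn))
        got = [c.counts() for c in ic.reconstruct_confusion(n, metrics)]
        assert sorted(got) == sorted(expected)


class TestCohortSummary:
    def test_wilms_tumor_reference_row(self):
        summary = ic.cohort_summary(planted_cohort_calls())
        wt = summary.loc["Wilms tumor"]
        assert wt["characterized"] == 17
        assert wt["icr1_gom"] == 14 and wt["icr1_gom_pct"] == 82.35
        assert wt["icr2_lom"] == 7 and wt["icr2_lom_pct"] == 41.18

    def test_totals_sum_across_strata(self):
        summary = ic.cohort_summary(planted_cohort_calls())
        types = summary.drop(index="TOTAL")
        for col in ("characterized", "icr1_lom", "icr1_gom", "icr2_lom"):
            assert types[col].sum() == summary.loc["TOTAL", col]

    def test_invariant_to_sample_order(self):
        calls = planted_cohort_calls()
        shuffled = calls.sample(frac=1, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            ic.cohort_summary(calls), ic.cohort_summary(shuffled)
        )

    def test_missing_region_call_rejected(self):
        calls = planted_cohort_calls()
        calls.loc[0, "icr2_status"] = np.nan
        with pytest.raises(InputError):
            ic.cohort_summary(calls)


class TestReferenceData:
    def test_cohort_counts_total_99(self):
        counts = published_cohort_counts()
        assert counts["characterized"].sum() == 99
        assert len(counts) == 18

    def test_platform_metric_rows(self):
        mets = published_platform_metrics()
        assert list(mets["n"]) == [29, 29, 29]
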