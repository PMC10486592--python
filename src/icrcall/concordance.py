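"""Cross-platform concordance: 2×2 tables, diagnostic metrics, confusion
reconstruction from printed metrics, and cohort summaries.

Status calls binarize by pooling LOM and GOM into ALTERED.  Diagnostics are
the usual screening-test quantities in percent; "agreement" is overall
accuracy 100·(tp+tn)/n.  ``reconstruct_confusion`` inverts a published
metric row back into the integer table(s) consistent with it, by exhaustive
enumeration — handy for desk-checking reported sensitivity/specificity
against cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping

import pandas as pd

from .exceptions import InputError
from .regions import BinaryStatus, MethStatus, binarize  # re-export binarize

__all__ = [
    "binarize",
    "ConfusionTable",
    "DiagnosticMetrics",
    "confusion",
    "diagnostics",
    "reconstruct_confusion",
    "cohort_summary",
    "round_half_up",
]


def round_half_up(x: float | Fraction, decimals: int = 1) -> float:
    """Decimal half-up rounding (ties away from the lower value)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(str(x))
    q = Decimal(1).scaleb(-decimals)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 concordance counts; the reference assay defines positivity."""

    tp: int
    fn: int
    fp: int
    tn: int
    reference: str = "reference"
    test: str = "test"

    def __post_init__(self) -> None:
        for name, v in (("tp", self.tp), ("fn", self.fn), ("fp", self.fp),
                        ("tn", self.tn)):
            if v < 0:
                raise InputError(f"{name} must be >= 0, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def counts(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fn, self.fp, self.tn)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Screening-test metrics in percent; None where the denominator is 0."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    agreement: float | None

    def rounded(self, decimals: int = 1) -> "DiagnosticMetrics":
        r = lambda v: None if v is None else round_half_up(v, decimals)
        return DiagnosticMetrics(
            r(self.sensitivity), r(self.specificity), r(self.ppv),
            r(self.npv), r(self.agreement)
        )

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "agreement": self.agreement,
        }


def confusion(
    ref_calls: Mapping[str, BinaryStatus],
    test_calls: Mapping[str, BinaryStatus],
    reference: str = "reference",
    test: str = "test",
) -> ConfusionTable:
    """Cross-tabulate two binary call sets over the same samples."""
    ref_ids, test_ids = set(ref_calls), set(test_calls)
    if ref_ids != test_ids:
        only_ref = sorted(ref_ids - test_ids)
        only_test = sorted(test_ids - ref_ids)
        raise InputError(
            f"sample sets differ; only in reference: {only_ref}, "
            f"only in test: {only_test}"
        )
    tp = fn = fp = tn = 0
    for sid in ref_calls:
        r = BinaryStatus(ref_calls[sid]) is BinaryStatus.ALTERED
        t = BinaryStatus(test_calls[sid]) is BinaryStatus.ALTERED
        if r and t:
            tp += 1
        elif r and not t:
            fn += 1
        elif not r and t:
            fp += 1
        else:
            tn += 1
    return ConfusionTable(tp, fn, fp, tn, reference, test)


def diagnostics(table: ConfusionTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and overall agreement (percent)."""
    if table.n < 1:
        raise InputError("empty confusion table")

    def pct(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return DiagnosticMetrics(
        sensitivity=pct(table.tp, table.tp + table.fn),
        specificity=pct(table.tn, table.tn + table.fp),
        ppv=pct(table.tp, table.tp + table.fp),
        npv=pct(table.tn, table.tn + table.fn),
        agreement=pct(table.tp + table.tn, table.n),
    )


_METRIC_FRACTIONS = {
    "sensitivity": lambda tp, fn, fp, tn: (tp, tp + fn),
    "specificity": lambda tp, fn, fp, tn: (tn, tn + fp),
    "ppv": lambda tp, fn, fp, tn: (tp, tp + fp),
    "npv": lambda tp, fn, fp, tn: (tn, tn + fn),
    "agreement": lambda tp, fn, fp, tn: (tp + tn, tp + fn + fp + tn),
}


def reconstruct_confusion(
    n: int,
    reported: Mapping[str, float],
    decimals: int = 1,
) -> list[ConfusionTable]:
    """All integer 2×2 tables of size ``n`` matching the reported metrics.

    A candidate matches when every supplied metric, computed exactly and
    rounded half-up to ``decimals`` places, equals the reported value (and
    is defined).  Returns every candidate; an empty list means the reported
    row is not arithmetically consistent with ``n``.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    unknown = set(reported) - set(_METRIC_FRACTIONS)
    if unknown:
        raise InputError(f"unknown metrics: {sorted(unknown)}")
    if len(reported) < 2:
        raise InputError("supply at least two metrics")
    targets = {k: round_half_up(v, decimals) for k, v in reported.items()}
    out = []
    for tp in range(n + 1):
        for fn in range(n - tp + 1):
            for fp in range(n - tp - fn + 1):
                tn = n - tp - fn - fp
                ok = True
                for name, value in targets.items():
                    num, den = _METRIC_FRACTIONS[name](tp, fn, fp, tn)
                    if den == 0:
                        ok = False
                        break
                    got = round_half_up(Fraction(100 * num, den), decimals)
                    if got != value:
                        ok = False
                        break
                if ok:
                    out.append(ConfusionTable(tp, fn, fp, tn))
    return out


def cohort_summary(calls: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Per-tumor-type counts of ICR1 LOM/GOM and ICR2 LOM with percentages.

    ``calls`` needs columns sample_id, tumor_type, icr1_status, icr2_status.
    Output rows are per type plus a TOTAL row; percentages are of each
    type's characterized count (None where the stratum is empty) and an
    any-ICR1-alteration column pools LOM and GOM.
    """
    required = {"sample_id", "tumor_type", "icr1_status", "icr2_status"}
    missing = required - set(calls.columns)
    if missing:
        raise InputError(f"summary input missing columns: {sorted(missing)}")
    if calls[["icr1_status", "icr2_status"]].isna().any().any():
        bad = calls.loc[
            calls[["icr1_status", "icr2_status"]].isna().any(axis=1), "sample_id"
        ].tolist()
        raise InputError(f"samples missing a region call: {bad}")

    def summarize(group: pd.DataFrame) -> dict[str, object]:
        n = len(group)
        lom1 = int((group["icr1_status"] == MethStatus.LOM.value).sum())
        gom1 = int((group["icr1_status"] == MethStatus.GOM.value).sum())
        lom2 = int((group["icr2_status"] == MethStatus.LOM.value).sum())
        pct = lambda k: None if n == 0 else round_half_up(
            Fraction(100 * k, n), decimals
        )
        return {
            "characterized": n,
            "icr1_lom": lom1,
            "icr1_lom_pct": pct(lom1),
            "icr1_gom": gom1,
            "icr1_gom_pct": pct(gom1),
            "icr1_altered": lom1 + gom1,
            "icr1_altered_pct": pct(lom1 + gom1),
            "icr2_lom": lom2,
            "icr2_lom_pct": pct(lom2),
        }

    rows = {}
    for tumor_type, group in calls.groupby("tumor_type", sort=True):
        rows[tumor_type] = summarize(group)
    rows["TOTAL"] = summarize(calls)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "tumor_type"
    return out
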