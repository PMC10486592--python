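"""MS-MLPA methylation-ratio classification and copy-number calling.

The ME030 kit probes H19 (ICR1) and KvDMR (ICR2).  Band definitions:

* H19: LOM < 40%, normal 41–59%, GOM > 59%.  The unassigned gap
  [40%, 41%) is called NORMAL with a borderline flag.
* KvDMR: LOM < 44%, normal above; there is no GOM category.  Exactly 44%
  is NORMAL with a borderline flag.

Copy-number ratios are classified with conventional MLPA cutoffs
(loss < 0.7, gain > 1.3), configurable — the kit's own cutoffs are not
published alongside the methylation bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .exceptions import InputError
from .regions import MLPA_H19_BAND, MLPA_KVDMR_BAND, MethStatus

logger = logging.getLogger(__name__)

CNV_LOSS_BELOW = 0.7
CNV_GAIN_ABOVE = 1.3


def classify_h19(ratio: float) -> tuple[MethStatus, bool]:
    """Classify an H19/ICR1 methylation ratio; returns (status, borderline)."""
    return MLPA_H19_BAND.classify(ratio)


def classify_kvdmr(ratio: float) -> tuple[MethStatus, bool]:
    """Classify a KvDMR/ICR2 methylation ratio; GOM is never emitted."""
    return MLPA_KVDMR_BAND.classify(ratio)


def call_cnv(
    cn_ratio: float,
    gain_above: float = CNV_GAIN_ABOVE,
    loss_below: float = CNV_LOSS_BELOW,
) -> str:
    """Classify a copy-number ratio into LOSS / NORMAL / GAIN."""
    if cn_ratio < 0:
        raise InputError(f"copy-number ratio must be >= 0, got {cn_ratio}")
    if cn_ratio < loss_below:
        return "LOSS"
    if cn_ratio > gain_above:
        return "GAIN"
    return "NORMAL"


@dataclass(frozen=True)
class MlpaSampleResult:
    sample_id: str
    h19_ratio: float
    kvdmr_ratio: float
    h19_status: MethStatus
    kvdmr_status: MethStatus
    h19_borderline: bool
    kvdmr_borderline: bool
    cnv_calls: Mapping[str, str]


def _rescale_if_percent(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Auto-rescale 0–100 inputs to fractions, with a logged warning."""
    vals = df[cols].to_numpy(dtype=float)
    if vals.size and vals.max() > 1.5:
        logger.warning(
            "MS-MLPA methylation ratios look like percentages (max=%.3g); "
            "rescaling by 1/100",
            vals.max(),
        )
        df = df.copy()
        df[cols] = df[cols] / 100.0
    return df


def call_mlpa(
    table: pd.DataFrame,
    gain_above: float = CNV_GAIN_ABOVE,
    loss_below: float = CNV_LOSS_BELOW,
) -> pd.DataFrame:
    """Classify each row of an MS-MLPA ratio table.

    Expects columns sample_id, h19_ratio, kvdmr_ratio and optionally
    ``cnv_<region>`` copy-number columns.  Returns a tidy frame with one
    row per sample carrying both region statuses and CNV calls.
    """
    required = {"sample_id", "h19_ratio", "kvdmr_ratio"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"MS-MLPA table missing columns: {sorted(missing)}")
    table = _rescale_if_percent(table, ["h19_ratio", "kvdmr_ratio"])
    cnv_cols = [c for c in table.columns if c.startswith("cnv_")]
    rows = []
    for _, rec in table.iterrows():
        h19_status, h19_bl = classify_h19(float(rec["h19_ratio"]))
        kv_status, kv_bl = classify_kvdmr(float(rec["kvdmr_ratio"]))
        row = {
            "sample_id": rec["sample_id"],
            "h19_ratio": float(rec["h19_ratio"]),
            "kvdmr_ratio": float(rec["kvdmr_ratio"]),
            "h19_status": h19_status.value,
            "kvdmr_status": kv_status.value,
            "h19_borderline": h19_bl,
            "kvdmr_borderline": kv_bl,
        }
        for c in cnv_cols:
            row[f"{c}_call"] = call_cnv(float(rec[c]), gain_above, loss_below)
        rows.append(row)
    return pd.DataFrame(rows)


def write_calls(calls: pd.DataFrame, tsv_path: str | Path,
                json_path: str | Path | None = None) -> None:
    calls.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        calls.to_json(json_path, orient="records", indent=2)
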