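"""Region-level methylation calling from array beta values.

Probes inside each ICR are averaged per sample and the regional mean is
classified against the array band: mean beta in [0.40, 0.60] is NORMAL,
below 0.40 is LOM, above 0.60 is GOM.  Quality control (detection p-values,
normalization, probe masking) is assumed to have happened upstream; missing
beta values are simply dropped from the mean and counted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import BetaMatrix, RegionCall, calls_to_frame
from .exceptions import EmptyRegionError, InputError, NoDataError
from .regions import DEFAULT_REGIONS, EPIC_BAND, IcrRegion, MethStatus, in_region


def select_region_probes(matrix: BetaMatrix, region: IcrRegion) -> list[str]:
    """Probes of the matrix inside ``region``, ordered by genomic position."""
    man = matrix.manifest
    chrom_ok = man["chrom"] == region.chrom
    pos = man["pos"].astype(int)
    inside = chrom_ok & (pos >= region.start) & (pos <= region.end)
    hits = man.loc[inside].sort_values("pos")
    probes = [p for p in hits.index if p in set(matrix.probe_ids)]
    if not probes:
        raise EmptyRegionError(region.name)
    # membership must agree with the scalar predicate
    assert all(in_region(int(man.loc[p, "pos"]), region) for p in probes)
    return probes


def region_mean(
    matrix: BetaMatrix, probes: Sequence[str], sample_id: str
) -> tuple[float, int]:
    """Unweighted mean over non-missing probe values; returns (mean, n_used)."""
    if len(probes) == 0:
        raise InputError("empty probe list")
    vals = matrix.beta.loc[sample_id, list(probes)].to_numpy(dtype=float)
    used = np.isfinite(vals)
    if not used.any():
        raise NoDataError(
            f"all {len(probes)} probe values missing for sample {sample_id!r}"
        )
    return float(vals[used].mean()), int(used.sum())


def classify_epic(mean_level: float) -> MethStatus:
    """Classify a regional mean beta against the array band."""
    status, _ = EPIC_BAND.classify(mean_level)
    return status


def call_epic(
    matrix: BetaMatrix, regions: Sequence[IcrRegion] = DEFAULT_REGIONS
) -> pd.DataFrame:
    """Call every sample at every region.

    Returns a tidy frame (sample_id, region, mean_level, status,
    n_probes_used, borderline).  Row/column order of the input does not
    affect the calls.
    """
    calls: list[RegionCall] = []
    for region in regions:
        probes = select_region_probes(matrix, region)
        for sample_id in matrix.sample_ids:
            mean, n_used = region_mean(matrix, probes, sample_id)
            status, borderline = EPIC_BAND.classify(mean)
            calls.append(
                RegionCall(sample_id, region.name, mean, status, n_used, borderline)
            )
    return calls_to_frame(calls)


def write_calls(calls: pd.DataFrame, tsv_path: str | Path,
                json_path: str | Path | None = None) -> None:
    calls.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        calls.to_json(json_path, orient="records", indent=2)
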