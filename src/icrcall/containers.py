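"""Core data containers shared across calling stages."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .regions import MethStatus


@dataclass
class BetaMatrix:
    """Samples × probes methylation fractions plus a coordinate manifest.

    ``beta``: DataFrame indexed by sample_id, columns are probe ids, values
    in [0,1] (NaN = missing).  ``manifest``: DataFrame indexed by probe_id
    with columns chrom, pos (1-based) and optionally region.
    """

    beta: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise InputError("beta values outside [0,1]")
        if self.beta.index.has_duplicates:
            raise InputError("duplicate sample_ids in beta matrix")
        missing = set(self.beta.columns) - set(self.manifest.index)
        if missing:
            raise InputError(
                f"probes absent from manifest: {sorted(missing)[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.columns)

    def to_tsv(self, beta_path: str | Path, manifest_path: str | Path) -> None:
        self.beta.to_csv(beta_path, sep="\t", index_label="sample_id")
        self.manifest.to_csv(manifest_path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, beta_path: str | Path, manifest_path: str | Path) -> "BetaMatrix":
        beta = pd.read_csv(beta_path, sep="\t", index_col="sample_id")
        manifest = pd.read_csv(manifest_path, sep="\t", index_col="probe_id")
        return cls(beta=beta, manifest=manifest)


@dataclass(frozen=True)
class RegionCall:
    """Per-sample, per-region methylation status with the level behind it."""

    sample_id: str
    region: str
    mean_level: float
    status: MethStatus
    n_probes_used: int
    borderline: bool = False

    def __post_init__(self) -> None:
        if self.n_probes_used < 1:
            raise InputError("n_probes_used must be >= 1")


def calls_to_frame(calls) -> pd.DataFrame:
    """Tabulate RegionCalls (one row per sample × region)."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "region": [c.region for c in calls],
            "mean_level": [c.mean_level for c in calls],
            "status": [c.status.value for c in calls],
            "n_probes_used": [c.n_probes_used for c in calls],
            "borderline": [c.borderline for c in calls],
        }
    )


@dataclass(frozen=True)
class DpcrWell:
    """Two-channel dPCR partition counts for one well."""

    sample_id: str
    meth_positives: int
    unmeth_positives: int
    total_partitions: int = 26_000
    vpf: float = 1.0
    partition_volume_nl: float = 0.34

    def __post_init__(self) -> None:
        if self.total_partitions < 1:
            raise InputError("total_partitions must be >= 1")
        for name, k in (("meth_positives", self.meth_positives),
                        ("unmeth_positives", self.unmeth_positives)):
            if not 0 <= k <= self.total_partitions:
                raise InputError(
                    f"{name}={k} outside [0, total_partitions={self.total_partitions}]"
                )
        if self.vpf <= 0:
            raise InputError("vpf must be > 0")
        if self.partition_volume_nl <= 0:
            raise InputError("partition_volume_nl must be > 0")
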