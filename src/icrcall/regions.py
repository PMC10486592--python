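"""Genomic definitions, threshold bands and the methylation-status vocabulary.

The two imprinted control regions (ICRs) at 11p15.5 govern parent-of-origin
expression of *IGF2/H19* (ICR1) and the *KCNQ1OT1/KvDMR* cluster (ICR2).  A
normally imprinted CpG carries one methylated allele, so its expected
methylation fraction is ~0.5; departures are classified as loss (LOM) or gain
(GOM) of methylation relative to a platform-specific band around 0.5.

Coordinates are stored 1-based inclusive (GRCh37/hg19), matching how array
manifests print them; conversion to 0-based half-open intervals happens only
at I/O boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import InputError


class MethStatus(str, enum.Enum):
    """Region-level methylation status relative to the imprinted ~50% baseline."""

    LOM = "LOM"
    NORMAL = "NORMAL"
    GOM = "GOM"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class BinaryStatus(str, enum.Enum):
    """Binarized status: LOM and GOM pool into ALTERED."""

    ALTERED = "ALTERED"
    NOT_ALTERED = "NOT_ALTERED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Rank order used for monotonicity checks (LOM < NORMAL < GOM).
STATUS_ORDER: Mapping[MethStatus, int] = {
    MethStatus.LOM: 0,
    MethStatus.NORMAL: 1,
    MethStatus.GOM: 2,
}


@dataclass(frozen=True)
class IcrRegion:
    """An imprinted control region on hg19, 1-based inclusive coordinates."""

    name: str
    chrom: str
    start: int
    end: int
    n_expected_probes: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(
                f"region {self.name!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.n_expected_probes < 1:
            raise InputError(f"region {self.name!r}: n_expected_probes must be >= 1")

    def to_half_open(self) -> tuple[str, int, int]:
        """Return (chrom, start0, end) as a 0-based half-open interval."""
        return self.chrom, self.start - 1, self.end


def in_region(position: int, region: IcrRegion) -> bool:
    """True iff ``position`` (1-based) lies within ``region``, both ends inclusive."""
    if position < 1:
        raise InputError(f"position must be >= 1, got {position}")
    return region.start <= position <= region.end


#: Default ICR definitions: ICR1 upstream of H19, ICR2 at KvDMR.
ICR1 = IcrRegion("ICR1", "chr11", 2019379, 2020007, 17)
ICR2 = IcrRegion("ICR2", "chr11", 2720540, 2721394, 7)
DEFAULT_REGIONS: tuple[IcrRegion, ...] = (ICR1, ICR2)


def regions_from_config(entries) -> tuple[IcrRegion, ...]:
    """Build a region set from a list of mapping entries.

    Each entry needs name, chrom, start, end; ``n_expected_probes`` defaults
    to the default region of the same name, else is required.
    """
    defaults = {r.name: r for r in DEFAULT_REGIONS}
    out = []
    seen = set()
    for e in entries:
        name = e["name"]
        if name in seen:
            raise InputError(f"duplicate region name {name!r}")
        seen.add(name)
        n = e.get("n_expected_probes")
        if n is None:
            if name not in defaults:
                raise InputError(f"region {name!r}: n_expected_probes required")
            n = defaults[name].n_expected_probes
        out.append(IcrRegion(name, e["chrom"], int(e["start"]), int(e["end"]), int(n)))
    if not out:
        raise InputError("empty region set")
    return tuple(out)


@dataclass(frozen=True)
class ThresholdBand:
    """A platform band mapping a methylation fraction to LOM/NORMAL/GOM.

    ``lom_below``: values strictly below are LOM.  ``gom_above``: values
    strictly above are GOM (absent for assays that define no GOM category).
    Everything else is NORMAL.  Two optional borderline rules flag NORMAL
    calls that sit in a zone the assay definition leaves ambiguous:
    ``borderline_below`` flags NORMAL values strictly below it, and
    ``flag_at_lom_bound`` flags a NORMAL value exactly at ``lom_below``.

    Boundary inclusivity is a package decision (the published band
    definitions do not state it); ``boundary_rule`` records it in prose so it
    travels with serialized output.
    """

    lom_below: float
    gom_above: float | None = None
    borderline_below: float | None = None
    flag_at_lom_bound: bool = False
    boundary_rule: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.lom_below <= 1.0:
            raise InputError(f"lom_below outside [0,1]: {self.lom_below}")
        if self.gom_above is not None:
            if not 0.0 <= self.gom_above <= 1.0:
                raise InputError(f"gom_above outside [0,1]: {self.gom_above}")
            if self.lom_below > self.gom_above:
                raise InputError("lom_below must be <= gom_above")

    def classify(self, value: float) -> tuple[MethStatus, bool]:
        """Classify a fraction; returns (status, borderline flag)."""
        if not 0.0 <= value <= 1.0:
            raise InputError(f"methylation fraction outside [0,1]: {value}")
        if value < self.lom_below:
            return MethStatus.LOM, False
        if self.gom_above is not None and value > self.gom_above:
            return MethStatus.GOM, False
        borderline = False
        if self.borderline_below is not None and value < self.borderline_below:
            borderline = True
        if self.flag_at_lom_bound and value == self.lom_below:
            borderline = True
        return MethStatus.NORMAL, borderline


#: EPIC array band: mean beta in [0.40, 0.60] is normal, below/above is LOM/GOM.
EPIC_BAND = ThresholdBand(
    lom_below=0.40,
    gom_above=0.60,
    boundary_rule="0.40 and 0.60 inclusive in NORMAL (decision; source band "
    "states 'between 40% and 60%' without inclusivity)",
)

#: MS-MLPA H19/ICR1 band: LOM <40%, normal 41-59%, GOM >59%; the gap
#: [0.40, 0.41) is classified NORMAL with a borderline flag.
MLPA_H19_BAND = ThresholdBand(
    lom_below=0.40,
    gom_above=0.59,
    borderline_below=0.41,
    boundary_rule="[0.40, 0.41) is NORMAL+borderline (the assay definition "
    "leaves it unassigned); 0.59 inclusive in NORMAL",
)

#: MS-MLPA KvDMR/ICR2 band: LOM <44%, normal otherwise; no GOM category.
MLPA_KVDMR_BAND = ThresholdBand(
    lom_below=0.44,
    gom_above=None,
    flag_at_lom_bound=True,
    boundary_rule="exactly 0.44 is NORMAL+borderline (assay defines normal "
    ">44% and LOM <44%, leaving 44% unassigned); no GOM category",
)

#: cfDNA dPCR ICR1 band: methylated fraction in [0.40, 0.61] is normal.
DPCR_BAND = ThresholdBand(
    lom_below=0.40,
    gom_above=0.61,
    boundary_rule="0.40 and 0.61 inclusive in NORMAL ('between 40% and 61%' "
    "read inclusively)",
)

DEFAULT_BANDS: Mapping[str, ThresholdBand] = {
    "epic": EPIC_BAND,
    "mlpa_h19": MLPA_H19_BAND,
    "mlpa_kvdmr": MLPA_KVDMR_BAND,
    "dpcr_icr1": DPCR_BAND,
}


def binarize(status: MethStatus) -> BinaryStatus:
    """Pool LOM and GOM into ALTERED; NORMAL maps to NOT_ALTERED."""
    status = MethStatus(status)
    if status is MethStatus.NORMAL:
        return BinaryStatus.NOT_ALTERED
    return BinaryStatus.ALTERED
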