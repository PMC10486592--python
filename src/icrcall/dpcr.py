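"""Digital-PCR quantification of cfDNA ICR1 methylation.

A two-probe assay reads bisulfite-converted cfDNA in ~26,000-partition
nanoplates: one channel counts partitions positive for the methylated
CTCF-site-6 sequence, the other for the unmethylated sequence.  Positive
counts convert to mean copies per partition by the standard Poisson
occupancy correction

    lambda = -ln(1 - k/N)

(the vendor software performs this internally; the formula is the standard
dPCR estimator, reconstructed here).  The methylated fraction
``lambda_m / (lambda_m + lambda_u)`` is scale-free: the volume precision
factor (VPF) and partition volume affect only absolute concentration,
never the fraction or the status call.  ICR1 imprinting is NORMAL for
fractions in [0.40, 0.61], LOM below, GOM above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .containers import DpcrWell
from .exceptions import InputError, NoTemplateError, SaturationError
from .regions import DPCR_BAND, MethStatus


def poisson_lambda(positives: int, total: int) -> float:
    """Mean copies per partition from the positive-partition count."""
    if total < 1:
        raise InputError("total partitions must be >= 1")
    if not 0 <= positives <= total:
        raise InputError(f"positives={positives} outside [0, {total}]")
    if positives == total:
        raise SaturationError(
            f"all {total} partitions positive; lambda is undefined"
        )
    return -math.log(1.0 - positives / total)


def methylated_fraction(lambda_meth: float, lambda_unmeth: float) -> float:
    """Fraction of template molecules that are methylated."""
    if lambda_meth < 0 or lambda_unmeth < 0:
        raise InputError("lambda values must be >= 0")
    if lambda_meth + lambda_unmeth == 0:
        raise NoTemplateError("both channels empty; fraction undefined")
    return lambda_meth / (lambda_meth + lambda_unmeth)


def absolute_concentration(
    lam: float, partition_volume_nl: float = 0.34, vpf: float = 1.0
) -> float:
    """Copies per microliter: lambda over the VPF-scaled partition volume.

    The VPF multiplies the effective partition volume, so doubling it
    halves the reported concentration.  1 nL⁻¹ = 1000 µL⁻¹.
    """
    if lam < 0:
        raise InputError("lambda must be >= 0")
    if partition_volume_nl <= 0:
        raise InputError("partition volume must be > 0")
    if vpf <= 0:
        raise InputError("vpf must be > 0")
    return lam / (partition_volume_nl * vpf) * 1000.0


def classify_dpcr_icr1(fraction: float) -> MethStatus:
    """Call ICR1 imprinting status from the cfDNA methylated fraction."""
    status, _ = DPCR_BAND.classify(fraction)
    return status


@dataclass(frozen=True)
class DpcrResult:
    sample_id: str
    lambda_meth: float
    lambda_unmeth: float
    meth_fraction: float
    status: MethStatus
    conc_meth_per_ul: float
    conc_unmeth_per_ul: float
    saturated_meth: bool = False
    saturated_unmeth: bool = False


def quantify_well(well: DpcrWell) -> DpcrResult:
    """Quantify one well; a saturated channel is flagged, with NaN lambda."""
    sat_m = well.meth_positives == well.total_partitions
    sat_u = well.unmeth_positives == well.total_partitions
    lam_m = float("nan") if sat_m else poisson_lambda(
        well.meth_positives, well.total_partitions
    )
    lam_u = float("nan") if sat_u else poisson_lambda(
        well.unmeth_positives, well.total_partitions
    )
    if sat_m or sat_u:
        frac = float("nan")
        status = None
    else:
        frac = methylated_fraction(lam_m, lam_u)
        status = classify_dpcr_icr1(frac)
    conc = lambda lam: (
        float("nan")
        if math.isnan(lam)
        else absolute_concentration(lam, well.partition_volume_nl, well.vpf)
    )
    return DpcrResult(
        sample_id=well.sample_id,
        lambda_meth=lam_m,
        lambda_unmeth=lam_u,
        meth_fraction=frac,
        status=status,
        conc_meth_per_ul=conc(lam_m),
        conc_unmeth_per_ul=conc(lam_u),
        saturated_meth=sat_m,
        saturated_unmeth=sat_u,
    )


def quantify_table(table: pd.DataFrame,
                   partition_volume_nl: float = 0.34) -> pd.DataFrame:
    """Quantify a well table (sample_id, ch_meth_positives,
    ch_unmeth_positives, total_partitions, vpf)."""
    required = {"sample_id", "ch_meth_positives", "ch_unmeth_positives",
                "total_partitions"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"dPCR table missing columns: {sorted(missing)}")
    rows = []
    for _, rec in table.iterrows():
        well = DpcrWell(
            sample_id=str(rec["sample_id"]),
            meth_positives=int(rec["ch_meth_positives"]),
            unmeth_positives=int(rec["ch_unmeth_positives"]),
            total_partitions=int(rec["total_partitions"]),
            vpf=float(rec.get("vpf", 1.0)),
            partition_volume_nl=partition_volume_nl,
        )
        res = quantify_well(well)
        rows.append(
            {
                "sample_id": res.sample_id,
                "lambda_meth": res.lambda_meth,
                "lambda_unmeth": res.lambda_unmeth,
                "meth_fraction": res.meth_fraction,
                "status": res.status.value if res.status else "UNDEFINED",
                "conc_meth_per_ul": res.conc_meth_per_ul,
                "conc_unmeth_per_ul": res.conc_unmeth_per_ul,
                "saturated_meth": res.saturated_meth,
                "saturated_unmeth": res.saturated_unmeth,
            }
        )
    return pd.DataFrame(rows)


def primer_fasta() -> str:
    """The CTCF-site-6 primer/probe sequences shipped for documentation."""
    return resources.files("icrcall").joinpath("data/ctcf6_primers.fasta").read_text()


def write_results(results: pd.DataFrame, tsv_path: str | Path,
                  json_path: str | Path | None = None) -> None:
    results.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        results.to_json(json_path, orient="records", indent=2)
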