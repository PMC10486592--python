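"""End-to-end orchestration: simulate → call (three platforms) → cluster →
concordance → report, with a validated config and a reproducibility manifest.

Every stage writes plain-text outputs (TSV/CSV/JSON/newick) into the run
directory and registers them in ``run_manifest.json`` together with the
seed, the full config, its hash and package versions.  The same config and
seed reproduce byte-identical data files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster import bootstrap_consistency, complete_linkage, pearson_distance, plot_heatmap
from .concordance import (
    ConfusionTable,
    binarize,
    cohort_summary,
    confusion,
    diagnostics,
)
from .containers import BetaMatrix
from .dpcr import classify_dpcr_icr1, quantify_table
from .epic import call_epic
from .exceptions import IcrCallError, InputError
from .mlpa import call_mlpa
from .regions import DEFAULT_REGIONS, MethStatus, regions_from_config
from .simulate import (
    DEFAULT_MLPA_SUBSET,
    Genotype,
    NoiseModel,
    SyntheticTruth,
    simulate_beta_cohort,
    simulate_dpcr_cohort,
    simulate_mlpa,
    truths_to_frame,
    write_cohort,
)

logger = logging.getLogger(__name__)


class StageError(IcrCallError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class CohortGroup:
    """A homogeneous block of simulated samples."""

    tumor_type: str
    genotype: str
    n: int
    purity: float = 1.0
    cfdna_tumor_fraction: float = 0.0


@dataclass
class RunConfig:
    """Validated configuration for an end-to-end run."""

    cohort: list[CohortGroup]
    seed: int = 0
    outdir: str = "icrcall_run"
    noise_precision: float | None = 200.0
    probe_profile_sd: float = 0.15
    bootstrap: int = 1000
    dpcr_total_partitions: int = 26_000
    dpcr_copies_per_partition: float = 0.1
    dpcr_vpf: float = 1.0
    rounding_decimals: int = 1
    heatmap: bool = False
    regions: list[Mapping] | None = None
    mlpa_subset: Mapping[str, Sequence[int]] | None = None

    def validate(self) -> None:
        if not self.cohort:
            raise InputError("config defines zero cohort groups")
        total = sum(g.n for g in self.cohort)
        if total < 1:
            raise InputError("config defines zero samples")
        for g in self.cohort:
            Genotype(g.genotype)
            if g.n < 0:
                raise InputError(f"negative group size for {g.tumor_type}")
            if not 0 <= g.purity <= 1 or not 0 <= g.cfdna_tumor_fraction <= 1:
                raise InputError("purity and cfdna_tumor_fraction must be in [0,1]")
        if self.bootstrap < 1:
            raise InputError("bootstrap count must be >= 1")
        if self.dpcr_total_partitions < 1:
            raise InputError("dpcr_total_partitions must be >= 1")
        if self.dpcr_copies_per_partition <= 0:
            raise InputError("dpcr_copies_per_partition must be > 0")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        groups = [CohortGroup(**g) for g in d.pop("cohort", [])]
        return cls(cohort=groups, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def region_set(self):
        if self.regions is None:
            return DEFAULT_REGIONS
        return regions_from_config(self.regions)

    def build_truths(self) -> list[SyntheticTruth]:
        truths = []
        counter: dict[str, int] = {}
        for g in self.cohort:
            for _ in range(g.n):
                counter[g.tumor_type] = counter.get(g.tumor_type, 0) + 1
                truths.append(
                    SyntheticTruth(
                        sample_id=f"{g.tumor_type}-{counter[g.tumor_type]:02d}",
                        tumor_type=g.tumor_type,
                        genotype=Genotype(g.genotype),
                        purity=g.purity,
                        cfdna_tumor_fraction=g.cfdna_tumor_fraction,
                    )
                )
        return truths


def default_demo_config(outdir: str = "icrcall_run", seed: int = 0) -> RunConfig:
    """29-sample demo cohort: 15 ICR1 GOM, 11 ICR2 LOM, 3 normal."""
    return RunConfig(
        cohort=[
            CohortGroup("WT", Genotype.ICR1_GOM.value, 15, 1.0, 0.7),
            CohortGroup("HB", Genotype.ICR2_LOM.value, 11, 1.0, 0.7),
            CohortGroup("ES", Genotype.NORMAL.value, 3, 1.0, 0.0),
        ],
        seed=seed,
        outdir=outdir,
    )


def _status_map(df: pd.DataFrame, id_col: str, status_col: str) -> dict:
    return {
        str(r[id_col]): binarize(MethStatus(r[status_col]))
        for _, r in df.iterrows()
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the run manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = config.region_set()
    noise = NoiseModel(
        precision=config.noise_precision,
        probe_profile_sd=config.probe_profile_sd,
    )
    subset = config.mlpa_subset or DEFAULT_MLPA_SUBSET
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(np.random.default_rng(s).integers(2**31 - 1)) for s in seeds]
    files: dict[str, str] = {}
    stage = "simulate"
    try:
        truths = config.build_truths()
        beta = simulate_beta_cohort(truths, regions, noise, seed=stage_seed[0])
        mlpa_table = simulate_mlpa(truths, subset, noise, seed=stage_seed[1],
                                   regions=regions)
        dpcr_table = simulate_dpcr_cohort(
            truths,
            total_partitions=config.dpcr_total_partitions,
            copies_per_partition=config.dpcr_copies_per_partition,
            seed=stage_seed[2],
            vpf=config.dpcr_vpf,
        )
        files.update(write_cohort(outdir, truths, beta, mlpa_table,
                                  dpcr_table, config.seed))

        stage = "call-epic"
        epic_calls = call_epic(beta, regions)
        epic_calls.to_csv(outdir / "epic_calls.tsv", sep="\t", index=False)
        files["epic_calls"] = str(outdir / "epic_calls.tsv")

        stage = "call-mlpa"
        mlpa_calls = call_mlpa(mlpa_table)
        mlpa_calls.to_csv(outdir / "mlpa_calls.tsv", sep="\t", index=False)
        files["mlpa_calls"] = str(outdir / "mlpa_calls.tsv")

        stage = "call-dpcr"
        dpcr_results = quantify_table(dpcr_table)
        dpcr_results.to_csv(outdir / "dpcr_results.tsv", sep="\t", index=False)
        files["dpcr_results"] = str(outdir / "dpcr_results.tsv")

        stage = "cluster"
        tree = complete_linkage(pearson_distance(beta.beta))
        (outdir / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
        tree.merge_table().to_csv(outdir / "merges.tsv", sep="\t", index=False)
        consistency = bootstrap_consistency(
            beta.beta, n_bootstrap=config.bootstrap, seed=stage_seed[3]
        )
        consistency.to_frame().to_csv(
            outdir / "bootstrap_consistency.tsv", sep="\t", index=False
        )
        files["dendrogram"] = str(outdir / "dendrogram.nwk")
        files["merges"] = str(outdir / "merges.tsv")
        files["bootstrap_consistency"] = str(outdir / "bootstrap_consistency.tsv")
        if config.heatmap:
            plot_heatmap(beta.beta, tree, outdir / "heatmap.png",
                         manifest=beta.manifest)
            files["heatmap"] = str(outdir / "heatmap.png")

        stage = "concordance"
        report = build_concordance_report(epic_calls, mlpa_calls, dpcr_results)
        (outdir / "concordance.json").write_text(
            json.dumps(report, indent=2) + "\n"
        )
        files["concordance"] = str(outdir / "concordance.json")

        stage = "report"
        truth_frame = truths_to_frame(truths)
        summary_in = pd.DataFrame(
            {
                "sample_id": mlpa_calls["sample_id"],
                "tumor_type": truth_frame.set_index("sample_id").loc[
                    mlpa_calls["sample_id"], "tumor_type"
                ].to_numpy(),
                "icr1_status": mlpa_calls["h19_status"],
                "icr2_status": mlpa_calls["kvdmr_status"],
            }
        )
        summary = cohort_summary(summary_in, decimals=config.rounding_decimals)
        summary.to_csv(outdir / "cohort_summary.tsv", sep="\t")
        files["cohort_summary"] = str(outdir / "cohort_summary.tsv")
        metrics_rows = []
        for name, rep in report.items():
            row = {"comparison": name, "n": rep["n"], **rep["metrics"]}
            metrics_rows.append(row)
        pd.DataFrame(metrics_rows).to_csv(
            outdir / "platform_metrics.tsv", sep="\t", index=False
        )
        files["platform_metrics"] = str(outdir / "platform_metrics.tsv")
    except Exception as exc:  # noqa: BLE001 - stage attribution
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": {
            "icrcall": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": files,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def build_concordance_report(
    epic_calls: pd.DataFrame,
    mlpa_calls: pd.DataFrame,
    dpcr_results: pd.DataFrame,
) -> dict:
    """Cross-platform 2×2 tables and diagnostics.

    Technical comparisons take the array as reference against MS-MLPA at
    both ICRs; the biological comparison takes tumor MS-MLPA as reference
    against cfDNA dPCR at ICR1.
    """
    epic1 = _status_map(epic_calls[epic_calls["region"] == "ICR1"],
                        "sample_id", "status")
    epic2 = _status_map(epic_calls[epic_calls["region"] == "ICR2"],
                        "sample_id", "status")
    mlpa1 = _status_map(mlpa_calls, "sample_id", "h19_status")
    mlpa2 = _status_map(mlpa_calls, "sample_id", "kvdmr_status")
    usable = dpcr_results[dpcr_results["status"] != "UNDEFINED"]
    dpcr1 = _status_map(usable, "sample_id", "status")
    report = {}
    comparisons = [
        ("ICR1 Technical (EPIC/MS-MLPA)", epic1, mlpa1),
        ("ICR2 Technical (EPIC/MS-MLPA)", epic2, mlpa2),
        ("ICR1 Biological (MS-MLPA/cfDNA)",
         {k: v for k, v in mlpa1.items() if k in dpcr1}, dpcr1),
    ]
    for name, ref, test in comparisons:
        table = confusion(ref, test)
        mets = diagnostics(table).rounded(1)
        report[name] = {
            "n": table.n,
            "table": {"tp": table.tp, "fn": table.fn, "fp": table.fp,
                      "tn": table.tn},
            "metrics": mets.as_dict(),
        }
    return report


def longitudinal_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-patient cfDNA series: status per timepoint plus change flags.

    ``results`` needs columns patient_id, timepoint, meth_fraction with
    timepoints strictly increasing within each patient.
    """
    required = {"patient_id", "timepoint", "meth_fraction"}
    missing = required - set(results.columns)
    if missing:
        raise InputError(f"longitudinal input missing columns: {sorted(missing)}")
    if len(results) == 0:
        raise InputError("empty longitudinal series")
    rows = []
    for patient, group in results.groupby("patient_id", sort=True):
        tps = group["timepoint"].to_numpy()
        if not (np.diff(tps) > 0).all():
            raise InputError(
                f"timepoints for patient {patient!r} are not strictly increasing"
            )
        statuses = [classify_dpcr_icr1(float(f)) for f in group["meth_fraction"]]
        for i, ((_, rec), status) in enumerate(zip(group.iterrows(), statuses)):
            rows.append(
                {
                    "patient_id": patient,
                    "timepoint": rec["timepoint"],
                    "meth_fraction": float(rec["meth_fraction"]),
                    "status": status.value,
                    "status_changed": i > 0 and statuses[i] != statuses[i - 1],
                }
            )
    return pd.DataFrame(rows)
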