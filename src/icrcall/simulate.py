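"""Synthetic 11p15 cohort generator with known ground truth.

Emulates the three data layers the calling stages consume — an array-style
beta matrix with a coordinate manifest, an MS-MLPA methylation-ratio table,
and two-channel dPCR partition counts — from per-sample imprinting genotypes.

The statistical structure mirrors what the downstream analysis assumes:

* a normally imprinted CpG has expected methylation 0.5 (one methylated
  allele); a GOM region moves toward 0.9 and a LOM region toward 0.1 in pure
  tumor, with tumor purity mixing linearly back toward 0.5;
* per-CpG baseline offsets, shared by all samples of a cohort and centered
  within each region, give same-genotype samples the correlated profiles that
  array data show (individual CpGs of a DMR sit reproducibly above or below
  the regional mean); the offsets are attenuated by ``4·m·(1−m)`` so fully
  (un)methylated regions show the compressed between-CpG spread seen near the
  boundaries of the beta scale;
* cfDNA is a mixture of normal (50% methylated) and tumor-derived fragments;
  each dPCR channel occupies partitions with Poisson statistics.

Sampling noise is a mean-parameterized beta distribution: given mean ``m``
and precision ``s``, draws come from Beta(m·s, (1−m)·s).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .regions import DEFAULT_REGIONS, IcrRegion
from .containers import BetaMatrix, DpcrWell


class Genotype(str, enum.Enum):
    """Imprinting genotype of a tumor at the two 11p15 ICRs."""

    NORMAL = "NORMAL"
    ICR1_GOM = "ICR1_GOM"
    ICR1_LOM = "ICR1_LOM"
    ICR2_LOM = "ICR2_LOM"
    ICR1_GOM_ICR2_LOM = "ICR1_GOM_ICR2_LOM"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Expected methylation fraction per genotype and region in pure tumor.
#: The band definitions only give thresholds; these target levels are the
#: generator's own convention (config-exposed through NoiseModel).
DEFAULT_TARGET_MEANS: Mapping[str, Mapping[str, float]] = {
    Genotype.NORMAL.value: {"ICR1": 0.5, "ICR2": 0.5},
    Genotype.ICR1_GOM.value: {"ICR1": 0.9, "ICR2": 0.5},
    Genotype.ICR1_LOM.value: {"ICR1": 0.1, "ICR2": 0.5},
    Genotype.ICR2_LOM.value: {"ICR1": 0.5, "ICR2": 0.1},
    Genotype.ICR1_GOM_ICR2_LOM.value: {"ICR1": 0.9, "ICR2": 0.1},
}

#: Tumor allelic methylation at ICR1 as seen by the cfDNA assay (the dPCR
#: probes interrogate the allele directly, so GOM/LOM are fully 1.0/0.0).
DPCR_TUMOR_METH: Mapping[str, float] = {
    Genotype.NORMAL.value: 0.5,
    Genotype.ICR1_GOM.value: 1.0,
    Genotype.ICR1_LOM.value: 0.0,
    Genotype.ICR2_LOM.value: 0.5,
    Genotype.ICR1_GOM_ICR2_LOM.value: 1.0,
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated sample.

    ``altered_probes`` optionally restricts the epimutation to a subset of
    CpG indices per region (0-based, in genomic order); CpGs outside the
    subset stay at the normal 0.5 baseline.  This models partial-region
    epimutations, which an MS-MLPA probe subset can miss entirely.
    """

    sample_id: str
    tumor_type: str = "NA"
    genotype: Genotype = Genotype.NORMAL
    purity: float = 1.0
    cfdna_tumor_fraction: float = 0.0
    altered_probes: Mapping[str, tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise InputError(f"purity outside [0,1]: {self.purity}")
        if not 0.0 <= self.cfdna_tumor_fraction <= 1.0:
            raise InputError(
                f"cfdna_tumor_fraction outside [0,1]: {self.cfdna_tumor_fraction}"
            )
        object.__setattr__(self, "genotype", Genotype(self.genotype))


@dataclass(frozen=True)
class NoiseModel:
    """Noise for the beta-like sampling of methylation fractions.

    precision
        Dispersion of the mean-parameterized beta distribution (larger is
        quieter; sd ≈ sqrt(m(1−m)/(precision+1))).  ``None`` disables
        sampling entirely (the zero-noise limit).
    probe_profile_sd
        Standard deviation of the per-CpG baseline offsets (centered within
        each region, shared across samples, attenuated near 0/1).  0 disables
        them; they are also absent in the zero-noise limit.
    target_means
        genotype → region → expected methylation fraction in pure tumor.
    """

    precision: float | None = 100.0
    probe_profile_sd: float = 0.15
    target_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_TARGET_MEANS
    )

    def __post_init__(self) -> None:
        if self.precision is not None and self.precision <= 0:
            raise InputError(f"precision must be > 0, got {self.precision}")
        if self.probe_profile_sd < 0:
            raise InputError("probe_profile_sd must be >= 0")
        for g, per_region in self.target_means.items():
            for r, m in per_region.items():
                if not 0.0 < m < 1.0:
                    raise InputError(f"target mean for {g}/{r} outside (0,1): {m}")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        """The zero-noise limit: deterministic means, no probe offsets."""
        return cls(precision=None, probe_profile_sd=0.0)


def mix_purity(tumor_level: float, normal_level: float, purity: float):
    """Convex combination purity·tumor + (1−purity)·normal; accepts arrays."""
    for name, v in (("tumor_level", tumor_level), ("normal_level", normal_level),
                    ("purity", purity)):
        arr = np.asarray(v, dtype=float)
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise InputError(f"{name} outside [0,1]: {v}")
    out = np.asarray(purity) * np.asarray(tumor_level) + (
        1.0 - np.asarray(purity)
    ) * np.asarray(normal_level)
    return float(out) if out.ndim == 0 else out


def _probe_positions(region: IcrRegion) -> np.ndarray:
    """Evenly spaced integer probe positions spanning the region."""
    return np.unique(
        np.linspace(region.start, region.end, region.n_expected_probes).round()
    ).astype(int)


def build_manifest(regions: Sequence[IcrRegion] = DEFAULT_REGIONS) -> pd.DataFrame:
    """Synthetic probe manifest: probe_id, chrom, pos (1-based), region."""
    rows = []
    for region in regions:
        for i, pos in enumerate(_probe_positions(region)):
            rows.append(
                {
                    "probe_id": f"cg_{region.name}_{i + 1:02d}",
                    "chrom": region.chrom,
                    "pos": int(pos),
                    "region": region.name,
                }
            )
    return pd.DataFrame(rows)


def _tumor_probe_levels(
    truth: SyntheticTruth,
    region: IcrRegion,
    noise: NoiseModel,
) -> np.ndarray:
    """Per-CpG methylation of the pure tumor: genotype target at altered
    CpGs, 0.5 elsewhere."""
    target = noise.target_means[truth.genotype.value].get(region.name, 0.5)
    levels = np.full(region.n_expected_probes, target, dtype=float)
    if truth.altered_probes is not None and region.name in truth.altered_probes:
        mask = np.zeros(region.n_expected_probes, dtype=bool)
        idx = list(truth.altered_probes[region.name])
        if idx and (min(idx) < 0 or max(idx) >= region.n_expected_probes):
            raise InputError(
                f"altered_probes indices out of range for {region.name}"
            )
        mask[idx] = True
        levels[~mask] = 0.5
    return levels


def _probe_offsets(
    regions: Sequence[IcrRegion], noise: NoiseModel, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One centered offset vector per region, shared by the whole cohort."""
    offsets = {}
    for region in regions:
        if noise.probe_profile_sd > 0:
            off = rng.normal(0.0, noise.probe_profile_sd, region.n_expected_probes)
            off -= off.mean()
        else:
            off = np.zeros(region.n_expected_probes)
        offsets[region.name] = off
    return offsets


def _sample_beta(mean: np.ndarray, noise: NoiseModel, rng: np.random.Generator):
    if noise.precision is None:
        return mean.copy()
    a = mean * noise.precision
    b = (1.0 - mean) * noise.precision
    return rng.beta(a, b)


def simulate_beta_cohort(
    truths: Sequence[SyntheticTruth],
    regions: Sequence[IcrRegion] = DEFAULT_REGIONS,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> BetaMatrix:
    """Simulate an array-style beta matrix for a cohort.

    The expected regional mean for each sample equals
    ``mix_purity(genotype target, 0.5, purity)``; per-CpG means add the
    cohort's centered probe offsets, attenuated by ``4·m·(1−m)``.
    """
    if not truths:
        raise InputError("empty truth list")
    ids = [t.sample_id for t in truths]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sample_id in truth list")
    manifest = build_manifest(regions)
    rng = np.random.default_rng(seed)
    offsets = _probe_offsets(regions, noise, rng)
    cols: dict[str, np.ndarray] = {}
    by_region = []
    for region in regions:
        means = np.empty((len(truths), region.n_expected_probes))
        for i, truth in enumerate(truths):
            tumor = _tumor_probe_levels(truth, region, noise)
            mixed = mix_purity(tumor, np.full_like(tumor, 0.5), truth.purity)
            mu = mixed + offsets[region.name] * 4.0 * mixed * (1.0 - mixed)
            means[i] = np.clip(mu, 0.02, 0.98)
        by_region.append(_sample_beta(means, noise, rng))
    values = np.hstack(by_region)
    beta = pd.DataFrame(values, index=pd.Index(ids, name="sample_id"),
                        columns=manifest["probe_id"].tolist())
    return BetaMatrix(beta=beta, manifest=manifest.set_index("probe_id"))


#: Default MS-MLPA probe subset: evenly spaced CpG indices within each region
#: (4 of the 17 ICR1 CpGs, 3 of the 7 ICR2 CpGs).  The real kit's probe
#: placement is not public; evenly spaced coverage is the neutral choice and
#: is configurable.
DEFAULT_MLPA_SUBSET: Mapping[str, tuple[int, ...]] = {
    "ICR1": (0, 5, 11, 16),
    "ICR2": (0, 3, 6),
}


def simulate_mlpa(
    truths: Sequence[SyntheticTruth],
    probe_subset: Mapping[str, Sequence[int]] = DEFAULT_MLPA_SUBSET,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    regions: Sequence[IcrRegion] = DEFAULT_REGIONS,
) -> pd.DataFrame:
    """Simulate an MS-MLPA ratio table (sample_id, h19_ratio, kvdmr_ratio,
    cnv_ICR1, cnv_ICR2).

    Ratios are means over the probed CpG subset of per-CpG draws around the
    genotype/purity means.  MS-MLPA normalization removes probe-level
    baseline structure, so the array probe offsets are not applied here.
    Copy-number ratios default to 1.0 (two copies); copy-number-driven
    methylation change is not simulated.
    """
    if not truths:
        raise InputError("empty truth list")
    region_by_name = {r.name: r for r in regions}
    for name, idx in probe_subset.items():
        if len(idx) == 0:
            raise InputError(f"empty MS-MLPA probe subset for {name}")
        r = region_by_name[name]
        if min(idx) < 0 or max(idx) >= r.n_expected_probes:
            raise InputError(f"probe_subset indices out of range for {name}")
    rng = np.random.default_rng(seed)
    ratio_col = {"ICR1": "h19_ratio", "ICR2": "kvdmr_ratio"}
    rows = []
    for truth in truths:
        row: dict[str, object] = {"sample_id": truth.sample_id,
                                  "tumor_type": truth.tumor_type}
        for name, idx in probe_subset.items():
            region = region_by_name[name]
            tumor = _tumor_probe_levels(truth, region, noise)
            mixed = mix_purity(tumor, np.full_like(tumor, 0.5), truth.purity)
            sub = np.clip(mixed[list(idx)], 0.02, 0.98)
            row[ratio_col.get(name, f"{name.lower()}_ratio")] = float(
                _sample_beta(sub, noise, rng).mean()
            )
        for name in region_by_name:
            row[f"cnv_{name}"] = 1.0
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_dpcr(
    truth: SyntheticTruth,
    total_partitions: int = 26_000,
    copies_per_partition: float = 0.1,
    seed: int = 0,
    vpf: float = 1.0,
) -> DpcrWell:
    """Simulate one two-channel dPCR well from cfDNA.

    The cfDNA methylated fraction is ``p = (1−f)·0.5 + f·m_t`` with ``f`` the
    tumor fraction and ``m_t`` the tumor allelic methylation at ICR1.  Each
    channel's positive partitions are binomial with occupancy probability
    ``1 − exp(−rate·c)`` where the total concentration ``c`` (mean copies per
    partition) splits as ``p·c`` methylated, ``(1−p)·c`` unmethylated.
    """
    if total_partitions < 1:
        raise InputError("total_partitions must be >= 1")
    if copies_per_partition <= 0:
        raise InputError("copies_per_partition must be > 0")
    f = truth.cfdna_tumor_fraction
    m_t = DPCR_TUMOR_METH[truth.genotype.value]
    p = (1.0 - f) * 0.5 + f * m_t
    rng = np.random.default_rng(seed)
    q_meth = 1.0 - np.exp(-p * copies_per_partition)
    q_unmeth = 1.0 - np.exp(-(1.0 - p) * copies_per_partition)
    return DpcrWell(
        sample_id=truth.sample_id,
        meth_positives=int(rng.binomial(total_partitions, q_meth)),
        unmeth_positives=int(rng.binomial(total_partitions, q_unmeth)),
        total_partitions=total_partitions,
        vpf=vpf,
    )


def simulate_dpcr_cohort(
    truths: Sequence[SyntheticTruth],
    total_partitions: int = 26_000,
    copies_per_partition: float = 0.1,
    seed: int = 0,
    vpf: float = 1.0,
) -> pd.DataFrame:
    """Simulate one well per sample; returns the dPCR well table."""
    if not truths:
        raise InputError("empty truth list")
    seeds = np.random.SeedSequence(seed).spawn(len(truths))
    wells = [
        simulate_dpcr(t, total_partitions, copies_per_partition,
                      seed=np.random.default_rng(s).integers(2**31 - 1), vpf=vpf)
        for t, s in zip(truths, seeds)
    ]
    return pd.DataFrame(
        {
            "sample_id": [w.sample_id for w in wells],
            "ch_meth_positives": [w.meth_positives for w in wells],
            "ch_unmeth_positives": [w.unmeth_positives for w in wells],
            "total_partitions": [w.total_partitions for w in wells],
            "vpf": [w.vpf for w in wells],
        }
    )


def truths_to_frame(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    """Tabular view of the ground truth for recovery tests and output."""
    return pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in truths],
            "tumor_type": [t.tumor_type for t in truths],
            "genotype": [t.genotype.value for t in truths],
            "purity": [t.purity for t in truths],
            "cfdna_tumor_fraction": [t.cfdna_tumor_fraction for t in truths],
        }
    )


def write_cohort(
    outdir: str | Path,
    truths: Sequence[SyntheticTruth],
    beta: BetaMatrix,
    mlpa: pd.DataFrame,
    dpcr: pd.DataFrame,
    seed: int,
) -> dict[str, str]:
    """Write all simulated layers to ``outdir``; returns path mapping.

    Also records the seed in a small run-manifest JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "truth": outdir / "truth.tsv",
        "beta_matrix": outdir / "beta_matrix.tsv",
        "manifest": outdir / "probe_manifest.tsv",
        "mlpa": outdir / "mlpa_ratios.tsv",
        "dpcr": outdir / "dpcr_wells.csv",
        "simulate_manifest": outdir / "simulate_manifest.json",
    }
    truths_to_frame(truths).to_csv(paths["truth"], sep="\t", index=False)
    beta.to_tsv(paths["beta_matrix"], paths["manifest"])
    mlpa.to_csv(paths["mlpa"], sep="\t", index=False)
    dpcr.to_csv(paths["dpcr"], index=False)
    manifest = {
        "seed": seed,
        "n_samples": len(truths),
        "files": {k: str(v) for k, v in paths.items() if k != "simulate_manifest"},
    }
    paths["simulate_manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}
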