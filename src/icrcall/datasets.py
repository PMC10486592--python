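"""Built-in reference tables from the published 99-tumor pediatric series.

These are the printed cohort-level numbers the package's desk-scale checks
run against: per-tumor-type counts of ICR1/ICR2 methylation alterations in
99 sporadic embryonic tumors, and the cross-platform diagnostic-metric rows
for the 29 samples assayed on all platforms.  Counts are stored as
integers; percentages are always recomputed from counts.
"""

from __future__ import annotations

import io

import pandas as pd

from .regions import MethStatus

# characterized, ICR1 LOM, ICR1 GOM, ICR2 LOM per tumor type
_COHORT_COUNTS_TSV = """\
tumor_type	characterized	icr1_lom	icr1_gom	icr2_lom
Atypical teratoid rhabdoid tumor	2	0	0	0
Clear cell sarcoma of the kidney	2	0	0	0
Diffuse midline glioma H3 K27-altered	3	0	1	0
Embryonal rhabdomyosarcoma	4	0	4	3
Ewing sarcoma	17	0	0	0
Ganglioneuroblastoma	1	0	0	0
Hepatoblastoma	3	0	2	2
Medulloblastoma, unclassified	8	3	0	0
Medulloblastoma_G34	12	7	1	1
Medulloblastoma_SHH	4	1	1	0
Medulloblastoma_WNT	5	1	1	0
Neuroblastoma	16	0	7	1
Osteoblastoma	1	0	0	0
Pineoblastoma_FOXR2	1	1	0	0
Pineoblastoma_GRP1A	1	1	0	0
Pleomorphic xanthoastrocytoma	1	0	0	0
Rhabdomyosarcoma	1	0	1	0
Wilms tumor	17	0	14	7
"""

# n, sensitivity, specificity, PPV, NPV (percent) per platform comparison
_PLATFORM_METRICS_TSV = """\
comparison	n	sensitivity	specificity	ppv	npv
ICR1 Technical (EPIC/MS-MLPA)	29	93.3	92.9	93.3	92.9
ICR2 Technical (EPIC/MS-MLPA)	29	63.6	88.9	77.8	80.0
ICR1 Biological (MS-MLPA/cfDNA)	29	86.7	64.3	72.2	81.8
"""


def published_cohort_counts() -> pd.DataFrame:
    """Per-tumor-type alteration counts for the 99-tumor reference series."""
    return pd.read_csv(io.StringIO(_COHORT_COUNTS_TSV), sep="\t")


def published_platform_metrics() -> pd.DataFrame:
    """Published cross-platform diagnostic metrics (n=29 per comparison)."""
    return pd.read_csv(io.StringIO(_PLATFORM_METRICS_TSV), sep="\t")


def planted_cohort_calls() -> pd.DataFrame:
    """Expand the reference counts into a deterministic per-sample call table.

    Within each tumor type, ICR1 LOM samples come first, then ICR1 GOM, then
    normals; ICR2 LOM is assigned preferentially to samples that already
    carry an ICR1 alteration (matching the reported co-occurrence of ICR1
    GOM with ICR2 LOM).  Useful as a planted input for summary round-trips.
    """
    counts = published_cohort_counts()
    rows = []
    for _, rec in counts.iterrows():
        n = int(rec["characterized"])
        lom1, gom1, lom2 = int(rec["icr1_lom"]), int(rec["icr1_gom"]), int(
            rec["icr2_lom"]
        )
        icr1 = (
            [MethStatus.LOM.value] * lom1
            + [MethStatus.GOM.value] * gom1
            + [MethStatus.NORMAL.value] * (n - lom1 - gom1)
        )
        # ICR2 LOM sits on the ICR1-altered samples first (GOM before LOM,
        # mirroring the GOM+LOM co-occurrence), then on normals
        order = (
            list(range(lom1, lom1 + gom1))
            + list(range(lom1))
            + list(range(lom1 + gom1, n))
        )
        icr2 = [MethStatus.NORMAL.value] * n
        for i in order[:lom2]:
            icr2[i] = MethStatus.LOM.value
        slug = "".join(
            w[0] for w in str(rec["tumor_type"]).replace("_", " ").split()
        ).upper()
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{slug}-{i + 1:02d}",
                    "tumor_type": rec["tumor_type"],
                    "icr1_status": icr1[i],
                    "icr2_status": icr2[i],
                }
            )
    return pd.DataFrame(rows)
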