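# Methods

## Scope and model

icrcall operates at the level of *regional* methylation status at the two
11p15.5 imprinted control regions, on GRCh37/hg19 coordinates:

* ICR1 (H19/IGF2): chr11:2,019,379–2,020,007, covered by 17 array CpGs;
* ICR2 (KvDMR/KCNQ1OT1): chr11:2,720,540–2,721,394, covered by 7 CpGs.

Coordinates are stored 1-based inclusive, as array manifests print them;
conversion to 0-based half-open happens only at I/O boundaries. Region sets
are configurable; the defaults above are hard-coded.

The biological model is the standard imprinting one: a normally imprinted
CpG carries one methylated allele, so its expected methylation fraction is
0.5. An epimutation moves the regional level toward 1 (gain, GOM) or 0
(loss, LOM). All callers threshold a regional summary statistic against a
platform band; the bands themselves are the published interpretation rules
(array: 0.40/0.60; MS-MLPA H19: 0.40/0.59; MS-MLPA KvDMR: 0.44, no GOM
category; cfDNA dPCR at ICR1: 0.40/0.61).

### Boundary decisions

The published band definitions never state inclusivity at any cutoff, and
the H19 band has a genuinely unassigned zone (LOM < 40 %, normal 41–59 %).
icrcall's decisions, recorded in each band's `boundary_rule` string:

* array and dPCR cutoffs are inclusive in NORMAL;
* H19 values in [0.40, 0.41) are NORMAL with a `borderline` flag
  (conservative: no fourth status is invented);
* KvDMR exactly 0.44 is NORMAL with a `borderline` flag;
* binarization pools LOM and GOM into ALTERED.

### dPCR quantification

Positive-partition counts convert to mean copies per partition by the
standard Poisson occupancy estimator λ = −ln(1 − k/N). The vendor software
performs this internally; the formula here is a reconstruction of that
standard estimator, not a published equation. A fully positive channel
(k = N) is flagged saturated and yields no λ. The methylated fraction
λ_m/(λ_m + λ_u) is invariant to any joint rescaling of the two channels, so
the volume precision factor (VPF, default 1.0) and partition volume
(default 0.34 nL, typical for 26k nanoplates) enter only the absolute
concentration λ/(volume · VPF), reported but never used for status calling.

### Clustering and bootstrap support

Samples are compared by Pearson correlation distance d = 1 − r over their
joint 24-CpG profile and agglomerated with complete linkage
(scipy.cluster.hierarchy does the agglomeration; with tie-free distances
the merge sequence is the unique complete-linkage solution, and scipy's
deterministic ordering resolves the measure-zero tie cases). Cluster
stability is the ordinary bootstrap probability: resample the CpG columns
with replacement — features, as pvclust resamples — rebuild the tree, and
count the fraction of trees containing each original cluster as an exact
leaf set. The multiscale (AU) correction is not implemented; reported
values are plain BP, stated in the output metadata. Default B = 1000.
A bootstrap resample that leaves a profile constant (undefined correlation)
counts as supporting no cluster.

### Concordance arithmetic

Diagnostics follow the usual screening-test definitions in percent, with
"agreement" = 100·(tp + tn)/n. Undefined ratios (zero denominator) are
reported as absent, never as zero. Rounding throughout is decimal half-up
at the printed precision (1 decimal for metric rows, 2 for cohort
percentages), computed on exact integer fractions to avoid float-tie
artifacts. `reconstruct_confusion` enumerates every non-negative integer
(tp, fn, fp, tn) summing to n (C(n+3, 3) tuples ≈ 5 000 at n = 29) and
keeps those whose exactly-computed, half-up-rounded metrics equal all the
supplied values; it returns every candidate, so uniqueness is a checkable
outcome rather than an assumption. Note one consequence of strict half-up:
a stored reference count of 7/17 renders as 41.18 %, where truncation
would give 41.17 %.

In cross-platform comparisons the array is the reference against MS-MLPA
(technical), and tumor MS-MLPA is the reference against cfDNA dPCR
(biological).

## Synthetic cohorts

The generator exists so that every stage is testable against known ground
truth. Each sample carries a genotype from {NORMAL, ICR1_GOM, ICR1_LOM,
ICR2_LOM, ICR1_GOM_ICR2_LOM}, a tumor purity, and a cfDNA tumor fraction.

**Target levels.** Pure-tumor regional methylation defaults to 0.9 (GOM),
0.1 (LOM), 0.5 (normal). The published rules give only thresholds, not
levels; these defaults place altered regions well inside their bands while
leaving purity dilution meaningful, and are config-exposed
(`NoiseModel.target_means`).

**Purity mixing.** The observed level is the convex combination
purity·tumor + (1 − purity)·0.5, applied per CpG. Mosaic/heterogeneous
cases are represented by intermediate purity (no spatial substructure is
modeled).

**Noise.** Methylation fractions are drawn from a mean-parameterized beta
distribution, Beta(m·s, (1 − m)·s) with precision s (respecting the [0,1]
support; sd ≈ √(m(1−m)/(s+1))). Defaults: s = 100 for array-like data
(per-CpG sd ≈ 0.05 at m = 0.5), s = 200 where a quiet assay is wanted.
`NoiseModel.noiseless()` gives the deterministic limit.

**Per-CpG baseline structure.** Real array data show reproducible per-CpG
offsets around the regional mean (probe affinity plus genuine inter-CpG
variation within a DMR); without them, same-genotype samples would have
uncorrelated profiles and correlation-based clustering of a "normal" group
would be meaningless. The generator therefore draws one offset vector per
region per cohort (normal, sd 0.15 by default), *centers it within each
region* (so regional means stay exactly on target, and chance covariance
with the genotype step pattern vanishes) and attenuates it by 4·m·(1−m)
(fully methylated or unmethylated regions show compressed between-CpG
spread). Per-CpG means are clipped to [0.02, 0.98]; when a large offset
draw engages the clip the regional mean can shift by a few thousandths.
The MS-MLPA simulator does *not* apply these offsets: MLPA normalization
removes probe-level baselines, and its ratios are means over the probed
CpG subset only.

**MS-MLPA probe subset.** The kit's CpG placement is not public; the
default subset is evenly spaced (CpG indices 0, 5, 11, 16 of ICR1; 0, 3, 6
of ICR2), configurable. A per-truth `altered_probes` mask restricts an
epimutation to chosen CpGs, which reproduces the known detect/miss
discordance: a partial-region LOM is seen by the array's regional mean but
reported NORMAL by MS-MLPA whenever the probed subset misses the altered
CpGs.

**cfDNA.** A single tumor-fraction scalar f mixes tumor allelic
methylation at ICR1 (1.0 for GOM, 0.0 for LOM, 0.5 normal — the dPCR assay
reads the allele directly) with the 0.5 background:
p = (1 − f)·0.5 + f·m_t. Channel positives are binomial with occupancy
1 − exp(−p·c) and 1 − exp(−(1 − p)·c) at total concentration c copies per
partition (default 0.1) over N = 26 000 partitions. No fragment-length,
shedding or copy-number modeling.

### What passing tests do and do not show

The generator reproduces the *statistical shape* the analysis assumes —
bimodal/intermediate beta levels per genotype, purity dilution toward 0.5,
correlated within-genotype profiles, two-channel Poisson occupancy. It
does not emulate raw-intensity artifacts, detection failures, normalization
residuals, cross-reactive probes, copy-number-driven methylation change, or
real inter-patient heterogeneity. Recovery results on synthetic cohorts
therefore validate the calling/clustering arithmetic and its thresholds,
not the wet-lab robustness of the assays.

One quantified fragility worth knowing: at noise precision 200 a normal
KvDMR ratio (0.5, aggregate sd ≈ 0.02 over 3 probes) sits ~3 sd above the
0.44 LOM cutoff, so roughly one cohort in twenty miscalls a single sample;
ICR2 LOM rates on 29-sample cohorts can be off by one sample at unlucky
seeds. H19 margins are ≥ 4σ and effectively never flip.

## Problem sizes and numerical choices

Recovery tests use cohorts of 200 samples (5 seeds) for array calling,
B = 1000 bootstrap over 40 samples for cluster support, and 500 replicates
per methylated-fraction level for the dPCR round-trip (±0.03 tolerance at
N = 26 000, c = 0.1 — about three binomial standard errors). The brute-force
agglomeration oracle runs to n = 6; reconstruction enumerates all 4 960
tables at n = 29. Ties in agglomeration are avoided in fixtures (distinct
distances); rounding ties are resolved half-up on exact fractions. The
whole suite runs in a few seconds.

## Known limitations

* BP, not AU: bootstrap support values are the ordinary bootstrap
  proportion and are known to be conservative relative to pvclust's AU
  p-values for small feature counts.
* Upstream QC (detection p-values, normalization, probe masking, manual
  dPCR thresholding) is out of scope; inputs are taken as clean.
* No liftover; coordinates are hg19 only.
* The cohort summary recomputes percentages from integer counts; published
  tables that used truncation or contain typos will differ in the last
  digit, and a narrative ICR2 alteration rate that disagrees with its own
  column sum (14.6 % vs 14/99 = 14.1 %) is reported as recomputed.
* No confidence intervals on diagnostic metrics, and no clinical covariate
  association testing.
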