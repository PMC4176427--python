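# Methods

## The summarization model

A 450k-style experiment is a pair of probes × samples intensity matrices,
methylated (M) and unmethylated (U). `methylqc` derives three standard
measures per probe and sample:

* copy number `CN = M + U` — proportional to locus DNA abundance, the
  basis of sex prediction via X/Y dosage;
* Beta value `Beta = M / (M + U + offset)` — the methylation proportion
  in [0, 1). The offset (default **100** intensity units) regularizes
  low-intensity probes; the platform-standard value is kept as a
  parameter and recorded in the archive's provenance block;
* M-value `M-val = log2((M + ε) / (U + ε))` with ε = **1**, the
  variance-stabilized counterpart of Beta. For externally normalized Beta
  input the M-value is the logit, `log2(Beta / (1 − Beta))`, with Beta
  clipped to [1e−6, 1 − 1e−6] to avoid infinities. Both constants are
  stored in provenance.

Each measure is reduced, per sample, to a **quantile vector** on a fixed
grid of 500 evenly spaced probabilities including 0 and 1, using the
type-7 (linear interpolation) convention, `h = (n−1)p + 1`. Quantiles are
computed within six probe strata: autosomal Infinium I split by color
channel (IGrn, IRed), autosomal Infinium II, pooled chrX, pooled chrY,
and all-autosomal. The two chemistries have systematically different
Beta/M-value distributions, so mixing them hides channel-specific
artifacts; sex-chromosome strata pool both chemistries because the sex
predictor wants every X/Y probe. Whether to split chrX/chrY further by
chemistry was an open choice; pooling is recorded in the archive metadata
so the convention is always inspectable.

A stratum with no probes (e.g. a manifest without chrY) is recorded as
empty with a warning rather than an error, so partial manifests remain
usable; operations that require the stratum (sex prediction, density
curves) then fail with a named error.

### Reading medians from the grid

The 500-point grid `linspace(0, 1, 500)` does not contain p = 0.5
exactly. Medians (QC scatter, sex prediction) are therefore obtained by
linear interpolation of the stored quantile function at p = 0.5. The
stored function is itself piecewise linear in p, so the interpolation
error is bounded by one grid step of the quantile function,
`Q(0.5 + 1/499) − Q(0.5 − 1/499)` — negligible relative to the log2
medians being compared (observed ≲ 0.01 log2 units on 1,600-probe
strata), and the oracle tests bound it explicitly per sample.

### Archive format and determinism

A summary is one `.zip` holding `metadata.json` (schema version, label
raw/normalized, parameter record, sample IDs, quantile grid, phenotype
column dtypes) plus one TSV per (stratum, measure), control summaries,
phenotypes and PCA tables. Floats are written as shortest round-trip
decimal strings and re-read with round-trip parsing, zip entries carry a
fixed timestamp, and strata are stored as an ordered list — so
write → read → write is byte-identical and the stored object is
bit-for-bit reproducible. Size grows with samples × grid, not probes;
measured: a 100,000-probe, 20-sample archive is within ~1.2% of the
1,000-probe archive (the residual comes from the list of selected PCA
probe IDs, which caps at `n_top`).

## Sample QC

Per sample, `median_channel_intensities` reports log2 of the median raw
M and U intensity over all autosomal probes. `flag_low_quality` flags a
sample when the mean of the two values falls below a cutoff, default
**10.5** — an explicit, testable stand-in for the eyeballed selection
common in practice; it sits ~0.8 log2 units below the typical synthetic
cohort (medians ≈ 11.3) and is exposed as a parameter everywhere. A zero
median is floored at 1 intensity unit before log2 and flagged as
`zero_median`. Flagging is monotone in the cutoff by construction.

Density curves are rebuilt from the stored 500-point quantile vector
treated as an equal-weight pseudo-sample, with a Gaussian kernel and
Silverman's rule bandwidth `0.9 · min(sd, IQR/1.34) · n^(−1/5)` computed
on that pseudo-sample (floor `1e−6 · max(1, |c|)` for a constant vector
c). This is what makes plotting work from the compact summary alone. The
fidelity test compares the reconstructed curve to a KDE of the full
probe-level matrix **at the same bandwidth**: the comparison isolates
what quantile compression loses (measured < 0.2% of peak height at
10,000 probes). Comparing against a full-sample Silverman bandwidth
instead would mostly measure the n-dependence of the bandwidth rule —
about a 1.8× narrower kernel at 10,000 vs 500 points — not the quality of
the summary.

## Sex prediction

`xy_diff = log2(median CN on chrY) − log2(median CN on chrX)`. Log scale
stabilizes the measure across arrays of different overall brightness and
makes the AUTO cutoff translation-equivariant. Females sit near 0 −
log2-X-dosage, males are shifted up by the Y dosage and down-shifted X
(≈ +2.5 in the simulation: +1.5 from Y, +1 from halved X). The AUTO
cutoff runs 1-D 2-means with deterministic initialization at the min and
max of the diffs, Lloyd iterations to convergence, cutoff at the midpoint
of the final centers; the cluster with the larger center is male, and a
diff exactly at the cutoff is called male (documented tie-break). Manual
cutoffs reproduce the AUTO labels whenever they fall in the gap between
the two clusters. Mismatches against reported sex are exported with
reason `sex_mismatch`.

## PCA and design confounding

PCA runs on the `n_top` (default **20,000**) autosomal probes with the
largest across-sample population variance (ties at the boundary broken
lexicographically by probe ID). Probes are mean-centered but not scaled —
Beta values already share one scale — and scores come from the SVD of the
centered samples × probes matrix, retaining `min(10, samples − 1)`
components, with each score column's sign fixed so its largest-magnitude
entry is positive (bit-reproducible archives). `pc_association` runs a
one-way ANOVA of each score column on a categorical covariate; perfect
separation (zero within-group variance) is reported as p = 0 with a
`degenerate` flag. Under the null the p-values are uniform (KS ≈ 0.02–0.04
over 1,000 simulated datasets). The slide layout parser assumes the
450k 6 × 2 geometry (`R01C01`–`R06C02`); the geometry is a module constant.

## Synthetic data

The generator emulates the features the QC pipeline is designed to
detect, with one RNG stream and a fixed draw order (probes → samples →
controls) so a seed pins the whole dataset:

* per-probe methylation state from a trimodal mixture — unmethylated
  (mode 0.1), methylated (0.9), hemimethylated (0.5) at weights
  0.45/0.45/0.10, each mode with sd 0.03;
* per-probe brightness lognormal around `baseline_intensity` (default
  5,000, log2-sd 0.5), and multiplicative lognormal noise per channel
  with log2-sd `noise_sd_log2` (default 0.3). The two channels draw
  independent noise, so observed Beta values are noisy as on real arrays
  (a single shared factor would cancel out of Beta exactly);
* sex dosage: male chrY copy number × 2^1.5, chrX halved;
* batch: an additive Beta shift (clipped to [0, 1]) on a random fraction
  of autosomal probes, applied to samples of the second batch label and
  propagated to M/U with CN unchanged — the batch signal lives purely at
  the methylation level, which is what the PCA should find;
* failed arrays: all intensities multiplied by `low_quality_factor`
  (default 0.15, ≈ −2.7 log2 units, well below the 10.5 flag cutoff);
* NEGATIVE controls lognormal around 2% of baseline, plus a bright
  bisulfite-conversion control type.

Presets pin the three demonstration conditions: `clean_small` (2,000
probes, 8 samples, nothing injected), `fig2_batch` (20 samples on two
plates, Beta shift 0.1 on 30% of probes), `fig4_sex` (40 samples,
sex separation 1.5 log2 units, noise 0.3, one flipped sex label).

**What the simulation does not model**: probe cross-hybridization,
SNP-affected probes, dye bias beyond the I/II stratification, detection
p-values/beadcounts, spatial slide artifacts, and realistic correlation
structure between neighboring CpGs. Passing recovery tests therefore
show the pipeline's logic is correct under its stated model, not that
the default cutoffs are optimal for any particular real cohort.

## Problem sizes and numerical notes

The test suite and the acceptance script run desk-scale versions of each
analysis: 700–10,000 probes and 8–40 samples per cohort, 20 replicate
cohorts for the quantile-oracle sweep, 1,000 replicates for the null
calibration, and a single 100,000-probe cohort for the archive-size
check. Quantiles computed through the library agree with an independent
sort-and-interpolate oracle to ~1e−16 relative (a few double ulps;
intensities are O(1e4), so agreement is naturally measured relatively).
Missing intensities are rejected at read time rather than imputed;
sample-ID matching is exact and case-sensitive; all validation errors
name the first offending rows.
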