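# Methods

## Quantification model

The detector is assumed linear per analyte over the calibrated range:
`area = a·conc + b`, fitted by unweighted ordinary least squares on a
seven-level dilution ladder (stock / {1, 2, 5, 10, 20, 50, 100}). The
external standard method (ESM) inverts an analyte's own line,
`conc = (area − b)/a`; in single-point mode it divides by the unit response
`A_s/C_s`. The single-marker route (QAMS) uses only the internal standard's
unit response together with a relative correction factor per analyte,

```
f_k = (A_s/C_s) / (A_k/C_k),    C_k = A_k / (A_s/C_s) · f_k .
```

`f_k` is computed level-by-level on the shared ladder and aggregated as the
arithmetic mean with its RSD (sample SD, n−1). With zero intercepts and no
noise, `f_k` equals the slope ratio `a_s/a_k` exactly at every level and
QAMS reproduces ESM identically; with the small printed intercepts
(`b/a` ≲ 0.005 µg/mL) the two routes differ only near the quantification
limit. The internal standard's factor against itself is forced to exactly
1 (RSD 0) rather than recomputed, so rounding can never violate the
identity.

LOD and LOQ come from a user-supplied baseline noise SD at signal-to-noise
3 and 10, so `LOQ/LOD = 10/3` by construction. The source instrument's
noise level is not published; the packaged printed LOD/LOQ values are
fixtures, not recomputed quantities.

Mass fractions bridge extract concentration to dry material:
`mg/g = conc · V · d / (m · 1000)` with defaults m = 0.25 g, V = 10 mL,
dilution d = 1 (the reference extraction protocol).

## Peak location

Peaks are assigned by signed retention-time offsets from the internal
standard, `Δt_k = t_k − t_GV`, averaged over assigned reference runs. In an
unknown run the reference peak is the one nearest its expected position
(must lie within the tolerance, default 0.5 min); remaining analytes are
matched greedily by smallest |observed − expected offset|, ties broken by
analyte code, each peak used at most once. Unmatched analytes are flagged
absent, never silently dropped, and absent markers quantify as 0 mg/g —
the same convention the reference content table uses for its zero cells.
Assignment discards prior labels first, so it is idempotent.

## Validation statistics

RSD is `100·sd/mean` (n−1); for signed retention offsets the magnitude of
the mean is used. Spike recovery is `100·(found − original)/added`.
Default verdicts: RSD < 3 % for precision/stability/repeatability,
< 5 % for RCF durability and retention-offset stability, recovery within
95–105 %, and ESM-vs-QAMS relative error within ±5 %. All bounds are
configuration fields.

## Chemometrics

PCA operates on the correlation matrix of the content columns (z-scored,
sample SD): the printed coefficient table lies in [−1, 1] and the printed
composite scores are signed and centred, both consistent with standardized
inputs. Component *i* explains `100·λ_i/6` percent of variance; loadings
are `eigenvector·√λ`, sign-fixed so each component's loading sum is
non-negative (this reproduces every printed coefficient to 3 decimals).
Component scores are `Z_i = Σ_j a_ij x_j` on the standardized contents and
`Z = 0.62614·Z₁ + 0.17646·Z₂` by default (the two variance fractions).

Two reference-table inconsistencies surface here and are asserted red in
the acceptance tests rather than hidden:

* the printed per-batch composite scores are not an exact linear function
  of the printed contents under any convention (raw, centred, z-scored,
  eigenvector, unit-variance or regression scores); a least-squares fit of
  the printed scores on the two component scores leaves R² = 0.974. The
  default convention attains Spearman rank agreement 0.980 with the
  printed scores, which is what the test suite freezes;
* the Pearson correlation between the printed scores and the printed
  totals computes to 0.8804, while the source text states 0.875.

Four of the 75 printed relative-error cells are likewise inconsistent with
their own printed ESM/QAMS inputs (the largest discrepancy, 1.05
percentage points, traces to a five-significant-figure ESM cell that is
plainly a typographical slip). The packaged fixtures keep the tables
verbatim; the acceptance test reports the discrepancy.

Clustering is agglomerative with Euclidean distance. The default linkage
is between-groups average: on the reference data it reproduces the
published partitions exactly — 45/9 on the standardized 6-column matrix
with batch 51 set aside, and 41/12 on the 1-D aglycone ratios with batches
13 and 37 set aside — whereas Ward does not (32/22 and 34/19 on the 1-D
indicators). Matrix input is z-scored by column before clustering; 1-D
indicators are used as-is. Clusters are relabelled 1..k by ascending mean
indicator. Exclusions are always an explicit user list; a nearest-neighbour
helper (`flag_singletons`, cut-off 3× the median NN distance) is advisory
only.

Grading: unqualified below 3 mg/g total (inclusive qualification bound,
"not less than"), superior strictly above 8 mg/g total *and* strictly above
10 % aglycone share. The pipeline's default grading uses membership in the
top cluster of both partitions instead of the raw thresholds: the two
rules coincide on the reference data except for batch 51, which satisfies
both thresholds but was set aside as a dendrogram singleton in the
reference analysis; cluster grading therefore reproduces the published set
of nine superior batches. Threshold grading remains available
(`grading="threshold"`) and is monotone in both arguments.

## Synthetic data

The generator emulates three layers of the measurement process:

* **Standards** — areas on the true line with multiplicative Gaussian noise
  (CV-parameterized, default 1 %, the scale of the published instrument
  precision) plus optional additive detector noise for LOD/LOQ work.
* **Samples** — peak tables inverted from a true content vector through the
  preparation constants, with Gaussian retention-time jitter (default
  0.05 min) around nominal positions chosen in the published elution order
  (GC 10.5, C 14.2, GV 20.0, V 25.5, GH 32.0, H 40.5 min). Zero content
  emits no peak.
* **Populations** — batch content matrices drawn with the column moments
  and 6×6 correlation of the packaged reference matrix (computed from the
  fixture at call time). The truncated-normal family matches means, SDs
  and correlations closely (empirical correlations within 0.05 at
  n = 5000) but can zero out any column; the lognormal family
  (moment-matched marginals, Gaussian copula) is strictly positive but
  distorts correlations for the high-CV minor analytes. The pipeline
  simulation defaults to lognormal because real material always contains
  the dominant glycosides — an all-zero batch has no internal-standard
  peak and cannot be processed — while the generator itself defaults to
  truncated-normal where moment fidelity matters.

What the generator does **not** emulate: peak shapes and co-elution
(areas are generated directly; the optional trapezoid-with-baseline
integrator exists only for synthetic traces), inter-day drift, carryover,
matrix effects, and non-linearity at the range edges. Passing round-trip
tests therefore show that the computation chain is self-consistent and
unbiased under the assumed noise model, not that the analytical method
works on real extracts.

## Numerical choices

* Seeds: every generator accepts a seed or Generator; the pipeline spawns
  per-stage child seeds from one `SeedSequence`, so runs are
  byte-reproducible and stages are decoupled.
* Negative regression concentrations are clamped to 0 and flagged, not
  propagated.
* Relative error uses the ESM value as denominator, `(QAMS − ESM)/ESM`,
  and is undefined (NaN, flagged) where ESM = 0.
* Pearson correlation is used for method agreement and score–total
  association; Spearman only for rank-agreement diagnostics.
* Report rounding is 2 decimals for relative errors and 3–4 significant
  figures for contents; all internal computation is full precision.
* Degenerate inputs fail loudly: constant columns name the analyte,
  non-PSD correlation matrices raise before sampling, zero areas or
  concentrations name the offending ladder level.

## Problem sizes

The test suite and acceptance script run on the packaged 55-batch matrix
and on simulations of 12–55 batches, 1000 replicate runs for noise
calibration and 4000–20000 draws for sampling-property checks; the whole
suite completes in a few seconds on one core.

## Known limitations

* The published mean correction factors were measured from raw areas that
  are not public; the package checks them against calibration-slope ratios
  (within 1 % for GC) and treats the printed `f_H` as unvalidated, since
  it duplicates `f_GH` while the slope ratio implies ≈ 0.43.
* Exact reproduction of the printed per-batch composite scores is
  impossible from the printed inputs (see above); rank-level agreement is
  the supported property.
* The optional trace integrator uses a straight-line baseline between
  window endpoints and is not a substitute for instrument integration
  software on real chromatograms.
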