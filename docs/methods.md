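# Methods

## Signal model and preprocessing

Recordings are continuous multichannel EEG in microvolts, 28 channels in an
extended 10–20 montage (the 19 standard sites plus Oz, FC5/6, CP1/2, CP5/6,
PO1/2), nominally 500 Hz. Labels are matched case-insensitively and the
legacy temporal names T3/T4/T5/T6 are aliased to T7/T8/P7/P8; unknown labels
are hard errors. The montage's six 4-electrode regions (left/right frontal,
central, posterior) support region-averaged amplitude summaries.

Preprocessing order: (1) common average reference on the continuous
recording, (2) segmentation into consecutive non-overlapping 2048-ms epochs
from sample 0 (trailing remainder discarded), (3) per-channel linear
detrending of each epoch, (4) rejection of epochs with any detrended sample
outside ±100 μV. The rejection threshold is applied to *detrended* values —
the stricter of the two possible readings of the narrative order, and the
one we adopt throughout. Detrending is linear (constant + slope): it is
idempotent, so cleaning is a projection. A recording in which every epoch is
rejected is an error naming the recording, never silently empty.

## Spectral estimation

Each kept epoch is one Welch segment: Hamming window per channel, real FFT,
cross-spectral tensor S_ij(f) = X_i(f) X_j(f)* averaged over epochs. Using
whole epochs as segments (no sub-windows, no overlap) preserves the
resolution Δf = fs/N = 0.48828125 Hz that the 2048-ms epoch defines; any
sub-windowing would coarsen it. The one-sided density normalization
2/(fs Σw²) is applied; COH and iCOH are invariant to it, so it matters only
for absolute amplitude scales (which have no external reference here).

The analysis axis keeps DFT bins k = 1…92 (DC excluded), i.e. 0.488 to
44.921875 Hz. Printed range endpoints are rounded to ~3 decimals, so bin
centers are matched to them with a 0.01 Hz tolerance (the 44.921875 Hz bin
is *inside* a range printed as "44.921"). Band membership uses
lo ≤ center < hi on exact bin centers, giving 7 delta, 8 theta, 10 alpha,
14 beta1, 21 beta2 and 31 gamma bins; the gamma band's nominal 45 Hz top is
clipped by the analysis range (the range is the binding constraint).

## Connectivity

Coherency COHy_ij(f) = S_ij/sqrt(S_ii S_jj); COH = |COHy| and
iCOH = |Im COHy|, both in [0,1] with iCOH ≤ COH per bin. Band values
average the per-bin *measure* (the modulus, not the complex coherency), so
the band-level inequality is inherited from the per-bin one. Averaging the
moduli was chosen over averaging the complex coherency because the band
value then summarizes connectivity strength regardless of phase
consistency across bins; the alternative would partially cancel opposing
phases within a band. The choice matters for noise floors (below).

Edges are vectorized in fixed row-major upper-triangle order — with 28
channels, 378 pairs — and that order is recorded in every output so
saliences align across runs. Hub degree is the count of significant edges
incident to an electrode; ties for the maximum are all reported.

### Estimator noise floor

With n epochs, the coherency estimate of two *independent* signals is not
zero: E|γ̂| ≈ sqrt(π/4n) and E|Im γ̂| ≈ sqrt(1/πn) ≈ 0.040 at n = 200. Because band averaging averages moduli, this bias does
not shrink with band width; only the variance does. Consequently, at 200
epochs, mixing-only (volume-conduction) data show mean band iCOH ≈ 0.04
with a per-pair maximum ≈ 0.08 across 378 pairs — while neighbouring-pair
COH is 0.5–0.9. The meaningful volume-conduction check is therefore that
the all-pair mean iCOH stays below 0.05 and every pair stays at the noise
floor (≲ 0.12) — the mean an order of magnitude below neighbouring-pair
COH, the per-pair maximum well below the ~0.15 planted-effect shifts — not
that individual pairs beat the floor. The floor decays as 1/sqrt(n): the
per-bin mean coherence matches sqrt(π/4n) closely, which falls below 0.05
only beyond n ≈ 315 epochs.

## Mean-centered task PLS

Observations are one row per subject x condition (46 rows at the study's
12 + 11 sample sizes); features are the 378 band-edge values or the
28 x 92 channel-by-frequency amplitudes. The crossblock covariance between
the design and the data reduces to the group x condition cell-mean matrix;
we center *within group* (each group's mean across its conditions removed).
With 2 groups x 2 conditions this leaves each group a ±half-difference
contrast: the centered matrix has rank 2, so of the 4 LVs the last two have
numerically zero singular values and LV1 + LV2 always account for exactly
100% of the crossblock covariance. (Grand-mean centering would yield rank
3 and spread covariance over three LVs; it is incompatible with the
two-meaningful-LV structure this design targets.) Singular-vector sign is
fixed by making the largest-magnitude salience of each LV positive.

Permutation test: condition labels are shuffled independently within each
subject (a fair coin per subject); groups, a between-subject factor, are
never exchanged. p_k = #{s_k^perm ≥ s_k^obs}/n_perm, so an observed maximum
reports p = 0, printed as "< 1/n_perm"; the add-one convention is available
as an option. Permutation p-values are invariant to feature order and
subject relabeling.

Bootstrap: subjects are resampled with replacement within their group, both
conditions of a drawn subject moving together — no design cell can empty.
Each resample's saliences are sign-aligned to the observed ones per LV
(sign of the dot product; no Procrustes rotation). BSR = observed salience
/ bootstrap SE; features with numerically zero SE are flagged unstable and
excluded from significant sets. The default significance threshold
|BSR| ≥ 2 (≈95%) is configurable.

## Synthetic data generator

The generator emulates eyes-closed resting EEG statistically, not
biophysically:

- **Background**: one independent 1/f (exponent 1, low-frequency shelf at
  0.1 Hz) Gaussian source per electrode, RMS 12 μV per channel after
  mixing.
- **Volume conduction**: an instantaneous source-to-electrode kernel,
  Gaussian in schematic electrode distance (spread 0.35 head radii), rows
  normalized. Instantaneous mixing produces zero-lag correlations only:
  large COH between neighbours, no iCOH.
- **Rhythms**: narrowband filtered-noise oscillators (Gaussian spectral
  bump), by default one 10 Hz, 2 Hz-wide alpha at 6 μV, mixed like the
  background. Filtered noise rather than sinusoids keeps coherence < 1 and
  epoch-to-epoch phase realistic.
- **Couplings**: a coupling injects a shared narrowband oscillator into two
  electrodes, the second copy phase-rotated by the requested lag (90° by
  default) via the analytic-signal rotation. Strength is the injected RMS
  as a fraction of background RMS, with per-subject lognormal jitter
  (σ = 0.15). Injection is post-mixing, so the planted lag is exact.
  Injected power is matched across all four design cells: where a cell's
  coupling is weaker or absent, *independent* oscillators of compensating
  amplitude (quadrature-summed) are injected instead. Every cell therefore
  has identical spectral content and the cells differ only in phase-lagged
  coupling — amplitude analyses stay null and COH carries only the small
  modulus change that any genuine Im-component necessarily induces
  (COH ≥ iCOH pointwise, so a large planted iCOH effect cannot leave COH
  exactly null).
- **Default effect template** (the study conditions): a theta coupling
  (6 Hz carrier, 2 Hz bandwidth, strength 0.55) on the Pz hub — Pz to Cz,
  CP1, CP2, P3, P4, PO1, PO2, Oz — present only in (high, hypnosis); and
  beta1 couplings (16 Hz, 3 Hz bandwidth) on Cz- and PO2-centred hubs at
  strength 0.45 in all cells, dropping to 0.15 in (high, hypnosis). The
  strengths were fixed once from the generator's measured strength→iCOH
  map so the planted theta shift lands at ~0.15 band iCOH on coupled
  pairs, and induced band iCOH is monotone in strength.

Recordings are 4 minutes (≈117 epochs) by default; every recording's random
stream derives from (seed, subject, condition), so studies regenerate
bit-identically in any order. Under default amplitudes the ±100 μV
rejection trips rarely (acceptance ≈ 100%, comfortably above the 83% floor
observed in practice for resting EEG).

What the generator does *not* model: realistic lead fields or 3-D head
geometry, ocular/muscle artifacts, non-stationarity across a session,
heavy-tailed amplitude distributions, or cross-frequency structure. Passing
tests therefore certify the statistical machinery — estimator behaviour,
calibration, recovery, determinism — not robustness to real-world artifact
regimes.

## Study-level experiments and problem sizes

Type-I calibration: 200 null studies (6 subjects/group, 1-minute
recordings, 200 permutations, theta-iCOH analysis). With the k/n p-value
convention at 200 permutations, the exact null rate of p ≤ 0.05 is ~0.055;
the empirical rate is checked against the 95% binomial band around 0.05.
Recovery: 50 replicate planted studies (8 subjects/group, 1-minute
recordings, 200 permutations/bootstraps), scored on LV1 p ≤ 0.05, the
design-score contrast concentrating in the high group, ≥ 50% of planted
edges at |BSR| ≥ 2, and the hub maximum at Pz. These reduced sizes keep the
full suite to minutes while preserving ample power (the planted effect is
~6 bootstrap SEs at these sizes). `scripts/acceptance.py` uses 100 null
studies and 20 replicates, for the same reason.

## Numerical conventions and degenerate inputs

- Matrix-format recordings round-trip bit-exactly (values serialized via
  `repr`); EDF round-trips to 16-bit quantization of the per-channel
  physical range.
- Connectivity matrices are symmetrized (they are symmetric up to FFT
  round-off) and diagonals set to their exact theoretical values (COH 1,
  iCOH 0).
- A zero autospectrum at an analysis bin is an error naming channel and
  frequency; empty bands, empty design cells, single-condition subjects and
  unknown labels are errors, never warnings.
- Permutation/bootstrap streams are spawned per analysis from the config
  seed in a fixed order, so observed singular values and saliences are
  seed-independent and only resampling outputs change with the seed.
- Report tables format floats at fixed precision, making repeated runs
  byte-identical.

## Known limitations

- Sensor-space only; no source reconstruction, and no claim about the
  anatomical origin of hubs.
- iCOH underestimates true connectivity by discarding genuinely zero-lag
  coupling; COH overestimates it via volume conduction. The pipeline
  reports both, it does not reconcile them.
- The 12 band x measure analyses are deliberately not corrected for
  multiple comparisons (each band is treated as a separate question); the
  report prints the Bonferroni threshold for transparency.
- The permutation scheme exchanges conditions within subject only; whether
  group labels should also be permuted is a design choice on which
  reasonable analyses differ, and is not configurable in v1.
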