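# Methods

## Age from length rank

In a population at balanced exponential growth the age density is
`f(a) = 2^(1−a) ln 2` on `[0, 1)` (twice as many newborns as dividers),
with CDF `F(a) = 2(1 − 2^(−a))`. Because length increases monotonically
with age within the cycle, the empirical length rank is a consistent
estimator of `F(a)`, and inverting it gives

    age = ln(1 − 0.5·rank / (nCells − 1)) / ln(0.5),

`rank` the 0-based index in the ascending length sort. The denominator
`nCells − 1` makes the longest cell's age exactly 1; the last 5% age bin is
therefore closed so that cell is counted. Ties in length are broken by a
stable sort — every cell keeps a distinct integer rank, which keeps ages
monotone in rank (rank averaging would not). The transform assumes the
sample is at steady state and free of length-biased segmentation loss;
departures from steady state distort the mapping and no correction is
attempted.

## FCPlus: the midcell fluorescence surplus

Midcell is the central 0.8 μm of the cell axis. Per cell:

* `F_mid` — profile integral over the central window. The window width is
  generally not an integer number of pixels (12.224 px at the default
  15.28 px/μm), so edge pixels enter with their fractional overlap.
* Volumes use the sphero-cylinder (cylinder of radius `r = d/2` with
  hemispherical caps): `V = π r²(L − 2r) + (4/3)π r³`. The midcell window
  is treated as a pure cylinder slab, `V_mid = π r² · 0.8`; this is only
  well defined when `L > 0.8 + d`, and shorter cells are excluded from
  FCPlus (and counted in the log) while still participating in the age
  ranking. A plain-cylinder volume variant is available for comparison.
* `FCPlus = (F_mid/V_mid − F_rest/V_rest) · V_mid` — the fluorescence at
  midcell in excess of a volume-uniform distribution. It is 0 for a
  profile proportional to the local cross-section, equals the total
  fluorescence when all signal sits inside the window, and can be negative;
  negative values are preserved (clipping would bias the statistic upward
  in dim cells).

Background is removed beforehand by subtracting the modal camera intensity,
estimated as the center of the tallest histogram bin with bin width
`max(1 intensity unit, Freedman–Diaconis)`; ties go to the lowest bin, the
conservative choice for a background estimate. Post-subtraction negatives
are kept. Fluorescence profiles can be registered to their phase-contrast
reference by 1-D cross-correlation with parabolic sub-sample refinement
(±0.03 px residual on smooth profiles in practice); this is a generic 1-D
registration and makes no claim about the upstream imaging chain.

## Binned curves, normalization, calibration

Per-cell values are binned into 5% age classes; each occupied bin carries
its mean and a Student-t 95% CI half-width (`t` rather than `z` because
edge bins are often small; a single-cell bin gets half-width 0). Empty bins
are missing, never zero, and timing estimation interpolates across interior
gaps with a logged warning. Min–max normalization maps occupied-bin means
affinely onto [0, 1] (CIs scaled by the same factor) so curves from
proteins with different copy numbers and antibody affinities share a
timescale; replicate curves on the same grid are averaged unweighted, with
the averaged CI taken from between-replicate scatter. Molecule numbers are
a linear rescaling of FCPlus by `n_total / mean_total_F`, where
`mean_total_F` is the mean total fluorescence over **all** cells (the
calibration copy number, 133 molecules/cell for PBP4, is itself a culture
average) — a bin whose FCPlus equals the culture-average total corresponds
to 133 molecules at midcell.

## Timing: t0 and t1/2

`t0` is the earliest age at which the binned mean FCPlus is positive and
stays positive for ≥ 2 consecutive occupied bins (the persistence rule,
configurable, suppresses single-bin noise; the threshold is a plain sign
test on the mean, not mean − CI). The crossing age is linearly interpolated
between the last non-positive and first positive bin centers; a curve that
starts positive yields 0; a curve that never turns durably positive raises
a no-onset error — the correct outcome for a protein without midcell
localization. `fc_max` is the maximum of the raw binned means, taken
without smoothing (the plateau shape of typical curves makes the unsmoothed
maximum stable), and `t1/2` is the first age from `t0`
upward at which the curve reaches `fc_max/2`, again interpolated between
bracketing bin centers. Both estimates are exactly invariant under positive
rescaling of the curve. Reporting interpolated crossings rather than bin
centers is a choice; all validation tolerances are one bin (0.05) wide
accordingly.

Strain differences in `t0` or `t1/2` across biological replicates use the
two-sided unpaired Welch t-test (replicate counts routinely differ between
strains, so the unequal-variance form is the safe default; it is verified
in the tests against values frozen from an independent R `t.test` run).
Differences are also reported in percent of the division cycle. No
multiple-testing correction is applied across proteins or statistics.

## The synthetic population

The simulator generates the measurement tables the pipeline consumes, with
ground truth recorded per cell:

* **ages** by inverse-transform sampling of `f(a)`;
* **lengths** from a growth law with `L(1) = 2·L(0)` (exponential
  `L_b·2^a` by default, linear available); diameter fixed at 1.0 μm,
  birth length 2.0 μm — typical minimal-medium dimensions for *E. coli*;
* **expression**: expected total fluorescence proportional to cell volume
  (constant concentration) by default, or any caller-supplied age law —
  timing-recovery validation uses an age-constant law, for which the
  half-maximum of the FCPlus curve sits analytically at the rise midpoint;
* **recruitment**: midcell fraction 0 before the onset age `t0_true`,
  linear (or smoothstep) rise over `rise_width` to `plateau_fraction`,
  optional linear decline to 0 from `decline_age` to division. Defaults
  `t0_true = 0.25`, `rise_width = 0.2`, `plateau_fraction = 0.6` mirror an
  early-localizing divisome protein;
* **geometry of the signal**: the midcell component is a Gaussian ring of
  axial σ `ring_sigma = 0.12 μm` (constrained to < 0.4 μm so the ring mass
  stays essentially inside the analysis window), integrated exactly over
  pixels via the error function and renormalized to the cell interior; the
  remainder is uniform per unit axis length. Noiseless profiles therefore
  conserve the expression total to 10⁻⁶ relative;
* **noise**: per-cell lognormal brightness factor (mean 1, CV `noise_cv`,
  default 10% in validation runs) and optional per-sample Poisson counting
  noise. The constriction flag is set for ages above 0.8.

What the simulator does **not** emulate: off-center division asymmetry,
cell polarity, point-spread blurring and out-of-focus light, segmentation
errors, length-biased sampling, or departures from the ideal steady state.
Passing tests on simulated data therefore demonstrate the correctness of
the estimators under the steady-state model, not robustness to real-world
imaging artifacts.

The diffuse component being uniform per unit length (not per unit volume)
makes FCPlus very slightly negative for unrecruited cells — the polar caps
concentrate the diffuse signal into less volume. This is why the null
(no-recruitment) control correctly produces a no-onset error rather than a
curve hovering at exactly zero.

## Validation problem sizes

The test-suite and acceptance-script runs use: 10⁶ draws for the age-mean
check, 10⁵ for the Kolmogorov–Smirnov distance, 20 replicates of 5000
cells for timing recovery (accepting `|t0 − 0.25| ≤ 0.05` and
`|t1/2 − 0.35| ≤ 0.05`, i.e. one age bin), and 100 meta-repeats of a
6 + 6-replicate two-strain design (1000 cells per replicate, true onset
shift 0.08, replicate-level onset scatter sd 0.02) for the Welch
comparison. These sizes put Monte-Carlo noise well below the one-bin
tolerances while keeping a full run under a minute on one CPU.

## Demographs

Rows are cells sorted ascending by length, profiles center-aligned (fixed
immunolabeled cells carry no polarity, and division is modeled at the
center; no flipping heuristic is applied), kept at native pixel pitch and
NaN-padded outside the cell outline. Rendering maps intensities affinely to
16-bit gray (absent → 0, outline → 65535); passing an explicit shared
`(lo, hi)` scale to several conditions makes their rasters directly
comparable pixel for pixel. No row smoothing is applied.

## Known limitations

* The rank→age transform is only as good as the steady-state assumption;
  strains that fail to reach reproducible steady state will show inflated
  replicate-to-replicate timing scatter rather than a diagnosable bias.
* FCPlus excludes cells shorter than `0.8 + d` μm; in populations of very
  short cells the youngest bins can thin out.
* The molecule calibration inherits the uncertainty of the culture-average
  copy number and assumes fluorescence linearity in molecule count.
* `estimate_thalf` depends on the curve maximum; for expression laws that
  grow steeply with age the half-maximum age reflects expression growth as
  well as recruitment timing.
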