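# septime

Cell-division-cycle timing of midcell protein recruitment in rod-shaped
bacteria, from single-cell fluorescence snapshots.

## The problem

Many division proteins (FtsZ, FtsN, periplasmic enzymes such as PBP4)
relocate from a diffuse distribution to the midcell division site at a
characteristic moment of the cell cycle. Time-lapse imaging of fixed,
immunolabeled cells is impossible — but a population in balanced
("steady-state") exponential growth encodes time in its length
distribution: the probability that a cell has division-cycle age `a ∈ [0,1)`
is `f(a) = 2^(1−a) ln 2`, so sorting cells by length and applying

```
age = ln(1 − 0.5·rank/(nCells−1)) / ln(0.5)
```

converts a single snapshot of thousands of cells into a pseudo-time course.
`septime` implements this analysis end to end for per-cell measurement
tables (length, diameter, axial fluorescence profile):

* **age assignment** from length rank (formula above);
* **FCPlus**, the midcell fluorescence surplus: with midcell defined as the
  central 0.8 μm of the cell axis, `FCPlus = (C_mid − C_rest) · V_mid`,
  where `C` are fluorophore concentrations (integrated fluorescence over
  sphero-cylinder volume) at midcell and in the rest of the cell;
* **binned age curves** (5% age classes, Student-t 95% CIs), min–max
  normalization and replicate averaging;
* **arrival timing**: `t0`, the age at which FCPlus first turns durably
  positive, and `t1/2`, the age at which it first reaches half of its
  maximum;
* **strain comparison** of replicate-level `t0`/`t1/2` by two-sided
  unpaired Welch t-test;
* **molecule calibration**: FCPlus converted to molecule numbers via the
  culture-average copy number (133 molecules/cell for PBP4);
* **demographs**: length-sorted, center-aligned fluorescence maps;
* a **steady-state population simulator** with a known recruitment model
  (onset age, rise, plateau, optional late decline, Gaussian ring of
  configurable width, lognormal cell noise, Poisson counting noise) that
  gives every statistic above a ground truth.

## Worked example

```sh
septime simulate --n 3000 --seed 3 --t0-true 0.25 --out pop.csv
septime analyze pop.csv --out-dir .
septime timing pop_curve.csv --out timing.csv
cat timing.csv
```

prints (seed 3):

```
protein,strain,replicate_id,t0,t_half,fc_max,n_cells
,,pop_curve,0.2857027241855492,0.41881378328634805,1259.169160794954,3000
```

The simulated population had a true onset at age 0.25 and a linear rise to
its plateau over the following 0.2 of the cycle. The pipeline recovers
`t0 ≈ 0.29` — within one 5% age bin of the truth — and places the
half-maximum age at `≈ 0.42` (with the default volume-proportional
expression law the curve keeps growing after the plateau is reached, which
moves the half-maximum point later than the ramp midpoint; with an
age-constant expression law it lands at ≈ 0.35). `fc_max` is the largest
binned FCPlus value in fluorescence units.

The same objects are available as a library:

```python
import septime as st

law = st.GrowthLaw(birth_length=2.0, diameter=1.0)
model = st.RecruitmentModel(t0_true=0.25, rise_width=0.2, noise_cv=0.1)
pop, truth = st.simulate_population(3000, law, model, seed=3)
result = st.analyze_population(pop)          # per-cell FCPlus + binned curve
timing = st.timing_from_curve(result.curve)  # t0, t_half, fc_max
```

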