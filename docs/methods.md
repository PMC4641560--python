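# Methods

## The sectioning model

A spherical vesicle of true diameter `D` cut by a plane at a uniformly
random level produces a circular profile. Parametrising the cut by the
angle `φ`, with `sin φ` uniform on [−1, 1] (every distance from the
centre equally likely), the cut passes at distance `sin φ · D/2` from
the centre and the profile has apparent diameter `d = D cos φ`. The
apparent-diameter law follows in closed form:

    F(x; D) = P(d ≤ x) = 1 − √(1 − (x/D)²),   0 ≤ x ≤ D,

with density rising monotonically to an integrable singularity at
`x = D`, mean `(π/4)·D ≈ 0.785 D` and mode at `D`. Equatorial cuts are
likelier to land near the full diameter than polar cuts are to land
near any particular small value, so a monodisperse population yields a
negatively skewed profile histogram peaking in the bin that contains
`D` — while the *mean* section diameter understates `D` by a fifth.

Assumptions worth stating:

- **Ideal planes.** Section thickness is treated as zero. Physical
  ultrathin sections are ~100 nm thick, which truncates polar caps and
  over-represents large profiles slightly; the model ignores this, so
  fitted weights inherit that approximation.
- **Spheres.** Profiles of slightly ellipsoidal vesicles are handled at
  the measurement level (the two measured radii are averaged), not in
  the geometry.
- **Uniform sampling.** Every vesicle is equally likely to be cut at
  any level; no label-efficiency or visibility weighting.

`build_template` discretises the law into a bins-by-bins operator on
uniform diameter grids (default 0–700 nm in 25-nm bins, both axes).
Column `j` holds the apparent-bin probabilities for a sphere at the
representative diameter of true bin `j`. Two constructions are
provided: differencing the closed-form CDF at the apparent bin edges
(default), and enumerating cut levels at a fixed spacing (default 1 nm)
through the sphere. The enumerated construction is retained as a
cross-check; midpoint enumeration quantises each bin boundary to at
most ~2 cut levels, so the two constructions agree to `2/(D/step)` per
column (tested).

**Bin representatives.** Each 25-nm true bin is represented by its
upper edge, so the demonstration subpopulations "100 nm, 300 nm,
500 nm" are exactly representable; a midpoint mode is available
(`DiameterGrid(..., representative="midpoint")`).

**Binning convention.** Half-open `[lower, upper)` bins, final bin
closed; a value exactly on an interior edge belongs to the upper bin.
One deliberate exception: analytically, the mass of a sphere whose
diameter equals a bin's upper edge is assigned by CDF differences, so
the full-diameter cut (`d = D`, probability zero in the continuum)
counts toward the bin `D` closes; the enumerated construction mirrors
this.

**Detection floor.** With `min_detectable_diameter > 0` (the empirical
floor is 70 nm), sub-floor mass is removed from each column exactly
(including the partial bin the floor straddles), the column is
renormalised, and the removed fraction is recorded per column in
`truncated_mass`. Columns for spheres entirely below the floor are
zeroed and flagged with truncated mass 1. The Monte-Carlo sampler
discards and redraws sub-floor sections and reports the discard count.

## Unfolding

The observed section histogram, normalised to frequencies `y`, is
modelled as `y ≈ A w` with `w ≥ 0` (negative subpopulation fractions
are meaningless), solved by nonnegative least squares
(`scipy.optimize.nnls`). Weights are reported normalised to sum 1;
weights below 1e-9 after normalisation are reported as exactly zero.

- **Goodness of fit** is the squared Pearson correlation between
  observed and predicted normalised bin frequencies (the
  "linear-regression R²" convention for this kind of deconvolution).
  An intercept-free (uncentered) variant is recorded in the fit
  metadata, along with the solver convention, the template hash and the
  template condition number, so alternative conventions can be compared
  downstream. An unconstrained least-squares mode exists for
  diagnostics and is flagged in the metadata.
- **No smoothing or regularisation** is applied. The 25-nm binning
  itself conditions the problem: on the default grid the template's
  condition number is ≈ 5.3, and noise-free forward images of sparse
  weight vectors invert to ~1e-16. At n = 10⁴ sampled sections the
  1:2:1 three-component mixture is recovered with every bin weight
  within ±0.05 of truth and R² ≥ 0.95 (tested over 20 seeds).
- **Band fractions** aggregate normalised weight into half-open
  diameter bands (default edges 150/250/350/450/650 nm) by bin
  representative; weight below the first or at/above the last edge is
  reported separately so the parts always total 100%.
- **Peaks** are bins strictly greater than both neighbours; a flat run
  of maximal bins counts once, at its leftmost bin; grid boundaries act
  as −∞ (a monotone profile peaks at its end bin); zero-weight bins are
  never peaks. Peaks are ordered by decreasing weight.

## Measurements

One record per measured vesicle profile: strain (`WR`/`SHR`), region
(`NTS`/`RVLM`/`LC`; `CVLM` appears only in the confocal arm),
N/E marker (`DbH`/`VMAT2`, or `none` for NPY-only profiles), NPY
colabel flag, and the measured horizontal and vertical radii in nm. The
working diameter is `radius_h + radius_v` — twice the mean radius,
matching the convention of averaging the two measured radii of a
slightly elliptical profile. Max-axis or geometric-mean variants were
considered and rejected as defaults because the averaging convention is
the stated measurement procedure. A record with no N/E marker must
carry an NPY label (it would never have been recorded otherwise).

Files are CSV, UTF-8, dot decimal, one header row. Invalid rows are
rejected individually with line-numbered diagnostics (header = line 1);
the file fails only if required columns are missing. Floats are written
with `repr` so write→read round-trips are bit-identical.

`pool_ne_markers` flags DbH- and VMAT2-labeled records as one N/E
class (their size distributions are alike, so downstream analysis pools
them), keeping the original marker for audit; it is idempotent.
`filter_diameter_range` keeps `low ≤ d ≤ high` inclusive and accounts
exactly for removals below/above.

## Statistics

- **KS tests**: `D = sup |ECDF_x − ECDF_y|`, two-tailed. The p-value is
  asymptotic by default (Kolmogorov limit with the standard effective-n
  scaling, via `scipy.stats.ks_2samp`); exact enumeration is available
  for `n_x·n_y ≤ 10⁴`. At n = 80 vs 80 the asymptotic test is well
  calibrated: measured null rejection 5.1% at α = 0.05 over 2000
  replicates (tested with a [3%, 7%] band).
- **Summaries**: mean, median, quartiles by linear interpolation
  between order statistics, range.
- **Colocalization**: numerator = profiles with both an N/E marker and
  NPY. Default denominator = all N/E-labeled profiles (this convention
  reproduces the headline 24%/49%/54% from the printed counts
  18/75, 39/80, 41/76); the NPY-labeled denominator is computed
  alongside, and every output row records its convention. Percentages
  are reported to one decimal, nearest-integer for headline tables.
- **Cell-level coexpression**: per animal,
  `100 · n_coloc / (n_dbh_only + n_coloc)`; animals with no DbH-ir
  cells are excluded with a warning. Strain comparison by two-tailed
  unpaired t test (equal variances, n = 3 animals per strain in the
  default scenario); the degenerate all-identical case reports t = 0,
  p = 1 rather than NaN.

## Synthetic data: what it emulates and what it does not

No raw per-vesicle data are public; only group-level summaries. The
generator therefore states an explicit world calibrated to those
summaries — a green test establishes that the *pipeline* behaves
correctly in that world, not that the world equals the unpublished raw
data.

- **True populations** are truncated-Gaussian mixtures over (0, 700] nm
  (one or two components per group). Parameters were calibrated once,
  by Nelder–Mead search on a fixed common-random-numbers sample
  (`ldcv.calibration`), so that *detected sections* — forward-sectioned
  and restricted to the 70–650 nm detection window — hit each group's
  printed (mean, median) at the printed n (WR: 230/205 n=80 NTS,
  231/212 n=75 RVLM, 245/249 n=77 LC; SHR: 219/212 n=61 NTS, 318/304
  n=80 RVLM, 393/391 n=76 LC). The calibrated means are within 0.2% of
  target (tested at 1% with n = 10⁵ draws).
- **The NTS exception.** The printed NTS summaries order oppositely
  between strains (WR mean 230 > SHR 219, but WR median 205 < SHR 212).
  No two similarly-shaped distributions can reproduce all four numbers:
  hitting them exactly forces a population KS distance of ≈ 0.07 and a
  ~10% false-rejection rate at the printed n's, contradicting the
  reported strain similarity in NTS (p = .799). Since medians at
  n = 61–80 carry a sampling SE of ~12 nm, the two NTS mixtures were
  calibrated *jointly*: population KS distance minimised subject to
  exact means and medians within ±6 nm of printed. They land at 208.8
  and 208.9 nm (ordering preserved), population KS distance 0.05, and
  an NTS rejection rate of ~5% — the null floor, which is the best any
  faithful generator can do.
- **Detection window**: sections outside [70, 650] nm are discarded and
  redrawn; discard counts are recorded in the manifest. The rejection is
  two-sided because the measured range is stated as 70–650 nm.
- **Radii split**: each detected diameter `d` is split as
  `radius_h = d/(2+ε)`, `radius_v = d(1+ε)/(2+ε)`, `ε ~ U(−0.1, 0.1)`,
  so the radii differ by up to ~10% ("spherical or slightly ellipsoid")
  while `radius_h + radius_v = d` exactly.
- **NPY colabeling** is logistic in true diameter: midpoint at the
  group median, slope set so the upper-half median carries 2× the
  lower-half median's odds (colabels ride on the larger vesicles), and
  intercept solved by bisection so the mean probability equals the
  group's target fraction exactly (targets are the printed per-group
  colabeled/N/E-labeled count ratios). `colabel_odds_ratio=1` gives
  size-independent labeling.
- **NPY-only profiles** (`ne_marker = "none"`) are added per group so
  the NPY-labeled class has its printed sample size; they draw from the
  same size mixture, consistent with the reported similarity of
  NPY-labeled and N/E-labeled size distributions.
- **Confocal counts**: per-animal coexpression percentages are Gaussian
  around the printed strain mean with SD = printed SEM·√3 (n = 3
  animals), clipped to [0, 100], then converted to integer counts out
  of 120 DbH-ir cells per animal. The 120 is a choice (the per-animal
  totals are not printed; ~33 sections per region per animal makes a
  low-hundreds count realistic), as are the 90 ± 3% RVLM/CVLM means
  (stated only as "the majority"). NPY-only cell counts are Poisson
  with mean 60 — plumbing, not a calibration target.
- **Determinism**: one integer seed per spec; the full scenario spawns
  per-group seeds via `numpy` `SeedSequence`, so the same scenario seed
  reproduces byte-identical files, and the manifest records every
  generator parameter.

Features of real data *not* emulated: section thickness, lost polar
caps, labeling efficiency, gold-particle counts, within-animal
clustering (records are i.i.d. given the group), and any
region-specific NPY size interaction beyond the global odds-ratio-2
rule.

## Numerical choices

- NNLS via `scipy.optimize.nnls`; no tolerance tuning. Weight floor
  1e-9 post-normalisation.
- Avogadro constant fixed at the exact SI value 6.02214076e23; volumes
  in litres (1 nm³ = 1e-24 L).
- Quartiles: linear interpolation (numpy default).
- The KS statistic on continuous synthetic data never ties; ties in
  user data are handled by scipy's ECDF convention.
- The t test uses pooled variance; with three animals per strain this
  is the convention the printed comparisons imply.

## Known limitations

- The unfolding is a plug-in estimator: no uncertainty bands on the
  recovered weights (bootstrap would be the natural extension).
- At n ≈ 80 per group the recovered weight vectors are noisy even
  though band fractions and peak locations are stable; single-bin
  weights from small samples should not be over-read.
- The ~10 mM concentration figure depends cubically on the diameter
  chosen; the CLI therefore requires the diameter explicitly, and the
  analysis table shows the estimate across several printed diameters
  (24 mM at 235 nm down to 5 mM at 393 nm for 10⁵ molecules).
- The confocal comparison at printed dispersions has ~73% power for the
  LC contrast (t ≈ 3.4 at n = 3); a three-animal design detects that
  effect in roughly three of four repetitions, not reliably.
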