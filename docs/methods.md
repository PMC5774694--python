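# Methods

This note documents the models behind `fermphen`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate, and
the numerical decisions a user should know before trusting a green test.

## Must chemistry

**Theoretical CO₂ maximum.** Complete fermentation of hexose releases
0.482 g of CO₂ per gram of sugar; `theoretical_co2_max` is the linear map
tCO₂max = 0.482·[sugar] (g/L). All kinetic thresholds are fractions of this
quantity, so a must's sugar content fixes the scale of its kinetics.

**Molecular SO₂.** Only the undissociated SO₂ fraction of free SO₂ is
antimicrobial. Full speciation involves two equilibria plus temperature and
ethanol corrections; enological calculators fold these into lookup tables.
`molecular_so2` instead uses a single effective dissociation,

    molecular = free / (1 + 10^(pH − pKa_eff)),

with pKa_eff = 1.86, obtained by least squares against five reference musts
whose active SO₂ was determined with a standard enological calculator at
24 °C and 0.1 % vol ethanol (`fit_pka_eff` reproduces the calibration:
optimum 1.8596, maximum residual 0.011 mg/L over the five musts). The
residuals suggest the calculator applies small corrections beyond one
equilibrium; they are below the 2-decimal reporting precision, so the
one-parameter model is kept. Out of scope by design: bisulfite/sulfite
speciation, temperature-dependent pKa tables, SO₂ binding by acetaldehyde.

## Fermentation kinetics

**From weights to CO₂.** CO₂(tᵢ) = (w(t₀) − w(tᵢ)) / V with V the fermented
volume in litres; the first reading anchors the curve at zero. Balance noise
on w(t₀) therefore propagates as a common offset — irrelevant for threshold
differences, visible in the lag estimate at very low noise-to-signal.

**Smoother.** Loess: for each point of a regular 0.1 h grid, a quadratic is
fitted by weighted least squares to the nearest floor(0.45·n) observations,
weighted by the tricube kernel of distance scaled to the farthest neighbour.
This reproduces the classical loess implementations (validated against R's
`loess`, agreement ~1e-5 on shared inputs; the floor neighbour-count
convention matters for that agreement). The fitted curve is clipped at zero
and monotonized by running maximum before thresholding, because cumulative
release cannot decrease — raw weight logs can, through balance drift. Grid
points before the first observation are held at the boundary fit; a local
quadratic extrapolates poorly. Degenerate neighbourhoods (distance ties that
zero out all but fewer than three weights) fall back to the highest degree
their support allows.

**Trait extraction.** All six traits are read from the smoothed, monotonized
curve, not the raw points: *lp* is the linearly interpolated crossing of
2 g/L; *t35/t50/t80* are interpolated crossings of the corresponding
fraction of tCO₂max, minus *lp*; CO₂max is the final value of the curve;
V50_80 = (0.30·tCO₂max/0.482)/(t80 − t50), i.e. the hexose consumed between
the two thresholds over the time taken, which makes the *lp* convention
cancel. A curve that never reaches 80 % of tCO₂max is flagged `STUCK` (t80,
V50_80 undefined); one that never releases 2 g/L is flagged
`NO_LAG_REACHED`. Sugar-assay-based completion checks are an input-side
filter, not derived from the curve.

**Known accuracy limits.** A span-0.45 loess is a biased estimator of a
sigmoid: at realistic curve shapes (rates 0.06–0.10 h⁻¹, horizons of
100–200 h) the smoothing bias on threshold times is 0.3–1.5 h even for
noise-free input, concentrated at the lag corner where curvature is highest,
and grows with the observed plateau length (the span is a fraction of the
data, so a longer record widens every local window). This bias is a property
of the method — R's loess shows the same values — and dominates grid and
interpolation error by an order of magnitude. Benchmarks on simulated noisy
vials (balance noise 0.002 g, 2–3 weighings/day) give median |t50 error|
≈ 1.5 h and median |CO₂max error| ≈ 0.3 g/L. Users comparing strains are
unaffected to first order (the bias is shared), but absolute threshold times
carry this systematic component.

## Synthetic experiments

The generator emulates the reference factorial design: 4 strains × 2 musts ×
2 micro-oxygenation levels × 10 replicates = 160 vials, in 5 mL at 2.5
weighings/day with 0.002 g balance noise. Five reference must compositions
(two white, three red; sugars 194–220 g/L) ship with the package.

**Curves.** Each vial's true trajectory is a delayed logistic: zero up to an
onset, then a logistic rise rescaled to start at zero and saturate at the
plateau. Four generative parameters — onset (lag, h), onset-to-inflection
time (h), rate (h⁻¹) and plateau (g/L) — are each built additively from
grand mean, strain, must and micro-oxygenation effects plus strain×must and
strain×micro-oxygenation interactions and Gaussian residuals: exactly the
structure the ANOVA stage fits, which is what makes recovery tests
meaningful. The plateau tracks 97 % of each must's tCO₂max (completed
fermentations) and is clipped at tCO₂max (stoichiometry). Weighing times are
gamma-jittered (CV ≈ 30 %) around the configured frequency, from inoculation
to one day past 99.5 % of the plateau, so the plateau itself is observed —
stopping at 95 % would bias the extracted CO₂max several g/L low.
Closed-form inversion of the trajectory provides the true kinetic traits for
every vial, returned alongside the data.

**Metabolites.** End-point traits (glycerol, acetic acid, malic acid, SO₂,
pyruvate) are drawn directly from the same additive structure; no
within-fermentation dynamics. Default magnitudes are enologically plausible
(glycerol ≈ 5 g/L with a ~15 % micro-oxygenation increase, acetic acid
≈ 0.4 g/L decreased by oxygenation, residual malic acid dominated by the
must, lag phase dominated by strain).

**Reproducibility.** One master seed; each vial's random stream is derived
with a counter-based spawn key, so any subset of vials regenerates
identically regardless of iteration order.

**What a green test does not establish.** The generator shares its curve
family with none of the analysis code (the smoother is model-free), but it
is still an idealization: no stuck fermentations unless requested, no
outlier weighings, no heteroscedastic assay error, no correlated metabolite
panels beyond what the factorial effects induce, no ester chemistry or
oxygen-transfer physics. Recovery and calibration results quantify the
pipeline under this stated world, not under every failure mode of real data.

## G × E statistics

**Decomposition.** Sequential (type I) sums of squares for Strain, Must,
MicroOxygenation, Strain×Must, Strain×MicroOxygenation and residual, each as
percent of total SS. The designs this package targets are balanced, where
the decomposition is order-invariant and the type choice is moot; unbalanced
input is accepted with a logged warning. Internally the blocked design
matrix is QR-factorized once, so a permutation replicate costs one matrix
product — 5 000 permutations of a 160-vial trait take milliseconds. Empty
strain×must or strain×oxygenation cells make an interaction inestimable and
raise an error naming the cell. A constant response reports 100 % residual.

**Permutation test.** The response is permuted across all rows;
p = (1 + #{F* ≥ F}) / (n_perm + 1) per term, with F from the sequential SS
and the full-model residual mean square. Default n_perm = 5 000; a seed is
mandatory. Monte-Carlo calibration (200 null datasets) keeps the type-I
error within [0.02, 0.08] at α = 0.05 and the null p-distribution uniform
by KS check.

**Post hoc.** Tukey HSD uses the pooled one-way fit and the studentized
range; the compact letter display uses insert-and-absorb (groups sharing a
letter do not differ at α). Letters are assigned walking groups in
descending mean order. Wilcoxon–Mann–Whitney is exact for tie-free samples
up to n = 25 per group, asymptotic with tie correction otherwise; two fully
tied samples give p = 1 rather than an error. Stars follow the usual
convention (*** < 0.001, ** < 0.01, * < 0.05, "." < 0.1). No
multiple-testing correction across traits is applied.

**CV tables.** CV % = 100·sd/|mean| per (strain, condition, trait) cell
across replicates (sample sd); zero-mean cells are flagged undefined.
Condition summaries average over strains; the "cumulated CV" sums those
averages over traits (the height of a stacked reliability bar).

## Phenomics

**Normalization.** Within each must, each trait is centred and scaled to
unit sample sd. This removes the (dominant) must main effect so strain
behaviour can be compared across musts — and, deliberately, also hides
strain×must interactions; the robustness analysis therefore runs on the
*raw* per-must means.

**Correlations and PCA.** Spearman rho with average ranks on ties and
per-pair significance at α = 0.05; constant traits are flagged, not fatal.
PCA operates on centred unit-variance variables; axis variances are percent
of total (summing to 100) and loadings are variable–axis correlations, the
quantity drawn on a correlation circle. For the survey layout the intended
observations are per-(strain, must) replicate means.

**Dispersion, ranking, clustering.** Strain dispersion is the mean pairwise
Euclidean distance between strains within a must, per trait class (kinetic
vs metabolic), on normalized values — a measure of how well a must
discriminates strains. Rank heatmaps rank strains 1..n per trait (average
ranks on ties) so every trait weighs equally, then cluster strains by
complete linkage on Euclidean distances between rank vectors; leaf order is
the standard scipy convention, documented so golden files stay stable.
Strongly rank-correlated trait pairs trigger a redundancy warning, since
they double-weight the clustering — the survey convention keeps only three,
weakly correlated kinetic traits (CO₂max, lp, V50_80) beside the
metabolites.

**Robustness.** Per strain × trait, the sample variance of the per-must
mean values (raw scale, so genuine strain×must response drives it; adding a
constant to a strain changes nothing, rescaling a trait scales its variances
quadratically). Per trait, the floor(0.25·n) highest-variance strains form
the fluctuating quartile — 8 of 35, vs 27 robust; the floor convention is
deliberate so a 35-strain survey yields the conventional 8/27 split.
Group contrasts per must use Tukey letters over the must×group cells with a
two-sample Wilcoxon as the distribution-free fallback; the variance matrix
is additionally returned column-standardized for heatmap display.

## Pipeline and formats

Long/tidy CSV is the single interchange dialect (UTF-8, `.` decimal, header
row required): weighing logs as one row per balance reading, traits as one
row per vial, all writers round-trip through their paired readers. Times
are hours from inoculation; volumes are mL in files. A YAML config drives
`run_pipeline` (kinetics → trait assembly → G×E → phenomics); any
stochastic stage refuses to run without a seed, seeds are logged, and
reruns of the same config are bit-identical. A spreadsheet import helper
converts supplementary-style XLSX sheets to the CSV schema.

## Limitations

- No mechanistic fermentation model (biomass, nitrogen dynamics); the loess
  is descriptive and its threshold-time bias (above) is inherent.
- Fixed-effects ANOVA only; no REML/mixed models, no multiple-testing
  correction across traits.
- The robustness quartile is a convention, not an inference: membership near
  the cut is sensitive to replicate noise.
- Ester panels (or any extra metabolite set) are treated as ordinary trait
  columns; no compound-specific chemistry.
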