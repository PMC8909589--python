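# Methods

This note records the model, its assumptions, the parameter choices and
the known limitations of the `grenzray` package, in the spirit of the
model documentation shipped by simulation packages.

## Damage model

One Monte Carlo sample represents the damage deposited by 1 Gy in 1 Gbp
of genomic DNA, condensed onto a single double-stranded segment of
`segment_length_bp` base pairs. The segment length is *not* a physical
genome length: it sets the local damage density, and with it the
probability that elementary damages aggregate into clustered lesions.

* The number of elementary damages per sample is Poisson with mean
  `lesion_rate` (damages per Gy per Gbp at 21% O₂). Poisson is the
  minimal assumption for independently deposited damages.
* Positions are uniform over the segment, strands equiprobable, and the
  damage kind is a strand break with probability 1/(1 + `bd_to_sb_ratio`).
  The default ratio of 3 base damages per strand break is the standard
  radiolysis value; calibration against a target spectrum treats it as a
  free parameter and typically settles nearer 2.
* Two damages separated by at least `n_min_bp = 9` bp belong to
  different clusters; opposite-strand breaks pair into a DSB when
  separated by at most `dsb_window_bp = 10` bp. The two thresholds are
  deliberately independent parameters because the damage taxonomy uses
  both numbers; both are configurable.
* Cluster classification uses only the strand breaks in a cluster (base
  damages contribute to multiplicity, not to the class): no break → BD;
  one break → SSB; breaks on one strand → SSB⁺; breaks on both strands
  with no pair within the window → 2SSB; one pair → DSB (DSB⁺ if any
  unpaired break remains); two or more disjoint pairs → DSB⁺⁺. Pair
  counting is a left-to-right greedy sweep that matches each break to the
  earliest compatible opposite-strand break; for this interval structure
  the greedy matching is maximal, and the test suite checks it against
  an exhaustive pairing enumeration.
* Yields are per-sample means (per Gy per Gbp), SEM = s/√n, and the DSB
  lesion-multiplicity histogram Σᵢ counts the total lesion content of
  DSB-class clusters (support starts at i = 2). The published tables use
  n = 10 000 samples per condition, which is the simulator default; the
  pipeline and tests use n = 600–4 000 where only totals or histogram
  shapes are needed, a purely statistical trade-off (SEM scales as
  1/√n).
* Zero damage (lesion rate 0) is reported as an all-zero spectrum with
  an explicit flag rather than NaN percentages.

Energy (radiation-quality) dependence enters only through `lesion_rate`
and `segment_length_bp`, calibrated per quality against the packaged
yield tables. No track structure is simulated — the surrounding
pipeline consumes per-quality yields exactly as the published method
consumed precomputed per-energy yields.

### Oxygen dependence

The oxygen effect is a single multiplicative modifier on the lesion
induction rate: a Hill-type saturation with plateau `plateau_fraction`
at 0% O₂ and exactly 1 at the 21% reference,

    m(p) = a + (1 − a) · g(p)/g(21),   g(p) = pʰ / (pʰ + kʰ),

clipped at 1 above 21% O₂. This functional form is a calibrated
stand-in for oxygen-fixation chemistry, not a mechanistic model. The
defaults (a = 0.6164, k = 0.4859% O₂, h = 0.9509) were fitted once, by
least squares, to the total-SSB ratios of the packaged tables at
21/2/0.1% O₂ (0.9292 and 0.6882 relative to aerobic, averaged over the
five qualities) and to the ≈38% DSB floor near anoxia (plateau
√0.38 ≈ 0.616, since the simulated DSB yield scales roughly with the
square of the induction rate). The same scaling reproduces the
published DSB ratios without further tuning: m² at 2% gives 0.86
(tables: 6.9/8.1 = 0.85) and at 0.1% gives 0.47 (tables: 3.5/8.1 =
0.43).

### Calibration

`calibrate_lesion_rates` fits (`lesion_rate`, `segment_length_bp`,
`bd_to_sb_ratio`) by Nelder–Mead in log-parameter space, minimising a
yield-share-weighted squared relative error over the seven classes plus
double-weighted terms on the SSB and DSB totals. Every evaluation
re-simulates with the *same* seed (common random numbers), so the loss
is a deterministic function of the parameters; because Nelder–Mead can
stall on the mildly noisy surface, the fit restarts the simplex from
the (deterministically jittered) incumbent until the loss is below
5×10⁻³ and raises if it cannot reach 2×10⁻². The starting point comes
from moment heuristics (break count from the SSB/DSB totals, segment
length from the pairwise DSB-formation probability n_b²·w/2L).
Calibrated fits land the SSB and DSB totals within ~1–2% of the target,
i.e. well inside the 5% the validation asserts; matching to the printed
±0.1 SEMs is not attainable for a re-derived emulator and is not
claimed.

## Microdosimetry

z̄_F = 0.204·LET/d² Gy with LET in keV/μm and the target diameter d in
μm (8 μm, a typical V79 cell). The spectrum-weighted yield uses
trapezoidal quadrature on the union of the spectrum and yield-curve
energy grids, with the yield interpolated log-linearly in energy.
Extrapolating a yield curve outside its tabulated range raises an
error rather than guessing: the low-energy end dominates the systematic
bias, and silent extrapolation there would be untrustworthy.

## RMF mapping and survival endpoints

The garbled-typography risk in the α/β expressions is resolved as

    α = [1 − f_R(1−θ)]Σ + κ·z̄_F·f_R·Σ²,   β = (κ/2)(f_R Σ)²,

which reduces to the documented low-LET limit α = θΣ at f_R = 1 and is
dimensionally consistent (Σ per cell per Gy, z̄_F in Gy). θ/κ defaults
are 5.79×10⁻³/5.59×10⁻⁵ at 21% and 2% O₂ and 4.25×10⁻³/4.5×10⁻⁵ at
0.1% O₂; the unrejoinable-lesion cutoff j is 13 at 21%/2% and 10 at
0.1% O₂. f_R comes from the simulated multiplicity histogram (the
published source never prints Σᵢ); with the calibrated damage model the
histogram tail is light and f_R ≈ 0.999 at j = 13.

α is extremely sensitive to f_R: the term (1 − f_R)Σ adds ≈ 0.2 Gy⁻¹
per percentage point of unrejoinable DSBs at Σ ≈ 20. Because Σᵢ is
unpublished, survival-level RBE and OER are validated as ranges and
trends (aerobic survival RBE within 1.0–1.6, survival OER within
2.0–2.8 and decreasing with LET across the Grenz qualities), not as
exact values.

Genome size G converts per-Gbp yields to per-cell Σ. It is calibrated
once, in closed form, so that the ⁶⁰Co aerobic α from the RMF mapping
(with f_R = 1) lands on the aerobic α–LET regression intercept at
LET = 0.24 keV/μm (α = 0.0466·0.24 + 0.2412 = 0.2524 Gy⁻¹), giving
G ≈ 5.38 Gbp — a plausible rodent-cell DNA content. Note the published
α–LET line itself (α rising to ≈0.55 Gy⁻¹ at 6.6 keV/μm) cannot be
reproduced from the printed DSB yields through this mapping: the yield
ratio across the Grenz range is 1.33 while the α ratio on that line is
2.17. The package therefore anchors the absolute α scale at the
reference quality and validates the slope qualitatively (positive,
R² > 0.9), which the pipeline satisfies (R² ≈ 0.98, intercept ≈ 0.245).

Iso-effect doses are the positive root of αD + βD² = −ln S (β = 0
falls back to −ln S/α; α = β = 0 is an error). The fraction-dose RBE
formula built on α = α_R + λ·LET with shared β is algebraically
identical to the two-quality dose-ratio computation; the test suite
checks the two routes agree to 1×10⁻⁸.

## Synthetic generators

The generators exist to exercise code paths with known ground truth;
they do not claim transport fidelity. Fluence spectra: monoenergetic
(single point), exponential tail (mean energy exact by construction,
default 2.8 keV — the mean secondary-electron energy of the titanium
K-shell beam), and a Kramers-form bremsstrahlung shape Φ ∝ (E_max−E)/E
truncated below 0.5 keV, zero at and above the tube voltage. The
stopping-power curve is a log-log interpolation of the packaged
monoenergetic-electron LET values with power-law edge extension.
Multiplicity histograms put a configurable mass at i = 2 with a
geometric tail; survival datasets apply multiplicative lognormal noise
(survival is positive with roughly proportional error). Everything is
seed-deterministic and returns its recipe as metadata.

Passing tests on these generators demonstrates numerical correctness
and parameter recovery, not agreement with measured beam spectra or
measured Σᵢ distributions — real spectra have characteristic lines,
filtration structure and anode-material dependence that the Kramers
shape ignores.

## Known limitations

* No photon/electron transport, no chemistry-stage radical diffusion,
  no repair kinetics beyond the RMF abstractions.
* The seven-class classifier treats any unpaired break in a DSB cluster
  as promoting it to DSB⁺, without re-checking the 10 bp proximity of
  the extra break to the pair; this convention is applied consistently
  in both the implementation and the brute-force reference.
* The oxygen modifier is an empirical saturation fitted to three
  conditions; between and beyond those concentrations it interpolates a
  shape, not chemistry.
* θ, κ and j are taken as fixed inputs per oxygen condition and are
  not fitted to new survival data.
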