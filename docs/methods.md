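# Methods

## Scope and data model

The package analyses reduced, absolute-scale 1-D scattering profiles
I(Q, E) (units 1/cm, Q in 1/Å, E in keV) measured at Ne energies below one
absorption edge of a resonant element. Detector reduction, background
subtraction and absolute calibration are assumed done upstream; inputs are
per-energy 3-column text profiles plus a manifest. All randomness in the
synthetic generators flows through one `numpy` generator per configuration
seed, so every dataset, fit and study is bit-reproducible.

## Anomalous dispersion

`DispersionTable` holds tabulated (E, f', f'') rows for one element near
one edge; lookups interpolate linearly and refuse to extrapolate, because
dispersion curves steepen rapidly toward an edge and extrapolation there
is silently wrong. Users supply beamline or literature tables as text
files. For self-contained synthetic work the package constructs *synthetic*
tables (`synthetic_edge_table`): f' follows the logarithmic divergence
characteristic of the region below an L3 edge (about −8 electrons 100 eV
below, −19 electrons 1 eV below), f'' drifts gently upward, rows are
log-spaced in distance from the edge. These are qualitatively shaped
stand-ins, not measured values; every synthetic analysis uses the same
table for generation and inversion, so decomposition and fit correctness
never depends on tabulated accuracy.

Electron densities are computed from chemical formulas (elemental Z and
atomic weights from gemmi) and mass densities, and kept in electrons/Å³
throughout; the classical electron radius enters only at intensity
assembly. The resonant split keeps the resonant atom's full Z in the
energy-independent part and carries number density × (f' + i f'')
separately, so the SAXS term stays energy-independent by construction.

## Stuhrmann decomposition

At each Q the model I(E) = S + 2 f'(E) C + (f'(E)² + f''(E)²) R is solved
by weighted least squares (weights 1/σ²) over the Ne energies,
independently per Q — no smoothness coupling across Q is imposed. The
design matrix [1, 2f', f'²+f''²] is checked for conditioning (column-
normalized condition number limit 1e8); scans whose energies share one f'
value are rejected as degenerate. The solver returns, besides the three
term vectors, their full per-Q 3×3 covariance. This matters: the three
estimates at one Q are strongly correlated (f'² is nearly collinear with
f' over a 100 eV window), and discarding the correlation distorts every
downstream chi-squared.

Negative resonant-term estimates arising from noise are *not* clipped by
default — clipping biases the fit — but a non-negative (NNLS) variant is
available. The Cauchy–Schwarz validity check C² ≤ S·R is applied as a
report, not a constraint. For noisy estimates the raw inequality fails by
chance on a large fraction of points (the per-Q resonant term can carry
>100% relative uncertainty), so when the covariance is available the check
flags only excesses that are both beyond the stated relative tolerance and
statistically significant (default 3σ via the delta method). On exact
model output the check reduces to the raw inequality, which the
shared-profile model satisfies with equality to 1e-10.

## Biphasic sphere forward model

Spheres are homogeneous mixtures of the two solute phases and solvent
(interpenetrating network picture); no radial structure, structure factor
S(Q) ≡ 1 (dilute aggregates), no resolution smearing. Two energy-
independent contrasts follow from volume-fraction weighting: Δρ₀ (excess
electrons/Å³) and ρ_res (resonant atoms/Å³). With Φ(x) = 3(sin x − x cos
x)/x³ (series-evaluated below x = 0.01 to avoid cancellation) and ⟨·⟩ the
log-normal radius average,

    S = norm (r_e Δρ₀)² ⟨V²Φ²⟩,  C = norm r_e² Δρ₀ ρ_res ⟨V²Φ²⟩,
    R = norm (r_e ρ_res)² ⟨V²Φ²⟩,

so C² = S·R identically. `norm` is the aggregate number density in 1/cm³;
with volumes in cm³ and scattering-length densities in 1/cm², intensities
come out in 1/cm.

Polydispersity conventions: `mean_radius` is the *median* of the
log-normal, `rsig` the standard deviation of ln R (the XModFit-style
convention; a linear-width reading would simply rescale the parameter).
The average uses 101-node Gauss–Legendre quadrature over ±5 rsig in log
space, weights renormalized to unit mass. Below rsig = 1e-8 the model
switches to the exact monodisperse form. The quadrature under-resolves the
form-factor oscillations at the highest qR, which makes the chi-squared
surface slightly jittery at fine parameter scales; the fit design below
absorbs this.

`guinier_radius` reports the intensity-weighted Rg: √(3/5) R in the
monodisperse limit, √(3/5 · ⟨R⁸⟩/⟨R⁶⟩) generally (V² ~ R⁶ weighting);
verified against the low-Q slope −Rg²/3 of ln S vs Q².

## Fitting and uncertainties

The fit minimizes the chi-squared of all three decomposed terms at once.
When the decomposition covariance is present, residuals at each Q are
whitened with the Cholesky factor of the 3×3 covariance. Because the
decomposition is a linear sufficient reduction of I(Q, E), this
chi-squared equals the raw-data chi-squared up to an additive constant —
which is why Δχ² = 1 profile intervals keep near-nominal one-parameter
coverage. Terms loaded from 7-column files fall back to diagonal weights.

The eight model parameters are not jointly identifiable from the term
amplitudes (only two independent amplitude combinations exist, since
C² = S·R): norm trades against volume fractions and densities. The default
therefore fixes the phase densities and volume fractions at their
configured values and frees norm, `Phase1_rmoles`, `Phase1_R` and `Rsig` —
a well-posed set: the curve shape pins the size distribution, the S
amplitude pins norm, and the C/S ratio pins the ion content. A
correlation-matrix condition number above 1e8 attaches an explicit
identifiability warning. Unit-scale differences are handled by
`x_scale='jac'`; covariance is not rescaled by reduced chi-squared
(uncertainties are absolute).

The chi-squared landscape ripples along `mean_radius` with period ≈ π/q_max
(form-factor oscillations), deep enough at percent-level uncertainties to
trap a trust-region step started ≥10% away. The fit therefore runs a
deterministic continuation: first on Q ≤ 8/R₀, then Q ≤ 25/R (both smooth
in R), each stage starting the next, before the final full-range fit. An
optional seeded multi-start (`n_starts` factor-2^U(−1,1) perturbations) is
layered on top for pathological cases; results are
deterministic given the start and seed.

`chi2_map` profiles one free parameter on a 41-point grid spanning ±4
approximate standard errors (clipped to bounds), re-optimizing the
remaining free parameters at each grid value, marching outward from the
optimum with warm starts; the Δχ² = 1 crossings are interpolated linearly.
A grid that fails to bracket the rise yields a one-sided interval plus a
warning.

Derived quantities: total ions per peptide = `Phase1_rmoles` + (phase-2
resonant ions ÷ phase-1 peptides), both as number densities × volume
fractions; per-phase molarity of the resonant element from density,
formula and molar mass; the two-edge element ratio as the quotient of the
two totals, with its uncertainty (when propagated from the two profiles)
treating the fits as independent.

## Speciation

1:1 binding uses the numerically stable smaller quadratic root (2c/(b+√D))
— no cancellation at strong binding. Competitive binding brackets the free
peptide concentration in [0, P₀] with Brent's method on the peptide mass
balance, which is strictly monotone, and verifies mass balances to 1e-12
relative before returning. The oversaturation label is a threshold
classification at added-metal:peptide ratio 1; aggregation itself is not
modelled thermodynamically. The shipped association constants set the
Tb:Lu and Tb:La affinity ratios to 1.6 and 35 with an absolute scale
(1.8e7 L/mol for Tb) typical of an engineered lanthanide-binding tag; they
are a documented convenience for synthetic work, not measurements. Note
that the bound-metal ratio equals the affinity ratio only in the dilute
limit where neither metal pool is depleted; at 10× excess with strong
binding, depletion alone shifts the ratio by several percent (tens of
percent for a ratio of 35), so the selectivity comparisons are made at
dilute-excess conditions (0.1 nM peptide, 1 nM each metal).

## Synthetic data: what it emulates, what it does not

The generator emulates the measurement protocol the analysis expects:
20 energies spanning the 100 eV window below the Tb or Lu L3 edge, spaced
uniformly in f' (denser in energy near the edge), a logarithmic 200-point
Q grid from 0.003 to 0.3 1/Å (typical 3.6 m pinhole geometry), absolute
intensities, and Gaussian noise σ = rel·I + floor (default 1% + 1e-5
1/cm) reported truthfully — appropriate for reduced, blank-subtracted
profiles, where counting statistics have been propagated into per-point
sigmas. Defaults describe a condensate from the 800 µM peptide / few-mM
lanthanide regime: 2.25 ions per peptide in the peptide phase
(`Phase1_volFrac` 0.08, density 1.35 g/cm³), a trace LnCl3·12H2O-rich
phase (volume fraction 0.002, density 1.5 g/cm³) bringing the total to
≈2.40 ions per peptide, median radius 400 Å with rsig 0.2, and norm 1e12
1/cm³ giving forward scattering of order 0.5 1/cm.

Not emulated: resolution smearing, inter-aggregate structure factor,
fibrillar morphologies, energy-dependent absorption or detector effects,
imperfect background subtraction, and any mismatch between the assumed and
true dispersion values. Passing recovery tests therefore demonstrates the
statistical machinery (decomposition, whitening, profiling, coverage) under
a correctly specified model — not robustness to the systematic errors real
beamline data carry.

## Study sizes and numerical choices

The parameter-recovery study uses 50 replicates of 20 energies × 200 Q
points at 1% noise, fits started 1.3× off truth, with a chi-squared
profile per replicate — sizes chosen so the full suite and the
reproduction script each run in minutes on one core while leaving the
binomial noise on a 50-replicate coverage estimate (±7%) smaller than the
acceptance band's width. Observed behaviour at these conditions: median
relative errors ~0.4% (ion count) and ~0.02% (median radius), coverage in
the low-to-mid 60% range (consistent with the nominal 68% within binomial
noise), reduced chi-squared within [0.5, 2] in all replicates.

Other numeric choices: condition limits 1e8 (design and identifiability),
decomposition via batched normal equations (3×3 solves; conditioning is
benign after column scaling), profile grids 41 × ±4 SE, optimizer
tolerances 1e-12 (1e-10 in continuation pre-stages), Brent tolerances at
machine precision.

## Known limitations

- Uniform-interior spheres only; no core–shell or cylinder variants.
- Element ratios assume the two edge fits are statistically independent;
  shared-geometry correlations are ignored in the ratio uncertainty.
- The synthetic dispersion tables are qualitative; analyses of real data
  must supply measured or tabulated f'/f''.
- Interval coverage is nominal only insofar as the noise model is correct
  and the full decomposition covariance is retained; terms read back from
  7-column files (diagonal sigmas) yield approximate intervals.
- The speciation module treats a single 1:1 site; secondary electrostatic
  association, protonation and ionic-strength effects are out of scope.
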