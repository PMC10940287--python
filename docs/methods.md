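# Methods

## Scope and model family

The package answers one question in three coupled ways: how much
thermodynamically available water does an enzyme see in a reacting organic
medium? The thermodynamic route computes the medium's water capacity and
activity from an activity-coefficient model; the process route propagates
those quantities along a fed-batch/all-in reaction coordinate with a water
inventory; the structural route measures, from particle coordinates, how
much water the enzyme surface withholds from the bulk phase.

Activity coefficients come from a **symmetric multicomponent Margules**
model, `Gᴱ/(nRT) = Σ_{i<j} A_ij x_i x_j`, with analytic partial-derivative
expressions `ln γ_k = Σ_j A_kj x_j − Gᴱ/(nRT)`. This family was chosen over
predictive quantum-chemistry-based models because it is transparent, has
closed forms for calibration, and its single pair parameter per binary maps
directly onto the hydrophilicity ordering the system exhibits. The price is
deliberate: absolute capacities and activities of the full quaternary
mixture are trend-level, not predictive. Signs, monotonicities, and the
inverse capacity/activity relation are the quantities the model is meant to
get right, and they are what the tests assert.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| A(H2O,CPME) | 3.5397 | — | calibrated: 0.7 wt% dissolved water in CPME |
| A(H2O,FA) | 0.5 | — | chosen: FA most hydrophilic of the organics |
| A(H2O,4VG) | 2.0 | — | chosen: 4VG between FA and CPME |
| organic–organic A | 0 | — | no printed anchor; near-athermal assumption |
| FA saturation in wet CPME | 31 | g/L | printed solubility anchor |
| bead moisture | 0.75 | mass fraction | midpoint of the 70–80% bead spec |
| CPME density | 0.86 | g/mL | literature value at 30 °C |
| conversion grid | 10 | states/batch | resolution/runtime balance |

The calibration inverts the binary closed form: the anchor mass fraction w
gives the saturation mole fraction x, and `A = ln(1/x)/(1−x)²` makes x an
exact root of `x·e^{A(1−x)²} = 1`. Calibration fails (by design) when the
implied A ≤ 2 (single-phase symmetric model) or when the target lies beyond
the organic branch's turning point, where it could not be the smallest
root. The FA and 4VG water parameters have no printed anchors; they were
fixed once so that FA raises the water capacity more strongly than 4VG
(both being more polar than CPME), which reproduces the observed
capacity-up-on-feed / capacity-down-on-conversion see-saw. They are
config-overridable and nothing in the package tunes them.

## Numerical choices

* **Capacity root find**: the water mole-fraction axis is scanned on a
  4096-point grid for the first sign change of `ln x + ln γ_w(x)`
  (excluding the trivial root at x = 1), then polished with Brent's method
  (xtol 1e-10, ≤200 iterations). No sign change means full miscibility,
  returned as capacity 1 with a flag rather than an error.
* **LLE flash**: successive substitution on activity-coefficient K-values
  with a Rachford–Rice inner solve, initialized from trial phases enriched
  in each component in turn; convergence at max|Δln K| < 1e-12; solutions
  with phases closer than 1e-4 in composition are treated as trivial and a
  no-split result is returned. Mole conservation is exact by construction
  (lever rule); the isoactivity residual is reported on the result.
* **Capacity-equivalent water**: the moles of water whose mole fraction in
  the full liquid equals the capacity, `n_w = x_cap/(1−x_cap)·n_solutes`
  (closed-form rearrangement). a_W = min(1, available/n_w): reservoirs are
  ideal (activity 1) until exhausted, and a_W falls in inverse proportion
  once the demand exceeds the inventory. Zero available water is flagged as
  an enzyme-inactive state, not an error.
* **Bulk detection**: r_bulk is the inner edge of the first shell from
  which the relative change of x_H2O between consecutive *populated* shells
  stays below the threshold for a persistence window (defaults 0.001 and 3
  shells). Relative-vs-absolute and the window are interpretation choices;
  a persistence window was chosen for robustness to single-shell noise.
  Unpopulated shells carry an undefined-fraction flag and never enter the
  detection or the bulk average, which is count-weighted over all shells at
  r ≥ r_bulk.
* **Saturation scan**: a continuous flat–rise–flat ("trapezoid") least
  squares fit with both knots searched on the observed N grid. The plateau
  is constrained flat because it represents a saturation level; leaving its
  slope free lets the fit chase plateau noise and biases the breakpoint
  rightward. The plateau-free alternative (flat lag + unbounded rise) is
  the null model; a plateau is only reported when the three-segment fit
  improves the null residual by ≥5%. Ties break toward the smallest N_sat.
  An all-constant series short-circuits to a degenerate plateau at the
  first point, since zero residuals make the improvement rule
  uninformative there.
* **Distances**: orthorhombic minimum image only (the target systems use
  cubic boxes); computed with a periodic k-d tree, which is exact for this
  metric. Coordinates are wrapped, never rejected. Which atom represents a
  molecule is a registry attribute of the input, not inferred.

## Synthetic data: what it emulates and what it does not

`gen_solvation_frames` plants water with radial weight `1 + α·e^{−d/λ}`
around a spherical macromolecule proxy (other species uniform), by
rejection sampling in the free volume. The exponential family was chosen
because its total weight has a spherical-shell closed form,
`∫w dV = V_free + α·4π(R²λ + 2Rλ² + 2λ³)`, so the expected far-field water
fraction — the recovery target — is analytic; the tail truncated at the
half-box is `e^{−(L/2−R)/λ}`-small and neglected. Defaults echo a solvated
enzyme box: 1400 water, 4000 CPME, 24 sodium particles in a 9.7 nm cubic
box. The generator conserves per-species counts exactly and is a pure
function of (spec, n_frames, seed).

What passing recovery tests show: the distance/shell/threshold pipeline is
unbiased and correctly calibrated against a known radial structure. What
they do not show: anything about force-field-accurate solvation physics —
the proxy is a smooth sphere, enrichment is monotone, and frames are
independent samples rather than correlated trajectory snapshots.

Desk-scale sampling also dictates the analysis settings used in tests and
examples: at 30 independent frames the per-shell shot noise (~2%) sits far
above the 0.1% production threshold, and the planted α = 5 enrichment
saturates x_H2O into a flat surface plateau that can false-trigger loose
thresholds at 0.05 nm shells. Recovery runs therefore use 0.15 nm shells
with threshold 0.05 — signal per shell grows with shell width, so the
surface plateau stays safely above threshold while the far field falls
below it. The implementation defaults remain 0.05 nm / 0.001, appropriate
for trajectory-scale statistics.

`gen_saturation_series` plants the lag/rise/plateau shape with Gaussian
noise on the plateau only, mirroring the droplet-formation fluctuations
seen past saturation. `gen_table1_scenarios` reproduces the ten all-in
campaign rows; the reservoir bead mass pools biocatalyst and support beads
(both are moist carriers of the same material), with the catalyst loading
kept separately for productivity accounting.

## Design choices on genuinely open points

* Water activity uses mole-fraction (Raoult) normalization throughout.
* The fed-batch trajectory treats FA as fully dissolved in fed-batch mode;
  only all-in mode engages the saturation cap and solid reserve.
* The reservoir inventory generalizes the fixed initially-dissolved-water
  picture: bead moisture is treated as fully thermodynamically extractable,
  and free water plus bead moisture pool into one ideal inventory (drawn
  free-water-first for reporting). Bead aggregation and mass-transfer
  phenomena are out of scope as transport effects.
* Conversion is a coordinate, not a kinetic time course: no rate constants
  are modelled, so states map to compositions, not times.
* The shell-fraction denominator counts every registered species including
  sodium; all labelled particles are counted (no exclusion of buried
  waters, which the input labelling is free to implement).
* Sodium appears only in trajectory bookkeeping; thermodynamic mixtures are
  salt-free.

## Limitations

Absolute capacities/activities of FA/4VG-rich mixtures are trend-level
(single-parameter symmetric binaries, no temperature dependence, fixed
30 °C system). The LLE flash is a local method; pathological multi-root
regions could require more initializations than the per-component trials
used. CO2 is removed from the liquid instantly (no solubility), the
acylation step is not modelled thermodynamically, and plain-text frame
formats only (XYZ/GRO/PDB subset) are supported — binary trajectory formats
are intentionally out of scope.
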