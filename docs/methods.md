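# Methods

## Physical model

Iodine stain enters tissue from a bath at the specimen surface, diffuses
through the pore water and sorbs linearly onto the solid tissue matrix. In
one spatial dimension with zone-wise constant properties, the pore-water
concentration c(x, t) [mmol/L] obeys

    (θ + ρ_b K_d) ∂c/∂t = ∂/∂x ( θ D ∂c/∂x ),

with per-zone porosity θ [-], dry-matter bulk density ρ_b [kg dry tissue per
L whole tissue], linear sorption partition coefficient K_d [L solution per kg
dry tissue], and a single aqueous diffusion coefficient D [m²/s]. The
CT-visible quantity is the total concentration per unit whole-tissue volume,

    C_T = (θ + ρ_b K_d) c = β c,

with capacity factor β. Within a homogeneous zone the equation reduces to
pure diffusion of c with effective coefficient D/R, retardation
R = 1 + ρ_b K_d / θ.

Boundary conditions: a constant areal influx N [m·mmol/(L·s)] at x = 0 (the
bath-facing surface) and zero flux at x = L. Initial condition c = 0. Two
flux conventions are supported (`SolverConfig.flux_convention`): "total"
(default) applies N directly to the total-concentration balance so that
∫ C_T dx = N t exactly; "pore" divides by the surface porosity first. The two
are the same equation written in different variables; the default makes the
global mass balance exact in the discrete solution.

## Reference domain

| zone        | extent (mm) | θ    | ρ_b (kg/L) | K_d (L/kg) | R     | β     |
|-------------|-------------|------|------------|------------|-------|-------|
| skin        | 0 – 0.7     | 0.8  | 0.16       | 200        | 41    | 32.8  |
| connective  | 0.7 – 0.8   | 0.8  | 0.16       | 100        | 21    | 16.8  |
| muscle      | 0.8 – 30    | 0.8  | 0.265      | 200        | 67.25 | 53.8  |

D = 1e-9 m²/s and N = 1.4e-6 m·mmol/(L·s) throughout. The connective→muscle
capacity jump β ratio is 53.8 / 16.8 ≈ 3.20, which produces the
characteristic step in total concentration at 0.8 mm while pore concentration
stays continuous. Zones are half-open intervals [start, end); a position
exactly on an interface belongs to the deeper zone.

The 30 mm extent is a numerical stand-in for a semi-infinite tissue block.
Note a caveat: with the calibrated parameters, the depth at which the day-30
total concentration falls to 1 % of its surface value converges to 2.16 cm
(verified on 600/60 s, 1200/30 s and 2400/15 s discretisations), slightly
beyond the 2 cm sometimes quoted for this threshold. Alternative readings —
the 1 %-of-surface threshold on *pore* concentration (2.01 cm) or relative to
the muscle *peak* (2.05 cm) — land near 2 cm, but this package keeps the
explicit definition (total concentration, surface reference) and reports the
converged 2.16 cm rather than adjusting the definition to match. The 30 mm
wall is far enough away that it does not influence any profile shallower than
~2.5 cm at day 30.

## Numerical scheme

Cell-centred finite volumes on a per-zone uniform grid (each zone receives
cells in proportion to its length, minimum three). Face conductances use the
harmonic mean of θD across the face, which is exact for piecewise-constant
coefficients and keeps flux continuous at zone interfaces. Time integration
is backward Euler, unconditionally stable, solved per step with a banded
(tridiagonal) direct solve. Conservation: the discrete total mass equals
N t to machine precision; the test suite enforces 0.1 % (loose) and the
solver itself is exact up to roundoff.

Verification oracles:
- Closed form for a homogeneous half-space with constant surface flux:
  c(0, t) = (N / θD) √(4 a t) / √π with a = D/R; agreement within 0.5 %.
- An independent explicit-Euler reference integration on the zoned problem.
- Self-convergence under simultaneous grid/time refinement (< 0.5 %).

Default discretisations are this package's own choice: 600 cells / 60 s
steps for reporting-quality fields, 320 cells / 900 s for fitting (where
hundreds of forward solves are needed). Both are in the asymptotic regime;
the fitting grid changes day-30 profiles by well under 0.5 %.

## Calibration chain

Raw 16-bit grayscale → corrected grayscale → HU → molarity:

1. **Per-scan affine correction** removes session-to-session scanner drift:
   `corrected = (raw − raw_air) · target_range / raw_range + target_air`,
   using each scan's measured air value and air-to-reference range. The
   bundled reference table maps five serial scans onto two common air levels
   (13192 for the first three sessions, 15206 for the last two).
2. **HU anchoring** uses two-point calibration against air (−1000 HU) and
   the formalin/water reference (0 HU): grayscale anchors 12800 and 18202.
3. **Molarity**: conc = HU / k − 150 − (50 if the specimen is stained),
   floored at zero, with k = 4.6 HU per (mmol/L). The 150 term is the
   unstained-tissue baseline; the 50 term compensates the HU shift of
   stain-free fixative in stained specimens. `k_factor_regression` refits k
   from reference-vial measurements (ordinary least squares); on the bundled
   vial table the regression slope is 3.38, noticeably below the adopted 4.6
   — the package exposes both and defaults to the adopted constant.

Effective staining time: solution stagnation and replacement mean actual days
map to effective days as identity up to day 5, a plateau at 5 until day 24,
then day − 19 afterwards (`effective_day`).

## Synthetic scan generator

`synth.generate` runs the forward model at a scan schedule (default: control
plus effective days 5, 5, 15, 30), then pushes concentrations *backwards*
through the calibration chain — molarity → HU → anchored grayscale → per-scan
distorted raw grayscale — and adds Gaussian noise (default σ = 80 grayscale
units, `numpy.random.default_rng(seed)`).

One deliberate choice: the generator's baseline HU for unstained tissue
defaults to k × 150 = 690 HU rather than a nearby literature value of
750 HU, so that generate → convert is an exact inverse (the control scan
converts to exactly zero, and noiseless closure holds to ~1e-13). Pass
`baseline_hu=750.0` to reproduce the alternative; converted concentrations
then carry a constant ≈13 mmol/L offset before the zero floor.

The generator covers a single 1-D transect per scan with shared positions
across scans; it does not model beam hardening, partial-volume blur, or
2-D/3-D geometry.

## Inverse calibration

`StainTransportModel` (statsmodels-style: model object, `fit()` returns a
results object with `params`, `summary()`, `predicted()`, `plot()`). Free
parameters are named `kd:<zone>` and `nbc`; zones sharing a name share one
K_d. Fitting runs `scipy.optimize.least_squares` (trust-region reflective)
in log10 parameter space with bounds K_d ∈ [1, 1000] L/kg,
N ∈ [1e-8, 1e-4] m·mmol/(L·s). Residuals are model-minus-observed total
concentration at each profile point, pooled over all profiles; each
objective evaluation is one forward PDE solve over the union of observed
effective days.

On noiseless synthetic data the fit recovers all four parameters to machine
precision from a distant start (K_d = 50/50/50, N = 5e-7) in ~45 forward
solves; with 5 % multiplicative noise, recovery is within 15 %. At least two
distinct effective days are required — a single time cannot separate K_d
from N.

## Limitations

- One-dimensional, zone-wise homogeneous, linear (Henry) sorption; no
  saturation, no concentration-dependent D, no swelling or fixation effects.
- Constant influx N is an idealisation of the bath boundary; a
  bath-concentration (Dirichlet/Robin) condition is not fitted, though a
  `bath_concentration` field exists on the domain for forward what-if runs.
- The calibration chain assumes the scanner response is affine per session
  and that the two-point HU anchoring holds across the full grayscale range.
- The k-factor discrepancy (regressed 3.38 vs adopted 4.6 HU per mmol/L)
  propagates linearly into absolute molarities; relative profile shapes and
  fitted K_d ratios are unaffected.
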