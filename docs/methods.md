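# Methods

## Trap-force model

The cell is a thin dielectric cylinder (radius ρ, thickness t ≪ ρ)
lying with its flat faces parallel to the propagation/polarization
plane, as a trapped RBC orients. The induced polarization in the beam's
field gives a gradient force; integrating the Gaussian intensity

    I(φ) = (2 Pw / π w0²) · exp(−2((rt + ρ cos φ)² + ρ² sin²φ)/w0²)

over the curved wall yields the closed-form magnitude

    |F| = (16 n1 Pw ρ² / (c w0²)) · |m²−1|/(m²+1)
          · exp(−2(ρ² + rt²)/w0²) · B(4 rt ρ / w0²),

with `B = I0`, the modified Bessel function of the first kind, order
zero: the angular integral `∫ exp(−a cos φ) dφ = 2π I0(a)`. At zero
offset the factor is exactly 1, giving the small-offset form. The
identification of the angular correction with I0 is verified at run
time against `trap_force_numeric`, an independent 2-D quadrature of the
surface integral (trapezoid in φ — spectrally accurate for the periodic
analytic integrand — and Gauss–Legendre in y across the thickness),
normalised to the same prefactor convention; the two agree to ~1e-14
relative, far inside the 1% oracle tolerance used by the tests. The
cylinder thickness cancels between the volume-normalised polarization
and the area element, so it never appears in the magnitude.

Numerical notes: the product `exp(−2(ρ²+rt²)/w0²)·I0(a)` is computed
with the exponentially scaled Bessel function `i0e` — since
`a = 4 rt ρ/w0² ≤ 2(ρ²+rt²)/w0²` (AM–GM), the combined exponent is
never positive and the evaluation cannot overflow. The quadrature
doubles its φ resolution until the result changes by < 1e-6 relative
(cap 4096 nodes). Force direction is reported as a sign along the
polarization axis: −1 (restoring) for `m > 1`, +1 for `m < 1`, zero
magnitude at index matching.

The small-offset approximation is judged by the dimensionless argument
`4 rt ρ/w0²`; a warning is logged above 0.1. Its relative error grows
monotonically with the argument and is below 0.1% at 0.05 (series:
`I0(x) = 1 + x²/4 + …`).

Default optical parameters — 30 mW at the trap, 1064 nm, w0 = 3 μm,
n1 = 1.334 (aqueous serum), m = 1.05 (RBC over medium) — are
representative configuration values for a near-infrared RBC tweezer,
not measured quantities; every force computation takes them explicitly.

## Drag model

The stretching force is the viscous drag from stage motion at constant
speed, modelled as Stokes sphere drag with a single dimensionless shape
factor: `F = shape_factor · 6π η r v`, η defaulting to 1.0 mPa·s
(aqueous medium, room temperature) and shape factor 1.0. Disc geometry
and wall proximity are absorbed into the shape factor, which
`calibrate_shape_factor` fits by through-origin least squares from
measured force/speed pairs. Unsteady drag, Faxén wall corrections and
deformation feedback are out of scope.

## Morphometry

`render_cell` draws an anti-aliased ellipse (1-px linear edge ramp from
the approximate signed distance to the boundary) plus Gaussian pixel
noise; a half-contrast threshold recovers the analytic outline to
sub-pixel accuracy. `segment_cell` uses Otsu's between-class-variance
threshold, infers polarity from the frame border, keeps the largest
connected component and fills holes. `measure_geometry` reports area as
pixel count × pixel area and semi-axes/orientation from second central
moments (the equivalent ellipse), which is noise-robust compared with
boundary fitting; tests show ≲0.5% radius error at the default
0.05 μm/px for cells of 2–8 μm and axis ratios 1–2, and < 3% bias at
pixel noise up to 10% of contrast. A cell's "diameter" is reported as
`2·r_equiv = 2√(area/π)`; the longitudinal semi-axis `r_max` is used
where the stretch axis matters.

## Elasticity metrics

Signed percent differences `%DR = 100(R − R_T)/R` and
`%DA = 100(A − A_T)/A` compare the trapped state against the free
(compression) or stretched (elongation) state. Stiffness is
`k = ΔF/ΔR` with `ΔR` the longitudinal radius change from trapped to
stretched (the stretch acts along the drag axis; `r_equiv` is available
by flag) and `ΔF` the net stretching force `drag − trap` by default
(`force_mode="drag"` uses the drag alone; the published summary values
cannot adjudicate between the two conventions). With forces in pN and
radii in μm, k is directly in μN/m. The per-cell axis ratio is taken
from the stretched state when present, else the trapped state.

## Trimming

Data reduction is the manual sort-and-delete procedure used for the
published cohort figures, encoded as explicit recipe data rather than
prose: each step sorts by one metric and removes fixed counts from each
end, ties broken by cell id so the removal set is independent of input
order. The built-in `hbss_fig6` recipe removes 2+1 (trap force), 2+2
(radius), 1+3 (area percent difference) = 11 of 49 cells; `hbas_fig6`
removes 2+2, 1+2, 0+3 = 10. Each application returns an audit log of
removed ids per step. Statistical outlier tests are deliberately not
used; the point is to reproduce the recipe exactly.

## Cohort statistics

Summaries report n, mean, sample SD (n−1 denominator), min and max.
Comparisons use the two-sided two-sample t-test in both pooled-variance
(df = na+nb−2) and Welch forms, flagged at the 0.05 and 0.01 levels.
When both samples are constant and equal, p = 1 by convention. Test
code cross-checks p-values against a permutation oracle and verifies
type-I calibration (rejection rate 0.05 ± 0.02 under the null across
1000 replicate pairs). No multiple-testing correction is applied,
matching the analysis being reproduced.

## Synthetic cohorts

The generator encodes the study conditions; its defaults are the
published cohort statistics wherever one exists, with unpublished
dispersion parameters chosen once as documented defaults.

**Morphology survey** (per cohort, default n = 200): diameters
~ Normal(4.02, 0.60) μm for sickle trait, Normal(6.60, 0.90) μm for
sickle anemia, truncated above 1 μm; free axis ratios
~ Normal(1.05, 0.03) clipped ≥ 1 (free RBCs are nearly round);
orientations uniform. Optionally each cell is rendered at 0.05 μm/px in
a 256-px frame with pixel noise at 5% of contrast.

**Elasticity experiment** (per cohort, default n = 49 = 7 subgroups ×
7 cells): free `r_max` from a truncated Normal on the published radius
range ([3.84, 5.38] mean 4.67 μm for HbAS; [4.45, 6.12] mean 5.24 μm
for HbSS), with scale set to a quarter of the range width — the printed
range read as a ±2σ band. Trapped radii apply an isotropic compression
drawn positive from Normal(12, 4)% for HbAS and Normal(8, 4)% for HbSS:
the two campaigns' published conclusions require the trait cohort to
compress more, so a single shared default would contradict the design
being emulated; the across-cohort mean stays 10%. Trap forces are drawn
about the published means (0.26/0.33 pN, coefficient of variation 0.25)
truncated below 95% of the cell's drag force, so every record satisfies
drag > trap (the trapped-equilibrium feasibility constraint; the
truncation shifts the cohort mean by ≪ 1%). Alternatively
`force_model: physical` computes each trap force from the optical model
at a random offset. Latent stiffness is drawn about the published means
(1.08/4.47 μN/m, cv 0.25, positive), and the stretched radius inverts
the stiffness definition: `r_stretched = r_trapped + (F_drag − F_trap)/k`.
Areas are elliptical (`π r_max r_min`). Recorded values carry
multiplicative measurement noise (1 + ε), ε ~ Normal(0, 0.002) — the
sub-pixel accuracy scale of moment-based radii at the default pixel
size — applied to the recorded, never the latent, geometry; the rare
noise draw that would invert the stretched/trapped ordering is redrawn
so the physical ordering holds in every record.

**Subgroup design.** The seven published subgroup drag means
(0.635–4.31 pN, mean 1.84 pN) are mutually inconsistent with the
published cohort-mean drags (1.20/1.27 pN), and rescaling that profile
to the cohort mean would push the weakest subgroup's drag below the
trap force, leaving some cells with no resolvable stretch. The default
subgroup design therefore spreads the cohort mean across seven drag
targets at multipliers 0.70–1.30 (mean preserved exactly); stage speeds
are back-solved from these through the Stokes model at the cohort mean
radius (≈ 8–21 μm/s, the order of magnitude used experimentally). The
published seven values remain available as a constant and as
calibration targets for the shape-factor fit, and explicit per-subgroup
targets or speeds can be configured.

Randomness uses NumPy's PCG64 (`default_rng`) throughout, seeded per
dataset; identical (config, seed) gives byte-identical datasets.

## What the synthetic data does and does not show

Passing recovery tests shows the pipeline is self-consistent: the
metrics invert the generative equations exactly at zero noise
(round-trip identity to 1e-6 relative) and recover configured cohort
means within sampling error (≲ 8% at n = 49, ≲ 1% at n ≈ 10⁴) under
realistic measurement noise. It does not validate the physical model
against real cells: real RBCs are biconcave discs rather than ellipses
or thin cylinders, their compliance is viscoelastic and
strain-dependent rather than a single linear k, refractive indices vary
between cells, and segmentation of phase-contrast micrographs is harder
than of the clean synthetic frames. Cohort differences are built in by
configuration, so significance results demonstrate the statistical
machinery, not a biological finding.

## Problem sizes

Default analyses use the experiment-scale sizes: 49-cell elasticity
cohorts, 200-cell morphology surveys, and a 9996-cell (7 × 1428)
scaled-up generator run for tight Monte-Carlo checks — the largest
multiple of seven below 10⁴, since elasticity cohorts divide evenly
into the seven subgroups.

## Known limitations

The closed-form trap force describes a centred-beam, thin-cylinder,
uniform-field idealisation; no axial trapping, torque transients or
Maxwell-stress formulation. Drag ignores wall corrections beyond the
scalar shape factor. The generator draws forces and stiffness
independently per cell (no radius–stiffness correlation), and the
morphology and elasticity populations are modelled as two distinct
datasets, mirroring the two measurement campaigns whose size statistics
are mutually inconsistent as one population.
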