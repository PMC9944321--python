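# Methods

This note records the models implemented in `mofsans`, the defaults and why
they were chosen, the numerical choices that matter, and what the synthetic
data do and do not establish about real measurements.

## Scattering-length-density arithmetic

All contrast calculations derive from bound coherent scattering lengths,
with protium and deuterium pinned to the conventional values
b_c(¹H) = −3.742 fm and b_c(²H) = +6.675 fm and the remaining elements from
the standard Sears compilation (`nsld_tables`, version 2024.1). Water
molecular volumes come from the ambient densities 0.9970 g·cm⁻³ (H₂O) and
1.1044 g·cm⁻³ (D₂O); volumes are assumed additive, so the mixture SLD is
affine in the D₂O volume fraction f_D and the match point is a closed-form
linear inversion. Match points are kept as exact fractions internally and
rounded to whole percent only at the reporting layer (53.6% → 54%).

A `Composition` partitions its hydrogens into exchangeable sites (bound to
N/O/S; they adopt the solvent H/D ratio for a configurable
`exchange_fraction`, default 0.9 for folded proteins — the common SANS
assumption) and non-exchangeable sites (replaced by D when the solute is
perdeuterated). The molecular volume is derived from the *as-specified*
formula and density before any substitution, so deuteration changes Σb but
not the occupied volume, as it should. The host framework's chemistry is
never reconstructed: its NSLD (3.15 × 10⁻⁶ Å⁻²) and skeletal density
(1.783 g·cm⁻³) are configuration inputs.

## The hierarchical framework model

The dry porous framework scatters as

I(q) = A·q⁻ⁿ + B/(1+(qξ)ᵐ) + Σᵢ₌₁³ Cᵢ·exp(−(q−q₀ᵢ)²/2Dᵢ²) + I_bgd.

Sign convention: n is positive in the denominator; a reported "exponent of
−3.4" is n = 3.4. The correlation exponent m is free (m = 2, the
Ornstein–Zernike case, when not fitted). Fitting is σ-weighted bounded
least squares (lmfit/trust-region-reflective) with multi-start: the first
start is the supplied initial guess, subsequent starts perturb every free
parameter by a uniform factor in [1±0.5], deterministically seeded. Bounds
only enforce the parameter domain (positivity, q₀ inside the data range);
where experimental σ is missing or non-positive, σ = √I floored at 1% of I
stands in (counting statistics). After convergence the Gaussian peaks are
reported in ascending-center order, since a perturbed start can converge
with the labels permuted. Fitted peak centers default to 0.085, 0.145 and
0.20 Å⁻¹ in the generator — plausible values inside the ordered-pore window
(0.06–0.25 Å⁻¹); they are configuration, not physics, because the true
centers depend on the lattice constant.

## Guinier analysis

ln I is regressed on q² over the largest low-q window satisfying
qmax·Rg ≤ 1.3 (the standard globular validity product), found by fixed-point
iteration on Rg with cycle detection. When the window holds at least ten
points, a quadratic-in-q² correction term is added and kept only if it
improves the fit significantly (F-like criterion) without flipping the
leading slope; the reported Rg comes from the q²-coefficient. This removes
the ~1.5% window bias the pure linear fit shows for compact shapes already
at qRg ≈ 1.3, while reducing exactly to the linear fit on ideal Guinier
data.

## Indirect Fourier transform

P(r) is expanded on 101 equally spaced nodes over [0, Dmax] with
P(0) = P(Dmax) = 0 imposed, and the σ-weighted linear system
I(q) = 4π∫P(r)·sinc(qr)·dr is solved with second-difference (curvature)
regularization and nonnegativity (scipy NNLS with a bounded-least-squares
fallback when the active-set algorithm stalls). Because the nonnegativity
constraint itself regularizes strongly, the classical L-curve is degenerate
here — the solution seminorm barely responds to the weight — so the
automatic α is chosen by a discrepancy-style rule instead: the largest
trial α whose reduced χ² stays within max(1, 1.2·χ²_min). Derived
quantities follow from moments: Rg² = ∫r²P dr / 2∫P dr, I(0) = 4π∫P dr;
P(r) peaks are local maxima with prominence ≥5% of the global maximum.

The Dmax scan runs the IFT over a grid with one shared α (chosen at the
upper bound so χ² is comparable across the grid) and returns the smallest
Dmax at the χ² plateau — consecutive change below 2% relative (floored at
χ² = 1, below which changes are noise) or χ² within 4% of the grid minimum
— whose P(r) carries ≤10% of its maximum near the endpoint. The 10%
endpoint threshold allows for regularization smearing on noisy data; on
clean single-particle curves the scan lands within a grid step of the true
diameter.

## Porod volume and Kratky heuristic

V_p = 2π²·I(0)/Q with Q = ∫q²I dq integrated trapezoidally over the data,
extended to q = 0 with the Guinier form and to q → ∞ with a q⁻⁴ tail whose
level averages q⁴I over the last quarter of the curve (several form-factor
oscillations; a short tail window would alias the oscillation phase). The
Kratky classification calls a curve "folded" when the lightly smoothed q²I
has its global maximum in the first 70% of the range and the final 20%
falls below 60% of that maximum; a Gaussian-chain plateau fails both.

## Debye scattering and contrast handling

For coordinates, each heavy atom with its implicit hydrogens becomes one
effective scatterer, b_eff = b_c + Σb(H/D after deuteration and exchange)
− ρ_solvent·V_group, with Fraser–MacRae–Suzuki displaced volumes. The Debye
double sum is exact up to 1000 scatterers; above that a pair-distance
histogram (0.5 Å bins) with per-bin mean distance and a second-order
variance correction evaluates the sum, agreeing with the exact path to
better than 10⁻⁴ relative (the exact path remains available and is the test
oracle). An optional uniform hydration shell adds voxel beads (2 Å grid,
3 Å thick, 10% density excess) around the envelope; no explicit water
geometry is modelled.

## Cage lattice and assemblies

Cage radii default to the published framework dimensions (9 / 24.5 / 30 Å
cages, 10 / 12 Å apertures). The center-to-center distance of adjacent
mesocages is nowhere printed; the default 51.5 Å is the value consistent
with the cage diameters and the confined-dimer length scale, and it is
configurable. Assemblies place one recentered monomer per cage along a
connected path, long axis along the cage-to-cage direction ("side-by-side"
= parallel axes; "perpendicular" rotates every second copy by 90°); a
monomer whose bounding sphere exceeds its cage radius is rejected.
Placement geometry (centering, extent) weighs atoms by |b_eff| so a
near-contrast-matched template still places sensibly. assembly_rg uses the
parallel-axis theorem and is exact for duplicated point clouds.

Classification ranks candidates by reduced χ² after a free intensity scale
plus, by default, a free flat background — a matrix-subtracted curve
retains an unknown incoherent offset. Mixtures are limited to the two
best-ranked candidates with a single weight in [0,1], deliberately
minimal. If no candidate (nor the mixture) reaches χ² ≤ 2 the result is
flagged inadequate. A P(r)-space route (L2 distance of area-normalized
distributions) is also provided.

## The synthetic generator

Defaults are the study conditions: 250 log-spaced q points over
0.0015–0.5 Å⁻¹ (the stated instrument coverage); dry-state ξ = 265 Å and
n = 3.4 with three Bragg peaks; wet matched state with the peaks removed,
the low-q level dropped (A = 2 × 10⁻⁷, a ~25× drop — solvent penetrates the
large-scale disordered pores, and at this level the correlation shoulder
remains identifiable, as the wet-state fit requires) and the background
raised by the protonated solvent fraction. The noise model is
σ(q) = noise_level·√(I(q)·I_max) — counting statistics — with
noise_level = 0.002 (0.2% at the forward intensity, giving ~5–10% relative
error on the protein shoulder, typical of reduced SANS from a strong
scatterer). The hosted-protein signal is scaled by a 5% protein volume
fraction, consistent with the reported loading (≈12 µmol per gram of
framework at ~82% efficiency). A seed fixes every random draw; equal seeds
give bit-identical curves. Ground-truth parameters, including the
protein-attributable signal (assembly term plus the flat incoherent
excess, both of which survive matrix subtraction), ride in curve metadata.

The synthetic GFP-scale monomer (`synthetic_gfp`) is a programmatic
stand-in, not experimental coordinates: an 11-stranded β-barrel of ~42 Å
length and ~24 Å outer diameter with a central helix and terminal loops,
~1900 heavy atoms with residue-template hydrogen counts and labile-H
flags, coordinate Rg ≈ 17.5 Å. It reproduces the size, composition,
H/D bookkeeping and contrast behaviour of a ~27 kDa β-barrel protein; it
does not reproduce the true fold's internal polarity segregation or
surface texture, so coordinate-level conclusions (e.g. CRYSON-grade
hydration effects) do not transfer. In particular, with a uniform shell
the apparent Rg of a *protonated* protein in D₂O comes out slightly
*below* the coordinate Rg (the shell's positive contrast opposes the
protein's negative contrast), whereas shell models fitted to experimental
curves can report larger values; this deviation is documented rather than
tuned away.

What passing tests show: the estimators recover known truths under
realistic counting noise, the subtraction and classification loop closes,
and all analytic oracles agree. What they do not show: performance on
real, resolution-smeared, imperfectly reduced data with structure-factor
effects, concentration series, or partially denatured protein.

## Known limitations

* No resolution smearing beyond the optional Δq column (not convolved by
  default); no multiple scattering; no polarization.
* The IFT α rule favors smoothness at χ² ≈ 1; very low-noise data may be
  slightly over-smoothed relative to a perceptual-criteria choice, shifting
  Dmax by a few Å.
* Orientation handling in assemblies is rigid (no per-cage orientation
  averaging beyond the side-by-side/perpendicular modes).
* The hydration shell is uniform; exchange in buried sites is treated with
  a single global fraction.
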