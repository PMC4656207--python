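# Methods

This note records the models, conventions, numerical choices and known
limitations of phaseloop, in the order the data flows.

## Conventions

* Structure factors use the positive-exponent convention
  F(h) = V·⟨ρ(x)·e^{+2πi h·x}⟩ over fractional coordinates x; map synthesis
  uses the conjugate kernel.  F(000) is excluded everywhere, so synthesized
  maps are zero-mean by construction.
* Unique reflections live on the Friedel hemisphere (h>0, or h=0,k>0, or
  h=k=0,l>0); Friedel mates are completed by conjugation at synthesis time.
* Fractional coordinates are the internal standard; orthogonalization puts
  the cell edge a along Cartesian x.
* Phases are degrees in [0,360) at the API surface; wrapped differences are
  reported on [0,180].
* FFT grids are chosen with spacing ≤ d_min/3 (not the Shannon d_min/2) to
  suppress aliasing through the nonlinear real-space operators, with
  FFT-friendly sizes from `scipy.fft.next_fast_len`.

## Scattering model

Atoms carry a single-Gaussian form factor f(s) = a·e^{−b·s²/4} (s = 1/d)
with one (a,b) pair per element (C,N,O,S and a carbon-like dummy scatterer
for auto-built pseudo-atoms).  The exact real-space pair of this form
factor is a Gaussian of variance (B+b)/(8π²), which is what
`gaussian_density_from_model` rasterizes — so the direct-summation and
rasterize-then-FFT routes agree to sampling error (<2% relative RMS at
d ≥ 2.5 Å on the test fixtures, ~1e-6 at fine sampling).  One-term form
factors are a deliberate simplification: adequate above ~2 Å, increasingly
wrong below; this package never works below 2.3 Å.

## EM-map preparation

Sharpening multiplies each coefficient by e^{+B·s²/4}; with the map's own
B unknown, B is user-supplied (no Guinier estimation).  FSC-based
weighting applies C_ref = √(2·FSC/(1+FSC)) per shell, zeroing shells with
FSC ≤ 0; frequencies beyond the curve's high-resolution end are zeroed
(an FSC table normally stops where the signal does).  Magnification
correction rescales features by the calibration factor about the cell
center with trilinear resampling, dividing values by scale³ so the
integrated density is conserved; the cell is kept fixed so downstream
bookkeeping never sees two cells for one map.  Boxing estimates the
molecular diameter as that of the smallest sphere containing voxels above
mean + 1σ and builds a cubic P1 cell of edge ≥ 2× that diameter — smaller
padding under-samples the molecular transform and is refused.

## Molecular replacement

Desk-scale exhaustive search, not maximum likelihood.  The boxed map's
complex transform, phase-referenced to the box center, is interpolated
trilinearly in reciprocal space at rotated reciprocal vectors; the
rotation score is the Pearson correlation between observed amplitudes and
|G(R^T s)| over a resolution window, on a ZYZ Euler grid whose α spacing
widens by 1/sin β to avoid pole oversampling, followed by a built-in
refinement pass at a quarter step around the top candidates.  The
translation function builds symmetry-expanded structure factors through
the phase-shift theorem, F(h) = Σ_j G(R^T s(hC_j))·e^{2πi(hC_j·t + h·v_j)},
and scores the same correlation on a fractional grid; the top score's
significance is the Z-score against the remaining grid scores.  Solutions
are defined only modulo crystal-symmetry-equivalent orientations and the
space group's permitted origin shifts (in P2₁: x,z shifts of ½, y free);
amplitude correlation is scale-invariant by construction.  Ties are broken
by lexicographic Euler order, then fractional-translation order.

## Density modification

The Wang-style solvent mask thresholds the sphere-smoothed |ρ| (periodic
FFT convolution with the analytic sphere transform, default radius 5 Å) at
the solvent-fraction quantile.  Two lessons are baked into the defaults
and worth stating because they decide whether the whole loop converges:

* **The mask must err toward keeping protein.**  A mask computed from a
  tight geometric solvent fraction bites into the molecule once smoothing
  blurs the boundary, and flattening then erases true signal on every
  pass (tens of degrees of phase error per pass).  The synthetic scenario
  therefore measures its solvent fraction with a generous 4 Å atomic
  radius; with that margin a full modification pass applied at the true
  phases costs only ~2–4°.
* **The histogram target must describe the same kind of region it is
  imposed on.**  The reference histogram is computed from a synthetic
  model's map at the working resolution *through the same Wang mask*
  (same fraction and smoothing radius) that density modification uses.
  Matching a tight atomic-envelope histogram onto the broader Wang region
  inflates contrast and destabilizes the iteration.

NCS averaging blends each operator's spherical source region toward the
mean of ρ(x) and ρ(op(x)) (trilinear, periodic), with a 3 Å cosine feather
at the sphere edge.  With exact operators it is close to idempotent but
not exactly: the band-limited periodic density inside the two spheres is
not exactly two-fold related, because each copy sits in a different
ripple/periodic-image environment (~1.5° of phase cost on a truth map).
On maps with additive noise the operator is neutral-to-helpful within 1°;
in isolation on strongly phase-noisy maps it can be globally neutral or
slightly harmful, because the spheres cover only ~a quarter of the cell
while the noise lives everywhere — its value is realized jointly with
solvent flattening inside the modification pass, where ablations show the
all-constraints pass clearly strongest.  Sphere masks and fixed operators
are a stated simplification; production systems refine fitted envelopes.

**Prime-and-switch.**  Each inner cycle synthesizes an m·F_obs·e^{iφ} map,
applies the enabled constraints, back-transforms, and replaces every
active reflection's phase with the modified map's phase — the starting
(model-derived) phases are never recombined inside DM; only the first map
is "primed" with them.  New figures of merit come from shellwise σA
between observed and modified-map amplitudes.  The extension schedule
(default: four shells equally spaced in 1/d³ between the EM and X-ray
resolutions) advances one shell per inner cycle until exhausted; remaining
inner cycles (default total 5) settle at the final resolution, and
convergence (mean |Δφ| < 1° per cycle) may only be declared once fully
extended.  One pass per shell deliberately leaves the first DM stage only
partially converged: the outer loop's later cycles then genuinely improve
on it, which is the regime the iterated method is designed for.  This
approximates the prime-and-switch strategy without the original
statistical-density-function machinery; the bias-removal contract is what
is preserved.

## Model building

Peaks are local maxima above mean + σ_cut·std, sub-voxel refined by a 1-D
quadratic per axis.  Chains grow greedily from the highest unused peak,
appending the highest peak at 3.8 ± 0.7 Å at either end; fragments shorter
than 4 are discarded (their members are released for other chains).
Determinism comes from height-then-lexicographic tie-breaks.  There is no
side-chain building, sequence docking or refinement: pseudo-Cα phasing at
uniform B = 30 Å² is enough to drive the loop at this scale, and the
σA-derived FOMs automatically down-weight a poor model.  Cα recovery
counts built atoms within 1.5 Å of a true main-chain atom after applying
crystal symmetry and the best origin shift, found by FFT cross-correlation
of Gaussian-smeared atom rasters on a ~1 Å grid (equivalent to the
exhaustive grid search, tractable at any cell size).

## σA, figures of merit, combination

E-values normalize amplitudes to ⟨E²⟩ = 1 in equal-count resolution shells
(shells below 8 reflections merge with a neighbour).  σA per shell is the
Pearson correlation of matched (E_obs, E_calc) clipped to [0, 0.999] — a
centered estimator is required because E-values are positive (the raw
product ⟨E_obs·E_calc⟩ is ~0.8 even for independent sets); the correlation
has the right limits (1 for a perfect model, 0 ± 1/√n under the null) and
replaces the maximum-likelihood refinement of the full treatment.
Figures of merit are m = I₁(X)/I₀(X) with X = 2σA·E_o·E_c/(1−σA²)
(centric reflections, flagged by h·R = −h, use tanh(X/2)).  The inverse
m → X uses the Best–Fisher seed plus vectorized Newton iterations
(round-trip error < 1e-10).  Phase combination is unimodal von Mises:
concentration vectors add, the combined FOM is I₁(|resultant|)/I₀(...),
clipped to [0, 0.9999].  Full Hendrickson–Lattman coefficients are not
needed because both sources here are unimodal.  The pipeline only ever
combines (DM phases, built-model phases) — never model with model.

## The outer loop

Default four cycles of DM → AMB → PHSCMB.  A wMPE/FOM regression right
after PHSCMB is expected and tolerated (the annealing-heating analogy);
only a material (>1°) DM-stage regression in two consecutive cycles aborts.
An optional early exit triggers when the mean FOM changes by <0.005
between cycles.

## Synthetic study conditions

One NCS copy is a toroidal-helix Cα trace (3.8 Å spacing, ~0.1 Å jitter,
major/tube radii ~10/4.2 Å with ±5% seeded variation) with a side-chain
pseudo-atom 2 Å outward per residue; a proper two-fold with a seeded axis
generates the second copy, placed to avoid clashes, and the exact
operators are returned.  Defaults mirror the emulated experiment: 60
residues per copy, a P1 cell of 61 × 64 × 67 Å, observed amplitudes to
2.3 Å with 5% multiplicative Gaussian noise, EM-like starting phases at
4.87 Å with 45° wrapped-Gaussian phase noise (constant FOM e^{−σ²/2} ≈
0.73, the expected cosine of the injected error), and a four-shell
extension schedule.  With those structural defaults the true solvent
fraction is ~0.90, not the ~0.5 of a typical protein crystal; the scenario
measures the real fraction from the ground-truth coordinates and uses
that, since density modification needs the actual value.  Consequences to
keep in mind when reading test results: very high solvent makes density
modification stronger than in a realistically packed cell, and the exact
NCS operators and noise-free constraints remove the envelope- and
operator-error failure modes of real data — passing tests show the
machinery and its couplings work, not that the method would succeed on any
particular crystal.  All randomness flows from a single seed through
per-purpose child streams; bundles are bit-reproducible.

Problem sizes used by the test suite and the acceptance script: the
standard scenario has ~45,000 unique reflections on a 80×84×90 grid; the
MR benchmark uses a 40-residue single copy in a 42×46×40 Å P2₁ cell at
3.5 Å; the builder benchmark a 40-residue trace at 2.5 Å.  These sizes
keep a full pipeline cycle at a few seconds while leaving every quantity
statistically stable.

## Known limitations

* Trilinear interpolation everywhere (NCS averaging, placement, transform
  sampling) is the resolution-limiting approximation.
* Spherical NCS masks without operator refinement; no automatic operator
  detection.
* Amplitude-correlation MR scoring is a monotone proxy for likelihood,
  fine at toy scale, not competitive on real data.
* No anomalous scattering, no free-set cross-validation, no atomic
  refinement; centric handling is limited to the P1/P2₁-level toys the
  package targets.
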