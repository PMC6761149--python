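# Methods

`oligosaxs` implements the solution small-angle X-ray scattering (SAXS)
analysis chain used to decide whether a protein is monomeric or forms
higher oligomers: profile reduction, reciprocal-space metrics, the
indirect Fourier transform, coordinate-model scattering, mixture and
ensemble decomposition, and ab initio shape reconstruction. This note
describes the models, the numerical choices, and what the synthetic
phantoms do and do not establish.

## Profiles and conventions

A scattering profile is the orientationally averaged intensity I(q) on a
strictly increasing momentum-transfer grid q (Å⁻¹), with optional
per-point standard errors σ. Grids in nm⁻¹ are converted at the I/O
boundary (q/10) and everything internal works in Å⁻¹. Coordinate models
are point scatterers: one site per non-hydrogen atom with the element's
electron count as weight (atomic mode), or one site per residue at the
heavy-atom centroid with uniform weight (residue mode, the default).
The residue representation has no atomic form factors or hydration
shell, so χ values are comparable between models fitted to the same
data (ranking) but not to hydration-aware atomic programs.

## Concentration series

Normalised curves I/c depend linearly on c to first order in the
structure factor, so the infinite-dilution curve is taken as the
per-q intercept of an ordinary regression of I/c on c (with one curve,
simply I/c). Low/high-concentration q-ranges are merged by a
least-squares scale over a user-chosen overlap window, keeping the
low-concentration curve below the overlap midpoint.

## Guinier analysis

For compact particles, ln I(q) = ln I(0) − q²Rg²/3 for qRg ≲ 1.3. The
fitting window is selected automatically: all contiguous windows of at
least 5 points are scanned (after `skip_low_q` points, a guard against
aggregation upturns); a window is admissible when its fitted slope is
negative, qmax·Rg ≤ 1.3 and qmin·Rg ≤ 0.65; the longest admissible
window wins, ties broken by weighted R². The scan stops after a
fifty-fold intensity drop from the first usable point — beyond that the
Guinier law is long invalid, and oscillatory tails would otherwise
admit spuriously long, flat windows.

On the selected window the reported parameters come from a refinement
that adds a quadratic term in q² (ln I = a + bq² + cq⁴) and takes
Rg = √(−3b). The linear law truncated at qRg ≈ 1.3 has a small
systematic curvature — for a homogeneous sphere the next series term is
−x⁴/350 — which biases a straight-line fit by about +1.7% in Rg; the
quadratic term removes this truncation bias and is exact for pure
exponentials. Parameter errors come from the weighted least-squares
covariance (σ_lnI = σ/I when σ is available).

## Porod invariant, volume, and masses

The invariant Q = ∫q²I dq is computed by trapezoidal integration on the
measured grid, closed at the low-q end with the Guinier plateau
contribution I(0)q₀³/3, and extended beyond qmax with Porod's law
I = K/q⁴, whose tail integral is exactly K/qmax. K is estimated as the
average of q⁴I over the trailing tenth of the grid rather than the last
point alone; the weakest intensities sit there and a single noisy
endpoint would otherwise dominate the tail term. A warning is issued
when q⁴I is not approximately flat at the high-q end.

The Porod volume Vp = 2π²I(0)/Q converts to an apparent molecular mass
with the average protein density expressed as 0.588 Da/Å³, rounded to
the nearest Dalton. Under the assumption that only monomers (mass M)
and dimers (2M) are present, an apparent weight-averaged mass M_app
implies a dimer weight fraction

    w = clip(M_app/M − 1, 0, 1),

reported as a percentage to one decimal. Mass from absolute forward
scattering, M = k_cal·I(0)/c, requires an instrument calibration
constant k_cal that the user must supply; the ratio-based dimer
fraction is the validated route.

## Pair-distance distribution P(r)

The forward model is I(q) = 4π∫₀^Dmax P(r) sinc(qr) dr, discretised
pointwise on a uniform r grid (default 101 points) with trapezoidal
quadrature and pinned endpoints P(0) = P(Dmax) = 0. The inverse problem
is σ-weighted least squares with a second-difference smoothness penalty
of weight α (made dimensionless by scaling the penalty block to the
design-matrix norm) and optional non-negativity (NNLS). α = "auto"
performs an L-curve corner search over 10⁻⁴…10⁴ (maximum curvature of
the log residual-norm vs log seminorm curve). Profiles without σ get a
counting-like 1% default (σ = 0.01·I_max·√(I/I_max + 0.01)) so the fit
statistic is on a meaningful scale; the result flags this assumption.
Real-space parameters follow from the moments: Rg² = ∫r²P dr/(2∫P dr),
I(0) = 4π∫P dr.

Dmax is estimated by scanning candidates and exploiting the shape of
chi(Dmax): the misfit falls steeply while Dmax is too small and
plateaus once the whole particle fits inside [0, Dmax]. The estimate is
the smallest candidate whose chi is within a factor 2 of the best chi
across the scan (the scan runs unconstrained, so positivity and
endpoint behaviour of the solution remain informative diagnostics and
enter a secondary quality score). A warning is raised when the optimum
sits on a scan boundary. With strong noise the plateau onset blurs and
the estimate degrades gracefully toward smaller, statistically
indistinguishable values — a degeneracy every indirect-transform
method shares.

## Debye scattering and χ fitting

I(q) = ΣᵢΣⱼ wᵢwⱼ sinc(q rᵢⱼ) is evaluated exactly over all pairs for
models up to 500 sites, and through a weighted pair-distance histogram
(default bin 0.5 Å) above that. Bins are represented by their
weight-averaged distance and a second-order variance correction
(E[sinc] ≈ sinc(q·d̄) + ½q²·var·sinc″), which keeps the binned curve
within χ ≈ 0.05 of the exact sum at 1% errors. I(0) equals (Σw)²
exactly in both paths. Excluded solvent, when per-site displaced
volumes are present, is a q-independent contrast reduction
w → w − γ·v·(Σw/Σv) with γ the solvent-contrast fraction; this keeps
the forward model linear in the weights.

A model curve is matched to data by weighted linear least squares for
a scale factor c (and optionally an additive constant b absorbing small
buffer-subtraction mismatches); χ is the square root of the reduced
χ² with N − p degrees of freedom (p = 1 or 2). Ranking sorts models by
χ ascending with ties broken by input order.

## Mixture decomposition

For dilute non-interacting mixtures the measured curve is a
non-negative combination of component form factors. Amplitudes are
found by σ-weighted bounded least squares (BVLS; the constant, when
enabled, is unbounded) and renormalised to fractions with the overall
scale factored out. With one component this reduces exactly to the
single-curve χ fit. For equal-contrast monomer/dimer mixtures the
fractions are weight fractions, consistent with the mass-route dimer
content: a mixed curve built per unit mass as
(1−w)·I_mono + (w/2)·I_dimer has I(0) ∝ (1+w)·M.

## Flexible pools and ensemble selection

Conformers are a rigid core plus per-segment self-avoiding random
walks: Cα–Cα steps of exactly 3.8 Å, hard-sphere clash cutoff 3.0 Å to
all previously placed sites, 100 direction attempts per step and 50
restarts per segment before failing. Sub-ensembles of fixed size are
selected by a genetic algorithm over member subsets: population 50,
elitism (top 5), single-point crossover with duplicate repair,
member-swap mutation at rate 0.1, 200 generations per round, three
independently seeded rounds with the best round returned. The initial
population is seeded with the best single members, so the selected
ensemble never fits worse than the best individual curve, and elitism
makes the best χ non-increasing across generations. The Rg distribution
of the selected members is reported as a flexibility diagnostic.

## Bead-model reconstruction

Shapes are beads on a simple cubic lattice with bead radius
0.62 × spacing (slightly overlapping spheres — simpler neighbour logic
than hexagonal packing and adequate at SAXS resolution), confined to a
spherical search volume. Starting from a compact ball (radius from a
Guinier estimate of the data when possible), Metropolis annealing over
single-bead occupancy flips minimises

    E = χ² + α·looseness,

where χ² is the reduced misfit of the bead Debye curve (with optimal
scale) and looseness is the fraction of occupied beads with fewer than
6 occupied neighbours in the 26-neighbourhood. α is set at the start to
10 × the initial χ² (floored at 10) so the two terms are on comparable
scales. Beads are treated as point scatterers; the bead form factor is
not applied, which costs a little fidelity at the highest q but keeps
the forward model identical to the phantom generators.

Moves that would disconnect the occupied set are rejected (a local
3×3×3 connectivity test, falling back to a full search when
inconclusive). Under P2 symmetry each flip is applied simultaneously to
a bead and its 180°-rotated mate about the z axis, so the constraint
holds at every accepted step by construction. For polydisperse data a
fixed monomer fraction f mixes an area-normalised monomer form factor
with the area-normalised bead curve before the scale fit; the fraction
is intensity-weighted on area-normalised components (the package's
stated convention). The initial temperature is calibrated so ~80% of
uphill moves are accepted, cooling is geometric (×0.98 per 1,000
attempted flips), and the run stops after 50 temperature steps without
best-energy improvement. The best-so-far configuration is tracked, so
the reported energy is non-increasing and seeded runs are
bit-reproducible.

Models are compared by the normalised spatial discrepancy

    NSD(A,B) = √(½[(1/(N_A d_B²))Σᵢ minⱼ ρ²(aᵢ,bⱼ)
                 + (1/(N_B d_A²))Σⱼ minᵢ ρ²(bⱼ,aᵢ)]),

with d the mean nearest-neighbour distance within each set; with
principal-axes alignment both sets are centred, the second is rotated
into the first's frame and all four proper axis-sign combinations are
tried. Averaging aligns all models to the member with the lowest mean
pairwise NSD, accumulates a lattice occupancy map, keeps beads present
in at least the cutoff fraction of models (default 0.5), and retains
the largest 26-connected component — keeping all components tied for
the largest size, so symmetric ties are not broken arbitrarily. Models
with fewer than two beads skip alignment (nearest-neighbour distance,
hence NSD, is undefined for them).

## Synthetic phantoms

The generators emulate the study system: a compact ~38 kDa monomer with
a flexible C-terminal tail, its two-fold-symmetric dimer, and
concentration-dependent monomer/dimer mixtures.

* The monomer stand-in is a 285-site globular core (uniform ball
  sample, radius 17.5 Å — protein-like packing for ~285 residues) with
  a 31-residue self-avoiding tail anchored at the surface.
* The dimer places the centred monomer and its 180°-rotated copy at a
  given centre separation, with exact C2 symmetry and a clash warning
  below 1 Å.
* The concentration series uses the binding isotherm w(c) = c/(c+K) —
  a deliberately simple stand-in for a low-micromolar association,
  with K in mg/ml — and builds per-unit-mass intensities
  (1−w)·I_mono + (w/2)·I_dimer so the apparent mass interpolates
  between M and 2M; defaults are 0.5–7 mg/ml and 2% noise.
* Noise is counting-like: σ(q) = level·I(0)·√(I/I(0) + 0.01), a
  1%-of-scale variance floor, applied as centred Gaussians; at level 0
  the σ column is still populated (vanishing effective level) because
  profiles require positive uncertainties.
* Closed-form sphere and Gaussian-chain curves provide exact oracles
  (globular Kratky maximum vs chain plateau).

Every generator records its parameters and seed in the profile
metadata and is bit-reproducible.

What the phantoms do not emulate: instrument smearing, detector
geometry, inter-particle interference beyond the linear concentration
term, buffer-subtraction artefacts beyond an additive constant, and
atomic-resolution contrast. Tests passing on phantoms therefore
validate the estimators and their statistical behaviour under
counting-like noise, not instrument-specific systematics.

## Problem sizes used in the validation suite

The shipped tests run the full chain at desk scale: 2,000-point ball
samples for Debye consistency, 50-replicate noise studies for mixture
recovery, 30-member pools for ensemble selection, and ~250-bead
phantoms with ≤150 annealing temperature steps for reconstruction.
These sizes were chosen so the statistical targets (e.g. mean fraction
error ≤ 0.02) are comfortably resolved while the whole suite stays
quick to run; all of them scale up by changing the schedule or pool
parameters.

## External validation on the deposited dataset

The experimentally derived quantities for the study protein — Rg of
23.0/31.6 Å (apo/holo), Dmax of 80.5/105.4 Å, the Porod volumes, the
published CRYSOL/OLIGOMER χ values (1.654/2.864/1.637/2.917) and the
NSD statistics of the deposited bead models — are properties of the
measured scattering curves and deposited coordinate files, not of this
code, and cannot be reproduced from synthetic phantoms. To reproduce
them, download the deposited raw data and coordinate models from
Zenodo (DOI 10.5281/zenodo.3375375) and run:

```bash
oligosaxs guinier --dat apo_merged.dat          # Rg, I(0)
oligosaxs pr --dat apo_merged.dat --scan 40:160:25
oligosaxs porod --dat apo_merged.dat
oligosaxs mass --vp <Vp> --monomer-mass 38014
oligosaxs rank --pdb-dir models/ --dat apo_merged.dat
oligosaxs mixture --dat holo.dat --component mono.dat --component dimer.dat
oligosaxs beads --dat holo.dat --symmetry P2 \
    --monomer-fraction 0.58 --monomer-curve mono.dat --seed 1
```

Exact agreement with the published χ values is not expected (the
residue-level forward model here has no hydration shell); ranking and
the mass/dimer-content arithmetic are the comparable quantities.

## Known limitations

* No instrument smearing or absolute-intensity calibration.
* The Guinier window search assumes a monotone low-q decay; strongly
  aggregated data needs `skip_low_q`.
* Dmax estimation under heavy noise is degenerate toward smaller
  values (see above).
* The annealer's compactness penalty favours globular solutions; very
  anisometric shapes may need a larger search radius and longer
  schedules.
* NSD alignment searches principal axes only; for near-spherical
  models with degenerate inertia eigenvalues the alignment can settle
  in a suboptimal sign combination (the reported transform is recorded
  so this is auditable).
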