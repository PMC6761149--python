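# oligosaxs

Small-angle X-ray scattering (SAXS) analysis of protein
oligomerisation.

Solution SAXS is often the deciding experiment for whether a protein is
monomeric or self-associates: the forward scattering I(0) and the Porod
volume both report the apparent (weight-averaged) molecular mass, the
radius of gyration and the pair-distance distribution P(r) report the
overall dimensions, and a measured curve can be decomposed into
monomer/dimer form factors or inverted into a low-resolution bead
shape. `oligosaxs` implements this full analysis chain as a tested
Python library with a thin command-line layer, for structural
biologists who want the standard SAXS toolbox workflow —
Guinier/Kratky/Porod analysis, GNOM-style P(r) inversion, CRYSOL-style
model fitting, OLIGOMER-style mixture decomposition, EOM-style
ensemble selection and DAMMIN-style bead reconstruction — in one
scriptable, seedable package, validated end-to-end on synthetic
phantoms with known ground truth.

## The quantities at the core

For a dilute solution of identical particles,

* Guinier law: `I(q) = I(0) exp(−q²Rg²/3)` for `qRg ≲ 1.3`;
* Porod invariant and volume: `Q = ∫q²I(q)dq`, `Vp = 2π²I(0)/Q`;
* apparent mass from the Porod volume: `M = 0.588 Da/Å³ × Vp`;
* dimer weight fraction of a pure monomer/dimer mixture with monomer
  mass `M₀`: `w = clip(M/M₀ − 1, 0, 1)`, since the weight-averaged
  mass of the mixture is `(1+w)·M₀`;
* indirect Fourier transform:
  `I(q) = 4π∫₀^Dmax P(r) sin(qr)/(qr) dr`, solved with smoothness
  regularisation and pinned endpoints;
* Debye formula for a coordinate model:
  `I(q) = Σᵢⱼ wᵢwⱼ sin(qrᵢⱼ)/(qrᵢⱼ)`, fitted to data by a scale (and
  optional constant) with reduced-χ scoring;
* ab initio shapes: beads on a lattice annealed to minimise
  `χ² + α·looseness` under connectivity (and optionally two-fold
  symmetry) constraints, compared by normalised spatial discrepancy
  (NSD).

See `docs/methods.md` for the complete model descriptions and
numerical choices.

## Worked example

Simulate a concentration series of a monomer/dimer equilibrium
(compact 285-residue core with a 31-residue flexible tail; dimer
fraction following the isotherm `w(c) = c/(c+K)` with `K = 5 mg/ml`;
1% counting noise), then analyse each curve and decompose it into the
known form factors:

```python
import numpy as np
from oligosaxs import guinier_fit, porod_volume, fit_mixture
from oligosaxs.debye import debye_curve
from oligosaxs.synthetic import (PhantomSpec, mixture_series,
                                 core_plus_tail_model, dimer_curve,
                                 default_q_grid)

spec = PhantomSpec(K=5.0, noise_level=0.01, seed=7,
                   concentrations=(0.5, 2.0, 5.0))
series = mixture_series(spec)

rng = np.random.default_rng(spec.seed)
mono = core_plus_tail_model(seed=int(rng.integers(2**31)))
q = default_q_grid()
mono_curve = debye_curve(mono, q)
_, dim_curve = dimer_curve(mono, spec.separation, q_grid=q)

for prof in series:
    g = guinier_fit(prof)
    por = porod_volume(prof, I0=g.I0)
    mix = fit_mixture(prof, [mono_curve, dim_curve])
    fm, fd = mix.fractions          # per-particle amplitude fractions
    w_fit = 2 * fd / (fm + 2 * fd)  # weight fraction (dimer mass = 2M)
    print(prof.concentration, g.Rg, por.Vp, w_fit,
          prof.meta["true_dimer_fraction"])
```

Output (formatted):

```
c (mg/ml)   Rg (A)   Vp (A^3)  dimer % (fit)  dimer % (true)
      0.5    17.98      17664            7.8             9.1
      2.0    21.56      22991           27.0            28.6
      5.0    23.07      25211           50.3            50.0
```

Reading the numbers: as the concentration rises the dimer fraction
grows along the isotherm, the apparent Rg swells from the monomer
value toward the dimer's, and the Porod volume (hence the apparent
mass) increases in step. The mixture decomposition recovers the true
dimer weight fraction to within ~1–2 percentage points at 1% noise;
the residual underestimate at the lowest concentration reflects the
weak dimer signal there, not a bias of the estimator (it is exact on
noiseless curves).

The same analyses are available from the shell:

```bash
oligosaxs simulate --conc 0.5,2,5 --noise 0.01 --seed 7 --out-dir phantoms/
oligosaxs guinier --dat phantoms/phantom_02.dat
oligosaxs pr --dat phantoms/phantom_02.dat --scan 40:160:25
oligosaxs mass --vp 65730 --monomer-mass 38014
oligosaxs beads --dat phantoms/phantom_02.dat --symmetry P2 --seed 1
```

Model-style interfaces mirror the functional ones: `Guinier(profile)`,
`PairDistance(profile, Dmax)`, `Mixture(data, components)`,
`DebyeFit(data, model)` and `BeadReconstruction(data, ...)` are
constructed from data and return a results object from `.fit()` with
the estimates, their uncertainties and a `summary()`.

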