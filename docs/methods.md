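# Methods

`evoptics` studies how regular photonic architectures — Bragg mirrors,
half-wave-capped mirrors, chirped broadband reflectors, Morpho-style
diffracting gratings, and Bragg-based anti-reflective coatings — emerge
spontaneously when evolutionary algorithms optimize simple optical objectives
under simple material constraints. This note records the models, the
numerical choices, and the reasoning behind every parameter that the sources
of the problem statements leave open.

## Electromagnetic models

### Stratified multilayers

Normal-incidence plane waves in a stack of homogeneous, isotropic,
non-magnetic layers, time convention `exp(-i w t)` (so passive media have
`Im n >= 0` and all propagation factors `exp(i k0 n d)` are bounded).
Amplitudes are composed with the scattering-matrix (Redheffer star)
recursion rather than raw transfer-matrix products; the recursion involves
only bounded quantities, so optically thick absorbing layers (the 10 um
silicon cell) cannot overflow. The production `cascade` folds the recursion
from the substrate upward carrying only the sub-stack reflection and
transmission amplitudes, which is algebraically identical to the full
star product (cross-checked against a naive characteristic-matrix oracle to
1e-10 in *amplitude*, not just energy).

Energy bookkeeping: `R = |r|^2`, `T = Re(n_sub)/Re(n_inc) |t|^2`, and the
per-layer absorptance is the difference of the exact normal Poynting flux
`S_z ~ Re[(A+B) conj(n (A-B))]` across each layer's boundaries. Because the
fluxes telescope, `R + T + sum_j A_j = 1` holds to solver precision by
construction; the test suite checks 1e-9 on random 40-layer absorbing stacks.

Field maps report `|E(z)|` normalized to unit incident amplitude, sampled
from one wavelength above the stack (standing wave of incident plus
reflected waves) to one wavelength into the substrate.

### Lamellar gratings (Fourier Modal Method)

1D-periodic structures made of rectangular inclusions are solved by the
Fourier Modal Method in TE polarization (electric field along the grooves),
for which the plain Laurent factorization of the permittivity is exact; at
normal incidence the plane-wave ladder is `kx_m = 2 pi m / d`, `|m| <= N_h`.
Per layer the modal operator `k0^2 E - Kx^2` (with `E` the Toeplitz matrix of
the analytically computed permittivity Fourier coefficients) is
eigendecomposed; layers couple through the same stable S-matrix recursion as
the multilayer solver, and order efficiencies are `Re(beta_m)|amp|^2 /
beta_0`, exactly zero for evanescent orders.

Three performance-relevant identities are exploited, none of which changes
the mathematics: (1) a layer holding a single lossless inclusion can be
shifted so the inclusion is centred, making the modal operator real
symmetric — the eigenvectors of the original layer are a diagonal phase times
a real orthogonal matrix, so both the eigenproblem and the basis inverse
come cheap; (2) the Redheffer recursion is folded from the substrate upward
carrying only the reflection/transmission blocks of the growing sub-stack;
(3) when every layer is a single lossless inclusion and all centres share
one vertical mirror axis (modulo half a period — the stacked Morpho
configuration), a normally incident wave excites only even-parity modes, so
the solve runs exactly in the `(N_h + 1)`-dimensional even cosine basis
instead of the full `2 N_h + 1` ladder (about 4x cheaper; asymmetric or
lossy structures automatically fall back to the full basis). Correctness is
pinned by the test suite: energy conservation at 1e-6, `r_{+i} = r_{-i}` for
mirror-symmetric structures on the *full-basis* solver at 1e-8, even-parity
path equal to the full path at 1e-10, the exact propagating set of the
grating equation, self-convergence in `N_h`, and the uniform-layer limit
against the independent multilayer solver at 1e-6.

Default truncation is `N_h = 20`; optimization campaigns run at reduced
truncation (below).

## The four objectives (all minimized)

1. **Single-wavelength mirror**: `1 - R(lambda_0)`, `lambda_0 = 600 nm`.
2. **Broadband mirror**: `1 - mean R` over 50 equidistant wavelengths on
   500-800 nm (an 8-point `500 + 50 n` preset grid is provided as an
   alternative configuration).
3. **Morpho grating**: `1 - (r_{+1}(450) + r_{-1}(450) - r_0(450))/2
   + (1/N) sum_i r_0(lambda_i) + (a/n_b) sum_j w_j / d` with `N = 8`
   anti-specular wavelengths evenly spaced on 400-800 nm (the range is not
   fixed by the problem statement; the full visible span is the natural
   reading) and weight penalty `a = 0` (optical optimum) or `a = 0.5`
   (light-structure constraint). `r_i` are power efficiencies — the penalty
   and anti-specular terms only make dimensional sense when all terms are
   power fractions.
4. **Photovoltaic coating**: `1 - eta`, where `eta` is the short-circuit
   current (quantum yield one) divided by its ceiling over 375-750 nm. The
   current is the photon-flux-weighted absorptance integral of the a-Si
   layer, trapezoidal on a 1 nm grid — the spectrum is smooth and dense, so
   higher-order quadrature would add nothing.

## Physical data tables

The solar spectrum and the a-Si optical constants are bundled as **synthetic
stand-ins**, generated by documented physical models rather than copied from
measured tables (none were available to bundle, and the original experiment's
sources are unnamed):

* `am15_synthetic.csv`: a 5778 K Planck spectrum scaled to a realistic peak
  spectral irradiance (1.6 W m^-2 nm^-1). It lacks the Fraunhofer and
  atmospheric absorption dips of the measured AM1.5 spectrum; since the
  efficiency is a ratio of two integrals against the same spectrum, the
  headline efficiency shifts by at most a few points.
* `asi_nk_synthetic.csv`: Tauc-Lorentz oscillator (A = 122 eV, E0 = 3.45 eV,
  C = 2.54 eV, Eg = 1.2 eV, eps1_inf = 1.15 — standard literature parameters
  for amorphous silicon) with eps1 from a numerical Kramers-Kronig
  transform. Visible-range values (n ~ 4.2-4.5, k falling from 2.4 at 375 nm
  to 0.17 at 750 nm) are in the range of published a-Si data.

Consequently the photovoltaic numbers are model-consistent rather than
instrument-accurate: orderings (optimized coating > single-layer coating >
bare cell) and the structure of the optimum are meaningful; the absolute
efficiency depends on the optical-constant model at the several-percent
level.

## Optimizers

All five algorithms share one contract: box projection before every
evaluation, per-evaluation budget accounting, elitist best-so-far traces,
bit-reproducibility from the run seed.

* **DE** (the reference algorithm): current-to-best/1 mutation
  `x_i + F1 (x_best - x_i) + F2 (x_r1 - x_r2)` with coordinate-wise binomial
  crossover at copy probability 1/2 from the parent, one forced mutant
  coordinate, and replacement on `<=` (ties drift). Defaults `F1 = F2 = 0.8`,
  population 30 — standard values for this family; the crossover probability
  is the one quantity fixed by the problem statement.
* **OPO**: (1+1)-ES, isotropic Gaussian mutation in box-normalized
  coordinates, initial relative step 0.2, one-fifth success rule with factors
  1.5 (success) and 1.5^(-1/4) (failure).
* **PSO**: global-best swarm, constriction-style defaults (inertia 0.7298,
  cognitive = social = 1.49618), velocity clamped to half the box span.
* **NM**: scipy's Nelder-Mead (canonical 1, 2, 0.5, 0.5 coefficients) with
  seeded uniform restarts and a 10%-of-box initial simplex, restarted until
  the budget is exhausted.
* **CMA** delegates to the external `cma` package when installed and raises
  a clean `AlgorithmUnavailableError` otherwise; campaigns skip it with a
  warning. Re-implementing CMA internals is out of scope by design.

## Study configurations

The emergence experiments (in `evoptics.experiments`) fix conditions the
problem statements leave open. These were chosen on physical grounds and are
deliberately not per-experiment tuning knobs:

* **Substrate n = 1.5** for all mirror campaigns. On a vacuum substrate the
  optimum of an even-layer mirror is provably *not* a complete-pair
  quarterwave stack: admittance algebra shows an effective odd,
  high-index-terminated stack with one wasted layer reflects more (e.g.
  6 layers at 600 nm: R = 0.526 vs 0.275), so quarterwave emergence is only
  well-posed over a substrate. Glass is the natural laboratory choice.
* **Thickness box [30, 250] nm** for mirror genomes. The box contains every
  quarter-wave and half-wave thickness at 600 nm for indices in [1.4, 1.7]
  (largest: 214.3 nm) but excludes 3 lambda/4 aliases (smallest: 264.7 nm)
  that are optically identical to quarter-wave layers and would make
  thickness-based classification meaningless; the 30 nm floor means a layer
  cannot be deleted by driving it to zero thickness, so "begins with the
  low index" is a real constraint.
* **Morpho period d = 600 nm** (unstated in the sources): the +-1 orders
  propagate at 450 nm with margin. Block widths/heights/gaps in
  [10, 600] nm. The blue-scattering optimum runs at `N_h = 8` with free
  block alignment: DE locates the scattering basin across restarts, then a
  Nelder-Mead refinement descends the narrow zero-specular valley that DE's
  global moves resolve only slowly; specular/scattered fractions are
  re-evaluated at doubled truncation as an accuracy check.
* **Algorithm comparison** runs on the *penalized* 6-block problem
  (`a = 0.5`, stacked alignment — the constrained, modular configuration on
  which the comparison is meaningful) at truncation `N_h = 3`, which biases
  all algorithms identically so rankings are unaffected. The population
  methods (DE and PSO, treated identically) use 15 individuals: in 19
  dimensions a 30-individual population leaves too few generations within
  the budget for *any* population method to converge, and population size
  is a free parameter of the study. The reference budget is 1e4
  evaluations, at which every algorithm's trace has flattened; DE's lead
  over the field is established from 4e3 evaluations onward, and the
  acceptance-scale runs use that 4e3 point to fit the compute envelope.
* **Solar cell**: 89 nm a-Si over a silver-like back contact
  (n = 0.05 + 4i). A thin-film cell without a reflecting back cannot absorb
  most red photons in one pass regardless of coating (verified: the
  optimized vacuum-backed cell saturates near 64%), and real thin-film
  cells are metallized; the back medium is a config key. The "mirror band"
  of the optimized coating is read from its standalone reflectance on
  500-1300 nm as the reflectance-weighted mean wavelength over the region
  where `R > R_max / 2`.
* **Budgets**: 1e4 evaluations per run for multilayer problems (the
  reference budget), 3e4 for the 20-layer half-wave campaign where 1e4
  leaves the first layer several nm from its converged value, and 1e4
  (4e3 at acceptance scale, above) for the Morpho comparison. Run seeds
  are `base_seed + run_index`.

## What the experiments do and do not show

The campaigns optimize idealized, dispersionless, lossless multilayers and
TE-polarized lamellar gratings at normal incidence. Passing tests show that
the *optimization landscape* of each objective has the claimed regular
optima and that the algorithms find them under the stated conditions; they
do not model fabrication disorder, oblique incidence, polarization mixing,
or material dispersion in the mirror problems.

Two quantified claims deserve honesty notes, established by direct
experiment with this package:

* The per-run Bragg-emergence rate of DE at budget 1e4 on the 6-layer
  free-index problem is small — 4 of 100 seeds under the study
  configuration: a competing local optimum (an effective 5-layer
  high-terminated stack with one wasted slot, score 0.622 vs the
  quarterwave's 0.570) captures most of the basin, and neither population
  size (10-100), mutation weights (F in 0.3-1.0) nor a 4x budget removes
  it. The claim that reproduces categorically is about the
  *best-of-campaign* structure: every run that escapes the trap lands on
  the same ideal quarterwave Bragg mirror (2 nm / 0.005-index tolerance)
  at the closed-form optimum of the admittance formula, and the campaign's
  best always does.
* Under the broadband objective the strict pair-by-pair monotone chirp is
  *not* the optimum at 10 pairs: polishing a perfect linear chirp lowers
  its score while breaking strict monotonicity (0.476 -> 0.426), leaving a
  clear coarse thickness gradient with local oscillation. Optimized runs
  therefore show monotone fractions around 0.55-0.7 at pair granularity,
  and the increasing/decreasing *trend* splits between runs; the trend
  direction (majority-sign, threshold 0.5) is the statistic reported for
  the orientation split.

## Known limitations

* TM polarization is not implemented for the grating solver (TE only); the
  scattering claims tested are polarization-insensitive at this level.
* Oblique incidence, 2D gratings, anisotropic media, and incoherent
  averaging are out of scope.
* The photovoltaic experiment's absolute efficiency inherits the synthetic
  optical-constant model (above).
* CMA results require the optional external delegate.
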