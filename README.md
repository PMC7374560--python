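# evoptics

*In silico* evolution of photonic structures: electromagnetic solvers,
objective functions and evolutionary optimizers that reproduce how the
stereotypical photonic architectures of the living world — Bragg mirrors,
half-wave-capped beetle mirrors, chirped broadband reflectors, the
*Morpho*-butterfly grating — and counter-intuitive engineered devices
(Bragg-mirror-based anti-reflective coatings for thin-film solar cells)
emerge spontaneously from simple optical objectives under simple material
constraints.

The package is aimed at photonics researchers and students of evolutionary
computation who want a compact, fully testable playground in which the
optimum of a well-posed optical problem *is* a known natural design.

## What is inside

| module | contents |
| --- | --- |
| `evoptics.multilayer` | stable S-matrix (Redheffer) solver for stratified media at normal incidence: `cascade`, `spectral_response` (R, T, per-layer A with exact energy bookkeeping), `field_profile` |
| `evoptics.grating` | TE Fourier Modal Method (RCWA) for 1D lamellar gratings: per-order reflected/transmitted efficiencies |
| `evoptics.genomes` | bounded real-vector search spaces and decoders: free-index / forced-alternation multilayers, *Morpho* block gratings (free or stacked alignment), solar-cell coatings |
| `evoptics.objectives` | the four scores, all minimized: `1 - R(lambda0)`; `1 - mean R` (500-800 nm); the blue-scattering/anti-specular/weight-penalty grating score; `1 - eta` for the solar cell |
| `evoptics.optimizers` | DE (current-to-best/1 with coordinate-wise crossover), (1+1)-ES, PSO, Nelder-Mead restarts, CMA (external delegate) behind one seeded `minimize` contract |
| `evoptics.campaigns` | multi-run campaigns with persistence/resume, sorted score profiles, and regularity classifiers (quarterwave, half-wave first layer, chirp direction) |
| `evoptics.oracles` | independent closed forms and a brute-force transfer matrix that cross-check every solver path; `selftest` |
| `evoptics.experiments` | the canned emergence experiments at desk scale |

Two small CSV tables (a synthetic AM1.5-style solar spectrum and synthetic
Tauc-Lorentz amorphous-silicon optical constants) are bundled; see
`docs/methods.md` for exactly what they model.

## A worked example

Evolve a 6-layer mirror at 600 nm, with thicknesses and refractive indices
free inside 1.4-1.7, and ask the classifier what emerged:

```python
import numpy as np
from evoptics import (MultilayerProblem, BraggObjectiveSpec, bragg_objective,
                      OptimizerConfig, minimize, classify_quarterwave)

problem = MultilayerProblem(6, mode="free_index", index_range=(1.4, 1.7),
                            thickness_range=(30, 250), substrate_index=1.5)
objective = bragg_objective(problem, BraggObjectiveSpec(lambda0=600.0))
result = minimize(objective, problem.bounds(),
                  OptimizerConfig("DE", budget=10_000, seed=71))
stack = problem.decode(result.x_best)
print(np.round(stack.thicknesses(), 2))
print([round(m.index.real, 4) for m, _ in stack.layers])
print(f"score {result.f_best:.5f}")
rep = classify_quarterwave(stack, 600.0, tol=2.0)
print(rep.is_quarterwave, rep.alternation_ok)
```

Output:

```
[ 88.24 107.14  88.24 107.14  88.24 107.14]
[1.7, 1.4, 1.7, 1.4, 1.7, 1.4]
score 0.57008
True True
```

The optimizer was never told about quarter-wave layers: 88.24 nm and
107.14 nm are exactly `600/(4*1.7)` and `600/(4*1.4)`, the indices sit at
the extreme allowed values and alternate starting high — the textbook Bragg
mirror, rediscovered from a random population. The score is `1 - R`, i.e.
this stack reflects 43% at 600 nm (6 lossless layers of weak index contrast
on glass; more pairs push R toward 1).

Not every seed gets there: most runs are captured by a competing local
optimum (an effective high-terminated stack with one wasted layer, score
0.622). Run a multi-seed campaign and it is the *best-of-campaign*
structure that is reliably the ideal Bragg mirror — every run that escapes
the trap lands on exactly this stack, at the closed-form optimum. See
`docs/methods.md` for the basin statistics.

The other experiments run the same way from `evoptics.experiments`
(`run_halfwave_emergence`, `run_chirped_mirrors`, `run_morpho_optimum`,
`run_solar_coating`, `run_algorithm_comparison`), and a CLI is available for
one-off solves (`evoptics spectrum|diffract|fieldmap|classify|optimize|campaign`).

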