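"""Canned study configurations reproducing the headline emergence experiments.

Each function defines one experiment — problem, objective, optimizer budget —
at desk scale, runs it, and returns the headline quantities. These are the
single source of truth shared by the test suite, the acceptance script and
the CLI, so every consumer measures exactly the same study conditions.

Configuration choices (documented in the methods note):

* Mirror problems sit on a glass-like substrate (n = 1.5). On a vacuum
  substrate the mathematical optimum of an even-layer-count mirror is an
  effective odd stack terminated by a high-index layer plus one wasted slot,
  not a complete-pair Bragg mirror, so the emergence experiments are only
  well-posed with a substrate.
* Layer thicknesses live in [30, 250] nm: the box contains every quarter- and
  half-wave motif at the 600 nm working wavelength for both allowed indices
  while excluding 3*lambda/4 aliases that are optically identical to
  quarter-wave layers (and would defeat thickness-based classification), and
  the 30 nm floor makes "begins with the low index" a real constraint rather
  than one deletable by a zero-thickness layer.
* Morpho campaigns run at reduced truncation and budget (the full-fidelity
  configuration is a flag away); the algorithm comparison uses the penalized
  (a = 0.5) 6-block (12-layer) problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .campaigns import (
    CampaignSpec,
    chirp_direction,
    classify_quarterwave,
    detect_halfwave_first_layer,
    run_campaign,
)
from .genomes import CoatingProblem, MorphoProblem, MultilayerProblem
from .grating import diffraction_efficiencies
from .multilayer import Stack, cascade
from .objectives import (
    BraggObjectiveSpec,
    BroadbandObjectiveSpec,
    MorphoObjectiveSpec,
    bragg_objective,
    broadband_objective,
    conversion_efficiency,
    load_asi_material,
    morpho_objective,
    photovoltaic_objective,
)
from .optimizers import minimize_de

LAMBDA0 = 600.0
SUBSTRATE = 1.5
THICKNESS_BOX = (30.0, 250.0)
MORPHO_PERIOD = 600.0


def bragg_problem(n_layers: int = 6) -> MultilayerProblem:
    """Free-index mirror problem of the Bragg-emergence campaign."""
    return MultilayerProblem(
        n_layers,
        mode="free_index",
        index_range=(1.4, 1.7),
        thickness_range=THICKNESS_BOX,
        substrate_index=SUBSTRATE,
    )


def run_bragg_emergence(n_runs: int = 100, budget: int = 10_000, base_seed: int = 0):
    """100x DE on the 6-layer free-index mirror; classify every best stack.

    Returns a dict with the per-run quarterwave count, the modal outcome, and
    the classification of the best-of-campaign structure.
    """
    prob = bragg_problem()
    spec = CampaignSpec(
        problem=prob,
        objective_factory=lambda p: bragg_objective(p, BraggObjectiveSpec(LAMBDA0)),
        algorithms=("DE",),
        n_runs=n_runs,
        budget=budget,
        base_seed=base_seed,
    )
    camp = run_campaign(spec)
    n_bragg = 0
    for _, row in camp.runs.iterrows():
        stack = prob.decode(camp.genome_of(row))
        rep = classify_quarterwave(stack, LAMBDA0, tol=2.0, index_tol=0.005)
        n_bragg += rep.is_quarterwave and rep.alternation_ok
    best_stack = prob.decode(camp.best_genome())
    best_rep = classify_quarterwave(best_stack, LAMBDA0, tol=2.0, index_tol=0.005)
    return {
        "n_runs": n_runs,
        "n_quarterwave_runs": int(n_bragg),
        "best_is_quarterwave": bool(best_rep.is_quarterwave and best_rep.alternation_ok),
        "best_score": float(camp.runs.score.min()),
        "campaign": camp,
    }


def run_halfwave_emergence(n_runs: int = 20, budget: int = 30_000, base_seed: int = 0):
    """Forced alternation starting low (20 layers): the lambda/2 first layer.

    The best-of-campaign structure's first-layer thickness is compared with
    the half-wave value lambda0/(2*1.4) and the quarter-wave value.
    """
    prob = MultilayerProblem(
        20,
        mode="forced_alternation",
        alternation_start="low",
        thickness_range=THICKNESS_BOX,
        substrate_index=SUBSTRATE,
    )
    spec = CampaignSpec(
        problem=prob,
        objective_factory=lambda p: bragg_objective(p, BraggObjectiveSpec(LAMBDA0)),
        algorithms=("DE",),
        n_runs=n_runs,
        budget=budget,
        base_seed=base_seed,
    )
    camp = run_campaign(spec)
    best_stack = prob.decode(camp.best_genome())
    t1 = best_stack.thicknesses()[0]
    halfwave = LAMBDA0 / (2 * 1.4)
    quarterwave = LAMBDA0 / (4 * 1.4)
    return {
        "first_layer_nm": float(t1),
        "halfwave_error_nm": float(abs(t1 - halfwave)),
        "ratio_to_quarterwave": float(t1 / quarterwave),
        "is_halfwave": detect_halfwave_first_layer(best_stack, LAMBDA0, tol=2.0),
        "best_score": float(camp.runs.score.min()),
        "campaign": camp,
    }


def run_chirped_mirrors(n_runs: int = 30, budget: int = 10_000, base_seed: int = 0):
    """Broadband-mirror campaign: thickness-gradient statistics per run.

    For every run the per-period optical-thickness trend is measured twice:
    with the strict 0.8 monotone-fraction threshold (classifier default) and
    with a bare-majority threshold that always assigns the trend direction,
    used for the increasing/decreasing split.
    """
    prob = MultilayerProblem(
        20,
        mode="forced_alternation",
        alternation_start="high",
        thickness_range=THICKNESS_BOX,
        substrate_index=SUBSTRATE,
    )
    spec = CampaignSpec(
        problem=prob,
        objective_factory=lambda p: broadband_objective(p, BroadbandObjectiveSpec()),
        algorithms=("DE",),
        n_runs=n_runs,
        budget=budget,
        base_seed=base_seed,
    )
    camp = run_campaign(spec)
    fractions, trends = [], []
    for _, row in camp.runs.sort_values("run").iterrows():
        stack = prob.decode(camp.genome_of(row))
        _, frac = chirp_direction(stack)
        trend, _ = chirp_direction(stack, threshold=0.5)
        fractions.append(frac)
        trends.append(trend)
    best_idx = int(camp.runs.score.idxmin())
    return {
        "monotone_fraction_best": float(fractions[int(camp.runs.loc[best_idx, "run"])]),
        "monotone_fractions": fractions,
        "trends": trends,
        "n_increasing": trends.count("increasing"),
        "n_decreasing": trends.count("decreasing"),
        "best_score": float(camp.runs.score.min()),
        "campaign": camp,
    }


def morpho_problem(n_blocks: int = 6, alignment: str = "free") -> MorphoProblem:
    return MorphoProblem(
        n_blocks,
        period=MORPHO_PERIOD,
        alignment=alignment,
        width_range=(10.0, 600.0),
        height_range=(10.0, 600.0),
        gap_range=(10.0, 600.0),
    )


def run_morpho_optimum(
    budget: int = 3_000,
    n_runs: int = 3,
    base_seed: int = 0,
    truncation: int = 8,
    n_blocks: int = 6,
    refine_budget: int = 6_000,
):
    """Blue-scattering optimum (a = 0) at desk scale; best-of-runs metrics.

    Desk-scale surrogate of the full-fidelity optimization: DE locates the
    scattering basin, then a simplex refinement descends the narrow
    zero-specular valley that DE's global moves resolve only slowly
    (``refine_budget = 0`` disables the refinement for a pure-DE run).
    Specular reflection and the scattered (non-zero-order) fraction at
    450 nm are re-evaluated at double truncation as an accuracy check.
    """
    prob = morpho_problem(n_blocks)
    spec = MorphoObjectiveSpec(a=0.0, truncation=truncation)
    f = morpho_objective(prob, spec)
    best = None
    for s in range(n_runs):
        res = minimize_de(f, prob.bounds(), budget=budget, seed=base_seed + s)
        if best is None or res.f_best < best.f_best:
            best = res
    x_best, f_best = best.x_best, best.f_best
    if refine_budget:
        from scipy.optimize import minimize as _sp_minimize

        pol = _sp_minimize(
            lambda x: f(np.minimum(np.maximum(x, prob.bounds().lower), prob.bounds().upper)),
            x_best,
            method="Nelder-Mead",
            options={"maxfev": refine_budget, "xatol": 1e-9, "fatol": 1e-13},
        )
        if pol.fun < f_best:
            x_best, f_best = np.asarray(pol.x), float(pol.fun)
    structure = prob.decode(x_best)
    de = diffraction_efficiencies(structure, 450.0, truncation)
    de_hi = diffraction_efficiencies(structure, 450.0, 2 * truncation)
    tot_hi = de_hi.total_reflected + de_hi.total_transmitted
    return {
        "best_score": float(f_best),
        "specular_percent": 100.0 * de.r(0),
        "scattered_percent": 100.0 * de.scattered_fraction(),
        "specular_percent_hi": 100.0 * de_hi.r(0),
        "scattered_percent_hi": 100.0 * de_hi.scattered_fraction() / tot_hi,
        "structure": structure,
        "result": best,
    }


def run_algorithm_comparison(
    n_runs: int = 20,
    budget: int = 10_000,
    base_seed: int = 0,
    truncation: int = 3,
    n_blocks: int = 6,
    population: int = 15,
):
    """Penalized Morpho problem (a = 0.5), DE vs OPO vs PSO vs NM medians.

    Uses the constrained configuration (stacked blocks + weight penalty) —
    the modular, regular problem on which the algorithm comparison is run.
    The population methods (DE, PSO) run with 15 individuals: at this budget
    and dimension a 30-individual population leaves too few generations for
    either to converge (see the methods note).
    """
    prob = morpho_problem(n_blocks, alignment="stacked")
    spec_obj = MorphoObjectiveSpec(a=0.5, truncation=truncation)
    spec = CampaignSpec(
        problem=prob,
        objective_factory=lambda p: morpho_objective(p, spec_obj),
        algorithms=("DE", "OPO", "PSO", "NM"),
        n_runs=n_runs,
        budget=budget,
        base_seed=base_seed,
        population=population,
    )
    camp = run_campaign(spec)
    medians = {
        algo: float(np.median(camp.scores(algo))) for algo in spec.algorithms
    }
    return {"medians": medians, "campaign": camp}


SILVER_BACK = complex(0.05, 4.0)  # metallized back contact of the thin cell


def run_solar_coating(
    n_layers: int = 12,
    budget: int = 10_000,
    n_runs: int = 3,
    base_seed: int = 0,
    absorber_thickness: float = 89.0,
    back_index: complex = SILVER_BACK,
):
    """Anti-reflective coating on the a-Si cell: efficiency and mirror band.

    Returns the optimized conversion efficiency eta (fraction of available
    photons absorbed in 375-750 nm), the best single-layer quarter-wave
    reference, and the centre of the stand-alone coating's high-reflectance
    band (the counter-intuitive infra-red Bragg mirror).
    """
    asi = load_asi_material()
    prob = CoatingProblem(
        n_layers,
        absorber=asi,
        absorber_thickness=absorber_thickness,
        thickness_range=(0.0, 300.0),
        back_index=back_index,
    )
    f = photovoltaic_objective(prob)
    best = None
    for s in range(n_runs):
        res = minimize_de(f, prob.bounds(), budget=budget, seed=base_seed + s)
        if best is None or res.f_best < best.f_best:
            best = res
    eta = 1.0 - best.f_best

    # single-layer quarter-wave reference (n = 1.4 film, thickness scanned)
    prob1 = CoatingProblem(
        1, absorber=asi, absorber_thickness=absorber_thickness, back_index=back_index
    )
    eta_single = max(
        conversion_efficiency(prob1, np.array([t])) for t in np.arange(60.0, 141.0, 2.0)
    )
    eta_bare = conversion_efficiency(prob1, np.array([0.0]))

    # stand-alone coating reflectance band (coating alone, vacuum both sides)
    layers = [(1.4 if j % 2 == 0 else 1.7, t) for j, t in enumerate(best.x_best)]
    coating = Stack(1.0, layers, 1.0)
    grid = np.linspace(500.0, 1300.0, 161)
    r, _ = cascade(coating, grid)
    R = np.abs(r) ** 2
    band = R > 0.5 * R.max()
    band_centre = float(np.average(grid[band], weights=R[band]))
    return {
        "eta": float(eta),
        "eta_percent": 100.0 * float(eta),
        "eta_single_layer": float(eta_single),
        "eta_bare": float(eta_bare),
        "band_centre_nm": band_centre,
        "coating": coating,
        "result": best,
    }
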