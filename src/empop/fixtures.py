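"""Synthetic study conditions: morphology populations, ground-truth feature
targets and the closed-loop parameter-recovery experiment.

The generator emulates the study conditions the pipeline is built for:

- a morphology population (soma, 60 um axon stub, one to three basal trees,
  an apical trunk with a tuft bifurcation) whose total lengths and surface
  areas spread several-fold across the population — cortical pyramidal-cell
  morphometrics typically vary 3-to-5-fold within a type — driven by a
  per-cell global scale drawn log-uniformly;
- "experimental" feature targets produced by simulating a known
  ground-truth parameter vector with parameter jitter across virtual cells,
  so that the whole pipeline (exemplar -> MCMC -> rho calibration ->
  adaptation -> selection) can be tested closed-loop: the ground truth is
  recoverable by construction.

Everything is deterministic per master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import mcmc, rho as rho_mod
from .cost import STRICT_THRESHOLD, VALIDITY_THRESHOLD, FeatureTarget, evaluate_emodel
from .generalize import SelectionConfig, evaluate_pairs, select_generalizable
from .morph import Morphology, Section, attach_ais_and_myelin, build_exemplar, write_swc
from .mcmc import BURNIN_SETTINGS, MAIN_SETTINGS, MCMCSettings, ParameterSpace
from .protocols import ProtocolSuite, run_suite
from .sim import build_cell

__all__ = [
    "FixtureConfig",
    "default_parameter_space",
    "gen_morph_population",
    "gen_targets",
    "fixture_problem",
    "run_fixture_sampling",
    "recovery_experiment",
]

#: fixed (non-sampled) mechanism parameters of the fixture e-model
BASE_PARAMS = {
    "all.pas.e": -90.0,
    "axonal.KdR.gbar": 0.5,
}

#: 6-parameter sampled space: somatic/axonal NaT, somatic/basal KdR, global
#: leak and Ih conductance densities (S/cm^2)
DEFAULT_BOUNDS = {
    "somatic.NaT.gbar": (0.01, 0.2),
    "axonal.NaT.gbar": (0.3, 4.0),
    "somatic.KdR.gbar": (0.005, 0.1),
    "basal.KdR.gbar": (0.0, 0.02),
    "all.pas.g": (2e-5, 2e-4),
    "all.Ih.gbar": (0.0, 3e-4),
}

#: ground-truth parameter vector used to manufacture feature targets
P_TRUE = {
    "somatic.NaT.gbar": 0.08,
    "axonal.NaT.gbar": 1.5,
    "somatic.KdR.gbar": 0.03,
    "basal.KdR.gbar": 0.005,
    "all.pas.g": 6e-5,
    "all.Ih.gbar": 5e-5,
}


def default_parameter_space() -> ParameterSpace:
    return ParameterSpace.from_dict(DEFAULT_BOUNDS)


def fixture_suite() -> ProtocolSuite:
    """Desk-scale protocol suite: 100 ms pre, 400 ms steps at 150%/200%,
    integrated at dt = 0.05 ms throughout (targets and evaluations share the
    same grid, so the comparison is self-consistent)."""
    return ProtocolSuite(step_duration=400.0, dt=0.05)


@dataclass
class FixtureConfig:
    n_morphs: int = 12
    spread: float = 4.0  # fold-range of total surface area across the population
    seed: int = 42
    param_jitter_sd: float = 0.05  # normalized-coordinate jitter for virtual cells
    sd_floor_frac: float = 0.05  # target sd floor as a fraction of |mean|
    sd_floor_abs: float = 1e-3  # absolute floor for near-zero features
    n_virtual_cells: int = 10

    def __post_init__(self) -> None:
        if self.spread < 1:
            raise ValueError("spread factor must be >= 1")
        if self.param_jitter_sd <= 0:
            raise ValueError("jitter sd must be > 0")


# ---------------------------------------------------------------------------
# Morphology population
# ---------------------------------------------------------------------------

# base (scale = 1) geometry, um
_SOMA_RADIUS = 8.0
_AXON_DIAM = 1.2
_BASAL_TOTAL = 600.0
_BASAL_ROOT_FRAC = 0.4
_APICAL_TRUNK = 400.0
_APICAL_BRANCH = 150.0


def _rotate_xy(points: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    out = points.copy()
    out[:, 0] = c * points[:, 0] - s * points[:, 1]
    out[:, 1] = s * points[:, 0] + c * points[:, 1]
    return out


def _straight(p0, direction, length, d0, d1, n=3) -> np.ndarray:
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    ts = np.linspace(0.0, 1.0, n)
    pts = np.empty((n, 4))
    pts[:, :3] = np.asarray(p0) + np.outer(ts * length, direction)
    pts[:, 3] = d0 + (d1 - d0) * ts
    return pts


def _one_morph(scale: float, n_basal: int, angle: float) -> Morphology:
    """Deterministic cell geometry at a global scale, rotated by ``angle``."""
    sections: dict[int, Section] = {}
    sid = 0

    def add(stype, pts, parent=None) -> int:
        nonlocal sid
        sections[sid] = Section(id=sid, stype=stype, points=pts, parent=parent)
        sid += 1
        return sid - 1

    s = scale
    # axon stub: two 30 um sections straight down
    a0 = add("axon", _straight([0, 0, 0], [0, -1, 0], 30.0, _AXON_DIAM * s, _AXON_DIAM * s, n=2))
    add("axon", _straight([0, -30.0, 0], [0, -1, 0], 30.0, _AXON_DIAM * s, _AXON_DIAM * s, n=2), parent=a0)

    # basal trees: root + two daughters, fixed total cable per tree
    per_tree = _BASAL_TOTAL * s / n_basal
    root_len = _BASAL_ROOT_FRAC * per_tree
    child_len = (per_tree - root_len) / 2
    for k in range(n_basal):
        theta = angle + 2 * math.pi * k / n_basal + 0.5
        u = [math.cos(theta), -0.3, math.sin(theta)]
        root_pts = _straight([0, 0, 0], u, root_len, 1.8 * s, 1.2 * s)
        r = add("basal", root_pts)
        tip = root_pts[-1, :3]
        for sgn in (-1.0, 1.0):
            w = [math.cos(theta + sgn * 0.5), -0.4, math.sin(theta + sgn * 0.5)]
            pts = np.vstack([root_pts[-1], _straight(tip, w, child_len, 1.2 * s, 0.7 * s)[1:]])
            add("basal", pts, parent=r)

    # apical trunk + tuft bifurcation, straight up
    trunk_pts = _straight([0, 0, 0], [0, 1, 0], _APICAL_TRUNK * s, 2.2 * s, 1.5 * s)
    tr = add("apical", trunk_pts)
    tip = trunk_pts[-1, :3]
    for sgn in (-1.0, 1.0):
        w = _rotate_xy(np.array([[sgn * 0.4, 1.0, 0.0]]), angle)[0]
        pts = np.vstack([trunk_pts[-1], _straight(tip, w, _APICAL_BRANCH * s, 1.4 * s, 0.8 * s)[1:]])
        add("apical", pts, parent=tr)

    m = Morphology(soma_radius=_SOMA_RADIUS * s, soma_length=_SOMA_RADIUS * s, sections=sections)
    m.validate()
    return m


def gen_morph_population(
    cfg: FixtureConfig, out_dir: str | Path | None = None
) -> list[Morphology]:
    """Generate the morphology population; per-cell global scale is drawn
    log-uniformly so the max/min total-area ratio approaches ``cfg.spread``.

    The basal tree count (1-3) is drawn once per population so that at
    spread 1 all cells are identical up to rotation.  With ``out_dir`` the
    cells are also written as ``cell_<i>.swc``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    n_basal = int(rng.integers(1, 4))
    # surface area scales as the square of the global scale, so a fold-range
    # of `spread` in area needs a fold-range of sqrt(spread) in scale
    half = 0.25 * math.log(cfg.spread)
    pop = []
    for i in range(cfg.n_morphs):
        s = math.exp(rng.uniform(-half, half))
        angle = float(rng.uniform(0, 2 * math.pi))
        m = _one_morph(s, n_basal, angle)
        m.metadata["source"] = f"cell_{i}"
        m.metadata["scale"] = s
        pop.append(m)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(pop):
            write_swc(m, out_dir / f"cell_{i}.swc")
    return pop


# ---------------------------------------------------------------------------
# Feature targets from a ground-truth model
# ---------------------------------------------------------------------------

class TargetGenerationError(RuntimeError):
    pass


def gen_targets(
    space: ParameterSpace,
    p_true: dict[str, float],
    cfg: FixtureConfig,
    exemplar: Morphology,
    suite: ProtocolSuite | None = None,
    base_params: dict[str, float] | None = None,
) -> list[FeatureTarget]:
    """Simulate virtual cells at the ground truth with normalized-coordinate
    parameter jitter; per-feature target mean/sd are the empirical moments,
    with the sd floored at ``sd_floor_frac`` of |mean| (absolute floor for
    near-zero features).  Any non-spiking virtual cell halves the jitter and
    retries, erroring out after three attempts."""
    suite = suite or fixture_suite()
    base = BASE_PARAMS if base_params is None else base_params
    p_hat_true = space.normalize(np.array([p_true[n] for n in space.names]))
    jitter = cfg.param_jitter_sd
    rng_master = np.random.SeedSequence([cfg.seed, 202])
    for attempt in range(3):
        rng = np.random.default_rng(rng_master)
        rows: list[dict] = []
        failed = False
        for _ in range(cfg.n_virtual_cells):
            p_hat = np.clip(p_hat_true + jitter * rng.standard_normal(space.n), -1, 1)
            params = space.to_dict(space.denormalize(p_hat))
            cell = build_cell(exemplar, {**base, **params})
            fv = run_suite(cell, suite)
            if fv.non_spiking:
                failed = True
                break
            rows.append(dict(fv.items()))
        if not failed:
            break
        jitter /= 2
    else:
        raise TargetGenerationError("virtual cells keep failing to spike")

    keys = sorted(set().union(*(set(r) for r in rows)))
    targets = []
    for key in keys:
        vals = np.array([r[key] for r in rows if key in r])
        if len(vals) < max(2, cfg.n_virtual_cells // 2):
            continue  # feature too unreliable to constrain
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        sd = max(sd, cfg.sd_floor_frac * abs(mean), cfg.sd_floor_abs)
        targets.append(FeatureTarget(protocol=key[0], feature=key[1], mean=mean, sd=sd))
    return targets


# ---------------------------------------------------------------------------
# The packaged fixture problem and the recovery experiment
# ---------------------------------------------------------------------------

@dataclass
class FixtureProblem:
    space: ParameterSpace
    exemplar: Morphology
    population: list[Morphology]
    targets: list[FeatureTarget]
    suite: ProtocolSuite
    base_params: dict[str, float]
    p_true: dict[str, float]

    def evaluator(self, feature_set: str = "full"):
        """Cost evaluator on the exemplar; remembers the last rheobase as a
        bracket hint for the next (nearby) evaluation."""
        state = {"hint": None}

        def _eval(params: dict[str, float]):
            res = evaluate_emodel(
                params, self.exemplar, self.suite, self.targets,
                feature_set=feature_set, base_params=self.base_params,
                threshold_hint=state["hint"],
            )
            thr = res.features.get(("global", "threshold_current")) if res.features else None
            state["hint"] = thr
            return res

        return _eval


def fixture_problem(cfg: FixtureConfig | None = None) -> FixtureProblem:
    """Build the full fixture problem: population, exemplar (axons replaced
    by the population-mean AIS + myelin on every cell) and simulated feature
    targets around the ground-truth parameters."""
    cfg = cfg or FixtureConfig()
    pop = gen_morph_population(cfg)
    exemplar = build_exemplar(pop)
    ais_d = exemplar.metadata["exemplar"]["ais_diameter"]
    pop = [attach_ais_and_myelin(m, ais_d) for m in pop]
    space = default_parameter_space()
    suite = fixture_suite()
    targets = gen_targets(space, P_TRUE, cfg, exemplar, suite)
    return FixtureProblem(
        space=space, exemplar=exemplar, population=pop, targets=targets,
        suite=suite, base_params=dict(BASE_PARAMS), p_true=dict(P_TRUE),
    )


def run_fixture_sampling(
    seed: int = 42,
    burnin: MCMCSettings = BURNIN_SETTINGS,
    main: MCMCSettings = MAIN_SETTINGS,
    cfg: FixtureConfig | None = None,
    problem: FixtureProblem | None = None,
):
    """Two-phase MCMC on the fixture problem; returns (problem, records,
    diagnostics of the main phase)."""
    if problem is None:
        problem = fixture_problem(cfg or FixtureConfig(seed=seed))
    records = mcmc.run_two_phase(
        problem.space, problem.evaluator("full"), burnin=burnin, main=main, seed=seed
    )
    diag = mcmc.diagnostics(records, phase="main")
    return problem, records, diag


def _best_distinct(records, k: int, threshold: float):
    """k lowest-cost main-phase records with distinct parameter vectors."""
    main = sorted(
        (r for r in records if r.phase == "main" and r.cost < threshold),
        key=lambda r: r.cost,
    )
    out, seen = [], set()
    for r in main:
        key = tuple(np.round(r.p_hat, 12))
        if key not in seen:
            seen.add(key)
            out.append(r)
        if len(out) == k:
            break
    return out


def recovery_experiment(
    seed: int = 42,
    cfg: FixtureConfig | None = None,
    burnin: MCMCSettings | None = None,
    main: MCMCSettings | None = None,
    n_emodels: int = 5,
    selection: SelectionConfig | None = None,
) -> dict:
    """Closed-loop, desk-scale run of the whole pipeline.

    Generates fixtures, samples e-models with two-phase MCMC (4 chains x 100
    burn-in, 4 chains x 300 main by default), calibrates rho targets and
    resistance surrogates for the best distinct sampled models, adapts and
    evaluates all (model, morphology) pairs, and selects a generalizable
    sub-population.  Reports best-sample cost, the fraction of main-phase
    samples below the validity threshold, the parameter-recovery error of
    the best sample (as a fraction of each bound width) and pair-validity
    fractions before/after selection.
    """
    cfg = cfg or FixtureConfig(seed=seed)
    burnin = burnin or MCMCSettings(temperature=5.0, proposal_sd=0.2, steps=100, chains=4, phase="burnin")
    main = main or MCMCSettings(temperature=0.5, proposal_sd=0.02, steps=300, chains=4, phase="main")
    selection = selection or SelectionConfig()

    problem, records, diag = run_fixture_sampling(seed, burnin, main, cfg=cfg)
    space = problem.space
    main_recs = [r for r in records if r.phase == "main"]
    best = min(main_recs, key=lambda r: r.cost)
    frac_below = float(np.mean([r.cost < VALIDITY_THRESHOLD for r in main_recs]))

    p_true_vec = np.array([problem.p_true[n] for n in space.names])
    width = space.upper - space.lower
    recovery = {
        name: float(abs(best.params[i] - p_true_vec[i]) / width[i])
        for i, name in enumerate(space.names)
    }

    chosen = _best_distinct(records, n_emodels, STRICT_THRESHOLD)
    if not chosen:
        chosen = _best_distinct(records, n_emodels, VALIDITY_THRESHOLD)
    emodels = {f"em{i}": space.to_dict(r.params) for i, r in enumerate(chosen)}

    rho_targets: dict[str, rho_mod.RhoTargets] = {}
    surrogates = {}
    for eid, params in emodels.items():
        full = {**problem.base_params, **params}
        soma_sur = rho_mod.fit_resistance_surrogate(problem.exemplar, full, "soma")
        ais_sur = rho_mod.fit_resistance_surrogate(problem.exemplar, full, "AIS")
        if soma_sur.poor_fit or ais_sur.poor_fit:
            continue
        try:
            rho_targets[eid] = rho_mod.calibrate_rho_targets(
                params, problem.exemplar, problem.targets, problem.suite,
                base_params=problem.base_params, emodel=eid, mtype="fixture",
            )
        except rho_mod.RhoError:
            continue
        surrogates[eid] = (soma_sur, ais_sur)
    emodels = {eid: emodels[eid] for eid in rho_targets}

    morphs = {m.metadata.get("source", f"m{i}"): m for i, m in enumerate(problem.population)}
    matrix = evaluate_pairs(
        emodels, morphs, problem.targets, problem.suite,
        adapt=True, rho_targets=rho_targets, surrogates=surrogates,
        base_params=problem.base_params,
    )
    matrix_noadapt = evaluate_pairs(
        emodels, morphs, problem.targets, problem.suite,
        adapt=False, base_params=problem.base_params,
    )
    sel_models, sel_morphs = select_generalizable(matrix, selection)
    if sel_models:
        rows = [matrix.emodels.index(e) for e in sel_models]
        cols = [matrix.morphologies.index(m) for m in sel_morphs]
        after = float(np.mean(matrix.status[np.ix_(rows, cols)] == "VALID"))
    else:
        after = 0.0

    return {
        "seed": seed,
        "best_cost": float(best.cost),
        "best_params": space.to_dict(best.params),
        "frac_main_below_threshold": frac_below,
        "param_recovery_fraction_of_bounds": recovery,
        "acceptance_rate": diag["acceptance_rate"],
        "autocorr_lag_below_0p1": diag["lag_below_0p1"],
        "n_emodels_calibrated": len(emodels),
        "pair_valid_fraction": matrix.valid_fraction(),
        "pair_valid_fraction_noadapt": matrix_noadapt.valid_fraction(),
        "selected_models": sel_models,
        "selected_morphologies": sel_morphs,
        "pair_valid_fraction_after_selection": after,
        "matrix": matrix,
        "matrix_noadapt": matrix_noadapt,
        "records": records,
        "problem": problem,
    }
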