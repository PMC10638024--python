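"""Metropolis-Hastings sampling of the normalized parameter hypercube.

Parameters are sampled from P(p) proportional to exp(-C(p)/T) where C is the
max-|z| model cost and T a temperature: low T concentrates samples at cost
minima, T -> infinity recovers uniform sampling of the hypercube.  Each
parameter is affinely normalized to [-1, 1] so that bound sizes and units do
not bias the isotropic Gaussian proposal.

The production schedule has two phases: a short high-temperature burn-in
(T = 5, proposal sd 0.2) started from uniform-random points, whose best
records re-seed the main chains (T = 0.5, proposal sd 0.02).  Proposals
falling outside the hypercube are re-sampled until inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSpace",
    "MCMCSettings",
    "BURNIN_SETTINGS",
    "MAIN_SETTINGS",
    "ChainRecord",
    "propose",
    "mh_accept",
    "run_chain",
    "run_two_phase",
    "diagnostics",
    "records_to_frame",
    "autocorrelation",
]


@dataclass
class ParameterSpace:
    """Named, bounded parameters with an affine map to the unit hypercube."""

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if len(self.names) != len(self.lower) or len(self.names) != len(self.upper):
            raise ValueError("names and bounds must have equal length")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @classmethod
    def from_dict(cls, bounds: dict[str, tuple[float, float]]) -> "ParameterSpace":
        names = list(bounds)
        lo = np.array([bounds[n][0] for n in names])
        hi = np.array([bounds[n][1] for n in names])
        return cls(names=names, lower=lo, upper=hi)

    @property
    def n(self) -> int:
        return len(self.names)

    def normalize(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if np.any(p < self.lower - 1e-12) or np.any(p > self.upper + 1e-12):
            raise ValueError("parameter vector outside bounds")
        return 2 * (p - self.lower) / (self.upper - self.lower) - 1

    def denormalize(self, p_hat: np.ndarray) -> np.ndarray:
        p_hat = np.asarray(p_hat, dtype=float)
        if np.any(np.abs(p_hat) > 1 + 1e-12):
            raise ValueError("normalized vector outside [-1, 1] hypercube")
        return self.lower + (p_hat + 1) * (self.upper - self.lower) / 2

    def to_dict(self, p: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, np.asarray(p, dtype=float)))


@dataclass
class MCMCSettings:
    temperature: float  # sd units
    proposal_sd: float  # normalized units
    steps: int
    chains: int = 8
    phase: str = "main"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.proposal_sd < 0:
            raise ValueError("proposal sd must be >= 0")


BURNIN_SETTINGS = MCMCSettings(temperature=5.0, proposal_sd=0.2, steps=200, phase="burnin")
MAIN_SETTINGS = MCMCSettings(temperature=0.5, proposal_sd=0.02, steps=1000, phase="main")


@dataclass
class ChainRecord:
    iteration: int
    chain: int
    phase: str
    p_hat: np.ndarray
    params: np.ndarray
    cost: float
    zscores: dict = field(default_factory=dict)
    accepted: bool = True
    draw: float = math.nan
    status: str = "VALID"
    features: dict = field(default_factory=dict)


RESAMPLE_LIMIT = 100_000


def propose(p_hat: np.ndarray, eps: float, rng: np.random.Generator) -> np.ndarray:
    """Isotropic normal proposal truncated to the hypercube by re-sampling."""
    if eps == 0:
        return p_hat.copy()
    for _ in range(RESAMPLE_LIMIT):
        cand = p_hat + eps * rng.standard_normal(len(p_hat))
        if np.all(np.abs(cand) <= 1.0):
            return cand
    raise RuntimeError(f"proposal re-sampling exceeded {RESAMPLE_LIMIT} draws (eps={eps})")


def mh_accept(c_current: float, c_proposed: float, temperature: float, draw: float) -> bool:
    """Accept iff exp((C_current - C_proposed)/T) >= a with a ~ U(0, 1)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if c_proposed <= c_current:
        return True  # ratio >= 1 >= a
    return math.exp((c_current - c_proposed) / temperature) >= draw


def _evaluate(evaluator, space: ParameterSpace, p_hat: np.ndarray):
    """Call the user evaluator; returns (cost, zscores, status, features)."""
    params = space.denormalize(p_hat)
    result = evaluator(space.to_dict(params))
    if hasattr(result, "cost"):
        fv = getattr(result, "features", None)
        feats = dict(fv.items()) if fv is not None else {}
        return (
            float(result.cost),
            dict(getattr(result, "zscores", {}) or {}),
            getattr(result, "status", "VALID"),
            feats,
        )
    return float(result), {}, "VALID", {}


def run_chain(
    space: ParameterSpace,
    evaluator,
    settings: MCMCSettings,
    rng: np.random.Generator,
    chain_id: int = 0,
    p_hat0: np.ndarray | None = None,
) -> list[ChainRecord]:
    """One Metropolis-Hastings chain; the start point is recorded at
    iteration 0 and each subsequent step appends exactly one record.

    Evaluator failures mark the record and the chain continues from its
    previous state.
    """
    p_hat = (
        p_hat0.copy()
        if p_hat0 is not None
        else rng.uniform(-1.0, 1.0, size=space.n)
    )
    cost, z, status, feats = _evaluate(evaluator, space, p_hat)
    records = [
        ChainRecord(
            iteration=0, chain=chain_id, phase=settings.phase, p_hat=p_hat.copy(),
            params=space.denormalize(p_hat), cost=cost, zscores=z, status=status,
            features=feats,
        )
    ]
    for it in range(1, settings.steps + 1):
        cand = propose(p_hat, settings.proposal_sd, rng)
        draw = float(rng.uniform(0.0, 1.0))
        try:
            c_cand, z_cand, status_cand, f_cand = _evaluate(evaluator, space, cand)
        except Exception as exc:  # noqa: BLE001 - evaluation failure, keep going
            records.append(
                ChainRecord(
                    iteration=it, chain=chain_id, phase=settings.phase,
                    p_hat=p_hat.copy(), params=space.denormalize(p_hat),
                    cost=cost, zscores=z, accepted=False, draw=draw,
                    status=f"FAILED:{exc}", features=feats,
                )
            )
            continue
        if mh_accept(cost, c_cand, settings.temperature, draw):
            p_hat, cost, z, status, feats = cand, c_cand, z_cand, status_cand, f_cand
            accepted = True
        else:
            accepted = False
        records.append(
            ChainRecord(
                iteration=it, chain=chain_id, phase=settings.phase,
                p_hat=p_hat.copy(), params=space.denormalize(p_hat),
                cost=cost, zscores=z, accepted=accepted, draw=draw, status=status,
                features=feats,
            )
        )
    return records


def run_two_phase(
    space: ParameterSpace,
    evaluator,
    burnin: MCMCSettings = BURNIN_SETTINGS,
    main: MCMCSettings = MAIN_SETTINGS,
    seed: int = 0,
) -> list[ChainRecord]:
    """Burn-in chains from uniform starts, then main chains re-seeded from
    the k lowest-cost burn-in records (k = main chain count, ties broken by
    record order).  All records of both phases are returned; per-chain RNGs
    are spawned deterministically from the master seed."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(burnin.chains + main.chains)
    all_records: list[ChainRecord] = []
    burn_records: list[ChainRecord] = []
    for c in range(burnin.chains):
        rng = np.random.default_rng(child_seeds[c])
        recs = run_chain(space, evaluator, replace(burnin, phase="burnin"), rng, chain_id=c)
        burn_records.extend(recs)
    all_records.extend(burn_records)

    order = sorted(range(len(burn_records)), key=lambda i: burn_records[i].cost)
    starts = [burn_records[i].p_hat for i in order[: main.chains]]
    while len(starts) < main.chains:  # fewer burn-in records than chains
        starts.append(starts[len(starts) % max(len(starts), 1)])
    for c in range(main.chains):
        rng = np.random.default_rng(child_seeds[burnin.chains + c])
        recs = run_chain(
            space, evaluator, replace(main, phase="main"), rng,
            chain_id=c, p_hat0=starts[c],
        )
        all_records.extend(recs)
    return all_records


def records_to_frame(records: list[ChainRecord], space: ParameterSpace) -> pd.DataFrame:
    """Flatten chain records to a DataFrame with param: and z: columns."""
    rows = []
    for r in records:
        row = {
            "phase": r.phase,
            "chain": r.chain,
            "iteration": r.iteration,
            "accepted": r.accepted,
            "cost": r.cost,
            "status": r.status,
        }
        for name, value in zip(space.names, r.params):
            row[f"param:{name}"] = value
        for key, value in r.zscores.items():
            proto, feat = key if isinstance(key, tuple) else ("", key)
            row[f"z:{proto}/{feat}"] = value
        for key, value in r.features.items():
            proto, feat = key if isinstance(key, tuple) else ("", key)
            row[f"feat:{proto}/{feat}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Normalized autocovariance of a series, lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag is None:
        max_lag = n - 1
    x = x - x.mean()
    var = float(np.dot(x, x))
    if var == 0:
        return np.concatenate([[1.0], np.zeros(max_lag)])
    full = np.correlate(x, x, mode="full")[n - 1 : n + max_lag]
    return full / var


def diagnostics(
    records: list[ChainRecord],
    phase: str = "main",
    validity_threshold: float = 5.0,
    max_lag: int = 200,
) -> dict:
    """Sampler-health summary of one phase.

    Returns per-chain acceptance rates, the chain-averaged normalized cost
    autocorrelation with the first lag below 0.1, cost-saturation fractions
    per feature (how often each feature attains the max and thus defines the
    cost), and the records filtered below the validity threshold.
    """
    recs = [r for r in records if r.phase == phase]
    by_chain: dict[int, list[ChainRecord]] = {}
    for r in recs:
        by_chain.setdefault(r.chain, []).append(r)
    acceptance = {}
    acfs = []
    for c, chain in sorted(by_chain.items()):
        chain = sorted(chain, key=lambda r: r.iteration)
        moves = [r for r in chain if r.iteration > 0]
        if len(chain) < 2:
            raise ValueError(f"chain {c} has fewer than 2 records")
        acceptance[c] = sum(r.accepted for r in moves) / len(moves)
        costs = np.array([r.cost for r in chain])
        acfs.append(autocorrelation(costs, min(max_lag, len(costs) - 1)))
    min_len = min(len(a) for a in acfs)
    acf = np.mean([a[:min_len] for a in acfs], axis=0)
    below = np.where(acf < 0.1)[0]
    lag_below = int(below[0]) if len(below) else None

    saturation: dict = {}
    n_sat = 0
    for r in recs:
        if r.zscores:
            key = max(r.zscores, key=lambda k: abs(r.zscores[k]))
            saturation[key] = saturation.get(key, 0) + 1
            n_sat += 1
    if n_sat:
        saturation = {k: v / n_sat for k, v in saturation.items()}
    filtered = [r for r in recs if r.cost < validity_threshold]
    return {
        "acceptance_rate": acceptance,
        "autocorrelation": acf,
        "lag_below_0p1": lag_below,
        "feature_saturation": saturation,
        "filtered": filtered,
    }
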