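"""Feature targets, z-scores and the max-|z| model cost.

A model's quality against a set of experimental feature targets is

    C(p) = max_i |f_i(p) - mean_i| / sd_i

the maximum absolute z-score over all evaluated features.  The max (rather
than the sum) prevents any single feature from being traded away against
already-good ones and keeps redundant features from biasing the cost.

Missing (undefined) features and non-spiking models score the ``max_cost``
sentinel (default 250 sd), which dominates any realistic z-score; plots and
smoothing conventionally clip at 8 sd.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .morph import Morphology
from .protocols import FeatureVector, ProtocolSuite, run_suite
from .sim import build_cell

__all__ = [
    "MAX_COST",
    "VALIDITY_THRESHOLD",
    "STRICT_THRESHOLD",
    "FeatureTarget",
    "CostResult",
    "zscores",
    "max_cost_of",
    "sum_cost_of",
    "evaluate_emodel",
    "load_targets",
    "save_targets",
]

MAX_COST = 250.0  # sd; sentinel for missing features / non-spiking models
CLIP_COST = 8.0  # sd; visualization / smoothing clip
VALIDITY_THRESHOLD = 5.0  # sd; C* below which a model is valid
STRICT_THRESHOLD = 3.0  # sd; strict validity used for subsampling

#: feature names excluded from the reduced set (redundant derived features,
#: mirroring the discard of dendrite-sensitive/redundant families)
REDUCED_EXCLUDES = ("ISI_mean", "inv_time_to_first_spike")


@dataclass(frozen=True)
class FeatureTarget:
    protocol: str
    feature: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"{self.protocol}/{self.feature}: sd must be > 0")

    @property
    def key(self) -> tuple[str, str]:
        return (self.protocol, self.feature)


@dataclass
class CostResult:
    """Per-feature z-scores and the scalar max-|z| cost."""

    zscores: dict[tuple[str, str], float]
    cost: float
    status: str  # VALID | FEATURE_FAIL | NON_SPIKING | FAILED
    missing: list[tuple[str, str]] = field(default_factory=list)
    features: FeatureVector | None = None
    error: str | None = None

    def to_frame(self):
        """One row per feature z-score plus a summary row (cost, status)."""
        import pandas as pd

        rows = [
            {"protocol": p, "feature": f, "z": z, "missing": (p, f) in self.missing}
            for (p, f), z in sorted(self.zscores.items())
        ]
        rows.append({"protocol": "", "feature": "cost", "z": self.cost, "missing": False})
        frame = pd.DataFrame(rows, columns=["protocol", "feature", "z", "missing"])
        frame.attrs["status"] = self.status
        return frame


def zscores(
    features: FeatureVector | dict,
    targets: list[FeatureTarget],
    max_cost: float = MAX_COST,
) -> tuple[dict[tuple[str, str], float], list[tuple[str, str]]]:
    """Absolute z-score per target; missing features score ``max_cost``."""
    values = features.values if isinstance(features, FeatureVector) else features
    z: dict[tuple[str, str], float] = {}
    missing: list[tuple[str, str]] = []
    for tgt in targets:
        f = values.get(tgt.key)
        if f is None or not np.isfinite(f):
            z[tgt.key] = max_cost
            missing.append(tgt.key)
        else:
            z[tgt.key] = abs(f - tgt.mean) / tgt.sd
    return z, missing


def max_cost_of(z: dict, max_cost: float = MAX_COST) -> float:
    """C = max |z_i|, clipped at the ``max_cost`` sentinel."""
    if not z:
        raise ValueError("no z-scores to aggregate")
    return float(min(max(abs(v) for v in z.values()), max_cost))


def sum_cost_of(z: dict) -> float:
    """Sum-of-scores alternative, kept for comparison only."""
    if not z:
        raise ValueError("no z-scores to aggregate")
    return float(sum(abs(v) for v in z.values()))


def select_targets(
    targets: list[FeatureTarget], feature_set: str = "full"
) -> list[FeatureTarget]:
    if feature_set == "full":
        return list(targets)
    if feature_set == "reduced":
        return [t for t in targets if t.feature not in REDUCED_EXCLUDES]
    raise ValueError(f"unknown feature set {feature_set!r}")


def evaluate_emodel(
    params: dict[str, float],
    morph: Morphology,
    suite: ProtocolSuite,
    targets: list[FeatureTarget],
    feature_set: str = "full",
    *,
    soma_scale: float = 1.0,
    ais_scale: float = 1.0,
    base_params: dict[str, float] | None = None,
    validity_threshold: float = VALIDITY_THRESHOLD,
    max_cost: float = MAX_COST,
    threshold_hint: float | None = None,
) -> CostResult:
    """Build the cell, run the protocol suite and score it against targets.

    ``base_params`` are fixed (non-sampled) mechanism parameters applied
    before ``params``.  Non-spiking models get status NON_SPIKING and the
    maximal cost; simulation failures are recorded, not raised.
    """
    use_targets = select_targets(targets, feature_set)
    full = dict(base_params or {})
    full.update(params)
    try:
        cell = build_cell(morph, full, soma_scale=soma_scale, ais_scale=ais_scale)
        fv = run_suite(cell, suite, threshold_hint=threshold_hint)
    except Exception as exc:  # noqa: BLE001 - failures become a status
        return CostResult(zscores={}, cost=max_cost, status="FAILED", error=str(exc))
    if fv.non_spiking:
        z = {t.key: max_cost for t in use_targets}
        return CostResult(
            zscores=z, cost=max_cost, status="NON_SPIKING", features=fv,
            missing=[t.key for t in use_targets],
        )
    z, missing = zscores(fv, use_targets, max_cost)
    cost = max_cost_of(z, max_cost)
    status = "VALID" if cost < validity_threshold else "FEATURE_FAIL"
    return CostResult(zscores=z, cost=cost, status=status, missing=missing, features=fv)


# ---------------------------------------------------------------------------
# Target I/O (JSON or CSV with columns protocol, feature, mean, sd)
# ---------------------------------------------------------------------------

def load_targets(path: str | Path) -> list[FeatureTarget]:
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        with path.open() as fh:
            rows = list(csv.DictReader(fh))
    return [
        FeatureTarget(
            protocol=r["protocol"],
            feature=r["feature"],
            mean=float(r["mean"]),
            sd=float(r["sd"]),
        )
        for r in rows
    ]


def save_targets(targets: list[FeatureTarget], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {"protocol": t.protocol, "feature": t.feature, "mean": t.mean, "sd": t.sd}
        for t in targets
    ]
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    else:
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["protocol", "feature", "mean", "sd"])
            writer.writeheader()
            writer.writerows(rows)
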