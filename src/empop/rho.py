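"""Rho factors: relative input resistances between soma, AIS and dendrites.

The excitability coupling between the spike-initiating axon initial segment
and the somatodendritic load is summarized by two resistance ratios,

    rho     = Rin_soma / Rin_nosoma
    rho_AIS = Rin_AIS  / Rin_noAIS

where Rin_soma and Rin_AIS are input resistances of the isolated soma and
AIS, Rin_nosoma the input resistance of all neurites joined at the soma
location but without the soma (probed at a zero-area junction node at the
beginning of the AIS), and Rin_noAIS the input resistance of the soma plus
dendrites without the AIS, probed at the soma.

Matching per-(e-model, m-type) target rho factors by rescaling the soma and
AIS surface areas generalizes a fixed electrical model across a morphology
population.  Targets are calibrated by a smoothed 10x10 grid search of the
model cost over AIS/soma scales on the m-type exemplar; size -> resistance
maps are order-3 polynomial fits in log-log over scales 0.1-10, inverted by
root finding during the iterative two-round adaptation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cost import CLIP_COST, MAX_COST, FeatureTarget, evaluate_emodel
from .morph import Morphology
from .protocols import ProtocolSuite
from .sim import build_cell, input_resistance

__all__ = [
    "ComponentResistances",
    "RhoFactors",
    "ResistanceSurrogate",
    "RhoTargets",
    "component_resistances",
    "fit_resistance_surrogate",
    "calibrate_rho_targets",
    "adapt_ais_soma",
    "AdaptationResult",
]

SCALE_GRID = np.linspace(0.5, 1.5, 10)  # calibration grid, endpoints inclusive
SMOOTH_SD = 0.1  # Gaussian kernel sd in scale units
SURROGATE_SCALES = (0.1, 10.0)  # fitted range
SURROGATE_RMS_TOL = 0.05  # log-space RMS above which the fit is poor
PROBE_AMP = -0.02  # nA


class RhoError(RuntimeError):
    pass


@dataclass
class ComponentResistances:
    rin_soma: float  # MOhm, isolated soma
    rin_ais: float  # MOhm, isolated AIS (probed at its proximal end)
    rin_nosoma: float  # MOhm, all neurites without soma, probed at the junction
    rin_noais: float  # MOhm, soma + dendrites without AIS, probed at soma

    def rho_factors(self) -> "RhoFactors":
        return RhoFactors(
            rho=self.rin_soma / self.rin_nosoma,
            rho_ais=self.rin_ais / self.rin_noais,
        )


@dataclass
class RhoFactors:
    rho: float
    rho_ais: float


def _measure(cell, site: int = 0) -> float:
    r = input_resistance(cell, site=site, probe_amp=PROBE_AMP, method="steady").rin
    if r <= 0 or not math.isfinite(r):
        raise RhoError(f"non-positive component input resistance: {r}")
    return r


def component_resistances(
    morph: Morphology,
    params: dict[str, float],
    *,
    soma_scale: float = 1.0,
    ais_scale: float = 1.0,
    max_seg_length: float | None = None,
) -> ComponentResistances:
    """Measure the four component input resistances of a cell.

    Active conductances are present and at rest; the probe is a small
    hyperpolarizing current (-0.02 nA).
    """
    if not any(s.stype == "AIS" for s in morph.sections.values()):
        raise RhoError("morphology has no AIS sections")
    kw: dict = {}
    if max_seg_length is not None:
        kw["max_seg_length"] = max_seg_length
    soma = build_cell(
        morph, params, soma_scale=soma_scale, include_regions={"somatic"}, **kw
    )
    ais = build_cell(
        morph, params, ais_scale=ais_scale,
        include_regions={"axonal"}, junction_root=True, **kw
    )
    nosoma = build_cell(
        morph, params, ais_scale=ais_scale,
        include_regions={"axonal", "myelin", "basal", "apical"},
        junction_root=True, **kw
    )
    noais = build_cell(
        morph, params, soma_scale=soma_scale,
        include_regions={"somatic", "basal", "apical"}, **kw
    )
    return ComponentResistances(
        rin_soma=_measure(soma),
        rin_ais=_measure(ais),
        rin_nosoma=_measure(nosoma),
        rin_noais=_measure(noais),
    )


@dataclass
class ResistanceSurrogate:
    """Cubic polynomial of log10(Rin / MOhm) vs log10(scale)."""

    component: str  # "soma" | "AIS"
    coefficients: np.ndarray  # np.polyval order
    rms: float  # log-space residual RMS
    scale_range: tuple[float, float] = SURROGATE_SCALES
    poor_fit: bool = False

    def predict(self, scale: float | np.ndarray) -> np.ndarray:
        return 10.0 ** np.polyval(self.coefficients, np.log10(scale))

    def invert(self, target_rin: float, offset: float = 0.0) -> tuple[float, bool]:
        """Scale whose predicted Rin equals ``target_rin``.

        Roots of the cubic are searched inside the fitted log-range; with
        multiple roots the one nearest scale 1.0 wins.  Out-of-range targets
        clamp to the range boundary and set the ``clamped`` flag.

        ``offset`` shifts the curve in log10(Rin): the surrogate is fitted on
        the exemplar's component, and anchoring it with the log-resistance
        offset of the actual cell's component makes the inversion transfer
        across morphologies (the scale dependence is shared, the absolute
        level is not).
        """
        lo, hi = np.log10(self.scale_range)
        coeffs = self.coefficients.copy()
        coeffs[-1] += offset - np.log10(target_rin)
        roots = np.roots(coeffs)
        real = [float(r.real) for r in roots if abs(r.imag) < 1e-9 and lo - 1e-9 <= r.real <= hi + 1e-9]
        if real:
            best = min(real, key=lambda x: abs(x))  # nearest to scale 1 (log 0)
            return 10.0**best, False
        # clamp to whichever boundary gets closer to the target
        pred_lo, pred_hi = self.predict(10.0**lo), self.predict(10.0**hi)
        d_lo = abs(np.log10(pred_lo) - np.log10(target_rin))
        d_hi = abs(np.log10(pred_hi) - np.log10(target_rin))
        return (10.0**lo if d_lo <= d_hi else 10.0**hi), True


def fit_resistance_surrogate(
    morph: Morphology,
    params: dict[str, float],
    component: str,
    n_scales: int = 13,
    rms_tol: float = SURROGATE_RMS_TOL,
) -> ResistanceSurrogate:
    """Fit the isolated-component resistance model over scales 0.1-10.

    Poor fits (log RMS above ``rms_tol``) are flagged: such e-models are
    excluded from adaptation rather than adapted with an unreliable model.
    """
    if n_scales < 8:
        raise ValueError("need >= 8 scale points for a stable cubic fit")
    if component not in ("soma", "AIS"):
        raise ValueError("component must be 'soma' or 'AIS'")
    scales = np.geomspace(*SURROGATE_SCALES, n_scales)
    rins = []
    for s in scales:
        if component == "soma":
            cell = build_cell(morph, params, soma_scale=s, include_regions={"somatic"})
        else:
            cell = build_cell(
                morph, params, ais_scale=s, include_regions={"axonal"}, junction_root=True
            )
        rins.append(_measure(cell))
    x = np.log10(scales)
    y = np.log10(rins)
    coeffs = np.polyfit(x, y, 3)
    rms = float(np.sqrt(np.mean((np.polyval(coeffs, x) - y) ** 2)))
    return ResistanceSurrogate(
        component=component, coefficients=coeffs, rms=rms, poor_fit=rms > rms_tol
    )


@dataclass
class RhoTargets:
    """Calibrated target rho factors for one (e-model, m-type) pair."""

    rho: float
    rho_ais: float
    emodel: str = ""
    mtype: str = ""
    grid_point: tuple[float, float] = (1.0, 1.0)  # (ais_scale, soma_scale)
    smoothed_cost: float = math.nan

    def to_json(self) -> dict:
        return {
            "emodel": self.emodel, "mtype": self.mtype,
            "rho": self.rho, "rho_ais": self.rho_ais,
            "ais_scale": self.grid_point[0], "soma_scale": self.grid_point[1],
            "smoothed_cost": self.smoothed_cost,
        }


def calibrate_rho_targets(
    params: dict[str, float],
    exemplar: Morphology,
    targets: list[FeatureTarget],
    suite: ProtocolSuite | None = None,
    *,
    base_params: dict[str, float] | None = None,
    emodel: str = "",
    mtype: str = "",
    grid: np.ndarray = SCALE_GRID,
    evaluator=None,
) -> RhoTargets:
    """Grid-search AIS/soma scales on the exemplar for the lowest smoothed
    reduced-feature cost, then convert the best grid point to rho factors.

    Costs are clipped at 8 sd before Gaussian smoothing (sd 0.1 in scale
    units, reflective boundaries).  Ties break deterministically toward the
    lowest AIS scale, then the lowest soma scale.  ``evaluator`` may replace
    the default cost evaluation (signature (ais_scale, soma_scale) -> cost).
    """
    suite = suite or ProtocolSuite()
    raw = np.empty((len(grid), len(grid)))  # [ais, soma]
    for i, ais_s in enumerate(grid):
        for j, soma_s in enumerate(grid):
            if evaluator is not None:
                c = float(evaluator(ais_s, soma_s))
            else:
                res = evaluate_emodel(
                    params, exemplar, suite, targets, feature_set="reduced",
                    soma_scale=soma_s, ais_scale=ais_s, base_params=base_params,
                )
                c = res.cost
            raw[i, j] = c
    if np.all(raw >= MAX_COST):  # every grid point non-spiking or failed
        raise RhoError(f"all grid points failed for e-model {emodel!r} / m-type {mtype!r}")
    costs = np.minimum(raw, CLIP_COST)
    sigma_px = SMOOTH_SD / (grid[1] - grid[0])
    smooth = ndimage.gaussian_filter(costs, sigma=sigma_px, mode="reflect")
    best_flat = np.flatnonzero(smooth == smooth.min())[0]  # row-major: lowest ais, then soma
    i, j = np.unravel_index(best_flat, smooth.shape)
    ais_s, soma_s = float(grid[i]), float(grid[j])
    comp = component_resistances(
        exemplar, {**(base_params or {}), **params}, soma_scale=soma_s, ais_scale=ais_s
    )
    rf = comp.rho_factors()
    return RhoTargets(
        rho=rf.rho, rho_ais=rf.rho_ais, emodel=emodel, mtype=mtype,
        grid_point=(ais_s, soma_s), smoothed_cost=float(smooth[i, j]),
    )


@dataclass
class AdaptationResult:
    soma_scale: float
    ais_scale: float
    achieved: RhoFactors
    clamped: bool = False


def adapt_ais_soma(
    morph: Morphology,
    params: dict[str, float],
    targets: RhoTargets,
    soma_surrogate: ResistanceSurrogate,
    ais_surrogate: ResistanceSurrogate,
    n_rounds: int = 2,
) -> AdaptationResult:
    """Iteratively set AIS and soma scales so the cell's rho factors match
    their targets.

    Each round first sizes the AIS (required Rin_AIS = rho_AIS_target *
    Rin_noAIS measured on the current cell, inverted through the AIS
    surrogate), then the soma (required Rin_soma = rho_target * Rin_nosoma
    with the freshly scaled AIS).  Two rounds converge to within a few
    percent of the targets.
    """
    if soma_surrogate.poor_fit or ais_surrogate.poor_fit:
        raise RhoError("surrogate resistance fit flagged poor; e-model not adaptable")
    soma_scale, ais_scale = 1.0, 1.0
    clamped = False
    for _ in range(n_rounds):
        noais = build_cell(
            morph, params, soma_scale=soma_scale,
            include_regions={"somatic", "basal", "apical"},
        )
        rin_noais = _measure(noais)
        # anchor the exemplar-fitted surrogate on this cell's own component
        ais_now = build_cell(
            morph, params, ais_scale=ais_scale,
            include_regions={"axonal"}, junction_root=True,
        )
        off_ais = math.log10(_measure(ais_now)) - math.log10(
            float(ais_surrogate.predict(ais_scale))
        )
        ais_scale, c1 = ais_surrogate.invert(targets.rho_ais * rin_noais, offset=off_ais)
        nosoma = build_cell(
            morph, params, ais_scale=ais_scale,
            include_regions={"axonal", "myelin", "basal", "apical"}, junction_root=True,
        )
        rin_nosoma = _measure(nosoma)
        soma_now = build_cell(
            morph, params, soma_scale=soma_scale, include_regions={"somatic"}
        )
        off_soma = math.log10(_measure(soma_now)) - math.log10(
            float(soma_surrogate.predict(soma_scale))
        )
        soma_scale, c2 = soma_surrogate.invert(targets.rho * rin_nosoma, offset=off_soma)
        clamped = clamped or c1 or c2
    comp = component_resistances(
        morph, params, soma_scale=soma_scale, ais_scale=ais_scale
    )
    return AdaptationResult(
        soma_scale=soma_scale, ais_scale=ais_scale,
        achieved=comp.rho_factors(), clamped=clamped,
    )


def save_rho_targets(targets: dict[tuple[str, str], RhoTargets], path: str | Path) -> None:
    rows = [t.to_json() for t in targets.values()]
    Path(path).write_text(json.dumps(rows, indent=2) + "\n")


def load_rho_targets(path: str | Path) -> dict[tuple[str, str], RhoTargets]:
    rows = json.loads(Path(path).read_text())
    out = {}
    for r in rows:
        out[(r["emodel"], r["mtype"])] = RhoTargets(
            rho=r["rho"], rho_ais=r["rho_ais"], emodel=r["emodel"], mtype=r["mtype"],
            grid_point=(r["ais_scale"], r["soma_scale"]),
            smoothed_cost=r.get("smoothed_cost", math.nan),
        )
    return out
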