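"""Multi-compartment conductance-based simulator on morphology trees.

Each membrane compartment obeys

    c_m du/dt = -sum_k I_k(u, states) + I_axial + I(t)

with the ionic currents I_k supplied by the built-in channel set
(:mod:`empop.channels`).  Voltage steps are implicit Euler: with gating
states frozen over a step the ionic currents are linear in u, so each step
solves one symmetric tree-structured linear system by Hines elimination
(children eliminated into parents, then forward substitution).  Gating
states relax exactly (exponential integration of their linear relaxation)
using voltage-indexed lookup tables.

Units: lengths um, diameters um, areas cm^2 internally, voltage mV, time ms,
currents nA, membrane conductance densities S/cm^2, compartment conductances
uS (so uS * mV = nA), capacitance scaled so C/dt is in nA/mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import channels
from .morph import Morphology

__all__ = [
    "CompartmentalCell",
    "StimulusStep",
    "Trace",
    "SimulationError",
    "discretize",
    "build_cell",
    "simulate",
    "steady_state",
    "input_resistance",
    "builtin_mechanisms",
]

DEFAULT_DT = 0.025  # ms
DEFAULT_MAX_SEG_LENGTH = 60.0  # um
#: the myelin sheath insulates: membrane capacitance AND conductance densities
#: under myelin are reduced by this factor
MYELIN_MEMBRANE_FACTOR = 1.0 / 50.0

REGION_CODES = {"somatic": 0, "axonal": 1, "myelin": 2, "basal": 3, "apical": 4}
_STYPE_TO_REGION = {
    "soma": "somatic",
    "axon": "axonal",
    "AIS": "axonal",
    "myelin": "myelin",
    "basal": "basal",
    "apical": "apical",
}
#: parameter-region aliases: "all" covers every region, "alldend" the dendrites
REGION_GROUPS = {
    "all": ("somatic", "axonal", "myelin", "basal", "apical"),
    "alldend": ("basal", "apical"),
    "somatic": ("somatic",),
    "axonal": ("axonal",),
    "myelin": ("myelin",),
    "basal": ("basal",),
    "apical": ("apical",),
}


class SimulationError(RuntimeError):
    pass


@dataclass
class StimulusStep:
    """Square current step at one compartment (amplitude in nA)."""

    delay: float
    duration: float
    amplitude: float
    site: int = -1  # compartment index; -1 = soma

    def __post_init__(self) -> None:
        if self.delay < 0 or self.duration < 0:
            raise ValueError("delay and duration must be >= 0")


@dataclass
class Trace:
    """Voltage trace on a uniform time grid."""

    t: np.ndarray  # ms
    v: np.ndarray  # mV
    dt: float

    def __post_init__(self) -> None:
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")

    def to_csv(self, path) -> None:
        """Write the trace as two-column CSV (t_ms, v_mv)."""
        import pandas as pd

        pd.DataFrame({"t_ms": self.t, "v_mv": self.v}).to_csv(path, index=False)


@dataclass
class CompartmentalCell:
    """Flat arrays describing a discretized cell.

    ``parent[i] < i`` for every non-root compartment (root is index 0), which
    is the ordering the Hines solver requires.  Conductance densities are per
    compartment in S/cm^2; ``area`` is in cm^2 with the soma counting lateral
    plus end caps and neurites lateral frusta only.
    """

    parent: np.ndarray  # int32, -1 for root
    area: np.ndarray  # cm^2
    cm: np.ndarray  # uF/cm^2
    g_axial: np.ndarray  # uS coupling to parent (0 for root)
    region: np.ndarray  # int8 codes per REGION_CODES
    memb_scale: np.ndarray  # conductance-density multiplier (myelin insulation)
    g_pas: np.ndarray  # S/cm^2
    e_pas: np.ndarray  # mV
    gbar_nat: np.ndarray
    gbar_kdr: np.ndarray
    gbar_ih: np.ndarray
    soma_index: int = 0
    soma_scale: float = 1.0
    ais_scale: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.parent)

    def total_area(self) -> float:
        return float(self.area.sum())

    def with_params(self, params: dict[str, float]) -> "CompartmentalCell":
        """Return a copy with ``region.mechanism.gbar`` parameters applied."""
        out = CompartmentalCell(
            parent=self.parent,
            area=self.area,
            cm=self.cm.copy(),
            g_axial=self.g_axial,
            region=self.region,
            memb_scale=self.memb_scale,
            g_pas=self.g_pas.copy(),
            e_pas=self.e_pas.copy(),
            gbar_nat=self.gbar_nat.copy(),
            gbar_kdr=self.gbar_kdr.copy(),
            gbar_ih=self.gbar_ih.copy(),
            soma_index=self.soma_index,
            soma_scale=self.soma_scale,
            ais_scale=self.ais_scale,
            meta=dict(self.meta),
        )
        apply_parameters(out, params)
        return out


_PARAM_ARRAYS = {
    ("pas", "g"): "g_pas",
    ("pas", "e"): "e_pas",
    ("NaT", "gbar"): "gbar_nat",
    ("KdR", "gbar"): "gbar_kdr",
    ("Ih", "gbar"): "gbar_ih",
}


def apply_parameters(cell: CompartmentalCell, params: dict[str, float]) -> None:
    """Set mechanism parameters addressed as ``region.mechanism.field``.

    ``region`` may be a single region, ``all`` or ``alldend``.  Conductance
    values must be >= 0.
    """
    for key, value in params.items():
        try:
            region, mech, fieldname = key.split(".")
        except ValueError as exc:
            raise KeyError(f"bad parameter name {key!r}; expected region.mech.field") from exc
        if (mech, fieldname) not in _PARAM_ARRAYS:
            raise KeyError(f"unknown mechanism parameter {mech}.{fieldname}")
        if fieldname != "e" and value < 0:
            raise ValueError(f"{key} must be >= 0, got {value}")
        arr = getattr(cell, _PARAM_ARRAYS[(mech, fieldname)])
        codes = [REGION_CODES[r] for r in REGION_GROUPS[region]]
        mask = np.isin(cell.region, codes)
        arr[mask] = value


def builtin_mechanisms() -> dict[str, dict]:
    """Registry of the built-in channel set (pas, NaT, KdR, Ih)."""
    return channels.registry()


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def _frustum_lateral_area_um2(r0: float, r1: float, length: float) -> float:
    return math.pi * (r0 + r1) * math.sqrt(length**2 + (r1 - r0) ** 2)


def discretize(
    m: Morphology,
    max_seg_length: float = DEFAULT_MAX_SEG_LENGTH,
    *,
    soma_scale: float = 1.0,
    ais_scale: float = 1.0,
    cm: float = 1.0,
    ra: float = 100.0,
    include_regions: set[str] | None = None,
    junction_root: bool = False,
    myelin_max_seg_length: float = 250.0,
) -> CompartmentalCell:
    """Split a morphology into compartments no longer than ``max_seg_length``.

    ``soma_scale`` multiplies the soma cylinder's radius and length jointly
    (surface area scales as scale^2); ``ais_scale`` multiplies AIS diameters
    only.  ``include_regions`` restricts the build to a subset of
    {"somatic", "axonal", "myelin", "basal", "apical"}; when the soma is
    excluded, ``junction_root`` must be True and a near-zero-area passive
    junction node replaces it as the root, which is the probe site for
    soma-less input-resistance measurements.
    """
    if max_seg_length <= 0:
        raise ValueError("max_seg_length must be > 0")
    include = include_regions or set(REGION_CODES)
    has_soma = "somatic" in include
    if not has_soma and not junction_root:
        raise ValueError("excluding the soma requires junction_root=True")

    parents: list[int] = []
    areas: list[float] = []
    cms: list[float] = []
    gax: list[float] = []
    regions: list[int] = []
    sec_last_comp: dict[int, int] = {}
    half_r_axial: list[float] = []  # MOhm, half axial resistance of each comp

    def add_comp(parent: int, area_cm2: float, cm_i: float, region: int, half_r: float) -> int:
        idx = len(parents)
        parents.append(parent)
        areas.append(area_cm2)
        cms.append(cm_i)
        regions.append(region)
        half_r_axial.append(half_r)
        gax.append(0.0)
        return idx

    if has_soma:
        r = m.soma_radius * soma_scale
        length = m.soma_length * soma_scale
        area = (2 * math.pi * r * length + 2 * math.pi * r**2) * 1e-8  # cm^2
        # soma axial resistance: cylinder of radius r, length L (half each way)
        r_ax = ra * (length * 1e-4) / (math.pi * (r * 1e-4) ** 2) / 1e6  # MOhm
        add_comp(-1, area, cm, REGION_CODES["somatic"], r_ax / 2)
    else:
        # near-zero-area passive junction node
        add_comp(-1, 1e-12, cm, REGION_CODES["somatic"], 0.0)

    # process sections parent-before-child
    order: list[int] = []
    stack = [s.id for s in sorted(m.roots(), key=lambda s: s.id, reverse=True)]
    while stack:
        sid = stack.pop()
        order.append(sid)
        stack.extend(c.id for c in sorted(m.children(sid), key=lambda s: s.id, reverse=True))

    skipped: set[int] = set()
    for sid in order:
        sec = m.sections[sid]
        region_name = _STYPE_TO_REGION[sec.stype]
        if region_name not in include or (sec.parent in skipped):
            skipped.add(sid)
            continue
        region = REGION_CODES[region_name]
        dscale = ais_scale if sec.stype == "AIS" else 1.0
        cm_i = cm * MYELIN_MEMBRANE_FACTOR if sec.stype == "myelin" else cm
        seg_cap = myelin_max_seg_length if sec.stype == "myelin" else max_seg_length

        arc = sec.arc_lengths()
        total = arc[-1]
        nseg = max(1, math.ceil(total / seg_cap - 1e-9))
        bounds = np.linspace(0.0, total, nseg + 1)
        radii = np.interp(bounds, arc, sec.points[:, 3]) * dscale / 2.0
        parent_comp = 0 if sec.parent is None else sec_last_comp[sec.parent]
        for i in range(nseg):
            seg_len = bounds[i + 1] - bounds[i]
            r0, r1 = radii[i], radii[i + 1]
            area = _frustum_lateral_area_um2(r0, r1, seg_len) * 1e-8
            # axial resistance of a linearly tapering frustum
            r_ax = ra * (seg_len * 1e-4) / (math.pi * (r0 * 1e-4) * (r1 * 1e-4)) / 1e6
            idx = add_comp(parent_comp, area, cm_i, region, r_ax / 2)
            parent_comp = idx
        sec_last_comp[sid] = parent_comp

    parent_arr = np.asarray(parents, dtype=np.int64)
    n = len(parent_arr)
    g_axial = np.zeros(n)
    for i in range(1, n):
        r_half = half_r_axial[i] + half_r_axial[parent_arr[i]]
        g_axial[i] = 1.0 / max(r_half, 1e-12)  # uS (1/MOhm)

    region_arr = np.asarray(regions, dtype=np.int8)
    memb = np.where(region_arr == REGION_CODES["myelin"], MYELIN_MEMBRANE_FACTOR, 1.0)
    zeros = np.zeros(n)
    cell = CompartmentalCell(
        parent=parent_arr,
        area=np.asarray(areas),
        cm=np.asarray(cms),
        g_axial=g_axial,
        region=region_arr,
        memb_scale=memb,
        g_pas=zeros.copy(),
        e_pas=np.full(n, channels.DEFAULT_E_PAS),
        gbar_nat=zeros.copy(),
        gbar_kdr=zeros.copy(),
        gbar_ih=zeros.copy(),
        soma_index=0,
        soma_scale=soma_scale,
        ais_scale=ais_scale,
        meta={"has_soma": has_soma},
    )
    return cell


def build_cell(
    m: Morphology,
    params: dict[str, float] | None = None,
    *,
    soma_scale: float = 1.0,
    ais_scale: float = 1.0,
    max_seg_length: float = DEFAULT_MAX_SEG_LENGTH,
    include_regions: set[str] | None = None,
    junction_root: bool = False,
) -> CompartmentalCell:
    """Discretize a morphology and apply an e-model parameter dict."""
    cell = discretize(
        m,
        max_seg_length,
        soma_scale=soma_scale,
        ais_scale=ais_scale,
        include_regions=include_regions,
        junction_root=junction_root,
    )
    if params:
        apply_parameters(cell, params)
    return cell


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lerp(table, row, v, v_min, inv_step):
    x = (v - v_min) * inv_step
    if x <= 0.0:
        return table[row, 0]
    n = table.shape[1]
    if x >= n - 1:
        return table[row, n - 1]
    i = int(x)
    f = x - i
    return table[row, i] * (1.0 - f) + table[row, i + 1] * f


@njit(cache=True)
def _hines_solve(parent, diag, offdiag, rhs, v):
    n = diag.shape[0]
    for i in range(n - 1, 0, -1):
        p = parent[i]
        f = offdiag[i] / diag[i]
        diag[p] -= f * offdiag[i]
        rhs[p] += f * rhs[i]
    v[0] = rhs[0] / diag[0]
    for i in range(1, n):
        v[i] = (rhs[i] + offdiag[i] * v[parent[i]]) / diag[i]


@njit(cache=True, fastmath=True)
def _steady_iter(
    parent,
    g_axial,
    g_pas_us,
    e_pas,
    g_nat_us,
    g_kdr_us,
    g_ih_us,
    open_tab,  # (3, n_v): NaT/KdR/Ih open fractions at steady state
    v_min,
    inv_step,
    v,
    i_vec,
    tol,
    max_iter,
    e_na,
    e_k,
    e_h,
):
    """Damped fixed-point iteration to the steady state; returns iterations
    used or -1 on non-convergence."""
    n = parent.shape[0]
    diag = np.empty(n)
    rhs = np.empty(n)
    v_new = np.empty(n)
    for it in range(max_iter):
        for i in range(n):
            vi = v[i]
            g_ion = g_pas_us[i]
            drive = g_pas_us[i] * e_pas[i] + i_vec[i]
            if g_nat_us[i] > 0.0:
                g = g_nat_us[i] * _lerp(open_tab, 0, vi, v_min, inv_step)
                g_ion += g
                drive += g * e_na
            if g_kdr_us[i] > 0.0:
                g = g_kdr_us[i] * _lerp(open_tab, 1, vi, v_min, inv_step)
                g_ion += g
                drive += g * e_k
            if g_ih_us[i] > 0.0:
                g = g_ih_us[i] * _lerp(open_tab, 2, vi, v_min, inv_step)
                g_ion += g
                drive += g * e_h
            diag[i] = g_ion
            rhs[i] = drive
        for i in range(1, n):
            g = g_axial[i]
            diag[i] += g
            diag[parent[i]] += g
        _hines_solve(parent, diag, g_axial, rhs, v_new)
        damp = 0.5 if it < 3 else 1.0
        err = 0.0
        for i in range(n):
            step = v_new[i] - v[i]
            a = abs(step)
            if a > err:
                err = a
            v[i] = v[i] + damp * step
        if err < tol:
            return it + 1
    return -1


@njit(cache=True, fastmath=True)
def _run(
    parent,
    c_over_dt,
    g_axial,
    g_pas_us,
    e_pas,
    g_nat_us,
    g_kdr_us,
    g_ih_us,
    inf_tab,
    dec_tab,
    v_min,
    inv_step,
    v,
    m,
    h,
    ngate,
    q,
    i_const,
    step_amp,
    step_site,
    step_on_idx,
    step_off_idx,
    n_steps,
    record_site,
    out,
    stop_threshold,
    e_na,
    e_k,
    e_h,
):
    """Advance n_steps of implicit Euler; record ``record_site`` voltage.

    Returns the index of the last written sample + 1.  In probe mode
    (finite stop_threshold) the run ends early either when the recorded
    voltage crosses the threshold upward (spike) or when it has been
    flat (change < 1e-7 mV per 100 ms checkpoint window) and safely
    sub-threshold during the stimulus — a settled sub-threshold cell
    cannot spike later, so the probe outcome is already decided.
    """
    n = parent.shape[0]
    diag = np.empty(n)
    rhs = np.empty(n)
    out[0] = v[record_site]
    written = 1
    prev_rec = v[record_site]
    probe_mode = stop_threshold < 1e30
    ncheck = 2000  # checkpoint interval for the settle test
    check_v = 1e30
    for step in range(n_steps):
        in_step = (step >= step_on_idx) and (step < step_off_idx)
        for i in range(n):
            vi = v[i]
            # exact exponential relaxation of gates, tables indexed once
            x = (vi - v_min) * inv_step
            if x < 0.0:
                x = 0.0
            elif x > inf_tab.shape[1] - 1.000001:
                x = inf_tab.shape[1] - 1.000001
            k = int(x)
            f = x - k
            g_ion = g_pas_us[i]
            e_drive = g_pas_us[i] * e_pas[i]
            if g_nat_us[i] > 0.0:
                mi = inf_tab[0, k] * (1.0 - f) + inf_tab[0, k + 1] * f
                di = dec_tab[0, k] * (1.0 - f) + dec_tab[0, k + 1] * f
                m[i] = mi + (m[i] - mi) * di
                hi = inf_tab[1, k] * (1.0 - f) + inf_tab[1, k + 1] * f
                dh = dec_tab[1, k] * (1.0 - f) + dec_tab[1, k + 1] * f
                h[i] = hi + (h[i] - hi) * dh
                g = g_nat_us[i] * m[i] * m[i] * m[i] * h[i]
                g_ion += g
                e_drive += g * e_na
            if g_kdr_us[i] > 0.0:
                ni = inf_tab[2, k] * (1.0 - f) + inf_tab[2, k + 1] * f
                dn = dec_tab[2, k] * (1.0 - f) + dec_tab[2, k + 1] * f
                ngate[i] = ni + (ngate[i] - ni) * dn
                n4 = ngate[i] * ngate[i]
                n4 *= n4
                g = g_kdr_us[i] * n4
                g_ion += g
                e_drive += g * e_k
            if g_ih_us[i] > 0.0:
                qi = inf_tab[3, k] * (1.0 - f) + inf_tab[3, k + 1] * f
                dq = dec_tab[3, k] * (1.0 - f) + dec_tab[3, k + 1] * f
                q[i] = qi + (q[i] - qi) * dq
                g = g_ih_us[i] * q[i]
                g_ion += g
                e_drive += g * e_h
            diag[i] = c_over_dt[i] + g_ion
            rhs[i] = c_over_dt[i] * vi + e_drive + i_const[i]
            if in_step and i == step_site:
                rhs[i] += step_amp
        for i in range(1, n):
            g = g_axial[i]
            diag[i] += g
            diag[parent[i]] += g
        _hines_solve(parent, diag, g_axial, rhs, v)
        rec = v[record_site]
        if not np.isfinite(rec):
            return -(step + 1)  # signal non-finite state
        out[written] = rec
        written += 1
        if probe_mode:
            if prev_rec < stop_threshold <= rec:
                return written  # spike detected
            if in_step and (step - step_on_idx) % ncheck == 0:
                if (
                    step - step_on_idx >= ncheck
                    and abs(rec - check_v) < 1e-7
                    and rec < stop_threshold - 2.0
                ):
                    return written  # settled sub-threshold: no spike possible
                check_v = rec
        prev_rec = rec
    return written


# ---------------------------------------------------------------------------
# Python-level drivers
# ---------------------------------------------------------------------------

def _conductances_us(cell: CompartmentalCell):
    a = cell.area * cell.memb_scale * 1e6  # S/cm^2 * cm^2 -> S; *1e6 -> uS
    return (
        cell.g_pas * a,
        cell.gbar_nat * a,
        cell.gbar_kdr * a,
        cell.gbar_ih * a,
    )


_TABLE_CACHE: dict[float, tuple] = {}


def _tables(dt: float):
    key = round(dt, 9)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = channels.build_gate_tables(dt)
    return _TABLE_CACHE[key]


def steady_state(
    cell: CompartmentalCell,
    i_inj: np.ndarray | float = 0.0,
    site: int | None = None,
    v0: float | np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 300,
) -> np.ndarray:
    """Steady-state voltages under a constant injected current.

    Damped fixed-point iteration: gates are set to their steady-state values
    at the current voltage and the resulting linear resistive tree is solved;
    repeated until the update is below ``tol``.  Falls back to long time
    integration if the iteration does not converge (strong regenerative
    currents).  Intended for sub-threshold operating points.
    """
    n = cell.n
    i_vec = np.zeros(n)
    if np.isscalar(i_inj):
        i_vec[site if site is not None else cell.soma_index] = float(i_inj)
    else:
        i_vec = np.asarray(i_inj, dtype=float)
    g_pas_us, g_nat_us, g_kdr_us, g_ih_us = _conductances_us(cell)
    if v0 is None:
        v = np.full(n, float(np.mean(cell.e_pas)))
    elif np.isscalar(v0):
        v = np.full(n, float(v0))
    else:
        v = np.asarray(v0, dtype=float).copy()
    grid, open_na, open_k, open_h = channels._steady_table()
    open_tab = np.vstack([open_na, open_k, open_h])
    status = _steady_iter(
        cell.parent, cell.g_axial, g_pas_us, cell.e_pas,
        g_nat_us, g_kdr_us, g_ih_us,
        open_tab, grid[0], 1.0 / (grid[1] - grid[0]),
        v, i_vec, tol, max_iter,
        channels.E_NA, channels.E_K, channels.E_H,
    )
    if status > 0:
        return v
    # fall back to relaxation by simulation: spontaneously active cells have
    # no stable fixed point, so a short coarse integration supplies the
    # operating-point voltages instead
    _, v_final, _ = _simulate_arrays(
        cell, i_vec, 0.0, 0, 0, 150.0, 0.1, v_init=v, record_site=cell.soma_index
    )
    return v_final


def _simulate_arrays(
    cell: CompartmentalCell,
    i_const: np.ndarray,
    step_amp: float,
    step_on_idx: int,
    step_off_idx: int,
    duration: float,
    dt: float,
    v_init: np.ndarray | None = None,
    states_init: tuple | None = None,
    record_site: int = 0,
    stop_threshold: float = math.inf,
    step_site: int | None = None,
):
    n = cell.n
    g_pas_us, g_nat_us, g_kdr_us, g_ih_us = _conductances_us(cell)
    c_over_dt = cell.cm * cell.area * 1e3 / dt  # nA/mV
    inf_tab, dec_tab, v_min, inv_step = _tables(dt)
    if v_init is None:
        v = np.full(n, float(np.mean(cell.e_pas)))
    else:
        v = np.asarray(v_init, dtype=float).copy()
    if states_init is None:
        m, _ = channels.gate_inf_tau("m", v)
        h, _ = channels.gate_inf_tau("h", v)
        ng, _ = channels.gate_inf_tau("n", v)
        q, _ = channels.gate_inf_tau("q", v)
    else:
        m, h, ng, q = (s.copy() for s in states_init)
    n_steps = int(round(duration / dt))
    out = np.empty(n_steps + 1)
    written = _run(
        cell.parent,
        c_over_dt,
        cell.g_axial,
        g_pas_us,
        cell.e_pas,
        g_nat_us,
        g_kdr_us,
        g_ih_us,
        inf_tab,
        dec_tab,
        v_min,
        inv_step,
        v,
        m,
        h,
        ng,
        q,
        i_const,
        step_amp,
        step_site if step_site is not None else cell.soma_index,
        step_on_idx,
        step_off_idx,
        n_steps,
        record_site,
        out,
        stop_threshold if stop_threshold is not None else math.inf,
        channels.E_NA,
        channels.E_K,
        channels.E_H,
    )
    if written < 0:
        step = -written
        raise SimulationError(
            f"non-finite membrane potential at t={step * dt:.3f} ms "
            f"(recorded compartment {record_site})"
        )
    t = np.arange(written) * dt
    trace = Trace(t=t, v=out[:written].copy(), dt=dt)
    return trace, v, (m, h, ng, q)


def simulate(
    cell: CompartmentalCell,
    stimuli: list[StimulusStep] | None = None,
    duration: float = 1000.0,
    dt: float = DEFAULT_DT,
    *,
    record_site: int | None = None,
    holding: float = 0.0,
    init_steady: bool = True,
    stop_at_spike: float | None = None,
) -> Trace:
    """Run the cell for ``duration`` ms and record one site (default soma).

    A constant ``holding`` current is applied at the soma for the whole run.
    At most one square step stimulus is supported on top of it (the protocol
    suite never needs more).  With ``init_steady`` the run starts from the
    steady state under the holding current.  ``stop_at_spike`` ends the run
    early when the recorded voltage crosses that threshold upward.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    stimuli = stimuli or []
    if len(stimuli) > 1:
        raise ValueError("at most one step stimulus per run")
    rec = record_site if record_site is not None else cell.soma_index
    i_const = np.zeros(cell.n)
    i_const[cell.soma_index] += holding
    if stimuli:
        st = stimuli[0]
        site = st.site if st.site >= 0 else cell.soma_index
        on = int(round(st.delay / dt))
        off = int(round((st.delay + st.duration) / dt))
        amp = st.amplitude
    else:
        site, on, off, amp = cell.soma_index, 0, 0, 0.0
    v0 = steady_state(cell, i_const) if init_steady else None
    trace, _, _ = _simulate_arrays(
        cell,
        i_const,
        amp,
        on,
        off,
        duration,
        dt,
        v_init=v0,
        record_site=rec,
        stop_threshold=stop_at_spike if stop_at_spike is not None else math.inf,
        step_site=site,
    )
    return trace


def point_cell(
    area_cm2: float,
    params: dict[str, float] | None = None,
    cm: float = 1.0,
) -> CompartmentalCell:
    """Single isopotential compartment of the given membrane area (cm^2)."""
    n = 1
    cell = CompartmentalCell(
        parent=np.array([-1], dtype=np.int64),
        area=np.array([area_cm2]),
        cm=np.array([cm]),
        g_axial=np.zeros(n),
        region=np.array([REGION_CODES["somatic"]], dtype=np.int8),
        memb_scale=np.ones(n),
        g_pas=np.zeros(n),
        e_pas=np.full(n, channels.DEFAULT_E_PAS),
        gbar_nat=np.zeros(n),
        gbar_kdr=np.zeros(n),
        gbar_ih=np.zeros(n),
    )
    if params:
        apply_parameters(cell, params)
    return cell


@dataclass
class InputResistanceResult:
    rin: float  # MOhm
    v_base: float
    v_end: float
    steady: bool  # False when the pre-probe baseline still drifts

    def __float__(self) -> float:
        return self.rin


def input_resistance(
    cell: CompartmentalCell,
    site: int | None = None,
    probe_amp: float = -0.02,
    probe_dur: float = 500.0,
    dt: float = 0.05,
    method: str = "sim",
    holding: float = 0.0,
) -> InputResistanceResult:
    """Input resistance at a compartment from a small hyperpolarizing probe.

    ``method="sim"`` runs a probe step simulation from the steady state and
    uses (V_end - V_base) / probe_amp; ``method="steady"`` solves the two
    steady states directly (same value, much faster).
    """
    if probe_amp == 0:
        raise ValueError("probe_amp must be non-zero")
    s = site if site is not None else cell.soma_index
    if method == "steady":
        i0 = np.zeros(cell.n)
        i0[cell.soma_index] += holding
        v_base = steady_state(cell, i0)[s]
        i1 = i0.copy()
        i1[s] += probe_amp
        v_end = steady_state(cell, i1, v0=v_base)[s]
        return InputResistanceResult(
            rin=float((v_end - v_base) / probe_amp),
            v_base=float(v_base),
            v_end=float(v_end),
            steady=True,
        )
    pre = 50.0
    trace = simulate(
        cell,
        [StimulusStep(delay=pre, duration=probe_dur, amplitude=probe_amp, site=s)],
        duration=pre + probe_dur,
        dt=dt,
        record_site=s,
        holding=holding,
        init_steady=True,
    )
    base_win = trace.v[trace.t < pre]
    v_base = float(base_win[-max(1, len(base_win) // 2):].mean())
    drift = float(abs(base_win[-1] - base_win[0]))
    v_end = float(trace.v[-1])
    return InputResistanceResult(
        rin=(v_end - v_base) / probe_amp,
        v_base=v_base,
        v_end=v_end,
        steady=drift < 0.05,
    )
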