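"""Minimal Hodgkin-Huxley channel set for the built-in compartmental simulator.

Four mechanisms cover the dynamics the downstream algorithms exercise:

``pas``
    Linear leak, I = g_pas (u - e_pas).  Default e_pas = -90 mV.
``NaT``
    Transient sodium, m^3 h, published-style kinetics (half-activation near
    -38 mV, inactivation near -66 mV), reversal +50 mV.  Carries the spike
    upstroke; sampled somatically and axonally.
``KdR``
    Delayed-rectifier potassium, n^4, shifted classic kinetics, reversal
    -85 mV.  Repolarizes the spike and sets repetitive firing.
``Ih``
    Non-inactivating hyperpolarization-activated cation current, first-order
    gate with half-activation -82 mV, reversal -45 mV.  Produces sag and
    biases the resting potential.

Rates are at a nominal fixed temperature (no q10 correction).  Gating state
updates use exact exponential relaxation per time step, with x_inf and the
per-step decay factor tabulated on a voltage grid.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GATES",
    "MECHANISMS",
    "E_NA",
    "E_K",
    "E_H",
    "DEFAULT_E_PAS",
    "gate_inf_tau",
    "build_gate_tables",
    "steady_conductance_factors",
    "registry",
]

E_NA = 50.0  # mV
E_K = -85.0  # mV
E_H = -45.0  # mV
DEFAULT_E_PAS = -90.0  # mV

#: gating variables in kernel order
GATES = ("m", "h", "n", "q")

#: mechanism name -> (gates used, reversal)
MECHANISMS = {
    "pas": ((), None),
    "NaT": (("m", "h"), E_NA),
    "KdR": (("n",), E_K),
    "Ih": (("q",), E_H),
}


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 handled."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x / y) < 1e-6
    out[small] = y * (1 + x[small] / y / 2)
    out[~small] = x[~small] / (1 - np.exp(-x[~small] / y))
    return out


def gate_inf_tau(gate: str, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state activation and time constant (ms) of one gate at voltage v."""
    v = np.asarray(v, dtype=float)
    if gate == "m":  # NaT activation
        alpha = 0.182 * _vtrap(v + 38.0, 6.0)
        beta = 0.124 * _vtrap(-(v + 38.0), 6.0)
        tau = 1.0 / (alpha + beta)
        return alpha * tau, np.maximum(tau, 0.02)
    if gate == "h":  # NaT inactivation
        alpha = 0.015 * _vtrap(-(v + 66.0), 6.0)
        beta = 0.015 * _vtrap(v + 66.0, 6.0)
        tau = 1.0 / (alpha + beta)
        return alpha * tau, np.maximum(tau, 0.1)
    if gate == "n":  # KdR activation (fast delayed rectifier)
        inf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 9.0))
        tau = 0.5 + 4.0 / (1.0 + np.exp((v + 30.0) / 12.0))
        return inf, tau
    if gate == "q":  # Ih activation
        inf = 1.0 / (1.0 + np.exp((v + 82.0) / 7.0))
        tau = np.full_like(v, 40.0)
        return inf, tau
    raise KeyError(gate)


# voltage grid for gating lookup tables
V_MIN, V_MAX, V_STEP = -120.0, 60.0, 0.1


def build_gate_tables(dt: float) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Tabulate x_inf and exp(-dt/tau) for all gates on the voltage grid.

    Returns (inf_table, decay_table, v_min, inv_step); tables have shape
    (n_gates, n_voltages) in GATES order.
    """
    v = np.arange(V_MIN, V_MAX + V_STEP / 2, V_STEP)
    inf = np.empty((len(GATES), len(v)))
    dec = np.empty_like(inf)
    for i, g in enumerate(GATES):
        gi, gt = gate_inf_tau(g, v)
        inf[i] = gi
        dec[i] = np.exp(-dt / gt)
    return inf, dec, V_MIN, 1.0 / V_STEP


_STEADY_TABLE: tuple | None = None


def _steady_table():
    global _STEADY_TABLE
    if _STEADY_TABLE is None:
        v = np.arange(V_MIN, V_MAX + V_STEP / 2, V_STEP)
        m, _ = gate_inf_tau("m", v)
        h, _ = gate_inf_tau("h", v)
        n, _ = gate_inf_tau("n", v)
        q, _ = gate_inf_tau("q", v)
        _STEADY_TABLE = (v, m**3 * h, n**4, q)
    return _STEADY_TABLE


def steady_conductance_factors(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Open fractions (m_inf^3 h_inf, n_inf^4, q_inf) at steady state.

    Interpolated from the same voltage grid the kernels use.
    """
    grid, na, k, ih = _steady_table()
    v = np.asarray(v, dtype=float)
    return np.interp(v, grid, na), np.interp(v, grid, k), np.interp(v, grid, ih)


class DuplicateMechanismError(ValueError):
    pass


def registry() -> dict[str, dict]:
    """Built-in mechanism registry: name -> description of gates/reversal."""
    reg: dict[str, dict] = {}
    for name, (gates, reversal) in MECHANISMS.items():
        if name in reg:
            raise DuplicateMechanismError(name)
        reg[name] = {"gates": gates, "reversal": reversal}
    return reg
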