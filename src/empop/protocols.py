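"""Stimulation protocols and spike-train feature extraction.

The protocol suite mirrors standard somatic current-clamp characterization:
find the holding current that keeps the soma at a target potential (default
-83 mV), find the rheobase by bisection between the holding current and the
current that would depolarize the cell to -30 mV (estimated from the input
resistance; a cell needing more than that is declared non-spiking), then run
square steps expressed as a percentage of the rheobase on top of the holding
current.

Feature definitions (frozen here; names follow common electrophysiology
usage):

- ``voltage_base``: mean voltage over the last 50% of the pre-stimulus window.
- ``spikecount``: number of upward crossings of the detection threshold
  (default -20 mV) during the step.
- ``mean_frequency``: spikecount / step duration, in Hz.
- ``AP_amplitude``: mean over spikes of (peak voltage - voltage at the upward
  threshold crossing), mV.
- ``AHP_depth``: mean over inter-spike intervals of (minimum voltage within
  the interval - voltage_base), mV; needs >= 2 spikes.
- ``ISI_mean``: mean inter-spike interval (peak-to-peak), ms; needs >= 2
  spikes.  Per-interval values are available from :func:`spike_features`.
- ``time_to_first_spike``: first peak time - step onset, ms.
- ``inv_time_to_first_spike``: 1000 / time_to_first_spike, Hz.
- ``holding_current`` / ``threshold_current``: nA, protocol-level features
  (the threshold is the step amplitude above holding).

Features undefined for a trace (e.g. AHP with fewer than two spikes) are
*missing*, never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sim import CompartmentalCell, SimulationError, StimulusStep, input_resistance, simulate, steady_state

__all__ = [
    "NON_SPIKING",
    "FeatureVector",
    "ProtocolSuite",
    "detect_spikes",
    "spike_features",
    "extract_features",
    "search_holding",
    "search_threshold",
    "run_suite",
]

SPIKE_THRESHOLD = -20.0  # mV

#: sentinel for cells that cannot spike within the allowed current range
NON_SPIKING = "NON_SPIKING"

STEP_FEATURES = (
    "voltage_base",
    "spikecount",
    "mean_frequency",
    "AP_amplitude",
    "AHP_depth",
    "ISI_mean",
    "time_to_first_spike",
    "inv_time_to_first_spike",
)
GLOBAL_FEATURES = ("holding_current", "threshold_current")


@dataclass
class FeatureVector:
    """Map (protocol, feature name) -> value; missing features are absent."""

    values: dict[tuple[str, str], float] = field(default_factory=dict)
    non_spiking: bool = False

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)

    def items(self):
        return self.values.items()

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self):
        """Rows (protocol, feature, value, missing_flag) as a DataFrame."""
        import pandas as pd

        rows = [
            {"protocol": p, "feature": f, "value": v, "missing": False}
            for (p, f), v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["protocol", "feature", "value", "missing"])


@dataclass
class ProtocolSuite:
    """Protocol configuration for one characterization run."""

    holding_target: float = -83.0  # mV
    non_spiking_bound: float = -30.0  # mV
    step_amplitudes: tuple[float, ...] = (150.0, 200.0)  # % of rheobase
    pre_duration: float = 100.0  # ms before step onset
    step_duration: float = 1000.0  # ms
    post_duration: float = 50.0  # ms
    bisection_tol: float = 1e-3  # nA
    dt: float = 0.025  # ms
    search_dt: float = 0.05  # ms; coarser grid for spike/no-spike bisection probes
    spike_threshold: float = SPIKE_THRESHOLD

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.step_amplitudes):
            raise ValueError("step amplitudes must be > 0")
        if self.bisection_tol <= 0:
            raise ValueError("bisection tolerance must be > 0")

    @property
    def total_duration(self) -> float:
        return self.pre_duration + self.step_duration + self.post_duration

    def protocol_name(self, pct: float) -> str:
        return f"step_{pct:g}"


def detect_spikes(
    trace, threshold: float = SPIKE_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Spike peak times and indices from upward threshold crossings.

    One spike per upward crossing; the peak is the maximum between that
    crossing and the next downward crossing (or trace end).
    """
    v = np.asarray(trace.v)
    above = v >= threshold
    up = np.where(~above[:-1] & above[1:])[0] + 1
    down = np.where(above[:-1] & ~above[1:])[0] + 1
    peaks = []
    for u in up:
        later_down = down[down > u]
        end = later_down[0] if len(later_down) else len(v)
        peaks.append(u + int(np.argmax(v[u:end])))
    idx = np.asarray(peaks, dtype=int)
    return trace.t[idx] if len(idx) else np.empty(0), idx


def spike_features(trace, threshold: float = SPIKE_THRESHOLD) -> dict:
    """Per-spike quantities: peak times/voltages, crossing voltages, ISIs."""
    v = np.asarray(trace.v)
    above = v >= threshold
    up = np.where(~above[:-1] & above[1:])[0] + 1
    peak_times, peak_idx = detect_spikes(trace, threshold)
    return {
        "peak_times": peak_times,
        "peak_voltages": v[peak_idx] if len(peak_idx) else np.empty(0),
        "crossing_voltages": v[up] if len(up) else np.empty(0),
        "isi_values": np.diff(peak_times),
    }


def extract_features(
    trace,
    stim_start: float,
    stim_end: float,
    names: tuple[str, ...] = STEP_FEATURES,
    threshold: float = SPIKE_THRESHOLD,
) -> dict[str, float]:
    """Extract the documented scalar features from one step trace.

    Only spikes whose peaks fall inside the stimulus window count.  Undefined
    features are omitted from the returned dict.
    """
    t, v = np.asarray(trace.t), np.asarray(trace.v)
    sf = spike_features(trace, threshold)
    in_win = (sf["peak_times"] >= stim_start) & (sf["peak_times"] <= stim_end)
    peak_times = sf["peak_times"][in_win]
    peak_v = sf["peak_voltages"][in_win]
    crossing_v = sf["crossing_voltages"][: len(sf["peak_times"])][in_win]
    nspikes = len(peak_times)
    duration_s = (stim_end - stim_start) / 1000.0

    out: dict[str, float] = {}
    pre = v[t < stim_start]
    if len(pre):
        base = float(pre[len(pre) // 2 :].mean())  # last 50% of pre-stim window
        out["voltage_base"] = base
    else:
        base = float("nan")
    if "spikecount" in names:
        out["spikecount"] = float(nspikes)
    if "mean_frequency" in names:
        out["mean_frequency"] = nspikes / duration_s
    if nspikes >= 1:
        out["AP_amplitude"] = float(np.mean(peak_v - crossing_v))
        tts = float(peak_times[0] - stim_start)
        out["time_to_first_spike"] = tts
        if tts > 0:
            out["inv_time_to_first_spike"] = 1000.0 / tts
    if nspikes >= 2:
        isis = np.diff(peak_times)
        out["ISI_mean"] = float(np.mean(isis))
        mins = []
        idx = np.searchsorted(t, peak_times)
        for a, b in zip(idx[:-1], idx[1:]):
            mins.append(float(v[a:b].min()))
        if np.isfinite(base):
            out["AHP_depth"] = float(np.mean(mins) - base)
    return {k: out[k] for k in names if k in out}


class BracketError(RuntimeError):
    pass


def search_holding(
    cell: CompartmentalCell,
    target: float = -83.0,
    tol: float = 1e-3,
    bracket: float = 0.5,
    max_expand: int = 5,
) -> float:
    """Holding current (nA) that keeps the soma at ``target`` mV at steady
    state, by bisection on the steady-state voltage."""
    last_v = {"v": None}

    def v_at(i: float) -> float:
        v = steady_state(cell, i, v0=last_v["v"])
        last_v["v"] = v  # warm-start the next solve from the previous one
        return float(v[cell.soma_index])

    lo, hi = -bracket, bracket
    v_lo, v_hi = v_at(lo), v_at(hi)
    for _ in range(max_expand):
        if v_lo <= target <= v_hi:
            break
        lo, hi = lo * 2, hi * 2
        v_lo, v_hi = v_at(lo), v_at(hi)
    else:
        raise BracketError(
            f"holding target {target} mV not bracketed within +-{bracket * 2**max_expand} nA"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if v_at(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _spikes_during_step(
    cell: CompartmentalCell,
    holding: float,
    amp: float,
    suite: ProtocolSuite,
    early_stop: bool = True,
) -> bool:
    """True when a step of ``amp`` nA above holding elicits >= 1 spike."""
    trace = simulate(
        cell,
        [StimulusStep(suite.pre_duration, suite.step_duration, amp)],
        duration=suite.pre_duration + suite.step_duration,
        dt=suite.search_dt,
        holding=holding,
        stop_at_spike=suite.spike_threshold if early_stop else None,
    )
    times, _ = detect_spikes(trace, suite.spike_threshold)
    return bool(np.any(times >= suite.pre_duration))


def search_threshold(
    cell: CompartmentalCell,
    holding: float,
    suite: ProtocolSuite | None = None,
    rin: float | None = None,
    hint: float | None = None,
) -> float | str:
    """Rheobase step amplitude (nA above holding) by spike/no-spike bisection.

    The upper bound is the current needed to reach the non-spiking bound
    (-30 mV) from the holding target, estimated from the input resistance;
    returns :data:`NON_SPIKING` when even that does not elicit a spike.

    ``hint`` (a previous threshold of a nearby model) narrows the initial
    bracket; if the narrow bracket does not verify, the search falls back to
    the full one.  The result is invariant (within tolerance) to the
    starting bracket.
    """
    suite = suite or ProtocolSuite()
    if hint is not None and hint > 0:
        pad = 10 * suite.bisection_tol
        lo, hi = max(hint - pad, 0.0), hint + pad
        if not _spikes_during_step(cell, holding, lo, suite) and _spikes_during_step(
            cell, holding, hi, suite
        ):
            while hi - lo > suite.bisection_tol:
                mid = 0.5 * (lo + hi)
                if _spikes_during_step(cell, holding, mid, suite):
                    hi = mid
                else:
                    lo = mid
            return hi
    if rin is None:
        rin = input_resistance(cell, method="steady", holding=holding).rin
    if rin <= 0:
        raise SimulationError(f"non-positive input resistance {rin:.2f} MOhm")
    upper = (suite.non_spiking_bound - suite.holding_target) / rin  # nA
    lo, hi = 0.0, upper
    if _spikes_during_step(cell, holding, lo, suite):
        return 0.0  # already spiking at holding: bracket degenerate
    if not _spikes_during_step(cell, holding, hi, suite):
        return NON_SPIKING
    while hi - lo > suite.bisection_tol:
        mid = 0.5 * (lo + hi)
        if _spikes_during_step(cell, holding, mid, suite):
            hi = mid
        else:
            lo = mid
    return hi


def run_suite(
    cell: CompartmentalCell,
    suite: ProtocolSuite | None = None,
    threshold_hint: float | None = None,
) -> FeatureVector:
    """Full characterization: holding, rheobase, percent-rheobase steps.

    On a non-spiking cell the returned vector is flagged and carries no step
    features ("subsequent protocols are not evaluated").
    """
    suite = suite or ProtocolSuite()
    fv = FeatureVector()
    holding = search_holding(cell, suite.holding_target, suite.bisection_tol)
    fv.values[("global", "holding_current")] = holding
    threshold = search_threshold(cell, holding, suite, hint=threshold_hint)
    if threshold == NON_SPIKING:
        fv.non_spiking = True
        return fv
    fv.values[("global", "threshold_current")] = threshold
    for pct in suite.step_amplitudes:
        amp = threshold * pct / 100.0
        trace = simulate(
            cell,
            [StimulusStep(suite.pre_duration, suite.step_duration, amp)],
            duration=suite.total_duration,
            dt=suite.dt,
            holding=holding,
        )
        feats = extract_features(
            trace,
            suite.pre_duration,
            suite.pre_duration + suite.step_duration,
            threshold=suite.spike_threshold,
        )
        proto = suite.protocol_name(pct)
        for name, value in feats.items():
            fv.values[(proto, name)] = value
    return fv
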