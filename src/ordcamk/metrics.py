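"""Per-beat measurements: APD90, EAD detection, peaks, deactivation times.

Definitions
-----------
APD90
    Time from maximum upstroke velocity (within the stimulus window) to
    90 % repolarization, V crossing V_peak - 0.9 (V_peak - V_rest) with
    V_rest taken just before the stimulus; the crossing is linearly
    interpolated.  If the beat never repolarizes the full cycle length is
    returned and flagged.
EAD detection
    A depolarization event during repolarization: after the AP peak,
    while V is above a voltage threshold (-40 mV by default), dV/dt
    turning from negative to positive followed by a rise of at least
    ``delta_v`` (1 mV by default) counts as one event.  The prominence
    requirement gives hysteresis against small-amplitude noise.
Late-Na deactivation time
    Time from the |I_NaL| extremum until |I_NaL| first decays below a
    fixed fraction of it.  The fraction (default 0.05) was calibrated
    once so the control condition (CL 2000 ms, 85 % I_Kr block)
    reproduces its reference deactivation time and then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocols import BeatTrace

EAD_DELTA_V = 1.0          # mV, minimum secondary depolarization
EAD_V_THRESHOLD = -40.0    # mV, repolarization window floor
INAL_DECAY_FRACTION = 0.05  # of peak |I_NaL|; calibrated once, frozen
STIM_WINDOW = 20.0          # ms, window for locating the upstroke


@dataclass(frozen=True)
class BeatMetrics:
    """Measurements of a single paced beat."""

    beat_index: int
    apd90: float                      # ms
    repolarization_failure: bool
    ead_count: int
    ead_times: tuple                  # ms, onset of each event
    peak_amplitudes: dict             # current -> |extremum| (uA/uF)
    inal_deactivation_time: float     # ms
    inal_deactivation_flagged: bool
    camk_active_max: float


def apd90(trace: BeatTrace) -> tuple[float, bool]:
    """(APD90 in ms, repolarization-failure flag) for one beat."""
    t, v = trace.t, trace.v
    v_rest = float(v[0])
    dvdt = np.gradient(v, t)
    in_window = t <= STIM_WINDOW
    i_up = int(np.argmax(np.where(in_window, dvdt, -np.inf)))
    t_up = float(t[i_up])
    if 0 < i_up < v.size - 1:
        # parabolic sub-sample refinement so the upstroke time is stable
        # under grid refinement
        g0, g1, g2 = dvdt[i_up - 1], dvdt[i_up], dvdt[i_up + 1]
        denom = g0 - 2.0 * g1 + g2
        if abs(denom) > 1e-12:
            off = 0.5 * (g0 - g2) / denom
            dt = t[i_up + 1] - t[i_up]
            t_up += float(np.clip(off, -1.0, 1.0)) * dt
    i_peak = i_up + int(np.argmax(v[i_up:]))
    v_peak = float(v[i_peak])
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    below = np.nonzero(v[i_peak:] < v90)[0]
    if below.size == 0:
        return float(t[-1] - t_up), True
    i = i_peak + int(below[0])
    # linear interpolation at the crossing
    t90 = t[i - 1] + (v90 - v[i - 1]) * (t[i] - t[i - 1]) / (v[i] - v[i - 1])
    return float(t90 - t_up), False


def detect_eads(trace: BeatTrace, delta_v: float = EAD_DELTA_V,
                v_threshold: float = EAD_V_THRESHOLD) -> tuple[int, tuple]:
    """Count depolarization events during repolarization of one beat."""
    t, v = trace.t, trace.v
    # initial AP peak: first downturn after the upstroke (the absolute
    # maximum could be an EAD hump, which must stay inside the scan)
    dvdt = np.gradient(v, t)
    i_up = int(np.argmax(np.where(t <= STIM_WINDOW, dvdt, -np.inf)))
    i_peak = i_up
    while i_peak < v.size - 1 and v[i_peak + 1] >= v[i_peak]:
        i_peak += 1
    count = 0
    times = []
    run_max = v[i_peak]
    run_min = v[i_peak]
    t_min = t[i_peak]
    armed = False  # a fall of >= delta_v below the running max was seen
    for i in range(i_peak + 1, v.size):
        if v[i] < v_threshold:
            break
        if not armed:
            run_max = max(run_max, v[i])
            if v[i] <= run_max - delta_v:
                armed = True
                run_min = v[i]
                t_min = t[i]
        else:
            if v[i] < run_min:
                run_min = v[i]
                t_min = t[i]
            elif v[i] >= run_min + delta_v:
                # secondary depolarization of at least delta_v
                count += 1
                times.append(float(t_min))
                armed = False
                run_max = v[i]
    return count, tuple(times)


def classify_ead_pattern(ead_counts) -> str:
    """'none', 'stable', 'alternating' or 'indeterminate' for >= 4 beats."""
    counts = [int(c) for c in ead_counts]
    if len(counts) < 4:
        raise ValueError("classification needs at least 4 beats")
    present = [c > 0 for c in counts]
    if not any(present):
        return "none"
    if all(present):
        return "stable"
    if all(present[i] != present[i + 1] for i in range(len(present) - 1)):
        return "alternating"
    return "indeterminate"


def peak_amplitude(trace: BeatTrace, current: str) -> float:
    """Magnitude of the signed extremum of one current within the beat."""
    x = trace[current]
    return float(np.max(np.abs(x)))


def inal_deactivation_time(
        trace: BeatTrace,
        decay_fraction: float = INAL_DECAY_FRACTION) -> tuple[float, bool]:
    """(deactivation time in ms, no-crossing flag) from the |I_NaL| peak."""
    t = trace.t
    x = np.abs(trace["INaL"])
    i_peak = int(np.argmax(x))
    thresh = decay_fraction * x[i_peak]
    below = np.nonzero(x[i_peak:] < thresh)[0]
    if below.size == 0:
        return float(t[-1] - t[i_peak]), True
    i = i_peak + int(below[0])
    return float(t[i] - t[i_peak]), False


def measure_beat(trace: BeatTrace,
                 currents=("INaL", "ICaL", "ICaK", "ICaNa", "Ito", "IKr",
                           "IKs", "INaCa"),
                 decay_fraction: float = INAL_DECAY_FRACTION) -> BeatMetrics:
    """All per-beat metrics for one trace."""
    a, failed = apd90(trace)
    n_ead, times = detect_eads(trace)
    deact, flagged = inal_deactivation_time(trace, decay_fraction)
    return BeatMetrics(
        beat_index=trace.beat_index,
        apd90=a,
        repolarization_failure=failed,
        ead_count=n_ead,
        ead_times=times,
        peak_amplitudes={c: peak_amplitude(trace, c) for c in currents},
        inal_deactivation_time=deact,
        inal_deactivation_flagged=flagged,
        camk_active_max=float(trace["CaMKactive"].max()),
    )


def measure_run(result) -> list[BeatMetrics]:
    """Metrics for every recorded beat of a run."""
    return [measure_beat(tr) for tr in result.traces]


def percent_change(value: float, control: float) -> float:
    """100 * (value - control) / control."""
    return 100.0 * (value - control) / control
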