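"""Pacing protocols: fixed-CL stimulation, pre-pacing, scenario presets.

A run paces the myocyte with a rectangular stimulus at a fixed cycle
length for ``n_beats`` beats (500 by default, the protocol used for all
reported results) and records uniformly sampled traces of the final
beats.  The default engine is the compiled adaptive Rush--Larsen /
forward-Euler integrator with the solver step capped at 2 ms; a
scipy-LSODA path over the same right-hand side is available as a
cross-check (``solver="lsoda"``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import _kernel as _k
from .beta_adrenergic import RegulationConfig
from .ionic_base import CellState, IntegrationError, build_params, initial_state

#: Trace channels: name -> kernel signal code (current index, or
#: -(state_index + 1) for state variables).
TRACE_CHANNELS = {
    "V": -(_k.IV + 1),
    "INaL": _k.C_INAL,
    "ICaL": _k.C_ICAL,
    "ICaK": _k.C_ICAK,
    "ICaNa": _k.C_ICANA,
    "Ito": _k.C_ITO,
    "IKr": _k.C_IKR,
    "IKs": _k.C_IKS,
    "IK1": _k.C_IK1,
    "INaCa_i": _k.C_INACA_I,
    "INaCa_ss": _k.C_INACA_SS,
    "INaK": _k.C_INAK,
    "Jrel": _k.C_JREL,
    "Jup": _k.C_JUP,
    "CaMKactive": _k.C_CAMKA,
    "CaMKactive_ox": _k.C_CAMKA_OX,
    "Cai": -(_k.ICAI + 1),
    "Cass": -(_k.ICASS + 1),
    "Cansr": -(_k.ICANSR + 1),
}


@dataclass(frozen=True)
class Protocol:
    """Pacing and solver configuration."""

    cycle_length: float              # ms
    n_beats: int = 500
    ikr_block: float = 0.0           # fraction of GKr removed
    stim_amplitude: float = -80.0    # uA/uF
    stim_duration: float = 0.5       # ms
    max_step: float = 2.0            # ms, solver step upper bound
    dt_min: float = 1.0e-4           # ms
    dv_max_per_step: float = 0.5     # mV, accuracy limiter on dV
    plateau_step_cap: float = 0.5    # ms, step cap while V > -70 mV
    sample_dt: float = 0.1           # ms, uniform trace grid
    n_trace_beats: int = 8
    celltype: str = "endo"
    solver: str = "rl"               # "rl" (default) or "lsoda"
    lsoda_rtol: float = 1.0e-6
    lsoda_atol: float = 1.0e-8

    def __post_init__(self) -> None:
        if self.cycle_length <= self.stim_duration:
            raise ValueError("cycle_length must exceed stimulus duration")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if not 0.0 <= self.ikr_block <= 1.0:
            raise ValueError("ikr_block must lie in [0, 1]")
        if self.solver not in ("rl", "lsoda"):
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass
class BeatTrace:
    """Uniformly sampled time series of one paced beat."""

    beat_index: int
    t: np.ndarray                 # ms, from stimulus onset
    signals: dict                 # name -> np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "INaCa":
            return self.signals["INaCa_i"] + self.signals["INaCa_ss"]
        return self.signals[name]

    @property
    def v(self) -> np.ndarray:
        return self.signals["V"]

    def to_dataframe(self):
        import pandas as pd

        cols = {"time_ms": self.t, "V_mV": self.signals["V"]}
        for name in ("INaL", "ICaL", "ICaK", "ICaNa", "Ito", "IKr", "IKs"):
            cols[name] = self.signals[name]
        cols["INaCa"] = self["INaCa"]
        cols["Cai_mM"] = self.signals["Cai"]
        cols["Cass_mM"] = self.signals["Cass"]
        cols["CaMKactive"] = self.signals["CaMKactive"]
        cols["beat"] = np.full(self.t.size, self.beat_index, dtype=int)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class ConvergenceReport:
    """Outcome of the end-of-beat state convergence check."""

    period1_distance: float
    period2_distance: float
    classification: str      # "period-1" | "period-2" | "unconverged"
    n_beats: int
    rtol: float


@dataclass
class RunResult:
    protocol: Protocol
    regulation: RegulationConfig
    beat_states: np.ndarray          # (n_beats, NSTATE) end-of-beat states
    traces: list                     # BeatTrace for the final beats
    final_state: CellState
    convergence: ConvergenceReport


def _relative_linf(a: np.ndarray, b: np.ndarray, rtol: float) -> float:
    scale = 1.0e-8 / rtol + np.abs(b)
    return float(np.max(np.abs(a - b) / scale))


def steady_state_check(states: np.ndarray,
                       rtol: float = 1.0e-6) -> ConvergenceReport:
    """Classify end-of-beat state convergence as period-1 or period-2.

    ``states`` holds one row per beat; at least 4 beats are required.
    Distances are relative L-infinity norms between states one and two
    beats apart.
    """
    states = np.asarray(states)
    if states.ndim != 2 or states.shape[0] < 4:
        raise ValueError("steady_state_check needs at least 4 beats")
    d1 = _relative_linf(states[-1], states[-2], rtol)
    d2 = _relative_linf(states[-1], states[-3], rtol)
    if d1 <= rtol:
        cls = "period-1"
    elif d2 <= rtol:
        cls = "period-2"
    else:
        cls = "unconverged"
    return ConvergenceReport(period1_distance=d1, period2_distance=d2,
                             classification=cls, n_beats=states.shape[0],
                             rtol=rtol)


def _record_beat(y: np.ndarray, p: np.ndarray, protocol: Protocol,
                 beat_index: int) -> BeatTrace:
    nsamp = int(round(protocol.cycle_length / protocol.sample_dt)) + 1
    names = list(TRACE_CHANNELS)
    sig_idx = np.array([TRACE_CHANNELS[n] for n in names], dtype=np.int64)
    rec_t = np.zeros(nsamp)
    rec_s = np.zeros((nsamp, len(names)))
    n = _k.integrate_beat(y, p, protocol.cycle_length, protocol.max_step,
                          protocol.dt_min, protocol.dv_max_per_step,
                          protocol.plateau_step_cap, protocol.sample_dt,
                          rec_t, rec_s, sig_idx)
    if n < 0:
        raise IntegrationError(
            f"integration diverged during beat {beat_index}")
    return BeatTrace(beat_index=beat_index, t=rec_t[:n].copy(),
                     signals={nm: rec_s[:n, i].copy()
                              for i, nm in enumerate(names)})


def _lsoda_beat(y: np.ndarray, p: np.ndarray, protocol: Protocol,
                beat_index: int, record: bool):
    from scipy.integrate import solve_ivp

    tgrid = (np.arange(0.0, protocol.cycle_length + protocol.sample_dt / 2,
                       protocol.sample_dt) if record else None)
    # split at the stimulus edge: LSODA must not smooth over the pulse
    edge = protocol.stim_duration
    ys = []
    trace = {"t": [], "y": []}
    for t0, t1 in ((0.0, edge), (edge, protocol.cycle_length)):
        tev = (tgrid[(tgrid >= t0) & (tgrid <= t1)] if record else None)
        sol = solve_ivp(lambda t, yy: _k.rhs(t, yy, p), (t0, t1), y,
                        method="LSODA", max_step=protocol.max_step,
                        rtol=protocol.lsoda_rtol, atol=protocol.lsoda_atol,
                        t_eval=tev)
        if not sol.success:
            raise IntegrationError(
                f"LSODA failed during beat {beat_index} at t={sol.t[-1]:.3f}"
                f" ms: {sol.message}")
        y = sol.y[:, -1].copy()
        if record:
            trace["t"].append(sol.t)
            trace["y"].append(sol.y)
    if not record:
        return y, None
    tt = np.concatenate(trace["t"])
    yy = np.concatenate(trace["y"], axis=1)
    tt, keep = np.unique(tt, return_index=True)
    yy = yy[:, keep]
    # currents on the sampled grid
    dy = np.zeros(_k.NSTATE)
    yinf = np.zeros(_k.NSTATE)
    ytau = np.zeros(_k.NSTATE)
    cur = np.zeros(_k.NCUR)
    names = list(TRACE_CHANNELS)
    sig = np.zeros((tt.size, len(names)))
    for i, ti in enumerate(tt):
        _k.derivatives(ti if ti < protocol.cycle_length else ti - 1e-9,
                       yy[:, i].copy(), p, dy, yinf, ytau, cur)
        for s, nm in enumerate(names):
            code = TRACE_CHANNELS[nm]
            sig[i, s] = cur[code] if code >= 0 else yy[-code - 1, i]
    return y, BeatTrace(beat_index=beat_index, t=tt,
                        signals={nm: sig[:, s].copy()
                                 for s, nm in enumerate(names)})


def run_protocol(protocol: Protocol,
                 regulation: RegulationConfig | None = None,
                 start_state: CellState | None = None) -> RunResult:
    """Pace the model and return end-of-beat states plus final-beat traces.

    Deterministic for fixed inputs and solver settings.  Traces are kept
    for the final ``protocol.n_trace_beats`` beats (at least 2, so that
    alternans is visible).
    """
    reg = regulation or RegulationConfig()
    p = build_params(reg, protocol)
    state = (start_state.copy() if start_state is not None
             else initial_state())
    y = state.values
    n_rec = min(max(protocol.n_trace_beats, 2), protocol.n_beats)
    n_plain = protocol.n_beats - n_rec
    beat_states = np.zeros((protocol.n_beats, _k.NSTATE))

    if protocol.solver == "lsoda":
        traces = []
        for b in range(protocol.n_beats):
            y, tr = _lsoda_beat(y, p, protocol, b, record=(b >= n_plain))
            beat_states[b] = y
            if tr is not None:
                traces.append(tr)
    else:
        if n_plain > 0:
            ok = _k.pace(y, p, n_plain, protocol.cycle_length,
                         protocol.max_step, protocol.dt_min,
                         protocol.dv_max_per_step, protocol.plateau_step_cap,
                         beat_states[:n_plain])
            if ok < 0:
                raise IntegrationError(
                    "integration diverged during pre-pacing")
        traces = []
        for b in range(n_plain, protocol.n_beats):
            traces.append(_record_beat(y, p, protocol, b))
            beat_states[b] = y

    final = CellState(y.copy())
    final.validate()
    conv = (steady_state_check(beat_states)
            if protocol.n_beats >= 4 else
            ConvergenceReport(np.inf, np.inf, "unconverged",
                              protocol.n_beats, 1.0e-6))
    return RunResult(protocol=protocol, regulation=reg,
                     beat_states=beat_states, traces=traces,
                     final_state=final, convergence=conv)


# ---------------------------------------------------------------------------
# scenario presets

def scenario(cycle_length: float = 2000.0, ikr_block: float = 0.0,
             iso_uM: float = 0.0, overexpressed: str | None = None,
             n_beats: int = 500, **protocol_kw):
    """Build (Protocol, RegulationConfig) for one study condition.

    ``overexpressed`` names the single CaMKII target assigned
    CaMK_0 = 0.12 (all others stay at the 0.05 control value).
    """
    overrides = {overexpressed: 0.12} if overexpressed else {}
    return (Protocol(cycle_length=cycle_length, ikr_block=ikr_block,
                     n_beats=n_beats, **protocol_kw),
            RegulationConfig(iso_uM=iso_uM, camk0_overrides=overrides))


def list_presets() -> list[str]:
    root = importlib.resources.files("ordcamk") / "presets"
    return sorted(f.name[:-5] for f in root.iterdir()
                  if f.name.endswith(".yaml"))


def load_preset(name: str):
    """Load a shipped scenario preset.

    Returns (Protocol, RegulationConfig, metadata dict).
    """
    res = importlib.resources.files("ordcamk") / "presets" / f"{name}.yaml"
    try:
        text = res.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown preset {name!r}; available: {list_presets()}") from None
    doc = yaml.safe_load(text)
    prot = Protocol(**doc.get("protocol", {}))
    reg = RegulationConfig(**doc.get("regulation", {}))
    meta = {k: v for k, v in doc.items()
            if k not in ("protocol", "regulation")}
    return prot, reg, meta


def with_beats(protocol: Protocol, n_beats: int) -> Protocol:
    """Copy of ``protocol`` with a different pre-pacing depth."""
    return replace(protocol, n_beats=n_beats)
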