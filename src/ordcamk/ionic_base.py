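"""The ORd human ventricular myocyte model as a right-hand-side evaluation.

This module is the typed surface over the compiled kernel: the full set
of ionic currents, pumps, exchangers, buffers and Ca-handling fluxes of
the O'Hara--Rudy dynamic model, with the regulatory hooks (CaMKII
tracks, PKA fractions, I_Kr blockage) resolved from a
:class:`~ordcamk.beta_adrenergic.RegulationConfig`.

The state vector holds 42 components: membrane potential, 28
Hodgkin--Huxley gates, the L-type Ca channel mode fraction ``nca``, two
SR-release fluxes, eight ion concentrations and two CaMKtrap tracks
(control and overexpressed).  I_Kr blockage is maximal-conductance
scaling: G_Kr is multiplied by (1 - blockage fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from . import _kernel as _k
from ._kernel import CURRENT_NAMES, STATE_NAMES
from .beta_adrenergic import RegulationConfig
from .camkii_pathway import ALPHA_CAMK, BETA_CAMK, KM_CAM

if TYPE_CHECKING:  # pragma: no cover
    from .protocols import Protocol

CELLTYPES = {"endo": 0, "epi": 1, "M": 2}

#: Kernel parameter slots for each CaMKII phosphorylation user.  INa (fast)
#: and Jrel are CaMKII substrates in the base model but are not
#: overexpression targets, so they stay on the control track.
_TARGET_SLOTS = {
    "INa": (_k.P_CAMK0_INA, _k.P_TRK_INA),
    "INaL": (_k.P_CAMK0_INAL, _k.P_TRK_INAL),
    "ICaL": (_k.P_CAMK0_ICAL, _k.P_TRK_ICAL),
    "ICaK": (_k.P_CAMK0_ICAK, _k.P_TRK_ICAK),
    "ICaNa": (_k.P_CAMK0_ICANA, _k.P_TRK_ICANA),
    "Ito": (_k.P_CAMK0_ITO, _k.P_TRK_ITO),
    "Jrel": (_k.P_CAMK0_JREL, _k.P_TRK_JREL),
    "SERCA": (_k.P_CAMK0_SERCA, _k.P_TRK_SERCA),
}


class IntegrationError(RuntimeError):
    """Raised when the state leaves the finite/physiological domain."""


@dataclass
class CellState:
    """Full ODE state of the myocyte.

    Thin wrapper over the kernel's state vector with named access;
    ``values`` is the array the integrator works on.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (_k.NSTATE,):
            raise ValueError(
                f"state vector must have {_k.NSTATE} components")

    def __getitem__(self, name: str) -> float:
        return float(self.values[STATE_NAMES.index(name)])

    @property
    def v(self) -> float:
        return float(self.values[_k.IV])

    @property
    def ca_ss(self) -> float:
        return float(self.values[_k.ICASS])

    @property
    def camktrap(self) -> float:
        return float(self.values[_k.ICAMKT])

    def copy(self) -> "CellState":
        return CellState(self.values.copy())

    def validate(self) -> None:
        """Check finiteness and the gating/concentration invariants."""
        bad = [n for n, x in zip(STATE_NAMES, self.values)
               if not np.isfinite(x)]
        if bad:
            raise IntegrationError(
                f"non-finite state component(s): {', '.join(bad)}")
        for idx in range(_k.IM, _k.IJRELNP):
            if not 0.0 <= self.values[idx] <= 1.0:
                raise IntegrationError(
                    f"gate {STATE_NAMES[idx]} outside [0, 1]: "
                    f"{self.values[idx]}")
        for idx in (_k.INAI, _k.INASS, _k.IKI, _k.IKSS, _k.ICAI,
                    _k.ICASS, _k.ICANSR, _k.ICAJSR):
            if not self.values[idx] > 0.0:
                raise IntegrationError(
                    f"concentration {STATE_NAMES[idx]} not positive: "
                    f"{self.values[idx]}")

    def as_dict(self) -> dict:
        return {n: float(x) for n, x in zip(STATE_NAMES, self.values)}


@dataclass(frozen=True)
class CurrentSet:
    """Named instantaneous currents (uA/uF) and fluxes (mM/ms)."""

    values: tuple

    def __getitem__(self, name: str) -> float:
        return float(self.values[CURRENT_NAMES.index(name)])

    @property
    def inaca(self) -> float:
        """Total Na/Ca exchanger current (myoplasmic + subspace)."""
        return self["INaCa_i"] + self["INaCa_ss"]

    def total_membrane_current(self) -> float:
        """Sum of all membrane currents including the stimulus;
        equals -dV/dt."""
        names = ("INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr",
                 "IKs", "IK1", "INaCa_i", "INaCa_ss", "INaK", "INab",
                 "IKb", "IpCa", "ICab", "Istim")
        return float(sum(self[n] for n in names))

    def as_dict(self) -> dict:
        return {n: float(x) for n, x in zip(CURRENT_NAMES, self.values)}


def initial_state() -> CellState:
    """ORd published resting state (pre-pacing equilibrates it)."""
    return CellState(_k.INITIAL_STATE.copy())


def build_params(reg: RegulationConfig, protocol: "Protocol") -> np.ndarray:
    """Resolve regulation + protocol into the kernel parameter vector."""
    p = np.zeros(_k.NPARAM)
    p[_k.P_CELLTYPE] = CELLTYPES[protocol.celltype]
    if not 0.0 <= protocol.ikr_block <= 1.0:
        raise ValueError("ikr_block must lie in [0, 1]")
    p[_k.P_IKR_BLOCK] = protocol.ikr_block
    p[_k.P_STIM_AMP] = protocol.stim_amplitude
    p[_k.P_STIM_DUR] = protocol.stim_duration

    fr = reg.fractions()
    from .beta_adrenergic import f_avail, frac_iks_avail
    from .serca_coupling import f_pka_plb
    p[_k.P_VSHIFT] = fr.vshift
    p[_k.P_PERM] = fr.perm_scale
    p[_k.P_TD] = fr.td_scale
    p[_k.P_FAVAIL] = f_avail(fr.lcc_ratio)
    p[_k.P_FRACIKS] = frac_iks_avail(fr.iks_ratio)
    p[_k.P_FPKAPLB] = f_pka_plb(fr.plb_ratio)

    tmap = reg.target_map()
    if reg.shared_trap:
        # one trap ODE, driven by the overexpressed CaMK_0, shared by all
        p[_k.P_CAMK0_T0] = tmap.camk0_overexpressed
        p[_k.P_CAMK0_T1] = tmap.camk0_overexpressed
    else:
        p[_k.P_CAMK0_T0] = reg.camk0_default
        p[_k.P_CAMK0_T1] = tmap.camk0_overexpressed
    for name, (slot_camk0, slot_trk) in _TARGET_SLOTS.items():
        if name in ("INa", "Jrel"):
            p[slot_camk0] = reg.camk0_default
            p[slot_trk] = 0.0
        else:
            p[slot_camk0] = tmap.camk0_for(name)
            p[slot_trk] = 0.0 if reg.shared_trap else float(
                tmap.track_for(name))
    p[_k.P_KM_CAMK] = reg.km_camk
    p[_k.P_KM_CAM] = KM_CAM
    p[_k.P_A_CAMK] = ALPHA_CAMK
    p[_k.P_B_CAMK] = BETA_CAMK
    return p


def compute_currents(state: CellState, reg: RegulationConfig,
                     protocol: "Protocol",
                     t_in_beat: float | None = None) -> CurrentSet:
    """Evaluate every current and flux at ``state``.

    ``t_in_beat`` selects the stimulus phase; by default the stimulus is
    off (evaluation outside the pulse).
    """
    state.validate()
    p = build_params(reg, protocol)
    t = protocol.stim_duration + 1.0 if t_in_beat is None else t_in_beat
    dy = np.zeros(_k.NSTATE)
    yinf = np.zeros(_k.NSTATE)
    ytau = np.zeros(_k.NSTATE)
    cur = np.zeros(_k.NCUR)
    _k.derivatives(t, state.values, p, dy, yinf, ytau, cur)
    return CurrentSet(tuple(cur))


def state_derivative(t: float, state: CellState, reg: RegulationConfig,
                     protocol: "Protocol") -> np.ndarray:
    """d(state)/dt at beat-time ``t`` (ms), including dCaMKtrap/dt."""
    state.validate()
    p = build_params(reg, protocol)
    return _k.rhs(t, state.values, p)
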