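"""CaMKII activation kinetics with per-target overexpression.

CaMKII cycles between a Ca/calmodulin-bound active fraction and an
autonomously active "trapped" fraction.  The bound fraction follows the
subspace Ca concentration instantaneously,

    CaMKbound = CaMK_0 * (1 - CaMKtrap) / (1 + KmCaM / Ca_ss),

while trapping is dynamic:

    dCaMKtrap/dt = alpha * CaMKbound * (CaMKbound + CaMKtrap)
                   - beta * CaMKtrap.

Total activity is CaMKactive = CaMKbound + CaMKtrap.  CaMK_0 is the
equilibrium fraction of active binding sites: 0.05 in control and 0.12
for overexpression.  Overexpression can be applied to a single
phosphorylation target; because activation is one dynamical system, the
package runs one CaMKtrap ODE per distinct CaMK_0 value in use (at most
two) and routes each target to its track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ALPHA_CAMK = 0.05    # ms^-1
BETA_CAMK = 0.00068  # ms^-1
KM_CAM = 0.0015      # mM, CaM half-saturation of the bound fraction
CAMK0_CONTROL = 0.05
CAMK0_OVEREXPRESSED = 0.12

#: Phosphorylation targets that can be routed to the overexpressed track.
TARGETS = ("INaL", "ICaL", "ICaK", "ICaNa", "Ito", "SERCA")


def camk_bound(camk0: float, camktrap: float, ca_ss: float,
               km_cam: float = KM_CAM) -> float:
    """Ca/CaM-bound CaMKII fraction at subspace Ca ``ca_ss`` (mM)."""
    if not ca_ss > 0.0:
        raise ValueError(f"ca_ss must be > 0, got {ca_ss}")
    if not 0.0 <= camktrap <= 1.0:
        raise ValueError(f"camktrap must lie in [0, 1], got {camktrap}")
    return camk0 * (1.0 - camktrap) / (1.0 + km_cam / ca_ss)


def camk_trap_derivative(camkbound: float, camktrap: float,
                         alpha: float = ALPHA_CAMK,
                         beta: float = BETA_CAMK) -> float:
    """Rate of change of the trapped fraction (ms^-1)."""
    return alpha * camkbound * (camkbound + camktrap) - beta * camktrap


def camk_active(camk0: float, camktrap: float, ca_ss: float,
                km_cam: float = KM_CAM) -> float:
    """Total active CaMKII fraction: bound + trapped."""
    return camk_bound(camk0, camktrap, ca_ss, km_cam) + camktrap


@dataclass(frozen=True)
class CaMKIIState:
    """Snapshot of one CaMKII activity track."""

    camk0: float
    bound: float
    trap: float

    @property
    def active(self) -> float:
        return self.bound + self.trap


@dataclass(frozen=True)
class TargetMap:
    """Routing of phosphorylation targets to CaMKII activity tracks.

    ``camk0`` maps each target to the CaMK_0 governing its bound fraction;
    ``track`` maps each target to 0 (control CaMKtrap ODE) or 1
    (overexpressed CaMKtrap ODE).  Targets sharing a CaMK_0 share one
    CaMKtrap state variable.
    """

    camk0: dict = field(default_factory=dict)
    track: dict = field(default_factory=dict)
    camk0_default: float = CAMK0_CONTROL
    camk0_overexpressed: float = CAMK0_CONTROL  # value driving track 1

    @classmethod
    def from_overrides(cls, overrides: dict | None = None,
                       camk0_default: float = CAMK0_CONTROL) -> "TargetMap":
        """Build a two-track map from per-target CaMK_0 overrides.

        All overrides must share one value (a single overexpressed track);
        unknown target names are rejected.
        """
        overrides = dict(overrides or {})
        for name in overrides:
            if name not in TARGETS:
                raise KeyError(
                    f"unknown CaMKII target {name!r}; expected one of "
                    f"{TARGETS}")
        distinct = {v for v in overrides.values() if v != camk0_default}
        if len(distinct) > 1:
            raise ValueError(
                "at most one overexpressed CaMK_0 value is supported, got "
                f"{sorted(distinct)}")
        camk0_over = distinct.pop() if distinct else camk0_default
        camk0 = {t: overrides.get(t, camk0_default) for t in TARGETS}
        track = {t: (1 if camk0[t] != camk0_default else 0) for t in TARGETS}
        return cls(camk0=camk0, track=track, camk0_default=camk0_default,
                   camk0_overexpressed=camk0_over)

    def camk0_for(self, target: str) -> float:
        if target not in self.camk0:
            raise KeyError(f"unknown CaMKII target {target!r}")
        return self.camk0[target]

    def track_for(self, target: str) -> int:
        if target not in self.track:
            raise KeyError(f"unknown CaMKII target {target!r}")
        return self.track[target]


def camk_active_for_target(target: str, targets: TargetMap, ca_ss: float,
                           trap_control: float, trap_overexpressed: float,
                           km_cam: float = KM_CAM) -> float:
    """Active CaMKII seen by one phosphorylation target.

    The bound fraction uses the target's own CaMK_0; the trapped fraction
    comes from the track the target is routed to.
    """
    trap = (trap_overexpressed if targets.track_for(target) == 1
            else trap_control)
    return camk_active(targets.camk0_for(target), trap, ca_ss, km_cam)
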