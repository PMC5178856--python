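"""Combined CaMKII + PKA regulation of SR Ca uptake (SERCA/PLB).

PKA phosphorylation of phospholamban relieves SERCA inhibition; CaMKII
phosphorylates SERCA directly.  The two meet in the phosphorylated-SERCA
fraction

    fJupp = 1 / (1 + Km_CaMK * fPKA_PLB / CaMKactive),

where fPKA_PLB = plb_ratio / 4 + 3/4 (plb_ratio is the non-phosphorylated
PLB fraction relative to baseline, so fPKA_PLB < 1 under ISO lowers the
half-saturation point and raises uptake).  Total uptake is the convex
blend of the non-phosphorylated and phosphorylated SERCA populations
minus the SR leak:

    Jup = (1 - fJupp) * Jupnp + fJupp * Jupp - Jleak.
"""

from __future__ import annotations

from dataclasses import dataclass

from .beta_adrenergic import KM_CAMK


def f_pka_plb(plb_ratio: float) -> float:
    """PLB phosphorylation factor; 1.0 at baseline, 0.75 fully phosphorylated."""
    if plb_ratio < 0.0:
        raise ValueError("plb_ratio must be >= 0")
    return plb_ratio / 4.0 + 0.75


def f_jupp(camk_active: float, fpka_plb: float = 1.0,
           km_camk: float = KM_CAMK) -> float:
    """Fraction of SERCA pumps in the CaMKII-phosphorylated population."""
    if camk_active < 0.0:
        raise ValueError("camk_active must be >= 0")
    if camk_active == 0.0:
        return 0.0
    return 1.0 / (1.0 + km_camk * fpka_plb / camk_active)


def j_up(fjupp: float, jupnp: float, jupp: float, jleak: float) -> float:
    """Total SR uptake flux (mM/ms)."""
    return (1.0 - fjupp) * jupnp + fjupp * jupp - jleak


@dataclass(frozen=True)
class UptakeTerms:
    """Resolved uptake quantities for one state evaluation."""

    fpka_plb: float
    fjupp: float
    jupnp: float
    jupp: float
    jleak: float

    @property
    def jup(self) -> float:
        return j_up(self.fjupp, self.jupnp, self.jupp, self.jleak)
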