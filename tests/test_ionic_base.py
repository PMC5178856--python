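"""Base ionic model: current bookkeeping, blockage scaling, invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ordcamk import _kernel as _k
from ordcamk.beta_adrenergic import RegulationConfig
from ordcamk.ionic_base import (CellState, IntegrationError, build_params,
                                compute_currents, initial_state,
                                state_derivative)
from ordcamk.protocols import Protocol


def _protocol(**kw):
    kw.setdefault("cycle_length", 1000.0)
    kw.setdefault("n_beats", 1)
    return Protocol(**kw)


def _depolarized_state() -> CellState:
    """A plateau-like state with open K channels (for conductance tests)."""
    s = initial_state()
    s.values[_k.IV] = 0.0
    s.values[_k.IXRF] = 0.5
    s.values[_k.IXRS] = 0.5
    s.values[_k.IXS1] = 0.4
    s.values[_k.IXS2] = 0.4
    return s


class TestIKrBlock:
    def test_blockage_scales_conductance(self):
        s = _depolarized_state()
        reg = RegulationConfig()
        i_unblocked = compute_currents(s, reg, _protocol())["IKr"]
        assert i_unblocked != 0.0
        i_85 = compute_currents(s, reg, _protocol(ikr_block=0.85))["IKr"]
        assert i_85 == pytest.approx(0.15 * i_unblocked, rel=1e-12)
        i_full = compute_currents(s, reg, _protocol(ikr_block=1.0))["IKr"]
        assert i_full == 0.0

    def test_all_other_currents_untouched_by_block(self):
        s = _depolarized_state()
        reg = RegulationConfig()
        a = compute_currents(s, reg, _protocol()).as_dict()
        b = compute_currents(s, reg, _protocol(ikr_block=0.85)).as_dict()
        for name in a:
            if name != "IKr":
                assert a[name] == b[name]


def test_dvdt_is_negative_total_membrane_current():
    reg = RegulationConfig()
    prot = _protocol()
    for state in (initial_state(), _depolarized_state()):
        dy = state_derivative(100.0, state, reg, prot)
        cur = compute_currents(state, reg, prot, t_in_beat=100.0)
        assert dy[_k.IV] == pytest.approx(-cur.total_membrane_current(),
                                          rel=1e-12)


def test_finite_difference_voltage_matches_summed_currents():
    """dV/dt re-derived by finite-differencing the integrated V matches
    -sum(currents) within solver tolerance."""
    reg = RegulationConfig()
    prot = _protocol()
    p = build_params(reg, prot)
    y0 = initial_state()
    y0.values[_k.IV] = -60.0  # off the fixed point so dV/dt is appreciable
    h = 1.0e-3
    sol = solve_ivp(lambda t, y: _k.rhs(t, y, p), (100.0, 100.0 + h),
                    y0.values, method="LSODA", rtol=1e-10, atol=1e-12)
    fd = (sol.y[_k.IV, -1] - y0.values[_k.IV]) / h
    cur = compute_currents(y0, reg, prot, t_in_beat=100.0)
    assert fd == pytest.approx(-cur.total_membrane_current(), rel=1e-3)


def test_resting_state_is_a_fixed_point_without_stimulus():
    """Relaxed without pacing, every derivative component vanishes."""
    reg = RegulationConfig()
    prot = _protocol(cycle_length=50000.0, stim_amplitude=0.0)
    p = build_params(reg, prot)
    y = initial_state().values
    dummy_t = np.zeros(0)
    dummy_s = np.zeros((0, 0))
    dummy_i = np.zeros(0, dtype=np.int64)
    for _ in range(20):  # 1000 s of quiescence
        _k.integrate_beat(y, p, 50000.0, 2.0, 1e-4, 0.5, 0.5, 1.0,
                          dummy_t, dummy_s, dummy_i)
    dy = state_derivative(1000.0, CellState(y), reg, prot)
    scale = np.abs(y) + 1e-3
    assert np.max(np.abs(dy) / scale) < 1e-6  # per ms


def test_nonfinite_state_raises_naming_component():
    s = initial_state()
    s.values[_k.ICAI] = np.nan
    with pytest.raises(IntegrationError, match="cai"):
        compute_currents(s, RegulationConfig(), _protocol())


def test_gates_bounded_and_concentrations_positive_after_pacing(sim):
    """500-beat runs keep every gate in [0, 1] and concentrations > 0."""
    for cl in (500.0, 2000.0):
        res = sim.run(cycle_length=cl)
        res.final_state.validate()  # raises on violation
        v = res.beat_states[:, _k.IV]
        assert np.all((v >= -100.0) & (v <= 70.0))


def test_baseline_neutrality_of_modified_quantities():
    """ISO off + control CaMK_0 + no blockage leaves every hook neutral."""
    p = build_params(RegulationConfig(), _protocol())
    assert p[_k.P_FAVAIL] == 1.0
    assert p[_k.P_FRACIKS] == 1.0
    assert p[_k.P_FPKAPLB] == 1.0
    assert p[_k.P_VSHIFT] == 3.94
    assert p[_k.P_PERM] == 1.0
    assert p[_k.P_TD] == 1.0
    assert p[_k.P_IKR_BLOCK] == 0.0
    # both CaMKII tracks carry the control CaMK_0
    assert p[_k.P_CAMK0_T0] == p[_k.P_CAMK0_T1] == 0.05
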