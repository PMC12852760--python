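"""Two-pool Bloch-McConnell propagation: dipolar rates, oracles, decay curves."""

import numpy as np
import pytest

import raffsim as rs
from raffsim.dynamics import bloch_mcconnell_matrix, packet_propagator


def _dipolar_oracle(tau_c=10e-12, B0=9.4, gamma_mhz=42.576,
                    hbar=1.054571628e-34, r=158e-12):
    """Straight transcription of the closed-form like-spin dipolar rates,
    evaluated step by step, independent of the library routine."""
    mu0_over_4pi = 1e-7
    gamma = 2.0 * np.pi * gamma_mhz * 1e6
    b = mu0_over_4pi * hbar * gamma * gamma / (r * r * r)
    w0 = gamma * B0
    J0 = tau_c
    J1 = tau_c / (1.0 + (w0 * tau_c) ** 2)
    J2 = tau_c / (1.0 + (2.0 * w0 * tau_c) ** 2)
    R1 = (3.0 / 10.0) * b * b * (J1 + 4.0 * J2)
    R2 = (3.0 / 20.0) * b * b * (3.0 * J0 + 5.0 * J1 + 2.0 * J2)
    return R1, R2


class TestDipolarRates:
    def test_matches_independent_closed_form(self):
        R1, R2 = rs.dipolar_rates()
        oR1, oR2 = _dipolar_oracle()
        assert R1 == pytest.approx(oR1, rel=1e-12)
        assert R2 == pytest.approx(oR2, rel=1e-12)

    def test_extreme_narrowing_limit(self):
        R1, R2 = rs.dipolar_rates()
        assert R1 / R2 == pytest.approx(1.0, abs=2e-3)

    def test_linear_in_tau_c_in_narrowing_limit(self):
        # residual curvature from the (w0 tau_c)^2 terms is below 1 %
        R1a, R2a = rs.dipolar_rates(rs.DipolarParams(tau_c=10e-12))
        R1b, R2b = rs.dipolar_rates(rs.DipolarParams(tau_c=20e-12))
        assert R1b / R1a == pytest.approx(2.0, rel=1e-2)
        assert R2b / R2a == pytest.approx(2.0, rel=1e-2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            rs.DipolarParams(tau_c=-1e-12)


class TestTwoPoolSystem:
    def test_fn1_healthy_fraction(self, healthy_system):
        assert healthy_system.pool_A.fraction == pytest.approx(1.5e-8, rel=1e-12)
        assert healthy_system.pool_A.fraction + healthy_system.pool_B.fraction == 1.0

    def test_upregulated_is_tenfold(self, healthy_system):
        up = rs.build_two_pool_system("Fn1", "upregulated")
        assert up.pool_A.fraction == pytest.approx(
            10 * healthy_system.pool_A.fraction, rel=1e-12
        )

    def test_offsets_follow_population_split(self, healthy_system):
        s = healthy_system
        assert s.pool_A.offset == pytest.approx(
            2 * np.pi * s.pool_B.fraction * 500.0, rel=1e-12
        )
        assert s.pool_B.offset == pytest.approx(
            2 * np.pi * s.pool_A.fraction * 500.0, rel=1e-12
        )

    def test_detailed_balance(self, healthy_system):
        # equilibrium fluxes match: k_AB P_A = k_BA P_B
        s = healthy_system
        assert s.k_AB * s.pool_A.fraction == pytest.approx(
            s.k_BA * s.pool_B.fraction, rel=1e-12
        )

    def test_tau_ex_switch(self):
        fast = rs.build_two_pool_system("Fn1", "healthy", tau_ex_as_rate=False)
        assert fast.k_ex == pytest.approx(1000.0)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown solute"):
            rs.build_two_pool_system("Col1a1", "healthy")


class TestPropagation:
    def test_norm_conserved_without_relaxation(self, healthy_system, tl1_packet):
        system = healthy_system.without_relaxation()
        m0 = healthy_system.equilibrium()
        U = packet_propagator(system, tl1_packet)
        y = np.concatenate([m0.components, [1.0]])
        for _ in range(8):
            y = U @ y
        assert np.linalg.norm(y[:6]) == pytest.approx(m0.norm(), rel=1e-8)

    def test_rotary_echo_refocusing_is_exact(self, healthy_system):
        """On resonance with relaxation off, the packet returns the
        magnetization to its start; the deviation stays at machine level
        when the sampling is doubled."""
        system = healthy_system.without_relaxation()
        m0 = np.concatenate([healthy_system.equilibrium().components, [1.0]])
        for ns in (128, 256):
            packet = rs.make_raff2_packet(625.0, 1.0, n_samples=ns)
            U = packet_propagator(system, packet)
            out = U @ m0
            # on-resonance water refocuses at machine level
            assert np.linalg.norm(out[3:6] - m0[3:6]) < 1e-12
            # residual comes only from the dilute off-resonant pool
            assert np.linalg.norm(out - m0) < 4 * system.pool_A.fraction

    def test_inversion_recovery_closed_form(self, healthy_system):
        R1 = healthy_system.pool_B.R1
        silence = rs.RFShape(np.zeros(64), np.zeros(64), dt=2e-3)
        minus_z = rs.MagState(-healthy_system.equilibrium().components)
        t_rec = 0.1
        (state,) = rs.propagate(healthy_system, silence, minus_z, [t_rec])
        expected = 1.0 - 2.0 * np.exp(-R1 * t_rec)
        assert state.mz_total == pytest.approx(expected, abs=1e-6)

    def test_pi_pulse_inverts_single_pool(self):
        single = rs.TwoPoolSystem(
            pool_A=rs.Pool(0.0, 0.0, 0.0, 0.0),
            pool_B=rs.Pool(1.0, 0.0, 0.0, 0.0),
            k_ex=0.0,
        )
        f = 625.0
        pulse = rs.make_comparison_pulse("HARD", duration=1.0 / (2 * f), peak_hz=f)
        eq = rs.MagState(np.array([0, 0, 0, 0, 0, 1.0]))
        (state,) = rs.propagate(single, pulse, eq, [pulse.duration])
        assert state.components[5] == pytest.approx(-1.0, abs=1e-6)

    def test_ode_agrees_with_expm(self, healthy_system, tl1_packet):
        m0 = healthy_system.equilibrium()
        t_end = tl1_packet.packet_duration
        (a,) = rs.propagate(healthy_system, tl1_packet, m0, [t_end], engine="expm")
        (b,) = rs.propagate(healthy_system, tl1_packet, m0, [t_end], engine="ode")
        assert np.allclose(a.components, b.components, rtol=1e-7, atol=1e-9)

    def test_equilibrium_is_fixed_point(self, healthy_system):
        eq = healthy_system.equilibrium()
        silence = rs.RFShape(np.zeros(32), np.zeros(32), dt=5e-3)
        (state,) = rs.propagate(healthy_system, silence, eq, [silence.duration])
        assert np.allclose(state.components, eq.components, atol=1e-12)

    def test_record_time_out_of_range_rejected(self, healthy_system, tl1_packet):
        with pytest.raises(ValueError, match="record_at"):
            rs.propagate(
                healthy_system, tl1_packet, healthy_system.equilibrium(), [1.0]
            )


class TestDecayCurves:
    def test_initial_conditions(self, healthy_system, tl1_packet):
        cp, cm = rs.simulate_decay_curves(healthy_system, tl1_packet)
        assert cp.signal[0] == pytest.approx(1.0, abs=1e-12)
        assert cm.signal[0] == pytest.approx(-1.0, abs=1e-12)
        assert cp.times.size == 33
        assert cp.times[-1] == pytest.approx(64 * tl1_packet.packet_duration, rel=1e-12)

    def test_upregulation_leaves_curves_unchanged(self, tl1_packet, healthy_system):
        up = rs.build_two_pool_system("Fn1", "upregulated")
        cp_h, _ = rs.simulate_decay_curves(healthy_system, tl1_packet)
        cp_u, _ = rs.simulate_decay_curves(up, tl1_packet)
        assert np.allclose(cp_h.signal, cp_u.signal, rtol=1e-6, atol=1e-6)

    def test_stretched_train_decays_deeper(self, healthy_system):
        cp_short, _ = rs.simulate_decay_curves(
            healthy_system, rs.make_raff2_packet(625.0, 0.6)
        )
        cp_long, _ = rs.simulate_decay_curves(
            healthy_system, rs.make_raff2_packet(625.0, 2.0)
        )
        assert np.all(cp_long.signal[1:] < cp_short.signal[1:])

    def test_sampling_contract(self, healthy_system, tl1_packet):
        with pytest.raises(ValueError):
            rs.simulate_decay_curves(healthy_system, tl1_packet, max_packets=0)
        with pytest.raises(ValueError):
            rs.simulate_decay_curves(healthy_system, tl1_packet, n_timepoints=2)

    def test_fitted_rate_converges_in_waveform_sampling(self, healthy_system):
        fits = []
        for ns in (128, 256):
            p = rs.make_raff2_packet(625.0, 1.0, n_samples=ns)
            fits.append(rs.fit_ss_model(*rs.simulate_decay_curves(healthy_system, p)))
        assert abs(fits[1].R - fits[0].R) / fits[0].R < 5e-3
        assert abs(fits[1].SS_fraction - fits[0].SS_fraction) < 5e-3


class TestRelaxationTable:
    def test_small_table(self, healthy_system):
        methods = [
            ("RAFF2 TL1.0", rs.make_raff2_packet(625.0, 1.0)),
            ("RAFF1", rs.make_raffn_packet(1)),
        ]
        df = rs.simulate_relaxation_table(
            scenarios=[("Fn1", "healthy")], methods=methods
        )
        assert list(df["method"]) == ["RAFF2 TL1.0", "RAFF1"]
        assert df["converged"].all()
        tl1 = df[df.method == "RAFF2 TL1.0"].iloc[0]
        assert 0 < tl1.SS < 1
        assert tl1.R > 0
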