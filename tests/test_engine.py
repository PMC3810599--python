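"""Hybrid SSA/field engine: event kinetics, charge bookkeeping, coupling."""

import math

import numpy as np
import pytest

from tetvolt.channels import (ChannelModel, GHKCurrentSpec,
                              OhmicCurrentSpec, Transition, HH_RATES,
                              hh_potassium_channel, hh_sodium_channel)
from tetvolt.constants import ELEMENTARY_CHARGE
from tetvolt.engine import Simulation, total_ions_probe, vertex_mean_probe
from tetvolt.mesh import CompartmentProps, generate_cylinder_mesh
from tetvolt.solver import (EFieldSystem, build_assembly, step,
                            vertex_capacitances)

ALPHA, BETA = 300.0, 700.0


def two_state_channel(alpha=ALPHA, beta=BETA, current=None):
    conducting = {"open": current} if current else {}
    return ChannelModel("cc", ["closed", "open"],
                        [Transition("closed", "open", alpha),
                         Transition("open", "closed", beta)],
                        conducting=conducting)


@pytest.fixture(scope="module")
def patch():
    """Tiny nearly-isopotential cylinder used as a membrane patch."""
    fx = generate_cylinder_mesh(2e-6, 2e-6, 24, polygon_order=4)
    asm = build_assembly(fx.mesh, CompartmentProps(sigma=1e4), fx.membrane,
                         c_spec=0.01)
    return fx, asm


def fresh_system(asm, dt=1e-4, v=-65e-3, **kw):
    return EFieldSystem(asm, dt, v_init=v, **kw)


def per_tri(fx, n):
    """Explicit per-triangle channel counts for the patch fixture."""
    return np.full(len(fx.membrane.tris), n)


class TestSSA:
    def test_no_propensity_no_event_before_horizon(self, patch):
        fx, asm = patch
        sim = Simulation(fresh_system(asm), channels=[], seed=0)
        executed, t = sim.ssa_step(1.0)
        assert executed is None and t == 1.0

    def test_two_state_stationary_open_fraction(self, patch):
        """Long-run open fraction equals alpha/(alpha+beta) within 3
        standard errors after ~1e5 events."""
        fx, asm = patch
        n_per_tri = 50
        sim = Simulation(fresh_system(asm),
                         channels=[(two_state_channel(), per_tri(fx, n_per_tri))],
                         seed=1)
        sim.advance(0.25, 1e-3)
        assert sim.n_events > 1e5
        counts = sim.state.counts[0]
        n_ch = counts.sum()
        p = ALPHA / (ALPHA + BETA)
        se = math.sqrt(p * (1 - p) / n_ch)
        assert counts[:, 1].sum() / n_ch == pytest.approx(p, abs=3 * se)

    def test_channel_count_conserved_per_triangle(self, patch):
        fx, asm = patch
        sim = Simulation(fresh_system(asm),
                         channels=[(two_state_channel(), per_tri(fx, 20))], seed=3)
        before = sim.state.counts[0].sum(axis=1).copy()
        sim.advance(0.05, 1e-3)
        np.testing.assert_array_equal(sim.state.counts[0].sum(axis=1),
                                      before)

    def test_ghk_event_charge_and_ion_move(self, patch):
        fx, asm = patch
        ghk = GHKCurrentSpec(p_s=1e-19, z_s=2, temperature=293.15,
                             ion="Ca", transport=True)
        ch = ChannelModel("ca", ["o"], [], conducting={"o": ghk})
        sim = Simulation(fresh_system(asm), channels=[(ch, per_tri(fx, 5))],
                         ions={"Ca": (0.1, 2.0)}, seed=2)
        inner0 = sim.ions["Ca"].counts.copy()
        executed, _ = sim.ssa_step(10.0)
        assert executed is not None
        tri = executed[0]
        # one divalent ion moved between the bath and the inner tet; the
        # triangle booked exactly 2e of charge (as integer units of e)
        assert abs(sim.state.acc_charge_units[tri]) == 2
        moved = sim.ions["Ca"].counts - inner0
        assert abs(moved).sum() == 1
        assert moved[sim.inner_tets[tri]] == -sim.ions["Ca"].bath_ledger

    def test_charge_bookkeeping_is_integer_exact(self, patch):
        fx, asm = patch
        ghk = GHKCurrentSpec(p_s=1e-19, z_s=2, temperature=293.15,
                             ion="Ca", transport=True)
        ch = ChannelModel("ca", ["o"], [], conducting={"o": ghk})
        sim = Simulation(fresh_system(asm), channels=[(ch, per_tri(fx, 5))],
                         ions={"Ca": (0.1, 2.0)}, seed=4)
        net = 0
        for _ in range(200):
            before = sim.ions["Ca"].bath_ledger
            executed, _ = sim.ssa_step(10.0)
            if executed is None:
                break
            net += int(sim.ions["Ca"].bath_ledger - before)
        assert int(sim.state.acc_charge_units.sum()) == 2 * net

    def test_ion_conservation_over_run(self, patch):
        fx, asm = patch
        # low permeability keeps the single-ion event rate desk-sized
        ghk = GHKCurrentSpec(p_s=1e-23, z_s=1, temperature=293.15,
                             ion="Na", transport=True)
        ch = ChannelModel("na", ["o"], [], conducting={"o": ghk})
        sim = Simulation(fresh_system(asm), channels=[(ch, per_tri(fx, 10))],
                         ions={"Na": (10.0, 140.0)}, seed=5)
        probe = total_ions_probe("Na")
        total0 = probe(sim)
        sim.advance(0.005, 5e-4)
        assert sim.n_events > 100
        assert probe(sim) == total0

    def test_bit_identical_reproducibility(self, patch):
        fx, asm = patch

        def run(seed):
            sim = Simulation(fresh_system(asm),
                             channels=[(two_state_channel(), per_tri(fx, 20))],
                             seed=seed)
            traj = sim.advance(0.02, 1e-3)
            return sim.state.counts[0].copy(), sim.n_events, traj.times

        c1, n1, t1 = run(11)
        c2, n2, t2 = run(11)
        c3, n3, _ = run(12)
        assert np.array_equal(c1, c2) and n1 == n2
        np.testing.assert_array_equal(t1, t2)
        assert not (np.array_equal(c1, c3) and n1 == n3)


class TestCommunication:
    def test_passive_hybrid_equals_pure_field(self, patch):
        """With no channels the hybrid loop reproduces the plain field
        trajectory exactly (communication lands on every target)."""
        fx, asm = patch
        shunt = vertex_capacitances(fx.membrane, c_spec=0.25)
        sys_a = fresh_system(asm, dt=1e-4, shunt_g=shunt,
                             shunt_e=np.full(asm.n, -65e-3))
        sys_a.inject(fx.end0_vertices, 1e-12)
        sys_b = fresh_system(asm, dt=1e-4, shunt_g=shunt,
                             shunt_e=np.full(asm.n, -65e-3))
        sys_b.inject(fx.end0_vertices, 1e-12)

        sim = Simulation(sys_a, channels=[], seed=0)
        traj = sim.advance(5e-3, 1e-4)
        for _ in range(50):
            step(sys_b)
        assert np.array_equal(sys_a.phi, sys_b.phi)
        assert traj.comm_intervals.max() <= 1e-4 + 1e-18

    def test_mean_communication_interval_not_longer(self, patch):
        fx, asm = patch
        sim = Simulation(fresh_system(asm),
                         channels=[(two_state_channel(), per_tri(fx, 50))], seed=6)
        traj = sim.advance(0.05, 1e-3)
        assert traj.comm_intervals.max() <= 1e-3 + 1e-15
        assert traj.comm_intervals.mean() <= 1e-3

    def test_stochastic_mean_matches_deterministic(self, patch):
        """Law of large numbers: with 1000 channels per triangle the mean
        stochastic voltage stays within 3 SE of the deterministic mode."""
        fx, asm = patch
        el = np.full(asm.n, -65e-3)
        shunt = vertex_capacitances(fx.membrane, c_spec=0.25)
        # total channel conductance comparable to the leak so the explicit
        # coupling stays stable and the deflection is a few millivolts
        cur = OhmicCurrentSpec(g=1e-16, e_rev=0.0)
        ch = two_state_channel(alpha=40.0, beta=60.0, current=cur)
        probes = {"v": vertex_mean_probe(np.arange(asm.n))}

        def stoch(seed):
            sysm = fresh_system(asm, dt=2e-4, shunt_g=shunt, shunt_e=el)
            sim = Simulation(sysm, channels=[(ch, per_tri(fx, 1000))],
                             seed=seed)
            traj = sim.advance(0.02, 2e-4, probes=probes)
            grid = np.arange(0, 0.0201, 2e-4)
            return np.interp(grid, traj.times, traj.probes["v"])

        runs = np.array([stoch(s) for s in range(50)])
        sysm = fresh_system(asm, dt=2e-4, shunt_g=shunt, shunt_e=el)
        det = Simulation(sysm, channels=[(ch, per_tri(fx, 1000))], deterministic=True)
        dtraj = det.deterministic_advance(0.02, 2e-4, probes=probes)
        mean = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / math.sqrt(len(runs))
        diff = np.abs(mean - dtraj.probes["v"])
        assert np.all(diff[1:] <= 3 * se[1:] + 1e-12)


class TestDeterministic:
    def test_two_state_relaxation_closed_form(self, patch):
        fx, asm = patch
        sim = Simulation(fresh_system(asm),
                         channels=[(two_state_channel(), per_tri(fx, 50))],
                         deterministic=True)
        sim.state.counts[0][:, 0] = 50.0
        sim.state.counts[0][:, 1] = 0.0
        t_end = 5e-3
        sim.deterministic_advance(t_end, 1e-4, rtol=1e-9, atol=1e-12)
        frac = sim.state.counts[0][0, 1] / 50.0
        p_inf = ALPHA / (ALPHA + BETA)
        expect = p_inf * (1 - math.exp(-(ALPHA + BETA) * t_end))
        assert frac == pytest.approx(expect, rel=1e-6)

    def test_zero_rates_fractions_constant(self, patch):
        fx, asm = patch
        ch = ChannelModel("frozen", ["a", "b"],
                          [Transition("a", "b", 0.0),
                           Transition("b", "a", 0.0)])
        sim = Simulation(fresh_system(asm), channels=[(ch, per_tri(fx, 10))],
                         deterministic=True)
        sim.state.counts[0][:, 0] = 7.0
        sim.state.counts[0][:, 1] = 3.0
        sim.deterministic_advance(2e-3, 1e-4)
        np.testing.assert_allclose(sim.state.counts[0][:, 0], 7.0)

    def test_hh_patch_spike_matches_reference_ode(self, patch):
        """Squid HH patch under current clamp: the spike matches an
        independent classic HH integration to 1e-3 V."""
        from scipy.integrate import solve_ivp
        fx, asm = patch
        A = fx.membrane.area
        gl, el_v = 0.25, -65e-3
        gna, gk, gs = 1200.0, 360.0, 20e-12
        shunt = vertex_capacitances(fx.membrane, c_spec=gl)
        sysm = fresh_system(asm, dt=5e-6, shunt_g=shunt,
                            shunt_e=np.full(asm.n, el_v))
        sim = Simulation(sysm, channels=[(hh_sodium_channel(), gna / gs),
                                         (hh_potassium_channel(), gk / gs)],
                         deterministic=True)
        i_stim = 1.0 * A          # 1 A/m^2, suprathreshold
        sysm.inject(fx.end0_vertices, i_stim)
        traj = sim.deterministic_advance(
            0.03, 5e-6, probes={"v": vertex_mean_probe(np.arange(asm.n))})

        def hh(t, y):
            v, m, h, n = y
            dv = (i_stim - gna * A * m ** 3 * h * (v - 50e-3)
                  - gk * A * n ** 4 * (v + 77e-3)
                  - gl * A * (v - el_v)) / (0.01 * A)
            return [dv,
                    HH_RATES["alpha_m"](v) * (1 - m) -
                    HH_RATES["beta_m"](v) * m,
                    HH_RATES["alpha_h"](v) * (1 - h) -
                    HH_RATES["beta_h"](v) * h,
                    HH_RATES["alpha_n"](v) * (1 - n) -
                    HH_RATES["beta_n"](v) * n]

        def ss(a, b):
            return HH_RATES[a](-65e-3) / (HH_RATES[a](-65e-3) +
                                          HH_RATES[b](-65e-3))

        sol = solve_ivp(hh, [0, 0.03],
                        [-65e-3, ss("alpha_m", "beta_m"),
                         ss("alpha_h", "beta_h"), ss("alpha_n", "beta_n")],
                        t_eval=traj.times, rtol=1e-10, atol=1e-13,
                        method="LSODA")
        assert traj.probes["v"].max() > 0.02     # an actual spike fired
        assert np.abs(traj.probes["v"] - sol.y[0]).max() <= 1e-3

    def test_ghk_transport_continuous_and_conserving(self, patch):
        """Deterministic GHK transport moves ions down the electrochemical
        gradient while conserving total ion number exactly."""
        fx, asm = patch
        ghk = GHKCurrentSpec(p_s=1e-21, z_s=2, temperature=293.15,
                             ion="Ca", transport=True)
        ch = ChannelModel("ca", ["o"], [], conducting={"o": ghk})
        sim = Simulation(fresh_system(asm),
                         channels=[(ch, per_tri(fx, 5))],
                         ions={"Ca": (0.1, 2.0)}, deterministic=True)
        tot0 = sim.ions["Ca"].counts.sum() + sim.ions["Ca"].bath_ledger
        inner0 = sim.ions["Ca"].counts.sum()
        sim.deterministic_advance(0.01, 1e-4)
        tot1 = sim.ions["Ca"].counts.sum() + sim.ions["Ca"].bath_ledger
        assert tot1 == pytest.approx(tot0, rel=1e-12)
        # Ca enters at -65 mV against a 20x outside gradient
        assert sim.ions["Ca"].counts.sum() > inner0

    def test_bad_efield_dt_rejected(self, patch):
        fx, asm = patch
        sim = Simulation(fresh_system(asm), channels=[])
        with pytest.raises(ValueError):
            sim.advance(0.01, 0.0)
        with pytest.raises(ValueError):
            sim.deterministic_advance(0.01, -1e-5)
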