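"""Hybrid stochastic membrane simulation: SSA channel kinetics coupled to
the field solver by an adaptive communication step.

Channel gating (voltage-dependent Markov transitions) and single-ion GHK
passage events run in an exact Gillespie direct-method SSA over all
membrane triangles.  Every triangle accumulates the charge carried by its
GHK events; at each communication point (the last SSA event time not
exceeding the requested field step -- usually slightly earlier, never
later) the accumulated charge is divided by the elapsed interval, combined
with Ohmic currents sampled at the current potential, and handed to the
backward-Euler field solve, after which triangle potentials and all
voltage-dependent propensities are refreshed and the charges reset.

A deterministic mode integrates the same Markov schemes as per-triangle
master-equation ODEs (adaptive embedded Runge-Kutta within each window)
with currents from expected open counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import (ChannelModel, GHKCurrentSpec, OhmicCurrentSpec,
                       ghk_single_channel_current)
from .constants import AVOGADRO, ELEMENTARY_CHARGE
from .solver import EFieldSystem, step as field_step

__all__ = ["IonPool", "PatchState", "Simulation", "Trajectory"]


@dataclass(eq=False)
class IonPool:
    """Discrete ion bookkeeping for one transported species.

    Inner concentrations are sampled per membrane triangle from its inner
    tetrahedron (ion count / tet volume); the outer side is a bath held at
    fixed concentration whose exchanged ions are ledgered so that total ion
    number is conserved exactly.
    """

    name: str
    inner_conc: float            # initial intracellular conc, mol/m^3
    bath_conc: float             # extracellular (bath) conc, mol/m^3
    counts: np.ndarray = None    # per-tet ion counts (stochastic: integer)
    bath_ledger: float = 0.0     # net ions moved into the bath

    def concentrations(self, tet_ids, tet_volumes):
        return self.counts[tet_ids] / (AVOGADRO * tet_volumes[tet_ids])


@dataclass(eq=False)
class PatchState:
    """Per-membrane-triangle channel state counts and charge bookkeeping."""

    counts: list                  # per channel: (ntris, nstates) array
    acc_charge_units: np.ndarray  # accumulated charge since last field
                                  # update, integer units of e (outward > 0)
    v_m: np.ndarray               # local membrane potential per triangle, V


@dataclass(eq=False)
class Trajectory:
    times: np.ndarray
    probes: dict                 # label -> values at each recorded time
    comm_intervals: np.ndarray = None
    n_events: int = 0

    def trace(self, label):
        return self.times, self.probes[label]


class Simulation:
    """Membrane channels on triangles + the potential field on vertices.

    Parameters
    ----------
    system:
        An assembled field system (its membrane is where channels live;
        passive leak, stimuli and clamps are configured on it directly).
    channels:
        Sequence of ``(ChannelModel, density)`` with density in channels
        per m^2, or ``(ChannelModel, counts)`` with an explicit integer
        per-triangle count array.
    ions:
        Mapping ion name -> (inner_conc, bath_conc) in mol/m^3 for species
        transported by GHK currents.  Non-transported ("pure current") GHK
        species fall back to these fixed concentrations as well.
    """

    def __init__(self, system: EFieldSystem,
                 channels=(), ions: dict | None = None, seed: int = 0,
                 deterministic: bool = False):
        self.deterministic = deterministic
        self.system = system
        membrane = system.assembly.membrane
        if membrane is None:
            raise ValueError("the field system has no membrane surface")
        self.membrane = membrane
        self.mesh = membrane.mesh
        self.tris = membrane.tris
        self.ntris = len(self.tris)
        self.inner_tets = membrane.inner_tets
        self.tet_volumes = self.mesh.tet_volumes
        self.rng = np.random.default_rng(seed)
        self.time = 0.0
        self._last_field_time = 0.0
        self.n_events = 0

        self.ions: dict[str, IonPool] = {}
        for name, (ci, co) in (ions or {}).items():
            counts = np.rint(ci * AVOGADRO * self.tet_volumes).astype(float)
            self.ions[name] = IonPool(name=name, inner_conc=ci, bath_conc=co,
                                      counts=counts)

        self.models: list[ChannelModel] = []
        self.totals: list[np.ndarray] = []       # channels per triangle
        counts = []
        for model, dens in channels:
            self.models.append(model)
            if np.ndim(dens) == 0:
                tot = np.rint(dens * membrane.tri_areas).astype(np.int64)
            else:
                tot = np.asarray(dens, np.int64).copy()
            self.totals.append(tot)
            counts.append(np.zeros((self.ntris, model.n_states),
                                   dtype=float if deterministic
                                   else np.int64))
        self.state = PatchState(
            counts=counts,
            acc_charge_units=np.zeros(self.ntris, dtype=np.int64),
            v_m=self._membrane_potentials())
        self._init_states_at_rest()

        # flat SSA event layout: per channel, gating transitions then GHK
        # single-ion events of its conducting states
        self._events = []      # (kind, ch, payload)
        for ci, model in enumerate(self.models):
            for ti, tr in enumerate(model.transitions):
                self._events.append(("gate", ci, ti))
            for sname, spec in model.conducting.items():
                if isinstance(spec, GHKCurrentSpec):
                    self._events.append(("ghk", ci,
                                         (model.state_index(sname), spec)))
        self._prop = np.zeros((self.ntris, len(self._events)))
        self._ghk_dir = np.zeros((self.ntris, len(self._events)))
        self._refresh_propensities()

    # -- setup helpers ------------------------------------------------------

    def _membrane_potentials(self) -> np.ndarray:
        """Membrane potential of a triangle: mean of its vertex potentials."""
        return self.system.phi[self.tris].mean(axis=1)

    def _stationary(self, model: ChannelModel, v: float) -> np.ndarray:
        q = np.zeros((model.n_states, model.n_states))
        for tr in model.transitions:
            i, j = model.state_index(tr.src), model.state_index(tr.dst)
            r = float(tr.rate_at(v))
            q[i, i] -= r
            q[i, j] += r
        a = np.vstack([q.T, np.ones(model.n_states)])
        b = np.zeros(model.n_states + 1)
        b[-1] = 1.0
        p, *_ = np.linalg.lstsq(a, b, rcond=None)
        return np.clip(p, 0.0, None) / max(p.sum(), 1e-300)

    def _init_states_at_rest(self):
        """Start channels at the stationary gating distribution of the
        initial potential (exact fractions in deterministic mode, a seeded
        multinomial draw per triangle in stochastic mode)."""
        for ci, model in enumerate(self.models):
            cache: dict[float, np.ndarray] = {}
            for t in range(self.ntris):
                v = float(self.state.v_m[t])
                if v not in cache:
                    cache[v] = self._stationary(model, v)
                p = cache[v]
                if self.deterministic:
                    self.state.counts[ci][t] = self.totals[ci][t] * p
                else:
                    self.state.counts[ci][t] = self.rng.multinomial(
                        int(self.totals[ci][t]), p / p.sum())

    # -- propensities -------------------------------------------------------

    def _refresh_propensities(self, tri_ids=None):
        sl = slice(None) if tri_ids is None else tri_ids
        v = self.state.v_m[sl]
        for ei, (kind, ci, payload) in enumerate(self._events):
            model = self.models[ci]
            cnt = self.state.counts[ci][sl]
            if kind == "gate":
                tr = model.transitions[payload]
                src = model.state_index(tr.src)
                self._prop[sl, ei] = tr.rate_at(v) * cnt[..., src]
            else:
                sidx, spec = payload
                pool = self.ions.get(spec.ion)
                if spec.transport and pool is not None:
                    s_i = pool.concentrations(self.inner_tets[sl],
                                              self.tet_volumes)
                    s_o = pool.bath_conc
                elif pool is not None:
                    s_i, s_o = pool.inner_conc, pool.bath_conc
                else:
                    s_i, s_o = 0.0, spec.bath_conc
                i_s = ghk_single_channel_current(spec, v, s_i, s_o)
                self._prop[sl, ei] = np.abs(i_s) * cnt[..., sidx] / (
                    abs(spec.z_s) * ELEMENTARY_CHARGE)
                self._ghk_dir[sl, ei] = np.sign(i_s) * np.sign(spec.z_s)

    # -- SSA ----------------------------------------------------------------

    def ssa_step(self, horizon: float):
        """Execute one Gillespie direct-method event before ``horizon``.

        Returns ``(executed, t)``: the event tuple (tri, kind, ...) and the
        new clock, or ``(None, horizon)`` if no event fires in time.
        """
        a0 = float(self._prop.sum())
        if a0 <= 0.0:
            return None, horizon
        tau = self.rng.exponential(1.0 / a0)
        if self.time + tau > horizon:
            return None, horizon
        u = self.rng.random() * a0
        flat = self._prop.ravel()
        idx = int(np.searchsorted(np.cumsum(flat), u))
        idx = min(idx, flat.size - 1)
        tri, ei = divmod(idx, len(self._events))
        kind, ci, payload = self._events[ei]
        model = self.models[ci]
        if kind == "gate":
            tr = model.transitions[payload]
            s, d = model.state_index(tr.src), model.state_index(tr.dst)
            self.state.counts[ci][tri, s] -= 1
            self.state.counts[ci][tri, d] += 1
        else:
            sidx, spec = payload
            direction = int(self._ghk_dir[tri, ei])  # +1: inner -> outer
            self.state.acc_charge_units[tri] += spec.z_s * direction
            pool = self.ions.get(spec.ion)
            if spec.transport and pool is not None:
                tet = self.inner_tets[tri]
                pool.counts[tet] -= direction
                pool.bath_ledger += direction
        self.time += tau
        self.n_events += 1
        self._refresh_propensities(np.array([tri]))
        return (tri, kind, ci, payload), self.time

    # -- currents at communication -----------------------------------------

    def _ohmic_tri_currents(self) -> np.ndarray:
        """Outward Ohmic current per triangle at the current potentials."""
        out = np.zeros(self.ntris)
        for ci, model in enumerate(self.models):
            for sname, spec in model.conducting.items():
                if isinstance(spec, OhmicCurrentSpec):
                    n_open = self.state.counts[ci][:, model.state_index(sname)]
                    out += n_open * spec.g * (self.state.v_m - spec.e_rev)
        return out

    def _communicate(self, elapsed: float):
        """Fig.-2 style field update: total charge / elapsed + Ohmic."""
        i_out = self._ohmic_tri_currents()
        i_out += self.state.acc_charge_units * ELEMENTARY_CHARGE / elapsed
        field_step(self.system, tri_currents=-i_out, elapsed=elapsed)
        self.state.v_m = self._membrane_potentials()
        self.state.acc_charge_units[:] = 0
        self._last_field_time = self.time
        self._refresh_propensities()

    # -- drivers ------------------------------------------------------------

    def advance(self, t_end: float, efield_dt: float,
                probes: dict | None = None) -> Trajectory:
        """Hybrid SSA/field run until ``t_end``.

        SSA events execute while they fall before the next sync target
        (last field update + efield_dt); communication happens at the SSA
        clock value reached, never past the target.
        """
        if efield_dt <= 0:
            raise ValueError("efield_dt must be > 0")
        probes = probes or {}
        times, rec = [], {k: [] for k in probes}
        intervals = []
        self._record(times, rec, probes)
        while self.time < t_end - 1e-15:
            target = min(self.time + efield_dt, t_end)
            last_event_t = None
            while True:
                executed, t = self.ssa_step(target)
                if executed is None:
                    break
                last_event_t = t
            sync_t = last_event_t if last_event_t is not None else target
            elapsed = sync_t - self._last_field_time
            self.time = sync_t
            self._communicate(elapsed)
            intervals.append(elapsed)
            self._record(times, rec, probes)
        return Trajectory(times=np.array(times),
                          probes={k: np.array(v) for k, v in rec.items()},
                          comm_intervals=np.array(intervals),
                          n_events=self.n_events)

    def deterministic_advance(self, t_end: float, efield_dt: float,
                              probes: dict | None = None,
                              rtol: float = 1e-5,
                              atol: float = 1e-8) -> Trajectory:
        """Deterministic mode: per-triangle master-equation ODEs.

        State fractions evolve inside each window by an adaptive embedded
        Runge-Kutta (Bogacki-Shampine 3(2)) with rates held at the window's
        starting potential; currents use expected open counts; GHK
        transport updates concentrations from the window-mean open
        fraction.
        """
        if efield_dt <= 0:
            raise ValueError("efield_dt must be > 0")
        probes = probes or {}
        fracs = [c.astype(float) / np.maximum(t[:, None], 1)
                 for c, t in zip(self.state.counts, self.totals)]
        times, rec = [], {k: [] for k in probes}
        self._record(times, rec, probes)
        v_prev = self.state.v_m.copy()
        while self.time < t_end - 1e-15:
            elapsed = min(efield_dt, t_end - self.time)
            # predicted mid-window potential (linear trend): centres both
            # the frozen gating rates and the explicit currents on the
            # backward-Euler interval
            v_mid = 1.5 * self.state.v_m - 0.5 * v_prev
            v_prev = self.state.v_m.copy()
            i_out = np.zeros(self.ntris)
            for ci, model in enumerate(self.models):
                start = fracs[ci].copy()
                fracs[ci] = _rk23_window(model, fracs[ci], v_mid,
                                         elapsed, rtol, atol, efield_dt)
                mean_frac = 0.5 * (start + fracs[ci])
                for sname, spec in model.conducting.items():
                    sidx = model.state_index(sname)
                    if isinstance(spec, OhmicCurrentSpec):
                        # window-mean open count centres the explicit
                        # current on the interval
                        n_open = mean_frac[:, sidx] * self.totals[ci]
                        i_out += n_open * spec.g * (v_mid - spec.e_rev)
                    else:
                        pool = self.ions.get(spec.ion)
                        if spec.transport and pool is not None:
                            s_i = pool.concentrations(self.inner_tets,
                                                      self.tet_volumes)
                            s_o = pool.bath_conc
                        elif pool is not None:
                            s_i, s_o = pool.inner_conc, pool.bath_conc
                        else:
                            s_i, s_o = 0.0, spec.bath_conc
                        i_s = ghk_single_channel_current(
                            spec, v_mid, s_i, s_o)
                        i_ghk = i_s * mean_frac[:, sidx] * self.totals[ci]
                        i_out += i_s * fracs[ci][:, sidx] * self.totals[ci]
                        if spec.transport and pool is not None:
                            dions = i_ghk * elapsed / (spec.z_s *
                                                       ELEMENTARY_CHARGE)
                            np.subtract.at(pool.counts, self.inner_tets,
                                           dions)
                            pool.bath_ledger += float(dions.sum())
            field_step(self.system, tri_currents=-i_out, elapsed=elapsed)
            self.time += elapsed
            self.state.v_m = self._membrane_potentials()
            self._record(times, rec, probes)
        for ci in range(len(self.models)):
            self.state.counts[ci] = fracs[ci] * self.totals[ci][:, None]
        return Trajectory(times=np.array(times),
                          probes={k: np.array(v) for k, v in rec.items()})

    # -- probes -------------------------------------------------------------

    def _record(self, times, rec, probes):
        times.append(self.time)
        for label, fn in probes.items():
            rec[label].append(fn(self))


_FLOW_OP_CACHE: dict = {}


def _channel_flow_operator(model: ChannelModel):
    """(source indices, transition->state incidence matrix) for a model."""
    key = id(model)
    if key not in _FLOW_OP_CACHE:
        srcs = np.array([model.state_index(t.src)
                         for t in model.transitions], dtype=np.int64)
        inc = np.zeros((len(model.transitions), model.n_states))
        for k, t in enumerate(model.transitions):
            inc[k, model.state_index(t.src)] -= 1.0
            inc[k, model.state_index(t.dst)] += 1.0
        _FLOW_OP_CACHE[key] = (srcs, inc)
    return _FLOW_OP_CACHE[key]


_RATE_EVAL_CACHE: dict = {}


def _channel_rate_evaluator(model: ChannelModel):
    """Vectorised v -> (ntris, ntrans) rate evaluation.

    When every voltage-dependent transition is tabulated on one common
    grid (the default tabulation), a single fused interpolation serves all
    transitions; otherwise rates are evaluated one transition at a time.
    """
    from .channels import VDepRateTable
    key = id(model)
    if key in _RATE_EVAL_CACHE:
        return _RATE_EVAL_CACHE[key]
    tables = [t.rate for t in model.transitions]
    grids = [t.v_grid for t in tables if isinstance(t, VDepRateTable)]
    if grids and all(g.shape == grids[0].shape and
                     g[0] == grids[0][0] and g[-1] == grids[0][-1]
                     for g in grids):
        g0 = grids[0]
        step_inv = (len(g0) - 1) / (g0[-1] - g0[0])
        mat = np.stack([t.rates if isinstance(t, VDepRateTable)
                        else np.full(len(g0), float(t)) for t in tables],
                       axis=1)                      # (npts, ntrans)

        def evaluate(v):
            x = np.clip((np.asarray(v, float) - g0[0]) * step_inv,
                        0.0, len(g0) - 1.000001)
            i0 = x.astype(np.int64)
            w = (x - i0)[:, None]
            return mat[i0] * (1.0 - w) + mat[i0 + 1] * w
    else:
        def evaluate(v):
            v = np.asarray(v, float)
            return np.stack([np.asarray(t.rate_at(v), float) *
                             np.ones(v.shape) for t in model.transitions],
                            axis=1)
    _RATE_EVAL_CACHE[key] = evaluate
    return evaluate


def vertex_mean_probe(vertex_ids, weights=None):
    """Probe: (weighted) mean potential over a vertex set."""
    vertex_ids = np.asarray(vertex_ids, np.int64)
    if weights is not None:
        w = np.asarray(weights, float)
        w = w / w.sum()
        return lambda sim: float(sim.system.phi[vertex_ids] @ w)
    return lambda sim: float(sim.system.phi[vertex_ids].mean())


def total_ions_probe(name):
    """Probe: total ion count (inner tets + bath ledger); conserved."""
    return lambda sim: float(sim.ions[name].counts.sum() +
                             sim.ions[name].bath_ledger)


def _rk23_window(model: ChannelModel, y: np.ndarray, v_m: np.ndarray,
                 window: float, rtol: float, atol: float,
                 efield_dt: float) -> np.ndarray:
    """Integrate dp/dt = Q(v)^T p over one window, rates frozen at v_m."""
    if not model.transitions:
        return y
    srcs, incidence = _channel_flow_operator(model)
    rates = _channel_rate_evaluator(model)(v_m)

    def rhs(yv):
        return (rates * yv[:, srcs]) @ incidence

    t, h = 0.0, window
    while t < window - 1e-18 * window:
        h = min(h, window - t)
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.75 * h * k2)
        y3 = y + h * (2 * k1 + 3 * k2 + 4 * k3) / 9.0
        k4 = rhs(y3)
        err = h * np.abs(-5 * k1 / 72 + k2 / 12 + k3 / 9 - k4 / 8)
        tol = atol + rtol * np.abs(y3)
        ratio = float((err / tol).max())
        if ratio <= 1.0:
            t += h
            y = y3
        h = h * min(5.0, max(0.1, 0.9 * ratio ** (-1.0 / 3.0)
                             if ratio > 0 else 5.0))
        if h < 1e-9 * efield_dt:
            raise RuntimeError(
                "gating ODE tolerance failure; reduce efield_dt")
    return np.clip(y, 0.0, None)
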