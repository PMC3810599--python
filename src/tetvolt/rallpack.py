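"""Rallpack benchmark suite: analytic cable references and mesh runners.

The Rallpacks are standard accuracy benchmarks for neural simulators:

* Rallpack 1 -- uniform passive cable (1 mm x 1 um cylinder, sealed ends,
  0.1 nA step current at one end), compared against the separation-of-
  variables series solution of the finite cable equation.
* Rallpack 2 -- symmetric branched passive cable obeying the 3/2 power
  law.  The symmetric tree satisfies Rall's equivalent-cylinder conditions
  exactly, so the transient reference is the finite-cable series on the
  equivalent cylinder; a recursive-impedance composition provides the DC
  profile and an independent cross-check.
* Rallpack 3 -- the passive cable of Rallpack 1 plus squid Hodgkin-Huxley
  sodium/potassium channels; no analytic solution exists, so accuracy is
  measured against a supplied reference trace (e.g. from a cable-equation
  simulator) or by internal time-step convergence.

Standard Rallpack parameters: axial resistivity 1.0 Ohm m, membrane
resistance 4.0 Ohm m^2, specific capacitance 0.01 F/m^2 (1 uF/cm^2),
resting potential -65 mV, injected current 0.1 nA.
"""

from __future__ import annotations

import json
import math
import time as _time
from dataclasses import dataclass

import numpy as np

from . import channels as _ch
from .engine import Simulation
from .mesh import (CompartmentProps, generate_branched_mesh,
                   generate_cylinder_mesh, surface_correction_factor)
from .ordering import (OrderingPermutation, breadth_first_order,
                       identity_ordering, principal_axis_order, VertexGraph)
from .solver import (EFieldSystem, build_assembly, step as field_step,
                     vertex_capacitances)

__all__ = [
    "CableParams",
    "Trace",
    "analytic_cable",
    "rms_difference",
    "spike_timing_difference",
    "branched_dc_profile",
    "equivalent_cylinder",
    "run_rallpack1",
    "run_rallpack2",
    "run_rallpack3",
    "RALLPACK",
]

# published Rallpack suite constants (SI)
RALLPACK = dict(
    r_axial=1.0,          # Ohm m
    r_membrane=4.0,       # Ohm m^2
    c_spec=0.01,          # F/m^2
    e_rest=-65e-3,        # V
    i_inject=0.1e-9,      # A
    length=1e-3,          # m (Rallpack 1/3 cable)
    diameter=1e-6,        # m
    g_na=1200.0,          # S/m^2 (Rallpack 3)
    g_k=360.0,            # S/m^2
    e_na=50e-3,           # V
    e_k=-77e-3,           # V
    g_leak=0.25,          # S/m^2 = 1 / r_membrane
)


@dataclass
class CableParams:
    """Passive finite-cable parameters (sealed ends, step current at x=0)."""

    length: float          # m
    diameter: float        # m
    r_axial: float         # Ohm m
    r_membrane: float      # Ohm m^2
    c_spec: float          # F/m^2
    e_rest: float = 0.0    # V (reference offset added to the deflection)
    i_inject: float = 0.0  # A

    def __post_init__(self):
        for name in ("length", "diameter", "r_axial", "r_membrane",
                     "c_spec"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def lam(self) -> float:
        """Space constant sqrt(r_m / r_a) of the cable (m)."""
        r_m = self.r_membrane / (math.pi * self.diameter)
        r_a = self.r_axial / (math.pi * self.diameter ** 2 / 4.0)
        return math.sqrt(r_m / r_a)

    @property
    def r_inf(self) -> float:
        """Characteristic input resistance of the semi-infinite cable."""
        r_m = self.r_membrane / (math.pi * self.diameter)
        r_a = self.r_axial / (math.pi * self.diameter ** 2 / 4.0)
        return math.sqrt(r_m * r_a)

    @property
    def tau(self) -> float:
        return self.r_membrane * self.c_spec

    @property
    def electrotonic_length(self) -> float:
        return self.length / self.lam


@dataclass
class Trace:
    """A sampled voltage trace on a strictly increasing time grid."""

    times: np.ndarray     # s
    values: np.ndarray    # V
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")


def analytic_cable(params: CableParams, x: float, t_grid) -> Trace:
    """Series solution for a sealed-end finite cable with a step current.

    V(x, t) = e_rest + I R_inf [ cosh(L - X)/sinh L
              - sum_n c_n cos(n pi x / l) exp(-t (1 + (n pi / L)^2)/tau) ]

    with X = x/lambda, L = l/lambda, c_0 = 1/L and
    c_n = (2/L)/(1 + (n pi / L)^2); truncated when the series tail at the
    smallest positive time is below 1e-9 V.  t = 0 returns the resting
    potential exactly.
    """
    t = np.asarray(t_grid, float)
    lam, L, tau = params.lam, params.electrotonic_length, params.tau
    I, R = params.i_inject, params.r_inf
    X = x / lam
    v_ss = I * R * math.cosh(L - X) / math.sinh(L)

    pos = t[t > 0]
    t_min = pos.min() if pos.size else tau
    # exponent >= 25 at n = N kills the tail; add margin for the 1/n^2 decay
    N = int(max(50, math.ceil(L / math.pi * math.sqrt(25.0 * tau / t_min))
                + 10))
    n = np.arange(N + 1)
    c = np.where(n == 0, 1.0 / L, (2.0 / L) / (1.0 + (n * math.pi / L) ** 2))
    cosx = np.cos(n * math.pi * x / params.length)
    decay = (1.0 + (n * math.pi / L) ** 2) / tau
    with np.errstate(under="ignore"):
        series = (c * cosx) @ np.exp(-np.outer(decay, np.maximum(t, 0.0)))
    v = v_ss - I * R * series
    v[t <= 0] = 0.0
    return Trace(times=t, values=params.e_rest + v,
                 label=f"analytic x={x * 1e6:.0f}um")


def rms_difference(a: Trace, b: Trace) -> float:
    """RMS of (a - b) over a's time window, b resampled by linear
    interpolation; volts."""
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if lo > hi:
        raise ValueError("traces cover disjoint time ranges")
    mask = (a.times >= lo - 1e-15) & (a.times <= hi + 1e-15)
    bv = np.interp(a.times[mask], b.times, b.values)
    d = a.values[mask] - bv
    return float(np.sqrt(np.mean(d * d)))


def _refine_peak(times, values, i):
    """Sub-sample peak time by parabolic interpolation around sample i."""
    if i == 0 or i == len(values) - 1:
        return times[i]
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return times[i]
    delta = 0.5 * (y0 - y2) / denom
    return times[i] + delta * (times[i + 1] - times[i - 1]) / 2.0


def spike_timing_difference(a: Trace, b: Trace,
                            threshold: float = 0.0) -> float:
    """Mean |dt| between paired spike peaks (local maxima above 0 mV)."""
    from scipy.signal import find_peaks
    pa, _ = find_peaks(a.values, height=threshold)
    pb, _ = find_peaks(b.values, height=threshold)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("both traces must contain at least one spike")
    if len(pa) != len(pb):
        raise ValueError(
            f"unequal spike counts: {len(pa)} vs {len(pb)}")
    ta = np.array([_refine_peak(a.times, a.values, i) for i in pa])
    tb = np.array([_refine_peak(b.times, b.values, i) for i in pb])
    return float(np.mean(np.abs(ta - tb)))


# ---------------------------------------------------------------------------
# branched references
# ---------------------------------------------------------------------------

def equivalent_cylinder(levels: int, root: CableParams) -> CableParams:
    """Rall's equivalent cylinder of the symmetric 3/2-law tree.

    Daughter lengths scale by 2^(-1/3) and diameters by 2^(-2/3), so each
    level contributes the same electrotonic length and the tree collapses
    exactly to a cylinder of the root diameter and ``levels`` times the
    root length (membrane area is conserved as well).
    """
    return CableParams(
        length=levels * root.length, diameter=root.diameter,
        r_axial=root.r_axial, r_membrane=root.r_membrane,
        c_spec=root.c_spec, e_rest=root.e_rest, i_inject=root.i_inject)


def branched_dc_profile(levels: int, root: CableParams):
    """Steady-state potentials by recursive impedance composition.

    Returns ``(r_in, v_nodes)``: the root input resistance and the list of
    potentials at the root and at each junction depth down to the tips for
    the root's injected current (deflections, without e_rest).
    """
    lengths = root.length * 2.0 ** (-np.arange(levels) / 3.0)
    diams = root.diameter * 2.0 ** (-2.0 * np.arange(levels) / 3.0)

    def r_inf(d):
        r_m = root.r_membrane / (math.pi * d)
        r_a = root.r_axial / (math.pi * d ** 2 / 4.0)
        return math.sqrt(r_m * r_a)

    def lam(d):
        r_m = root.r_membrane / (math.pi * d)
        r_a = root.r_axial / (math.pi * d ** 2 / 4.0)
        return math.sqrt(r_m / r_a)

    # rho = R_inf / R_load at the branch's distal end (0 for sealed tips)
    rhos, r_in = [0.0] * levels, None
    for lev in range(levels - 1, -1, -1):
        Lk = lengths[lev] / lam(diams[lev])
        ri = r_inf(diams[lev])
        rho = rhos[lev]
        r_here = ri * (1.0 + rho * math.tanh(Lk)) / (rho + math.tanh(Lk))
        if lev > 0:
            rhos[lev - 1] = r_inf(diams[lev - 1]) / (r_here / 2.0)
        else:
            r_in = r_here
    v = root.i_inject * r_in
    v_nodes = [v]
    for lev in range(levels):
        Lk = lengths[lev] / lam(diams[lev])
        rho = rhos[lev]
        ratio = (math.cosh(0.0) + rho * math.sinh(0.0)) / \
                (math.cosh(Lk) + rho * math.sinh(Lk))
        # V at distal end relative to proximal end of this branch
        v = v * (1.0 + rho * 0.0) / (math.cosh(Lk) + rho * math.sinh(Lk))
        v_nodes.append(v)
    return r_in, np.array(v_nodes)


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------

def _make_ordering(mesh, ordering, seed=0, start_fraction=None):
    if isinstance(ordering, OrderingPermutation):
        return ordering
    if ordering in (None, "raw"):
        return identity_ordering(mesh.n_vertices)
    if ordering == "axis":
        return principal_axis_order(mesh)
    if ordering == "bfs":
        g = VertexGraph.from_mesh(mesh)
        frac = start_fraction if start_fraction is not None else \
            min(1.0, 48.0 / mesh.n_vertices)
        return breadth_first_order(g, start_fraction=frac, seed=seed)
    raise ValueError(f"unknown ordering {ordering!r}")


def _passive_system(mesh, membrane, ideal_area, dt, perm,
                    p=RALLPACK) -> tuple[EFieldSystem, float]:
    """Assembled system with surface-corrected passive membrane."""
    f = surface_correction_factor(membrane, ideal_area)
    props = CompartmentProps(sigma=1.0 / p["r_axial"])
    asm = build_assembly(mesh, props, membrane, c_spec=p["c_spec"] * f)
    shunt_g = vertex_capacitances(membrane, c_spec=f / p["r_membrane"],
                                  n=mesh.n_vertices)
    sys = EFieldSystem(asm, dt, perm=perm, shunt_g=shunt_g,
                       shunt_e=np.full(mesh.n_vertices, p["e_rest"]),
                       v_init=p["e_rest"])
    return sys, f


def _probe_weights(system, vertices):
    w = system.assembly.C[vertices]
    if w.sum() <= 0:
        raise ValueError("probe vertex set carries no membrane capacitance")
    return w / w.sum()


def run_rallpack1(ntets: int = 200_000, efield_dt: float = 1e-5,
                  t_end: float = 0.25, ordering="axis",
                  seed: int = 0) -> dict:
    """Uniform passive cable benchmark on a generated cylinder mesh.

    0.1 nA is injected area-weighted over the 0 um end cap; the probes are
    the capacitance-weighted mean potentials over the membrane vertices of
    each end; both are compared with the analytic finite-cable series.
    """
    p = RALLPACK
    params = CableParams(p["length"], p["diameter"], p["r_axial"],
                         p["r_membrane"], p["c_spec"], p["e_rest"],
                         p["i_inject"])
    t0 = _time.perf_counter()
    fx = generate_cylinder_mesh(params.length, params.diameter, ntets)
    mesh = fx.mesh
    lateral = fx.lateral_membrane
    t_mesh = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    perm = _make_ordering(mesh, ordering, seed=seed)
    t_order = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    system, f = _passive_system(mesh, lateral, fx.ideal_lateral_area,
                                efield_dt, perm)
    system.inject(fx.end0_vertices, params.i_inject, split="area_weighted")
    t_asm = _time.perf_counter() - t0

    w0 = _probe_weights(system, fx.end0_vertices)
    w1 = _probe_weights(system, fx.end1_vertices)
    nsteps = int(round(t_end / efield_dt))
    times = np.arange(nsteps + 1) * efield_dt
    v0 = np.empty(nsteps + 1)
    v1 = np.empty(nsteps + 1)
    v0[0] = system.phi[fx.end0_vertices] @ w0
    v1[0] = system.phi[fx.end1_vertices] @ w1
    t0 = _time.perf_counter()
    for k in range(1, nsteps + 1):
        field_step(system)
        v0[k] = system.phi[fx.end0_vertices] @ w0
        v1[k] = system.phi[fx.end1_vertices] @ w1
    t_solve = _time.perf_counter() - t0

    tr0 = Trace(times, v0, "0um")
    tr1 = Trace(times, v1, "1000um")
    ref0 = analytic_cable(params, 0.0, times)
    ref1 = analytic_cable(params, params.length, times)
    return {
        "benchmark": "rallpack1",
        "rms_mV": {"0um": rms_difference(tr0, ref0) * 1e3,
                   "1000um": rms_difference(tr1, ref1) * 1e3},
        "mesh": {"ntets": mesh.n_tets, "nverts": mesh.n_vertices,
                 "surface_area_error": fx.surface_area_error,
                 "surface_correction": f,
                 "polygon_order": fx.polygon_order},
        "ordering": {"kind": getattr(perm, "provenance", "raw"),
                     "half_bandwidth": system.half_bandwidth},
        "efield_dt": efield_dt, "t_end": t_end,
        "timings_s": {"mesh": t_mesh, "ordering": t_order,
                      "assembly": t_asm, "solve": t_solve},
        "traces": {"0um": tr0, "1000um": tr1,
                   "ref_0um": ref0, "ref_1000um": ref1},
    }


def run_rallpack2(levels: int = 8, target_ntets: int = 60_000,
                  efield_dt: float = 1e-5, t_end: float = 0.25,
                  ordering="bfs", seed: int = 0) -> dict:
    """Branched passive cable benchmark on the symmetric 3/2-law tree."""
    p = RALLPACK
    root = CableParams(32e-6, 16e-6, p["r_axial"], p["r_membrane"],
                       p["c_spec"], p["e_rest"], p["i_inject"])
    t0 = _time.perf_counter()
    fx = generate_branched_mesh(levels, root.length, root.diameter,
                                target_ntets=target_ntets)
    mesh = fx.mesh
    lateral = fx.membrane.restricted(fx.lateral_tris)
    t_mesh = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    perm = _make_ordering(mesh, ordering, seed=seed)
    t_order = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    system, f = _passive_system(mesh, lateral, fx.ideal_area, efield_dt,
                                perm)
    system.inject(fx.root_end_vertices, root.i_inject,
                  split="area_weighted")
    t_asm = _time.perf_counter() - t0

    w0 = _probe_weights(system, fx.root_end_vertices)
    w1 = _probe_weights(system, fx.leaf_end_vertices)
    nsteps = int(round(t_end / efield_dt))
    times = np.arange(nsteps + 1) * efield_dt
    v0 = np.empty(nsteps + 1)
    v1 = np.empty(nsteps + 1)
    v0[0] = system.phi[fx.root_end_vertices] @ w0
    v1[0] = system.phi[fx.leaf_end_vertices] @ w1
    t0 = _time.perf_counter()
    for k in range(1, nsteps + 1):
        field_step(system)
        v0[k] = system.phi[fx.root_end_vertices] @ w0
        v1[k] = system.phi[fx.leaf_end_vertices] @ w1
    t_solve = _time.perf_counter() - t0

    eq = equivalent_cylinder(levels, root)
    tr0 = Trace(times, v0, "0um")
    tr1 = Trace(times, v1, "tip")
    ref0 = analytic_cable(eq, 0.0, times)
    ref1 = analytic_cable(eq, eq.length, times)
    return {
        "benchmark": "rallpack2",
        "rms_mV": {"0um": rms_difference(tr0, ref0) * 1e3,
                   "tip": rms_difference(tr1, ref1) * 1e3},
        "mesh": {"ntets": mesh.n_tets, "nverts": mesh.n_vertices,
                 "levels": levels,
                 "path_length_um": fx.path_length * 1e6,
                 "surface_area_error": fx.surface_area_error,
                 "surface_correction": f},
        "ordering": {"kind": getattr(perm, "provenance", "raw"),
                     "half_bandwidth": system.half_bandwidth},
        "efield_dt": efield_dt, "t_end": t_end,
        "timings_s": {"mesh": t_mesh, "ordering": t_order,
                      "assembly": t_asm, "solve": t_solve},
        "traces": {"0um": tr0, "tip": tr1,
                   "ref_0um": ref0, "ref_tip": ref1},
    }


def run_rallpack3(ntets: int = 1200, efield_dt: float = 5e-6,
                  t_end: float = 0.25, mode: str = "deterministic",
                  ordering="axis", seed: int = 0,
                  reference: dict | None = None,
                  channel_scale: float = 1.0) -> dict:
    """Hodgkin-Huxley cable benchmark (squid Na/K channels + leak).

    ``reference`` may map probe labels ('0um', '1000um') to Trace objects
    (e.g. loaded from a cable-equation simulator export); metrics are then
    RMS voltage difference and mean spike-peak timing offset.  Without a
    reference, traces are still produced.  ``channel_scale`` < 1 thins the
    stochastic channel population (single-channel conductance is scaled up
    to keep the macroscopic density) for desk-scale stochastic runs.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ValueError("mode must be 'deterministic' or 'stochastic'")
    p = RALLPACK
    params = CableParams(p["length"], p["diameter"], p["r_axial"],
                         p["r_membrane"], p["c_spec"], p["e_rest"],
                         p["i_inject"])
    fx = generate_cylinder_mesh(params.length, params.diameter, ntets)
    mesh = fx.mesh
    lateral = fx.lateral_membrane
    perm = _make_ordering(mesh, ordering, seed=seed)
    system, f = _passive_system(mesh, lateral, fx.ideal_lateral_area,
                                efield_dt, perm)
    system.inject(fx.end0_vertices, params.i_inject, split="area_weighted")

    g_single = 20e-12 / channel_scale
    na = _ch.hh_sodium_channel(g_single=g_single, e_rev=p["e_na"])
    kk = _ch.hh_potassium_channel(g_single=g_single, e_rev=p["e_k"])
    dens_na = p["g_na"] * f / g_single
    dens_k = p["g_k"] * f / g_single
    sim = Simulation(system, channels=[(na, dens_na), (kk, dens_k)],
                     seed=seed, deterministic=(mode == "deterministic"))

    from .engine import vertex_mean_probe
    probes = {
        "0um": vertex_mean_probe(fx.end0_vertices,
                                 _probe_weights(system, fx.end0_vertices)),
        "1000um": vertex_mean_probe(fx.end1_vertices,
                                    _probe_weights(system,
                                                   fx.end1_vertices)),
    }
    if mode == "deterministic":
        traj = sim.deterministic_advance(t_end, efield_dt, probes=probes)
    else:
        traj = sim.advance(t_end, efield_dt, probes=probes)
    traces = {k: Trace(traj.times, traj.probes[k], k) for k in probes}

    report = {
        "benchmark": "rallpack3", "mode": mode,
        "mesh": {"ntets": mesh.n_tets, "nverts": mesh.n_vertices,
                 "surface_area_error": fx.surface_area_error,
                 "surface_correction": f},
        "efield_dt": efield_dt, "t_end": t_end, "seed": seed,
        "traces": traces,
    }
    if reference:
        rms, spikes = {}, {}
        for label, ref in reference.items():
            if label in traces:
                rms[label] = rms_difference(traces[label], ref) * 1e3
                try:
                    spikes[label] = spike_timing_difference(
                        traces[label], ref) * 1e6
                except ValueError:
                    pass
        report["rms_mV"] = rms
        report["spike_dt_us"] = spikes
    return report


def load_reference_trace(path, label="") -> Trace:
    """Load a 2-column CSV reference trace (time_s, volts)."""
    data = np.loadtxt(path, delimiter=",", comments="#", skiprows=0)
    return Trace(data[:, 0], data[:, 1], label or str(path))


def save_traces_csv(path, traces: dict) -> None:
    """Write traces sharing a time grid to CSV (header: time_s,<labels>)."""
    labels = list(traces)
    t = traces[labels[0]].times
    cols = [t] + [np.interp(t, traces[k].times, traces[k].values)
                  for k in labels]
    header = ",".join(["time_s"] + labels)
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header,
               comments="")


def report_to_json(report: dict, path=None) -> str:
    """Serialise a runner report (traces dropped) to JSON."""
    out = {k: v for k, v in report.items() if k != "traces"}
    s = json.dumps(out, indent=2, default=float)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s
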