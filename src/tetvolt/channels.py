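"""Channel object model and single-channel current formulas.

A channel is a Markov scheme over named states; transitions carry either a
constant rate (1/s) or a voltage-dependent rate table, and conducting
states map to a current description: Ohmic (single-channel conductance and
reversal potential) or Goldman-Hodgkin-Katz (single-channel permeability,
constant-field electrodiffusion, optionally with discrete ion transport
between compartments).

All quantities are strict SI: volts, amps, siemens, m^3/s, mol/m^3, kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ELEMENTARY_CHARGE, FARADAY, GAS_CONSTANT

__all__ = [
    "VDepRateTable",
    "OhmicCurrentSpec",
    "GHKCurrentSpec",
    "Transition",
    "ChannelModel",
    "ghk_single_channel_current",
    "ghk_transport_rate",
    "ohmic_current",
    "vdep_rate",
    "nernst_potential",
    "tabulate_rate",
    "hh_sodium_channel",
    "hh_potassium_channel",
    "HH_RATES",
]

# default tabulation span for voltage-dependent rates
_V_MIN, _V_MAX, _V_STEP = -150e-3, 100e-3, 0.01e-3
# series-expansion switch for the GHK flux at small reduced voltage
_GHK_SERIES_U = 1e-4


@dataclass(eq=False)
class VDepRateTable:
    """Voltage-dependent rate on a strictly increasing voltage grid.

    Linear interpolation between grid points; outside the grid the end
    values are held (clamping is preferred over extrapolation).
    """

    v_grid: np.ndarray      # V
    rates: np.ndarray       # 1/s

    def __post_init__(self):
        self.v_grid = np.asarray(self.v_grid, float)
        self.rates = np.asarray(self.rates, float)
        if self.v_grid.ndim != 1 or self.v_grid.shape != self.rates.shape:
            raise ValueError("v_grid and rates must be 1-D and equal length")
        if np.any(np.diff(self.v_grid) <= 0):
            raise ValueError("v_grid must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0 over the tabulated range")

    def __call__(self, v_m):
        return np.interp(v_m, self.v_grid, self.rates)


def vdep_rate(table: VDepRateTable, v_m) -> float | np.ndarray:
    """Rate at membrane voltage ``v_m`` (linear interpolation, clamped)."""
    return table(v_m)


def tabulate_rate(fn, v_min: float = _V_MIN, v_max: float = _V_MAX,
                  step: float = _V_STEP) -> VDepRateTable:
    """Tabulate a closed-form rate function over a voltage grid."""
    npts = int(round((v_max - v_min) / step)) + 1
    v = np.linspace(v_min, v_max, npts)
    return VDepRateTable(v, np.asarray(fn(v), float))


@dataclass(eq=False)
class OhmicCurrentSpec:
    """Single-channel Ohmic current: g * (V_m - E_rev); no ion transport."""

    g: float        # single-channel conductance, S
    e_rev: float    # reversal potential, V

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("single-channel conductance must be >= 0")


@dataclass(eq=False)
class GHKCurrentSpec:
    """Single-channel GHK (constant-field) current of one ion species."""

    p_s: float              # single-channel permeability, m^3/s
    z_s: int                # ion valence (non-zero integer)
    temperature: float      # K
    ion: str = "ion"
    transport: bool = True  # move discrete ions (False: "pure current")
    bath_conc: float = 0.0  # outer concentration for surface membranes, mol/m^3

    def __post_init__(self):
        if self.p_s < 0:
            raise ValueError("permeability must be >= 0")
        if int(self.z_s) != self.z_s or self.z_s == 0:
            raise ValueError("valence must be a non-zero integer")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(eq=False)
class Transition:
    src: str
    dst: str
    rate: float | VDepRateTable

    def rate_at(self, v_m):
        if isinstance(self.rate, VDepRateTable) or callable(self.rate):
            return self.rate(v_m)
        return self.rate if np.isscalar(v_m) else np.full(np.shape(v_m),
                                                          float(self.rate))


@dataclass(eq=False)
class ChannelModel:
    """Markov scheme over named channel states.

    ``conducting`` maps a state name to its current spec (Ohmic or GHK);
    non-conducting states carry no current.
    """

    name: str
    states: list[str]
    transitions: list[Transition]
    conducting: dict[str, OhmicCurrentSpec | GHKCurrentSpec] = \
        field(default_factory=dict)

    def __post_init__(self):
        known = set(self.states)
        for t in self.transitions:
            if t.src not in known or t.dst not in known:
                raise ValueError(
                    f"transition {t.src}->{t.dst} references an undeclared "
                    f"state of channel {self.name}")
            if not isinstance(t.rate, VDepRateTable) and t.rate < 0:
                raise ValueError("transition rates must be >= 0")
        for s in self.conducting:
            if s not in known:
                raise ValueError(f"conducting state {s} is not declared")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name: str) -> int:
        return self.states.index(name)


def nernst_potential(z: int, conc_in: float, conc_out: float,
                     temperature: float) -> float:
    """Reversal potential (RT / zF) ln([S]_o / [S]_i)."""
    return (GAS_CONSTANT * temperature / (z * FARADAY)) * \
        math.log(conc_out / conc_in)


def ghk_single_channel_current(spec: GHKCurrentSpec, v_m, s_i, s_o):
    """Single-channel GHK current (A) of ion S.

        I_s = P_s z_s^2 (V_m F^2 / RT) *
              ([S]_i - [S]_o exp(-z_s V_m F/RT)) / (1 - exp(-z_s V_m F/RT))

    Sign convention: positive current is an outward flux of positive
    charge; V_m is inside minus outside.  Near V_m = 0 the removable
    singularity is evaluated by a 2nd-order series in u = z V F/RT, which
    tends to  P z F ([S]_i - [S]_o)  as V -> 0.
    """
    v_m = np.asarray(v_m, float)
    s_i = np.asarray(s_i, float)
    s_o = np.asarray(s_o, float)
    if np.any(s_i < 0) or np.any(s_o < 0):
        raise ValueError("concentrations must be >= 0")
    z = spec.z_s
    u = z * v_m * FARADAY / (GAS_CONSTANT * spec.temperature)
    pref = spec.p_s * z * FARADAY
    small = np.abs(u) < _GHK_SERIES_U
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        em = np.exp(-u)
        exact = pref * u * (s_i - s_o * em) / (1.0 - em)
    series = pref * ((s_i - s_o) + 0.5 * u * (s_i + s_o)
                     + u * u * (s_i - s_o) / 12.0)
    out = np.where(small, series, exact)
    return float(out) if out.ndim == 0 else out


def ghk_transport_rate(spec: GHKCurrentSpec, v_m, s_i, s_o, n_open):
    """SSA propensity for single-ion passage events.

    Returns ``(rate, direction)``: the event rate |I_s| / (|z_s| e) * n_open
    in ions per second, and the signed ion displacement per event
    (+1: inner -> outer, the direction of a positive outward current of a
    positive ion; -1: outer -> inner).
    """
    i_s = ghk_single_channel_current(spec, v_m, s_i, s_o)
    rate = np.abs(i_s) / (abs(spec.z_s) * ELEMENTARY_CHARGE) * n_open
    direction = np.sign(i_s) * np.sign(spec.z_s)
    return rate, direction


def ohmic_current(spec: OhmicCurrentSpec, v_m, n_open):
    """Total Ohmic current ``n_open * g * (V_m - E_rev)`` (A, outward > 0)."""
    return n_open * spec.g * (np.asarray(v_m, float) - spec.e_rev)


# ---------------------------------------------------------------------------
# Hodgkin-Huxley (squid giant axon) kinetics, resting potential at -65 mV.
# Rates in 1/s as functions of membrane voltage in volts.
# ---------------------------------------------------------------------------

def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity at x = 0."""
    x = np.asarray(x, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(x / y) < 1e-6, y * (1.0 - x / (2.0 * y)),
                       x / np.expm1(np.clip(x / y, -500, 500)))
    return out


def _alpha_m(v):
    vm = np.asarray(v, float) * 1e3  # mV
    return 1e3 * 0.1 * _vtrap(-(vm + 40.0), 10.0)


def _beta_m(v):
    vm = np.asarray(v, float) * 1e3
    return 1e3 * 4.0 * np.exp(-(vm + 65.0) / 18.0)


def _alpha_h(v):
    vm = np.asarray(v, float) * 1e3
    return 1e3 * 0.07 * np.exp(-(vm + 65.0) / 20.0)


def _beta_h(v):
    vm = np.asarray(v, float) * 1e3
    return 1e3 * 1.0 / (1.0 + np.exp(-(vm + 35.0) / 10.0))


def _alpha_n(v):
    vm = np.asarray(v, float) * 1e3
    return 1e3 * 0.01 * _vtrap(-(vm + 55.0), 10.0)


def _beta_n(v):
    vm = np.asarray(v, float) * 1e3
    return 1e3 * 0.125 * np.exp(-(vm + 65.0) / 80.0)


HH_RATES = {
    "alpha_m": _alpha_m, "beta_m": _beta_m,
    "alpha_h": _alpha_h, "beta_h": _beta_h,
    "alpha_n": _alpha_n, "beta_n": _beta_n,
}


def hh_sodium_channel(g_single: float = 20e-12, e_rev: float = 50e-3,
                      tabulated: bool = True) -> ChannelModel:
    """8-state Markov sodium channel (3 m-gates x 1 h-gate).

    States m{i}h{j}: i activated m particles, j the inactivation particle;
    conducting state m3h1 with an Ohmic single-channel current.
    """
    def R(fn):
        return tabulate_rate(fn) if tabulated else fn

    states = [f"m{i}h{j}" for j in (0, 1) for i in range(4)]
    trans = []
    for j in (0, 1):
        for i in range(3):
            trans.append(Transition(f"m{i}h{j}", f"m{i+1}h{j}",
                                    R(lambda v, k=3 - i: k * _alpha_m(v))))
            trans.append(Transition(f"m{i+1}h{j}", f"m{i}h{j}",
                                    R(lambda v, k=i + 1: k * _beta_m(v))))
    for i in range(4):
        trans.append(Transition(f"m{i}h0", f"m{i}h1", R(_alpha_h)))
        trans.append(Transition(f"m{i}h1", f"m{i}h0", R(_beta_h)))
    return ChannelModel(
        name="NaHH", states=states, transitions=trans,
        conducting={"m3h1": OhmicCurrentSpec(g=g_single, e_rev=e_rev)})


def hh_potassium_channel(g_single: float = 20e-12, e_rev: float = -77e-3,
                         tabulated: bool = True) -> ChannelModel:
    """5-state Markov potassium channel (4 n-gates), conducting at n4."""
    def R(fn):
        return tabulate_rate(fn) if tabulated else fn

    states = [f"n{i}" for i in range(5)]
    trans = []
    for i in range(4):
        trans.append(Transition(f"n{i}", f"n{i+1}",
                                R(lambda v, k=4 - i: k * _alpha_n(v))))
        trans.append(Transition(f"n{i+1}", f"n{i}",
                                R(lambda v, k=i + 1: k * _beta_n(v))))
    return ChannelModel(
        name="KHH", states=states, transitions=trans,
        conducting={"n4": OhmicCurrentSpec(g=g_single, e_rev=e_rev)})
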