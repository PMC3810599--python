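"""Structured simulation configs (YAML) with conventional-unit conversion.

Internally everything is strict SI; the config layer accepts the units
electrophysiologists write models in -- Ohm cm, uF/cm^2, mS/cm^2, mV, ms,
mM, pS -- and converts once at load time.  A config describes the
compartment, the membrane (capacitance + leak), ion species, channel
Markov schemes with their currents, and the simulation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .channels import (ChannelModel, GHKCurrentSpec, OhmicCurrentSpec,
                       Transition, VDepRateTable, HH_RATES,
                       hh_potassium_channel, hh_sodium_channel,
                       tabulate_rate)
from .mesh import CompartmentProps

__all__ = ["SimConfig", "load_config", "parse_config"]


class ConfigError(ValueError):
    pass


@dataclass(eq=False)
class SimConfig:
    props: CompartmentProps
    c_spec: float                      # F/m^2
    leak_g: float                      # S/m^2
    leak_e: float                      # V
    channels: list                     # [(ChannelModel, density per m^2)]
    ions: dict                         # name -> (inner, bath) mol/m^3
    dt_efield: float = 1e-5            # s
    t_end: float = 0.01                # s
    v_init: float = -65e-3             # V
    seed: int = 0
    stim_current: float = 0.0          # A
    stim_site: str = "end0"
    deterministic: bool = True


def _get_scaled(d: dict, base: str, conversions: dict, default=None):
    """Fetch ``base`` in any of several unit spellings, converting to SI."""
    hits = [(k, f) for k, f in conversions.items() if k in d]
    if not hits:
        if default is None:
            raise ConfigError(f"missing config key {base}")
        return default
    if len(hits) > 1:
        raise ConfigError(f"conflicting spellings for {base}: "
                          f"{[k for k, _ in hits]}")
    k, f = hits[0]
    return float(d[k]) * f


def _rate_from_spec(spec) -> float | VDepRateTable:
    if isinstance(spec, (int, float)):
        return float(spec)
    if "rate_per_s" in spec and "v_mV" not in spec:
        return float(spec["rate_per_s"])
    if "rate_per_ms" in spec and "v_mV" not in spec:
        return float(spec["rate_per_ms"]) * 1e3
    if "rate_builtin" in spec:
        name = spec["rate_builtin"]
        if name not in HH_RATES:
            raise ConfigError(f"unknown builtin rate {name!r} "
                              f"(have {sorted(HH_RATES)})")
        return tabulate_rate(HH_RATES[name])
    if "v_mV" in spec:
        v = np.asarray(spec["v_mV"], float) * 1e-3
        if "rate_per_s" in spec:
            r = np.asarray(spec["rate_per_s"], float)
        elif "rate_per_ms" in spec:
            r = np.asarray(spec["rate_per_ms"], float) * 1e3
        else:
            raise ConfigError("rate table needs rate_per_s or rate_per_ms")
        return VDepRateTable(v, r)
    raise ConfigError(f"cannot parse rate spec {spec!r}")


def _current_from_spec(spec) -> OhmicCurrentSpec | GHKCurrentSpec:
    if "ohmic" in spec:
        o = spec["ohmic"]
        return OhmicCurrentSpec(
            g=_get_scaled(o, "g", {"g_pS": 1e-12, "g_S": 1.0}),
            e_rev=_get_scaled(o, "e_rev", {"e_rev_mV": 1e-3, "e_rev_V": 1.0}))
    if "ghk" in spec:
        g = spec["ghk"]
        return GHKCurrentSpec(
            p_s=_get_scaled(g, "p", {"p_m3_per_s": 1.0,
                                     "p_cm_per_s_times_area_um2": 1e-14}),
            z_s=int(g["z"]),
            temperature=float(g.get("temperature_K", 293.15)),
            ion=g.get("ion", "ion"),
            transport=bool(g.get("transport", True)),
            bath_conc=_get_scaled(g, "bath", {"bath_mM": 1.0,
                                              "bath_mol_per_m3": 1.0},
                                  default=0.0))
    raise ConfigError(f"conducting state needs 'ohmic' or 'ghk': {spec!r}")


def _channel_from_spec(spec) -> tuple[ChannelModel, float]:
    density = _get_scaled(spec, "density",
                          {"density_per_um2": 1e12, "density_per_m2": 1.0})
    if "builtin" in spec:
        g_single = _get_scaled(spec, "g_single",
                               {"g_single_pS": 1e-12}, default=20e-12)
        e_rev = _get_scaled(spec, "e_rev",
                            {"e_rev_mV": 1e-3}, default=None) \
            if any(k in spec for k in ("e_rev_mV",)) else None
        if spec["builtin"] == "hh_sodium":
            model = hh_sodium_channel(g_single=g_single,
                                      e_rev=e_rev if e_rev is not None
                                      else 50e-3)
        elif spec["builtin"] == "hh_potassium":
            model = hh_potassium_channel(g_single=g_single,
                                         e_rev=e_rev if e_rev is not None
                                         else -77e-3)
        else:
            raise ConfigError(f"unknown builtin channel {spec['builtin']!r}")
        return model, density
    states = list(spec["states"])

    def _tr(t):
        rest = {k: v for k, v in t.items() if k not in ("from", "to")}
        rspec = rest["rate"] if isinstance(rest.get("rate"),
                                           (int, float)) else rest
        return Transition(t["from"], t["to"], _rate_from_spec(rspec))

    transitions = [_tr(t) for t in spec.get("transitions", [])]
    conducting = {s: _current_from_spec(c)
                  for s, c in (spec.get("conducting") or {}).items()}
    model = ChannelModel(name=spec.get("name", "channel"), states=states,
                         transitions=transitions, conducting=conducting)
    return model, density


def parse_config(doc: dict) -> SimConfig:
    comp = doc.get("compartment", {})
    sigma = None
    if "conductivity_S_per_m" in comp:
        sigma = float(comp["conductivity_S_per_m"])
    else:
        rho = _get_scaled(comp, "resistivity",
                          {"resistivity_ohm_m": 1.0,
                           "resistivity_ohm_cm": 1e-2}, default=1.0)
        sigma = 1.0 / rho
    props = CompartmentProps(sigma=sigma)

    mem = doc.get("membrane", {})
    c_spec = _get_scaled(mem, "c_spec", {"c_spec_uF_per_cm2": 1e-2,
                                         "c_spec_F_per_m2": 1.0},
                         default=0.01)
    leak = mem.get("leak", {})
    leak_g = _get_scaled(leak, "g", {"g_mS_per_cm2": 10.0,
                                     "g_S_per_m2": 1.0}, default=0.0)
    leak_e = _get_scaled(leak, "e_rev", {"e_rev_mV": 1e-3, "e_rev_V": 1.0},
                         default=-65e-3)

    ions = {}
    for name, sp in (doc.get("ions") or {}).items():
        ci = _get_scaled(sp, "inner", {"inner_mM": 1.0,
                                       "inner_mol_per_m3": 1.0})
        co = _get_scaled(sp, "bath", {"bath_mM": 1.0,
                                      "bath_mol_per_m3": 1.0})
        ions[name] = (ci, co)

    channels = [_channel_from_spec(c) for c in (doc.get("channels") or [])]

    sim = doc.get("sim", {})
    stim = sim.get("stim", {})
    return SimConfig(
        props=props, c_spec=c_spec, leak_g=leak_g, leak_e=leak_e,
        channels=channels, ions=ions,
        dt_efield=_get_scaled(sim, "dt_efield",
                              {"dt_efield_ms": 1e-3, "dt_efield_s": 1.0},
                              default=1e-5),
        t_end=_get_scaled(sim, "t_end", {"t_end_ms": 1e-3, "t_end_s": 1.0},
                          default=0.01),
        v_init=_get_scaled(sim, "v_init", {"v_init_mV": 1e-3,
                                           "v_init_V": 1.0},
                           default=-65e-3),
        seed=int(sim.get("seed", 0)),
        stim_current=_get_scaled(stim, "i", {"i_nA": 1e-9, "i_A": 1.0},
                                 default=0.0),
        stim_site=stim.get("site", "end0"),
        deterministic=bool(sim.get("deterministic", True)))


def load_config(path) -> SimConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return parse_config(doc)
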