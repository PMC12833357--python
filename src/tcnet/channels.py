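"""Ionic-current formalism and cell templates for the six cell classes.

Every intrinsic current follows ``I = gbar * m^N * h^M * (V - E_rev)``
(positive outward; the membrane equation subtracts it).  Gates relax with
first-order kinetics toward a voltage-dependent steady state.  Cortical cells
(RS, IB, NRS, LTS) share one channel inventory -- fast and persistent Na,
five K currents (transient Ka, slowly-inactivating K2, delayed-rectifier Kdr,
M-type Km, plus Ca-dependent Kc and Kahp), low- and high-threshold Ca, the
anomalous rectifier h, and leak -- with class-specific conductance densities
that set the firing phenotype (regular spiking vs intrinsic bursting vs
low-threshold spiking).  Thalamic relay (TC) cells carry leak, K-leak, Na, K,
the low-threshold Ca current and the h-current; reticular (RE) cells carry
leak, Na, K and a slower low-threshold Ca current.

Conductance densities below are this package's calibration of the
single-compartment reductions; they are configuration, not physics, and can
be overridden per cell template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import gate_functions

__all__ = [
    "GatingKinetics",
    "ChannelSpec",
    "CalciumPool",
    "CellSpec",
    "cell_template",
    "ionic_current",
    "gate_step",
    "classify_firing",
    "DEFAULT_AREA_CM2",
    "REST_TARGETS",
]

#: Compartment area: cylindrical soma with length = diameter = 173 um
#: (pi * d * L ~= 9.4e-4 cm^2).  Converts injected nA to current density and
#: sets the relative weight of the uS-scale synaptic conductances against the
#: intrinsic conductance densities; calibrated so network firing rates stay
#: physiological under the fitted synaptic tables.
DEFAULT_AREA_CM2 = math.pi * 3e-4

#: Target resting potentials (mV) used to calibrate the holding current of
#: cortical cells (thalamic cells carry no holding current).
REST_TARGETS = {"RS": -65.0, "IB": -72.0, "NRS": -65.0, "LTS": -65.0}


@dataclass(frozen=True)
class GatingKinetics:
    """First-order gate: ``dx/dt = (steady_state(V) - x) / time_constant(V)``."""

    steady_state: callable
    time_constant: callable


@dataclass(frozen=True)
class ChannelSpec:
    """One ionic conductance.

    ``g_max`` is a conductance density in mS/cm^2 (with V in mV the current
    comes out in uA/cm^2); ``N``/``M`` are the activation/inactivation
    exponents.  ``calcium_dependent`` marks Kc (conductance saturates with
    intracellular Ca) and Kahp (gate driven by Ca, not voltage);
    ``calcium_source`` marks the Ca currents feeding the intracellular pool.
    """

    name: str
    g_max: float
    E_rev: float
    N: int = 0
    M: int = 0
    activation: GatingKinetics | None = None
    inactivation: GatingKinetics | None = None
    calcium_dependent: bool = False
    calcium_source: bool = False

    def __post_init__(self):
        if self.g_max < 0:
            raise ValueError(f"channel {self.name}: g_max must be non-negative")
        if self.N < 0 or self.M < 0:
            raise ValueError(f"channel {self.name}: gating exponents must be >= 0")
        if self.N == 0 and self.M == 0 and (self.activation or self.inactivation):
            raise ValueError(f"channel {self.name}: leak-type channel has no gates")


@dataclass(frozen=True)
class CalciumPool:
    """First-order intracellular Ca pool driven by the Ca currents.

    ``dCa/dt = -Ca/tau - influx_gain * (I_CaT + I_CaL)`` with Ca in the
    dimensionless units the Ca-dependent K kinetics expect (Kc saturates at
    ``Ca = 250``).
    """

    tau: float = 100.0  # ms
    influx_gain: float = 2.0  # Ca units per (uA/cm^2 * ms)
    kc_saturation: float = 250.0
    kahp_alpha_gain: float = 2e-5  # alpha = min(gain * Ca, alpha_max)
    kahp_alpha_max: float = 0.01
    kahp_beta: float = 0.001


@dataclass(frozen=True)
class CellSpec:
    """A single-compartment cell: capacitance, area, channels, holding current."""

    cell_class: str
    Cm: float  # uF/cm^2
    channels: tuple
    area: float = DEFAULT_AREA_CM2
    I_hold: float = 0.0  # nA
    calcium_pool: CalciumPool | None = None
    V_init: float = -65.0

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("area must be positive")

    def channel(self, name: str) -> ChannelSpec:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"{self.cell_class} has no channel {name!r}")

    def without_channel(self, name: str) -> "CellSpec":
        """Copy of this cell with one channel's conductance zeroed."""
        chans = tuple(
            replace(ch, g_max=0.0) if ch.name == name else ch for ch in self.channels
        )
        return replace(self, channels=chans)

    def with_conductance(self, name: str, g_max: float) -> "CellSpec":
        chans = tuple(
            replace(ch, g_max=g_max) if ch.name == name else ch
            for ch in self.channels
        )
        return replace(self, channels=chans)


# --------------------------------------------------------------------------
# conductance densities (mS/cm^2) per cell class

_E_NA, _E_K, _E_CA, _E_AR = 50.0, -95.0, 125.0, -35.0

# (channel, density) per cortical class; the inventory is identical across
# RS/IB/NRS/LTS, only densities differ.  IB cells get stronger persistent Na
# and high-threshold Ca with weaker M/AHP adaptation (burst-promoting); LTS
# interneurons get a strong low-threshold Ca current (rebound bursts).
_CORTICAL_DENSITIES = {
    "RS": dict(Leak=0.10, Naf=100.0, Nap=0.06, Ka=20.0, K2=0.5, Kdr=80.0,
               Km=2.0, Kc=12.0, Kahp=0.15, CaT=0.10, CaL=0.30, h=0.05),
    "IB": dict(Leak=0.10, Naf=100.0, Nap=0.35, Ka=20.0, K2=0.5, Kdr=80.0,
               Km=0.3, Kc=20.0, Kahp=0.60, CaT=0.30, CaL=2.50, h=0.05),
    "NRS": dict(Leak=0.10, Naf=100.0, Nap=0.06, Ka=20.0, K2=0.5, Kdr=80.0,
                Km=2.0, Kc=12.0, Kahp=0.25, CaT=0.10, CaL=0.30, h=0.05),
    "LTS": dict(Leak=0.10, Naf=100.0, Nap=0.02, Ka=10.0, K2=0.3, Kdr=80.0,
                Km=0.3, Kc=5.0, Kahp=0.05, CaT=1.50, CaL=0.10, h=0.05),
}
_E_LEAK_CORTICAL = -70.0

# IB cells need several spikes of Ca influx before the fast Ca-gated K
# current terminates the cluster: higher Kc saturation -> multi-spike bursts.
_CORTICAL_POOLS = {
    "RS": CalciumPool(),
    "IB": CalciumPool(tau=80.0, kc_saturation=1000.0),
    "NRS": CalciumPool(),
    "LTS": CalciumPool(),
}

_TC_DENSITIES = dict(Leak=0.01, KLeak=0.0035, Naf=90.0, K=10.0, CaT=2.0, h=0.017)
_RE_DENSITIES = dict(Leak=0.05, Naf=200.0, K=20.0, CaT=3.0)
_E_LEAK_TC, _E_LEAK_RE, _E_CA_THAL, _E_H_TC = -70.0, -85.0, 120.0, -43.0

# per-channel structure: (N, M, E_rev key, calcium flags)
_CORTICAL_CHANNEL_FORMS = {
    "Naf": (3, 1, _E_NA, False, False),
    "Nap": (1, 0, _E_NA, False, False),
    "Ka": (4, 1, _E_K, False, False),
    "K2": (1, 1, _E_K, False, False),
    "Kdr": (4, 0, _E_K, False, False),
    "Km": (1, 0, _E_K, False, False),
    "Kc": (1, 0, _E_K, True, False),
    "Kahp": (1, 0, _E_K, True, False),
    "CaT": (2, 1, _E_CA, False, True),
    "CaL": (2, 0, _E_CA, False, True),
    "h": (1, 0, _E_AR, False, False),
}


def _gk(family, channel, gate):
    x_inf, tau = gate_functions(family, channel, gate)
    return GatingKinetics(x_inf, tau)


def _cortical_channels(cls: str, overrides: dict | None = None):
    dens = dict(_CORTICAL_DENSITIES[cls])
    if overrides:
        dens.update(overrides)
    chans = [ChannelSpec("Leak", dens["Leak"], _E_LEAK_CORTICAL)]
    for name, (N, M, E, ca_dep, ca_src) in _CORTICAL_CHANNEL_FORMS.items():
        act = None if name == "Kahp" else _gk("cortical", name, "m")
        inact = _gk("cortical", name, "h") if M else None
        chans.append(
            ChannelSpec(name, dens[name], E, N, M, act, inact,
                        calcium_dependent=ca_dep, calcium_source=ca_src)
        )
    return tuple(chans)


def _tc_channels(overrides: dict | None = None):
    dens = dict(_TC_DENSITIES)
    if overrides:
        dens.update(overrides)
    return (
        ChannelSpec("Leak", dens["Leak"], _E_LEAK_TC),
        ChannelSpec("KLeak", dens["KLeak"], _E_K),
        ChannelSpec("Naf", dens["Naf"], _E_NA, 3, 1,
                    _gk("TC", "Naf", "m"), _gk("TC", "Naf", "h")),
        ChannelSpec("K", dens["K"], _E_K, 4, 0, _gk("TC", "K", "m")),
        ChannelSpec("CaT", dens["CaT"], _E_CA_THAL, 2, 1,
                    _gk("TC", "CaT", "m"), _gk("TC", "CaT", "h"),
                    calcium_source=True),
        ChannelSpec("h", dens["h"], _E_H_TC, 1, 0, _gk("TC", "h", "m")),
    )


def _re_channels(overrides: dict | None = None):
    dens = dict(_RE_DENSITIES)
    if overrides:
        dens.update(overrides)
    return (
        ChannelSpec("Leak", dens["Leak"], _E_LEAK_RE),
        ChannelSpec("Naf", dens["Naf"], _E_NA, 3, 1,
                    _gk("RE", "Naf", "m"), _gk("RE", "Naf", "h")),
        ChannelSpec("K", dens["K"], _E_K, 4, 0, _gk("RE", "K", "m")),
        ChannelSpec("CaT", dens["CaT"], _E_CA_THAL, 2, 1,
                    _gk("RE", "CaT", "m"), _gk("RE", "CaT", "h"),
                    calcium_source=True),
    )


def cell_template(cell_class: str, g_overrides: dict | None = None,
                  area: float = DEFAULT_AREA_CM2) -> CellSpec:
    """Build the default :class:`CellSpec` for one cell class.

    ``g_overrides`` replaces individual conductance densities (mS/cm^2).
    Cortical classes use Cm = 0.9 uF/cm^2; LTS/TC/RE use 1.0 uF/cm^2.
    """
    if cell_class in ("RS", "IB", "NRS"):
        return CellSpec(cell_class, 0.9, _cortical_channels(cell_class, g_overrides),
                        area=area, calcium_pool=_CORTICAL_POOLS[cell_class],
                        V_init=-65.0)
    if cell_class == "LTS":
        return CellSpec(cell_class, 1.0, _cortical_channels("LTS", g_overrides),
                        area=area, calcium_pool=_CORTICAL_POOLS["LTS"],
                        V_init=-65.0)
    if cell_class == "TC":
        return CellSpec(cell_class, 1.0, _tc_channels(g_overrides),
                        area=area, V_init=-68.0)
    if cell_class == "RE":
        return CellSpec(cell_class, 1.0, _re_channels(g_overrides),
                        area=area, V_init=-75.0)
    raise ValueError(f"unknown cell class {cell_class!r}")


# --------------------------------------------------------------------------
# operations

def cell_table() -> "pd.DataFrame":
    """Human-readable registry of every cell template: one row per channel
    with conductance density, reversal, gating exponents and flags."""
    import pandas as pd

    rows = []
    for cls in ("RS", "IB", "NRS", "LTS", "TC", "RE"):
        cell = cell_template(cls)
        for ch in cell.channels:
            rows.append({
                "cell_class": cls, "Cm_uF_cm2": cell.Cm,
                "area_cm2": cell.area, "channel": ch.name,
                "g_max_mS_cm2": ch.g_max, "E_rev_mV": ch.E_rev,
                "N": ch.N, "M": ch.M,
                "calcium_dependent": ch.calcium_dependent,
                "calcium_source": ch.calcium_source,
            })
    return pd.DataFrame(rows)


def ionic_current(channel: ChannelSpec, V, m: float = 1.0, h: float = 1.0):
    """``gbar * m^N * h^M * (V - E_rev)``, positive outward.

    Units follow ``g_max``: a density in mS/cm^2 gives uA/cm^2 (or S/cm^2
    gives mA/cm^2) with V in mV.
    """
    if channel.g_max < 0:
        raise ValueError("g_max must be non-negative")
    m, h = np.asarray(m, dtype=float), np.asarray(h, dtype=float)
    if np.any((m < 0) | (m > 1)) or np.any((h < 0) | (h > 1)):
        raise ValueError("gate values must lie in [0, 1]")
    out = channel.g_max * m**channel.N * h**channel.M * (
        np.asarray(V, dtype=float) - channel.E_rev
    )
    return float(out) if np.ndim(out) == 0 else out


def gate_step(kinetics: GatingKinetics, gate: float, V: float, dt: float) -> float:
    """Exact-exponential update of a first-order gate over one step.

    ``x(t+dt) = x_inf + (x - x_inf) * exp(-dt / tau(V))`` -- unconditionally
    stable and exact for fixed V.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0.0 <= gate <= 1.0:
        raise ValueError("gate must lie in [0, 1]")
    x_inf = float(kinetics.steady_state(V))
    tau = float(kinetics.time_constant(V))
    return x_inf + (gate - x_inf) * math.exp(-dt / tau)


def classify_firing(voltage: np.ndarray, dt: float, spike_threshold: float = 0.0,
                    burst_isi: float = 15.0, quiescent_isi: float = 50.0,
                    burst_fraction: float = 0.3) -> str:
    """Label a voltage trace as regular_spiking, bursting, or silent.

    A cell is *bursting* when at least ``burst_fraction`` of its inter-spike
    intervals are shorter than ``burst_isi`` ms while the ISI distribution
    also contains intervals longer than ``quiescent_isi`` ms (ISI-bimodality
    heuristic); otherwise any spiking cell is *regular_spiking*.
    """
    voltage = np.asarray(voltage, dtype=float)
    if voltage.size == 0:
        raise ValueError("empty voltage trace")
    from .engine import detect_spikes  # local import avoids a cycle at import time

    spikes = detect_spikes(voltage, dt, threshold=spike_threshold)
    if len(spikes) == 0:
        return "silent"
    if len(spikes) < 2:
        return "regular_spiking"
    isi = np.diff(spikes)
    short = np.mean(isi < burst_isi)
    if short >= burst_fraction and np.any(isi > quiescent_isi):
        return "bursting"
    return "regular_spiking"
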