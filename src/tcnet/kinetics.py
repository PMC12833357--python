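"""Voltage-dependent gating kinetics for all ionic channels.

Each entry maps a (cell family, channel, gate) to a pair of callables
``x_inf(V)`` and ``tau_x(V)`` (V in mV, tau in ms) describing first-order
gate relaxation ``dx/dt = (x_inf(V) - x) / tau_x(V)``.

Cortical channels (fast and persistent Na, transient / slowly-inactivating /
delayed-rectifier / M-type / Ca-dependent K, low- and high-threshold Ca, and
the anomalous rectifier) follow the single-compartment reduction of the
Traub-family cortical cell models.  Thalamic channels follow the classical
TC/RE relay and reticular cell models (Hodgkin-Huxley Na/K with a voltage
offset, low-threshold Ca current with slower kinetics in RE, and the
hyperpolarization-activated cation current in TC), evaluated at body
temperature.  All rate functions are finite on [-130, 70] mV.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GATE_REGISTRY", "gate_functions", "rates_to_inf_tau"]


def _exp(x):
    # clipped exponential: keeps table construction finite at extreme voltages
    return np.exp(np.clip(x, -60.0, 60.0))


def _safe_expm1_ratio(x):
    """x / (exp(x) - 1), continuous at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    denom = np.where(small, 1.0, np.expm1(np.clip(x, -60, 60)))
    return np.where(small, 1.0 - x / 2.0, x / denom)


def rates_to_inf_tau(alpha, beta):
    """Convert rate functions alpha(V), beta(V) to (x_inf, tau_x) callables."""

    def x_inf(V):
        a, b = alpha(V), beta(V)
        return a / (a + b)

    def tau_x(V):
        return 1.0 / (alpha(V) + beta(V))

    return x_inf, tau_x


# ---------------------------------------------------------------- cortical

def _naf_m_inf(V):
    return 1.0 / (1.0 + _exp((-V - 34.5) / 10.0))


def _naf_m_tau(V):
    V = np.asarray(V, dtype=float)
    return np.where(
        V <= -26.5,
        0.025 + 0.14 * _exp((V + 26.5) / 10.0),
        0.02 + 0.145 * _exp((-V - 26.5) / 10.0),
    )


def _naf_h_inf(V):
    return 1.0 / (1.0 + _exp((V + 59.4) / 10.7))


def _naf_h_tau(V):
    return 0.15 + 1.15 / (1.0 + _exp((V + 33.5) / 15.0))


def _nap_m_inf(V):
    return 1.0 / (1.0 + _exp((-V - 48.0) / 10.0))


def _nap_m_tau(V):
    V = np.asarray(V, dtype=float)
    return np.where(
        V <= -40.0,
        0.025 + 0.14 * _exp((V + 40.0) / 10.0),
        0.02 + 0.145 * _exp((-V - 40.0) / 10.0),
    )


def _kdr_m_inf(V):
    return 1.0 / (1.0 + _exp((-V - 29.5) / 10.0))


def _kdr_m_tau(V):
    V = np.asarray(V, dtype=float)
    return 0.25 + 4.35 * _exp(-np.abs(V + 10.0) / 10.0)


def _ka_m_inf(V):
    return 1.0 / (1.0 + _exp((-V - 60.0) / 8.5))


def _ka_m_tau(V):
    return 0.185 + 0.5 / (_exp((V + 35.8) / 19.7) + _exp((-V - 79.7) / 12.7))


def _ka_h_inf(V):
    return 1.0 / (1.0 + _exp((V + 78.0) / 6.0))


def _ka_h_tau(V):
    V = np.asarray(V, dtype=float)
    tau = 0.5 / (_exp((V + 46.0) / 5.0) + _exp((-V - 238.0) / 37.5))
    return np.where(V <= -63.0, tau, 9.7)


def _k2_m_inf(V):
    return 1.0 / (1.0 + _exp((-V - 10.0) / 17.0))


def _k2_m_tau(V):
    return 4.95 + 0.5 / (_exp((V - 81.0) / 25.6) + _exp((-V - 132.0) / 18.0))


def _k2_h_inf(V):
    return 1.0 / (1.0 + _exp((V + 58.0) / 10.6))


def _k2_h_tau(V):
    return 60.0 + 0.5 / (_exp((V - 1.33) / 200.0) + _exp((-V - 130.0) / 7.1))


def _km_alpha(V):
    return 0.02 / (1.0 + _exp((-V - 20.0) / 5.0))


def _km_beta(V):
    return 0.01 * _exp((-V - 43.0) / 18.0)


def _kc_alpha(V):
    V = np.asarray(V, dtype=float)
    lo = _exp((V + 50.0) / 11.0 - (V + 53.5) / 27.0) / 18.975
    hi = 2.0 * _exp((-V - 53.5) / 27.0)
    return np.where(V <= -10.0, lo, hi)


def _kc_beta(V):
    V = np.asarray(V, dtype=float)
    b = 2.0 * _exp((-V - 53.5) / 27.0) - _kc_alpha(V)
    return np.where(V <= -10.0, np.maximum(b, 1e-6), 1e-6)


def _cat_m_inf(V):
    return 1.0 / (1.0 + _exp((-V - 56.0) / 6.2))


def _cat_m_tau(V):
    return 0.204 + 0.333 / (_exp((V + 15.8) / 18.2) + _exp((-V - 131.0) / 16.7))


def _cat_h_inf(V):
    return 1.0 / (1.0 + _exp((V + 80.0) / 4.0))


def _cat_h_tau(V):
    V = np.asarray(V, dtype=float)
    return np.where(
        V <= -81.0,
        0.333 * _exp((V + 466.0) / 66.6),
        9.32 + 0.333 * _exp(-(V + 21.0) / 10.5),
    )


def _cal_alpha(V):
    return 1.6 / (1.0 + _exp(-0.072 * (np.asarray(V, dtype=float) - 5.0)))


def _cal_beta(V):
    return 0.02 * 5.0 * _safe_expm1_ratio((np.asarray(V, dtype=float) + 8.9) / 5.0)


def _ar_m_inf(V):
    return 1.0 / (1.0 + _exp((V + 75.0) / 5.5))


def _ar_m_tau(V):
    V = np.asarray(V, dtype=float)
    return 1.0 / (_exp(-14.59 - 0.086 * V) + _exp(-1.87 + 0.0701 * V))


# ---------------------------------------------------------------- thalamic
# HH Na/K with a voltage offset setting spike threshold near -50 mV.

_VT_TC = -52.0
_VT_RE = -52.0


def _hh_na_m_inf_tau(vt):
    def alpha(V):
        x = 13.0 - (np.asarray(V, dtype=float) - vt)
        return 0.32 * 4.0 * _safe_expm1_ratio(x / 4.0)

    def beta(V):
        x = (np.asarray(V, dtype=float) - vt) - 40.0
        return 0.28 * 5.0 * _safe_expm1_ratio(x / 5.0)

    return rates_to_inf_tau(alpha, beta)


def _hh_na_h_inf_tau(vt):
    def alpha(V):
        return 0.128 * _exp((17.0 - (np.asarray(V, dtype=float) - vt)) / 18.0)

    def beta(V):
        return 4.0 / (1.0 + _exp((40.0 - (np.asarray(V, dtype=float) - vt)) / 5.0))

    return rates_to_inf_tau(alpha, beta)


def _hh_k_n_inf_tau(vt):
    def alpha(V):
        x = 15.0 - (np.asarray(V, dtype=float) - vt)
        return 0.032 * 5.0 * _safe_expm1_ratio(x / 5.0)

    def beta(V):
        return 0.5 * _exp((10.0 - (np.asarray(V, dtype=float) - vt)) / 40.0)

    return rates_to_inf_tau(alpha, beta)


# TC low-threshold Ca current (relay-cell kinetics at 36 C)
_PHI_M_T = 3.55 ** 1.2
_PHI_H_T = 3.0 ** 1.2


def _tc_cat_m_inf(V):
    return 1.0 / (1.0 + _exp(-(V + 57.0) / 6.2))


def _tc_cat_m_tau(V):
    return (
        0.612 + 1.0 / (_exp(-(V + 132.0) / 16.7) + _exp((V + 16.8) / 18.2))
    ) / _PHI_M_T


def _tc_cat_h_inf(V):
    return 1.0 / (1.0 + _exp((V + 81.0) / 4.0))


def _tc_cat_h_tau(V):
    V = np.asarray(V, dtype=float)
    return (
        np.where(
            V < -80.0,
            _exp((V + 467.0) / 66.6),
            28.0 + _exp(-(V + 22.0) / 10.5),
        )
        / _PHI_H_T
    )


# RE low-threshold Ca current: slower kinetics than TC
def _re_cat_m_inf(V):
    return 1.0 / (1.0 + _exp(-(V + 52.0) / 7.4))


def _re_cat_m_tau(V):
    return (3.0 + 1.0 / (_exp((V + 27.0) / 10.0) + _exp(-(V + 102.0) / 15.0))) / 6.9


def _re_cat_h_inf(V):
    return 1.0 / (1.0 + _exp((V + 80.0) / 5.0))


def _re_cat_h_tau(V):
    return (85.0 + 1.0 / (_exp((V + 48.0) / 4.0) + _exp(-(V + 407.0) / 50.0))) / 3.73


# TC hyperpolarization-activated cation current
def _tc_h_inf(V):
    return 1.0 / (1.0 + _exp((V + 75.0) / 5.5))


def _tc_h_tau(V):
    return 20.0 + 1000.0 / (_exp((V + 71.5) / 14.2) + _exp(-(V + 89.0) / 11.6))


_tc_na_m = _hh_na_m_inf_tau(_VT_TC)
_tc_na_h = _hh_na_h_inf_tau(_VT_TC)
_tc_k_n = _hh_k_n_inf_tau(_VT_TC)
_re_na_m = _hh_na_m_inf_tau(_VT_RE)
_re_na_h = _hh_na_h_inf_tau(_VT_RE)
_re_k_n = _hh_k_n_inf_tau(_VT_RE)

_km = rates_to_inf_tau(_km_alpha, _km_beta)
_kc = rates_to_inf_tau(_kc_alpha, _kc_beta)
_cal = rates_to_inf_tau(_cal_alpha, _cal_beta)

#: (family, channel, gate) -> (x_inf, tau_x).  Family "cortical" covers
#: RS/IB/NRS/LTS; families "TC" and "RE" are the thalamic cell classes.
GATE_REGISTRY = {
    ("cortical", "Naf", "m"): (_naf_m_inf, _naf_m_tau),
    ("cortical", "Naf", "h"): (_naf_h_inf, _naf_h_tau),
    ("cortical", "Nap", "m"): (_nap_m_inf, _nap_m_tau),
    ("cortical", "Kdr", "m"): (_kdr_m_inf, _kdr_m_tau),
    ("cortical", "Ka", "m"): (_ka_m_inf, _ka_m_tau),
    ("cortical", "Ka", "h"): (_ka_h_inf, _ka_h_tau),
    ("cortical", "K2", "m"): (_k2_m_inf, _k2_m_tau),
    ("cortical", "K2", "h"): (_k2_h_inf, _k2_h_tau),
    ("cortical", "Km", "m"): _km,
    ("cortical", "Kc", "m"): _kc,
    ("cortical", "CaT", "m"): (_cat_m_inf, _cat_m_tau),
    ("cortical", "CaT", "h"): (_cat_h_inf, _cat_h_tau),
    ("cortical", "CaL", "m"): _cal,
    ("cortical", "h", "m"): (_ar_m_inf, _ar_m_tau),
    ("TC", "Naf", "m"): _tc_na_m,
    ("TC", "Naf", "h"): _tc_na_h,
    ("TC", "K", "m"): _tc_k_n,
    ("TC", "CaT", "m"): (_tc_cat_m_inf, _tc_cat_m_tau),
    ("TC", "CaT", "h"): (_tc_cat_h_inf, _tc_cat_h_tau),
    ("TC", "h", "m"): (_tc_h_inf, _tc_h_tau),
    ("RE", "Naf", "m"): _re_na_m,
    ("RE", "Naf", "h"): _re_na_h,
    ("RE", "K", "m"): _re_k_n,
    ("RE", "CaT", "m"): (_re_cat_m_inf, _re_cat_m_tau),
    ("RE", "CaT", "h"): (_re_cat_h_inf, _re_cat_h_tau),
}


def gate_functions(family: str, channel: str, gate: str):
    """Look up (x_inf, tau_x) for one gate of one channel."""
    try:
        return GATE_REGISTRY[(family, channel, gate)]
    except KeyError:
        raise KeyError(
            f"no gating kinetics registered for {family}/{channel}/{gate}"
        ) from None
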