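"""Synthetic signals, spike trains and brute-force oracles for testing.

Everything here is deterministic: noise streams are seeded explicitly
(default seed 1234) and regenerating a fixture always yields the same
samples, so no fixture data needs to be checked in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synapses import SynapseSpec

__all__ = [
    "SyntheticSignalSpec",
    "make_tone_mixture",
    "make_spike_train",
    "make_spike_voltage",
    "synapse_oracle",
]

DEFAULT_SEED = 1234


@dataclass(frozen=True)
class SyntheticSignalSpec:
    """A mixture of sinusoids plus optional white noise and linear trend."""

    components: tuple = ()  # ((freq_hz, amplitude, phase_rad), ...)
    noise_sd: float = 0.0
    duration_ms: float = 6000.0
    fs: float = 10_000.0
    trend_slope: float = 0.0  # units per second
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")


def make_tone_mixture(spec: SyntheticSignalSpec) -> np.ndarray:
    """Deterministic tone mixture sampled at ``spec.fs``."""
    n = int(round(spec.duration_ms / 1000.0 * spec.fs))
    t = np.arange(n) / spec.fs
    out = np.zeros(n)
    for freq, amp, *rest in spec.components:
        phase = rest[0] if rest else 0.0
        out += amp * np.sin(2 * np.pi * freq * t + phase)
    out += spec.trend_slope * t
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        out += rng.normal(0.0, spec.noise_sd, size=n)
    return out


def make_spike_train(pattern: str, duration_ms: float = 1000.0, *,
                     interval: float = 100.0, n_per_burst: int = 3,
                     intra: float = 5.0, inter: float = 300.0,
                     start: float = 0.0) -> np.ndarray:
    """Deterministic spike-time list (ms).

    ``pattern="regular"`` emits events every ``interval`` ms;
    ``pattern="burst"`` emits clusters of ``n_per_burst`` spikes ``intra`` ms
    apart with ``inter`` ms between cluster onsets; ``pattern="empty"``
    emits nothing.
    """
    if pattern == "empty":
        return np.zeros(0)
    if pattern == "regular":
        if interval <= 0:
            raise ValueError("interval must be positive")
        return np.arange(start, start + duration_ms - 1e-9, interval)
    if pattern == "burst":
        if intra <= 0 or inter <= 0:
            raise ValueError("intervals must be positive")
        times = []
        t = start
        while t < start + duration_ms:
            for k in range(n_per_burst):
                tk = t + k * intra
                if tk < start + duration_ms:
                    times.append(tk)
            t += inter
        return np.asarray(times)
    raise ValueError(f"unknown pattern {pattern!r}")


def make_spike_voltage(spike_times_ms: np.ndarray, duration_ms: float,
                       dt: float = 0.1, rest: float = -65.0,
                       peak: float = 30.0, width_ms: float = 1.0) -> np.ndarray:
    """Voltage trace with a triangular spike waveform at each event;
    suitable input for threshold-crossing spike detection."""
    n = int(round(duration_ms / dt))
    v = np.full(n, rest)
    half = max(1, int(round(width_ms / (2 * dt))))
    for t in np.asarray(spike_times_ms, dtype=float):
        c = int(round(t / dt))
        for k in range(-half, half + 1):
            i = c + k
            if 0 <= i < n:
                frac = 1.0 - abs(k) / half
                v[i] = max(v[i], rest + (peak - rest) * frac)
    return v


def synapse_oracle(spec: SynapseSpec, spike_times_ms, horizon_ms: float,
                   dt: float = 0.001, s0: float = 0.0) -> np.ndarray:
    """Brute-force numerical integration of the two-state receptor scheme.

    Integrates ``ds/dt = alpha * C(t) * (1 - s) - beta * s`` with a
    classical Runge-Kutta step, where ``C(t) = C_max`` while any transmitter
    pulse is active and 0 otherwise (a new presynaptic spike retriggers the
    pulse window).  Serves as the independent oracle for the closed-form
    pulse solution.  ``dt`` must be fine (<= 0.001 ms), and spike times /
    pulse durations should align with the step grid so the transmitter
    concentration is constant within each step.
    """
    n = int(round(horizon_ms / dt)) + 1
    s = np.empty(n)
    s[0] = s0
    spike_times = np.sort(np.asarray(spike_times_ms, dtype=float))
    pulse_end = -np.inf
    k = 0
    val = s0
    a, b = spec.alpha, spec.beta
    for i in range(1, n):
        t = (i - 1) * dt
        while k < spike_times.size and spike_times[k] <= t:
            pulse_end = spike_times[k] + spec.C_dur
            k += 1
        # C is constant over [t, t + dt) when boundaries align with the grid
        c = spec.C_max if t < pulse_end else 0.0
        ac = a * c
        k1 = ac * (1.0 - val) - b * val
        y2 = val + 0.5 * dt * k1
        k2 = ac * (1.0 - y2) - b * y2
        y3 = val + 0.5 * dt * k2
        k3 = ac * (1.0 - y3) - b * y3
        y4 = val + dt * k3
        k4 = ac * (1.0 - y4) - b * y4
        val += (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        s[i] = val
    return s
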