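"""LFP synthesis and spectral state classification.

The virtual electrode sees a point-source local field potential: each
recorded layer-5 cell contributes its total postsynaptic current divided by
its distance to the electrode,

    V_ext(t) = (R_e / 4 pi) * sum_i I_syn,i(t) / r_i,

with extracellular resistivity R_e = 230 Ohm*cm.  Recorded cells of each
population sit on a line 20 um apart; the electrode is 50 um from the line's
center.  The LFP is detrended, band-passed 1-15 Hz (zero-phase Butterworth,
order 4), and analysed with Welch's method (Hann window, 20,000-sample
segments, 1,000-sample overlap at 10 kHz -> 0.5 Hz bins).  Band powers over
2.5-5 Hz (spike-wave discharge) and 7-10 Hz (spindle) classify the network
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal as sps

__all__ = [
    "LFPGeometry",
    "SpectralSummary",
    "SWD_BAND",
    "SPINDLE_BAND",
    "compute_lfp",
    "lfp_from_result",
    "preprocess",
    "welch_psd",
    "band_metrics",
    "spectrogram",
]

SWD_BAND = (2.5, 5.0)
SPINDLE_BAND = (7.0, 10.0)
TOTAL_BAND = (1.0, 15.0)

NPERSEG = 20_000
NOVERLAP = 1_000


@dataclass(frozen=True)
class LFPGeometry:
    """Electrode geometry for the point-source LFP."""

    spacing_um: float = 20.0
    electrode_offset_um: float = 50.0
    resistivity_ohm_cm: float = 230.0

    def distances_cm(self, n_cells: int) -> np.ndarray:
        """Distances (cm) from each of ``n_cells`` on a line to the electrode
        placed ``electrode_offset_um`` perpendicular to the line's center."""
        x = (np.arange(n_cells) - (n_cells - 1) / 2) * self.spacing_um
        r_um = np.hypot(x, self.electrode_offset_um)
        return r_um * 1e-4


@dataclass
class SpectralSummary:
    """PSD-derived description of one network state."""

    freqs: np.ndarray
    psd: np.ndarray
    peak_frequency: float  # Hz
    swd_power: float  # V^2 (band integral 2.5-5 Hz)
    spindle_power: float  # V^2 (band integral 7-10 Hz)
    swd_rel: float  # fraction of 1-15 Hz power
    spindle_rel: float
    state: str  # {"spindle", "SWD", "intermediate"}
    label: str = ""

    def to_record(self) -> dict:
        return {
            "label": self.label,
            "peak_hz": self.peak_frequency,
            "swd_power": self.swd_power,
            "spindle_power": self.spindle_power,
            "swd_rel": self.swd_rel,
            "spindle_rel": self.spindle_rel,
            "state": self.state,
        }


def compute_lfp(currents_nA: np.ndarray, distances_cm: np.ndarray,
                resistivity_ohm_cm: float = 230.0) -> np.ndarray:
    """Point-source LFP (V) from per-cell postsynaptic currents.

    ``currents_nA`` is (n_samples, n_cells); linear in each current and in
    1/r for each source.
    """
    currents_nA = np.atleast_2d(np.asarray(currents_nA, dtype=float))
    distances_cm = np.asarray(distances_cm, dtype=float)
    if np.any(distances_cm <= 0):
        raise ValueError("all source-electrode distances must be positive")
    if currents_nA.shape[1] != distances_cm.size:
        raise ValueError("one distance per current source required")
    amps = currents_nA * 1e-9
    return (resistivity_ohm_cm / (4 * np.pi)) * (amps / distances_cm).sum(axis=1)


def lfp_from_result(result, geometry: LFPGeometry | None = None) -> np.ndarray:
    """LFP series (V) from a :class:`~tcnet.engine.SimResult`.

    Recorded cells are grouped by population; each population's recorded
    subset forms its own line with the electrode 50 um from its center, and
    contributions sum (the potential is linear in its sources).
    """
    geometry = geometry or LFPGeometry()
    classes = [c for c, _ in result.recorded_cells]
    lfp = np.zeros(result.syn_currents.shape[0])
    for cls in dict.fromkeys(classes):  # preserve order, unique
        cols = [k for k, (c, _) in enumerate(result.recorded_cells) if c == cls]
        r = geometry.distances_cm(len(cols))
        lfp += compute_lfp(result.syn_currents[:, cols].astype(float), r,
                           geometry.resistivity_ohm_cm)
    return lfp


def preprocess(lfp: np.ndarray, fs: float, order: int = 4,
               band: tuple = TOTAL_BAND) -> np.ndarray:
    """Linear detrend followed by zero-phase Butterworth band-pass (1-15 Hz)."""
    lfp = np.asarray(lfp, dtype=float)
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt needs a minimum padding length; enforce a sane input size
    if lfp.size < 3 * (2 * order + 1):
        raise ValueError("series shorter than filter warm-up")
    detrended = sps.detrend(lfp, type="linear")
    return sps.sosfiltfilt(sos, detrended)


def welch_psd(filtered: np.ndarray, fs: float,
              nperseg: int = NPERSEG, noverlap: int = NOVERLAP):
    """Welch PSD with a Hann window; at fs = 10 kHz and 20,000-sample
    segments the bin width is 0.5 Hz.  Returns (freqs, psd)."""
    filtered = np.asarray(filtered, dtype=float)
    if filtered.size < nperseg:
        raise ValueError(
            f"need at least {nperseg} samples for one Welch segment")
    return sps.welch(filtered, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=noverlap)


def band_metrics(freqs: np.ndarray, psd: np.ndarray, label: str = ""
                 ) -> SpectralSummary:
    """Peak frequency, band powers, and the spindle/SWD state label.

    Peak frequency is the argmax PSD bin within the 1-15 Hz analysis band
    (ties resolve to the lowest frequency).  The state is *spindle* when the
    peak lies in 7-10 Hz and spindle relative power exceeds SWD relative
    power, *SWD* when the peak lies in 2.5-5 Hz and SWD relative power
    exceeds spindle relative power, else *intermediate*.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs.size == 0 or psd.size != freqs.size:
        raise ValueError("empty or mismatched PSD")

    def band_power(lo, hi):
        m = (freqs >= lo) & (freqs <= hi)
        if m.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[m], freqs[m]))

    total = band_power(*TOTAL_BAND)
    swd = band_power(*SWD_BAND)
    spindle = band_power(*SPINDLE_BAND)
    swd_rel = swd / total if total > 0 else 0.0
    spindle_rel = spindle / total if total > 0 else 0.0

    in_band = (freqs >= TOTAL_BAND[0]) & (freqs <= TOTAL_BAND[1])
    if not in_band.any():
        raise ValueError("PSD does not cover the 1-15 Hz analysis band")
    sub_f, sub_p = freqs[in_band], psd[in_band]
    peak = float(sub_f[int(np.argmax(sub_p))])

    if SPINDLE_BAND[0] <= peak <= SPINDLE_BAND[1] and spindle_rel > swd_rel:
        state = "spindle"
    elif SWD_BAND[0] <= peak <= SWD_BAND[1] and swd_rel > spindle_rel:
        state = "SWD"
    else:
        state = "intermediate"
    return SpectralSummary(freqs, psd, peak, swd, spindle, swd_rel,
                           spindle_rel, state, label=label)


def spectrogram(filtered: np.ndarray, fs: float, nperseg: int = 10_000,
                noverlap: int = 9_000):
    """Short-time spectral map (Hann window, 1 s segments, 0.1 s hop at
    10 kHz).  Returns (freqs, times, Sxx)."""
    filtered = np.asarray(filtered, dtype=float)
    nperseg = min(nperseg, filtered.size)
    noverlap = min(noverlap, nperseg - 1)
    return sps.spectrogram(filtered, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=noverlap)
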