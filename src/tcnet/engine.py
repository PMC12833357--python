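"""Time-stepping engine: settle -> stimulate -> record protocols.

Compiles a :class:`~tcnet.network.Network` into flat state arrays, runs the
compiled kernel, and wraps the recordings in a :class:`SimResult`.  The
integrator is fully deterministic (no noise process exists in the model;
spontaneous activity arises from intrinsic TC dynamics), so identical
configurations produce bitwise-identical results.

Cortical holding currents are calibrated at build time by bisection so each
isolated cortical cell rests at its target potential; thalamic cells carry
no holding current and rest where their leak currents put them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables
from ._kernel import run_kernel
from .channels import (DEFAULT_AREA_CM2, REST_TARGETS, CellSpec, cell_template)
from .network import Network

__all__ = ["Protocol", "SimResult", "run", "run_current_protocol",
           "detect_spikes", "calibrate_hold"]

CLASS_ORDER = tables.CELL_CLASSES  # ("RS","IB","NRS","LTS","TC","RE")
_CLS_IDX = {c: k for k, c in enumerate(CLASS_ORDER)}

_NMAX = 128
_NG_MAX = 16
_NCH_MAX = 13
_V_TABLE = (-130.0, 70.0, 0.05)  # vmin, vmax, dv
_SPIKE_CAP = 4_000_000


@dataclass(frozen=True)
class Protocol:
    """Settle -> stimulate -> record protocol.

    The network integrates for ``settle_duration`` ms unrecorded; at settle
    end a ``stim_amplitude`` nA pulse of ``stim_duration`` ms is injected
    into ``n_stim`` layer-6 NRS cells nearest the line's center, and the
    following ``record_duration`` ms are recorded at ``record_dt`` ms
    (10 kHz), the sampling rate the spectral pipeline expects.
    """

    settle_duration: float = 2000.0
    record_duration: float = 6000.0
    stim_amplitude: float = 1.0  # nA
    stim_duration: float = 100.0  # ms
    n_stim: int = 5
    dt: float = 0.025  # ms
    record_dt: float = 0.1  # ms -> 10 kHz

    def __post_init__(self):
        if self.dt <= 0 or self.record_dt <= 0:
            raise ValueError("dt and record_dt must be positive")
        ratio = self.record_dt / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dt must divide record_dt")

    @property
    def fs(self) -> float:
        """Recording sampling frequency in Hz."""
        return 1000.0 / self.record_dt

    @property
    def welch_ready(self) -> bool:
        """True when the recording covers two full 20,000-sample Welch
        segments at 1,000-sample overlap (>= 39,000 samples)."""
        return self.record_duration * self.fs / 1000.0 >= 2 * 20_000 - 1_000

    @classmethod
    def standard(cls) -> "Protocol":
        p = cls()
        assert p.record_duration >= 4000.0
        return p


@dataclass
class SimResult:
    """Recorded output of one simulation.

    ``voltages`` is (n_samples, n_cells) float32 with cells ordered
    RS, IB, NRS, LTS, TC, RE (offsets in ``class_offsets``); ``syn_currents``
    holds the total synaptic current (nA) onto each LFP-recorded cell.
    """

    time: np.ndarray  # ms, recording grid
    voltages: np.ndarray
    class_offsets: dict
    class_counts: dict
    spikes: pd.DataFrame  # columns: cell_class, cell_idx, time_ms
    syn_currents: np.ndarray  # (n_samples, n_recorded)
    recorded_cells: list  # [(cell_class, idx), ...]
    record_dt: float
    label: str = ""

    @property
    def fs(self) -> float:
        return 1000.0 / self.record_dt

    def voltage(self, cell_class: str, idx: int = 0) -> np.ndarray:
        off = self.class_offsets[cell_class]
        if idx >= self.class_counts[cell_class]:
            raise IndexError(f"{cell_class} has {self.class_counts[cell_class]} cells")
        return self.voltages[:, off + idx].astype(float)

    def spike_times(self, cell_class: str, idx: int) -> np.ndarray:
        m = (self.spikes["cell_class"] == cell_class) & (self.spikes["cell_idx"] == idx)
        return self.spikes.loc[m, "time_ms"].to_numpy()

    def spike_raster_table(self) -> pd.DataFrame:
        return self.spikes.copy()

    def save(self, path) -> None:
        """Serialize to HDF5 (voltages, synaptic currents, spikes, metadata)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["label"] = self.label
            f.attrs["record_dt"] = self.record_dt
            f.create_dataset("time", data=self.time)
            f.create_dataset("voltages", data=self.voltages, compression="gzip")
            f.create_dataset("syn_currents", data=self.syn_currents,
                             compression="gzip")
            g = f.create_group("spikes")
            g.create_dataset(
                "cell_class",
                data=np.array([_CLS_IDX[c] for c in self.spikes["cell_class"]]),
            )
            g.create_dataset("cell_idx", data=self.spikes["cell_idx"].to_numpy())
            g.create_dataset("time_ms", data=self.spikes["time_ms"].to_numpy())
            f.attrs["recorded_cells"] = np.array(
                [f"{c}:{i}" for c, i in self.recorded_cells], dtype="S16"
            )
            f.attrs["class_order"] = np.array(list(CLASS_ORDER), dtype="S8")
            f.attrs["class_counts"] = np.array(
                [self.class_counts[c] for c in CLASS_ORDER]
            )

    @classmethod
    def load(cls, path) -> "SimResult":
        import h5py

        with h5py.File(path, "r") as f:
            counts = {c: int(n) for c, n in
                      zip(CLASS_ORDER, f.attrs["class_counts"])}
            offsets, off = {}, 0
            for c in CLASS_ORDER:
                offsets[c] = off
                off += counts[c]
            spikes = pd.DataFrame({
                "cell_class": [CLASS_ORDER[k] for k in f["spikes/cell_class"][:]],
                "cell_idx": f["spikes/cell_idx"][:],
                "time_ms": f["spikes/time_ms"][:],
            })
            rec = [tuple(x.decode().split(":")) for x in f.attrs["recorded_cells"]]
            rec = [(c, int(i)) for c, i in rec]
            return cls(
                time=f["time"][:], voltages=f["voltages"][:],
                class_offsets=offsets, class_counts=counts, spikes=spikes,
                syn_currents=f["syn_currents"][:], recorded_cells=rec,
                record_dt=float(f.attrs["record_dt"]),
                label=str(f.attrs["label"]),
            )


# --------------------------------------------------------------------------
# compilation

def _build_gate_tables(cells: dict, dt: float):
    """Voltage lookup tables x_inf and exp(-dt/tau) per (class, gate row)."""
    vmin, vmax, dv = _V_TABLE
    grid = np.arange(vmin, vmax + dv / 2, dv)
    nv = grid.size
    xinf = np.zeros((len(CLASS_ORDER), _NG_MAX, nv))
    efact = np.ones((len(CLASS_ORDER), _NG_MAX, nv))
    gate_index = {}
    for c, cls in enumerate(CLASS_ORDER):
        row = 0
        for ch in cells[cls].channels:
            for kind, kin in (("m", ch.activation), ("h", ch.inactivation)):
                if kin is None and not (ch.name == "Kahp" and kind == "m"):
                    continue
                gate_index[(cls, ch.name, kind)] = row
                if kin is not None:
                    xi = np.asarray(kin.steady_state(grid), dtype=float)
                    tau = np.asarray(kin.time_constant(grid), dtype=float)
                    if np.any(tau <= 0) or np.any(~np.isfinite(tau)):
                        raise ValueError(
                            f"non-positive time constant for {cls}/{ch.name}/{kind}")
                    xinf[c, row] = np.clip(xi, 0.0, 1.0)
                    efact[c, row] = np.exp(-dt / tau)
                row += 1
        if row > _NG_MAX:
            raise ValueError("gate table overflow")
    return grid, xinf, efact, gate_index


class CompiledNetwork:
    """Flat array representation of a Network, ready for the kernel."""

    def __init__(self, network: Network, dt: float,
                 cells: dict | None = None, calibrate: bool = True):
        cfg = network.config
        self.network = network
        self.dt = dt
        self.counts = np.array(
            [network.layout.counts[c] for c in CLASS_ORDER], dtype=np.int64)
        if self.counts.max() > _NMAX:
            raise ValueError("population exceeds compiled capacity")
        area = getattr(cfg, "area_cm2", None) or DEFAULT_AREA_CM2
        self.cells = cells or {
            cls: cell_template(cls, cfg.g_overrides.get(cls), area=area)
            for cls in CLASS_ORDER
        }
        self.area = self.cells["RS"].area
        self.Cm = np.array([self.cells[c].Cm for c in CLASS_ORDER])

        grid, self.xinf_tab, self.efact_tab, self.gate_index = \
            _build_gate_tables(self.cells, dt)
        self.vmin, self.dv = grid[0], grid[1] - grid[0]

        nc = len(CLASS_ORDER)
        self.n_chan = np.zeros(nc, dtype=np.int64)
        self.chan_g = np.zeros((nc, _NCH_MAX))
        self.chan_E = np.zeros((nc, _NCH_MAX))
        self.chan_N = np.zeros((nc, _NCH_MAX), dtype=np.int64)
        self.chan_M = np.zeros((nc, _NCH_MAX), dtype=np.int64)
        self.chan_act = -np.ones((nc, _NCH_MAX), dtype=np.int64)
        self.chan_inact = -np.ones((nc, _NCH_MAX), dtype=np.int64)
        self.chan_mode = np.zeros((nc, _NCH_MAX), dtype=np.int64)
        self.chan_casrc = np.zeros((nc, _NCH_MAX), dtype=np.int64)
        self.n_gates = np.zeros(nc, dtype=np.int64)
        self.ca_tau = np.zeros(nc)
        self.ca_gain = np.zeros(nc)
        self.kc_sat = np.ones(nc)
        self.kahp_gain = np.zeros(nc)
        self.kahp_amax = np.zeros(nc)
        self.kahp_beta = np.zeros(nc)
        for c, cls in enumerate(CLASS_ORDER):
            cell = self.cells[cls]
            self.n_chan[c] = len(cell.channels)
            pool = cell.calcium_pool
            if pool is not None:
                self.ca_tau[c] = pool.tau
                self.ca_gain[c] = pool.influx_gain
                self.kc_sat[c] = pool.kc_saturation
                self.kahp_gain[c] = pool.kahp_alpha_gain
                self.kahp_amax[c] = pool.kahp_alpha_max
                self.kahp_beta[c] = pool.kahp_beta
            for k, ch in enumerate(cell.channels):
                self.chan_g[c, k] = ch.g_max
                self.chan_E[c, k] = ch.E_rev
                self.chan_N[c, k] = ch.N
                self.chan_M[c, k] = ch.M
                if (cls, ch.name, "m") in self.gate_index:
                    self.chan_act[c, k] = self.gate_index[(cls, ch.name, "m")]
                if (cls, ch.name, "h") in self.gate_index:
                    self.chan_inact[c, k] = self.gate_index[(cls, ch.name, "h")]
                if ch.name == "Kc":
                    self.chan_mode[c, k] = 1
                elif ch.name == "Kahp":
                    self.chan_mode[c, k] = 2
                if ch.calcium_source:
                    self.chan_casrc[c, k] = 1
            self.n_gates[c] = max(
                [self.gate_index[key] + 1 for key in self.gate_index
                 if key[0] == cls] or [0])

        # projections -> CSR
        P = len(network.projections)
        self.p_pre = np.array([_CLS_IDX[p.pre_class] for p in network.projections],
                              dtype=np.int64)
        self.p_post = np.array([_CLS_IDX[p.post_class] for p in network.projections],
                               dtype=np.int64)
        self.p_Esyn = np.array([p.synapse.E_syn for p in network.projections],
                               dtype=float)
        self.p_sinf = np.array([p.synapse.s_inf for p in network.projections],
                               dtype=float)
        self.p_tau = np.array([p.synapse.tau_s for p in network.projections],
                              dtype=float)
        self.p_beta = np.array([p.synapse.beta for p in network.projections],
                               dtype=float)
        self.p_cdur = np.array([p.synapse.C_dur for p in network.projections],
                               dtype=float)
        with np.errstate(divide="ignore"):
            self.p_pfact = np.exp(-dt / self.p_tau) if P else np.zeros(0)
            self.p_dfact = np.exp(-self.p_beta * dt) if P else np.zeros(0)
        self.indptr = np.zeros((P, _NMAX + 1), dtype=np.int64)
        e_pre, e_w = [], []
        pos = 0
        for pi, proj in enumerate(network.projections):
            w = proj.weight
            n_post = network.layout.counts[proj.post_class]
            by_post = [[] for _ in range(n_post)]
            for post_i, pre_j in proj.edges:
                by_post[post_i].append(pre_j)
            for i in range(_NMAX + 1):
                self.indptr[pi, i] = pos
            for i in range(n_post):
                self.indptr[pi, i] = pos
                for pre_j in by_post[i]:
                    e_pre.append(pre_j)
                    e_w.append(w)
                    pos += 1
            for i in range(n_post, _NMAX + 1):
                self.indptr[pi, i] = pos
        self.e_pre = np.array(e_pre, dtype=np.int64) if e_pre else \
            np.zeros(0, dtype=np.int64)
        self.e_w = np.array(e_w) if e_w else np.zeros(0)

        # holding currents (cortical classes only; Eqs for TC/RE carry none)
        self.hold_nA = np.zeros(nc)
        if calibrate:
            for cls in ("RS", "IB", "NRS", "LTS"):
                self.hold_nA[_CLS_IDX[cls]] = calibrate_hold(
                    cls, cell=self.cells[cls], dt=dt)

    def fresh_state(self):
        nc = len(CLASS_ORDER)
        v = np.zeros((nc, _NMAX))
        gates = np.zeros((nc, _NG_MAX, _NMAX))
        ca = np.zeros((nc, _NMAX))
        for c, cls in enumerate(CLASS_ORDER):
            cell = self.cells[cls]
            v[c, :] = cell.V_init
            vi = cell.V_init
            for ch in cell.channels:
                for kind, kin in (("m", ch.activation), ("h", ch.inactivation)):
                    if kin is None:
                        continue
                    row = self.gate_index[(cls, ch.name, kind)]
                    gates[c, row, :] = float(np.clip(kin.steady_state(vi), 0, 1))
        P = len(self.p_pre)
        s = np.zeros((P, _NMAX))
        pulse_end = np.full((P, _NMAX), -1e30)
        last_spike = np.full((nc, _NMAX), -1e30)
        return v, gates, ca, s, pulse_end, last_spike


# --------------------------------------------------------------------------
# running

def _default_recorded_cells(network: Network, per_population: int = 10):
    """LFP subset: evenly index-spaced layer-5 RS and IB cells."""
    cells = []
    for cls in ("RS", "IB"):
        n = network.layout.counts[cls]
        k = min(per_population, n)
        idx = np.unique(np.round(np.linspace(0, n - 1, k)).astype(int))
        cells.extend((cls, int(i)) for i in idx)
    return cells


def run(network: Network, protocol: Protocol | None = None,
        recorded_cells: list | None = None, compiled: CompiledNetwork | None = None
        ) -> SimResult:
    """Integrate the network through the settle->stimulate->record protocol.

    The stimulus targets the ``n_stim`` NRS cells nearest the center of the
    layer-6 line, starting at settle end.  Raises ``RuntimeError`` with the
    first offending cell and time on numerical blow-up (|V| > 150 mV).
    """
    protocol = protocol or Protocol()
    comp = compiled or CompiledNetwork(network, protocol.dt)
    v, gates, ca, s, pulse_end, last_spike = comp.fresh_state()

    n_nrs = network.layout.counts["NRS"]
    center = (n_nrs - 1) / 2
    order = np.argsort(np.abs(np.arange(n_nrs) - center), kind="stable")
    stim_idx = np.sort(order[: protocol.n_stim]).astype(np.int64)

    recorded = recorded_cells or _default_recorded_cells(network)
    rec_cls = np.array([_CLS_IDX[c] for c, _ in recorded], dtype=np.int64)
    rec_idx = np.array([i for _, i in recorded], dtype=np.int64)

    dt = protocol.dt
    n_settle = int(round(protocol.settle_duration / dt))
    n_record = int(round(protocol.record_duration / dt))
    rec_every = int(round(protocol.record_dt / dt))
    n_samples = n_record // rec_every
    n_cells = network.layout.total
    offsets, off = {}, 0
    for cls in CLASS_ORDER:
        offsets[cls] = off
        off += network.layout.counts[cls]
    class_offset = np.array([offsets[c] for c in CLASS_ORDER], dtype=np.int64)

    v_rec = np.zeros((n_samples, n_cells), dtype=np.float32)
    syn_rec = np.zeros((n_samples, len(recorded)), dtype=np.float32)
    spk_cls = np.zeros(_SPIKE_CAP, dtype=np.int32)
    spk_idx = np.zeros(_SPIKE_CAP, dtype=np.int32)
    spk_t = np.zeros(_SPIKE_CAP)
    spk_count = np.zeros(1, dtype=np.int64)
    syn_acc = np.zeros((len(CLASS_ORDER), _NMAX))
    rec_cursor = np.zeros(1, dtype=np.int64)

    stim_on = protocol.settle_duration
    stim_off = stim_on + protocol.stim_duration

    status, bc, bi, bt = run_kernel(
        comp.counts, comp.Cm, comp.hold_nA, comp.area,
        v, gates, ca,
        comp.n_chan, comp.chan_g, comp.chan_E, comp.chan_N, comp.chan_M,
        comp.chan_act, comp.chan_inact, comp.chan_mode, comp.chan_casrc,
        comp.vmin, comp.dv, comp.xinf_tab, comp.efact_tab,
        comp.ca_tau, comp.ca_gain, comp.kc_sat, comp.kahp_gain,
        comp.kahp_amax, comp.kahp_beta,
        comp.p_pre, comp.p_post, comp.p_Esyn, comp.p_sinf, comp.p_pfact,
        comp.p_beta, comp.p_dfact, comp.p_cdur, comp.p_tau,
        s, pulse_end, comp.indptr, comp.e_pre, comp.e_w,
        _CLS_IDX["NRS"], stim_idx, protocol.stim_amplitude, stim_on, stim_off,
        0.0, dt, n_settle + n_record, n_settle, rec_every,
        class_offset, v_rec, rec_cls, rec_idx, syn_rec,
        spk_cls, spk_idx, spk_t, spk_count,
        last_spike, syn_acc, rec_cursor,
    )
    if status != 0:
        raise RuntimeError(
            f"numerical blow-up: cell {CLASS_ORDER[bc]}[{bi}] at t = {bt:.3f} ms")

    n_spk = int(spk_count[0])
    in_window = spk_t[:n_spk] >= protocol.settle_duration
    spikes = pd.DataFrame({
        "cell_class": [CLASS_ORDER[k] for k in spk_cls[:n_spk][in_window]],
        "cell_idx": spk_idx[:n_spk][in_window].astype(int),
        "time_ms": spk_t[:n_spk][in_window] - protocol.settle_duration,
    })
    time = np.arange(n_samples) * protocol.record_dt
    result = SimResult(
        time=time, voltages=v_rec, class_offsets=offsets,
        class_counts=dict(network.layout.counts), spikes=spikes,
        syn_currents=syn_rec, recorded_cells=list(recorded),
        record_dt=protocol.record_dt, label=network.config.label,
    )
    bad = ~np.isfinite(result.voltages)
    if bad.any():
        raise RuntimeError("non-finite voltage in recording")
    return result


_SINGLE_CELL_CACHE: dict = {}


def _cell_key(cell: CellSpec):
    pool = cell.calcium_pool
    pool_key = None if pool is None else (
        pool.tau, pool.influx_gain, pool.kc_saturation,
        pool.kahp_alpha_gain, pool.kahp_alpha_max, pool.kahp_beta)
    return (cell.cell_class, cell.Cm, cell.area, pool_key,
            tuple((ch.name, ch.g_max, ch.E_rev, ch.N, ch.M)
                  for ch in cell.channels))


def _single_cell_compiled(cell_class: str, cell: CellSpec, dt: float
                          ) -> "CompiledNetwork":
    """One-cell-per-class compiled network, cached (no per-run state)."""
    from .network import NetworkConfig, PopulationLayout, Network

    key = (_cell_key(cell), dt)
    if key not in _SINGLE_CELL_CACHE:
        cells = {cls: (cell if cls == cell_class else cell_template(cls))
                 for cls in CLASS_ORDER}
        layout = PopulationLayout({c: 1 for c in CLASS_ORDER})
        net = Network(NetworkConfig(), layout, [])
        _SINGLE_CELL_CACHE[key] = CompiledNetwork(
            net, dt, cells=cells, calibrate=False)
    return _SINGLE_CELL_CACHE[key]


def run_current_protocol(cell_class: str, segments, dt: float = 0.025,
                         record_dt: float = 0.1, cell: CellSpec | None = None,
                         hold_nA: float | None = None):
    """Integrate one isolated cell through a sequence of current steps.

    ``segments`` is a list of (duration_ms, injected_nA).  Returns
    (time_ms, voltage_mV).  Used for calibration, phenotype checks and
    rebound-burst experiments; no synapses are present.
    """
    cell = cell or cell_template(cell_class)
    comp = _single_cell_compiled(cell_class, cell, dt)
    if hold_nA is not None:
        comp.hold_nA[_CLS_IDX[cell_class]] = hold_nA

    v, gates, ca, s, pulse_end, last_spike = comp.fresh_state()
    rec_every = int(round(record_dt / dt))
    c = _CLS_IDX[cell_class]
    traces = []
    t0 = 0.0
    spk_cls = np.zeros(100_000, dtype=np.int32)
    spk_idx = np.zeros(100_000, dtype=np.int32)
    spk_t = np.zeros(100_000)
    spk_count = np.zeros(1, dtype=np.int64)
    syn_acc = np.zeros((len(CLASS_ORDER), _NMAX))
    class_offset = np.arange(len(CLASS_ORDER), dtype=np.int64)
    rec_cls = np.zeros(0, dtype=np.int64)
    rec_idx = np.zeros(0, dtype=np.int64)
    syn_rec = np.zeros((0, 0), dtype=np.float32)
    base_hold = comp.hold_nA[c]
    for duration, amp in segments:
        n_steps = int(round(duration / dt))
        n_samples = n_steps // rec_every
        v_rec = np.zeros((n_samples, len(CLASS_ORDER)), dtype=np.float32)
        rec_cursor = np.zeros(1, dtype=np.int64)
        comp.hold_nA[c] = base_hold + amp
        status, bc, bi, bt = run_kernel(
            comp.counts, comp.Cm, comp.hold_nA, comp.area,
            v, gates, ca,
            comp.n_chan, comp.chan_g, comp.chan_E, comp.chan_N, comp.chan_M,
            comp.chan_act, comp.chan_inact, comp.chan_mode, comp.chan_casrc,
            comp.vmin, comp.dv, comp.xinf_tab, comp.efact_tab,
            comp.ca_tau, comp.ca_gain, comp.kc_sat, comp.kahp_gain,
            comp.kahp_amax, comp.kahp_beta,
            comp.p_pre, comp.p_post, comp.p_Esyn, comp.p_sinf, comp.p_pfact,
            comp.p_beta, comp.p_dfact, comp.p_cdur, comp.p_tau,
            s, pulse_end, comp.indptr, comp.e_pre, comp.e_w,
            -1, np.zeros(0, dtype=np.int64), 0.0, 0.0, -1.0,
            t0, dt, n_steps, 0, rec_every,
            class_offset, v_rec, rec_cls, rec_idx, syn_rec,
            spk_cls, spk_idx, spk_t, spk_count,
            last_spike, syn_acc, rec_cursor,
        )
        if status != 0:
            raise RuntimeError(
                f"numerical blow-up in single-cell run at t = {bt:.3f} ms")
        traces.append(v_rec[:, c].astype(float))
        t0 += n_steps * dt
    comp.hold_nA[c] = base_hold
    voltage = np.concatenate(traces)
    time = np.arange(voltage.size) * record_dt
    return time, voltage


def detect_spikes(voltage: np.ndarray, dt: float, threshold: float = 0.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Spike times (ms) from upward threshold crossings with a refractory
    merge window."""
    voltage = np.asarray(voltage, dtype=float)
    above = voltage >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = crossings * dt
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] > refractory:
            kept.append(t)
    return np.asarray(kept)


_HOLD_CACHE: dict = {}


def calibrate_hold(cell_class: str, target: float | None = None,
                   cell: CellSpec | None = None, dt: float = 0.025,
                   settle_ms: float = 1500.0, tol: float = 0.1) -> float:
    """Bisection on the holding current so the isolated cell rests at
    ``target`` mV (class defaults in :data:`REST_TARGETS`).  Results are
    cached per (class, conductance set, dt)."""
    target = REST_TARGETS[cell_class] if target is None else target
    cell = cell or cell_template(cell_class)
    key = (cell_class, target, dt,
           tuple((ch.name, ch.g_max, ch.E_rev) for ch in cell.channels))
    if key in _HOLD_CACHE:
        return _HOLD_CACHE[key]

    def final_v(hold):
        _, trace = run_current_protocol(
            cell_class, [(settle_ms, 0.0)], dt=dt, record_dt=1.0,
            cell=cell, hold_nA=hold)
        if trace[-500:].max() > -20.0:  # spiking: above any subthreshold target
            return 0.0
        return float(np.mean(trace[-300:]))

    lo, hi = -5.0, 5.0
    v_lo, v_hi = final_v(lo), final_v(hi)
    if not (v_lo < target < v_hi):
        raise RuntimeError(
            f"cannot bracket target rest {target} mV for {cell_class} "
            f"(range gives {v_lo:.1f}..{v_hi:.1f} mV)")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        v_mid = final_v(mid)
        if abs(v_mid - target) < tol:
            break
        if v_mid < target:
            lo = mid
        else:
            hi = mid
    _HOLD_CACHE[key] = mid
    return mid
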