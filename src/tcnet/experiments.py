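"""Scenario matrix: compositions x inhibition level x ALLO x enhancement.

Every simulated condition in the study is a point on four axes: the layer-5
composition (nIB, nRS), the cortical GABA_A conductance fraction (1.0 =
healthy, 0.1 = diseased), whether the ALLO transform is applied to all
GABA_A synapses, and the frontocortical enhancement factors
(F_IBIB, F_IBNRS, F_NRSIB).  This module runs single scenarios end-to-end
(build -> settle -> stimulate -> record -> LFP -> PSD -> state label),
sweeps the inhibition axis, and produces the remission matrix that asks
whether ALLO restores spindles in each composition with and without
enhanced frontocortical connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import signal as sig
from .engine import Protocol, SimResult, run
from .network import NetworkConfig, build_network

__all__ = ["Scenario", "run_scenario", "sweep_gaba", "remission_matrix",
           "ENHANCEMENT_FACTORS", "COMPOSITIONS"]

#: Frontocortical enhancement used for the treatment-non-responder variant.
ENHANCEMENT_FACTORS = (7.0, 5.0, 3.0)

#: Layer-5 (nIB, nRS) compositions studied.
COMPOSITIONS = ((75, 25), (5, 95), (95, 5), (50, 50))


@dataclass(frozen=True)
class Scenario:
    """One fully specified simulation condition."""

    n_ib: int = 75
    n_rs: int = 25
    cortical_gaba_fraction: float = 1.0
    allo: bool = False
    enhancement: tuple = (1.0, 1.0, 1.0)
    label: str = ""

    def config(self) -> NetworkConfig:
        return NetworkConfig(
            n_ib=self.n_ib, n_rs=self.n_rs,
            cortical_gaba_fraction=self.cortical_gaba_fraction,
            allo=self.allo, enhancement=tuple(self.enhancement),
        )

    @property
    def name(self) -> str:
        return self.label or self.config().label


def run_scenario(scenario: Scenario, protocol: Protocol | None = None,
                 return_result: bool = False):
    """Run one scenario and summarize its LFP spectrum.

    Builds the network for the scenario's composition (in-degrees follow the
    min/ceil rule), applies mutation scaling / ALLO / enhancement, runs the
    standard protocol, computes the filtered-LFP Welch PSD and returns a
    :class:`~tcnet.signal.SpectralSummary` (optionally with the raw
    :class:`~tcnet.engine.SimResult`).  Deterministic.
    """
    protocol = protocol or Protocol()
    net = build_network(scenario.config())
    result = run(net, protocol)
    lfp = sig.lfp_from_result(result)
    filtered = sig.preprocess(lfp, result.fs)
    freqs, psd = sig.welch_psd(filtered, result.fs)
    summary = sig.band_metrics(freqs, psd, label=scenario.name)
    if return_result:
        return summary, result
    return summary


def sweep_gaba(composition=(75, 25), fractions=(0.05, 0.1, 0.2, 0.4, 1.0),
               enhancement=(1.0, 1.0, 1.0), protocol: Protocol | None = None
               ) -> pd.DataFrame:
    """Network frequency response to varying cortical GABA_A inhibition.

    Runs one Control-synapse scenario per fraction and collates
    (gaba_fraction, peak_frequency, swd relative power, state), sorted by
    fraction ascending.
    """
    fractions = sorted(fractions)
    if not fractions:
        raise ValueError("at least one GABA_A fraction required")
    n_ib, n_rs = composition
    rows = []
    for frac in fractions:
        summary = run_scenario(
            Scenario(n_ib, n_rs, cortical_gaba_fraction=frac,
                     enhancement=enhancement),
            protocol=protocol,
        )
        rows.append({
            "gaba_fraction": frac,
            "peak_frequency": summary.peak_frequency,
            "swd_relative_power": summary.swd_rel,
            "spindle_relative_power": summary.spindle_rel,
            "state": summary.state,
        })
    return pd.DataFrame(rows)


def remission_matrix(compositions=COMPOSITIONS,
                     factors=ENHANCEMENT_FACTORS,
                     gaba_fraction: float = 0.1,
                     protocol: Protocol | None = None) -> pd.DataFrame:
    """Post-ALLO state for every composition x {baseline, enhanced}.

    Each cell of the matrix initializes the network to the diseased state
    (10% cortical GABA_A), applies the ALLO transform to all GABA_A
    synapses, runs the protocol, and reports the resulting state label and
    peak frequency.
    """
    rows = []
    for n_ib, n_rs in compositions:
        for enh_label, enh in (("baseline", (1.0, 1.0, 1.0)),
                               ("enhanced", factors)):
            summary = run_scenario(
                Scenario(n_ib, n_rs, cortical_gaba_fraction=gaba_fraction,
                         allo=True, enhancement=enh),
                protocol=protocol,
            )
            rows.append({
                "composition": f"{n_ib}-{n_rs}",
                "connectivity": enh_label,
                "state": summary.state,
                "peak_frequency": summary.peak_frequency,
                "spindle_rel": summary.spindle_rel,
                "swd_rel": summary.swd_rel,
            })
    return pd.DataFrame(rows)
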