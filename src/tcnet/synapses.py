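"""Two-state kinetic receptor model for AMPA, GABA_A and GABA_B synapses.

A presynaptic spike at time ``t0`` releases a square transmitter pulse of
concentration ``C_max`` lasting ``C_dur`` milliseconds.  The fraction of open
receptor channels ``s`` relaxes toward ``s_inf = alpha*C_max/(alpha*C_max +
beta)`` with time constant ``tau_s = 1/(alpha*C_max + beta)`` while transmitter
is present, and decays as ``exp(-beta*t)`` afterwards.  The synaptic current is
``gbar * s * (V - E_syn)``.

Two systemic modifiers act on GABA_A synapses:

* a loss-of-function receptor mutation, modelled as a multiplicative scale
  ``gaba_scale`` in (0, 1] on the maximal conductance of GABA_A synapses onto
  cortical pyramidal cells (RS, IB, NRS);
* the neurosteroid allopregnanolone (ALLO), a positive allosteric modulator,
  modelled as a fixed transform of every GABA_A synapse:
  ``alpha x 1.58``, ``beta x 0.74``, ``gbar x 1.11``, ``C_dur x 1.14``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SynapseSpec",
    "SynapseState",
    "ALLO_FACTORS",
    "DEFAULT_E_SYN",
    "s_profile",
    "synaptic_current",
    "apply_allo",
    "apply_mutation",
]

#: Multiplicative parameter changes of a GABA_A synapse under physiological
#: allopregnanolone: binding rate up, unbinding rate down (longer decay),
#: slightly larger conductance and transmitter pulse.
ALLO_FACTORS = {"alpha": 1.58, "beta": 0.74, "gbar": 1.11, "C_dur": 1.14}

#: Reversal potentials (mV) per receptor type.
DEFAULT_E_SYN = {"AMPA": 0.0, "GABA_A": -80.0, "GABA_B": -95.0}

_RECEPTORS = ("AMPA", "GABA_A", "GABA_B")
_CORTICAL_PYRAMIDS = ("RS", "IB", "NRS")


@dataclass(frozen=True)
class SynapseSpec:
    """Parameters of one receptor-type connection class.

    Attributes
    ----------
    receptor : {"AMPA", "GABA_A", "GABA_B"}
    gbar : float
        Maximal synaptic conductance (uS), shared across a postsynaptic
        cell's in-degree (each edge carries ``gbar / n_in``).
    alpha : float
        Transmitter binding rate ((ms*mM)^-1).
    beta : float
        Unbinding rate (ms^-1); ``1/beta`` sets the post-pulse decay time.
    C_dur : float
        Transmitter pulse duration (ms); 0.3 ms for Control synapses.
    C_max : float
        Transmitter concentration during the pulse (mM).
    E_syn : float
        Reversal potential (mV).
    variant : {"Control", "post-ALLO"}
    gaba_scale : float
        Mutation scale on the maximal conductance, in (0, 1].
    pre_class, post_class : str or None
        Cell classes the projection links (used to validate modifiers).
    """

    receptor: str
    gbar: float
    alpha: float
    beta: float
    C_dur: float = 0.3
    C_max: float = 0.5
    E_syn: float | None = None
    variant: str = "Control"
    gaba_scale: float = 1.0
    pre_class: str | None = None
    post_class: str | None = None

    def __post_init__(self):
        if self.receptor not in _RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.E_syn is None:
            object.__setattr__(self, "E_syn", DEFAULT_E_SYN[self.receptor])
        if self.gbar < 0:
            raise ValueError("gbar must be non-negative")
        for name in ("alpha", "beta", "C_dur", "C_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.gaba_scale <= 1.0:
            raise ValueError("gaba_scale must lie in (0, 1]")
        if self.variant not in ("Control", "post-ALLO"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def s_inf(self) -> float:
        """Open fraction the pulse drives toward: alpha*C_max/(alpha*C_max+beta)."""
        ac = self.alpha * self.C_max
        return ac / (ac + self.beta)

    @property
    def tau_s(self) -> float:
        """Relaxation time constant during the pulse: 1/(alpha*C_max+beta) (ms)."""
        return 1.0 / (self.alpha * self.C_max + self.beta)

    @property
    def g_effective(self) -> float:
        """Maximal conductance after mutation scaling (uS)."""
        return self.gbar * self.gaba_scale


@dataclass
class SynapseState:
    """Dynamic state of one synapse: open fraction and pulse bookkeeping."""

    s: float = 0.0
    pulse_clock: float = math.inf  # ms since most recent presynaptic spike
    active: bool = False


def s_profile(spec: SynapseSpec, s0: float, t):
    """Closed-form open fraction ``t`` ms after a presynaptic spike.

    During the transmitter pulse (``t < C_dur``) the open fraction relaxes
    exponentially toward ``s_inf``; after pulse end it decays with rate
    ``beta`` from the pulse-end value.  Accepts scalar or array ``t``.
    """
    if not 0.0 <= s0 <= 1.0:
        raise ValueError("s0 must lie in [0, 1]")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    s_inf, tau = spec.s_inf, spec.tau_s
    in_pulse = s_inf + (s0 - s_inf) * np.exp(-t / tau)
    s_end = s_inf + (s0 - s_inf) * math.exp(-spec.C_dur / tau)
    after = s_end * np.exp(-spec.beta * (t - spec.C_dur))
    out = np.where(t < spec.C_dur, in_pulse, after)
    return float(out) if out.ndim == 0 else out


def synaptic_current(spec: SynapseSpec, s, V, n_in: int = 1):
    """Synaptic current ``(gbar/n_in) * gaba_scale * s * (V - E_syn)``.

    ``gbar`` in uS and ``V`` in mV give a current in nA (positive outward);
    the membrane equation converts it to a density and subtracts it.
    """
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("s must lie in [0, 1]")
    if n_in < 1:
        raise ValueError("n_in must be >= 1")
    out = (spec.g_effective / n_in) * s * (np.asarray(V, dtype=float) - spec.E_syn)
    return float(out) if out.ndim == 0 else out


def apply_allo(spec: SynapseSpec) -> SynapseSpec:
    """Return the post-ALLO variant of a Control GABA_A synapse.

    The transform is a one-shot modification of the receptor kinetics;
    applying it to a synapse that is already post-ALLO is an error, as is
    applying it to a non-GABA_A synapse (ALLO acts on the GABA_A receptor).
    """
    if spec.receptor != "GABA_A":
        raise ValueError("ALLO transform applies to GABA_A synapses only")
    if spec.variant != "Control":
        raise ValueError("synapse is already post-ALLO")
    return replace(
        spec,
        alpha=spec.alpha * ALLO_FACTORS["alpha"],
        beta=spec.beta * ALLO_FACTORS["beta"],
        gbar=spec.gbar * ALLO_FACTORS["gbar"],
        C_dur=spec.C_dur * ALLO_FACTORS["C_dur"],
        variant="post-ALLO",
    )


def apply_mutation(spec: SynapseSpec, fraction: float) -> SynapseSpec:
    """Scale a cortical-pyramidal GABA_A synapse to ``fraction`` of baseline.

    Models a loss-of-function GABA_A receptor-subunit mutation expressed in
    cortical pyramidal neurons of both layers; the maximal conductance is
    multiplied by ``fraction`` in (0, 1].
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if spec.receptor != "GABA_A":
        raise ValueError("mutation scaling applies to GABA_A synapses only")
    if spec.post_class is not None and spec.post_class not in _CORTICAL_PYRAMIDS:
        raise ValueError(
            "mutation scaling targets cortical pyramidal cells (RS, IB, NRS), "
            f"not {spec.post_class}"
        )
    return replace(spec, gaba_scale=fraction)
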