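# Methods

## The model

`tcnet` simulates a 475-cell thalamocortical network built from
single-compartment conductance-based neurons of six classes: layer-5
regular-spiking (RS, 25 cells by default) and intrinsically-bursting (IB, 75)
pyramids, layer-6 non-tufted regular-spiking pyramids (NRS, 75), deep
low-threshold-spiking interneurons (LTS, 100), thalamocortical relay cells
(TC, 100) and thalamic reticular cells (RE, 100).  Each membrane follows

    Cm dV/dt = I_hold - sum(I_ion) - sum(I_syn) + I_stim,

with every intrinsic current of the form `I = gbar * m^N * h^M * (V - E)` and
first-order voltage-dependent gating.  Cortical cells carry fast and
persistent Na, transient (Ka), slowly-inactivating (K2), delayed-rectifier
(Kdr), M-type (Km) and two Ca-gated K currents (Kc, Kahp), low- and
high-threshold Ca currents, an anomalous rectifier, and leak; TC cells carry
leak, K-leak, Na, K, the low-threshold Ca current I_T and the
hyperpolarization-activated cation current I_h; RE cells carry leak, Na, K
and a slower I_T.  Specific capacitance is 0.9 uF/cm^2 for the layer-5/6
pyramids and 1.0 uF/cm^2 for LTS/TC/RE.

Synapses use the two-state kinetic receptor model: a presynaptic spike at
`t0` releases transmitter at concentration `C_max = 0.5 mM` for
`C_dur = 0.3 ms`, and the open fraction obeys
`ds/dt = alpha*C*(1-s) - beta*s`, giving the closed form with
`s_inf = alpha*C_max/(alpha*C_max+beta)` and `tau_s = 1/(alpha*C_max+beta)`
during the pulse and exponential decay at rate `beta` afterwards.  Synaptic
current is `(gbar/n_in) * s * (V - E_syn)` per edge with `E_AMPA = 0 mV`,
`E_GABA_A = -80 mV`, `E_GABA_B = -95 mV`.  The per-projection maximal
conductances and the AMPA/GABA_A binding/unbinding rates are the fitted
values shipped in `tcnet.tables`.

Connectivity is one-dimensional: each class occupies a line; each
postsynaptic cell receives its `n_in` nearest presynaptic neighbors
(ties to the lower index, no wraparound, no self-edges), where

    n_in = clamp(min(base, ceil(base * n_pre / n_post)), 1, n_pre)

with `base = 11` inside cortex or thalamus and `base = 21` across them.
This rule reproduces the published in-degree table for the default 75-25
(nIB:nRS) layout exactly (an exhaustive test asserts all 24 entries) and
regenerates in-degrees for the 95-5, 5-95 and 50-50 layer-5 compositions.
Each edge carries `gbar/n_in`, so a cell's total inbound conductance per
projection is composition-independent.

Two disease/treatment axes modify GABA_A synapses only:

* **Cortical disinhibition** (GABA_A receptor-subunit mutation): the maximal
  conductance of GABA_A synapses onto cortical pyramids (RS, IB, NRS) is
  multiplied by a fraction in (0, 1]; 0.1 is the diseased state.
* **Allopregnanolone (ALLO)**: every GABA_A synapse, cortical and thalamic,
  is transformed by alpha x 1.58, beta x 0.74, gbar x 1.11, C_dur x 1.14
  (faster binding, ~35% longer decay, slightly larger conductance and pulse).

**Frontocortical enhancement** multiplies gbar of IB->IB, IB->NRS and
NRS->IB by (7, 5, 3), modelling the increased frontal connectivity observed
in treatment non-responders.

## Numerics

Gates and synaptic open fractions use exact-exponential updates; the
membrane potential uses an explicit update at `dt = 0.025 ms`.  Gate
steady states and update factors are tabulated on a 0.05 mV grid over
[-130, 70] mV with linear interpolation; transmitter-pulse boundaries that
fall inside a step are handled with an exact two-phase update.  Spikes are
upward 0 mV crossings with a 2 ms refractory merge.  Recordings are
downsampled to 0.1 ms (10 kHz).  The integrator aborts with a diagnostic if
any |V| exceeds 150 mV.  There is no noise process anywhere: runs are
bitwise reproducible, and a dt-halving test checks that reported peak
frequencies move by at most one 0.5-Hz PSD bin.

The protocol settles the network for 2 s, then injects 1 nA for 100 ms into
the five NRS cells nearest the line's center and records 6 s.  The test
suite uses 1.5 s + 4 s (still two full Welch segments) to keep runtimes
reasonable; `scripts/acceptance.py` uses the full protocol.

## Signal pipeline

The LFP is a point-source sum over a recorded subset (10 evenly
index-spaced cells per layer-5 population, configurable) of total
postsynaptic currents: `V_ext = (R_e/4pi) * sum_i I_i/r_i` with
`R_e = 230 Ohm cm`, cells 20 um apart on a line and the electrode 50 um
from its center.  The trace is linearly detrended, band-passed 1-15 Hz
(order-4 Butterworth, zero-phase), and analysed with Welch's method (Hann
window, 20,000-sample segments, 1,000-sample overlap at 10 kHz; 0.5 Hz
bins).  Band powers are trapezoidal integrals over 2.5-5 Hz (SWD) and
7-10 Hz (spindle), relative to total 1-15 Hz power; the peak frequency is
the argmax bin in 1-15 Hz (ties to the lower bin).  A state is labelled
*spindle* (peak in 7-10 Hz and spindle relative power dominant), *SWD*
(peak in 2.5-5 Hz and SWD relative power dominant) or *intermediate*.

## Calibration choices and their rationale

The published description fixes the network architecture, synaptic
parameter tables, stimulus, LFP geometry and spectral pipeline, but the
per-channel gating kinetics, conductance densities, holding currents, cell
geometry, calcium-pool constants and GABA_B kinetics live in supplementary
material that is not available here.  The package therefore implements the
cited parent models -- a Traub-family single-compartment cortical reduction
and the classical Destexhe TC/RE thalamic cells -- and calibrates the open
constants itself.  All of these sit in a registry/configuration layer so
alternative values can be dropped in without touching the integrator.

* **GABA_B kinetics.** The fitted tables list one (alpha, beta) pair per
  connection, assigned here to the AMPA/GABA_A component.  Giving GABA_B
  the same millisecond-scale rates makes it dynamically indistinguishable
  from GABA_A, and the model then has no slow inhibition at all: in that
  variant cortical disinhibition *speeds up* the network rather than
  producing 2.5-5 Hz discharges.  GABA_B components therefore use slow
  two-state kinetics, alpha = 0.09 (ms mM)^-1 and beta = 0.0053 ms^-1
  (~190 ms decay, the scale of measured GABA_B IPSCs).  This is the one
  deliberate departure from the shared-rate reading of the tables.
* **Compartment area.** Injected currents and uS-scale synaptic
  conductances are converted to densities by the compartment area.  A
  100 um cylinder makes the fixed synaptic conductances overwhelm the
  intrinsic currents (every population fires 90-200 Hz); the default is a
  173 um cylinder (9.42e-4 cm^2), which restores physiological rates.
  Config-overridable.
* **Holding currents.** Cortical I_hold is calibrated at build time by
  bisection so each isolated cell rests at its target (-65 mV for RS, NRS,
  LTS).  The IB cell is given -72 mV: with its burst-generating persistent
  Na density it has no quiescent state at -65 mV.  TC and RE cells carry no
  holding current; TC rests near -62 mV and discharges spontaneously
  (the source of ongoing network activity), RE rests near -75 mV.
* **Firing phenotypes.** Densities per class were tuned so that RS/NRS
  cells spike regularly with adaptation, IB cells fire 2-4 spike bursts
  (persistent Na + high-threshold Ca depolarization terminated by the fast
  Ca-gated K current, whose pool saturation is raised so several spikes of
  Ca influx are needed to stop a cluster), LTS interneurons fire rebound
  bursts after hyperpolarization (low-threshold Ca), and TC cells produce
  rebound bursts after release from hyperpolarization that vanish when the
  low-threshold Ca current is removed (asserted in tests).
* **Calcium pool.** First-order, 100 ms decay (80 ms for IB), driven by
  the Ca currents; Kc conductance saturates with pool level, Kahp
  activation is proportional to it.
* **Classifier.** A cell is "bursting" when >= 30% of its inter-spike
  intervals are under 15 ms while intervals over 50 ms also occur.

## Where the calibration lands

With these choices the full pipeline produces, under the standard protocol:
a 5-6 Hz oscillation at 100% cortical GABA_A; a 5 Hz SWD-labelled state at
10% (the published diseased peak is 5 Hz); SWD-band relative power that
rises as inhibition is removed in every composition; ALLO consistently
*reduces* SWD-band power at baseline connectivity (e.g. 0.16 -> 0.06 for
75-25) without fully restoring a 7-10 Hz spindle peak; and under (7, 5, 3)
frontocortical enhancement ALLO *fails* to reduce SWD power in the 50-50
network (0.29 -> 0.36) -- the directional form of the non-resolution
result.  The healthy-state peak stays near 5.5 Hz rather than the published
7-7.5 Hz: the spindle pacing frequency is controlled by the unpublished
thalamic kinetics and densities, and the acceptance suite documents these
deviations explicitly rather than hiding them.  All numbers above are
recomputed by `scripts/acceptance.py` and the test suite at run time.

## What the synthetic fixtures do and do not show

Unit tests validate the signal pipeline against deterministic tone
mixtures, seeded band-limited noise and synthetic spike trains, and the
synapse closed form against a brute-force Runge-Kutta oracle.  These
fixtures establish correctness of the analysis machinery, not realism of
the network dynamics; network-level claims are tested only through full
simulations.

## Known limitations

* Gating kinetics and densities are this package's calibration of the
  cited parent models, not the original fitted set; peak frequencies shift
  accordingly (see above).
* GABA_B is a linear two-state channel; the G-protein cascade that makes
  real GABA_B responses burst-selective is out of scope, which removes one
  nonlinearity believed to sharpen the spindle/SWD switch.
* One-dimensional topology, zero conduction delays, no noise, no
  multi-compartment morphology, no short-term plasticity.
* The network sits near a bistable boundary between an active oscillating
  state and a quiescent state; some parameter neighborhoods collapse to
  quiescence, which is why the calibration is shipped as explicit
  configuration rather than free knobs.
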