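"""Canonical synaptic parameter tables of the thalamocortical network.

The network couples six cell classes (layer-5 RS and IB pyramids, layer-6 NRS
pyramids, deep LTS interneurons, thalamocortical relay TC and thalamic
reticular RE cells) through AMPA, GABA_A and GABA_B synapses.  For every
projection the model needs a maximal conductance ``gbar`` (uS), a transmitter
binding rate ``alpha`` ((ms*mM)^-1) and an unbinding rate ``beta`` (ms^-1).
These values were fitted to make the default network express spindle
oscillations and are treated as inputs here.

Projections between two cortical classes or two thalamic classes use a
connection radius of 11 index units; projections that cross between cortex and
thalamus use 21.

The fitted parameter set lists one (alpha, beta) pair per pre->post
connection.  Those rates are assigned to the AMPA or GABA_A component.
GABA_B components (LTS->pyramidal, RE->TC) carry their own maximal
conductance but use slow receptor kinetics (alpha = 0.09 (ms*mM)^-1,
beta = 0.0053 ms^-1, decay ~190 ms): a GABA_B channel that merely shared
its GABA_A partner's millisecond-scale rates would be indistinguishable
from a slightly more hyperpolarizing GABA_A synapse and could not supply
the slow inhibition that separates 2.5-5 Hz discharges from 7-10 Hz
spindles.  The slow rates are this package's calibration choice for the
unresolved GABA_B kinetics.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CORTICAL_CLASSES = ("RS", "IB", "NRS", "LTS")
THALAMIC_CLASSES = ("TC", "RE")
CELL_CLASSES = CORTICAL_CLASSES + THALAMIC_CLASSES

#: Default population sizes: 25 layer-5 RS, 75 layer-5 IB, 75 layer-6 NRS,
#: 100 deep LTS interneurons, 100 TC relay cells, 100 RE reticular cells.
DEFAULT_COUNTS = {"RS": 25, "IB": 75, "NRS": 75, "LTS": 100, "TC": 100, "RE": 100}

#: Slow GABA_B receptor kinetics (decay ~190 ms); see module docstring.
GABA_B_ALPHA = 0.09  # (ms*mM)^-1
GABA_B_BETA = 0.0053  # ms^-1

# (pre, post, receptor, gbar uS, alpha (ms*mM)^-1, beta ms^-1)
_SYNAPSE_ROWS = [
    # AMPA: intracortical
    ("RS", "RS", "AMPA", 0.3, 0.05, 0.15),
    ("RS", "IB", "AMPA", 0.7, 0.05, 0.05),
    ("RS", "NRS", "AMPA", 0.3, 0.1, 0.01),
    ("RS", "LTS", "AMPA", 0.1, 0.5, 0.2),
    ("IB", "RS", "AMPA", 1.0, 0.1, 0.15),
    ("IB", "IB", "AMPA", 0.3, 0.1, 0.05),
    ("IB", "NRS", "AMPA", 0.05, 0.1, 0.01),
    ("IB", "LTS", "AMPA", 0.08, 0.05, 0.08),
    ("NRS", "RS", "AMPA", 0.1, 0.05, 0.05),
    ("NRS", "IB", "AMPA", 0.3, 0.1, 0.01),
    ("NRS", "NRS", "AMPA", 2.0, 0.05, 0.03),
    ("NRS", "LTS", "AMPA", 0.2, 0.625, 0.109),
    # AMPA: corticothalamic (layer 6 is the only cortical output to thalamus)
    ("NRS", "TC", "AMPA", 0.02, 0.75, 0.3),
    ("NRS", "RE", "AMPA", 2.4, 0.8, 0.09),
    # AMPA: thalamocortical and intrathalamic
    ("TC", "RS", "AMPA", 1.0, 1.0, 0.15),
    ("TC", "IB", "AMPA", 0.7, 1.0, 0.15),
    ("TC", "NRS", "AMPA", 1.2, 0.07, 0.006),
    ("TC", "LTS", "AMPA", 0.4, 0.149, 0.048),
    ("TC", "RE", "AMPA", 0.2, 0.94, 0.18),
    # GABA_A: LTS is the sole cortical inhibitory source
    ("LTS", "RS", "GABA_A", 0.09, 0.1, 0.2),
    ("LTS", "IB", "GABA_A", 0.1, 0.05, 0.7),
    ("LTS", "NRS", "GABA_A", 0.75, 0.1, 0.01),
    ("RE", "TC", "GABA_A", 0.02, 20.0, 0.162),
    ("RE", "RE", "GABA_A", 0.2, 20.0, 0.162),
    # GABA_B: own gbar, slow receptor kinetics (see module docstring)
    ("LTS", "RS", "GABA_B", 0.03, GABA_B_ALPHA, GABA_B_BETA),
    ("LTS", "IB", "GABA_B", 0.03, GABA_B_ALPHA, GABA_B_BETA),
    ("LTS", "NRS", "GABA_B", 0.03, GABA_B_ALPHA, GABA_B_BETA),
    ("RE", "TC", "GABA_B", 0.04, GABA_B_ALPHA, GABA_B_BETA),
]


def synapse_table() -> pd.DataFrame:
    """Long-form table of every projection: one row per (pre, post, receptor)."""
    return pd.DataFrame(
        _SYNAPSE_ROWS, columns=["pre", "post", "receptor", "gbar", "alpha", "beta"]
    )


def parameter_matrix(parameter: str, receptor: str | None = None) -> pd.DataFrame:
    """Pivot one parameter into a pre x post matrix (NaN = no projection).

    Parameters
    ----------
    parameter : {"gbar", "alpha", "beta"}
    receptor : optionally restrict to one receptor type.
    """
    tab = synapse_table()
    if receptor is not None:
        tab = tab[tab["receptor"] == receptor]
    else:
        # collapse dual-receptor pairs onto the GABA_A/AMPA row
        tab = tab[tab["receptor"] != "GABA_B"]
    return tab.pivot(index="pre", columns="post", values=parameter).reindex(
        index=list(CELL_CLASSES), columns=list(CELL_CLASSES)
    )


def base_radius(pre: str, post: str) -> int:
    """Connection radius in index units: 11 within cortex or within thalamus,
    21 between cortex and thalamus."""
    pre_cortical = pre in CORTICAL_CLASSES
    post_cortical = post in CORTICAL_CLASSES
    return 11 if pre_cortical == post_cortical else 21


def write_tables(directory: str | Path) -> list[Path]:
    """Export the synaptic parameter set as TSV files (one per parameter,
    plus the long-form master table)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    path = directory / "synapses.tsv"
    synapse_table().to_csv(path, sep="\t", index=False)
    written.append(path)
    for parameter in ("gbar", "alpha", "beta"):
        path = directory / f"{parameter}.tsv"
        parameter_matrix(parameter).to_csv(path, sep="\t")
        written.append(path)
    return written


def read_synapse_table(path: str | Path) -> pd.DataFrame:
    """Read a long-form synapse table written by :func:`write_tables`."""
    tab = pd.read_csv(path, sep="\t")
    required = {"pre", "post", "receptor", "gbar", "alpha", "beta"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"synapse table missing columns: {sorted(missing)}")
    return tab
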