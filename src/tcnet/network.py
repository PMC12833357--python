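"""Population layout, connectivity and network construction.

Each cell class occupies a one-dimensional line; cell ``i`` of a class with
``n`` cells sits at normalized position ``i/(n-1)``.  A postsynaptic cell
receives input from the ``n_in`` presynaptic cells nearest to it in
normalized position (ties broken toward lower index, no wraparound, no
self-edges in recurrent projections).  The per-projection in-degree follows

    n_in = clamp(min(base, ceil(base * n_pre / n_post)), 1, n_pre)

with ``base = 11`` within cortex or within thalamus and ``base = 21`` for
projections crossing between them; for the default 75-25 (nIB:nRS) layout
this rule reproduces the published in-degree table exactly and is used to
regenerate in-degrees for other layer-5 compositions.  Each edge carries the
weight ``gbar / n_in`` so that a cell's summed inbound conductance for one
projection equals ``gbar`` regardless of composition.

Frontocortical enhancement multiplies the maximal conductances of the
IB->IB, IB->NRS and NRS->IB projections by configurable factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import tables
from .synapses import SynapseSpec, apply_allo, apply_mutation

__all__ = [
    "PopulationLayout",
    "ProjectionSpec",
    "NetworkConfig",
    "Network",
    "in_degree",
    "connect",
    "apply_enhancement",
    "build_network",
]

_ENHANCED_PROJECTIONS = (("IB", "IB"), ("IB", "NRS"), ("NRS", "IB"))


@dataclass(frozen=True)
class PopulationLayout:
    """Cell counts per class; layer 5 holds IB + RS = 100 cells."""

    counts: dict

    def __post_init__(self):
        for cls in tables.CELL_CLASSES:
            if self.counts.get(cls, 0) < 1:
                raise ValueError(f"population {cls} must have at least one cell")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def positions(self, cls: str) -> np.ndarray:
        """Normalized positions on [0, 1] for one class."""
        n = self.counts[cls]
        if n == 1:
            return np.array([0.5])
        return np.arange(n) / (n - 1)

    @classmethod
    def default(cls, n_ib: int = 75, n_rs: int = 25) -> "PopulationLayout":
        if n_ib + n_rs != 100:
            raise ValueError("layer 5 must hold 100 cells (n_ib + n_rs)")
        counts = dict(tables.DEFAULT_COUNTS)
        counts["IB"], counts["RS"] = n_ib, n_rs
        return cls(counts)


def in_degree(base: int, n_pre: int, n_post: int) -> int:
    """Per-postsynaptic-cell in-degree for one projection.

    ``min(base, ceil(base * n_pre / n_post))`` clamped to ``[1, n_pre]``:
    projections from smaller onto larger populations are thinned in
    proportion to the size ratio, capped at the connection radius.
    """
    if n_pre < 1 or n_post < 1:
        raise ValueError("population sizes must be >= 1")
    n = min(base, math.ceil(base * n_pre / n_post))
    return max(1, min(n, n_pre))


@dataclass
class ProjectionSpec:
    """One receptor-type connection class between two populations."""

    pre_class: str
    post_class: str
    synapse: SynapseSpec
    base_radius: int
    n_in: int
    enhancement: float = 1.0
    edges: np.ndarray | None = None  # (n_edges, 2): [post_idx, pre_idx]

    @property
    def weight(self) -> float:
        """Per-edge conductance: gbar / n_in x enhancement x mutation scale (uS)."""
        return self.synapse.g_effective * self.enhancement / self.n_in


@dataclass
class NetworkConfig:
    """Declarative description of one network variant.

    ``n_ib``/``n_rs`` set the layer-5 composition; ``cortical_gaba_fraction``
    scales GABA_A conductance onto cortical pyramids (1.0 = healthy, 0.1 =
    diseased); ``allo`` applies the post-ALLO transform to every GABA_A
    synapse; ``enhancement`` holds the (F_IBIB, F_IBNRS, F_NRSIB) factors.
    """

    n_ib: int = 75
    n_rs: int = 25
    cortical_gaba_fraction: float = 1.0
    allo: bool = False
    enhancement: tuple = (1.0, 1.0, 1.0)
    synapse_table: pd.DataFrame | None = None
    g_overrides: dict = field(default_factory=dict)  # per-class channel densities
    area_cm2: float | None = None  # compartment area; None -> class default

    def __post_init__(self):
        if not 0.0 < self.cortical_gaba_fraction <= 1.0:
            raise ValueError("cortical_gaba_fraction must lie in (0, 1]")
        if len(self.enhancement) != 3 or any(f < 1 for f in self.enhancement):
            raise ValueError("enhancement must be three factors >= 1")

    @property
    def label(self) -> str:
        parts = [f"{self.n_ib}-{self.n_rs}",
                 f"gaba{int(round(100 * self.cortical_gaba_fraction))}"]
        if self.allo:
            parts.append("ALLO")
        if tuple(self.enhancement) != (1.0, 1.0, 1.0):
            parts.append("F" + "-".join(f"{f:g}" for f in self.enhancement))
        return "_".join(parts)


@dataclass
class Network:
    """A realized network: layout plus fully wired projections."""

    config: NetworkConfig
    layout: PopulationLayout
    projections: list

    @property
    def n_cells(self) -> int:
        return self.layout.total

    def projection(self, pre: str, post: str, receptor: str) -> ProjectionSpec:
        for p in self.projections:
            if (p.pre_class, p.post_class, p.synapse.receptor) == (pre, post, receptor):
                return p
        raise KeyError(f"no projection {pre}->{post} ({receptor})")

    def edge_table(self) -> pd.DataFrame:
        """All edges as a flat table (pre_class, pre_idx, post_class,
        post_idx, receptor, weight)."""
        rows = []
        for p in self.projections:
            for post_i, pre_j in p.edges:
                rows.append((p.pre_class, int(pre_j), p.post_class, int(post_i),
                             p.synapse.receptor, p.weight))
        return pd.DataFrame(
            rows, columns=["pre_class", "pre_idx", "post_class", "post_idx",
                           "receptor", "weight"]
        )


def connect(pre_positions: np.ndarray, post_positions: np.ndarray, n_in: int,
            same_class: bool = False) -> np.ndarray:
    """Edge list giving every postsynaptic cell its ``n_in`` nearest
    presynaptic neighbors in normalized position.

    Ties break toward the lower presynaptic index; recurrent projections
    (``same_class``) exclude the self-edge.  Returns an (n_post * n_in, 2)
    integer array of [post_idx, pre_idx] rows, deterministic by construction.
    """
    n_pre = len(pre_positions)
    if n_in > (n_pre - 1 if same_class else n_pre):
        raise ValueError(f"n_in={n_in} exceeds available presynaptic cells")
    edges = np.empty((len(post_positions) * n_in, 2), dtype=np.int64)
    k = 0
    for post_i, x in enumerate(post_positions):
        d = np.abs(pre_positions - x)
        if same_class:
            d = d.copy()
            d[post_i] = np.inf
        # stable sort on distance -> ties resolve toward lower index
        order = np.argsort(d, kind="stable")[:n_in]
        for pre_j in sorted(order):
            edges[k] = (post_i, pre_j)
            k += 1
    return edges


def apply_enhancement(synapse_table: pd.DataFrame,
                      factors: tuple) -> pd.DataFrame:
    """Scale gbar of the frontocortical projections IB->IB, IB->NRS, NRS->IB.

    ``factors`` = (F_IBIB, F_IBNRS, F_NRSIB), each >= 1.  All other
    projections are untouched; factors of 1 return an identical table.
    """
    if any(f < 1 for f in factors):
        raise ValueError("enhancement factors must be >= 1")
    tab = synapse_table.copy()
    for (pre, post), factor in zip(_ENHANCED_PROJECTIONS, factors):
        mask = (tab["pre"] == pre) & (tab["post"] == post)
        if not mask.any():
            raise KeyError(f"projection {pre}->{post} not present in table")
        tab.loc[mask, "gbar"] *= factor
    return tab


def build_network(config: NetworkConfig) -> Network:
    """Realize the full projection set for one configuration.

    Applies, in order: frontocortical enhancement of the conductance table,
    construction of one ProjectionSpec per (pre, post, receptor) row,
    GABA_A mutation scaling on cortical pyramidal targets, and (optionally)
    the ALLO transform of every GABA_A synapse.  Deterministic: identical
    configs yield identical edge lists and weights.
    """
    layout = PopulationLayout.default(config.n_ib, config.n_rs)
    tab = config.synapse_table if config.synapse_table is not None \
        else tables.synapse_table()
    tab = apply_enhancement(tab, config.enhancement)

    projections = []
    for row in tab.itertuples(index=False):
        base = tables.base_radius(row.pre, row.post)
        n_pre, n_post = layout.counts[row.pre], layout.counts[row.post]
        n_in = in_degree(base, n_pre, n_post)
        if row.pre == row.post and n_pre > 1:
            # recurrent projections exclude the self-edge; tiny populations
            # cannot supply more neighbors than n_pre - 1
            n_in = min(n_in, n_pre - 1)
        spec = SynapseSpec(
            receptor=row.receptor, gbar=row.gbar, alpha=row.alpha, beta=row.beta,
            pre_class=row.pre, post_class=row.post,
        )
        if (spec.receptor == "GABA_A" and row.post in ("RS", "IB", "NRS")
                and config.cortical_gaba_fraction < 1.0):
            spec = apply_mutation(spec, config.cortical_gaba_fraction)
        if config.allo and spec.receptor == "GABA_A":
            spec = apply_allo(spec)
        edges = connect(
            layout.positions(row.pre), layout.positions(row.post), n_in,
            same_class=(row.pre == row.post),
        )
        # enhancement is already folded into gbar via the table; keep the
        # ProjectionSpec factor at 1 so weights are not double-scaled
        projections.append(
            ProjectionSpec(row.pre, row.post, spec, base, n_in, 1.0, edges)
        )
    return Network(config, layout, projections)
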