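"""Signed bipartite grazer x ASV networks built from significant effects.

For each interaction mode (trophic, non-trophic) and sign (positive,
negative) we assemble one bipartite network whose rows are grazer
species and whose columns are the ASVs with at least one significant
edge of that mode and sign. Edge weight is |DI|; the sign lives in
network metadata so every downstream metric consumes non-negative
"interaction frequencies", as the weighted nestedness definitions
assume. Grazer rows are always retained, even when empty, so the same
five rows stay comparable across the four networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["BipartiteNetwork", "build_networks", "binarize", "to_graph"]

NETWORK_KEYS = (
    ("trophic", "positive"),
    ("trophic", "negative"),
    ("non_trophic", "positive"),
    ("non_trophic", "negative"),
)


@dataclass
class BipartiteNetwork:
    """Grazers x ASVs non-negative weight matrix for one (mode, sign)."""

    weights: pd.DataFrame  # grazers x ASVs, |DI| of significant edges, 0 = absent
    mode: str
    sign: str
    family: pd.Series | None = None  # per-column family annotation
    meta: dict = field(default_factory=dict)

    @property
    def grazers(self) -> list:
        return list(self.weights.index)

    @property
    def asv_ids(self) -> list:
        return list(self.weights.columns)

    @property
    def n_edges(self) -> int:
        return int((self.weights.to_numpy() > 0).sum())

    @property
    def is_empty(self) -> bool:
        return self.n_edges == 0

    def edge_set(self) -> frozenset:
        gi, ai = np.nonzero(self.weights.to_numpy() > 0)
        return frozenset(
            (self.weights.index[i], self.weights.columns[j]) for i, j in zip(gi, ai)
        )


def build_networks(effects: pd.DataFrame, taxonomy: pd.DataFrame | None = None) -> dict:
    """Four signed networks (TI+, TI-, NTI+, NTI-) from an effect table.

    Edge (g, a) enters network (mode, sign) iff the effect is flagged
    significant, has the matching mode, and sign(di_mean) = sign;
    its weight is |di_mean|. ASVs without a significant edge in a given
    network are dropped from that network's columns; all grazers are kept.
    """
    required = {"grazer", "target", "mode", "di_mean", "significant"}
    missing = required - set(effects.columns)
    if missing:
        raise ValueError(f"effect table missing column(s): {sorted(missing)}")
    grazers = sorted(effects["grazer"].unique())
    out = {}
    for mode, sign in NETWORK_KEYS:
        sub = effects[
            (effects["mode"] == mode)
            & effects["significant"]
            & ((effects["di_mean"] > 0) if sign == "positive" else (effects["di_mean"] < 0))
        ]
        wide = (
            sub.assign(weight=sub["di_mean"].abs())
            .pivot_table(index="grazer", columns="target", values="weight", fill_value=0.0)
            .reindex(index=grazers, fill_value=0.0)
        )
        wide = wide.loc[:, wide.sum(axis=0) > 0] if wide.shape[1] else wide
        fam = None
        if taxonomy is not None and "family" in taxonomy.columns:
            fam = taxonomy["family"].reindex(wide.columns)
        net = BipartiteNetwork(
            weights=wide.astype(float), mode=mode, sign=sign, family=fam,
            meta={"n_edges": int((wide.to_numpy() > 0).sum())},
        )
        if net.is_empty:
            warnings.warn(f"empty network for mode={mode!r} sign={sign!r}", stacklevel=2)
        out[(mode, sign)] = net
    return out


def binarize(network) -> pd.DataFrame:
    """0/1 presence matrix: entry 1 iff weight > 0. Idempotent."""
    w = network.weights if isinstance(network, BipartiteNetwork) else pd.DataFrame(network)
    return (w > 0).astype(int)


def to_graph(network: BipartiteNetwork) -> nx.Graph:
    """networkx bipartite graph with weight/sign/mode edge attributes."""
    g = nx.Graph()
    g.add_nodes_from(network.grazers, bipartite="grazer")
    for a in network.asv_ids:
        fam = None
        if network.family is not None:
            fam = network.family.get(a)
        g.add_node(a, bipartite="asv", **({"family": fam} if fam is not None else {}))
    arr = network.weights.to_numpy()
    for i, j in zip(*np.nonzero(arr > 0)):
        g.add_edge(
            network.grazers[i],
            network.asv_ids[j],
            weight=float(arr[i, j]),
            sign=network.sign,
            mode=network.mode,
        )
    return g
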