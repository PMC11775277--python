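"""EM-connectivity summaries from synapse tables.

A :class:`SynapseTable` holds weighted directed edges between annotated
neurons (cell class, hemisphere side, hemilateral partner, skeleton node
count, neuromere).  The analyses are:

* fraction of total input a target (pair) receives, per partner or per
  class, with skeletons below the reconstruction threshold pooled into an
  ``unreconstructed`` bucket that stays in the denominator;
* strong-partner filtering: a hemilateral partner pair is a strong partner
  when any single member-to-member connection carries at least 3 synapses;
* fragment flagging: node count < 1,500 marks a neuron as not
  reconstructed up to recognition, except sensory neurons;
* directed synaptic hop distances over the ≥3-synapse graph, and grouping
  of motor neurons by their distance signature from a set of seed neurons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SynapseTable",
    "fraction_of_input",
    "strong_partners",
    "flag_fragments",
    "synaptic_distance",
    "motor_group",
    "NODE_THRESHOLD",
    "MIN_SYNAPSES",
]

NODE_THRESHOLD = 1500  # skeletons below this node count are fragments
MIN_SYNAPSES = 3  # strong-partner synapse threshold

CONNECTION_TYPES = {"axo-dendritic", "axo-axonic", "dendro-dendritic", "unknown"}
NEURON_CLASSES = {
    "brain",
    "SEZ",
    "sensory",
    "local",
    "ascending",
    "descending",
    "motor",
    "fragment-candidate",
}

_EDGE_COLS = ["pre_id", "post_id", "synapse_count", "connection_type"]
_NEURON_COLS = ["id", "name", "cell_class", "side", "partner_id", "node_count", "neuromere"]


@dataclass
class SynapseTable:
    """Weighted directed synapse edges plus neuron metadata."""

    edges: pd.DataFrame
    neurons: pd.DataFrame

    def __post_init__(self) -> None:
        for col in _EDGE_COLS:
            if col not in self.edges.columns:
                raise ValueError(f"edges table missing column {col!r}")
        for col in _NEURON_COLS:
            if col not in self.neurons.columns:
                raise ValueError(f"neurons table missing column {col!r}")
        if len(self.edges):
            counts = self.edges["synapse_count"]
            if (counts < 1).any() or (counts != counts.astype(int)).any():
                raise ValueError("synapse_count must be integers >= 1")
            known = set(self.neurons["id"])
            dangling = set(self.edges["pre_id"]) | set(self.edges["post_id"])
            missing = dangling - known
            if missing:
                raise ValueError(f"edges reference unknown neurons: {sorted(missing)[:5]}")
        bad_cls = set(self.neurons["cell_class"]) - NEURON_CLASSES
        if bad_cls:
            raise ValueError(f"unknown neuron classes: {sorted(bad_cls)}")

    def neuron(self, nid: str) -> pd.Series:
        row = self.neurons[self.neurons["id"] == nid]
        if row.empty:
            raise KeyError(nid)
        return row.iloc[0]

    def pair_of(self, nid: str) -> list[str]:
        """The hemilateral pair containing ``nid`` (singleton if unpaired)."""
        row = self.neuron(nid)
        partner = row["partner_id"]
        if isinstance(partner, str) and partner and partner in set(self.neurons["id"]):
            return sorted({nid, partner})
        return [nid]

    @classmethod
    def from_csv(cls, edges_path: str | Path, neurons_path: str | Path) -> "SynapseTable":
        return cls(
            edges=pd.read_csv(edges_path),
            neurons=pd.read_csv(neurons_path),
        )

    def to_csv(self, edges_path: str | Path, neurons_path: str | Path) -> None:
        self.edges.to_csv(edges_path, index=False)
        self.neurons.to_csv(neurons_path, index=False)

    @classmethod
    def from_suffix_convention(cls, edges: pd.DataFrame, neurons: pd.DataFrame) -> "SynapseTable":
        """Loader for exports using the ``name_l`` / ``name_r`` id suffix
        convention: fills ``side`` and ``partner_id`` from the id."""
        neurons = neurons.copy()
        ids = set(neurons["id"])
        sides, partners = [], []
        for nid in neurons["id"]:
            if nid.endswith("_l") or nid.endswith("_r"):
                side = nid[-1]
                other = nid[:-1] + ("r" if side == "l" else "l")
                sides.append(side)
                partners.append(other if other in ids else "")
            else:
                sides.append("unknown")
                partners.append("")
        neurons["side"] = sides
        neurons["partner_id"] = partners
        return cls(edges=edges, neurons=neurons)


def flag_fragments(table: SynapseTable, node_threshold: int = NODE_THRESHOLD) -> SynapseTable:
    """Annotate neurons with ``is_fragment``: node count strictly below the
    threshold and class not sensory (sensory skeletons are exempt)."""
    neurons = table.neurons.copy()
    neurons["is_fragment"] = (neurons["node_count"] < node_threshold) & (
        neurons["cell_class"] != "sensory"
    )
    return SynapseTable(edges=table.edges, neurons=neurons)


def fraction_of_input(
    table: SynapseTable,
    target_ids: list[str] | str,
    group_by: str = "partner",
    node_threshold: int = NODE_THRESHOLD,
    connection_types: list[str] | None = None,
) -> pd.Series:
    """Fraction of the target's total input synapses per group.

    ``group_by="partner"`` groups by presynaptic hemilateral pair (by
    neuron ``name``); ``group_by="class"`` groups by presynaptic cell
    class.  Fragment skeletons are pooled into an ``unreconstructed``
    bucket in both modes but always stay in the denominator, so the
    fractions sum to 1.  ``connection_types`` restricts the analysis to a
    subset of synapse types (e.g. ``["axo-axonic"]``); the default pools
    all types.
    """
    if isinstance(target_ids, str):
        target_ids = [target_ids]
    if group_by not in ("partner", "class"):
        raise ValueError("group_by must be 'partner' or 'class'")
    flagged = flag_fragments(table, node_threshold)
    incoming = flagged.edges[flagged.edges["post_id"].isin(target_ids)]
    if connection_types is not None:
        incoming = incoming[incoming["connection_type"].isin(connection_types)]
    if incoming.empty:
        raise ValueError(f"targets {target_ids} have no incoming synapses")
    meta = flagged.neurons.set_index("id")
    pre = meta.loc[incoming["pre_id"]]
    frag = pre["is_fragment"].to_numpy() | (pre["cell_class"] == "fragment-candidate").to_numpy()
    if group_by == "partner":
        keys = np.where(frag, "unreconstructed", pre["name"].to_numpy())
    else:
        keys = np.where(frag, "unreconstructed", pre["cell_class"].to_numpy())
    totals = (
        pd.DataFrame({"group": keys, "count": incoming["synapse_count"].to_numpy()})
        .groupby("group")["count"]
        .sum()
    )
    return (totals / totals.sum()).sort_values(ascending=False)


def strong_partners(
    table: SynapseTable,
    pair_ids: list[str] | str,
    direction: str = "down",
    min_synapses: int = MIN_SYNAPSES,
) -> pd.DataFrame:
    """Hemilateral partner pairs strongly connected to a seed pair.

    A partner pair qualifies when the maximum synapse count on any single
    seed-member ↔ partner-member connection (in the stated direction) is at
    least ``min_synapses``.  Returns one row per qualifying partner pair
    with its member ids and the maximum count.
    """
    if isinstance(pair_ids, str):
        pair_ids = [pair_ids]
    known = set(table.neurons["id"])
    unknown = set(pair_ids) - known
    if unknown:
        raise KeyError(f"unknown neuron ids: {sorted(unknown)}")
    if direction == "down":
        edges = table.edges[table.edges["pre_id"].isin(pair_ids)]
        partner_col = "post_id"
    elif direction == "up":
        edges = table.edges[table.edges["post_id"].isin(pair_ids)]
        partner_col = "pre_id"
    else:
        raise ValueError("direction must be 'up' or 'down'")
    if edges.empty:
        return pd.DataFrame(columns=["partner_name", "members", "max_synapses"])
    meta = table.neurons.set_index("id")
    rows = {}
    for pid, sub in edges.groupby(partner_col):
        name = meta.loc[pid, "name"]
        best = int(sub.groupby([("pre_id" if direction == "down" else "post_id"), partner_col])[
            "synapse_count"
        ].sum().max())
        if name not in rows or best > rows[name]["max_synapses"]:
            members = table.pair_of(pid)
            rows[name] = {"partner_name": name, "members": members, "max_synapses": best}
        else:
            rows[name]["members"] = sorted(set(rows[name]["members"]) | set(table.pair_of(pid)))
    df = pd.DataFrame([r for r in rows.values() if r["max_synapses"] >= min_synapses])
    if df.empty:
        return pd.DataFrame(columns=["partner_name", "members", "max_synapses"])
    return df.sort_values("max_synapses", ascending=False).reset_index(drop=True)


def _filtered_graph(table: SynapseTable, min_synapses: int) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(table.neurons["id"])
    agg = table.edges.groupby(["pre_id", "post_id"])["synapse_count"].sum()
    for (pre, post), cnt in agg.items():
        if cnt >= min_synapses:
            g.add_edge(pre, post)
    return g


def synaptic_distance(
    table: SynapseTable,
    source_ids: list[str] | str,
    target_ids: list[str] | str,
    min_synapses: int = MIN_SYNAPSES,
) -> dict[str, float]:
    """Shortest directed hop count from any source to each target over the
    graph of connections carrying at least ``min_synapses`` synapses;
    ``inf`` where unreachable."""
    if isinstance(source_ids, str):
        source_ids = [source_ids]
    if isinstance(target_ids, str):
        target_ids = [target_ids]
    g = _filtered_graph(table, min_synapses)
    out: dict[str, float] = {}
    lengths: dict[str, float] = {}
    for s in source_ids:
        if s not in g:
            raise KeyError(f"unknown source {s!r}")
        for node, d in nx.single_source_shortest_path_length(g, s).items():
            if node not in lengths or d < lengths[node]:
                lengths[node] = d
    for tgt in target_ids:
        if tgt not in g:
            raise KeyError(f"unknown target {tgt!r}")
        out[tgt] = float(lengths.get(tgt, np.inf))
    return out


def motor_group(
    table: SynapseTable,
    seeds: dict[str, list[str]],
    min_synapses: int = MIN_SYNAPSES,
) -> pd.DataFrame:
    """Group motor neurons by their distance signature from each seed set.

    ``seeds`` maps a seed name to its member ids; each motor neuron gets
    the tuple of hop distances (one per seed), and neurons sharing a tuple
    form a group.
    """
    motors = table.neurons[table.neurons["cell_class"] == "motor"]["id"].tolist()
    if not motors:
        return pd.DataFrame(columns=["id", "group", *seeds])
    cols = {}
    for name, ids in seeds.items():
        cols[name] = synaptic_distance(table, ids, motors, min_synapses)
    rows = []
    for m in motors:
        sig = tuple(cols[name][m] for name in seeds)
        rows.append({"id": m, **{name: cols[name][m] for name in seeds}, "signature": sig})
    df = pd.DataFrame(rows)
    codes = {sig: i for i, sig in enumerate(sorted(set(df["signature"]), key=str))}
    df["group"] = df["signature"].map(codes)
    return df.drop(columns=["signature"])
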