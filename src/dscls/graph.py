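"""Residue interaction graphs and centrality-based hub scoring.

Residues are nodes; an edge joins residues whose motions are correlated above
a threshold, optionally also required to be in spatial contact in at least
one representative conformation. Edge weight is |correlation| in (0, 1];
path-based measures traverse length -ln(weight) so that correlation
multiplies along a path while length adds.

Six node-centrality measures are computed (weighted degree, closeness,
betweenness, current-flow closeness, current-flow betweenness, eigenvector);
their per-node average z-score is the composite hub score that ranks
candidate stability centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .correlation import CorrelationMatrix
from .ensemble_io import Conformation

__all__ = [
    "ResidueGraph",
    "CentralityProfile",
    "EmptyGraphError",
    "build_graph",
    "centrality_profile",
    "composite_hub_score",
]

CENTRALITY_MEASURES = (
    "degree",
    "closeness",
    "betweenness",
    "current_flow_closeness",
    "current_flow_betweenness",
    "eigenvector",
)


class EmptyGraphError(ValueError):
    """No edges survive the thresholds."""


@dataclass
class ResidueGraph:
    """Weighted undirected residue graph plus construction provenance."""

    graph: nx.Graph  # nodes 0..R-1, edge attrs: weight, length
    n_residues: int
    metric_kind: str  # "NDCC" | "NLMI"
    contact_filtered: bool
    corr_min: float
    path_length_rule: str = "-ln(weight)"

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        return sorted(
            (min(i, j), max(i, j), d["weight"]) for i, j, d in self.graph.edges(data=True)
        )

    def weighted_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_residues)
        for node, val in self.graph.degree(weight="weight"):
            deg[node] = val
        return deg


@dataclass
class CentralityProfile:
    """Per-node values of the six centrality measures plus component ids."""

    values: dict[str, np.ndarray]  # measure -> (R,) array
    component_id: np.ndarray  # (R,) int, -1 for nodes absent from the graph
    n_residues: int

    def as_dataframe(self):
        import pandas as pd

        data = {m: self.values[m] for m in CENTRALITY_MEASURES}
        data["component"] = self.component_id
        return pd.DataFrame(data, index=range(self.n_residues))


def build_graph(
    corr: CorrelationMatrix,
    reps: list[Conformation] | None = None,
    corr_min: float = 0.5,
    contact_cutoff: float = 10.0,
    exclude_adjacent: int = 1,
) -> ResidueGraph:
    """Threshold a correlation matrix into a residue graph.

    Edge (i, j) exists iff |i-j| > exclude_adjacent, |corr_ij| >= corr_min,
    and — when representative conformations are supplied — the minimum CA-CA
    distance over the representatives is <= contact_cutoff. Sequence-adjacent
    pairs are excluded because backbone connectivity correlates them
    trivially. Weight is |corr_ij|.
    """
    R = corr.n_residues
    absC = np.abs(corr.values)
    contact_ok = None
    if reps:
        dmin = np.full((R, R), np.inf)
        for conf in reps:
            ca = conf.coords if conf.n_atoms == R else _ca_coords(conf, R)
            d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
            dmin = np.minimum(dmin, d)
        contact_ok = dmin <= contact_cutoff
    G = nx.Graph()
    G.add_nodes_from(range(R))
    ii, jj = np.triu_indices(R, k=exclude_adjacent + 1)
    keep = absC[ii, jj] >= corr_min
    if contact_ok is not None:
        keep &= contact_ok[ii, jj]
    for i, j in zip(ii[keep], jj[keep]):
        w = float(absC[i, j])
        w = min(w, 1.0)
        G.add_edge(int(i), int(j), weight=w, length=float(-np.log(w)) if w < 1 else 0.0)
    if G.number_of_edges() == 0:
        raise EmptyGraphError(
            f"no edges with |corr| >= {corr_min}"
            + (f" and contact <= {contact_cutoff} A" if contact_ok is not None else "")
            + "; lower corr_min or raise contact_cutoff"
        )
    return ResidueGraph(
        graph=G,
        n_residues=R,
        metric_kind=corr.kind,
        contact_filtered=contact_ok is not None,
        corr_min=corr_min,
    )


def _ca_coords(conf: Conformation, n_residues: int) -> np.ndarray:
    ca = np.full((n_residues, 3), np.nan)
    for k in range(conf.n_atoms):
        if conf.atom_names[k] == "CA":
            ca[int(conf.residue_indices[k])] = conf.coords[k]
    if np.isnan(ca).any():
        raise ValueError("representative conformation lacks CA atoms for some residues")
    return ca


def centrality_profile(rgraph: ResidueGraph) -> CentralityProfile:
    """Compute the six centrality measures, per connected component.

    Path-based measures (closeness, betweenness) traverse -ln(weight)
    lengths; current-flow measures treat weights as conductances; the
    eigenvector centrality of each component is scaled to unit maximum.
    Nodes outside a component — and singleton components, for which flow
    measures are undefined — score 0 on the affected measures.
    """
    G = rgraph.graph
    R = rgraph.n_residues
    vals = {m: np.zeros(R) for m in CENTRALITY_MEASURES}
    comp_id = np.full(R, -1, dtype=int)
    components = sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c)))
    for cid, comp in enumerate(components):
        for node in comp:
            comp_id[node] = cid
        sub = G.subgraph(comp)
        n = len(comp)
        for node, val in sub.degree(weight="weight"):
            vals["degree"][node] = val
        if n < 2:
            continue
        for node, val in nx.closeness_centrality(sub, distance="length").items():
            vals["closeness"][node] = val
        for node, val in nx.betweenness_centrality(
            sub, weight="length", normalized=True
        ).items():
            vals["betweenness"][node] = val
        for node, val in nx.current_flow_closeness_centrality(
            sub, weight="weight"
        ).items():
            vals["current_flow_closeness"][node] = val
        if n > 2:
            cfb = nx.current_flow_betweenness_centrality(
                sub, weight="weight", normalized=True
            )
        else:
            cfb = {node: 0.0 for node in comp}
        for node, val in cfb.items():
            vals["current_flow_betweenness"][node] = val
        # leading eigenvector of the component's weight matrix (dense eigh:
        # robust on tiny components where sparse solvers cannot run)
        comp_nodes = sorted(comp)
        W = nx.to_numpy_array(sub, nodelist=comp_nodes, weight="weight")
        w_eig, V = np.linalg.eigh(W)
        lead = np.abs(V[:, -1])
        emax = lead.max()
        for node, val in zip(comp_nodes, lead):
            vals["eigenvector"][node] = val / emax if emax > 0 else 0.0
    return CentralityProfile(values=vals, component_id=comp_id, n_residues=R)


def composite_hub_score(profile: CentralityProfile) -> np.ndarray:
    """Average per-measure z-score over the largest connected component.

    Nodes outside the largest component get a -inf sentinel so they can
    never rank as hubs. A measure with zero variance across the component
    carries no ranking information and is dropped with a warning.
    """
    in_main = profile.component_id == 0  # components sorted largest-first
    scores = np.full(profile.n_residues, -np.inf)
    if not in_main.any():
        return scores
    zs = []
    for m in CENTRALITY_MEASURES:
        x = profile.values[m][in_main]
        sd = x.std()
        if sd <= 1e-15:
            warnings.warn(
                f"centrality measure {m!r} is constant on the main component; "
                "dropped from the composite score",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        zs.append((x - x.mean()) / sd)
    if not zs:
        scores[in_main] = 0.0
        return scores
    scores[in_main] = np.mean(zs, axis=0)
    return scores
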