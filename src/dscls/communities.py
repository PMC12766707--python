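"""Community structure of the residue network and per-residue roles.

Partitioning runs in two stages. Louvain modularity maximization (seeded,
deterministic) gives the coarse communities. Each Louvain community is then
refined by k-clique percolation on its induced subgraph: two k-cliques are
adjacent when they share k-1 nodes, and each maximal union of adjacent
k-cliques becomes a refined community. Nodes of the Louvain community that
belong to no k-clique ("unvisited" nodes) are merged into the adjacent
refined community with which they share at least k-1 neighbors, or failing
that k-2 neighbors — ties broken by the largest shared edge-weight sum, then
the lowest community id. Anything still unmatched becomes a singleton.
Percolation overlap (a node in two k-clique communities) is collapsed by the
same tie rule, so the final assignment is a true partition.

Roles: within each community the node with the largest intra-community edge
weight is the leader; a non-leader touching >= 2 other communities or with
more inter- than intra-community weight is a key connector; everyone else is
a follower. Leaders and followers form the stable intra-community core,
key connectors carry the communication between communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "CommunityPartition",
    "RoleAssignment",
    "louvain_partition",
    "clique_percolation_refine",
    "assign_roles",
]


@dataclass
class CommunityPartition:
    assignment: dict[int, int]  # node -> community id, ids dense 0..C-1
    modularity: float
    method_trace: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = set(self.assignment.values())
        if ids and ids != set(range(len(ids))):
            raise ValueError("community ids must be dense 0..C-1")

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cid: int) -> set[int]:
        return {n for n, c in self.assignment.items() if c == cid}

    def communities(self) -> list[set[int]]:
        return [self.members(c) for c in range(self.n_communities)]


@dataclass
class RoleAssignment:
    roles: dict[int, str]  # node -> "leader" | "follower" | "key_connector"

    def of_kind(self, kind: str) -> set[int]:
        return {n for n, r in self.roles.items() if r == kind}


def _densify(assignment: dict[int, int]) -> dict[int, int]:
    """Relabel community ids densely, ordered by each community's lowest node."""
    groups: dict[int, list[int]] = {}
    for node, cid in assignment.items():
        groups.setdefault(cid, []).append(node)
    order = sorted(groups, key=lambda c: min(groups[c]))
    remap = {old: new for new, old in enumerate(order)}
    return {node: remap[cid] for node, cid in assignment.items()}


def louvain_partition(
    rgraph, resolution: float = 1.0, seed: int = 0
) -> CommunityPartition:
    """Seeded Louvain modularity partition of the residue graph.

    The returned modularity is recomputed directly for the final partition
    (weight-aware Newman-Girvan modularity at the given resolution).
    """
    G = rgraph.graph if hasattr(rgraph, "graph") else rgraph
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    assignment: dict[int, int] = {}
    for cid, comm in enumerate(sorted(comms, key=min)):
        for node in comm:
            assignment[node] = cid
    assignment = _densify(assignment)
    mod = nx.community.modularity(
        G,
        [
            {n for n, c in assignment.items() if c == cid}
            for cid in range(len(set(assignment.values())))
        ],
        weight="weight",
        resolution=resolution,
    )
    return CommunityPartition(
        assignment=assignment, modularity=float(mod), method_trace=("louvain",)
    )


def _shared_weight(G: nx.Graph, node: int, community: set[int]) -> tuple[int, float]:
    """(#neighbors inside community, summed edge weight into it)."""
    nbrs = set(G.neighbors(node)) & community
    w = sum(G[node][u].get("weight", 1.0) for u in nbrs)
    return len(nbrs), w


def clique_percolation_refine(
    rgraph, partition: CommunityPartition, k: int = 3
) -> CommunityPartition:
    """Refine a Louvain partition by k-clique percolation within communities.

    Refinement never crosses Louvain boundaries: percolation, the k-1/k-2
    shared-neighbor merging of unvisited nodes, and the overlap collapse all
    operate inside one Louvain community's induced subgraph. Ids are
    re-densified at the end.
    """
    if k < 3:
        raise ValueError("clique percolation needs k >= 3")
    G = rgraph.graph if hasattr(rgraph, "graph") else rgraph
    assignment: dict[int, int] = {}
    next_id = 0
    for cid in range(partition.n_communities):
        members = partition.members(cid)
        sub = G.subgraph(members)
        perc = [set(c) for c in nx.community.k_clique_communities(sub, k)]
        perc.sort(key=min)
        local: dict[int, int] = {}
        claimed: dict[int, list[int]] = {}
        for pid, comm in enumerate(perc):
            for node in comm:
                claimed.setdefault(node, []).append(pid)
        # collapse percolation overlap by the tie rule
        for node, pids in claimed.items():
            if len(pids) == 1:
                local[node] = pids[0]
            else:
                best = max(
                    pids,
                    key=lambda p: (
                        _shared_weight(sub, node, perc[p] - {node})[1],
                        -p,
                    ),
                )
                local[node] = best
        # merge unvisited nodes via shared k-1 / k-2 neighbors
        unvisited = sorted(members - set(claimed))
        refined = {p: set(c) for p, c in enumerate(perc)}
        for node in unvisited:
            placed = False
            for need in (k - 1, k - 2):
                candidates = []
                for pid, comm in refined.items():
                    n_shared, w_shared = _shared_weight(sub, node, comm - {node})
                    if n_shared >= need:
                        candidates.append((w_shared, -pid, pid))
                if candidates:
                    _, _, pid = max(candidates)
                    local[node] = pid
                    placed = True
                    break
            if not placed:
                pid = len(refined)
                refined[pid] = set()
                local[node] = pid
            refined[local[node]] = refined.get(local[node], set()) | {node}
        for node, pid in local.items():
            assignment[node] = next_id + pid
        next_id += max(local.values(), default=-1) + 1
    assignment = _densify(assignment)
    comms = [
        {n for n, c in assignment.items() if c == cid}
        for cid in range(len(set(assignment.values())))
    ]
    mod = nx.community.modularity(G, comms, weight="weight")
    return CommunityPartition(
        assignment=assignment,
        modularity=float(mod),
        method_trace=partition.method_trace + (f"cpm(k={k})",),
    )


def assign_roles(rgraph, partition: CommunityPartition) -> RoleAssignment:
    """Classify every node as leader, follower, or key connector.

    For node v with community c(v): w_in = summed weight to same-community
    neighbors, w_out = summed weight to other communities, n_ext = number of
    distinct other communities touched. The per-community argmax of w_in is
    the leader (ties to the lowest node id); non-leaders with n_ext >= 2 or
    w_out > w_in are key connectors; the rest follow.
    """
    G = rgraph.graph if hasattr(rgraph, "graph") else rgraph
    assignment = partition.assignment
    w_in: dict[int, float] = {}
    w_out: dict[int, float] = {}
    n_ext: dict[int, int] = {}
    for node in assignment:
        cid = assignment[node]
        wi = wo = 0.0
        ext: set[int] = set()
        for u in G.neighbors(node):
            if u not in assignment:
                continue
            w = G[node][u].get("weight", 1.0)
            if assignment[u] == cid:
                wi += w
            else:
                wo += w
                ext.add(assignment[u])
        w_in[node], w_out[node], n_ext[node] = wi, wo, len(ext)
    roles: dict[int, str] = {}
    for cid in range(partition.n_communities):
        members = sorted(partition.members(cid))
        leader = max(members, key=lambda n: (w_in[n], -n))
        roles[leader] = "leader"
        for node in members:
            if node == leader:
                continue
            if n_ext[node] >= 2 or w_out[node] > w_in[node]:
                roles[node] = "key_connector"
            else:
                roles[node] = "follower"
    return RoleAssignment(roles=roles)
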