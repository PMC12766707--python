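"""DSCLS identification, variant comparison, and mutation proposal.

A dynamic stability center of local structure (DSCLS) is a topologically
strong hub of the residue network together with the surrounding residues it
is tightly coupled to — the subnetworks that carry a protein's structural
stability. Identification proceeds from the network artifacts of the earlier
stages:

1. seed hubs = top quantile of the composite centrality score, plus every
   key connector and leader whose composite score is non-negative;
2. catalytic-pocket residues and weakly connected residues (weighted degree
   below a floor) are excluded — stability engineering must not touch the
   active site, and weak nodes are not stability centers;
3. each surviving hub grows to its neighbors across edges at least as strong
   as ``grow_weight_min``;
4. connected components of the grown subgraph with at least ``min_size``
   residues are the DSCLSs; their internal edges and any noncovalent-contact
   evidence between members are recorded.

Coverage — the fraction of residues inside any DSCLS — summarizes a
variant's stability basis; gains, losses, fusions, fissions and relocations
of DSCLSs between a wild type and a mutant are detected by Jaccard matching
of residue sets. Mutation candidates are residues that could strengthen an
existing DSCLS or nucleate a new one, directed toward aromatic or charged
side chains (strong hubs are enriched in F/Y/W/R/E/K, weak ones in
aliphatics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .communities import CommunityPartition, RoleAssignment
from .ensemble_io import ResidueAnnotation
from .graph import CentralityProfile, ResidueGraph, composite_hub_score

__all__ = [
    "DSCLS",
    "DSCLSMap",
    "DsclsParams",
    "VariantComparison",
    "MutationCandidate",
    "identify_dscls",
    "consensus_dscls",
    "compare_variants",
    "propose_mutations",
]


@dataclass(frozen=True)
class DsclsParams:
    """Thresholds steering DSCLS identification (all dimensionless).

    ``weak_degree_min=None`` resolves at run time to the 25th percentile of
    the graph's weighted-degree distribution; ``grow_weight_min=None`` to
    corr_min + 0.1.
    """

    hub_quantile: float = 0.15
    weak_degree_min: float | None = None
    grow_weight_min: float | None = None
    min_size: int = 4


@dataclass
class DSCLS:
    id: int
    residues: frozenset[int]
    seed_hubs: frozenset[int]
    internal_edges: tuple[tuple[int, int, float], ...]
    interaction_evidence: tuple = ()
    source_metric: str = "NDCC"

    def __post_init__(self) -> None:
        if not self.seed_hubs <= self.residues:
            raise ValueError("seed hubs must be members of the DSCLS")


@dataclass
class DSCLSMap:
    variant_label: str
    dscls_list: list[DSCLS]
    n_residues: int
    excluded_catalytic: frozenset[int] = frozenset()
    excluded_weak: frozenset[int] = frozenset()
    params: dict = field(default_factory=dict)
    graph: ResidueGraph | None = None  # not serialized

    @property
    def coverage_fraction(self) -> float:
        covered = set().union(*(d.residues for d in self.dscls_list)) if self.dscls_list else set()
        return len(covered) / self.n_residues

    @property
    def covered_residues(self) -> frozenset[int]:
        if not self.dscls_list:
            return frozenset()
        return frozenset(set().union(*(d.residues for d in self.dscls_list)))

    def to_dict(self) -> dict:
        return {
            "variant_label": self.variant_label,
            "n_residues": self.n_residues,
            "coverage_fraction": self.coverage_fraction,
            "excluded_catalytic": sorted(self.excluded_catalytic),
            "excluded_weak": sorted(self.excluded_weak),
            "params": dict(sorted(self.params.items())),
            "dscls": [
                {
                    "id": d.id,
                    "source_metric": d.source_metric,
                    "residues": sorted(d.residues),
                    "seed_hubs": sorted(d.seed_hubs),
                    "internal_edges": [
                        [i, j, round(w, 10)] for i, j, w in d.internal_edges
                    ],
                    "n_contacts": len(d.interaction_evidence),
                }
                for d in self.dscls_list
            ],
        }


@dataclass
class VariantComparison:
    matching: list[tuple[int, int, float]]  # (wt_id, mut_id, jaccard)
    events: list[dict]  # kind + member ids
    coverage_delta: float

    def to_dict(self) -> dict:
        return {
            "matching": [[w, m, round(j, 10)] for w, m, j in self.matching],
            "events": self.events,
            "coverage_delta": self.coverage_delta,
        }


@dataclass(frozen=True)
class MutationCandidate:
    residue_index: int
    current_aa: str
    proposed_aa: str
    rationale: str  # "strengthen_existing" | "nucleate_new"
    adjacency_score: float


# mutation direction: toward aromatic / charged side chains
STABILIZING_AA = frozenset("FYWREK")
_SUBSTITUTION = {
    "A": "F", "V": "F", "L": "F", "I": "F", "M": "F", "C": "F",
    "T": "Y", "S": "Y", "G": "Y", "P": "Y",
    "N": "R", "Q": "R", "H": "R",
    "D": "E",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def identify_dscls(
    rgraph: ResidueGraph,
    profile: CentralityProfile,
    partition: CommunityPartition,
    roles: RoleAssignment,
    annotation: ResidueAnnotation | None = None,
    params: DsclsParams = DsclsParams(),
    contacts=(),
    variant_label: str = "variant",
) -> DSCLSMap:
    """Extract the DSCLS subnetworks of one variant.

    An empty map (no hubs survive exclusion) is a valid result, not an
    error — a destabilized variant may genuinely have none.
    """
    annotation = annotation or ResidueAnnotation()
    annotation.validate(rgraph.n_residues)
    score = composite_hub_score(profile)
    degree = rgraph.weighted_degree()
    finite = score[np.isfinite(score)]
    weak_min = (
        float(np.percentile(degree[degree > 0], 25)) if params.weak_degree_min is None
        else params.weak_degree_min
    )
    grow_min = (
        rgraph.corr_min + 0.1 if params.grow_weight_min is None
        else params.grow_weight_min
    )

    hubs: set[int] = set()
    if finite.size:
        cutoff = float(np.quantile(finite, 1.0 - params.hub_quantile))
        hubs |= {i for i in range(rgraph.n_residues) if score[i] >= cutoff}
    hubs |= {n for n in roles.of_kind("key_connector") if score[n] >= 0}
    hubs |= {n for n in roles.of_kind("leader") if score[n] >= 0}

    catalytic = set(annotation.catalytic_pocket)
    weak = {i for i in range(rgraph.n_residues) if degree[i] < weak_min}
    excluded = catalytic | weak
    hubs -= excluded

    # grow hubs across strong edges, then take connected components
    grown: set[int] = set(hubs)
    G = rgraph.graph
    for h in hubs:
        for u in G.neighbors(h):
            if u in excluded:
                continue
            if G[h][u]["weight"] >= grow_min:
                grown.add(u)
    sub_edges = [
        (min(i, j), max(i, j), d["weight"])
        for i, j, d in G.edges(data=True)
        if i in grown and j in grown and d["weight"] >= grow_min
    ]
    H = nx.Graph()
    H.add_nodes_from(grown)
    H.add_weighted_edges_from(sub_edges)
    dscls_list: list[DSCLS] = []
    comps = sorted(nx.connected_components(H), key=min)
    for comp in comps:
        if len(comp) < params.min_size:
            continue
        residues = frozenset(comp)
        internal = tuple(
            sorted((i, j, w) for i, j, w in sub_edges if i in comp and j in comp)
        )
        evidence = tuple(
            c for c in contacts if c.residue_i in comp and c.residue_j in comp
        )
        dscls_list.append(
            DSCLS(
                id=len(dscls_list),
                residues=residues,
                seed_hubs=frozenset(hubs & comp),
                internal_edges=internal,
                interaction_evidence=evidence,
                source_metric=rgraph.metric_kind,
            )
        )
    used_params = {
        "hub_quantile": params.hub_quantile,
        "weak_degree_min": weak_min,
        "grow_weight_min": grow_min,
        "min_size": params.min_size,
        "corr_min": rgraph.corr_min,
        "metric": rgraph.metric_kind,
    }
    return DSCLSMap(
        variant_label=variant_label,
        dscls_list=dscls_list,
        n_residues=rgraph.n_residues,
        excluded_catalytic=frozenset(catalytic),
        excluded_weak=frozenset(weak - catalytic),
        params=used_params,
        graph=rgraph,
    )


def _jaccard(a: frozenset[int], b: frozenset[int]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def consensus_dscls(map_ndcc: DSCLSMap, map_nlmi: DSCLSMap) -> DSCLSMap:
    """Reconcile the two metric-specific maps into one consensus map.

    Residues supported by both metrics — unions of pairwise intersections of
    DSCLSs whose Jaccard overlap is >= 0.25 — are re-formed into connected
    components on the NDCC graph. Identical inputs reproduce themselves;
    disjoint inputs give an empty consensus.
    """
    if map_ndcc.n_residues != map_nlmi.n_residues:
        raise ValueError("variant maps disagree on residue count")
    consensus: set[int] = set()
    for a in map_ndcc.dscls_list:
        for b in map_nlmi.dscls_list:
            if _jaccard(a.residues, b.residues) >= 0.25:
                consensus |= a.residues & b.residues
    dscls_list: list[DSCLS] = []
    if consensus and map_ndcc.graph is not None:
        H = map_ndcc.graph.graph.subgraph(consensus)
        min_size = int(map_ndcc.params.get("min_size", 1))
        for comp in sorted(nx.connected_components(H), key=min):
            if len(comp) < min_size:
                continue
            internal = tuple(
                sorted(
                    (min(i, j), max(i, j), d["weight"])
                    for i, j, d in H.subgraph(comp).edges(data=True)
                )
            )
            hubs = frozenset().union(
                *(d.seed_hubs for d in map_ndcc.dscls_list)
            ) & frozenset(comp)
            dscls_list.append(
                DSCLS(
                    id=len(dscls_list),
                    residues=frozenset(comp),
                    seed_hubs=hubs,
                    internal_edges=internal,
                    source_metric="consensus",
                )
            )
    elif consensus:
        # no graph attached: each consensus residue set stands as given
        dscls_list.append(
            DSCLS(
                id=0,
                residues=frozenset(consensus),
                seed_hubs=frozenset(),
                internal_edges=(),
                source_metric="consensus",
            )
        )
    return DSCLSMap(
        variant_label=map_ndcc.variant_label,
        dscls_list=dscls_list,
        n_residues=map_ndcc.n_residues,
        excluded_catalytic=map_ndcc.excluded_catalytic,
        excluded_weak=map_ndcc.excluded_weak & map_nlmi.excluded_weak,
        params={**map_ndcc.params, "metric": "consensus"},
        graph=map_ndcc.graph,
    )


def compare_variants(wt: DSCLSMap, mut: DSCLSMap) -> VariantComparison:
    """Match DSCLSs between variants and classify the structural events.

    Candidate links are DSCLS pairs with Jaccard >= 0.3, processed in
    descending Jaccard (ties to the lowest id pair); a link is accepted while
    either of its endpoints is still unlinked, so one mutant DSCLS absorbing
    two wild-type DSCLSs appears as two accepted links. Events: a mutant
    DSCLS linked to >= 2 wild-type DSCLSs is a fusion (the symmetric case a
    fission); an unlinked wild-type DSCLS is a loss, an unlinked mutant one a
    gain; a one-to-one link with Jaccard < 0.6 is a relocation.
    """
    if wt.n_residues != mut.n_residues:
        raise ValueError("variant maps disagree on residue count")
    pairs = []
    for a in wt.dscls_list:
        for b in mut.dscls_list:
            j = _jaccard(a.residues, b.residues)
            if j >= 0.3:
                pairs.append((j, a.id, b.id))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    wt_links: dict[int, list[int]] = {}
    mut_links: dict[int, list[int]] = {}
    matching: list[tuple[int, int, float]] = []
    for j, w, m in pairs:
        if w not in wt_links or m not in mut_links:
            matching.append((w, m, j))
            wt_links.setdefault(w, []).append(m)
            mut_links.setdefault(m, []).append(w)
    events: list[dict] = []
    for m, ws in sorted(mut_links.items()):
        if len(ws) >= 2:
            events.append({"kind": "fusion", "wt_ids": sorted(ws), "mut_ids": [m]})
    for w, ms in sorted(wt_links.items()):
        if len(ms) >= 2:
            events.append({"kind": "fission", "wt_ids": [w], "mut_ids": sorted(ms)})
    for w, m, j in matching:
        if len(wt_links[w]) == 1 and len(mut_links[m]) == 1 and j < 0.6:
            events.append({"kind": "relocation", "wt_ids": [w], "mut_ids": [m]})
    for a in wt.dscls_list:
        if a.id not in wt_links:
            events.append({"kind": "loss", "wt_ids": [a.id], "mut_ids": []})
    for b in mut.dscls_list:
        if b.id not in mut_links:
            events.append({"kind": "gain", "wt_ids": [], "mut_ids": [b.id]})
    return VariantComparison(
        matching=matching,
        events=events,
        coverage_delta=mut.coverage_fraction - wt.coverage_fraction,
    )


def propose_mutations(
    rgraph: ResidueGraph,
    dscls_map: DSCLSMap,
    sequence: str,
    annotation: ResidueAnnotation | None = None,
    top_n: int = 10,
    profile: CentralityProfile | None = None,
) -> list[MutationCandidate]:
    """Rank residues whose substitution could reinforce the DSCLS network.

    Eligible residues are non-catalytic and not already aromatic/charged.
    A residue adjacent (in the graph) to a DSCLS strengthens that existing
    center (score = summed edge weight into DSCLS members); a hub with
    non-negative composite score outside every DSCLS could nucleate a new
    one (score = its composite score). Substitutions follow the
    aromatic/charged direction: small hydrophobics -> F, small polars -> Y,
    amide-like -> R, D -> E.
    """
    if len(sequence) != rgraph.n_residues:
        raise ValueError(
            f"sequence length {len(sequence)} != residue count {rgraph.n_residues}"
        )
    annotation = annotation or ResidueAnnotation()
    annotation.validate(rgraph.n_residues)
    covered = dscls_map.covered_residues
    if profile is None:
        from .graph import centrality_profile

        profile = centrality_profile(rgraph)
    score = composite_hub_score(profile)
    G = rgraph.graph
    candidates: list[MutationCandidate] = []
    for i in range(rgraph.n_residues):
        aa = sequence[i]
        if aa in STABILIZING_AA or i in annotation.catalytic_pocket:
            continue
        proposed = _SUBSTITUTION.get(aa)
        if proposed is None:
            continue
        adj_weight = sum(
            G[i][u]["weight"] for u in G.neighbors(i) if u in covered
        ) if i in G else 0.0
        if adj_weight > 0:
            candidates.append(
                MutationCandidate(
                    residue_index=i,
                    current_aa=aa,
                    proposed_aa=proposed,
                    rationale="strengthen_existing",
                    adjacency_score=float(adj_weight),
                )
            )
        elif i not in covered and np.isfinite(score[i]) and score[i] >= 0:
            candidates.append(
                MutationCandidate(
                    residue_index=i,
                    current_aa=aa,
                    proposed_aa=proposed,
                    rationale="nucleate_new",
                    adjacency_score=float(score[i]),
                )
            )
    candidates.sort(key=lambda c: (-c.adjacency_score, c.residue_index))
    return candidates[:top_n]
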