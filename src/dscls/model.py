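"""Model/Results interface to the full DSCLS workflow.

:class:`StabilityNetworkModel` is built from a conformational ensemble plus
analysis options; :meth:`~StabilityNetworkModel.fit` executes the staged
workflow — RMSD stable-window selection, free-energy-landscape clustering,
NDCC/NLMI correlation matrices, residue-network construction, centrality and
community analysis, DSCLS identification — and returns a
:class:`StabilityNetworkResults` carrying every intermediate artifact, a
``summary()`` table, variant comparison, mutation proposal and serialization.

    >>> model = StabilityNetworkModel.from_synthetic(spec)
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .communities import (
    CommunityPartition,
    RoleAssignment,
    assign_roles,
    clique_percolation_refine,
    louvain_partition,
)
from .core import (
    DSCLSMap,
    DsclsParams,
    MutationCandidate,
    THREE_TO_ONE,
    VariantComparison,
    compare_variants,
    consensus_dscls,
    identify_dscls,
    propose_mutations,
)
from .correlation import CorrelationMatrix, ndcc_matrix, nlmi_matrix
from .ensemble_io import Ensemble, ResidueAnnotation, select_calpha
from .fel import (
    ConformationClusters,
    FELGrid,
    PCAModel,
    build_fel,
    cluster_conformations,
    fit_pca,
    representative_conformations,
)
from .graph import (
    CentralityProfile,
    ResidueGraph,
    build_graph,
    centrality_profile,
    composite_hub_score,
)
from .trajectory import (
    SeriesResult,
    StableWindow,
    detect_stable_windows,
    radius_of_gyration,
    rmsd_series,
    rmsf_per_residue,
    stable_frame_indices,
)

__all__ = ["AnalysisOptions", "StabilityNetworkModel", "StabilityNetworkResults"]


@dataclass(frozen=True)
class AnalysisOptions:
    """All tunable thresholds of the workflow, with their defaults.

    ``stable_window=None`` resolves to max(10, 5% of frames);
    ``contact_cutoff=None`` disables the representative-conformation contact
    filter (appropriate for coarse synthetic chains whose spatial layout is
    arbitrary); ``superpose=False`` is the right setting for generator
    output, which is already expressed in a common frame.
    """

    metric: str = "both"  # "ndcc" | "nlmi" | "both"
    superpose: bool = True
    stable_window: int | None = None
    stable_std_max: float = 0.3  # A
    n_clusters: int = 5
    fel_bins: int = 50
    temperature: float = 300.15  # K
    corr_min: float = 0.5
    contact_cutoff: float | None = None  # A, None disables
    exclude_adjacent: int = 1
    louvain_resolution: float = 1.0
    cpm_k: int = 3
    seed: int = 0
    hub_quantile: float = 0.15
    weak_degree_min: float | None = None
    grow_weight_min: float | None = None
    min_size: int = 4

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StabilityNetworkModel:
    """The DSCLS workflow, configured for one conformational ensemble."""

    def __init__(
        self,
        ensemble: Ensemble,
        annotation: ResidueAnnotation | None = None,
        options: AnalysisOptions = AnalysisOptions(),
        variant_label: str = "variant",
    ):
        self.ensemble = ensemble
        self.annotation = annotation or ResidueAnnotation()
        self.options = options
        self.variant_label = variant_label

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_pdb(cls, path, **kwargs) -> "StabilityNetworkModel":
        from .ensemble_io import read_multimodel_pdb

        return cls(read_multimodel_pdb(path), **kwargs)

    @classmethod
    def from_coord_table(cls, path, **kwargs) -> "StabilityNetworkModel":
        from .ensemble_io import read_coord_table

        return cls(read_coord_table(path), **kwargs)

    @classmethod
    def from_synthetic(cls, spec, options: AnalysisOptions | None = None, **kwargs):
        """Build from a synthetic spec; superposition defaults off."""
        from .synthetic import sample_correlated_ensemble

        ensemble, truth = sample_correlated_ensemble(spec)
        if options is None:
            options = AnalysisOptions(superpose=False)
        model = cls(ensemble, options=options, **kwargs)
        model.ground_truth = truth
        return model

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "StabilityNetworkResults":
        opt = self.options
        ca = select_calpha(self.ensemble)
        self.annotation.validate(ca.n_residues)

        rmsd = rmsd_series(ca, reference="first")
        window = opt.stable_window or max(10, ca.n_frames // 20)
        window = min(window, ca.n_frames)
        windows = detect_stable_windows(rmsd, window=window, std_max=opt.stable_std_max)
        frames, fallback = stable_frame_indices(windows, ca.n_frames)

        pca = fit_pca(ca)
        fel = build_fel(pca, bins=opt.fel_bins, temperature=opt.temperature)
        n_clusters = min(opt.n_clusters, ca.n_frames)
        clusters = cluster_conformations(pca, n_clusters=n_clusters)
        reps = representative_conformations(ca, clusters)

        metrics = ("NDCC", "NLMI") if opt.metric == "both" else (opt.metric.upper(),)
        corr: dict[str, CorrelationMatrix] = {}
        graphs: dict[str, ResidueGraph] = {}
        profiles: dict[str, CentralityProfile] = {}
        partitions: dict[str, CommunityPartition] = {}
        roles: dict[str, RoleAssignment] = {}
        maps: dict[str, DSCLSMap] = {}
        dscls_params = DsclsParams(
            hub_quantile=opt.hub_quantile,
            weak_degree_min=opt.weak_degree_min,
            grow_weight_min=opt.grow_weight_min,
            min_size=opt.min_size,
        )
        for kind in metrics:
            fn = ndcc_matrix if kind == "NDCC" else nlmi_matrix
            corr[kind] = fn(ca, window=frames, superpose=opt.superpose)
            graphs[kind] = build_graph(
                corr[kind],
                reps=reps if opt.contact_cutoff is not None else None,
                corr_min=opt.corr_min,
                contact_cutoff=opt.contact_cutoff or 10.0,
                exclude_adjacent=opt.exclude_adjacent,
            )
            profiles[kind] = centrality_profile(graphs[kind])
            louv = louvain_partition(
                graphs[kind], resolution=opt.louvain_resolution, seed=opt.seed
            )
            partitions[kind] = clique_percolation_refine(graphs[kind], louv, k=opt.cpm_k)
            roles[kind] = assign_roles(graphs[kind], partitions[kind])
            maps[kind] = identify_dscls(
                graphs[kind],
                profiles[kind],
                partitions[kind],
                roles[kind],
                annotation=self.annotation,
                params=dscls_params,
                variant_label=self.variant_label,
            )
        if len(metrics) == 2:
            final = consensus_dscls(maps["NDCC"], maps["NLMI"])
        else:
            final = maps[metrics[0]]
        return StabilityNetworkResults(
            model=self,
            rmsd=rmsd,
            stable_windows=windows,
            stable_frames=frames,
            used_fallback_frames=fallback,
            pca=pca,
            fel=fel,
            clusters=clusters,
            representatives=reps,
            correlation=corr,
            graphs=graphs,
            profiles=profiles,
            partitions=partitions,
            roles=roles,
            metric_maps=maps,
            dscls_map=final,
        )


@dataclass
class StabilityNetworkResults:
    """Everything the fitted workflow produced, with reporting helpers."""

    model: StabilityNetworkModel
    rmsd: SeriesResult
    stable_windows: list[StableWindow]
    stable_frames: np.ndarray
    used_fallback_frames: bool
    pca: PCAModel
    fel: FELGrid
    clusters: ConformationClusters
    representatives: list
    correlation: dict[str, CorrelationMatrix]
    graphs: dict[str, ResidueGraph]
    profiles: dict[str, CentralityProfile]
    partitions: dict[str, CommunityPartition]
    roles: dict[str, RoleAssignment]
    metric_maps: dict[str, DSCLSMap]
    dscls_map: DSCLSMap

    @property
    def coverage_fraction(self) -> float:
        return self.dscls_map.coverage_fraction

    def hub_scores(self, metric: str = "NDCC") -> np.ndarray:
        return composite_hub_score(self.profiles[metric])

    def sequence(self) -> str:
        names = self.model.ensemble.residue_sequence()
        return "".join(THREE_TO_ONE.get(n, "A") for n in names)

    def compare(self, other: "StabilityNetworkResults") -> VariantComparison:
        """Treat ``self`` as wild type and ``other`` as the mutant."""
        return compare_variants(self.dscls_map, other.dscls_map)

    def propose(self, top_n: int = 10, sequence: str | None = None) -> list[MutationCandidate]:
        metric = "NDCC" if "NDCC" in self.graphs else next(iter(self.graphs))
        return propose_mutations(
            self.graphs[metric],
            self.dscls_map,
            sequence or self.sequence(),
            annotation=self.model.annotation,
            top_n=top_n,
            profile=self.profiles[metric],
        )

    def summary(self) -> str:
        opt = self.model.options
        lines = [
            "Dynamic stability centers of local structure",
            "=" * 52,
            f"variant:            {self.model.variant_label}",
            f"frames / residues:  {self.model.ensemble.n_frames} / {self.dscls_map.n_residues}",
            f"stable frames used: {len(self.stable_frames)}"
            + ("  (fallback: final 50%)" if self.used_fallback_frames else ""),
            f"metrics:            {', '.join(sorted(self.correlation))}",
            f"corr_min / grow:    {opt.corr_min} / {self.dscls_map.params.get('grow_weight_min')}",
        ]
        for kind in sorted(self.graphs):
            g = self.graphs[kind]
            p = self.partitions[kind]
            lines.append(
                f"{kind}: {g.graph.number_of_edges()} edges, "
                f"{p.n_communities} communities (Q={p.modularity:.3f}), "
                f"{len(self.metric_maps[kind].dscls_list)} DSCLS, "
                f"coverage {self.metric_maps[kind].coverage_fraction:.3f}"
            )
        lines.append("-" * 52)
        lines.append(
            f"final map ({self.dscls_map.params.get('metric', '?')}): "
            f"{len(self.dscls_map.dscls_list)} DSCLS, "
            f"coverage {self.dscls_map.coverage_fraction:.3f}"
        )
        for d in self.dscls_map.dscls_list:
            res = sorted(d.residues)
            shown = ",".join(map(str, res[:10])) + ("..." if len(res) > 10 else "")
            lines.append(
                f"  DSCLS {d.id}: {len(d.residues)} residues "
                f"({len(d.internal_edges)} edges) [{shown}]"
            )
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def save(self, outdir) -> dict:
        """Write all stage artifacts to ``outdir``; returns the manifest.

        Output is deterministic for a fixed model configuration: JSON keys
        sorted, floats rounded, no timestamps.
        """
        os.makedirs(outdir, exist_ok=True)
        opt_dict = self.model.options.to_dict()
        manifest = {
            "package_version": __version__,
            "variant_label": self.model.variant_label,
            "options": opt_dict,
            "config_hash": hashlib.sha256(
                json.dumps(opt_dict, sort_keys=True).encode()
            ).hexdigest(),
            "ensemble_source": self.model.ensemble.source,
            "topology_hash": self.model.ensemble.topology_hash,
            "n_frames": self.model.ensemble.n_frames,
            "n_residues": self.dscls_map.n_residues,
            "used_fallback_frames": self.used_fallback_frames,
        }
        _write_json(os.path.join(outdir, "manifest.json"), manifest)
        _write_tsv(
            os.path.join(outdir, "rmsd.tsv"),
            ["frame", "rmsd"],
            [(f, round(float(v), 6)) for f, v in enumerate(self.rmsd.values)],
        )
        _write_json(
            os.path.join(outdir, "stable_windows.json"),
            [
                {
                    "start_frame": w.start_frame,
                    "end_frame": w.end_frame,
                    "mean_rmsd": round(w.mean_rmsd, 6),
                    "rmsd_std": round(w.rmsd_std, 6),
                }
                for w in self.stable_windows
            ],
        )
        np.savetxt(
            os.path.join(outdir, "fel.tsv"),
            np.where(np.isfinite(self.fel.free_energy), self.fel.free_energy, -1.0),
            delimiter="\t",
            fmt="%.6f",
            header="free energy (k_BT); -1 marks empty bins",
        )
        _write_json(
            os.path.join(outdir, "clusters.json"),
            {
                "n_clusters": self.clusters.n_clusters,
                "labels": self.clusters.labels.tolist(),
                "representatives": self.clusters.representatives.tolist(),
            },
        )
        for kind in sorted(self.correlation):
            np.savetxt(
                os.path.join(outdir, f"correlation_{kind.lower()}.tsv"),
                self.correlation[kind].values,
                delimiter="\t",
                fmt="%.8f",
            )
            _write_tsv(
                os.path.join(outdir, f"edges_{kind.lower()}.tsv"),
                ["i", "j", "weight"],
                [(i, j, round(w, 8)) for i, j, w in self.graphs[kind].edges],
            )
            prof = self.profiles[kind]
            rows = []
            for node in range(prof.n_residues):
                rows.append(
                    (node,)
                    + tuple(round(float(prof.values[m][node]), 8) for m in prof.values)
                    + (int(prof.component_id[node]),)
                )
            _write_tsv(
                os.path.join(outdir, f"centrality_{kind.lower()}.tsv"),
                ["node"] + list(prof.values) + ["component"],
                rows,
            )
            part = self.partitions[kind]
            _write_json(
                os.path.join(outdir, f"communities_{kind.lower()}.json"),
                {
                    "assignment": {str(n): c for n, c in sorted(part.assignment.items())},
                    "modularity": round(part.modularity, 10),
                    "method_trace": list(part.method_trace),
                    "roles": {str(n): r for n, r in sorted(self.roles[kind].roles.items())},
                },
            )
            _write_json(
                os.path.join(outdir, f"dscls_{kind.lower()}.json"),
                self.metric_maps[kind].to_dict(),
            )
        _write_json(os.path.join(outdir, "dscls_final.json"), self.dscls_map.to_dict())
        return manifest

    # -- plotting ----------------------------------------------------------

    def plot_fel(self, ax=None):
        """Free-energy landscape heat map over (PC1, PC2), in k_BT."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fe = np.ma.masked_invalid(self.fel.free_energy)
        mesh = ax.pcolormesh(
            self.fel.bin_edges_pc1, self.fel.bin_edges_pc2, fe.T, shading="auto"
        )
        ax.set_xlabel("PC1 (A)")
        ax.set_ylabel("PC2 (A)")
        plt.colorbar(mesh, ax=ax, label="free energy (k_BT)")
        return ax


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def _write_tsv(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
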