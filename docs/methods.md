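# Methods

## Overview

`dscls` identifies *dynamic stability centers of local structure* (DSCLSs):
strong-hub subnetworks of a protein's residue cross-correlation network,
together with the surrounding residues they are tightly coupled to and the
noncovalent interactions that stabilize them. The workflow runs from a
conformational ensemble (multi-model PDB, a plain-text CA coordinate table,
or the built-in synthetic generators) through:

1. **Trajectory metrics** — RMSD/RMSF/Rg series after Kabsch superposition;
   flat stretches of the RMSD series ("stable windows") select the frames
   used for correlation estimation, so that correlations are not estimated
   across conformational transitions.
2. **Free-energy landscape** — PCA of the superposed CA covariance, a 2-D
   histogram of the (PC1, PC2) projection converted to free energy
   G = −k_BT ln(ρ/ρ_max), Ward hierarchical clustering of the projections
   with a predefined cluster count, and one representative frame per
   cluster (nearest the centroid).
3. **Cross-correlation matrices** — NDCC and NLMI (definitions below).
4. **Residue network** — thresholded |correlation| edges, optionally
   contact-filtered through the representative conformations; six node
   centralities; a composite hub score.
5. **Communities** — seeded Louvain partitioning refined by k-clique
   percolation with a shared-neighbor merging rule; leader / follower /
   key-connector roles.
6. **DSCLS extraction** — hubs grown across strong edges, away from the
   catalytic pocket and weakly connected residues; coverage statistics;
   variant comparison; mutation proposal toward aromatic/charged residues.

## Correlation measures

With fluctuation vectors Δr_i(t) = r_i(t) − ⟨r_i⟩ over the selected frames:

* **NDCC** — C_ij = ⟨Δr_i·Δr_j⟩ / (⟨|Δr_i|²⟩⟨|Δr_j|²⟩)^{1/2}, in [−1, 1].
  Signed, but blind to correlated motion along perpendicular directions.
* **NLMI** — the Gaussian mutual information
  I_ij = ½[ln det C_i + ln det C_j − ln det C_ij] from the 3×3 marginal and
  6×6 joint fluctuation covariances, mapped onto a correlation scale by
  NLMI_ij = (1 − e^{−2 I_ij/3})^{1/2} ∈ [0, 1], diagonal 1 by convention.
  A singular joint covariance gets a trace-scaled ridge (1e−9·tr/6) with a
  warning.

For isotropic Gaussian fluctuations with i.i.d. axes and per-axis residue
correlation r, NDCC = r and NLMI = |r| exactly in expectation. The synthetic
generator is built to realize this identity, which is what the calibration
tests exploit.

## Superposition and its interaction with synthetic data

All trajectory metrics and correlation estimators superpose frames onto a
two-pass iterative mean by default, as MD analysis requires. For the
synthetic generators this default is wrong on purpose-built grounds: the
generators emit frames already expressed in a common laboratory frame, and
fully coherent block motion — the planted signal — is mathematically
indistinguishable from rigid-body drift, so a least-squares rigid fit
removes a large part of it (measured: a planted pair correlation is biased
by roughly −3.5/R; at R = 60 a ρ = 0.8 block drops to near zero). RMSF and
both correlation estimators therefore take `superpose=False`, which is the
setting used for all recovery and calibration experiments and the default
for `StabilityNetworkModel.from_synthetic`. Real trajectories must keep the
default. This is a genuine limitation of superposed dynamic
cross-correlation analysis, not of the generator: collective motions with a
large rigid-body component are partially invisible to it.

## Synthetic generators and ground truth

`sample_correlated_ensemble` draws per-axis displacements jointly from
N(0, s²·R) where s is `fluctuation_scale` (default 1 Å) and R is the planted
residue correlation matrix: ρ_in inside blocks (default 0.8), ρ_out across
blocks (default 0.05), and — for a planted hub — the hub's *entire row* set
to ρ_hub (default 0.45). The full-row construction is forced by positive
semidefiniteness: a residue cannot stay fully correlated with its own block
and couple ≳0.3 to two independent blocks, because its squared factor
loadings would exceed one. Generation fails loudly on a non-PSD target; no
silent repair, so ground truth is always exact. The standard fixture is 60
residues in three equal blocks with one hub (residue 10).

The mean structure is a self-avoiding 3.8 Å virtual-bond random walk (or an
ideal helix-like spiral). `sample_enm_ensemble` instead draws isotropic
Gaussian fluctuations with per-axis covariance equal to the pseudoinverse of
the contact-network Laplacian (cutoff 10 Å) — the closed-form Gaussian
network model, used to test RMSF against an analytic profile.

What the generators do *not* emulate: anharmonicity, multi-basin dynamics,
side chains, solvent, sequence-dependent flexibility, and spatial layouts in
which sequence-contiguous blocks are also spatially compact. Passing
recovery tests therefore demonstrates correctness of the estimators and the
graph/community/DSCLS logic under the stated model, not performance on real
trajectories.

## Network construction and centralities

Edge (i, j) requires |i−j| > 1 (backbone neighbors are trivially
correlated), |corr| ≥ `corr_min`, and — when representatives are supplied —
min-over-representatives CA–CA distance ≤ `contact_cutoff` (10 Å). Edge
weight is |corr|; path-based measures traverse length −ln(weight) so that
correlation multiplies along paths while length adds. Default
`corr_min` = 0.5; recovery experiments on the synthetic fixture use 0.4 so
that hub edges (ρ_hub = 0.45) participate, with `grow_weight_min` = 0.4 for
the same reason. The contact filter defaults off in the pipeline because
the pseudo-chain's spatial layout carries no signal; set `contact_cutoff`
for real structures.

Six centralities: weighted degree; closeness and betweenness on −ln(weight)
lengths; current-flow closeness (reciprocal total effective resistance) and
current-flow betweenness (weights as conductances), computed per connected
component; eigenvector centrality as the leading eigenvector of each
component's weight matrix scaled to unit maximum (dense `eigh`, robust on
two-node components). Nodes outside a component score 0 on its measures.
The composite hub score is the mean per-measure z-score over the largest
component; constant measures are dropped with a warning; nodes outside the
largest component carry a −∞ sentinel so they can never rank as hubs.

## Communities, refinement and roles

Louvain (seeded, deterministic node order; modularity recomputed directly
for the returned partition) gives the coarse structure. Each Louvain
community is refined by k-clique percolation (default k = 3, the smallest
meaningful clique) on its induced subgraph. Nodes in no k-clique are merged
into the adjacent refined community sharing ≥ k−1 neighbors, else ≥ k−2;
ties break by largest shared edge-weight sum, then lowest community id.
Overlapping percolation membership is collapsed by the same tie rule, so the
result is a true partition; shared neighbors are counted within the
candidate community only. Refinement never crosses Louvain boundaries.

Roles: per community, the argmax of intra-community weight is the leader
(ties to the lowest node id); a non-leader touching ≥ 2 foreign communities
or with more inter- than intra-community weight is a key connector; the
rest are followers.

## DSCLS identification and comparison

Seed hubs are the top `hub_quantile` (default 15%) of the composite score
plus all leaders and key connectors with non-negative score. Catalytic
residues (user-supplied; no automatic pocket detection) and weak residues
(weighted degree below `weak_degree_min`, default the 25th percentile) are
excluded. Hubs grow to neighbors across edges ≥ `grow_weight_min` (default
`corr_min` + 0.1); connected components of the grown subgraph with
≥ `min_size` (default 4) residues are the DSCLSs. One graph is built per
metric with the contact filter taking the minimum distance over all
representatives — a single consolidated graph rather than per-representative
runs, because the contact criterion is already defined as a minimum over
representatives. "Coverage" is the residue-count fraction inside any DSCLS
(not a spatial volume) and is labeled as such.

NDCC and NLMI maps are reconciled by consensus: unions of pairwise
intersections of DSCLSs with Jaccard ≥ 0.25, re-formed into connected
components on the NDCC graph.

Variant comparison links DSCLS pairs with Jaccard ≥ 0.3 greedily in
descending Jaccard (ties to the lowest id pair), accepting a link while
either endpoint is unlinked — deliberately many-to-many so that one mutant
DSCLS absorbing two wild-type ones registers as a *fusion* (symmetrically
*fission*); unlinked DSCLSs are *losses*/*gains*; one-to-one links with
Jaccard < 0.6 are *relocations*.

Mutation proposal targets non-catalytic residues that are not already
aromatic or charged: graph neighbors of a DSCLS (score = summed edge weight
into it, "strengthen_existing") and non-negative-score hubs outside all
DSCLSs ("nucleate_new"). Substitutions go toward the aromatic/charged set
F/Y/W/R/E/K (small hydrophobics → F, small polars → Y, amide-like → R,
D → E) — a directional heuristic reflecting the enrichment of strong hubs
in aromatic and charged residues, not a ΔΔG claim.

## Noncovalent contact criteria

Hydrogen bond: donor heavy atom (N/O/S) to acceptor (N/O) ≤ 3.5 Å, plus a
D–H···A angle ≥ 120° when explicit hydrogens are present. Hydrophobic:
side-chain carbon pair of two apolar residues ≤ 5.0 Å. Salt bridge: basic
side-chain N (Arg NH1/NH2/NE, Lys NZ, His ND1/NE2) to carboxylate O
(Asp OD1/OD2, Glu OE1/OE2) ≤ 4.0 Å. Aromatic: ring-centroid distance
≤ 7.0 Å for F/Y/W/H (W uses its six-membered ring; incomplete rings are
skipped with a warning). All cutoffs configurable; one contact per residue
pair per frame; |i−j| ≥ 2 sequence separation throughout. Cation–π and
energy-based scoring are out of scope.

## Numerical and determinism choices

* PCA by SVD of centered superposed coordinates; eigenvalues use ddof = 1;
  eigenvector signs fixed so each vector's largest-magnitude component is
  positive; clustering operates on the 2-D projection only.
* FEL: occupied-bin minimum exactly 0; empty bins +∞; counts conserve the
  frame total. Default 50 bins, 300.15 K (grid stored in k_BT).
* Stable windows: sliding window max(10, 5% of frames), std ≤ 0.3 Å
  (population std); maximal unions of passing windows; the recorded
  `rmsd_std` is the worst passing sub-window, which is what the threshold
  bounds. If nothing passes, the final 50% of frames are used with a
  logged warning so the pipeline cannot dead-end.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); rerunning a configuration reproduces every
  artifact byte-for-byte (JSON keys sorted, floats rounded, no
  timestamps).
* Problem sizes for the standard experiments: calibration at 20,000 frames
  × 10 residues; community recovery at 5,000 frames × 60 residues; hub
  recovery at 20 replicates × 2,000 frames × 60 residues — sizes at which
  sampling error is comfortably below the decision thresholds.

## Known limitations

* Superposed correlation analysis under-reports collective motions with a
  large rigid-body component (see above); this is inherent to the method.
* Louvain refinement and the CPM merge rule assume a meaningful weighted
  graph; on near-complete graphs (uniform strong correlation) community
  structure is arbitrary.
* The comparison event taxonomy is heuristic: deeply reorganized variants
  may register as simultaneous loss + gain rather than relocation.
* The substitution table is directional, not quantitative; candidate
  ranking reflects network adjacency, not folding energetics.
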