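# Methods

`metanets` identifies the spatial extents of metacommunities in a patchy
landscape from current and historical habitat maps, and scores candidate
delineations against observed species diversity. This note documents the
model, the numerical conventions, the synthetic data the tests run on, and
the limits of what those tests show.

## Model and procedure

**Habitat networks.** At each time step the habitat layer is reduced to a set
of disjoint patches (connected groups of habitat cells, 8-neighbour by
default). Patches are nodes of an undirected graph; two patches are linked
when the minimum boundary-to-boundary Euclidean distance between them is at
most a dispersal threshold θ, with the distance as edge weight. The edge rule
is the closed inequality d ≤ θ so the conventional round thresholds
(250, 500, 750, 1000, 2000 m — the span of odonate dispersal estimates) are
inclusive. Patches too far apart for a direct link can still share a
component through chains of intermediate stepping-stone patches.

**Harmonization.** The habitat series is assumed loss-only: no new habitat
emerges over the study period. Apparent new habitat in an earlier-vs-later
comparison is treated as digitisation error and corrected by backward
propagation — the mask at time t becomes the cell-wise union of all masks at
times ≥ t. The operation is idempotent and produces exact superset nesting,
which downstream stages rely on: every current patch is spatially nested in
some patch at every earlier time.

**Delineation.** Connected components of the network at a chosen time step
and θ are the candidate metacommunities. Current patches are assigned to the
component whose (source-time) patches maximally overlap them by area; under
harmonization this reduces to containment and ties have measure zero (ties
break by distance to the nearest member boundary, then lexicographic id).
An abiotic alternative assigns current patches to named partition polygons
(e.g. watersheds) by their representative interior point (`point` mode,
default) or by maximal overlap (`overlap` mode). Extent polygons (convex
hulls) are reporting artefacts only; all scoring uses membership.

**Evaluation.** Species occurrence points are snapped to containing current
patches (closed containment) and collapsed to presence/absence. All
unordered pairs of data patches within a 15 km separation form the shared
pair universe; beyond that distance Jaccard dissimilarity saturates near 1
and carries no signal. Pairwise Jaccard dissimilarity
β = 1 − |S_i∩S_j|/|S_i∪S_j| is binarized at the median over the pair
universe (β < median → low, β ≥ median → high; ties go high so the modal
saturated value cannot absorb the low class). The median is computed once,
not per delineation, so κ values are comparable across time steps: a
delineation only re-distributes pairs into within/between. Each delineation
is scored by the 2×2 table of pair class × β class: accuracy, precision
(positive cell = within∧low), and Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e
from the marginals. A two-sided Welch t-test compares the within and between
β distributions (a pooled Student variant is available by config), and
`direction_ok` records whether mean within-β < mean between-β. The `best`
delineation maximises κ among rows with the right direction; exact κ ties
(identical induced partitions) resolve to the first row in input (time)
order — with distinct partitions and hundreds of pairs, exact ties
otherwise do not occur.

Pairs touching unassigned patches or single-patch metacommunities are
excluded per delineation and reported (`n_excluded`); a delineation with
fewer than two within or two between pairs is flagged degenerate rather
than scored.

**Gamma–size analysis.** Per metacommunity, gamma richness is the union of
species over member current patches; size metrics (total area, patch count,
mean shortest-path "network diameter") are measured at the delineation's
source time step — the historical extent is the quantity of interest, not
the shrunken current footprint. Here "network diameter" means the mean
weighted shortest-path distance over all patch pairs of a component, the
metacommunity-size sense; the graph-theoretic maximum is reported alongside
for transparency. Pearson correlations use natural-log-transformed
predictors (correlation is invariant to log base); gamma itself is not
transformed by default (a sensitivity flag exists). Metacommunities that are
singletons or have species data in fewer than two patches are excluded from
these analyses, since a single data patch cannot separate local from
regional diversity.

**Least-cost hook.** Network distances can alternatively be computed as
least-cost paths on a resistance grid (8-neighbour moves, diagonal step cost
×√2, step cost = mean cell resistance × step length). With the default
uniform resistance this approximates Euclidean distance to within the
8-neighbour anisotropy bound (2·cos(π/8)−√2 ≈ 8.24%, attained near 22.5°
directions). No attempt is made to parameterise a non-uniform historical
resistance surface.

## Synthetic data: what it emulates, what it does not

The generator produces the study conditions the pipeline is validated
against, with ground truth known by construction.

*Landscape.* Patches are discs rasterised to a 25 m grid, organised in
chains ("clusters"): consecutive edge-to-edge gaps are drawn from
(0.4, 0.8) × `cluster_spread` (default 150 m, so gaps of 60–120 m stay below
the smallest tested θ with margin for raster discretisation), and clusters
are separated by at least `inter_cluster_gap` = 5 km, which exceeds the
largest tested θ — so at the first time step the network components equal
the clusters at every tested threshold. Defaults (5 clusters of 18–22
patches in a 45 × 45 km extent) are sized so that after degradation the
current layer carries on the order of 80 patches with species data, matching
the scale of the wetland monitoring record this stands in for (88 monitored
patches).

*Degradation.* Each step removes surviving patches with probability 0.12 and
shrinks the survivors' radii by 15%, in place. Nesting therefore holds
exactly without harmonization (harmonization is still exercised and must act
as the identity). With small within-chain gaps, a single removal cannot
bridge a chain past θ = 500 m; occasional adjacent removals split a chain
into balanced halves. This keeps the number of current-network components
small (typically 6–9) — which matters because the community model divides
one fixed regional species pool among the ground-truth groups.

*Communities.* A regional pool of S = 60 species; 30% is common to all
ground-truth metacommunities, the remainder is split equally as private
pools among groups with ≥ 2 patches (an isolated single-patch group draws a
nested subset of the common pool rather than endemics). Each member patch
carries each pool species with probability 0.5 (optionally damped by
exp(−λ·graph distance) to the pool's central patch; λ = 0 by default), then
every patch × species cell flips with probability 0.05. One occurrence point
per present species is placed uniformly inside the patch polygon. Under
these defaults the median pairwise Jaccard dissimilarity over the ≤ 15 km
pair universe falls at ≈ 0.75 (within the 0.7–0.9 saturation band typical of
presence-only wetland insect data). The `historical` regime seeds
communities from the earliest step's clusters (an extinction-debt world:
current composition reflects past connectivity); the `current` regime seeds
them from the current network's components (no debt). Placement, degradation
and community sampling use independent random streams spawned from one
master seed, so the two regimes share statistically identical landscapes.

*What passing tests do and do not show.* Recovery of the seeding time step
in ≥ 90% of seeded replicates shows that the evaluation machinery detects a
debt signal of the modelled form at the modelled scale; measured across
arbitrary seed sets the per-replicate recovery probability is about
0.82–0.88, i.e. the experiment operates near its design threshold. The
generator omits several features of real data: observation effort gradients
and detection failure, abundance information, environmental niche structure,
patch-quality covariates, recolonisation, and gradual (rather than stepwise)
habitat change. Success on synthetic data bounds what the method can do when
its assumptions hold; it does not certify performance on any particular
empirical dataset.

## Numerical conventions and degenerate inputs

- Distances and coordinates are planar metres; CRS metadata is carried but
  never reprojected (mismatched CRS is a hard error).
- Shortest paths use Dijkstra; node order is lexicographic, so outputs are
  reproducible.
- Non-binary rasters require an explicit binarization threshold; silent
  coercion is an error.
- Undefined quantities are NaN flags, not exceptions, wherever downstream
  filtering is the correct response: β of a species-empty patch, diameter of
  a singleton component, κ under degenerate marginals, Pearson r under a
  zero-variance predictor.
- All-identical β values make binarization impossible and raise a
  degenerate-evaluation error; a delineation with no between pairs is
  flagged degenerate in the results table instead of aborting the batch.
- CSV floats are written at 12 significant digits; a rerun with the same
  config and seeds is byte-identical.
- Raster grid sizes in the default study (1800 × 1800 cells, three steps)
  and replicate counts (50 per regime, 100 for correlation recovery) keep a
  full validation run in the low minutes on one CPU.

## Known limitations

- Vector input layers are trusted to be valid and pairwise disjoint;
  `PatchLayer.validate_disjoint` exists but is not called on every path.
- The watershed delineation carries no source-time size metrics, so the
  gamma–size analysis reports NaN diameter for abiotic sources.
- GeoPackage is not supported; vector I/O is GeoJSON, raster I/O is ESRI
  ASCII grid or single-band (Geo)TIFF with pixel-scale/tiepoint tags.
- The least-cost hook measures between patch raster cells; for extended
  patches its endpoints differ from polygon boundaries by up to about one
  cell, which is visible at short ranges.
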