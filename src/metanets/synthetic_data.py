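"""Synthetic landscapes and communities with known metacommunity ground truth.

The generator emulates the study system the pipeline targets: a patchy
wetland landscape organised in well-separated clusters of patches, a habitat
time series that only loses habitat (patches disappear or shrink, never
appear), and species communities whose composition reflects membership in
either the *historical* (earliest, extinction-debt regime) or the *current*
patch clusters. Ground truth is known by construction, so every pipeline
stage — harmonization, network components, delineation, evaluation — can be
tested end to end without licensed survey data.

Construction guarantees:

* clusters are separated by more than the largest tested dispersal threshold,
  so at the first time step the network components equal the clusters at any
  tested threshold;
* within a cluster, patches form a chain whose consecutive edge-to-edge gaps
  stay below the smallest tested threshold, so a cluster starts as one
  component;
* degradation removes whole patches and shrinks survivors in place, so every
  later layer is spatially nested in every earlier one (the series is
  harmonized by construction).

Default magnitudes follow the study system: dispersal thresholds of
250–2000 m, cluster separation of 5 km, patch radii of tens of metres on a
25 m grid, and per-step loss rates strong enough that a majority of patches
disappear over the series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Point

from .habitat_network import build_network, components, pairwise_edge_distance
from .landscape_io import (
    GridTransform,
    HabitatMask,
    OccurrenceRecords,
    PatchLayer,
    label_patches,
)

__all__ = [
    "LandscapeParams",
    "DegradationParams",
    "CommunityParams",
    "SyntheticLandscape",
    "SyntheticSeries",
    "generate_landscape",
    "degrade",
    "generate_communities",
    "simulate_study",
    "write_fixtures",
]


@dataclass(frozen=True)
class LandscapeParams:
    """Cluster-of-patches landscape geometry.

    ``cluster_spread`` is the within-cluster spacing scale: consecutive
    edge-to-edge gaps along a cluster's patch chain are drawn uniformly from
    (0.4, 0.8) x cluster_spread, keeping them under the smallest tested
    dispersal threshold with margin for raster discretisation.
    ``inter_cluster_gap`` must exceed the largest tested threshold so that
    ground-truth components equal clusters at the first time step.

    Defaults are sized to the study system being emulated: after the default
    degradation the current layer carries on the order of 80-90 patches with
    species data, the scale of the wetland monitoring record this generator
    stands in for.
    """

    extent: tuple[float, float] = (45_000.0, 45_000.0)
    n_clusters: int = 5
    patches_per_cluster: tuple[int, int] = (18, 22)
    cluster_spread: float = 150.0
    inter_cluster_gap: float = 5_000.0
    patch_radius: tuple[float, float] = (50.0, 100.0)
    cell_size: float = 25.0
    seed: int = 0


@dataclass(frozen=True)
class DegradationParams:
    """Habitat-loss process: per-step patch removal and in-place shrinkage.

    Defaults give cumulative survival of ~0.56 over two transitions — the
    majority-loss, strong-fragmentation regime the historical record shows.
    """

    n_steps: int = 3
    removal_prob: float = 0.12
    shrink_fraction: float = 0.15
    seed: int = 0


@dataclass(frozen=True)
class CommunityParams:
    """Species pool and sampling parameters for community generation.

    Each ground-truth metacommunity shares ``pool_overlap`` of the regional
    pool with all others and holds an equal share of the rest privately.
    A member patch carries each pool species with probability
    ``per_patch_occupancy`` (times exp(-distance_decay x graph distance to
    the pool centroid patch) when decay is enabled), after which every
    patch x species cell flips with probability ``noise_rate``.
    """

    regional_pool: int = 60
    pool_overlap: float = 0.3
    per_patch_occupancy: float = 0.5
    distance_decay: float = 0.0
    noise_rate: float = 0.05
    debt_regime: Literal["historical", "current"] = "historical"
    seed: int = 0


@dataclass(frozen=True)
class Disc:
    x: float
    y: float
    r: float
    cluster: int


@dataclass
class SyntheticLandscape:
    """One time step: discs, their raster mask, labelled patches, truth labels."""

    discs: list[Disc]
    mask: HabitatMask
    layer: PatchLayer
    cluster_of: dict[str, int]


@dataclass
class SyntheticSeries:
    """Time-ordered degraded landscapes (step 0 = original)."""

    steps: list[SyntheticLandscape]

    @property
    def layers(self) -> list[PatchLayer]:
        return [s.layer for s in self.steps]

    @property
    def masks(self) -> list[HabitatMask]:
        return [s.mask for s in self.steps]

    @property
    def current(self) -> SyntheticLandscape:
        return self.steps[-1]


def _rasterize_discs(
    discs: Sequence[Disc], extent: tuple[float, float], cell: float, label: int
) -> HabitatMask:
    nx_ = int(round(extent[0] / cell))
    ny = int(round(extent[1] / cell))
    grid = np.zeros((ny, nx_), dtype=np.uint8)
    transform = GridTransform(x0=0.0, y0=extent[1], cell=cell)
    for d in discs:
        c0 = max(0, int((d.x - d.r) / cell) - 1)
        c1 = min(nx_ - 1, int((d.x + d.r) / cell) + 1)
        r_top = max(0, int((extent[1] - (d.y + d.r)) / cell) - 1)
        r_bot = min(ny - 1, int((extent[1] - (d.y - d.r)) / cell) + 1)
        rows = np.arange(r_top, r_bot + 1)
        cols = np.arange(c0, c1 + 1)
        cx = (cols + 0.5) * cell
        cy = extent[1] - (rows + 0.5) * cell
        inside = (cx[None, :] - d.x) ** 2 + (cy[:, None] - d.y) ** 2 <= d.r**2
        grid[np.ix_(rows, cols)] |= inside.astype(np.uint8)
    return HabitatMask(grid=grid, transform=transform, timestep_label=label)


def _landscape_from_discs(
    discs: Sequence[Disc], p: LandscapeParams, label: int
) -> SyntheticLandscape:
    mask = _rasterize_discs(discs, p.extent, p.cell_size, label)
    layer = label_patches(mask, connectivity=8)
    t = mask.transform
    cluster_of: dict[str, int] = {}
    # map each patch to the cluster of the discs whose centres it contains
    cell_owner = {}
    for patch in layer.patches:
        for rc in patch.cells or ():
            cell_owner[rc] = patch.patch_id
    for d in discs:
        row = int((p.extent[1] - d.y) / t.cell)
        col = int(d.x / t.cell)
        pid = cell_owner.get((row, col))
        if pid is None:
            continue  # disc too small to register on the grid
        prev = cluster_of.get(pid)
        if prev is not None and prev != d.cluster:
            raise RuntimeError("clusters merged during rasterisation")
        cluster_of[pid] = d.cluster
    return SyntheticLandscape(
        discs=list(discs), mask=mask, layer=layer, cluster_of=cluster_of
    )


def _build_cluster(
    rng: np.random.Generator, p: LandscapeParams, cluster: int
) -> list[Disc]:
    """Chain of discs with controlled consecutive gaps, local coordinates."""
    lo, hi = p.patches_per_cluster
    n = int(rng.integers(lo, hi + 1))
    r_lo, r_hi = p.patch_radius
    for _attempt in range(40):
        discs = [Disc(0.0, 0.0, float(rng.uniform(r_lo, r_hi)), cluster)]
        heading = float(rng.uniform(0, 2 * np.pi))
        ok = True
        for _ in range(n - 1):
            placed = False
            for _try in range(60):
                step_heading = heading + float(rng.uniform(-0.6, 0.6))
                r_new = float(rng.uniform(r_lo, r_hi))
                gap = float(rng.uniform(0.4, 0.8)) * p.cluster_spread
                prev = discs[-1]
                dist = prev.r + gap + r_new
                x = prev.x + dist * np.cos(step_heading)
                y = prev.y + dist * np.sin(step_heading)
                clearance = 2 * p.cell_size
                if all(
                    np.hypot(x - d.x, y - d.y) >= d.r + r_new + clearance
                    for d in discs[:-1]
                ):
                    discs.append(Disc(x, y, r_new, cluster))
                    heading = step_heading
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            # recentre so the cluster's reach from its anchor point is minimal
            cx = (min(d.x - d.r for d in discs) + max(d.x + d.r for d in discs)) / 2
            cy = (min(d.y - d.r for d in discs) + max(d.y + d.r for d in discs)) / 2
            return [Disc(d.x - cx, d.y - cy, d.r, cluster) for d in discs]
    raise RuntimeError("failed to build a non-overlapping patch chain")


def generate_landscape(p: LandscapeParams) -> SyntheticLandscape:
    """Seeded clustered landscape with ground-truth cluster labels.

    Cluster centres are rejection-sampled so that the edge-to-edge distance
    between patches of different clusters exceeds ``inter_cluster_gap``;
    raises after bounded retries when the extent is too small.
    """
    rng = np.random.default_rng(p.seed)
    clusters = [_build_cluster(rng, p, k) for k in range(p.n_clusters)]
    reaches = [
        max(np.hypot(d.x, d.y) + d.r for d in discs) for discs in clusters
    ]
    w, h = p.extent
    for _restart in range(60):
        centres: list[tuple[float, float]] = []
        failed = False
        for k in range(p.n_clusters):
            margin = reaches[k] + 2 * p.cell_size
            for _try in range(4000):
                cx = float(rng.uniform(margin, w - margin))
                cy = float(rng.uniform(margin, h - margin))
                if all(
                    np.hypot(cx - ox, cy - oy)
                    >= p.inter_cluster_gap + reaches[k] + reaches[j]
                    for j, (ox, oy) in enumerate(centres)
                ):
                    centres.append((cx, cy))
                    break
            else:
                failed = True
                break
        if not failed:
            break
    else:
        raise RuntimeError(
            "extent too small to place clusters at the requested separation"
        )
    discs = [
        Disc(d.x + cx, d.y + cy, d.r, d.cluster)
        for (cx, cy), cluster in zip(centres, clusters)
        for d in cluster
    ]
    return _landscape_from_discs(discs, p, label=0)


def degrade(
    land: SyntheticLandscape,
    p: DegradationParams,
    landscape_params: LandscapeParams,
    labels: Sequence[int] | None = None,
) -> SyntheticSeries:
    """Habitat-loss time series from an initial landscape.

    Each step removes every surviving disc with ``removal_prob`` and shrinks
    the survivors' radii by ``shrink_fraction``; the outputs are nested by
    construction and already satisfy the harmonization invariant. If all
    discs disappear before the final step the series is truncated with a
    warning.
    """
    rng = np.random.default_rng(p.seed)
    if labels is None:
        labels = list(range(p.n_steps))
    if len(labels) != p.n_steps:
        raise ValueError("labels length must equal n_steps")
    steps = [
        SyntheticLandscape(
            discs=land.discs,
            mask=HabitatMask(grid=land.mask.grid, transform=land.mask.transform,
                             timestep_label=int(labels[0])),
            layer=land.layer,
            cluster_of=land.cluster_of,
        )
    ]
    discs = list(land.discs)
    for t in range(1, p.n_steps):
        survivors = [d for d in discs if rng.random() >= p.removal_prob]
        discs = [
            Disc(d.x, d.y, d.r * (1.0 - p.shrink_fraction), d.cluster)
            for d in survivors
        ]
        if not discs:
            warnings.warn(f"all patches lost before step {t}; series truncated")
            break
        steps.append(_landscape_from_discs(discs, landscape_params, int(labels[t])))
    return SyntheticSeries(steps=steps)


def _random_point_in(geom, rng: np.random.Generator) -> tuple[float, float]:
    minx, miny, maxx, maxy = geom.bounds
    for _ in range(1000):
        x = float(rng.uniform(minx, maxx))
        y = float(rng.uniform(miny, maxy))
        if geom.covers(Point(x, y)):
            return x, y
    pt = geom.representative_point()
    return float(pt.x), float(pt.y)


def generate_communities(
    current_layer: PatchLayer,
    groups: dict[str, int],
    p: CommunityParams,
    network=None,
) -> OccurrenceRecords:
    """Sample species occurrences whose similarity structure follows ``groups``.

    ``groups`` maps every current patch id to its ground-truth metacommunity.
    Patches of one group draw from a shared pool (a common block of the
    regional pool plus the group's private block); observation points are
    placed uniformly inside patch polygons, one per present species.
    """
    rng = np.random.default_rng(p.seed)
    if not groups:
        raise ValueError("groups mapping is empty")
    group_ids = sorted(set(groups.values()))
    group_sizes = {g: sum(1 for gg in groups.values() if gg == g) for g in group_ids}
    # private species go to groups that can express compositional identity
    # (>= 2 patches); an isolated single-patch group draws a nested subset of
    # the common regional pool instead of endemics of its own
    private_groups = [g for g in group_ids if group_sizes[g] >= 2] or group_ids
    S = p.regional_pool
    n_common = int(round(S * p.pool_overlap))
    n_private = (S - n_common) // len(private_groups)
    if n_common + n_private == 0:
        raise ValueError("species pools are empty under these parameters")
    species_names = [f"sp{k:03d}" for k in range(S)]
    pools: dict[int, np.ndarray] = {}
    for g in group_ids:
        if g in private_groups:
            g_idx = private_groups.index(g)
            private = np.arange(
                n_common + g_idx * n_private, n_common + (g_idx + 1) * n_private
            )
            pools[g] = np.concatenate([np.arange(n_common), private])
        else:
            pools[g] = np.arange(n_common)

    decay_mult: dict[str, dict[str, float]] = {}
    if p.distance_decay > 0:
        if network is None:
            raise ValueError("distance_decay > 0 requires a habitat network")
        import networkx as nx

        for g in group_ids:
            members = [pid for pid, gg in groups.items() if gg == g]
            xs = [current_layer[pid].geometry.centroid.x for pid in members]
            ys = [current_layer[pid].geometry.centroid.y for pid in members]
            cx, cy = np.mean(xs), np.mean(ys)
            centroid_patch = min(
                members,
                key=lambda pid: np.hypot(
                    current_layer[pid].geometry.centroid.x - cx,
                    current_layer[pid].geometry.centroid.y - cy,
                ),
            )
            dists = nx.single_source_dijkstra_path_length(
                network.graph, centroid_patch, weight="weight"
            )
            decay_mult[g] = {
                pid: float(np.exp(-p.distance_decay * dists.get(pid, np.inf)))
                for pid in members
            }

    xs: list[float] = []
    ys: list[float] = []
    sp: list[str] = []
    for patch in current_layer.patches:
        pid = patch.patch_id
        if pid not in groups:
            continue
        g = groups[pid]
        present = np.zeros(S, dtype=bool)
        mult = decay_mult.get(g, {}).get(pid, 1.0) if p.distance_decay > 0 else 1.0
        occ = rng.random(len(pools[g])) < p.per_patch_occupancy * mult
        present[pools[g][occ]] = True
        flips = rng.random(S) < p.noise_rate
        present ^= flips
        for k in np.flatnonzero(present):
            x, y = _random_point_in(patch.geometry, rng)
            xs.append(x)
            ys.append(y)
            sp.append(species_names[k])
    return OccurrenceRecords(x=np.array(xs), y=np.array(ys), species=sp)


# ---------------------------------------------------------------------------
# Whole-study simulation


@dataclass
class StudyData:
    """A complete synthetic study: habitat series, communities, ground truth."""

    series: SyntheticSeries
    records: OccurrenceRecords
    truth_groups: dict[str, int]     # grouping the communities were seeded from
    regime: str
    theta: float


def _seed_from(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def current_component_groups(
    layer: PatchLayer, theta: float
) -> dict[str, int]:
    """Ground-truth grouping of current patches by current-network components."""
    dm = pairwise_edge_distance(layer)
    net = build_network(dm, theta, layer.timestep_label)
    return components(net).labels()


def simulate_study(
    master_seed: int,
    regime: Literal["historical", "current"] = "historical",
    theta: float = 500.0,
    landscape: LandscapeParams | None = None,
    degradation: DegradationParams | None = None,
    community: CommunityParams | None = None,
) -> StudyData:
    """Generate one complete synthetic study with a chosen debt regime.

    Placement, degradation and community sampling each get an independent
    random stream derived from ``master_seed``, so the two regimes can be
    compared on statistically identical landscapes. In the ``historical``
    regime communities are seeded from the earliest time step's clusters
    (extinction-debt signal); in the ``current`` regime from the components
    of the final (current) network at dispersal threshold ``theta``.
    """
    lp = landscape or LandscapeParams()
    dp = degradation or DegradationParams()
    cp = community or CommunityParams()
    s_place, s_degr, s_comm = np.random.SeedSequence(master_seed).spawn(3)
    lp = replace(lp, seed=_seed_from(s_place))
    dp = replace(dp, seed=_seed_from(s_degr))
    cp = replace(cp, seed=_seed_from(s_comm), debt_regime=regime)

    land = generate_landscape(lp)
    series = degrade(land, dp, lp)
    current = series.current

    if regime == "historical":
        # cluster identity of each current patch (clusters = earliest components)
        truth = dict(current.cluster_of)
    elif regime == "current":
        truth = current_component_groups(current.layer, theta)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    records = generate_communities(current.layer, truth, cp)
    return StudyData(series=series, records=records, truth_groups=truth,
                     regime=regime, theta=theta)


def write_fixtures(outdir: str | Path, master_seed: int = 42) -> dict:
    """Write a small deterministic dataset in the formats the pipeline reads.

    Emits per-step habitat masks (.asc), an occurrence CSV, a two-polygon
    abiotic partition (GeoJSON) splitting the extent, and a run config (INI).
    Returns the paths.
    """
    import json

    from shapely.geometry import box, mapping

    from .landscape_io import write_mask, write_occurrences

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # deliberately small: a 3-cluster landscape keeps fixture files and the
    # end-to-end smoke/determinism runs light
    fixture_landscape = LandscapeParams(
        extent=(18_000.0, 18_000.0),
        n_clusters=3,
        patches_per_cluster=(6, 8),
    )
    study = simulate_study(master_seed, regime="historical",
                           landscape=fixture_landscape)
    mask_paths = []
    labels = []
    for step in study.series.steps:
        path = outdir / f"habitat_t{step.mask.timestep_label}.asc"
        write_mask(step.mask, path)
        mask_paths.append(str(path))
        labels.append(step.mask.timestep_label)
    occ_path = outdir / "occurrences.csv"
    write_occurrences(study.records, occ_path)

    w, h = fixture_landscape.extent
    halves = [
        ("WS_west", box(0, 0, w / 2, h)),
        ("WS_east", box(w / 2, 0, w, h)),
    ]
    ws_path = outdir / "watersheds.geojson"
    with open(ws_path, "w") as fh:
        json.dump(
            {
                "type": "FeatureCollection",
                "features": [
                    {
                        "type": "Feature",
                        "properties": {"name": name},
                        "geometry": mapping(geom),
                    }
                    for name, geom in halves
                ],
            },
            fh,
        )

    cfg_path = outdir / "run.ini"
    with open(cfg_path, "w") as fh:
        fh.write("[inputs]\n")
        fh.write("masks = " + ", ".join(mask_paths) + "\n")
        fh.write("labels = " + ", ".join(str(l) for l in labels) + "\n")
        fh.write(f"occurrences = {occ_path}\n")
        fh.write(f"watersheds = {ws_path}\n")
        fh.write("\n[network]\nthresholds = 250, 500, 750, 1000, 2000\n")
        fh.write("connectivity = 8\nmin_patch_area = 0\n")
        fh.write("\n[evaluation]\npairing_limit = 15000\n")
        fh.write("binarize = median\nttest = welch\n")
    return {
        "masks": mask_paths,
        "labels": labels,
        "occurrences": str(occ_path),
        "watersheds": str(ws_path),
        "config": str(cfg_path),
    }
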