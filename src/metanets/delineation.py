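"""Metacommunity delineations: from network components or abiotic polygons.

A delineation partitions the *current* patches into metacommunities. Network
sources group current patches by the component (at some time step and
dispersal threshold) that their habitat descends from; abiotic sources (e.g.
watershed polygons) group them by containment. Extent polygons are convex
hulls of member geometries and serve reporting only — classification uses
membership, never the hull geometry, since true metacommunity boundaries are
fuzzy.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from shapely.geometry import mapping
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .habitat_network import ComponentPartition
from .landscape_io import PatchLayer

__all__ = [
    "Metacommunity",
    "Delineation",
    "delineate_from_components",
    "delineate_from_polygons",
]


@dataclass
class Metacommunity:
    mc_id: str
    members: list[str]              # current-patch ids
    source_patches: list[str]       # member patch ids at the source time step
    extent: BaseGeometry | None
    singleton: bool


@dataclass
class Delineation:
    """A partition of current patches into metacommunities."""

    source: str                     # e.g. "network:t=1899:theta=500" or "abiotic:WS"
    timestep_label: int | None
    theta: float | None
    metacommunities: list[Metacommunity]
    unassigned: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mc in self.metacommunities:
            overlap = seen & set(mc.members)
            if overlap:
                raise ValueError(f"patches assigned twice: {sorted(overlap)}")
            seen |= set(mc.members)
        if seen & set(self.unassigned):
            raise ValueError("patch both assigned and unassigned")

    def membership(self, include_singletons: bool = True) -> dict[str, str]:
        """current patch id -> mc_id."""
        out: dict[str, str] = {}
        for mc in self.metacommunities:
            if mc.singleton and not include_singletons:
                continue
            for pid in mc.members:
                out[pid] = mc.mc_id
        return out

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for mc in self.metacommunities:
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "mc_id": mc.mc_id,
                        "singleton": mc.singleton,
                        "n_members": len(mc.members),
                    },
                    "geometry": mapping(mc.extent) if mc.extent is not None else None,
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    def membership_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["patch_id", "mc_id", "source", "timestep", "theta"])
            for mc in self.metacommunities:
                for pid in sorted(mc.members):
                    w.writerow([pid, mc.mc_id, self.source,
                                self.timestep_label, self.theta])
            for pid in sorted(self.unassigned):
                w.writerow([pid, "", self.source, self.timestep_label, self.theta])


def delineate_from_components(
    partition: ComponentPartition,
    current_layer: PatchLayer,
    source_layer: PatchLayer,
) -> Delineation:
    """Turn network components into metacommunities of current patches.

    Each component of the source-time network becomes one metacommunity; a
    current patch joins the metacommunity whose member (source-time) patches
    maximally overlap it by area. On a harmonized series every current patch
    is nested in some source patch, so the assignment is containment; zero
    overlap against every component sends the patch to ``unassigned`` with a
    warning. Ties (measure-zero after harmonization) break by distance to the
    nearest member patch boundary, then lexicographic mc_id.
    """
    if len(partition.components) == 0:
        raise ValueError("empty component partition")
    net = partition.network
    comp_geoms: list[BaseGeometry] = []
    mcs: list[Metacommunity] = []
    for k, comp in enumerate(partition.components):
        src = sorted(comp)
        geom = unary_union([source_layer[p].geometry for p in src])
        comp_geoms.append(geom)
        mcs.append(
            Metacommunity(
                mc_id=f"mc{k:03d}",
                members=[],
                source_patches=src,
                extent=geom.convex_hull,
                singleton=len(src) == 1,
            )
        )
    unassigned: list[str] = []
    for patch in current_layer.patches:
        overlaps = [patch.geometry.intersection(g).area for g in comp_geoms]
        best = max(overlaps)
        if best <= 0:
            unassigned.append(patch.patch_id)
            continue
        cand = [k for k, ov in enumerate(overlaps) if ov == best]
        if len(cand) > 1:
            cand.sort(
                key=lambda k: (
                    patch.geometry.distance(comp_geoms[k].boundary),
                    mcs[k].mc_id,
                )
            )
        mcs[cand[0]].members.append(patch.patch_id)
    if unassigned:
        warnings.warn(
            f"{len(unassigned)} current patches overlap no component "
            "(was the series harmonized?)"
        )
    return Delineation(
        source=f"network:t={net.timestep_label}:theta={net.theta:g}",
        timestep_label=net.timestep_label,
        theta=net.theta,
        metacommunities=mcs,
        unassigned=unassigned,
    )


def delineate_from_polygons(
    polygons: Sequence[tuple[str, BaseGeometry]],
    current_layer: PatchLayer,
    name: str = "WS",
    mode: Literal["point", "overlap"] = "point",
) -> Delineation:
    """Group current patches by abiotic partition polygons (e.g. watersheds).

    With ``mode='point'`` a patch belongs to the polygon that covers its
    representative interior point (point-on-surface); with ``mode='overlap'``
    to the polygon of maximal area overlap. Patches matched by no polygon go
    to ``unassigned``. Singletons are metacommunities with <= 1 member patch.
    """
    mcs = [
        Metacommunity(
            mc_id=str(pname),
            members=[],
            source_patches=[],
            extent=geom.convex_hull,
            singleton=False,
        )
        for pname, geom in polygons
    ]
    unassigned: list[str] = []
    for patch in current_layer.patches:
        k_best: int | None = None
        if mode == "point":
            pt = patch.geometry.representative_point()
            for k, (_, geom) in enumerate(polygons):
                if geom.covers(pt):
                    k_best = k
                    break
        else:
            overlaps = [patch.geometry.intersection(g).area for _, g in polygons]
            if max(overlaps, default=0.0) > 0:
                k_best = int(max(range(len(overlaps)), key=lambda k: overlaps[k]))
        if k_best is None:
            unassigned.append(patch.patch_id)
        else:
            mcs[k_best].members.append(patch.patch_id)
    for mc in mcs:
        mc.singleton = len(mc.members) <= 1
    return Delineation(
        source=f"abiotic:{name}",
        timestep_label=None,
        theta=None,
        metacommunities=mcs,
        unassigned=unassigned,
    )
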