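"""Habitat layer and occurrence I/O, time-series harmonization, patch labelling.

Habitat information enters the pipeline either as binary raster masks (one per
time step, all on a common grid) or directly as vector patch layers. Because
habitat in the study system only disappears or shrinks over time, earlier
layers are *harmonized* to contain all later habitat: a cell that is habitat
at any time t is forced to be habitat at every earlier time. This corrects
digitisation misalignment between map series and encodes the assumption that
no new habitat emerged.

Coordinates are planar metres (a projected CRS is assumed throughout); CRS
metadata is carried along but never reprojected — mixing CRSs is a hard error.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "GridTransform",
    "HabitatMask",
    "Patch",
    "PatchLayer",
    "OccurrenceRecords",
    "read_mask",
    "read_mask_series",
    "write_mask",
    "harmonize_time_series",
    "harmonize_vector_series",
    "label_patches",
    "read_occurrences",
    "write_occurrences",
    "read_patch_layer",
    "write_patch_layer",
]


class GridMismatchError(ValueError):
    """Raised when masks of a series do not share shape/georeferencing."""


@dataclass(frozen=True)
class GridTransform:
    """Affine cell->map mapping for a north-up, square-cell grid.

    ``x0, y0`` are the map coordinates of the grid's top-left corner;
    ``cell`` is the cell edge length in metres (> 0). Row indices grow
    southwards (decreasing y), column indices grow eastwards.
    """

    x0: float
    y0: float
    cell: float

    def __post_init__(self) -> None:
        if not self.cell > 0:
            raise ValueError(f"cell size must be > 0, got {self.cell}")

    def cell_center(self, row, col):
        """Map coordinates of the centre of cell (row, col). Accepts arrays."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell
        y = self.y0 - (np.asarray(row) + 0.5) * self.cell
        return x, y

    def cell_box(self, row: int, col: int) -> BaseGeometry:
        x = self.x0 + col * self.cell
        y = self.y0 - row * self.cell
        return box(x, y - self.cell, x + self.cell, y)

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell


@dataclass
class HabitatMask:
    """Binary habitat raster at one time step (1 = habitat)."""

    grid: np.ndarray
    transform: GridTransform
    timestep_label: int
    crs: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        vals = np.unique(self.grid)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(
                f"mask at t={self.timestep_label} is not binary (values {vals[:10]})"
            )
        self.grid = self.grid.astype(np.uint8)

    def same_grid(self, other: "HabitatMask") -> bool:
        return self.grid.shape == other.grid.shape and self.transform == other.transform


@dataclass(frozen=True)
class Patch:
    """A habitat patch: stable id, planar geometry, area in m².

    ``cells`` holds the (row, col) raster cells of the patch when it was
    derived from a mask; vector-sourced patches leave it None.
    """

    patch_id: str
    geometry: BaseGeometry
    area: float
    cells: frozenset | None = None

    def __post_init__(self) -> None:
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise ValueError(f"patch {self.patch_id}: invalid or empty geometry")
        if not self.area > 0:
            raise ValueError(f"patch {self.patch_id}: area must be > 0")


@dataclass
class PatchLayer:
    """Timestamped collection of disjoint habitat patches with stable ids."""

    timestep_label: int
    patches: list[Patch] = field(default_factory=list)
    transform: GridTransform | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        ids = [p.patch_id for p in self.patches]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate patch ids in layer t={self.timestep_label}")
        self._by_id = {p.patch_id: p for p in self.patches}

    def __len__(self) -> int:
        return len(self.patches)

    def __getitem__(self, patch_id: str) -> Patch:
        return self._by_id[patch_id]

    def __contains__(self, patch_id: str) -> bool:
        return patch_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [p.patch_id for p in self.patches]

    def geometries(self) -> list[BaseGeometry]:
        return [p.geometry for p in self.patches]

    def validate_disjoint(self) -> None:
        """Assert patches overlap pairwise with zero area (touching allowed)."""
        from shapely.strtree import STRtree

        geoms = self.geometries()
        tree = STRtree(geoms)
        for i, g in enumerate(geoms):
            for j in tree.query(g, predicate="intersects"):
                if j <= i:
                    continue
                if g.intersection(geoms[j]).area > 1e-9:
                    raise ValueError(
                        f"patches {self.patches[i].patch_id} and "
                        f"{self.patches[j].patch_id} overlap"
                    )


@dataclass
class OccurrenceRecords:
    """Point species observations: (x, y, species) in map metres."""

    x: np.ndarray
    y: np.ndarray
    species: list[str]
    n_malformed: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("occurrence coordinates must be finite")
        if any(not s for s in self.species):
            raise ValueError("species names must be non-empty")

    def __len__(self) -> int:
        return len(self.species)


# ---------------------------------------------------------------------------
# Raster I/O: ESRI ASCII grid (.asc) and single-band (Geo)TIFF via tifffile.

_GEOTIFF_PIXELSCALE = 33550
_GEOTIFF_TIEPOINT = 33922


def _read_asc(path: Path) -> tuple[np.ndarray, GridTransform]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        grid = np.loadtxt(fh)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    grid = grid.reshape(nrows, ncols)
    cell = header["cellsize"]
    transform = GridTransform(
        x0=header["xllcorner"], y0=header["yllcorner"] + nrows * cell, cell=cell
    )
    return grid, transform


def _write_asc(path: Path, grid: np.ndarray, transform: GridTransform) -> None:
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {transform.x0:.6f}\n")
        fh.write(f"yllcorner {transform.y0 - nrows * transform.cell:.6f}\n")
        fh.write(f"cellsize {transform.cell:.6f}\n")
        fh.write("NODATA_value -9999\n")
        np.savetxt(fh, grid.astype(int), fmt="%d")


def _read_tiff(path: Path) -> tuple[np.ndarray, GridTransform]:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        grid = page.asarray()
        tags = page.tags
        if _GEOTIFF_PIXELSCALE in tags and _GEOTIFF_TIEPOINT in tags:
            sx, sy = tags[_GEOTIFF_PIXELSCALE].value[:2]
            tp = tags[_GEOTIFF_TIEPOINT].value
            # tiepoint: raster (i, j, k) -> model (x, y, z); anchor at pixel origin
            i, j = tp[0], tp[1]
            x, y = tp[3], tp[4]
            if abs(sx - sy) > 1e-9:
                raise GridMismatchError(f"{path}: non-square cells ({sx} x {sy})")
            transform = GridTransform(x0=x - i * sx, y0=y + j * sy, cell=sx)
        else:
            transform = GridTransform(x0=0.0, y0=float(grid.shape[0]), cell=1.0)
    if grid.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    return grid, transform


def _write_tiff(path: Path, grid: np.ndarray, transform: GridTransform) -> None:
    import tifffile

    pixelscale = (transform.cell, transform.cell, 0.0)
    tiepoint = (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0)
    tifffile.imwrite(
        str(path),
        grid.astype(np.uint8),
        extratags=[
            (_GEOTIFF_PIXELSCALE, "d", 3, pixelscale),
            (_GEOTIFF_TIEPOINT, "d", 6, tiepoint),
        ],
    )


def read_mask(
    path: str | Path, timestep_label: int, binarize_at: float | None = None
) -> HabitatMask:
    """Read one binary habitat raster (.asc or .tif/.tiff).

    Non-binary rasters are rejected unless ``binarize_at`` is given, in which
    case values >= binarize_at map to 1 (silent coercion is forbidden).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        grid, transform = _read_tiff(path)
    else:
        grid, transform = _read_asc(path)
    vals = np.unique(grid)
    if not np.isin(vals, (0, 1)).all():
        if binarize_at is None:
            raise ValueError(
                f"{path}: raster is not binary and no binarization threshold is "
                f"configured (values include {vals[:5]})"
            )
        grid = (grid >= binarize_at).astype(np.uint8)
    return HabitatMask(grid=grid, transform=transform, timestep_label=timestep_label)


def read_mask_series(
    paths: Sequence[str | Path],
    labels: Sequence[int],
    binarize_at: float | None = None,
) -> list[HabitatMask]:
    """Read a time-ordered series of aligned habitat masks.

    All files must share grid shape and georeferencing; a mismatch is a hard
    error naming the offending file.
    """
    if len(paths) != len(labels):
        raise ValueError("paths and labels must have equal length")
    order = np.argsort(labels)
    masks = []
    ref: HabitatMask | None = None
    for k in order:
        m = read_mask(paths[k], int(labels[k]), binarize_at=binarize_at)
        if ref is not None and not m.same_grid(ref):
            raise GridMismatchError(
                f"grid mismatch: {paths[k]} does not match {paths[order[0]]}"
            )
        ref = ref or m
        masks.append(m)
    return masks


def write_mask(mask: HabitatMask, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_tiff(path, mask.grid, mask.transform)
    else:
        _write_asc(path, mask.grid, mask.transform)


# ---------------------------------------------------------------------------
# Harmonization


def harmonize_time_series(masks: Sequence[HabitatMask]) -> list[HabitatMask]:
    """Backward-propagate habitat so earlier masks contain all later habitat.

    The output mask at time t is the cell-wise union of the input masks at all
    times >= t; the latest mask is unchanged. Idempotent. Requires >= 2 masks
    with strictly increasing timestep labels on a common grid.
    """
    if len(masks) < 2:
        raise ValueError("harmonization needs at least two masks")
    labels = [m.timestep_label for m in masks]
    if any(b <= a for a, b in zip(labels, labels[1:])):
        raise ValueError(f"timestep labels must be strictly increasing, got {labels}")
    for m in masks[1:]:
        if not m.same_grid(masks[0]):
            raise GridMismatchError(f"mask at t={m.timestep_label}: grid mismatch")
    out: list[HabitatMask] = []
    acc = np.zeros_like(masks[0].grid)
    for m in reversed(masks):
        acc = acc | m.grid
        out.append(
            HabitatMask(grid=acc.copy(), transform=m.transform,
                        timestep_label=m.timestep_label, crs=m.crs)
        )
    return out[::-1]


def harmonize_vector_series(layers: Sequence[PatchLayer]) -> list[PatchLayer]:
    """Vector analogue of mask harmonization.

    The layer at time t becomes the geometric union of all layers at times
    >= t, re-split into connected patches with deterministic ids (north-to-
    south, then west-to-east by bounding box). The latest layer is unchanged.
    """
    if len(layers) < 2:
        raise ValueError("harmonization needs at least two layers")
    labels = [la.timestep_label for la in layers]
    if any(b <= a for a, b in zip(labels, labels[1:])):
        raise ValueError(f"timestep labels must be strictly increasing, got {labels}")
    out: list[PatchLayer] = [layers[-1]]
    acc = unary_union([p.geometry for p in layers[-1].patches])
    for layer in reversed(layers[:-1]):
        acc = unary_union([acc] + [p.geometry for p in layer.patches])
        parts = list(acc.geoms) if acc.geom_type == "MultiPolygon" else [acc]
        parts.sort(key=lambda g: (-g.bounds[3], g.bounds[0]))
        patches = [
            Patch(patch_id=f"p{k:04d}", geometry=g, area=g.area)
            for k, g in enumerate(parts)
        ]
        out.append(PatchLayer(timestep_label=layer.timestep_label, patches=patches,
                              crs=layer.crs))
    return out[::-1]


# ---------------------------------------------------------------------------
# Patch labelling


def label_patches(
    mask: HabitatMask, connectivity: int = 8, min_patch_area: float = 0.0
) -> PatchLayer:
    """Group connected habitat cells into patches with polygon geometries.

    Patch ids are deterministic given the mask: patches are numbered in
    row-major order of their first (top-left) cell. Area is
    cell_count x cell_area. 8-neighbour connectivity is the default, so
    diagonally adjacent habitat cells belong to one patch.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labeled = measure.label(mask.grid, connectivity=1 if connectivity == 4 else 2)
    n = labeled.max()
    if n == 0:
        warnings.warn(f"mask at t={mask.timestep_label} has no habitat cells")
        return PatchLayer(timestep_label=mask.timestep_label, patches=[],
                          transform=mask.transform, crs=mask.crs)
    # order labels by row-major position of each patch's first cell
    first_cell = np.full(n + 1, np.iinfo(np.int64).max, dtype=np.int64)
    flat = labeled.ravel()
    nz = np.flatnonzero(flat)
    np.minimum.at(first_cell, flat[nz], nz)
    order = np.argsort(first_cell[1:], kind="stable")
    t = mask.transform
    all_rows, all_cols = np.nonzero(labeled)
    cell_labels = labeled[all_rows, all_cols]
    sorter = np.argsort(cell_labels, kind="stable")
    ends = np.searchsorted(cell_labels[sorter], np.arange(1, n + 1), side="right")
    patches = []
    for new_idx, lab0 in enumerate(order):
        sel = sorter[0 if lab0 == 0 else ends[lab0 - 1]: ends[lab0]]
        rows, cols = all_rows[sel], all_cols[sel]
        area = len(rows) * t.cell_area
        if area < min_patch_area:
            continue
        geom = unary_union([t.cell_box(r, c) for r, c in zip(rows, cols)])
        patches.append(
            Patch(
                patch_id=f"p{new_idx:04d}",
                geometry=geom,
                area=area,
                cells=frozenset(zip(rows.tolist(), cols.tolist())),
            )
        )
    return PatchLayer(timestep_label=mask.timestep_label, patches=patches,
                      transform=mask.transform, crs=mask.crs)


# ---------------------------------------------------------------------------
# Occurrence CSV I/O


def read_occurrences(path: str | Path) -> OccurrenceRecords:
    """Read point occurrences from CSV with header ``x,y,species``.

    Malformed rows (non-numeric coordinates, empty species) are skipped and
    logged with their line number; an optional ``site_id`` column is ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    xs: list[float] = []
    ys: list[float] = []
    sp: list[str] = []
    n_bad = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"x", "y", "species"} <= set(
            reader.fieldnames
        ):
            raise ValueError(
                f"{path}: required columns x,y,species not found "
                f"(got {reader.fieldnames})"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                x = float(row["x"])
                y = float(row["y"])
            except (TypeError, ValueError):
                logger.warning("%s line %d: non-numeric coordinates, skipped", path, lineno)
                n_bad += 1
                continue
            species = (row["species"] or "").strip()
            if not species or not (np.isfinite(x) and np.isfinite(y)):
                logger.warning("%s line %d: malformed row, skipped", path, lineno)
                n_bad += 1
                continue
            xs.append(x)
            ys.append(y)
            sp.append(species)
    if not sp:
        warnings.warn(f"{path}: no valid occurrence records")
    return OccurrenceRecords(x=np.array(xs), y=np.array(ys), species=sp,
                             n_malformed=n_bad)


def write_occurrences(records: OccurrenceRecords, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "species"])
        for x, y, s in zip(records.x, records.y, records.species):
            w.writerow([f"{x:.12g}", f"{y:.12g}", s])


# ---------------------------------------------------------------------------
# Vector patch-layer I/O (GeoJSON)


def write_patch_layer(layer: PatchLayer, path: str | Path) -> None:
    """Write a patch layer as GeoJSON with a ``patch_id`` property."""
    features = [
        {
            "type": "Feature",
            "properties": {"patch_id": p.patch_id, "area_m2": p.area},
            "geometry": mapping(p.geometry),
        }
        for p in layer.patches
    ]
    doc = {
        "type": "FeatureCollection",
        "metadata": {"timestep_label": layer.timestep_label, "crs": layer.crs},
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_patch_layer(path: str | Path, timestep_label: int | None = None) -> PatchLayer:
    """Read a GeoJSON patch layer; features must carry a ``patch_id`` property."""
    with open(path) as fh:
        doc = json.load(fh)
    meta = doc.get("metadata", {})
    label = timestep_label if timestep_label is not None else meta.get("timestep_label")
    if label is None:
        raise ValueError(f"{path}: no timestep label in file or argument")
    patches = []
    for k, feat in enumerate(doc.get("features", [])):
        geom = shape(feat["geometry"])
        pid = feat.get("properties", {}).get("patch_id")
        if pid is None:
            raise ValueError(f"{path}: feature {k} lacks a patch_id property")
        patches.append(Patch(patch_id=str(pid), geometry=geom, area=geom.area))
    return PatchLayer(timestep_label=int(label), patches=patches,
                      crs=meta.get("crs"))
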