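"""Patch x species occurrence matrix, Jaccard beta-diversity, gamma richness.

Occurrence points are snapped to the current-time patch that contains them
(closed containment: boundary points belong to the patch). Repeat visits
collapse to presence/absence — the monitoring data carry no abundances, so
all diversity metrics here are incidence-based.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from shapely.geometry import Point
from shapely.strtree import STRtree

from .landscape_io import OccurrenceRecords, PatchLayer

__all__ = [
    "OccurrenceMatrix",
    "BetaMatrix",
    "build_occurrence_matrix",
    "jaccard_beta",
    "beta_matrix",
    "gamma_richness",
]


@dataclass
class OccurrenceMatrix:
    """Binary presence/absence matrix over current-time patches with data.

    Rows are patch ids that received at least one occurrence point; columns
    are species observed in at least one retained patch. ``n_dropped`` counts
    points that fell outside every patch.
    """

    presence: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        vals = self.presence.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix must be binary")
        self.presence = self.presence.astype(np.int8)

    @property
    def patch_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    def species_set(self, patch_id: str) -> frozenset:
        row = self.presence.loc[patch_id]
        return frozenset(row.index[row == 1])

    def to_csv(self, path: str | Path) -> None:
        self.presence.to_csv(path, index_label="patch_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceMatrix":
        return cls(presence=pd.read_csv(path, index_col="patch_id"))


@dataclass
class BetaMatrix:
    """Symmetric Jaccard dissimilarity matrix over patches with data."""

    patch_ids: list[str]
    beta: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        if b.shape != (len(self.patch_ids),) * 2:
            raise ValueError("beta matrix shape mismatch")
        if np.nanmax(b, initial=0) > 1 + 1e-12 or np.nanmin(b, initial=0) < -1e-12:
            raise ValueError("Jaccard dissimilarities must lie in [0, 1]")
        self.beta = b

    def lookup(self, i: str, j: str) -> float:
        a = self.patch_ids.index(i)
        b = self.patch_ids.index(j)
        return float(self.beta[a, b])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.beta, index=self.patch_ids, columns=self.patch_ids).to_csv(
            path, index_label="patch_id"
        )


def build_occurrence_matrix(
    records: OccurrenceRecords, layer: PatchLayer
) -> OccurrenceMatrix:
    """Assign occurrence points to containing patches and build the matrix.

    Containment is closed (points on a patch boundary count as inside; a
    point on a shared boundary goes to the lexicographically smallest patch
    id, which is deterministic). Points outside all patches are dropped and
    counted. Patches without any point and species never assigned are absent
    from the matrix.
    """
    if len(layer) == 0:
        raise ValueError("current patch layer is empty")
    geoms = layer.geometries()
    ids = layer.ids
    tree = STRtree(geoms)
    points = [Point(x, y) for x, y in zip(records.x, records.y)]
    cells: dict[tuple[str, str], int] = {}
    n_dropped = 0
    if points:
        q_idx, t_idx = tree.query(points, predicate="intersects")
        hits: dict[int, list[int]] = {}
        for q, t in zip(q_idx, t_idx):
            hits.setdefault(int(q), []).append(int(t))
        for k in range(len(points)):
            if k not in hits:
                n_dropped += 1
                continue
            pid = min(ids[t] for t in hits[k])
            cells[(pid, records.species[k])] = 1
    if n_dropped:
        warnings.warn(f"{n_dropped} occurrence points fell outside all patches")
    if not cells:
        warnings.warn("no occurrence points landed in any patch")
        return OccurrenceMatrix(presence=pd.DataFrame(), n_dropped=n_dropped)
    kept_patches = sorted({p for p, _ in cells})
    kept_species = sorted({s for _, s in cells})
    mat = pd.DataFrame(0, index=kept_patches, columns=kept_species, dtype=np.int8)
    for (p, s) in cells:
        mat.loc[p, s] = 1
    return OccurrenceMatrix(presence=mat, n_dropped=n_dropped)


def jaccard_beta(m: OccurrenceMatrix, i: str, j: str) -> float:
    """Jaccard dissimilarity 1 - |Si ∩ Sj| / |Si ∪ Sj| between two patches.

    Returns NaN (flagged missing) if either patch has no species, so the
    pair is excluded downstream rather than silently scored.
    """
    a = m.presence.loc[i].to_numpy(bool)
    b = m.presence.loc[j].to_numpy(bool)
    union = np.count_nonzero(a | b)
    if a.sum() == 0 or b.sum() == 0:
        return float("nan")
    inter = np.count_nonzero(a & b)
    return 1.0 - inter / union


def beta_matrix(m: OccurrenceMatrix) -> BetaMatrix:
    """All pairwise Jaccard dissimilarities of the occurrence matrix."""
    x = m.presence.to_numpy(bool)
    if x.shape[0] < 2:
        return BetaMatrix(patch_ids=m.patch_ids, beta=np.zeros((x.shape[0],) * 2))
    beta = squareform(pdist(x, metric="jaccard"))
    empty = x.sum(axis=1) == 0
    beta[empty, :] = np.nan
    beta[:, empty] = np.nan
    np.fill_diagonal(beta, 0.0)
    return BetaMatrix(patch_ids=m.patch_ids, beta=beta)


def gamma_richness(m: OccurrenceMatrix, member_patches: Iterable[str]) -> float:
    """Total species richness (size of the union of species sets) over members.

    Member ids absent from the matrix are ignored; if no member has data the
    result is NaN (flagged missing).
    """
    members = [p for p in member_patches if p in m.presence.index]
    if not members:
        return float("nan")
    sub = m.presence.loc[members].to_numpy(bool)
    return float(np.count_nonzero(sub.any(axis=0)))
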