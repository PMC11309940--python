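"""Gamma diversity vs metacommunity size, and time trends of metacommunities.

Metacommunity theory expects regional (gamma) species richness to scale with
metacommunity size — total habitat area, number of patches, or network
"diameter" in the mean-shortest-path sense. These analyses correlate gamma
richness of delineated metacommunities against log-transformed size metrics
(the richness itself is left untransformed), and summarise how patch counts
and areas per metacommunity change along the habitat time series.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .delineation import Delineation
from .diversity import OccurrenceMatrix, gamma_richness
from .habitat_network import HabitatNetwork, network_diameter
from .landscape_io import PatchLayer

__all__ = [
    "build_gamma_records",
    "correlate_gamma",
    "summarize_timeseries",
    "PREDICTORS",
]

PREDICTORS = ("total_area", "n_patches", "diameter")


def build_gamma_records(
    d: Delineation,
    matrix: OccurrenceMatrix,
    source_network: HabitatNetwork | None = None,
    source_layer: PatchLayer | None = None,
) -> pd.DataFrame:
    """One record per metacommunity: gamma richness and size metrics.

    Size metrics (total_area, n_patches, diameter) are measured on the
    delineation's *source* time step, i.e. the historical extent that defines
    the metacommunity; gamma is the union richness over member *current*
    patches. Metacommunities that are singletons or have species data in
    fewer than two patches are flagged ``included=False`` and skipped by the
    correlation analyses (a single data patch cannot separate within-patch
    from regional diversity).
    """
    rows = []
    data_ids = set(matrix.patch_ids)
    for mc in d.metacommunities:
        n_data = len(data_ids & set(mc.members))
        gamma = gamma_richness(matrix, mc.members)
        if source_layer is not None and mc.source_patches:
            areas = [source_layer[p].area for p in mc.source_patches]
            total_area = float(np.sum(areas))
            n_patches = len(mc.source_patches)
        else:
            total_area = np.nan
            n_patches = len(mc.members)
        if source_network is not None and mc.source_patches:
            diam = network_diameter(source_network, mc.source_patches)
        else:
            diam = np.nan
        rows.append(
            dict(
                mc_id=mc.mc_id,
                gamma=gamma,
                total_area=total_area,
                n_patches=n_patches,
                diameter=diam,
                n_data_patches=n_data,
                included=(not mc.singleton) and n_data >= 2 and np.isfinite(gamma),
            )
        )
    return pd.DataFrame(rows)


def correlate_gamma(
    records: pd.DataFrame,
    predictor: str,
    transform: Literal["log", "none"] = "log",
    transform_gamma: bool = False,
) -> dict:
    """Pearson correlation of (optionally log-transformed) size vs gamma.

    Records flagged excluded and records with missing predictor values are
    dropped; at least three usable records are required. Natural log is used
    (the correlation is invariant to log base). Returns a dict with predictor,
    transform, pearson_r, p_value and n; a zero-variance predictor flags r as
    NaN instead of raising.
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"predictor must be one of {PREDICTORS}")
    sub = records[records["included"]].copy()
    x = sub[predictor].to_numpy(dtype=float)
    y = sub["gamma"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if transform == "log":
        if (x <= 0).any():
            raise ValueError(f"{predictor}: log transform needs positive values")
        x = np.log(x)
    if transform_gamma:
        y = np.log(y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 usable records, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return dict(predictor=predictor, transform=transform,
                    pearson_r=float("nan"), p_value=float("nan"), n=n)
    r, p = stats.pearsonr(x, y)
    return dict(predictor=predictor, transform=transform,
                pearson_r=float(r), p_value=float(p), n=n)


def correlation_table(
    records: pd.DataFrame, transform: Literal["log", "none"] = "log"
) -> pd.DataFrame:
    """Correlations of gamma against every size predictor."""
    rows = []
    for pred in PREDICTORS:
        try:
            rows.append(correlate_gamma(records, pred, transform=transform))
        except ValueError:
            rows.append(dict(predictor=pred, transform=transform,
                             pearson_r=float("nan"), p_value=float("nan"), n=0))
    return pd.DataFrame(rows)


def summarize_timeseries(
    delineations: Sequence[Delineation],
    layers: Sequence[PatchLayer],
    matrix: OccurrenceMatrix,
) -> pd.DataFrame:
    """Mean patch count and mean patch area per metacommunity over time.

    For each time step's delineation, metacommunities qualify when they hold
    species data in more than one current patch; over those, the mean member
    patch count and the mean member patch area (both at the source time step)
    are reported. Steps with no qualifying metacommunity yield NaN.
    """
    by_label = {la.timestep_label: la for la in layers}
    data_ids = set(matrix.patch_ids)
    rows = []
    for d in delineations:
        if d.timestep_label is None or d.timestep_label not in by_label:
            continue
        src = by_label[d.timestep_label]
        counts = []
        mean_areas = []
        for mc in d.metacommunities:
            if len(data_ids & set(mc.members)) < 2:
                continue
            counts.append(len(mc.source_patches))
            mean_areas.append(
                float(np.mean([src[p].area for p in mc.source_patches]))
            )
        rows.append(
            dict(
                timestep=d.timestep_label,
                theta=d.theta,
                n_metacommunities=len(counts),
                mean_n_patches=float(np.mean(counts)) if counts else float("nan"),
                mean_patch_area=float(np.mean(mean_areas)) if mean_areas else float("nan"),
            )
        )
    return pd.DataFrame(rows).sort_values("timestep").reset_index(drop=True)


def scatter_plot(
    records: pd.DataFrame, predictor: str, path, transform: str = "log"
) -> None:
    """Optional predictor-vs-gamma scatter written as SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = records[records["included"]]
    x = sub[predictor].to_numpy(dtype=float)
    if transform == "log":
        x = np.log(x)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(x, sub["gamma"], s=18)
    ax.set_xlabel(f"{'log ' if transform == 'log' else ''}{predictor}")
    ax.set_ylabel("gamma richness")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
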