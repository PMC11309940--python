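"""Score metacommunity delineations against pairwise beta-diversity.

The evaluation asks: do patch pairs *within* a delineated metacommunity have
lower species-composition dissimilarity than pairs *between* metacommunities?
Pairs are restricted to a surrounding-distance limit (default 15 km) because
more distant pairs saturate at dissimilarity 1 and carry no signal.

Beta values are binarized at the median over the shared pair universe, and
each delineation's within/between labelling is scored against the low/high
classes with accuracy, precision and Cohen's kappa; a two-sided Welch t-test
checks that the within and between beta distributions differ, and a
direction flag records whether they differ the expected way (mean within <
mean between). The delineation maximising kappa among those with the right
direction is flagged ``best``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .delineation import Delineation
from .diversity import OccurrenceMatrix, beta_matrix
from .habitat_network import pairwise_edge_distance
from .landscape_io import PatchLayer

__all__ = [
    "enumerate_pairs",
    "classify_pairs",
    "binarize_beta",
    "agreement_metrics",
    "beta_distribution_test",
    "evaluate_all",
    "DegenerateEvaluation",
    "PAIRING_LIMIT_M",
]

#: Default surrounding-distance limit for patch pairs (metres).
PAIRING_LIMIT_M = 15_000.0


class DegenerateEvaluation(RuntimeError):
    """Raised when an evaluation cannot be scored (e.g. no between pairs)."""


def enumerate_pairs(
    matrix: OccurrenceMatrix, layer: PatchLayer, limit: float = PAIRING_LIMIT_M
) -> pd.DataFrame:
    """All unordered pairs of data patches within the separation limit.

    Separation is the edge-to-edge Euclidean distance between patch
    boundaries, the same convention used for network edges. Returns a frame
    with columns patch_i, patch_j, separation_m.
    """
    data_ids = [pid for pid in matrix.patch_ids if pid in layer]
    if len(data_ids) < 2:
        return pd.DataFrame(columns=["patch_i", "patch_j", "separation_m"])
    sub = PatchLayer(
        timestep_label=layer.timestep_label,
        patches=[layer[pid] for pid in data_ids],
    )
    dm = pairwise_edge_distance(sub)
    rows = []
    for a in range(len(data_ids)):
        for b in range(a + 1, len(data_ids)):
            if dm.d[a, b] <= limit:
                rows.append((data_ids[a], data_ids[b], float(dm.d[a, b])))
    return pd.DataFrame(rows, columns=["patch_i", "patch_j", "separation_m"])


def classify_pairs(
    pairs: pd.DataFrame, d: Delineation
) -> tuple[pd.Series, int]:
    """Label each pair 'within'/'between' under a delineation.

    Pairs touching unassigned patches or singleton metacommunities are
    ineligible (NaN label); the count of exclusions is returned alongside.
    """
    member = d.membership(include_singletons=False)
    labels = []
    n_excluded = 0
    for i, j in zip(pairs["patch_i"], pairs["patch_j"]):
        mi, mj = member.get(i), member.get(j)
        if mi is None or mj is None:
            labels.append(None)
            n_excluded += 1
        else:
            labels.append("within" if mi == mj else "between")
    return pd.Series(labels, index=pairs.index, dtype="object"), n_excluded


def binarize_beta(
    beta: Sequence[float], threshold: float | Literal["median"] = "median"
) -> tuple[pd.Series, float]:
    """Binarize beta values into 'low' (< threshold) / 'high' (>= threshold).

    With the default median threshold at most half the values fall strictly
    below it. All-identical values are degenerate and raise.
    """
    vals = np.asarray(beta, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two beta values to binarize")
    thr = float(np.median(vals)) if threshold == "median" else float(threshold)
    if np.nanmin(vals) == np.nanmax(vals):
        raise DegenerateEvaluation("all beta values identical; cannot binarize")
    classes = pd.Series(np.where(vals < thr, "low", "high"))
    return classes, thr


def agreement_metrics(contingency: np.ndarray) -> tuple[float, float, float]:
    """Accuracy, precision and Cohen's kappa of a within/between x low/high table.

    Rows: pair class (within, between); columns: beta class (low, high).
    Agreement means within&low or between&high. Precision takes (within, low)
    as the positive cell: n_within_low / n_low. Kappa is (p_o - p_e)/(1 - p_e)
    with p_e from the row/column marginals; degenerate marginals (p_e = 1)
    flag kappa as NaN.
    """
    c = np.asarray(contingency, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("contingency must be 2x2")
    n = c.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    p_o = (c[0, 0] + c[1, 1]) / n
    col_low = c[:, 0].sum()
    precision = c[0, 0] / col_low if col_low > 0 else float("nan")
    row_m = c.sum(axis=1) / n
    col_m = c.sum(axis=0) / n
    p_e = row_m[0] * col_m[0] + row_m[1] * col_m[1]
    kappa = float("nan") if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
    return float(p_o), float(precision), float(kappa)


def beta_distribution_test(
    within: Sequence[float],
    between: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float, float, bool]:
    """Two-sided t-test on within vs between beta distributions.

    Welch (unequal variance) by default; set ``equal_var=True`` for the
    pooled Student variant. Returns (t, p, df, direction_ok) where
    direction_ok is True when mean(within) < mean(between) — the ordering a
    well-chosen delineation should produce.
    """
    w = np.asarray(within, dtype=float)
    b = np.asarray(between, dtype=float)
    if len(w) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two values")
    res = stats.ttest_ind(w, b, equal_var=equal_var)
    direction_ok = bool(np.mean(w) < np.mean(b))
    return float(res.statistic), float(res.pvalue), float(res.df), direction_ok


def evaluate_all(
    delineations: Sequence[Delineation],
    matrix: OccurrenceMatrix,
    layer: PatchLayer,
    limit: float = PAIRING_LIMIT_M,
    threshold: float | Literal["median"] = "median",
    equal_var: bool = False,
    pairs: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every delineation on a shared pair universe.

    The pair universe (data patches within ``limit``) and the beta
    binarization threshold are computed once, so changing the delineation
    only re-distributes pairs into within/between — kappa values are then
    comparable across time steps and sources. Per-delineation eligibility
    exclusions (singletons, unassigned) are reported in ``n_excluded``.

    Returns (results, diagnostics): one results row per delineation with a
    ``best`` flag on the row maximising kappa among direction_ok rows, and a
    per-pair diagnostics frame (separation, beta, classes per delineation).
    """
    if pairs is None:
        pairs = enumerate_pairs(matrix, layer, limit=limit)
    if len(pairs) == 0:
        raise DegenerateEvaluation("no eligible patch pairs within the limit")
    bm = beta_matrix(matrix)
    idx = {pid: k for k, pid in enumerate(bm.patch_ids)}
    beta_vals = np.array(
        [bm.beta[idx[i], idx[j]] for i, j in zip(pairs["patch_i"], pairs["patch_j"])]
    )
    keep = np.isfinite(beta_vals)
    pairs = pairs.loc[keep].reset_index(drop=True)
    beta_vals = beta_vals[keep]
    beta_class, thr = binarize_beta(beta_vals, threshold=threshold)

    diag = pairs.copy()
    diag["beta"] = beta_vals
    diag["beta_class"] = beta_class.values

    rows = []
    for d in delineations:
        pair_class, n_excluded = classify_pairs(pairs, d)
        eligible = pair_class.notna()
        pc = pair_class[eligible]
        bc = beta_class[eligible.values].reset_index(drop=True)
        n_within = int((pc == "within").sum())
        n_between = int((pc == "between").sum())
        diag[f"pair_class[{d.source}]"] = pair_class.values
        if n_within < 2 or n_between < 2:
            rows.append(
                dict(source=d.source, timestep=d.timestep_label, theta=d.theta,
                     n_within=n_within, n_between=n_between, n_excluded=n_excluded,
                     accuracy=np.nan, precision=np.nan, kappa=np.nan,
                     t_stat=np.nan, p_value=np.nan, direction_ok=False,
                     degenerate=True)
            )
            continue
        pcv = pc.reset_index(drop=True)
        cont = np.array(
            [
                [(pcv.eq("within") & bc.eq("low")).sum(),
                 (pcv.eq("within") & bc.eq("high")).sum()],
                [(pcv.eq("between") & bc.eq("low")).sum(),
                 (pcv.eq("between") & bc.eq("high")).sum()],
            ],
            dtype=float,
        )
        acc, prec, kappa = agreement_metrics(cont)
        bv = beta_vals[eligible.values]
        t, p, _, direction_ok = beta_distribution_test(
            bv[pcv == "within"], bv[pcv == "between"], equal_var=equal_var
        )
        rows.append(
            dict(source=d.source, timestep=d.timestep_label, theta=d.theta,
                 n_within=n_within, n_between=n_between, n_excluded=n_excluded,
                 accuracy=acc, precision=prec, kappa=kappa,
                 t_stat=t, p_value=p, direction_ok=direction_ok,
                 degenerate=False)
        )
    results = pd.DataFrame(rows)
    results["best"] = False
    ok = results["direction_ok"] & results["kappa"].notna()
    if ok.any():
        best_idx = results.loc[ok, "kappa"].idxmax()
        results.loc[best_idx, "best"] = True
    results.attrs["beta_threshold"] = thr
    return results, diag
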