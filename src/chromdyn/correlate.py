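"""Mark-signal / expression correlation over the time course, per gene set.

For each gene in a user-supplied set (one id per line), expression (FPKM) and
windowed mark signal (RPM) are first averaged across replicates within each
time point, then a Pearson r is computed over the n time-point pairs. With
only a handful of time points r is reported without a p-value. A companion
stage-wise clustering orders a gene set by when it peaks.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .timecourse import ExpressionMatrix, SignalMatrix, timepoint_means, _zscore_rows


def read_gene_set(path) -> list[str]:
    """Plain-text gene set: one id per line, blank lines and '#' ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return ids


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xc, yc = x - x.mean(), y - y.mean()
    sx = float(np.sqrt((xc ** 2).sum()))
    sy = float(np.sqrt((yc ** 2).sum()))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float((xc * yc).sum() / (sx * sy))


def timecourse_correlation(expr: ExpressionMatrix, signal: SignalMatrix,
                           gene_set: list[str] | None = None) -> pd.DataFrame:
    """Per-gene Pearson r between replicate-mean FPKM and RPM across time.

    Returns a frame with columns ``r, n_timepoints, mark, scheme, note``;
    genes with zero variance in either vector get r = NaN and a reason.
    """
    e_means = timepoint_means(expr.values, expr.meta)
    s_means = timepoint_means(signal.values, signal.meta)
    if list(e_means.columns) != list(s_means.columns):
        raise ValueError("expression and signal cover different timepoints")
    n_tp = e_means.shape[1]
    if n_tp < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    if gene_set is None:
        gene_set = [g for g in e_means.index if g in s_means.index]
    missing = [g for g in gene_set if g not in e_means.index
               or g not in s_means.index]
    if missing:
        raise KeyError(f"genes absent from a matrix: {missing[:5]}")
    rows = []
    for g in gene_set:
        x = e_means.loc[g].to_numpy()
        y = s_means.loc[g].to_numpy()
        r = pearson_r(x, y)
        note = ""
        if np.isnan(r):
            note = ("zero variance in expression" if np.ptp(x) == 0
                    else "zero variance in signal")
        rows.append({"gene": g, "r": r, "n_timepoints": n_tp,
                     "mark": signal.mark, "scheme": signal.scheme, "note": note})
    return pd.DataFrame(rows).set_index("gene")


def stagewise_heatmap_table(expr: ExpressionMatrix, gene_set: list[str],
                            k: int = 3, seed: int = 0) -> pd.DataFrame:
    """Cluster a gene set by the stage where it is expressed.

    Z-scored timepoint means are k-means clustered (default k = 3: the
    normal / inflammation / tumor trichotomy) and rows ordered by cluster then
    peak time — a plot-ready table for a stage-wise heatmap. Constant genes
    are assigned but flagged ``zero_variance``.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    if k > len(gene_set):
        raise ValueError(f"k={k} exceeds the {len(gene_set)} genes")
    means = timepoint_means(expr.values, expr.meta).loc[gene_set]
    Z = _zscore_rows(means)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
    tab = pd.DataFrame(Z, index=means.index, columns=means.columns)
    tab["zero_variance"] = means.std(axis=1).to_numpy() == 0
    tab["peak_timepoint"] = means.columns[np.argmax(Z, axis=1)]
    tab["peak_order"] = np.argmax(Z, axis=1)
    # order clusters by their mean peak time so the heatmap reads as a stage cascade
    order = pd.Series(km.labels_, index=means.index, name="raw")
    peak_by_cluster = tab.groupby(order)["peak_order"].mean().sort_values()
    remap = {raw: i + 1 for i, raw in enumerate(peak_by_cluster.index)}
    tab["stage_cluster"] = order.map(remap)
    tab = tab.sort_values(["stage_cluster", "peak_order"])
    tab.index.name = "gene"
    return tab.drop(columns="peak_order")
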