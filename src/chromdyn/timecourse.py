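"""Time-course analysis of expression and windowed histone-mark signal.

Normalization (TMM scaling factors, FPKM, windowed RPM), detection of dynamic
features by ordinary least squares on a degree-4 polynomial in time with an
R-squared cutoff (default 0.7, strict), and k-means clustering of standardized
dynamic profiles with silhouette-guided choice of k over 3..9 unless k is
fixed. The same machinery serves gene expression and per-gene enhancer signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .grid import BinnedTrack

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #

def _check_meta(values: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "timepoint", "week", "replicate"}
    if not required <= set(meta.columns):
        raise ValueError(f"sample metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample").loc[list(values.columns)].reset_index()
    return meta


@dataclass
class ExpressionMatrix:
    """Genes x samples values plus sample metadata (timepoint, week, replicate)."""

    values: pd.DataFrame
    meta: pd.DataFrame
    normalization: str = "counts"   # counts | fpkm | tmm-cpm | log2

    def __post_init__(self):
        self.meta = _check_meta(self.values, self.meta)


@dataclass
class SignalMatrix:
    """Genes x samples RPM for one mark over a named window scheme."""

    values: pd.DataFrame
    meta: pd.DataFrame
    mark: str
    scheme: str

    def __post_init__(self):
        self.meta = _check_meta(self.values, self.meta)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("RPM values must be non-negative")


# --------------------------------------------------------------------------- #
# normalization
# --------------------------------------------------------------------------- #

def tmm_factors(counts: pd.DataFrame, trim_M: float = 0.30,
                trim_A: float = 0.05, ref: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (edgeR's TMM).

    For each sample vs a reference column, gene-wise log2 abundance ratios (M)
    and mean log2 abundances (A) are computed on genes expressed in both;
    genes in the extreme ``trim_M`` tails of M and ``trim_A`` tails of A are
    discarded and the factor is 2 to the precision-weighted mean of the
    surviving M values. Factors are rescaled to geometric mean 1.

    The default reference is the column whose upper-quartile (of counts
    scaled by library size) is closest to the mean upper-quartile.
    """
    X = counts.to_numpy(dtype=np.float64)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    if ref is None:
        f75 = np.array([np.quantile(X[:, j] / lib[j], 0.75)
                        for j in range(X.shape[1])])
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_j = list(counts.columns).index(ref)
    xr, Nr = X[:, ref_j], lib[ref_j]

    log_factors = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref_j:
            continue
        x, N = X[:, j], lib[j]
        keep = (x > 0) & (xr > 0)
        if not keep.any():
            raise ValueError(f"sample {counts.columns[j]!r} shares no expressed "
                             "genes with the reference")
        M = np.log2((x[keep] / N) / (xr[keep] / Nr))
        A = 0.5 * np.log2((x[keep] / N) * (xr[keep] / Nr))
        w = (N - x[keep]) / (N * x[keep]) + (Nr - xr[keep]) / (Nr * xr[keep])
        n = len(M)
        rM, rA = rankdata(M), rankdata(A)
        sel = ((rM >= n * trim_M + 1) & (rM <= n * (1 - trim_M))
               & (rA >= n * trim_A + 1) & (rA <= n * (1 - trim_A)))
        if not sel.any():
            sel = np.ones(n, dtype=bool)
        wm = np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel])
        log_factors[j] = wm
    log_factors -= log_factors.mean()      # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")


def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million mapped fragments.

    ``fpkm = count / (length/1e3) / (library/1e6)``. Library sizes default to
    column sums.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    if (lengths <= 0).any():
        bad = counts.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)


# --------------------------------------------------------------------------- #
# windowed signal
# --------------------------------------------------------------------------- #

# scheme name -> (anchor, inner_bp, outer_bp); inner > 0 means an annulus that
# excludes the +/- inner core (for enhancer schemes this removes TSS-proximal
# nucleosome-free-region signal).
WINDOW_SCHEMES: dict[str, tuple[str, int, int]] = {
    "tss_1.5kb": ("tss", 0, 1_500),
    "tss_1.5-10kb": ("tss", 1_500, 10_000),
    "tss_10-100kb": ("tss", 10_000, 100_000),
    "genebody_2kb": ("gene_body", 0, 2_000),
    "genebody_1.5-10kb": ("gene_body", 1_500, 10_000),
    "genebody_10-100kb": ("gene_body", 10_000, 100_000),
}


def _window_bounds(gene: pd.Series, anchor: str, inner: int, outer: int):
    """Raw (outer_start, outer_end, core_start, core_end) for one gene.

    Bounds may run past chromosome edges; callers clip at bin lookup. For a
    solid window (inner == 0) the core is empty.
    """
    if anchor == "tss":
        c = int(gene["start"]) if gene.get("strand", "+") != "-" else int(gene["end"])
        s = e = c
    elif anchor == "gene_body":
        s, e = int(gene["start"]), int(gene["end"])
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return s - outer, e + outer, s - inner, e + inner


def window_rpm(track: BinnedTrack, genes: pd.DataFrame, scheme: str) -> pd.Series:
    """Reads-per-million signal per gene over a named window scheme.

    Bins overlapping the window count fully (200-bp accounting); windows are
    truncated at chromosome ends with a logged note. RPM = window count sum /
    library size x 1e6.
    """
    if scheme not in WINDOW_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; "
                         f"known: {sorted(WINDOW_SCHEMES)}")
    anchor, inner, outer = WINDOW_SCHEMES[scheme]
    if track.library_size <= 0:
        raise ValueError("track has zero library size")
    grid = track.grid
    out = {}
    truncated = 0
    for _, g in genes.iterrows():
        total = 0.0
        if g["chrom"] in grid.chroms:
            clen = grid.chrom_length(g["chrom"])
            olo, ohi, clo, chi = _window_bounds(g, anchor, inner, outer)
            if olo < 0 or ohi > clen:
                truncated += 1
            blo, bhi = grid.interval_bins(g["chrom"], olo, ohi)
            sel = track.values[blo:bhi]
            if inner > 0:
                # annulus: drop every bin overlapping the excluded core
                cblo, cbhi = grid.interval_bins(g["chrom"], clo, chi)
                idx = np.arange(blo, bhi)
                sel = sel[(idx < cblo) | (idx >= cbhi)]
            total = float(sel.sum())
        out[g["name"]] = total / track.library_size * 1e6
    if truncated:
        logger.info("window_rpm: %d windows truncated at chromosome ends",
                    truncated)
    return pd.Series(out, name=scheme)


def signal_matrix(tracks: dict, genes: pd.DataFrame, scheme: str,
                  meta: pd.DataFrame, mark: str) -> SignalMatrix:
    """Assemble a genes x samples SignalMatrix from per-sample tracks.

    ``tracks`` maps sample name -> BinnedTrack; ``meta`` must cover the same
    sample names.
    """
    cols = {s: window_rpm(tr, genes, scheme) for s, tr in tracks.items()}
    values = pd.DataFrame(cols)
    return SignalMatrix(values=values, meta=meta, mark=mark, scheme=scheme)


# --------------------------------------------------------------------------- #
# polynomial fits
# --------------------------------------------------------------------------- #

@dataclass
class TimecourseResult:
    """Per-feature degree-d fit, R-squared, dynamic flag and cluster id."""

    table: pd.DataFrame          # coef_0..coef_d, r2, dynamic, cluster
    degree: int
    r2_cutoff: float | None = None
    chosen_k: int | None = None
    silhouette: pd.DataFrame | None = None

    @property
    def dynamic_features(self) -> pd.Index:
        return self.table.index[self.table["dynamic"]]


def fit_polynomial_timecourse(values: pd.DataFrame, meta: pd.DataFrame,
                              degree: int = 4) -> TimecourseResult:
    """OLS degree-``degree`` polynomial fit of every feature against time.

    Replicates are repeated observations at the same time coordinate; time
    (weeks) is centred and scaled before building the Vandermonde design for
    conditioning. R2 = 1 - SSR/SST, clamped to [0, 1]; zero-variance features
    get R2 = 0 by convention.
    """
    meta = _check_meta(values, meta)
    t = meta["week"].to_numpy(dtype=np.float64)
    if len(np.unique(t)) < degree + 1:
        raise ValueError(
            f"{len(np.unique(t))} distinct timepoints cannot support degree "
            f"{degree}; lower the degree")
    ts = (t - t.mean()) / t.std()
    X = np.vander(ts, degree + 1, increasing=True)     # samples x (degree+1)
    Y = values.to_numpy(dtype=np.float64).T            # samples x features
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef
    resid = Y - fitted
    ssr = (resid ** 2).sum(axis=0)
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ssr / sst
    r2 = np.where(sst <= 0, 0.0, r2)
    r2 = np.clip(r2, 0.0, 1.0)
    tab = pd.DataFrame(coef.T, index=values.index,
                       columns=[f"coef_{i}" for i in range(degree + 1)])
    tab["r2"] = r2
    tab["dynamic"] = False
    tab["cluster"] = pd.array([pd.NA] * len(tab), dtype="Int64")
    tab.index.name = "feature"
    return TimecourseResult(table=tab, degree=degree)


def select_dynamic(result: TimecourseResult,
                   r2_cutoff: float = 0.7) -> pd.Index:
    """Flag features with R2 strictly above the cutoff as dynamic."""
    result.table["dynamic"] = result.table["r2"] > r2_cutoff
    result.r2_cutoff = r2_cutoff
    return result.dynamic_features


def timepoint_means(values: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Features x timepoints replicate means, columns in time order."""
    meta = _check_meta(values, meta)
    order = meta.drop_duplicates("timepoint").sort_values("week")["timepoint"]
    cols = {}
    for tp in order:
        samp = meta.loc[meta["timepoint"] == tp, "sample"]
        cols[tp] = values[list(samp)].mean(axis=1)
    return pd.DataFrame(cols)


def _zscore_rows(means: pd.DataFrame) -> np.ndarray:
    Z = means.to_numpy(dtype=np.float64)
    mu = Z.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0           # flat profiles standardize to all-zero
    return (Z - mu) / sd


def cluster_profiles(values: pd.DataFrame, meta: pd.DataFrame,
                     k: int | None = None, k_range=range(3, 10),
                     seed: int = 0, n_init: int = 10):
    """K-means clustering of per-feature standardized timepoint-mean profiles.

    Profiles are z-scored per feature so clusters capture shape, not
    magnitude. If ``k`` is None, k is scanned over ``k_range`` and chosen by
    maximum mean silhouette. Returns ``(labels, chosen_k, silhouette_table)``.
    """
    means = timepoint_means(values, meta)
    Z = _zscore_rows(means)
    n = Z.shape[0]
    sil_rows = []
    if k is None:
        candidates = [kk for kk in k_range if 2 <= kk <= n - 1]
        if not candidates:
            raise ValueError("k_range has no feasible k for this feature count")
        best = None
        for kk in candidates:
            km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit(Z)
            s = silhouette_score(Z, km.labels_)
            sil_rows.append({"k": kk, "silhouette": s})
            if best is None or s > best[0]:
                best = (s, kk, km.labels_)
        _, k, labels = best
    else:
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} features")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
        labels = km.labels_
    labels = pd.Series(labels + 1, index=values.index, name="cluster")
    sil = pd.DataFrame(sil_rows) if sil_rows else None
    return labels, int(k), sil


def timecourse_analysis(values: pd.DataFrame, meta: pd.DataFrame,
                        degree: int = 4, r2_cutoff: float = 0.7,
                        k: int | None = None, k_range=range(3, 10),
                        seed: int = 0) -> TimecourseResult:
    """Full dynamic-feature workflow: fit, R2 filter, cluster the dynamic set."""
    result = fit_polynomial_timecourse(values, meta, degree=degree)
    dyn = select_dynamic(result, r2_cutoff=r2_cutoff)
    if len(dyn) >= 2:
        try:
            labels, chosen_k, sil = cluster_profiles(
                values.loc[dyn], meta, k=k, k_range=k_range, seed=seed)
            result.table.loc[dyn, "cluster"] = labels.astype("Int64")
            result.chosen_k = chosen_k
            result.silhouette = sil
        except ValueError as exc:
            logger.warning("clustering skipped: %s", exc)
    return result
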