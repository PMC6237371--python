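"""Region counting, expression filtering, normalization and subtype profiling.

Counts are region x sample integers with per-sample metadata (immunophenotype,
molecular subtype, batch).  Normalization is a deliberately simple stand-in
for DESeq2's regularized log transform: median-of-ratios size factors
followed by ``log2(count/size_factor + pseudocount)``; it preserves the
clustering structure the subtype analyses rely on but is not
DESeq2-equivalent, and is labelled as such in output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .intervals import IntervalSet

IMMUNOPHENOTYPES = ("pre-B", "pre-T", "control")

NORMALIZATION_LABEL = "median-of-ratios size factors + log2 (rld stand-in, not DESeq2)"


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Sample metadata: index sample_id, columns immunophenotype, subtype, batch."""
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    for col in ("immunophenotype", "subtype", "batch"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample_ids in metadata")
    bad = set(meta["immunophenotype"]) - set(IMMUNOPHENOTYPES)
    if bad:
        raise ValueError(f"unknown immunophenotype(s) {sorted(bad)}; expected {IMMUNOPHENOTYPES}")
    return meta


class CountMatrix:
    """Region x sample integer counts plus region info and sample metadata.

    ``regions`` is a DataFrame indexed by region id with at least columns
    ``chrom`` and ``autosomal`` (bool); ``counts`` is indexed by region id
    with sample-id columns; ``meta`` is indexed by sample id.
    """

    def __init__(self, counts: pd.DataFrame, regions: pd.DataFrame,
                 meta: Optional[pd.DataFrame] = None) -> None:
        counts = counts.copy()
        if not np.issubdtype(np.asarray(counts.to_numpy()).dtype, np.integer):
            arr = counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not counts.index.equals(regions.index):
            if set(counts.index) != set(regions.index):
                raise ValueError("counts and regions indexed by different region ids")
            regions = regions.loc[counts.index]
        for col in ("chrom", "autosomal"):
            if col not in regions.columns:
                raise ValueError(f"regions missing column {col!r}")
        if meta is not None:
            meta = validate_meta(meta)
            missing = [s for s in counts.columns if s not in meta.index]
            if missing:
                raise ValueError(f"samples without metadata: {missing}")
            meta = meta.loc[list(counts.columns)]
        self.counts = counts
        self.regions = regions.copy()
        self.meta = meta

    @property
    def n_regions(self) -> int:
        return len(self.counts)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "region", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, regions: pd.DataFrame,
                 meta: Optional[pd.DataFrame] = None) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t")
        df = df.set_index(df.columns[0])
        df.index.name = "region"
        return cls(df, regions, meta)


def count_fragments(fragments: dict[str, IntervalSet], calls: IntervalSet,
                    regions_info: Optional[pd.DataFrame] = None,
                    meta: Optional[pd.DataFrame] = None) -> CountMatrix:
    """Count stranded fragments per call per sample, htseq-union style.

    A fragment is counted for a call iff it overlaps it (>= 1 bp) on the same
    strand; fragments overlapping two or more same-strand calls are discarded
    as ambiguous.  ``calls`` must carry region ids in the name field.
    """
    ids = [iv.name for iv in calls]
    if any(i is None for i in ids) or len(set(ids)) != len(ids):
        raise ValueError("calls must carry unique names (region ids)")
    call_groups: dict = {}
    for key, s, e, idx in calls.groups(by_strand=True):
        names = calls.df.loc[idx, "name"].to_numpy()
        call_groups[key] = (s, e, names)
    counts = pd.DataFrame(0, index=pd.Index(ids, name="region"),
                          columns=list(fragments), dtype=np.int64)
    for sample, frags in fragments.items():
        for key, fs, fe, _ in frags.groups(by_strand=True):
            grp = call_groups.get(key)
            if grp is None:
                continue
            cs, ce, cnames = grp
            cmax = np.maximum.accumulate(ce)
            for s0, e0 in zip(fs, fe):
                hi = int(np.searchsorted(cs, e0, side="left"))
                hits = [cnames[j] for j in range(hi) if ce[j] > s0]
                if len(hits) == 1:
                    counts.loc[hits[0], sample] += 1
    if regions_info is None:
        df = calls.df.set_index("name")
        regions_info = pd.DataFrame({
            "chrom": df["chrom"], "start": df["start"], "end": df["end"],
            "strand": df["strand"], "autosomal": True,
        })
        regions_info = regions_info.loc[ids]
    return CountMatrix(counts, regions_info, meta)


def filter_min_expressed(cm: CountMatrix, min_reads: int = 100, min_samples: int = 3,
                         autosomal_only: bool = True) -> CountMatrix:
    """Keep regions with >= min_reads in >= min_samples samples (autosomal only by default)."""
    qualifying = (cm.counts >= min_reads).sum(axis=1) >= min_samples
    keep = qualifying
    if autosomal_only:
        keep = keep & cm.regions["autosomal"].astype(bool)
    return CountMatrix(cm.counts.loc[keep], cm.regions.loc[keep], cm.meta)


def normalize_log(counts: pd.DataFrame, pseudocount: float = 1.0):
    """Median-of-ratios size factors + log2 transform (rld stand-in).

    Size factor per sample = median over all-positive regions of
    count / geometric-mean(region); falls back to total-count scaling (with a
    warning) when no region is positive in every sample.  Returns
    ``(normalized, size_factors, info)`` where info labels the method.
    """
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if allpos.any():
        ref = arr[allpos]
        log_gm = np.mean(np.log(ref), axis=1, keepdims=True)
        ratios = ref / np.exp(log_gm)
        size_factors = np.median(ratios, axis=0)
        method = NORMALIZATION_LABEL
    else:
        warnings.warn("no region with all-positive counts; falling back to total-count size factors")
        totals = arr.sum(axis=0)
        size_factors = totals / totals.mean() if totals.sum() else np.ones(arr.shape[1])
        method = NORMALIZATION_LABEL + "; total-count fallback"
    sf = pd.Series(size_factors, index=counts.columns, name="size_factor")
    norm = pd.DataFrame(
        np.log2(arr / size_factors[np.newaxis, :] + pseudocount),
        index=counts.index, columns=counts.columns,
    )
    return norm, sf, {"method": method, "pseudocount": pseudocount}


@dataclass
class ClusterResult:
    k: int
    assignment: pd.Series  # sample -> cluster label (1..k)
    linkage_matrix: np.ndarray
    purity: Optional[float] = None


def hierarchical_clusters(norm: pd.DataFrame, k: int, linkage: str = "complete",
                          metric: str = "euclidean") -> ClusterResult:
    """Agglomerative clustering of samples (columns) cut at k clusters.

    Euclidean distance over regions by default; deterministic for a given
    column order (scipy's merge order breaks distance ties by lowest pair
    index).
    """
    n = norm.shape[1]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    X = norm.to_numpy().T
    Z = scipy_linkage(X, method=linkage, metric=metric)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(k=k, assignment=pd.Series(labels, index=norm.columns), linkage_matrix=Z)


def cluster_from_distance(dist: pd.DataFrame, k: int, linkage: str = "complete") -> ClusterResult:
    """Same machinery on a precomputed symmetric distance matrix."""
    n = len(dist)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if np.isnan(dist.to_numpy()).any():
        raise ValueError("distance matrix contains missing values")
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = scipy_linkage(condensed, method=linkage)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(k=k, assignment=pd.Series(labels, index=dist.index), linkage_matrix=Z)


def cluster_purity(assignment: pd.Series, true_labels: pd.Series) -> float:
    """Purity = (1/N) * sum over clusters of the largest true-label class size."""
    if set(assignment.index) != set(true_labels.index):
        raise ValueError("assignment and true_labels cover different samples")
    labels = true_labels.loc[assignment.index]
    total = 0
    for _, idx in assignment.groupby(assignment).groups.items():
        total += labels.loc[idx].value_counts().iloc[0]
    return float(total) / len(assignment)


def subtype_specific(norm: pd.DataFrame, meta: pd.DataFrame, subtype: str,
                     min_fold: float = 2.0, top_n: Optional[int] = None,
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """Regions expressed >= min_fold higher in ``subtype`` than any other subtype.

    Folds are computed on the linear scale (2**value - pseudocount, floored
    at 0) as mean-in-subtype over the best other-subtype mean; regions silent
    everywhere else get fold = inf and rank first.  Returns a DataFrame
    (region, fold) sorted by fold descending.
    """
    meta = validate_meta(meta)
    groups = meta.loc[list(norm.columns), "subtype"]
    if subtype not in set(groups):
        raise ValueError(f"subtype {subtype!r} absent from metadata")
    linear = np.maximum(2.0 ** norm.to_numpy() - pseudocount, 0.0)
    linear = pd.DataFrame(linear, index=norm.index, columns=norm.columns)
    in_mean = linear.loc[:, (groups == subtype).to_numpy()].mean(axis=1)
    others = sorted(set(groups) - {subtype})
    if not others:
        raise ValueError("need at least one other subtype to compare against")
    other_means = pd.concat(
        {g: linear.loc[:, (groups == g).to_numpy()].mean(axis=1) for g in others}, axis=1
    )
    best_other = other_means.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = in_mean / best_other
    fold = fold.where(~((in_mean > 0) & (best_other == 0)), np.inf)
    fold = fold.fillna(0.0)  # 0/0: silent everywhere
    out = pd.DataFrame({"region": norm.index, "fold": fold.to_numpy()})
    out = out[out["fold"] >= min_fold]
    out = out.sort_values(["fold", "region"], ascending=[False, True], kind="mergesort")
    if top_n is not None:
        out = out.head(top_n)
    return out.reset_index(drop=True)


def pca_project(norm: pd.DataFrame, n_components: int = 2):
    """Region-centered SVD projection of samples.

    Returns ``(coords, variance_fractions)``; the sign of each component is
    fixed so its largest-magnitude loading is positive.
    """
    if n_components > min(norm.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    X = norm.to_numpy().T  # samples x regions
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("degenerate all-constant matrix")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for i in range(n_components):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    coords = U[:, :n_components] * S[:n_components]
    var = S**2
    frac = var[:n_components] / var.sum()
    cols = [f"PC{i+1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=norm.columns, columns=cols), frac
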