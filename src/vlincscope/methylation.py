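"""CpG methylation: WGBS count tracks, binned metaprofiles and 450K probes.

A WGBS track holds per-CpG methylated/unmethylated read counts; beta =
meth / (meth + unmeth) is defined only for covered CpGs.  Promoter
metaprofiles split the upstream flank, the region body and the downstream
flank into ten bins each (unweighted mean beta of covered CpGs per bin,
missing when a bin holds none), oriented 5'->3' by the linked vlincRNA
strand.  450K-style beta matrices are filtered with the standard detection
p-value / sex-chromosome / SNP-overlap rules and averaged over promoters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass


import numpy as np
import pandas as pd

from .expression import ClusterResult, cluster_from_distance
from .genome import GenomeLayout
from .intervals import IntervalSet


class MethylationTrack:
    """Per-CpG methylated/unmethylated counts, unique positions per chromosome."""

    def __init__(self, df: pd.DataFrame) -> None:
        for col in ("chrom", "pos", "meth", "unmeth"):
            if col not in df.columns:
                raise ValueError(f"methylation frame missing column {col!r}")
        df = df[["chrom", "pos", "meth", "unmeth"]].copy()
        df["chrom"] = df["chrom"].astype(str)
        for col in ("pos", "meth", "unmeth"):
            df[col] = df[col].astype(np.int64)
        if (df[["meth", "unmeth"]].to_numpy() < 0).any():
            raise ValueError("negative counts")
        if df.duplicated(["chrom", "pos"]).any():
            dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
            raise ValueError(f"duplicate CpG at {dup['chrom']}:{dup['pos']}")
        self.df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def beta(self) -> pd.Series:
        tot = self.df["meth"] + self.df["unmeth"]
        with np.errstate(invalid="ignore"):
            return self.df["meth"] / tot.replace(0, np.nan)

    def total_counts(self) -> int:
        return int(self.df[["meth", "unmeth"]].to_numpy().sum())

    @classmethod
    def from_tsv(cls, path) -> "MethylationTrack":
        df = pd.read_csv(path, sep="\t", names=["chrom", "pos", "meth", "unmeth"],
                         comment="#", header=None)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)


def merge_wgbs(tracks: list[MethylationTrack]) -> MethylationTrack:
    """Sum C/T read counts per CpG across replicate tracks (union of positions)."""
    if not tracks:
        raise ValueError("no tracks to merge")
    cat = pd.concat([t.df for t in tracks], ignore_index=True)
    merged = cat.groupby(["chrom", "pos"], as_index=False)[["meth", "unmeth"]].sum()
    return MethylationTrack(merged)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def binned_profile(track: MethylationTrack, regions: IntervalSet, *,
                   flank: int = 10_000, bins_per_part: int = 10,
                   coverage_weighted: bool = False,
                   orient_by_strand: bool = True):
    """30-bin methylation metaprofile over regions and ±flank.

    Returns ``(matrix, occupancy, mean_curve)``: matrix is regions x
    (3*bins_per_part) mean betas (NaN where a bin holds no covered CpG),
    occupancy the covered-CpG count per bin, and mean_curve the across-region
    mean ignoring missing bins.  Body bins use exact fractional boundaries
    rounded half-up; flank bins are flank/bins_per_part each.  Rows of
    minus-strand regions are reversed so every row reads 5'->3'
    (``orient_by_strand=False`` keeps genomic left-to-right).
    """
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    n_bins = 3 * bins_per_part
    by_chrom = {str(k): sub for k, sub in track.df.groupby("chrom")}
    rows, occ_rows, keys = [], [], []
    for iv in regions:
        L = iv.length
        if L < bins_per_part:
            raise ValueError(
                f"region {iv.chrom}:{iv.start}-{iv.end} shorter than bins_per_part ({bins_per_part})"
            )
        edges = [iv.start - flank + _round_half_up(i * flank / bins_per_part)
                 for i in range(bins_per_part)]
        edges += [iv.start + _round_half_up(i * L / bins_per_part)
                  for i in range(bins_per_part)]
        edges += [iv.end + _round_half_up(i * flank / bins_per_part)
                  for i in range(bins_per_part + 1)]
        edges = np.array(edges, dtype=np.int64)
        vals = np.full(n_bins, np.nan)
        occ = np.zeros(n_bins, dtype=np.int64)
        sub = by_chrom.get(iv.chrom)
        if sub is not None:
            pos = sub["pos"].to_numpy()
            meth = sub["meth"].to_numpy()
            unmeth = sub["unmeth"].to_numpy()
            tot = meth + unmeth
            lo = np.searchsorted(pos, edges[:-1], side="left")
            hi = np.searchsorted(pos, edges[1:], side="left")
            for b in range(n_bins):
                sel = slice(lo[b], hi[b])
                t = tot[sel]
                covered = t > 0
                if covered.any():
                    occ[b] = int(covered.sum())
                    if coverage_weighted:
                        vals[b] = meth[sel][covered].sum() / t[covered].sum()
                    else:
                        vals[b] = float(np.mean(meth[sel][covered] / t[covered]))
        if orient_by_strand and iv.strand == "-":
            vals = vals[::-1]
            occ = occ[::-1]
        rows.append(vals)
        occ_rows.append(occ)
        keys.append(iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}")
    cols = (
        [f"up{i+1}" for i in range(bins_per_part)]
        + [f"body{i+1}" for i in range(bins_per_part)]
        + [f"down{i+1}" for i in range(bins_per_part)]
    )
    matrix = pd.DataFrame(rows, index=keys, columns=cols)
    occupancy = pd.DataFrame(occ_rows, index=keys, columns=cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN bins
        mean_curve = matrix.mean(axis=0, skipna=True)
    return matrix, occupancy, mean_curve


def promoter_mean_meth(track: MethylationTrack, regions: IntervalSet) -> pd.Series:
    """Unweighted mean beta of covered CpGs per region (NaN when none)."""
    by_chrom = {str(k): sub for k, sub in track.df.groupby("chrom")}
    out = {}
    for iv in regions:
        key = iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
        sub = by_chrom.get(iv.chrom)
        val = np.nan
        if sub is not None:
            pos = sub["pos"].to_numpy()
            lo, hi = np.searchsorted(pos, [iv.start, iv.end], side="left")
            meth = sub["meth"].to_numpy()[lo:hi]
            tot = meth + sub["unmeth"].to_numpy()[lo:hi]
            covered = tot > 0
            if covered.any():
                val = float(np.mean(meth[covered] / tot[covered]))
        out[key] = val
    return pd.Series(out, name="mean_beta")


# ---------------------------------------------------------------------------
# 450K-style probe matrices
# ---------------------------------------------------------------------------

@dataclass
class ProbeMatrix:
    """Probe beta values with annotation and detection p-values.

    ``betas``/``detection_p``: probes x samples; ``annot``: indexed by probe
    id with columns chrom, pos, snp_flag.
    """

    betas: pd.DataFrame
    annot: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.betas.index.equals(self.detection_p.index) or \
           list(self.betas.columns) != list(self.detection_p.columns):
            raise ValueError("betas and detection_p must share probes and samples")
        missing = [p for p in self.betas.index if p not in self.annot.index]
        if missing:
            raise ValueError(f"probes without annotation, e.g. {missing[:3]}")
        for col in ("chrom", "pos", "snp_flag"):
            if col not in self.annot.columns:
                raise ValueError(f"probe annotation missing column {col!r}")
        b = self.betas.to_numpy(dtype=float)
        if b.size and (np.nanmin(b) < 0 or np.nanmax(b) > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.betas)


def filter_probes(pm: ProbeMatrix, layout: GenomeLayout, *,
                  det_p_thresh: float = 0.01, max_fail_frac: float = 0.20) -> ProbeMatrix:
    """Drop failed probes, sex-chromosome probes and SNP-overlapping probes.

    A probe fails when its detection p exceeds ``det_p_thresh`` in strictly
    more than ``max_fail_frac`` of samples (a probe failing in exactly that
    fraction is kept).
    """
    annot = pm.annot.loc[pm.betas.index]
    fail_frac = (pm.detection_p > det_p_thresh).mean(axis=1)
    keep = (fail_frac <= max_fail_frac)
    keep &= annot["chrom"].map(lambda c: c in layout and layout.is_autosome(c))
    keep &= ~annot["snp_flag"].astype(bool)
    idx = pm.betas.index[keep]
    return ProbeMatrix(pm.betas.loc[idx], pm.annot.loc[idx], pm.detection_p.loc[idx])


def probe_promoter_means(pm: ProbeMatrix, regions: IntervalSet):
    """Mean probe beta per region per sample.

    Returns ``(matrix, n_regions_with_probes, n_probes_used, regions_without)``.
    A probe overlapping two regions contributes to both.  Regions with no
    probes are excluded from the matrix and listed separately.
    """
    annot = pm.annot.loc[pm.betas.index]
    by_chrom = {str(k): sub for k, sub in annot.groupby("chrom")}
    rows = {}
    without = []
    used: set = set()
    for iv in regions:
        key = iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
        sub = by_chrom.get(iv.chrom)
        probe_ids = []
        if sub is not None:
            hit = sub[(sub["pos"] >= iv.start) & (sub["pos"] < iv.end)]
            probe_ids = list(hit.index)
        if probe_ids:
            rows[key] = pm.betas.loc[probe_ids].mean(axis=0)
            used.update(probe_ids)
        else:
            without.append(key)
    matrix = pd.DataFrame(rows).T
    if len(matrix):
        matrix.columns = pm.betas.columns
    return matrix, len(rows), len(used), without


def meth_correlation_cluster(matrix: pd.DataFrame, k: int, linkage: str = "complete"):
    """Pairwise-complete Pearson correlation of samples + clustering on 1 - r.

    ``matrix`` is regions x samples.  Pairs with < 2 common observations get
    a missing correlation (with a warning); clustering requires a complete
    correlation matrix.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    corr = matrix.corr(method="pearson", min_periods=2)
    if corr.isna().any().any():
        warnings.warn("correlation missing for sample pair(s) with < 2 common observations")
    d = (1.0 - corr).to_numpy(copy=True)
    np.fill_diagonal(d, 0.0)
    dist = pd.DataFrame(d, index=corr.index, columns=corr.columns)
    result: ClusterResult = cluster_from_distance(dist, k, linkage=linkage)
    return corr, result
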