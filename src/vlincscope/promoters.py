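"""Promoter chromatin-state analysis for vlincRNA calls.

Candidate promoters are +-10 kb windows around each call's 5' start (the
start coordinate for + calls, the end coordinate for - calls).  Chromatin
segmentations (ChromHMM-style dense BED) are post-processed into "active"
regions — H3K4me3-bearing states, merged when < 1 kb apart and kept when
>= 400 bp — which refine candidate promoters and drive a shuffle-background
enrichment test with a Fisher exact p and an empirical permutation p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .coverage import CoverageTrack, coverage_from_intervals
from .genome import GenomeLayout
from .intervals import IntervalSet, merge_within, overlaps_any, shuffle_intervals

# H3K4me3-present states of the Roadmap Epigenomics 15-state model
ROADMAP15_ACTIVE_STATES = frozenset({"1", "2", "3", "10", "11"})


@dataclass(frozen=True)
class PromoterParams:
    flank: int = 10_000
    state_merge_gap: int = 1_000
    min_active_len: int = 400
    n_shuffles: int = 1000
    active_states: frozenset = frozenset({"Active"})

    def __post_init__(self) -> None:
        for name in ("flank", "state_merge_gap", "min_active_len", "n_shuffles"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.active_states:
            raise ValueError("active_states must be non-empty")


class PromoterSet:
    """Candidate (and optionally refined) promoter intervals per vlincRNA id.

    Backed by a DataFrame indexed by vlincRNA id with columns ``chrom``,
    ``strand``, ``cand_start``, ``cand_end`` and nullable ``ref_start``,
    ``ref_end``.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        for col in ("chrom", "strand", "cand_start", "cand_end"):
            if col not in df.columns:
                raise ValueError(f"PromoterSet frame missing column {col!r}")
        df = df.copy()
        for col in ("ref_start", "ref_end"):
            if col not in df.columns:
                df[col] = pd.NA
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list:
        return list(self.df.index)

    def candidates(self) -> IntervalSet:
        d = self.df
        return IntervalSet.from_records(
            [(r.chrom, int(r.cand_start), int(r.cand_end), r.strand, idx, None)
             for idx, r in zip(d.index, d.itertuples(index=False))]
        )

    def refined(self) -> IntervalSet:
        """Refined intervals only (ids without a refinement are omitted); strand from the call."""
        rows = []
        for idx, r in zip(self.df.index, self.df.itertuples(index=False)):
            if pd.notna(r.ref_start):
                rows.append((r.chrom, int(r.ref_start), int(r.ref_end), r.strand, idx, None))
        return IntervalSet.from_records(rows)

    @property
    def n_refined(self) -> int:
        return int(self.df["ref_start"].notna().sum())

    @property
    def refined_fraction(self) -> float:
        return self.n_refined / len(self.df) if len(self.df) else float("nan")


def candidate_promoters(calls, layout: GenomeLayout, flank: int = 10_000) -> PromoterSet:
    """±flank window around each call's 5' start, clipped to chromosome bounds.

    ``calls`` is a list of :class:`~vlincscope.discovery.VlincCall` or an
    :class:`IntervalSet` with ids in the name field and strand +/-.
    """
    if isinstance(calls, IntervalSet):
        items = [(iv.name, iv.chrom, iv.start, iv.end, iv.strand) for iv in calls]
    else:
        items = [(c.id, c.chrom, c.start, c.end, c.strand) for c in calls]
    rows = {}
    for cid, chrom, start, end, strand in items:
        if strand not in ("+", "-"):
            raise ValueError(f"call {cid}: promoter requires a +/- strand, got {strand!r}")
        if cid is None or cid in rows:
            raise ValueError(f"calls must carry unique ids (got {cid!r})")
        center = start if strand == "+" else end
        lo = max(0, center - flank)
        hi = min(layout.length_of(chrom), center + flank)
        rows[cid] = (chrom, strand, lo, hi)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["chrom", "strand", "cand_start", "cand_end"])
    df.index.name = "id"
    return PromoterSet(df)


def read_state_bed(path, layout: Optional[GenomeLayout] = None, *, on_unknown: str = "skip") -> IntervalSet:
    """Read a 4-column dense segmentation BED (chrom, start, end, state label)."""
    from .intervals import read_bed

    iset = read_bed(path, layout, on_unknown=on_unknown)
    if len(iset) and iset.df["name"].isna().any():
        raise ValueError(f"{path}: segmentation records must carry a state label in column 4")
    return iset


def active_regions(states: IntervalSet, params: PromoterParams,
                   known_states: Optional[set] = None) -> IntervalSet:
    """Post-process a chromatin segmentation into active regions.

    Keeps segments whose state label is in ``params.active_states``, merges
    survivors separated by < state_merge_gap, and retains merged regions of
    length >= min_active_len.  If ``known_states`` is given, any segment
    label outside it raises (listing the offending labels).
    """
    labels = states.df["name"].astype(str)
    if known_states is not None:
        bad = sorted(set(labels) - set(known_states))
        if bad:
            raise ValueError(f"unknown state label(s) {bad}; known: {sorted(known_states)}")
    keep = labels.isin({str(s) for s in params.active_states})
    active = IntervalSet(states.df[keep.to_numpy()].assign(strand="."))
    merged = merge_within(active, params.state_merge_gap)
    out = merged.df[(merged.df["end"] - merged.df["start"]) >= params.min_active_len]
    return IntervalSet(out, is_sorted=True)


def refine_promoters(promoters: PromoterSet, active: IntervalSet) -> PromoterSet:
    """Assign each candidate the longest overlapping active region (tie: leftmost)."""
    by_chrom = {str(k): sub.sort_values("start") for k, sub in active.df.groupby("chrom")}
    df = promoters.df.copy()
    ref_start = []
    ref_end = []
    for r in df.itertuples(index=False):
        sub = by_chrom.get(r.chrom)
        best = None
        if sub is not None:
            ov = sub[(sub["start"] < r.cand_end) & (sub["end"] > r.cand_start)]
            if len(ov):
                lens = ov["end"] - ov["start"]
                cand = ov[lens == lens.max()].sort_values("start").iloc[0]
                best = (int(cand["start"]), int(cand["end"]))
        ref_start.append(best[0] if best else pd.NA)
        ref_end.append(best[1] if best else pd.NA)
    df["ref_start"] = ref_start
    df["ref_end"] = ref_end
    return PromoterSet(df)


@dataclass
class EnrichmentResult:
    """Observed vs shuffle-background promoter/active-chromatin overlap."""

    n: int
    n_obs_overlap: int
    random_overlap_counts: np.ndarray
    mean_random: float
    fold: float
    fisher_p: float
    fisher_table: list
    permutation_p: Optional[float] = None

    @property
    def obs_fraction(self) -> float:
        return self.n_obs_overlap / self.n

    @property
    def mean_random_fraction(self) -> float:
        return self.mean_random / self.n

    @classmethod
    def from_counts(cls, n_obs: int, mean_random: float, n: int,
                    alternative: str = "two-sided") -> "EnrichmentResult":
        """Build the fold and Fisher test directly from overlap counts.

        Used both internally after shuffling and for worked examples where
        the observed and mean-random counts are given.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        if n_obs == 0 and mean_random == 0:
            warnings.warn("no observed and no random overlap; fold defined as 0")
            fold = 0.0
        elif mean_random == 0:
            fold = float("inf")
        else:
            fold = (n_obs / n) / (mean_random / n)
        r = int(round(mean_random))
        table = [[n_obs, n - n_obs], [r, n - r]]
        _, p = fisher_exact(table, alternative=alternative)
        return cls(n=n, n_obs_overlap=n_obs, random_overlap_counts=np.array([], dtype=int),
                   mean_random=float(mean_random), fold=fold, fisher_p=float(p),
                   fisher_table=table)


def _shuffled_overlap_counts(cand: IntervalSet, active: IntervalSet, layout: GenomeLayout,
                             n_reps: int, seed: int) -> np.ndarray:
    """Overlap counts of length-preserving uniform re-placements of ``cand``.

    Same placement model as :func:`~vlincscope.intervals.shuffle_intervals`
    (chromosome ∝ length among those long enough, start uniform), but run as
    vectorized array arithmetic so thousands of replicates are cheap.
    """
    from .intervals import _union_runs

    rng = np.random.default_rng(seed)
    names = layout.names
    clens = np.array([layout.length_of(c) for c in names], dtype=np.int64)
    runs = {}
    for key, s, e, _ in active.groups(by_strand=False):
        runs[key[0]] = _union_runs(s, e)
    ivlens = (cand.df["end"] - cand.df["start"]).to_numpy()
    n = len(ivlens)
    p_global = clens / clens.sum()
    counts = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        ci = rng.choice(len(names), size=n, p=p_global)
        for i in np.flatnonzero(clens[ci] < ivlens):
            fit = clens >= ivlens[i]
            ci[i] = np.flatnonzero(fit)[int(rng.choice(int(fit.sum()), p=clens[fit] / clens[fit].sum()))]
        starts = (rng.random(n) * (clens[ci] - ivlens + 1)).astype(np.int64)
        ends = starts + ivlens
        total = 0
        for k in range(len(names)):
            sel = ci == k
            if not sel.any():
                continue
            entry = runs.get(names[k])
            if entry is None:
                continue
            rs, re = entry
            j = np.searchsorted(re, starts[sel], side="right")
            hit = (j < len(rs)) & (rs[np.minimum(j, len(rs) - 1)] < ends[sel])
            total += int(hit.sum())
        counts[r] = total
    return counts


def overlap_enrichment(promoters: PromoterSet, active: IntervalSet, layout: GenomeLayout,
                       params: PromoterParams, seed: int, *,
                       exclude: Optional[IntervalSet] = None,
                       alternative: str = "two-sided") -> EnrichmentResult:
    """Shuffle-background enrichment of candidate promoters in active chromatin.

    Overlap is >= 1 bp, strand-agnostic.  Each of ``params.n_shuffles``
    replicates re-places the candidate windows uniformly (lengths preserved)
    and recounts overlaps; fold = observed fraction / mean random fraction.
    A Fisher exact p is computed on [[obs, n-obs], [round(mean_random),
    n-round(mean_random)]] and an empirical permutation p
    ``(1 + #{reps >= obs}) / (n_shuffles + 1)`` is reported alongside.
    """
    if params.n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    cand = promoters.candidates()
    n = len(cand)
    if n < 1:
        raise ValueError("empty promoter set")
    n_obs = int(overlaps_any(cand, active).sum())
    if exclude is not None:
        reps = shuffle_intervals(cand, layout, params.n_shuffles, seed, exclude)
        counts = np.array([int(overlaps_any(r, active).sum()) for r in reps])
    else:
        counts = _shuffled_overlap_counts(cand, active, layout, params.n_shuffles, seed)
    mean_random = float(counts.mean())
    res = EnrichmentResult.from_counts(n_obs, mean_random, n, alternative=alternative)
    res.random_overlap_counts = counts
    res.permutation_p = (1 + int((counts >= n_obs).sum())) / (params.n_shuffles + 1)
    return res


def expression_stratified_overlap(promoters: PromoterSet, active: IntervalSet,
                                  expression: pd.Series, n_bins: int = 8) -> pd.DataFrame:
    """Overlap fraction per expression bin (bin 1 / Q1 = highest expression).

    Promoters are sorted by ``expression`` descending (ties broken by id for
    determinism) and split into ``n_bins`` groups; a remainder is spread one
    extra promoter per leading bin.  ``n_bins=4`` gives the quartile view.
    """
    missing = [i for i in promoters.ids if i not in expression.index or pd.isna(expression.loc[i])]
    if missing:
        raise ValueError(f"missing expression values for {len(missing)} promoter(s), e.g. {missing[:3]}")
    cand = promoters.candidates()
    flags = pd.Series(overlaps_any(cand, active), index=[iv.name for iv in cand])
    order_df = pd.DataFrame({
        "expr": expression.loc[promoters.ids].to_numpy(),
        "pid": promoters.ids,
    })
    order = order_df.sort_values(["expr", "pid"], ascending=[False, True],
                                 kind="mergesort")["pid"].tolist()
    n = len(order)
    base, rem = divmod(n, n_bins)
    rows = []
    pos = 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        ids = order[pos:pos + size]
        pos += size
        n_ov = int(flags.loc[ids].sum()) if ids else 0
        rows.append({"bin": b + 1, "n": size, "n_overlap": n_ov,
                     "fraction": n_ov / size if size else float("nan")})
    return pd.DataFrame(rows)


def density_profile(signal: Union[CoverageTrack, IntervalSet], regions: IntervalSet,
                    window: int = 10_000, n_bins: int = 100,
                    layout: Optional[GenomeLayout] = None) -> pd.DataFrame:
    """Normalized signal density in fixed windows around region centers.

    For each region the ±window span around its center is split into
    ``n_bins`` equal bins; bin values are summed base-coverage normalized to
    reads-per-million of the track total.  Bins outside the genome are NaN
    (excluded from column means).  Rows are ordered by row sum descending,
    ready for heatmap export; ``.mean(axis=0)`` of the result is the profile
    curve.
    """
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    if isinstance(signal, IntervalSet):
        signal = coverage_from_intervals(signal, layout)
    total = signal.total_signal()
    if total == 0:
        raise ValueError("signal track is empty")
    if layout is None:
        layout = signal.layout
    width = 2 * window
    edges_rel = np.round(np.linspace(0, width, n_bins + 1)).astype(np.int64)
    rows = {}
    for iv in regions:
        center = (iv.start + iv.end) // 2
        lo = center - window
        clen = layout.length_of(iv.chrom) if layout is not None else None
        vals = np.full(n_bins, np.nan)
        # sum depth over each bin from the run-length track, both strands
        run_sets = [signal.runs(iv.chrom, s) for s in signal.strands()]
        for b in range(n_bins):
            bs, be = lo + int(edges_rel[b]), lo + int(edges_rel[b + 1])
            if bs < 0 or (clen is not None and be > clen):
                continue  # outside genome: missing
            acc = 0
            for st, en, de in run_sets:
                if len(st) == 0:
                    continue
                j0 = int(np.searchsorted(en, bs, side="right"))
                for j in range(j0, len(st)):
                    if st[j] >= be:
                        break
                    acc += (min(int(en[j]), be) - max(int(st[j]), bs)) * int(de[j])
            vals[b] = acc / (total / 1e6)
        key = iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"
        rows[key] = vals
    mat = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[f"bin{b+1}" for b in range(n_bins)])
    order = mat.sum(axis=1, skipna=True).sort_values(ascending=False, kind="mergesort").index
    return mat.loc[order]
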