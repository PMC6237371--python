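"""vlincRNA discovery from pooled strand-specific coverage.

The procedure: mask protein-coding gene bases on the matching strand, keep
covered bases at or above the per-strand read-density quantile (Q3 by
default), drop blacklisted bases, merge surviving bases closer than 500 bp,
merge the resulting segments closer than 10 kb, and keep segments of at
least 50 kb as stranded vlincRNA calls.  A "far-from-genes" subset keeps
calls at least 10 kb from any gene regardless of strand.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .coverage import CoverageTrack
from .intervals import IntervalSet, distance_filter, merge_within, subtract

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscoveryParams:
    """Tunable thresholds of the discovery pipeline (defaults = study settings).

    ``mapq_min`` is documentation of the upstream alignment filter: coverage
    supplied as bedGraph is expected to come from MAPQ >= 40 alignments.
    """

    mapq_min: int = 40
    density_quantile: float = 0.75
    base_merge_gap: int = 500
    segment_merge_gap: int = 10_000
    min_length: int = 50_000
    far_gene_dist: int = 10_000
    reciprocal_overlap_frac: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.density_quantile < 1):
            raise ValueError("density_quantile must be in (0, 1)")
        for name in ("base_merge_gap", "segment_merge_gap", "min_length", "far_gene_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_length < self.segment_merge_gap:
            raise ValueError("min_length must be >= segment_merge_gap")

    def scaled(self, factor: float) -> "DiscoveryParams":
        """Proportionally shrink all bp parameters (for fast small-genome tests)."""
        return replace(
            self,
            base_merge_gap=max(1, round(self.base_merge_gap * factor)),
            segment_merge_gap=max(1, round(self.segment_merge_gap * factor)),
            min_length=max(1, round(self.min_length * factor)),
            far_gene_dist=max(1, round(self.far_gene_dist * factor)),
        )


@dataclass(frozen=True)
class VlincCall:
    """A stranded >= min_length intergenic transcript call."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str
    call_class: str = "all"  # "all" | "far_from_genes"

    @property
    def length(self) -> int:
        return self.end - self.start


def calls_to_intervalset(calls: list[VlincCall]) -> IntervalSet:
    return IntervalSet.from_records(
        [(c.chrom, c.start, c.end, c.strand, c.id, float(c.length)) for c in calls]
    ).sort()


def quantile_threshold(depths: np.ndarray, counts: np.ndarray, q: float) -> Optional[int]:
    """Nearest-rank quantile of the covered-base depth multiset.

    ``depths``/``counts`` describe the multiset as depth-sorted run-length
    pairs.  The threshold is the depth at 0-based rank ``floor(q*N)`` (capped
    at N-1) of the N covered bases, so e.g. the 8-base multiset
    {1,1,1,1,2,2,3,100} at q=0.75 yields 3.
    """
    n = int(counts.sum())
    if n == 0:
        return None
    rank = min(math.floor(q * n), n - 1)
    cum = np.cumsum(counts)
    idx = int(np.searchsorted(cum, rank, side="right"))
    return int(depths[idx])


def density_threshold(track: CoverageTrack, q: float, *, joint: bool = False):
    """Keep bases at or above the q-quantile of covered-base read depth.

    Quantiles are computed per strand by default (``joint`` pools both
    strands).  Returns ``(filtered_track, {strand: threshold})``; a strand
    with no covered bases gets threshold None (emptied, with a warning).
    """
    strands = track.strands()
    thresholds: dict[str, Optional[int]] = {}
    if joint:
        ds, ns = [], []
        for s in strands:
            d, n = track.depth_multiset(s)
            ds.append(d)
            ns.append(n)
        if ds:
            d = np.concatenate(ds)
            n = np.concatenate(ns)
            order = np.argsort(d, kind="mergesort")
            t = quantile_threshold(d[order], n[order], q)
        else:
            t = None
        thresholds = {s: t for s in strands}
    else:
        for s in strands:
            d, n = track.depth_multiset(s)
            thresholds[s] = quantile_threshold(d, n, q)
    for s, t in thresholds.items():
        if t is None:
            warnings.warn(f"strand {s!r}: no covered bases; density threshold undefined, strand emptied")
    return track.threshold(thresholds), thresholds


def discover_vlincs(
    track: CoverageTrack,
    genes: IntervalSet,
    blacklist: IntervalSet,
    params: DiscoveryParams = DiscoveryParams(),
    *,
    joint_quantile: bool = False,
    bridge_masked: bool = True,
) -> list[VlincCall]:
    """Run the full discovery pipeline on a pooled coverage track.

    Stage order is fixed: (1) strand-aware gene masking, (2) density
    threshold, (3) blacklist masking on both strands, (4) merge covered bases
    < base_merge_gap apart, (5) merge segments < segment_merge_gap apart,
    (6) keep length >= min_length.  With ``bridge_masked`` (default) merging
    may span gene/blacklist gaps — masked bases were removed, not turned into
    barriers; ``bridge_masked=False`` re-subtracts the masks after merging so
    they break segments.
    """
    t1 = track.mask(genes, strand_aware=True)
    logger.info("after gene mask: %d covered bases", t1.covered_bases())
    t2, thresholds = density_threshold(t1, params.density_quantile, joint=joint_quantile)
    logger.info("density thresholds %s; %d covered bases kept", thresholds, t2.covered_bases())
    t3 = t2.mask(blacklist, strand_aware=False)
    logger.info("after blacklist mask: %d covered bases", t3.covered_bases())
    covered = t3.covered_intervals()
    seg1 = merge_within(covered, params.base_merge_gap)
    seg2 = merge_within(seg1, params.segment_merge_gap)
    if not bridge_masked:
        # genes break same-strand segments; blacklist breaks both strands
        seg2 = subtract(seg2, genes, strand_aware=True)
        seg2 = subtract(seg2, blacklist, strand_aware=False)
    calls = []
    for iv in seg2.sort():
        if iv.length >= params.min_length:
            calls.append(
                VlincCall(iv.chrom, iv.start, iv.end, iv.strand,
                          id=f"vlinc_{iv.chrom}_{iv.start}_{iv.strand}")
            )
    logger.info("%d vlincRNA calls >= %d bp", len(calls), params.min_length)
    return calls


def far_from_genes(calls: list[VlincCall], genes: IntervalSet,
                   params: DiscoveryParams = DiscoveryParams()) -> list[VlincCall]:
    """Subset of calls at least ``far_gene_dist`` from any gene, strand-agnostic."""
    iset = calls_to_intervalset(calls)
    kept = distance_filter(iset, genes, params.far_gene_dist)
    kept_ids = {iv.name for iv in kept}
    return [replace(c, call_class="far_from_genes") for c in calls if c.id in kept_ids]


@dataclass
class CatalogComparison:
    """Reciprocal-overlap sharing of calls with named public catalogs."""

    per_call_counts: dict  # call id -> number of catalogs shared with
    per_catalog_shared: dict  # catalog name -> number of calls shared
    unique_calls: list  # call ids shared with no catalog
    n_calls: int

    @property
    def unique_fraction(self) -> float:
        return len(self.unique_calls) / self.n_calls if self.n_calls else float("nan")


def _reciprocal_shared(u_start, u_end, u_strand, cat_df, frac, stranded) -> bool:
    ulen = u_end - u_start
    sub = cat_df[cat_df["start"].lt(u_end) & cat_df["end"].gt(u_start)]
    for v in sub.itertuples(index=False):
        if stranded and v.strand != u_strand:
            continue
        ov = min(u_end, v.end) - max(u_start, v.start)
        if ov >= frac * ulen and ov >= frac * (v.end - v.start):
            return True
    return False


def compare_catalogs(
    calls: list[VlincCall],
    catalogs: dict[str, IntervalSet],
    frac: float = 0.25,
    respect_strand: Optional[dict[str, bool]] = None,
) -> CatalogComparison:
    """Count, per call, how many catalogs share it by reciprocal overlap.

    A call u is shared with catalog D iff some v in D overlaps u by at least
    ``frac`` of u's length AND ``frac`` of v's length, on the same strand
    when the catalog is flagged stranded (default True per catalog —
    unstranded public sets are flagged False).
    """
    respect_strand = respect_strand or {}
    per_call = {c.id: 0 for c in calls}
    per_cat = {name: 0 for name in catalogs}
    for name, cat in catalogs.items():
        stranded = respect_strand.get(name, True)
        by_chrom = {str(k): sub for k, sub in cat.df.groupby("chrom")}
        for c in calls:
            sub = by_chrom.get(c.chrom)
            if sub is None:
                continue
            if _reciprocal_shared(c.start, c.end, c.strand, sub, frac, stranded):
                per_call[c.id] += 1
                per_cat[name] += 1
    unique = [cid for cid, n in per_call.items() if n == 0]
    return CatalogComparison(per_call, per_cat, unique, n_calls=len(calls))


# ---------------------------------------------------------------------------
# Evaluation against planted truth
# ---------------------------------------------------------------------------

def jaccard(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = max(0, min(a_end, b_end) - max(a_start, b_start))
    union = (a_end - a_start) + (b_end - b_start) - inter
    return inter / union if union else 0.0


def recovery_rate(calls: list[VlincCall], truth: IntervalSet, min_jaccard: float = 0.8) -> float:
    """Fraction of truth intervals matched by a same-strand call at >= min_jaccard."""
    n_hit = 0
    for t in truth:
        best = 0.0
        for c in calls:
            if c.chrom == t.chrom and c.strand == t.strand:
                best = max(best, jaccard(c.start, c.end, t.start, t.end))
        if best >= min_jaccard:
            n_hit += 1
    return n_hit / len(truth) if len(truth) else float("nan")
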