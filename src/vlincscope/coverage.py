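"""Run-length, strand-resolved per-base read depth.

A :class:`CoverageTrack` stores, per (chromosome, strand), sorted
non-overlapping runs ``(start, end, depth)`` with depth > 0; uncovered bases
have depth 0 implicitly.  Canonical form merges adjacent equal-depth runs.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .genome import GenomeLayout
from .intervals import IntervalSet, _union_runs

Key = tuple[str, str]  # (chrom, strand)


def _canonicalize(starts, ends, depths):
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    depths = np.asarray(depths, dtype=np.int64)
    if (depths < 0).any():
        raise ValueError("negative depth")
    keep = depths > 0
    starts, ends, depths = starts[keep], ends[keep], depths[keep]
    order = np.argsort(starts, kind="mergesort")
    starts, ends, depths = starts[order], ends[order], depths[order]
    if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
        i = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
        raise ValueError(f"overlapping coverage runs at [{starts[i]},{ends[i]}) and [{starts[i+1]},{ends[i+1]})")
    if len(starts) == 0:
        return starts, ends, depths
    # merge adjacent runs with equal depth
    new = np.empty(len(starts), dtype=bool)
    new[0] = True
    new[1:] = (starts[1:] != ends[:-1]) | (depths[1:] != depths[:-1])
    idx = np.flatnonzero(new)
    out_starts = starts[new]
    out_depths = depths[new]
    last = np.append(idx[1:] - 1, len(starts) - 1)
    out_ends = ends[last]
    return out_starts, out_ends, out_depths


class CoverageTrack:
    """Strand-specific base coverage as run-length segments."""

    def __init__(self, runs: Optional[dict] = None, layout: Optional[GenomeLayout] = None) -> None:
        self._runs: dict[Key, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.layout = layout
        if runs:
            for key, (s, e, d) in runs.items():
                s, e, d = _canonicalize(s, e, d)
                if layout is not None and len(e) and e[-1] > layout.length_of(key[0]):
                    raise ValueError(
                        f"coverage run ends at {int(e[-1])} beyond chromosome {key[0]} "
                        f"({layout.length_of(key[0])})"
                    )
                if len(s):
                    self._runs[key] = (s, e, d)

    # -- accessors ----------------------------------------------------
    @property
    def keys(self) -> list[Key]:
        return sorted(self._runs)

    def runs(self, chrom: str, strand: str):
        """(starts, ends, depths) arrays for one (chrom, strand); empty arrays if none."""
        empty = np.array([], dtype=np.int64)
        return self._runs.get((chrom, strand), (empty, empty, empty))

    def strands(self) -> list[str]:
        return sorted({k[1] for k in self._runs})

    def covered_bases(self, strand: Optional[str] = None) -> int:
        tot = 0
        for (c, s), (st, en, de) in self._runs.items():
            if strand is None or s == strand:
                tot += int((en - st).sum())
        return tot

    def total_signal(self, strand: Optional[str] = None) -> int:
        """Sum of depth x run length (total sequenced bases)."""
        tot = 0
        for (c, s), (st, en, de) in self._runs.items():
            if strand is None or s == strand:
                tot += int(((en - st) * de).sum())
        return tot

    def depth_multiset(self, strand: str):
        """(depths, base_counts) over covered bases of one strand, depth-sorted."""
        ds, ns = [], []
        for (c, s), (st, en, de) in self._runs.items():
            if s == strand:
                ds.append(de)
                ns.append(en - st)
        if not ds:
            return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        d = np.concatenate(ds)
        n = np.concatenate(ns)
        order = np.argsort(d, kind="mergesort")
        return d[order], n[order]

    def covered_intervals(self, strand: Optional[str] = None) -> IntervalSet:
        """Covered bases (depth >= 1) as maximal intervals, carrying strand."""
        rows = []
        for (c, s), (st, en, de) in sorted(self._runs.items()):
            if strand is not None and s != strand:
                continue
            us, ue = _union_runs(st, en)
            for a, b in zip(us, ue):
                rows.append((c, int(a), int(b), s, None, None))
        return IntervalSet.from_records(rows).sort()

    # -- transformations ----------------------------------------------
    def mask(self, intervals: IntervalSet, *, strand_aware: bool = True) -> "CoverageTrack":
        """Zero coverage over ``intervals`` (same strand only when strand_aware)."""
        masks: dict = {}
        for key, s, e, _ in intervals.groups(by_strand=strand_aware):
            masks[key] = _union_runs(s, e)
        out = {}
        for (chrom, strand), (st, en, de) in self._runs.items():
            mkey = (chrom, strand) if strand_aware else (chrom,)
            m = masks.get(mkey)
            if m is None:
                out[(chrom, strand)] = (st, en, de)
                continue
            ms, me = m
            ns, ne, nd = [], [], []
            for s0, e0, d0 in zip(st, en, de):
                lo = int(np.searchsorted(me, s0, side="right"))
                cur = int(s0)
                for j in range(lo, len(ms)):
                    if ms[j] >= e0:
                        break
                    if ms[j] > cur:
                        ns.append(cur); ne.append(int(ms[j])); nd.append(int(d0))
                    cur = max(cur, int(me[j]))
                    if cur >= e0:
                        break
                if cur < e0:
                    ns.append(cur); ne.append(int(e0)); nd.append(int(d0))
            if ns:
                out[(chrom, strand)] = (np.array(ns), np.array(ne), np.array(nd))
        return CoverageTrack(out, layout=self.layout)

    def threshold(self, min_depth) -> "CoverageTrack":
        """Keep runs with depth >= min_depth (scalar, or dict per strand; None empties the strand)."""
        out = {}
        for (chrom, strand), (st, en, de) in self._runs.items():
            t = min_depth.get(strand) if isinstance(min_depth, dict) else min_depth
            if t is None:
                continue
            keep = de >= t
            if keep.any():
                out[(chrom, strand)] = (st[keep], en[keep], de[keep])
        return CoverageTrack(out, layout=self.layout)

    def add(self, other: "CoverageTrack") -> "CoverageTrack":
        """Depth-wise sum of two tracks (for pooling samples)."""
        out = {}
        for key in set(self._runs) | set(other._runs):
            s1, e1, d1 = self.runs(*key)
            s2, e2, d2 = other.runs(*key)
            # sweep over breakpoints
            edges = np.unique(np.concatenate([s1, e1, s2, e2]))
            if len(edges) < 2:
                continue
            mid = edges[:-1]
            depth = np.zeros(len(mid), dtype=np.int64)
            for st, en, de in ((s1, e1, d1), (s2, e2, d2)):
                if len(st) == 0:
                    continue
                idx = np.searchsorted(st, mid, side="right") - 1
                ok = idx >= 0
                sel = idx[ok]
                inside = mid[ok] < en[sel]
                vals = np.zeros(ok.sum(), dtype=np.int64)
                vals[inside] = de[sel[inside]]
                depth[ok] += vals
            out[key] = (mid, edges[1:], depth)
        return CoverageTrack(out, layout=self.layout or other.layout)

    # -- I/O ----------------------------------------------------------
    @classmethod
    def from_bedgraph(cls, path, layout: GenomeLayout, *, strand: str = ".",
                      on_unknown: str = "skip") -> "CoverageTrack":
        """Read one bedGraph (0-based half-open, integer depths) onto one strand."""
        per_chrom: dict[str, list] = {}
        skipped = set()
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise ValueError(f"{path}: line {i}: expected 4 bedGraph columns, got {len(f)}")
                try:
                    start, end = int(f[1]), int(f[2])
                    depth = float(f[3])
                except ValueError:
                    raise ValueError(f"{path}: line {i}: non-numeric fields") from None
                if depth != int(depth):
                    raise ValueError(f"{path}: line {i}: non-integer depth {depth}")
                depth = int(depth)
                if depth < 0:
                    raise ValueError(f"{path}: line {i}: negative depth {depth}")
                if not (0 <= start < end):
                    raise ValueError(f"{path}: line {i}: invalid interval [{start}, {end})")
                chrom = f[0]
                if chrom not in layout:
                    if on_unknown == "error":
                        raise ValueError(f"{path}: line {i}: unknown chromosome {chrom!r}")
                    skipped.add(chrom)
                    continue
                if end > layout.length_of(chrom):
                    raise ValueError(
                        f"{path}: line {i}: record ends at {end} beyond chromosome {chrom} "
                        f"({layout.length_of(chrom)})"
                    )
                per_chrom.setdefault(chrom, []).append((start, end, depth))
        if skipped:
            warnings.warn(f"{path}: skipped records on unknown chromosome(s) {sorted(skipped)}")
        runs = {}
        for chrom, recs in per_chrom.items():
            arr = np.array(recs, dtype=np.int64)
            runs[(chrom, strand)] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(runs, layout=layout)

    @classmethod
    def from_bedgraph_pair(cls, path_plus, path_minus, layout: GenomeLayout, *,
                           on_unknown: str = "skip") -> "CoverageTrack":
        """Read a (+, -) pair of strand-specific bedGraphs into one track."""
        plus = cls.from_bedgraph(path_plus, layout, strand="+", on_unknown=on_unknown)
        minus = cls.from_bedgraph(path_minus, layout, strand="-", on_unknown=on_unknown)
        runs = dict(plus._runs)
        runs.update(minus._runs)
        return cls(runs, layout=layout)

    def to_bedgraph(self, path, strand: str) -> None:
        with open(path, "w") as fh:
            for (chrom, s) in sorted(self._runs):
                if s != strand:
                    continue
                st, en, de = self._runs[(chrom, s)]
                for a, b, d in zip(st, en, de):
                    fh.write(f"{chrom}\t{a}\t{b}\t{d}\n")

    def to_bedgraph_pair(self, path_plus, path_minus) -> None:
        self.to_bedgraph(path_plus, "+")
        self.to_bedgraph(path_minus, "-")

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoverageTrack) or set(self._runs) != set(other._runs):
            return False
        return all(
            all(np.array_equal(x, y) for x, y in zip(self._runs[k], other._runs[k]))
            for k in self._runs
        )


def pool_tracks(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Depth-wise sum of per-sample tracks (the pooled discovery input)."""
    if not tracks:
        return CoverageTrack()
    out = tracks[0]
    for t in tracks[1:]:
        out = out.add(t)
    return out


def coverage_from_intervals(iset: IntervalSet, layout: Optional[GenomeLayout] = None) -> CoverageTrack:
    """Stack intervals into depth-1-per-interval coverage (fragment pileup)."""
    runs: dict = {}
    rows: dict = {}
    for key, s, e, _ in iset.groups(by_strand=True):
        rows[key] = (s, e)
    for key, (s, e) in rows.items():
        edges = np.unique(np.concatenate([s, e]))
        mid = edges[:-1]
        depth = np.zeros(len(mid), dtype=np.int64)
        left = np.searchsorted(mid, s, side="left")
        right = np.searchsorted(mid, e, side="left")
        np.add.at(depth, left, 1)
        over = right < len(mid)
        np.subtract.at(depth, right[over], 1)
        depth = np.cumsum(depth)
        # trailing corrections for intervals ending at the last edge are implicit
        runs[key] = (mid, edges[1:], depth)
    return CoverageTrack(runs, layout=layout)
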