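"""Shared fixtures and independent brute-force oracles.

The oracles re-implement interval and pipeline semantics on explicit
per-base boolean/integer arrays over toy genomes, deliberately ignoring the
run-length machinery of the package, so equivalence tests are meaningful.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from vlincscope import GenomeLayout, IntervalSet


@pytest.fixture
def toy_layout():
    return GenomeLayout([("chr1", 100_000, True), ("chr2", 50_000, True)])


# ---------------------------------------------------------------------------
# per-base mask oracles
# ---------------------------------------------------------------------------

def mask_from_intervals(iset: IntervalSet, chrom: str, strand, size: int) -> np.ndarray:
    m = np.zeros(size, dtype=bool)
    for iv in iset:
        if iv.chrom == chrom and (strand is None or iv.strand == strand):
            m[iv.start:iv.end] = True
    return m


def runs_from_mask(m: np.ndarray) -> list[tuple[int, int]]:
    out = []
    i = 0
    n = len(m)
    while i < n:
        if m[i]:
            j = i
            while j < n and m[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def merge_mask_oracle(m: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Merge covered runs whose separating gap is strictly < max_gap."""
    runs = runs_from_mask(m)
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def discover_oracle(depth_by_key: dict, genes: IntervalSet, blacklist: IntervalSet,
                    layout: GenomeLayout, q: float, base_gap: int, seg_gap: int,
                    min_len: int) -> list[tuple[str, int, int, str]]:
    """Whole-pipeline per-base reference: returns (chrom, start, end, strand) calls.

    ``depth_by_key`` maps (chrom, strand) to a dense integer depth array of
    chromosome length.
    """
    strands = sorted({k[1] for k in depth_by_key})
    calls = []
    # stage 1+2: gene masking then per-strand quantile over covered bases
    masked = {}
    for (chrom, strand), depth in depth_by_key.items():
        depth = depth.copy()
        gm = mask_from_intervals(genes, chrom, strand, len(depth))
        depth[gm] = 0
        masked[(chrom, strand)] = depth
    for strand in strands:
        pooled = np.concatenate([d for (c, s), d in masked.items() if s == strand])
        covered = pooled[pooled >= 1]
        if len(covered) == 0:
            continue
        covered = np.sort(covered)
        thr = covered[min(math.floor(q * len(covered)), len(covered) - 1)]
        for chrom in layout.names:
            depth = masked.get((chrom, strand))
            if depth is None:
                continue
            keep = depth >= thr
            bl = mask_from_intervals(blacklist, chrom, None, len(depth))
            keep &= ~bl
            segs = merge_mask_oracle(keep, base_gap)
            m2 = np.zeros(len(depth), dtype=bool)
            for s, e in segs:
                m2[s:e] = True
            segs2 = merge_mask_oracle(m2, seg_gap)
            for s, e in segs2:
                if e - s >= min_len:
                    calls.append((chrom, s, e, strand))
    return sorted(calls)


def purity_oracle(assignment: dict, labels: dict) -> float:
    clusters = {}
    for sample, c in assignment.items():
        clusters.setdefault(c, []).append(labels[sample])
    total = 0
    for members in clusters.values():
        total += max(members.count(l) for l in set(members))
    return total / len(assignment)


def filter_oracle(counts: np.ndarray, autosomal: np.ndarray, min_reads: int,
                  min_samples: int, autosomal_only: bool) -> list[int]:
    kept = []
    for i in range(counts.shape[0]):
        n_ok = 0
        for j in range(counts.shape[1]):
            if counts[i, j] >= min_reads:
                n_ok += 1
        if n_ok >= min_samples and (autosomal[i] or not autosomal_only):
            kept.append(i)
    return kept


def active_regions_oracle(segments: list[tuple[str, int, int, str]], active_labels: set,
                          merge_gap: int, min_len: int, genome_size: int) -> list[tuple[str, int, int]]:
    out = []
    chroms = sorted({c for c, *_ in segments})
    for chrom in chroms:
        m = np.zeros(genome_size, dtype=bool)
        for c, s, e, lab in segments:
            if c == chrom and lab in active_labels:
                m[s:e] = True
        for s, e in merge_mask_oracle(m, merge_gap):
            if e - s >= min_len:
                out.append((chrom, s, e))
    return sorted(out)
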