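"""Synthetic genomes, coverage, counts, chromatin states and methylation.

The generator plants ground truth for every pipeline stage: intergenic
50 kb–1 Mb transcribed blocks on both strands over a multi-chromosome
genome, strand-specific coverage with per-window expression bursts and
sparse background noise, subtype-structured negative-binomial count
matrices, an "Active"/"Quiescent" chromatin segmentation placing active
segments at expressed-vlincRNA promoters, and CpG methylation that is
hypomethylated inside active promoters against a hypermethylated genome.

Distribution choices (Poisson depths with lognormal bursts, negative
binomial counts, Beta methylation) are emulation targets for the structure
of real data, not claims about it; see the methods note for rationale.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome import Chromosome, GenomeLayout
from .intervals import IntervalSet, _union_runs
from .methylation import MethylationTrack


def _default_subtype_map() -> dict:
    return {"HHD": 8, "t(12;21)": 8, "Other": 8, "pre-T": 8}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    bp-valued fields can be shrunk proportionally with :meth:`scaled` so the
    whole pipeline runs on toy genomes in milliseconds (lengths below 50 kb
    are then expected).
    """

    seed: int = 0
    n_chrom: int = 3
    chrom_length: int = 10_000_000
    n_genes: int = 40
    gene_length_range: tuple = (5_000, 50_000)
    n_vlincs: int = 20
    vlinc_length_range: tuple = (50_000, 1_000_000)  # log-uniform
    n_samples_per_subtype: dict = field(default_factory=_default_subtype_map)
    expression_mean_range: tuple = (8.0, 16.0)  # log-uniform per-vlinc level
    subtype_fold: float = 8.0
    nb_dispersion: float = 0.2
    background_noise_depth: int = 1
    noise_window_density: float = 0.005
    read_depth_scale: float = 1.0
    burst_sigma: float = 1.5  # lognormal sigma of per-window expression bursts
    coverage_window: int = 200
    gene_depth: float = 5.0
    count_depth: float = 20.0  # per-unit-level mean fragment count per sample
    n_specific_per_subtype: int = 3
    batch_shift: float = 0.0
    active_promoter_prob_expressed: float = 0.9
    active_len_range: tuple = (600, 3_000)
    meth_beta_active: tuple = (2.0, 8.0)
    meth_beta_background: tuple = (8.0, 2.0)
    cpg_spacing: int = 500
    cpg_coverage: float = 30.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_chrom", "chrom_length", "n_vlincs"):
            if getattr(self, name) < 0 or (name != "n_vlincs" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.scale >= 1.0 and self.vlinc_length_range[0] < 50_000:
            raise ValueError("vlinc lengths must be >= 50 kb unless running in scaled mode")

    def scaled(self, factor: float) -> "SimulationConfig":
        """Shrink every bp parameter by one common factor (toy-genome mode)."""
        s = lambda x: max(1, round(x * factor))
        return replace(
            self,
            chrom_length=s(self.chrom_length),
            gene_length_range=(s(self.gene_length_range[0]), s(self.gene_length_range[1])),
            vlinc_length_range=(s(self.vlinc_length_range[0]), s(self.vlinc_length_range[1])),
            coverage_window=s(self.coverage_window),
            active_len_range=(s(self.active_len_range[0]), s(self.active_len_range[1])),
            cpg_spacing=s(self.cpg_spacing),
            scale=self.scale * factor,
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth, filled in progressively by the simulate_* ops."""

    config: SimulationConfig
    layout: GenomeLayout
    genes: IntervalSet
    vlincs: pd.DataFrame  # id-indexed: chrom, start, end, strand, level
    specific: dict = field(default_factory=dict)  # subtype -> [vlinc ids]
    active_flags: Optional[pd.Series] = None  # vlinc id -> promoter got an active segment
    active_segments: Optional[IntervalSet] = None
    cpg_true_beta: Optional[pd.DataFrame] = None  # chrom, pos, true_beta

    def vlincs_as_intervalset(self) -> IntervalSet:
        return IntervalSet.from_records(
            [(r.chrom, int(r.start), int(r.end), r.strand, idx, None)
             for idx, r in zip(self.vlincs.index, self.vlincs.itertuples(index=False))]
        ).sort()

    def to_json(self, path) -> None:
        obj = {
            "seed": self.config.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(self.config).items()},
            "chromosomes": [[c.name, c.length, int(c.is_autosome)] for c in self.layout.chromosomes],
            "genes": [[iv.chrom, iv.start, iv.end, iv.strand, iv.name] for iv in self.genes],
            "vlincs": [
                {"id": idx, "chrom": r.chrom, "start": int(r.start), "end": int(r.end),
                 "strand": r.strand, "level": float(r.level)}
                for idx, r in zip(self.vlincs.index, self.vlincs.itertuples(index=False))
            ],
            "specific": {k: list(v) for k, v in self.specific.items()},
            "active_flags": (None if self.active_flags is None
                             else {str(k): bool(v) for k, v in self.active_flags.items()}),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _place_features(rng, layout: GenomeLayout, lengths, placed=None, max_tries=2000):
    """Place features uniformly at random without violating pairwise gaps.

    ``lengths`` is a list of (length, min_separation) pairs; two features
    must be separated by the larger of their two separations.  Returns the
    placements and the running placed list (for chaining feature kinds).
    """
    names = layout.names
    clens = np.array([layout.length_of(n) for n in names], dtype=float)
    placed = list(placed or [])  # (chrom, start, end, sep)
    out = []
    for L, sep in lengths:
        ok = False
        for _ in range(max_tries):
            fit = clens >= L
            p = clens * fit
            p = p / p.sum()
            ci = int(rng.choice(len(names), p=p))
            chrom = names[ci]
            start = int(rng.integers(0, layout.length_of(chrom) - L + 1))
            end = start + L
            conflict = False
            for (c2, s2, e2, sep2) in placed:
                if c2 != chrom:
                    continue
                gap_needed = max(sep, sep2)
                if start < e2 + gap_needed and s2 < end + gap_needed:
                    conflict = True
                    break
            if not conflict:
                placed.append((chrom, start, end, sep))
                out.append((chrom, start, end))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place all features without overlap; the genome is too small "
                "for the requested feature load — increase chrom_length or n_chrom"
            )
    return out, placed


def simulate_genome(config: SimulationConfig) -> SyntheticTruth:
    """Lay out chromosomes, protein-coding genes and planted vlincRNAs.

    vlincRNAs never overlap genes and keep >= 10 kb (scaled) clearance from
    them, so every planted vlincRNA belongs to the far-from-genes class;
    vlincRNAs keep enough mutual clearance that the 10 kb segment merge
    cannot fuse two plants on the same strand.  Deterministic given the seed.
    """
    rng = _rng(config, 1)
    chroms = [Chromosome(f"chr{i+1}", config.chrom_length, True) for i in range(config.n_chrom)]
    layout = GenomeLayout(chroms)
    lo, hi = config.vlinc_length_range
    vlinc_lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), size=config.n_vlincs))
    vlinc_lengths = np.sort(vlinc_lengths.astype(np.int64))[::-1]  # longest first packs better
    vlinc_sep = max(1, round(25_000 * config.scale))
    gene_sep = max(1, round(15_000 * config.scale))
    total = vlinc_lengths.sum() + config.n_genes * config.gene_length_range[1]
    if total + (config.n_vlincs + config.n_genes) * vlinc_sep > 0.8 * layout.total_length:
        raise RuntimeError("requested feature load does not fit the genome; increase its size")
    vplaced, placed = _place_features(rng, layout, [(int(L), vlinc_sep) for L in vlinc_lengths])
    gene_lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1,
                                size=config.n_genes)
    gplaced, _ = _place_features(rng, layout, [(int(L), gene_sep) for L in gene_lengths],
                                 placed=placed)
    strands = rng.choice(["+", "-"], size=config.n_vlincs + config.n_genes)
    lo_l, hi_l = config.expression_mean_range
    levels = np.exp(rng.uniform(math.log(lo_l), math.log(hi_l), size=config.n_vlincs))
    vdf = pd.DataFrame(
        [(f"tv{i:02d}", c, s, e, strands[i], float(levels[i]))
         for i, (c, s, e) in enumerate(vplaced)],
        columns=["id", "chrom", "start", "end", "strand", "level"],
    ).set_index("id")
    vdf = vdf.sort_values(["chrom", "start"], kind="mergesort")
    genes = IntervalSet.from_records(
        [(c, s, e, strands[config.n_vlincs + j], f"gene_{j:03d}", None)
         for j, (c, s, e) in enumerate(gplaced)]
    ).sort()
    return SyntheticTruth(config=config, layout=layout, genes=genes, vlincs=vdf)


def _windowed_runs(rng, start: int, end: int, window: int, lam_fn):
    """Poisson depth per window over [start, end); returns run triplets."""
    n_win = max(1, math.ceil((end - start) / window))
    lam = lam_fn(n_win)
    depths = rng.poisson(lam)
    ws = start + window * np.arange(n_win, dtype=np.int64)
    we = np.minimum(ws + window, end)
    keep = depths > 0
    return ws[keep], we[keep], depths[keep].astype(np.int64)


def simulate_coverage(truth: SyntheticTruth, config: Optional[SimulationConfig] = None, *,
                      n_datasets: int = 1, null_expression: bool = False,
                      stage_seed: int = 2) -> CoverageTrack:
    """Strand-specific coverage of the planted genome.

    Depth over each vlincRNA window is Poisson(level * read_depth_scale *
    n_datasets * lognormal burst); gene bodies get Poisson(gene_depth *
    n_datasets) on their own strand (to exercise masking); sparse background
    noise windows get depth ``background_noise_depth`` away from planted
    features.  ``n_datasets`` emulates pooling that many datasets.  With
    ``null_expression`` the planted blocks are silenced and only genes and
    noise remain.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, stage_seed])
    w = config.coverage_window
    runs: dict = {}

    def _acc(key, triplet):
        runs.setdefault(key, [[], [], []])
        for lst, arr in zip(runs[key], triplet):
            lst.append(arr)

    feature_spans: dict = {}  # (chrom, strand) -> list of (start, end)
    for idx, r in zip(truth.vlincs.index, truth.vlincs.itertuples(index=False)):
        feature_spans.setdefault((r.chrom, r.strand), []).append((int(r.start), int(r.end)))
        if null_expression:
            continue
        level = float(r.level) * config.read_depth_scale * n_datasets
        sig = config.burst_sigma
        triplet = _windowed_runs(
            rng, int(r.start), int(r.end), w,
            lambda n: level * rng.lognormal(0.0, sig, size=n),
        )
        _acc((r.chrom, r.strand), triplet)
    for iv in truth.genes:
        feature_spans.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
        lam = config.gene_depth * n_datasets
        triplet = _windowed_runs(rng, iv.start, iv.end, w, lambda n: np.full(n, lam))
        _acc((iv.chrom, iv.strand), triplet)
    # background noise away from planted features
    for chrom in truth.layout.names:
        clen = truth.layout.length_of(chrom)
        n_win = clen // w
        for strand in ("+", "-"):
            mask = rng.random(n_win) < config.noise_window_density
            idxs = np.flatnonzero(mask)
            if len(idxs) == 0:
                continue
            ws = idxs.astype(np.int64) * w
            we = ws + w
            spans = sorted(feature_spans.get((chrom, strand), []))
            if spans:
                fs = np.array([s for s, _ in spans], dtype=np.int64)
                fe = np.array([e for _, e in spans], dtype=np.int64)
                j = np.searchsorted(fe, ws, side="right")
                hit = (j < len(fs)) & (fs[np.minimum(j, len(fs) - 1)] < we)
                ws, we = ws[~hit], we[~hit]
            if len(ws):
                depths = np.full(len(ws), config.background_noise_depth, dtype=np.int64)
                _acc((chrom, strand), (ws, we, depths))
    final = {}
    for key, (ss, es, ds) in runs.items():
        final[key] = (np.concatenate(ss), np.concatenate(es), np.concatenate(ds))
    return CoverageTrack(final, layout=truth.layout)


def simulate_counts(truth: SyntheticTruth, config: Optional[SimulationConfig] = None):
    """Subtype-structured negative-binomial count matrix.

    Per-region base mean is ``level * count_depth``; for each subtype a
    disjoint set of ``n_specific_per_subtype`` regions is boosted by
    ``subtype_fold`` in that subtype's samples.  Returns
    ``(CountMatrix, meta)`` and records the specific sets in the truth.
    """
    from .expression import CountMatrix

    config = config or truth.config
    rng = _rng(config, 3)
    subtypes = list(config.n_samples_per_subtype)
    if len(subtypes) < 2:
        raise ValueError("need at least 2 subtypes")
    ids = list(truth.vlincs.index)
    pool = list(ids)
    specific: dict = {}
    for st in subtypes:
        k = min(config.n_specific_per_subtype, len(pool))
        chosen = list(rng.choice(pool, size=k, replace=False)) if k else []
        specific[st] = [str(c) for c in chosen]
        pool = [p for p in pool if p not in set(chosen)]
    truth.specific = specific
    samples, meta_rows = [], []
    for st in subtypes:
        for j in range(config.n_samples_per_subtype[st]):
            sid = f"{st}_{j+1:02d}"
            samples.append((sid, st))
            pheno = "pre-T" if st == "pre-T" else ("control" if st == "control" else "pre-B")
            batch = "b2" if (config.batch_shift > 0 and j % 2) else "b1"
            meta_rows.append((sid, pheno, st, batch))
    base = truth.vlincs["level"].to_numpy() * config.count_depth
    counts = np.zeros((len(ids), len(samples)), dtype=np.int64)
    disp = config.nb_dispersion
    for sj, (sid, st) in enumerate(samples):
        m = base.copy()
        boost = np.isin(np.array(ids), np.array(specific[st], dtype=object))
        m[boost] *= config.subtype_fold
        if config.batch_shift > 0 and meta_rows[sj][3] == "b2":
            m = m * (1.0 + config.batch_shift)
        if disp > 0:
            n_par = 1.0 / disp
            p_par = n_par / (n_par + m)
            counts[:, sj] = rng.negative_binomial(n_par, p_par)
        else:
            counts[:, sj] = rng.poisson(m)
    cdf = pd.DataFrame(counts, index=pd.Index(ids, name="region"),
                       columns=[s for s, _ in samples])
    regions = pd.DataFrame({
        "chrom": truth.vlincs["chrom"],
        "autosomal": [truth.layout.is_autosome(c) for c in truth.vlincs["chrom"]],
    }, index=truth.vlincs.index)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "immunophenotype", "subtype", "batch"])
    cm = CountMatrix(cdf, regions, meta)
    return cm, cm.meta


def simulate_chromatin_and_meth(truth: SyntheticTruth, config: Optional[SimulationConfig] = None, *,
                                decouple_active: bool = False):
    """Chromatin segmentation and CpG methylation with planted active promoters.

    Expressed vlincRNA promoters receive an "Active" segment (length uniform
    in ``active_len_range``, centered near the 5' start) with probability
    ``active_promoter_prob_expressed``; everything else is "Quiescent".
    CpGs sit every ``cpg_spacing`` bp; their true beta is Beta(2,8) inside
    active segments, Beta(8,2) elsewhere, observed through binomial counts
    at Poisson(``cpg_coverage``) depth.  With ``decouple_active`` the same
    number and sizes of active segments are placed uniformly at random,
    severing the link to promoters (the null for enrichment calibration).
    """
    config = config or truth.config
    rng = _rng(config, 4)
    layout = truth.layout
    seg_rows = []
    flags = {}
    jitter = max(1, round(2_000 * config.scale))
    for idx, r in zip(truth.vlincs.index, truth.vlincs.itertuples(index=False)):
        expressed = float(r.level) > 0
        got = expressed and (rng.random() < config.active_promoter_prob_expressed)
        if got:
            L = int(rng.integers(config.active_len_range[0], config.active_len_range[1] + 1))
            if decouple_active:
                chrom = layout.names[int(rng.integers(0, len(layout)))]
                start = int(rng.integers(0, layout.length_of(chrom) - L + 1))
            else:
                chrom = r.chrom
                tss = int(r.start) if r.strand == "+" else int(r.end)
                center = tss + int(rng.integers(-jitter, jitter + 1))
                start = max(0, min(center - L // 2, layout.length_of(chrom) - L))
            seg_rows.append((chrom, start, start + L, ".", "Active", None))
        flags[idx] = bool(got) and not decouple_active
    active = IntervalSet.from_records(seg_rows).sort()
    # Quiescent = complement of active segments, giving a dense segmentation
    state_rows = []
    by_chrom: dict = {}
    for key, s, e, _ in active.groups(by_strand=False):
        by_chrom[key[0]] = _union_runs(s, e)
    for chrom in layout.names:
        clen = layout.length_of(chrom)
        cur = 0
        us, ue = by_chrom.get(chrom, (np.array([], dtype=np.int64),) * 2)
        for s, e in zip(us, ue):
            if s > cur:
                state_rows.append((chrom, cur, int(s), ".", "Quiescent", None))
            state_rows.append((chrom, int(s), int(e), ".", "Active", None))
            cur = int(e)
        if cur < clen:
            state_rows.append((chrom, cur, clen, ".", "Quiescent", None))
    states = IntervalSet.from_records(state_rows).sort()
    # CpG methylation
    meth_rows = []
    a_act, b_act = config.meth_beta_active
    a_bg, b_bg = config.meth_beta_background
    true_rows = []
    for chrom in layout.names:
        clen = layout.length_of(chrom)
        pos = np.arange(config.cpg_spacing, clen, config.cpg_spacing, dtype=np.int64)
        us, ue = by_chrom.get(chrom, (np.array([], dtype=np.int64),) * 2)
        inside = np.zeros(len(pos), dtype=bool)
        if len(us):
            j = np.searchsorted(ue, pos, side="right")
            inside = (j < len(us)) & (us[np.minimum(j, len(us) - 1)] <= pos)
        beta = np.where(inside, rng.beta(a_act, b_act, size=len(pos)),
                        rng.beta(a_bg, b_bg, size=len(pos)))
        tot = rng.poisson(config.cpg_coverage, size=len(pos))
        meth = rng.binomial(tot, beta)
        df = pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth, "unmeth": tot - meth})
        meth_rows.append(df)
        true_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "true_beta": beta}))
    track = MethylationTrack(pd.concat(meth_rows, ignore_index=True))
    truth.active_flags = pd.Series(flags)
    truth.active_segments = active
    truth.cpg_true_beta = pd.concat(true_rows, ignore_index=True)
    return states, track


def simulate_all(config: SimulationConfig, outdir=None) -> dict:
    """Run every generator stage; optionally write all outputs under ``outdir``.

    Returns a dict with truth, pooled coverage track, count matrix, states
    and methylation track.
    """
    truth = simulate_genome(config)
    n_total = sum(config.n_samples_per_subtype.values())
    pooled = simulate_coverage(truth, n_datasets=n_total)
    cm, meta = simulate_counts(truth)
    states, meth = simulate_chromatin_and_meth(truth)
    out = {"truth": truth, "pooled_coverage": pooled, "counts": cm,
           "meta": meta, "states": states, "methylation": meth}
    if outdir is not None:
        import os

        from .intervals import write_bed

        os.makedirs(outdir, exist_ok=True)
        truth.layout.to_tsv(os.path.join(outdir, "genome.tsv"))
        write_bed(truth.genes, os.path.join(outdir, "genes.bed"))
        truth.to_json(os.path.join(outdir, "truth.json"))
        pooled.to_bedgraph_pair(os.path.join(outdir, "pooled.plus.bedgraph"),
                                os.path.join(outdir, "pooled.minus.bedgraph"))
        cm.to_tsv(os.path.join(outdir, "counts.tsv"))
        meta.reset_index().to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
        write_bed(states, os.path.join(outdir, "states.bed"))
        meth.to_tsv(os.path.join(outdir, "methylation.tsv"))
    return out
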