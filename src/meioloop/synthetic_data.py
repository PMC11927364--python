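"""Synthetic genomes with planted CTCF loop anchors, signal tracks and
recombination features.

The generator emulates the statistical structure of the pipeline's real
inputs — convergently oriented CTCF anchor pairs, fragment coverage enriched
at anchors, ssDNA/crossover hotspots enriched at anchors and inside loops,
haplotype-block boundaries biased toward anchors — with every effect size a
configuration knob, so each downstream stage has a known planted answer.

Planted fold semantics
----------------------
Hotspot folds are expressed relative to the *realized genome-average* density,
because that is the quantity the circular-permutation ratio estimates: the
background density is solved self-consistently so that the genome-wide mean
density equals the configured per-Mb rate while anchor-dilated blocks sit at
``fold x`` that mean.  Fold combinations that would drive the background
density to zero or below raise a :class:`ConfigError`.

All randomness flows from a single ``numpy`` Generator seeded by
``SimulationConfig.seed``; a fixed seed reproduces the dataset (and its
on-disk files) bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (GenomeLayout, LoopSet, RegionSet, SignalTrack,
                        ValidationError, write_ctcf_sites,
                        write_expression_table)

__all__ = ["SimulationConfig", "SimulatedDataset", "ConfigError",
           "simulate_genome", "plant_ctcf_landscape", "simulate_tracks",
           "plant_recombination", "simulate_dataset", "plant_window_outcome"]

CTCF_MOTIF_WIDTH = 19  # bp, core CTCF consensus scale


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent or infeasible."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults model a 20 Mb, five-chromosome genome with 50 planted loops and
    the enrichment folds reported for anchors versus ssDNA/crossover maps
    (~3.5x); fragment geometry matches the 136 bp median fragment length of
    the source assay.
    """

    # genome
    n_chromosomes: int = 5
    chrom_length: int = 4_000_000
    gc_mean: float = 0.41
    # CTCF landscape / true loops
    n_true_loops: int = 50
    loop_length_min: int = 10_000
    loop_length_max: int = 2_000_000
    decoy_ctcf_per_mb: float = 25.0
    # signal tracks
    fragment_median_length: int = 136
    fragment_rate_per_bp: float = 0.01
    anchor_signal_fold: float = 5.0
    loop_interior_signal_fold: float = 1.0
    extra_peaks_per_mb: float = 10.0
    genes_per_mb: float = 8.0
    gene_in_loop_fraction: float = 0.5
    # recombination features
    ssdna_per_mb: float = 8.0
    ssdna_anchor_fold: float = 3.5
    ssdna_loop_fold: float = 1.2
    crossover_per_mb: float = 4.0
    crossover_anchor_fold: float = 3.5
    crossover_loop_fold: float = 1.15
    hotspot_width_min: int = 1_000
    hotspot_width_max: int = 2_000
    hapblock_median_bp: int = 15_000
    hapblock_anchor_bias: float = 0.5
    hapblock_min_bp: int = 1_000
    # geometry / placement
    anchor_block: int = 5_000
    telomere_bias_beta: float = 0.0
    noise_level: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0:
            raise ConfigError("need at least one chromosome")
        if self.chrom_length < self.loop_length_min:
            raise ConfigError("chromosomes shorter than the minimum loop length")
        for name in ("anchor_signal_fold", "loop_interior_signal_fold",
                     "ssdna_anchor_fold", "ssdna_loop_fold",
                     "crossover_anchor_fold", "crossover_loop_fold"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.gene_in_loop_fraction <= 1:
            raise ConfigError("gene_in_loop_fraction must lie in [0, 1]")
        if not 0 <= self.hapblock_anchor_bias <= 1:
            raise ConfigError("hapblock_anchor_bias must lie in [0, 1]")
        if self.noise_level < 0:
            raise ConfigError("noise_level must be >= 0")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _smooth_field(n: int, kernel_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth random field over n bins."""
    raw = rng.standard_normal(n + 2 * kernel_bins)
    k = np.exp(-0.5 * (np.arange(-kernel_bins, kernel_bins + 1) / (kernel_bins / 3)) ** 2)
    k /= k.sum()
    sm = np.convolve(raw, k, mode="same")[kernel_bins:kernel_bins + n]
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[GenomeLayout, SignalTrack, SignalTrack]:
    """Build the chromosome layout plus GC and replication-timing tracks.

    GC is a smooth field around ``gc_mean`` in 1 kb bins, clipped to [0, 1];
    replication timing is a z-scaled smooth field in 1 kb bins (positive =
    early).  Deterministic for a given config/rng state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layout = GenomeLayout({f"chr{i + 1}": config.chrom_length
                           for i in range(config.n_chromosomes)})
    gc_rows, rt_rows = [], []
    for chrom in layout.chroms:
        n = layout.length(chrom) // 1000
        starts = np.arange(n) * 1000
        gc = np.clip(config.gc_mean
                     + 0.05 * config.noise_level * _smooth_field(n, 10, rng), 0, 1)
        rt = _smooth_field(n, 50, rng)
        gc_rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                     "end": starts + 1000, "value": gc}))
        rt_rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                     "end": starts + 1000, "value": rt}))
    gc_track = SignalTrack(pd.concat(gc_rows, ignore_index=True), layout=layout)
    rt_track = SignalTrack(pd.concat(rt_rows, ignore_index=True), layout=layout)
    return layout, gc_track, rt_track


# ---------------------------------------------------------------------------
# telomere-biased placement helper
# ---------------------------------------------------------------------------


def _telomere_weights(positions: np.ndarray, chrom_len: int, beta: float,
                      eps: float = 0.01) -> np.ndarray:
    """Placement density ~ (relative telomere distance + eps)^(-beta)."""
    rel = np.minimum(positions, chrom_len - positions) / chrom_len
    return (rel + eps) ** (-beta)


def _sample_positions(n: int, chrom_len: int, beta: float,
                      rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if beta == 0:
        return rng.integers(0, chrom_len, size=n)
    grid = np.linspace(0, chrom_len, 2049)
    mids = (grid[:-1] + grid[1:]) / 2
    w = _telomere_weights(mids, chrom_len, beta)
    bins = rng.choice(len(mids), size=n, p=w / w.sum())
    lo = grid[bins]
    return (lo + rng.random(n) * (grid[bins + 1] - grid[bins])).astype(np.int64)


# ---------------------------------------------------------------------------
# CTCF landscape and true loops
# ---------------------------------------------------------------------------


def plant_ctcf_landscape(layout: GenomeLayout, config: SimulationConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[pd.DataFrame, LoopSet]:
    """Place true convergent anchor pairs and decoy CTCF sites.

    Each true loop contributes a '+' site at its left anchor and a '-' site at
    its right anchor; decoys are uniform with random strands.  Motif score and
    conservation are drawn from shifted distributions for true anchors, and
    peak strength is the genome-wide percentile of a latent cut-site intensity
    that is upshifted at true anchors.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = layout.chroms
    lens = np.array([layout.length(c) for c in chroms])
    margin = config.anchor_block  # keep anchors clear of chromosome ends

    n = config.n_true_loops
    log_lo, log_hi = np.log(config.loop_length_min), np.log(config.loop_length_max)
    loop_len = np.exp(rng.uniform(log_lo, log_hi, size=n)).astype(np.int64)
    cap = lens.max() - 2 * margin
    if n and (loop_len > cap).any():
        raise ConfigError("requested loops exceed placeable capacity")
    loop_chrom_idx = np.empty(n, dtype=np.int64)
    loop_start = np.empty(n, dtype=np.int64)
    for i in range(n):
        room = lens - loop_len[i] - 2 * margin
        ok = room > 0
        if not ok.any():
            raise ConfigError("requested loops exceed placeable capacity")
        p = np.where(ok, room, 0).astype(float)
        ci = rng.choice(len(chroms), p=p / p.sum())
        loop_chrom_idx[i] = ci
        if config.telomere_bias_beta > 0:
            pos = _sample_positions(1, int(lens[ci] - loop_len[i] - 2 * margin),
                                    config.telomere_bias_beta, rng)[0] + margin
        else:
            pos = rng.integers(margin, lens[ci] - loop_len[i] - margin)
        loop_start[i] = pos
    loop_chrom = np.array(chroms, dtype=object)[loop_chrom_idx] if n else np.empty(0, dtype=object)

    loops = LoopSet(pd.DataFrame({"chrom": loop_chrom,
                                  "mid1": loop_start,
                                  "mid2": loop_start + loop_len}),
                    layout=layout)

    # decoy sites
    dec_chrom, dec_pos = [], []
    for c, L in zip(chroms, lens):
        k = rng.poisson(config.decoy_ctcf_per_mb * L / 1e6)
        pos = _sample_positions(k, int(L), config.telomere_bias_beta, rng)
        pos = np.clip(pos, margin, L - margin - 1)
        dec_chrom.extend([c] * k)
        dec_pos.append(pos)
    dec_pos = np.concatenate(dec_pos) if dec_pos else np.empty(0, dtype=np.int64)

    site_chrom = np.concatenate([loop_chrom, loop_chrom,
                                 np.array(dec_chrom, dtype=object)])
    site_mid = np.concatenate([loop_start, loop_start + loop_len, dec_pos])
    site_strand = np.concatenate([np.full(n, "+"), np.full(n, "-"),
                                  rng.choice(["+", "-"], size=len(dec_pos))])
    is_true = np.concatenate([np.ones(2 * n, dtype=bool),
                              np.zeros(len(dec_pos), dtype=bool)])
    loop_id = np.concatenate([np.arange(n), np.arange(n),
                              np.full(len(dec_pos), -1)]).astype(np.int64)

    m = len(site_mid)
    sd = config.noise_level
    motif_score = np.where(is_true, rng.normal(12.0, 1.5 * sd, m),
                           rng.normal(9.0, 1.5 * sd, m))
    conservation = np.clip(np.where(is_true, rng.beta(6, 2, m), rng.beta(2, 4, m)),
                           0, 1)
    latent = rng.lognormal(0.0, 0.5 * sd if sd > 0 else 1e-9, m)
    latent[is_true] *= config.anchor_signal_fold
    # genome-wide percentile of cut-site intensity
    peak_strength = (pd.Series(latent).rank(method="average") - 0.5) / m

    half = CTCF_MOTIF_WIDTH // 2
    sites = pd.DataFrame({
        "chrom": site_chrom.astype(str),
        "start": site_mid - half,
        "end": site_mid + half + 1,
        "strand": site_strand,
        "motif_score": motif_score,
        "conservation": conservation,
        "peak_strength": peak_strength.to_numpy(),
        "is_true_anchor": is_true,
        "loop_id": loop_id,
    })
    sites["mid"] = site_mid
    sites = sites.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return sites, loops


# ---------------------------------------------------------------------------
# signal tracks: fragments, peaks, expression
# ---------------------------------------------------------------------------


def _merged_spans(loops: LoopSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return loops.spans().merged().chrom_arrays() if len(loops) else {}


def simulate_tracks(layout: GenomeLayout, sites: pd.DataFrame, true_loops: LoopSet,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[RegionSet, RegionSet, pd.DataFrame]:
    """Fragments, accessibility peaks with strength, and an expression table.

    Fragment midpoints are Poisson with the background rate multiplied by
    ``anchor_signal_fold`` within +/-1 kb of true anchors (and by
    ``loop_interior_signal_fold`` inside loop spans); fragment lengths are
    log-normal with the configured median.  A fraction of gene TSSs is placed
    inside true loops.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = layout.chroms
    rate = config.fragment_rate_per_bp
    anchor_mids = sites.loc[sites.get("is_true_anchor",
                                      pd.Series(False, index=sites.index)), :]

    frag_chrom, frag_mid = [], []
    loop_spans = _merged_spans(true_loops)
    for c in chroms:
        L = layout.length(c)
        k = rng.poisson(rate * L)
        mids = rng.integers(0, L, size=k)
        frag_chrom.extend([c] * k)
        frag_mid.append(mids)
        if config.loop_interior_signal_fold > 1 and c in loop_spans:
            ms, me = loop_spans[c]
            for s, e in zip(ms, me):
                k2 = rng.poisson(rate * (config.loop_interior_signal_fold - 1) * (e - s))
                frag_chrom.extend([c] * k2)
                frag_mid.append(rng.integers(s, e, size=k2))
    if config.anchor_signal_fold > 1:
        sub = anchor_mids
        for c, mid in zip(sub["chrom"], sub["mid"]):
            L = layout.length(c)
            lo, hi = max(mid - 1000, 0), min(mid + 1000, L)
            k = rng.poisson(rate * (config.anchor_signal_fold - 1) * (hi - lo))
            frag_chrom.extend([c] * k)
            frag_mid.append(rng.integers(lo, hi, size=k))
    frag_mid = np.concatenate(frag_mid) if frag_mid else np.empty(0, dtype=np.int64)
    frag_len = np.maximum(np.round(config.fragment_median_length
                                   * np.exp(rng.normal(0, 0.25, len(frag_mid)))), 30
                          ).astype(np.int64)
    frag_chrom = np.array(frag_chrom, dtype=object)
    starts = frag_mid - frag_len // 2
    ends = starts + frag_len
    clens = np.array([layout.length(c) for c in frag_chrom]) if len(frag_chrom) else np.empty(0)
    starts = np.maximum(starts, 0)
    ends = np.minimum(ends, clens).astype(np.int64) if len(frag_chrom) else ends
    keep = ends > starts
    fragments = RegionSet.from_arrays(frag_chrom[keep], starts[keep], ends[keep],
                                      layout=layout)

    # accessibility peaks: one per CTCF site plus scattered extras
    pk_chrom = list(sites["chrom"])
    pk_mid = list(sites["mid"])
    pk_latent = list(np.where(sites.get("is_true_anchor", False),
                              rng.lognormal(0, 0.5, len(sites)) * config.anchor_signal_fold,
                              rng.lognormal(0, 0.5, len(sites))))
    for c in chroms:
        L = layout.length(c)
        k = rng.poisson(config.extra_peaks_per_mb * L / 1e6)
        pk_chrom.extend([c] * k)
        pk_mid.extend(rng.integers(0, L, size=k).tolist())
        pk_latent.extend(rng.lognormal(0, 0.5, k).tolist())
    pk_mid = np.asarray(pk_mid, dtype=np.int64)
    pk_latent = np.asarray(pk_latent)
    width = np.maximum(rng.normal(400, 50, len(pk_mid)), 100).astype(np.int64)
    pk_chrom = np.array(pk_chrom, dtype=object)
    clens = np.array([layout.length(c) for c in pk_chrom])
    ps = np.maximum(pk_mid - width // 2, 0)
    pe = np.minimum(pk_mid + width // 2, clens)
    strength = (pd.Series(pk_latent).rank(method="average") - 0.5) / len(pk_latent)
    peaks = RegionSet.from_arrays(pk_chrom, ps, pe, layout=layout,
                                  score=strength.to_numpy())

    # expression: TSSs, a configurable fraction inside true loops
    total_mb = layout.total_length / 1e6
    n_genes = rng.poisson(config.genes_per_mb * total_mb)
    in_loop = (rng.random(n_genes) < config.gene_in_loop_fraction) & (len(true_loops) > 0)
    g_chrom = np.empty(n_genes, dtype=object)
    g_tss = np.empty(n_genes, dtype=np.int64)
    ldf = true_loops.df
    for i in range(n_genes):
        if in_loop[i]:
            j = rng.integers(0, len(ldf))
            g_chrom[i] = ldf["chrom"].iloc[j]
            g_tss[i] = rng.integers(ldf["mid1"].iloc[j], ldf["mid2"].iloc[j])
        else:
            ci = rng.choice(len(chroms))
            g_chrom[i] = chroms[ci]
            g_tss[i] = rng.integers(0, layout.length(chroms[ci]))
    expression = pd.DataFrame({
        "gene_id": [f"gene_{i}" for i in range(n_genes)],
        "chrom": g_chrom.astype(str),
        "tss": g_tss,
        "scaled_expression": rng.normal(0, 1, n_genes),
    }).sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)
    return fragments, peaks, expression


# ---------------------------------------------------------------------------
# recombination features
# ---------------------------------------------------------------------------


def _class_regions(layout: GenomeLayout, true_loops: LoopSet, anchor_block: int,
                   dilate: int) -> tuple[dict, dict, dict]:
    """Partition each chromosome into anchor-dilated blocks, loop interiors
    and background; returns per-chrom (starts, ends) for the first two."""
    anchors = (true_loops.anchors(anchor_block // 2 + dilate).merged().chrom_arrays()
               if len(true_loops) else {})
    interiors = {}
    spans = _merged_spans(true_loops)
    for c, (s, e) in spans.items():
        segs_s, segs_e = [s.copy()], [e.copy()]
        out_s, out_e = _subtract(s, e, *(anchors.get(c, (np.empty(0, np.int64),
                                                         np.empty(0, np.int64)))))
        interiors[c] = (out_s, out_e)
    return anchors, interiors, spans


def _subtract(s: np.ndarray, e: np.ndarray, ms: np.ndarray, me: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Subtract merged intervals (ms, me) from merged intervals (s, e)."""
    out_s, out_e = [], []
    for a, b in zip(s, e):
        cur = a
        i0 = np.searchsorted(me, a, side="right")
        for j in range(i0, len(ms)):
            if ms[j] >= b:
                break
            if ms[j] > cur:
                out_s.append(cur)
                out_e.append(min(ms[j], b))
            cur = max(cur, me[j])
        if cur < b:
            out_s.append(cur)
            out_e.append(b)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def _place_in_segments(n: int, seg_s: np.ndarray, seg_e: np.ndarray,
                       rng: np.random.Generator, chrom_len: int,
                       beta: float) -> np.ndarray:
    """n positions uniform (or telomere-weighted) within the given segments."""
    if n == 0 or len(seg_s) == 0:
        return np.empty(0, dtype=np.int64)
    w = (seg_e - seg_s).astype(float)
    if beta > 0:
        w = w * _telomere_weights((seg_s + seg_e) / 2, chrom_len, beta)
    idx = rng.choice(len(seg_s), size=n, p=w / w.sum())
    return (seg_s[idx] + rng.random(n) * (seg_e[idx] - seg_s[idx])).astype(np.int64)


def _plant_hotspots(layout: GenomeLayout, true_loops: LoopSet,
                    config: SimulationConfig, per_mb: float, anchor_fold: float,
                    loop_fold: float, rng: np.random.Generator) -> RegionSet:
    w_lo, w_hi = config.hotspot_width_min, config.hotspot_width_max
    dilate = (w_lo + w_hi) // 4  # mean half-width, so centers see fold x density
    anchors, interiors, _ = _class_regions(layout, true_loops,
                                           config.anchor_block, dilate)
    G = layout.total_length
    bp_a = sum(int((e - s).sum()) for s, e in anchors.values())
    bp_i = sum(int((e - s).sum()) for s, e in interiors.values())
    fr_a, fr_i = bp_a / G, bp_i / G
    fr_bg = 1 - fr_a - fr_i
    if fr_bg <= 0:
        raise ConfigError("anchor/interior classes cover the whole genome")
    c_bg = (1 - anchor_fold * fr_a - loop_fold * fr_i) / fr_bg
    if c_bg <= 0:
        raise ConfigError(
            "planted folds infeasible: background density would be <= 0 "
            f"(anchor fold {anchor_fold}, loop fold {loop_fold}, "
            f"anchor fraction {fr_a:.3f}, interior fraction {fr_i:.3f})")
    rho = per_mb / 1e6  # genome-average center density
    chrom_rows = []
    beta = config.telomere_bias_beta
    for chrom in layout.chroms:
        L = layout.length(chrom)
        a_s, a_e = anchors.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        i_s, i_e = interiors.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        bg_s, bg_e = _subtract(np.array([0]), np.array([L]),
                               *merge_sorted((a_s, a_e), (i_s, i_e)))
        for (ss, ee), fold in (((a_s, a_e), anchor_fold),
                               ((i_s, i_e), loop_fold),
                               ((bg_s, bg_e), c_bg)):
            bp = int((ee - ss).sum())
            k = rng.poisson(rho * fold * bp)
            centers = _place_in_segments(k, ss, ee, rng, L, beta)
            if len(centers):
                widths = rng.integers(w_lo, w_hi + 1, size=len(centers))
                chrom_rows.append(pd.DataFrame({
                    "chrom": chrom,
                    "start": np.maximum(centers - widths // 2, 0),
                    "end": np.minimum(centers + (widths - widths // 2), L)}))
    if not chrom_rows:
        return RegionSet(layout=layout)
    df = pd.concat(chrom_rows, ignore_index=True)
    return RegionSet(df[df["end"] > df["start"]], layout=layout)


def merge_sorted(a: tuple[np.ndarray, np.ndarray],
                 b: tuple[np.ndarray, np.ndarray]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Union of two merged interval lists as a merged list."""
    from .core_data import merge_intervals
    s = np.concatenate([a[0], b[0]])
    e = np.concatenate([a[1], b[1]])
    if len(s) == 0:
        return s.astype(np.int64), e.astype(np.int64)
    return merge_intervals(s, e)


def plant_recombination(layout: GenomeLayout, true_loops: LoopSet,
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[RegionSet, RegionSet, RegionSet]:
    """ssDNA hotspots, crossover events and haplotype blocks.

    ssDNA and crossover hotspots are 1-2 kb regions placed at ``fold x`` the
    genome-average density within anchor blocks (and ``loop_fold x`` inside
    loop interiors); haplotype-block boundaries are snapped to anchor
    midpoints with the configured probability, and only blocks >= the minimum
    size are emitted.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ssdna = _plant_hotspots(layout, true_loops, config, config.ssdna_per_mb,
                            config.ssdna_anchor_fold, config.ssdna_loop_fold, rng)
    crossovers = _plant_hotspots(layout, true_loops, config,
                                 config.crossover_per_mb,
                                 config.crossover_anchor_fold,
                                 config.crossover_loop_fold, rng)

    # haplotype blocks: renewal process of boundaries, anchor-snapped
    anchor_mids: dict[str, np.ndarray] = {}
    for chrom, sub in true_loops.df.groupby("chrom", sort=False):
        anchor_mids[chrom] = np.sort(np.concatenate([sub["mid1"], sub["mid2"]]))
    rows = []
    for chrom in layout.chroms:
        L = layout.length(chrom)
        sizes = []
        total = 0
        while total < L:
            s = int(config.hapblock_median_bp * np.exp(rng.normal(0, 1.0)))
            s = max(s, 200)
            sizes.append(s)
            total += s
        bounds = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
        bounds = bounds[bounds <= L]
        if len(bounds) == 0 or bounds[-1] != L:
            bounds = np.append(bounds, L)
        mids = anchor_mids.get(chrom, np.empty(0, dtype=np.int64))
        for mid in mids:
            if rng.random() < config.hapblock_anchor_bias and len(bounds) > 2:
                j = int(np.argmin(np.abs(bounds - mid)))
                if 0 < j < len(bounds) - 1:
                    bounds[j] = mid
        bounds = np.unique(bounds)
        bs, be = bounds[:-1], bounds[1:]
        keep = (be - bs) >= config.hapblock_min_bp
        rows.append(pd.DataFrame({"chrom": chrom, "start": bs[keep],
                                  "end": be[keep]}))
    blocks = RegionSet(pd.concat(rows, ignore_index=True), layout=layout)
    return ssdna, crossovers, blocks


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """Everything one pipeline run consumes, generated from a single seed."""

    config: SimulationConfig
    layout: GenomeLayout
    gc_track: SignalTrack
    replication_timing: SignalTrack
    sites: pd.DataFrame
    true_loops: LoopSet
    fragments: RegionSet
    peaks: RegionSet
    expression: pd.DataFrame
    ssdna: RegionSet
    crossovers: RegionSet
    hapblocks: RegionSet

    def write(self, outdir: str | Path) -> None:
        """Emit the dataset in the formats the readers consume."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.layout.to_file(out / "chrom.sizes")
        self.gc_track.to_bedgraph(out / "gc.bedgraph")
        self.replication_timing.to_bedgraph(out / "replication_timing.bedgraph")
        write_ctcf_sites(self.sites.drop(columns=["is_true_anchor", "loop_id"],
                                         errors="ignore"), out / "ctcf_sites.tsv")
        self.true_loops.to_bedpe(out / "true_loops.bedpe")
        self.fragments.to_bed(out / "fragments.bed")
        self.peaks.to_bed(out / "peaks.bed")
        write_expression_table(self.expression, out / "expression.tsv")
        self.ssdna.to_bed(out / "ssdna.bed")
        self.crossovers.to_bed(out / "crossovers.bed")
        self.hapblocks.to_bed(out / "hapblocks.bed")


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Run the full generator chain deterministically from ``config.seed``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    layout, gc_track, rt_track = simulate_genome(config, rng)
    sites, loops = plant_ctcf_landscape(layout, config, rng)
    fragments, peaks, expression = simulate_tracks(layout, sites, loops, config, rng)
    ssdna, crossovers, blocks = plant_recombination(layout, loops, config, rng)
    return SimulatedDataset(config, layout, gc_track, rt_track, sites, loops,
                            fragments, peaks, expression, ssdna, crossovers,
                            blocks)


# ---------------------------------------------------------------------------
# planted window outcomes
# ---------------------------------------------------------------------------


def plant_window_outcome(table: pd.DataFrame, weights: dict[str, float],
                         prevalence: float = 0.15,
                         rng: np.random.Generator | None = None,
                         seed: int = 0) -> np.ndarray:
    """Binary outcome per genome window driven by the named feature columns.

    The linear predictor is the weighted sum of z-scored features; the
    intercept is solved by bisection so the mean Bernoulli probability equals
    ``prevalence``.  Used to plant a known driver structure for the window
    classifier.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    score = np.zeros(len(table))
    for name, w in weights.items():
        col = table[name].to_numpy(dtype=float)
        sd = col.std()
        score += w * (col - col.mean()) / (sd if sd > 0 else 1.0)
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2
        p = 1 / (1 + np.exp(-(score + mid)))
        if p.mean() > prevalence:
            hi = mid
        else:
            lo = mid
    p = 1 / (1 + np.exp(-(score + (lo + hi) / 2)))
    return (rng.random(len(table)) < p).astype(int)
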