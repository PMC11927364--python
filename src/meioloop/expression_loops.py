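"""Cell-type loop catalogs, promoter/loop overlap classes, expression-shift
tests and the ssDNA -> crossover progression statistics.

Loops from different cell types are matched by anchor-midpoint proximity
(default 5 kb, the anchor-block radius); a loop is *private* to a cell type
when no other type carries an equivalent loop.  ssDNA hotspots are
partitioned by their overlap with recombination hotspots, and the association
between that progression and chromatin looping is summarized as an odds
ratio with a Woolf (log) confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import LoopSet, RegionSet, ValidationError, overlap_mask

__all__ = ["private_loops", "promoter_overlap_classes", "expression_shift_test",
           "HotspotPartition", "partition_ssdna", "loop_overlap_odds_ratio",
           "loop_expression_level"]


def _match_mask(a: LoopSet, b: LoopSet, tolerance: int) -> np.ndarray:
    """Per a-loop: does b contain a loop with both midpoints within
    ``tolerance``?"""
    out = np.zeros(len(a), dtype=bool)
    bdf = b.df
    pos = 0
    for chrom, sub in a.df.groupby("chrom", sort=False):
        n = len(sub)
        t = bdf[bdf["chrom"] == chrom]
        if len(t):
            t1 = t["mid1"].to_numpy()
            t2 = t["mid2"].to_numpy()
            order = np.argsort(t1, kind="mergesort")
            t1, t2 = t1[order], t2[order]
            m1 = sub["mid1"].to_numpy()
            m2 = sub["mid2"].to_numpy()
            lo = np.searchsorted(t1, m1 - tolerance, side="left")
            hi = np.searchsorted(t1, m1 + tolerance, side="right")
            hit = np.zeros(n, dtype=bool)
            for k in range(n):
                if lo[k] < hi[k]:
                    hit[k] = np.any(np.abs(t2[lo[k]:hi[k]] - m2[k]) <= tolerance)
            out[pos:pos + n] = hit
        pos += n
    return out


def private_loops(catalog: dict[str, LoopSet],
                  tolerance: int = 5000) -> dict[str, LoopSet]:
    """Loops present in exactly one cell type.

    A loop is private to type ``t`` iff no loop of any other type matches it
    (both anchor midpoints within ``tolerance``).  With a single-type catalog
    every loop is private.
    """
    out = {}
    for name, loops in catalog.items():
        mask = np.ones(len(loops), dtype=bool)
        for other, oloops in catalog.items():
            if other == name or not len(oloops):
                continue
            mask &= ~_match_mask(loops, oloops, tolerance)
        out[name] = LoopSet(loops.df[mask], layout=loops.layout)
    return out


def promoter_overlap_classes(tss: pd.DataFrame, loops: LoopSet,
                             promoter_flank: int = 2000,
                             anchor_flank: int = 1000) -> pd.DataFrame:
    """Classify each gene promoter against a loop set.

    The promoter is TSS +/- ``promoter_flank``; ``at_anchor`` when it overlaps
    an anchor midpoint +/- ``anchor_flank``, ``in_loop`` when it overlaps a
    loop span.  The classes are reported independently (a gene can be both);
    ``outside`` means neither.
    """
    prom = RegionSet.from_arrays(tss["chrom"],
                                 np.maximum(tss["tss"] - promoter_flank, 0),
                                 tss["tss"].to_numpy() + promoter_flank)
    # recover original row order: RegionSet sorts, so annotate then merge back
    key = prom.df[["chrom", "start"]].copy()
    in_loop = overlap_mask(prom, loops.spans()) if len(loops) else \
        np.zeros(len(prom), dtype=bool)
    at_anchor = overlap_mask(prom, loops.anchors(anchor_flank)) if len(loops) \
        else np.zeros(len(prom), dtype=bool)
    key["in_loop"] = in_loop
    key["at_anchor"] = at_anchor
    left = tss.copy()
    left["start"] = np.maximum(left["tss"] - promoter_flank, 0)
    merged = left.merge(key.drop_duplicates(["chrom", "start"]),
                        on=["chrom", "start"], how="left")
    out = pd.DataFrame({
        "gene_id": merged["gene_id"] if "gene_id" in merged.columns
        else np.arange(len(merged)),
        "chrom": merged["chrom"], "tss": merged["tss"],
        "in_loop": merged["in_loop"].astype(bool),
        "at_anchor": merged["at_anchor"].astype(bool),
    })
    out["outside"] = ~(out["in_loop"] | out["at_anchor"])
    return out


def expression_shift_test(log2fc: pd.Series, genes_a, genes_b,
                          alternative: str = "two-sided") -> dict:
    """Unpaired rank-sum comparison of log2 fold-changes between two disjoint
    gene groups."""
    genes_a = list(genes_a)
    genes_b = list(genes_b)
    if not genes_a or not genes_b:
        raise ValidationError("both gene groups must be non-empty")
    if set(genes_a) & set(genes_b):
        raise ValidationError("gene groups overlap")
    va = log2fc.loc[genes_a].to_numpy(dtype=float)
    vb = log2fc.loc[genes_b].to_numpy(dtype=float)
    res = stats.mannwhitneyu(va, vb, alternative=alternative)
    return {"median_a": float(np.median(va)), "median_b": float(np.median(vb)),
            "n_a": len(va), "n_b": len(vb),
            "statistic": float(res.statistic), "p": float(res.pvalue),
            "alternative": alternative}


@dataclass
class HotspotPartition:
    """ssDNA hotspots split by recombination-hotspot overlap."""

    ssdna_rec_pos: RegionSet  # ssDNA that are also recombination hotspots
    ssdna_rec_neg: RegionSet  # ssDNA that did not progress to hotspots

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.ssdna_rec_pos), len(self.ssdna_rec_neg)


def partition_ssdna(ssdna: RegionSet,
                    rec_hotspots: RegionSet) -> HotspotPartition:
    """Partition ssDNA hotspots by any-overlap with recombination hotspots."""
    if len(rec_hotspots):
        mask = overlap_mask(ssdna, rec_hotspots)
    else:
        mask = np.zeros(len(ssdna), dtype=bool)
    return HotspotPartition(
        ssdna_rec_pos=RegionSet(ssdna.df[mask], layout=ssdna.layout),
        ssdna_rec_neg=RegionSet(ssdna.df[~mask], layout=ssdna.layout))


def loop_overlap_odds_ratio(partition: HotspotPartition,
                            loops: LoopSet) -> dict:
    """Odds ratio of loop overlap for progressed vs non-progressed ssDNA.

    2x2 table: {rec+/rec-} x {loop overlap +/-}; OR = ad/bc with a Woolf CI
    (log-OR +/- 1.96 * sqrt(sum of reciprocal cells)).  Zero cells trigger a
    0.5 continuity correction, flagged in the result.
    """
    spans = loops.spans()
    pos = overlap_mask(partition.ssdna_rec_pos, spans) \
        if len(partition.ssdna_rec_pos) else np.zeros(0, dtype=bool)
    neg = overlap_mask(partition.ssdna_rec_neg, spans) \
        if len(partition.ssdna_rec_neg) else np.zeros(0, dtype=bool)
    a = int(pos.sum())
    b = int(len(pos) - a)
    c = int(neg.sum())
    d = int(len(neg) - c)
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5 for x in (a, b, c, d)) if corrected
                      else (a, b, c, d))
    odds_ratio = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = np.log(odds_ratio)
    ci = (float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se)))
    return {"table": [[a, b], [c, d]], "odds_ratio": float(odds_ratio),
            "ci95": ci, "continuity_corrected": corrected}


def loop_expression_level(loops: LoopSet, expression: pd.DataFrame,
                          stat: str = "mean") -> pd.DataFrame:
    """Per-loop expression: mean (or sum) of scaled expression over genes
    whose TSS lies inside the loop span; loops without a TSS score 0 and are
    flagged."""
    if stat not in ("mean", "sum"):
        raise ValueError("stat must be 'mean' or 'sum'")
    exp_by_chrom = {c: s.sort_values("tss")
                    for c, s in expression.groupby("chrom", sort=False)}
    values = np.zeros(len(loops))
    has_tss = np.zeros(len(loops), dtype=bool)
    pos = 0
    for chrom, sub in loops.df.groupby("chrom", sort=False):
        n = len(sub)
        if chrom in exp_by_chrom:
            e = exp_by_chrom[chrom]
            tss = e["tss"].to_numpy()
            vals = e["scaled_expression"].to_numpy(dtype=float)
            cum = np.concatenate([[0.0], np.cumsum(vals)])
            lo = np.searchsorted(tss, sub["mid1"].to_numpy(), side="left")
            hi = np.searchsorted(tss, sub["mid2"].to_numpy(), side="left")
            cnt = hi - lo
            tot = cum[hi] - cum[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                v = tot / cnt if stat == "mean" else tot
                v = np.where(cnt > 0, v, 0.0)
            values[pos:pos + n] = v
            has_tss[pos:pos + n] = cnt > 0
        pos += n
    out = loops.df[["chrom", "mid1", "mid2"]].copy()
    out["expression_level"] = values
    out["has_tss"] = has_tss
    return out
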