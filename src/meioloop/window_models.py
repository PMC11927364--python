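"""1-kb genome windows, loop geometry refinement, and random-forest models of
recombination outcomes.

Windows tile each chromosome on a fixed grid (trailing remainder bases are
dropped); loop geometry distinguishes 5-kb anchor blocks from anchor-free
loop interiors (loops pruned by 2.5 kb per end, internal anchors excised).
The classifier predicts a binary per-window outcome (ssDNA hotspot overlap,
recombination-hotspot overlap, haplotype-block overlap) from genomic
covariates after a 70/30 split, with a randomized hyperparameter search
(10 draws: 50-200 trees, depth 1-20) scored by 5-fold CV on the training
split only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .core_data import (GenomeLayout, LoopSet, RegionSet, SignalTrack,
                        ValidationError, merge_intervals)

__all__ = ["build_windows", "RefinedLoopGeometry", "refine_loop_geometry",
           "annotate_windows", "binary_overlap_outcome", "train_window_model",
           "WindowModelResult", "feature_correlations"]

logger = logging.getLogger(__name__)


def build_windows(layout: GenomeLayout, size: int = 1000,
                  blacklist: RegionSet | None = None) -> RegionSet:
    """Fixed-grid tiling of the genome into ``floor(L/size)`` windows per
    chromosome, dropping windows that touch the blacklist."""
    if size < 1:
        raise ValidationError("window size must be >= 1")
    rows = []
    for chrom in layout.chroms:
        n = layout.length(chrom) // size
        starts = np.arange(n, dtype=np.int64) * size
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                  "end": starts + size}))
    windows = RegionSet(pd.concat(rows, ignore_index=True), layout=layout)
    if blacklist is not None and len(blacklist):
        for chrom in blacklist.df["chrom"].unique():
            if chrom not in layout:
                raise ValidationError(f"blacklist chromosome {chrom!r} off layout")
        from .core_data import overlap_mask
        keep = ~overlap_mask(windows, blacklist)
        windows = RegionSet(windows.df[keep], layout=layout)
    return windows


@dataclass
class RefinedLoopGeometry:
    """Anchor blocks and anchor-free pruned loop interiors."""

    anchors: RegionSet  # one block per anchor (5 kb by default)
    interiors: RegionSet  # pruned spans minus every anchor block
    n_empty_interiors: int


def refine_loop_geometry(loops: LoopSet, anchor_block: int = 5000,
                         prune: int = 2500) -> RefinedLoopGeometry:
    """Split loops into anchor blocks and excised interiors.

    Anchor blocks are ``anchor_block`` bp centered on each anchor midpoint.
    Each interior is ``[mid1 + prune, mid2 - prune)`` minus every overlapping
    anchor block (removing anchors of nested/overlapping loops).  Loops
    shorter than ``2*prune`` yield an empty interior (logged, not an error).
    """
    half = anchor_block // 2
    anchors = loops.anchors(half)
    blocks = anchors.merged().chrom_arrays()
    rows = []
    n_empty = 0
    for row in loops.df.itertuples(index=False):
        s, e = row.mid1 + prune, row.mid2 - prune
        if e <= s:
            n_empty += 1
            continue
        ms, me = blocks.get(row.chrom, (np.empty(0, np.int64),
                                        np.empty(0, np.int64)))
        segs, sege = _subtract_one(s, e, ms, me)
        if not len(segs):
            n_empty += 1
            continue
        rows.append(pd.DataFrame({"chrom": row.chrom, "start": segs,
                                  "end": sege}))
    if n_empty:
        logger.info("%d loops yield empty interiors after pruning/excision",
                    n_empty)
    interiors = (RegionSet(pd.concat(rows, ignore_index=True),
                           layout=loops.layout)
                 if rows else RegionSet(layout=loops.layout))
    return RefinedLoopGeometry(anchors=anchors, interiors=interiors,
                               n_empty_interiors=n_empty)


def _subtract_one(s: int, e: int, ms: np.ndarray, me: np.ndarray):
    """[s, e) minus merged intervals; returns (starts, ends) arrays."""
    out_s, out_e = [], []
    cur = s
    i0 = np.searchsorted(me, s, side="right")
    for j in range(i0, len(ms)):
        if ms[j] >= e:
            break
        if ms[j] > cur:
            out_s.append(cur)
            out_e.append(min(ms[j], e))
        cur = max(cur, me[j])
    if cur < e:
        out_s.append(cur)
        out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _grid_interval_counts(n: int, size: int, starts: np.ndarray,
                          ends: np.ndarray) -> np.ndarray:
    """Number of intervals overlapping each grid window (pair counts)."""
    cnt = np.zeros(n + 1, dtype=np.int64)
    lo = np.clip(starts // size, 0, n - 1)
    hi = np.clip((ends - 1) // size, 0, n - 1)
    np.add.at(cnt, lo, 1)
    np.add.at(cnt, hi + 1, -1)
    return np.cumsum(cnt)[:n]


def annotate_windows(windows: RegionSet, layout: GenomeLayout, *,
                     gc_track: SignalTrack | None = None,
                     replication: SignalTrack | None = None,
                     expression: pd.DataFrame | None = None,
                     loops: LoopSet | None = None,
                     geometry: RefinedLoopGeometry | None = None,
                     sites: pd.DataFrame | None = None,
                     fragments: RegionSet | None = None,
                     anchor_block: int = 5000) -> pd.DataFrame:
    """Per-window predictor table.

    Continuous tracks enter as coverage-weighted means, region features as
    overlap counts; ``telomere_distance`` is the absolute distance (bp) of the
    window midpoint to the nearest chromosome end.  ``max_anchor_strength`` is
    the largest peak strength among anchor-site blocks touching the window
    (0 where no anchor overlaps).
    """
    wdf = windows.df
    sizes = windows.widths
    if len(np.unique(sizes)) != 1:
        raise ValidationError("annotate_windows expects a fixed-size grid")
    size = int(sizes[0])
    out = wdf[["chrom", "start", "end"]].copy()
    chrom_arr = wdf["chrom"].to_numpy(dtype=object)
    lens = np.array([layout.length(c) for c in chrom_arr], dtype=np.int64)
    mids = windows.midpoints
    out["telomere_distance"] = np.minimum(mids, lens - mids)
    if gc_track is not None:
        out["gc"] = gc_track.mean_in(chrom_arr, wdf["start"].to_numpy(),
                                     wdf["end"].to_numpy())
    if replication is not None:
        out["replication_timing"] = replication.mean_in(
            chrom_arr, wdf["start"].to_numpy(), wdf["end"].to_numpy())

    # grid-based counters per chromosome, subset to retained windows
    def per_chrom_counts(region_arrays) -> np.ndarray:
        res = np.zeros(len(wdf), dtype=np.int64)
        for chrom, sub_idx in wdf.groupby("chrom", sort=False).groups.items():
            n = layout.length(chrom) // size
            if chrom in region_arrays:
                s, e = region_arrays[chrom]
                grid = _grid_interval_counts(n, size, s, e)
            else:
                grid = np.zeros(n, dtype=np.int64)
            w_idx = wdf.loc[sub_idx, "start"].to_numpy() // size
            res[wdf.index.get_indexer(sub_idx)] = grid[w_idx]
        return res

    if expression is not None:
        res = np.zeros(len(wdf))
        cnt = np.zeros(len(wdf), dtype=np.int64)
        exp_by_chrom = {c: s for c, s in expression.groupby("chrom", sort=False)}
        for chrom, sub_idx in wdf.groupby("chrom", sort=False).groups.items():
            n = layout.length(chrom) // size
            grid = np.zeros(n)
            gcnt = np.zeros(n, dtype=np.int64)
            if chrom in exp_by_chrom:
                sub = exp_by_chrom[chrom]
                b = np.clip(sub["tss"].to_numpy() // size, 0, n - 1)
                np.add.at(grid, b, sub["scaled_expression"].to_numpy(dtype=float))
                np.add.at(gcnt, b, 1)
            w_idx = wdf.loc[sub_idx, "start"].to_numpy() // size
            pos = wdf.index.get_indexer(sub_idx)
            res[pos] = grid[w_idx]
            cnt[pos] = gcnt[w_idx]
        out["expression"] = res
        out["gene_count"] = cnt
    if loops is not None:
        out["loop_count"] = per_chrom_counts(loops.spans().chrom_arrays())
    if geometry is not None:
        out["anchor_count"] = per_chrom_counts(geometry.anchors.chrom_arrays())
        out["interior_overlap"] = (per_chrom_counts(
            geometry.interiors.chrom_arrays()) > 0).astype(int)
        # max anchor strength per window
        strength = np.zeros(len(wdf))
        if sites is not None and "is_true_anchor" in sites.columns:
            anchor_sites = sites[sites["is_true_anchor"]]
        elif sites is not None:
            anchor_sites = sites
        else:
            anchor_sites = None
        if anchor_sites is not None and len(anchor_sites):
            half = anchor_block // 2
            for chrom, sub_idx in wdf.groupby("chrom", sort=False).groups.items():
                n = layout.length(chrom) // size
                grid = np.zeros(n)
                sub = anchor_sites[anchor_sites["chrom"] == chrom]
                for mid, ps in zip(sub["mid"], sub["peak_strength"]):
                    lo = max((mid - half) // size, 0)
                    hi = min((mid + half - 1) // size, n - 1)
                    if hi >= lo:
                        grid[lo:hi + 1] = np.maximum(grid[lo:hi + 1], ps)
                w_idx = wdf.loc[sub_idx, "start"].to_numpy() // size
                strength[wdf.index.get_indexer(sub_idx)] = grid[w_idx]
        out["max_anchor_strength"] = strength
    if fragments is not None:
        res = np.zeros(len(wdf), dtype=np.int64)
        frag_mid = {c: (s + e) // 2 for c, (s, e)
                    in fragments.chrom_arrays().items()}
        for chrom, sub_idx in wdf.groupby("chrom", sort=False).groups.items():
            n = layout.length(chrom) // size
            grid = np.zeros(n, dtype=np.int64)
            if chrom in frag_mid:
                b = np.clip(frag_mid[chrom] // size, 0, n - 1)
                np.add.at(grid, b, 1)
            w_idx = wdf.loc[sub_idx, "start"].to_numpy() // size
            res[wdf.index.get_indexer(sub_idx)] = grid[w_idx]
        out["atac_signal"] = res.astype(float)

    feature_cols = [c for c in out.columns if c not in ("chrom", "start", "end")]
    bad = out[feature_cols].isna().any(axis=1)
    if bad.any():
        logger.info("dropping %d windows with missing predictor values",
                    int(bad.sum()))
        out = out[~bad].reset_index(drop=True)
    return out


def binary_overlap_outcome(windows: pd.DataFrame, regions: RegionSet,
                           min_fraction: float | None = None) -> np.ndarray:
    """0/1 outcome per window: any overlap with the region set, or coverage
    >= ``min_fraction`` of the window when given."""
    wset = RegionSet(windows[["chrom", "start", "end"]])
    if min_fraction is None:
        from .core_data import overlap_mask
        return overlap_mask(wset, regions).astype(int)
    from .enrichment import _coverage_fn
    funcs = _coverage_fn(regions)
    frac = np.zeros(len(wset))
    pos = 0
    for chrom, (s, e) in wset.chrom_arrays().items():
        n = len(s)
        if chrom in funcs:
            F = funcs[chrom]
            frac[pos:pos + n] = (F(e) - F(s)) / (e - s)
        pos += n
    return (frac >= min_fraction).astype(int)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


@dataclass
class WindowModelResult:
    """Best hyperparameters, held-out test AUC and MDI importances."""

    model: RandomForestClassifier
    feature_names: list[str]
    best_n_estimators: int
    best_max_depth: int
    search_results: pd.DataFrame  # n_estimators, max_depth, cv_auc
    test_auc: float
    importances: pd.Series


def train_window_model(table: pd.DataFrame, outcome: np.ndarray,
                       features: list[str] | None = None,
                       train_frac: float = 0.70, n_draws: int = 10,
                       trees_range: tuple[int, int] = (50, 200),
                       depth_range: tuple[int, int] = (1, 20),
                       cv: int = 5, seed: int = 0) -> WindowModelResult:
    """Randomized-search random forest for a binary window outcome.

    The table is split 70/30 (stratified); ``n_draws`` random
    (n_estimators, max_depth) pairs are scored by ``cv``-fold CV ROC-AUC on
    the training split only, the best is refit on the full training split and
    evaluated once on the untouched test split.
    """
    y = np.asarray(outcome)
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome must contain both classes")
    if features is None:
        features = [c for c in table.columns
                    if c not in ("chrom", "start", "end")]
    X = table[features].to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_frac, stratify=y, random_state=seed)
    rng = np.random.default_rng(seed)
    draws = [(int(rng.integers(trees_range[0], trees_range[1] + 1)),
              int(rng.integers(depth_range[0], depth_range[1] + 1)))
             for _ in range(n_draws)]
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    results = []
    for n_est, depth in draws:
        aucs = []
        for tr, te in skf.split(X_tr, y_tr):
            clf = RandomForestClassifier(n_estimators=n_est, max_depth=depth,
                                         random_state=seed, n_jobs=1)
            clf.fit(X_tr[tr], y_tr[tr])
            aucs.append(roc_auc_score(y_tr[te],
                                      clf.predict_proba(X_tr[te])[:, 1]))
        results.append({"n_estimators": n_est, "max_depth": depth,
                        "cv_auc": float(np.mean(aucs))})
    res_df = pd.DataFrame(results)
    best = res_df.loc[res_df["cv_auc"].idxmax()]
    final = RandomForestClassifier(n_estimators=int(best["n_estimators"]),
                                   max_depth=int(best["max_depth"]),
                                   random_state=seed, n_jobs=1)
    final.fit(X_tr, y_tr)
    test_auc = float(roc_auc_score(y_te, final.predict_proba(X_te)[:, 1]))
    return WindowModelResult(
        model=final, feature_names=list(features),
        best_n_estimators=int(best["n_estimators"]),
        best_max_depth=int(best["max_depth"]),
        search_results=res_df, test_auc=test_auc,
        importances=pd.Series(final.feature_importances_, index=list(features)))


def feature_correlations(table: pd.DataFrame,
                         features: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between window predictors."""
    if features is None:
        features = [c for c in table.columns
                    if c not in ("chrom", "start", "end")]
    return table[features].corr(method="spearman")
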