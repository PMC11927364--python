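"""Candidate anchor pairs, loop features, random-forest training and
loop-set comparison.

The classifier follows the established anchor-pair framework: all
same-chromosome ordered CTCF site pairs 10 kb - 2 Mb apart are candidates;
each is described by the loop length, signal summaries over both anchors
(mean/std), flanking windows and the loop interior, per-site motif features
and the pair orientation; a random forest with unbounded depth and sqrt
feature subsampling is scored by stratified 10-fold cross-validation (five
iterations) or, as a robustness check, by 5-fold chromosome-grouped CV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .core_data import (MAX_LOOP_LENGTH, MIN_LOOP_LENGTH, GenomeLayout,
                        LoopSet, RegionSet, ValidationError)

__all__ = ["generate_candidate_pairs", "label_candidates",
           "compute_loop_features", "train_loop_classifier",
           "train_ctcf_only_classifier", "predict_loops",
           "evaluate_against_truth", "pet_support_sweep",
           "TrainedLoopModel", "CTCF_ONLY_FEATURES", "DEFAULT_SHIFT"]

logger = logging.getLogger(__name__)

#: half the median fragment length (136/2): fragment positions are shifted by
#: this much toward their midpoints before counting.
DEFAULT_SHIFT = 68

ORIENTATIONS = ("convergent", "tandem", "divergent")


# ---------------------------------------------------------------------------
# candidates
# ---------------------------------------------------------------------------


def generate_candidate_pairs(sites: pd.DataFrame,
                             min_len: int = MIN_LOOP_LENGTH,
                             max_len: int = MAX_LOOP_LENGTH,
                             require_convergent: bool = False) -> pd.DataFrame:
    """All same-chromosome ordered site pairs with motif-midpoint distance in
    ``[min_len, max_len]``.

    ``sites`` must be sorted by (chrom, start) and carry a ``mid`` column (as
    produced by :func:`meioloop.core_data.validate_ctcf_sites`).  Orientation
    is annotated from the strands: (+,-) convergent, (-,+) divergent, equal
    strands tandem.
    """
    if "mid" not in sites.columns:
        raise ValidationError("site table lacks 'mid' column; validate it first")
    rows = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        mids = sub["mid"].to_numpy()
        if np.any(np.diff(mids) < 0):
            raise ValidationError(f"sites on {chrom} are not sorted by position")
        idx = sub.index.to_numpy()
        lo = np.searchsorted(mids, mids + min_len, side="left")
        hi = np.searchsorted(mids, mids + max_len, side="right")
        counts = np.maximum(hi - lo, 0)
        i1 = np.repeat(np.arange(len(mids)), counts)
        i2 = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) \
            if counts.sum() else np.empty(0, dtype=np.int64)
        strands = sub["strand"].to_numpy()
        s1, s2 = strands[i1], strands[i2]
        orientation = np.where((s1 == "+") & (s2 == "-"), "convergent",
                               np.where((s1 == "-") & (s2 == "+"),
                                        "divergent", "tandem"))
        df = pd.DataFrame({
            "chrom": chrom,
            "site1": idx[i1], "site2": idx[i2],
            "mid1": mids[i1], "mid2": mids[i2],
            "strand1": s1, "strand2": s2,
            "length": mids[i2] - mids[i1],
            "orientation": orientation,
        })
        rows.append(df)
    out = (pd.concat(rows, ignore_index=True) if rows else
           pd.DataFrame(columns=["chrom", "site1", "site2", "mid1", "mid2",
                                 "strand1", "strand2", "length", "orientation"]))
    if require_convergent:
        out = out[out["orientation"] == "convergent"].reset_index(drop=True)
    return out


def label_candidates(candidates: pd.DataFrame, true_loops: LoopSet,
                     anchor_tolerance: int = 1000, seed: int = 0
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """Label candidates against truth and draw a length-matched negative set.

    A candidate is positive iff both its anchor midpoints fall within
    ``anchor_tolerance`` of the two anchor midpoints of the *same* truth loop.
    Negatives are sampled 1:1 from the unlabeled candidates, matched to the
    positive length distribution by decile bins (fixed seed).

    Returns ``(training_frame, y)`` where the frame is the concatenation of
    positives and matched negatives (original candidate index preserved).
    """
    if len(candidates) < len(true_loops):
        raise ValidationError("fewer candidates than truth loops")
    pos_mask = np.zeros(len(candidates), dtype=bool)
    for chrom, sub in candidates.groupby("chrom", sort=False):
        t = true_loops.df[true_loops.df["chrom"] == chrom]
        if not len(t):
            continue
        t1 = t["mid1"].to_numpy()
        t2 = t["mid2"].to_numpy()
        order = np.argsort(t1, kind="mergesort")
        t1s, t2s = t1[order], t2[order]
        m1 = sub["mid1"].to_numpy()
        m2 = sub["mid2"].to_numpy()
        lo = np.searchsorted(t1s, m1 - anchor_tolerance, side="left")
        hi = np.searchsorted(t1s, m1 + anchor_tolerance, side="right")
        hit = np.zeros(len(sub), dtype=bool)
        for k in range(len(sub)):
            if lo[k] < hi[k]:
                hit[k] = np.any(np.abs(t2s[lo[k]:hi[k]] - m2[k])
                                <= anchor_tolerance)
        pos_mask[candidates.index.get_indexer(sub.index)] = hit

    positives = candidates[pos_mask]
    pool = candidates[~pos_mask]
    if not len(positives):
        return candidates.iloc[:0], np.empty(0, dtype=int)
    rng = np.random.default_rng(seed)
    edges = np.quantile(positives["length"], np.linspace(0, 1, 11))
    edges[0] -= 1  # include left edge
    neg_parts = []
    pool_len = pool["length"].to_numpy()
    for d in range(10):
        n_pos = int(((positives["length"] > edges[d])
                     & (positives["length"] <= edges[d + 1])).sum())
        in_bin = pool.index[(pool_len > edges[d]) & (pool_len <= edges[d + 1])]
        if n_pos == 0:
            continue
        if len(in_bin) < n_pos:
            logger.warning("decile %d: only %d negatives for %d positives",
                           d, len(in_bin), n_pos)
            take = in_bin
        else:
            take = rng.choice(in_bin, size=n_pos, replace=False)
        neg_parts.append(pool.loc[np.sort(take)])
    negatives = pd.concat(neg_parts) if neg_parts else pool.iloc[:0]
    train = pd.concat([positives, negatives])
    y = np.concatenate([np.ones(len(positives), dtype=int),
                        np.zeros(len(negatives), dtype=int)])
    return train, y


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def _point_index(chrom: np.ndarray, pos: np.ndarray, weight: np.ndarray
                 ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chrom (sorted positions, cumulative weight) for window sums."""
    out = {}
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "w": weight})
    for c, sub in df.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
        p = sub["pos"].to_numpy()[order]
        w = sub["w"].to_numpy()[order]
        out[c] = (p, np.concatenate([[0.0], np.cumsum(w)]))
    return out


def _window_sums(index, chrom, starts, ends) -> np.ndarray:
    res = np.zeros(len(starts))
    for c in np.unique(chrom):
        if c not in index:
            continue
        p, cw = index[c]
        sel = chrom == c
        lo = np.searchsorted(p, starts[sel], side="left")
        hi = np.searchsorted(p, ends[sel], side="left")
        res[sel] = cw[hi] - cw[lo]
    return res


def compute_loop_features(candidates: pd.DataFrame,
                          fragments: RegionSet | None = None,
                          peaks: RegionSet | None = None,
                          expression: pd.DataFrame | None = None,
                          sites: pd.DataFrame | None = None,
                          anchor_window: int = 4000,
                          shift: int = DEFAULT_SHIFT,
                          layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Feature matrix for candidate pairs, aligned to ``candidates.index``.

    Per signal track (``frag`` = shifted fragment counts, ``peak`` = summed
    peak strengths at peak centers, ``expr`` = summed scaled expression at
    TSSs): mean and std over the two anchor windows, counts in the abutting
    left/right flank windows, and the per-kb density between the inner anchor
    edges.  Fragments are counted once each, at ``start + shift`` (the shift
    moves the position toward the fragment midpoint).  Plus loop length,
    per-pair motif score / conservation / peak strength means and a one-hot
    orientation.
    """
    chrom = candidates["chrom"].to_numpy(dtype=object)
    m1 = candidates["mid1"].to_numpy()
    m2 = candidates["mid2"].to_numpy()
    half = anchor_window // 2

    tracks = {}
    if fragments is not None:
        fdf = fragments.df
        tracks["frag"] = _point_index(fdf["chrom"].to_numpy(dtype=object),
                                      fdf["start"].to_numpy() + shift,
                                      np.ones(len(fdf)))
    if peaks is not None:
        pdf = peaks.df
        w = pdf["score"].to_numpy(dtype=float) if "score" in pdf.columns \
            else np.ones(len(pdf))
        tracks["peak"] = _point_index(pdf["chrom"].to_numpy(dtype=object),
                                      ((pdf["start"] + pdf["end"]) // 2).to_numpy(),
                                      w)
    if expression is not None:
        tracks["expr"] = _point_index(expression["chrom"].to_numpy(dtype=object),
                                      expression["tss"].to_numpy(),
                                      expression["scaled_expression"]
                                      .to_numpy(dtype=float))

    def clip(arr_lo, arr_hi):
        lo = np.maximum(arr_lo, 0)
        if layout is not None:
            lens = np.array([layout.length(c) for c in chrom])
            hi = np.minimum(arr_hi, lens)
            n_clip = int(((arr_lo < 0) | (arr_hi > lens)).sum())
            if n_clip:
                logger.info("%d windows clipped at chromosome ends", n_clip)
        else:
            hi = arr_hi
        return lo, np.maximum(hi, lo)

    X = pd.DataFrame(index=candidates.index)
    X["length"] = m2 - m1
    for name, idx in tracks.items():
        a1 = _window_sums(idx, chrom, *clip(m1 - half, m1 + half))
        a2 = _window_sums(idx, chrom, *clip(m2 - half, m2 + half))
        left = _window_sums(idx, chrom, *clip(m1 - 3 * half, m1 - half))
        right = _window_sums(idx, chrom, *clip(m2 + half, m2 + 3 * half))
        ib_lo, ib_hi = clip(m1 + half, m2 - half)
        between = _window_sums(idx, chrom, ib_lo, ib_hi)
        width = np.maximum(ib_hi - ib_lo, 1)
        X[f"{name}_anchor_avg"] = (a1 + a2) / 2
        X[f"{name}_anchor_std"] = np.abs(a1 - a2) / 2
        X[f"{name}_left"] = left
        X[f"{name}_right"] = right
        X[f"{name}_in_between"] = between / width * 1000
    if sites is not None:
        for col in ("motif_score", "conservation", "peak_strength"):
            v = sites[col].to_numpy(dtype=float)
            X[f"{col}_avg"] = (v[candidates["site1"].to_numpy()]
                               + v[candidates["site2"].to_numpy()]) / 2
    for o in ORIENTATIONS:
        X[f"orientation_{o}"] = (candidates["orientation"] == o).astype(int)
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ValidationError("non-finite feature values")
    return X


#: the reduced feature set of the CTCF-only robustness model: peak strength,
#: motif conservation and orientation (length optionally retained).
CTCF_ONLY_FEATURES = ["peak_strength_avg", "conservation_avg",
                      "orientation_convergent", "orientation_tandem",
                      "orientation_divergent"]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainedLoopModel:
    """A fitted tree ensemble with fold-wise CV metrics and MDI importances."""

    model: RandomForestClassifier
    feature_names: list[str]
    cv_metrics: pd.DataFrame  # columns: iteration, fold, roc_auc, pr_auc[, test_chroms]
    importances: pd.Series  # mean decrease impurity, sums to 1
    scheme: str
    seed: int

    @property
    def mean_roc_auc(self) -> float:
        return float(self.cv_metrics["roc_auc"].mean())

    @property
    def mean_pr_auc(self) -> float:
        return float(self.cv_metrics["pr_auc"].mean())

    def manifest(self) -> dict:
        return {"format_version": 1, "scheme": self.scheme, "seed": self.seed,
                "feature_names": self.feature_names,
                "n_estimators": self.model.n_estimators,
                "mean_roc_auc": self.mean_roc_auc,
                "mean_pr_auc": self.mean_pr_auc}

    def save(self, path: str | Path) -> None:
        """Persist the fitted model next to a JSON manifest recording the
        feature schema and seed."""
        path = Path(path)
        joblib.dump(self.model, path)
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def _new_forest(n_estimators, max_depth, max_features, seed):
    return RandomForestClassifier(n_estimators=n_estimators,
                                  max_depth=max_depth,
                                  max_features=max_features,
                                  random_state=seed, n_jobs=1)


def train_loop_classifier(X: pd.DataFrame, y: np.ndarray,
                          scheme: str = "stratified10x5",
                          chroms: np.ndarray | None = None,
                          n_estimators: int = 100,
                          max_depth: int | None = None,
                          max_features: str = "sqrt",
                          seed: int = 0) -> TrainedLoopModel:
    """Fit the loop random forest under one of two cross-validation schemes.

    ``stratified10x5``: five iterations of shuffled stratified 10-fold CV.
    ``chrom_grouped5``: 5-fold grouped CV where no chromosome contributes rows
    to both the train and test side of a fold (requires ``chroms``).  Fold
    metrics are computed on held-out folds only; the returned model is refit
    on all rows.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("need both classes to train the classifier")
    Xv = X.to_numpy(dtype=float)
    records = []
    if scheme == "stratified10x5":
        for it in range(5):
            cv = StratifiedKFold(n_splits=10, shuffle=True,
                                 random_state=seed * 100 + it)
            for fold, (tr, te) in enumerate(cv.split(Xv, y)):
                clf = _new_forest(n_estimators, max_depth, max_features, seed)
                clf.fit(Xv[tr], y[tr])
                prob = clf.predict_proba(Xv[te])[:, 1]
                records.append({"iteration": it, "fold": fold,
                                "roc_auc": roc_auc_score(y[te], prob),
                                "pr_auc": average_precision_score(y[te], prob)})
    elif scheme == "chrom_grouped5":
        if chroms is None:
            raise ValidationError("chrom_grouped5 requires the chroms array")
        chroms = np.asarray(chroms)
        if len(np.unique(chroms)) < 5:
            raise ValidationError("chromosome-grouped CV needs >= 5 chromosomes")
        cv = GroupKFold(n_splits=5)
        for fold, (tr, te) in enumerate(cv.split(Xv, y, groups=chroms)):
            assert not set(chroms[tr]) & set(chroms[te])
            rec = {"iteration": 0, "fold": fold,
                   "test_chroms": ",".join(sorted(set(chroms[te]))),
                   "train_chroms": ",".join(sorted(set(chroms[tr])))}
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                rec.update(roc_auc=np.nan, pr_auc=np.nan)
            else:
                clf = _new_forest(n_estimators, max_depth, max_features, seed)
                clf.fit(Xv[tr], y[tr])
                prob = clf.predict_proba(Xv[te])[:, 1]
                rec.update(roc_auc=roc_auc_score(y[te], prob),
                           pr_auc=average_precision_score(y[te], prob))
            records.append(rec)
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")

    final = _new_forest(n_estimators, max_depth, max_features, seed)
    final.fit(Xv, y)
    imp = pd.Series(final.feature_importances_, index=list(X.columns))
    return TrainedLoopModel(model=final, feature_names=list(X.columns),
                            cv_metrics=pd.DataFrame(records),
                            importances=imp, scheme=scheme, seed=seed)


def train_ctcf_only_classifier(X: pd.DataFrame, y: np.ndarray,
                               include_length: bool = True,
                               **kwargs) -> TrainedLoopModel:
    """The reduced robustness model: CTCF peak strength, motif conservation
    and orientation only (optionally keeping loop length)."""
    cols = (["length"] if include_length else []) + \
        [c for c in CTCF_ONLY_FEATURES if c in X.columns]
    return train_loop_classifier(X[cols], y, **kwargs)


# ---------------------------------------------------------------------------
# prediction and truth comparison
# ---------------------------------------------------------------------------


def predict_loops(model: TrainedLoopModel, candidates: pd.DataFrame,
                  X: pd.DataFrame, threshold: float = 0.5,
                  layout: GenomeLayout | None = None) -> LoopSet:
    """De novo loop calls: candidates with predicted probability >= threshold
    (ties at the threshold included)."""
    if list(X.columns) != model.feature_names:
        raise ValidationError(
            f"feature schema mismatch: model expects {model.feature_names}")
    prob = model.model.predict_proba(X.to_numpy(dtype=float))[:, 1]
    keep = prob >= threshold
    df = pd.DataFrame({"chrom": candidates["chrom"].to_numpy()[keep],
                       "mid1": candidates["mid1"].to_numpy()[keep],
                       "mid2": candidates["mid2"].to_numpy()[keep],
                       "probability": prob[keep]})
    return LoopSet(df, layout=layout)


def _match_midpoint_spans(a: LoopSet, b: LoopSet, reciprocal: float
                          ) -> np.ndarray:
    """Boolean per a-loop: does a b-loop match at >= the reciprocal overlap?

    Loops are compared as midpoint-to-midpoint spans.
    """
    out = np.zeros(len(a), dtype=bool)
    bdf = b.df
    pos = 0
    for chrom, sub in a.df.groupby("chrom", sort=False):
        n = len(sub)
        tb = bdf[bdf["chrom"] == chrom]
        if len(tb):
            a1 = sub["mid1"].to_numpy()[:, None]
            a2 = sub["mid2"].to_numpy()[:, None]
            b1 = tb["mid1"].to_numpy()[None, :]
            b2 = tb["mid2"].to_numpy()[None, :]
            inter = np.maximum(np.minimum(a2, b2) - np.maximum(a1, b1), 0)
            rec = np.minimum(inter / (a2 - a1), inter / (b2 - b1))
            out[pos:pos + n] = (rec >= reciprocal).any(axis=1)
        pos += n
    return out


def evaluate_against_truth(predicted: LoopSet, truth: LoopSet,
                           min_pet: int = 1,
                           reciprocal: float = 0.99) -> dict:
    """Compare predicted loops to ground-truth loops with PET support.

    Both sets are restricted to 10 kb - 2 Mb; truth is filtered to
    ``pet_count >= min_pet`` when the column is present.  Loops match when
    their midpoint spans reciprocally overlap by at least ``reciprocal``.
    Fractions are ``None`` when the corresponding denominator is empty.
    """
    pred = predicted.filter_length()
    tr = truth.filter_length()
    if "pet_count" in tr.df.columns:
        tr = LoopSet(tr.df[tr.df["pet_count"] >= min_pet], layout=tr.layout)
    res = {"n_predicted": len(pred), "n_truth": len(tr), "min_pet": min_pet,
           "reciprocal": reciprocal}
    res["truth_recovered_frac"] = (
        float(_match_midpoint_spans(tr, pred, reciprocal).mean())
        if len(tr) and len(pred) else (0.0 if len(tr) and not len(pred) else None))
    res["predicted_supported_frac"] = (
        float(_match_midpoint_spans(pred, tr, reciprocal).mean())
        if len(pred) and len(tr) else (0.0 if len(pred) and not len(tr) else None))
    if not len(tr):
        res["truth_recovered_frac"] = None
        res["predicted_supported_frac"] = None if not len(pred) else 0.0
    return res


def pet_support_sweep(predicted: LoopSet, truth: LoopSet,
                      min_pets: list[int] = (1, 2, 3, 4, 5),
                      reciprocal: float = 0.99) -> pd.DataFrame:
    """Truth-support fractions across a sweep of minimum PET counts."""
    rows = [evaluate_against_truth(predicted, truth, min_pet=m,
                                   reciprocal=reciprocal) for m in min_pets]
    return pd.DataFrame(rows)
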