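"""Telomere-relative distance statistics and chromosomal bin distributions.

The distance of a feature to the nearest telomere is the smallest of the four
end-to-end distances (feature 5'/3' end to chromosome 5'/3' end); the relative
distance divides by the chromosome length and therefore lies in [0, 0.5].
Uniformly placed features have an expected relative distance of exactly 1/4
(E[min(U, 1-U)] = 1/4 for U uniform on [0, 1]).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import GenomeLayout, RegionSet, ValidationError

__all__ = ["relative_telomere_distance", "telomere_stats",
           "mean_relative_distance", "chromosome_bin_distribution"]


def relative_telomere_distance(layout: GenomeLayout, chrom, start,
                               end=None) -> np.ndarray:
    """Relative distance to the nearest telomere, vectorized.

    For intervals the minimum of the four end/telomere distances is used; with
    ``end=None`` the features are points.  Values lie in [0, 0.5].
    """
    chrom = np.atleast_1d(np.asarray(chrom, dtype=object))
    start = np.atleast_1d(np.asarray(start, dtype=np.int64))
    lens = np.array([layout.length(c) for c in chrom], dtype=np.int64)
    if (start < 0).any() or (start > lens).any():
        raise ValidationError("feature outside layout")
    if end is None:
        dist = np.minimum(start, lens - start)
    else:
        end = np.atleast_1d(np.asarray(end, dtype=np.int64))
        if (end > lens).any() or (end < start).any():
            raise ValidationError("feature outside layout")
        four = np.stack([start, lens - start, end, lens - end])
        dist = four.min(axis=0)
    return dist / lens


def telomere_stats(features: RegionSet, layout: GenomeLayout) -> pd.DataFrame:
    """Per-feature absolute (bp) and relative telomere distances."""
    df = features.df
    chrom = df["chrom"].to_numpy(dtype=object)
    lens = np.array([layout.length(c) for c in chrom], dtype=np.int64)
    rel = relative_telomere_distance(layout, chrom, df["start"].to_numpy(),
                                     df["end"].to_numpy())
    return pd.DataFrame({"chrom": chrom, "start": df["start"],
                         "end": df["end"],
                         "absolute_distance": (rel * lens).astype(np.int64),
                         "relative_distance": rel})


def mean_relative_distance(features, layout: GenomeLayout,
                           positions=None, chrom=None) -> float:
    """Mean relative telomere distance of a feature set.

    ``features`` may be a :class:`RegionSet`; alternatively pass point
    ``positions`` with their ``chrom`` array.
    """
    if features is not None:
        if not len(features):
            raise ValidationError("empty feature set")
        return float(telomere_stats(features, layout)["relative_distance"].mean())
    if positions is None or chrom is None or not len(positions):
        raise ValidationError("empty feature set")
    return float(relative_telomere_distance(layout, chrom, positions).mean())


def chromosome_bin_distribution(features: RegionSet, layout: GenomeLayout,
                                n_bins: int = 100, fold: bool = True
                                ) -> pd.DataFrame:
    """Feature proportions across equal chromosome bins.

    Each chromosome is cut into ``n_bins`` equal bins and each feature is
    assigned to the bin of its midpoint.  With ``fold=True`` symmetric bins
    are folded by their distance to the nearest telomere, so the returned
    classes are indexed by the bin's relative telomeric distance; otherwise
    per-bin proportions are returned in chromosomal order.  Proportions sum
    to 1 either way.
    """
    if n_bins < 2:
        raise ValidationError("need at least 2 bins")
    if not len(features):
        raise ValidationError("empty feature set")
    df = features.df
    mids = features.midpoints
    lens = np.array([layout.length(c) for c in df["chrom"]], dtype=np.int64)
    bins = np.minimum((mids * n_bins) // lens, n_bins - 1).astype(int)
    if fold:
        cls = np.minimum(bins, n_bins - 1 - bins)
        counts = np.bincount(cls, minlength=(n_bins + 1) // 2)
        classes = np.arange(len(counts))
        return pd.DataFrame({
            "distance_class": classes,
            "relative_distance": (classes + 0.5) / n_bins,
            "proportion": counts / counts.sum(),
        })
    counts = np.bincount(bins, minlength=n_bins)
    return pd.DataFrame({
        "bin": np.arange(n_bins),
        "relative_distance": np.minimum(np.arange(n_bins) + 0.5,
                                        n_bins - 0.5 - np.arange(n_bins)) / n_bins,
        "proportion": counts / counts.sum(),
    })
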