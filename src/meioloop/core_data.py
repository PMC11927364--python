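"""Genomic primitives and flat-file I/O for the loop/recombination pipeline.

Conventions
-----------
* All coordinates are 0-based, half-open ``[start, end)`` internally.  BED-family
  files on disk use the same convention, so import/export is direct; 1-based
  browser coordinates must be converted by the caller.
* Region sets are kept sorted by ``(chrom, start, end)`` and validated on
  construction (``start < end``, within the chromosome when a layout is given).
* Chromatin loops are stored canonically as the two anchor *midpoints*; BEDPE
  import collapses anchor intervals to midpoints and export reconstitutes
  fixed-half-width anchors.

The small searchsorted kernels here (merged-interval hit testing, interval
counting, coverage integrals) are the primitives the circular-permutation and
profile machinery calls in tight loops, so they are written once against plain
numpy arrays and reused everywhere.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MIN_LOOP_LENGTH",
    "MAX_LOOP_LENGTH",
    "RECOMBINATION_HOTSPOT_THRESHOLD",
    "FormatError",
    "ValidationError",
    "GenomeLayout",
    "RegionSet",
    "LoopSet",
    "SignalTrack",
    "read_regions",
    "count_overlaps",
    "overlap_mask",
    "count_overlapping_regions",
    "reciprocal_overlap",
    "define_recombination_hotspots",
    "read_expression_table",
    "write_expression_table",
    "read_ctcf_sites",
    "write_ctcf_sites",
    "validate_ctcf_sites",
]

#: Model-facing loop length bounds (bp): candidate anchor pairs and ground-truth
#: loops outside this range are excluded throughout the pipeline.
MIN_LOOP_LENGTH = 10_000
MAX_LOOP_LENGTH = 2_000_000

#: Recombination-rate cutoff (cM/Mb) defining a recombination hotspot,
#: >= 10x the genome-wide average paternal rate.
RECOMBINATION_HOTSPOT_THRESHOLD = 9.85


class FormatError(ValueError):
    """A file did not parse under the named dialect."""


class ValidationError(ValueError):
    """Records violate an invariant (coordinates, layout, value ranges)."""


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome name -> length (bp) table."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        d = dict(self.lengths)
        if not d:
            raise ValidationError("layout must contain at least one chromosome")
        for name, ln in d.items():
            if int(ln) <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {ln}")
        object.__setattr__(self, "lengths", {str(k): int(v) for k, v in d.items()})

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ValidationError(f"chromosome {chrom!r} not in layout") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column chrom.sizes TSV."""
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, ln in self.lengths.items():
                fh.write(f"{name}\t{ln}\n")


# ---------------------------------------------------------------------------
# region sets
# ---------------------------------------------------------------------------


def _empty_region_frame() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


class RegionSet:
    """A validated, sorted collection of genomic intervals.

    Backed by a pandas DataFrame with at least ``chrom``, ``start``, ``end``
    columns; extra columns (``name``, ``score``, ``strand``, ...) ride along.
    """

    def __init__(self, df: pd.DataFrame | None = None,
                 layout: GenomeLayout | None = None) -> None:
        if df is None or len(df) == 0:
            df = _empty_region_frame() if df is None or not len(df) else df
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"region frame missing column {col!r}")
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValidationError(
                f"record {bad[0]}: invalid interval [{row['start']}, {row['end']})")
        if layout is not None:
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in layout:
                    raise ValidationError(f"chromosome {chrom!r} not in layout")
                if (sub["end"] > layout.length(chrom)).any():
                    raise ValidationError(
                        f"interval on {chrom} extends past chromosome end")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self._df = df.reset_index(drop=True)
        self.layout = layout

    # -- basics ------------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RegionSet({len(self)} regions)"

    @classmethod
    def from_arrays(cls, chrom, start, end, layout: GenomeLayout | None = None,
                    **extra) -> "RegionSet":
        data = {"chrom": np.asarray(chrom), "start": np.asarray(start),
                "end": np.asarray(end)}
        data.update({k: np.asarray(v) for k, v in extra.items()})
        return cls(pd.DataFrame(data), layout=layout)

    @property
    def widths(self) -> np.ndarray:
        return (self._df["end"] - self._df["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self._df["start"] + self._df["end"]) // 2).to_numpy()

    def chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self._df.groupby("chrom", sort=False):
            out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        return out

    def merged(self) -> "RegionSet":
        """Union of the set: overlapping or book-ended intervals are fused."""
        chroms, starts, ends = [], [], []
        for chrom, (s, e) in self.chrom_arrays().items():
            ms, me = merge_intervals(s, e)
            chroms.extend([chrom] * len(ms))
            starts.append(ms)
            ends.append(me)
        if not chroms:
            return RegionSet(layout=self.layout)
        return RegionSet.from_arrays(np.array(chroms), np.concatenate(starts),
                                     np.concatenate(ends), layout=self.layout)

    def total_coverage(self) -> int:
        m = self.merged()
        return int(m.widths.sum())

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_bed(cls, path: str | Path,
                 layout: GenomeLayout | None = None) -> "RegionSet":
        df = _read_table(path, header=None)
        if df is None:
            return cls(layout=layout)
        ncol = df.shape[1]
        if ncol < 3:
            raise FormatError(f"{path}: BED needs >=3 columns, found {ncol}")
        names = ["chrom", "start", "end", "name", "score", "strand"][:min(ncol, 6)]
        df = df.iloc[:, : len(names)]
        df.columns = names
        _coerce_int(df, ["start", "end"], path)
        try:
            return cls(df, layout=layout)
        except ValidationError as err:
            raise ValidationError(f"{path}: {err}") from None

    def to_bed(self, path: str | Path) -> None:
        cols = [c for c in ("chrom", "start", "end", "name", "score", "strand")
                if c in self._df.columns]
        self._df[cols].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 layout: GenomeLayout | None = None) -> "RegionSet":
        df = _read_table(path, header=0)
        if df is None:
            return cls(layout=layout)
        return cls(df, layout=layout)

    def to_tsv(self, path: str | Path) -> None:
        self._df.to_csv(path, sep="\t", index=False)


def merge_intervals(starts: np.ndarray, ends: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted-by-start intervals; book-ended intervals are joined."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    run_end = np.maximum.accumulate(e)
    new_run = np.empty(len(s), dtype=bool)
    new_run[0] = True
    new_run[1:] = s[1:] > run_end[:-1]
    idx = np.flatnonzero(new_run)
    ms = s[idx]
    me = np.empty(len(idx), dtype=e.dtype)
    me[:-1] = run_end[idx[1:] - 1]
    me[-1] = run_end[-1]
    return ms, me


def hits_merged(starts: np.ndarray, ends: np.ndarray,
                m_starts: np.ndarray, m_ends: np.ndarray) -> np.ndarray:
    """Boolean mask: which query intervals overlap a merged, disjoint set."""
    if len(m_starts) == 0 or len(starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(m_starts, ends, side="left")
    prev_end = np.where(idx > 0, m_ends[np.maximum(idx - 1, 0)], -1)
    return prev_end > starts


# ---------------------------------------------------------------------------
# loops
# ---------------------------------------------------------------------------


class LoopSet:
    """Chromatin loops stored as anchor midpoints.

    Columns: ``chrom``, ``mid1``, ``mid2`` (bp, ``mid1 < mid2``), plus
    ``probability`` for predicted loops or ``pet_count`` for ground truth.
    """

    def __init__(self, df: pd.DataFrame | None = None,
                 layout: GenomeLayout | None = None) -> None:
        if df is None or len(df) == 0:
            df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                               "mid1": pd.Series(dtype=np.int64),
                               "mid2": pd.Series(dtype=np.int64)}) \
                if df is None or not len(df) else df
        df = df.copy()
        for col in ("chrom", "mid1", "mid2"):
            if col not in df.columns:
                raise ValidationError(f"loop frame missing column {col!r}")
        df["chrom"] = df["chrom"].astype(str)
        df["mid1"] = df["mid1"].astype(np.int64)
        df["mid2"] = df["mid2"].astype(np.int64)
        if (df["mid1"] >= df["mid2"]).any():
            raise ValidationError("loops require mid1 < mid2")
        if layout is not None:
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in layout:
                    raise ValidationError(f"chromosome {chrom!r} not in layout")
                if (sub["mid2"] > layout.length(chrom)).any():
                    raise ValidationError(f"loop on {chrom} past chromosome end")
        self._df = df.sort_values(["chrom", "mid1", "mid2"],
                                  kind="mergesort").reset_index(drop=True)
        self.layout = layout

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LoopSet({len(self)} loops)"

    @property
    def lengths(self) -> np.ndarray:
        return (self._df["mid2"] - self._df["mid1"]).to_numpy()

    def filter_length(self, min_len: int = MIN_LOOP_LENGTH,
                      max_len: int = MAX_LOOP_LENGTH) -> "LoopSet":
        ln = self.lengths
        keep = (ln >= min_len) & (ln <= max_len)
        return LoopSet(self._df[keep], layout=self.layout)

    def spans(self) -> RegionSet:
        """Loops as [mid1, mid2) intervals."""
        return RegionSet.from_arrays(self._df["chrom"], self._df["mid1"],
                                     self._df["mid2"], layout=self.layout)

    def anchors(self, half_width: int = 2500) -> RegionSet:
        """Both anchors of every loop as blocks of 2*half_width bp."""
        chrom = np.concatenate([self._df["chrom"], self._df["chrom"]])
        mids = np.concatenate([self._df["mid1"], self._df["mid2"]])
        start = np.maximum(mids - half_width, 0)
        end = mids + half_width
        if self.layout is not None:
            lens = np.array([self.layout.length(c) for c in chrom])
            end = np.minimum(end, lens)
        return RegionSet.from_arrays(chrom, start, end, layout=self.layout)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_bedpe(cls, path: str | Path, layout: GenomeLayout | None = None,
                   score: str | None = None) -> "LoopSet":
        """Read a BEDPE file, collapsing anchor intervals to their midpoints.

        ``score`` names the interpretation of column 8: ``"pet_count"`` for
        ground-truth loops or ``"probability"`` for predictions (``None``
        ignores the column).
        """
        df = _read_table(path, header=None)
        if df is None:
            return cls(layout=layout)
        if df.shape[1] < 6:
            raise FormatError(f"{path}: BEDPE needs >=6 columns, found {df.shape[1]}")
        cols = df.iloc[:, :6].copy()
        cols.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
        _coerce_int(cols, ["start1", "end1", "start2", "end2"], path)
        if (cols["chrom1"].astype(str) != cols["chrom2"].astype(str)).any():
            bad = (cols["chrom1"].astype(str) != cols["chrom2"].astype(str)).idxmax()
            raise FormatError(f"{path}: line {bad + 1}: inter-chromosomal record")
        mid1 = (cols["start1"] + cols["end1"]) // 2
        mid2 = (cols["start2"] + cols["end2"]) // 2
        # orient so mid1 < mid2 regardless of anchor order on disk
        lo = np.minimum(mid1, mid2)
        hi = np.maximum(mid1, mid2)
        out = pd.DataFrame({"chrom": cols["chrom1"].astype(str),
                            "mid1": lo, "mid2": hi})
        if score is not None:
            if df.shape[1] < 8:
                raise FormatError(f"{path}: column 8 ({score}) absent")
            vals = pd.to_numeric(df.iloc[:, 7], errors="coerce")
            if vals.isna().any():
                bad = int(vals.isna().idxmax())
                raise FormatError(f"{path}: line {bad + 1}: non-numeric {score}")
            out[score] = vals.astype(int if score == "pet_count" else float).to_numpy()
        return cls(out, layout=layout)

    def to_bedpe(self, path: str | Path, half_width: int = 2500) -> None:
        """Write BEDPE with reconstituted anchors; column 7 is a loop id and
        column 8 carries the probability / PET count when present."""
        df = self._df
        score_col = next((c for c in ("probability", "pet_count")
                          if c in df.columns), None)
        with open(path, "w") as fh:
            for i, row in enumerate(df.itertuples(index=False)):
                s1 = max(row.mid1 - half_width, 0)
                s2 = max(row.mid2 - half_width, 0)
                score = getattr(row, score_col) if score_col else "."
                fh.write(f"{row.chrom}\t{s1}\t{row.mid1 + half_width}\t"
                         f"{row.chrom}\t{s2}\t{row.mid2 + half_width}\t"
                         f"loop_{i}\t{score}\n")


# ---------------------------------------------------------------------------
# generic readers / overlap operations
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, header) -> pd.DataFrame | None:
    try:
        df = pd.read_csv(path, sep="\t", header=header, comment="#")
    except pd.errors.EmptyDataError:
        return None
    except (pd.errors.ParserError, ValueError) as err:
        raise FormatError(f"{path}: {err}") from None
    return df if len(df) else None


def _coerce_int(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 1
            raise FormatError(f"{path}: line {line}: non-integer {col!r} field")
        df[col] = vals.astype(np.int64)


def read_regions(path: str | Path, format: str = "bed",
                 layout: GenomeLayout | None = None,
                 score: str | None = None) -> RegionSet | LoopSet:
    """Read a region file under the named dialect.

    ``format`` is one of ``"bed"`` (BED3/BED6 -> RegionSet), ``"bedpe"``
    (-> LoopSet), or ``"tsv"`` (headered chrom/start/end table -> RegionSet).
    """
    fmt = format.lower()
    if fmt == "bed":
        return RegionSet.from_bed(path, layout=layout)
    if fmt == "bedpe":
        return LoopSet.from_bedpe(path, layout=layout, score=score)
    if fmt == "tsv":
        return RegionSet.from_tsv(path, layout=layout)
    raise ValueError(f"unknown format {format!r}")


def _check_universe(a: RegionSet, b: RegionSet) -> None:
    la, lb = getattr(a, "layout", None), getattr(b, "layout", None)
    if la is not None and lb is not None and la.lengths != lb.lengths:
        raise ValidationError("region sets live on different chromosome universes")


def overlap_mask(a: RegionSet, b: RegionSet) -> np.ndarray:
    """Per-region boolean: does each region of A overlap >=1 region of B?

    Order follows ``a.df`` rows (sorted canonical order).
    """
    _check_universe(a, b)
    merged = b.merged().chrom_arrays()
    mask = np.zeros(len(a), dtype=bool)
    pos = 0
    for chrom, (s, e) in a.chrom_arrays().items():
        n = len(s)
        if chrom in merged:
            ms, me = merged[chrom]
            mask[pos:pos + n] = hits_merged(s, e, ms, me)
        pos += n
    return mask


def count_overlaps(a: RegionSet, b: RegionSet) -> int:
    """Number of regions in A overlapping at least one region of B by >=1 bp.

    This is the query-region count (not the pair count) used as the test
    statistic in circular permutations.
    """
    return int(overlap_mask(a, b).sum())


def count_overlapping_regions(a: RegionSet, b: RegionSet) -> np.ndarray:
    """For each region of A, the number of B regions it overlaps (pair count)."""
    _check_universe(a, b)
    barr = b.chrom_arrays()
    out = np.zeros(len(a), dtype=np.int64)
    pos = 0
    for chrom, (s, e) in a.chrom_arrays().items():
        n = len(s)
        if chrom in barr:
            bs, be = barr[chrom]
            be_sorted = np.sort(be)
            out[pos:pos + n] = (np.searchsorted(bs, e, side="left")
                                - np.searchsorted(be_sorted, s, side="right"))
        pos += n
    return out


def reciprocal_overlap(a: tuple, b: tuple) -> float:
    """min(|a&b|/|a|, |a&b|/|b|) for two intervals on the same chromosome.

    Intervals are ``(start, end)`` or ``(chrom, start, end)`` tuples.
    """
    if len(a) == 3 or len(b) == 3:
        if len(a) != 3 or len(b) != 3 or a[0] != b[0]:
            raise ValidationError("intervals must be on the same chromosome")
        a, b = a[1:], b[1:]
    (as_, ae), (bs, be) = a, b
    if ae <= as_ or be <= bs:
        raise ValidationError("zero-length interval in reciprocal overlap")
    inter = max(0, min(ae, be) - max(as_, bs))
    return min(inter / (ae - as_), inter / (be - bs))


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------


class SignalTrack:
    """A step function over the genome (bedGraph semantics).

    Segments are non-overlapping within a chromosome; positions not covered by
    any segment have value 0.
    """

    def __init__(self, df: pd.DataFrame, layout: GenomeLayout | None = None,
                 require_nonnegative: bool = False) -> None:
        df = df.copy()
        for col in ("chrom", "start", "end", "value"):
            if col not in df.columns:
                raise ValidationError(f"track frame missing column {col!r}")
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["value"] = df["value"].astype(float)
        if not np.isfinite(df["value"]).all():
            raise ValidationError("track values must be finite")
        if require_nonnegative and (df["value"] < 0).any():
            raise ValidationError("track values must be non-negative")
        if (df["start"] >= df["end"]).any():
            raise ValidationError("track segments require start < end")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValidationError(f"overlapping track segments on {chrom}")
            if layout is not None and sub["end"].iloc[-1] > layout.length(chrom):
                raise ValidationError(f"track on {chrom} past chromosome end")
        self._df = df
        self.layout = layout

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @classmethod
    def from_bedgraph(cls, path: str | Path,
                      layout: GenomeLayout | None = None) -> "SignalTrack":
        df = _read_table(path, header=None)
        if df is None:
            df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        else:
            if df.shape[1] < 4:
                raise FormatError(f"{path}: bedGraph needs 4 columns")
            df = df.iloc[:, :4]
            df.columns = ["chrom", "start", "end", "value"]
        return cls(df, layout=layout)

    def to_bedgraph(self, path: str | Path) -> None:
        self._df.to_csv(path, sep="\t", header=False, index=False,
                        float_format="%.6g")

    def _integrals(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per chrom: (segment starts, segment ends, cumulative integral at
        segment starts)."""
        out = {}
        for chrom, sub in self._df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            v = sub["value"].to_numpy()
            seg = v * (e - s)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            out[chrom] = (s, e, (cum, v))
        return out

    def mean_in(self, chrom: np.ndarray, starts: np.ndarray,
                ends: np.ndarray) -> np.ndarray:
        """Coverage-weighted mean value in each query window (0 where the
        window has no covered base)."""
        chrom = np.asarray(chrom, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        res = np.zeros(len(starts), dtype=float)
        integ = self._integrals()
        for c in np.unique(chrom):
            sel = chrom == c
            if c not in integ:
                continue
            s_arr, e_arr, (cum, v) = integ[c]

            def F(x):
                i = np.searchsorted(s_arr, x, side="right") - 1
                i = np.clip(i, 0, len(s_arr) - 1)
                inside = np.clip(x - s_arr[i], 0, e_arr[i] - s_arr[i])
                return cum[i] + v[i] * inside

            def covered(x):
                i = np.searchsorted(s_arr, x, side="right") - 1
                i = np.clip(i, 0, len(s_arr) - 1)
                cov_cum = np.concatenate([[0], np.cumsum(e_arr - s_arr)])
                inside = np.clip(x - s_arr[i], 0, e_arr[i] - s_arr[i])
                return cov_cum[i] + inside

            ws, we = starts[sel], ends[sel]
            area = F(we) - F(ws)
            cov = covered(we) - covered(ws)
            with np.errstate(invalid="ignore", divide="ignore"):
                m = np.where(cov > 0, area / np.maximum(cov, 1), 0.0)
            res[sel] = m
        return res


def define_recombination_hotspots(rate_track: SignalTrack,
                                  threshold: float = RECOMBINATION_HOTSPOT_THRESHOLD
                                  ) -> RegionSet:
    """Maximal runs of the rate track at or above ``threshold`` cM/Mb,
    adjacent segments merged."""
    df = rate_track.df
    if (df["value"] < 0).any():
        raise ValidationError("recombination rates must be non-negative")
    hot = df[df["value"] >= threshold]
    if not len(hot):
        return RegionSet(layout=rate_track.layout)
    return RegionSet.from_arrays(hot["chrom"], hot["start"], hot["end"],
                                 layout=rate_track.layout).merged()


# ---------------------------------------------------------------------------
# expression tables and CTCF sites
# ---------------------------------------------------------------------------

EXPRESSION_COLUMNS = ("gene_id", "chrom", "tss", "scaled_expression")


def read_expression_table(path: str | Path,
                          layout: GenomeLayout | None = None) -> pd.DataFrame:
    """TSV with header gene_id/chrom/tss/scaled_expression."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: expression table missing columns {missing}")
    df["tss"] = df["tss"].astype(np.int64)
    if layout is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in layout or (sub["tss"] >= layout.length(chrom)).any():
                raise ValidationError(f"TSS outside layout on {chrom}")
    return df.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df[list(EXPRESSION_COLUMNS)].to_csv(path, sep="\t", index=False)


CTCF_COLUMNS = ("chrom", "start", "end", "strand", "motif_score",
                "conservation", "peak_strength")


def validate_ctcf_sites(df: pd.DataFrame,
                        layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Canonicalize an oriented CTCF motif-site table.

    Returns a copy sorted by (chrom, start) with an added ``mid`` column.
    """
    missing = [c for c in CTCF_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"CTCF site table missing columns {missing}")
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError("CTCF sites require strand '+' or '-'")
    ps = df["peak_strength"].astype(float)
    if ((ps < 0) | (ps > 1)).any():
        raise ValidationError("peak_strength must lie in [0, 1]")
    if (df["start"] >= df["end"]).any():
        raise ValidationError("CTCF motif intervals require start < end")
    if layout is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in layout or (sub["end"] > layout.length(chrom)).any():
                raise ValidationError(f"CTCF site outside layout on {chrom}")
    df["mid"] = (df["start"] + df["end"]) // 2
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def read_ctcf_sites(path: str | Path,
                    layout: GenomeLayout | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_ctcf_sites(df, layout=layout)


def write_ctcf_sites(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in df.columns if c != "mid"]
    df[cols].to_csv(path, sep="\t", index=False)
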