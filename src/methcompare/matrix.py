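"""Aggregation matrices and their averaging statistics.

An *aggregation matrix* collects a sparse per-site signal — here bisulfite
methylation rates in [0, 1] — for ``n`` genomic regions laid out against a
common anchor, one region per row and one relative position per column.
Positions at which a region carries no CpG dinucleotide cannot be
methylated and are *missing*, recorded in an explicit boolean mask.

Three averaging statistics are defined over the observed cells:

``C``
    the mean of the per-column averages (the field-standard "%mCG"
    metaplot value),
``R``
    the mean of the per-row (per-region) averages,
``M``
    the mean over all observed cells.

On a fully observed matrix the three coincide; with missing data they can
be arbitrarily different, and :func:`witness_matrix` constructs, for any
rational target triple ``(r, c, m)`` in the open unit interval, a matrix
realizing all three exactly.  The divergence of ``C`` from ``R`` when CpG
loss (deamination) is coupled to methylation state is the Yule-Simpson
bias this package exists to diagnose and correct.

Coordinates are 0-based half-open (BED convention).  Column index ``j`` of
either side of a junction always means "``j`` base pairs from the boundary
in the 5'->3' sense"; minus-strand regions are orientation-flipped when the
matrix is built.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "AggregationMatrix",
    "JunctionMatrixPair",
    "SummaryStats",
    "summary_stats",
    "column_profile",
    "build_matrix_pair",
    "witness_matrix",
]


class AggregationMatrix:
    """An ``n x m`` grid of fractions in [0, 1] with a missingness mask.

    Parameters
    ----------
    values : array-like of float, shape (n, m)
        Observed methylation rates.  Cells that are masked out may hold
        any value (``nan`` conventionally); they are overwritten with
        ``nan`` on construction.
    mask : array-like of bool, shape (n, m), optional
        ``True`` where a value is observed.  Defaults to ``~isnan(values)``.
    row_labels : sequence of str, optional
        Region identifiers, one per row.
    orientation : {"toward_boundary", "away_from_boundary"}
        Whether column 0 is the position adjacent to the boundary
        (the default for junction matrices) or the most distal one.
    """

    __slots__ = ("values", "mask", "row_labels", "orientation")

    def __init__(self, values, mask=None, row_labels=None,
                 orientation="toward_boundary"):
        values = np.array(values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValidationError(
                f"aggregation matrix must be 2-D with n, m >= 1; "
                f"got shape {values.shape}")
        if mask is None:
            mask = ~np.isnan(values)
        else:
            mask = np.array(mask, dtype=bool)
            if mask.shape != values.shape:
                raise ValidationError(
                    f"mask shape {mask.shape} != values shape {values.shape}")
        values = np.where(mask, values, np.nan)
        observed = values[mask]
        if observed.size:
            if not np.all(np.isfinite(observed)):
                raise ValidationError("observed cells must be finite")
            if observed.min() < 0.0 or observed.max() > 1.0:
                raise ValidationError(
                    "observed methylation values must lie in [0, 1]")
        if orientation not in ("toward_boundary", "away_from_boundary"):
            raise ValidationError(f"unknown orientation {orientation!r}")
        if row_labels is None:
            row_labels = [f"r{i}" for i in range(values.shape[0])]
        else:
            row_labels = [str(x) for x in row_labels]
            if len(row_labels) != values.shape[0]:
                raise ValidationError("row_labels length != number of rows")
        self.values = values
        self.mask = mask
        self.row_labels = row_labels
        self.orientation = orientation

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "AggregationMatrix":
        return AggregationMatrix(self.values.copy(), self.mask.copy(),
                                 list(self.row_labels), self.orientation)

    def equals(self, other: "AggregationMatrix") -> bool:
        """Exact equality of mask, observed values, labels, orientation."""
        return (self.mask.shape == other.mask.shape
                and np.array_equal(self.mask, other.mask)
                and np.array_equal(self.values[self.mask],
                                   other.values[other.mask])
                and self.row_labels == other.row_labels
                and self.orientation == other.orientation)

    def __repr__(self):
        return (f"<AggregationMatrix {self.n}x{self.m}, "
                f"{self.n_observed}/{self.n * self.m} observed>")


@dataclass
class JunctionMatrixPair:
    """Two row-coupled aggregation matrices flanking one boundary type.

    Row ``i`` of ``left`` and row ``i`` of ``right`` derive from the same
    boundary instance (e.g. one specific intron-exon junction); ``left``
    is the 5' side.  Both matrices are oriented toward the boundary:
    column 0 is adjacent to it.
    """

    left: AggregationMatrix
    right: AggregationMatrix
    row_labels: list = None
    build_report: dict = None

    def __post_init__(self):
        if self.left.n != self.right.n:
            raise ValidationError(
                f"coupled matrices must share rows: {self.left.n} != "
                f"{self.right.n}")
        if self.row_labels is None:
            self.row_labels = list(self.left.row_labels)
        if len(self.row_labels) != self.left.n:
            raise ValidationError("row_labels length != number of rows")

    @property
    def n(self) -> int:
        return self.left.n

    def copy(self) -> "JunctionMatrixPair":
        return JunctionMatrixPair(self.left.copy(), self.right.copy(),
                                  list(self.row_labels))

    def swapped(self) -> "JunctionMatrixPair":
        """The same pair with left and right exchanged."""
        return JunctionMatrixPair(self.right.copy(), self.left.copy(),
                                  list(self.row_labels))


@dataclass
class SummaryStats:
    """The three averaging statistics of one matrix plus the count-value
    correlation.

    ``r`` is the Pearson correlation between the number of observed sites
    in each row and that row's mean — the signature of
    deamination-coupled missingness (negative when methylated regions
    have fewer CpGs).  ``nan`` when fewer than two rows have data or the
    counts are constant.
    """

    C: float
    R: float
    M: float
    r: float
    n_rows_used: int = 0
    n_cols_used: int = 0

    def as_dict(self) -> dict:
        return {"C": self.C, "R": self.R, "M": self.M, "r": self.r,
                "n_rows_used": self.n_rows_used,
                "n_cols_used": self.n_cols_used}


def summary_stats(matrix: AggregationMatrix) -> SummaryStats:
    """Compute ``C``, ``R``, ``M`` and the count-methylation Pearson ``r``.

    Rows (columns) with no observed cell have no mean and are excluded
    from ``R`` (``C``) and from ``r``.  Raises
    :class:`~methcompare.errors.ValidationError` on an all-missing matrix.
    """
    mask = matrix.mask
    vals = np.where(mask, matrix.values, 0.0)
    total = mask.sum()
    if total == 0:
        raise ValidationError("no observed data: all cells are missing")

    row_cnt = mask.sum(axis=1)
    col_cnt = mask.sum(axis=0)
    row_ok = row_cnt > 0
    col_ok = col_cnt > 0
    row_means = vals.sum(axis=1)[row_ok] / row_cnt[row_ok]
    col_means = vals.sum(axis=0)[col_ok] / col_cnt[col_ok]

    R = float(row_means.mean())
    C = float(col_means.mean())
    M = float(vals.sum() / total)

    counts = row_cnt[row_ok].astype(float)
    if counts.size >= 2 and counts.std() > 0 and row_means.std() > 0:
        r = float(np.corrcoef(counts, row_means)[0, 1])
    else:
        r = float("nan")
    return SummaryStats(C=C, R=R, M=M, r=r,
                        n_rows_used=int(row_ok.sum()),
                        n_cols_used=int(col_ok.sum()))


def column_profile(matrix: AggregationMatrix, min_obs: int = 1,
                   bin_width: int = 1) -> pd.DataFrame:
    """Per-column average and observed count — the "%mCG" profile.

    Columns (or fixed-width bins of ``bin_width`` consecutive columns)
    with fewer than ``min_obs`` observed cells are reported with
    ``average = nan``.  Returns a DataFrame with columns
    ``position`` (distance of the bin start from the boundary, in
    columns), ``average`` and ``count``.
    """
    if min_obs < 0:
        raise ValidationError("min_obs must be >= 0")
    if bin_width < 1:
        raise ValidationError("bin_width must be >= 1")
    mask = matrix.mask
    vals = np.where(mask, matrix.values, 0.0)
    m = matrix.m
    starts = np.arange(0, m, bin_width)
    rows = []
    for s in starts:
        sl = slice(s, min(s + bin_width, m))
        cnt = int(mask[:, sl].sum())
        avg = float(vals[:, sl].sum() / cnt) if cnt >= max(min_obs, 1) \
            else float("nan")
        if cnt < min_obs:
            avg = float("nan")
        rows.append((int(s), avg, cnt))
    return pd.DataFrame(rows, columns=["position", "average", "count"])


# ---------------------------------------------------------------------------
# Junction matrix construction
# ---------------------------------------------------------------------------

def build_matrix_pair(calls: pd.DataFrame, boundaries: pd.DataFrame,
                      upstream_span: int = None,
                      downstream_span: int = None) -> JunctionMatrixPair:
    """Place per-CpG calls into a row-coupled pair of junction matrices.

    ``calls`` must have columns ``chrom, pos, rate`` (as produced by
    :func:`methcompare.io.read_calls`); at most one record per
    ``(chrom, pos)``.  ``boundaries`` must have columns
    ``chrom, boundary_pos, strand, upstream_span, downstream_span, label``
    (:func:`methcompare.io.read_boundaries`); spans may be overridden by
    the keyword arguments but must be uniform because the matrices are
    rectangular.

    Cell ``(i, j)`` of the left (right) matrix holds the call rate ``j``
    base pairs upstream (downstream) of boundary ``i`` in the
    transcription sense: for a plus-strand boundary at ``b`` the left side
    reads genomic positions ``b-1-j`` and the right side ``b+j``; for a
    minus-strand boundary the two sides are exchanged, so column 0 is
    always adjacent to the boundary.  A boundary on a chromosome absent
    from the call index simply yields an all-missing row, counted in
    ``pair.build_report``.
    """
    if upstream_span is None:
        spans = boundaries["upstream_span"].unique()
        if len(spans) != 1:
            raise ValidationError(
                "non-uniform upstream spans; pass upstream_span explicitly")
        upstream_span = int(spans[0])
    if downstream_span is None:
        spans = boundaries["downstream_span"].unique()
        if len(spans) != 1:
            raise ValidationError(
                "non-uniform downstream spans; pass downstream_span explicitly")
        downstream_span = int(spans[0])
    if upstream_span < 1 or downstream_span < 1:
        raise ValidationError("spans must be positive")

    if calls.duplicated(subset=["chrom", "pos"]).any():
        raise ValidationError(
            "duplicate (chrom, pos) records in calls; collapse CG dyads "
            "first (methcompare.io.collapse_cg_dyads)")
    index = {chrom: dict(zip(sub["pos"].to_numpy(),
                             sub["rate"].to_numpy()))
             for chrom, sub in calls.groupby("chrom", sort=False)}

    nb = len(boundaries)
    left = np.full((nb, upstream_span), np.nan)
    right = np.full((nb, downstream_span), np.nan)
    n_empty_left = n_empty_right = 0
    labels = []
    for i, row in enumerate(boundaries.itertuples(index=False)):
        labels.append(str(row.label))
        chrom_calls = index.get(row.chrom, {})
        b = int(row.boundary_pos)
        if row.strand == "+":
            up_pos = b - 1 - np.arange(upstream_span)
            down_pos = b + np.arange(downstream_span)
        else:
            up_pos = b + np.arange(upstream_span)
            down_pos = b - 1 - np.arange(downstream_span)
        hit = False
        for j, p in enumerate(up_pos):
            v = chrom_calls.get(int(p))
            if v is not None:
                left[i, j] = v
                hit = True
        if not hit:
            n_empty_left += 1
        hit = False
        for j, p in enumerate(down_pos):
            v = chrom_calls.get(int(p))
            if v is not None:
                right[i, j] = v
                hit = True
        if not hit:
            n_empty_right += 1

    report = {"n_boundaries": nb,
              "rows_all_missing_left": n_empty_left,
              "rows_all_missing_right": n_empty_right}
    return JunctionMatrixPair(
        AggregationMatrix(left, row_labels=labels),
        AggregationMatrix(right, row_labels=labels),
        row_labels=labels, build_report=report)


# ---------------------------------------------------------------------------
# Witness construction: any rational (r, c, m) is realizable
# ---------------------------------------------------------------------------

def _as_fraction(x, tol: float) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, tuple):
        return Fraction(*x)
    if isinstance(x, numbers.Integral):
        return Fraction(int(x))
    if isinstance(x, numbers.Real):
        exact = Fraction(float(x))
        for max_den in (100, 1000, 10_000, 100_000, 1_000_000):
            fr = exact.limit_denominator(max_den)
            if abs(fr - exact) <= tol:
                return fr
        raise ValidationError(
            f"no rational with denominator <= 1e6 approximates {x!r} "
            f"within {tol}; pass a Fraction or (num, den) tuple")
    raise ValidationError(f"cannot interpret {x!r} as a rational")


def witness_matrix(r, c, m, max_size: int = 10_000,
                   float_tol: float = 1e-9) -> AggregationMatrix:
    """Construct a matrix with ``R = r``, ``C = c``, ``M = m`` exactly.

    ``r, c, m`` may be :class:`fractions.Fraction`, ``(num, den)`` tuples,
    or floats (snapped to a nearby rational within ``float_tol``); all
    must lie strictly in (0, 1).

    The construction is bipartite: "hi" rows intersect "hi" columns in a
    block of ones and "lo" rows intersect "lo" columns in a block of
    zeros, every other cell missing.  Any hi row/column mean is exactly 1
    and any lo mean exactly 0, so with ``r = a/b`` the matrix gets ``a*k1``
    hi rows out of ``b*k1``, with ``c = e/d`` it gets ``e*k2`` hi columns
    out of ``d*k2``, and with ``m = g/f`` the one-block gets ``g*t`` of
    ``f*t`` total cells.  Integers ``k1, k2, t`` are searched so that each
    block can cover every one of its rows and columns while fitting in its
    grid; cells are then dealt to rows round-robin with a global cyclic
    column counter, which guarantees full coverage.

    Raises :class:`~methcompare.errors.ValidationError` when no layout
    fits within ``max_size`` rows/columns.
    """
    r = _as_fraction(r, float_tol)
    c = _as_fraction(c, float_tol)
    m = _as_fraction(m, float_tol)
    for name, x in (("r", r), ("c", c), ("m", m)):
        if not (0 < x < 1):
            raise ValidationError(f"{name} must lie strictly in (0, 1)")

    a, b = r.numerator, r.denominator
    e, d = c.numerator, c.denominator
    g, f = m.numerator, m.denominator

    def block_bounds(nrows, ncols, ncells):
        """Cells must cover every row and column but fit the grid."""
        return max(nrows, ncols) <= ncells <= nrows * ncols

    found = None
    for s in range(2, 161):
        for k1 in range(1, s):
            k2 = s - k1
            if b * k1 > max_size or d * k2 > max_size:
                continue
            hi_r, lo_r = a * k1, (b - a) * k1
            hi_c, lo_c = e * k2, (d - e) * k2
            # feasible t interval from both blocks' bounds
            t_lo = max(math.ceil(max(hi_r, hi_c) / g),
                       math.ceil(max(lo_r, lo_c) / (f - g)), 1)
            t_hi = min((hi_r * hi_c) // g, (lo_r * lo_c) // (f - g))
            if t_lo <= t_hi:
                found = (k1, k2, t_lo)
                break
        if found:
            break
    if found is None:
        raise ValidationError(
            f"no witness layout for (r, c, m) = ({r}, {c}, {m}) within "
            f"max_size={max_size}; try a larger cap")

    k1, k2, t = found
    hi_r, lo_r = a * k1, (b - a) * k1
    hi_c, lo_c = e * k2, (d - e) * k2
    n_hi, n_lo = g * t, (f - g) * t

    n_rows, n_cols = b * k1, d * k2
    values = np.full((n_rows, n_cols), np.nan)

    def fill(row_ids, col_ids, ncells, value):
        # deal cells to rows as evenly as possible, columns cyclically;
        # ncells >= len(col_ids) guarantees every column is visited
        nr, nc = len(row_ids), len(col_ids)
        base, extra = divmod(ncells, nr)
        cyc = 0
        for ri, row in enumerate(row_ids):
            take = base + (1 if ri < extra else 0)
            for _ in range(take):
                values[row, col_ids[cyc % nc]] = value
                cyc += 1

    fill(list(range(hi_r)), list(range(hi_c)), n_hi, 1.0)
    fill(list(range(hi_r, n_rows)), list(range(hi_c, n_cols)), n_lo, 0.0)
    return AggregationMatrix(values)
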