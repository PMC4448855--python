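"""Reading and writing methylation calls, boundary definitions and
aggregation matrices.

File dialects
-------------
* **Calls**: tab-delimited, five columns per line —
  ``chrom  pos  strand  rate  coverage`` with ``pos`` 0-based, ``strand``
  in ``{+,-}``, ``rate`` a fraction in [0, 1] and ``coverage`` a
  non-negative read count.  Lines starting with ``#`` and blank lines are
  ignored.
* **Boundaries**: BED with the strand in column 6.
* **Matrices**: TSV with a leading ``#orientation=`` comment line, a
  header row, one region label column, and ``NA`` as the missing-value
  token.  Round-trips are lossless (Python float repr).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .matrix import AggregationMatrix, JunctionMatrixPair

__all__ = [
    "read_calls", "write_calls", "collapse_cg_dyads",
    "read_boundaries", "filter_boundaries",
    "read_matrix", "write_matrix", "read_pair", "write_pair",
]

CALL_COLUMNS = ["chrom", "pos", "strand", "rate", "coverage"]
NA_TOKEN = "NA"


def read_calls(path, min_coverage: int = 3) -> pd.DataFrame:
    """Parse a per-CpG call file, dropping records below ``min_coverage``.

    Bisulfite pipelines conventionally report a rate only for sites with
    adequate read support; the default keeps sites overlapped by at least
    three reads.  Record order is preserved.  Malformed lines raise
    :class:`~methcompare.errors.ParseError` naming the line number;
    out-of-range rates raise :class:`~methcompare.errors.ValidationError`.
    """
    if min_coverage < 0:
        raise ValidationError("min_coverage must be >= 0")
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(
                    f"{path}: line {ln}: expected 5 tab-delimited fields, "
                    f"got {len(fields)}")
            chrom, pos_s, strand, rate_s, cov_s = fields
            try:
                pos = int(pos_s)
                rate = float(rate_s)
                cov = int(cov_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from None
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {ln}: strand must be + or -, "
                    f"got {strand!r}")
            if pos < 0:
                raise ValidationError(f"{path}: line {ln}: pos must be >= 0")
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(
                    f"{path}: line {ln}: rate {rate} outside [0, 1]")
            if cov < 0:
                raise ValidationError(
                    f"{path}: line {ln}: coverage must be >= 0")
            if cov >= min_coverage:
                records.append((chrom, pos, strand, rate, cov))
    return pd.DataFrame(records, columns=CALL_COLUMNS)


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", header=False, index=False,
                 columns=CALL_COLUMNS)


def collapse_cg_dyads(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge the two strand calls of a CG dyad into one site record.

    A CpG dinucleotide exposes a cytosine on each strand: a plus-strand
    call at position ``p`` and a minus-strand call at ``p + 1`` measure
    the same methylatable unit.  When both are present they are combined
    into a single plus-strand record at the dyad start ``p`` with a
    coverage-weighted mean rate and summed coverage.  Unpaired
    minus-strand calls are re-anchored to their dyad start (``pos - 1``)
    so matrix placement is strand-consistent.
    """
    plus = calls[calls["strand"] == "+"]
    minus = calls[calls["strand"] == "-"]
    minus_idx = {(c, p): i for c, p, i
                 in zip(minus["chrom"], minus["pos"], minus.index)}
    used_minus = set()
    records = []
    for row in plus.itertuples(index=False):
        key = (row.chrom, row.pos + 1)
        j = minus_idx.get(key)
        if j is not None:
            other = minus.loc[j]
            tot = row.coverage + other["coverage"]
            if tot > 0:
                rate = (row.rate * row.coverage
                        + other["rate"] * other["coverage"]) / tot
            else:
                rate = (row.rate + other["rate"]) / 2.0
            records.append((row.chrom, row.pos, "+", float(rate), int(tot)))
            used_minus.add(j)
        else:
            records.append(tuple(row))
    for j, row in zip(minus.index, minus.itertuples(index=False)):
        if j not in used_minus:
            records.append((row.chrom, max(row.pos - 1, 0), "+",
                            row.rate, row.coverage))
    out = pd.DataFrame(records, columns=CALL_COLUMNS)
    return out.sort_values(["chrom", "pos"], kind="stable",
                           ignore_index=True)


# ---------------------------------------------------------------------------
# Boundaries
# ---------------------------------------------------------------------------

def read_boundaries(path, upstream_span: int, downstream_span: int,
                    anchor: str = "start") -> pd.DataFrame:
    """Turn BED intervals into boundary instances.

    ``anchor`` selects which end of each interval is the functional
    boundary, in the transcription (5'->3') sense: ``"start"`` anchors at
    the interval's 5' end — the genomic start for ``+`` records and the
    genomic end for ``-`` records — and ``"end"`` at the 3' end.  The
    strand field (BED column 6) is required.  Returns a DataFrame with
    columns ``chrom, boundary_pos, strand, upstream_span,
    downstream_span, label``.
    """
    if anchor not in ("start", "end"):
        raise ValidationError(f"anchor must be 'start' or 'end', got {anchor!r}")
    if upstream_span < 1 or downstream_span < 1:
        raise ValidationError("spans must be positive")
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {ln}: BED record needs >= 6 fields "
                    f"(strand required), got {len(fields)}")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            name = fields[3] if fields[3] else f"b{ln}"
            strand = fields[5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from None
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {ln}: strand must be + or -, "
                    f"got {strand!r}")
            if not 0 <= start < end:
                raise ParseError(
                    f"{path}: line {ln}: invalid interval [{start}, {end})")
            five_prime_start = (strand == "+") == (anchor == "start")
            boundary = start if five_prime_start else end
            records.append((chrom, boundary, strand,
                            upstream_span, downstream_span, name))
    return pd.DataFrame(records, columns=[
        "chrom", "boundary_pos", "strand",
        "upstream_span", "downstream_span", "label"])


def filter_boundaries(instances: pd.DataFrame,
                      min_upstream: int = 0,
                      min_downstream: int = 0,
                      exclusion: Iterable = ()) -> tuple:
    """Apply record-level predicates to boundary instances.

    Predicates: both flank spans at least the given minimum (the
    junction-selection rule "flanking features at least N bp long"), and
    no overlap of the instance's genomic footprint
    (``[boundary - 5' span, boundary + 3' span)`` in genomic coordinates)
    with any interval in ``exclusion`` (an iterable of
    ``(chrom, start, end)`` triples).

    Returns ``(retained, report)`` where ``report`` counts discarded
    instances per predicate (an instance may fail several).  Predicates
    are order-independent; the retained set is always a subset of the
    input.
    """
    excl_by_chrom = {}
    for chrom, start, end in exclusion:
        excl_by_chrom.setdefault(chrom, []).append((int(start), int(end)))

    keep = np.ones(len(instances), dtype=bool)
    n_flank = n_overlap = 0
    for i, row in enumerate(instances.itertuples(index=False)):
        ok = True
        if row.upstream_span < min_upstream or \
                row.downstream_span < min_downstream:
            n_flank += 1
            ok = False
        if row.strand == "+":
            lo = row.boundary_pos - row.upstream_span
            hi = row.boundary_pos + row.downstream_span
        else:
            lo = row.boundary_pos - row.downstream_span
            hi = row.boundary_pos + row.upstream_span
        for (s, e) in excl_by_chrom.get(row.chrom, ()):
            if lo < e and s < hi:
                n_overlap += 1
                ok = False
                break
        keep[i] = ok
    report = {"n_input": len(instances),
              "n_retained": int(keep.sum()),
              "discarded_min_flank": n_flank,
              "discarded_exclusion_overlap": n_overlap}
    return instances[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Matrix TSV
# ---------------------------------------------------------------------------

def write_matrix(matrix: AggregationMatrix, path) -> None:
    """Serialize a matrix losslessly; missing cells become ``NA``."""
    for lab in matrix.row_labels:
        if "\t" in lab or "\n" in lab:
            raise ValidationError(f"row label {lab!r} contains a delimiter")
        if lab == NA_TOKEN:
            raise ValidationError(
                f"row label collides with the missing-value token "
                f"{NA_TOKEN!r}")
    with open(path, "w") as fh:
        fh.write(f"#orientation={matrix.orientation}\n")
        fh.write("region\t" + "\t".join(str(j) for j in range(matrix.m))
                 + "\n")
        for lab, vrow, mrow in zip(matrix.row_labels, matrix.values,
                                   matrix.mask):
            cells = []
            for v, ok in zip(vrow, mrow):
                if ok:
                    s = repr(float(v))
                    if s == NA_TOKEN:  # defensive; floats never print NA
                        raise ValidationError("value collides with NA token")
                    cells.append(s)
                else:
                    cells.append(NA_TOKEN)
            fh.write(lab + "\t" + "\t".join(cells) + "\n")


def read_matrix(path) -> AggregationMatrix:
    orientation = "toward_boundary"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#orientation="):
            orientation = first.strip().split("=", 1)[1]
            header = fh.readline()
        else:
            header = first
        if not header.startswith("region"):
            raise ParseError(f"{path}: missing matrix header row")
        ncol = len(header.rstrip("\n").split("\t")) - 1
        labels, rows = [], []
        for ln, line in enumerate(fh, 3):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != ncol + 1:
                raise ParseError(
                    f"{path}: line {ln}: expected {ncol + 1} fields, "
                    f"got {len(fields)}")
            labels.append(fields[0])
            try:
                rows.append([float("nan") if f == NA_TOKEN else float(f)
                             for f in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: matrix has no data rows")
    return AggregationMatrix(np.array(rows), row_labels=labels,
                             orientation=orientation)


def write_pair(pair: JunctionMatrixPair, prefix) -> tuple:
    """Write ``<prefix>.left.tsv`` and ``<prefix>.right.tsv``."""
    left_path = f"{prefix}.left.tsv"
    right_path = f"{prefix}.right.tsv"
    write_matrix(pair.left, left_path)
    write_matrix(pair.right, right_path)
    return left_path, right_path


def read_pair(left_path, right_path) -> JunctionMatrixPair:
    left = read_matrix(left_path)
    right = read_matrix(right_path)
    if left.row_labels != right.row_labels:
        raise ValidationError(
            "left and right matrices have different region labels; "
            "rows must be coupled")
    return JunctionMatrixPair(left, right)
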