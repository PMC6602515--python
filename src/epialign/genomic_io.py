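"""Reading and writing the standard genomic formats.

Covers BED6 / BED3+ (narrowPeak) region lists, FASTA slicing, peak-to-state
annotation, promoter extraction from a TSS table, and serialization of
alignment outcomes to TSV/JSON.  Coordinates are 0-based half-open (BED
convention) throughout.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_scoring import EpiRegion, GenomicInterval

logger = logging.getLogger("epialign")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class BedParseError(ValueError):
    """Malformed BED line; message carries the 1-based line number."""


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def read_bed6(path: Union[str, os.PathLike]) -> List[GenomicInterval]:
    """Parse a BED6 file into intervals, preserving input order.

    Lines must have >= 6 tab-separated columns; ``track``/``browser``
    header lines and blank lines are skipped.  Errors name the offending
    line number.
    """
    return _read_bed(path, min_cols=6)


def read_bed_peaks(path: Union[str, os.PathLike]) -> List[GenomicInterval]:
    """Parse a peak file: BED3 or wider (narrowPeak columns ignored)."""
    return _read_bed(path, min_cols=3)


def _read_bed(path: Union[str, os.PathLike], min_cols: int) -> List[GenomicInterval]:
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {min_cols} tab-separated "
                    f"columns, got {len(cols)}"
                )
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = cols[3] if len(cols) > 3 else "."
            try:
                score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = cols[5] if len(cols) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed6(intervals: Iterable[GenomicInterval], path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


@dataclass
class PeakSet:
    """Peak intervals indexed per chromosome, merged on construction.

    Overlapping or bookended peaks are unioned: the binary state model
    only asks whether a base is covered.
    """

    trees: Dict[str, IntervalTree]

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "PeakSet":
        trees: Dict[str, IntervalTree] = {}
        for iv in intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        for tree in trees.values():
            tree.merge_overlaps(strict=False)
        return cls(trees=trees)

    @classmethod
    def from_bed(cls, path: Union[str, os.PathLike]) -> "PeakSet":
        return cls.from_intervals(read_bed_peaks(path))

    @property
    def chroms(self) -> List[str]:
        return sorted(self.trees)

    def coverage(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Binary vector over [start, end): 1 where covered by a peak."""
        states = np.zeros(end - start, dtype=np.int8)
        tree = self.trees.get(chrom)
        if tree is None:
            return states
        for hit in tree.overlap(start, end):
            lo = max(hit.begin, start) - start
            hi = min(hit.end, end) - start
            states[lo:hi] = 1
        return states


def annotate_states(interval: GenomicInterval, seq: str, peaks: PeakSet) -> EpiRegion:
    """Overlay peak coverage on a region to build an :class:`EpiRegion`.

    ``states[i]`` is 1 iff reference base ``interval.start + i`` lies in a
    peak.  For minus-strand regions — whose ``seq`` is already reverse
    complemented — the state vector is reversed to match the sequence
    orientation.  A chromosome absent from the peak set yields all-zero
    states with a logged warning rather than an error.
    """
    if len(seq) != len(interval):
        raise ValueError(
            f"sequence length {len(seq)} != interval length {len(interval)}"
        )
    if peaks.trees and interval.chrom not in peaks.trees:
        logger.warning(
            "chromosome %r absent from peak set (has %s); states set to 0",
            interval.chrom,
            ",".join(peaks.chroms[:5]),
        )
    states = peaks.coverage(interval.chrom, interval.start, interval.end)
    if interval.strand == "-":
        states = states[::-1].copy()
    return EpiRegion(interval=interval, seq=seq, states=states)


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: gene name, chromosome, 0-based position, strand."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or - (got {self.strand!r})")


def read_tss_table(path: Union[str, os.PathLike]) -> List[TssRecord]:
    """Read a TSS table: 4 tab-separated columns gene, chrom, tss, strand."""
    out: List[TssRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                out.append(TssRecord(cols[0], cols[1], int(cols[2]), cols[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def extract_promoters(
    tss_records: Sequence[TssRecord],
    upstream: int = 1000,
    downstream: int = 500,
) -> List[GenomicInterval]:
    """Promoter windows around TSSs, strand-aware and clipped at 0.

    The default (-1000, +500) window spans 1000 bp upstream through
    500 bp downstream of the TSS in transcription direction: for a +
    strand gene ``[tss - upstream, tss + downstream)``, mirrored for -
    strand.  Records with an unknown strand are skipped with a warning.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    out: List[GenomicInterval] = []
    for rec in tss_records:
        if rec.strand == "+":
            start, end = rec.tss - upstream, rec.tss + downstream
        elif rec.strand == "-":
            start, end = rec.tss - downstream, rec.tss + upstream
        else:  # unreachable through TssRecord, but tolerate raw tuples
            logger.warning("skipping TSS %r: unknown strand %r", rec.gene, rec.strand)
            continue
        start = max(0, start)
        if end <= start:
            logger.warning("skipping TSS %r: empty promoter window", rec.gene)
            continue
        out.append(GenomicInterval(rec.chrom, start, end, rec.strand, rec.gene))
    return out


def slice_fasta(fasta: Union[Mapping[str, str], "object"], interval: GenomicInterval) -> str:
    """Extract the (strand-resolved) sequence of an interval.

    ``fasta`` may be a ``pyfaidx.Fasta`` handle or any mapping from
    chromosome name to sequence string.  Minus-strand intervals are
    reverse complemented; output is uppercase.
    """
    try:
        record = fasta[interval.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {interval.chrom!r} not in FASTA") from exc
    chrom_len = len(record)
    if interval.end > chrom_len:
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            f"out of bounds (chromosome length {chrom_len})"
        )
    seq = str(record[interval.start : interval.end]).upper()
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


def build_region(
    fasta,
    interval: GenomicInterval,
    peaks: PeakSet,
) -> EpiRegion:
    """Slice sequence and overlay peak states for one region."""
    return annotate_states(interval, slice_fasta(fasta, interval), peaks)


# --------------------------------------------------------------------------
# Result serialization

RESULT_COLUMNS = [
    "query_chrom", "query_start", "query_end", "query_name", "query_strand",
    "epi_hit_chrom", "epi_hit_start", "epi_hit_end",
    "T_epi", "S_epi", "E_epi",
    "T_epi_per_kb", "S_epi_per_kb", "snr_epi",
    "seq_hit_chrom", "seq_hit_start", "seq_hit_end",
    "S_seq", "T_seq", "E_seq",
    "S_seq_per_kb", "T_seq_per_kb", "snr_seq",
    "e_range_min", "e_range_max",
    "hits_overlap", "altered",
]


def outcomes_to_frame(outcomes: Iterable) -> pd.DataFrame:
    rows = [o.to_record() for o in outcomes]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(
    outcomes: Iterable,
    path: Union[str, os.PathLike],
    format: str = "tsv",
) -> None:
    """Write one row per query outcome as TSV or JSON.

    The JSON form is a list of records mirroring the TSV columns; numeric
    fields round-trip bit-exactly (floats serialised with repr precision).
    """
    frame = outcomes_to_frame(outcomes)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        records = frame.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown result format {format!r} (use tsv or json)")


def read_results_json(path: Union[str, os.PathLike]) -> List[dict]:
    with open(path) as fh:
        return json.load(fh)
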