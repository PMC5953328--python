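"""Sequence-read loading, minimal preprocessing, and QC statistics.

Implements the read-level subset of a repertoire-sequencing preprocessing
stage: FASTQ / FASTA / FASTA+QUAL loading (with transparent gzip and bzip2
decompression), mean-quality and length filtering, duplicate collapsing,
and the summary statistics used for pre/post-filter comparison charts —
read-length, GC-content and mean-quality histograms, per-position base
composition, and per-position quality quantiles (10th percentile, quartiles,
median, 90th percentile).

Conventions
-----------
* Phred scores are decoded with the +33 offset only; legacy +64 data is not
  autodetected.
* Mean read quality is the arithmetic mean of integer Phred scores.
* Quantiles use linear interpolation between order statistics (the common
  "type 7" rule, numpy's default).
* GC percent is ``100*(G+C)/(A+C+G+T)`` per read — ambiguous bases are
  excluded from the denominator — binned by ``floor``.  All-N reads have
  undefined GC content and are excluded from the GC histogram (counted in
  ``ReadStatistics.n_gc_undefined``).
"""

from __future__ import annotations

import bz2
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import PairedFastaQualIterator


class ReadFormatError(ValueError):
    """Raised for malformed or mismatched sequence-read files."""


class QualityDataError(ValueError):
    """Raised when a quality-based operation is asked of reads without
    quality scores."""


@dataclass
class SequenceRead:
    """A single sequencing read: bases over {A,C,G,T,N} plus optional
    Phred qualities of the same length."""

    read_id: str
    bases: str
    qualities: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ReadFormatError(
                f"read {self.read_id!r}: {len(self.qualities)} quality values "
                f"for {len(self.bases)} bases"
            )

    def mean_quality(self) -> float:
        if self.qualities is None:
            raise QualityDataError(
                f"read {self.read_id!r} carries no quality scores"
            )
        return float(np.mean(self.qualities)) if self.qualities else 0.0


@dataclass
class ReadStatistics:
    """Summary statistics for a read set (chart-ready aggregates)."""

    n_reads: int = 0
    length_histogram: Dict[int, int] = field(default_factory=dict)
    gc_histogram: Dict[int, int] = field(default_factory=dict)
    n_gc_undefined: int = 0
    mean_quality_histogram: Dict[int, int] = field(default_factory=dict)
    mean_quality_median: Optional[float] = None
    #: base letter -> per-position counts (index 0 = read position 1)
    base_composition: Dict[str, List[int]] = field(default_factory=dict)
    #: per position: (p10, q1, median, q3, p90); empty where no read with
    #: qualities covers the position
    quality_quantiles: List[Optional[Tuple[float, float, float, float, float]]] = field(
        default_factory=list
    )

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "length_histogram": dict(self.length_histogram),
            "gc_histogram": dict(self.gc_histogram),
            "n_gc_undefined": self.n_gc_undefined,
            "mean_quality_histogram": dict(self.mean_quality_histogram),
            "mean_quality_median": self.mean_quality_median,
            "base_composition": {k: list(v) for k, v in self.base_composition.items()},
            "quality_quantiles": [
                list(q) if q is not None else None for q in self.quality_quantiles
            ],
        }


@dataclass
class PrePostComparison:
    """Side-by-side statistics before and after filtering, with the
    per-length difference curve (pre count minus post count)."""

    pre: ReadStatistics
    post: ReadStatistics
    length_difference: Dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pre": self.pre.to_dict(),
            "post": self.post.to_dict(),
            "length_difference": dict(self.length_difference),
        }


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    if path.suffix == ".bz2":
        return bz2.open(path, "rt")
    return open(path, "r")


def load_reads(
    path,
    format: str = "fastq",
    qual_path=None,
) -> List[SequenceRead]:
    """Load reads from FASTQ, FASTA, or paired FASTA+QUAL files.

    Parameters
    ----------
    path
        Sequence file; ``.gz`` / ``.bz2`` suffixes are decompressed
        transparently.
    format
        One of ``"fastq"``, ``"fasta"``, ``"fasta+qual"``.
    qual_path
        The QUAL file, required for ``fasta+qual``.
    """
    if format == "fastq":
        reads: List[SequenceRead] = []
        with _open_text(path) as fh:
            iterator = SeqIO.parse(fh, "fastq")
            index = 0
            while True:
                try:
                    rec = next(iterator)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise ReadFormatError(
                        f"{path}: malformed FASTQ at record {index + 1}: {exc}"
                    ) from exc
                reads.append(
                    SequenceRead(
                        read_id=rec.id,
                        bases=str(rec.seq).upper(),
                        qualities=list(rec.letter_annotations["phred_quality"]),
                    )
                )
                index += 1
        return reads
    if format == "fasta":
        with _open_text(path) as fh:
            return [
                SequenceRead(read_id=rec.id, bases=str(rec.seq).upper())
                for rec in SeqIO.parse(fh, "fasta")
            ]
    if format == "fasta+qual":
        if qual_path is None:
            raise ValueError("format 'fasta+qual' requires qual_path")
        with _open_text(path) as fasta_fh, _open_text(qual_path) as qual_fh:
            try:
                return [
                    SequenceRead(
                        read_id=rec.id,
                        bases=str(rec.seq).upper(),
                        qualities=list(rec.letter_annotations["phred_quality"]),
                    )
                    for rec in PairedFastaQualIterator(fasta_fh, qual_fh)
                ]
            except ValueError as exc:
                raise ReadFormatError(
                    f"{path} / {qual_path}: FASTA/QUAL mismatch: {exc}"
                ) from exc
    raise ValueError(f"unknown read format {format!r}")


def write_fastq(reads: Sequence[SequenceRead], path) -> None:
    """Write reads as Phred+33 FASTQ (reads must carry qualities)."""
    with open(path, "w") as fh:
        for read in reads:
            if read.qualities is None:
                raise QualityDataError(
                    f"read {read.read_id!r} has no qualities; cannot write FASTQ"
                )
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_reads(
    reads: Sequence[SequenceRead],
    min_mean_quality: Optional[float],
    min_length: int,
) -> Tuple[List[SequenceRead], List[SequenceRead]]:
    """Partition reads into (kept, discarded).

    A read is discarded iff its mean quality is below ``min_mean_quality``
    (when that threshold is not ``None``) or its length is below
    ``min_length``.  Requesting the quality criterion on reads that carry no
    qualities raises :class:`QualityDataError`.
    """
    if min_length < 0 or (min_mean_quality is not None and min_mean_quality < 0):
        raise ValueError("thresholds must be non-negative")
    kept: List[SequenceRead] = []
    discarded: List[SequenceRead] = []
    for read in reads:
        fails = len(read.bases) < min_length
        if min_mean_quality is not None:
            fails = fails or read.mean_quality() < min_mean_quality
        (discarded if fails else kept).append(read)
    return kept, discarded


def collapse_duplicates(
    reads: Sequence[SequenceRead],
) -> List[Tuple[SequenceRead, int]]:
    """Collapse reads with identical base strings.

    Returns one ``(representative, copy_count)`` pair per distinct base
    string, in order of first occurrence; the representative is the first
    read seen with that sequence.  Copy counts sum to the input size.
    """
    order: List[str] = []
    groups: Dict[str, Tuple[SequenceRead, int]] = {}
    for read in reads:
        if read.bases in groups:
            rep, n = groups[read.bases]
            groups[read.bases] = (rep, n + 1)
        else:
            groups[read.bases] = (read, 1)
            order.append(read.bases)
    return [groups[bases] for bases in order]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

_QUANTILE_POINTS = (10.0, 25.0, 50.0, 75.0, 90.0)


def compute_read_statistics(reads: Sequence[SequenceRead]) -> ReadStatistics:
    """Single-pass summary statistics over a read set.

    Empty input yields zeroed statistics.  Positions beyond a read's length
    contribute nothing to per-position aggregates: the denominator at each
    position is the number of reads covering it.
    """
    stats = ReadStatistics(n_reads=len(reads))
    if not reads:
        return stats

    max_len = max(len(r.bases) for r in reads)
    composition = {b: [0] * max_len for b in "ACGTN"}
    per_position_quals: List[List[int]] = [[] for _ in range(max_len)]
    mean_quals: List[float] = []

    for read in reads:
        length = len(read.bases)
        stats.length_histogram[length] = stats.length_histogram.get(length, 0) + 1

        at = cg = 0
        for pos, base in enumerate(read.bases):
            counts = composition.get(base)
            if counts is None:  # non-ACGT symbols counted as ambiguous
                counts = composition["N"]
            counts[pos] += 1
            if base in "GC":
                cg += 1
            elif base in "AT":
                at += 1
        denom = at + cg
        if denom == 0:
            stats.n_gc_undefined += 1
        else:
            gc_bin = int(100.0 * cg / denom)
            stats.gc_histogram[gc_bin] = stats.gc_histogram.get(gc_bin, 0) + 1

        if read.qualities is not None:
            mq = read.mean_quality()
            mean_quals.append(mq)
            q_bin = int(mq)
            stats.mean_quality_histogram[q_bin] = (
                stats.mean_quality_histogram.get(q_bin, 0) + 1
            )
            for pos, q in enumerate(read.qualities):
                per_position_quals[pos].append(q)

    stats.base_composition = composition
    if mean_quals:
        stats.mean_quality_median = float(np.median(mean_quals))
    stats.quality_quantiles = [
        tuple(np.percentile(quals, _QUANTILE_POINTS)) if quals else None
        for quals in per_position_quals
    ]
    return stats


def compare_pre_post(
    pre_reads: Sequence[SequenceRead], post_reads: Sequence[SequenceRead]
) -> PrePostComparison:
    """Compute statistics for both read sets plus the per-length
    pre-minus-post difference curve over the union of observed lengths."""
    pre = compute_read_statistics(pre_reads)
    post = compute_read_statistics(post_reads)
    lengths = sorted(set(pre.length_histogram) | set(post.length_histogram))
    diff = {
        length: pre.length_histogram.get(length, 0)
        - post.length_histogram.get(length, 0)
        for length in lengths
    }
    return PrePostComparison(pre=pre, post=post, length_difference=diff)
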