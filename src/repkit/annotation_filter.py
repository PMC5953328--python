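"""Secondary filtering of annotated rearrangements with per-rule accounting.

After V(D)J gene assignment, a repertoire table still contains rearrangements
that are unusable for mutation analysis: frame-shifted alignments, out-of-frame
junctions, stop codons, truncated reads, poor germline identity, missing CDR3s,
incomplete V-gene coverage, and singleton reads likely to carry sequencing
errors.  This module removes them with plain logical tests on the annotation
fields and reports, for every rule, how many records violated it — a record
violating several rules increments each rule's counter but is removed once.

Rules are evaluated in full for every record (no short-circuiting) so the
report attributes every violation.  A record that lacks the field an enabled
rule needs is treated as violating that rule (strict policy: missing evidence
never passes).  Finally, samples whose surviving unique-record count falls
below a minimum are excluded altogether, since too-small repertoires cannot
support downstream statistics.

The V-gene coverage rule is expressed against a codon numbering scheme
(Chothia in the original analyses).  The numbering is pluggable: any mapping
from codon number to a germline nucleotide interval.  The default is the
identity numbering — codon ``c`` occupies germline nucleotides ``3c-2 .. 3c``
— which is an approximation suitable when the germline set is ungapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

from .airr_io import Rearrangement, records_by_sample


class FilterConfigError(ValueError):
    """Raised when an enabled rule cannot be evaluated on the given data."""


class NumberingError(ValueError):
    """Raised when a codon numbering lacks a codon required for coverage."""


#: Record-level rule names, in evaluation order.
RULE_NAMES: Tuple[str, ...] = (
    "frameshift_indels",
    "out_of_frame_junction",
    "stop_codon",
    "truncated_read_length",
    "v_identity",
    "missing_cdr3",
    "coverage",
    "duplicate_count",
)


@dataclass
class FilterConfig:
    """Thresholds and switches for the record-level rules plus the
    per-sample minimum.

    Defaults reproduce a stringent B-cell mutation-analysis setup: drop
    frame-shifted, out-of-frame or stopped rearrangements, require at least
    85% V-gene germline identity, a CDR3, read coverage of codons 31–92,
    at least two raw copies per unique read, and at least 10 surviving
    unique reads per sample.
    """

    exclude_frameshift_indels: bool = True
    require_in_frame_junction: bool = True
    exclude_stop_codon: bool = True
    min_read_length: Optional[int] = None
    min_v_identity: Optional[float] = 0.85
    require_cdr3: bool = True
    coverage_codon_range: Optional[Tuple[int, int]] = (31, 92)
    min_duplicate_count: int = 2
    min_unique_per_sample: int = 10

    def __post_init__(self) -> None:
        if self.min_read_length is not None and self.min_read_length < 0:
            raise ValueError("min_read_length must be non-negative")
        if self.min_v_identity is not None and self.min_v_identity < 0:
            raise ValueError("min_v_identity must be non-negative")
        if self.min_duplicate_count < 0 or self.min_unique_per_sample < 0:
            raise ValueError("counts must be non-negative")
        if (
            self.coverage_codon_range is not None
            and self.coverage_codon_range[0] > self.coverage_codon_range[1]
        ):
            # an inverted range covers no codons: vacuously satisfied
            self.coverage_codon_range = None


@dataclass
class FilterReport:
    """Accounting for one filtering pass."""

    n_input: int = 0
    n_kept: int = 0
    per_rule_violation_counts: Dict[str, int] = field(default_factory=dict)
    per_sample_kept: Dict[str, int] = field(default_factory=dict)
    excluded_samples: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "per_rule_violation_counts": dict(self.per_rule_violation_counts),
            "per_sample_kept": dict(self.per_sample_kept),
            "excluded_samples": list(self.excluded_samples),
        }


Numbering = Mapping[int, Tuple[int, int]]


def identity_numbering(codon_start: int, codon_end: int) -> Dict[int, Tuple[int, int]]:
    """The default codon numbering: codon ``c`` spans germline nucleotides
    ``3c-2 .. 3c`` (1-based, closed)."""
    return {c: (3 * c - 2, 3 * c) for c in range(codon_start, codon_end + 1)}


def check_coverage(
    record: Rearrangement,
    codon_start: int,
    codon_end: int,
    numbering: Optional[Numbering] = None,
) -> bool:
    """Does the read's V alignment span every nucleotide of codons
    ``codon_start .. codon_end`` of the germline, under ``numbering``?

    The record must carry ``v_germline_start`` / ``v_germline_end`` (the
    germline interval its V alignment covers).  An inverted codon range is
    vacuously covered.

    Raises
    ------
    NumberingError
        If the numbering lacks any codon in the range.
    """
    if codon_start > codon_end:
        return True
    if numbering is None:
        numbering = identity_numbering(codon_start, codon_end)
    need_start = None
    need_end = None
    for codon in range(codon_start, codon_end + 1):
        try:
            s, e = numbering[codon]
        except KeyError as exc:
            raise NumberingError(
                f"numbering does not define codon {codon}"
            ) from exc
        need_start = s if need_start is None else min(need_start, s)
        need_end = e if need_end is None else max(need_end, e)
    if record.v_germline_start is None or record.v_germline_end is None:
        return False
    return record.v_germline_start <= need_start and record.v_germline_end >= need_end


# ---------------------------------------------------------------------------
# per-rule predicates: True means the record VIOLATES the rule
# ---------------------------------------------------------------------------

def _violates_frameshift(rec: Rearrangement) -> bool:
    flag = rec.extra.get("v_frameshift")
    if flag is not None:
        return flag.strip().lower() in {"t", "true", "1"}
    if rec.sequence_alignment is None or rec.germline_alignment is None:
        return True  # cannot prove in-frame: strict policy
    insertions = rec.germline_alignment.count("-")
    deletions = rec.sequence_alignment.count("-")
    return insertions % 3 != 0 or deletions % 3 != 0


def _violates_out_of_frame(rec: Rearrangement) -> bool:
    return rec.vj_in_frame is not True


def _violates_stop_codon(rec: Rearrangement) -> bool:
    return rec.stop_codon is not False


def _violates_missing_cdr3(rec: Rearrangement) -> bool:
    return not rec.junction


def _rule_predicates(
    config: FilterConfig, numbering: Optional[Numbering]
) -> Dict[str, Callable[[Rearrangement], bool]]:
    predicates: Dict[str, Callable[[Rearrangement], bool]] = {}
    if config.exclude_frameshift_indels:
        predicates["frameshift_indels"] = _violates_frameshift
    if config.require_in_frame_junction:
        predicates["out_of_frame_junction"] = _violates_out_of_frame
    if config.exclude_stop_codon:
        predicates["stop_codon"] = _violates_stop_codon
    if config.min_read_length is not None:
        min_len = config.min_read_length
        predicates["truncated_read_length"] = (
            lambda rec: rec.sequence is None or len(rec.sequence) < min_len
        )
    if config.min_v_identity is not None:
        min_ident = config.min_v_identity
        predicates["v_identity"] = (
            lambda rec: rec.v_identity is None or rec.v_identity < min_ident
        )
    if config.require_cdr3:
        predicates["missing_cdr3"] = _violates_missing_cdr3
    if config.coverage_codon_range is not None:
        start, end = config.coverage_codon_range
        predicates["coverage"] = lambda rec: not check_coverage(
            rec, start, end, numbering
        )
    if config.min_duplicate_count > 0:
        min_dup = config.min_duplicate_count
        predicates["duplicate_count"] = lambda rec: rec.duplicate_count < min_dup
    return predicates


_RULE_FIELDS = {
    "frameshift_indels": ("sequence_alignment", "germline_alignment"),
    "out_of_frame_junction": ("vj_in_frame",),
    "stop_codon": ("stop_codon",),
    "truncated_read_length": ("sequence",),
    "v_identity": ("v_identity",),
    "missing_cdr3": ("junction",),
    "coverage": ("v_germline_start", "v_germline_end"),
    "duplicate_count": ("duplicate_count",),
}


def _check_fields_present(
    records: Sequence[Rearrangement], rules: Sequence[str]
) -> None:
    """An enabled rule whose required fields are absent on *every* record is
    a configuration error (the caller probably fed the wrong table)."""
    if not records:
        return
    for rule in rules:
        fields = _RULE_FIELDS[rule]
        if rule == "frameshift_indels" and any(
            "v_frameshift" in rec.extra for rec in records
        ):
            continue
        for fname in fields:
            if all(getattr(rec, fname) is None for rec in records):
                raise FilterConfigError(
                    f"rule {rule!r} is enabled but field {fname!r} is absent "
                    "on every record"
                )


def apply_filters(
    records: Sequence[Rearrangement],
    config: Optional[FilterConfig] = None,
    numbering: Optional[Numbering] = None,
) -> Tuple[List[Rearrangement], FilterReport]:
    """Apply all enabled record-level rules, then the per-sample minimum.

    Returns the kept records (input order preserved) and a
    :class:`FilterReport`.  ``per_rule_violation_counts`` counts every
    violation of every enabled rule; the ``min_unique_per_sample`` entry
    counts records dropped because their whole sample was excluded.
    """
    if config is None:
        config = FilterConfig()
    predicates = _rule_predicates(config, numbering)
    _check_fields_present(records, list(predicates))

    report = FilterReport(n_input=len(records))
    report.per_rule_violation_counts = {name: 0 for name in predicates}
    survivors: List[Rearrangement] = []
    for rec in records:
        violated = False
        for name, predicate in predicates.items():
            if predicate(rec):
                report.per_rule_violation_counts[name] += 1
                violated = True
        if not violated:
            survivors.append(rec)

    if config.min_unique_per_sample > 0:
        by_sample = records_by_sample(survivors)
        retained, excluded = filter_samples_min_unique(
            by_sample, config.min_unique_per_sample
        )
        excluded_set = set(excluded)
        n_dropped = sum(len(by_sample[s]) for s in excluded)
        kept = [rec for rec in survivors if (rec.sample_id or "") not in excluded_set]
        report.excluded_samples = excluded
        report.per_rule_violation_counts["min_unique_per_sample"] = n_dropped
    else:
        kept = survivors

    report.n_kept = len(kept)
    counts: Dict[str, int] = {}
    for rec in kept:
        key = rec.sample_id or ""
        counts[key] = counts.get(key, 0) + 1
    report.per_sample_kept = counts
    return kept, report


def filter_samples_min_unique(
    per_sample_records: Mapping[str, Sequence[Rearrangement]],
    min_unique: int,
) -> Tuple[List[str], List[str]]:
    """Split sample ids into (retained, excluded) by their unique-record
    count; a sample is retained iff it holds at least ``min_unique`` records.
    Both lists are sorted for reproducibility."""
    retained = sorted(
        s for s, recs in per_sample_records.items() if len(recs) >= min_unique
    )
    excluded = sorted(
        s for s, recs in per_sample_records.items() if len(recs) < min_unique
    )
    return retained, excluded
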