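"""Read and write AIRR rearrangement TSV and study-metadata TSV files.

The rearrangement table is the central exchange format of the package: one
row per annotated V(D)J rearrangement, header-driven, tab-delimited, using
the AIRR community column vocabulary.  The dialect is deliberately strict —
no quoting, tabs and newlines are forbidden inside values — so that a
write/read round trip is bit-exact for every populated field.

Coordinates (``fwr1_start`` .. ``cdr3_end``, ``v_germline_start/end``)
follow the AIRR convention: 1-based, closed intervals.  Tri-state booleans
(``productive``, ``stop_codon``, ``vj_in_frame``) serialize as ``T`` / ``F``
/ empty.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple


class AirrFormatError(ValueError):
    """Raised when a TSV file violates the expected rearrangement format."""


class SerializationError(ValueError):
    """Raised when a field value cannot be encoded in the strict TSV dialect."""


class MetadataError(ValueError):
    """Raised for malformed study-metadata tables."""


#: Ordered AIRR column vocabulary handled as first-class fields.
STANDARD_COLUMNS: Tuple[str, ...] = (
    "sequence_id",
    "sequence",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "stop_codon",
    "vj_in_frame",
    "v_identity",
    "sequence_alignment",
    "germline_alignment",
    "v_germline_start",
    "v_germline_end",
    "fwr1_start",
    "fwr1_end",
    "cdr1_start",
    "cdr1_end",
    "fwr2_start",
    "fwr2_end",
    "cdr2_start",
    "cdr2_end",
    "fwr3_start",
    "fwr3_end",
    "cdr3_start",
    "cdr3_end",
    "duplicate_count",
    "sample_id",
    "clone_id",
)

_BOOL_COLUMNS = frozenset({"productive", "stop_codon", "vj_in_frame"})
_INT_COLUMNS = frozenset(
    {
        "v_germline_start",
        "v_germline_end",
        "fwr1_start",
        "fwr1_end",
        "cdr1_start",
        "cdr1_end",
        "fwr2_start",
        "fwr2_end",
        "cdr2_start",
        "cdr2_end",
        "fwr3_start",
        "fwr3_end",
        "cdr3_start",
        "cdr3_end",
        "duplicate_count",
    }
)
_FLOAT_COLUMNS = frozenset({"v_identity"})

#: Region coordinate fields in biological 5'→3' order.
REGION_FIELDS: Tuple[str, ...] = (
    "fwr1_start",
    "fwr1_end",
    "cdr1_start",
    "cdr1_end",
    "fwr2_start",
    "fwr2_end",
    "cdr2_start",
    "cdr2_end",
    "fwr3_start",
    "fwr3_end",
    "cdr3_start",
    "cdr3_end",
)


@dataclass
class Rearrangement:
    """One annotated V(D)J rearrangement (one row of an AIRR TSV).

    Unknown columns from the file are preserved verbatim in ``extra`` and
    written back on serialization, so foreign annotations survive a round
    trip through this package.
    """

    sequence_id: str
    sequence: Optional[str] = None
    v_call: Optional[str] = None
    d_call: Optional[str] = None
    j_call: Optional[str] = None
    junction: Optional[str] = None
    junction_aa: Optional[str] = None
    productive: Optional[bool] = None
    stop_codon: Optional[bool] = None
    vj_in_frame: Optional[bool] = None
    v_identity: Optional[float] = None
    sequence_alignment: Optional[str] = None
    germline_alignment: Optional[str] = None
    v_germline_start: Optional[int] = None
    v_germline_end: Optional[int] = None
    fwr1_start: Optional[int] = None
    fwr1_end: Optional[int] = None
    cdr1_start: Optional[int] = None
    cdr1_end: Optional[int] = None
    fwr2_start: Optional[int] = None
    fwr2_end: Optional[int] = None
    cdr2_start: Optional[int] = None
    cdr2_end: Optional[int] = None
    fwr3_start: Optional[int] = None
    fwr3_end: Optional[int] = None
    cdr3_start: Optional[int] = None
    cdr3_end: Optional[int] = None
    duplicate_count: int = 1
    sample_id: Optional[str] = None
    clone_id: Optional[str] = None
    extra: Dict[str, str] = field(default_factory=dict)

    def region_boundaries(self) -> Dict[str, Tuple[int, int]]:
        """Region name → (start, end) in sequence_alignment coordinates.

        Only regions whose start and end are both populated are returned.
        """
        out: Dict[str, Tuple[int, int]] = {}
        for region in ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3", "cdr3"):
            s = getattr(self, f"{region}_start")
            e = getattr(self, f"{region}_end")
            if s is not None and e is not None:
                out[region.upper()] = (s, e)
        return out


@dataclass
class RepertoireSample:
    """One repertoire sample row from the study-metadata table."""

    sample_id: str
    subject_id: Optional[str] = None
    miairr_fields: Dict[str, str] = field(default_factory=dict)
    custom_fields: Dict[str, str] = field(default_factory=dict)


@dataclass
class SampleGroup:
    """A user-defined, named set of samples (e.g. Control vs Treatment)."""

    name: str
    sample_ids: List[str] = field(default_factory=list)


# Standard MiAIRR-style metadata column names recognised as such; everything
# else in a metadata file becomes a custom field.  All are optional.
STANDARD_METADATA_FIELDS = frozenset(
    {
        "sample_id",
        "subject_id",
        "study_id",
        "organism",
        "sex",
        "age",
        "tissue",
        "cell_subset",
        "cell_phenotype",
        "disease_diagnosis",
        "sample_type",
        "template_class",
        "library_generation_method",
        "sequencing_platform",
        "pcr_target_locus",
    }
)

DEFAULT_GROUP_COLUMN = "sample_group"


# ---------------------------------------------------------------------------
# value codecs
# ---------------------------------------------------------------------------

_TRUE_TOKENS = {"t", "true", "1"}
_FALSE_TOKENS = {"f", "false", "0"}


def _parse_bool(token: str, column: str, line_no: int) -> Optional[bool]:
    low = token.strip().lower()
    if low == "":
        return None
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise AirrFormatError(
        f"line {line_no}: cannot parse {column}={token!r} as a boolean"
    )


def _parse_cell(column: str, token: str, line_no: int):
    if column in _BOOL_COLUMNS:
        return _parse_bool(token, column, line_no)
    if token == "":
        return 1 if column == "duplicate_count" else None
    if column in _INT_COLUMNS:
        try:
            return int(token)
        except ValueError as exc:
            raise AirrFormatError(
                f"line {line_no}: cannot parse {column}={token!r} as an integer"
            ) from exc
    if column in _FLOAT_COLUMNS:
        try:
            return float(token)
        except ValueError as exc:
            raise AirrFormatError(
                f"line {line_no}: cannot parse {column}={token!r} as a number"
            ) from exc
    return token


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "T" if value else "F"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _check_encodable(text: str, column: str) -> str:
    if "\t" in text or "\n" in text or "\r" in text:
        raise SerializationError(
            f"value for column {column!r} contains a tab or newline, which the "
            "TSV dialect forbids"
        )
    return text


# ---------------------------------------------------------------------------
# rearrangement TSV
# ---------------------------------------------------------------------------

def read_rearrangements(path) -> List[Rearrangement]:
    """Parse an AIRR rearrangement TSV into a list of :class:`Rearrangement`.

    Row order is preserved.  Unknown columns are kept verbatim in
    ``Rearrangement.extra``.  A missing ``duplicate_count`` column (or empty
    cell) defaults to 1, matching the AIRR semantics of "at least the one
    observed read".

    Raises
    ------
    AirrFormatError
        If the ``sequence_id`` column is absent, or a data row has a
        different number of fields than the header (the message names the
        offending line number, 1-based including the header).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if header_line == "":
            raise AirrFormatError(f"{path}: empty file, expected a header row")
        header = header_line.rstrip("\r\n").split("\t")
        if "sequence_id" not in header:
            raise AirrFormatError(f"{path}: required column 'sequence_id' missing")
        known = set(STANDARD_COLUMNS)
        records: List[Rearrangement] = []
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if line == "":
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise AirrFormatError(
                    f"{path}: ragged row at line {line_no}: expected "
                    f"{len(header)} fields, found {len(cells)}"
                )
            kwargs: Dict[str, object] = {}
            extra: Dict[str, str] = {}
            for column, token in zip(header, cells):
                if column in known:
                    kwargs[column] = _parse_cell(column, token, line_no)
                elif token != "":
                    extra[column] = token
            if "duplicate_count" not in header:
                kwargs["duplicate_count"] = 1
            records.append(Rearrangement(extra=extra, **kwargs))  # type: ignore[arg-type]
    return records


def write_rearrangements(records: Sequence[Rearrangement], path) -> None:
    """Write records as an AIRR rearrangement TSV (header always emitted).

    Standard columns come first in AIRR vocabulary order, then any extra
    columns present on at least one record, in first-seen order.
    """
    extra_cols: List[str] = []
    seen = set()
    standard = set(STANDARD_COLUMNS)
    for rec in records:
        for name in rec.extra:
            if name in standard:
                raise SerializationError(
                    f"extra column {name!r} collides with a standard AIRR column"
                )
            if name not in seen:
                seen.add(name)
                extra_cols.append(name)
    header = list(STANDARD_COLUMNS) + extra_cols
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in records:
            cells = []
            for column in STANDARD_COLUMNS:
                cells.append(
                    _check_encodable(_format_cell(getattr(rec, column)), column)
                )
            for column in extra_cols:
                cells.append(
                    _check_encodable(_format_cell(rec.extra.get(column)), column)
                )
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# study metadata TSV
# ---------------------------------------------------------------------------

def read_metadata(
    path, group_column: str = DEFAULT_GROUP_COLUMN
) -> Tuple[List[RepertoireSample], List[SampleGroup]]:
    """Parse a study-metadata TSV: one row per sample.

    ``group_column`` may hold several semicolon-separated group labels; the
    returned groups are constructed from the union of labels, in first-seen
    order, each listing its member samples in file order.  A sample with an
    empty group cell belongs to no group but is still returned.

    Raises
    ------
    MetadataError
        On a missing ``sample_id`` column, a duplicate sample_id, or a
        ragged row.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if header_line == "":
            raise MetadataError(f"{path}: empty file, expected a header row")
        header = header_line.rstrip("\r\n").split("\t")
        if "sample_id" not in header:
            raise MetadataError(f"{path}: required column 'sample_id' missing")
        samples: List[RepertoireSample] = []
        seen_ids = set()
        group_members: Dict[str, List[str]] = {}
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if line == "":
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise MetadataError(
                    f"{path}: ragged row at line {line_no}: expected "
                    f"{len(header)} fields, found {len(cells)}"
                )
            row = dict(zip(header, cells))
            sample_id = row.pop("sample_id")
            if sample_id in seen_ids:
                raise MetadataError(f"{path}: duplicate sample_id {sample_id!r}")
            seen_ids.add(sample_id)
            subject_id = row.pop("subject_id", "") or None
            labels = [
                lab.strip()
                for lab in row.pop(group_column, "").split(";")
                if lab.strip()
            ]
            miairr = {
                k: v
                for k, v in row.items()
                if k in STANDARD_METADATA_FIELDS and v != ""
            }
            custom = {
                k: v
                for k, v in row.items()
                if k not in STANDARD_METADATA_FIELDS and v != ""
            }
            samples.append(
                RepertoireSample(
                    sample_id=sample_id,
                    subject_id=subject_id,
                    miairr_fields=miairr,
                    custom_fields=custom,
                )
            )
            for lab in labels:
                group_members.setdefault(lab, []).append(sample_id)
    groups = [SampleGroup(name=n, sample_ids=ids) for n, ids in group_members.items()]
    return samples, groups


def write_metadata(
    samples: Sequence[RepertoireSample],
    groups: Sequence[SampleGroup],
    path,
    group_column: str = DEFAULT_GROUP_COLUMN,
) -> None:
    """Write samples (and their group memberships) back to a metadata TSV."""
    membership: Dict[str, List[str]] = {}
    for grp in groups:
        for sid in grp.sample_ids:
            membership.setdefault(sid, []).append(grp.name)

    miairr_cols: List[str] = []
    custom_cols: List[str] = []
    for sample in samples:
        for k in sample.miairr_fields:
            if k not in miairr_cols:
                miairr_cols.append(k)
        for k in sample.custom_fields:
            if k not in custom_cols:
                custom_cols.append(k)
    header = ["sample_id", "subject_id", group_column] + miairr_cols + custom_cols
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for sample in samples:
            cells = [
                _check_encodable(sample.sample_id, "sample_id"),
                _check_encodable(sample.subject_id or "", "subject_id"),
                ";".join(membership.get(sample.sample_id, [])),
            ]
            for k in miairr_cols:
                cells.append(
                    _check_encodable(sample.miairr_fields.get(k, ""), k)
                )
            for k in custom_cols:
                cells.append(
                    _check_encodable(sample.custom_fields.get(k, ""), k)
                )
            fh.write("\t".join(cells) + "\n")


def records_by_sample(
    records: Sequence[Rearrangement],
) -> Dict[str, List[Rearrangement]]:
    """Group rearrangements by ``sample_id`` (records without one share the
    empty-string key), preserving record order within each sample."""
    out: Dict[str, List[Rearrangement]] = {}
    for rec in records:
        out.setdefault(rec.sample_id or "", []).append(rec)
    return out
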