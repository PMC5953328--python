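"""Comparison of repertoire characteristics across samples and groups.

Two kinds of comparison are supported, mirroring how repertoire studies
contrast user-defined sample groups (e.g. treated vs control animals):

* **Numeric aggregation** — for per-sample category→value tables (gene
  usage fractions, CDR3-length fractions, ...), the group mean, sample
  variance (n−1 denominator) and SD per category.  A category absent from a
  sample is a genuine zero, not missing data, so group means of relative
  tables stay normalized.

* **Sharing analysis** — for per-sample combination-key tables
  (V–J, V–J–CDR3, ...), the *sharing level* of each key within a group
  (how many samples contain it: level 1 is intragroup unique, ≥2 is
  intragroup shared) and, between two disjoint groups, the intergroup
  classification: a key present in at least one sample of both groups is
  intergroup shared, otherwise unique to the group containing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .airr_io import Rearrangement, SampleGroup


class GroupError(ValueError):
    """Raised for malformed group definitions or missing sample tables."""


@dataclass
class GroupStatistic:
    """Mean/variance/SD of one category across a group's samples."""

    category: object
    per_sample_values: Dict[str, float]
    mean: float
    variance: Optional[float]  # None for single-sample groups (undefined)
    sd: Optional[float]


@dataclass
class SharingRecord:
    """One combination key with its per-sample abundance and sharing
    classification."""

    key: tuple
    per_sample_abundance: Dict[str, int]
    sharing_level: int
    group_size: int
    intragroup_class: str  # "unique" | "shared"
    intergroup_class: Optional[str] = None  # "unique-to-A"|"unique-to-B"|"shared"
    group_sharing_levels: Dict[str, int] = field(default_factory=dict)


def aggregate_group(
    per_sample_tables: Mapping[str, Mapping[object, float]],
    group: SampleGroup,
) -> List[GroupStatistic]:
    """Per-category mean, sample variance and SD over a group's samples.

    The category universe is the union over the group's samples; a sample
    lacking a category contributes 0.  Variance uses the n−1 denominator
    and is reported as None (undefined) for single-sample groups.
    """
    if not group.sample_ids:
        raise GroupError(f"group {group.name!r} has no samples")
    for sid in group.sample_ids:
        if sid not in per_sample_tables:
            raise GroupError(
                f"group {group.name!r}: no table for sample {sid!r}"
            )
    categories: List[object] = []
    seen = set()
    for sid in group.sample_ids:
        for cat in per_sample_tables[sid]:
            if cat not in seen:
                seen.add(cat)
                categories.append(cat)
    n = len(group.sample_ids)
    stats: List[GroupStatistic] = []
    for cat in categories:
        values = {
            sid: float(per_sample_tables[sid].get(cat, 0.0))
            for sid in group.sample_ids
        }
        vec = list(values.values())
        mean = sum(vec) / n
        if n > 1:
            variance = sum((v - mean) ** 2 for v in vec) / (n - 1)
            sd = math.sqrt(variance)
        else:
            variance = None
            sd = None
        stats.append(
            GroupStatistic(
                category=cat,
                per_sample_values=values,
                mean=mean,
                variance=variance,
                sd=sd,
            )
        )
    return stats


KeyTables = Mapping[str, Mapping[tuple, int]]


def intragroup_sharing(
    per_sample_keys: KeyTables,
    group: SampleGroup,
) -> List[SharingRecord]:
    """Sharing level of every key present in at least one group sample.

    Keys are emitted in deterministic (sorted) order.  A key's sharing
    level is the number of group samples containing it; level 1 is
    classified intragroup unique, anything higher intragroup shared.
    """
    if not group.sample_ids:
        raise GroupError(f"group {group.name!r} has no samples")
    for sid in group.sample_ids:
        if sid not in per_sample_keys:
            raise GroupError(
                f"group {group.name!r}: no key table for sample {sid!r}"
            )
    all_keys = set()
    for sid in group.sample_ids:
        all_keys.update(per_sample_keys[sid])
    records: List[SharingRecord] = []
    for key in sorted(all_keys):
        abundance = {
            sid: per_sample_keys[sid][key]
            for sid in group.sample_ids
            if key in per_sample_keys[sid]
        }
        level = len(abundance)
        records.append(
            SharingRecord(
                key=key,
                per_sample_abundance=abundance,
                sharing_level=level,
                group_size=len(group.sample_ids),
                intragroup_class="unique" if level == 1 else "shared",
            )
        )
    return records


def intergroup_compare(
    per_sample_keys: KeyTables,
    group_a: SampleGroup,
    group_b: SampleGroup,
) -> List[SharingRecord]:
    """Classify every key in the union of two disjoint groups.

    A key present in ≥1 sample of both groups is ``shared``; otherwise it is
    ``unique-to-<group>``.  Each record keeps per-sample abundances (over
    both groups) and the per-group sharing levels.
    """
    overlap = set(group_a.sample_ids) & set(group_b.sample_ids)
    if overlap:
        raise GroupError(
            f"groups {group_a.name!r} and {group_b.name!r} share samples: "
            f"{sorted(overlap)}"
        )
    for grp in (group_a, group_b):
        if not grp.sample_ids:
            raise GroupError(f"group {grp.name!r} has no samples")
        for sid in grp.sample_ids:
            if sid not in per_sample_keys:
                raise GroupError(
                    f"group {grp.name!r}: no key table for sample {sid!r}"
                )
    all_keys = set()
    for grp in (group_a, group_b):
        for sid in grp.sample_ids:
            all_keys.update(per_sample_keys[sid])
    records: List[SharingRecord] = []
    for key in sorted(all_keys):
        abundance: Dict[str, int] = {}
        levels = {group_a.name: 0, group_b.name: 0}
        for grp in (group_a, group_b):
            for sid in grp.sample_ids:
                if key in per_sample_keys[sid]:
                    abundance[sid] = per_sample_keys[sid][key]
                    levels[grp.name] += 1
        in_a = levels[group_a.name] > 0
        in_b = levels[group_b.name] > 0
        if in_a and in_b:
            cls = "shared"
        elif in_a:
            cls = f"unique-to-{group_a.name}"
        else:
            cls = f"unique-to-{group_b.name}"
        total_level = levels[group_a.name] + levels[group_b.name]
        records.append(
            SharingRecord(
                key=key,
                per_sample_abundance=abundance,
                sharing_level=total_level,
                group_size=len(group_a.sample_ids) + len(group_b.sample_ids),
                intragroup_class="unique" if total_level == 1 else "shared",
                intergroup_class=cls,
                group_sharing_levels=levels,
            )
        )
    return records


def cross_sample_dedup(
    per_sample_records: Mapping[str, Sequence[Rearrangement]],
) -> Tuple[Dict[str, List[Rearrangement]], int]:
    """Drop records whose exact nucleotide sequence occurs in two or more
    samples (a pre-step for classifier workflows that must not learn
    sample-shared reads).  Returns the filtered mapping and the number of
    removed records."""
    seen_in: Dict[str, set] = {}
    for sid, recs in per_sample_records.items():
        for rec in recs:
            if rec.sequence:
                seen_in.setdefault(rec.sequence, set()).add(sid)
    shared = {seq for seq, sids in seen_in.items() if len(sids) >= 2}
    out: Dict[str, List[Rearrangement]] = {}
    n_removed = 0
    for sid, recs in per_sample_records.items():
        kept = [rec for rec in recs if rec.sequence not in shared]
        n_removed += len(recs) - len(kept)
        out[sid] = kept
    return out, n_removed
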