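"""Replacement/silent somatic-mutation analysis on paired alignments.

Given an observed sequence alignment and the germline alignment it was
called against (equal-length gapped strings), every position where both
carry a determined, non-gap base and the bases differ is a point mutation.
Each mutation is classified at the codon level: the full germline codon is
translated against the fully-observed codon (all substitutions in that codon
applied at once), and the mutation is *replacement* if the amino acids
differ, *silent* otherwise.  Every nucleotide record in a multiply-mutated
codon carries the codon's class, which keeps nucleotide-level and
codon-level tallies consistent.

Codons containing a gap or an N in either string are *non-informative*:
they yield no calls and their positions are excluded from frequency
denominators, so ambiguity never inflates mutation frequencies.

Summaries report, per region (FWR1..CDR3) and for the whole V gene
(FWR1–FWR3; CDR3 and anything downstream is junction diversity, not
mutation evidence), the replacement and silent counts, the mutation
frequency (mutated positions / informative positions) and the R:S ratio
(flagged undefined, not infinite, when no silent mutations exist).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

REGIONS = ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3", "CDR3")
#: Regions contributing to the whole-V summary.
V_REGIONS = ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3")
UNASSIGNED = "unassigned"

_GAPS = frozenset("-.")
_DETERMINED = frozenset("ACGT")


class AlignmentError(ValueError):
    """Raised for unusable alignment pairs."""


@dataclass(frozen=True)
class Mutation:
    """One nucleotide substitution, classified at the codon level."""

    alignment_position: int  # 1-based into the gapped alignment
    germline_base: str
    observed_base: str
    codon_number: int
    region: str
    codon_class: str  # "replacement" | "silent"


@dataclass
class RegionMutationStats:
    n_replacement: int = 0
    n_silent: int = 0
    n_informative_positions: int = 0

    @property
    def mutation_frequency(self) -> float:
        if self.n_informative_positions == 0:
            return 0.0
        return (self.n_replacement + self.n_silent) / self.n_informative_positions

    @property
    def rs_ratio(self) -> Optional[float]:
        """Replacement:silent ratio; None when undefined (no silent
        mutations)."""
        if self.n_silent == 0:
            return None
        return self.n_replacement / self.n_silent


@dataclass
class MutationSummary:
    per_region: Dict[str, RegionMutationStats] = field(default_factory=dict)
    whole_v: RegionMutationStats = field(default_factory=RegionMutationStats)

    def to_rows(self) -> List[Tuple[str, int, int, int, float, Optional[float]]]:
        rows = []
        for name, st in list(self.per_region.items()) + [("V", self.whole_v)]:
            rows.append(
                (
                    name,
                    st.n_replacement,
                    st.n_silent,
                    st.n_informative_positions,
                    st.mutation_frequency,
                    st.rs_ratio,
                )
            )
        return rows


RegionBoundaries = Mapping[str, Tuple[int, int]]


def _region_of(position: int, boundaries: RegionBoundaries) -> str:
    for name, (start, end) in boundaries.items():
        if start <= position <= end:
            return name.upper()
    return UNASSIGNED


def _iter_codons(
    sequence_alignment: str,
    germline_alignment: str,
    reading_frame_offset: int,
):
    """Yield (codon_number, positions, germ_codon, obs_codon, informative)
    for every complete codon in the alignment."""
    length = len(sequence_alignment)
    codon_number = 0
    start = reading_frame_offset
    while start + 2 <= length - 1 + 1:  # positions are 1-based
        positions = (start, start + 1, start + 2)
        if positions[2] > length:
            break
        codon_number += 1
        germ = germline_alignment[start - 1 : start + 2]
        obs = sequence_alignment[start - 1 : start + 2]
        informative = all(b in _DETERMINED for b in germ) and all(
            b in _DETERMINED for b in obs
        )
        yield codon_number, positions, germ, obs, informative
        start += 3


def call_mutations(
    sequence_alignment: str,
    germline_alignment: str,
    region_boundaries: Optional[RegionBoundaries] = None,
    reading_frame_offset: int = 1,
) -> List[Mutation]:
    """Identify and classify point mutations between the two alignments.

    ``reading_frame_offset`` is the 1-based alignment position where codon 1
    begins.  Positions in codons containing a gap or N (in either string)
    produce no calls.
    """
    if len(sequence_alignment) != len(germline_alignment):
        raise AlignmentError(
            f"alignment lengths differ: {len(sequence_alignment)} vs "
            f"{len(germline_alignment)}"
        )
    if not (1 <= reading_frame_offset <= max(len(sequence_alignment), 1)):
        raise AlignmentError(
            f"reading_frame_offset {reading_frame_offset} outside alignment"
        )
    boundaries = region_boundaries or {}
    mutations: List[Mutation] = []
    for codon_number, positions, germ, obs, informative in _iter_codons(
        sequence_alignment, germline_alignment, reading_frame_offset
    ):
        if not informative:
            continue
        if germ == obs:
            continue
        germ_aa = str(Seq(germ).translate())
        obs_aa = str(Seq(obs).translate())
        codon_class = "silent" if germ_aa == obs_aa else "replacement"
        for pos, gb, ob in zip(positions, germ, obs):
            if gb != ob:
                mutations.append(
                    Mutation(
                        alignment_position=pos,
                        germline_base=gb,
                        observed_base=ob,
                        codon_number=codon_number,
                        region=_region_of(pos, boundaries),
                        codon_class=codon_class,
                    )
                )
    return mutations


def count_informative_positions(
    sequence_alignment: str,
    germline_alignment: str,
    region_boundaries: Optional[RegionBoundaries] = None,
    reading_frame_offset: int = 1,
) -> Dict[str, int]:
    """Informative-position counts per region (positions in fully
    determined codons), including an ``unassigned`` bucket."""
    if len(sequence_alignment) != len(germline_alignment):
        raise AlignmentError(
            f"alignment lengths differ: {len(sequence_alignment)} vs "
            f"{len(germline_alignment)}"
        )
    boundaries = region_boundaries or {}
    counts: Dict[str, int] = {}
    for _, positions, _, _, informative in _iter_codons(
        sequence_alignment, germline_alignment, reading_frame_offset
    ):
        if not informative:
            continue
        for pos in positions:
            region = _region_of(pos, boundaries)
            counts[region] = counts.get(region, 0) + 1
    return counts


def summarize_mutations(
    mutations: Sequence[Mutation],
    region_boundaries: Optional[RegionBoundaries] = None,
    n_informative_per_region: Optional[Mapping[str, int]] = None,
) -> MutationSummary:
    """Tally mutations per region and for the whole V gene.

    ``n_informative_per_region`` should come from
    :func:`count_informative_positions` on the same alignment.  Mutations
    whose region is not a known boundary name are kept under
    ``unassigned`` (never dropped).
    """
    informative = dict(n_informative_per_region or {})
    summary = MutationSummary()
    region_names = list(REGIONS) + [UNASSIGNED]
    for name in region_names:
        summary.per_region[name] = RegionMutationStats(
            n_informative_positions=informative.get(name, 0)
        )
    known = set(summary.per_region)
    for mut in mutations:
        region = mut.region if mut.region in known else UNASSIGNED
        st = summary.per_region[region]
        if mut.codon_class == "replacement":
            st.n_replacement += 1
        else:
            st.n_silent += 1
    for name in V_REGIONS:
        st = summary.per_region[name]
        summary.whole_v.n_replacement += st.n_replacement
        summary.whole_v.n_silent += st.n_silent
        summary.whole_v.n_informative_positions += st.n_informative_positions
    return summary


def analyze_record(record, reading_frame_offset: int = 1) -> MutationSummary:
    """Convenience: call and summarize mutations for one rearrangement
    (using its region coordinates, which index the sequence alignment)."""
    if record.sequence_alignment is None or record.germline_alignment is None:
        raise AlignmentError(
            f"record {record.sequence_id!r} lacks alignment strings"
        )
    boundaries = record.region_boundaries()
    muts = call_mutations(
        record.sequence_alignment,
        record.germline_alignment,
        boundaries,
        reading_frame_offset,
    )
    informative = count_informative_positions(
        record.sequence_alignment,
        record.germline_alignment,
        boundaries,
        reading_frame_offset,
    )
    return summarize_mutations(muts, boundaries, informative)
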