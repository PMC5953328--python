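"""Per-sample repertoire characterization.

Covers the descriptive statistics a repertoire study reports for each
sample:

* gene-segment usage at any level of the IMGT nomenclature hierarchy
  (locus → family → gene → allele), absolute or relative;
* usage of V–J / V–D–J / V–J–CDR3 combinations;
* clonal grouping by shared V/J genes and junction similarity
  (single-linkage at a Hamming-distance threshold);
* ranked and cumulative clonal abundance;
* the Hill-number diversity profile over a sweep of the order parameter q,
  generalizing richness (q=0), exponential Shannon entropy (q=1) and the
  inverse Simpson index (q=2);
* CDR3 length, amino-acid composition, and physicochemical properties
  (Kyte–Doolittle hydropathy, Henderson–Hasselbalch net charge, aromaticity).

Multi-call fields ("IGHV1-69*02,IGHV1-69*04") are handled by policy:
``first_call`` trusts the aligner's ranking, ``fractional`` spreads a
record's weight over its distinct calls, ``drop_ambiguous`` discards
ambiguous records from the tally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .airr_io import Rearrangement


class GeneCallError(ValueError):
    """Raised for gene-call strings that do not follow IMGT nomenclature."""


class CloneConfigError(ValueError):
    """Raised for inconsistent clone-assignment settings."""


# ---------------------------------------------------------------------------
# gene-call grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneCall:
    """A decomposed IMGT gene call; ``gene`` starts with ``family``, which
    starts with ``locus``."""

    locus: str
    family: str
    gene: str
    allele: Optional[str] = None

    def at_level(self, level: str) -> str:
        if level == "locus":
            return self.locus
        if level == "family":
            return self.family
        if level == "gene":
            return self.gene
        if level == "allele":
            return self.gene + (self.allele or "")
        raise ValueError(f"unknown hierarchy level {level!r}")


_GENE_RE = re.compile(
    r"^(?P<locus>IG[HKL]|TR[ABGD])"
    r"(?P<segment>[VDJC])"
    r"(?P<family>[A-Za-z0-9]+)"
    r"(?P<genepart>(?:[-/][A-Za-z0-9.]+)*)"
    r"(?:\*(?P<allele>[0-9A-Za-z_]+))?$"
)


def parse_gene_call(text: str) -> List[GeneCall]:
    """Decompose a (possibly multi-valued, comma-separated) gene-call string.

    >>> parse_gene_call("IGHV3-23*01")[0]
    GeneCall(locus='IGH', family='IGHV3', gene='IGHV3-23', allele='*01')
    """
    calls: List[GeneCall] = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        m = _GENE_RE.match(token)
        if m is None:
            raise GeneCallError(f"cannot parse gene call {token!r}")
        locus = m.group("locus")
        family = locus + m.group("segment") + m.group("family")
        gene = family + m.group("genepart")
        allele = f"*{m.group('allele')}" if m.group("allele") else None
        calls.append(GeneCall(locus=locus, family=family, gene=gene, allele=allele))
    if not calls:
        raise GeneCallError(f"empty gene-call string {text!r}")
    return calls


# ---------------------------------------------------------------------------
# gene usage
# ---------------------------------------------------------------------------

@dataclass
class GeneUsageTable:
    segment: str
    level: str
    mode: str
    entries: Dict[str, float]
    n_assigned: int
    ambiguous_policy: str

    def to_rows(self) -> List[Tuple[str, float]]:
        return sorted(self.entries.items())


_SEGMENT_FIELD = {"V": "v_call", "D": "d_call", "J": "j_call"}


def _record_level_names(
    rec: Rearrangement, segment: str, level: str
) -> Optional[List[str]]:
    """Distinct names at ``level`` for the record's call, preserving call
    order; None when the call field is empty."""
    call = getattr(rec, _SEGMENT_FIELD[segment])
    if not call:
        return None
    names: List[str] = []
    for gc in parse_gene_call(call):
        name = gc.at_level(level)
        if name not in names:
            names.append(name)
    return names


def compute_gene_usage(
    records: Sequence[Rearrangement],
    segment: str = "V",
    level: str = "gene",
    mode: str = "relative",
    policy: str = "first_call",
) -> GeneUsageTable:
    """Tally gene-segment usage at a hierarchy level.

    ``n_assigned`` counts records contributing to the tally.  In
    ``relative`` mode entries are divided by ``n_assigned``.  Under the
    ``fractional`` policy a record with k distinct names at the level
    contributes 1/k to each.
    """
    segment = segment.upper()
    if segment not in _SEGMENT_FIELD:
        raise ValueError(f"segment must be V, D or J, got {segment!r}")
    if policy not in {"first_call", "fractional", "drop_ambiguous"}:
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    if mode not in {"absolute", "relative"}:
        raise ValueError(f"mode must be 'absolute' or 'relative', got {mode!r}")
    if records and all(
        not getattr(rec, _SEGMENT_FIELD[segment]) for rec in records
    ):
        raise ValueError(
            f"field {_SEGMENT_FIELD[segment]!r} is empty on every record"
        )

    entries: Dict[str, float] = {}
    n_assigned = 0
    for rec in records:
        names = _record_level_names(rec, segment, level)
        if names is None:
            continue
        if policy == "first_call":
            contributions = {names[0]: 1.0}
        elif policy == "fractional":
            contributions = {name: 1.0 / len(names) for name in names}
        else:  # drop_ambiguous
            if len(names) > 1:
                continue
            contributions = {names[0]: 1.0}
        n_assigned += 1
        for name, w in contributions.items():
            entries[name] = entries.get(name, 0.0) + w

    if mode == "relative" and n_assigned > 0:
        entries = {k: v / n_assigned for k, v in entries.items()}
    return GeneUsageTable(
        segment=segment,
        level=level,
        mode=mode,
        entries=entries,
        n_assigned=n_assigned,
        ambiguous_policy=policy,
    )


# ---------------------------------------------------------------------------
# combination usage
# ---------------------------------------------------------------------------

KEY_TYPES = ("VJ", "VDJ", "VJ_CDR3aa", "VJ_CDR3nt")


def combination_usage(
    records: Sequence[Rearrangement],
    key_type: str = "VJ",
    level: str = "gene",
    policy: str = "first_call",
) -> Tuple[Dict[tuple, int], int]:
    """Count V–J / V–D–J / V–J–CDR3 combinations.

    Keys are tuples of gene names at ``level`` (first-call resolution of
    ambiguous calls by default) plus, for the CDR3 key types, the junction
    string at the amino-acid or nucleotide sequence level.  Records lacking
    any required component are excluded; the second return value counts
    them.
    """
    if key_type not in KEY_TYPES:
        raise ValueError(f"unknown key type {key_type!r}")
    counts: Dict[tuple, int] = {}
    n_excluded = 0
    for rec in records:
        parts: List[str] = []
        ok = True
        for seg in ("V", "D", "J") if key_type == "VDJ" else ("V", "J"):
            names = _record_level_names(rec, seg, level)
            if names is None:
                ok = False
                break
            parts.append(names[0])
        if ok and key_type == "VJ_CDR3aa":
            if rec.junction_aa:
                parts.append(rec.junction_aa)
            else:
                ok = False
        if ok and key_type == "VJ_CDR3nt":
            if rec.junction:
                parts.append(rec.junction)
            else:
                ok = False
        if not ok:
            n_excluded += 1
            continue
        key = tuple(parts)
        counts[key] = counts.get(key, 0) + 1
    return counts, n_excluded


# ---------------------------------------------------------------------------
# clone assignment
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def assign_clones(
    records: Sequence[Rearrangement],
    same_v_gene: bool = True,
    same_j_gene: bool = True,
    same_junction_length: bool = True,
    max_junction_hamming: int = 0,
) -> Tuple[List[Rearrangement], List[Rearrangement]]:
    """Group records into clones; returns (assigned, unassigned).

    Records agreeing on every enabled key (V gene, J gene, junction length)
    are single-linkage clustered on junction-nucleotide Hamming distance at
    threshold ``max_junction_hamming``.  Clone ids are deterministic:
    clusters are ordered by the lexicographically smallest ``sequence_id``
    of their members and labelled ``clone_0001`` onward.  ``clone_id`` is
    set in place on the assigned records.  Records without a junction are
    returned unassigned.
    """
    if max_junction_hamming > 0 and not same_junction_length:
        raise CloneConfigError(
            "a positive Hamming threshold requires same_junction_length "
            "(Hamming distance is defined only for equal lengths)"
        )
    assigned = [rec for rec in records if rec.junction]
    unassigned = [rec for rec in records if not rec.junction]

    # partition by the enabled keys
    partitions: Dict[tuple, List[Rearrangement]] = {}
    for rec in assigned:
        key_parts: List[object] = []
        if same_v_gene:
            names = _record_level_names(rec, "V", "gene")
            key_parts.append(names[0] if names else None)
        if same_j_gene:
            names = _record_level_names(rec, "J", "gene")
            key_parts.append(names[0] if names else None)
        if same_junction_length:
            key_parts.append(len(rec.junction))  # type: ignore[arg-type]
        partitions.setdefault(tuple(key_parts), []).append(rec)

    clusters: List[List[Rearrangement]] = []
    for members in partitions.values():
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i].junction, members[j].junction
                if len(a) == len(b) and _hamming(a, b) <= max_junction_hamming:
                    uf.union(i, j)
        roots: Dict[int, List[Rearrangement]] = {}
        for i, rec in enumerate(members):
            roots.setdefault(uf.find(i), []).append(rec)
        clusters.extend(roots.values())

    clusters.sort(key=lambda ms: min(rec.sequence_id for rec in ms))
    width = max(4, len(str(len(clusters))))
    for idx, members in enumerate(clusters, start=1):
        cid = f"clone_{idx:0{width}d}"
        for rec in members:
            rec.clone_id = cid
    return assigned, unassigned


# ---------------------------------------------------------------------------
# clonal abundance
# ---------------------------------------------------------------------------

@dataclass
class ClonalAbundance:
    """Clones ranked by descending abundance with relative and cumulative
    fractions."""

    ranked: List[Tuple[str, float, float]]  # (clone_id, count, fraction)
    cumulative: List[float]


def clonal_abundance(
    records: Sequence[Rearrangement], weight: str = "duplicate_count"
) -> ClonalAbundance:
    """Aggregate record weights per clone and rank clones by abundance.

    ``weight`` is ``"duplicate_count"`` (each record contributes its raw
    copy number) or ``"unique"`` (each record contributes 1).  Ties in
    count are broken lexicographically by clone id for reproducibility.
    """
    if weight not in {"duplicate_count", "unique"}:
        raise ValueError(f"unknown weighting {weight!r}")
    totals: Dict[str, float] = {}
    for rec in records:
        if rec.clone_id is None:
            raise ValueError(f"record {rec.sequence_id!r} has no clone_id")
        w = rec.duplicate_count if weight == "duplicate_count" else 1
        totals[rec.clone_id] = totals.get(rec.clone_id, 0.0) + w
    grand = sum(totals.values())
    order = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    ranked = [(cid, cnt, cnt / grand) for cid, cnt in order]
    cumulative: List[float] = []
    acc = 0.0
    for _, _, frac in ranked:
        acc += frac
        cumulative.append(acc)
    return ClonalAbundance(ranked=ranked, cumulative=cumulative)


# ---------------------------------------------------------------------------
# diversity profile
# ---------------------------------------------------------------------------

@dataclass
class DiversityProfile:
    """Hill diversity numbers over a sweep of the order parameter q."""

    points: List[Tuple[float, float]]
    shannon_entropy: float

    def named_indices(self) -> Dict[str, float]:
        """Richness, exp(Shannon) and inverse Simpson as named values."""
        lookup = dict(self.points)
        out = {}
        for name, q in (("richness", 0.0), ("exp_shannon", 1.0), ("inverse_simpson", 2.0)):
            if q in lookup:
                out[name] = lookup[q]
        return out


DEFAULT_Q_GRID = [round(0.1 * i, 10) for i in range(41)]  # 0.0 .. 4.0


def hill_number(fractions: Sequence[float], q: float) -> float:
    """The Hill diversity number of order q:
    ``(sum p_i^q)^(1/(1-q))`` for q != 1, and its limit ``exp(-sum p ln p)``
    at q = 1."""
    p = np.asarray(fractions, dtype=float)
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 0.0:
        return float(len(p))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def diversity_profile(
    fractions: Sequence[float], q_grid: Optional[Sequence[float]] = None
) -> DiversityProfile:
    """Evaluate the Hill profile of a clone-abundance distribution.

    ``fractions`` must be positive and sum to 1 (within 1e-9); ``q_grid``
    defaults to 0–4 in steps of 0.1.
    """
    p = np.asarray(fractions, dtype=float)
    if p.size == 0:
        raise ValueError("empty abundance vector")
    if np.any(p <= 0):
        raise ValueError("abundance fractions must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {p.sum()!r}, expected 1")
    if q_grid is None:
        q_grid = DEFAULT_Q_GRID
    if any(q < 0 for q in q_grid):
        raise ValueError("q values must be non-negative")
    points = [(float(q), hill_number(p, float(q))) for q in q_grid]
    shannon = float(-np.sum(p * np.log(p)))
    return DiversityProfile(points=points, shannon_entropy=shannon)


# ---------------------------------------------------------------------------
# CDR3 profile
# ---------------------------------------------------------------------------

#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Sidechain pKa values (EMBOSS convention).  Termini are excluded: the CDR3
# is an internal fragment of the receptor chain.
_PKA_POSITIVE: Mapping[str, float] = {"K": 10.54, "R": 12.48, "H": 6.04}
_PKA_NEGATIVE: Mapping[str, float] = {"D": 3.90, "E": 4.07, "C": 8.18, "Y": 10.46}

_AROMATIC = frozenset("FWY")


def gravy(peptide: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle index."""
    if not peptide:
        raise ValueError("empty peptide")
    return sum(KYTE_DOOLITTLE[aa] for aa in peptide) / len(peptide)


def net_charge(peptide: str, ph: float = 7.4) -> float:
    """Henderson–Hasselbalch net sidechain charge at the given pH."""
    pos = sum(
        1.0 / (1.0 + 10.0 ** (ph - pka))
        for aa in peptide
        for pka in (_PKA_POSITIVE.get(aa),)
        if pka is not None
    )
    neg = sum(
        1.0 / (1.0 + 10.0 ** (pka - ph))
        for aa in peptide
        for pka in (_PKA_NEGATIVE.get(aa),)
        if pka is not None
    )
    return pos - neg


def aromaticity(peptide: str) -> float:
    """Fraction of aromatic residues (F, W, Y)."""
    if not peptide:
        raise ValueError("empty peptide")
    return sum(aa in _AROMATIC for aa in peptide) / len(peptide)


@dataclass
class CDR3Profile:
    length_distribution_nt: Dict[int, float]
    length_distribution_aa: Dict[int, float]
    aa_composition: Dict[str, float]
    gravy_values: List[float]
    net_charge_values: List[float]
    aromaticity_values: List[float]
    ph: float
    n_unique_cdr3: int
    n_unique_vj_cdr3: int
    n_stop_excluded: int


def cdr3_profile(records: Sequence[Rearrangement], ph: float = 7.4) -> CDR3Profile:
    """Length, composition and physicochemistry of the CDR3/junction set.

    Nucleotide lengths come from ``junction``; amino-acid metrics from
    ``junction_aa``.  Sequences containing a stop ("*") are excluded from
    the amino-acid metrics and counted in ``n_stop_excluded``.
    """
    nt_lengths: Dict[int, int] = {}
    aa_lengths: Dict[int, int] = {}
    aa_counts: Dict[str, int] = {}
    gravies: List[float] = []
    charges: List[float] = []
    aromatics: List[float] = []
    unique_aa = set()
    unique_vj = set()
    n_stop = 0

    for rec in records:
        if rec.junction:
            nt_lengths[len(rec.junction)] = nt_lengths.get(len(rec.junction), 0) + 1
        aa = rec.junction_aa
        if not aa:
            continue
        if "*" in aa:
            n_stop += 1
            continue
        aa_lengths[len(aa)] = aa_lengths.get(len(aa), 0) + 1
        for residue in aa:
            aa_counts[residue] = aa_counts.get(residue, 0) + 1
        gravies.append(gravy(aa))
        charges.append(net_charge(aa, ph))
        aromatics.append(aromaticity(aa))
        unique_aa.add(aa)
        v_names = _record_level_names(rec, "V", "gene")
        j_names = _record_level_names(rec, "J", "gene")
        unique_vj.add(
            (v_names[0] if v_names else None, j_names[0] if j_names else None, aa)
        )

    def _normalize(hist: Dict) -> Dict:
        total = sum(hist.values())
        return {k: v / total for k, v in hist.items()} if total else {}

    return CDR3Profile(
        length_distribution_nt=_normalize(nt_lengths),
        length_distribution_aa=_normalize(aa_lengths),
        aa_composition=_normalize(aa_counts),
        gravy_values=gravies,
        net_charge_values=charges,
        aromaticity_values=aromatics,
        ph=ph,
        n_unique_cdr3=len(unique_aa),
        n_unique_vj_cdr3=len(unique_vj),
        n_stop_excluded=n_stop,
    )
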