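"""Synthetic repertoire generator with known ground truth.

Emulates the data a repertoire-sequencing pipeline consumes — FASTQ reads
and an annotated rearrangement table — from a configurable generative
model, so every analysis stage can be exercised offline and its estimates
checked against the configured truth:

1. A small built-in germline set (V genes of 96 codons, J genes of 16
   codons, free of stop codons) stands in for a reference database.
2. Clones are drawn first: each clone picks a V and J gene from the
   configured usage distributions and a junction (random in-frame
   nucleotide string bracketed by the canonical Cys/Trp codons); clone
   sizes follow a power law or an explicit size list.
3. Each read of a clone receives independent somatic hypermutation: every
   V-gene position substitutes with probability ``shm_rate``.  Substitutions
   that would create a stop codon are re-targeted to a different base so
   simulated repertoires stay productive (real pipelines would discard
   stopped reads upstream); the mutation count is unaffected.
4. Reads carry per-base Phred qualities from a truncated normal; optional
   artifact rates inject low-quality or short reads for QC testing.

The generator is fully deterministic under a fixed seed (one NumPy
generator drives all sampling), and the emitted annotations are internally
consistent: gene calls match the germline actually used, alignment pairs
are observed-vs-unmutated germline, region coordinates are valid, and
``v_identity`` equals one minus the realized mutation fraction.

:func:`inject_violations` deterministically corrupts a chosen fraction of
records so that each violates exactly one named filtering rule, recording
which — this makes filter precision/recall exactly measurable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .airr_io import Rearrangement
from .annotation_filter import RULE_NAMES
from .read_qc import SequenceRead

_BASES = "ACGT"
_STOPS = frozenset({"TAA", "TAG", "TGA"})

V_LENGTH_CODONS = 96
J_LENGTH_CODONS = 16

#: V-gene region boundaries in codons (1-based, closed), loosely following
#: standard antibody domain architecture.
V_REGION_CODONS: Mapping[str, Tuple[int, int]] = {
    "FWR1": (1, 26),
    "CDR1": (27, 38),
    "FWR2": (39, 55),
    "CDR2": (56, 65),
    "FWR3": (66, 96),
}


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """A random nucleotide string of ``n_codons`` codons with no stops."""
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def _default_germline() -> Dict[str, List[Tuple[str, str]]]:
    rng = np.random.default_rng(424242)
    v_names = ["IGHV1-2*01", "IGHV3-23*01", "IGHV4-34*01"]
    j_names = ["IGHJ4*02", "IGHJ6*02"]
    d_names = ["IGHD3-10*01", "IGHD6-19*01"]
    return {
        "V": [(n, _random_orf(rng, V_LENGTH_CODONS)) for n in v_names],
        "D": [(n, _random_orf(rng, 5)) for n in d_names],
        "J": [(n, _random_orf(rng, J_LENGTH_CODONS)) for n in j_names],
    }


DEFAULT_GERMLINE = _default_germline()


def _validate_probability_map(pmap: Mapping, what: str) -> None:
    total = sum(pmap.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} probabilities sum to {total!r}, expected 1")
    if any(p < 0 for p in pmap.values()):
        raise ValueError(f"{what} probabilities must be non-negative")


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults give a plausible small IGH
    repertoire: 50 clones with power-law sizes over 1,000 reads, ~380 nt
    productive sequences, 2% per-site hypermutation, Phred ≈ 38 reads."""

    seed: int = 0
    germline: Dict[str, List[Tuple[str, str]]] = field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_GERMLINE.items()
        }
    )
    v_usage: Optional[Dict[str, float]] = None  # None -> uniform
    j_usage: Optional[Dict[str, float]] = None
    d_usage: Optional[Dict[str, float]] = None  # None -> no d_call emitted
    n_records: int = 1000
    n_clones: int = 50
    clone_sizes: Optional[List[int]] = None  # explicit sizes override
    power_law_exponent: float = 1.5
    junction_length_distribution: Dict[int, float] = field(
        default_factory=lambda: {36: 0.25, 39: 0.25, 42: 0.25, 45: 0.25}
    )
    shm_rate: float = 0.02
    read_quality_mean: float = 38.0
    read_quality_sd: float = 4.0
    duplicate_count_range: Tuple[int, int] = (2, 5)
    artifact_rates: Dict[str, float] = field(default_factory=dict)
    sample_id: str = "sim1"

    def __post_init__(self) -> None:
        if self.n_clones < 1 or not self.germline.get("V") or not self.germline.get("J"):
            raise ValueError("degenerate config: need >=1 clone and V/J germline genes")
        if not (0.0 <= self.shm_rate <= 1.0):
            raise ValueError("shm_rate must lie in [0, 1]")
        for rate in self.artifact_rates.values():
            if not (0.0 <= rate <= 1.0):
                raise ValueError("artifact rates must lie in [0, 1]")
        _validate_probability_map(self.junction_length_distribution, "junction length")
        for name, usage in (("v_usage", self.v_usage), ("j_usage", self.j_usage),
                            ("d_usage", self.d_usage)):
            if usage is not None:
                _validate_probability_map(usage, name)


@dataclass
class SimulatedRepertoire:
    """Generator output: reads, annotations, and the per-record truth."""

    reads: List[SequenceRead]
    annotations: List[Rearrangement]
    truth: pd.DataFrame
    config: SimulationConfig

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _draw_usage(
    rng: np.random.Generator,
    genes: Sequence[Tuple[str, str]],
    usage: Optional[Mapping[str, float]],
) -> Tuple[str, str]:
    names = [n for n, _ in genes]
    if usage is None:
        idx = rng.integers(len(names))
        return genes[int(idx)]
    probs = [usage.get(n, 0.0) for n in names]
    total = sum(probs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError("usage map does not cover the germline gene names")
    idx = rng.choice(len(names), p=probs)
    return genes[int(idx)]


def _power_law_sizes(n_clones: int, n_records: int, exponent: float) -> List[int]:
    """Deterministic clone sizes ∝ rank^-exponent summing to n_records,
    each at least 1."""
    if n_records < n_clones:
        raise ValueError("need at least one record per clone")
    weights = np.arange(1, n_clones + 1, dtype=float) ** (-exponent)
    sizes = np.maximum(1, np.round(weights / weights.sum() * n_records)).astype(int)
    diff = int(sizes.sum()) - n_records
    i = 0
    while diff != 0:
        idx = i % n_clones
        if diff > 0 and sizes[idx] > 1:
            sizes[idx] -= 1
            diff -= 1
        elif diff < 0:
            sizes[idx] += 1
            diff += 1
        i += 1
    return [int(s) for s in sizes]


def _generate_junction(rng: np.random.Generator, length: int) -> str:
    """A junction of the given length: conserved Cys codon ... Trp codon
    with random non-stop codons between when in frame, else random bases."""
    if length % 3 == 0 and length >= 9:
        middle = _random_orf(rng, length // 3 - 2)
        return "TGT" + middle + "TGG"
    return "".join(rng.choice(list(_BASES), size=length))


def _mutate_v(
    rng: np.random.Generator, germ_v: str, shm_rate: float
) -> Tuple[str, int]:
    """Apply per-site substitutions codon-wise, re-targeting any
    substitution that would create a stop codon.  Returns (mutated sequence,
    mutation count)."""
    out_codons: List[str] = []
    n_mut = 0
    for start in range(0, len(germ_v), 3):
        codon = germ_v[start : start + 3]
        hit = [i for i in range(len(codon)) if rng.random() < shm_rate]
        if not hit:
            out_codons.append(codon)
            continue
        for _ in range(100):
            bases = list(codon)
            for i in hit:
                choices = [b for b in _BASES if b != codon[i]]
                bases[i] = choices[int(rng.integers(3))]
            candidate = "".join(bases)
            if len(candidate) < 3 or candidate not in _STOPS:
                out_codons.append(candidate)
                n_mut += len(hit)
                break
        else:  # pragma: no cover - practically unreachable
            out_codons.append(codon)
    return "".join(out_codons), n_mut


def simulate_repertoire(config: Optional[SimulationConfig] = None) -> SimulatedRepertoire:
    """Draw a repertoire clone-first and emit reads, annotations and truth.

    See the module docstring for the generative model.  Identical configs
    (including the seed) produce byte-identical FASTQ and TSV output.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)

    sizes = (
        list(config.clone_sizes)
        if config.clone_sizes is not None
        else _power_law_sizes(config.n_clones, config.n_records, config.power_law_exponent)
    )
    if config.clone_sizes is not None and len(sizes) != config.n_clones:
        raise ValueError("clone_sizes length must equal n_clones")

    j_lengths = sorted(config.junction_length_distribution)
    j_probs = [config.junction_length_distribution[l] for l in j_lengths]

    v_len_nt = None
    reads: List[SequenceRead] = []
    annotations: List[Rearrangement] = []
    truth_rows: List[dict] = []
    rec_index = 0

    region_coords: Dict[str, Tuple[int, int]] = {}

    for clone_idx, size in enumerate(sizes, start=1):
        clone_id = f"tclone_{clone_idx:04d}"
        v_name, v_seq = _draw_usage(rng, config.germline["V"], config.v_usage)
        j_name, j_seq = _draw_usage(rng, config.germline["J"], config.j_usage)
        d_name = None
        if config.d_usage is not None:
            d_name, _ = _draw_usage(rng, config.germline["D"], config.d_usage)
        if v_len_nt is None:
            v_len_nt = len(v_seq)
        jl = int(rng.choice(j_lengths, p=j_probs))
        junction = _generate_junction(rng, jl)
        in_frame = jl % 3 == 0
        junction_aa = str(Seq(junction).translate()) if in_frame else None

        for _ in range(size):
            rec_index += 1
            seq_id = f"{config.sample_id}-{rec_index:06d}"
            mut_v, n_mut = _mutate_v(rng, v_seq, config.shm_rate)
            sequence = mut_v + junction + j_seq
            aln = mut_v + junction
            germ_aln = v_seq + junction
            if not region_coords:
                for region, (cs, ce) in V_REGION_CODONS.items():
                    region_coords[region] = (3 * cs - 2, 3 * ce)
            dup = int(
                rng.integers(
                    config.duplicate_count_range[0],
                    config.duplicate_count_range[1] + 1,
                )
            )
            rec = Rearrangement(
                sequence_id=seq_id,
                sequence=sequence,
                v_call=v_name,
                d_call=d_name,
                j_call=j_name,
                junction=junction,
                junction_aa=junction_aa,
                productive=in_frame,
                stop_codon=False,
                vj_in_frame=in_frame,
                v_identity=round(1.0 - n_mut / len(v_seq), 6),
                sequence_alignment=aln,
                germline_alignment=germ_aln,
                v_germline_start=1,
                v_germline_end=len(v_seq),
                fwr1_start=region_coords["FWR1"][0],
                fwr1_end=region_coords["FWR1"][1],
                cdr1_start=region_coords["CDR1"][0],
                cdr1_end=region_coords["CDR1"][1],
                fwr2_start=region_coords["FWR2"][0],
                fwr2_end=region_coords["FWR2"][1],
                cdr2_start=region_coords["CDR2"][0],
                cdr2_end=region_coords["CDR2"][1],
                fwr3_start=region_coords["FWR3"][0],
                fwr3_end=region_coords["FWR3"][1],
                cdr3_start=len(v_seq) + 1,
                cdr3_end=len(v_seq) + jl,
                duplicate_count=dup,
                sample_id=config.sample_id,
            )
            annotations.append(rec)

            artifact = None
            read_bases = sequence
            q_mean = config.read_quality_mean
            if rng.random() < config.artifact_rates.get("short_length", 0.0):
                artifact = "short_length"
                cut = int(rng.integers(50, 200))
                read_bases = sequence[:cut]
            if rng.random() < config.artifact_rates.get("low_quality", 0.0):
                artifact = "low_quality" if artifact is None else artifact
                q_mean = 20.0
            quals = np.clip(
                np.round(
                    rng.normal(q_mean, config.read_quality_sd, size=len(read_bases))
                ),
                2,
                40,
            ).astype(int)
            reads.append(
                SequenceRead(read_id=seq_id, bases=read_bases, qualities=list(quals))
            )
            truth_rows.append(
                {
                    "sequence_id": seq_id,
                    "sample_id": config.sample_id,
                    "true_v": v_name,
                    "true_d": d_name or "",
                    "true_j": j_name,
                    "true_clone": clone_id,
                    "junction": junction,
                    "n_mutations": n_mut,
                    "read_artifact": artifact or "",
                    "violation": "",
                }
            )

    truth = pd.DataFrame(truth_rows)
    return SimulatedRepertoire(
        reads=reads, annotations=annotations, truth=truth, config=config
    )


# ---------------------------------------------------------------------------
# violation injection
# ---------------------------------------------------------------------------

def _corrupt(rec: Rearrangement, rule: str, rng: np.random.Generator,
             min_read_length: int) -> Rearrangement:
    rec = copy.deepcopy(rec)
    if rule == "frameshift_indels":
        # single-nucleotide insertion: extra base in the read alignment,
        # gap in the germline alignment
        pos = int(rng.integers(3, len(rec.sequence_alignment) - 3))
        base = _BASES[int(rng.integers(4))]
        rec.sequence_alignment = (
            rec.sequence_alignment[:pos] + base + rec.sequence_alignment[pos:]
        )
        rec.germline_alignment = (
            rec.germline_alignment[:pos] + "-" + rec.germline_alignment[pos:]
        )
    elif rule == "out_of_frame_junction":
        rec.vj_in_frame = False
        rec.productive = False
    elif rule == "stop_codon":
        rec.stop_codon = True
        rec.productive = False
    elif rule == "truncated_read_length":
        cut = int(rng.integers(50, min_read_length))
        rec.sequence = rec.sequence[:cut]
    elif rule == "v_identity":
        rec.v_identity = round(float(rng.uniform(0.60, 0.845)), 4)
    elif rule == "missing_cdr3":
        rec.junction = None
        rec.junction_aa = None
        rec.cdr3_start = None
        rec.cdr3_end = None
    elif rule == "coverage":
        # alignment starts past codon 31 (germline position 91)
        rec.v_germline_start = int(rng.integers(95, 150))
    elif rule == "duplicate_count":
        rec.duplicate_count = 1
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    return rec


def inject_violations(
    records: Sequence[Rearrangement],
    rule: str,
    fraction: float,
    seed: int,
    exclude_ids: Sequence[str] = (),
    min_read_length: int = 200,
) -> Tuple[List[Rearrangement], List[str]]:
    """Corrupt exactly ``round(fraction * len(records))`` records so each
    violates only ``rule``.

    ``exclude_ids`` protects records (e.g. already corrupted with another
    rule) from selection.  Returns the new record list (order preserved)
    and the injected sequence ids.
    """
    if rule not in RULE_NAMES:
        raise ValueError(f"unknown filter rule {rule!r}")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_target = int(round(fraction * len(records)))
    eligible = [
        i for i, rec in enumerate(records) if rec.sequence_id not in set(exclude_ids)
    ]
    if n_target > len(eligible):
        raise ValueError(
            f"cannot inject {n_target} violations: only {len(eligible)} "
            "eligible records"
        )
    chosen = set(
        int(i) for i in rng.choice(eligible, size=n_target, replace=False)
    )
    out: List[Rearrangement] = []
    injected: List[str] = []
    for i, rec in enumerate(records):
        if i in chosen:
            out.append(_corrupt(rec, rule, rng, min_read_length))
            injected.append(rec.sequence_id)
        else:
            out.append(rec)
    return out, injected


def inject_violation_suite(
    records: Sequence[Rearrangement],
    rates: Mapping[str, float],
    seed: int,
    min_read_length: int = 200,
) -> Tuple[List[Rearrangement], Dict[str, str]]:
    """Inject several rules at once on disjoint record sets.

    Returns the corrupted record list and a map sequence_id → violated rule.
    """
    labels: Dict[str, str] = {}
    current = list(records)
    for offset, (rule, fraction) in enumerate(sorted(rates.items())):
        current, injected = inject_violations(
            current,
            rule,
            fraction,
            seed=seed + offset,
            exclude_ids=list(labels),
            min_read_length=min_read_length,
        )
        for sid in injected:
            labels[sid] = rule
    return current, labels
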