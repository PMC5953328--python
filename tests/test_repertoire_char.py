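"""Gene-call grammar, usage tallies, clone clustering vs brute force,
abundance, Hill diversity closed forms, and CDR3 physicochemistry."""

import math

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from repkit.airr_io import Rearrangement
from repkit.repertoire_char import (
    CloneConfigError,
    GeneCallError,
    aromaticity,
    assign_clones,
    cdr3_profile,
    clonal_abundance,
    combination_usage,
    compute_gene_usage,
    diversity_profile,
    gravy,
    hill_number,
    net_charge,
    parse_gene_call,
)


def rec(i, v=None, d=None, j=None, junction=None, junction_aa=None, dup=1):
    return Rearrangement(
        sequence_id=f"r{i:03d}", v_call=v, d_call=d, j_call=j,
        junction=junction, junction_aa=junction_aa, duplicate_count=dup,
    )


# -- gene-call grammar -------------------------------------------------------

@pytest.mark.parametrize(
    "text,locus,family,gene,allele",
    [
        ("IGHV3-23*01", "IGH", "IGHV3", "IGHV3-23", "*01"),
        ("TRBJ2-7*01", "TRB", "TRBJ2", "TRBJ2-7", "*01"),
        ("IGHV1-2", "IGH", "IGHV1", "IGHV1-2", None),
        ("IGKV1D-39*01", "IGK", "IGKV1D", "IGKV1D-39", "*01"),
        ("IGHJ4*02", "IGH", "IGHJ4", "IGHJ4", "*02"),
    ],
)
def test_nomenclature_decomposition(text, locus, family, gene, allele):
    (call,) = parse_gene_call(text)
    assert (call.locus, call.family, call.gene, call.allele) == (
        locus, family, gene, allele,
    )
    # hierarchy containment chain
    assert call.gene.startswith(call.family)
    assert call.family.startswith(call.locus)


def test_multi_call_string():
    calls = parse_gene_call("IGHV1-69*02,IGHV1-69*04")
    assert len(calls) == 2
    assert calls[0].gene == calls[1].gene == "IGHV1-69"
    assert [c.allele for c in calls] == ["*02", "*04"]


def test_unparseable_token_raises_with_token():
    with pytest.raises(GeneCallError, match="BOGUS"):
        parse_gene_call("BOGUS")


# -- gene usage --------------------------------------------------------------

def test_relative_usage_at_gene_and_family_level():
    records = [rec(0, v="IGHV1-2"), rec(1, v="IGHV1-2"), rec(2, v="IGHV3-23")]
    gene = compute_gene_usage(records, "V", "gene", "relative")
    assert gene.entries == pytest.approx({"IGHV1-2": 2 / 3, "IGHV3-23": 1 / 3})
    family = compute_gene_usage(records, "V", "family", "relative")
    assert family.entries == pytest.approx({"IGHV1": 2 / 3, "IGHV3": 1 / 3})


def test_fractional_policy_splits_ambiguous_calls():
    records = [rec(0, v="IGHV1-2*02,IGHV1-3*01")]
    table = compute_gene_usage(records, "V", "gene", "absolute", "fractional")
    assert table.entries == pytest.approx({"IGHV1-2": 0.5, "IGHV1-3": 0.5})


def test_policies_differ_on_ambiguity():
    records = [rec(0, v="IGHV1-2,IGHV3-23"), rec(1, v="IGHV1-2")]
    first = compute_gene_usage(records, "V", "gene", "absolute", "first_call")
    assert first.entries == {"IGHV1-2": 2.0}
    dropped = compute_gene_usage(records, "V", "gene", "absolute", "drop_ambiguous")
    assert dropped.entries == {"IGHV1-2": 1.0}
    assert dropped.n_assigned == 1


@pytest.mark.parametrize("level", ["locus", "family", "gene", "allele"])
@pytest.mark.parametrize("policy", ["first_call", "fractional", "drop_ambiguous"])
def test_relative_usage_sums_to_one_all_levels_and_policies(level, policy, rng):
    pool = ["IGHV1-2*01", "IGHV1-69*02,IGHV1-69*04", "IGHV3-23*01",
            "IGHV4-34*01", "IGHV1-2*01,IGHV3-23*02"]
    records = [rec(i, v=pool[int(rng.integers(len(pool)))]) for i in range(200)]
    table = compute_gene_usage(records, "V", level, "relative", policy)
    assert sum(table.entries.values()) == pytest.approx(1.0, abs=1e-9)
    absolute = compute_gene_usage(records, "V", level, "absolute", policy)
    assert sum(absolute.entries.values()) == pytest.approx(absolute.n_assigned)


def test_all_records_missing_segment_is_error():
    with pytest.raises(ValueError, match="d_call"):
        compute_gene_usage([rec(0, v="IGHV1-2")], "D", "gene")


# -- combination usage -------------------------------------------------------

def test_vj_combination_counting():
    records = [
        rec(0, v="IGHV1-2*01", j="IGHJ4*02"),
        rec(1, v="IGHV1-2*02", j="IGHJ4*01"),  # same genes, other alleles
        rec(2, v="IGHV3-23", j="IGHJ6"),
    ]
    counts, excluded = combination_usage(records, "VJ", "gene")
    assert counts == {("IGHV1-2", "IGHJ4"): 2, ("IGHV3-23", "IGHJ6"): 1}
    assert excluded == 0


def test_cdr3_key_types_distinguish_sequences():
    records = [
        rec(0, v="IGHV1-2", j="IGHJ4", junction="TGTGCG", junction_aa="CA"),
        rec(1, v="IGHV1-2", j="IGHJ4", junction="TGTGCC", junction_aa="CA"),
    ]
    aa_counts, _ = combination_usage(records, "VJ_CDR3aa")
    nt_counts, _ = combination_usage(records, "VJ_CDR3nt")
    assert list(aa_counts.values()) == [2]
    assert len(nt_counts) == 2


def test_missing_component_excluded_and_counted():
    records = [rec(0, v="IGHV1-2", j="IGHJ4"), rec(1, v="IGHV1-2", d=None, j="IGHJ4")]
    counts, excluded = combination_usage(records, "VDJ")
    assert counts == {}
    assert excluded == 2


# -- clone assignment --------------------------------------------------------

def brute_force_clones(records, threshold):
    """Independent single-linkage: grow connected components by repeated
    sweeps over all record pairs."""
    def linked(a, b):
        if (a.v_call or "").split(",")[0].split("*")[0] != (b.v_call or "").split(",")[0].split("*")[0]:
            return False
        if (a.j_call or "").split(",")[0].split("*")[0] != (b.j_call or "").split(",")[0].split("*")[0]:
            return False
        if len(a.junction) != len(b.junction):
            return False
        return sum(x != y for x, y in zip(a.junction, b.junction)) <= threshold

    groups = [{r.sequence_id} for r in records]
    changed = True
    while changed:
        changed = False
        for i, a in enumerate(records):
            for b in records[i + 1:]:
                if linked(a, b):
                    ga = next(g for g in groups if a.sequence_id in g)
                    gb = next(g for g in groups if b.sequence_id in g)
                    if ga is not gb:
                        groups.remove(gb)
                        ga.update(gb)
                        changed = True
    return {frozenset(g) for g in groups}


def _random_clone_instance(rng):
    n = int(rng.integers(2, 21))
    junctions = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 7)) * 3))
                 for _ in range(max(2, n // 3))]
    records = []
    for i in range(n):
        base = junctions[int(rng.integers(len(junctions)))]
        # mutate a couple of positions
        chars = list(base)
        for _ in range(int(rng.integers(0, 3))):
            pos = int(rng.integers(len(chars)))
            chars[pos] = "ACGT"[int(rng.integers(4))]
        records.append(
            rec(i, v=f"IGHV{int(rng.integers(1, 3))}-2", j="IGHJ4",
                junction="".join(chars))
        )
    return records


@pytest.mark.parametrize("threshold", [0, 1, 3])
def test_assign_clones_matches_brute_force(threshold, rng):
    for _ in range(40):
        records = _random_clone_instance(rng)
        assigned, _ = assign_clones(records, max_junction_hamming=threshold)
        mine = {}
        for r in assigned:
            mine.setdefault(r.clone_id, set()).add(r.sequence_id)
        assert {frozenset(g) for g in mine.values()} == brute_force_clones(
            records, threshold
        )


def test_identical_junctions_cluster_different_lengths_split():
    a = rec(0, v="IGHV1-2", j="IGHJ4", junction="TGTGCGTGG")
    b = rec(1, v="IGHV1-2", j="IGHJ4", junction="TGTGCGTGG")
    c = rec(2, v="IGHV1-2", j="IGHJ4", junction="TGTGCGAAATGG")
    assign_clones([a, b, c])
    assert a.clone_id == b.clone_id != c.clone_id


def test_hamming_threshold_boundary():
    a = rec(0, v="IGHV1-2", j="IGHJ4", junction="TGTGCGTGG")
    b = rec(1, v="IGHV1-2", j="IGHJ4", junction="TGTGCCTGG")  # distance 1
    assign_clones([a, b], max_junction_hamming=1)
    assert a.clone_id == b.clone_id
    assign_clones([a, b], max_junction_hamming=0)
    assert a.clone_id != b.clone_id


def test_hamming_without_length_key_is_config_error():
    with pytest.raises(CloneConfigError):
        assign_clones([], same_junction_length=False, max_junction_hamming=1)


def test_records_without_junction_left_unassigned():
    a = rec(0, v="IGHV1-2", j="IGHJ4", junction="TGTTGG")
    b = rec(1, v="IGHV1-2", j="IGHJ4")
    assigned, unassigned = assign_clones([a, b])
    assert [r.sequence_id for r in unassigned] == ["r001"]
    assert b.clone_id is None


# -- clonal abundance --------------------------------------------------------

def test_abundance_fractions_and_cumulative():
    records = [
        rec(0, junction="AAA", dup=6), rec(1, junction="AAA", dup=0 + 3),
        rec(2, junction="AAA", dup=1),
    ]
    for r, cid in zip(records, ["A", "B", "C"]):
        r.clone_id = cid
    ab = clonal_abundance(records)
    assert [(c, f) for c, _, f in ab.ranked] == [
        ("A", pytest.approx(0.6)), ("B", pytest.approx(0.3)),
        ("C", pytest.approx(0.1)),
    ]
    assert ab.cumulative == pytest.approx([0.6, 0.9, 1.0])


def test_abundance_tie_break_by_clone_id_stable():
    records = []
    for i, cid in enumerate(["z", "a", "m"]):
        r = rec(i, junction="AAA", dup=2)
        r.clone_id = cid
        records.append(r)
    ab = clonal_abundance(records)
    assert [c for c, _, _ in ab.ranked] == ["a", "m", "z"]


def test_abundance_requires_clone_ids():
    with pytest.raises(ValueError, match="clone_id"):
        clonal_abundance([rec(0, junction="AAA")])


def test_unique_weighting_ignores_duplicate_count():
    r1, r2 = rec(0, dup=100), rec(1, dup=1)
    r1.clone_id = "A"
    r2.clone_id = "B"
    ab = clonal_abundance([r1, r2], weight="unique")
    assert [f for _, _, f in ab.ranked] == pytest.approx([0.5, 0.5])


# -- diversity ---------------------------------------------------------------

def test_uniform_distribution_is_flat_at_richness():
    profile = diversity_profile([0.25] * 4)
    for _, d in profile.points:
        assert d == pytest.approx(4.0, rel=1e-9)


def test_hill_closed_form_examples():
    p = [0.75, 0.25]
    assert hill_number(p, 0) == pytest.approx(2.0)
    assert hill_number(p, 2) == pytest.approx(1 / (0.5625 + 0.0625), rel=1e-12)
    shannon = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
    assert hill_number(p, 1) == pytest.approx(math.exp(shannon), rel=1e-12)
    assert math.exp(shannon) == pytest.approx(1.7548, abs=5e-5)


@pytest.mark.parametrize("trial", range(20))
def test_profile_monotone_non_increasing_and_closed_forms(trial):
    rng = np.random.default_rng(4000 + trial)
    k = int(rng.integers(2, 40))
    p = rng.dirichlet(np.ones(k) * rng.uniform(0.3, 3))
    p = p / p.sum()
    profile = diversity_profile(list(p))
    ds = [d for _, d in profile.points]
    for a, b in zip(ds, ds[1:]):
        assert b <= a + 1e-9
    lookup = dict(profile.points)
    assert lookup[0.0] == pytest.approx(k)
    assert lookup[1.0] == pytest.approx(
        math.exp(-sum(x * math.log(x) for x in p)), rel=1e-9
    )
    assert lookup[2.0] == pytest.approx(1 / sum(x * x for x in p), rel=1e-9)


def test_non_normalized_fractions_rejected():
    with pytest.raises(ValueError):
        diversity_profile([0.5, 0.4])
    with pytest.raises(ValueError):
        diversity_profile([1.2, -0.2])


# -- CDR3 profile ------------------------------------------------------------

def test_gravy_matches_hand_calculation_and_biopython():
    assert gravy("CARDYW") == pytest.approx(
        (2.5 + 1.8 - 4.5 - 3.5 - 1.3 - 0.9) / 6
    )
    for pep in ("CARDYW", "CAKGGSYFDYW", "MATTS"):
        assert gravy(pep) == pytest.approx(ProteinAnalysis(pep).gravy())


def test_aromaticity_examples():
    assert aromaticity("FWY") == 1.0
    assert aromaticity("FWYA") == 0.75
    assert aromaticity("CARD") == 0.0
    assert aromaticity("CDWF") == pytest.approx(
        ProteinAnalysis("CDWF").aromaticity()
    )


def test_net_charge_signs_and_neutral_ph():
    assert net_charge("KKK") > 2.5
    assert net_charge("DDD") < -2.5
    assert abs(net_charge("GGG")) == 0.0
    # acidic pH protonates carboxyl groups: charge rises
    assert net_charge("DE", ph=2.0) > net_charge("DE", ph=7.4)


def test_cdr3_profile_unique_counts_and_distributions():
    records = [
        rec(0, v="IGHV1-2", j="IGHJ4", junction="TGTGCGTGG", junction_aa="CAW"),
        rec(1, v="IGHV3-23", j="IGHJ4", junction="TGTGCGTGG", junction_aa="CAW"),
        rec(2, v="IGHV1-2", j="IGHJ4", junction="TGTGCGAAATGG",
            junction_aa="CAKW"),
    ]
    profile = cdr3_profile(records)
    assert profile.n_unique_cdr3 == 2
    assert profile.n_unique_vj_cdr3 == 3
    assert sum(profile.length_distribution_nt.values()) == pytest.approx(1.0)
    assert sum(profile.length_distribution_aa.values()) == pytest.approx(1.0)
    assert sum(profile.aa_composition.values()) == pytest.approx(1.0)


def test_stop_containing_cdr3_excluded_from_aa_metrics():
    records = [
        rec(0, junction="TGTTAATGG", junction_aa="C*W"),
        rec(1, junction="TGTGCGTGG", junction_aa="CAW"),
    ]
    profile = cdr3_profile(records)
    assert profile.n_stop_excluded == 1
    assert len(profile.gravy_values) == 1
    # nt lengths still count both records
    assert sum(profile.length_distribution_nt.values()) == pytest.approx(1.0)
    assert profile.length_distribution_nt[9] == pytest.approx(1.0)
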