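"""Per-rule filtering semantics, coverage arithmetic, and sample minimums."""

import numpy as np
import pytest

from repkit import SimulationConfig, simulate_repertoire
from repkit.airr_io import Rearrangement
from repkit.annotation_filter import (
    FilterConfig,
    FilterConfigError,
    NumberingError,
    RULE_NAMES,
    apply_filters,
    check_coverage,
    filter_samples_min_unique,
    identity_numbering,
)
from repkit.synthetic import inject_violation_suite, inject_violations


def clean_record(i=0, sample_id="s1", **overrides):
    """A record violating no default rule."""
    fields = dict(
        sequence_id=f"r{i}",
        sequence="A" * 300,
        junction="TGTGCGTGG",
        junction_aa="CAW",
        vj_in_frame=True,
        stop_codon=False,
        productive=True,
        v_identity=0.95,
        sequence_alignment="ACGT" * 72,
        germline_alignment="ACGT" * 72,
        v_germline_start=1,
        v_germline_end=288,
        duplicate_count=3,
        sample_id=sample_id,
    )
    fields.update(overrides)
    return Rearrangement(**fields)


def relaxed_config(**overrides):
    kwargs = dict(min_unique_per_sample=0)
    kwargs.update(overrides)
    return FilterConfig(**kwargs)


class TestRecordRules:
    def test_clean_records_all_pass(self):
        records = [clean_record(i) for i in range(12)]
        kept, report = apply_filters(records, FilterConfig())
        assert report.n_kept == 12
        assert all(v == 0 for v in report.per_rule_violation_counts.values())

    @pytest.mark.parametrize(
        "overrides,rule",
        [
            ({"stop_codon": True}, "stop_codon"),
            ({"vj_in_frame": False}, "out_of_frame_junction"),
            ({"v_identity": 0.84}, "v_identity"),
            ({"junction": None, "junction_aa": None}, "missing_cdr3"),
            ({"duplicate_count": 1}, "duplicate_count"),
            ({"v_germline_start": 100}, "coverage"),
        ],
    )
    def test_single_rule_violations(self, overrides, rule):
        records = [clean_record(0, **overrides), clean_record(1)]
        kept, report = apply_filters(records, relaxed_config())
        assert [r.sequence_id for r in kept] == ["r1"]
        assert report.per_rule_violation_counts[rule] == 1
        assert sum(report.per_rule_violation_counts.values()) == 1

    def test_boundary_values_are_kept(self):
        """0.85 identity, 2 copies are at the inclusive keep boundary."""
        records = [clean_record(0, v_identity=0.85, duplicate_count=2)]
        kept, _ = apply_filters(records, relaxed_config())
        assert len(kept) == 1

    def test_frameshift_from_gapped_alignment(self):
        # a 1-nt insertion (gap in germline) shifts the frame
        rec = clean_record(
            0,
            sequence_alignment="ACGTA" + "ACGT" * 20,
            germline_alignment="ACGT-" + "ACGT" * 20,
        )
        _, report = apply_filters([rec], relaxed_config())
        assert report.per_rule_violation_counts["frameshift_indels"] == 1
        # a full-codon indel is not frame-shifting
        rec2 = clean_record(
            1,
            sequence_alignment="ACGTTT" + "ACGT" * 20,
            germline_alignment="ACG---" + "ACGT" * 20,
        )
        _, report2 = apply_filters([rec2], relaxed_config())
        assert report2.per_rule_violation_counts["frameshift_indels"] == 0

    def test_truncated_read_length_rule(self):
        records = [clean_record(0, sequence="A" * 199), clean_record(1)]
        kept, report = apply_filters(
            records, relaxed_config(min_read_length=200)
        )
        assert [r.sequence_id for r in kept] == ["r1"]
        assert report.per_rule_violation_counts["truncated_read_length"] == 1

    def test_multi_violation_counted_per_rule_removed_once(self):
        rec = clean_record(0, stop_codon=True, vj_in_frame=False, duplicate_count=1)
        kept, report = apply_filters([rec], relaxed_config())
        assert kept == []
        assert report.n_input - report.n_kept == 1
        for rule in ("stop_codon", "out_of_frame_junction", "duplicate_count"):
            assert report.per_rule_violation_counts[rule] == 1

    def test_strict_missing_field_policy(self):
        rec = clean_record(0, v_identity=None)
        other = clean_record(1)
        kept, report = apply_filters([rec, other], relaxed_config())
        assert [r.sequence_id for r in kept] == ["r1"]
        assert report.per_rule_violation_counts["v_identity"] == 1

    def test_universally_absent_field_is_configuration_error(self):
        records = [clean_record(i, v_identity=None) for i in range(3)]
        with pytest.raises(FilterConfigError, match="v_identity"):
            apply_filters(records, relaxed_config())

    def test_disabling_all_rules_is_identity(self):
        records = [
            clean_record(0, stop_codon=True, v_identity=0.1, duplicate_count=1)
        ]
        config = FilterConfig(
            exclude_frameshift_indels=False,
            require_in_frame_junction=False,
            exclude_stop_codon=False,
            min_v_identity=None,
            require_cdr3=False,
            coverage_codon_range=None,
            min_duplicate_count=0,
            min_unique_per_sample=0,
        )
        kept, report = apply_filters(records, config)
        assert kept == records
        assert report.per_rule_violation_counts == {}


class TestCoverage:
    def test_full_alignment_covers_default_range(self):
        rec = clean_record(0, v_germline_start=1, v_germline_end=300)
        assert check_coverage(rec, 31, 92) is True

    def test_late_start_misses_codon_31(self):
        # codon 31 starts at germline nucleotide 91 under identity numbering
        rec = clean_record(0, v_germline_start=100, v_germline_end=300)
        assert check_coverage(rec, 31, 92) is False
        rec = clean_record(0, v_germline_start=91, v_germline_end=276)
        assert check_coverage(rec, 31, 92) is True
        rec = clean_record(0, v_germline_start=92, v_germline_end=276)
        assert check_coverage(rec, 31, 92) is False

    def test_inverted_range_vacuously_true(self):
        rec = clean_record(0, v_germline_start=500, v_germline_end=501)
        assert check_coverage(rec, 92, 31) is True

    def test_numbering_missing_codon_is_error(self):
        rec = clean_record(0)
        numbering = identity_numbering(31, 91)  # lacks codon 92
        with pytest.raises(NumberingError, match="92"):
            check_coverage(rec, 31, 92, numbering)


class TestSampleMinimum:
    def test_boundary_inclusive(self):
        per_sample = {
            "small": [clean_record(i, "small") for i in range(9)],
            "exact": [clean_record(i, "exact") for i in range(10)],
        }
        retained, excluded = filter_samples_min_unique(per_sample, 10)
        assert retained == ["exact"]
        assert excluded == ["small"]

    def test_min_zero_retains_all(self):
        per_sample = {"a": [], "b": [clean_record(0, "b")]}
        retained, excluded = filter_samples_min_unique(per_sample, 0)
        assert retained == ["a", "b"]
        assert excluded == []

    def test_apply_filters_drops_whole_small_samples(self):
        records = [clean_record(i, "big") for i in range(12)] + [
            clean_record(100 + i, "tiny") for i in range(3)
        ]
        kept, report = apply_filters(records, FilterConfig())
        assert report.excluded_samples == ["tiny"]
        assert {r.sample_id for r in kept} == {"big"}
        assert report.per_sample_kept == {"big": 12}


class TestProperties:
    def test_order_independence(self):
        rng = np.random.default_rng(3)
        sim = simulate_repertoire(SimulationConfig(seed=11, n_records=120, n_clones=12))
        records, _ = inject_violation_suite(
            sim.annotations, {"stop_codon": 0.2, "v_identity": 0.2}, seed=4
        )
        kept1, _ = apply_filters(records, relaxed_config())
        shuffled = list(records)
        rng.shuffle(shuffled)
        kept2, _ = apply_filters(shuffled, relaxed_config())
        assert {r.sequence_id for r in kept1} == {r.sequence_id for r in kept2}

    def test_kept_set_matches_brute_force(self):
        sim = simulate_repertoire(SimulationConfig(seed=13, n_records=400, n_clones=40))
        rates = {r: 0.08 for r in RULE_NAMES if r != "truncated_read_length"}
        records, labels = inject_violation_suite(sim.annotations, rates, seed=9)
        config = relaxed_config()
        kept, _ = apply_filters(records, config)
        # brute force: re-evaluate every rule on every record independently
        expected = set()
        for rec in records:
            ok = (
                rec.vj_in_frame is True
                and rec.stop_codon is False
                and rec.v_identity is not None and rec.v_identity >= 0.85
                and bool(rec.junction)
                and rec.duplicate_count >= 2
                and rec.germline_alignment.count("-") % 3 == 0
                and rec.sequence_alignment.count("-") % 3 == 0
                and rec.v_germline_start is not None
                and rec.v_germline_start <= 91
                and rec.v_germline_end >= 276
            )
            if ok:
                expected.add(rec.sequence_id)
        assert {r.sequence_id for r in kept} == expected

    def test_monotonicity_in_thresholds(self):
        sim = simulate_repertoire(SimulationConfig(seed=17, n_records=200, n_clones=20))
        records, _ = inject_violations(sim.annotations, "v_identity", 0.3, seed=2)
        kept_counts = [
            apply_filters(records, relaxed_config(min_v_identity=t))[1].n_kept
            for t in (0.5, 0.85, 0.99)
        ]
        assert kept_counts == sorted(kept_counts, reverse=True)
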