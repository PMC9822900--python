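"""CNV-level gates and the cascade: boundaries, oracle equivalence, order."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvcascade.cnv_filter import (
    CascadeConfig,
    confidence_filter,
    control_overlap_filter,
    derive_promoters,
    genic_filter,
    overlaps,
    population_variant_filter,
    run_cascade,
    snp_count_filter,
    visual_inspection_filter,
)
from cnvcascade.models import (
    AnnotationFeature,
    FeatureClass,
    GenomicInterval,
)
from conftest import make_call, random_calls


def bruteforce_control_overlap(case_calls, control_calls, type_matched=False):
    """O(n*m) all-pairs oracle for the case/control comparison."""
    retained = []
    for case in case_calls:
        hit = any(
            case.interval.overlaps(ctrl.interval)
            and (not type_matched or ctrl.cnv_type == case.cnv_type)
            for ctrl in control_calls
        )
        if not hit:
            retained.append(case)
    return retained


class TestConfidenceFilter:
    @pytest.mark.parametrize(
        "conf,retained", [(29.99, False), (30.0, True), (None, False), (100.0, True)]
    )
    def test_strictly_below_threshold_excluded(self, conf, retained):
        kept, entry = confidence_filter([make_call(conf=conf)])
        assert (len(kept) == 1) is retained
        assert entry.step_id == "IV"


class TestSnpCountFilter:
    @pytest.mark.parametrize("n,retained", [(2, False), (3, True), (150, True)])
    def test_minimum_support(self, n, retained):
        kept, _ = snp_count_filter([make_call(num_snps=n)])
        assert (len(kept) == 1) is retained


class TestControlOverlap:
    def test_any_type_overlap_excludes(self):
        case = make_call(chrom="1", start=100, end=200, copy_state=1)
        control = make_call(chrom="1", start=150, end=160, sample_id="c",
                            copy_state=3)
        kept, _ = control_overlap_filter([case], [control])
        assert kept == []

    def test_single_shared_base_excludes(self):
        case = make_call(chrom="1", start=100, end=200)
        control = make_call(chrom="1", start=200, end=300, sample_id="c")
        kept, _ = control_overlap_filter([case], [control])
        assert kept == []

    def test_no_controls_on_chromosome_retains(self):
        case = make_call(chrom="1", start=100, end=200)
        control = make_call(chrom="2", start=100, end=200, sample_id="c")
        kept, _ = control_overlap_filter([case], [control])
        assert kept == [case]

    def test_type_matched_variant_spares_cross_type(self):
        case = make_call(chrom="1", start=100, end=200, copy_state=1)
        control = make_call(chrom="1", start=150, end=160, sample_id="c",
                            copy_state=3)
        kept, _ = control_overlap_filter([case], [control], type_matched=True)
        assert kept == [case]

    def test_reciprocal_overlap_variant(self):
        case = make_call(chrom="1", start=1, end=1000)
        sliver = make_call(chrom="1", start=1000, end=1000, sample_id="c")
        kept, _ = control_overlap_filter([case], [sliver], min_reciprocal=0.5)
        assert kept == [case]
        big = make_call(chrom="1", start=1, end=1100, sample_id="c")
        kept, _ = control_overlap_filter([case], [big], min_reciprocal=0.5)
        assert kept == []

    @pytest.mark.parametrize("type_matched", [False, True])
    def test_interval_tree_matches_bruteforce_oracle(self, type_matched):
        """120 randomized instances, up to 50 cases x 200 controls."""
        rng = np.random.default_rng(20260101)
        for _ in range(120):
            cases = random_calls(rng, int(rng.integers(0, 51)), "case")
            controls = random_calls(rng, int(rng.integers(0, 201)), "ctrl")
            kept, entry = control_overlap_filter(
                cases, controls, type_matched=type_matched
            )
            oracle = bruteforce_control_overlap(cases, controls, type_matched)
            assert [c.key() for c in kept] == [c.key() for c in oracle]
            assert entry.n_in == entry.n_out + len(entry.excluded_ids)

    def test_input_order_does_not_change_retained_set(self):
        rng = np.random.default_rng(7)
        cases = random_calls(rng, 30, "case")
        controls = random_calls(rng, 60, "ctrl")
        kept_fwd, _ = control_overlap_filter(cases, controls)
        kept_rev, _ = control_overlap_filter(cases[::-1], controls[::-1])
        assert {c.key() for c in kept_fwd} == {c.key() for c in kept_rev}


class TestPopulationVariantFilter:
    @staticmethod
    def pop(fc, start=100, end=200):
        return AnnotationFeature(GenomicInterval("1", start, end), fc, "p")

    @pytest.mark.parametrize(
        "copy_state,fc,retained",
        [
            (1, FeatureClass.POP_LOSS, False),  # loss vs catalogued loss
            (1, FeatureClass.POP_GAIN, True),  # loss vs catalogued gain
            (3, FeatureClass.POP_GAIN, False),  # gain vs catalogued gain
            (3, FeatureClass.POP_LOSS, True),  # gain vs catalogued loss
        ],
    )
    def test_type_matched_exclusion(self, copy_state, fc, retained):
        call = make_call(chrom="1", start=150, end=160, copy_state=copy_state)
        kept, _ = population_variant_filter([call], [self.pop(fc)])
        assert (len(kept) == 1) is retained


class TestGenicFilter:
    gene_plus = AnnotationFeature(
        GenomicInterval("1", 10_000, 20_000), FeatureClass.CODING_GENE, "G", "+"
    )
    gene_minus = AnnotationFeature(
        GenomicInterval("1", 50_000, 60_000), FeatureClass.CODING_GENE, "H", "-"
    )

    def test_gene_body_overlap_retains(self):
        call = make_call(chrom="1", start=15_000, end=15_100)
        kept, _ = genic_filter([call], [self.gene_plus])
        assert kept == [call]

    def test_upstream_promoter_window_retains(self):
        call = make_call(chrom="1", start=9_999, end=9_999)  # 1 bp upstream
        kept, _ = genic_filter([call], [self.gene_plus])
        assert kept == [call]

    def test_minus_strand_promoter_is_downstream_in_coordinates(self):
        call = make_call(chrom="1", start=60_001, end=60_001)
        kept, _ = genic_filter([call], [self.gene_minus])
        assert kept == [call]
        upstream_in_coords = make_call(chrom="1", start=49_000, end=49_999)
        kept, _ = genic_filter([upstream_in_coords], [self.gene_minus])
        assert kept == []

    def test_intergenic_call_beyond_window_excluded(self):
        call = make_call(chrom="1", start=7_000, end=7_500)
        kept, _ = genic_filter([call], [self.gene_plus])
        assert kept == []

    def test_window_size_is_configurable(self):
        call = make_call(chrom="1", start=7_000, end=7_500)
        kept, _ = genic_filter([call], [self.gene_plus],
                               promoter_upstream_bp=5_000)
        assert kept == [call]

    def test_explicit_promoters_honored(self):
        promoter = AnnotationFeature(
            GenomicInterval("1", 1, 5), FeatureClass.PROMOTER, "P"
        )
        call = make_call(chrom="1", start=3, end=4)
        kept, _ = genic_filter([call], [self.gene_plus, promoter])
        assert kept == [call]

    def test_strandless_gene_is_an_error_when_deriving(self):
        gene = AnnotationFeature(
            GenomicInterval("1", 100, 200), FeatureClass.CODING_GENE, "G", "."
        )
        with pytest.raises(ValueError, match="strand"):
            genic_filter([make_call()], [gene])

    def test_promoter_clipped_at_chromosome_start(self):
        gene = AnnotationFeature(
            GenomicInterval("1", 500, 900), FeatureClass.CODING_GENE, "G", "+"
        )
        (promoter,) = derive_promoters([gene], upstream_bp=2000)
        assert (promoter.interval.start, promoter.interval.end) == (1, 499)


class TestVisualInspection:
    def test_flagged_calls_dropped_default_pass(self):
        calls = [make_call(sample_id="a"), make_call(sample_id="b")]
        kept, _ = visual_inspection_filter(calls)
        assert kept == calls
        kept, entry = visual_inspection_filter(
            calls, frozenset({calls[0].key()})
        )
        assert kept == [calls[1]]
        assert entry.step_id == "IX"


class TestCascade:
    def test_empty_inputs_give_empty_output_and_zero_trace(self):
        final, trace = run_cascade([], [], [], [])
        assert final == []
        assert all(e.n_in == 0 for e in trace.entries)

    def test_monotone_and_conserving(self):
        rng = np.random.default_rng(99)
        from cnvcascade.synthetic_cohort import CohortConfig, generate_cohort, generate_tracks

        config = CohortConfig(n_cases=25, n_controls=40, seed=5)
        samples, calls, _ = generate_cohort(config)
        tracks = generate_tracks(config)
        cases = [c for c in calls if c.sample_id.startswith("case")]
        ctrls = [c for c in calls if c.sample_id.startswith("control")]
        final, trace = run_cascade(samples, cases, ctrls, tracks)
        for e in trace.entries:
            assert e.n_out <= e.n_in
            assert e.n_in == e.n_out + len(e.excluded_ids)
        final_keys = {c.key() for c in final}
        assert final_keys <= {c.key() for c in cases}

    def test_case_call_order_permutation_invariant(self):
        from cnvcascade.synthetic_cohort import CohortConfig, generate_cohort, generate_tracks

        config = CohortConfig(n_cases=20, n_controls=30, seed=8)
        samples, calls, _ = generate_cohort(config)
        tracks = generate_tracks(config)
        cases = [c for c in calls if c.sample_id.startswith("case")]
        ctrls = [c for c in calls if c.sample_id.startswith("control")]
        fwd, _ = run_cascade(samples, cases, ctrls, tracks)
        rev, _ = run_cascade(samples, cases[::-1], ctrls[::-1], tracks)
        assert {c.key() for c in fwd} == {c.key() for c in rev}

    def test_population_and_genic_steps_commute(self):
        """VII then VIII equals VIII then VII: both are independent exclusions."""
        rng = np.random.default_rng(3)
        calls = random_calls(rng, 80, "s")
        tracks = [
            AnnotationFeature(GenomicInterval("1", 2000, 4000),
                              FeatureClass.POP_LOSS, "pl"),
            AnnotationFeature(GenomicInterval("2", 1000, 6000),
                              FeatureClass.POP_GAIN, "pg"),
            AnnotationFeature(GenomicInterval("1", 5000, 9000),
                              FeatureClass.CODING_GENE, "G", "+"),
            AnnotationFeature(GenomicInterval("3", 100, 8000),
                              FeatureClass.CODING_GENE, "H", "-"),
        ]
        pop = [f for f in tracks if f.feature_class in
               (FeatureClass.POP_LOSS, FeatureClass.POP_GAIN)]
        genes = [f for f in tracks if f.feature_class is FeatureClass.CODING_GENE]
        a, _ = population_variant_filter(calls, pop)
        a, _ = genic_filter(a, genes)
        b, _ = genic_filter(calls, genes)
        b, _ = population_variant_filter(b, pop)
        assert [c.key() for c in a] == [c.key() for c in b]

    def test_degenerate_confidence_threshold_empties_the_report(self):
        from cnvcascade.synthetic_cohort import CohortConfig, generate_cohort, generate_tracks

        config = CohortConfig(n_cases=10, n_controls=10, seed=2)
        samples, calls, _ = generate_cohort(config)
        tracks = generate_tracks(config)
        cases = [c for c in calls if c.sample_id.startswith("case")]
        ctrls = [c for c in calls if c.sample_id.startswith("control")]
        final, _ = run_cascade(
            samples, cases, ctrls, tracks, CascadeConfig(min_conf=1e9)
        )
        assert final == []
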