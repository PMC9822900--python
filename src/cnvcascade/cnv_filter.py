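"""CNV-level filters and the full prioritization cascade.

After sample QC, individual calls pass through five gates:

IV.   confidence: the caller's maximum log Bayes factor must reach a
      threshold (default 30); calls without a confidence value fail.
V.    support: at least ``min_snps`` consecutive called SNPs (default 3).
VI.   case/control comparison: any case call overlapped (>= 1 bp) by any
      control call is dropped — by default regardless of the control call's
      type, per the literal any-overlap rule; type-matched and
      reciprocal-overlap variants are available as flags.
VII.  population variation: a loss overlapping a catalogued population loss
      is dropped, a gain overlapping a catalogued population gain is
      dropped; cross-type overlap never excludes.
VIII. genic residency: a call must overlap a coding gene or a promoter
      (strand-aware upstream window, default 2 kb) to be retained.
IX.   visual inspection: calls flagged as failing an external visual review
      are dropped; the flag is a pass-through, never computed here.

Overlap queries run against per-chromosome interval indexes (a merged
disjoint union for the large control cohort, interval trees for the small
annotation tracks); correctness of both is pinned against a brute-force
all-pairs oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .models import (
    AnnotationFeature,
    CnvCall,
    CnvType,
    FeatureClass,
    FilterTrace,
    GenomicInterval,
    SampleRecord,
    TraceEntry,
)
from . import sample_qc

CallKey = tuple[str, str, int, int, str]


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share >= 1 base (1-based inclusive ends)."""
    return a.overlaps(b)


def _build_trees(
    intervals: Iterable[tuple[GenomicInterval, object]]
) -> dict[str, IntervalTree]:
    """Index intervals per chromosome; inclusive ends become half-open +1."""
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end + 1, payload
        )
    return trees


def _query(trees: Mapping[str, IntervalTree], iv: GenomicInterval):
    tree = trees.get(iv.chrom)
    return tree.overlap(iv.start, iv.end + 1) if tree is not None else ()


def confidence_filter(
    calls: Sequence[CnvCall], min_conf: float = 30.0, *, cohort: str = ""
) -> tuple[list[CnvCall], TraceEntry]:
    """Criterion IV: drop calls whose confidence is below ``min_conf``.

    The comparison is strict ("below"): a call exactly at the threshold is
    retained.  A call without a confidence value cannot be certified and is
    excluded.
    """
    retained = [c for c in calls if c.conf is not None and c.conf >= min_conf]
    excluded = [c.key() for c in calls if c.conf is None or c.conf < min_conf]
    entry = TraceEntry(
        step_id="IV",
        unit="cnvs",
        n_in=len(calls),
        n_out=len(retained),
        excluded_ids=tuple(excluded),
        cohort=cohort,
    )
    return retained, entry


def snp_count_filter(
    calls: Sequence[CnvCall], min_snps: int = 3, *, cohort: str = ""
) -> tuple[list[CnvCall], TraceEntry]:
    """Criterion V: drop calls supported by fewer than ``min_snps`` SNPs."""
    retained = [c for c in calls if c.num_snps >= min_snps]
    excluded = [c.key() for c in calls if c.num_snps < min_snps]
    entry = TraceEntry(
        step_id="V",
        unit="cnvs",
        n_in=len(calls),
        n_out=len(retained),
        excluded_ids=tuple(excluded),
        cohort=cohort,
    )
    return retained, entry


def _reciprocal_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / a.size, inter / b.size)


def _merged_union(
    intervals: Iterable[GenomicInterval],
) -> dict[str, tuple[list[int], list[int]]]:
    """Per-chromosome disjoint union of intervals, sorted by start.

    A cohort of control calls contains thousands of duplicated common-CNV
    intervals; merging them into a disjoint union makes the any-overlap
    query a single bisection (ends are strictly increasing once merged).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    union: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda x: (x.start, x.end))
        starts: list[int] = []
        ends: list[int] = []
        for iv in ivs:
            if starts and iv.start <= ends[-1]:
                if iv.end > ends[-1]:
                    ends[-1] = iv.end
            else:
                starts.append(iv.start)
                ends.append(iv.end)
        union[chrom] = (starts, ends)
    return union


def _union_overlaps(
    union: Mapping[str, tuple[list[int], list[int]]], iv: GenomicInterval
) -> bool:
    from bisect import bisect_right

    entry = union.get(iv.chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = bisect_right(starts, iv.end) - 1
    return i >= 0 and ends[i] >= iv.start


def control_overlap_filter(
    case_calls: Sequence[CnvCall],
    control_calls: Sequence[CnvCall],
    *,
    type_matched: bool = False,
    min_reciprocal: float = 0.0,
) -> tuple[list[CnvCall], TraceEntry]:
    """Step VI: drop case calls overlapped by one or more control calls.

    Defaults implement the literal any-overlap rule: a single shared base
    with a control call of either type excludes the case call.
    ``type_matched=True`` requires the control call to be of the same type;
    ``min_reciprocal`` in (0,1] requires that fraction of reciprocal overlap
    before exclusion.

    Existence-only queries run against a merged per-chromosome union of the
    control intervals (cohort-scale control sets carry heavy duplication);
    the reciprocal-overlap variant needs individual control intervals and
    falls back to a per-chromosome scan.  Both paths are pinned against the
    brute-force all-pairs oracle in the test suite.
    """
    retained, excluded = [], []
    if min_reciprocal > 0.0:
        by_chrom: dict[str, list[CnvCall]] = {}
        for ctrl in control_calls:
            by_chrom.setdefault(ctrl.interval.chrom, []).append(ctrl)
        for call in case_calls:
            hit = any(
                call.interval.overlaps(ctrl.interval)
                and (not type_matched or ctrl.cnv_type == call.cnv_type)
                and _reciprocal_fraction(call.interval, ctrl.interval)
                >= min_reciprocal
                for ctrl in by_chrom.get(call.interval.chrom, ())
            )
            (excluded if hit else retained).append(call)
    else:
        if type_matched:
            unions = {
                cnv_type: _merged_union(
                    c.interval for c in control_calls if c.cnv_type is cnv_type
                )
                for cnv_type in CnvType
            }
            def _hit(call: CnvCall) -> bool:
                return _union_overlaps(unions[call.cnv_type], call.interval)
        else:
            union = _merged_union(c.interval for c in control_calls)
            def _hit(call: CnvCall) -> bool:
                return _union_overlaps(union, call.interval)
        for call in case_calls:
            (excluded if _hit(call) else retained).append(call)
    entry = TraceEntry(
        step_id="VI",
        unit="cnvs",
        n_in=len(case_calls),
        n_out=len(retained),
        excluded_ids=tuple(c.key() for c in excluded),
        cohort="case",
    )
    return retained, entry


def population_variant_filter(
    calls: Sequence[CnvCall], pop_features: Sequence[AnnotationFeature]
) -> tuple[list[CnvCall], TraceEntry]:
    """Step VII: type-matched exclusion against a population-CNV catalogue.

    Losses are excluded iff they overlap a catalogued population loss, gains
    iff they overlap a catalogued population gain.  Overlap with the opposite
    type never excludes a call.
    """
    loss_trees = _build_trees(
        (f.interval, f)
        for f in pop_features
        if f.feature_class is FeatureClass.POP_LOSS
    )
    gain_trees = _build_trees(
        (f.interval, f)
        for f in pop_features
        if f.feature_class is FeatureClass.POP_GAIN
    )
    retained, excluded = [], []
    for call in calls:
        trees = loss_trees if call.cnv_type is CnvType.LOSS else gain_trees
        if _query(trees, call.interval):
            excluded.append(call.key())
        else:
            retained.append(call)
    entry = TraceEntry(
        step_id="VII",
        unit="cnvs",
        n_in=len(calls),
        n_out=len(retained),
        excluded_ids=tuple(excluded),
        cohort="case",
    )
    return retained, entry


def derive_promoters(
    gene_features: Iterable[AnnotationFeature], upstream_bp: int = 2000
) -> list[AnnotationFeature]:
    """Derive strand-aware promoter windows upstream of each gene.

    For a "+" gene the promoter is ``[start - upstream_bp, start - 1]``; for
    a "-" gene it is ``[end + 1, end + upstream_bp]``.  Windows are clipped
    at position 1; a gene starting at base 1 has no upstream window on the
    "+" strand.  A gene without strand information cannot be given a
    promoter and raises an error.
    """
    promoters: list[AnnotationFeature] = []
    for gene in gene_features:
        if gene.feature_class is not FeatureClass.CODING_GENE:
            continue
        iv = gene.interval
        if gene.strand == "+":
            start, end = max(1, iv.start - upstream_bp), iv.start - 1
        elif gene.strand == "-":
            start, end = iv.end + 1, iv.end + upstream_bp
        else:
            raise ValueError(
                f"gene {gene.name!r} has no strand; cannot derive a promoter"
            )
        if start > end:  # gene starts at the first base of the chromosome
            continue
        promoters.append(
            AnnotationFeature(
                interval=GenomicInterval(iv.chrom, start, end),
                feature_class=FeatureClass.PROMOTER,
                name=f"{gene.name}_promoter",
                strand=gene.strand,
            )
        )
    return promoters


def genic_filter(
    calls: Sequence[CnvCall],
    gene_features: Sequence[AnnotationFeature],
    promoter_upstream_bp: int = 2000,
) -> tuple[list[CnvCall], TraceEntry]:
    """Step VIII: retain only calls residing in coding or promoter regions.

    Explicit promoter features in ``gene_features`` are honored; when none
    are supplied, promoters are derived strand-aware from the coding genes
    with an upstream window of ``promoter_upstream_bp``.
    """
    genes = [f for f in gene_features if f.feature_class is FeatureClass.CODING_GENE]
    promoters = [f for f in gene_features if f.feature_class is FeatureClass.PROMOTER]
    if not promoters:
        promoters = derive_promoters(genes, promoter_upstream_bp)
    trees = _build_trees((f.interval, f) for f in [*genes, *promoters])
    retained, excluded = [], []
    for call in calls:
        if _query(trees, call.interval):
            retained.append(call)
        else:
            excluded.append(call.key())
    entry = TraceEntry(
        step_id="VIII",
        unit="cnvs",
        n_in=len(calls),
        n_out=len(retained),
        excluded_ids=tuple(excluded),
        cohort="case",
    )
    return retained, entry


def visual_inspection_filter(
    calls: Sequence[CnvCall],
    failed_calls: Optional[frozenset[CallKey]] = None,
) -> tuple[list[CnvCall], TraceEntry]:
    """Step IX: drop calls failing an externally supplied visual review.

    Visual inspection of the underlying array intensities is a manual step;
    its outcome enters the cascade as a set of failing call keys.  The
    default (no flags) passes every call, and the step still appears in the
    trace so the accounting is complete.
    """
    failed = failed_calls or frozenset()
    retained = [c for c in calls if c.key() not in failed]
    excluded = [c.key() for c in calls if c.key() in failed]
    entry = TraceEntry(
        step_id="IX",
        unit="cnvs",
        n_in=len(calls),
        n_out=len(retained),
        excluded_ids=tuple(excluded),
        cohort="case",
    )
    return retained, entry


@dataclass(frozen=True)
class CascadeConfig:
    """All thresholds of the cascade, with the standard defaults."""

    call_rate_threshold: float = 0.98
    sd_multiplier: float = 2.0
    min_conf: float = 30.0
    min_snps: int = 3
    promoter_upstream_bp: int = 2000
    control_overlap_type_matched: bool = False
    control_overlap_min_reciprocal: float = 0.0
    exclude_unknown_sex: bool = False
    failed_inspection: frozenset = frozenset()


def run_cascade(
    samples: Sequence[SampleRecord],
    case_calls: Sequence[CnvCall],
    control_calls: Sequence[CnvCall],
    tracks: Sequence[AnnotationFeature],
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[CnvCall], FilterTrace]:
    """Run the full cascade I–IX and return surviving case calls plus trace.

    Sample QC (I–III) and the per-call quality gates (IV–V) are applied to
    cases and controls independently; the comparative and annotation steps
    (VI–IX) apply to case calls only.  Empty cohorts skip the outlier step
    (no standard deviation is estimable from fewer than two samples).
    """
    trace = FilterTrace()
    case_calls = list(case_calls)
    control_calls = list(control_calls)

    surviving_case_calls = case_calls
    surviving_control_calls = control_calls
    for cohort_name, cohort_samples, cohort_calls in (
        ("case", [s for s in samples if s.cohort.value == "case"], case_calls),
        ("control", [s for s in samples if s.cohort.value == "control"], control_calls),
    ):
        if len(cohort_samples) >= 2:
            kept_samples, entries = sample_qc.run_sample_qc(
                cohort_samples,
                cohort_calls,
                call_rate_threshold=config.call_rate_threshold,
                sd_multiplier=config.sd_multiplier,
                exclude_unknown_sex=config.exclude_unknown_sex,
                cohort=cohort_name,
            )
        else:
            kept_samples, entries = list(cohort_samples), []
        for e in entries:
            trace.add(e)
        kept_ids = {s.sample_id for s in kept_samples}
        kept_calls = [c for c in cohort_calls if c.sample_id in kept_ids]
        dropped = tuple(
            c.key() for c in cohort_calls if c.sample_id not in kept_ids
        )
        trace.add(
            TraceEntry(
                step_id="sample_qc_call_drop",
                unit="cnvs",
                n_in=len(cohort_calls),
                n_out=len(kept_calls),
                excluded_ids=dropped,
                cohort=cohort_name,
            )
        )
        kept_calls, e4 = confidence_filter(
            kept_calls, config.min_conf, cohort=cohort_name
        )
        trace.add(e4)
        kept_calls, e5 = snp_count_filter(
            kept_calls, config.min_snps, cohort=cohort_name
        )
        trace.add(e5)
        if cohort_name == "case":
            surviving_case_calls = kept_calls
        else:
            surviving_control_calls = kept_calls

    kept, e6 = control_overlap_filter(
        surviving_case_calls,
        surviving_control_calls,
        type_matched=config.control_overlap_type_matched,
        min_reciprocal=config.control_overlap_min_reciprocal,
    )
    trace.add(e6)
    kept, e7 = population_variant_filter(
        kept,
        [f for f in tracks if f.feature_class in (FeatureClass.POP_LOSS, FeatureClass.POP_GAIN)],
    )
    trace.add(e7)
    kept, e8 = genic_filter(
        kept,
        [f for f in tracks if f.feature_class in (FeatureClass.CODING_GENE, FeatureClass.PROMOTER)],
        config.promoter_upstream_bp,
    )
    trace.add(e8)
    kept, e9 = visual_inspection_filter(kept, config.failed_inspection)
    trace.add(e9)
    return kept, trace
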