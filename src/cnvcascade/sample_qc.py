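"""Sample-level quality control for array-based molecular karyotyping.

Three exclusion criteria are applied, in order, before any CNV-level
filtering:

I.   sex mismatch between the assumed (recorded) and called (array) sex;
II.  genotyping call rate below a threshold (default 98%);
III. an outlying number of CNV calls per individual, more than a multiple
     (default 2) of the cohort standard deviation above the cohort mean.

Each filter returns the retained samples together with a conservation-checked
trace entry, so the cascade can account for every excluded individual.
Criterion III is computed on the survivors of I and II, separately within
each cohort, and is deliberately not idempotent: removing outliers changes
the mean and standard deviation, so a second application may trim further.
"""

from __future__ import annotations

import statistics
from collections import Counter
from typing import Iterable, Sequence

from .models import CnvCall, SampleRecord, Sex, TraceEntry


def sex_mismatch_filter(
    samples: Sequence[SampleRecord],
    *,
    exclude_unknown: bool = False,
    cohort: str = "",
) -> tuple[list[SampleRecord], TraceEntry]:
    """Exclude samples whose assumed and called sex disagree (criterion I).

    Samples with ``unknown`` in either field are retained by default: an
    unknown cannot demonstrate a mismatch.  Set ``exclude_unknown=True`` to
    treat unknowns as failures.
    """
    retained, excluded = [], []
    for s in samples:
        unknown = Sex.UNKNOWN in (s.assumed_sex, s.called_sex)
        if unknown:
            (excluded if exclude_unknown else retained).append(s)
        elif s.assumed_sex != s.called_sex:
            excluded.append(s)
        else:
            retained.append(s)
    entry = TraceEntry(
        step_id="I",
        unit="samples",
        n_in=len(samples),
        n_out=len(retained),
        excluded_ids=tuple(s.sample_id for s in excluded),
        cohort=cohort,
    )
    return retained, entry


def call_rate_filter(
    samples: Sequence[SampleRecord],
    threshold: float = 0.98,
    *,
    cohort: str = "",
) -> tuple[list[SampleRecord], TraceEntry]:
    """Exclude samples with call rate strictly below ``threshold`` (criterion II).

    The comparison is strict: a call rate exactly at the threshold passes.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0,1], got {threshold}")
    retained = [s for s in samples if s.call_rate >= threshold]
    excluded = [s.sample_id for s in samples if s.call_rate < threshold]
    entry = TraceEntry(
        step_id="II",
        unit="samples",
        n_in=len(samples),
        n_out=len(retained),
        excluded_ids=tuple(excluded),
        cohort=cohort,
    )
    return retained, entry


def cnv_counts_per_sample(
    samples: Sequence[SampleRecord], calls: Iterable[CnvCall]
) -> dict[str, int]:
    """CNV call count for every sample, zero for samples with no calls."""
    counts = Counter(c.sample_id for c in calls)
    return {s.sample_id: counts.get(s.sample_id, 0) for s in samples}


def cnv_count_outlier_filter(
    samples: Sequence[SampleRecord],
    calls: Iterable[CnvCall],
    sd_multiplier: float = 2.0,
    *,
    cohort: str = "",
) -> tuple[list[SampleRecord], TraceEntry]:
    """Exclude samples with an outlying CNV count (criterion III).

    A sample is excluded when its call count strictly exceeds
    ``mean + sd_multiplier * sd``, where mean and sd are computed over the
    input samples themselves (sd is the sample standard deviation, n-1
    denominator).  The trim is one-sided: an excess of calls indicates a
    failed array, a deficit does not.  With fewer than two samples the
    standard deviation is undefined and an error is raised.
    """
    if len(samples) < 2:
        raise ValueError(
            "CNV-count outlier filtering needs at least 2 samples to "
            "estimate a standard deviation"
        )
    counts = cnv_counts_per_sample(samples, calls)
    values = list(counts.values())
    mean = statistics.fmean(values)
    sd = statistics.stdev(values)
    cutoff = mean + sd_multiplier * sd
    retained = [s for s in samples if counts[s.sample_id] <= cutoff]
    excluded = [s.sample_id for s in samples if counts[s.sample_id] > cutoff]
    entry = TraceEntry(
        step_id="III",
        unit="samples",
        n_in=len(samples),
        n_out=len(retained),
        excluded_ids=tuple(excluded),
        cohort=cohort,
    )
    return retained, entry


def run_sample_qc(
    samples: Sequence[SampleRecord],
    calls: Iterable[CnvCall],
    *,
    call_rate_threshold: float = 0.98,
    sd_multiplier: float = 2.0,
    exclude_unknown_sex: bool = False,
    cohort: str = "",
) -> tuple[list[SampleRecord], list[TraceEntry]]:
    """Apply criteria I -> II -> III in order within one cohort.

    CNV counts for criterion III are computed on the survivors of I and II
    only, so samples already excluded cannot distort the outlier threshold.
    """
    calls = list(calls)
    after_sex, e1 = sex_mismatch_filter(
        samples, exclude_unknown=exclude_unknown_sex, cohort=cohort
    )
    after_rate, e2 = call_rate_filter(
        after_sex, call_rate_threshold, cohort=cohort
    )
    after_outlier, e3 = cnv_count_outlier_filter(
        after_rate, calls, sd_multiplier, cohort=cohort
    )
    return after_outlier, [e1, e2, e3]
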