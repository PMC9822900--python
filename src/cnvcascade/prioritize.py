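"""Turn surviving CNV calls into a prioritization report.

Computes event sizes, gene content, trio inheritance labels, the
microscopic/submicroscopic category, an upper bound on the population
frequency implied by the control screen, and cohort-level summary
statistics (events, deletions/duplications, carriers, percent of cases).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .models import (
    AnnotationFeature,
    Category,
    CnvCall,
    CnvType,
    FeatureClass,
    GenomicInterval,
    Inheritance,
    PrioritizedCnv,
)

#: Interstitial events at least this large are visible on a conventional
#: karyotype regardless of the terminal flag.
MICROSCOPIC_SIZE_BP = 5_000_000


def cnv_size(interval: GenomicInterval) -> int:
    """Size in base pairs between the first and last affected SNP, inclusive."""
    return interval.end - interval.start + 1


def annotate_genes(
    call: CnvCall, gene_features: Sequence[AnnotationFeature]
) -> list[str]:
    """Names of all coding genes overlapping the call, deduplicated and sorted."""
    names = {
        f.name
        for f in gene_features
        if f.feature_class is FeatureClass.CODING_GENE
        and f.interval.overlaps(call.interval)
    }
    return sorted(names)


class AmbiguousInheritanceError(ValueError):
    """The CNV was observed in both parents; a single label cannot be assigned."""


def infer_inheritance(
    parental_observations: Mapping[str, str]
) -> Inheritance:
    """Classify a child-carried CNV from parental presence calls.

    ``parental_observations`` maps ``"mother"``/``"father"`` to one of
    ``"present"``, ``"absent"``, ``"missing"`` (no DNA available).  A parent
    not in the mapping counts as missing.

    Both parents absent -> de novo; exactly one parent present -> maternal
    or paternal; no parent present but at least one missing -> unknown
    (transmission cannot be excluded).  Both parents present is ambiguous
    and raises :class:`AmbiguousInheritanceError`.
    """
    allowed = {"present", "absent", "missing"}
    obs = {}
    for parent in ("mother", "father"):
        value = parental_observations.get(parent, "missing")
        if value not in allowed:
            raise ValueError(
                f"contradictory or unknown observation for {parent}: {value!r}"
            )
        obs[parent] = value
    if obs["mother"] == "present" and obs["father"] == "present":
        raise AmbiguousInheritanceError(
            "CNV observed in both parents; maternal and paternal transmission "
            "are both consistent"
        )
    if obs["mother"] == "present":
        return Inheritance.MATERNAL
    if obs["father"] == "present":
        return Inheritance.PATERNAL
    if obs["mother"] == "absent" and obs["father"] == "absent":
        return Inheritance.DE_NOVO
    return Inheritance.UNKNOWN


def classify_category(
    call: CnvCall,
    terminal: bool,
    size_threshold_bp: int = MICROSCOPIC_SIZE_BP,
) -> Category:
    """Microscopic iff the event is terminal or at least ``size_threshold_bp``.

    Terminal rearrangements (extending to a chromosome end, including the
    segments of unbalanced translocations) are visible on a conventional
    karyotype even when small, so the terminal flag overrides size.
    """
    if terminal or cnv_size(call.interval) >= size_threshold_bp:
        return Category.MICROSCOPIC
    return Category.SUBMICROSCOPIC


def control_frequency_bound(
    n_controls: int, n_carriers_in_controls: int = 0
) -> float:
    """Upper bound on the population frequency implied by a control screen.

    Observing ``k`` carriers among ``n`` controls bounds the frequency
    strictly below ``(k + 1) / n``; for a CNV absent from all controls the
    bound is ``1 / n``.
    """
    if n_controls < 1:
        raise ValueError("need at least one control to bound a frequency")
    if n_carriers_in_controls < 0:
        raise ValueError("carrier count cannot be negative")
    return (n_carriers_in_controls + 1) / n_controls


def default_locus_label(call: CnvCall) -> str:
    prefix = "del" if call.cnv_type is CnvType.LOSS else "dup"
    return f"{prefix}{call.interval}"


def build_report(
    calls: Sequence[CnvCall],
    gene_features: Sequence[AnnotationFeature],
    *,
    n_controls: int,
    terminal_flags: Optional[Mapping[tuple, bool]] = None,
    parental_observations: Optional[Mapping[tuple, Mapping[str, str]]] = None,
    locus_labels: Optional[Mapping[tuple, str]] = None,
    control_carriers: Optional[Mapping[tuple, int]] = None,
    size_threshold_bp: int = MICROSCOPIC_SIZE_BP,
) -> list[PrioritizedCnv]:
    """Assemble prioritized CNV events from surviving per-sample calls.

    Calls from different samples are unified into one event when they match
    exactly in interval, type and category — the criterion under which an
    affected sib-pair sharing identical printed coordinates contributes one
    event with two carriers.  (Category participates in the key so that a
    terminal translocation segment is never merged with an interstitial
    deletion that happens to share coordinates.)  All per-event maps are
    keyed by ``call.key()`` of any carrier's call.
    """
    terminal_flags = terminal_flags or {}
    parental_observations = parental_observations or {}
    locus_labels = locus_labels or {}
    control_carriers = control_carriers or {}

    events: dict[tuple, dict] = {}
    for call in calls:
        terminal = bool(terminal_flags.get(call.key(), False))
        category = classify_category(call, terminal, size_threshold_bp)
        event_key = (*call.locus_key(), category.value)
        bucket = events.setdefault(
            event_key,
            {"call": call, "carriers": [], "terminal": terminal,
             "category": category, "keys": []},
        )
        bucket["carriers"].append(call.sample_id)
        bucket["keys"].append(call.key())

    report: list[PrioritizedCnv] = []
    for bucket in events.values():
        call: CnvCall = bucket["call"]
        obs: Mapping[str, str] = {}
        label = None
        carriers_in_controls = 0
        for key in bucket["keys"]:
            obs = parental_observations.get(key, obs) or obs
            label = locus_labels.get(key, label)
            carriers_in_controls = max(
                carriers_in_controls, control_carriers.get(key, 0)
            )
        report.append(
            PrioritizedCnv(
                call=call,
                carriers=tuple(sorted(set(bucket["carriers"]))),
                locus_label=label or default_locus_label(call),
                size_bp=cnv_size(call.interval),
                genes=tuple(annotate_genes(call, gene_features)),
                inheritance=infer_inheritance(obs),
                category=bucket["category"],
                terminal=bucket["terminal"],
                control_frequency_bound=control_frequency_bound(
                    n_controls, carriers_in_controls
                ),
            )
        )
    from .models import CHROMOSOMES

    report.sort(key=lambda p: (CHROMOSOMES.index(p.call.interval.chrom),
                               p.call.interval.start, p.call.interval.end))
    return report


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level yield of the prioritization cascade."""

    n_events: int
    n_microscopic: int
    n_submicroscopic: int
    n_deletions: int
    n_duplications: int
    n_microdeletions: int  # submicroscopic losses
    n_microduplications: int  # submicroscopic gains
    n_carrier_individuals: int
    pct_of_cases: int
    n_enrolled: int


def summarize(
    prioritized: Sequence[PrioritizedCnv], n_enrolled: int
) -> CohortSummary:
    """Summarize prioritized events against the enrolled cohort size.

    Counts are over distinct events (a sib-pair sharing one CNV is one
    event with two carriers); the percentage of cases is
    ``round(100 * carriers / n_enrolled)``.  The denominator is the number
    of individuals enrolled, not the number surviving QC; callers wanting
    the QC-passed denominator pass it explicitly.
    """
    if n_enrolled < 1:
        raise ValueError("n_enrolled must be >= 1")
    carriers = set()
    for p in prioritized:
        carriers.update(p.carriers)
    n_events = len(prioritized)
    n_micro = sum(1 for p in prioritized if p.category is Category.MICROSCOPIC)
    n_del = sum(1 for p in prioritized if p.call.cnv_type is CnvType.LOSS)
    submicro = [p for p in prioritized if p.category is Category.SUBMICROSCOPIC]
    n_microdel = sum(1 for p in submicro if p.call.cnv_type is CnvType.LOSS)
    pct = round(100 * len(carriers) / n_enrolled)
    return CohortSummary(
        n_events=n_events,
        n_microscopic=n_micro,
        n_submicroscopic=n_events - n_micro,
        n_deletions=n_del,
        n_duplications=n_events - n_del,
        n_microdeletions=n_microdel,
        n_microduplications=len(submicro) - n_microdel,
        n_carrier_individuals=len(carriers),
        pct_of_cases=pct,
        n_enrolled=n_enrolled,
    )
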