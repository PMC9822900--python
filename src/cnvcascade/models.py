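"""Core domain types for the CNV prioritization cascade.

All coordinates are 1-based inclusive on hg19 chromosome labels without a
``chr`` prefix.  This matches the convention of SNP-array CNV callers, where
an interval is delimited by the first and last array probe inside the event
and its size is ``end - start + 1``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

#: Allowed chromosome labels (autosomes plus sex chromosomes, hg19 naming).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_CHROM_SET = frozenset(CHROMOSOMES)


def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix and validate the chromosome label."""
    chrom = label[3:] if label.lower().startswith("chr") else label
    if chrom not in _CHROM_SET:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive chromosomal span; the unit of all overlap algebra."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.chrom not in _CHROM_SET:
            raise ValueError(f"unknown chromosome label: {self.chrom!r}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"start must not exceed end: {self.start} > {self.end}"
            )

    @property
    def size(self) -> int:
        """Number of bases covered, ``end - start + 1``."""
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base.

        Adjacent intervals (``self.end + 1 == other.start``) do not overlap;
        a single shared base does.
        """
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:  # e.g. "2:72623204-72939279"
        return f"{self.chrom}:{self.start}-{self.end}"


class CnvType(str, enum.Enum):
    LOSS = "loss"
    GAIN = "gain"


@dataclass(frozen=True)
class CnvCall:
    """One SNP-array CNV call: interval + copy state + supporting evidence.

    ``conf`` is the caller's maximum log Bayes factor for the event; ``None``
    means the caller reported no confidence, which downstream filters treat
    as failing any confidence threshold.
    """

    interval: GenomicInterval
    sample_id: str
    copy_state: int
    num_snps: int
    conf: Optional[float] = None
    start_snp_id: Optional[str] = None
    end_snp_id: Optional[str] = None
    extra: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.copy_state not in (0, 1, 3, 4):
            raise ValueError(
                f"copy_state must be in {{0,1,3,4}} (2 is not a CNV), "
                f"got {self.copy_state}"
            )
        if self.num_snps < 1:
            raise ValueError(f"num_snps must be >= 1, got {self.num_snps}")

    @property
    def cnv_type(self) -> CnvType:
        return CnvType.LOSS if self.copy_state < 2 else CnvType.GAIN

    def key(self) -> tuple[str, str, int, int, str]:
        """Identity of the call as (sample, chrom, start, end, type)."""
        iv = self.interval
        return (self.sample_id, iv.chrom, iv.start, iv.end, self.cnv_type.value)

    def locus_key(self) -> tuple[str, int, int, str]:
        """Identity of the event locus, ignoring the carrier."""
        iv = self.interval
        return (iv.chrom, iv.start, iv.end, self.cnv_type.value)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Cohort(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True)
class SampleRecord:
    """Per-individual QC attributes, cohort membership and family links."""

    sample_id: str
    assumed_sex: Sex = Sex.UNKNOWN
    called_sex: Sex = Sex.UNKNOWN
    call_rate: float = 1.0
    cohort: Cohort = Cohort.CASE
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    visual_inspection_pass: Optional[bool] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"call_rate must lie in [0,1], got {self.call_rate}")
        for pid in (self.mother_id, self.father_id):
            if pid is not None and pid == self.sample_id:
                raise ValueError(
                    f"sample {self.sample_id!r} cannot be its own parent"
                )


class FeatureClass(str, enum.Enum):
    CODING_GENE = "coding_gene"
    PROMOTER = "promoter"
    POP_LOSS = "pop_loss"
    POP_GAIN = "pop_gain"


@dataclass(frozen=True)
class AnnotationFeature:
    """An annotation-track interval: a gene, a promoter, or a population CNV."""

    interval: GenomicInterval
    feature_class: FeatureClass
    name: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")


@dataclass(frozen=True)
class TraceEntry:
    """One accounting row of the filter cascade.

    Conservation (``n_in == n_out + len(excluded_ids)``) is enforced at
    construction so a filter can never silently drop or duplicate records.
    """

    step_id: str
    unit: str  # "samples" or "cnvs"
    n_in: int
    n_out: int
    excluded_ids: tuple = ()
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.unit not in ("samples", "cnvs"):
            raise ValueError(f"unit must be 'samples' or 'cnvs', got {self.unit!r}")
        if self.n_in != self.n_out + len(self.excluded_ids):
            raise ValueError(
                f"trace conservation violated at step {self.step_id}: "
                f"{self.n_in} != {self.n_out} + {len(self.excluded_ids)}"
            )


@dataclass
class FilterTrace:
    """Ordered per-step in/out accounting for samples and CNV calls."""

    entries: list[TraceEntry] = field(default_factory=list)

    def add(self, entry: TraceEntry) -> None:
        self.entries.append(entry)

    def extend(self, other: "FilterTrace") -> None:
        self.entries.extend(other.entries)

    def total_excluded(self, unit: str) -> int:
        return sum(len(e.excluded_ids) for e in self.entries if e.unit == unit)


class Inheritance(str, enum.Enum):
    DE_NOVO = "de_novo"
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    UNKNOWN = "unknown"


class Category(str, enum.Enum):
    MICROSCOPIC = "microscopic"
    SUBMICROSCOPIC = "submicroscopic"


@dataclass(frozen=True)
class PrioritizedCnv:
    """A surviving CNV event annotated for the final report.

    One record per distinct event; a CNV shared by siblings contributes a
    single record with both carriers listed.
    """

    call: CnvCall
    carriers: tuple[str, ...]
    locus_label: str
    size_bp: int
    genes: tuple[str, ...]
    inheritance: Inheritance
    category: Category
    terminal: bool
    control_frequency_bound: float

    def __post_init__(self) -> None:
        iv = self.call.interval
        if self.size_bp != iv.end - iv.start + 1:
            raise ValueError(
                f"size_bp {self.size_bp} inconsistent with interval {iv}"
            )
        if not self.carriers:
            raise ValueError("a prioritized CNV needs at least one carrier")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Raw Ct readings for one sample at one locus.

    ``housekeeping_cts`` maps each of the (typically three) reference-gene
    labels to its replicate Ct list.  ``math.inf`` encodes the
    no-amplification sentinel (zero template copies).
    """

    sample_id: str
    locus: str
    target_cts: tuple[float, ...]
    housekeeping_cts: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        if len(self.target_cts) < 1:
            raise ValueError("at least one target replicate is required")
        for gene, cts in self.housekeeping_cts.items():
            if len(cts) < 1:
                raise ValueError(f"housekeeping gene {gene!r} has no replicates")


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Relative-quantification result and integer copy-number call."""

    sample_id: str
    locus: str
    delta_ct: float
    delta_delta_ct: float
    relative_quantity: float
    cn_call: Optional[int]  # None encodes no_call
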