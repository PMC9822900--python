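"""Bundled validation fixture: 13 confirmed CNV events in 14 individuals.

This fixture encodes the final, qPCR-confirmed yield of a published
genome-wide CNV screen of 450 individuals with anorectal malformations
against 4392 (4066 post-QC) healthy controls: four microscopic chromosomal
anomalies (two unbalanced terminal translocations, two terminal de novo
duplications) and nine submicroscopic CNVs — seven microdeletions and two
microduplications — carried by 12 singletons and one affected sib-pair.

Coordinates (hg19, first and last affected SNP, 1-based inclusive), event
types, carrier counts, gene content and inheritance are the published
values.  Everything the screen did not print is synthetic: call-support
attributes (SNP counts, confidence scores) are nominal placeholders, and
the gene track places each published gene symbol at a plausible span
overlapping its CNV — it is a stand-in for a real annotation track, not a
faithful gene model.  An unbalanced translocation is represented by its
deleted segment (the segment named in the karyotype label); the reciprocal
duplicated segment belongs to the same anomaly and is not a separate event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .models import (
    AnnotationFeature,
    CnvCall,
    Cohort,
    FeatureClass,
    GenomicInterval,
    PrioritizedCnv,
    SampleRecord,
    Sex,
)
from . import prioritize

#: Individuals enrolled in the screen (denominator of the headline yield).
N_ENROLLED = 450
#: Controls surviving QC, against which absence bounds the CNV frequency.
N_CONTROLS_QC = 4066

# (individual, sex, mother available, father available)
_INDIVIDUALS = [
    ("individual_01", Sex.FEMALE, False, False),
    ("individual_02", Sex.FEMALE, False, False),
    ("individual_03", Sex.MALE, True, True),
    ("individual_04", Sex.MALE, True, True),
    ("individual_05", Sex.FEMALE, True, True),
    ("individual_06", Sex.MALE, True, True),
    ("individual_07", Sex.MALE, True, True),
    ("individual_08", Sex.MALE, True, True),
    ("individual_09", Sex.FEMALE, True, True),
    ("individual_10", Sex.MALE, True, True),
    ("individual_11", Sex.MALE, False, False),
    ("individual_12", Sex.FEMALE, True, True),
    ("individual_13", Sex.MALE, True, True),
    ("individual_14", Sex.FEMALE, True, True),
]

# One row per carrier call:
# (sample, label, chrom, start, end, type, terminal, mother_obs, father_obs)
# where the parental observations feed the inheritance classifier
# (present / absent / missing).
_CALLS = [
    ("individual_01", "46,XX,der(11)t(11;16)(q24.2;q22.2)",
     "11", 127078525, 134923456, "loss", True, "missing", "missing"),
    ("individual_02", "46,XX,der(22)t(22;9)(q11.21;p)",
     "22", 18875445, 21461607, "loss", True, "missing", "missing"),
    ("individual_03", "46,XY,dup(3)(q26.31-q29)",
     "3", 171615261, 196805528, "gain", True, "absent", "absent"),
    ("individual_04", "46,XY,dup(17)(q25.3-qter)",
     "17", 80545076, 81033874, "gain", True, "absent", "absent"),
    ("individual_05", "del2p13.2",
     "2", 72623204, 72939279, "loss", False, "present", "absent"),
    ("individual_06", "dup2p13.2",
     "2", 72882934, 73015587, "gain", False, "present", "absent"),
    ("individual_07", "dup2p13.2",
     "2", 72882934, 73015587, "gain", False, "present", "absent"),
    ("individual_08", "del4p16.2",
     "4", 5162593, 5427691, "loss", False, "absent", "present"),
    ("individual_09", "del7q31.33",
     "7", 126392369, 126439453, "loss", False, "absent", "present"),
    ("individual_10", "dup17q12",
     "17", 33786176, 33968102, "gain", False, "present", "absent"),
    ("individual_11", "del9p24.1",
     "9", 4973080, 5000904, "loss", False, "missing", "missing"),
    ("individual_12", "del16q12.1",
     "16", 50135837, 51522044, "loss", False, "absent", "absent"),
    ("individual_13", "del18q32",
     "18", 76501085, 77373296, "loss", False, "absent", "absent"),
    ("individual_14", "del22q11.21",
     "22", 18875445, 21461607, "loss", False, "absent", "absent"),
]

# Synthetic gene placements: (name, chrom, start, end, strand).  Spans are
# approximate transcript extents chosen to overlap the CNVs that report them.
_GENES = [
    ("EXOC6B", "2", 72529406, 73227056, "-"),
    ("STK32B", "4", 5053453, 5502725, "-"),
    ("GRM8", "7", 126078652, 126896872, "-"),
    ("JAK2", "9", 4985033, 5128183, "+"),
    # dup17q12 content
    ("AP2B1", "17", 33914109, 33968102, "+"),
    ("LINC02001", "17", 33790000, 33805000, "+"),
    ("LOC107985033", "17", 33810000, 33820000, "-"),
    ("PEX12", "17", 33901775, 33922107, "-"),
    ("SLFN12L", "17", 33840000, 33860000, "+"),
    ("SLFN14", "17", 33866000, 33880000, "-"),
    ("SNORD7", "17", 33882000, 33883000, "+"),
    # del16q12.1 content
    ("ADCY7", "16", 50300000, 50350000, "+"),
    ("BRD7", "16", 50346000, 50400000, "-"),
    ("CYLD", "16", 50775000, 50835000, "+"),
    ("HEATR3", "16", 50100000, 50160000, "+"),
    ("NKD1", "16", 50582000, 50680000, "+"),
    ("NOD2", "16", 50731000, 50766000, "+"),
    ("PAPD5", "16", 50190000, 50270000, "+"),
    ("SALL1", "16", 51169000, 51185000, "-"),
    ("SNX20", "16", 50700000, 50710000, "-"),
    # del18q32 content
    ("ATP9B", "18", 76829000, 77150000, "+"),
    ("NFATC1", "18", 77155000, 77290000, "+"),
    ("SALL3", "18", 76740000, 76780000, "+"),
    # candidate genes inside the large terminal duplications
    ("FOXK2", "17", 80477593, 80562483, "+"),
    ("LPP", "3", 187871064, 188608460, "+"),
]


@dataclass(frozen=True)
class StudyFixture:
    """The bundled validated-CNV cohort: samples, calls, tracks, trio data."""

    samples: tuple[SampleRecord, ...]
    calls: tuple[CnvCall, ...]
    tracks: tuple[AnnotationFeature, ...]
    parental_observations: Mapping[tuple, Mapping[str, str]]
    terminal_flags: Mapping[tuple, bool]
    locus_labels: Mapping[tuple, str]
    n_enrolled: int = N_ENROLLED
    n_controls: int = N_CONTROLS_QC

    def build_report(self) -> list[PrioritizedCnv]:
        """Prioritized events with computed sizes, genes, inheritance, category."""
        return prioritize.build_report(
            self.calls,
            self.tracks,
            n_controls=self.n_controls,
            terminal_flags=self.terminal_flags,
            parental_observations=self.parental_observations,
            locus_labels=self.locus_labels,
        )

    def summary(self) -> prioritize.CohortSummary:
        return prioritize.summarize(self.build_report(), self.n_enrolled)


def load_fixture() -> StudyFixture:
    """Assemble the fixture from its literal tables."""
    samples = []
    for sid, sex, has_mother, has_father in _INDIVIDUALS:
        samples.append(
            SampleRecord(
                sample_id=sid,
                assumed_sex=sex,
                called_sex=sex,
                call_rate=0.995,
                cohort=Cohort.CASE,
                mother_id=f"{sid}_mother" if has_mother else None,
                father_id=f"{sid}_father" if has_father else None,
            )
        )

    calls = []
    parental: dict[tuple, dict[str, str]] = {}
    terminal: dict[tuple, bool] = {}
    labels: dict[tuple, str] = {}
    for sid, label, chrom, start, end, cnv_type, is_terminal, mobs, fobs in _CALLS:
        call = CnvCall(
            interval=GenomicInterval(chrom, start, end),
            sample_id=sid,
            copy_state=1 if cnv_type == "loss" else 3,
            num_snps=50,  # synthetic placeholder; not published
            conf=99.0,  # synthetic placeholder; not published
        )
        calls.append(call)
        parental[call.key()] = {"mother": mobs, "father": fobs}
        terminal[call.key()] = is_terminal
        labels[call.key()] = label

    tracks = tuple(
        AnnotationFeature(
            interval=GenomicInterval(chrom, start, end),
            feature_class=FeatureClass.CODING_GENE,
            name=name,
            strand=strand,
        )
        for name, chrom, start, end, strand in _GENES
    )
    return StudyFixture(
        samples=tuple(samples),
        calls=tuple(calls),
        tracks=tracks,
        parental_observations=parental,
        terminal_flags=terminal,
        locus_labels=labels,
    )
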