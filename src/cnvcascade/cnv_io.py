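"""Readers and writers for the pipeline's external text formats.

Supported formats:

* caller ``rawcnv`` text (one CNV call per line, read and write),
* BED3/BED6 annotation tracks (read; converted to 1-based inclusive),
* sample metadata TSV (read/write),
* the prioritization report TSV (read/write),
* qPCR Ct tables as CSV (read/write).

All conversion between the BED convention (0-based half-open) and the
internal convention (1-based inclusive) happens here and nowhere else.
"""

from __future__ import annotations

import csv
import math
import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .models import (
    AnnotationFeature,
    CnvCall,
    Cohort,
    FeatureClass,
    GenomicInterval,
    PrioritizedCnv,
    QpcrMeasurement,
    SampleRecord,
    Sex,
    normalize_chrom,
)

PathLike = Union[str, Path]

_REGION_RE = re.compile(r"^(?:chr)?([0-9XYxy]+):([0-9.,]+)-([0-9.,]+)$")
_STATE_RE = re.compile(r"^state(\d+),cn=(\d+)$")

# rawcnv state index for each copy number (state2 = one-copy loss, etc.)
_CN_TO_STATE = {0: 1, 1: 2, 3: 5, 4: 6}

_KNOWN_KEYS = ("numsnp", "length", "startsnp", "endsnp", "conf")


def _parse_position(token: str, *, allow_digit_separators: bool) -> int:
    """Parse a base position, optionally tolerating '.' or ',' digit groups."""
    if token.isdigit():
        return int(token)
    if allow_digit_separators:
        stripped = token.replace(".", "").replace(",", "")
        if stripped.isdigit():
            return int(stripped)
    raise ValueError(f"bad coordinate: {token!r}")


def parse_region(
    token: str, *, allow_digit_separators: bool = False
) -> GenomicInterval:
    """Parse ``chrN:start-end`` (1-based inclusive) into a GenomicInterval."""
    m = _REGION_RE.match(token.strip())
    if not m:
        raise ValueError(f"bad region token: {token!r}")
    chrom = normalize_chrom("chr" + m.group(1).upper())
    start = _parse_position(m.group(2), allow_digit_separators=allow_digit_separators)
    end = _parse_position(m.group(3), allow_digit_separators=allow_digit_separators)
    return GenomicInterval(chrom, start, end)


def _parse_rawcnv_line(line: str, lineno: int) -> CnvCall:
    tokens = line.split()
    if len(tokens) < 4:
        raise ValueError(f"line {lineno}: too few fields in rawcnv line")
    try:
        interval = parse_region(tokens[0])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc

    num_snps: Optional[int] = None
    copy_state: Optional[int] = None
    sample_id: Optional[str] = None
    conf: Optional[float] = None
    start_snp = end_snp = None
    extra: list[tuple[str, str]] = []

    for tok in tokens[1:]:
        state_m = _STATE_RE.match(tok)
        if state_m:
            cn = int(state_m.group(2))
            if cn == 2:
                raise ValueError(
                    f"line {lineno}: cn=2 is not a copy-number variant"
                )
            copy_state = cn
            continue
        if "=" in tok:
            key, _, value = tok.partition("=")
            key = key.lower()
            if key == "numsnp":
                num_snps = int(value.replace(",", ""))
            elif key == "startsnp":
                start_snp = value
            elif key == "endsnp":
                end_snp = value
            elif key == "conf":
                conf = float(value)
            elif key == "length":
                pass  # redundant with the interval; recomputed on write
            else:
                extra.append((key, value))
            continue
        if sample_id is None:
            sample_id = tok
        else:
            extra.append((tok, ""))

    if copy_state is None:
        raise ValueError(f"line {lineno}: missing state/cn token")
    if num_snps is None:
        raise ValueError(f"line {lineno}: missing numsnp token")
    if sample_id is None:
        raise ValueError(f"line {lineno}: missing sample identifier")

    try:
        return CnvCall(
            interval=interval,
            sample_id=sample_id,
            copy_state=copy_state,
            num_snps=num_snps,
            conf=conf,
            start_snp_id=start_snp,
            end_snp_id=end_snp,
            extra=tuple(extra),
        )
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc


def read_penncnv(path: PathLike) -> list[CnvCall]:
    """Read a caller ``rawcnv`` file into CnvCall records.

    Coordinates are taken verbatim as 1-based inclusive.  Lines reporting a
    diploid state (``cn=2``) are rejected: by definition they are not CNVs.
    Malformed lines raise ValueError naming the offending line number.
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            calls.append(_parse_rawcnv_line(line, lineno))
    return calls


def format_rawcnv_line(call: CnvCall) -> str:
    iv = call.interval
    fields = [
        f"chr{iv.chrom}:{iv.start}-{iv.end}",
        f"numsnp={call.num_snps}",
        f"length={iv.size}",
        f"state{_CN_TO_STATE[call.copy_state]},cn={call.copy_state}",
        call.sample_id,
    ]
    if call.start_snp_id is not None:
        fields.append(f"startsnp={call.start_snp_id}")
    if call.end_snp_id is not None:
        fields.append(f"endsnp={call.end_snp_id}")
    if call.conf is not None:
        fields.append(f"conf={call.conf:g}")
    fields.extend(f"{k}={v}" if v else k for k, v in call.extra)
    return " ".join(fields)


def write_penncnv(calls: Iterable[CnvCall], path: PathLike) -> None:
    """Write calls back out in the caller's rawcnv dialect."""
    with open(path, "w") as fh:
        for call in calls:
            fh.write(format_rawcnv_line(call) + "\n")


def read_bed_track(
    path: PathLike, feature_class: FeatureClass
) -> list[AnnotationFeature]:
    """Read a BED3/BED6 file as annotation features of one class.

    BED is 0-based half-open; internal coordinates are 1-based inclusive, so
    ``internal_start = bed_start + 1`` and ``internal_end = bed_end``.  An
    internal length of ``end - start + 1`` therefore equals the BED length
    ``bed_end - bed_start`` for every record.
    """
    feature_class = FeatureClass(feature_class)
    features: list[AnnotationFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 columns")
            chrom = normalize_chrom(cols[0])
            bed_start, bed_end = int(cols[1]), int(cols[2])
            if bed_end <= bed_start:
                raise ValueError(
                    f"line {lineno}: BED end {bed_end} must exceed start {bed_start}"
                )
            name = cols[3] if len(cols) > 3 and cols[3] else f"feature_{lineno}"
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            features.append(
                AnnotationFeature(
                    interval=GenomicInterval(chrom, bed_start + 1, bed_end),
                    feature_class=feature_class,
                    name=name,
                    strand=strand,
                )
            )
    return features


def write_bed_track(features: Iterable[AnnotationFeature], path: PathLike) -> None:
    """Write features as BED6 (internal 1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for feat in features:
            iv = feat.interval
            fh.write(
                f"chr{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{feat.name}\t0\t{feat.strand}\n"
            )


# --- sample metadata -------------------------------------------------------

_SAMPLE_COLUMNS = [
    "sample_id",
    "assumed_sex",
    "called_sex",
    "call_rate",
    "cohort",
    "mother_id",
    "father_id",
    "visual_inspection_pass",
]


def write_samples(samples: Iterable[SampleRecord], path: PathLike) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "assumed_sex": s.assumed_sex.value,
                "called_sex": s.called_sex.value,
                "call_rate": f"{s.call_rate:.6f}",
                "cohort": s.cohort.value,
                "mother_id": s.mother_id or "",
                "father_id": s.father_id or "",
                "visual_inspection_pass": ""
                if s.visual_inspection_pass is None
                else str(s.visual_inspection_pass).lower(),
            }
        )
    pd.DataFrame(rows, columns=_SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_samples(path: PathLike) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    samples = []
    for row in df.itertuples(index=False):
        vip = getattr(row, "visual_inspection_pass", "")
        samples.append(
            SampleRecord(
                sample_id=row.sample_id,
                assumed_sex=Sex(row.assumed_sex or "unknown"),
                called_sex=Sex(row.called_sex or "unknown"),
                call_rate=float(row.call_rate),
                cohort=Cohort(row.cohort),
                mother_id=row.mother_id or None,
                father_id=row.father_id or None,
                visual_inspection_pass=None if vip == "" else vip == "true",
            )
        )
    return samples


# --- prioritization report -------------------------------------------------

REPORT_COLUMNS = [
    "sample_id",
    "locus",
    "chrom",
    "start",
    "end",
    "size_bp",
    "cnv_type",
    "genes",
    "inheritance",
    "category",
    "control_frequency_bound",
]


def write_report(prioritized: Sequence[PrioritizedCnv], path: PathLike) -> None:
    """Write the prioritization report as TSV, one row per distinct CNV event.

    Multiple carriers of a shared event (an affected sib-pair) are joined
    with commas in the ``sample_id`` column.  Column order is fixed and the
    file round-trips through :func:`read_report`.
    """
    rows = []
    for p in prioritized:
        iv = p.call.interval
        rows.append(
            {
                "sample_id": ",".join(p.carriers),
                "locus": p.locus_label,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "size_bp": p.size_bp,
                "cnv_type": p.call.cnv_type.value,
                "genes": ",".join(p.genes),
                "inheritance": p.inheritance.value,
                "category": p.category.value,
                "control_frequency_bound": f"{p.control_frequency_bound:.8g}",
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_report(path: PathLike) -> pd.DataFrame:
    """Read a prioritization report back as a DataFrame (text columns as str)."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "sample_id": str, "genes": str},
        keep_default_na=False,
    )


# --- qPCR Ct tables --------------------------------------------------------

_QPCR_COLUMNS = ["sample_id", "locus", "gene", "role", "replicate", "ct"]


def write_qpcr_csv(measurements: Iterable[QpcrMeasurement], path: PathLike) -> None:
    """Write Ct readings in long form: one row per replicate well.

    A no-amplification well is written as an empty ``ct`` field.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_QPCR_COLUMNS)
        for m in measurements:
            for i, ct in enumerate(m.target_cts, start=1):
                writer.writerow(
                    [m.sample_id, m.locus, "target", "target", i,
                     "" if math.isinf(ct) else f"{ct:.4f}"]
                )
            for gene, cts in m.housekeeping_cts.items():
                for i, ct in enumerate(cts, start=1):
                    writer.writerow(
                        [m.sample_id, m.locus, gene, "housekeeping", i,
                         "" if math.isinf(ct) else f"{ct:.4f}"]
                    )


def read_qpcr_csv(path: PathLike) -> list[QpcrMeasurement]:
    """Read a long-form Ct CSV back into per-sample measurements."""
    targets: dict[tuple[str, str], list[float]] = defaultdict(list)
    housekeeping: dict[tuple[str, str], dict[str, list[float]]] = defaultdict(
        lambda: defaultdict(list)
    )
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["sample_id"], row["locus"])
            ct = math.inf if row["ct"] == "" else float(row["ct"])
            if row["role"] == "target":
                targets[key].append(ct)
            else:
                housekeeping[key][row["gene"]].append(ct)
    measurements = []
    for key in targets:
        sample_id, locus = key
        measurements.append(
            QpcrMeasurement(
                sample_id=sample_id,
                locus=locus,
                target_cts=tuple(targets[key]),
                housekeeping_cts={
                    g: tuple(cts) for g, cts in housekeeping[key].items()
                },
            )
        )
    return measurements
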