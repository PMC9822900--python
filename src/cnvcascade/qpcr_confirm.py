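"""ΔΔCt relative quantification and copy-number confirmation.

The comparative Ct method with three housekeeping reference genes:

    ΔCt   = mean(target Ct) − mean over genes of (per-gene mean Ct)
    ΔΔCt  = ΔCt(sample) − ΔCt(calibrator)
    RQ    = E^(−ΔΔCt)        with amplification efficiency E = 2 by default

A diploid calibrator has RQ 1; a heterozygous deletion halves the template
and shifts the target one cycle later (RQ 0.5); a three-copy duplication
gives RQ 1.5.  The integer copy number is ``2·RQ`` binned around the
theoretical RQ values, with a guard band near bin edges in which no call is
made.  Confirmation requires the called copy number to deviate from 2 in
the direction the array predicted; inheritance is classified from the
parents' calls at the same locus.
"""

from __future__ import annotations

import math
from statistics import fmean
from typing import Mapping, Optional, Sequence

from .models import (
    CnvCall,
    CnvType,
    CopyNumberEstimate,
    Inheritance,
    QpcrMeasurement,
)
from .prioritize import infer_inheritance

#: RQ bin edges between copy numbers 0|1, 1|2, 2|3, 3|4.
RQ_BIN_EDGES = (0.25, 0.75, 1.25, 1.75)

#: Half-width of the no-call guard band around each bin edge, in RQ units.
NO_CALL_GUARD = 0.05


def _finite(values: Sequence[float]) -> list[float]:
    return [v for v in values if math.isfinite(v)]


def delta_ct(measurement: QpcrMeasurement, n_reference_genes: int = 3) -> float:
    """ΔCt: mean target Ct minus the averaged per-gene housekeeping means.

    The reference is the unweighted mean of the per-gene mean Cts, not the
    pooled replicate mean, so unequal replicate counts across reference
    genes do not bias the normalization.  A target that never amplified
    (all replicates at the no-amplification sentinel) yields ``+inf``,
    consistent with zero template copies.
    """
    if len(measurement.housekeeping_cts) < n_reference_genes:
        raise ValueError(
            f"need {n_reference_genes} housekeeping genes, got "
            f"{sorted(measurement.housekeeping_cts)}"
        )
    gene_means = []
    for gene, cts in measurement.housekeeping_cts.items():
        finite = _finite(cts)
        if not finite:
            raise ValueError(f"housekeeping gene {gene!r} never amplified")
        gene_means.append(fmean(finite))
    reference = fmean(gene_means)
    target_finite = _finite(measurement.target_cts)
    if not target_finite:
        return math.inf
    return fmean(target_finite) - reference


def delta_delta_ct(
    sample_dct: float, calibrator_dct: float, efficiency: float = 2.0
) -> tuple[float, float]:
    """ΔΔCt against a diploid calibrator, and the relative quantity E^(−ΔΔCt)."""
    ddct = sample_dct - calibrator_dct
    rq = 0.0 if math.isinf(ddct) and ddct > 0 else efficiency ** (-ddct)
    return ddct, rq


def call_copy_number(relative_quantity: float) -> Optional[int]:
    """Bin an RQ value into an integer copy number 0–4, or no call.

    The estimated copy number is ``2·RQ``; bins are centred on the
    theoretical RQ values 0, 0.5, 1, 1.5, 2 with edges at 0.25/0.75/1.25/1.75.
    Values within ±0.05 of an edge fall in the guard band and return None
    (no call) rather than an arbitrary side of the boundary.
    """
    if relative_quantity < 0:
        raise ValueError("relative quantity cannot be negative")
    for edge in RQ_BIN_EDGES:
        if abs(relative_quantity - edge) < NO_CALL_GUARD:
            return None
    for cn, edge in enumerate(RQ_BIN_EDGES):
        if relative_quantity < edge:
            return cn
    return 4


def estimate_copy_number(
    measurement: QpcrMeasurement,
    calibrator: QpcrMeasurement,
    efficiency: float = 2.0,
) -> CopyNumberEstimate:
    """Full ΔΔCt chain for one sample against the plate calibrator."""
    dct = delta_ct(measurement)
    cal_dct = delta_ct(calibrator)
    ddct, rq = delta_delta_ct(dct, cal_dct, efficiency)
    return CopyNumberEstimate(
        sample_id=measurement.sample_id,
        locus=measurement.locus,
        delta_ct=dct,
        delta_delta_ct=ddct,
        relative_quantity=rq,
        cn_call=call_copy_number(rq),
    )


def _deviates(cn: int, cnv_type: CnvType) -> bool:
    return cn < 2 if cnv_type is CnvType.LOSS else cn > 2


def confirm(
    child: CopyNumberEstimate,
    predicted: CnvCall,
    mother: Optional[CopyNumberEstimate] = None,
    father: Optional[CopyNumberEstimate] = None,
) -> tuple[bool, Inheritance, str]:
    """Confirm an array-predicted CNV by qPCR and classify its inheritance.

    The prediction is confirmed iff the child's called copy number deviates
    from 2 in the predicted direction (loss: CN < 2; gain: CN > 2).  A
    parent whose call deviates in the same direction counts as carrying the
    CNV ("present"); a parent called CN 2 (or deviating the other way) is
    "absent"; a parent without an estimate or without a call is "missing".
    Returns (confirmed, inheritance, reason).
    """
    if child.cn_call is None:
        return False, Inheritance.UNKNOWN, "child_no_call"
    if not _deviates(child.cn_call, predicted.cnv_type):
        return False, Inheritance.UNKNOWN, "no_deviation"

    def observe(parent: Optional[CopyNumberEstimate]) -> str:
        if parent is None or parent.cn_call is None:
            return "missing"
        return "present" if _deviates(parent.cn_call, predicted.cnv_type) else "absent"

    inheritance = infer_inheritance(
        {"mother": observe(mother), "father": observe(father)}
    )
    return True, inheritance, "confirmed"


def confirm_trio(
    measurements: Mapping[str, QpcrMeasurement],
    calibrator_id: str,
    child_id: str,
    predicted: CnvCall,
    mother_id: Optional[str] = None,
    father_id: Optional[str] = None,
    efficiency: float = 2.0,
) -> tuple[bool, Inheritance, dict[str, CopyNumberEstimate]]:
    """Run the ΔΔCt chain for a trio plate and confirm the predicted CNV.

    ``measurements`` maps sample ids (including the calibrator) to their
    Ct readings at one locus.
    """
    calibrator = measurements[calibrator_id]
    estimates = {
        sid: estimate_copy_number(m, calibrator, efficiency)
        for sid, m in measurements.items()
        if sid != calibrator_id
    }
    confirmed, inheritance, _ = confirm(
        estimates[child_id],
        predicted,
        mother=estimates.get(mother_id) if mother_id else None,
        father=estimates.get(father_id) if father_id else None,
    )
    return confirmed, inheritance, estimates
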