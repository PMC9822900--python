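"""Synthetic cohorts, annotation tracks, and qPCR plates.

The generator emulates the statistical structure the cascade assumes in a
SNP-array CNV screen: per-sample genotyping call rates, occasional recorded/
called sex mismatches, overdispersed CNV counts with a small fraction of
failed-array outliers, a pool of common CNV loci shared between cases and
controls, a population-variation catalogue covering those loci, and rare
spiked-in CNVs with known ground truth for recovery benchmarking.  It does
not model per-SNP intensity signal, batch effects, or linkage structure —
calls are placed independently along hg19-sized chromosomes.

Everything is deterministic under a fixed seed: each component draws from
its own child of one seed sequence, so cohort and tracks agree on the
common-pool loci without sharing mutable state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .models import (
    AnnotationFeature,
    CnvCall,
    CnvType,
    Cohort,
    FeatureClass,
    GenomicInterval,
    Inheritance,
    QpcrMeasurement,
    SampleRecord,
    Sex,
)

#: hg19 chromosome sizes (autosomes + X), used to place synthetic intervals.
CHROM_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560,
}

_CHROMS = tuple(CHROM_LENGTHS)
_CHROM_WEIGHTS = np.array([CHROM_LENGTHS[c] for c in _CHROMS], dtype=float)
_CHROM_WEIGHTS /= _CHROM_WEIGHTS.sum()


@dataclass(frozen=True)
class SpikeSpec:
    """A CNV spiked into the cohort with known ground truth.

    ``in_controls`` seeds the same event into control samples (so the
    case/control comparison must reject it); ``in_pop_track`` guarantees a
    type-matched population feature over the locus (so the population
    filter must reject it); ``genic`` guarantees an overlapping coding gene
    (so the genic filter must retain it).
    """

    interval: GenomicInterval
    cnv_type: CnvType
    num_snps: int = 50
    conf: float = 99.0
    inheritance_truth: Inheritance = Inheritance.UNKNOWN
    in_controls: bool = False
    in_pop_track: bool = False
    genic: bool = True

    def copy_state(self) -> int:
        return 1 if self.cnv_type is CnvType.LOSS else 3


@dataclass(frozen=True)
class SpikePlacement:
    """Ground-truth record: which sample received which spike."""

    spec: SpikeSpec
    sample_id: str


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults are calibrated to the scale of a large case/control array
    screen: ~16 CNV calls per individual on average, a call-rate
    distribution leaving roughly 9% of samples under the 98% QC threshold,
    a ~0.5% recorded/called sex discordance rate, and ~3% of samples with
    grossly inflated call counts emulating failed arrays.
    """

    n_cases: int = 450
    n_controls: int = 4392
    seed: int = 0
    call_rate_mean: float = 0.99
    call_rate_sd: float = 0.008
    sex_mismatch_rate: float = 0.005
    cnv_count_mean: float = 16.0
    cnv_count_dispersion: float = 4.0
    outlier_sample_rate: float = 0.03
    outlier_multiplier: float = 4.0
    common_cnv_pool_size: int = 30
    sharing_rate: float = 0.15
    spike_specs: tuple[SpikeSpec, ...] = ()
    n_genes: int = 400
    n_pop_loss: int = 150
    n_pop_gain: int = 150
    call_rate_threshold: float = 0.98  # used to select clean spike carriers

    def __post_init__(self) -> None:
        for name in ("sex_mismatch_rate", "outlier_sample_rate", "sharing_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {value}")
        for name in ("n_cases", "n_controls", "common_cnv_pool_size",
                     "n_genes", "n_pop_loss", "n_pop_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cannot be negative")
        if self.cnv_count_dispersion <= 0:
            raise ValueError("cnv_count_dispersion must be positive")


@dataclass(frozen=True)
class PoolLocus:
    interval: GenomicInterval
    cnv_type: CnvType


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("pool", "samples", "calls", "spikes", "tracks")
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, ss.spawn(len(names)))
    }


def _random_interval(
    rng: np.random.Generator, min_len: int, max_len: int
) -> GenomicInterval:
    chrom = _CHROMS[rng.choice(len(_CHROMS), p=_CHROM_WEIGHTS)]
    length = int(rng.integers(min_len, max_len + 1))
    start = int(rng.integers(1, CHROM_LENGTHS[chrom] - length))
    return GenomicInterval(chrom, start, start + length - 1)


def _overlaps_any(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in others)


def pool_loci(config: CohortConfig) -> list[PoolLocus]:
    """The common CNV loci shared between cases and controls.

    Derived from the config seed alone, so the cohort generator and the
    track generator agree on them.  Loci never overlap a spike interval;
    a spike that cannot be separated from the pool (after resampling) is a
    configuration error, because a pool locus over a case-only spike would
    corrupt the ground truth.
    """
    rng = _streams(config.seed)["pool"]
    spike_ivs = [s.interval for s in config.spike_specs]
    loci: list[PoolLocus] = []
    for i in range(config.common_cnv_pool_size):
        for _ in range(1000):
            iv = _random_interval(rng, 50_000, 500_000)
            if not _overlaps_any(iv, spike_ivs):
                break
        else:
            raise ValueError(
                "could not place a common-pool locus clear of the spike "
                "intervals; spike configuration leaves no room"
            )
        cnv_type = CnvType.LOSS if i % 2 == 0 else CnvType.GAIN
        loci.append(PoolLocus(iv, cnv_type))
    for spec in config.spike_specs:
        if not spec.in_controls and _overlaps_any(
            spec.interval, [l.interval for l in loci]
        ):
            raise ValueError(
                f"case-only spike at {spec.interval} collides with a "
                "common-pool locus; this would corrupt the ground truth"
            )
    return loci


def _draw_call_rates(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _pool_call(locus: PoolLocus, sample_id: str, rng: np.random.Generator) -> CnvCall:
    conf = float(max(30.0, rng.normal(75.0, 15.0)))
    return CnvCall(
        interval=locus.interval,
        sample_id=sample_id,
        copy_state=1 if locus.cnv_type is CnvType.LOSS else 3,
        num_snps=max(3, locus.interval.size // 3000),
        conf=round(conf, 3),
    )


def _background_call(
    sample_id: str,
    rng: np.random.Generator,
    forbidden: Sequence[GenomicInterval],
) -> CnvCall:
    for _ in range(1000):
        iv = _random_interval(rng, 5_000, 200_000)
        if not _overlaps_any(iv, forbidden):
            break
    else:  # pragma: no cover - only reachable with pathological spike sets
        raise ValueError("could not place a background call clear of spikes")
    copy_state = int(rng.choice([0, 1, 1, 1, 3, 3, 4]))
    if rng.random() < 0.05:
        num_snps = int(rng.integers(1, 3))  # exercises the SNP-support gate
    else:
        num_snps = max(3, int(rng.poisson(iv.size / 4000)) + 1)
    conf: Optional[float]
    if rng.random() < 0.03:
        conf = None  # caller reported no confidence
    else:
        conf = round(float(max(0.0, rng.normal(55.0, 20.0))), 3)
    return CnvCall(
        interval=iv,
        sample_id=sample_id,
        copy_state=copy_state,
        num_snps=num_snps,
        conf=conf,
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SampleRecord], list[CnvCall], list[SpikePlacement]]:
    """Generate samples, CNV calls and spike ground truth for one cohort.

    Spiked CNVs are placed in distinct QC-clean case samples (concordant
    sex, call rate at or above the threshold, not a count outlier), cycling
    through the clean samples when there are more spikes than samples.
    Spikes with ``in_controls=True`` are additionally seeded into three
    clean control samples.  Control calls never overlap a case-only spike
    interval, so spike recovery truth is exact by construction.
    """
    rng_s = _streams(config.seed)["samples"]
    rng_c = _streams(config.seed)["calls"]
    rng_k = _streams(config.seed)["spikes"]
    loci = pool_loci(config)
    spike_ivs = [s.interval for s in config.spike_specs]

    samples: list[SampleRecord] = []
    outlier_ids: set[str] = set()
    for cohort, n, prefix in (
        (Cohort.CASE, config.n_cases, "case"),
        (Cohort.CONTROL, config.n_controls, "control"),
    ):
        call_rates = _draw_call_rates(
            rng_s, n, config.call_rate_mean, config.call_rate_sd
        )
        for i in range(n):
            sid = f"{prefix}_{i + 1:04d}"
            assumed = Sex.MALE if rng_s.random() < 0.5 else Sex.FEMALE
            if rng_s.random() < config.sex_mismatch_rate:
                called = Sex.FEMALE if assumed is Sex.MALE else Sex.MALE
            else:
                called = assumed
            if rng_s.random() < config.outlier_sample_rate:
                outlier_ids.add(sid)
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    assumed_sex=assumed,
                    called_sex=called,
                    call_rate=float(call_rates[i]),
                    cohort=cohort,
                )
            )

    counts: dict[str, int] = {}
    for s in samples:
        count = int(
            rng_c.negative_binomial(
                config.cnv_count_dispersion,
                config.cnv_count_dispersion
                / (config.cnv_count_dispersion + config.cnv_count_mean),
            )
        )
        if s.sample_id in outlier_ids:
            count = int(count * config.outlier_multiplier)
        counts[s.sample_id] = count

    calls: list[CnvCall] = []
    for s in samples:
        count = counts[s.sample_id]
        shared = [
            locus for locus in loci if rng_c.random() < config.sharing_rate
        ]
        for locus in shared:
            calls.append(_pool_call(locus, s.sample_id, rng_c))
        for _ in range(max(0, count - len(shared))):
            calls.append(_background_call(s.sample_id, rng_c, spike_ivs))

    truth: list[SpikePlacement] = []
    if config.spike_specs:
        def clean(s: SampleRecord) -> bool:
            return (
                s.assumed_sex == s.called_sex
                and s.call_rate >= config.call_rate_threshold
                and s.sample_id not in outlier_ids
            )

        # Carriers must also survive the CNV-count outlier trim, so prefer
        # clean samples whose realized call count sits at or below the
        # cohort mean: adding one spiked call cannot push them past a
        # mean + 2 SD cutoff of any overdispersed count distribution.
        case_pool = [s for s in samples if s.cohort is Cohort.CASE and clean(s)]
        if not case_pool:
            raise ValueError("no QC-clean case sample available for spikes")
        case_counts = [counts[s.sample_id] for s in samples if s.cohort is Cohort.CASE]
        mean_count = sum(case_counts) / max(1, len(case_counts))
        low = [s for s in case_pool if counts[s.sample_id] <= mean_count]
        clean_cases = sorted(
            low or case_pool, key=lambda s: (counts[s.sample_id], s.sample_id)
        )
        clean_controls = [
            s for s in samples if s.cohort is Cohort.CONTROL and clean(s)
        ]
        for i, spec in enumerate(config.spike_specs):
            carrier = clean_cases[i % len(clean_cases)]
            calls.append(
                CnvCall(
                    interval=spec.interval,
                    sample_id=carrier.sample_id,
                    copy_state=spec.copy_state(),
                    num_snps=spec.num_snps,
                    conf=spec.conf,
                )
            )
            truth.append(SpikePlacement(spec, carrier.sample_id))
            if spec.in_controls:
                if not clean_controls:
                    raise ValueError(
                        "spike requests control carriers but no QC-clean "
                        "control sample exists"
                    )
                k = min(3, len(clean_controls))
                picks = rng_k.choice(len(clean_controls), size=k, replace=False)
                for j in picks:
                    calls.append(
                        CnvCall(
                            interval=spec.interval,
                            sample_id=clean_controls[int(j)].sample_id,
                            copy_state=spec.copy_state(),
                            num_snps=spec.num_snps,
                            conf=spec.conf,
                        )
                    )
    return samples, calls, truth


def generate_tracks(config: CohortConfig) -> list[AnnotationFeature]:
    """Generate gene and population-variation tracks consistent with the cohort.

    Guarantees, by construction:

    * every common-pool locus is covered by a same-type population feature;
    * every spike with ``in_pop_track=True`` is covered by a same-type
      population feature, and no population feature touches a spike with
      ``in_pop_track=False``;
    * every spike with ``genic=True`` overlaps a coding gene, and no gene
      or derived promoter window comes near a spike with ``genic=False``;
    * coding genes do not overlap one another and carry a strand.
    """
    rng = _streams(config.seed)["tracks"]
    loci = pool_loci(config)
    features: list[AnnotationFeature] = []

    nonpop_spikes = [s.interval for s in config.spike_specs if not s.in_pop_track]
    nongenic_zones = [
        GenomicInterval(
            s.interval.chrom,
            max(1, s.interval.start - 10_000),
            s.interval.end + 10_000,
        )
        for s in config.spike_specs
        if not s.genic
    ]

    for i, locus in enumerate(loci):
        iv = locus.interval
        features.append(
            AnnotationFeature(
                interval=GenomicInterval(
                    iv.chrom, max(1, iv.start - 10_000), iv.end + 10_000
                ),
                feature_class=FeatureClass.POP_LOSS
                if locus.cnv_type is CnvType.LOSS
                else FeatureClass.POP_GAIN,
                name=f"pop_pool_{i + 1}",
            )
        )
    for i, spec in enumerate(config.spike_specs):
        if spec.in_pop_track:
            iv = spec.interval
            features.append(
                AnnotationFeature(
                    interval=GenomicInterval(
                        iv.chrom, max(1, iv.start - 1_000), iv.end + 1_000
                    ),
                    feature_class=FeatureClass.POP_LOSS
                    if spec.cnv_type is CnvType.LOSS
                    else FeatureClass.POP_GAIN,
                    name=f"pop_spike_{i + 1}",
                )
            )
    for fc, n in ((FeatureClass.POP_LOSS, config.n_pop_loss),
                  (FeatureClass.POP_GAIN, config.n_pop_gain)):
        placed = 0
        while placed < n:
            iv = _random_interval(rng, 20_000, 300_000)
            if _overlaps_any(iv, nonpop_spikes):
                continue
            features.append(
                AnnotationFeature(interval=iv, feature_class=fc,
                                  name=f"{fc.value}_{placed + 1}")
            )
            placed += 1

    gene_ivs: list[GenomicInterval] = []

    def _add_gene(iv: GenomicInterval, name: str) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            AnnotationFeature(
                interval=iv,
                feature_class=FeatureClass.CODING_GENE,
                name=name,
                strand=strand,
            )
        )
        gene_ivs.append(iv)

    for i, spec in enumerate(config.spike_specs):
        if not spec.genic:
            continue
        iv = spec.interval
        pad = max(0, iv.size // 10)
        _add_gene(
            GenomicInterval(iv.chrom, iv.start + pad,
                            max(iv.start + pad, iv.end - pad)),
            f"SPIKEG{i + 1}",
        )
    placed = 0
    while placed < config.n_genes:
        iv = _random_interval(rng, 2_000, 200_000)
        if _overlaps_any(iv, nongenic_zones) or _overlaps_any(iv, gene_ivs):
            continue
        # keep derived promoter windows clear of non-genic spikes too
        padded = GenomicInterval(
            iv.chrom, max(1, iv.start - 5_000), iv.end + 5_000
        )
        if _overlaps_any(padded, nongenic_zones):
            continue
        _add_gene(iv, f"GENE{placed + 1}")
        placed += 1
    return features


#: Default housekeeping reference genes and their baseline Ct values.
HOUSEKEEPING_BASELINES: dict[str, float] = {"CFTR": 24.0, "BNC1": 25.0, "RNA": 23.5}

#: Baseline target Ct for a diploid (two-copy) template.
DIPLOID_TARGET_CT = 26.0


def generate_qpcr_plate(
    locus: Union[GenomicInterval, str],
    members: Mapping[str, int],
    noise_sd: float = 0.15,
    replicates: int = 3,
    seed: int = 0,
    calibrator_id: str = "calibrator",
) -> list[QpcrMeasurement]:
    """Simulate one qPCR plate: target + three housekeeping genes per sample.

    Each member's true integer copy number shifts the target Ct by
    ``-log2(CN/2)`` relative to the diploid baseline (one copy amplifies one
    cycle later; three copies ~0.58 cycles earlier); housekeeping genes sit
    at fixed per-gene baselines.  Gaussian noise of ``noise_sd`` cycles is
    added per well.  A true copy number of zero never amplifies and is
    recorded as the no-amplification sentinel.  A diploid calibrator sample
    is always included on the plate.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd cannot be negative")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    for sid, cn in members.items():
        if cn not in (0, 1, 2, 3, 4):
            raise ValueError(f"true copy number for {sid!r} must be 0-4, got {cn}")
    if calibrator_id in members and members[calibrator_id] != 2:
        raise ValueError("the calibrator must be diploid")
    rng = np.random.default_rng(seed)
    locus_label = str(locus)

    def _measure(sample_id: str, cn: int) -> QpcrMeasurement:
        if cn == 0:
            target = tuple([math.inf] * replicates)
        else:
            base = DIPLOID_TARGET_CT - math.log2(cn / 2)
            target = tuple(
                float(base + rng.normal(0.0, noise_sd)) if noise_sd > 0 else base
                for _ in range(replicates)
            )
        housekeeping = {
            gene: tuple(
                float(baseline + rng.normal(0.0, noise_sd)) if noise_sd > 0 else baseline
                for _ in range(replicates)
            )
            for gene, baseline in HOUSEKEEPING_BASELINES.items()
        }
        return QpcrMeasurement(
            sample_id=sample_id,
            locus=locus_label,
            target_cts=target,
            housekeeping_cts=housekeeping,
        )

    plate = [_measure(calibrator_id, 2)]
    for sid, cn in members.items():
        if sid != calibrator_id:
            plate.append(_measure(sid, cn))
    return plate


def reference_fixture():
    """The bundled 13-event validation fixture (see :mod:`cnvcascade.fixture`)."""
    from .fixture import load_fixture

    return load_fixture()
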