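#!/usr/bin/env python
"""Simulate a case/control SNP-array CNV cohort and write its input files.

Generates a 450-case / 4392-control cohort with the default study
conditions (overdispersed CNV counts, ~9% of samples below the 98%
call-rate threshold, 0.5% sex discordance, 3% failed-array outliers, 30
shared common-CNV loci) plus 20 clean spiked CNVs with known truth, and
writes rawcnv calls, sample metadata and annotation tracks under
results/simulated/.
"""

from pathlib import Path

from cnvcascade import cnv_io
from cnvcascade.models import FeatureClass
from cnvcascade.synthetic_cohort import CohortConfig, generate_cohort, generate_tracks

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "tests"))
from conftest import spike_set  # reproducible spike placement helper

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 20260101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = CohortConfig(seed=SEED, spike_specs=spike_set(SEED, 20))
    samples, calls, truth = generate_cohort(config)
    tracks = generate_tracks(config)
    cnv_io.write_samples(samples, OUT / "samples.tsv")
    cnv_io.write_penncnv(calls, OUT / "calls.rawcnv")
    for fc in FeatureClass:
        cnv_io.write_bed_track(
            [f for f in tracks if f.feature_class is fc], OUT / f"{fc.value}.bed"
        )
    with open(OUT / "spike_truth.tsv", "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tcnv_type\n")
        for t in truth:
            iv = t.spec.interval
            fh.write(f"{t.sample_id}\t{iv.chrom}\t{iv.start}\t{iv.end}"
                     f"\t{t.spec.cnv_type.value}\n")
    print(f"{len(samples)} samples, {len(calls)} CNV calls "
          f"({len(truth)} spiked), tracks and truth written to {OUT}")


if __name__ == "__main__":
    main()
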