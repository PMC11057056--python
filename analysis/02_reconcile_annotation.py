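#!/usr/bin/env python
"""Reconcile gene content from read coverage: MAPQ-filtered per-base depth
over the toy contig and extraction of low-coverage (<5 read) regions, the
regions whose gene content would have to come from the transcriptome."""

import numpy as np

from common import WORKDIR, run_through
from sawselect.io import read_bed

run_through("reconcile")

out = WORKDIR / "outputs" / "reconcile"
coverage = np.loadtxt(out / "coverage.tsv", dtype=int)
low = read_bed(out / "low_coverage.bed")
print(f"contig of {coverage.size} bases; mean depth {coverage.mean():.1f}")
print(f"low-coverage regions (<5 reads): "
      f"{[(iv.start, iv.end) for iv in low]}")
print(f"bases below threshold: {sum(len(iv) for iv in low)} "
      f"({100 * sum(len(iv) for iv in low) / coverage.size:.0f}% of the contig)")
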