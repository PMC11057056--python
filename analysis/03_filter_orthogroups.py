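#!/usr/bin/env python
"""Curate the synthetic orthogroup collection with the pre-selection rules:
one-sequence-per-taxon coverage, annotation-based paralog splitting, and the
+/-100 amino-acid length-outlier filter."""

import pandas as pd

from common import WORKDIR, run_through

run_through("orthofilter")

out = WORKDIR / "outputs" / "orthofilter"
report = pd.read_csv(out / "curation_report.tsv", sep="\t").set_index("metric")["value"]
print(f"input orthogroups:            {report['input_groups']}")
print(f"failed taxon coverage:        {report['failed_taxon_coverage']}")
print(f"subgroups after paralog split:{report['split_into']:>5}")
print(f"failed coverage after split:  {report['failed_post_split_coverage']}")
print(f"members removed by length:    {report['members_removed_by_length']}")
print(f"surviving groups:             {report['surviving']}")
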