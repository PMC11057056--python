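#!/usr/bin/env python
"""Cluster the called PSGs on (omega, percent sites under selection,
delta-GRAVY) with k-means in standardized feature space, and test the first
cluster for annotation-term enrichment with the hypergeometric test."""

import pandas as pd

from common import WORKDIR, run_through

run_through("cluster")

out = WORKDIR / "outputs" / "cluster"
clusters = pd.read_csv(out / "clusters.tsv", sep="\t")
if clusters.empty:
    print("no PSGs were called, nothing to cluster")
else:
    print("PSG feature table with cluster assignments:")
    print(clusters.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
    print("\ncluster sizes:", clusters["cluster"].value_counts().to_dict())
enr_path = out / "enrichment.tsv"
if enr_path.exists():
    enr = pd.read_csv(enr_path, sep="\t")
    print("\nterm enrichment of cluster 0 vs all tested genes:")
    print(enr.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
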