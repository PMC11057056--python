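#!/usr/bin/env python
"""Biochemical divergence of each gene between the sawfish and the little
skate: GRAVY per protein and the sawfish-minus-skate difference that feeds
the clustering features."""

import pandas as pd

from common import WORKDIR, run_through

run_through("profile")

gravy = pd.read_csv(WORKDIR / "outputs" / "profile" / "gravy.tsv", sep="\t")
print("grand average of hydropathy (Kyte-Doolittle), per gene:")
print(gravy.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
biggest = gravy.iloc[gravy.delta_gravy.abs().idxmax()]
print(f"\nlargest hydropathy shift: {biggest.gene_id} "
      f"(delta GRAVY {biggest.delta_gravy:+.4f})")
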