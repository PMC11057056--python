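#!/usr/bin/env python
"""Electrosensory channel characterization on the synthetic panel: pore
motif verification (the K+ selectivity filter T-x-G-Y-G), FPKM expression
in rostral skin, and junction-read quantification of alternative exon
retention."""

import pandas as pd

from common import WORKDIR, run_through

run_through("electro")

out = WORKDIR / "outputs" / "electro"
motifs = pd.read_csv(out / "pore_motifs.tsv", sep="\t")
print("pore-motif hits:")
print(motifs.to_string(index=False) if not motifs.empty else "  none")
fpkm = pd.read_csv(out / "fpkm.tsv", sep="\t")
print("\nrostral-skin expression (FPKM):")
print(fpkm[["transcript_id", "count", "length_nt", "fpkm"]]
      .to_string(index=False, float_format=lambda x: f"{x:.2f}"))
exon = pd.read_csv(out / "exon_inclusion.tsv", sep="\t").iloc[0]
print(f"\nalternative exon [{int(exon.exon_start)}, {int(exon.exon_end)}): "
      f"{int(exon.inclusion_reads)} inclusion vs {int(exon.skipping_reads)} skipping "
      f"junction reads -> inclusion fraction {exon.inclusion_fraction:.2f} (exon retained)")
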