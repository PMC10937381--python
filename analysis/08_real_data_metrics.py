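#!/usr/bin/env python
"""Linker/NFR metrics from user-supplied MNase-seq fragment files.

The same readout as 05_nucleosome_metrics.py, but on real data: place
post-alignment fragment intervals (BED3) under data/gse220647/ as
<condition>_fragments.bed, with tf_sites.bed (BED6, Abf1/Reb1 sites)
and chrom.sizes alongside.  Sequencing data are not distributed with
this repository; see the GEO accession in the deposited study for the
libraries this layout expects.
"""

import sys
from pathlib import Path

import pandas as pd

from nucdomains import nucprofiles as nprof

DATA = Path("data/gse220647")

if not DATA.exists():
    sys.exit(f"no {DATA}/ directory: stage fragment BED files first "
             f"(see module docstring)")

anchors_bed = pd.read_csv(DATA / "tf_sites.bed", sep="\t", header=None)
anchors = pd.DataFrame({
    "chrom": anchors_bed[0],
    "pos": (anchors_bed[1] + anchors_bed[2]) // 2,
    "strand": anchors_bed[5] if anchors_bed.shape[1] > 5 else "+"})
sizes = pd.read_csv(DATA / "chrom.sizes", sep="\t", header=None)
lengths = dict(zip(sizes[0], sizes[1]))

rows = []
for bed in sorted(DATA.glob("*_fragments.bed")):
    name = bed.name.replace("_fragments.bed", "")
    frags = pd.read_csv(bed, sep="\t", header=None, usecols=[0, 1, 2],
                        names=["chrom", "start", "end"])
    track = nprof.dyad_coverage(frags, lengths)
    comp = nprof.composite(track, anchors, 3001)
    m = nprof.nucleosome_metrics(nprof.call_profile_peaks(comp))
    rows.append({"condition": name,
                 "mean_linker_bp": round(m.mean_linker, 2),
                 "nfr_width_bp": round(m.nfr_width, 2),
                 "n_fragments": len(frags)})
    print(f"{name}: linker {m.mean_linker:.1f} bp, "
          f"NFR {m.nfr_width:.1f} bp")

out = Path("results/real_data_metrics.tsv")
out.parent.mkdir(exist_ok=True)
pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
print(f"wrote {out}")
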