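#!/usr/bin/env python
"""Simulate remodeled chromatin for the three spacing remodelers.

For INO80, Chd1 and ISW2, plants phased nucleosome arrays around TF
sites with the remodeler's linker/NFR signature, then samples ligation
pairs and MNase fragments.  Artifacts go to results/synth/<preset>/.
"""

from pathlib import Path

from nucdomains import pairs as prs
from nucdomains import synthgen as sg
from nucdomains.presets import get_preset

OUT = Path("results/synth")
SEED = 42
SITES = [5_000, 15_000, 25_000]
LENGTH = 30_000

for name in ("ino80", "chd1", "isw2"):
    out = OUT / name
    out.mkdir(parents=True, exist_ok=True)
    cfg = sg.GeneratorConfig(
        contigs=[("chrSim", LENGTH, False)], tf_sites={"chrSim": SITES},
        preset=get_preset(name), n_pairs=500_000, n_fragments=500_000,
        undigested_frac=0.05, seed=SEED)
    gt = sg.make_ground_truth(cfg)
    raw = sg.simulate_ligation_pairs(gt, cfg)
    prs.write_pairs(raw, out / "pairs_raw.txt")
    frags = sg.simulate_mnase_fragments(gt, cfg.n_fragments, seed=SEED + 7)
    frags.to_csv(out / "fragments.bed", sep="\t", header=False, index=False)
    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write("# planted dyads (chrSim)\n")
        for d in gt.dyads["chrSim"]:
            fh.write(f"chrSim\t{d}\n")
    print(f"{name}: {len(gt.dyads['chrSim'])} nucleosomes, "
          f"{len(raw)} pairs, {len(frags)} fragments -> {out}")
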