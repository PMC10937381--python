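"""End-to-end workflows: synthetic chromatin -> pairs -> matrices ->
insulation -> nucleosome profiles (-> 3D structure).

Each stage writes its artifacts under the output directory with a
machine-readable provenance header (tool version, seed, config hash)
and the run report carries conservation counts and, when ground truth
is present, the parameter-recovery summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .presets import get_preset
from . import insulation as ins
from . import matrices as mx
from . import nucprofiles as nprof
from . import pairs as prs
from . import struct3d as s3d
from . import synthgen as sg


@dataclass
class PipelineConfig:
    """Fixed numeric settings of the standard analysis.

    Resolutions 20/40/80 bp, insulation windows 400/640/800 bp, 3,000 bp
    pile-up and insulation-composite windows, 3,001 bp MNase composite
    window.
    """

    outdir: str = "results/pipeline"
    preset: str = "ino80"
    seed: int = 42
    contig_length: int = 40_000
    circular: bool = False
    tf_sites: list = field(default_factory=lambda: [8_000, 20_000, 32_000])
    n_pairs: int = 500_000
    n_fragments: int = 500_000
    resolutions: list = field(default_factory=lambda: [20, 40, 80])
    insulation_windows: list = field(default_factory=lambda: [400, 640, 800])
    pileup_window_bp: int = 3000
    composite_window_bp: int = 3001
    run_structure: bool = False
    structure_nucleosomes: int = 50
    pairs_path: str | None = None  # skip synthesis, load instead
    fragments_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        d = asdict(self)
        for key in ("outdir", "pairs_path", "fragments_path"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(cfg: PipelineConfig, stage: str) -> list[str]:
    return [
        f"#tool: nucdomains {__version__}",
        f"#stage: {stage}",
        f"#seed: {cfg.seed}",
        f"#config_hash: {cfg.config_hash()}",
    ]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed,
                    "config_hash": cfg.config_hash(), "stages": {}}

    preset = get_preset(cfg.preset)
    gcfg = sg.GeneratorConfig(
        contigs=[("synth_contig", cfg.contig_length, cfg.circular)],
        tf_sites={"synth_contig": list(cfg.tf_sites)},
        preset=preset, n_pairs=cfg.n_pairs, n_fragments=cfg.n_fragments,
        seed=cfg.seed)
    gt = sg.make_ground_truth(gcfg)
    contig_lengths = {n: L for n, (L, _) in gt.contigs.items()}

    # --- pairs ---------------------------------------------------------
    if cfg.pairs_path:
        if not Path(cfg.pairs_path).exists():
            raise FileNotFoundError(f"pairs file not found: {cfg.pairs_path}")
        raw_pairs = prs.read_pairs(cfg.pairs_path)
        gt_known = False
    else:
        raw_pairs = sg.simulate_ligation_pairs(gt, gcfg)
        prs.write_pairs(raw_pairs, out / "pairs_raw.txt",
                        provenance_header(cfg, "synth") +
                        raw_pairs.attrs.get("headers", []))
        gt_known = True
    kept, stats = prs.process_pairs(raw_pairs)
    prs.write_pairs(kept, out / "pairs_filtered.txt",
                    provenance_header(cfg, "pairs"))
    report["stages"]["pairs"] = {
        "n_input": stats.n_input, "n_kept": stats.n_kept,
        "n_interchromosomal": stats.n_interchromosomal,
        "n_short": stats.n_short,
        "n_negative_shift": stats.n_negative_shift,
        "orientation_fractions": stats.orientation_fractions(),
    }

    # --- matrices ------------------------------------------------------
    mats = {}
    for res in cfg.resolutions:
        mats[res] = mx.bin_pairs(kept, res, contig_lengths)
        mx.write_sparse_triplets(
            mats[res], out / f"matrix_{res}bp.txt",
            provenance_header(cfg, f"matrix_{res}bp"))
        mx.write_bins_bed(mats[res], out / f"bins_{res}bp.bed")
    report["stages"]["matrices"] = {
        str(res): {"total": m.total(), "n_bins": m.n_bins}
        for res, m in mats.items()}
    conserved = all(m.total() == stats.n_kept for m in mats.values())
    report["stages"]["matrices"]["count_conserved"] = conserved

    anchors = gt.tf_anchors()
    meta = mx.pileup(mats[min(cfg.resolutions)], anchors,
                     cfg.pileup_window_bp)
    np.savetxt(out / "pileup.txt", meta, fmt="%.5f",
               header="\n".join(provenance_header(cfg, "pileup")))
    curve = mx.decay_curve(kept)
    report["stages"]["decay"] = {
        c: float(np.nansum(f)) for c, f in curve.frequency.items()}

    # --- insulation ----------------------------------------------------
    res80 = 80 if 80 in mats else max(cfg.resolutions)
    insul = {}
    for w in cfg.insulation_windows:
        insul[w] = ins.insulation_score(mats[res80], w)
        with open(out / f"insulation_w{w}.bedgraph", "w") as fh:
            for h in provenance_header(cfg, f"insulation_w{w}"):
                fh.write(h + "\n")
            for contig, s in insul[w].scores.items():
                pos = insul[w].positions(contig)
                for p, v in zip(pos, s):
                    if np.isfinite(v):
                        fh.write(f"{contig}\t{p - res80 // 2}"
                                 f"\t{p + res80 - res80 // 2}\t{v:.5f}\n")
    prof = insul[max(cfg.insulation_windows)]
    calls = ins.call_boundaries(prof)
    thr = ins.mark_strong(calls)
    with open(out / "boundaries.bed", "w") as fh:
        for h in provenance_header(cfg, "boundaries"):
            fh.write(h + "\n")
        for b in calls:
            name = "strong" if b.strong else "weak"
            fh.write(f"{b.contig}\t{b.position}\t{b.position + 1}"
                     f"\t{name}\t{b.prominence:.5f}\n")
    report["stages"]["insulation"] = {
        "n_boundaries": len(calls),
        "n_strong": sum(b.strong for b in calls),
        "li_threshold": thr,
    }
    if gt_known:
        centers = gt.nfr_centers()["synth_contig"]
        strong = [b.position for b in calls if b.strong]
        hits = sum(
            any(abs(s - c) <= 2 * res80 for s in strong) for c in centers)
        report["stages"]["insulation"]["boundary_recall_vs_planted"] = (
            hits / len(centers) if len(centers) else float("nan"))

    # --- nucleosome profiles ------------------------------------------
    if cfg.fragments_path:
        if not Path(cfg.fragments_path).exists():
            raise FileNotFoundError(
                f"fragments file not found: {cfg.fragments_path}")
        import pandas as pd
        frags = pd.read_csv(cfg.fragments_path, sep="\t", header=None,
                            names=["chrom", "start", "end"])
    else:
        frags = sg.simulate_mnase_fragments(
            gt, gcfg.n_fragments, gcfg.frag_len_mean, gcfg.frag_len_sd,
            seed=cfg.seed + 7, midpoint_sd=gcfg.midpoint_sd)
    track = nprof.dyad_coverage(frags, contig_lengths)
    nprof.write_bedgraph(track, out / "dyad_coverage.bedgraph")
    comp = nprof.composite(track, anchors, cfg.composite_window_bp)
    peaks = nprof.call_profile_peaks(comp)
    metrics = nprof.nucleosome_metrics(peaks)
    report["stages"]["profiles"] = {
        "n_fragments_kept": track.meta["n_fragments_kept"],
        "recovered_linker_bp": metrics.mean_linker,
        "recovered_nfr_bp": metrics.nfr_width,
    }
    if gt_known:
        report["stages"]["profiles"]["planted_linker_bp"] = preset.linker_bp
        report["stages"]["profiles"]["planted_nfr_bp"] = preset.nfr_bp

    # --- 3D structure (optional) --------------------------------------
    if cfg.run_structure:
        d = gt.dyads["synth_contig"][: cfg.structure_nucleosomes]
        loci = mx.NucleosomeLoci({"synth_contig": d})
        nmat = mx.bin_to_nucleosomes(kept, loci)
        model = s3d.build_topology(loci, seed=cfg.seed)
        restraints = s3d.restraints_from_matrix(nmat)
        sched = s3d.AnnealSchedule(seed=cfg.seed)
        coords, trace = s3d.anneal(model, restraints, sched)
        s3d.write_structure(model, coords, out / "structure.pdb")
        np.savetxt(out / "energy_trace.tsv", trace, fmt="%.4f")
        report["stages"]["structure"] = {
            "n_beads": model.n_beads,
            "initial_energy": float(trace[0]),
            "final_energy": float(trace[-1]),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
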