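"""Standard validation experiments on synthetic chromatin.

Each function sets up the study conditions for one recovery experiment
— generate chromatin with planted structure, run the full analysis
path, measure how well the planted parameters come back — and returns
plain dicts of numbers.  The experiments dimension the synthetic data
to the scales where the estimators are well conditioned: genome-wide
composites average over dozens of TF sites (the in vivo analyses use
>100), and contact analyses use 10^6 ligation pairs per condition.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse, stats

from . import insulation as ins
from . import matrices as mx
from . import nucprofiles as nprof
from . import pairs as prs
from . import struct3d as s3d
from . import synthgen as sg
from .presets import RemodelerPreset, get_preset

#: NFR-width ordering used for the width-vs-insulation comparison
WIDTH_ORDERED_PRESETS = ("isw2", "chd1", "ino80")  # NFRs 68 < 92 < 126


def recover_nucleosome_metrics(preset_name: str, seed: int = 42,
                               n_fragments: int = 1_000_000,
                               n_sites: int = 25,
                               site_spacing: int = 4_000) -> dict:
    """Plant arrays with a remodeler preset; recover linker and NFR.

    MNase fragments are simulated at the given depth, dyad coverage is
    composited over the planted TF sites (3,001 bp windows) and peak
    calling yields the linker lengths and NFR width.
    """
    preset = get_preset(preset_name)
    sites = list(range(site_spacing, site_spacing * (n_sites + 1),
                       site_spacing))
    length = site_spacing * (n_sites + 1) + 2_000
    cfg = sg.GeneratorConfig(
        contigs=[("chrSim", length, False)], tf_sites={"chrSim": sites},
        preset=preset, n_fragments=n_fragments, seed=seed)
    gt = sg.make_ground_truth(cfg)
    frags = sg.simulate_mnase_fragments(gt, n_fragments, seed=seed)
    track = nprof.dyad_coverage(frags, {"chrSim": length})
    comp = nprof.composite(track, gt.tf_anchors(), 3001)
    peaks = nprof.call_profile_peaks(comp)
    m = nprof.nucleosome_metrics(peaks)
    return {
        "preset": preset_name,
        "planted_linker_bp": preset.linker_bp,
        "planted_nfr_bp": preset.nfr_bp,
        "recovered_linker_bp": m.mean_linker,
        "recovered_nfr_bp": m.nfr_width,
        "n_fragments": n_fragments,
    }


def recover_boundaries(seed: int, n_pairs: int = 1_000_000,
                       slack_bp: int = 160) -> dict:
    """Five planted NFRs on 30 kb; call strong insulation boundaries.

    Precision = strong boundaries within ``slack_bp`` of a planted NFR
    center / all strong boundaries; recall = planted centers recovered.
    Insulation at 80 bp bins, 800 bp window, Li-thresholded prominence.
    """
    sites = [3_000, 9_000, 15_000, 21_000, 27_000]
    cfg = sg.GeneratorConfig(
        contigs=[("chrSim", 30_000, False)], tf_sites={"chrSim": sites},
        preset=get_preset("ino80"), n_pairs=n_pairs, seed=seed)
    gt = sg.make_ground_truth(cfg)
    kept, _ = prs.process_pairs(sg.simulate_ligation_pairs(gt, cfg))
    m = mx.bin_pairs(kept, 80, {"chrSim": 30_000})
    prof = ins.insulation_score(m, 800)
    calls = ins.call_boundaries(prof)
    ins.mark_strong(calls)
    strong = np.array([b.position for b in calls if b.strong])
    centers = gt.nfr_centers()["chrSim"]
    if strong.size == 0:
        return {"precision": 0.0, "recall": 0.0, "n_strong": 0}
    near = np.abs(strong[:, None] - centers[None, :]) <= slack_bp
    return {
        "precision": float(near.any(axis=1).mean()),
        "recall": float(near.any(axis=0).mean()),
        "n_strong": int(strong.size),
    }


def insulation_minimum_for_preset(preset_name: str, seed: int,
                                  n_pairs: int = 1_000_000) -> tuple:
    """(NFR width, composite insulation minimum) for one remodeler."""
    preset = get_preset(preset_name)
    sites = [3_000, 9_000, 15_000, 21_000, 27_000]
    cfg = sg.GeneratorConfig(
        contigs=[("chrSim", 30_000, False)], tf_sites={"chrSim": sites},
        preset=preset, n_pairs=n_pairs, seed=seed)
    gt = sg.make_ground_truth(cfg)
    kept, _ = prs.process_pairs(sg.simulate_ligation_pairs(gt, cfg))
    m = mx.bin_pairs(kept, 80, {"chrSim": 30_000})
    prof = ins.insulation_score(m, 800)
    _, _, minimum = ins.insulation_at_anchors(prof, gt.tf_anchors())
    return preset.nfr_bp, minimum


def nfr_width_vs_insulation(seed: int, n_pairs: int = 1_000_000) -> dict:
    """Composite insulation minima across the three NFR widths."""
    conds = [insulation_minimum_for_preset(p, seed, n_pairs)
             for p in WIDTH_ORDERED_PRESETS]
    r, p = ins.nfr_vs_insulation(conds)
    widths = [c[0] for c in conds]
    minima = [c[1] for c in conds]
    return {"widths": widths, "minima": minima, "pearson_r": r, "p": p,
            "strictly_decreasing": bool(
                minima[0] > minima[1] > minima[2])}


def linearization_boundary(seed: int, f_cut: float,
                           n_pairs: int = 1_000_000,
                           cut: int = 8_000, slack_bp: int = 160) -> dict:
    """Cut a circular plasmid; ask whether a boundary appears there.

    A 17 kb circular contig with two planted NFRs gets one restriction
    site mid-array; with full digestion the severed topology should
    create a strong insulation boundary at the cut.
    """
    cfg = sg.GeneratorConfig(
        contigs=[("plasmid", 17_000, True)],
        tf_sites={"plasmid": [4_000, 12_000]},
        preset=get_preset("ino80"), n_pairs=n_pairs, seed=seed,
        cut_sites={"plasmid": [cut]}, f_cut=f_cut)
    gt = sg.make_ground_truth(cfg)
    kept, _ = prs.process_pairs(sg.simulate_ligation_pairs(gt, cfg))
    m = mx.bin_pairs(kept, 80, {"plasmid": 17_000})
    prof = ins.insulation_score(m, 800)
    calls = ins.call_boundaries(prof)
    ins.mark_strong(calls)
    strong = [b.position for b in calls if b.strong]
    near = [abs(s - cut) for s in strong if abs(s - cut) <= slack_bp]
    return {
        "f_cut": f_cut,
        "boundary_at_cut": bool(near),
        "offset_bp": min(near) if near else None,
        "strong_positions": strong,
    }


def two_domain_restraints(n_nucleosomes: int = 50,
                          nrl: int = 188) -> tuple:
    """Synthetic two-domain contact matrix: dense intra, zero inter."""
    import pandas as pd
    n = n_nucleosomes
    dyads = np.arange(n) * nrl + 1_000
    domain = (np.arange(n) >= n // 2).astype(int)
    i, j = np.triu_indices(n, 1)
    same = domain[i] == domain[j]
    counts = np.where(same, np.round(200.0 / np.abs(i - j)), 0.0)
    keep = counts > 0
    mat = sparse.coo_matrix(
        (counts[keep], (i[keep], j[keep])), shape=(n, n)).tocsr()
    bins = pd.DataFrame({"chrom": "c", "start": dyads, "end": dyads + 1})
    nmat = mx.ContactMatrix(bins, mat, "nucleosome", {"c": (0, n)})
    loci = mx.NucleosomeLoci({"c": dyads})
    return loci, nmat, domain


def anneal_two_domains(seed: int, n_sweeps: int = 2_000) -> dict:
    """Anneal the two-domain toy; measure domain separation and the
    agreement between input restraint weights and model contacts."""
    loci, nmat, domain = two_domain_restraints()
    model = s3d.build_topology(loci, seed=0)
    restraints = s3d.restraints_from_matrix(nmat)
    sched = s3d.AnnealSchedule(n_sweeps=n_sweeps, seed=seed)
    coords, trace = s3d.anneal(model, restraints, sched)
    centers = model.histone_centers(coords)
    n = centers.shape[0]
    i, j = np.triu_indices(n, 1)
    d = np.linalg.norm(centers[i] - centers[j], axis=1)
    same = domain[i] == domain[j]
    contact_map = s3d.model_contact_map(model, coords)
    w_in = np.asarray(nmat.mat[i, j]).ravel()
    c_out = np.asarray(contact_map.mat[i, j]).ravel()
    rho = stats.spearmanr(np.log1p(w_in), c_out).statistic
    return {
        "intra_nm": float(d[same].mean()),
        "inter_nm": float(d[~same].mean()),
        "spearman": float(rho),
        "initial_energy": float(trace[0]),
        "final_energy": float(trace[-1]),
    }


def decay_exponent_recovery(seed: int, n_pairs: int = 1_000_000) -> dict:
    """Fit the contact-decay slope on irregular chromatin (alpha = 1)."""
    p = RemodelerPreset("irregular", 41, 0, spacing_sd_bp=40.0,
                        phased=False)
    cfg = sg.GeneratorConfig(
        contigs=[("chrSim", 200_000, False)], tf_sites={}, preset=p,
        n_pairs=n_pairs, seed=seed)
    gt = sg.make_ground_truth(cfg)
    kept, _ = prs.process_pairs(sg.simulate_ligation_pairs(gt, cfg))
    curve = mx.decay_curve(kept)
    slope = mx.fit_decay_slope(curve, "inward", 400, 8_000)
    return {"slope": slope, "alpha": cfg.decay_exponent,
            "n_pairs": n_pairs}


def replicate_correlation(seed: int, n_pairs: int = 1_000_000) -> dict:
    """Pearson r of two technical-replicate contact matrices."""
    cfg = sg.GeneratorConfig(
        contigs=[("chrSim", 30_000, False)],
        tf_sites={"chrSim": [5_000, 15_000, 25_000]},
        preset=get_preset("ino80"), n_pairs=n_pairs, seed=seed)
    gt = sg.make_ground_truth(cfg)
    mats = []
    for k in (1, 2):
        kept, _ = prs.process_pairs(
            sg.simulate_ligation_pairs(gt, cfg, seed=seed * 10 + k))
        mats.append(mx.bin_pairs(kept, 80, {"chrSim": 30_000}))
    return {"pearson_r": mx.matrix_correlation(*mats), "n_pairs": n_pairs}
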