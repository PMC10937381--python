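"""Synthetic chromatin generator with known ground truth.

Emulates the statistical structure of in vitro reconstituted chromatin
remodeled into phased, regularly spaced nucleosome arrays around
TF-bound nucleosome-free regions (NFRs):

* dyad lattices at the preset nucleosome repeat length (NRL) with
  Gaussian positional jitter, anchored at planted TF sites;
* MNase-style fragments whose midpoints scatter around dyads;
* chimeric ligation pairs drawn from a distance power law
  ``P(i,j) ∝ s^(-alpha)`` attenuated by ``beta(w)`` for every NFR of
  width ``w`` crossed, with the four read-orientation classes and the
  dyad ∓ 80 bp junction convention;
* optional circular-plasmid topology with cut-site linearization
  (incomplete digestion modeled by a cut fraction ``f_cut``).

Everything is deterministic per seed, so each downstream analysis stage
has an exact recovery test against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .presets import HALF_NUCLEOSOME_BP, NUCLEOSOME_BP, RemodelerPreset

JUNCTION_OFFSET_BP = 80  #: junction sits 80 bp outside the dyad it enters

#: read-direction combination per orientation class, for (left, right)
#: junction sides after canonical ordering
ORIENTATION_DIRS = {
    "inward": ("downstream", "upstream"),
    "outward": ("upstream", "downstream"),
    "tandem_entry": ("downstream", "downstream"),
    "tandem_exit": ("upstream", "upstream"),
}
ORIENTATION_CLASSES = tuple(ORIENTATION_DIRS)


def default_boundary_attenuation(w: np.ndarray | float, w0: float = 150.0):
    """Multiplicative contact attenuation per crossed NFR: exp(-w / w0).

    Wider NFRs attenuate more, so insulation strength grows with NFR
    width.  ``w0`` (bp) sets the scale; 150 bp ~ one persistence length.
    """
    return np.exp(-np.asarray(w, dtype=float) / w0)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic chromatin generator.

    ``contigs`` is a list of ``(name, length_bp, circular)``;
    ``tf_sites`` maps contig name to planted TF site coordinates.
    ``orientation_mix`` gives the probabilities of (inward, outward,
    tandem_entry, tandem_exit) and must sum to 1.
    """

    contigs: list[tuple[str, int, bool]]
    tf_sites: dict[str, Sequence[int]]
    preset: RemodelerPreset
    decay_exponent: float = 1.0
    boundary_attenuation: Callable[[float], float] | None = None
    attenuation_w0: float = 150.0
    n_pairs: int = 100_000
    n_fragments: int = 100_000
    frag_len_mean: float = 160.0
    frag_len_sd: float = 25.0
    midpoint_sd: float = 5.0
    orientation_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    undigested_frac: float = 0.0
    seed: int = 42
    cut_sites: dict[str, Sequence[int]] = field(default_factory=dict)
    f_cut: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.orientation_mix) - 1.0) > 1e-9:
            raise ValueError(
                f"orientation_mix must sum to 1, got {sum(self.orientation_mix)}"
            )
        if len(self.orientation_mix) != 4:
            raise ValueError("orientation_mix needs exactly 4 probabilities")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent alpha must be > 0")
        if not 0.0 <= self.f_cut <= 1.0:
            raise ValueError("f_cut must be in [0, 1]")
        lengths = {name: L for name, L, _ in self.contigs}
        for name, sites in self.tf_sites.items():
            if name not in lengths:
                raise ValueError(f"tf_sites references unknown contig {name!r}")
            s = np.asarray(sites)
            if s.size and (s.min() < 0 or s.max() >= lengths[name]):
                raise ValueError(f"TF site outside contig {name!r}")
        for name, cuts in self.cut_sites.items():
            if name not in lengths:
                raise ValueError(f"cut_sites references unknown contig {name!r}")
            c = np.asarray(cuts)
            if c.size and (c.min() < 0 or c.max() >= lengths[name]):
                raise ValueError(
                    f"cut site outside contig {name!r} (length {lengths[name]})"
                )

    def beta_of_width(self, w) -> np.ndarray:
        fn = self.boundary_attenuation
        if fn is None:
            b = default_boundary_attenuation(w, self.attenuation_w0)
        else:
            b = np.asarray([fn(x) for x in np.atleast_1d(np.asarray(w, float))])
        b = np.atleast_1d(np.asarray(b, dtype=float))
        if b.size and (b.min() < 0 or b.max() > 1):
            raise ValueError("boundary attenuation beta must lie in [0, 1]")
        return b


@dataclass
class GroundTruth:
    """Planted chromatin structure: the answer key for recovery tests."""

    dyads: dict[str, np.ndarray]
    nfr_intervals: dict[str, np.ndarray]  # (k, 2) half-open, 0-based
    domain_ids: dict[str, np.ndarray]  # per-dyad domain label
    tf_sites: dict[str, np.ndarray]
    contigs: dict[str, tuple[int, bool]]  # name -> (length, circular)
    preset: RemodelerPreset

    def tf_anchors(self) -> pd.DataFrame:
        """Planted TF sites as an oriented anchor table (all + strand)."""
        rows = [
            (name, int(pos), "+")
            for name, sites in self.tf_sites.items()
            for pos in sites
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])

    def nfr_centers(self) -> dict[str, np.ndarray]:
        return {
            name: iv.mean(axis=1) if len(iv) else np.empty(0)
            for name, iv in self.nfr_intervals.items()
        }


def _phased_array_dyads(
    sites: np.ndarray,
    length: int,
    circular: bool,
    preset: RemodelerPreset,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ideal (jitter-free) dyad lattice anchored at each TF site.

    Arrays grow outward from each NFR edge at NRL steps and stop at the
    midpoint to the neighboring NFR (or 73 bp short of a linear contig
    end, so whole nucleosomes fit).
    """
    nrl = preset.nrl
    first = preset.nfr_bp / 2.0 + HALF_NUCLEOSOME_BP
    out: list[np.ndarray] = []
    k = len(sites)
    for idx, s in enumerate(sites):
        if circular:
            gap_next = (sites[(idx + 1) % k] - s) % length if k > 1 else length
            gap_prev = (s - sites[idx - 1]) % length if k > 1 else length
            lim_down = gap_next / 2.0
            lim_up = gap_prev / 2.0
        else:
            lim_down = ((sites[idx + 1] - s) / 2.0 if idx + 1 < k
                        else length - HALF_NUCLEOSOME_BP - s)
            lim_up = ((s - sites[idx - 1]) / 2.0 if idx > 0
                      else s - HALF_NUCLEOSOME_BP)
        n_down = int(np.floor((lim_down - first) / nrl)) + 1
        n_up = int(np.floor((lim_up - first) / nrl)) + 1
        if n_down > 0:
            out.append(s + first + nrl * np.arange(n_down))
        if n_up > 0:
            out.append(s - first - nrl * np.arange(n_up))
    if not out:
        return np.empty(0)
    d = np.concatenate(out)
    if circular:
        d = np.mod(d, length)
    return np.sort(d)


def _unphased_dyads(
    sites: np.ndarray,
    nfrs: np.ndarray,
    length: int,
    circular: bool,
    preset: RemodelerPreset,
    rng: np.random.Generator,
) -> np.ndarray:
    """NRL lattice with uniform random phase per inter-NFR region."""
    nrl = preset.nrl
    if len(sites) == 0:
        lo = 0 if circular else HALF_NUCLEOSOME_BP
        hi = length if circular else length - HALF_NUCLEOSOME_BP
        phase = rng.uniform(0, nrl)
        return np.arange(lo + phase, hi, nrl)
    margin = HALF_NUCLEOSOME_BP
    out = []
    edges = []
    for (a, b) in nfrs:
        edges.append((a, b))
    edges.sort()
    # regions between consecutive NFRs (wrapping on circles)
    for i in range(len(edges)):
        start = edges[i][1] + margin
        if i + 1 < len(edges):
            stop = edges[i + 1][0] - margin
        elif circular:
            stop = edges[0][0] - margin + length
        else:
            stop = length - margin
        if stop <= start:
            continue
        phase = rng.uniform(0, nrl)
        out.append(np.arange(start + phase, stop, nrl))
    if not circular and edges:
        stop = edges[0][0] - margin
        phase = rng.uniform(0, nrl)
        seg = np.arange(margin + phase, stop, nrl)
        out.append(seg)
    if not out:
        return np.empty(0)
    d = np.concatenate(out)
    if circular:
        d = np.mod(d, length)
    return np.sort(d)


def make_ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Plant NFRs and nucleosome arrays per the configured preset.

    For phased presets the first dyads flank each TF site at
    ``site ± (nfr_bp/2 + 73)`` and subsequent dyads follow at NRL steps
    with i.i.d. Gaussian jitter of ``spacing_sd_bp`` around the ideal
    lattice.  Domain labels increment at every NFR.
    """
    preset = config.preset
    rng = np.random.default_rng(config.seed)
    dyads: dict[str, np.ndarray] = {}
    nfr_intervals: dict[str, np.ndarray] = {}
    domain_ids: dict[str, np.ndarray] = {}
    tf_sites: dict[str, np.ndarray] = {}
    contigs: dict[str, tuple[int, bool]] = {}

    first = preset.nfr_bp / 2.0 + HALF_NUCLEOSOME_BP
    for name, length, circular in config.contigs:
        contigs[name] = (length, circular)
        sites = np.sort(np.asarray(config.tf_sites.get(name, ()), dtype=float))
        tf_sites[name] = sites.astype(int)

        # expanded NFRs (NFR plus one half-nucleosome margin on each side)
        # must not overlap, and adjacent NFRs must leave room for >= 2
        # nucleosomes per array side.
        if len(sites) > 1:
            gaps = np.diff(sites)
            if circular:
                gaps = np.append(gaps, (sites[0] - sites[-1]) % length)
            if np.any(gaps < 2 * first):
                bad = int(np.argmin(gaps))
                raise ValueError(
                    f"expanded NFRs overlap on {name!r} between sites "
                    f"{int(sites[bad])} and {int(sites[(bad + 1) % len(sites)])}"
                )
            if np.any(gaps < 2 * (first + 2 * preset.nrl)):
                raise ValueError(
                    f"contig {name!r} too short: fewer than 2 nucleosomes fit "
                    f"between adjacent NFRs (need site spacing >= "
                    f"{2 * (first + 2 * preset.nrl):.0f} bp)"
                )
        if len(sites) == 1 and not circular:
            if sites[0] < first + 2 * preset.nrl or \
                    length - sites[0] < first + 2 * preset.nrl:
                raise ValueError(
                    f"contig {name!r} too short around site {int(sites[0])}: "
                    f"fewer than 2 nucleosomes fit on one side"
                )

        half = preset.nfr_bp / 2.0
        if preset.nfr_bp > 0 and len(sites):
            iv = np.stack(
                [np.floor(sites - half), np.floor(sites + half)], axis=1
            ).astype(int)
        else:
            iv = np.empty((0, 2), dtype=int)
        nfr_intervals[name] = iv

        if preset.phased:
            ideal = _phased_array_dyads(sites, length, circular, preset, rng)
        else:
            ideal = _unphased_dyads(sites, iv, length, circular, preset, rng)

        if preset.spacing_sd_bp > 0 and ideal.size:
            jittered = ideal + rng.normal(0, preset.spacing_sd_bp, ideal.size)
        else:
            jittered = ideal.copy()
        if circular:
            jittered = np.mod(jittered, length)
        else:
            jittered = np.clip(jittered, 0, length - 1)
        d = np.unique(np.round(jittered).astype(int))
        # jitter must not push a dyad center into an NFR
        for a, b in iv:
            inside = (d >= a) & (d < b)
            d[inside & (d < (a + b) // 2)] = a - 1
            d[inside & (d >= (a + b) // 2)] = b
        d = np.unique(d)
        dyads[name] = d

        if len(sites):
            ids = np.searchsorted(sites, d)
            if circular:
                ids = ids % len(sites)
            domain_ids[name] = ids
        else:
            domain_ids[name] = np.zeros(len(d), dtype=int)

    return GroundTruth(dyads, nfr_intervals, domain_ids, tf_sites, contigs,
                       preset)


def simulate_mnase_fragments(
    gt: GroundTruth,
    n_fragments: int,
    frag_len_mean: float = 160.0,
    frag_len_sd: float = 25.0,
    seed: int = 0,
    midpoint_sd: float = 5.0,
) -> pd.DataFrame:
    """Draw MNase-protected fragments around the planted dyads.

    Fragment midpoints scatter Normal(0, ``midpoint_sd``) around a
    uniformly chosen dyad; lengths are Normal(mean, sd) truncated to
    [100, 260] bp so the downstream 125-205 bp filter is exercised on
    both flanks.  Returns a BED-like frame (chrom, start, end).
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    all_dyads = [(name, d) for name, d in gt.dyads.items() if d.size]
    if not all_dyads:
        raise ValueError("ground truth has no dyads to sample from")
    rng = np.random.default_rng(seed)
    names = np.concatenate([np.full(d.size, i) for i, (_, d) in enumerate(all_dyads)])
    pool = np.concatenate([d for _, d in all_dyads])
    pick = rng.integers(0, pool.size, n_fragments)
    mids = pool[pick].astype(float)
    if midpoint_sd > 0:
        mids += rng.normal(0, midpoint_sd, n_fragments)
    if frag_len_sd > 0:
        a = (100 - frag_len_mean) / frag_len_sd
        b = (260 - frag_len_mean) / frag_len_sd
        lens = stats.truncnorm.rvs(a, b, loc=frag_len_mean, scale=frag_len_sd,
                                   size=n_fragments, random_state=rng)
    else:
        lens = np.full(n_fragments, float(np.clip(frag_len_mean, 100, 260)))
    lens = np.round(lens).astype(int)
    starts = np.round(mids - lens / 2.0).astype(int)
    chroms = np.array([all_dyads[i][0] for i in names[pick]], dtype=object)
    lengths = np.array([gt.contigs[c][0] for c in chroms])
    starts = np.clip(starts, 0, lengths - lens)
    return pd.DataFrame({"chrom": chroms, "start": starts,
                         "end": starts + lens})


@dataclass
class SamplingGeometry:
    """Pairwise sampling law over dyads, per contig.

    ``weights`` holds, for each contig, the mixture-normalized
    probability over upper-triangular dyad pairs (i < j), combining the
    uncut topology with weight ``1 - f_cut`` and the cut-site-severed
    topology with weight ``f_cut``.
    """

    contig_names: list[str]
    pair_index: dict[str, tuple[np.ndarray, np.ndarray]]
    weights: dict[str, np.ndarray]
    contig_mass: dict[str, float]


def _pair_weights_linearized(
    d: np.ndarray,
    centers: np.ndarray,
    betas: np.ndarray,
    length: int,
    circular: bool,
    alpha: float,
    cuts: np.ndarray,
) -> np.ndarray:
    """Unnormalized pair weights s^-alpha * prod(beta) for dyads ``d``.

    With cut sites the contig is severed into segments: cross-segment
    pairs get weight zero and distance is the linear path within the
    segment.  Without cuts, circular contigs use the shorter arc.
    """
    n = d.size
    ii, jj = np.triu_indices(n, k=1)
    di, dj = d[ii].astype(float), d[jj].astype(float)
    sep = dj - di

    # log-attenuation prefix over NFR centers (sorted)
    order = np.argsort(centers)
    c = np.asarray(centers, float)[order]
    b = np.asarray(betas, float)[order]
    zero = b <= 0
    logb = np.where(zero, 0.0, np.log(np.where(zero, 1.0, b)))
    S = np.concatenate([[0.0], np.cumsum(logb)])
    Z = np.concatenate([[0], np.cumsum(zero.astype(int))])

    def att_between(lo, hi):
        """prod of betas for centers strictly inside (lo, hi)."""
        a_idx = np.searchsorted(c, lo, side="right")
        b_idx = np.searchsorted(c, hi, side="left")
        n_zero = Z[b_idx] - Z[a_idx]
        att = np.exp(S[b_idx] - S[a_idx])
        att[n_zero > 0] = 0.0
        return att

    if cuts.size == 0:
        if circular:
            s_arc = np.minimum(sep, length - sep)
            use_inner = sep <= length - sep
            att = np.where(
                use_inner,
                att_between(di, dj),
                # outer arc: all centers except those on [di, dj]
                _outer_att(c, b, zero, di, dj),
            )
            s = s_arc
        else:
            att = att_between(di, dj)
            s = sep
        with np.errstate(divide="ignore"):
            w = np.where(s > 0, s, np.nan) ** (-alpha) * att
        return np.nan_to_num(w, nan=0.0)

    # severed topology: assign segments
    cs = np.sort(cuts.astype(float))
    seg_of = np.searchsorted(cs, d, side="right")
    if circular:
        seg_of = seg_of % len(cs) if len(cs) > 0 else seg_of
        # unroll wrap segment: coords before first cut belong with the
        # tail; map to pos + length
        lin = d.astype(float).copy()
        lin[d < cs[0]] += length
    else:
        lin = d.astype(float)
    same = seg_of[ii] == seg_of[jj]
    s = np.abs(lin[jj] - lin[ii])
    lo = np.minimum(lin[ii], lin[jj])
    hi = np.maximum(lin[ii], lin[jj])
    # centers in segment coordinates
    c_lin = c.copy()
    if circular and len(cs):
        c_lin[c < cs[0]] += length
    order2 = np.argsort(c_lin)
    c2, b2 = c_lin[order2], b[order2]
    zero2 = b2 <= 0
    logb2 = np.where(zero2, 0.0, np.log(np.where(zero2, 1.0, b2)))
    S2 = np.concatenate([[0.0], np.cumsum(logb2)])
    Z2 = np.concatenate([[0], np.cumsum(zero2.astype(int))])
    a_idx = np.searchsorted(c2, lo, side="right")
    b_idx = np.searchsorted(c2, hi, side="left")
    n_zero = Z2[b_idx] - Z2[a_idx]
    att = np.exp(S2[b_idx] - S2[a_idx])
    att[n_zero > 0] = 0.0
    with np.errstate(divide="ignore"):
        w = np.where(s > 0, s, np.nan) ** (-alpha) * att * same
    return np.nan_to_num(w, nan=0.0)


def _outer_att(c, b, zero, di, dj):
    """Attenuation along the outer (wrapping) arc: centers not in [di, dj]."""
    total_log = np.sum(np.where(zero, 0.0, np.log(np.where(zero, 1.0, b))))
    total_zero = int(zero.sum())
    S = np.concatenate([[0.0], np.cumsum(np.where(zero, 0.0,
                                                  np.log(np.where(zero, 1.0, b))))])
    Z = np.concatenate([[0], np.cumsum(zero.astype(int))])
    a_idx = np.searchsorted(c, di, side="left")
    b_idx = np.searchsorted(c, dj, side="right")
    inner_log = S[b_idx] - S[a_idx]
    inner_zero = Z[b_idx] - Z[a_idx]
    att = np.exp(total_log - inner_log)
    att[(total_zero - inner_zero) > 0] = 0.0
    return att


def apply_cut_sites(gt: GroundTruth, config: GeneratorConfig) -> SamplingGeometry:
    """Build the pair sampling law, mixing intact and cut topologies.

    A fraction ``f_cut`` of molecules treats every cut site as severed
    (linear segments, no cross-segment ligation); the remainder keeps
    the original topology, modeling incomplete restriction digestion.
    """
    alpha = config.decay_exponent
    names, pair_index, weights, mass = [], {}, {}, {}
    for name, (length, circular) in gt.contigs.items():
        d = gt.dyads[name]
        if d.size < 2:
            continue
        iv = gt.nfr_intervals[name]
        centers = iv.mean(axis=1) if len(iv) else np.empty(0)
        widths = (iv[:, 1] - iv[:, 0]).astype(float) if len(iv) else np.empty(0)
        betas = config.beta_of_width(widths) if len(iv) else np.empty(0)
        cuts = np.asarray(config.cut_sites.get(name, ()), dtype=float)

        w_uncut = _pair_weights_linearized(
            d, centers, betas, length, circular, alpha, np.empty(0))
        if cuts.size and config.f_cut > 0:
            w_cut = _pair_weights_linearized(
                d, centers, betas, length, circular, alpha, cuts)
            p_uncut = w_uncut / w_uncut.sum() if w_uncut.sum() > 0 else w_uncut
            p_cut = w_cut / w_cut.sum() if w_cut.sum() > 0 else w_cut
            w = (1 - config.f_cut) * p_uncut + config.f_cut * p_cut
        else:
            w = w_uncut
        if w.sum() == 0:
            continue
        ii, jj = np.triu_indices(d.size, k=1)
        names.append(name)
        pair_index[name] = (ii, jj)
        weights[name] = w / w.sum()
        # contig mass for allocating pairs across contigs: raw uncut sum
        mass[name] = float(w_uncut.sum())
    if not names:
        raise ValueError("no contig yields any valid dyad pair")
    return SamplingGeometry(names, pair_index, weights, mass)


def simulate_ligation_pairs(
    gt: GroundTruth, config: GeneratorConfig, seed: int | None = None
) -> pd.DataFrame:
    """Sample chimeric ligation pairs from the planted chromatin.

    Junction coordinates are emitted at ``dyad ∓ 80`` with read
    directions set by the drawn orientation class, so the downstream
    80 bp dyad shift exactly inverts the offset.  A fraction
    ``undigested_frac`` of additional sub-147 bp pairs exercises the
    short-distance filter.  ``seed`` overrides the config seed so
    technical replicates can be drawn from the same chromatin.
    """
    if sum(d.size for d in gt.dyads.values()) < 2:
        raise ValueError("need at least 2 dyads to ligate")
    geom = apply_cut_sites(gt, config)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)

    total_mass = sum(geom.contig_mass[n] for n in geom.contig_names)
    alloc = rng.multinomial(
        config.n_pairs,
        [geom.contig_mass[n] / total_mass for n in geom.contig_names],
    )
    classes = np.asarray(ORIENTATION_CLASSES, dtype=object)
    frames = []
    for name, n_c in zip(geom.contig_names, alloc):
        if n_c == 0:
            continue
        length, circular = gt.contigs[name]
        d = gt.dyads[name]
        ii, jj = geom.pair_index[name]
        idx = rng.choice(len(geom.weights[name]), size=n_c,
                         p=geom.weights[name])
        d1 = d[ii[idx]].astype(np.int64)
        d2 = d[jj[idx]].astype(np.int64)
        ori = classes[rng.choice(4, size=n_c, p=list(config.orientation_mix))]
        # left side gets the class's left direction, right side the right
        off = JUNCTION_OFFSET_BP
        p1 = np.where([ORIENTATION_DIRS[o][0] == "downstream" for o in ori],
                      d1 - off, d1 + off)
        p2 = np.where([ORIENTATION_DIRS[o][1] == "downstream" for o in ori],
                      d2 - off, d2 + off)
        dir1 = np.array([ORIENTATION_DIRS[o][0] for o in ori], dtype=object)
        dir2 = np.array([ORIENTATION_DIRS[o][1] for o in ori], dtype=object)
        if circular:
            p1, p2 = np.mod(p1, length), np.mod(p2, length)
        keep = (p1 >= 0) & (p2 >= 0) & (p1 < length) & (p2 < length)
        frames.append(pd.DataFrame({
            "chrom1": name, "pos1": p1[keep], "dir1": dir1[keep],
            "chrom2": name, "pos2": p2[keep], "dir2": dir2[keep],
            "orientation": "unset",
        }))

    if config.undigested_frac > 0:
        n_u = int(round(config.undigested_frac * config.n_pairs))
        pool_names = [n for n in gt.dyads if gt.dyads[n].size]
        pool = np.concatenate([gt.dyads[n] for n in pool_names])
        owner = np.concatenate(
            [np.full(gt.dyads[n].size, i) for i, n in enumerate(pool_names)])
        pick = rng.integers(0, pool.size, n_u)
        mid = pool[pick].astype(float)
        sep = rng.uniform(0, NUCLEOSOME_BP, n_u)
        p1 = np.round(mid - sep / 2).astype(np.int64) - JUNCTION_OFFSET_BP
        p2 = np.round(mid + sep / 2).astype(np.int64) + JUNCTION_OFFSET_BP
        chrom = np.array([pool_names[i] for i in owner[pick]], dtype=object)
        lengths = np.array([gt.contigs[c][0] for c in chrom])
        keep = (p1 >= 0) & (p2 < lengths)
        frames.append(pd.DataFrame({
            "chrom1": chrom[keep], "pos1": p1[keep], "dir1": "downstream",
            "chrom2": chrom[keep], "pos2": p2[keep], "dir2": "upstream",
            "orientation": "unset",
        }))

    out = pd.concat(frames, ignore_index=True)
    # canonical side order by (contig, pos)
    flip = (out["chrom1"] > out["chrom2"]) | (
        (out["chrom1"] == out["chrom2"]) & (out["pos1"] > out["pos2"]))
    if flip.any():
        f = flip.to_numpy()
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("dir1", "dir2")):
            va, vb = out[a].to_numpy().copy(), out[b].to_numpy().copy()
            out.loc[f, a] = vb[f]
            out.loc[f, b] = va[f]
    return out
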