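"""Diamond insulation scores and chromatin-domain boundary calling.

The insulation score of a bin is the mean contact frequency in the
square ("diamond") of cells linking the ``w`` bins on its left to the
``w`` bins on its right, expressed as log2 ratio to the contig-wide
mean.  Local minima of the score mark positions that contacts rarely
cross — domain boundaries.  Minima are ranked by topographic prominence
and split into strong/weak classes with Li's minimum cross-entropy
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .matrices import ContactMatrix


@dataclass
class InsulationProfile:
    """Per-bin insulation scores (log2 vs contig mean), NaN at margins."""

    scores: dict[str, np.ndarray]
    resolution_bp: int
    window_bp: int

    def positions(self, contig: str) -> np.ndarray:
        """Bin-center coordinates (bp)."""
        n = self.scores[contig].size
        return np.arange(n) * self.resolution_bp + self.resolution_bp // 2


@dataclass
class BoundaryCall:
    contig: str
    position: int  # bin center, bp
    prominence: float
    score_at_minimum: float
    strong: bool = False


def insulation_score(matrix: ContactMatrix, window_bp: int,
                     normalize: bool = True) -> InsulationProfile:
    """Diamond insulation score at every bin of every contig.

    For bin ``i`` and window ``w`` bins, the raw score is the mean count
    over cells (a, b) with ``i-w <= a < i < b <= i+w``; within ``w``
    bins of a contig end the diamond does not fit and the score is NaN.
    With ``normalize`` the returned score is
    ``log2(raw / mean_contig(raw))``.
    """
    if matrix.resolution == "nucleosome":
        raise ValueError("insulation is defined on bp-binned matrices")
    res = int(matrix.resolution)
    if window_bp % res:
        raise ValueError(f"window_bp ({window_bp}) must be a multiple of "
                         f"the resolution ({res})")
    w = window_bp // res
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    scores: dict[str, np.ndarray] = {}
    for contig, (lo, hi) in matrix.contig_bins.items():
        n = hi - lo
        if n <= 2 * w:
            raise ValueError(
                f"window ({w} bins) too large for contig {contig!r} "
                f"({n} bins)")
        D = matrix.dense(contig)
        # summed-area table: block sums in O(1) per bin
        P = np.zeros((n + 1, n + 1))
        P[1:, 1:] = D.cumsum(0).cumsum(1)
        raw = np.full(n, np.nan)
        for i in range(w, n - w):
            r0, r1 = i - w, i
            c0, c1 = i + 1, i + w + 1
            s = P[r1, c1] - P[r0, c1] - P[r1, c0] + P[r0, c0]
            raw[i] = s / (w * w)
        if normalize:
            m = np.nanmean(raw)
            with np.errstate(divide="ignore", invalid="ignore"):
                scores[contig] = np.log2(raw / m)
        else:
            scores[contig] = raw
    return InsulationProfile(scores, res, window_bp)


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Leftmost indices of interior local-minimum plateaus."""
    n = x.size
    out = []
    i = 1
    while i < n - 1:
        if x[i] < x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] > x[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


def call_boundaries(profile: InsulationProfile) -> list[BoundaryCall]:
    """Local minima of the insulation score, ranked by prominence.

    Prominence is the topographic prominence of the inverted profile:
    the climb from the minimum to the lower of the two enclosing key
    saddles.  Plateau minima report their leftmost bin.  NaN stretches
    split the profile into independently scanned segments.
    """
    calls: list[BoundaryCall] = []
    any_finite = False
    for contig, s in profile.scores.items():
        finite = np.isfinite(s)
        any_finite |= bool(finite.any())
        # contiguous finite runs
        idx = np.flatnonzero(finite)
        if idx.size == 0:
            continue
        splits = np.flatnonzero(np.diff(idx) > 1)
        for seg_idx in np.split(idx, splits + 1):
            if seg_idx.size < 3:
                continue
            seg = s[seg_idx]
            minima = _local_minima(seg)
            if minima.size == 0:
                continue
            prom = signal.peak_prominences(-seg, minima)[0]
            for m, p in zip(minima, prom):
                calls.append(BoundaryCall(
                    contig=contig,
                    position=int(seg_idx[m] * profile.resolution_bp
                                 + profile.resolution_bp // 2),
                    prominence=float(p),
                    score_at_minimum=float(seg[m]),
                ))
    if not any_finite:
        warnings.warn("all-NaN insulation profile: no boundaries called")
    calls.sort(key=lambda c: (c.contig, c.position))
    return calls


def li_threshold(values, tol: float = 1e-6, max_iter: int = 500) -> float:
    """Li's minimum cross-entropy threshold by fixed-point iteration.

    Starting from the sample mean, iterate
    ``t' = (mu_low - mu_high) / (ln mu_low - ln mu_high)`` where
    ``mu_low``/``mu_high`` are the means of values below/above ``t``,
    until the update moves less than ``tol``.  Values must be positive
    with at least two distinct entries.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("Li threshold undefined: need >= 2 distinct values")
    if v.min() <= 0:
        raise ValueError("Li threshold needs strictly positive values")
    t = v.mean()
    for _ in range(max_iter):
        low = v[v <= t]
        high = v[v > t]
        if low.size == 0 or high.size == 0:
            break
        mu_l, mu_h = low.mean(), high.mean()
        if mu_l == mu_h:
            break
        t_new = (mu_l - mu_h) / (np.log(mu_l) - np.log(mu_h))
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def mark_strong(boundaries: list[BoundaryCall],
                threshold: float | None = None) -> float:
    """Flag boundaries whose prominence clears the Li threshold.

    Returns the threshold used.  With fewer than two distinct
    prominences no split is possible and all boundaries stay weak.
    """
    proms = [b.prominence for b in boundaries if b.prominence > 0]
    if threshold is None:
        try:
            threshold = li_threshold(proms)
        except ValueError:
            for b in boundaries:
                b.strong = False
            return float("nan")
    for b in boundaries:
        b.strong = b.prominence >= threshold
    return float(threshold)


def insulation_at_anchors(profile: InsulationProfile, anchors: pd.DataFrame,
                          window_bp: int = 3000,
                          minimum_halfwidth_bp: int = 400
                          ) -> tuple[np.ndarray, np.ndarray, float]:
    """Composite insulation around anchors and its near-anchor minimum.

    Returns (offsets_bp, composite, minimum) where the composite is the
    across-anchor mean score per offset and the minimum is taken within
    ``±minimum_halfwidth_bp`` of the anchor.
    """
    res = profile.resolution_bp
    half = window_bp // (2 * res)
    rows = []
    for _, a in anchors.iterrows():
        contig = a["chrom"]
        if contig not in profile.scores:
            continue
        s = profile.scores[contig]
        b = int(a["pos"]) // res
        if b - half < 0 or b + half >= s.size:
            continue
        rows.append(s[b - half: b + half + 1])
    if not rows:
        raise ValueError("no interior anchors for the insulation composite")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        composite = np.nanmean(np.stack(rows), axis=0)
    offsets = (np.arange(-half, half + 1)) * res
    near = np.abs(offsets) <= minimum_halfwidth_bp
    minimum = float(np.nanmin(composite[near]))
    return offsets, composite, minimum


def boundary_anchor_overlap(boundaries: list[BoundaryCall],
                            anchors: pd.DataFrame,
                            contig_lengths: dict[str, int],
                            slack_bp: int = 200,
                            strong_only: bool = True,
                            n_permutations: int = 200,
                            seed: int = 0) -> dict:
    """Overlap of (strong) boundaries with anchor sites, plus a null.

    Reports the fraction of boundaries within ``slack_bp`` of an
    anchor, the reciprocal fraction of anchors with a nearby boundary,
    and an enrichment ratio against boundaries re-drawn uniformly
    within their contigs.
    """
    calls = [b for b in boundaries if b.strong or not strong_only]
    anchor_pos = {
        c: np.sort(g["pos"].to_numpy())
        for c, g in anchors.groupby("chrom")
    }

    def frac_near(positions_by_contig) -> tuple[int, int]:
        hit = tot = 0
        for contig, ps in positions_by_contig.items():
            ap = anchor_pos.get(contig)
            for p in ps:
                tot += 1
                if ap is not None and ap.size:
                    k = np.searchsorted(ap, p)
                    near = min(
                        abs(p - ap[max(k - 1, 0)]),
                        abs(p - ap[min(k, ap.size - 1)]))
                    hit += near <= slack_bp
        return hit, tot

    obs_by_contig: dict[str, list[int]] = {}
    for b in calls:
        obs_by_contig.setdefault(b.contig, []).append(b.position)
    hit, tot = frac_near(obs_by_contig)
    frac = hit / tot if tot else float("nan")

    # reciprocal: anchors with a boundary within slack
    b_pos = {c: np.sort(ps) for c, ps in obs_by_contig.items()}
    rhit = rtot = 0
    for contig, ap in anchor_pos.items():
        bp = b_pos.get(contig, np.empty(0))
        for p in ap:
            rtot += 1
            if len(bp):
                k = np.searchsorted(bp, p)
                near = min(abs(p - bp[max(k - 1, 0)]),
                           abs(p - bp[min(k, len(bp) - 1)]))
                rhit += near <= slack_bp
    rfrac = rhit / rtot if rtot else float("nan")

    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_permutations):
        shuffled = {
            c: rng.integers(0, contig_lengths[c], len(ps))
            for c, ps in obs_by_contig.items()
        }
        h, t = frac_near(shuffled)
        null.append(h / t if t else np.nan)
    null_mean = float(np.nanmean(null)) if null else float("nan")
    enrichment = frac / null_mean if null_mean and null_mean > 0 else float("inf")
    return {
        "fraction_boundaries_near_anchor": frac,
        "fraction_anchors_near_boundary": rfrac,
        "n_boundaries": tot,
        "n_anchors": rtot,
        "null_fraction": null_mean,
        "enrichment": enrichment,
    }


def nfr_vs_insulation(conditions) -> tuple[float, float]:
    """Pearson r (and two-sided p) of insulation minima vs NFR width.

    ``conditions`` is a sequence of (nfr_width_bp, insulation_minimum).
    """
    arr = np.asarray(list(conditions), dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 conditions")
    w, m = arr[:, 0], arr[:, 1]
    if np.ptp(w) == 0 or np.ptp(m) == 0:
        raise ValueError("zero variance in widths or minima")
    r, p = stats.pearsonr(w, m)
    return float(r), float(p)
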