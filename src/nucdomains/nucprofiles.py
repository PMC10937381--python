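"""MNase-seq dyad coverage, composite profiles and NFR/linker metrics.

Mono-nucleosome-sized fragments (125-205 bp) estimate nucleosome
positions: the fragment midpoint approximates the dyad.  Coverage is
computed from a 50 bp footprint centered on each midpoint and smoothed
with a 20 bp rolling mean.  Composites around anchor sites (TF binding
sites or +1 nucleosomes) expose the phased array, from which peak
calling derives the field's standard metrics:

* nucleosome repeat length (NRL) = peak-to-peak distance,
* linker length = NRL - 147,
* border-to-TF distance = first-peak offset - 73,
* NFR width = upstream + downstream border-to-TF distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .presets import HALF_NUCLEOSOME_BP, NUCLEOSOME_BP


@dataclass
class SignalTrack:
    """Per-base non-negative signal over contigs, with provenance."""

    data: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))


def rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with edge truncation (mass preserved inside)."""
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def dyad_coverage(fragments: pd.DataFrame,
                  contig_lengths: dict[str, int],
                  min_len: int = 125, max_len: int = 205,
                  footprint: int = 50, smooth: int = 20) -> SignalTrack:
    """Nucleosome dyad coverage from fragment intervals.

    Fragments outside [``min_len``, ``max_len``] are discarded; each
    kept fragment contributes a ``footprint``-wide unit interval
    centered on its midpoint; the summed coverage is smoothed with a
    centered ``smooth`` bp rolling mean.
    """
    data = {c: np.zeros(L) for c, L in contig_lengths.items()}
    lens = (fragments["end"] - fragments["start"]).to_numpy()
    keep = (lens >= min_len) & (lens <= max_len)
    kept = fragments.loc[keep]
    n_kept = 0
    for contig, grp in kept.groupby("chrom", sort=False):
        if contig not in data:
            raise ValueError(f"fragments on undeclared contig {contig!r}")
        L = contig_lengths[contig]
        mid = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
        lo = np.clip(mid - footprint // 2, 0, L)
        hi = np.clip(lo + footprint, 0, L)
        diff = np.zeros(L + 1)
        np.add.at(diff, lo, 1.0)
        np.add.at(diff, hi, -1.0)
        data[contig] = rolling_mean(np.cumsum(diff[:-1]), smooth)
        n_kept += len(grp)
    return SignalTrack(data, meta={
        "n_fragments_in": len(fragments), "n_fragments_kept": int(keep.sum()),
        "footprint": footprint, "smooth": smooth,
        "min_len": min_len, "max_len": max_len,
    })


@dataclass
class CompositeProfile:
    """Across-anchor mean signal on offsets -W..+W around the anchor."""

    offsets: np.ndarray
    values: np.ndarray
    n_anchors: int
    n_skipped: int = 0

    @property
    def halfwidth(self) -> int:
        return int(self.offsets[-1])


def composite(track: SignalTrack, anchors: pd.DataFrame, window_bp: int,
              normalize_per_window: bool = True) -> CompositeProfile:
    """Average anchor-centered signal windows, oriented by strand.

    ``window_bp`` is the full window (2,001 or 3,001 bp for halfwidths
    of 1,000/1,500).  Each window is divided by its own mean before
    averaging when ``normalize_per_window``; zero-mean and contig-edge
    windows are skipped and counted.
    """
    W = window_bp // 2
    rows = []
    skipped = 0
    for _, a in anchors.iterrows():
        contig = a["chrom"]
        if contig not in track.data:
            skipped += 1
            continue
        sig = track.data[contig]
        p = int(a["pos"])
        if p - W < 0 or p + W >= sig.size:
            skipped += 1
            continue
        win = sig[p - W: p + W + 1].astype(float)
        if a.get("strand", "+") == "-":
            win = win[::-1]
        if normalize_per_window:
            m = win.mean()
            if m == 0:
                skipped += 1
                continue
            win = win / m
        rows.append(win)
    if not rows:
        raise ValueError("all anchors skipped (edges or zero signal)")
    return CompositeProfile(np.arange(-W, W + 1), np.mean(rows, axis=0),
                            n_anchors=len(rows), n_skipped=skipped)


def call_profile_peaks(profile: CompositeProfile,
                       min_separation: int = 120,
                       exclusion_halfwidth: int = 50) -> np.ndarray:
    """Greedy peak calling on a composite nucleosome profile.

    Local maxima outside ``±exclusion_halfwidth`` of the anchor (to
    avoid calling the TF footprint itself) are accepted in decreasing
    height, enforcing ``min_separation`` between accepted peaks.
    Returns sorted peak offsets (bp).
    """
    v = profile.values
    off = profile.offsets
    cand = []
    i = 1
    n = v.size
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                cand.append(i)  # leftmost index of the plateau
            i = j + 1
        else:
            i += 1
    cand = [c for c in cand if abs(int(off[c])) > exclusion_halfwidth]
    cand.sort(key=lambda c: -v[c])
    accepted: list[int] = []
    for c in cand:
        if all(abs(off[c] - off[a]) >= min_separation for a in accepted):
            accepted.append(c)
    return np.sort(off[accepted]).astype(int)


@dataclass
class NucleosomeMetrics:
    """Array-regularity metrics derived from composite peak offsets."""

    first_peak_up: int
    first_peak_down: int
    nrl_up: np.ndarray
    nrl_down: np.ndarray
    linkers_up: np.ndarray
    linkers_down: np.ndarray
    border_to_tf_up: float
    border_to_tf_down: float
    nfr_width: float
    warnings: list = field(default_factory=list)

    @property
    def mean_linker(self) -> float:
        return float(np.mean(np.concatenate(
            [self.linkers_up, self.linkers_down])))


def nucleosome_metrics(peak_offsets: np.ndarray,
                       n_linkers: int = 3) -> NucleosomeMetrics:
    """Linker lengths, border-to-TF distances and NFR width from peaks.

    Per side of the anchor, the first ``n_linkers`` peak-to-peak gaps
    minus 147 give the linker lengths; the first peak offset minus 73
    gives the distance from the nucleosome border to the TF site; the
    NFR width is the sum of the two border distances.  Negative values
    are reported with a warning (ill-phased or overlapping arrays), not
    clamped.
    """
    peaks = np.sort(np.asarray(peak_offsets, dtype=float))
    up = -peaks[peaks < 0][::-1]  # distances from anchor, ascending
    down = peaks[peaks > 0]
    warns = []
    if up.size < 1 or down.size < 1:
        raise ValueError("need at least one peak on each side of the anchor")
    if up.size < n_linkers + 1 or down.size < n_linkers + 1:
        warns.append(
            f"fewer than {n_linkers + 1} peaks on one side; "
            f"linker list truncated")
    nrl_up = np.diff(up)[:n_linkers]
    nrl_down = np.diff(down)[:n_linkers]
    linkers_up = nrl_up - NUCLEOSOME_BP
    linkers_down = nrl_down - NUCLEOSOME_BP
    border_up = float(up[0] - HALF_NUCLEOSOME_BP)
    border_down = float(down[0] - HALF_NUCLEOSOME_BP)
    for label, vals in (("linker", np.concatenate([linkers_up, linkers_down])),
                        ("border", np.array([border_up, border_down]))):
        if np.any(vals < 0):
            warns.append(f"negative {label} distance: overlapping or "
                         f"ill-phased array")
    if warns:
        for w in warns:
            warnings.warn(w)
    return NucleosomeMetrics(
        first_peak_up=int(-up[0]), first_peak_down=int(down[0]),
        nrl_up=nrl_up, nrl_down=nrl_down,
        linkers_up=linkers_up, linkers_down=linkers_down,
        border_to_tf_up=border_up, border_to_tf_down=border_down,
        nfr_width=border_up + border_down, warnings=warns)


def sort_windows_by_signal(track: SignalTrack, anchors: pd.DataFrame,
                           offset: int = -160, width: int = 180,
                           top_fraction: float = 0.2) -> pd.DataFrame:
    """Order anchors by upstream signal; label a top fraction as bound.

    Per anchor the mean signal in a ``width`` bp window starting
    ``|offset|`` bp upstream (in the anchor's orientation) is computed;
    anchors come back sorted by decreasing signal (stable under ties)
    with a boolean ``top`` column marking the top ``top_fraction``
    (e.g. TF-bound genes, top 20%).
    """
    if "strand" not in anchors.columns:
        raise ValueError("anchors must carry a strand column for orientation")
    means = []
    for _, a in anchors.iterrows():
        sig = track.data.get(a["chrom"])
        if sig is None:
            means.append(np.nan)
            continue
        p = int(a["pos"])
        if a["strand"] == "-":
            lo, hi = p - offset, p - offset + width
        else:
            lo, hi = p + offset - width, p + offset
        lo, hi = max(lo, 0), min(hi, sig.size)
        means.append(float(sig[lo:hi].mean()) if hi > lo else np.nan)
    out = anchors.copy()
    out["window_mean"] = means
    out = out.sort_values("window_mean", ascending=False, kind="stable")
    n_top = int(round(top_fraction * len(out)))
    out["top"] = False
    out.iloc[:n_top, out.columns.get_loc("top")] = True
    return out.reset_index(drop=True)


def write_bedgraph(track: SignalTrack, path, precision: int = 4) -> None:
    """Run-length-encoded bedGraph export of a signal track."""
    with open(path, "w") as fh:
        for contig, sig in track.data.items():
            r = np.round(sig, precision)
            change = np.flatnonzero(np.diff(r)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [r.size]])
            for s, e in zip(starts, ends):
                if r[s] != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{r[s]}\n")
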