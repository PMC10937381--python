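"""Contact matrices, pile-ups, decay curves and replicate correlation.

Filtered, dyad-shifted ligation pairs are aggregated into symmetric
sparse contact matrices, either on fixed bp bins (20/40/80 bp) or on
nucleosome loci (one bin per dyad, each pair end assigned to its
nearest nucleosome).  Raw counts are kept throughout — no balancing;
``log10(1+x)`` is applied only for display and correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class NucleosomeLoci:
    """Sorted dyad coordinates per contig, for nucleosome-resolution binning."""

    dyads: dict[str, np.ndarray]
    assignment_max_bp: int = 100

    def __post_init__(self) -> None:
        clean = {}
        for name, d in self.dyads.items():
            arr = np.asarray(d, dtype=np.int64)
            u = np.unique(arr)
            if u.size != arr.size or np.any(np.diff(arr) < 0):
                arr = u
            clean[name] = arr
        self.dyads = clean

    @property
    def n_loci(self) -> int:
        return sum(d.size for d in self.dyads.values())


@dataclass
class ContactMatrix:
    """Symmetric contact counts stored upper-triangular and sparse.

    ``bins`` tiles the declared contigs without gaps in bp mode, or
    holds one single-bp bin per nucleosome dyad in nucleosome mode
    (``resolution == "nucleosome"``).
    """

    bins: pd.DataFrame  # chrom, start, end
    mat: sparse.csr_matrix  # upper-triangular counts, bin_i <= bin_j
    resolution: int | str
    contig_bins: dict[str, tuple[int, int]]  # half-open bin-index range
    n_discarded: int = 0

    @property
    def n_bins(self) -> int:
        return self.mat.shape[0]

    def total(self) -> int:
        return int(self.mat.sum())

    def dense(self, contig: str) -> np.ndarray:
        """Full symmetric dense submatrix for one contig."""
        lo, hi = self.contig_bins[contig]
        sub = self.mat[lo:hi, lo:hi].toarray().astype(float)
        return sub + np.triu(sub, 1).T

    def same_bins(self, other: "ContactMatrix") -> bool:
        return self.bins.shape == other.bins.shape and bool(
            (self.bins.values == other.bins.values).all())


def _bin_table(contigs: dict[str, int], resolution: int):
    rows, offsets, off = [], {}, 0
    for name, length in contigs.items():
        n = int(np.ceil(length / resolution))
        starts = np.arange(n) * resolution
        ends = np.minimum(starts + resolution, length)
        rows.append(pd.DataFrame(
            {"chrom": name, "start": starts, "end": ends}))
        offsets[name] = (off, off + n)
        off += n
    return pd.concat(rows, ignore_index=True), offsets


def bin_pairs(pairs: pd.DataFrame, resolution_bp: int,
              contigs: dict[str, int]) -> ContactMatrix:
    """Aggregate pairs on a fixed-resolution bin grid.

    Each pair increments exactly one cell (``floor(pos / resolution)``
    per side, upper triangle), so the matrix total equals the pair
    count.
    """
    bins, offsets = _bin_table(contigs, resolution_bp)
    n = len(bins)
    for col in ("chrom1", "chrom2"):
        unknown = set(pairs[col].unique()) - set(contigs)
        if unknown:
            raise ValueError(f"pairs reference undeclared contig(s): "
                             f"{sorted(unknown)}")
    off1 = pairs["chrom1"].map({c: o[0] for c, o in offsets.items()}).to_numpy()
    off2 = pairs["chrom2"].map({c: o[0] for c, o in offsets.items()}).to_numpy()
    b1 = off1 + pairs["pos1"].to_numpy() // resolution_bp
    b2 = off2 + pairs["pos2"].to_numpy() // resolution_bp
    i = np.minimum(b1, b2)
    j = np.maximum(b1, b2)
    mat = sparse.coo_matrix(
        (np.ones(len(pairs)), (i, j)), shape=(n, n)).tocsr()
    return ContactMatrix(bins, mat, resolution_bp, offsets)


def assign_to_nearest_dyad(pos: np.ndarray, dyads: np.ndarray,
                           max_bp: int) -> np.ndarray:
    """Index of the nearest dyad per position; -1 beyond ``max_bp``.

    Equidistant positions go to the leftmost of the two dyads.
    """
    idx = np.searchsorted(dyads, pos)
    left = np.clip(idx - 1, 0, dyads.size - 1)
    right = np.clip(idx, 0, dyads.size - 1)
    dl = np.abs(pos - dyads[left])
    dr = np.abs(pos - dyads[right])
    nearest = np.where(dl <= dr, left, right)  # tie -> leftmost
    dist = np.minimum(dl, dr)
    return np.where(dist <= max_bp, nearest, -1)


def bin_to_nucleosomes(pairs: pd.DataFrame, loci: NucleosomeLoci
                       ) -> ContactMatrix:
    """Aggregate pairs on nucleosome loci.

    Each pair end maps to its nearest dyad; ends farther than
    ``assignment_max_bp`` from any dyad discard the pair (counted on
    ``n_discarded``).
    """
    if loci.n_loci == 0:
        raise ValueError("empty nucleosome loci")
    offsets, rows, off = {}, [], 0
    for name, d in loci.dyads.items():
        rows.append(pd.DataFrame(
            {"chrom": name, "start": d, "end": d + 1}))
        offsets[name] = (off, off + d.size)
        off += d.size
    bins = pd.concat(rows, ignore_index=True)

    n = off
    i_all, j_all, discarded = [], [], 0
    for (c1, c2), grp in pairs.groupby(["chrom1", "chrom2"], sort=False):
        if c1 not in loci.dyads or c2 not in loci.dyads:
            discarded += len(grp)
            continue
        a1 = assign_to_nearest_dyad(grp["pos1"].to_numpy(),
                                    loci.dyads[c1], loci.assignment_max_bp)
        a2 = assign_to_nearest_dyad(grp["pos2"].to_numpy(),
                                    loci.dyads[c2], loci.assignment_max_bp)
        ok = (a1 >= 0) & (a2 >= 0)
        discarded += int((~ok).sum())
        g1 = a1[ok] + offsets[c1][0]
        g2 = a2[ok] + offsets[c2][0]
        i_all.append(np.minimum(g1, g2))
        j_all.append(np.maximum(g1, g2))
    if i_all:
        i = np.concatenate(i_all)
        j = np.concatenate(j_all)
        mat = sparse.coo_matrix(
            (np.ones(i.size), (i, j)), shape=(n, n)).tocsr()
    else:
        mat = sparse.csr_matrix((n, n))
    return ContactMatrix(bins, mat, "nucleosome", offsets,
                         n_discarded=discarded)


def pileup(matrix: ContactMatrix, anchors: pd.DataFrame,
           window_bp: int = 3000) -> np.ndarray:
    """Average contact-map snippets centered on anchor sites.

    Returns the element-wise mean of the (window/res)-sized square
    snippets around each usable anchor; anchors whose snippet would
    leave their contig are skipped.
    """
    if matrix.resolution == "nucleosome":
        raise ValueError("pileup needs a bp-binned matrix")
    res = int(matrix.resolution)
    n = window_bp // res
    half = n // 2
    acc = np.zeros((n, n))
    used = 0
    for _, row in anchors.iterrows():
        contig = row["chrom"]
        if contig not in matrix.contig_bins:
            continue
        lo, hi = matrix.contig_bins[contig]
        b = lo + int(row["pos"]) // res
        r0, r1 = b - half, b - half + n
        if r0 < lo or r1 > hi:
            continue
        sub = matrix.mat[r0:r1, r0:r1].toarray().astype(float)
        acc += sub + np.triu(sub, 1).T
        used += 1
    if used == 0:
        raise ValueError("no usable anchors for pileup "
                         "(all skipped at contig edges)")
    return acc / used


@dataclass
class DecayCurve:
    """Contact frequency vs genomic distance, per orientation class."""

    edges: np.ndarray  # log-spaced bp bin edges
    frequency: dict[str, np.ndarray]  # normalized to sum 1 per class
    log10_frequency: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        self.log10_frequency = {
            k: np.where(v > 0, np.log10(np.where(v > 0, v, 1.0)), np.nan)
            for k, v in self.frequency.items()
        }

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])


def decay_curve(pairs: pd.DataFrame, min_distance_bp: int = 147,
                bins_per_decade: int = 20,
                classes: tuple[str, ...] | None = None,
                max_distance_bp: int | None = None) -> DecayCurve:
    """Histogram pair distances in log-spaced bins, per orientation class.

    ``max_distance_bp`` fixes the upper edge (default: the largest
    observed distance), so curves from different samples share a grid.
    """
    dist = np.abs(pairs["pos2"].to_numpy() - pairs["pos1"].to_numpy())
    same = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    dist = dist[same]
    ori = pairs["orientation"].to_numpy()[same]
    if classes is None:
        classes = tuple(sorted(set(ori)))
    dmax = max_distance_bp if max_distance_bp is not None else max(
        dist.max() if dist.size else min_distance_bp + 1,
        min_distance_bp + 1)
    n_bins = max(int(np.ceil(
        bins_per_decade * np.log10(dmax / min_distance_bp))), 1)
    edges = np.geomspace(min_distance_bp, dmax + 1, n_bins + 1)
    freq = {}
    for cls in classes:
        d = dist[ori == cls]
        if d.size == 0:
            warnings.warn(f"orientation class {cls!r} has no pairs; "
                          f"curve is NaN")
            freq[cls] = np.full(n_bins, np.nan)
            continue
        h, _ = np.histogram(d, bins=edges)
        freq[cls] = h / h.sum()
    return DecayCurve(edges, freq)


def fit_decay_slope(curve: DecayCurve, cls: str,
                    smin: float = 400.0, smax: float = 6000.0) -> float:
    """Log-log slope of contact density vs distance over [smin, smax].

    The per-bin frequency is divided by the bin width before fitting,
    so a sampling law s^-alpha yields slope -alpha.
    """
    f = curve.frequency[cls]
    widths = np.diff(curve.edges)
    centers = curve.centers
    ok = (f > 0) & (centers >= smin) & (centers <= smax)
    if ok.sum() < 3:
        raise ValueError("too few populated bins in the fit range")
    slope, _ = np.polyfit(np.log10(centers[ok]),
                          np.log10(f[ok] / widths[ok]), 1)
    return float(slope)


def matrix_correlation(m1: ContactMatrix, m2: ContactMatrix,
                       max_distance_bp: int = 5000) -> float:
    """Pearson r of two matrices on log10(1+count), near-diagonal cells.

    All cells (including zeros) with bin separation up to
    ``max_distance_bp`` enter the correlation.
    """
    if not m1.same_bins(m2):
        raise ValueError("matrices have different bin tables")
    if m1.resolution == "nucleosome":
        raise ValueError("replicate correlation is defined on bp bins")
    res = int(m1.resolution)
    w = max_distance_bp // res
    x_all, y_all = [], []
    for contig in m1.contig_bins:
        d1 = m1.dense(contig)
        d2 = m2.dense(contig)
        n = d1.shape[0]
        i, j = np.triu_indices(n)
        band = (j - i) <= w
        x_all.append(d1[i[band], j[band]])
        y_all.append(d2[i[band], j[band]])
    x = np.log10(1 + np.concatenate(x_all))
    y = np.log10(1 + np.concatenate(y_all))
    return float(np.corrcoef(x, y)[0, 1])


def write_sparse_triplets(matrix: ContactMatrix, path,
                          header: list[str] | None = None) -> None:
    """Sparse triplet text (bin1 bin2 count) with the bin table inline-free."""
    coo = matrix.mat.tocoo()
    with open(path, "w") as fh:
        for h in header or []:
            fh.write(h + "\n")
        fh.write("#columns: bin1\tbin2\tcount\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{int(v)}\n")


def write_bins_bed(matrix: ContactMatrix, path) -> None:
    matrix.bins.to_csv(path, sep="\t", header=False, index=False)
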