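"""Coarse-grained 3D chromatin reconstruction by simulated annealing.

A nucleosome is modeled as four 3 nm histone beads on the superhelical
axis with 23 DNA beads (5.88 bp each) wrapped around them in a
left-handed superhelix of 1.65 turns, 4.18 nm radius and 2.39 nm pitch;
linker DNA continues the chain at one bead per 5.88 bp with a 2.0 nm
rise (0.34 nm/bp).  Contact counts from a nucleosome-binned matrix
become distance restraints with weight ``ln(1 + count)``, and the model
is relaxed by Metropolis single-bead annealing with geometric cooling.

The energy is

``E = Σ_bonds k_b (|d|-d0)^2 + Σ_linker-angles k_a θ^2
   + Σ_histone-overlaps k_rep (2r-|d|)^2
   + Σ_restraints w_ij k_r (|d|-d_contact)^2 [|d| > d_contact]``

with the angle stiffness set by the 50 nm DNA persistence length.
The reconstruction is descriptive (domain separation, not
thermodynamics) and bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .matrices import ContactMatrix, NucleosomeLoci
from .presets import NUCLEOSOME_BP


@dataclass(frozen=True)
class BeadGeometry:
    histone_beads_per_nucleosome: int = 4
    histone_bead_radius: float = 3.0  # nm
    bp_per_dna_bead: float = 5.88
    wrapped_beads_per_nucleosome: int = 23
    wrap_turns: float = 1.65  # left-handed
    wrap_radius: float = 4.18  # nm
    wrap_pitch: float = 2.39  # nm per turn
    dna_rise: float = 0.34  # nm/bp (standard B-DNA)

    @property
    def dna_bond_length(self) -> float:
        return self.bp_per_dna_bead * self.dna_rise  # 2.0 nm

    @property
    def wrap_axial_extent(self) -> float:
        return self.wrap_turns * self.wrap_pitch


KIND_HISTONE, KIND_WRAPPED, KIND_LINKER = 0, 1, 2
KIND_NAMES = {KIND_HISTONE: "histone", KIND_WRAPPED: "dna_wrapped",
              KIND_LINKER: "dna_linker"}


@dataclass
class BeadModel:
    """Bead coordinates, topology and per-nucleosome bookkeeping."""

    coords: np.ndarray  # (N, 3) nm
    kind: np.ndarray  # (N,) KIND_*
    nuc_id: np.ndarray  # (N,) nucleosome id, -1 for linker beads
    chain_id: np.ndarray  # (N,) contig index
    bonds: np.ndarray  # (M, 2)
    bond_rest: np.ndarray  # (M,)
    angles: np.ndarray  # (K, 3) linker bend triples
    histone_index: np.ndarray  # (n_nuc, 4)
    entry_exit: np.ndarray  # (n_nuc, 2) first/last wrapped bead
    nuc_axis: np.ndarray  # (n_nuc, 3) superhelical axis at init
    nuc_axis_point: np.ndarray  # (n_nuc, 3) point on the axis at init
    contigs: list = field(default_factory=list)
    dyads: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    geometry: BeadGeometry = field(default_factory=BeadGeometry)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def n_nucleosomes(self) -> int:
        return self.histone_index.shape[0]

    def histone_centers(self, coords: np.ndarray | None = None) -> np.ndarray:
        c = self.coords if coords is None else coords
        return c[self.histone_index].mean(axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian, sign-fixed)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 2] *= -1
    return Q


def _local_nucleosome(geom: BeadGeometry):
    """Wrapped-DNA and histone bead coordinates in the local frame.

    The superhelical axis is local +z.  The wrap advances clockwise
    when viewed down +z while climbing, i.e. a left-handed helix.
    """
    nw = geom.wrapped_beads_per_nucleosome
    total = np.deg2rad(geom.wrap_turns * 360.0)
    phi = np.linspace(0.0, total, nw)
    z = geom.wrap_pitch * phi / (2 * np.pi)
    wrap = np.stack([
        geom.wrap_radius * np.cos(phi),
        -geom.wrap_radius * np.sin(phi),  # left-handed
        z,
    ], axis=1)
    nh = geom.histone_beads_per_nucleosome
    hz = geom.wrap_axial_extent * (np.arange(nh) + 0.5) / nh
    hist = np.stack([np.zeros(nh), np.zeros(nh), hz], axis=1)
    return wrap, hist


def build_topology(loci: NucleosomeLoci, geometry: BeadGeometry | None = None,
                   seed: int = 0) -> BeadModel:
    """Lay out the bead chain for the given nucleosome loci.

    One chain per contig: 23 wrapped beads per nucleosome on the
    superhelix, ``round(linker_bp / 5.88)`` linker beads between
    consecutive nucleosomes, histone beads on the superhelical axis.
    Initialization follows a random walk with excluded-volume retries
    between histone cores.  Raises if consecutive dyads are closer than
    147 bp (overlapping nucleosomes).
    """
    geom = geometry or BeadGeometry()
    rng = np.random.default_rng(seed)
    wrap_local, hist_local = _local_nucleosome(geom)
    lb = geom.dna_bond_length

    coords, kind, nuc_id, chain_id = [], [], [], []
    bonds, bond_rest, angles = [], [], []
    histone_index, entry_exit, axes, axis_points = [], [], [], []
    dyads_flat, contigs = [], []

    nuc_counter = 0
    placed_hist: list[np.ndarray] = []
    for chain, (contig, d) in enumerate(loci.dyads.items()):
        contigs.append(contig)
        if d.size == 0:
            continue
        gaps = np.diff(d)
        bad = np.flatnonzero(gaps < NUCLEOSOME_BP)
        if bad.size:
            raise ValueError(
                f"overlapping nucleosomes on {contig!r} at dyads "
                f"{[(int(d[b]), int(d[b + 1])) for b in bad[:5]]}")
        attach = (np.array([0.0, 0.0, 0.0]) if not placed_hist
                  else placed_hist[-1].mean(0) + np.array([30.0, 0, 0]))
        prev_dna = -1  # global index of previous DNA bead in this chain
        for k, dyad in enumerate(d):
            # place the nucleosome: random orientation, entry bead at
            # the attach point; retry rotations that clash with
            # previously placed histone cores
            for _ in range(40):
                Q = _random_rotation(rng)
                shift = attach - wrap_local[0] @ Q.T
                hist = hist_local @ Q.T + shift
                if not placed_hist:
                    break
                prev = np.concatenate(placed_hist[-12:])
                dmin = np.sqrt(
                    ((prev[:, None, :] - hist[None, :, :]) ** 2
                     ).sum(-1)).min()
                if dmin >= 2 * geom.histone_bead_radius:
                    break
            wrap = wrap_local @ Q.T + shift
            base = len(coords)
            for m in range(geom.wrapped_beads_per_nucleosome):
                coords.append(wrap[m])
                kind.append(KIND_WRAPPED)
                nuc_id.append(nuc_counter)
                chain_id.append(chain)
            hbase = len(coords)
            for m in range(geom.histone_beads_per_nucleosome):
                coords.append(hist[m])
                kind.append(KIND_HISTONE)
                nuc_id.append(nuc_counter)
                chain_id.append(chain)
            placed_hist.append(hist)
            histone_index.append(
                list(range(hbase, hbase + geom.histone_beads_per_nucleosome)))
            entry_exit.append(
                [base, base + geom.wrapped_beads_per_nucleosome - 1])
            axes.append(Q @ np.array([0.0, 0.0, 1.0]))
            axis_points.append(shift)
            dyads_flat.append(int(dyad))

            # chain bonds through the wrap
            if prev_dna >= 0:
                bonds.append((prev_dna, base))
                bond_rest.append(lb)
            for m in range(geom.wrapped_beads_per_nucleosome - 1):
                bonds.append((base + m, base + m + 1))
                bond_rest.append(
                    float(np.linalg.norm(wrap[m + 1] - wrap[m])))
            # stiffening bonds: wrapped bead to nearest histone bead
            for m in range(geom.wrapped_beads_per_nucleosome):
                dh = np.linalg.norm(hist - wrap[m], axis=1)
                j = int(np.argmin(dh))
                bonds.append((base + m, hbase + j))
                bond_rest.append(float(dh[j]))
            # histone-histone backbone
            for m in range(geom.histone_beads_per_nucleosome - 1):
                bonds.append((hbase + m, hbase + m + 1))
                bond_rest.append(
                    float(np.linalg.norm(hist[m + 1] - hist[m])))
            prev_dna = base + geom.wrapped_beads_per_nucleosome - 1
            nuc_counter += 1

            # linker to the next nucleosome
            if k + 1 < d.size:
                linker_bp = int(gaps[k]) - NUCLEOSOME_BP
                n_l = int(round(linker_bp / geom.bp_per_dna_bead))
                exit_pos = np.asarray(coords[prev_dna])
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                first_linker = len(coords)
                for m in range(n_l):
                    coords.append(exit_pos + direction * lb * (m + 1))
                    kind.append(KIND_LINKER)
                    nuc_id.append(-1)
                    chain_id.append(chain)
                    prev = prev_dna if m == 0 else len(coords) - 2
                    bonds.append((prev, len(coords) - 1))
                    bond_rest.append(lb)
                # bend stiffness on linker interior joints
                for m in range(n_l):
                    center = first_linker + m
                    left = prev_dna if m == 0 else center - 1
                    right = center + 1 if m + 1 < n_l else -1
                    if right >= 0:
                        angles.append((left, center, right))
                attach = exit_pos + direction * lb * (n_l + 1)
                prev_dna = first_linker + n_l - 1 if n_l else prev_dna
                if n_l == 0:
                    attach = exit_pos + direction * lb

    if nuc_counter == 0:
        raise ValueError("no nucleosomes in loci")
    return BeadModel(
        coords=np.asarray(coords, dtype=np.float64),
        kind=np.asarray(kind, dtype=np.int8),
        nuc_id=np.asarray(nuc_id, dtype=np.int64),
        chain_id=np.asarray(chain_id, dtype=np.int64),
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_rest=np.asarray(bond_rest, dtype=np.float64),
        angles=(np.asarray(angles, dtype=np.int64).reshape(-1, 3)
                if angles else np.empty((0, 3), dtype=np.int64)),
        histone_index=np.asarray(histone_index, dtype=np.int64),
        entry_exit=np.asarray(entry_exit, dtype=np.int64),
        nuc_axis=np.asarray(axes, dtype=np.float64),
        nuc_axis_point=np.asarray(axis_points, dtype=np.float64),
        contigs=contigs,
        dyads=np.asarray(dyads_flat, dtype=np.int64),
        geometry=geom,
    )


@dataclass
class RestraintSet:
    """Pairwise nucleosome restraints from a contact matrix."""

    nuc_i: np.ndarray
    nuc_j: np.ndarray
    weight: np.ndarray  # ln(1 + count)
    d_contact: float = 11.0  # nm
    orientation: np.ndarray | None = None  # class tag per restraint

    def __len__(self) -> int:
        return self.nuc_i.size


def restraints_from_matrix(nuc_matrix: ContactMatrix,
                           d_contact: float = 11.0,
                           orientation_of_pair=None) -> RestraintSet:
    """One restraint per nonzero off-diagonal cell, weight ln(1+count)."""
    if nuc_matrix.resolution != "nucleosome":
        raise ValueError("restraints need a nucleosome-binned matrix")
    coo = nuc_matrix.mat.tocoo()
    off = coo.row != coo.col
    i, j, c = coo.row[off], coo.col[off], coo.data[off]
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    ori = None
    if orientation_of_pair is not None:
        ori = np.asarray(
            [orientation_of_pair.get((a, b), "") for a, b in zip(lo, hi)],
            dtype=object)
    return RestraintSet(lo.astype(np.int64), hi.astype(np.int64),
                        np.log1p(c.astype(float)), d_contact, ori)


@dataclass
class AnnealSchedule:
    t_start: float = 8.0
    t_end: float = 0.02
    n_sweeps: int = 2500
    move_size: float = 1.5  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_start > self.t_end > 0):
            raise ValueError("need t_start > t_end > 0")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")


def _csr_adjacency(n_beads: int, items: np.ndarray, per_item_beads):
    """Map bead -> indices of items (bonds/angles/restraints) touching it."""
    lists: list[list[int]] = [[] for _ in range(n_beads)]
    for idx in range(items.shape[0]):
        for b in per_item_beads(items[idx]):
            lists[int(b)].append(idx)
    ptr = np.zeros(n_beads + 1, dtype=np.int64)
    flat = []
    for b in range(n_beads):
        ptr[b + 1] = ptr[b] + len(lists[b])
        flat.extend(lists[b])
    return np.asarray(flat, dtype=np.int64), ptr


@njit(cache=True)
def _bead_energy(b, pos, coords,
                 bond_ij, bond_r0, badj, bptr,
                 ang, aadj, aptr,
                 r_bi, r_bj, r_w, radj, rptr,
                 hist_beads, is_hist,
                 kb, ka, krep, rrep, kr, d_c):
    e = 0.0
    for t in range(bptr[b], bptr[b + 1]):
        k = badj[t]
        i, j = bond_ij[k, 0], bond_ij[k, 1]
        other = j if i == b else i
        dx = pos[0] - coords[other, 0]
        dy = pos[1] - coords[other, 1]
        dz = pos[2] - coords[other, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += kb * (d - bond_r0[k]) ** 2
    for t in range(aptr[b], aptr[b + 1]):
        k = aadj[t]
        ia, ib, ic = ang[k, 0], ang[k, 1], ang[k, 2]
        ax = pos if ia == b else coords[ia]
        bx = pos if ib == b else coords[ib]
        cx = pos if ic == b else coords[ic]
        v1x, v1y, v1z = bx[0] - ax[0], bx[1] - ax[1], bx[2] - ax[2]
        v2x, v2y, v2z = cx[0] - bx[0], cx[1] - bx[1], cx[2] - bx[2]
        n1 = np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
        n2 = np.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
        if n1 > 0 and n2 > 0:
            c = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * n2)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            th = np.arccos(c)
            e += ka * th * th
    for t in range(rptr[b], rptr[b + 1]):
        k = radj[t]
        other = r_bj[k] if r_bi[k] == b else r_bi[k]
        dx = pos[0] - coords[other, 0]
        dy = pos[1] - coords[other, 1]
        dz = pos[2] - coords[other, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > d_c:
            e += r_w[k] * kr * (d - d_c) ** 2
    if is_hist[b]:
        for t in range(hist_beads.size):
            o = hist_beads[t]
            if o == b:
                continue
            dx = pos[0] - coords[o, 0]
            dy = pos[1] - coords[o, 1]
            dz = pos[2] - coords[o, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d < rrep:
                e += krep * (rrep - d) ** 2
    return e


@njit(cache=True)
def _total_energy(coords, bond_ij, bond_r0, ang,
                  r_bi, r_bj, r_w, hist_beads,
                  kb, ka, krep, rrep, kr, d_c):
    e = 0.0
    for k in range(bond_ij.shape[0]):
        d = np.sqrt(((coords[bond_ij[k, 0]] - coords[bond_ij[k, 1]]) ** 2
                     ).sum())
        e += kb * (d - bond_r0[k]) ** 2
    for k in range(ang.shape[0]):
        v1 = coords[ang[k, 1]] - coords[ang[k, 0]]
        v2 = coords[ang[k, 2]] - coords[ang[k, 1]]
        n1 = np.sqrt((v1 ** 2).sum())
        n2 = np.sqrt((v2 ** 2).sum())
        if n1 > 0 and n2 > 0:
            c = (v1 * v2).sum() / (n1 * n2)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            th = np.arccos(c)
            e += ka * th * th
    for k in range(r_bi.size):
        d = np.sqrt(((coords[r_bi[k]] - coords[r_bj[k]]) ** 2).sum())
        if d > d_c:
            e += r_w[k] * kr * (d - d_c) ** 2
    for a in range(hist_beads.size):
        for b in range(a + 1, hist_beads.size):
            d = np.sqrt(((coords[hist_beads[a]] - coords[hist_beads[b]]) ** 2
                         ).sum())
            if d < rrep:
                e += krep * (rrep - d) ** 2
    return e


@njit(cache=True)
def _anneal_kernel(coords, bond_ij, bond_r0, badj, bptr,
                   ang, aadj, aptr,
                   r_bi, r_bj, r_w, radj, rptr,
                   hist_beads, is_hist,
                   kb, ka, krep, rrep, kr, d_c,
                   t_start, t_end, n_sweeps, move_size, seed):
    np.random.seed(seed)
    n = coords.shape[0]
    trace = np.empty(n_sweeps + 1)
    trace[0] = _total_energy(coords, bond_ij, bond_r0, ang,
                             r_bi, r_bj, r_w, hist_beads,
                             kb, ka, krep, rrep, kr, d_c)
    ratio = t_end / t_start
    pos = np.empty(3)
    for sweep in range(n_sweeps):
        if n_sweeps > 1:
            T = t_start * ratio ** (sweep / (n_sweeps - 1))
        else:
            T = t_end
        for b in range(n):
            pos[0] = coords[b, 0] + np.random.normal() * move_size
            pos[1] = coords[b, 1] + np.random.normal() * move_size
            pos[2] = coords[b, 2] + np.random.normal() * move_size
            e_old = _bead_energy(
                b, coords[b], coords, bond_ij, bond_r0, badj, bptr,
                ang, aadj, aptr, r_bi, r_bj, r_w, radj, rptr,
                hist_beads, is_hist, kb, ka, krep, rrep, kr, d_c)
            e_new = _bead_energy(
                b, pos, coords, bond_ij, bond_r0, badj, bptr,
                ang, aadj, aptr, r_bi, r_bj, r_w, radj, rptr,
                hist_beads, is_hist, kb, ka, krep, rrep, kr, d_c)
            dE = e_new - e_old
            if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                coords[b, 0] = pos[0]
                coords[b, 1] = pos[1]
                coords[b, 2] = pos[2]
        trace[sweep + 1] = _total_energy(
            coords, bond_ij, bond_r0, ang, r_bi, r_bj, r_w, hist_beads,
            kb, ka, krep, rrep, kr, d_c)
    return trace


def anneal(model: BeadModel, restraints: RestraintSet | None = None,
           schedule: AnnealSchedule | None = None,
           k_bond: float = 100.0, k_angle: float = 12.5,
           k_repulsion: float = 5.0, k_restraint: float = 2.0
           ) -> tuple[np.ndarray, np.ndarray]:
    """Metropolis single-bead annealing; returns (coords, energy trace).

    ``k_angle`` = Lp / (2 l_bond) = 50 nm / 4 nm in kT per rad^2.
    Inward-tagged restraints act between the entry/exit wrapped DNA
    beads of the two nucleosomes; all others between histone-core
    beads.
    """
    sched = schedule or AnnealSchedule()
    coords = model.coords.copy()
    n = model.n_beads
    # resolve restraints to bead indices
    if restraints is not None and len(restraints):
        center_bead = model.histone_index[:, 1]
        bi = center_bead[restraints.nuc_i].copy()
        bj = center_bead[restraints.nuc_j].copy()
        if restraints.orientation is not None:
            inward = restraints.orientation == "inward"
            bi[inward] = model.entry_exit[restraints.nuc_i[inward], 1]
            bj[inward] = model.entry_exit[restraints.nuc_j[inward], 0]
        r_w = restraints.weight.astype(np.float64)
        d_c = float(restraints.d_contact)
    else:
        bi = np.empty(0, dtype=np.int64)
        bj = np.empty(0, dtype=np.int64)
        r_w = np.empty(0, dtype=np.float64)
        d_c = 11.0

    badj, bptr = _csr_adjacency(n, model.bonds, lambda it: (it[0], it[1]))
    aadj, aptr = _csr_adjacency(n, model.angles,
                                lambda it: (it[0], it[1], it[2]))
    r_items = np.stack([bi, bj], axis=1) if bi.size else np.empty((0, 2), int)
    radj, rptr = _csr_adjacency(n, r_items, lambda it: (it[0], it[1]))
    hist_beads = model.histone_index.ravel().astype(np.int64)
    is_hist = (model.kind == KIND_HISTONE)
    rrep = 2 * model.geometry.histone_bead_radius

    trace = _anneal_kernel(
        coords, model.bonds, model.bond_rest, badj, bptr,
        model.angles, aadj, aptr,
        bi, bj, r_w, radj, rptr,
        hist_beads, is_hist.astype(np.bool_),
        k_bond, k_angle, k_repulsion, rrep, k_restraint, d_c,
        sched.t_start, sched.t_end, sched.n_sweeps, sched.move_size,
        sched.seed)
    if not np.isfinite(trace).all() or not np.isfinite(coords).all():
        raise FloatingPointError("annealing diverged: non-finite energy "
                                 "or coordinates")
    return coords, trace


def model_contact_map(model: BeadModel, coords: np.ndarray,
                      cutoff_nm: float = 15.0) -> ContactMatrix:
    """Binary nucleosome contact map from histone-center distances."""
    from scipy import sparse
    import pandas as pd
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    centers = model.histone_centers(coords)
    n = centers.shape[0]
    d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
    i, j = np.where((d <= cutoff_nm) & (np.arange(n)[:, None] < np.arange(n)))
    mat = sparse.coo_matrix((np.ones(i.size), (i, j)), shape=(n, n)).tocsr()
    # one bin per nucleosome, grouped by chain
    chroms = [model.contigs[model.chain_id[model.histone_index[k, 0]]]
              for k in range(n)]
    bins = pd.DataFrame({"chrom": chroms, "start": model.dyads,
                         "end": model.dyads + 1})
    offsets = {}
    for c in dict.fromkeys(chroms):
        idx = [k for k, cc in enumerate(chroms) if cc == c]
        offsets[c] = (min(idx), max(idx) + 1)
    return ContactMatrix(bins, mat, "nucleosome", offsets)


def write_structure(model: BeadModel, coords: np.ndarray, path) -> None:
    """PDB-like export: one ATOM record per bead, one chain per contig."""
    path = str(path)
    kind_el = {KIND_HISTONE: "HB", KIND_WRAPPED: "DW", KIND_LINKER: "DL"}
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if path.endswith(".xyz"):
        with open(path, "w") as fh:
            fh.write(f"{model.n_beads}\n")
            fh.write("nucdomains coarse-grained beads (nm)\n")
            for k in range(model.n_beads):
                x, y, z = coords[k]
                fh.write(f"{kind_el[int(model.kind[k])]} "
                         f"{x:.3f} {y:.3f} {z:.3f}\n")
        return
    with open(path, "w") as fh:
        for k in range(model.n_beads):
            x, y, z = coords[k]
            ch = chains[int(model.chain_id[k]) % len(chains)]
            fh.write(
                f"ATOM  {k + 1:5d} {kind_el[int(model.kind[k])]:>4s} NUC "
                f"{ch}{int(model.nuc_id[k]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{kind_el[int(model.kind[k])]:>2s}\n")
        fh.write("END\n")


def read_structure_coords(path) -> np.ndarray:
    """Coordinates back from :func:`write_structure` output."""
    path = str(path)
    rows = []
    with open(path) as fh:
        if path.endswith(".xyz"):
            lines = fh.readlines()[2:]
            for line in lines:
                parts = line.split()
                if len(parts) >= 4:
                    rows.append([float(p) for p in parts[1:4]])
        else:
            for line in fh:
                if line.startswith("ATOM"):
                    rows.append([float(line[30:38]), float(line[38:46]),
                                 float(line[46:54])])
    return np.asarray(rows)
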