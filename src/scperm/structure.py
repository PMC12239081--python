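"""Bilayer structural metrics: density, thickness, APL, order, distances,
hydrogen bonds.

All z coordinates are taken relative to the bilayer center, defined per
frame as the mass-weighted mean z of the lipid atoms (this removes drift).
Histograms along z place bin *centers* on multiples of the bin width
relative to the center, so ideal fixtures land exactly on bin centers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import Snapshot, Trajectory, guess_masses
from .errors import ScpermError
from .io import select_atoms

__all__ = [
    "DensityProfile",
    "OrderParameterProfile",
    "HBondCriteria",
    "HBondGroup",
    "HBondReport",
    "DistanceDistribution",
    "density_profile",
    "membrane_thickness",
    "area_per_lipid",
    "order_parameter",
    "chain_distance_distribution",
    "count_hbonds",
]


class StructureError(ScpermError):
    """A structural metric could not be evaluated on the given trajectory."""


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------
def _bilayer_center(snap: Snapshot, center_idx: np.ndarray) -> float:
    m = guess_masses(snap.names[center_idx])
    return float(np.average(snap.positions[center_idx, 2], weights=m))


def _center_indices(snap: Snapshot, center_selection: str | None) -> np.ndarray:
    if center_selection is None:
        return np.arange(snap.n_atoms)
    idx = select_atoms(snap, center_selection)
    if len(idx) == 0:
        raise StructureError(f"center selection {center_selection!r} matches no atoms")
    return idx


def _z_edges(half_extent: float, bin_width: float) -> np.ndarray:
    """Bin edges symmetric about 0 with centers on multiples of bin_width."""
    n_half = int(math.ceil(half_extent / bin_width))
    return (np.arange(-n_half, n_half + 1) + 0.5) * bin_width


def _minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


# ----------------------------------------------------------------------
# density and thickness
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class DensityProfile:
    """Mass density along z per selection (amu/nm^3), frame-averaged."""

    z: np.ndarray  # bin centers, bilayer-center origin (nm)
    density: dict  # label -> array over bins
    n_frames: int
    bin_width: float
    box_area: float  # frame-mean lateral area (nm^2)

    def total_mass(self, label: str) -> float:
        """Selected mass implied by the profile (closure check)."""
        return float(np.sum(self.density[label]) * self.bin_width * self.box_area)


def density_profile(
    traj: Trajectory,
    selection: str | Mapping[str, str],
    bin_width: float = 0.02,
    center_selection: str | None = None,
) -> DensityProfile:
    """Mass-weighted density histogram along the membrane normal.

    ``selection`` may be a single expression or a mapping of labels to
    expressions; each is histogrammed separately against the same bins.
    Per frame the histogram is normalized by slab volume (bin width x
    lateral box area), then averaged over frames.
    """
    if bin_width <= 0:
        raise StructureError("bin_width must be positive")
    selections = {"selection": selection} if isinstance(selection, str) else dict(selection)
    first = traj[0]
    sel_idx = {}
    for label, expr in selections.items():
        idx = select_atoms(first, expr)
        if len(idx) == 0:
            raise StructureError(f"selection {expr!r} matches no atoms")
        sel_idx[label] = idx
    center_idx = _center_indices(first, center_selection)

    lz_max = max(fr.box[2] for fr in traj)
    edges = _z_edges(lz_max / 2.0 + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    sums = {label: np.zeros(len(centers)) for label in sel_idx}
    area_sum = 0.0
    for fr in traj:
        zc = _bilayer_center(fr, center_idx)
        area = fr.box[0] * fr.box[1]
        area_sum += area
        for label, idx in sel_idx.items():
            z = fr.positions[idx, 2] - zc
            m = guess_masses(fr.names[idx])
            hist, _ = np.histogram(z, bins=edges, weights=m)
            sums[label] += hist / (bin_width * area)
    n = traj.n_frames
    return DensityProfile(
        z=centers,
        density={k: v / n for k, v in sums.items()},
        n_frames=n,
        bin_width=bin_width,
        box_area=area_sum / n,
    )


def _peak_position(hist: np.ndarray, centers: np.ndarray) -> float:
    """Histogram mode refined by a quadratic fit through the 3 bins around it."""
    m = int(np.argmax(hist))
    if m == 0 or m == len(hist) - 1:
        return float(centers[m])
    denom = hist[m - 1] - 2.0 * hist[m] + hist[m + 1]
    if denom == 0:
        return float(centers[m])
    offset = 0.5 * (hist[m - 1] - hist[m + 1]) / denom
    return float(centers[m] + offset * (centers[1] - centers[0]))


def membrane_thickness(
    traj: Trajectory,
    marker_selection: str,
    n_blocks: int = 6,
    block_span: int | None = None,
    bin_width: float = 0.02,
    center_selection: str | None = None,
) -> tuple[float, float]:
    """Thickness from the headgroup-marker density peaks of the two leaflets.

    Frames are split into ``n_blocks`` contiguous blocks (``block_span``
    frames each, if given); each block's marker histogram yields one peak
    per leaflet (z < 0 and z > 0 relative to the bilayer center, quadratic
    sub-bin refinement), and the thickness is the peak separation.  Returns
    (mean, standard error) over blocks.
    """
    first = traj[0]
    marker_idx = select_atoms(first, marker_selection)
    if len(marker_idx) == 0:
        raise StructureError(f"marker selection {marker_selection!r} matches no atoms")
    center_idx = _center_indices(first, center_selection)

    frame_ids = np.arange(traj.n_frames)
    if block_span is not None:
        blocks = [frame_ids[i : i + block_span] for i in range(0, len(frame_ids), block_span)]
    else:
        blocks = np.array_split(frame_ids, min(n_blocks, len(frame_ids)))
    blocks = [b for b in blocks if len(b)]

    lz_max = max(fr.box[2] for fr in traj)
    edges = _z_edges(lz_max / 2.0 + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    upper = centers > 0
    lower = centers < 0

    values = []
    for b in blocks:
        hist = np.zeros(len(centers))
        for fi in b:
            fr = traj[fi]
            z = fr.positions[marker_idx, 2] - _bilayer_center(fr, center_idx)
            h, _ = np.histogram(z, bins=edges)
            hist += h
        if hist[upper].sum() == 0 or hist[lower].sum() == 0:
            raise StructureError("a leaflet has no marker atoms; cannot locate peaks")
        z_up = _peak_position(hist[upper], centers[upper])
        z_dn = _peak_position(hist[lower], centers[lower])
        values.append(z_up - z_dn)
    values = np.asarray(values)
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return float(values.mean()), se


def area_per_lipid(traj: Trajectory, n_lipids_per_leaflet: int) -> tuple[float, float]:
    """APL = Lx*Ly / n per frame; returns (time mean, std of the frame series).

    The error is the spread of the per-frame values around the average
    (population standard deviation), i.e. the box-area oscillation.
    """
    if n_lipids_per_leaflet <= 0:
        raise StructureError("n_lipids_per_leaflet must be positive")
    apl = np.array([fr.box[0] * fr.box[1] / n_lipids_per_leaflet for fr in traj])
    return float(apl.mean()), float(apl.std(ddof=0))


# ----------------------------------------------------------------------
# chain order
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class OrderParameterProfile:
    """S_z per interior chain carbon: 1 = aligned with the normal, -0.5 =
    perpendicular."""

    carbon_index: np.ndarray  # positions 2..n-1 along the named chain
    S_z: np.ndarray
    selection: str

    def __post_init__(self) -> None:
        s = np.asarray(self.S_z, dtype=float)
        if ((s < -0.5 - 1e-9) | (s > 1.0 + 1e-9)).any():
            raise ValueError("S_z must lie in [-0.5, 1]")


def _per_residue_indices(
    snap: Snapshot, atom_names: Sequence[str], resname: str | None
) -> np.ndarray:
    """(n_residues, n_names) atom indices, residues sorted by resid.

    Raises naming the lipid and atom if any residue misses a named atom.
    """
    res_mask = np.ones(snap.n_atoms, dtype=bool)
    if resname is not None:
        res_mask = snap.resnames == resname
    resids = np.unique(snap.resids[res_mask])
    out = np.empty((len(resids), len(atom_names)), dtype=int)
    for j, name in enumerate(atom_names):
        sel = res_mask & (snap.names == name)
        idx = np.flatnonzero(sel)
        found = snap.resids[idx]
        order = np.argsort(found)
        idx, found = idx[order], found[order]
        if len(idx) != len(resids) or (found != resids).any():
            missing = sorted(set(resids) - set(found))
            raise StructureError(
                f"atom {name!r} missing in residue(s) {missing[:5]}"
            )
        out[:, j] = idx
    return out


def order_parameter(
    traj: Trajectory,
    chain_atom_names: Sequence[str],
    resname: str | None = None,
) -> OrderParameterProfile:
    """S_z order parameter along a named chain.

    For interior carbon i the molecular axis is the vector from atom i-1 to
    atom i+1; with theta its angle to the box normal,
    S_z(i) = <(3 cos^2 theta - 1)/2> over lipids and frames.
    """
    if len(chain_atom_names) < 3:
        raise StructureError("need at least three chain atoms for an interior carbon")
    idx = _per_residue_indices(traj[0], chain_atom_names, resname)
    n_interior = len(chain_atom_names) - 2
    acc = np.zeros(n_interior)
    count = 0
    for fr in traj:
        pos = fr.positions[idx]  # (n_res, n_names, 3)
        axis = pos[:, 2:, :] - pos[:, :-2, :]  # (n_res, n_interior, 3)
        norm = np.linalg.norm(axis, axis=2)
        if (norm == 0).any():
            raise StructureError("degenerate chain axis (coincident atoms)")
        cos2 = (axis[:, :, 2] / norm) ** 2
        acc += (1.5 * cos2 - 0.5).mean(axis=0)
        count += 1
    return OrderParameterProfile(
        carbon_index=np.arange(2, len(chain_atom_names)),
        S_z=acc / count,
        selection=",".join(chain_atom_names) + (f" ({resname})" if resname else ""),
    )


# ----------------------------------------------------------------------
# chain-to-chain distance distribution
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class DistanceDistribution:
    """Pooled chain-chain distances with a Gaussian-kernel smoothed density."""

    distances: np.ndarray  # raw samples (nm)
    grid: np.ndarray
    density: np.ndarray  # integrates to 1
    modes: np.ndarray  # local maxima of the smoothed density (nm)
    bandwidth: float


def chain_distance_distribution(
    traj: Trajectory,
    atom_a_name: str,
    atom_b_name: str,
    bandwidth: float = 0.025,
    resname: str | None = None,
    lateral: bool = True,
) -> DistanceDistribution:
    """Distribution of the per-lipid distance between two named atoms.

    Distances are xy-projected ("lateral", minimum image) by default — the
    separation of a ceramide's two chain ends — with a 3-D mode available
    for cross-checks.  The pooled samples are smoothed with a fixed-width
    Gaussian kernel on a grid extending 6 bandwidths past the data, and
    modes are located from sign changes of the density's finite-difference
    derivative.
    """
    if bandwidth <= 0:
        raise StructureError("bandwidth must be positive")
    idx = _per_residue_indices(traj[0], [atom_a_name, atom_b_name], resname)
    dists = []
    for fr in traj:
        pa = fr.positions[idx[:, 0]]
        pb = fr.positions[idx[:, 1]]
        delta = _minimum_image(pa - pb, fr.box)
        if lateral:
            dists.append(np.hypot(delta[:, 0], delta[:, 1]))
        else:
            dists.append(np.linalg.norm(delta, axis=1))
    d = np.concatenate(dists)

    lo = d.min() - 6.0 * bandwidth
    hi = d.max() + 6.0 * bandwidth
    grid = np.linspace(lo, hi, max(int(np.ceil((hi - lo) / (bandwidth / 10.0))), 200) + 1)
    u = (grid[None, :] - d[:, None]) / bandwidth
    dens = np.exp(-0.5 * u**2).mean(axis=0) / (bandwidth * np.sqrt(2.0 * np.pi))

    sign = np.sign(np.diff(dens))
    modes = [
        float(grid[i + 1])
        for i in range(len(sign) - 1)
        if sign[i] > 0 and sign[i + 1] <= 0
    ]
    return DistanceDistribution(
        distances=d, grid=grid, density=dens, modes=np.asarray(modes), bandwidth=bandwidth
    )


# ----------------------------------------------------------------------
# hydrogen bonds
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion.

    Defaults follow the conventional donor-acceptor distance / hydrogen-
    donor-acceptor angle cutoffs of the standard MD analysis tools.
    """

    max_da_distance: float = 0.35  # nm
    max_hda_angle: float = 30.0  # degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0.0 < self.max_hda_angle <= 90.0):
            raise ValueError("angle cutoff must lie in (0, 90] degrees")


@dataclass(frozen=True)
class HBondGroup:
    """Named atom group for hydrogen-bond accounting.

    ``heavy_expr`` selects the heavy atoms; for donor groups
    ``hydrogen_expr`` selects the attached hydrogens, matched within the
    same residue (every matching hydrogen pairs with every donor heavy atom
    of its residue).
    """

    label: str
    heavy_expr: str
    hydrogen_expr: str | None = None


@dataclass(frozen=True)
class HBondEntry:
    mean_per_frame: float
    se_per_frame: float
    per_lipid: float
    per_lipid_se: float


@dataclass(frozen=True)
class HBondReport:
    """Mean hydrogen-bond counts per frame for each (donor, acceptor) pair,
    raw and normalized per lipid."""

    entries: dict  # (donor_label, acceptor_label) -> HBondEntry
    criteria: HBondCriteria
    normalizer: int
    n_frames: int


def _donor_pairs(snap: Snapshot, group: HBondGroup) -> tuple[np.ndarray, np.ndarray]:
    """(donor_idx, hydrogen_idx) pairs for a donor group."""
    if group.hydrogen_expr is None:
        raise StructureError(f"donor group {group.label!r} defines no hydrogens")
    d_idx = select_atoms(snap, group.heavy_expr)
    h_idx = select_atoms(snap, group.hydrogen_expr)
    if len(d_idx) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    dd, hh = [], []
    h_by_res: dict[int, list[int]] = {}
    for h in h_idx:
        h_by_res.setdefault(int(snap.resids[h]), []).append(int(h))
    for di in d_idx:
        hs = h_by_res.get(int(snap.resids[di]), [])
        if not hs:
            raise StructureError(
                f"donor atom {snap.names[di]!r} in residue {int(snap.resids[di])} "
                f"of group {group.label!r} has no matching hydrogen"
            )
        for h in hs:
            dd.append(int(di))
            hh.append(h)
    return np.asarray(dd, dtype=int), np.asarray(hh, dtype=int)


def count_hbonds(
    traj: Trajectory,
    donor_groups: Sequence[HBondGroup],
    acceptor_groups: Sequence[HBondGroup],
    criteria: HBondCriteria = HBondCriteria(),
    normalizer: int = 1,
) -> HBondReport:
    """Count geometric hydrogen bonds per (donor group, acceptor group).

    A bond exists iff the donor-acceptor distance (minimum image under the
    orthorhombic box) is within the cutoff and the hydrogen-donor-acceptor
    angle is within the angle cutoff; a donor with several hydrogens can
    form one bond per hydrogen.  Counts are averaged over frames and also
    reported divided by ``normalizer`` (a lipid count).
    """
    if normalizer <= 0:
        raise StructureError("normalizer must be a positive lipid count")
    first = traj[0]
    donors = {g.label: _donor_pairs(first, g) for g in donor_groups}
    acceptors = {g.label: select_atoms(first, g.heavy_expr) for g in acceptor_groups}

    counts: dict[tuple[str, str], list[float]] = {
        (dl, al): [] for dl in donors for al in acceptors
    }
    cos_min = math.cos(math.radians(criteria.max_hda_angle))
    for fr in traj:
        pos, box = fr.positions, fr.box
        for dl, (d_idx, h_idx) in donors.items():
            for al, a_idx in acceptors.items():
                if len(d_idx) == 0 or len(a_idx) == 0:
                    counts[(dl, al)].append(0.0)
                    continue
                da = _minimum_image(pos[a_idx][None, :, :] - pos[d_idx][:, None, :], box)
                dist = np.linalg.norm(da, axis=2)
                dh = _minimum_image(pos[h_idx] - pos[d_idx], box)
                dh_norm = np.linalg.norm(dh, axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    cosang = np.einsum("pad,pd->pa", da, dh) / (dist * dh_norm[:, None])
                same = d_idx[:, None] == a_idx[None, :]
                bond = (dist <= criteria.max_da_distance) & (cosang >= cos_min) & ~same
                counts[(dl, al)].append(float(bond.sum()))

    entries = {}
    for key, vals in counts.items():
        v = np.asarray(vals)
        mean = float(v.mean())
        se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        entries[key] = HBondEntry(
            mean_per_frame=mean,
            se_per_frame=se,
            per_lipid=mean / normalizer,
            per_lipid_se=se / normalizer,
        )
    return HBondReport(
        entries=entries, criteria=criteria, normalizer=normalizer, n_frames=traj.n_frames
    )
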