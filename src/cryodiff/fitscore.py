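"""Rigid-body placement of atomic models in density and fit scoring.

Two complementary scores characterize a fit, mirroring standard practice
for assessing rigid-body dockings into intermediate-resolution maps:

* ``fraction_inside`` — the fraction of atoms whose (trilinearly
  interpolated) map value lies at or above a sigma contour (default 3
  sigma above the map mean, the contour used for display of such maps);
* ``correlation_of_fit`` — the about-mean Pearson correlation between a
  simulated density of the model and the experimental map over a masked
  region (default: the map's 3 sigma contour region).

A local exhaustive search over a rotation/translation grid (defaults
+/-10 degrees in 2 degree steps, +/-10 A in 1 A steps, about the ligand
centroid) evaluates both scores for every pose, merges poses into
clusters within one grid step of a cluster exemplar, and reports the
per-cluster hit rate (members / all evaluated poses).  The best fit is
the pose with the greatest occupation of density (highest
``fraction_inside``; ties broken by correlation, then by deterministic
pose ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volgrid import VoxelGrid

__all__ = [
    "AtomicModel",
    "FitPose",
    "SearchGrid",
    "FitSearchResult",
    "read_structure",
    "write_structure",
    "simulate_density",
    "fraction_inside",
    "correlation_of_fit",
    "rigid_body_search",
    "select_best_fit",
]

# van der Waals radii (A) and atomic numbers for elements common in proteins
ELEMENT_PARAMS: dict[str, tuple[float, int]] = {
    "H": (1.20, 1),
    "C": (1.70, 6),
    "N": (1.55, 7),
    "O": (1.52, 8),
    "S": (1.80, 16),
    "P": (1.80, 15),
    "SE": (1.90, 34),
}
DEFAULT_ELEMENT = ("C", 1.70, 6)

# formal side-chain charges (e) by (residue name, atom name); everything
# else defaults to 0 — a deliberately coarse assignment sufficient for a
# screened-Coulomb interface model
ATOM_CHARGES: dict[tuple[str, str], float] = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "NE"): 0.2,
    ("ARG", "NH1"): 0.4,
    ("ARG", "NH2"): 0.4,
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
    ("HIS", "ND1"): 0.1,
    ("HIS", "NE2"): 0.1,
}

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class AtomicModel:
    """A flat atom table with a receptor/ligand chain partition."""

    chain: np.ndarray  # str per atom
    resnum: np.ndarray  # int per atom
    resname: np.ndarray  # str per atom
    atom_name: np.ndarray  # str per atom
    element: np.ndarray  # str per atom
    coords: np.ndarray  # (n, 3) A
    charge: np.ndarray  # e per atom
    radius: np.ndarray  # vdW A per atom
    atomic_number: np.ndarray  # int per atom
    receptor_chains: frozenset = frozenset()
    ligand_chains: frozenset = frozenset()

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        if np.any(self.radius <= 0):
            raise ValueError("atom radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, mask: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            self.chain[mask],
            self.resnum[mask],
            self.resname[mask],
            self.atom_name[mask],
            self.element[mask],
            self.coords[mask],
            self.charge[mask],
            self.radius[mask],
            self.atomic_number[mask],
            self.receptor_chains,
            self.ligand_chains,
        )

    def chain_mask(self, chains) -> np.ndarray:
        return np.isin(self.chain, list(chains))

    @property
    def receptor(self) -> "AtomicModel":
        return self.select(self.chain_mask(self.receptor_chains))

    @property
    def ligand(self) -> "AtomicModel":
        return self.select(self.chain_mask(self.ligand_chains))

    def residues(self):
        """Ordered unique (chain, resnum, resname) keys."""
        seen = {}
        for c, rn, rnm in zip(self.chain, self.resnum, self.resname):
            seen.setdefault((str(c), int(rn)), str(rnm))
        return [(c, rn, nm) for (c, rn), nm in seen.items()]

    def with_coords(self, coords: np.ndarray) -> "AtomicModel":
        out = self.select(np.ones(self.n_atoms, dtype=bool))
        out.coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        return out

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def _assign_params(resname: str, atom_name: str, element: str):
    el = element.upper()
    if el not in ELEMENT_PARAMS:
        el, radius, z = DEFAULT_ELEMENT
    else:
        radius, z = ELEMENT_PARAMS[el]
    charge = ATOM_CHARGES.get((resname, atom_name), 0.0)
    return charge, radius, z


def read_structure(
    path,
    receptor_chains=(),
    ligand_chains=(),
) -> AtomicModel:
    """Read a PDB coordinate file into an :class:`AtomicModel`.

    Partial charges and van der Waals radii are assigned from the packaged
    per-residue/per-element tables; unknown elements fall back to carbon
    parameters.  If no chain partition is given, all chains are treated as
    receptor.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    chains, resnums, resnames, names, elements, coords = [], [], [], [], [], []
    for model in st:
        for ch in model:
            for res in ch:
                for atom in res:
                    chains.append(ch.name)
                    resnums.append(res.seqid.num)
                    resnames.append(res.name)
                    names.append(atom.name)
                    elements.append(atom.element.name.upper())
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if not coords:
        raise ValueError(f"no atoms found in {path}")
    n = len(coords)
    charge = np.zeros(n)
    radius = np.zeros(n)
    z = np.zeros(n, dtype=np.int64)
    for i in range(n):
        charge[i], radius[i], z[i] = _assign_params(resnames[i], names[i], elements[i])
    all_chains = set(chains)
    rec = frozenset(receptor_chains) or (
        all_chains - set(ligand_chains) if ligand_chains else frozenset(all_chains)
    )
    return AtomicModel(
        np.array(chains),
        np.array(resnums, dtype=np.int64),
        np.array(resnames),
        np.array(names),
        np.array(elements),
        np.array(coords),
        charge,
        radius,
        z,
        frozenset(rec),
        frozenset(ligand_chains),
    )


def write_structure(model: AtomicModel, path) -> None:
    """Write an :class:`AtomicModel` as a PDB file."""
    st = gemmi.Structure()
    st.name = "cryodiff"
    md = gemmi.Model("1")
    for cname in dict.fromkeys(model.chain.tolist()):
        ch = gemmi.Chain(str(cname))
        sel = model.chain == cname
        cur_res = None
        cur_key = None
        for i in np.flatnonzero(sel):
            key = (int(model.resnum[i]), str(model.resname[i]))
            if key != cur_key:
                cur_res = gemmi.Residue()
                cur_res.name = str(model.resname[i])
                cur_res.seqid = gemmi.SeqId(int(model.resnum[i]), " ")
                ch.add_residue(cur_res)
                cur_res = ch[-1]
                cur_key = key
            atom = gemmi.Atom()
            atom.name = str(model.atom_name[i])
            atom.element = gemmi.Element(str(model.element[i]))
            atom.pos = gemmi.Position(*model.coords[i])
            cur_res.add_atom(atom)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# --------------------------------------------------------------------------
# density simulation and scoring

def simulate_density(
    model: AtomicModel,
    voxel_size: float,
    resolution_A: float,
    geometry: VoxelGrid | None = None,
) -> VoxelGrid:
    """Sum-of-Gaussians density for an atomic model.

    Each atom contributes an isotropic Gaussian with FWHM equal to the
    nominal resolution and peak amplitude proportional to its atomic
    number (so the integrated density of each atom is also proportional
    to its atomic number).  If ``geometry`` is given the density is
    accumulated on that grid; otherwise a new grid is created padding the
    model's bounding box by twice the resolution.
    """
    if model.n_atoms == 0:
        raise ValueError("cannot simulate density for an empty model")
    if resolution_A < 2.0 * voxel_size:
        raise ValueError(
            f"resolution {resolution_A} A below Nyquist for voxel {voxel_size} A"
        )
    sigma = resolution_A * FWHM_TO_SIGMA
    if geometry is None:
        margin = 2.0 * resolution_A
        lo = model.coords.min(axis=0) - margin
        hi = model.coords.max(axis=0) + margin
        n_vox = np.ceil((hi - lo) / voxel_size).astype(int) + 1
        data = np.zeros(tuple(n_vox))
        origin = lo
    else:
        voxel_size = geometry.voxel_size
        data = np.zeros(geometry.shape)
        origin = geometry.origin
    _accumulate_gaussians(
        data, origin, voxel_size, model.coords, model.atomic_number.astype(float), sigma
    )
    return VoxelGrid(data, voxel_size, origin)


def _accumulate_gaussians(data, origin, voxel_size, coords, amplitudes, sigma):
    """Add per-atom Gaussians into ``data`` (truncated at 4 sigma)."""
    cut = 4.0 * sigma
    r_vox = int(np.ceil(cut / voxel_size))
    shape = np.array(data.shape)
    frac = (coords - origin) / voxel_size
    offsets = np.arange(-r_vox, r_vox + 1)
    for f, amp in zip(frac, amplitudes):
        c = np.rint(f).astype(int)
        lo = np.maximum(c - r_vox, 0)
        hi = np.minimum(c + r_vox, shape - 1)
        if np.any(lo > hi):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        dx = (ax[0] - f[0]) * voxel_size
        dy = (ax[1] - f[1]) * voxel_size
        dz = (ax[2] - f[2]) * voxel_size
        d2 = (
            dx[:, None, None] ** 2
            + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2
        )
        data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += amp * np.exp(
            -0.5 * d2 / sigma**2
        )


def _interp_at(grid: VoxelGrid, coords: np.ndarray) -> np.ndarray:
    """Trilinear map values at physical coordinates; NaN outside the box."""
    frac = (coords - grid.origin) / grid.voxel_size
    vals = ndimage.map_coordinates(
        grid.data, frac.T, order=1, mode="constant", cval=np.nan
    )
    inside = np.all(frac >= 0, axis=1) & np.all(
        frac <= np.array(grid.shape) - 1, axis=1
    )
    vals = np.where(inside, vals, np.nan)
    return vals


def fraction_inside(
    model: AtomicModel, grid: VoxelGrid, sigma_threshold: float = 3.0
) -> float:
    """Fraction of atoms at or above the map's sigma contour.

    Atoms falling outside the grid bounds count as outside the contour, so
    poses near the box edge remain comparable.
    """
    level = grid.contour_level(sigma_threshold)
    vals = _interp_at(grid, model.coords)
    inside = np.nan_to_num(vals, nan=-np.inf) >= level
    return float(inside.mean())


def correlation_of_fit(
    model: AtomicModel,
    grid: VoxelGrid,
    resolution_A: float,
    mask: np.ndarray | None = None,
    sigma_threshold: float = 3.0,
) -> float:
    """About-mean Pearson correlation of simulated vs experimental density.

    Evaluated over voxels inside ``mask`` (boolean array); by default the
    grid's own ``sigma_threshold`` contour region.
    """
    if mask is None:
        mask = grid.data >= grid.contour_level(sigma_threshold)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("correlation mask is empty")
    sim = simulate_density(model, grid.voxel_size, resolution_A, geometry=grid)
    x = sim.data[mask]
    y = grid.data[mask]
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


# --------------------------------------------------------------------------
# exhaustive local search

def _axis_range(value, step) -> np.ndarray:
    """(-v..v) or (lo, hi) sampled at the given step, inclusive of ends."""
    if np.isscalar(value):
        lo, hi = -float(value), float(value)
    else:
        lo, hi = float(value[0]), float(value[1])
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


@dataclass
class SearchGrid:
    """Local rotation/translation grid about the ligand centroid.

    ``rot_range`` / ``trans_range`` may be scalars (symmetric +/- range)
    or per-axis (lo, hi) pairs, allowing reduced subsets of the full grid.
    """

    rot_range: object = 10.0  # degrees
    rot_step: float = 2.0
    trans_range: object = 10.0  # A
    trans_step: float = 1.0
    pivot: np.ndarray | None = None

    def __post_init__(self):
        if self.rot_step <= 0 or self.trans_step <= 0:
            raise ValueError("steps must be positive")

    def _per_axis(self, value):
        if np.isscalar(value) or (
            hasattr(value, "__len__") and len(value) == 2 and np.isscalar(value[0])
        ):
            return [value, value, value]
        return list(value)

    def rotation_angles(self) -> list[np.ndarray]:
        return [_axis_range(v, self.rot_step) for v in self._per_axis(self.rot_range)]

    def translations(self) -> list[np.ndarray]:
        return [
            _axis_range(v, self.trans_step) for v in self._per_axis(self.trans_range)
        ]


@dataclass(frozen=True)
class FitPose:
    """A rigid transform with its two fit scores.

    The transform maps ligand coordinates as
    ``x' = R (x - pivot) + pivot + translation`` with R the intrinsic
    x-y-z Euler rotation of ``euler_deg``.
    """

    euler_deg: tuple[float, float, float]
    translation: tuple[float, float, float]
    correlation: float
    fraction_inside: float

    @property
    def rotation(self) -> np.ndarray:
        """Unit quaternion (x, y, z, w) of the rotation."""
        q = Rotation.from_euler("xyz", self.euler_deg, degrees=True).as_quat()
        return q / np.linalg.norm(q)

    def apply(self, coords: np.ndarray, pivot: np.ndarray) -> np.ndarray:
        R = Rotation.from_euler("xyz", self.euler_deg, degrees=True)
        return R.apply(coords - pivot) + pivot + np.asarray(self.translation)

    def sort_key(self):
        return self.euler_deg + self.translation


@dataclass
class FitSearchResult:
    """All scored poses with clusters, hit rates, and the selected fit."""

    poses: list[FitPose]
    clusters: list[list[int]] = field(default_factory=list)
    hit_rates: list[float] = field(default_factory=list)
    best_by_occupancy: FitPose | None = None
    pivot: np.ndarray | None = None

    def to_table(self, path) -> None:
        import pandas as pd

        cluster_of = {}
        for ci, members in enumerate(self.clusters):
            for m in members:
                cluster_of[m] = ci
        rows = [
            {
                "rot_x_deg": p.euler_deg[0],
                "rot_y_deg": p.euler_deg[1],
                "rot_z_deg": p.euler_deg[2],
                "trans_x_A": p.translation[0],
                "trans_y_A": p.translation[1],
                "trans_z_A": p.translation[2],
                "correlation": p.correlation,
                "fraction_inside": p.fraction_inside,
                "cluster": cluster_of.get(i, -1),
            }
            for i, p in enumerate(self.poses)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def rigid_body_search(
    model: AtomicModel,
    grid: VoxelGrid,
    search: SearchGrid | None = None,
    resolution_A: float = 10.0,
    sigma_threshold: float = 3.0,
) -> FitSearchResult:
    """Exhaustively score every pose on the search grid.

    The model's ligand partition (or the whole model if no partition is
    set) is transformed about the pivot; each pose is scored for
    ``fraction_inside`` and masked ``correlation_of_fit``.  Poses are then
    merged into clusters whenever they lie within one rotation step (per
    Euler angle) and one translation step (per axis) of a cluster
    exemplar, in descending occupancy order; ``hit_rates`` are cluster
    sizes divided by the total number of evaluated poses.
    """
    search = search or SearchGrid()
    ligand = model.ligand if model.ligand_chains else model
    if ligand.n_atoms == 0:
        raise ValueError("empty ligand partition")
    pivot = search.pivot if search.pivot is not None else ligand.centroid()
    pivot = np.asarray(pivot, dtype=np.float64)

    level = grid.contour_level(sigma_threshold)
    mask = grid.data >= level
    if not mask.any():
        raise ValueError("density has no voxels above the contour")
    y = grid.data[mask]
    yc = y - y.mean()
    y_norm = np.sqrt((yc**2).sum())
    sigma = resolution_A * FWHM_TO_SIGMA
    amps = ligand.atomic_number.astype(float)

    rot_axes = search.rotation_angles()
    trans_axes = search.translations()
    poses: list[FitPose] = []
    base = ligand.coords - pivot
    any_inbounds = False
    for ax in rot_axes[0]:
        for ay in rot_axes[1]:
            for az in rot_axes[2]:
                R = Rotation.from_euler("xyz", (ax, ay, az), degrees=True)
                rotated = R.apply(base) + pivot
                for tx in trans_axes[0]:
                    for ty in trans_axes[1]:
                        for tz in trans_axes[2]:
                            coords = rotated + (tx, ty, tz)
                            frac = (coords - grid.origin) / grid.voxel_size
                            inb = np.all(frac >= 0, axis=1) & np.all(
                                frac <= np.array(grid.shape) - 1, axis=1
                            )
                            if inb.any():
                                any_inbounds = True
                            vals = ndimage.map_coordinates(
                                grid.data, frac.T, order=1, mode="constant", cval=0.0
                            )
                            fin = float(((vals >= level) & inb).mean())
                            sim = np.zeros(grid.shape)
                            _accumulate_gaussians(
                                sim, grid.origin, grid.voxel_size, coords, amps, sigma
                            )
                            x = sim[mask]
                            xc = x - x.mean()
                            denom = np.sqrt((xc**2).sum()) * y_norm
                            corr = float((xc * yc).sum() / denom) if denom > 0 else 0.0
                            poses.append(
                                FitPose(
                                    (float(ax), float(ay), float(az)),
                                    (float(tx), float(ty), float(tz)),
                                    corr,
                                    fin,
                                )
                            )
    if not poses or not any_inbounds:
        raise ValueError("search produced no in-bounds poses")

    result = FitSearchResult(poses=poses, pivot=pivot)
    _cluster_poses(result, search)
    result.best_by_occupancy = select_best_fit(result)
    return result


def _cluster_poses(result: FitSearchResult, search: SearchGrid) -> None:
    """Greedy exemplar clustering within one grid step per degree of freedom."""
    eps = 1e-9
    order = sorted(
        range(len(result.poses)),
        key=lambda i: (
            -result.poses[i].fraction_inside,
            -result.poses[i].correlation,
            result.poses[i].sort_key(),
        ),
    )
    exemplars: list[int] = []
    clusters: list[list[int]] = []
    for i in order:
        p = result.poses[i]
        placed = False
        for ci, ex in enumerate(exemplars):
            q = result.poses[ex]
            if all(
                abs(a - b) <= search.rot_step + eps
                for a, b in zip(p.euler_deg, q.euler_deg)
            ) and all(
                abs(a - b) <= search.trans_step + eps
                for a, b in zip(p.translation, q.translation)
            ):
                clusters[ci].append(i)
                placed = True
                break
        if not placed:
            exemplars.append(i)
            clusters.append([i])
    total = len(result.poses)
    result.clusters = clusters
    result.hit_rates = [len(c) / total for c in clusters]


def select_best_fit(result: FitSearchResult) -> FitPose:
    """Pose with the greatest occupation of density.

    Maximizes ``fraction_inside``; ties broken by higher correlation, then
    by deterministic lexicographic ordering of the pose parameters (so the
    selection is invariant to pose-list order).
    """
    if not result.poses:
        raise ValueError("empty search result")
    return min(
        result.poses,
        key=lambda p: (-p.fraction_inside, -p.correlation, p.sort_key()),
    )
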