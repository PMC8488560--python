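"""Seeded generators for every input the analysis pipeline consumes.

Reconstruction ensembles are emulated as a fixed ground-truth density
plus independent additive Gaussian noise per member — the idealization
under which the per-voxel two-sample t test is exactly calibrated.  The
ground truth is a "cage fragment": pseudo-atoms arranged as three legs
radiating from a central vertex with compact domains at the leg tips,
loosely evoking the hub of a clathrin lattice where three terminal
domains converge.  A second condition can carry planted extra "ligand"
density (a compact Gaussian blob), and members can be given a smooth
B-factor-like radial amplitude attenuation to emulate quality differences
between reconstructions.

Toy two-chain atomic complexes provide inputs for the interface
energetics: two short strands facing each other across a gap, with
charged side-chain termini reaching into the interface.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffsig import MapEnsemble
from .fitscore import AtomicModel, _assign_params
from .volgrid import VoxelGrid

__all__ = [
    "EnsembleSpec",
    "ToyComplexSpec",
    "make_ensemble",
    "apply_radial_attenuation",
    "make_toy_complex",
]


@dataclass
class EnsembleSpec:
    """Recipe for one condition's reconstruction ensemble.

    Defaults give a 48^3 box at 2.0 A/voxel with four members and unit
    white noise — large enough for ~1e5 analyzable voxels, small enough
    for sub-minute runs.
    """

    grid_size: int = 48
    voxel_size: float = 2.0
    n_members: int = 4
    noise_sigma: float = 1.0
    gt_amplitude: float = 10.0  # peak pseudo-atom amplitude of the ground truth
    ligand_amplitude: float = 0.0  # peak of the planted blob (0 disables)
    ligand_center: tuple[float, float, float] | None = None  # A, defaults above hub
    ligand_sigma_A: float = 4.0
    b_factor: float = 0.0  # A^2, radial attenuation applied to each member
    colored_noise_A: float = 0.0  # low-pass the noise at this cutoff (0 = white)
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.n_members < 2:
            raise ValueError("n_members must be at least 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.b_factor < 0:
            raise ValueError("b_factor must be nonnegative")


@dataclass
class ToyComplexSpec:
    """Recipe for a toy two-chain complex with a charged interface."""

    n_residues_receptor: int = 12
    n_residues_ligand: int = 12
    charged_fraction: float = 0.5
    separation_A: float = 11.0  # backbone-plane distance; leaves ~3 A between
    # opposing charged termini, inside salt-bridge range
    clash_limit_A: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.charged_fraction <= 1.0:
            raise ValueError("charged_fraction must be in [0, 1]")


# --------------------------------------------------------------------------
# density ensembles

def _hub_pseudo_atoms(spec: EnsembleSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pseudo-atom positions (A), amplitudes, and widths of the ground truth.

    Three legs radiate from the box center at 120 degree intervals,
    curving gently out of plane, each ending in a compact cluster.
    """
    box = spec.grid_size * spec.voxel_size
    center = np.full(3, box / 2.0)
    positions, amps, widths = [], [], []
    leg_len = 0.38 * box
    n_per_leg = 12
    for k in range(3):
        phi = 2.0 * np.pi * k / 3.0
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        for i in range(n_per_leg):
            t = (i + 1) / n_per_leg
            # gentle downward curvature, like legs bending from a vertex
            pos = center + u * (t * leg_len) + np.array([0.0, 0.0, -0.25 * t**2 * leg_len])
            positions.append(pos)
            amps.append(spec.gt_amplitude)
            widths.append(3.0)
        # terminal cluster at the leg tip
        tip = positions[-1]
        for d in ((3.0, 0, 0), (-3.0, 0, 0), (0, 3.0, 0), (0, -3.0, 0), (0, 0, 3.0)):
            positions.append(tip + np.array(d))
            amps.append(0.8 * spec.gt_amplitude)
            widths.append(3.0)
    return np.array(positions), np.array(amps), np.array(widths)


def _render_gaussians(
    shape: tuple[int, int, int],
    voxel_size: float,
    positions: np.ndarray,
    amplitudes: np.ndarray,
    widths: np.ndarray,
) -> np.ndarray:
    data = np.zeros(shape)
    grid_max = np.array(shape) - 1
    for pos, amp, sig in zip(positions, amplitudes, widths):
        r_vox = int(np.ceil(4.0 * sig / voxel_size))
        c = np.rint(pos / voxel_size).astype(int)
        lo = np.maximum(c - r_vox, 0)
        hi = np.minimum(c + r_vox, grid_max)
        if np.any(lo > hi):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) * voxel_size - pos[d] for d in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += amp * np.exp(
            -0.5 * d2 / sig**2
        )
    return data


def _ligand_density(spec: EnsembleSpec) -> np.ndarray:
    box = spec.grid_size * spec.voxel_size
    if spec.ligand_center is None:
        center = np.array([box / 2.0, box / 2.0, box / 2.0 + 0.12 * box])
    else:
        center = np.asarray(spec.ligand_center, dtype=np.float64)
    return _render_gaussians(
        (spec.grid_size,) * 3,
        spec.voxel_size,
        center[None, :],
        np.array([spec.ligand_amplitude]),
        np.array([spec.ligand_sigma_A]),
    )


def make_ensemble(spec: EnsembleSpec) -> tuple[MapEnsemble, VoxelGrid, VoxelGrid]:
    """Generate one condition's ensemble plus ground truth and ligand mask.

    Each member is ``ground truth (+ planted ligand) + fresh noise``,
    optionally B-factor attenuated.  The ligand mask marks voxels where
    the planted density exceeds half its maximum (empty if no ligand).
    Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.grid_size,) * 3
    positions, amps, widths = _hub_pseudo_atoms(spec)
    gt_data = _render_gaussians(shape, spec.voxel_size, positions, amps, widths)
    gt = VoxelGrid(gt_data, spec.voxel_size)

    if spec.ligand_amplitude > 0:
        lig = _ligand_density(spec)
        mask_data = (lig > 0.5 * lig.max()).astype(np.float64)
        signal = gt_data + lig
    else:
        mask_data = np.zeros(shape)
        signal = gt_data
    ligand_mask = VoxelGrid(mask_data, spec.voxel_size)

    members = []
    for _ in range(spec.n_members):
        noise = rng.standard_normal(shape) * spec.noise_sigma
        member = VoxelGrid(signal + noise, spec.voxel_size)
        if spec.colored_noise_A > 0:
            from .volgrid import lowpass_filter

            noisy = lowpass_filter(
                VoxelGrid(noise, spec.voxel_size), spec.colored_noise_A
            )
            member = VoxelGrid(signal + noisy.data, spec.voxel_size)
        if spec.b_factor > 0:
            member = apply_radial_attenuation(member, spec.b_factor)
        members.append(member)
    return MapEnsemble(members, spec.label), gt, ligand_mask


def apply_radial_attenuation(grid: VoxelGrid, b_factor: float) -> VoxelGrid:
    """Multiply Fourier amplitudes by ``exp(-B s^2 / 4)``.

    ``s`` is spatial frequency in 1/A and ``B`` the attenuation parameter
    in A^2 — the amplitude fall-off conventionally used to describe
    resolution-dependent signal loss.  Phases (and the DC term) are
    preserved.
    """
    if b_factor < 0:
        raise ValueError("b_factor must be nonnegative")
    if b_factor == 0:
        return grid.with_data(grid.data.copy())
    freqs = [np.fft.fftfreq(n, d=grid.voxel_size) for n in grid.shape]
    s2 = (
        freqs[0][:, None, None] ** 2
        + freqs[1][None, :, None] ** 2
        + freqs[2][None, None, :] ** 2
    )
    h = np.exp(-b_factor * s2 / 4.0)
    return grid.with_data(np.fft.ifftn(np.fft.fftn(grid.data) * h).real)


# --------------------------------------------------------------------------
# toy complexes

_CHARGED = ("LYS", "ARG", "GLU", "ASP")
_NEUTRAL = ("ALA", "SER", "LEU", "GLY", "THR", "VAL")
# terminal side-chain atom carried by each residue type (beyond C-beta)
_TERMINAL_ATOM = {
    "LYS": ("NZ", "N"),
    "ARG": ("NH1", "N"),
    "GLU": ("OE1", "O"),
    "ASP": ("OD1", "O"),
    "SER": ("OG", "O"),
    "LEU": ("CD1", "C"),
    "THR": ("OG1", "O"),
    "VAL": ("CG1", "C"),
}


def make_toy_complex(spec: ToyComplexSpec) -> tuple[AtomicModel, list[dict]]:
    """Deterministic two-chain pseudo-protein with a charged interface.

    Chain R (receptor) lies in the z = 0 plane and chain L (ligand) in
    the z = separation plane, each a strand of residues spaced 3.8 A
    along x.  Every residue carries backbone N/CA/C/O plus C-beta, and
    charged residues extend a charged terminal pseudo-atom toward the
    interface.  Opposing charged residues are paired with opposite signs
    so the interface is attractive.  Returns the model and the list of
    cross-interface residue contacts (terminal-atom pairs within 6 A).

    Raises ``ValueError`` if the separation would bring atoms below the
    clash limit.
    """
    rng = np.random.default_rng(spec.seed)
    reach = 4.0  # terminal-atom extension beyond the CA plane
    gap = spec.separation_A - 2.0 * reach
    if gap < spec.clash_limit_A:
        raise ValueError(
            f"separation {spec.separation_A} A leaves a {gap:.1f} A gap, below "
            f"the clash limit {spec.clash_limit_A} A"
        )

    chains, resnums, resnames, names, elements, coords = [], [], [], [], [], []

    def add_atom(chain, resnum, resname, name, element, xyz):
        chains.append(chain)
        resnums.append(resnum)
        resnames.append(resname)
        names.append(name)
        elements.append(element)
        coords.append(xyz)

    n_pairs = min(spec.n_residues_receptor, spec.n_residues_ligand)
    charged_pair = rng.random(n_pairs) < spec.charged_fraction
    pair_sign = rng.random(n_pairs) < 0.5  # True: receptor basic / ligand acidic

    def build_chain(chain_id, n_res, z0, direction, start_resnum):
        """direction +1 extends side chains toward +z, -1 toward -z."""
        for i in range(n_res):
            resnum = start_resnum + i
            x = 3.8 * i
            y = float(rng.uniform(-0.3, 0.3))
            if i < n_pairs and charged_pair[i]:
                basic = pair_sign[i] if chain_id == "R" else not pair_sign[i]
                resname = str(rng.choice(("LYS", "ARG"))) if basic else str(
                    rng.choice(("GLU", "ASP"))
                )
            else:
                resname = str(rng.choice(_NEUTRAL))
            add_atom(chain_id, resnum, resname, "N", "N", [x - 1.2, y, z0])
            add_atom(chain_id, resnum, resname, "CA", "C", [x, y, z0])
            add_atom(chain_id, resnum, resname, "C", "C", [x + 1.2, y + 0.4, z0])
            add_atom(chain_id, resnum, resname, "O", "O", [x + 1.3, y + 1.5, z0])
            if resname != "GLY":
                add_atom(
                    chain_id, resnum, resname, "CB", "C",
                    [x, y, z0 + direction * 1.5],
                )
            if resname in _TERMINAL_ATOM and resname not in ("SER", "THR", "VAL", "LEU"):
                term_name, term_el = _TERMINAL_ATOM[resname]
                add_atom(
                    chain_id, resnum, resname, term_name, term_el,
                    [x, y, z0 + direction * reach],
                )

    build_chain("R", spec.n_residues_receptor, 0.0, +1, 101)
    build_chain("L", spec.n_residues_ligand, spec.separation_A, -1, 201)

    n = len(coords)
    charge = np.zeros(n)
    radius = np.zeros(n)
    z = np.zeros(n, dtype=np.int64)
    for i in range(n):
        charge[i], radius[i], z[i] = _assign_params(resnames[i], names[i], elements[i])
    model = AtomicModel(
        np.array(chains),
        np.array(resnums, dtype=np.int64),
        np.array(resnames),
        np.array(names),
        np.array(elements),
        np.array(coords),
        charge,
        radius,
        z,
        receptor_chains=frozenset({"R"}),
        ligand_chains=frozenset({"L"}),
    )

    # verify clash-free construction
    c = model.coords
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    # only check non-bonded pairs: exempt atoms within the same residue and
    # peptide-bonded neighbours (|resnum difference| <= 1 in the same chain)
    bonded = (model.chain[:, None] == model.chain[None, :]) & (
        np.abs(model.resnum[:, None] - model.resnum[None, :]) <= 1
    )
    d[bonded] = np.inf
    if d.min() < spec.clash_limit_A:
        raise ValueError(f"generated geometry clashes at {d.min():.2f} A")

    # terminal-atom contact list across the interface
    contacts = []
    rec, lig = model.receptor, model.ligand
    term_names = {v[0] for v in _TERMINAL_ATOM.values()}
    for i in range(rec.n_atoms):
        if str(rec.atom_name[i]) not in term_names:
            continue
        for j in range(lig.n_atoms):
            if str(lig.atom_name[j]) not in term_names:
                continue
            dist = float(np.linalg.norm(rec.coords[i] - lig.coords[j]))
            if dist <= 6.0:
                contacts.append(
                    {
                        "receptor_residue": f"{rec.chain[i]}{rec.resnum[i]}",
                        "ligand_residue": f"{lig.chain[j]}{lig.resnum[j]}",
                        "distance_A": dist,
                    }
                )
    return model, contacts
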