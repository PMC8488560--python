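"""Interface energetics: alanine scanning, constellations, salt bridges.

The scan machinery follows server-style computational alanine scanning:
single-point truncation of a residue's side chain beyond C-beta with all
other coordinates fixed, and

``ddG = E_interface(truncated) - E_interface(wild type)``

so that a residue which stabilizes the interface (makes the interface
energy more favourable) has a positive ddG in kJ/mol.  A constellation
scan truncates a residue group simultaneously; its cooperativity is

``cooperativity = constellation ddG - sum of individual ddGs``.

The energy function here is an explicitly generic stand-in: a screened
Coulomb term with distance-dependent dielectric eps(r) = 4r and a 12-6
steric term, summed over receptor-ligand atom pairs within a cutoff.
With such a strictly pairwise-additive model, a constellation confined to
one side of the interface has zero cooperativity by construction; nonzero
cooperativity requires many-body terms (as in empirical forcefields used
for published scans) or groups spanning both sides.  Absolute ddG
magnitudes from this model are therefore not comparable to forcefield
values; the scan/constellation machinery, thresholds, and cooperativity
arithmetic are the point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .fitscore import AtomicModel

__all__ = [
    "EnergyModel",
    "ScanResult",
    "ConstellationResult",
    "interface_energy",
    "alanine_scan",
    "constellation_scan",
    "cooperativity",
    "hotspot_report",
    "salt_bridges",
    "load_published_constellations",
]

# backbone + C-beta atoms kept by the truncation rule
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "CB", "OXT", "H", "HA"})

# side-chain atoms defining salt-bridge donors/acceptors
BASIC_ATOMS = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}

COULOMB_KJ = 1389.35  # kJ mol^-1 A e^-2 (Coulomb constant in vacuum)


@dataclass
class EnergyModel:
    """Screened Coulomb + 12-6 steric pairwise interface energy.

    ``E = sum_pairs [ k q_i q_j / (dielectric_factor * r^2)
                      + well_depth ((r0/r)^12 - 2 (r0/r)^6) ]``

    with ``r0 = radius_i + radius_j`` and pairs restricted to
    receptor-ligand atom pairs within ``cutoff_A``.  The ``1/r^2``
    Coulomb form is the distance-dependent dielectric eps(r) =
    dielectric_factor * r.  Energies are in kJ/mol.
    """

    coulomb_constant: float = COULOMB_KJ
    dielectric_factor: float = 4.0
    well_depth: float = 0.4  # kJ/mol
    cutoff_A: float = 8.0
    hard_core_A: float = 1.0  # pairs closer than this trigger a clash warning

    def __post_init__(self):
        if self.cutoff_A <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ScanResult:
    """Per-residue alanine-scan ddG table (kJ/mol)."""

    records: pd.DataFrame  # columns: chain, resnum, resname, ddG

    def ddg(self, chain: str, resnum: int) -> float:
        row = self.records[
            (self.records.chain == chain) & (self.records.resnum == resnum)
        ]
        if row.empty:
            raise KeyError(f"residue {chain}{resnum} not in scan")
        return float(row.ddG.iloc[0])

    def to_table(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class ConstellationResult:
    """Group ddG, summed individual ddGs, and their difference."""

    residues: tuple[str, ...]  # chain-prefixed labels, e.g. ("B804", "B812")
    constellation_ddG: float
    summed_individual_ddG: float
    cooperativity: float = field(init=False)

    def __post_init__(self):
        self.cooperativity = cooperativity(
            self.constellation_ddG, self.summed_individual_ddG
        )

    @property
    def label(self) -> str:
        return "_".join(self.residues)


def cooperativity(constellation_ddG: float, summed_individual_ddG: float) -> float:
    """Cooperativity of a residue group: group ddG minus summed singles."""
    return constellation_ddG - summed_individual_ddG


# --------------------------------------------------------------------------
# energies

def _pair_energy(rec: AtomicModel, lig: AtomicModel, energy: EnergyModel) -> float:
    if rec.n_atoms == 0 or lig.n_atoms == 0:
        return 0.0
    d = np.linalg.norm(rec.coords[:, None, :] - lig.coords[None, :, :], axis=2)
    within = d <= energy.cutoff_A
    if not within.any():
        return 0.0
    clashes = within & (d < energy.hard_core_A)
    if clashes.any():
        pairs = [
            f"{rec.chain[i]}{rec.resnum[i]}:{rec.atom_name[i]}-"
            f"{lig.chain[j]}{lig.resnum[j]}:{lig.atom_name[j]} ({d[i, j]:.2f} A)"
            for i, j in zip(*np.nonzero(clashes))
        ]
        warnings.warn(
            "atoms closer than hard-core distance: " + ", ".join(pairs[:10]),
            stacklevel=3,
        )
        d = np.maximum(d, energy.hard_core_A)
    qq = rec.charge[:, None] * lig.charge[None, :]
    coul = energy.coulomb_constant * qq / (energy.dielectric_factor * d**2)
    r0 = rec.radius[:, None] + lig.radius[None, :]
    x6 = (r0 / d) ** 6
    steric = energy.well_depth * (x6**2 - 2.0 * x6)
    total = np.where(within, coul + steric, 0.0)
    return float(total.sum())


def interface_energy(model: AtomicModel, energy: EnergyModel | None = None) -> float:
    """Receptor-ligand interaction energy (kJ/mol) of a two-part complex."""
    energy = energy or EnergyModel()
    rec, lig = model.receptor, model.ligand
    if rec.n_atoms == 0 or lig.n_atoms == 0:
        raise ValueError("model must have non-empty receptor and ligand partitions")
    return _pair_energy(rec, lig, energy)


def _truncate(model: AtomicModel, residues: set[tuple[str, int]]) -> AtomicModel:
    """Remove side-chain atoms beyond C-beta for the given residues."""
    keep = np.ones(model.n_atoms, dtype=bool)
    for i in range(model.n_atoms):
        if (str(model.chain[i]), int(model.resnum[i])) in residues:
            if model.atom_name[i] not in BACKBONE_ATOMS:
                keep[i] = False
    return model.select(keep)


def _scannable(model: AtomicModel, side: str):
    part = model.receptor if side == "receptor" else model.ligand
    return part.residues()


def alanine_scan(
    model: AtomicModel,
    side: str = "ligand",
    energy: EnergyModel | None = None,
) -> ScanResult:
    """Single-point alanine scan of one side of the interface.

    For each residue on the chosen side, the side chain beyond C-beta is
    removed (coordinates otherwise fixed) and
    ``ddG = E(truncated) - E(wild type)`` is recorded.  Gly and Ala give 0
    by construction; Pro is scanned by the same rule with a warning;
    non-Gly residues lacking a C-beta are skipped with a warning.
    """
    if side not in ("receptor", "ligand"):
        raise ValueError("side must be 'receptor' or 'ligand'")
    energy = energy or EnergyModel()
    e_wt = interface_energy(model, energy)
    rows = []
    for chain, resnum, resname in _scannable(model, side):
        if resname in ("GLY", "ALA"):
            rows.append(dict(chain=chain, resnum=resnum, resname=resname, ddG=0.0))
            continue
        res_atoms = (model.chain == chain) & (model.resnum == resnum)
        names = set(model.atom_name[res_atoms])
        if "CB" not in names:
            warnings.warn(
                f"residue {chain}{resnum} ({resname}) has no CB; skipped",
                stacklevel=2,
            )
            continue
        if resname == "PRO":
            warnings.warn(
                f"residue {chain}{resnum} is proline; truncated by the same rule",
                stacklevel=2,
            )
        truncated = _truncate(model, {(chain, resnum)})
        e_mut = interface_energy(truncated, energy)
        rows.append(
            dict(chain=chain, resnum=resnum, resname=resname, ddG=e_mut - e_wt)
        )
    return ScanResult(pd.DataFrame(rows, columns=["chain", "resnum", "resname", "ddG"]))


def constellation_scan(
    model: AtomicModel,
    groups: list[list[tuple[str, int]]],
    energy: EnergyModel | None = None,
    scan: ScanResult | None = None,
    side: str = "ligand",
) -> list[ConstellationResult]:
    """Simultaneous truncation of residue groups, with cooperativity.

    ``groups`` are lists of (chain, residue number) pairs.  Individual
    ddGs are taken from ``scan`` (computed via :func:`alanine_scan` if not
    supplied); the constellation ddG truncates all members at once.
    """
    energy = energy or EnergyModel()
    if scan is None:
        scan = alanine_scan(model, side=side, energy=energy)
    known = {(c, int(r)) for c, r in zip(scan.records.chain, scan.records.resnum)}
    e_wt = interface_energy(model, energy)
    results = []
    for group in groups:
        members = [(str(c), int(r)) for c, r in group]
        if not members:
            raise ValueError("empty constellation group")
        for m in members:
            if m not in known:
                raise ValueError(f"residue {m[0]}{m[1]} not scannable in this model")
        truncated = _truncate(model, set(members))
        group_ddg = interface_energy(truncated, energy) - e_wt
        summed = sum(scan.ddg(c, r) for c, r in members)
        results.append(
            ConstellationResult(
                residues=tuple(f"{c}{r}" for c, r in members),
                constellation_ddG=group_ddg,
                summed_individual_ddG=summed,
            )
        )
    return results


def hotspot_report(
    scan: ScanResult,
    single_threshold: float = 5.0,
    constellation_threshold: float = 3.0,
) -> dict:
    """Hot spots (ddG at or above ``single_threshold``) and constellation
    candidates (ddG strictly greater than ``constellation_threshold``),
    each sorted by descending ddG."""
    if single_threshold <= 0 or constellation_threshold <= 0:
        raise ValueError("thresholds must be positive")
    df = scan.records.sort_values("ddG", ascending=False)
    label = lambda row: f"{row.chain}{row.resnum}"
    hot = [label(r) for r in df.itertuples() if r.ddG >= single_threshold]
    cand = [label(r) for r in df.itertuples() if r.ddG > constellation_threshold]
    return {
        "single_threshold": single_threshold,
        "constellation_threshold": constellation_threshold,
        "hot_spots": hot,
        "constellation_candidates": cand,
    }


def salt_bridges(model: AtomicModel, distance_cutoff_A: float = 4.0) -> list[dict]:
    """Cross-interface basic-nitrogen / acidic-oxygen contacts.

    Reports every (basic side-chain N, acidic side-chain O) residue pair
    across the receptor/ligand interface whose minimum atom distance is at
    or below the cutoff.  The output is symmetric in which side carries
    the base and which the acid.
    """
    rec, lig = model.receptor, model.ligand
    out = []
    for a_side, b_side in ((rec, lig), (lig, rec)):
        basic = [
            i
            for i in range(a_side.n_atoms)
            if (str(a_side.resname[i]), str(a_side.atom_name[i])) in BASIC_ATOMS
        ]
        acidic = [
            j
            for j in range(b_side.n_atoms)
            if (str(b_side.resname[j]), str(b_side.atom_name[j])) in ACIDIC_ATOMS
        ]
        pairs = {}
        for i in basic:
            for j in acidic:
                dist = float(np.linalg.norm(a_side.coords[i] - b_side.coords[j]))
                key = (
                    str(a_side.chain[i]),
                    int(a_side.resnum[i]),
                    str(b_side.chain[j]),
                    int(b_side.resnum[j]),
                )
                if dist <= distance_cutoff_A and (
                    key not in pairs or dist < pairs[key]["distance_A"]
                ):
                    pairs[key] = {
                        "basic_residue": f"{key[0]}{key[1]}",
                        "basic_resname": str(a_side.resname[i]),
                        "acidic_residue": f"{key[2]}{key[3]}",
                        "acidic_resname": str(b_side.resname[j]),
                        "distance_A": dist,
                    }
        out.extend(pairs.values())
    # deduplicate mirror entries
    seen = set()
    unique = []
    for rec_ in sorted(out, key=lambda r: (r["basic_residue"], r["acidic_residue"])):
        key = (rec_["basic_residue"], rec_["acidic_residue"])
        if key not in seen:
            seen.add(key)
            unique.append(rec_)
    return unique


# --------------------------------------------------------------------------
# published constellation data

def load_published_constellations() -> pd.DataFrame:
    """Published BAlaS constellation table for the clathrin terminal-domain
    / beta2-appendage interface (and alpha-appendage controls).

    Columns: protein, constellation, constellation_ddG, summed_individual_ddG,
    printed_cooperativity — all energies in kJ/mol.  Two rows print a
    cooperativity differing by 0.1 kJ/mol from the column arithmetic
    (rounding of unrounded inputs upstream); ``is_self_consistent`` marks
    the rows where the printed value matches the arithmetic exactly at the
    printed precision.
    """
    with resources.files("cryodiff.data").joinpath(
        "balas_constellations.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    computed = (df.constellation_ddG - df.summed_individual_ddG).round(1)
    df["computed_cooperativity"] = computed
    df["is_self_consistent"] = np.isclose(
        computed, df.printed_cooperativity, atol=1e-9
    )
    return df
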