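"""Structure handling: PDB input, accessible surface area and superposition.

The accessible-surface-area engine is a Shrake–Rupley implementation: each
atom is probed with a deterministic Fibonacci lattice of test points on its
solvent-expanded sphere, and the accessible fraction is scaled by the sphere
area. Per-residue side-chain ASA is expressed as a ratio to the same side
chain in a random-coil reference (an extended Gly-X-Gly tripeptide computed
with the same engine and parameters), yielding the burial classes
low (<20 %), partial (20–50 %) and high (>50 %).

Rigid-body superposition uses the Kabsch algorithm (SVD with a determinant
correction so the rotation is always proper).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io

from .geometry import BACKBONE_ATOMS, AtomRecord, build_gxg

# van der Waals radii for heavy atoms, Å
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

LOW_THRESHOLD = 0.20
HIGH_THRESHOLD = 0.50


class ASAClass(str, Enum):
    LOW = "low"
    PARTIAL = "partial"
    HIGH = "high"


@dataclass(frozen=True)
class ASAEntry:
    chain: str
    residue_number: int
    residue_name: str
    sidechain_asa: float
    ratio: float
    asa_class: ASAClass


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def read_structure(path: str | Path, chain: str | None = None,
                   model: int = 1, keep_hetero: bool = False) -> list[AtomRecord]:
    """Read ATOM records from a PDB file into AtomRecords.

    Keeps one model, resolves alternate locations by highest occupancy (ties
    broken toward altloc 'A'), strips hydrogens and, by default, waters and
    hetero ligands.
    """
    pdb_file = pdb_io.PDBFile.read(str(path))
    atoms = pdb_io.get_structure(pdb_file, model=model, altloc="occupancy")
    mask = atoms.element != "H"
    if not keep_hetero:
        mask &= struc.filter_amino_acids(atoms)
    if chain is not None:
        mask &= atoms.chain_id == chain
    atoms = atoms[mask]
    recs = []
    for i in range(atoms.array_length()):
        recs.append(AtomRecord(
            serial=i + 1, name=str(atoms.atom_name[i]),
            residue_name=str(atoms.res_name[i]), chain=str(atoms.chain_id[i]),
            residue_number=int(atoms.res_id[i]),
            xyz=tuple(float(v) for v in atoms.coord[i]),
            element=str(atoms.element[i]).upper()))
    return recs


def write_pdb(atoms: list[AtomRecord], path: str | Path) -> None:
    """Write AtomRecords as a minimal single-model PDB file."""
    with open(path, "w") as fh:
        for a in atoms:
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {a.serial:5d} {name}{'':1s}{a.residue_name:>3s} {a.chain:1s}"
                f"{a.residue_number:4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n")
        fh.write("END\n")


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _radii(atoms: list[AtomRecord]) -> np.ndarray:
    r = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        try:
            r[i] = VDW_RADII[a.element.upper()]
        except KeyError:
            raise ValueError(f"unknown element {a.element!r} (atom {a.serial})") from None
    return r


def shrake_rupley(atoms: list[AtomRecord], probe_radius: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Å².

    For each atom, test points on the solvent-expanded sphere of radius
    r + probe are checked for occlusion by neighbouring expanded spheres; the
    accessible fraction times 4π(r+probe)² is the atom's ASA.
    """
    if not atoms:
        raise ValueError("no atoms")
    if n_points < 1:
        raise ValueError("n_points must be positive")
    coords = np.array([a.xyz for a in atoms])
    radii = _radii(atoms) + probe_radius
    sphere = _fibonacci_sphere(n_points)
    asa = np.empty(len(atoms))
    for i in range(len(atoms)):
        d = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.where((d < radii + radii[i]) & (np.arange(len(atoms)) != i))[0]
        pts = coords[i] + radii[i] * sphere
        if neigh.size:
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            accessible = np.all(d2 >= radii[neigh] ** 2, axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        asa[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return asa


def sidechain_atom_indices(atoms: list[AtomRecord], chain: str, residue_number: int) -> list[int]:
    """Indices of side-chain heavy atoms; for glycine the Cα stands in."""
    idx = [i for i, a in enumerate(atoms)
           if a.chain == chain and a.residue_number == residue_number]
    if not idx:
        raise KeyError(f"residue {chain}/{residue_number} not found")
    resname = atoms[idx[0]].residue_name
    if resname == "GLY":
        side = [i for i in idx if atoms[i].name == "CA"]
    else:
        side = [i for i in idx if atoms[i].name not in BACKBONE_ATOMS]
    if not side:
        raise KeyError(f"residue {chain}/{residue_number} has no side-chain atoms")
    return side


@lru_cache(maxsize=None)
def coil_reference_asa(resname: str, probe_radius: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_N_POINTS) -> float:
    """Side-chain ASA of residue type in the extended Gly-X-Gly coil reference.

    Computed with the same engine and parameters as the query structure, so the
    ratio is self-consistent rather than tied to an external constant table.
    """
    tri = build_gxg(resname)
    asa = shrake_rupley(tri, probe_radius=probe_radius, n_points=n_points)
    side = sidechain_atom_indices(tri, "A", 2)
    return float(asa[side].sum())


def classify_ratio(ratio: float, low: float = LOW_THRESHOLD,
                   high: float = HIGH_THRESHOLD) -> ASAClass:
    if ratio < low:
        return ASAClass.LOW
    if ratio > high:
        return ASAClass.HIGH
    return ASAClass.PARTIAL


def sidechain_ratio(atoms: list[AtomRecord], chain: str, residue_number: int,
                    probe_radius: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS,
                    asa: np.ndarray | None = None,
                    low: float = LOW_THRESHOLD, high: float = HIGH_THRESHOLD) -> ASAEntry:
    """Side-chain ASA ratio and burial class for one residue.

    ``asa`` may carry a precomputed per-atom ASA for the full structure to
    avoid recomputation when tabulating every residue.
    """
    side = sidechain_atom_indices(atoms, chain, residue_number)
    if asa is None:
        asa = shrake_rupley(atoms, probe_radius=probe_radius, n_points=n_points)
    sc_asa = float(asa[side].sum())
    resname = atoms[side[0]].residue_name
    ref = coil_reference_asa(resname, probe_radius, n_points)
    ratio = sc_asa / ref
    return ASAEntry(chain=chain, residue_number=residue_number, residue_name=resname,
                    sidechain_asa=sc_asa, ratio=ratio,
                    asa_class=classify_ratio(ratio, low, high))


def asa_table(atoms: list[AtomRecord], probe_radius: float = DEFAULT_PROBE,
              n_points: int = DEFAULT_N_POINTS, low: float = LOW_THRESHOLD,
              high: float = HIGH_THRESHOLD) -> list[ASAEntry]:
    """ASAEntry for every amino-acid residue in the structure, in chain order."""
    asa = shrake_rupley(atoms, probe_radius=probe_radius, n_points=n_points)
    seen: list[tuple[str, int]] = []
    for a in atoms:
        key = (a.chain, a.residue_number)
        if key not in seen and a.residue_name != "DUM":
            seen.append(key)
    return [sidechain_ratio(atoms, ch, num, probe_radius, n_points, asa=asa,
                            low=low, high=high)
            for ch, num in seen]


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal least-squares superposition of B onto A.

    Returns the proper rotation R, translation t (so that B @ R.T + t best
    matches A) and the RMSD over the paired points after the transform.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must both be N×3")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = (B @ R.T + t) - A
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)
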