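"""Ideal-geometry construction of single residues and short peptides.

Heavy-atom coordinates come from the Chemical Component Dictionary templates
bundled with biotite; residues are chained into extended conformations by a
rigid-body placement that keeps consecutive Cα atoms ~3.8 Å apart along one
axis. The Gly-X-Gly extended tripeptide built here serves as the random-coil
reference conformation for side-chain accessibility ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure.info as struc_info

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
CA_CA_EXTENDED = 3.8  # Å, consecutive Cα spacing in an extended chain


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a structure."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    xyz: tuple[float, float, float]
    element: str


def _ideal_heavy_atoms(resname: str) -> tuple[list[str], np.ndarray, list[str]]:
    """Heavy-atom names, coordinates (Å) and elements for a CCD residue template."""
    try:
        tmpl = struc_info.residue(resname.upper())
    except KeyError:
        raise ValueError(f"unknown residue type {resname!r}") from None
    if tmpl is None:
        raise ValueError(f"unknown residue type {resname!r}")
    names = set(tmpl.atom_name)
    if not {"N", "CA", "C"} <= names:
        raise ValueError(f"{resname!r} is not an amino-acid component")
    keep = tmpl.element != "H"
    return (list(tmpl.atom_name[keep]), np.asarray(tmpl.coord[keep], dtype=float),
            list(tmpl.element[keep]))


def _orient(names: list[str], coords: np.ndarray) -> np.ndarray:
    """Place CA at the origin with the N→C backbone direction along +x."""
    idx = {n: i for i, n in enumerate(names)}
    ca, n, c = coords[idx["CA"]], coords[idx["N"]], coords[idx["C"]]
    x = c - n
    x /= np.linalg.norm(x)
    ref = ca - n
    z = np.cross(x, ref)
    if np.linalg.norm(z) < 1e-6:  # degenerate, pick any perpendicular
        z = np.cross(x, [0.0, 0.0, 1.0])
    z /= np.linalg.norm(z)
    y = np.cross(z, x)
    rot = np.stack([x, y, z])  # rows = new basis
    return (coords - ca) @ rot.T


def _records(names, coords, elements, resnames, resnums, chain="A", serial0=1):
    recs = []
    for i, (nm, xyz, el, rn, num) in enumerate(zip(names, coords, elements, resnames, resnums)):
        recs.append(AtomRecord(serial=serial0 + i, name=nm, residue_name=rn, chain=chain,
                               residue_number=int(num), xyz=tuple(float(v) for v in xyz),
                               element=el))
    return recs


def build_residue(resname: str, center: np.ndarray | None = None,
                  residue_number: int = 1) -> list[AtomRecord]:
    """An isolated residue (heavy atoms, ideal geometry), optionally re-centered."""
    names, coords, elements = _ideal_heavy_atoms(resname)
    coords = _orient(names, coords)
    if center is not None:
        coords = coords + np.asarray(center, dtype=float)
    n = len(names)
    return _records(names, coords, elements, [resname.upper()] * n,
                    [residue_number] * n)


def build_extended_chain(resnames: list[str]) -> list[AtomRecord]:
    """Chain residues in an extended (coil-like) conformation.

    Each residue keeps its ideal internal geometry; successive residues are
    translated along +x by the extended Cα–Cα spacing, with alternating 180°
    flips about the chain axis to mimic the alternating pleat of an extended
    strand. Terminal OXT atoms of internal residues are dropped.
    """
    all_names: list[str] = []
    all_coords: list[np.ndarray] = []
    all_elements: list[str] = []
    all_resnames: list[str] = []
    all_resnums: list[int] = []
    flip = np.diag([1.0, -1.0, -1.0])
    for i, rn in enumerate(resnames):
        names, coords, elements = _ideal_heavy_atoms(rn)
        coords = _orient(names, coords)
        if i % 2:
            coords = coords @ flip.T
        coords = coords + np.array([i * CA_CA_EXTENDED, 0.0, 0.0])
        for nm, xyz, el in zip(names, coords, elements):
            if nm == "OXT" and i < len(resnames) - 1:
                continue
            all_names.append(nm)
            all_coords.append(xyz)
            all_elements.append(el)
            all_resnames.append(rn.upper())
            all_resnums.append(i + 1)
    return _records(all_names, np.array(all_coords), all_elements, all_resnames, all_resnums)


def build_gxg(resname: str) -> list[AtomRecord]:
    """The Gly-X-Gly extended tripeptide used as the random-coil ASA reference."""
    return build_extended_chain(["GLY", resname, "GLY"])


def build_shell(center: np.ndarray, radius: float = 8.0, n_atoms: int = 400,
                element: str = "C", serial0: int = 10000) -> list[AtomRecord]:
    """A closed spherical shell of dummy atoms that fully occludes its interior."""
    k = np.arange(n_atoms)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n_atoms)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    pts = np.stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta),
                    np.cos(phi)], axis=1) * radius + np.asarray(center, dtype=float)
    n = len(pts)
    return _records(["DUM"] * n, pts, [element] * n, ["DUM"] * n,
                    list(range(9000, 9000 + n)), chain="Z", serial0=serial0)


def build_helix(resname: str = "ALA", n_residues: int = 10) -> list[AtomRecord]:
    """A toy α-helix: ideal residues placed on a helical lattice (100°/1.5 Å rise)."""
    recs: list[AtomRecord] = []
    serial = 1
    for i in range(n_residues):
        names, coords, elements = _ideal_heavy_atoms(resname)
        coords = _orient(names, coords)
        ang = np.deg2rad(100.0 * i)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                        [np.sin(ang), np.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        # side chains point outward from a 2.3 Å helical axis offset
        coords = (coords + np.array([2.3, 0.0, 0.0])) @ rot.T
        coords = coords + np.array([0.0, 0.0, 1.5 * i])
        keep = [(nm, xyz, el) for nm, xyz, el in zip(names, coords, elements)
                if not (nm == "OXT" and i < n_residues - 1)]
        recs.extend(_records([k[0] for k in keep], np.array([k[1] for k in keep]),
                             [k[2] for k in keep], [resname.upper()] * len(keep),
                             [i + 1] * len(keep), serial0=serial))
        serial += len(keep)
    return recs
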