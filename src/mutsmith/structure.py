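"""Protein structure container and geometry operations.

A light chain→residue→atom container with coordinates in Angstrom, per-atom
van der Waals radii and coarse partial charges. PDB files are parsed with
gemmi (alternate locations resolved to highest occupancy) and written as
plain ATOM records. Operations cover the structure-preparation steps of the
engineering protocol: biological-dimer selection with an inter-chain clash
scan, dual residue numbering (crystal vs full sequence), N-domain
truncation, tripeptide extraction for the unfolded-state proxy, and
hydrogen-bond geometry with ideal polar-hydrogen placement.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from mutsmith.geometry import bond_angle, place_atom, rotation_about_axis
from mutsmith.params import partial_charge, vdw_radius

__all__ = [
    "Atom",
    "Residue",
    "MolecularStructure",
    "NumberingMap",
    "MutationSpec",
    "read_pdb",
    "write_pdb",
    "select_biological_dimer",
    "truncate_range",
    "tripeptide_segment",
    "hbond_geometry",
    "place_polar_hydrogens",
]

HBOND_CUTOFF = 3.5  # Angstrom, H...acceptor classification cutoff
CLASH_TOLERANCE = 0.4  # Angstrom subtracted from vdW-sum in clash scans


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    vdw_radius: float
    partial_charge: float = 0.0
    serial: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: non-positive vdW radius")


@dataclass
class Residue:
    name: str  # 3-letter code
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass
class MolecularStructure:
    """Chains of residues of atoms; the shared in-memory structure type."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    title: str = ""

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        for res in self.chains[chain]:
            if res.number == number and res.icode == icode:
                return res
        raise KeyError(f"chain {chain}: no residue {number}{icode}")

    def atoms(self) -> Iterator[tuple[str, Residue, Atom]]:
        for cid, residues in self.chains.items():
            for res in residues:
                for atom in res.atoms:
                    yield cid, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coordinates(self) -> np.ndarray:
        return np.array([a.coords for _, _, a in self.atoms()])

    def set_coordinates(self, coords: np.ndarray) -> None:
        flat = list(self.atoms())
        if len(flat) != len(coords):
            raise ValueError("coordinate array size mismatch")
        for (_, _, atom), xyz in zip(flat, coords):
            atom.coords = np.asarray(xyz, dtype=float)

    def copy(self) -> "MolecularStructure":
        return copy.deepcopy(self)

    def validate(self) -> None:
        for cid, residues in self.chains.items():
            keys = [r.key for r in residues]
            if len(set(keys)) != len(keys):
                raise ValueError(f"chain {cid}: duplicate residue keys")
            for r in residues:
                if not r.atoms:
                    raise ValueError(f"chain {cid} residue {r.number}: no atoms")


@dataclass
class NumberingMap:
    """Affine map between crystal-structure and full-sequence numbering.

    full-sequence number = crystal number + ``offset``. For the system this
    package was built around the offset is +15 (e.g. crystal 165 ↔ sequence
    180).
    """

    offset: int = 15
    valid_range: tuple[int, int] | None = None

    def _check(self, site: int) -> None:
        if self.valid_range and not self.valid_range[0] <= site <= self.valid_range[1]:
            raise ValueError(f"site {site} outside valid range {self.valid_range}")

    def to_sequence(self, crystal_site: int) -> int:
        self._check(crystal_site)
        return crystal_site + self.offset

    def to_crystal(self, sequence_site: int) -> int:
        return sequence_site - self.offset


@dataclass
class MutationSpec:
    """``chain:site:WT>MUT`` one-letter mutation specification."""

    chain: str
    site: int
    wt_aa: str
    mut_aa: str
    tag: str = ""

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        try:
            chain, site, sub = text.split(":")
            wt, mut = sub.split(">")
            return cls(chain=chain, site=int(site), wt_aa=wt, mut_aa=mut)
        except ValueError as exc:
            raise ValueError(f"bad mutation spec {text!r}; expected chain:site:W>M") from exc

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.site}{self.mut_aa}"


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> MolecularStructure:
    """Parse a PDB file; alternate locations keep the highest-occupancy copy."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    out = MolecularStructure(title=st.name)
    for chain in model:
        residues = []
        for res in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    vdw_radius=vdw_radius(a.element.name),
                    partial_charge=partial_charge(res.name, a.name),
                    serial=a.serial,
                )
                for a in best.values()
            ]
            residues.append(
                Residue(name=res.name, number=res.seqid.num, icode=res.seqid.icode.strip(), atoms=atoms)
            )
        if residues:
            out.chains[chain.name] = residues
    out.validate()
    return out


def write_pdb(structure: MolecularStructure, path: str | Path) -> None:
    lines = []
    serial = 0
    for cid, residues in structure.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{res.name:>4s} {cid:1s}"
                    f"{res.number:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Dimer selection and clash scan
# ---------------------------------------------------------------------------

def interchain_clashes(
    structure: MolecularStructure,
    chain_a: str,
    chain_b: str,
    tolerance: float = CLASH_TOLERANCE,
) -> list[tuple[tuple, tuple, float]]:
    """Inter-chain atom pairs closer than r_vdw(i) + r_vdw(j) − tolerance."""
    flat_a = [(res, atom) for res in structure.chains[chain_a] for atom in res.atoms]
    flat_b = [(res, atom) for res in structure.chains[chain_b] for atom in res.atoms]
    if not flat_a or not flat_b:
        return []
    xa = np.array([a.coords for _, a in flat_a])
    xb = np.array([a.coords for _, a in flat_b])
    ra = np.array([a.vdw_radius for _, a in flat_a])
    rb = np.array([a.vdw_radius for _, a in flat_b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    cut = ra[:, None] + rb[None, :] - tolerance
    clashes = []
    for i, j in zip(*np.nonzero(d < cut)):
        res_i, atom_i = flat_a[i]
        res_j, atom_j = flat_b[j]
        clashes.append(
            (
                (chain_a, res_i.number, atom_i.name),
                (chain_b, res_j.number, atom_j.name),
                float(d[i, j]),
            )
        )
    return clashes


def select_biological_dimer(
    structure: MolecularStructure,
    chains: Sequence[str] = ("C", "D"),
    tolerance: float = CLASH_TOLERANCE,
) -> tuple[MolecularStructure, list]:
    """Extract the requested chain pair and report its inter-chain clashes."""
    for cid in chains:
        if cid not in structure.chains:
            raise KeyError(f"chain {cid!r} not present (has {sorted(structure.chains)})")
    out = MolecularStructure(
        chains={cid: copy.deepcopy(structure.chains[cid]) for cid in chains},
        title=structure.title,
    )
    report = interchain_clashes(out, chains[0], chains[1], tolerance) if len(chains) == 2 else []
    return out, report


# ---------------------------------------------------------------------------
# Truncation and segments
# ---------------------------------------------------------------------------

def truncate_range(
    structure: MolecularStructure, residue_range: tuple[int, int] = (2, 109)
) -> MolecularStructure:
    """Remove residues in the closed number range from every chain.

    Used to drop a domain (e.g. the dimerization N-domain) that is far from
    all mutation sites, shrinking the energy calculations.
    """
    lo, hi = residue_range
    out = structure.copy()
    for cid in list(out.chains):
        out.chains[cid] = [r for r in out.chains[cid] if not lo <= r.number <= hi]
        if not out.chains[cid]:
            del out.chains[cid]
    return out


def tripeptide_segment(
    structure: MolecularStructure, chain: str, site: int
) -> tuple[MolecularStructure, bool]:
    """Extract residues site−1..site+1 with parent coordinates (no refit).

    Returns (segment, at_terminus); at a chain terminus only the existing
    two residues are returned and the flag is set.
    """
    residues = structure.chains[chain]
    idx = next((i for i, r in enumerate(residues) if r.number == site), None)
    if idx is None:
        raise KeyError(f"chain {chain}: no residue {site}")
    lo, hi = max(0, idx - 1), min(len(residues), idx + 2)
    segment = [copy.deepcopy(residues[i]) for i in range(lo, hi)]
    at_terminus = len(segment) < 3
    return MolecularStructure(chains={chain: segment}), at_terminus


# ---------------------------------------------------------------------------
# Polar hydrogens and hydrogen-bond geometry
# ---------------------------------------------------------------------------

_HYDROXYLS = {  # residue -> (H name, O name, antecedent heavy, torsion root)
    "SER": ("HG", "OG", "CB", "CA"),
    "THR": ("HG1", "OG1", "CB", "CA"),
    "TYR": ("HH", "OH", "CZ", "CE1"),
    "CYS": ("HG", "SG", "CB", "CA"),
}


def _acceptor_atoms(structure: MolecularStructure) -> list[np.ndarray]:
    acc = []
    for _, res, atom in structure.atoms():
        if atom.element in ("O", "N") and atom.name not in ("N",):
            acc.append(atom.coords)
    return acc


def place_polar_hydrogens(structure: MolecularStructure, torsion_step: float = 10.0) -> MolecularStructure:
    """Add missing polar hydrogens with ideal geometry.

    Backbone amide H is placed in the peptide plane opposite the carbonyl O
    of the preceding residue. Hydroxyl/thiol hydrogens are built at ideal
    bond length/angle with the torsion scanned in ``torsion_step`` degree
    increments to minimize the distance to the nearest acceptor (O/N).
    """
    out = structure.copy()
    acceptors = _acceptor_atoms(out)
    for cid, residues in out.chains.items():
        for i, res in enumerate(residues):
            # backbone amide H
            if (
                i > 0
                and res.name != "PRO"
                and not res.has_atom("H")
                and res.has_atom("N")
                and res.has_atom("CA")
                and residues[i - 1].has_atom("C")
            ):
                n = res.atom("N").coords
                ca = res.atom("CA").coords
                cprev = residues[i - 1].atom("C").coords
                direction = (n - ca) / np.linalg.norm(n - ca) + (n - cprev) / np.linalg.norm(n - cprev)
                direction /= np.linalg.norm(direction)
                res.atoms.append(
                    Atom("H", "H", n + 1.01 * direction, vdw_radius("H"), partial_charge(res.name, "H"))
                )
            if res.name in _HYDROXYLS:
                hname, oname, cname, rootname = _HYDROXYLS[res.name]
                if res.has_atom(hname) or not (res.has_atom(oname) and res.has_atom(cname)):
                    continue
                o = res.atom(oname).coords
                c = res.atom(cname).coords
                root = res.atom(rootname).coords
                bond = 1.34 if oname == "SG" else 0.96
                best_pos, best_d = None, math.inf
                for tor in np.arange(0.0, 360.0, torsion_step):
                    pos = place_atom(root, c, o, bond, 109.5, float(tor))
                    near = min(
                        (float(np.linalg.norm(pos - a)) for a in acceptors if np.linalg.norm(a - o) > 0.1),
                        default=math.inf,
                    )
                    if near < best_d:
                        best_d, best_pos = near, pos
                if best_pos is not None:
                    res.atoms.append(
                        Atom(hname, "H", best_pos, vdw_radius("H"), partial_charge(res.name, hname))
                    )
    return out


def hbond_geometry(
    structure: MolecularStructure,
    donor: tuple[str, int, str],
    hydrogen: tuple[str, int, str],
    acceptor: tuple[str, int, str],
) -> dict:
    """H-bond geometry between (chain, residue number, atom name) specs.

    Returns the H···acceptor distance (Å), the donor-H-acceptor angle
    (degrees), and whether the contact classifies as hydrogen-bonded under a
    3.5 Å cutoff.
    """
    d = structure.residue(donor[0], donor[1]).atom(donor[2]).coords
    h = structure.residue(hydrogen[0], hydrogen[1]).atom(hydrogen[2]).coords
    a = structure.residue(acceptor[0], acceptor[1]).atom(acceptor[2]).coords
    dist = float(np.linalg.norm(h - a))
    angle = bond_angle(d, h, a)
    return {"distance": dist, "angle": angle, "bonded": dist < HBOND_CUTOFF}
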