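"""In-silico point mutagenesis by ideal-geometry side-chain replacement.

The backbone (N, CA, C, O) of the mutated residue is kept fixed. The new
side chain is grafted from an ideal-geometry residue template (CCD component
coordinates shipped with biotite) superimposed on the local backbone, then
its chi-1/chi-2 torsions are scanned on a 15-degree grid and the rotamer
with the fewest hard-sphere clashes against the rest of the structure is
kept. The procedure is deterministic: ties break toward the first grid
point scanned.

This is a deliberately simple rotamer builder adequate for the
surface-exposed sites the selection cascade targets; it makes no attempt at
rotamer-library statistics or off-rotamer minimization.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
import biotite.structure.info as binfo

from mutsmith.geometry import dihedral_angle, rotation_about_axis
from mutsmith.params import AA_1TO3, AA_3TO1, partial_charge, vdw_radius
from mutsmith.structure import Atom, MolecularStructure, MutationSpec

__all__ = ["mutate_residue", "apply_mutations", "CHI_ATOMS"]

BACKBONE = ("N", "CA", "C", "O", "H", "OXT")
CHI_STEP = 15.0  # degrees
CLASH_TOL = 0.4  # Angstrom

# chi-1 / chi-2 defining atom quadruples (heavy atoms only)
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


def _template(res_name: str) -> tuple[dict[str, np.ndarray], dict[str, list[str]]]:
    """Ideal heavy-atom coordinates and bond adjacency for a residue type."""
    arr = binfo.residue(res_name)
    keep = (arr.element != "H") & (arr.atom_name != "OXT")
    idx = np.nonzero(keep)[0]
    names = list(arr.atom_name[idx])
    coords = {n: arr.coord[i].astype(float) for n, i in zip(names, idx)}
    adj: dict[str, list[str]] = {n: [] for n in names}
    for i, j, _ in arr.bonds.as_array():
        if i in idx and j in idx:
            a, b = arr.atom_name[i], arr.atom_name[j]
            adj[a].append(b)
            adj[b].append(a)
    return coords, adj


def _downstream(adj: dict[str, list[str]], axis_a: str, axis_b: str) -> list[str]:
    """Atoms on the axis_b side when the axis_a-axis_b bond is cut."""
    seen = {axis_a, axis_b}
    stack = [axis_b]
    moving = []
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                moving.append(nb)
                stack.append(nb)
    return moving


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid transform (R, t) minimizing RMSD of mobile onto target."""
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cm, ct


def _clash_count(side_coords: np.ndarray, side_radii: np.ndarray,
                 env_coords: np.ndarray, env_radii: np.ndarray) -> int:
    if len(env_coords) == 0 or len(side_coords) == 0:
        return 0
    d = np.linalg.norm(side_coords[:, None, :] - env_coords[None, :, :], axis=-1)
    cut = side_radii[:, None] + env_radii[None, :] - CLASH_TOL
    return int(np.count_nonzero(d < cut))


def mutate_residue(
    structure: MolecularStructure,
    spec: MutationSpec,
    chi_step: float = CHI_STEP,
) -> MolecularStructure:
    """Return a copy of ``structure`` with one residue mutated.

    Refuses to act when the wild-type residue recorded in ``spec`` does not
    match the structure (guards against numbering mix-ups). All atoms
    outside the mutated residue are left bit-identical.
    """
    out = structure.copy()
    res = out.residue(spec.chain, spec.site)
    if AA_3TO1.get(res.name) != spec.wt_aa:
        raise ValueError(
            f"wild-type mismatch at {spec.chain}:{spec.site}: structure has "
            f"{res.name}, spec says {spec.wt_aa}"
        )
    for bb in ("N", "CA", "C"):
        if not res.has_atom(bb):
            raise ValueError(f"{spec.chain}:{spec.site}: backbone atom {bb} missing")

    mut3 = AA_1TO3[spec.mut_aa]
    backbone_atoms = [a for a in res.atoms if a.name in BACKBONE]
    res.name = mut3
    res.atoms = backbone_atoms
    for a in res.atoms:
        a.partial_charge = partial_charge(mut3, a.name)
    if mut3 == "GLY":
        return out

    coords, adj = _template(mut3)
    tmpl_bb = np.array([coords["N"], coords["CA"], coords["C"]])
    target_bb = np.array([res.atom(n).coords for n in ("N", "CA", "C")])
    R, cm, ct = _kabsch(tmpl_bb, target_bb)
    placed = {n: (R @ (c - cm)) + ct for n, c in coords.items() if n not in BACKBONE}

    side_names = sorted(placed, key=lambda n: list(coords).index(n))
    chis = CHI_ATOMS.get(mut3, [])

    def chi_coords(chi_values: tuple[float, ...]) -> dict[str, np.ndarray]:
        pos = {n: p.copy() for n, p in placed.items()}
        pos.update({n: res.atom(n).coords for n in ("N", "CA", "C")})
        for (a, b, c, d), target in zip(chis, chi_values):
            current = dihedral_angle(pos[a], pos[b], pos[c], pos[d])
            rot = rotation_about_axis(pos[c] - pos[b], target - current)
            pivot = pos[b]
            for name in _downstream(adj, b, c):
                if name in pos and name not in ("N", "CA", "C"):
                    pos[name] = pivot + rot @ (pos[name] - pivot)
        return {n: p for n, p in pos.items() if n in placed}

    env = [
        (a.coords, a.vdw_radius)
        for cid, r, a in out.atoms()
        if not (cid == spec.chain and r.key == res.key)
    ]
    env_coords = np.array([e[0] for e in env]) if env else np.zeros((0, 3))
    env_radii = np.array([e[1] for e in env]) if env else np.zeros(0)
    side_radii = np.array([vdw_radius(n[0]) for n in side_names])

    if chis:
        grid = np.arange(0.0, 360.0, chi_step)
        best, best_clash = None, None
        for chi1 in grid:
            for chi2 in grid if len(chis) > 1 else [None]:
                values = (chi1,) if chi2 is None else (chi1, chi2)
                pos = chi_coords(values)
                sc = np.array([pos[n] for n in side_names])
                n_clash = _clash_count(sc, side_radii, env_coords, env_radii)
                if best_clash is None or n_clash < best_clash:
                    best, best_clash = pos, n_clash
        placed = best
    # amend: ensure dict covers side chain only
    for name in side_names:
        name = str(name)
        elem = "S" if name.startswith("S") and len(name) > 1 else name[0]
        res.atoms.append(
            Atom(
                name=name,
                element=elem,
                coords=placed[name],
                vdw_radius=vdw_radius(elem),
                partial_charge=partial_charge(mut3, name),
            )
        )
    return out


def apply_mutations(
    structure: MolecularStructure,
    specs: list[MutationSpec],
    chi_step: float = CHI_STEP,
) -> MolecularStructure:
    """Apply a list of mutations sequentially (deterministic order as given)."""
    out = structure
    for spec in specs:
        out = mutate_residue(out, spec, chi_step=chi_step)
    return out
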