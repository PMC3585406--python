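"""Finite-difference linearized Poisson-Boltzmann electrostatics.

Solves  div(eps grad phi) - eps_s kappa^2(r) phi = -4 pi C rho  on a regular
cubic grid, with the potential phi in kT/e, lengths in Angstrom and charges
in e (C = e^2/(4 pi eps0 kT), ~560.5 A kT/e^2 at 298.15 K). The physics
mirrors the classic continuum setup: a low-dielectric solute region (atom
spheres inflated by the water-probe radius), high-dielectric solvent,
Debye screening outside a Stern ion-exclusion layer, trilinear charge
spreading, and Debye-Hueckel monopole boundary conditions. The grid is
sized so the solute's longest dimension fills a configurable percentage of
the cube (default 70%).

The linear system is symmetric positive definite and is solved by
preconditioned conjugate gradients; non-convergence raises instead of
warning. Maps are exported in Gaussian CUBE format (header in bohr, values
z-fastest). Mutant-minus-wild-type difference maps and surface-patch
statistics support the potential-steering analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from mutsmith.structure import MolecularStructure

__all__ = [
    "GridSpec",
    "PotentialGrid",
    "PatchDefinition",
    "solve_lpbe",
    "write_cube",
    "read_cube",
    "grid_subtract",
    "patch_stats",
]

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
KCALMOL_PER_E2_A = 332.0636  # Coulomb constant, kcal/mol * A / e^2
GAS_CONSTANT = 1.98720425e-3  # kcal/mol/K
AVOGADRO_PER_LITER_TO_PER_A3 = 6.02214076e-4  # mol/L -> particles/A^3


@dataclass(frozen=True)
class GridSpec:
    """Continuum-electrostatics grid parameters."""

    scale: float = 1.0  # grids per Angstrom
    fill_percent: float = 70.0
    eps_protein: float = 2.0
    eps_solvent: float = 80.0
    ionic_strength: float = 0.15  # mol/L
    probe_radius: float = 1.4  # Angstrom
    stern_layer: float = 2.0  # Angstrom
    temperature: float = 298.15  # K
    box_size: float | None = None  # Angstrom; overrides fill sizing
    center: tuple[float, float, float] | None = None  # fixes the cube center
    # (wild-type and mutant maps must share box_size + center to be
    # subtractable without resampling)
    max_points: int = 129  # per axis, safety cap
    cg_tol: float = 1e-8
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not 0.0 < self.fill_percent < 100.0:
            raise ValueError("fill_percent must lie in (0, 100)")
        if self.eps_protein < 1.0 or self.eps_solvent < 1.0:
            raise ValueError("dielectric constants must be >= 1")

    @property
    def coulomb_kT(self) -> float:
        """e^2/(4 pi eps0 kT) in Angstrom * kT/e^2."""
        return KCALMOL_PER_E2_A / (GAS_CONSTANT * self.temperature)

    @property
    def kappa_squared(self) -> float:
        """Debye screening kappa^2 (A^-2) in the solvent dielectric."""
        n_ion = self.ionic_strength * AVOGADRO_PER_LITER_TO_PER_A3
        return 8.0 * np.pi * self.coulomb_kT * n_ion / self.eps_solvent


@dataclass
class PotentialGrid:
    """Electrostatic potential (kT/e) on a regular orthogonal grid."""

    origin: np.ndarray  # Angstrom
    spacing: float  # Angstrom
    values: np.ndarray  # shape (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("potential grid needs >= 2 points per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite potential values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coordinates(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.values.shape[axis])

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the potential at Cartesian points."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            tuple(self.axis_coordinates(i) for i in range(3)),
            self.values,
            bounds_error=False,
            fill_value=0.0,
        )
        return interp(np.atleast_2d(points))

    def same_geometry(self, other: "PotentialGrid", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) < tol
            and np.all(np.abs(self.origin - other.origin) < tol)
        )


@dataclass
class PatchDefinition:
    """A named surface patch, selected by residue numbers per chain."""

    label: str
    residues: list[tuple[str, int]]  # (chain, residue number)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"patch {self.label!r} selects no residues")


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def _grid_geometry(
    coords: np.ndarray, radii: np.ndarray, spec: GridSpec
) -> tuple[np.ndarray, float, int]:
    spacing = 1.0 / spec.scale
    if spec.center is not None:
        center = np.asarray(spec.center, dtype=float)
    else:
        center = 0.5 * (
            (coords - radii[:, None]).min(axis=0) + (coords + radii[:, None]).max(axis=0)
        )
    if spec.box_size is not None:
        side = float(spec.box_size)
    else:
        extent = (coords + radii[:, None]).max(axis=0) - (coords - radii[:, None]).min(axis=0)
        side = max(float(extent.max()), 1.0) / (spec.fill_percent / 100.0)
    n = int(np.ceil(side / spacing)) + 1
    if n > spec.max_points:
        raise ValueError(
            f"grid of {n} points/axis exceeds cap {spec.max_points}; "
            "reduce scale or box size"
        )
    origin = center - 0.5 * (n - 1) * spacing
    return origin, spacing, n


def _inside_spheres(
    points: np.ndarray, coords: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Boolean mask: point lies inside any atom sphere of given radii."""
    mask = np.zeros(len(points), dtype=bool)
    for xyz, r in zip(coords, radii):
        sub = ~mask
        if not sub.any():
            break
        d2 = np.sum((points[sub] - xyz) ** 2, axis=1)
        hit = np.zeros(len(points), dtype=bool)
        hit[np.nonzero(sub)[0][d2 <= r * r]] = True
        mask |= hit
    return mask


def solve_lpbe(structure: MolecularStructure, spec: GridSpec) -> PotentialGrid:
    """Solve the linearized PBE for a structure with assigned charges/radii."""
    flat = list(structure.atoms())
    if not flat:
        raise ValueError("structure has no atoms")
    coords = np.array([a.coords for _, _, a in flat])
    radii = np.array([a.vdw_radius for _, _, a in flat])
    charges = np.array([a.partial_charge for _, _, a in flat])

    origin, h, n = _grid_geometry(coords, radii, spec)
    C = spec.coulomb_kT
    kappa2 = spec.kappa_squared

    ax = origin[0] + h * np.arange(n)
    ay = origin[1] + h * np.arange(n)
    az = origin[2] + h * np.arange(n)

    # face dielectric maps: sample face-center points against inflated spheres
    eps_faces = []
    infl = radii + spec.probe_radius
    for axis in range(3):
        shape = [n, n, n]
        shape[axis] -= 1
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1)
        face_pts = 0.5 * (
            pts[tuple(slice(0, -1) if k == axis else slice(None) for k in range(3))]
            + pts[tuple(slice(1, None) if k == axis else slice(None) for k in range(3))]
        )
        inside = _inside_spheres(face_pts.reshape(-1, 3), coords, infl).reshape(shape)
        eps = np.where(inside, spec.eps_protein, spec.eps_solvent)
        eps_faces.append(eps)

    # ion accessibility: solvent nodes outside solute + Stern layer
    gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
    nodes = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    ion_excluded = _inside_spheres(nodes, coords, infl + spec.stern_layer).reshape(n, n, n)
    kappa2_map = np.where(ion_excluded, 0.0, spec.eps_solvent * kappa2)

    # trilinear charge spreading
    q_grid = np.zeros((n, n, n))
    for xyz, q in zip(coords, charges):
        if q == 0.0:
            continue
        t = (xyz - origin) / h
        i0 = np.clip(np.floor(t).astype(int), 0, n - 2)
        f = t - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (f[0] if dx else 1 - f[0])
                        * (f[1] if dy else 1 - f[1])
                        * (f[2] if dz else 1 - f[2])
                    )
                    q_grid[i0[0] + dx, i0[1] + dy, i0[2] + dz] += q * w

    # Dirichlet boundary: Debye-Hueckel monopoles
    phi = np.zeros((n, n, n))
    boundary = np.zeros((n, n, n), dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    bpts = nodes.reshape(n, n, n, 3)[boundary]
    bvals = np.zeros(len(bpts))
    kappa = np.sqrt(kappa2)
    for xyz, q in zip(coords, charges):
        if q == 0.0:
            continue
        r = np.linalg.norm(bpts - xyz, axis=1)
        r = np.maximum(r, 1e-6)
        bvals += C * q * np.exp(-kappa * r) / (spec.eps_solvent * r)
    phi[boundary] = bvals

    # assemble 7-point stencil over interior nodes
    interior = ~boundary
    idx = -np.ones((n, n, n), dtype=int)
    idx[interior] = np.arange(interior.sum())
    n_unknown = int(interior.sum())
    rows, cols, vals = [], [], []
    rhs = np.zeros(n_unknown)

    ii, jj, kk = np.nonzero(interior)
    center_ids = idx[ii, jj, kk]
    diag = kappa2_map[ii, jj, kk] * h * h
    rhs += 4.0 * np.pi * C * q_grid[ii, jj, kk] / h

    neighbor_offsets = [
        (0, (-1, 0, 0)),
        (0, (1, 0, 0)),
        (1, (0, -1, 0)),
        (1, (0, 1, 0)),
        (2, (0, 0, -1)),
        (2, (0, 0, 1)),
    ]
    for axis, (dx, dy, dz) in neighbor_offsets:
        ni, nj, nk = ii + dx, jj + dy, kk + dz
        fi = ii + min(dx, 0) if axis == 0 else ii
        fj = jj + min(dy, 0) if axis == 1 else jj
        fk = kk + min(dz, 0) if axis == 2 else kk
        eps_f = eps_faces[axis][fi, fj, fk]
        diag += eps_f
        nb_interior = interior[ni, nj, nk]
        rows.extend(center_ids[nb_interior])
        cols.extend(idx[ni[nb_interior], nj[nb_interior], nk[nb_interior]])
        vals.extend(-eps_f[nb_interior])
        nb_b = ~nb_interior
        np.add.at(rhs, center_ids[nb_b], eps_f[nb_b] * phi[ni[nb_b], nj[nb_b], nk[nb_b]])

    rows.extend(center_ids)
    cols.extend(center_ids)
    vals.extend(diag)
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n_unknown, n_unknown))

    precond = sparse.diags(1.0 / A.diagonal())
    x, info = cg(A, rhs, rtol=spec.cg_tol, maxiter=spec.max_iterations, M=precond)
    if info != 0:
        residual = float(np.linalg.norm(A @ x - rhs))
        raise RuntimeError(
            f"PB solver did not converge in {spec.max_iterations} iterations "
            f"(residual {residual:.3e})"
        )
    phi[interior] = x
    return PotentialGrid(origin=origin, spacing=h, values=phi)


# ---------------------------------------------------------------------------
# CUBE I/O
# ---------------------------------------------------------------------------

def write_cube(
    grid: PotentialGrid,
    path: str | Path,
    structure: MolecularStructure | None = None,
    comment: str = "electrostatic potential (kT/e)",
) -> Path:
    """Write a Gaussian CUBE file (header in bohr, values z-fastest)."""
    path = Path(path)
    nx, ny, nz = grid.dims
    b = BOHR_PER_ANGSTROM
    atoms = list(structure.atoms()) if structure is not None else []
    lines = [comment, "generated by mutsmith"]
    ox, oy, oz = grid.origin * b
    lines.append(f"{len(atoms):5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}")
    for count, vec in ((nx, (grid.spacing * b, 0, 0)), (ny, (0, grid.spacing * b, 0)), (nz, (0, 0, grid.spacing * b))):
        lines.append(f"{count:5d}{vec[0]:12.6f}{vec[1]:12.6f}{vec[2]:12.6f}")
    atomic_numbers = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}
    for _, _, atom in atoms:
        z = atomic_numbers.get(atom.element, 6)
        x, y, zc = atom.coords * b
        lines.append(f"{z:5d}{atom.partial_charge:12.6f}{x:12.6f}{y:12.6f}{zc:12.6f}")
    flat = grid.values.reshape(nx * ny, nz)
    for row in range(nx * ny):
        vals = grid.values.reshape(nx, ny, nz)[row // ny, row % ny]
        for start in range(0, nz, 6):
            lines.append("".join(f"{v:13.5e}" for v in vals[start : start + 6]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_cube(path: str | Path) -> PotentialGrid:
    """Read a Gaussian CUBE file written by :func:`write_cube`."""
    tokens_lines = Path(path).read_text().splitlines()
    if len(tokens_lines) < 6:
        raise ValueError("truncated CUBE header")
    header = tokens_lines[2].split()
    natoms = int(header[0])
    origin = np.array(list(map(float, header[1:4]))) / BOHR_PER_ANGSTROM
    dims = []
    spacings = []
    for axis, line in enumerate(tokens_lines[3:6]):
        parts = line.split()
        dims.append(int(parts[0]))
        vec = np.array(list(map(float, parts[1:4])))
        off_axis = np.delete(vec, axis)
        if np.any(np.abs(off_axis) > 1e-9):
            raise ValueError("non-orthogonal CUBE axes are not supported")
        spacings.append(vec[axis] / BOHR_PER_ANGSTROM)
    if abs(spacings[0] - spacings[1]) > 1e-9 or abs(spacings[0] - spacings[2]) > 1e-9:
        raise ValueError("anisotropic spacing not supported")
    values_text = " ".join(tokens_lines[6 + natoms :])
    values = np.fromstring(values_text, sep=" ")
    nx, ny, nz = dims
    if values.size != nx * ny * nz:
        raise ValueError(f"expected {nx * ny * nz} values, found {values.size}")
    return PotentialGrid(origin=origin, spacing=float(spacings[0]), values=values.reshape(nx, ny, nz))


# ---------------------------------------------------------------------------
# Difference maps and patch statistics
# ---------------------------------------------------------------------------

def grid_subtract(mutant: PotentialGrid, wt: PotentialGrid) -> PotentialGrid:
    """Element-wise mutant − WT difference map; geometries must match."""
    if not mutant.same_geometry(wt):
        raise ValueError("grid geometries differ; refusing to resample silently")
    return PotentialGrid(
        origin=mutant.origin.copy(),
        spacing=mutant.spacing,
        values=mutant.values - wt.values,
    )


def patch_stats(
    diff: PotentialGrid,
    structure: MolecularStructure,
    patches: Sequence[PatchDefinition],
    probe_radius: float = 1.4,
    shell_width: float | None = None,
) -> dict[str, dict[str, float]]:
    """Mean/min/max potential change over each patch's surface shell.

    The shell consists of grid points within ``probe + shell_width`` of a
    patch atom's surface but outside every atom's probe-inflated sphere
    (i.e. solvent-side points hugging the molecular surface).
    """
    shell = shell_width if shell_width is not None else diff.spacing
    all_coords = np.array([a.coords for _, _, a in structure.atoms()])
    all_infl = np.array([a.vdw_radius for _, _, a in structure.atoms()]) + probe_radius
    nx, ny, nz = diff.dims
    axes = [diff.axis_coordinates(i) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    in_solute = _inside_spheres(nodes, all_coords, all_infl)

    out: dict[str, dict[str, float]] = {}
    for patch in patches:
        atoms = []
        for chain, number in patch.residues:
            res = structure.residue(chain, number)
            atoms.extend(res.atoms)
        if not atoms:
            raise ValueError(f"patch {patch.label!r} matches no atoms")
        pc = np.array([a.coords for a in atoms])
        pr = np.array([a.vdw_radius for a in atoms]) + probe_radius + shell
        near = _inside_spheres(nodes, pc, pr)
        sel = near & ~in_solute
        if not sel.any():
            raise ValueError(f"patch {patch.label!r} has no surface grid points")
        vals = diff.values.reshape(-1)[sel]
        out[patch.label] = {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n_points": int(sel.sum()),
        }
    return out
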