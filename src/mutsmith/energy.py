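"""Simplified molecular-mechanics + generalized-Born energy function.

The evaluator is a pluggable, self-contained stand-in for a full force
field, preserving the *bookkeeping* of the stability/affinity protocol
(multi-parameterization averaging, minimized-structure energies) while
staying desk-scale. Terms:

* bonded: harmonic restraints on detected covalent bonds (reference length
  = input geometry), k = ``bond_k``;
* van der Waals: Lennard-Jones 12-6 with element-based parameters,
  1-2/1-3 pairs excluded, 1-4 scaled by 0.5;
* Coulomb: 332.0636 q_i q_j / (eps_in r_ij), same exclusions;
* GB polar: Still pairwise formula with fixed Born radii alpha_i equal to
  the intrinsic (vdW) radius — an isolated ion reproduces the Born formula
  exactly; no descreening, which keeps the term analytic and differentiable;
* nonpolar: gamma_np times total SASA (evaluation only; not part of the
  minimized objective).

Three bundled parameterizations ("setA", "setB", "setC") differ in LJ well
depths, radii inflation and the nonpolar coefficient; results are averaged
across parameterizations exactly as a multi-force-field protocol would.
Raw magnitudes are NOT comparable to any published force-field energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.distance import cdist

from mutsmith.sasa import atom_sasa
from mutsmith.structure import MolecularStructure

__all__ = [
    "EnergyParams",
    "EnergyBreakdown",
    "EnergyModel",
    "total_energy",
    "minimize_structure",
    "DEFAULT_PARAMETERIZATIONS",
]

COULOMB_CONSTANT = 332.0636  # kcal/mol * Angstrom / e^2
GB_HALF_CONSTANT = COULOMB_CONSTANT / 2.0

LJ_EPSILON = {"H": 0.02, "C": 0.10, "N": 0.16, "O": 0.20, "S": 0.25, "P": 0.20}


@dataclass(frozen=True)
class EnergyParams:
    """One parameterization of the simplified energy function."""

    name: str = "setA"
    eps_scale: float = 1.0
    radius_shift: float = 0.0  # added to vdW radii for LJ sigma
    eps_in: float = 1.0  # internal dielectric for Coulomb
    eps_out: float = 80.0  # solvent dielectric for GB
    gamma_np: float = 0.005  # kcal/mol/A^2 nonpolar surface coefficient
    bond_k: float = 300.0  # kcal/mol/A^2
    lj_scale14: float = 0.5
    coul_scale14: float = 0.5

    def __post_init__(self) -> None:
        if self.eps_in <= 0 or self.eps_out <= 0:
            raise ValueError("dielectric constants must be positive")


DEFAULT_PARAMETERIZATIONS = (
    EnergyParams(name="setA", eps_scale=1.0, radius_shift=0.0, gamma_np=0.005),
    EnergyParams(name="setB", eps_scale=0.85, radius_shift=0.05, gamma_np=0.007),
    EnergyParams(name="setC", eps_scale=1.15, radius_shift=-0.05, gamma_np=0.006),
)


@dataclass
class EnergyBreakdown:
    bonded: float = 0.0
    vdw: float = 0.0
    coulomb: float = 0.0
    gb_polar: float = 0.0
    nonpolar: float = 0.0

    @property
    def total(self) -> float:
        return self.bonded + self.vdw + self.coulomb + self.gb_polar + self.nonpolar

    def as_dict(self) -> dict[str, float]:
        return {
            "bonded": self.bonded,
            "vdw": self.vdw,
            "coulomb": self.coulomb,
            "gb_polar": self.gb_polar,
            "nonpolar": self.nonpolar,
            "total": self.total,
        }


def _detect_bonds(flat: list, coords: np.ndarray) -> list[tuple[int, int, float]]:
    """Covalent bonds by distance: heavy-heavy < 1.95 A (2.2 with S),
    X-H < 1.25 A. Quadratic scan; structures here are desk-scale."""
    n = len(flat)
    if n < 2:
        return []
    d = cdist(coords, coords)
    bonds = []
    for i in range(n):
        for j in range(i + 1, n):
            ei = flat[i][2].element
            ej = flat[j][2].element
            if "H" in (ei, ej):
                cut = 1.25
            elif "S" in (ei, ej):
                cut = 2.2
            else:
                cut = 1.95
            if d[i, j] < cut:
                bonds.append((i, j, float(d[i, j])))
    return bonds


class EnergyModel:
    """Energy/gradient evaluator bound to one structure topology."""

    def __init__(self, structure: MolecularStructure, params: EnergyParams):
        self.params = params
        self.flat = list(structure.atoms())
        n = len(self.flat)
        self.n_atoms = n
        self.charges = np.array([a.partial_charge for _, _, a in self.flat])
        radii = np.array([a.vdw_radius for _, _, a in self.flat])
        self.born_radii = radii.copy()
        lj_r = radii + params.radius_shift
        self.sigma = (2.0 * lj_r) / 2 ** (1 / 6)  # rmin = 2 r_vdw
        self.eps = params.eps_scale * np.array(
            [LJ_EPSILON.get(a.element, 0.1) for _, _, a in self.flat]
        )
        self.sasa_radii = radii
        coords0 = np.array([a.coords for _, _, a in self.flat]) if n else np.zeros((0, 3))
        self.bonds = _detect_bonds(self.flat, coords0)
        self.scale = self._nonbonded_scale(n)

    def _nonbonded_scale(self, n: int) -> np.ndarray:
        """Pair scaling: 0 for 1-2/1-3, scale14 for 1-4, 1 otherwise."""
        scale = np.ones((n, n)) - np.eye(n) if n else np.zeros((0, 0))
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        for i in range(n):
            for j in adj[i]:
                scale[i, j] = 0.0
                for k in adj[j]:
                    if k != i:
                        scale[i, k] = 0.0  # 1-3
        # mark 1-4 after 1-2/1-3 zeros
        for i in range(n):
            for j in adj[i]:
                for k in adj[j] - {i}:
                    for l in adj[k] - {j}:
                        if l != i and scale[i, l] != 0.0:
                            scale[i, l] = -1.0  # placeholder for 1-4
        scale[scale == -1.0] = 1.0  # replaced per-term with scale14 factors
        # store separate 1-4 mask
        mask14 = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in adj[i]:
                for k in adj[j] - {i}:
                    for l in adj[k] - {j}:
                        if l != i and scale[i, l] != 0.0:
                            mask14[i, l] = mask14[l, i] = True
        self.mask14 = mask14
        return scale

    # -- evaluation ---------------------------------------------------------

    def energy_grad(
        self, coords: np.ndarray, softcore: bool = False
    ) -> tuple[EnergyBreakdown, np.ndarray]:
        """Differentiable terms (bonded, LJ, Coulomb, GB) and their gradient."""
        p = self.params
        n = self.n_atoms
        bd = EnergyBreakdown()
        grad = np.zeros((n, 3))
        if n == 0:
            return bd, grad
        coords = coords.reshape(n, 3)

        for i, j, r0 in self.bonds:
            rij = coords[i] - coords[j]
            r = np.linalg.norm(rij)
            bd.bonded += p.bond_k * (r - r0) ** 2
            g = 2 * p.bond_k * (r - r0) * rij / r
            grad[i] += g
            grad[j] -= g

        tau = 1.0 / p.eps_in - 1.0 / p.eps_out
        bd.gb_polar = float(
            (-GB_HALF_CONSTANT * tau * self.charges**2 / self.born_radii).sum()
        )

        if n > 1:
            diff = coords[:, None, :] - coords[None, :, :]
            r = np.sqrt(np.sum(diff**2, axis=-1))
            np.fill_diagonal(r, 1.0)
            iu = np.triu_indices(n, 1)

            lj_scale = self.scale.copy()
            lj_scale[self.mask14] = p.lj_scale14
            coul_scale = self.scale.copy()
            coul_scale[self.mask14] = p.coul_scale14

            sig = 0.5 * (self.sigma[:, None] + self.sigma[None, :])
            eps = np.sqrt(self.eps[:, None] * self.eps[None, :])
            if softcore:
                # capped repulsion for initial clash relief
                r_eff = np.sqrt(r**2 + (0.5 * sig) ** 2)
            else:
                r_eff = r
            sr6 = (sig / r_eff) ** 6
            e_lj = 4 * eps * (sr6**2 - sr6) * lj_scale
            bd.vdw = float(e_lj[iu].sum())
            dedr = (24 * eps * (sr6 - 2 * sr6**2) / r_eff) * lj_scale
            dedr *= r / r_eff if softcore else 1.0

            e_c = COULOMB_CONSTANT * np.outer(self.charges, self.charges) / (p.eps_in * r)
            bd.coulomb = float((e_c * coul_scale)[iu].sum())
            dedr_c = -(e_c * coul_scale) / r

            ab = np.outer(self.born_radii, self.born_radii)
            expo = np.exp(-(r**2) / (4.0 * ab))
            fgb = np.sqrt(r**2 + ab * expo)
            qq = np.outer(self.charges, self.charges)
            e_gb_pair = -GB_HALF_CONSTANT * tau * qq / fgb
            # off-diagonal pairs count once with factor 2 in the Still sum
            bd.gb_polar += float(2 * e_gb_pair[iu].sum())
            dfdr = (r - 0.25 * r * expo) / fgb
            dedr_gb = 2 * GB_HALF_CONSTANT * tau * qq / fgb**2 * dfdr

            dedr_total = dedr + dedr_c + dedr_gb
            np.fill_diagonal(dedr_total, 0.0)
            unit = diff / r[..., None]
            grad += np.sum(dedr_total[..., None] * unit, axis=1)
        return bd, grad.ravel()

    def breakdown(self, coords: np.ndarray | None = None) -> EnergyBreakdown:
        """Full decomposition including the nonpolar (SASA) term."""
        if coords is None:
            coords = np.array([a.coords for _, _, a in self.flat]) if self.n_atoms else np.zeros((0, 3))
        bd, _ = self.energy_grad(np.asarray(coords, dtype=float))
        if self.n_atoms:
            total_area = atom_sasa(coords.reshape(-1, 3), self.sasa_radii).sum()
            bd.nonpolar = float(self.params.gamma_np * total_area)
        return bd


def total_energy(structure: MolecularStructure, params: EnergyParams) -> EnergyBreakdown:
    """Energy decomposition of a structure under one parameterization."""
    for _, res, a in structure.atoms():
        if a.vdw_radius <= 0:
            raise ValueError(f"atom {a.name} of {res.name}{res.number} lacks parameters")
    return EnergyModel(structure, params).breakdown(structure.coordinates())


@dataclass
class MinimizationResult:
    coords: np.ndarray
    energy_start: float
    energy_end: float
    rms_gradient: float
    iterations: int
    converged: bool


def minimize_energy(
    energy_grad,
    coords0: np.ndarray,
    rms_tol: float = 0.01,
    max_iterations: int = 5000,
) -> MinimizationResult:
    """L-BFGS minimization of any ``f(x) -> (E, grad)`` to an RMS-per-atom
    gradient tolerance (kcal/mol/Å)."""
    x0 = np.asarray(coords0, dtype=float).ravel()
    n_atoms = max(1, x0.size // 3)

    def fun(x):
        e, g = energy_grad(x)
        e = e.total if isinstance(e, EnergyBreakdown) else float(e)
        return e, np.asarray(g, dtype=float)

    e0, g0 = fun(x0)
    if np.sqrt(np.sum(g0**2) / n_atoms) <= rms_tol:
        return MinimizationResult(x0.reshape(-1, 3), e0, e0, float(np.sqrt(np.sum(g0**2) / n_atoms)), 0, True)

    res = scipy_minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iterations, "gtol": 1e-12, "ftol": 1e-14},
    )
    e_end, g_end = fun(res.x)
    rms = float(np.sqrt(np.sum(np.asarray(g_end) ** 2) / n_atoms))
    return MinimizationResult(
        coords=res.x.reshape(-1, 3),
        energy_start=float(e0),
        energy_end=float(e_end),
        rms_gradient=rms,
        iterations=int(res.nit),
        converged=rms <= rms_tol or bool(res.success),
    )


def minimize_structure(
    structure: MolecularStructure,
    params: EnergyParams,
    rms_tol: float = 0.01,
    max_iterations: int = 5000,
    softcore_first: bool = True,
) -> tuple[MolecularStructure, MinimizationResult]:
    """Minimize a structure; returns (minimized copy, trajectory summary).

    Steric clashes in the input are relieved first with a soft-core van der
    Waals ramp (50 L-BFGS iterations) before the full potential is applied.
    """
    model = EnergyModel(structure, params)
    coords = structure.coordinates()
    if model.n_atoms == 0:
        return structure.copy(), MinimizationResult(coords, 0.0, 0.0, 0.0, 0, True)
    if softcore_first:
        soft = minimize_energy(
            lambda x: model.energy_grad(x, softcore=True), coords, rms_tol=rms_tol, max_iterations=50
        )
        coords = soft.coords
    result = minimize_energy(model.energy_grad, coords, rms_tol=rms_tol, max_iterations=max_iterations)
    out = structure.copy()
    out.set_coordinates(result.coords)
    return out, result
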