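"""Finite-difference linearized PB solver, CUBE I/O, difference maps."""

import numpy as np
import pytest

from mutsmith.pb import (
    BOHR_PER_ANGSTROM,
    GridSpec,
    PatchDefinition,
    PotentialGrid,
    grid_subtract,
    patch_stats,
    read_cube,
    solve_lpbe,
    write_cube,
)
from mutsmith.structure import Atom, MolecularStructure, Residue
from mutsmith.synthetic import toy_structure

UNIFORM = GridSpec(
    scale=1.0, box_size=40.0, eps_protein=80.0, eps_solvent=80.0,
    ionic_strength=0.0, probe_radius=0.0, stern_layer=0.0,
)
SPHERE = GridSpec(
    scale=1.0, box_size=40.0, eps_protein=2.0, eps_solvent=80.0,
    ionic_strength=0.15, probe_radius=0.0, stern_layer=2.0,
)


def off_axis_point(r):
    p = np.array([0.3, 0.2, 0.1])
    return p / np.linalg.norm(p) * r


@pytest.fixture(scope="module")
def ion():
    return toy_structure("charged_sphere", charge=1.0, radius=2.0)


@pytest.fixture(scope="module")
def sphere_solution(ion):
    return solve_lpbe(ion, SPHERE)


class TestSolver:
    def test_zero_charges_zero_potential(self):
        neutral = toy_structure("charged_sphere", charge=0.0, radius=2.0)
        grid = solve_lpbe(neutral, SPHERE)
        assert np.abs(grid.values).max() == 0.0

    def test_uniform_dielectric_matches_coulomb(self, ion):
        grid = solve_lpbe(ion, UNIFORM)
        C = UNIFORM.coulomb_kT
        for r in (5.0, 7.0, 10.0):
            phi = grid.interpolate(off_axis_point(r))[0]
            exact = C / (80.0 * r)
            assert abs(phi - exact) / exact < 0.03

    def test_debye_hueckel_sphere_exterior(self, ion, sphere_solution):
        """Dielectric sphere with a Stern shell: exterior potential follows
        the screened-Coulomb closed form phi = C q e^{-k(r-b)} / (eps r (1+kb))."""
        kappa = np.sqrt(SPHERE.kappa_squared)
        b = 2.0 + SPHERE.stern_layer
        for r in (6.0, 8.0, 10.0):
            phi = sphere_solution.interpolate(off_axis_point(r))[0]
            exact = SPHERE.coulomb_kT * np.exp(-kappa * (r - b)) / (80.0 * (1 + kappa * b) * r)
            assert abs(phi - exact) / exact < 0.05

    def test_linearity_superposition(self):
        """Linearity holds for a fixed dielectric/screening map: solving the
        same two-sphere geometry with charge sets (q,0), (0,-q) and (q,-q)
        must superpose exactly."""

        def system(qa, qb):
            res_a = Residue("SPH", 1, atoms=[Atom("Q", "C", np.array([-4.0, 0.0, 0.0]), 2.0, qa)])
            res_b = Residue("SPH", 2, atoms=[Atom("Q", "C", np.array([4.0, 0.0, 0.0]), 2.0, qb)])
            return MolecularStructure(chains={"A": [res_a, res_b]})

        spec = GridSpec(scale=1.0, box_size=40.0, probe_radius=0.0, center=(0.0, 0.0, 0.0))
        ga = solve_lpbe(system(1.0, 0.0), spec)
        gb = solve_lpbe(system(0.0, -1.0), spec)
        gab = solve_lpbe(system(1.0, -1.0), spec)
        assert np.abs(gab.values - (ga.values + gb.values)).max() < 1e-6

    def test_charge_scaling(self, ion, sphere_solution):
        double = toy_structure("charged_sphere", charge=2.0, radius=2.0)
        grid = solve_lpbe(double, SPHERE)
        assert np.abs(grid.values - 2 * sphere_solution.values).max() < 1e-6

    def test_grid_cap_enforced(self, ion):
        with pytest.raises(ValueError, match="cap"):
            solve_lpbe(ion, GridSpec(scale=4.0, box_size=100.0))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GridSpec(scale=-1.0)
        with pytest.raises(ValueError):
            GridSpec(fill_percent=120.0)
        with pytest.raises(ValueError):
            GridSpec(eps_protein=0.5)


class TestCube:
    def test_small_grid_z_fastest_layout(self, tmp_path):
        values = np.arange(8.0).reshape(2, 2, 2)
        grid = PotentialGrid(origin=np.zeros(3), spacing=1.0, values=values)
        path = write_cube(grid, tmp_path / "g.cube")
        data_lines = path.read_text().splitlines()[6:]
        flat = [float(tok) for line in data_lines for tok in line.split()]
        # z varies fastest: x0y0z0, x0y0z1, x0y1z0, ...
        assert flat == [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]

    def test_roundtrip(self, tmp_path, rng):
        values = rng.normal(size=(5, 4, 3))
        grid = PotentialGrid(origin=np.array([1.0, -2.0, 0.5]), spacing=0.8, values=values)
        back = read_cube(write_cube(grid, tmp_path / "r.cube"))
        assert back.dims == grid.dims
        assert np.abs(back.origin - grid.origin).max() < 1e-6
        assert np.allclose(back.values, grid.values, rtol=1e-4, atol=1e-8)

    def test_origin_in_bohr(self, tmp_path):
        grid = PotentialGrid(origin=np.array([1.0, 0.0, 0.0]), spacing=1.0, values=np.zeros((2, 2, 2)))
        path = write_cube(grid, tmp_path / "b.cube")
        header = path.read_text().splitlines()[2].split()
        assert float(header[1]) == pytest.approx(1.8897261, abs=1e-5)
        assert float(header[1]) == pytest.approx(BOHR_PER_ANGSTROM, abs=1e-5)


class TestDifferenceMaps:
    def test_self_subtraction_zero(self, sphere_solution):
        diff = grid_subtract(sphere_solution, sphere_solution)
        assert np.abs(diff.values).max() == 0.0

    def test_extra_negative_charge_negative_nearby(self):
        spec = GridSpec(scale=1.0, box_size=40.0, probe_radius=0.0, center=(0.0, 0.0, 0.0))
        wt = toy_structure("charged_sphere", charge=0.0, radius=2.0)
        extra = Residue("SPH", 2, atoms=[Atom("Q", "C", np.array([5.0, 0.0, 0.0]), 1.5, -1.0)])
        mut = MolecularStructure(chains={"A": wt.chains["A"] + [extra]})
        diff = grid_subtract(solve_lpbe(mut, spec), solve_lpbe(wt, spec))
        phi_near = diff.interpolate(np.array([8.0, 0.0, 0.0]))[0]
        assert phi_near < 0

    def test_geometry_mismatch_rejected(self, sphere_solution):
        other = PotentialGrid(
            origin=sphere_solution.origin + 1.0,
            spacing=sphere_solution.spacing,
            values=sphere_solution.values,
        )
        with pytest.raises(ValueError, match="geometries"):
            grid_subtract(other, sphere_solution)


class TestPatchStats:
    def test_uniform_zero_difference(self, ion, sphere_solution):
        zero = PotentialGrid(
            origin=sphere_solution.origin, spacing=sphere_solution.spacing,
            values=np.zeros(sphere_solution.dims),
        )
        stats = patch_stats(zero, ion, [PatchDefinition("A", [("A", 1)])], probe_radius=0.0)
        assert stats["A"]["mean"] == stats["A"]["min"] == stats["A"]["max"] == 0.0

    def test_negative_charge_lining_cleft(self):
        """A mutant adding a negative charge in the cleft makes the cleft
        patch mean negative while a far-side patch stays near zero."""
        wt = toy_structure("two_domain_dimer", cleft=12.0, n_residues=6)
        xyz = wt.coordinates()
        spec = GridSpec(
            scale=1.0, box_size=48.0, probe_radius=0.0, max_points=129,
            center=tuple(0.5 * (xyz.min(axis=0) + xyz.max(axis=0))),
        )
        mut = wt.copy()
        # place the extra charge on the cleft-facing CA of chain C
        ca_c = max(wt.chains["C"], key=lambda r: r.atom("CA").coords[0])
        mut.residue("C", ca_c.number).atom("CA").partial_charge = -1.0
        diff = grid_subtract(solve_lpbe(mut, spec), solve_lpbe(wt, spec))
        far_res = min(wt.chains["C"], key=lambda r: r.atom("CA").coords[0])
        stats = patch_stats(
            diff, wt,
            [PatchDefinition("cleft", [("C", ca_c.number)]),
             PatchDefinition("far", [("C", far_res.number)])],
        )
        assert stats["cleft"]["mean"] < -0.05
        assert abs(stats["far"]["mean"]) < abs(stats["cleft"]["mean"]) / 3

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            PatchDefinition("empty", [])
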