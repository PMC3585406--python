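"""C-alpha anisotropic network model (ANM): Hessian, modes, GHz frequencies.

Each residue contributes one node (its C-alpha). Node pairs closer than the
cutoff r_c (default 15 Å) are joined by a Hookean spring of uniform force
constant gamma (default 1.0 kcal/(mol·Å²); a distance-weight exponent of 0
means uniform springs). The 3N x 3N Hessian of this potential has exactly
six zero eigenvalues for any non-collinear 3-D structure (rigid-body
translations and rotations); the remaining eigenpairs are the vibrational
modes. Mode frequencies follow

    nu_i = (1/2 pi) sqrt(gamma lambda_i / m)

with gamma converted kcal/(mol·Å²) -> N/m (x 0.69477) and the node mass m
(default 110 Da, an average residue mass) -> kg, reported in GHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import squareform, pdist

from mutsmith.structure import MolecularStructure

__all__ = [
    "ElasticNetwork",
    "ModeSet",
    "calpha_coordinates",
    "anm_hessian",
    "compute_modes",
    "mode_frequencies",
    "mode_table",
    "write_nmd",
]

KCAL_PER_MOL_A2_TO_N_PER_M = 6.947695e-21 / 1e-20  # = 0.6947695
DALTON_TO_KG = 1.66053907e-27
ZERO_MODE_RTOL = 1e-8


@dataclass(frozen=True)
class ElasticNetwork:
    """ANM parameters: cutoff, force constant, weighting, node mass."""

    cutoff: float = 15.0  # Angstrom
    gamma: float = 1.0  # kcal/(mol*A^2)
    weight_exponent: float = 0.0  # 0 = uniform springs
    node_mass: float = 110.0  # Da

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.gamma <= 0 or self.node_mass <= 0:
            raise ValueError("cutoff, gamma and node mass must be positive")


@dataclass
class ModeSet:
    """Eigenpairs of an ANM Hessian, ascending, with rigid modes flagged."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, 3N x n_modes
    n_zero_modes: int
    network: ElasticNetwork

    @property
    def vibrational_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero_modes :]

    @property
    def frequencies_ghz(self) -> np.ndarray:
        return mode_frequencies(
            self.vibrational_eigenvalues, self.network.gamma, self.network.node_mass
        )


def calpha_coordinates(structure: MolecularStructure) -> np.ndarray:
    """One C-alpha per residue, in chain order."""
    coords = []
    for _, res, atom in structure.atoms():
        if atom.name == "CA":
            coords.append(atom.coords)
    if len(coords) < 2:
        raise ValueError("need at least two C-alpha nodes")
    return np.array(coords)


def anm_hessian(coords: np.ndarray, network: ElasticNetwork = ElasticNetwork()) -> np.ndarray:
    """Dense 3N x 3N ANM Hessian from node coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need >= 2 nodes")
    d = squareform(pdist(coords))
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            r = d[i, j]
            if r > network.cutoff or r == 0.0:
                continue
            gamma_ij = network.gamma * r ** (-network.weight_exponent)
            u = (coords[j] - coords[i]) / r
            block = gamma_ij * np.outer(u, u)
            H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
            H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= block
            H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
            H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += block
    return H


def compute_modes(
    source: MolecularStructure | np.ndarray,
    network: ElasticNetwork = ElasticNetwork(),
    n_modes: int = 36,
) -> ModeSet:
    """Smallest ``n_modes`` eigenpairs of the ANM Hessian.

    Modes with eigenvalue below 1e-8 of the largest are flagged rigid-body;
    any valid 3-D (non-collinear) structure has exactly six. Collinear node
    sets are rejected (their rotational modes are degenerate).
    """
    coords = (
        calpha_coordinates(source)
        if isinstance(source, MolecularStructure)
        else np.asarray(source, dtype=float)
    )
    n = len(coords)
    if n_modes > 3 * n:
        raise ValueError(f"n_modes={n_modes} exceeds 3N={3 * n}")
    centered = coords - coords.mean(axis=0)
    if n >= 3:
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise ValueError("all nodes are collinear; rotational modes degenerate")
    H = anm_hessian(coords, network)
    eigenvalues, eigenvectors = eigh(H)
    lam_max = float(eigenvalues[-1])
    if lam_max <= 0:
        raise ValueError("network has no connected springs")
    n_zero = int(np.sum(eigenvalues < ZERO_MODE_RTOL * lam_max))
    keep = min(n_modes + n_zero, 3 * n)
    return ModeSet(
        eigenvalues=eigenvalues[:keep],
        eigenvectors=eigenvectors[:, :keep],
        n_zero_modes=n_zero,
        network=network,
    )


def mode_frequencies(
    eigenvalues: np.ndarray, gamma: float, node_mass: float
) -> np.ndarray:
    """Frequencies in GHz: nu = (1/2 pi) sqrt(gamma lambda / m)."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        lam = np.where(lam > 0, lam, 0.0)
    k_si = gamma * lam * KCAL_PER_MOL_A2_TO_N_PER_M  # N/m
    m_si = node_mass * DALTON_TO_KG
    omega = np.sqrt(k_si / m_si)  # rad/s
    return omega / (2.0 * np.pi) / 1e9


def mode_table(
    wt_modes: dict[str, ModeSet] | dict[str, Sequence[float]],
    mut_modes: dict[str, ModeSet] | dict[str, Sequence[float]],
    modes: Sequence[int] = (1, 2, 3),
) -> dict:
    """Per-parameterization and averaged mode-frequency comparison.

    ``wt_modes``/``mut_modes`` map a parameterization label to either a
    :class:`ModeSet` or a pre-computed frequency list (GHz, mode 1 first).
    Averages are arithmetic means across labels; differences mutant − WT
    are reported in MHz.
    """

    def freq(entry, mode_index: int) -> float:
        if isinstance(entry, ModeSet):
            return float(entry.frequencies_ghz[mode_index - 1])
        return float(entry[mode_index - 1])

    labels = sorted(wt_modes)
    if sorted(mut_modes) != labels:
        raise ValueError("WT and mutant parameterization labels differ")
    table: dict = {"labels": labels, "modes": {}}
    for m in modes:
        wt_vals = {lab: freq(wt_modes[lab], m) for lab in labels}
        mut_vals = {lab: freq(mut_modes[lab], m) for lab in labels}
        wt_avg = float(np.mean(list(wt_vals.values())))
        mut_avg = float(np.mean(list(mut_vals.values())))
        table["modes"][m] = {
            "wt": wt_vals,
            "mutant": mut_vals,
            "wt_average_ghz": wt_avg,
            "mutant_average_ghz": mut_avg,
            "difference_mhz": (mut_avg - wt_avg) * 1000.0,
        }
    return table


def write_nmd(
    modeset: ModeSet,
    coords: np.ndarray,
    path: str | Path,
    name: str = "mutsmith_anm",
    n_modes: int = 3,
) -> Path:
    """Export vibrational modes in NMD format for viewers."""
    path = Path(path)
    lines = [f"name {name}", "coordinates " + " ".join(f"{x:.3f}" for x in np.asarray(coords).ravel())]
    start = modeset.n_zero_modes
    for k in range(start, min(start + n_modes, modeset.eigenvectors.shape[1])):
        vec = modeset.eigenvectors[:, k]
        lines.append(
            f"mode {k - start + 1} {modeset.eigenvalues[k]:.6e} "
            + " ".join(f"{v:.4f}" for v in vec)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
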