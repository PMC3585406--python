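"""Solvent-accessible surface area (Shrake–Rupley) and surface classification.

Accessibility is computed by rolling a probe sphere (default 1.4 Å) over
atom-centered spheres sampled with a Fibonacci point lattice. Relative SASA
divides a residue's area by its Gly-X-Gly maximum; residues at or above the
relative-SASA threshold (default 0.25) are classified as surface-exposed.
"""

from __future__ import annotations

import numpy as np

from mutsmith.params import MAX_SASA
from mutsmith.structure import MolecularStructure

__all__ = ["sphere_points", "atom_sasa", "residue_exposure"]


def sphere_points(n: int) -> np.ndarray:
    """Near-uniform unit-sphere points via the Fibonacci (golden-angle) lattice."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _local_frame(directions: np.ndarray) -> np.ndarray:
    """Deterministic rotation matrix from an atom's occluder directions.

    Test-point sampling is not rotation-invariant, so each atom's lattice is
    oriented by the principal axes of its occluders' unit directions
    (second moments; signs fixed by the first moment). The frame co-rotates
    with any rigid motion of the neighborhood, making per-atom areas
    orientation-independent, and it depends only on the *local* geometry, so
    areas of well-separated components are exactly additive.
    """
    M = directions.T @ directions
    s = directions.sum(axis=0)
    _, vecs = np.linalg.eigh(M)
    vecs = vecs[:, ::-1]  # descending moment
    for k in range(2):
        proj = float(s @ vecs[:, k])
        if abs(proj) > 1e-9:
            if proj < 0:
                vecs[:, k] = -vecs[:, k]
        elif vecs[np.argmax(np.abs(vecs[:, k])), k] < 0:
            vecs[:, k] = -vecs[:, k]
    vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])
    return vecs


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (Å²) by Shrake–Rupley test-point counting."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    pts = sphere_points(n_points)
    expanded = radii + probe
    out = np.zeros(n)
    if n == 0:
        return out
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    for i in range(n):
        # neighbors whose expanded spheres can occlude atom i's surface
        cut = (expanded[i] + expanded) ** 2
        nbr = np.nonzero((d2[i] < cut) & (np.arange(n) != i))[0]
        if len(nbr):
            offsets = coords[nbr] - coords[i]
            frame = _local_frame(offsets / np.linalg.norm(offsets, axis=1, keepdims=True))
            surf = coords[i] + expanded[i] * (pts @ frame.T)
            occluded = np.zeros(n_points, dtype=bool)
            for j in nbr:
                occluded |= (
                    np.sum((surf - coords[j]) ** 2, axis=-1) < expanded[j] ** 2
                )
            frac = 1.0 - occluded.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return out


def residue_exposure(
    structure: MolecularStructure,
    probe: float = 1.4,
    n_points: int = 960,
    rsasa_threshold: float = 0.25,
) -> dict[tuple[str, int], dict]:
    """Per-residue SASA, relative SASA, and surface classification.

    Returns ``{(chain, residue number): {sasa, rsasa, surface, name}}``.
    Residues without a Gly-X-Gly reference area get ``rsasa=None`` and are
    classified by absolute area (> 30 Å²).
    """
    flat = list(structure.atoms())
    coords = np.array([a.coords for _, _, a in flat])
    radii = np.array([a.vdw_radius for _, _, a in flat])
    areas = atom_sasa(coords, radii, probe=probe, n_points=n_points)
    out: dict[tuple[str, int], dict] = {}
    for (cid, res, _), area in zip(flat, areas):
        rec = out.setdefault(
            (cid, res.number), {"sasa": 0.0, "rsasa": None, "surface": False, "name": res.name}
        )
        rec["sasa"] += float(area)
    for key, rec in out.items():
        ref = MAX_SASA.get(rec["name"])
        if ref:
            rec["rsasa"] = rec["sasa"] / ref
            rec["surface"] = rec["rsasa"] >= rsasa_threshold
        else:
            rec["surface"] = rec["sasa"] > 30.0
    return out
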