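"""Synthetic-data generators: homolog-style MSAs, toy structures, fixtures.

Every pipeline stage is testable at desk scale without downloads:

* :func:`synth_msa` samples a homolog alignment whose per-column residue
  distributions match a specification (by default the published 500-sequence
  profiles at the four engineered sites, plus constructed profiles at the
  other candidate sites and strongly conserved background columns), with one
  statistically coupled column pair generated by a comonotone coupling of
  the two marginal distributions;
* :func:`toy_structure` builds ideal helices, two-domain toy dimers with a
  configurable cleft, charged spheres and C-alpha spring chains carrying
  exact parameters for analytic tests;
* :func:`fixture_bundle` returns paths to the bundled reference-value files
  (site profiles, energy and mode-frequency records, pKa tables) used by
  the bookkeeping stages.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from mutsmith.alignment import SequenceAlignment
from mutsmith.geometry import place_atom
from mutsmith.params import AA_1TO3, GAP, partial_charge, vdw_radius
from mutsmith.structure import Atom, MolecularStructure, Residue

__all__ = [
    "MsaSpec",
    "default_msa_spec",
    "synth_msa",
    "default_pair_alignment",
    "toy_structure",
    "fixture_bundle",
    "load_fixture",
]

# ---------------------------------------------------------------------------
# MSA generation
# ---------------------------------------------------------------------------

REFERENCE_ID = "acceptor_ref"

# candidate-site column distributions for the default homolog-style MSA:
# the four engineered sites use the published 500-sequence profiles
# ('X' = unlisted residues); the rest are constructed so that the selection
# cascade exercises every rule (low target frequency, gap-dominated column).
DEFAULT_COLUMNS: dict[int, dict[str, float]] = {
    149: {"N": 0.50, "S": 0.30, "D": 0.15, GAP: 0.05},
    160: {"N": 0.55, "V": 0.30, "S": 0.12, GAP: 0.03},
    165: {"D": 0.856, "S": 0.114, "N": 0.020, "Y": 0.002, GAP: 0.008},
    175: {"E": 0.760, "L": 0.206, "T": 0.008, "I": 0.008, GAP: 0.004, "X": 0.014},
    178: {"Q": 0.406, "H": 0.334, "T": 0.228, "D": 0.020, GAP: 0.004, "X": 0.008},
    206: {"R": 0.772, "C": 0.090, "Y": 0.076, "W": 0.022, GAP: 0.002, "X": 0.038},
    223: {GAP: 0.70, "Q": 0.20, "E": 0.10},
    224: {"M": 0.50, "L": 0.40, "I": 0.08, GAP: 0.02},
    347: {"C": 0.55, "F": 0.35, "Y": 0.08, GAP: 0.02},
}

# acceptor (reference) residues at the candidate sites
DEFAULT_REFERENCE = {149: "N", 160: "N", 165: "S", 175: "L", 178: "T", 206: "C", 223: "Q", 224: "M", 347: "C"}

# donor residues transferred at those sites
DEFAULT_DONOR = {149: "S", 160: "V", 165: "D", 175: "E", 178: "H", 206: "R", 223: "E", 224: "L", 347: "F"}

# buried decoys exercising the surface filter
BURIED_SITES = {170: ("A", "V"), 200: ("I", "L")}


@dataclass
class MsaSpec:
    """Specification of a synthetic homolog alignment."""

    n_sequences: int = 500
    start: int = 140
    n_columns: int = 221  # sites start .. start + n_columns - 1
    reference_id: str = REFERENCE_ID
    column_distributions: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COLUMNS.items()}
    )
    reference_residues: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_REFERENCE))
    coupled_pair: tuple[int, int] = (175, 178)
    coupled_joint: dict[tuple[str, str], float] | None = None  # None = comonotone
    background_conservation: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for site, dist in self.column_distributions.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"site {site}: probabilities sum to {total}, not 1")
        a, b = self.coupled_pair
        if self.coupled_joint is not None:
            for site, axis in ((a, 0), (b, 1)):
                marg: dict[str, float] = {}
                for pair, p in self.coupled_joint.items():
                    marg[pair[axis]] = marg.get(pair[axis], 0.0) + p
                for res, p in self.column_distributions[site].items():
                    if abs(marg.get(res, 0.0) - p) > 1e-6:
                        raise ValueError(
                            f"coupled joint marginal at site {site} inconsistent for {res!r}"
                        )

    @property
    def sites(self) -> range:
        return range(self.start, self.start + self.n_columns)


def default_msa_spec(seed: int = 0, n_sequences: int = 500) -> MsaSpec:
    return MsaSpec(seed=seed, n_sequences=n_sequences)


def _comonotone_joint(
    pa: dict[str, float], pb: dict[str, float]
) -> dict[tuple[str, str], float]:
    """Maximal-association coupling with the given marginals.

    Categories are stacked on [0, 1) in descending-probability order and the
    overlaps of the two partitions give the joint masses (comonotone
    coupling); the result is strongly dependent yet marginal-consistent.
    """
    order_a = sorted(pa, key=lambda r: (-pa[r], r))
    order_b = sorted(pb, key=lambda r: (-pb[r], r))
    joint: dict[tuple[str, str], float] = {}
    ia = ib = 0
    rem_a, rem_b = pa[order_a[0]], pb[order_b[0]]
    while ia < len(order_a) and ib < len(order_b):
        mass = min(rem_a, rem_b)
        if mass > 0:
            joint[(order_a[ia], order_b[ib])] = joint.get((order_a[ia], order_b[ib]), 0.0) + mass
        rem_a -= mass
        rem_b -= mass
        if rem_a <= 1e-12:
            ia += 1
            rem_a = pa[order_a[ia]] if ia < len(order_a) else 0.0
        if rem_b <= 1e-12:
            ib += 1
            rem_b = pb[order_b[ib]] if ib < len(order_b) else 0.0
    return joint


def synth_msa(spec: MsaSpec) -> SequenceAlignment:
    """Sample a homolog-style alignment; reproducible given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_cols = spec.n_columns
    n_seq = spec.n_sequences
    sites = list(spec.sites)

    # reference residues for background columns are drawn once, deterministically
    aa_pool = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    columns = np.empty((n_cols, n_seq), dtype="U1")
    reference = []
    site_a, site_b = spec.coupled_pair
    joint = spec.coupled_joint or _comonotone_joint(
        spec.column_distributions[site_a], spec.column_distributions[site_b]
    )
    pairs = sorted(joint)
    pair_probs = np.array([joint[p] for p in pairs])
    pair_probs = pair_probs / pair_probs.sum()
    pair_draw = rng.choice(len(pairs), size=n_seq - 1, p=pair_probs)

    for c, site in enumerate(sites):
        if site in spec.column_distributions:
            ref_res = spec.reference_residues.get(site)
            if site in (site_a, site_b):
                axis = 0 if site == site_a else 1
                sampled = np.array([pairs[k][axis] for k in pair_draw])
            else:
                dist = spec.column_distributions[site]
                res = sorted(dist)
                p = np.array([dist[r] for r in res])
                sampled = rng.choice(res, size=n_seq - 1, p=p / p.sum())
        else:
            ref_res = str(rng.choice(aa_pool))
            others = aa_pool[aa_pool != ref_res]
            p_other = (1.0 - spec.background_conservation) / len(others)
            res = [ref_res] + list(others)
            p = np.array([spec.background_conservation] + [p_other] * len(others))
            sampled = rng.choice(res, size=n_seq - 1, p=p / p.sum())
        if ref_res is None:
            ref_res = max(
                spec.column_distributions[site], key=lambda r: spec.column_distributions[site][r]
            )
        columns[c, 0] = ref_res
        columns[c, 1:] = sampled
        reference.append(ref_res)

    records = [(spec.reference_id, "".join(reference))]
    for s in range(1, n_seq):
        records.append((f"homolog_{s:04d}", "".join(columns[:, s])))
    return SequenceAlignment(records)


def default_pair_alignment(
    spec: MsaSpec | None = None,
    donor_id: str = "donor_thermophile",
) -> tuple[SequenceAlignment, dict[int, bool]]:
    """Donor/acceptor two-sequence alignment plus surface-exposure booleans.

    The acceptor sequence equals the homolog-MSA reference; the donor
    differs at the candidate sites and at two buried decoy sites used to
    exercise the surface filter.
    """
    spec = spec or default_msa_spec()
    msa = synth_msa(spec)
    acceptor = msa.sequence(spec.reference_id)
    donor = list(acceptor)
    surface: dict[int, bool] = {}
    for site, res in DEFAULT_DONOR.items():
        donor[site - spec.start] = res
        surface[site] = True
    for site, (acc_res, don_res) in BURIED_SITES.items():
        acceptor_list = list(acceptor)
        acceptor_list[site - spec.start] = acc_res
        acceptor = "".join(acceptor_list)
        donor[site - spec.start] = don_res
        surface[site] = False
    pair = SequenceAlignment([(spec.reference_id, acceptor), (donor_id, "".join(donor))])
    return pair, surface


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

def _backbone_helix(
    n_residues: int,
    sequence: str | None = None,
    chain: str = "A",
    phi: float = -57.0,
    psi: float = -47.0,
) -> MolecularStructure:
    """Ideal alpha-helix backbone (N, CA, C, O + CB) built by chain extension."""
    seq = sequence or "A" * n_residues
    if len(seq) != n_residues:
        raise ValueError("sequence length mismatch")
    omega = 180.0
    # seed atoms of residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    c0 = place_atom(np.array([-0.5, 1.0, 0.0]), n0, ca0, 1.525, 111.0, -60.0)
    positions = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_residues):
        prev = positions[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi)
        ca = place_atom(prev["CA"], prev["C"], n, 1.458, 121.7, omega)
        c = place_atom(prev["C"], n, ca, 1.525, 111.0, phi)
        positions.append({"N": n, "CA": ca, "C": c})
    residues = []
    for i, pos in enumerate(positions):
        res_name = AA_1TO3[seq[i]]
        # the uncapped N-terminus stays neutral (no amide H, no N charge),
        # so every residue — and hence each toy chain — carries zero net charge
        n_charge = partial_charge(res_name, "N") if i > 0 else 0.0
        atoms = [
            Atom("N", "N", pos["N"], vdw_radius("N"), n_charge),
            Atom("CA", "C", pos["CA"], vdw_radius("C"), 0.0),
            Atom("C", "C", pos["C"], vdw_radius("C"), partial_charge(res_name, "C")),
        ]
        if i > 0:
            prev_c = positions[i - 1]["C"]
            u = pos["N"] - pos["CA"]
            v = pos["N"] - prev_c
            direction = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            direction /= np.linalg.norm(direction)
            atoms.append(
                Atom("H", "H", pos["N"] + 1.01 * direction, vdw_radius("H"),
                     partial_charge(res_name, "H"))
            )
        # carbonyl O in the peptide plane (trans to the next N when present)
        if i + 1 < len(positions):
            o = place_atom(positions[i + 1]["N"], pos["CA"], pos["C"], 1.231, 120.8, 180.0)
        else:
            o = place_atom(pos["N"], pos["CA"], pos["C"], 1.231, 120.8, 0.0)
        atoms.append(Atom("O", "O", o, vdw_radius("O"), partial_charge(res_name, "O")))
        if seq[i] != "G":
            cb = place_atom(pos["N"], pos["C"], pos["CA"], 1.53, 110.5, 122.5)
            atoms.append(Atom("CB", "C", cb, vdw_radius("C"), 0.0))
        residues.append(Residue(name=res_name, number=i + 1, atoms=atoms))
    return MolecularStructure(chains={chain: residues})


def toy_structure(kind: str, seed: int = 0, **kwargs) -> MolecularStructure:
    """Build a toy structure: helix | two_domain_dimer | charged_sphere | spring_chain."""
    if kind == "helix":
        return _backbone_helix(
            kwargs.get("n_residues", 10),
            sequence=kwargs.get("sequence"),
            chain=kwargs.get("chain", "A"),
        )
    if kind == "spring_chain":
        n = kwargs.get("n_nodes", 10)
        spacing = kwargs.get("spacing", 3.8)
        residues = [
            Residue(
                name="GLY",
                number=i + 1,
                atoms=[Atom("CA", "C", np.array([i * spacing, 0.0, 0.0]), vdw_radius("C"))],
            )
            for i in range(n)
        ]
        return MolecularStructure(chains={kwargs.get("chain", "A"): residues})
    if kind == "charged_sphere":
        q = kwargs.get("charge", 1.0)
        a = kwargs.get("radius", 2.0)
        center = np.asarray(kwargs.get("center", (0.0, 0.0, 0.0)), dtype=float)
        res = Residue(name="SPH", number=1, atoms=[Atom("Q", "C", center, a, q)])
        return MolecularStructure(chains={kwargs.get("chain", "A"): [res]})
    if kind == "two_domain_dimer":
        cleft = kwargs.get("cleft", 12.0)
        n_res = kwargs.get("n_residues", 8)
        charges = kwargs.get("charges", {})  # (chain, resnum) -> charge on CA
        left = _backbone_helix(n_res, chain="C")
        right = _backbone_helix(n_res, chain="D")
        # rigid translate chain D along +x until the minimum inter-domain
        # CA-CA distance equals the requested cleft width
        ca_left = np.array([r.atom("CA").coords for r in left.chains["C"]])
        shift = np.array([1.0, 0.0, 0.0])
        offset = cleft + 30.0
        for _ in range(20):
            ca_right = np.array(
                [r.atom("CA").coords + offset * shift for r in right.chains["D"]]
            )
            dmin = np.min(
                np.linalg.norm(ca_left[:, None, :] - ca_right[None, :, :], axis=-1)
            )
            if abs(dmin - cleft) < 1e-6:
                break
            offset += cleft - dmin
        dimer = MolecularStructure(chains={"C": left.chains["C"], "D": right.chains["D"]})
        for res in dimer.chains["D"]:
            for atom in res.atoms:
                atom.coords = atom.coords + offset * shift
        for (chain, number), q in charges.items():
            dimer.residue(chain, number).atom("CA").partial_charge = q
        return dimer
    raise ValueError(
        f"unknown toy structure kind {kind!r}; "
        "available: helix, two_domain_dimer, charged_sphere, spring_chain"
    )


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

_FIXTURES = {
    "homolog_site_profiles": "homolog_site_profiles.json",
    "folding_energy_records": "folding_energy_records.json",
    "binding_energy_records": "binding_energy_records.json",
    "mode_frequency_records": "mode_frequency_records.json",
    "pka_records": "pka_records.json",
}


def fixture_bundle(names: str | list[str]) -> dict[str, Path]:
    """Paths to bundled read-only fixtures by name."""
    if isinstance(names, str):
        names = [names]
    out = {}
    for name in names:
        if name not in _FIXTURES:
            raise KeyError(
                f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
            )
        out[name] = Path(str(resources.files("mutsmith.data") / _FIXTURES[name]))
    return out


def load_fixture(name: str) -> dict:
    """Parsed JSON content of a bundled fixture."""
    return json.loads(fixture_bundle(name)[name].read_text())
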