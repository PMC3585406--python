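"""Folding/binding free-energy-change bookkeeping.

Folding stability change uses the folded-state energy minus a three-residue
segment as the unfolded-state proxy; the remainder of the unfolded-state
energy is mutation-independent and cancels, so it is never evaluated:

    dG(folding)  = G(folded) - [G0(unfolded) + sum G3(segments)]
    ddG          = dG(folding, WT) - dG(folding, mutant)
                 = [G(folded,WT) - sum G3(WT segments)]
                 - [G(folded,mut) - sum G3(mut segments)]

Positive ddG means the mutant monomer sits lower in energy relative to its
unfolded reference, i.e. the mutation stabilizes the monomer.

Binding affinity change compares dimer and monomer energies:

    ddG(binding)  = G(dimer) - G(C) - G(D)
    dddG          = ddG(binding, WT) - ddG(binding, mutant)

so positive dddG means the mutation increases dimer affinity.

Per-parameterization values are averaged across parameterizations and
across the two monomers, mirroring a multi-force-field protocol; a
two-parameter affine adjustment calibrates raw predictions against
experimentally anchored pairs. Additivity of single-site effects and a
neutral-band classification for binding changes complete the bookkeeping.
An externally supplied pKa table can be differenced to report
mutation-induced pKa shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Mapping, Sequence

import numpy as np

from mutsmith.energy import (
    DEFAULT_PARAMETERIZATIONS,
    EnergyModel,
    EnergyParams,
    minimize_structure,
    total_energy,
)
from mutsmith.structure import MolecularStructure, MutationSpec, tripeptide_segment

__all__ = [
    "FoldingDdG",
    "BindingDdG",
    "AdjustmentModel",
    "folding_ddg",
    "binding_ddg",
    "aggregate",
    "fit_adjustment",
    "additivity_check",
    "classify_binding_effect",
    "pka_shift_table",
]


@dataclass
class FoldingDdG:
    """Per-parameterization / per-monomer folding stability changes."""

    values: dict[tuple[str, str], float]  # (parameterization, monomer) -> ddG
    adjusted: float | None = None

    @property
    def per_monomer_average(self) -> dict[str, float]:
        monomers = sorted({m for _, m in self.values})
        return {
            m: fmean(v for (p, mm), v in self.values.items() if mm == m) for m in monomers
        }

    @property
    def average(self) -> float:
        return fmean(self.per_monomer_average.values())


@dataclass
class BindingDdG:
    """Per-parameterization binding-affinity change (WT vs mutant)."""

    wt: dict[str, float]  # parameterization -> ddG(binding, WT)
    mutant: dict[str, float]

    @property
    def difference(self) -> dict[str, float]:
        """dddG per parameterization; positive = increased dimer affinity."""
        return {p: self.wt[p] - self.mutant[p] for p in self.wt}

    @property
    def average(self) -> float:
        return fmean(self.difference.values())


@dataclass
class AdjustmentModel:
    """Affine (two-parameter) calibration of raw predictions."""

    slope: float
    intercept: float

    def apply(self, raw: float) -> float:
        return self.slope * raw + self.intercept


def _folded_minus_segments(
    structure: MolecularStructure,
    sites: Sequence[tuple[str, int]],
    params: EnergyParams,
    minimize: bool,
) -> dict[str, float]:
    """Per-chain G(folded) - sum G3(segments) for the chains in ``sites``."""
    if minimize:
        structure, _ = minimize_structure(structure, params)
    out: dict[str, float] = {}
    for chain in sorted({c for c, _ in sites}):
        chain_only = MolecularStructure(chains={chain: structure.chains[chain]})
        g_folded = total_energy(chain_only, params).total
        g3 = 0.0
        for c, site in sites:
            if c != chain:
                continue
            segment, _ = tripeptide_segment(structure, c, site)
            g3 += total_energy(segment, params).total
        out[chain] = g_folded - g3
    return out


def folding_ddg(
    wt_structure: MolecularStructure,
    mut_structure: MolecularStructure,
    specs: Sequence[MutationSpec],
    params_list: Sequence[EnergyParams] = DEFAULT_PARAMETERIZATIONS,
    minimize: bool = True,
) -> FoldingDdG:
    """Mutation-induced monomer stability change per parameterization and
    per monomer. Positive = mutant more stable."""
    if not specs:
        raise ValueError("no mutated sites given")
    sites = [(s.chain, s.site) for s in specs]
    values: dict[tuple[str, str], float] = {}
    for params in params_list:
        wt_terms = _folded_minus_segments(wt_structure, sites, params, minimize)
        mut_terms = _folded_minus_segments(mut_structure, sites, params, minimize)
        for chain in wt_terms:
            values[(params.name, chain)] = wt_terms[chain] - mut_terms[chain]
    return FoldingDdG(values=values)


def _binding_energy(
    dimer: MolecularStructure,
    chains: tuple[str, str],
    params: EnergyParams,
    minimize: bool,
    reminimize_monomers: bool,
) -> float:
    if minimize:
        dimer, _ = minimize_structure(dimer, params)
    g_dimer = total_energy(dimer, params).total
    g_mono = 0.0
    for chain in chains:
        mono = MolecularStructure(chains={chain: dimer.chains[chain]})
        if reminimize_monomers:
            mono, _ = minimize_structure(mono, params)
        g_mono += total_energy(mono, params).total
    return g_dimer - g_mono


def binding_ddg(
    wt_dimer: MolecularStructure,
    mut_dimer: MolecularStructure,
    chains: tuple[str, str] = ("C", "D"),
    params_list: Sequence[EnergyParams] = DEFAULT_PARAMETERIZATIONS,
    minimize: bool = True,
    reminimize_monomers: bool = False,
) -> BindingDdG:
    """Dimer-affinity change per parameterization.

    Monomers are the dimer's chains, either rigidly extracted (default) or
    independently re-minimized (``reminimize_monomers=True``).
    """
    wt = {
        p.name: _binding_energy(wt_dimer, chains, p, minimize, reminimize_monomers)
        for p in params_list
    }
    mut = {
        p.name: _binding_energy(mut_dimer, chains, p, minimize, reminimize_monomers)
        for p in params_list
    }
    return BindingDdG(wt=wt, mutant=mut)


def aggregate(records: Mapping[tuple[str, str], float]) -> dict:
    """Average a (parameterization, monomer) grid of energies.

    Returns per-monomer parameterization averages ('ave_parameterizations')
    and their mean over monomers ('ave_monomers'), the layout used by the
    result tables.
    """
    params = sorted({p for p, _ in records})
    monomers = sorted({m for _, m in records})
    for p in params:
        for m in monomers:
            if (p, m) not in records:
                raise KeyError(f"incomplete grid: missing ({p}, {m})")
    per_monomer = {m: fmean(records[(p, m)] for p in params) for m in monomers}
    return {
        "ave_parameterizations": per_monomer,
        "ave_monomers": fmean(per_monomer.values()),
    }


def fit_adjustment(pairs: Sequence[tuple[float, float]]) -> AdjustmentModel:
    """Least-squares affine fit of (raw, adjusted) calibration pairs."""
    if len(pairs) < 2:
        raise ValueError("need at least two calibration pairs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.allclose(x, x[0]):
        raise ValueError("calibration pairs are degenerate in the raw value")
    slope, intercept = np.polyfit(x, y, 1)
    return AdjustmentModel(slope=float(slope), intercept=float(intercept))


def additivity_check(
    single_mutant_ddgs: Sequence[float],
    combined_ddg: float,
    tolerance: float = 0.05,
) -> dict:
    """Compare the sum of single-site effects with the combined mutant.

    ``tolerance`` is relative (fraction of the combined effect); the verdict
    is 'additive' when the relative deviation stays within it.
    """
    total = float(sum(single_mutant_ddgs))
    abs_dev = abs(total - combined_ddg)
    denom = max(abs(combined_ddg), 1e-12)
    rel_dev = abs_dev / denom
    return {
        "sum": total,
        "combined": float(combined_ddg),
        "abs_deviation": abs_dev,
        "rel_deviation": rel_dev,
        "verdict": "additive" if rel_dev <= tolerance else "non-additive",
    }


def classify_binding_effect(ddd: float, neutral_band: float = 2.0) -> str:
    """'increase' / 'decrease' / 'no-effect' with a neutral band (kcal/mol)."""
    if abs(ddd) < neutral_band:
        return "no-effect"
    return "increase" if ddd > 0 else "decrease"


def pka_shift_table(
    wt: Mapping[str, float], mut: Mapping[str, float]
) -> dict[str, object]:
    """Per-residue pKa shift mutant − WT from externally supplied tables.

    Residues present in only one table are reported as absent, never as a
    zero shift.
    """
    for table in (wt, mut):
        for res, value in table.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite pKa for {res}")
    common = sorted(set(wt) & set(mut))
    return {
        "shifts": {res: float(mut[res]) - float(wt[res]) for res in common},
        "missing_in_mutant": sorted(set(wt) - set(mut)),
        "missing_in_wt": sorted(set(mut) - set(wt)),
    }
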