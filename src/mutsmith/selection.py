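"""The candidate-selection cascade for donor→acceptor mutation transfer.

Starting from a two-sequence donor/acceptor alignment, candidate sites are
the aligned, non-gap columns where the two sequences differ. The cascade then

1. keeps surface-exposed sites (exposure booleans supplied by the structure
   stage),
2. keeps sites that are *not* conserved in the homolog MSA (modal frequency
   below a threshold), flagging non-conserved sites that neighbor
   well-conserved ones as preferred,
3. drops sites on a manual exclusion list (e.g. proximity to an active site
   or to known disease positions),
4. applies the frequency rule: the donor residue must appear in at least 50%
   of the homolog MSA (gaps counted in the denominator),
5. adds back sites statistically coupled to a surviving site (coevolving
   partner rescue).

The final list is ordered by site number. Every stage is recorded in a
:class:`SelectionReport` so the narrowing of the candidate list is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from mutsmith.alignment import (
    ColumnProfile,
    SequenceAlignment,
    align_to_reference,
    column_profiles,
    correlated_pairs,
)
from mutsmith.params import GAP

__all__ = [
    "CandidateSite",
    "SelectionReport",
    "pairwise_candidates",
    "conservation_context",
    "frequency_rule",
    "finalize_selection",
    "select_mutations",
]


@dataclass
class CandidateSite:
    """One candidate donor→acceptor substitution at a reference site."""

    site: int
    wt_residue: str
    target_residue: str
    differs: bool = True
    surface: bool | None = None
    non_conserved: bool | None = None
    near_conserved: bool | None = None
    freq_pass: bool | None = None
    partner_site: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.differs and self.wt_residue == self.target_residue:
            raise ValueError(f"site {self.site}: differing candidate with identical residues")
        if self.partner_site == self.site:
            raise ValueError(f"site {self.site}: partner_site equals site")

    @property
    def label(self) -> str:
        return f"{self.wt_residue}{self.site}{self.target_residue}"


@dataclass
class SelectionReport:
    """Stage-by-stage record of the selection cascade."""

    stages: list[tuple[str, list[int]]] = field(default_factory=list)
    final: list[CandidateSite] = field(default_factory=list)

    def record(self, stage: str, sites: Sequence[int]) -> None:
        self.stages.append((stage, sorted(sites)))

    def stage_sites(self, stage: str) -> list[int]:
        for name, sites in self.stages:
            if name == stage:
                return sites
        raise KeyError(f"unknown stage {stage!r}")

    def to_dict(self) -> dict:
        return {
            "stages": [{"stage": s, "sites": sites, "count": len(sites)} for s, sites in self.stages],
            "final": [
                {
                    "site": c.site,
                    "wt": c.wt_residue,
                    "target": c.target_residue,
                    "label": c.label,
                    "surface": c.surface,
                    "non_conserved": c.non_conserved,
                    "near_conserved": c.near_conserved,
                    "freq_pass": c.freq_pass,
                    "partner_site": c.partner_site,
                    "score": c.score,
                }
                for c in self.final
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        lines = ["stage\tsite\twt\ttarget\tflags\tscore"]
        for stage, sites in self.stages:
            lines.append(f"{stage}\t{','.join(map(str, sites))}\t\t\t\t")
        for c in self.final:
            flags = ";".join(
                f"{k}={getattr(c, k)}"
                for k in ("surface", "non_conserved", "near_conserved", "freq_pass")
                if getattr(c, k) is not None
            )
            score = "" if c.score is None else f"{c.score:.4f}"
            lines.append(f"final\t{c.site}\t{c.wt_residue}\t{c.target_residue}\t{flags}\t{score}")
        Path(path).write_text("\n".join(lines) + "\n")


def pairwise_candidates(
    acceptor_id: str,
    donor_id: str,
    pair_alignment: SequenceAlignment,
    start: int = 1,
) -> list[CandidateSite]:
    """Candidate substitutions from a two-sequence donor/acceptor alignment.

    One candidate per aligned, non-gap, differing column, numbered in
    acceptor (reference) coordinates. Conserved columns and columns gapped
    in either sequence are excluded.
    """
    if pair_alignment.n_sequences != 2:
        raise ValueError("pair alignment must contain exactly two sequences")
    acc = pair_alignment.sequence(acceptor_id)
    don = pair_alignment.sequence(donor_id)
    col_to_site = align_to_reference(pair_alignment, acceptor_id, start)
    out = []
    for col, site in col_to_site.items():
        a, d = acc[col], don[col]
        if d == GAP or a == d:
            continue
        out.append(CandidateSite(site=site, wt_residue=a, target_residue=d))
    out.sort(key=lambda c: c.site)
    return out


def conservation_context(
    candidates: Sequence[CandidateSite],
    profiles: Mapping[int, ColumnProfile],
    conservation_threshold: float = 0.9,
    window: int = 2,
    drop_conserved: bool = True,
) -> list[CandidateSite]:
    """Flag candidates by MSA conservation of their column and neighborhood.

    ``non_conserved`` is true when the column's modal-residue frequency is
    below ``conservation_threshold``; such sites are retained (conserved ones
    dropped when ``drop_conserved``). ``near_conserved`` marks non-conserved
    sites with a conserved column within ±``window`` — a ranking preference,
    not a filter.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    kept = []
    for cand in candidates:
        if cand.site not in profiles:
            raise KeyError(f"no profile for candidate site {cand.site}")
        prof = profiles[cand.site]
        cand.non_conserved = prof.modal_frequency < conservation_threshold
        neighbors = [
            profiles[s]
            for s in range(cand.site - window, cand.site + window + 1)
            if s != cand.site and s in profiles
        ]
        cand.near_conserved = any(
            p.modal_frequency >= conservation_threshold for p in neighbors
        )
        if cand.non_conserved or not drop_conserved:
            kept.append(cand)
    return kept


def frequency_rule(
    candidates: Sequence[CandidateSite],
    profiles: Mapping[int, ColumnProfile],
    threshold: float = 0.50,
) -> list[CandidateSite]:
    """Keep candidates whose target residue reaches ``threshold`` frequency
    in the homolog MSA.

    The rule deletes candidates appearing in strictly *less* than the
    threshold fraction, so an exact-boundary frequency survives. The
    denominator includes gapped sequences.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    survivors = []
    for cand in candidates:
        prof = profiles[cand.site]
        cand.freq_pass = prof.frequency(cand.target_residue) >= threshold
        if cand.freq_pass:
            survivors.append(cand)
    return survivors


def finalize_selection(
    survivors: Sequence[CandidateSite],
    all_candidates: Sequence[CandidateSite],
    pairs: Mapping[int, Sequence[tuple[int, float]]],
    report: SelectionReport | None = None,
) -> SelectionReport:
    """Union of frequency survivors and their correlated partners.

    ``pairs`` maps a surviving anchor site to its detected coevolving
    partners. Partners are looked up among ``all_candidates`` (a partner may
    have failed the frequency rule — that is the point of the rescue). The
    final list is deduplicated and ordered by site number.
    """
    report = report or SelectionReport()
    by_site = {c.site: c for c in all_candidates}
    final: dict[int, CandidateSite] = {c.site: c for c in survivors}
    for anchor, partner_list in pairs.items():
        for partner, score in partner_list:
            if partner in final or partner not in by_site:
                continue
            cand = by_site[partner]
            cand.partner_site = anchor
            cand.score = score
            final[partner] = cand
    report.final = [final[s] for s in sorted(final)]
    report.record("final", list(final))
    return report


def select_mutations(
    pair_alignment: SequenceAlignment,
    homolog_msa: SequenceAlignment,
    acceptor_id: str,
    donor_id: str,
    msa_reference_id: str,
    start: int = 1,
    surface: Mapping[int, bool] | None = None,
    exclude: Sequence[int] = (),
    conservation_threshold: float = 0.9,
    window: int = 2,
    freq_threshold: float = 0.50,
    mi_threshold: float | None = None,
    seed: int = 0,
) -> SelectionReport:
    """Run the full selection cascade and return its report."""
    report = SelectionReport()

    candidates = pairwise_candidates(acceptor_id, donor_id, pair_alignment, start=start)
    report.record("pairwise_differences", [c.site for c in candidates])

    if surface is not None:
        for c in candidates:
            c.surface = surface.get(c.site, False)
        candidates = [c for c in candidates if c.surface]
        report.record("surface_exposed", [c.site for c in candidates])

    all_sites = sorted({s for c in candidates for s in range(c.site - window, c.site + window + 1)})
    mapped = set(align_to_reference(homolog_msa, msa_reference_id, start).values())
    profiles = {
        p.site: p
        for p in column_profiles(
            homolog_msa, [s for s in all_sites if s in mapped], msa_reference_id, start
        )
    }
    candidates = conservation_context(
        candidates, profiles, conservation_threshold=conservation_threshold, window=window
    )
    report.record("non_conserved", [c.site for c in candidates])

    candidates = [c for c in candidates if c.site not in set(exclude)]
    report.record("after_exclusions", [c.site for c in candidates])
    pre_frequency = list(candidates)

    survivors = frequency_rule(candidates, profiles, threshold=freq_threshold)
    report.record("frequency_rule", [c.site for c in survivors])

    partner_pool = [c.site for c in pre_frequency]
    pairs: dict[int, list[tuple[int, float]]] = {}
    survivor_sites = {c.site for c in survivors}
    for anchor in sorted(survivor_sites):
        others = [s for s in partner_pool if s != anchor and s not in survivor_sites]
        if not others:
            continue
        hits = correlated_pairs(
            homolog_msa,
            anchor,
            others,
            msa_reference_id,
            start=start,
            mi_threshold=mi_threshold,
            seed=seed,
        )
        if hits:
            pairs[anchor] = hits

    return finalize_selection(survivors, pre_frequency, pairs, report=report)
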