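"""Multiple-sequence-alignment containers, column statistics, and coevolution.

The selection protocol works on three alignment datasets: a two-sequence
donor/acceptor alignment, a cross-species alignment, and a large (~500
sequence) homolog alignment. This module holds the shared container plus the
column-level statistics that drive the selection cascade: reference-numbering
maps, per-column residue profiles (counts and percentages, gaps included),
and a mutual-information coevolution score with average-product correction
(APC) used to detect statistically coupled column pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

from mutsmith.params import ALPHABET21, GAP

__all__ = [
    "SequenceAlignment",
    "ColumnProfile",
    "align_to_reference",
    "column_profiles",
    "mutual_information",
    "apc_corrected_scores",
    "correlated_pairs",
]

MIN_RELIABLE_SEQUENCES = 30


@dataclass
class SequenceAlignment:
    """An aligned set of protein sequences (20 amino acids + gap)."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids are not unique")
        if self.n_columns < 1:
            raise ValueError("alignment has zero columns")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def sequence(self, record_id: str) -> str:
        for rid, seq in self.records:
            if rid == record_id:
                return seq
        raise KeyError(f"unknown sequence id: {record_id!r}")

    def column(self, index: int) -> str:
        if not 0 <= index < self.n_columns:
            raise IndexError(f"column {index} outside 0..{self.n_columns - 1}")
        return "".join(seq[index] for _, seq in self.records)

    @classmethod
    def read(cls, path: str | Path, fmt: str | None = None) -> "SequenceAlignment":
        """Read an aligned FASTA or Clustal file (format guessed by suffix)."""
        path = Path(path)
        if fmt is None:
            fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal", ".clw"} else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls([(rec.id, str(rec.seq).upper()) for rec in aln])

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.records:
                fh.write(f">{rid}\n{seq}\n")


@dataclass
class ColumnProfile:
    """Residue counts/frequencies of one alignment column (gaps included)."""

    site: int
    counts: dict[str, int]
    n_total: int = 0

    def __post_init__(self) -> None:
        if self.n_total == 0:
            self.n_total = sum(self.counts.values())
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative residue count")
        if sum(self.counts.values()) != self.n_total:
            raise ValueError("counts do not sum to n_total")

    def frequency(self, residue: str) -> float:
        """Fraction of sequences carrying ``residue``; denominator includes gaps."""
        return self.counts.get(residue, 0) / self.n_total

    def percentage(self, residue: str) -> float:
        return 100.0 * self.frequency(residue)

    @property
    def modal_residue(self) -> str:
        # deterministic tie-break: alphabetical among maxima
        best = max(self.counts.values())
        return min(r for r, c in self.counts.items() if c == best)

    @property
    def modal_frequency(self) -> float:
        return self.frequency(self.modal_residue)


def align_to_reference(
    alignment: SequenceAlignment, reference_id: str, start: int = 1
) -> dict[int, int]:
    """Map alignment column index -> reference residue number.

    Columns where the reference sequence has a gap are absent from the map.
    Numbering begins at ``start`` for the first non-gap reference position.
    """
    ref = alignment.sequence(reference_id)
    mapping: dict[int, int] = {}
    number = start
    for col, ch in enumerate(ref):
        if ch != GAP:
            mapping[col] = number
            number += 1
    return mapping


def column_profiles(
    alignment: SequenceAlignment,
    sites: Iterable[int],
    reference_id: str,
    start: int = 1,
) -> list[ColumnProfile]:
    """Per-column residue counts at the requested reference-numbered sites."""
    site_to_col = {v: k for k, v in align_to_reference(alignment, reference_id, start).items()}
    profiles = []
    for site in sites:
        if site not in site_to_col:
            raise KeyError(f"site {site} not resolvable in reference {reference_id!r}")
        col = alignment.column(site_to_col[site])
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        profiles.append(ColumnProfile(site=site, counts=counts, n_total=alignment.n_sequences))
    return profiles


def _column_indices(column: str) -> np.ndarray:
    lut = {ch: i for i, ch in enumerate(ALPHABET21)}
    # unknown characters (X etc.) are binned with the gap symbol
    return np.array([lut.get(ch, len(ALPHABET21) - 1) for ch in column])


def mutual_information(col_a: str, col_b: str) -> float:
    """MI of two aligned columns in nats; gap is a 21st symbol."""
    if len(col_a) != len(col_b):
        raise ValueError("columns have different depths")
    ia, ib = _column_indices(col_a), _column_indices(col_b)
    k = len(ALPHABET21)
    joint = np.zeros((k, k))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])))


def apc_corrected_scores(columns: Mapping[int, str]) -> dict[tuple[int, int], float]:
    """Average-product-corrected MI for every pair of the given columns.

    APC(a,b) = MI_mean(a) * MI_mean(b) / MI_mean(all); the corrected score is
    MI(a,b) - APC(a,b). Requires at least three columns for the correction to
    be meaningful; with exactly two, the raw MI is returned.
    """
    keys = sorted(columns)
    n = len(keys)
    if n < 2:
        raise ValueError("need at least two columns")
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi[i, j] = mi[j, i] = mutual_information(columns[keys[i]], columns[keys[j]])
    if n == 2:
        return {(keys[0], keys[1]): float(mi[0, 1])}
    row_mean = mi.sum(axis=1) / (n - 1)
    all_mean = mi.sum() / (n * (n - 1))
    out: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            apc = row_mean[i] * row_mean[j] / all_mean if all_mean > 0 else 0.0
            out[(keys[i], keys[j])] = float(mi[i, j] - apc)
    return out


def permutation_null_threshold(
    col_a: str,
    col_b: str,
    n_permutations: int = 200,
    n_sigma: float = 4.0,
    seed: int = 0,
) -> float:
    """MI threshold (mean + n_sigma * sd) from column-shuffle permutations."""
    rng = np.random.default_rng(seed)
    b = np.array(list(col_b))
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = mutual_information(col_a, "".join(rng.permutation(b)))
    return float(null.mean() + n_sigma * null.std())


def correlated_pairs(
    alignment: SequenceAlignment,
    anchor_site: int,
    candidate_partner_sites: Sequence[int],
    reference_id: str,
    start: int = 1,
    mi_threshold: float | None = None,
    n_permutations: int = 200,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Partner sites whose APC-corrected MI with the anchor column exceeds
    the threshold, sorted by descending score.

    With ``mi_threshold=None`` a per-pair permutation null (mean + 4 sd of
    ``n_permutations`` column shuffles) is used. Scores from alignments of
    fewer than 30 sequences are statistically unreliable and raise.
    """
    if alignment.n_sequences < MIN_RELIABLE_SEQUENCES:
        raise ValueError(
            f"coevolution scores need >= {MIN_RELIABLE_SEQUENCES} sequences; "
            f"got {alignment.n_sequences}"
        )
    site_to_col = {v: k for k, v in align_to_reference(alignment, reference_id, start).items()}
    if anchor_site not in site_to_col:
        raise KeyError(f"anchor site {anchor_site} unmapped in reference")
    partners = [s for s in candidate_partner_sites if s != anchor_site]
    cols = {anchor_site: alignment.column(site_to_col[anchor_site])}
    for s in partners:
        if s not in site_to_col:
            raise KeyError(f"partner site {s} unmapped in reference")
        cols[s] = alignment.column(site_to_col[s])
    scores = apc_corrected_scores(cols)

    def pair_score(a: int, b: int) -> float:
        return scores.get((min(a, b), max(a, b)), 0.0)

    hits = []
    for s in partners:
        sc = pair_score(anchor_site, s)
        thr = (
            mi_threshold
            if mi_threshold is not None
            else permutation_null_threshold(
                cols[anchor_site], cols[s], n_permutations=n_permutations, seed=seed
            )
        )
        if sc > thr:
            hits.append((s, sc))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits
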