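"""The core filter: select family members matching the pocket signature.

A dCache_1 domain is a candidate AI-2 receptor when the residues it
carries at the five reference pocket positions (R126, W128, Y144, D146,
D173 in PctA numbering) are identical to the reference signature.  Match
is strict residue identity; a gap or an ``X`` at a signature column
counts as a mismatch.  The match threshold ``k`` defaults to 5 (all five
residues) but can be lowered, e.g. to 4 to model the PctB/PctC case of
four-of-five conservation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core_io import AlignedFamily, ProteinMetadata
from .reference_map import ColumnMap, ReferencePocketModel, extract_signature


@dataclass(frozen=True)
class SequenceScreen:
    """Screen outcome for one family member."""

    id: str
    signature_string: str
    n_match: int
    matched_positions: tuple[int, ...]
    passes: bool


@dataclass(frozen=True)
class ScreenResult:
    per_sequence: tuple[SequenceScreen, ...]
    k: int
    summary: dict[int, int]  # n_match -> count

    @property
    def n_passing(self) -> int:
        return sum(1 for s in self.per_sequence if s.passes)

    def passing_ids(self) -> list[str]:
        return [s.id for s in self.per_sequence if s.passes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.per_sequence],
                "signature_string": [s.signature_string for s in self.per_sequence],
                "n_match": [s.n_match for s in self.per_sequence],
                "passes": [s.passes for s in self.per_sequence],
            }
        )


def screen_family(family: AlignedFamily, cmap: ColumnMap,
                  ref: ReferencePocketModel, k: int = 5) -> ScreenResult:
    """Score every row of the family against the reference signature.

    Raises if the column map does not cover all five signature positions
    (the alignment does not span the pocket) or if ``k`` is outside 0..5.
    """
    if not (0 <= k <= len(ref.signature)):
        raise ValueError(f"k must be in 0..{len(ref.signature)}, got {k}")
    missing = [p for p, _ in ref.signature if p not in cmap.refpos_to_col]
    if missing:
        raise ValueError(
            f"signature position(s) {missing} not covered by the column map; "
            "the alignment does not span the pocket"
        )
    results = []
    counts: Counter[int] = Counter()
    for rid, row in family.rows:
        sig = extract_signature(row, cmap, ref)
        matched = tuple(
            pos for (pos, aa), got in zip(ref.signature, sig) if got == aa
        )
        n = len(matched)
        counts[n] += 1
        results.append(SequenceScreen(
            id=rid, signature_string=sig, n_match=n,
            matched_positions=matched, passes=n >= k,
        ))
    return ScreenResult(per_sequence=tuple(results), k=k, summary=dict(counts))


def summarize_screen(result: ScreenResult,
                     metadata: Sequence[ProteinMetadata],
                     classes: dict[str, str] | None = None) -> pd.DataFrame:
    """Join screen results with metadata (phylum, optional class labels).

    ``classes`` maps accession -> functional class (see
    :mod:`dcache_ai2.domain_classify`); sequences lacking metadata are
    kept with class/phylum ``unknown``.  Duplicate metadata accessions
    are a hard error.
    """
    by_acc: dict[str, ProteinMetadata] = {}
    for m in metadata:
        if m.accession in by_acc:
            raise ValueError(f"duplicate accession {m.accession!r} in metadata")
        by_acc[m.accession] = m
    rows = []
    for s in result.per_sequence:
        meta = by_acc.get(s.id)
        rows.append({
            "id": s.id,
            "signature_string": s.signature_string,
            "n_match": s.n_match,
            "passes": s.passes,
            "class": (classes or {}).get(s.id, "unknown"),
            "phylum": meta.phylum if meta is not None else "unknown",
        })
    return pd.DataFrame(
        rows, columns=["id", "signature_string", "n_match", "passes",
                       "class", "phylum"])
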