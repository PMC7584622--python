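"""Anchoring family members to PctA reference residue numbering.

The screening logic compares pocket residues across thousands of dCache_1
domains.  Positions are only comparable once every sequence is expressed
in the numbering of a single reference — the *Pseudomonas aeruginosa*
chemoreceptor PctA, whose ligand-binding domain spans residues 36–261 and
whose AI-2 pocket signature is R126, W128, Y144, D146, D173.

Two anchoring routes are provided:

* :func:`build_column_map` — walk the reference row of a family MSA and
  assign each of its non-gap columns the next reference position;
  columns falling outside the reference domain are dropped.
* :func:`align_to_reference` — global pairwise alignment (BLOSUM62,
  affine gaps, open 11 / extend 1) for the convenience case where no
  family MSA is available.  Reports produced from this route should be
  labelled as pairwise-anchored.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import GAP, AlignedFamily, SequenceRecord

# five pocket positions whose joint conservation defines the candidate
# AI-2-binding dCache_1 subfamily
SIGNATURE: tuple[tuple[int, str], ...] = (
    (126, "R"), (128, "W"), (144, "Y"), (146, "D"), (173, "D"),
)
#: all pocket residues in close contact with the ligand in the docking model
EXTENDED_POCKET: frozenset[int] = frozenset(
    {101, 111, 121, 126, 128, 144, 146, 147, 173}
)
DOMAIN_SPAN: tuple[int, int] = (36, 261)
LOGO_REGION: tuple[int, int] = (100, 175)


def _synthetic_reference_sequence(length: int = 629, seed: int = 20201023) -> str:
    """Deterministic synthetic stand-in for the PctA chain.

    This is *not* the biological PctA sequence: it is a reproducible
    random amino-acid chain of PctA's length that carries the known
    pocket residues (Y101, M111, Y121, R126, W128, Y144, D146, A147,
    D173) at their correct positions, which is all the coordinate-based
    analyses require.  Supply the real sequence via
    :meth:`ReferencePocketModel.with_reference` to anchor real data.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    chars = rng.choice(alphabet, size=length).tolist()
    fixed = {101: "Y", 111: "M", 121: "Y", 126: "R", 128: "W",
             144: "Y", 146: "D", 147: "A", 173: "D"}
    for pos, aa in fixed.items():
        chars[pos - 1] = aa
    return "".join(chars)


@dataclass(frozen=True)
class ReferencePocketModel:
    """The reference sequence, its domain span and the pocket signature."""

    reference_id: str = "PctA"
    reference_sequence: str = field(default_factory=_synthetic_reference_sequence)
    domain_span: tuple[int, int] = DOMAIN_SPAN
    signature: tuple[tuple[int, str], ...] = SIGNATURE
    extended_pocket: frozenset[int] = EXTENDED_POCKET
    logo_region: tuple[int, int] = LOGO_REGION

    def __post_init__(self) -> None:
        start, end = self.domain_span
        for pos, aa in self.signature:
            if not (start <= pos <= end):
                raise ValueError(f"signature position {pos} outside domain span")
            if self.reference_sequence[pos - 1] != aa:
                raise ValueError(
                    f"reference residue at {pos} is "
                    f"{self.reference_sequence[pos - 1]!r}, expected {aa!r}"
                )
        if not set(p for p, _ in self.signature) <= self.extended_pocket:
            raise ValueError("extended pocket must contain the signature positions")

    @property
    def signature_positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.signature)

    @property
    def signature_string(self) -> str:
        return "".join(aa for _, aa in self.signature)

    def domain_sequence(self) -> str:
        start, end = self.domain_span
        return self.reference_sequence[start - 1:end]

    def with_reference(self, sequence: str,
                       reference_id: str | None = None) -> "ReferencePocketModel":
        """Return a copy anchored on a user-supplied reference sequence."""
        return ReferencePocketModel(
            reference_id=reference_id or self.reference_id,
            reference_sequence=sequence.upper(),
            domain_span=self.domain_span,
            signature=self.signature,
            extended_pocket=self.extended_pocket,
            logo_region=self.logo_region,
        )


@dataclass(frozen=True)
class ColumnMap:
    """Bidirectional map between alignment columns and reference positions.

    Columns and positions are both 1-based; only columns mapping inside
    the reference domain span are retained.
    """

    col_to_refpos: dict[int, int]
    refpos_to_col: dict[int, int]
    retained_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        for col, pos in self.col_to_refpos.items():
            if self.refpos_to_col.get(pos) != col:
                raise ValueError("col_to_refpos / refpos_to_col are not inverse")
        cols = sorted(self.col_to_refpos)
        positions = [self.col_to_refpos[c] for c in cols]
        if positions != sorted(positions):
            raise ValueError("reference positions not increasing along columns")
        if tuple(cols) != self.retained_columns:
            raise ValueError("retained_columns inconsistent with the map")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"col_to_refpos": {str(k): v for k, v in self.col_to_refpos.items()}},
            indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ColumnMap":
        data = json.loads(Path(path).read_text())
        c2r = {int(k): int(v) for k, v in data["col_to_refpos"].items()}
        return cls(
            col_to_refpos=c2r,
            refpos_to_col={v: k for k, v in c2r.items()},
            retained_columns=tuple(sorted(c2r)),
        )


def _split_coordinate_suffix(row_id: str) -> tuple[str, int | None]:
    """Parse a Stockholm-style ``id/start-end`` suffix if present."""
    if "/" in row_id:
        base, _, span = row_id.rpartition("/")
        parts = span.split("-")
        if len(parts) == 2 and all(p.isdigit() for p in parts):
            return base, int(parts[0])
    return row_id, None


def build_column_map(family: AlignedFamily, ref: ReferencePocketModel) -> ColumnMap:
    """Map alignment columns to reference positions via the reference row.

    Walking the reference row left to right, each non-gap column is
    assigned the next reference position, starting at the row's stated
    start coordinate (``id/start-end`` suffix) or the domain start when
    none is given.  Columns outside the domain span are excluded.
    Residue disagreement between the row and the reference sequence is a
    hard error.
    """
    ref_row = None
    start = None
    for rid, seq in family.rows:
        base, suffix_start = _split_coordinate_suffix(rid)
        if rid == ref.reference_id or base == ref.reference_id:
            ref_row = seq
            start = suffix_start if suffix_start is not None else ref.domain_span[0]
            break
    if ref_row is None:
        raise ValueError(
            f"reference id {ref.reference_id!r} not found in the alignment"
        )

    span_lo, span_hi = ref.domain_span
    col_to_refpos: dict[int, int] = {}
    pos = start
    for col0, aa in enumerate(ref_row):
        if aa == GAP:
            continue
        expected = ref.reference_sequence[pos - 1]
        if aa != expected:
            raise ValueError(
                f"reference row disagrees with reference sequence at "
                f"position {pos} (column {col0 + 1}): row has {aa!r}, "
                f"reference has {expected!r}"
            )
        if span_lo <= pos <= span_hi:
            col_to_refpos[col0 + 1] = pos
        pos += 1
    return ColumnMap(
        col_to_refpos=col_to_refpos,
        refpos_to_col={v: k for k, v in col_to_refpos.items()},
        retained_columns=tuple(sorted(col_to_refpos)),
    )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_to_reference(seq: SequenceRecord, ref: ReferencePocketModel,
                       aligner: Align.PairwiseAligner | None = None,
                       ) -> dict[int, int]:
    """Pairwise-anchor a sequence: map target position -> reference position.

    Positions aligned to gaps are absent from the map.  The reference
    side uses full-chain numbering (domain slice alignment is implicit
    in the scoring).
    """
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(ref.domain_sequence(), seq.residues)[0]
    mapping: dict[int, int] = {}
    ref_offset = ref.domain_span[0] - 1
    for (r_lo, r_hi), (t_lo, t_hi) in zip(*alignment.aligned):
        for k in range(r_hi - r_lo):
            mapping[t_lo + k + 1] = ref_offset + r_lo + k + 1
    return mapping


def extract_signature(row: str, cmap: ColumnMap, ref: ReferencePocketModel) -> str:
    """Residues of an aligned row at the five signature positions.

    Unmapped or gapped positions yield ``-``; degenerate inputs never
    raise.
    """
    out = []
    for pos, _ in ref.signature:
        col = cmap.refpos_to_col.get(pos)
        out.append(row[col - 1] if col is not None and col <= len(row) else GAP)
    return "".join(out)


def signature_from_map(seq: SequenceRecord, pos_map: dict[int, int],
                       ref: ReferencePocketModel) -> str:
    """Signature string via a pairwise target->reference position map."""
    inverse = {v: k for k, v in pos_map.items()}
    out = []
    for pos, _ in ref.signature:
        tpos = inverse.get(pos)
        out.append(seq.residues[tpos - 1] if tpos is not None else GAP)
    return "".join(out)
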