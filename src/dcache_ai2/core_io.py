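"""Readers and writers for the file formats the pipeline touches.

Formats
-------
* FASTA / aligned FASTA / Stockholm for sequences and alignments
  (Biopython ``SeqIO``/``AlignIO`` underneath; ``.`` gaps are normalized
  to ``-`` on input).
* A TSV protein-metadata table with columns ``accession``,
  ``architecture`` (semicolon-joined ``domain:start-end:evalue`` triples,
  1-based inclusive coordinates, Pfam convention), ``output_domains``
  (semicolon-joined) and ``lineage`` (semicolon-joined, superkingdom
  first).
* A CSV thermogram file: a protocol header block of ``key,value`` lines
  followed by per-injection rows.  All quantities are normalized to SI
  internally (mol/L, L, µJ for heats).
* Deterministic TSV/JSON report writing (fixed column order, fixed float
  format) so reruns are byte-stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("dcache_ai2")

#: Residues accepted in ungapped sequences.  'X' (unknown) is legal and is
#: treated as a mismatch by downstream consumers.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
SEQUENCE_ALPHABET = AMINO_ACIDS | {"X"}
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped amino-acid sequence.

    ``residues`` is upper case, drawn from the 20 standard letters plus X;
    gap characters are forbidden here (gapped rows live in
    :class:`AlignedFamily`).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record requires a non-empty id")
        if len(self.residues) < 1:
            raise FormatError(f"{self.id}: empty sequence")
        bad = set(self.residues) - SEQUENCE_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise FormatError(
                f"{self.id}: illegal residue character {self.residues[pos]!r} "
                f"at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedFamily:
    """A rectangular multiple alignment: ordered (id, gapped string) rows."""

    rows: tuple[tuple[str, str], ...]
    n_columns: int

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str]]) -> "AlignedFamily":
        rows = tuple((rid, seq.upper().replace(".", GAP)) for rid, seq in rows)
        if not rows:
            raise FormatError("alignment has no rows")
        n_cols = len(rows[0][1])
        seen: set[str] = set()
        for rid, seq in rows:
            if rid in seen:
                raise FormatError(f"duplicate row id {rid!r} in alignment")
            seen.add(rid)
            if len(seq) != n_cols:
                raise FormatError(
                    f"ragged alignment: row {rid!r} has {len(seq)} columns, "
                    f"expected {n_cols}"
                )
            bad = set(seq) - SEQUENCE_ALPHABET - {GAP}
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise FormatError(
                    f"{rid}: illegal character {seq[pos]!r} at column {pos + 1}"
                )
        return cls(rows=rows, n_columns=n_cols)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, seq in self.rows:
            if r == rid:
                return seq
        raise KeyError(rid)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class DomainHit:
    """One Pfam-style domain interval, 1-based inclusive."""

    name: str
    start: int
    end: int
    e_value: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"domain {self.name}: bad interval {self.start}-{self.end}"
            )
        if self.e_value < 0:
            raise FormatError(f"domain {self.name}: negative E-value")


@dataclass(frozen=True)
class ProteinMetadata:
    """Per-protein Pfam architecture, output domains and taxonomy."""

    accession: str
    domain_architecture: tuple[DomainHit, ...]
    output_domains: tuple[str, ...]
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.lineage:
            raise FormatError(f"{self.accession}: empty lineage")

    @property
    def phylum(self) -> str:
        """Second lineage element when a superkingdom leads, else 'unresolved'."""
        if self.lineage[0] in {"Bacteria", "Archaea", "Eukaryota", "Viruses"}:
            if len(self.lineage) >= 2:
                return self.lineage[1]
        return "unresolved"


@dataclass(frozen=True)
class ThermogramFile:
    """A parsed thermogram CSV: titration protocol plus per-injection heats.

    Units are SI throughout: volumes in L, concentrations in mol/L,
    heats in µJ, temperature in K.
    """

    cell_volume_L: float
    syringe_conc_M: float
    cell_conc_M: float
    temperature_K: float
    injection_volumes_L: tuple[float, ...]
    heats_uJ: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.cell_volume_L <= 0:
            raise FormatError("cell volume must be positive")
        if self.syringe_conc_M < 0 or self.cell_conc_M < 0:
            raise FormatError("concentrations must be non-negative")
        if any(v <= 0 for v in self.injection_volumes_L):
            raise FormatError("injection volumes must be positive")
        if len(self.heats_uJ) != len(self.injection_volumes_L):
            raise FormatError(
                f"{len(self.heats_uJ)} heats for "
                f"{len(self.injection_volumes_L)} injections"
            )


# ---------------------------------------------------------------------------
# FASTA / alignment I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read ungapped FASTA records in file order."""
    records = []
    ids: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        ids.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), description=desc)
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


_DIALECTS = {"aligned-fasta": "fasta", "stockholm": "stockholm"}


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> AlignedFamily:
    """Read a rectangular alignment.

    ``dialect`` is ``aligned-fasta`` or ``stockholm``; Stockholm GC/GS
    annotation lines are ignored, only sequence rows are kept.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    try:
        aln = AlignIO.read(str(path), _DIALECTS[dialect])
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    return AlignedFamily.from_rows((rec.id, str(rec.seq)) for rec in aln)


def write_alignment(family: AlignedFamily, path: str | Path,
                    dialect: str = "aligned-fasta") -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    from Bio.Align import MultipleSeqAlignment

    aln = MultipleSeqAlignment(
        _BioSeqRecord(Seq(seq), id=rid, description="") for rid, seq in family.rows
    )
    AlignIO.write(aln, str(path), _DIALECTS[dialect])


# ---------------------------------------------------------------------------
# protein metadata table
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["accession", "architecture", "output_domains", "lineage"]


def _parse_architecture(token: str, accession: str) -> tuple[DomainHit, ...]:
    hits = []
    if not token:
        return ()
    for part in token.split(";"):
        pieces = part.split(":")
        if len(pieces) != 3 or "-" not in pieces[1]:
            raise FormatError(
                f"{accession}: unparseable architecture token {part!r}"
            )
        name = pieces[0]
        start_s, end_s = pieces[1].split("-", 1)
        try:
            hits.append(DomainHit(name, int(start_s), int(end_s), float(pieces[2])))
        except ValueError as exc:
            raise FormatError(
                f"{accession}: unparseable architecture token {part!r}"
            ) from exc
    return tuple(hits)


def read_protein_table(path: str | Path) -> list[ProteinMetadata]:
    """Read the TSV metadata table.

    Rows with unparseable architecture tokens are skipped with a log
    entry; a missing required column is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records: list[ProteinMetadata] = []
    for _, row in df.iterrows():
        acc = row["accession"]
        try:
            arch = _parse_architecture(row["architecture"], acc)
            out = tuple(d for d in row["output_domains"].split(";") if d)
            lineage = tuple(t for t in row["lineage"].split(";") if t)
            records.append(ProteinMetadata(acc, arch, out, lineage))
        except FormatError as exc:
            logger.warning("skipping record %s: %s", acc, exc)
    return records


def write_protein_table(records: Sequence[ProteinMetadata], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "accession": r.accession,
            "architecture": ";".join(
                f"{h.name}:{h.start}-{h.end}:{h.e_value:g}"
                for h in r.domain_architecture
            ),
            "output_domains": ";".join(r.output_domains),
            "lineage": ";".join(r.lineage),
        })
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# thermogram CSV
# ---------------------------------------------------------------------------

_PROTOCOL_FIELDS = {
    "cell_volume_L": float,
    "syringe_conc_M": float,
    "cell_conc_M": float,
    "temperature_K": float,
}


def read_thermogram(path: str | Path) -> ThermogramFile:
    """Read a thermogram CSV.

    Layout: ``key,value`` protocol lines, then a ``injection,volume_L,heat_uJ``
    header and one row per injection.
    """
    protocol: dict[str, float] = {}
    volumes: list[float] = []
    heats: list[float] = []
    in_table = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0] == "injection":
                in_table = True
                continue
            if not in_table:
                if len(parts) != 2 or parts[0] not in _PROTOCOL_FIELDS:
                    raise FormatError(
                        f"{path}:{lineno}: unexpected protocol line {line!r}"
                    )
                protocol[parts[0]] = float(parts[1])
            else:
                if len(parts) != 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 columns")
                try:
                    volumes.append(float(parts[1]))
                    heats.append(float(parts[2]))
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric entry {line!r}"
                    ) from exc
    missing = sorted(set(_PROTOCOL_FIELDS) - set(protocol))
    if missing:
        raise FormatError(f"{path}: missing protocol field(s) {missing}")
    return ThermogramFile(
        cell_volume_L=protocol["cell_volume_L"],
        syringe_conc_M=protocol["syringe_conc_M"],
        cell_conc_M=protocol["cell_conc_M"],
        temperature_K=protocol["temperature_K"],
        injection_volumes_L=tuple(volumes),
        heats_uJ=tuple(heats),
    )


def write_thermogram(tg: ThermogramFile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"cell_volume_L,{tg.cell_volume_L:.10g}\n")
        fh.write(f"syringe_conc_M,{tg.syringe_conc_M:.10g}\n")
        fh.write(f"cell_conc_M,{tg.cell_conc_M:.10g}\n")
        fh.write(f"temperature_K,{tg.temperature_K:.10g}\n")
        fh.write("injection,volume_L,heat_uJ\n")
        for i, (v, q) in enumerate(zip(tg.injection_volumes_L, tg.heats_uJ), 1):
            fh.write(f"{i},{v:.10g},{q:.10g}\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(table: pd.DataFrame | dict, path: str | Path,
                 format: str = "tsv") -> None:
    """Write a report deterministically (fixed column order, '%.6g' floats)."""
    path = Path(path)
    if format == "tsv":
        if not isinstance(table, pd.DataFrame):
            table = pd.DataFrame(table)
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        if isinstance(table, pd.DataFrame):
            payload = table.to_dict(orient="records")
        else:
            payload = table
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: str | Path):
    return json.loads(Path(path).read_text())
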