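"""Functional classification of screened proteins from Pfam output domains.

A dCache_1 sensor passes its signal to whatever cytoplasmic output
module the protein carries.  The classifier maps Pfam-style output
domain names onto the canonical signal-transduction classes:

====  =============================================================
MCP   methyl-accepting chemotaxis proteins (MCPsignal, MA)
HK    sensor histidine kinases (HisKA variants, HATPase_c)
CSP   c-di-GMP synthases/phosphodiesterases (GGDEF, EAL, HD-GYP/HDc)
SP    serine phosphatases (SpoIIE, PP2C)
STK   serine/threonine kinases (Pkinase)
AC/GC adenylate / guanylate cyclases (Guanylate_cyc)
====  =============================================================

plus CNB-only (a cyclic-nucleotide-binding domain and nothing else) and
UNCHARACTERIZED (no output domains at all).  A protein with output
domains qualifying for several classes takes the first class in the
configured precedence order (default MCP > CSP > HK > SP > STK > AC/GC >
CNB-only).  Proteins with output domains matching no rule are labelled
OTHER-annotated.  Classification is total: every record gets a label.

The rule table is editable YAML (see :func:`load_rules`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .core_io import ProteinMetadata

UNCHARACTERIZED = "UNCHARACTERIZED"
OTHER = "OTHER-annotated"

#: Pfam names that denote the sensor itself, never an output module.
SENSOR_DOMAINS = frozenset({"dCache_1", "Cache_1", "Cache_2", "dCache_2"})

#: domain-name aliases normalized before rule lookup
ALIASES = {"HDc": "HD-GYP", "HD": "HD-GYP"}

DEFAULT_RULES: list[tuple[str, frozenset[str]]] = [
    ("MCP", frozenset({"MCPsignal", "MA"})),
    ("CSP", frozenset({"GGDEF", "EAL", "HD-GYP"})),
    ("HK", frozenset({"HisKA", "HisKA_2", "HisKA_3", "HATPase_c"})),
    ("SP", frozenset({"SpoIIE", "PP2C"})),
    ("STK", frozenset({"Pkinase"})),
    ("AC/GC", frozenset({"Guanylate_cyc"})),
    ("CNB-only", frozenset({"cNMP_binding"})),
]


@dataclass(frozen=True)
class ClassRuleSet:
    """Ordered precedence list of (class, qualifying domain names)."""

    rules: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.rules]
        if len(names) != len(set(names)):
            raise ValueError("each class may appear once in the precedence list")

    @classmethod
    def default(cls) -> "ClassRuleSet":
        return cls(rules=tuple(DEFAULT_RULES))

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.rules)

    def representative_domain(self, class_name: str) -> str | None:
        """A canonical qualifying domain for a class (for generators)."""
        for c, names in self.rules:
            if c == class_name:
                return sorted(names)[0]
        return None


def load_rules(path: str | Path) -> ClassRuleSet:
    """Load a YAML rule file: an ordered list of {class: [domains...]}."""
    data = yaml.safe_load(Path(path).read_text())
    rules = []
    for entry in data:
        (cls_name, domains), = entry.items()
        rules.append((cls_name, frozenset(domains)))
    return ClassRuleSet(rules=tuple(rules))


def dump_rules(rules: ClassRuleSet, path: str | Path) -> None:
    data = [{c: sorted(names)} for c, names in rules.rules]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def classify(meta: ProteinMetadata,
             rules: ClassRuleSet | None = None) -> tuple[str, tuple[str, ...]]:
    """Assign a functional class; returns (label, matched domain evidence).

    Special case: ``CNB-only`` requires the cyclic-nucleotide-binding
    domain to be the *only* output domain.
    """
    if rules is None:
        rules = ClassRuleSet.default()
    outputs = tuple(
        ALIASES.get(d, d) for d in meta.output_domains if d not in SENSOR_DOMAINS
    )
    if not outputs:
        return UNCHARACTERIZED, ()
    out_set = set(outputs)
    for cls_name, qualifying in rules.rules:
        hit = tuple(sorted(out_set & qualifying))
        if not hit:
            continue
        if cls_name == "CNB-only" and out_set - qualifying:
            continue
        return cls_name, hit
    return OTHER, ()


def classify_all(metadata: Iterable[ProteinMetadata],
                 rules: ClassRuleSet | None = None) -> dict[str, str]:
    """Accession -> class label for a metadata collection."""
    return {m.accession: classify(m, rules)[0] for m in metadata}


def rollup(table: pd.DataFrame, by: str = "class") -> pd.DataFrame:
    """Count rows by 'class', 'phylum' or 'class_phylum'.

    Input is the joined screen table (see
    :func:`dcache_ai2.signature_screen.summarize_screen`).  Sort order
    is deterministic: descending count, then name.
    """
    if by == "class":
        keys = ["class"]
    elif by == "phylum":
        keys = ["phylum"]
    elif by == "class_phylum":
        keys = ["class", "phylum"]
    else:
        raise ValueError(f"unknown rollup key {by!r}")
    if table.empty:
        return pd.DataFrame(columns=keys + ["count"])
    counts = Counter(tuple(row) for row in table[keys].itertuples(index=False))
    rows = [dict(zip(keys, key), count=n) for key, n in counts.items()]
    df = pd.DataFrame(rows)
    return df.sort_values(
        by=["count"] + keys, ascending=[False] + [True] * len(keys)
    ).reset_index(drop=True)
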