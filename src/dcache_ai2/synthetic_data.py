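"""Synthetic inputs with ground-truth labels for every pipeline stage.

The generators emit data with the statistical structure the analyses
assume — an aligned domain family with a planted five-residue pocket
signature at controllable prevalence, per-protein domain architectures
drawn from the functional classes the classifier knows, phylum labels,
and noisy one-site titrations with known parameters — together with the
ground truth, which test suites use as the oracle.

The family alignment is emitted directly (gap placement is part of the
generative model), so screening tests are independent of any aligner.
Every generator is fully deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GAP, AlignedFamily, DomainHit, ProteinMetadata
from .domain_classify import UNCHARACTERIZED, ClassRuleSet
from .itc_model import (OneSiteParams, Thermogram, TitrationProtocol,
                        simulate_titration)
from .reference_map import ReferencePocketModel

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: default class mix, shaped like the screened cohort: chemoreceptors
#: dominate, followed by histidine kinases and c-di-GMP enzymes, with a
#: small completely-uncharacterized tail (~3%) and a rare CNB-only case.
DEFAULT_CLASS_DISTRIBUTION: dict[str, float] = {
    "MCP": 0.55, "HK": 0.20, "CSP": 0.12, "SP": 0.04, "STK": 0.03,
    "AC/GC": 0.025, "CNB-only": 0.001, UNCHARACTERIZED: 0.034,
}

DEFAULT_PHYLUM_DISTRIBUTION: dict[str, float] = {
    "Proteobacteria": 0.50, "Firmicutes": 0.20, "Bacteroidetes": 0.10,
    "Actinobacteria": 0.08, "Spirochaetes": 0.05, "Cyanobacteria": 0.05,
    "Euryarchaeota": 0.02,
}

#: where each class's representative output domain is placed in the
#: synthetic architecture (positions after the sensor domain)
_OUTPUT_SPAN = (500, 560)


@dataclass(frozen=True)
class FamilyGenConfig:
    """Knobs of the family generator.

    ``full_match_fraction`` sequences carry all five signature residues,
    ``partial_match_fraction`` carry exactly four; the remainder are
    background draws guaranteed not to match all five.  The exact-count
    guarantee for full matches holds at ``signature_fidelity`` 1.
    """

    n_seqs: int = 2000
    reference: ReferencePocketModel = field(default_factory=ReferencePocketModel)
    full_match_fraction: float = 1535 / 18970
    partial_match_fraction: float = 0.05
    signature_fidelity: float = 1.0
    indel_rate: float = 0.0
    shuffle_gap_columns: bool = False
    class_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DISTRIBUTION))
    phylum_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_DISTRIBUTION))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs < 0:
            raise ValueError("n_seqs must be non-negative")
        for frac in (self.full_match_fraction, self.partial_match_fraction,
                     self.signature_fidelity):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.full_match_fraction + self.partial_match_fraction > 1.0 + 1e-12:
            raise ValueError("full + partial match fractions exceed 1")
        if self.indel_rate < 0 or self.indel_rate > 1:
            raise ValueError("indel_rate must lie in [0, 1]")
        for dist in (self.class_distribution, self.phylum_distribution):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("distribution weights must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError("negative distribution weight")


@dataclass(frozen=True)
class FamilyGroundTruth:
    """Generator-side labels: the oracle for screening and rollup tests.

    ``n_full_planted`` counts synthetic rows only; the reference row is
    always one further full match (see :meth:`expected_pass_count`).
    """

    n_match: dict[str, int]
    classes: dict[str, str]
    phyla: dict[str, str]
    n_full_planted: int
    n_partial_planted: int

    def expected_pass_count(self, k: int) -> int:
        """Rows (reference included) with at least k signature matches."""
        return sum(1 for v in self.n_match.values() if v >= k)


def generate_family(cfg: FamilyGenConfig,
                    rules: ClassRuleSet | None = None,
                    ) -> tuple[AlignedFamily, list[ProteinMetadata],
                               FamilyGroundTruth]:
    """Emit (alignment incl. reference row, metadata, ground truth).

    Architectures are drawn per the class distribution using the
    classifier's own rule table, so ``classify(generated) == planted``
    by construction.
    """
    if rules is None:
        rules = ClassRuleSet.default()
    ref = cfg.reference
    rng = np.random.default_rng(cfg.seed)

    span_lo, span_hi = ref.domain_span
    n_cols = span_hi - span_lo + 1
    sig_cols = {pos - span_lo: aa for pos, aa in ref.signature}

    n_full = round(cfg.full_match_fraction * cfg.n_seqs)
    n_partial = round(cfg.partial_match_fraction * cfg.n_seqs)
    n_partial = min(n_partial, cfg.n_seqs - n_full)
    kinds = np.array(["full"] * n_full + ["partial"] * n_partial
                     + ["background"] * (cfg.n_seqs - n_full - n_partial))
    rng.shuffle(kinds)

    rows: list[tuple[str, str]] = [(ref.reference_id, ref.domain_sequence())]
    n_match: dict[str, int] = {}
    sig_positions = list(sig_cols)

    for i, kind in enumerate(kinds):
        rid = f"SYN{i + 1:05d}"
        chars = rng.choice(_RESIDUES, size=n_cols)
        if kind == "full":
            for col, aa in sig_cols.items():
                if cfg.signature_fidelity >= 1.0 or \
                        rng.random() < cfg.signature_fidelity:
                    chars[col] = aa
        elif kind == "partial":
            mutated_col = sig_positions[rng.integers(len(sig_positions))]
            for col, aa in sig_cols.items():
                if col == mutated_col:
                    chars[col] = _draw_other(rng, aa)
                else:
                    chars[col] = aa
        else:
            # forbid an accidental five-of-five so the planted full count
            # is exact
            if all(chars[col] == aa for col, aa in sig_cols.items()):
                col = sig_positions[rng.integers(len(sig_positions))]
                chars[col] = _draw_other(rng, sig_cols[col])
        row = "".join(chars)
        n_match[rid] = sum(row[col] == aa for col, aa in sig_cols.items())
        rows.append((rid, row))

    if cfg.indel_rate > 0:
        rows = _insert_gap_columns(rows, cfg.indel_rate, rng)
    if cfg.shuffle_gap_columns:
        rows = _shuffle_gap_columns(rows, rng)

    classes_all = list(cfg.class_distribution)
    class_p = np.array([cfg.class_distribution[c] for c in classes_all])
    phyla_all = list(cfg.phylum_distribution)
    phylum_p = np.array([cfg.phylum_distribution[p] for p in phyla_all])

    metadata: list[ProteinMetadata] = []
    classes: dict[str, str] = {}
    phyla: dict[str, str] = {}
    ids = [rid for rid, _ in rows]
    for rid in ids:
        if rid == ref.reference_id:
            cls, phylum = "MCP", "Proteobacteria"
        else:
            cls = classes_all[rng.choice(len(classes_all), p=class_p)]
            phylum = phyla_all[rng.choice(len(phyla_all), p=phylum_p)]
        classes[rid] = cls
        phyla[rid] = phylum
        arch = [DomainHit("dCache_1", span_lo, span_hi, 1e-30)]
        outputs: tuple[str, ...] = ()
        if cls != UNCHARACTERIZED:
            rep = rules.representative_domain(cls)
            if rep is None:  # class unknown to the rule table
                rep = cls
            arch.append(DomainHit(rep, *_OUTPUT_SPAN, 1e-20))
            outputs = (rep,)
        metadata.append(ProteinMetadata(
            accession=rid, domain_architecture=tuple(arch),
            output_domains=outputs, lineage=("Bacteria", phylum),
        ))

    n_match[ref.reference_id] = len(ref.signature)
    family = AlignedFamily.from_rows(rows)
    truth = FamilyGroundTruth(
        n_match=n_match, classes=classes, phyla=phyla,
        n_full_planted=n_full,
        n_partial_planted=n_partial,
    )
    return family, metadata, truth


def _draw_other(rng: np.random.Generator, avoid: str) -> str:
    pool = _RESIDUES[_RESIDUES != avoid]
    return str(pool[rng.integers(len(pool))])


def _insert_gap_columns(rows: list[tuple[str, str]], rate: float,
                        rng: np.random.Generator) -> list[tuple[str, str]]:
    """Insert reference-gap (insertion) columns after random positions.

    The reference row gets a gap, other rows a coin-flip between a gap
    and a random residue; such columns fall outside the retained set of
    any column map built on the reference row.
    """
    n_cols = len(rows[0][1])
    insert_after = rng.random(n_cols) < rate
    out_seqs = {rid: [] for rid, _ in rows}
    ref_id = rows[0][0]
    for c in range(n_cols):
        for rid, seq in rows:
            out_seqs[rid].append(seq[c])
        if insert_after[c]:
            for rid, _ in rows:
                if rid == ref_id:
                    out_seqs[rid].append(GAP)
                else:
                    out_seqs[rid].append(
                        GAP if rng.random() < 0.5
                        else str(_RESIDUES[rng.integers(20)]))
    return [(rid, "".join(out_seqs[rid])) for rid, _ in rows]


def _shuffle_gap_columns(rows: list[tuple[str, str]],
                         rng: np.random.Generator) -> list[tuple[str, str]]:
    """Corruption mode: permute the columns where the reference is gapped.

    Stresses the column mapper — retained columns and screening results
    must be invariant under this shuffle.
    """
    ref_seq = rows[0][1]
    gap_cols = [c for c, aa in enumerate(ref_seq) if aa == GAP]
    perm = rng.permutation(len(gap_cols))
    out = []
    for rid, seq in rows:
        chars = list(seq)
        shuffled = [chars[gap_cols[p]] for p in perm]
        for c, aa in zip(gap_cols, shuffled):
            chars[c] = aa
        out.append((rid, "".join(chars)))
    return out


# ---------------------------------------------------------------------------
# ITC and assay generators
# ---------------------------------------------------------------------------

def generate_itc_dataset(protocol: TitrationProtocol, params: OneSiteParams,
                         noise_sd_uJ: float, n_replicates: int, seed: int,
                         ) -> list[tuple[Thermogram, Thermogram]]:
    """Replicate titrations plus matched dilution controls.

    The control mimics ligand-into-buffer injections: the constant
    background heat ``q_offset`` plus noise, no binding signal.
    Replicate streams are derived deterministically from the master
    seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    out = []
    dilution_params = OneSiteParams(Kd=1.0, n=1.0, dH=0.0,
                                    q_offset=params.q_offset)
    for rep in range(n_replicates):
        signal_rng = np.random.default_rng([seed, rep, 0])
        control_rng = np.random.default_rng([seed, rep, 1])
        signal = simulate_titration(protocol, params, noise_sd_uJ, signal_rng)
        control = simulate_titration(protocol, dilution_params, noise_sd_uJ,
                                     control_rng)
        out.append((signal, control))
    return out


@dataclass(frozen=True)
class AssayGenConfig:
    """Study-shaped assay effect sizes.

    Defaults mirror the chemoattraction condition: colony edges at
    6.5 mm toward / 3.5 mm away from the attractant spot (mean RI 0.65)
    and a five-fold capillary accumulation over buffer.
    """

    d1_mean_mm: float = 6.5
    d2_mean_mm: float = 3.5
    d_sd_mm: float = 0.3
    capillary_treatment_rate: float = 1000.0
    capillary_buffer_rate: float = 200.0
    n: int = 5

    def __post_init__(self) -> None:
        if min(self.d1_mean_mm, self.d2_mean_mm) <= 0 or self.d_sd_mm < 0:
            raise ValueError("distance parameters must be positive")
        if min(self.capillary_treatment_rate, self.capillary_buffer_rate) < 0:
            raise ValueError("capillary rates must be non-negative")
        if self.n < 1:
            raise ValueError("n must be at least 1")


def generate_assay_dataset(cfg: AssayGenConfig, seed: int,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gradient-plate distances (Gaussian) and capillary CFU (Poisson)."""
    rng = np.random.default_rng(seed)
    d1 = np.maximum(rng.normal(cfg.d1_mean_mm, cfg.d_sd_mm, cfg.n), 0.05)
    d2 = np.maximum(rng.normal(cfg.d2_mean_mm, cfg.d_sd_mm, cfg.n), 0.05)
    plate = pd.DataFrame({
        "replicate": np.arange(1, cfg.n + 1), "D1_mm": d1, "D2_mm": d2,
    })
    treatment = rng.poisson(cfg.capillary_treatment_rate, cfg.n)
    buffer_cfu = rng.poisson(cfg.capillary_buffer_rate, cfg.n)
    capillary = pd.DataFrame({
        "replicate": np.arange(1, cfg.n + 1),
        "treatment_cfu": treatment, "buffer_cfu": buffer_cfu,
    })
    return plate, capillary
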