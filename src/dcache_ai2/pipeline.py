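"""End-to-end orchestration: validated configs, deterministic reports.

``run_scan`` takes an alignment plus a metadata table and writes the
screen table, class and phylum rollups, the pocket position-frequency
matrix and a run manifest (input checksums, parameters, version).
``run_itc`` fits a batch of thermogram files; ``run_simulate`` emits
synthetic bundles.  Identical config + inputs produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .conservation_profile import compute_pfm, information_content
from .core_io import (read_alignment, read_protein_table, read_thermogram,
                      write_report, write_thermogram, ThermogramFile)
from .domain_classify import ClassRuleSet, classify_all, load_rules, rollup
from .itc_model import (OneSiteParams, Thermogram, TitrationProtocol,
                        fit_one_site, subtract_dilution)
from .reference_map import ReferencePocketModel, build_column_map
from .signature_screen import screen_family, summarize_screen
from .synthetic_data import FamilyGenConfig, generate_family

logger = logging.getLogger("dcache_ai2")


class ConfigError(ValueError):
    """A run configuration failed validation."""


@dataclass(frozen=True)
class RunConfig:
    """Inputs and parameters of a screening run."""

    alignment: Path
    table: Path | None = None
    dialect: str = "aligned-fasta"
    k: int = 5
    rules: Path | None = None
    logo_region: tuple[int, int] = (100, 175)
    out_dir: Path = Path("dcache_ai2_out")
    reference: ReferencePocketModel | None = None

    def validate(self) -> None:
        if not Path(self.alignment).exists():
            raise ConfigError(f"alignment file not found: {self.alignment}")
        if self.table is not None and not Path(self.table).exists():
            raise ConfigError(f"metadata table not found: {self.table}")
        if self.rules is not None and not Path(self.rules).exists():
            raise ConfigError(f"rule file not found: {self.rules}")
        if not 0 <= self.k <= 5:
            raise ConfigError(f"k must be in 0..5, got {self.k}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_scan(config: RunConfig) -> dict:
    """Screen an alignment; returns the manifest dict (also written)."""
    config.validate()
    ref = config.reference or ReferencePocketModel()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        family = read_alignment(config.alignment, config.dialect)
    except Exception as exc:
        raise RuntimeError(f"[read-alignment] {config.alignment}: {exc}") from exc
    try:
        cmap = build_column_map(family, ref)
    except Exception as exc:
        raise RuntimeError(f"[column-map] {config.alignment}: {exc}") from exc

    result = screen_family(family, cmap, ref, k=config.k)
    metadata = read_protein_table(config.table) if config.table else []
    rules = load_rules(config.rules) if config.rules else ClassRuleSet.default()
    classes = classify_all(metadata, rules)
    table = summarize_screen(result, metadata, classes)

    passing = table[table["passes"]]
    write_report(table, out / "screen.tsv", "tsv")
    write_report(rollup(passing, "class"), out / "rollup_class.tsv", "tsv")
    write_report(rollup(passing, "phylum"), out / "rollup_phylum.tsv", "tsv")

    pfm = compute_pfm(family, cmap, region=config.logo_region)
    pfm_df = pfm.to_frame()
    pfm_df["information_bits"] = information_content(pfm)
    write_report(pfm_df, out / "pfm.tsv", "tsv")

    manifest = {
        "version": __version__,
        "inputs": {
            "alignment": {"path": str(config.alignment),
                          "sha256": _sha256(config.alignment)},
            "table": ({"path": str(config.table),
                       "sha256": _sha256(config.table)}
                      if config.table else None),
        },
        "parameters": {"k": config.k, "dialect": config.dialect,
                       "logo_region": list(config.logo_region),
                       "reference_id": ref.reference_id},
        "results": {"n_screened": len(result.per_sequence),
                    "n_passing": result.n_passing,
                    "n_match_histogram": {str(k): v for k, v
                                          in sorted(result.summary.items())}},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def run_itc(paths: list[Path], out_dir: Path, fix_n: float | None = None,
            discard_first: bool = False) -> list[dict]:
    """Fit each thermogram CSV; writes one FitResult JSON per input."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports = []
    for path in paths:
        tf = read_thermogram(path)
        protocol = TitrationProtocol(
            syringe_conc_M=tf.syringe_conc_M, cell_conc_M=tf.cell_conc_M,
            cell_volume_L=tf.cell_volume_L,
            injection_volumes_L=tf.injection_volumes_L,
            temperature_K=tf.temperature_K,
        )
        fit = fit_one_site(Thermogram(heats_uJ=tf.heats_uJ), protocol,
                           fix_n=fix_n, discard_first=discard_first)
        report = {
            "input": str(path),
            "Kd_M": fit.params.Kd, "n": fit.params.n,
            "dH_J_per_mol": fit.params.dH, "q_offset_uJ": fit.params.q_offset,
            "stderr": fit.stderr, "rss": fit.rss,
            "wiseman_c": fit.wiseman_c, "converged": fit.converged,
            "n_fixed": fit.n_fixed, "warnings": list(fit.warnings),
        }
        out_path = out_dir / (Path(path).stem + ".fit.json")
        out_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        reports.append(report)
    return reports


def run_simulate_family(cfg: FamilyGenConfig, out_dir: Path) -> dict:
    """Generate a synthetic family bundle on disk (alignment + table + truth)."""
    from .core_io import write_alignment, write_protein_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    family, metadata, truth = generate_family(cfg)
    write_alignment(family, out_dir / "family.afa")
    write_protein_table(metadata, out_dir / "metadata.tsv")
    truth_payload = {
        "n_match": truth.n_match, "classes": truth.classes,
        "phyla": truth.phyla, "n_full_planted": truth.n_full_planted,
        "n_partial_planted": truth.n_partial_planted,
    }
    (out_dir / "truth.json").write_text(
        json.dumps(truth_payload, indent=2, sort_keys=True) + "\n")
    return truth_payload


def simulate_thermogram_file(protocol: TitrationProtocol,
                             params: OneSiteParams, noise_sd_uJ: float,
                             seed: int, path: Path) -> None:
    """Simulate one titration and write it as a thermogram CSV."""
    from .itc_model import simulate_titration

    tg = simulate_titration(protocol, params, noise_sd_uJ, seed)
    tf = ThermogramFile(
        cell_volume_L=protocol.cell_volume_L,
        syringe_conc_M=protocol.syringe_conc_M,
        cell_conc_M=protocol.cell_conc_M,
        temperature_K=protocol.temperature_K,
        injection_volumes_L=protocol.injection_volumes_L,
        heats_uJ=tg.heats_uJ,
    )
    write_thermogram(tf, path)
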