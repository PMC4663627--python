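"""Orchestration: reads -> cleaning -> duplex scan -> hairpin support -> stats.

One config drives the whole discovery path; outputs land in a run directory
together with a manifest (package version, parameters, input checksums) so
that identical configs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .duplex_scan import DuplexCall, ScanParams, find_duplex_pairs, write_calls
from .enrich_stats import CountSpectrum, bin_counts_pow2
from .hairpin_map import (
    HairpinSupport,
    hairpin_support,
    load_contigs,
    load_structures,
)
from .sra_io import CountTable, load_reads, write_count_table

log = logging.getLogger("srnaduplex")


@dataclass(frozen=True)
class HairpinThresholds:
    window: int = 300
    min_paired_fraction: float = 0.6
    min_cross_fraction: float = 0.5


@dataclass(frozen=True)
class PipelineConfig:
    reads: str
    output_dir: str
    reference: str | None = None
    structures: str | None = None
    read_format: str | None = None
    length_range: tuple[int, int] = (18, 30)
    scan: ScanParams = field(default_factory=ScanParams)
    hairpin: HairpinThresholds = field(default_factory=HairpinThresholds)
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys."""
    raw = yaml.safe_load(open(path)) or {}
    return _config_from_dict(raw)


def _build(cls, raw: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown {context} config key(s): {sorted(unknown)}")
    return raw


def _config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(_build(PipelineConfig, raw, "pipeline"))
    if "scan" in raw:
        raw["scan"] = ScanParams(**_build(ScanParams, raw["scan"], "scan"))
    if "hairpin" in raw:
        raw["hairpin"] = HairpinThresholds(
            **_build(HairpinThresholds, raw["hairpin"], "hairpin")
        )
    if "length_range" in raw:
        raw["length_range"] = tuple(raw["length_range"])
    return PipelineConfig(**raw)


@dataclass
class RunReport:
    table: CountTable
    calls: list[DuplexCall]
    supports: list[HairpinSupport]
    spectrum: CountSpectrum
    output_dir: Path
    n_species_loaded: int = 0
    n_species_after_reference: int = 0


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _spectrum_json(spectrum: CountSpectrum) -> dict:
    return {
        "bins": [
            {"low": lo, "high": hi, "species_fraction": f}
            for lo, hi, f in spectrum.bins
        ],
        "total_species": spectrum.total_species,
        "fraction_singletons": spectrum.fraction_singletons,
        "fraction_ge16": spectrum.fraction_ge16,
    }


def run_scan_pipeline(config: PipelineConfig) -> RunReport:
    """Execute load -> reference filter -> scan -> hairpin support -> stats.

    Writes ``counts.tsv``, ``calls.tsv``, ``spectrum.json``, optionally
    ``support.tsv``, and ``manifest.json`` under the run directory.  An empty
    reads file is a successful run with zero species and zero calls.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {"reads": config.reads}

    table = load_reads(config.reads, config.read_format, config.length_range)
    n_loaded = table.total_species
    log.info("loaded %d species (%d reads)", n_loaded, table.total_reads)

    contigs = None
    if config.reference:
        from .hairpin_map import filter_by_reference

        contigs = load_contigs(config.reference)
        inputs["reference"] = config.reference
        table = filter_by_reference(table, contigs)
        log.info("reference filter kept %d species", table.total_species)

    calls = find_duplex_pairs(table, config.scan)
    log.info("duplex scan: %d calls", len(calls))

    supports: list[HairpinSupport] = []
    if contigs is not None:
        structures = None
        if config.structures:
            structures = load_structures(config.structures)
            inputs["structures"] = config.structures
        th = config.hairpin
        supports = [
            hairpin_support(
                c, contigs, th.window, th.min_paired_fraction,
                th.min_cross_fraction, structures,
            )
            for c in calls
        ]
        log.info("hairpin support: %d/%d supported",
                 sum(s.supported for s in supports), len(calls))

    spectrum = bin_counts_pow2(table)

    write_count_table(table, out / "counts.tsv")
    write_calls(calls, out / "calls.tsv")
    with open(out / "spectrum.json", "w") as fh:
        json.dump(_spectrum_json(spectrum), fh, indent=1, sort_keys=True)
    if supports:
        with open(out / "support.tsv", "w") as fh:
            fh.write(
                "seq_a\tseq_b\tsupported\tcontig\tstrand\t"
                "paired_fraction_a\tpaired_fraction_b\t"
                "cross_pair_fraction_a\tcross_pair_fraction_b\n"
            )
            for c, s in zip(calls, supports):
                fh.write(
                    f"{c.read_a.seq}\t{c.read_b.seq}\t{int(s.supported)}\t"
                    f"{s.contig or ''}\t{s.strand or ''}\t"
                    f"{s.paired_fraction_a:.4f}\t{s.paired_fraction_b:.4f}\t"
                    f"{s.cross_pair_fraction_a:.4f}\t{s.cross_pair_fraction_b:.4f}\n"
                )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "scan": dataclasses.asdict(config.scan),
        "hairpin": dataclasses.asdict(config.hairpin),
        "length_range": list(config.length_range),
        "inputs": {k: _sha256(v) for k, v in inputs.items()},
        "n_species": table.total_species,
        "n_calls": len(calls),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return RunReport(
        table=table,
        calls=calls,
        supports=supports,
        spectrum=spectrum,
        output_dir=out,
        n_species_loaded=n_loaded,
        n_species_after_reference=table.total_species,
    )
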