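"""End-to-end pipeline: screen → physchem → charge → cluster → compare.

``run_pipeline`` takes a flat configuration (paths + thresholds),
executes every applicable stage, writes one TSV per stage plus a JSON
manifest, and returns the in-memory results. Output is a pure function
of (inputs, config): re-running with identical inputs reproduces
identical output checksums (the manifest records them).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .charge import RegionScheme, charge_table, region_histogram
from .compare import compare_metrics
from .constants import TABLES_VERSION
from .families import FamilyConfig, cluster_families, families_table, read_hit_table
from .io import read_disorder, read_fasta, dedup_exact, write_fasta
from .physchem import profile_table
from .screen import ScreenConfig, results_table, screen_proteome

log = logging.getLogger("wdpscan")


@dataclass
class PipelineConfig:
    proteome: str
    outdir: str
    intervals: str | None = None
    scores: str | None = None
    hits: str | None = None
    background: str | None = None
    min_fraction: float = 0.90
    min_length: int = 50
    score_threshold: float = 50.0
    score_direction: str = "below"
    max_evalue: float = 1e-4
    max_hits_per_query: int = 20
    strict: bool = True

    @classmethod
    def from_mapping(cls, mapping: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage the config enables; returns results + manifest."""
    outdir = Path(config.outdir)
    for name in ("proteome", "intervals", "scores", "hits", "background"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{name} input not found: {path}")
    if config.intervals is None and config.scores is None:
        raise ValueError("need an intervals or scores track file")
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    records = read_fasta(config.proteome, strict=config.strict)
    records, removed = dedup_exact(records)
    log.info("loaded %d unique proteins (%d duplicates removed)",
             len(records), len(removed))

    tracks = []
    if config.intervals:
        tracks += read_disorder(config.intervals, "intervals", proteome=records)
    if config.scores:
        tracks += read_disorder(config.scores, "scores", proteome=records,
                                source="plddt")

    screen_config = ScreenConfig(
        min_fraction=config.min_fraction, min_length=config.min_length,
        score_threshold=config.score_threshold,
        score_direction=config.score_direction,  # type: ignore[arg-type]
    )
    results, passing = screen_proteome(records, tracks, screen_config)
    screen_df = results_table(results)
    _write_tsv(screen_df, outdir / "screen.tsv")
    write_fasta(passing, outdir / "wdps.fasta")
    log.info("screen: %d/%d proteins pass (%.2f%%)", len(passing),
             len(records), 100 * len(passing) / max(len(records), 1))

    physchem_df = profile_table(passing) if passing else pd.DataFrame()
    _write_tsv(physchem_df, outdir / "physchem.tsv")

    charge_df = charge_table(passing) if passing else pd.DataFrame()
    _write_tsv(charge_df, outdir / "charge.tsv")
    histogram = region_histogram(charge_df) if len(charge_df) else \
        {f"R{i}": 0 for i in range(1, 6)}
    log.info("charge regions: %s", histogram)

    families_df = pd.DataFrame()
    n_families = 0
    if config.hits:
        hits = read_hit_table(config.hits, strict=config.strict)
        assignment = cluster_families(
            [r.id for r in passing], hits,
            FamilyConfig(max_evalue=config.max_evalue,
                         max_hits_per_query=config.max_hits_per_query))
        families_df = families_table(assignment)
        n_families = assignment.n_families
        _write_tsv(families_df, outdir / "families.tsv")
        log.info("families: %d components over %d proteins", n_families,
                 len(passing))

    comparison_df = pd.DataFrame()
    if config.background:
        bg_records = read_fasta(config.background, strict=config.strict)
        bg_records, _ = dedup_exact(bg_records)
        bg_profiles = profile_table(bg_records)
        bg_charge = charge_table(bg_records)
        wdp_table = physchem_df.merge(charge_df.drop(columns=["n"]), on="id")
        bg_table = bg_profiles.merge(bg_charge.drop(columns=["n"]), on="id")
        comparison_df = compare_metrics(wdp_table, bg_table)
        _write_tsv(comparison_df, outdir / "comparison.tsv")

    manifest = {
        "tool": "wdpscan",
        "version": __version__,
        "tables_version": TABLES_VERSION,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "input_checksums": {
            name: _sha256(Path(p)) for name, p in
            (("proteome", config.proteome), ("intervals", config.intervals),
             ("scores", config.scores), ("hits", config.hits),
             ("background", config.background)) if p
        },
        "output_checksums": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
        },
        "summary": {
            "n_proteins": len(records),
            "n_duplicates_removed": len(removed),
            "n_wdp": len(passing),
            "wdp_pass_rate": len(passing) / max(len(records), 1),
            "region_histogram": histogram,
            "n_families": n_families,
            "row_counts": {
                "screen": len(screen_df), "physchem": len(physchem_df),
                "charge": len(charge_df), "families": len(families_df),
                "comparison": len(comparison_df),
            },
        },
        "runtime_seconds": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "screen": screen_df, "physchem": physchem_df, "charge": charge_df,
        "families": families_df, "comparison": comparison_df,
        "manifest": manifest, "passing": passing,
    }
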