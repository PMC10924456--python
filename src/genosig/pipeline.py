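"""End-to-end orchestration: ingest -> count -> train -> maps -> stats -> scans.

A single :func:`run` call reproduces the whole analysis on a set of FASTA
assemblies and writes every artifact (TSV tables, BED-like tracks, PNG map
renders) plus a machine-readable manifest.  Identical config + inputs give
identical outputs; the only stochastic stage in the package is synthetic
data generation, which is seeded.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blsom import BLSOMConfig, BLSOMModel, init_lattice, save_model, train
from .diagnostics import (
    compute_umatrix,
    flag_special_zone_candidates,
    heatmap_bins,
    map_purity,
    node_table,
    render_heatmap,
    render_territory,
    render_umatrix,
    special_zone_table,
    territory_map,
)
from .ingest import concatenate_with_n, fragment_manifest, read_fasta, tile_windows
from .kmer import build_dege_index, composition_matrix
from .scan import flag_peaks, frequency_track, write_track
from .stats import fragment_stats_table, render_species_boxplots, species_boxplot_table

logger = logging.getLogger(__name__)

STAT_COLUMNS = ("gc_percent", "cg_percent", "gc_di_percent", "cg_gc_ratio", "cg_odds_ratio")
DEFAULT_TRACK_CLASSES = ("GA+TC", "AG+CT", "CG", "GC")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    window_size: int = 100_000
    k: int = 3
    blsom: BLSOMConfig = field(default_factory=BLSOMConfig)
    label_mode: str = "species"  # species | lineage | chromosome
    lineage_map: dict[str, str] = field(default_factory=dict)
    palette: str = "red_blue"
    min_valid_fraction: float = 0.5
    sz_quantile: float = 0.9
    track_classes: tuple[str, ...] = DEFAULT_TRACK_CLASSES
    heatmap_classes: tuple[str, ...] | None = None
    render_figures: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 2 <= self.k <= 5:
            raise ValueError("k must be in 2..5")
        if self.window_size < 10 * self.k:
            raise ValueError("window_size must be >= 10*k")
        if self.label_mode not in ("species", "lineage", "chromosome"):
            raise ValueError(f"unknown label_mode {self.label_mode!r}")


def _fragment_labels(matrix, config: RunConfig) -> np.ndarray:
    if config.label_mode == "species":
        return matrix.labels("species")
    if config.label_mode == "chromosome":
        return matrix.labels("source")
    species = matrix.labels("species")
    missing = sorted({s for s in species if s not in config.lineage_map})
    if missing:
        raise ValueError(f"lineage_map lacks entries for species: {', '.join(missing)}")
    return np.array([config.lineage_map[s] for s in species], dtype=object)


def _config_hash(config: RunConfig, inputs: dict[str, str]) -> str:
    payload = json.dumps(
        {"config": asdict(config), "inputs": sorted(inputs.items())},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: RunConfig, inputs: dict[str, str], out_dir) -> dict:
    """Run the full analysis on ``inputs`` (species label -> FASTA path).

    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _save(name: str, relpath: str):
        artifacts[name] = relpath
        return out / relpath

    # ingest ---------------------------------------------------------------
    records = []
    for species in sorted(inputs):
        recs = read_fasta(inputs[species], species)
        logger.info("%s: %d records, %d bp", species, len(recs), sum(r.length for r in recs))
        records.extend(concatenate_with_n(recs, min_length=config.window_size))
    fragments = []
    for rec in records:
        fragments.extend(tile_windows(rec, config.window_size, config.min_valid_fraction))
    if not fragments:
        raise RuntimeError("ingest stage produced no fragments")
    fragment_manifest(fragments).to_csv(
        _save("fragments", "fragments.tsv"), sep="\t", index=False
    )
    logger.info("tiled %d fragments of %d bp", len(fragments), config.window_size)

    # composition ----------------------------------------------------------
    index = build_dege_index(config.k)
    matrix = composition_matrix(fragments, index)
    matrix.to_tsv(_save("composition", "composition.tsv"))

    # BLSOM ----------------------------------------------------------------
    model = train(matrix, init_lattice(matrix, config.blsom), config.blsom)
    save_model(model, out / "model", fragments=matrix.fragments)
    artifacts["model"] = "model"
    logger.info("trained %dx%d lattice on %d fragments", model.I, model.J, matrix.n_fragments)

    # diagnostics ----------------------------------------------------------
    labels = _fragment_labels(matrix, config)
    grid = territory_map(model, labels)
    umatrix = compute_umatrix(model)
    purity = map_purity(model, labels)
    ntab = node_table(model, labels, umatrix)
    ntab.to_csv(_save("node_table", "node_table.tsv"), sep="\t", index=False)
    zones = flag_special_zone_candidates(model, labels, umatrix, config.sz_quantile)
    special_zone_table(model, matrix, zones).to_csv(
        _save("special_zones", "special_zones.tsv"), sep="\t", index=False
    )
    vacant = int((ntab["category"] == "vacant").sum())
    multiple = int((ntab["category"] == "multiple").sum())
    logger.info(
        "map purity %.3f; %d vacant and %d multiple-category nodes of %d",
        purity, vacant, multiple, model.n_nodes,
    )
    if config.render_figures:
        render_territory(grid, _save("territory_png", "territory.png"),
                         title=f"k={config.k} territory map ({config.label_mode})")
        render_umatrix(umatrix, _save("umatrix_png", "umatrix.png"))
        heat_classes = config.heatmap_classes
        if heat_classes is None:
            if index.n_classes <= 16:
                heat_classes = index.classes
            else:
                var = matrix.values.var(axis=0)
                top = np.argsort(var)[::-1][:8]
                heat_classes = tuple(index.classes[i] for i in sorted(top))
        (out / "heatmaps").mkdir(exist_ok=True)
        for lab in heat_classes:
            safe = lab.replace("+", "_")
            render_heatmap(
                heatmap_bins(model, index, lab),
                _save(f"heatmap_{safe}", f"heatmaps/{safe}.png"),
                title=lab, palette=config.palette,
            )

    # stats ----------------------------------------------------------------
    stats = fragment_stats_table(fragments)
    stats.to_csv(_save("fragment_stats", "fragment_stats.tsv"), sep="\t", index=False)
    box_tables = [species_boxplot_table(stats, col) for col in STAT_COLUMNS]
    pd.concat(box_tables, ignore_index=True).to_csv(
        _save("boxplot_summaries", "boxplot_summaries.tsv"), sep="\t", index=False
    )
    if config.render_figures:
        (out / "boxplots").mkdir(exist_ok=True)
        for col in ("gc_percent", "cg_odds_ratio"):
            render_species_boxplots(stats, col, _save(f"boxplot_{col}", f"boxplots/{col}.png"))

    # scans ----------------------------------------------------------------
    (out / "tracks").mkdir(exist_ok=True)
    peak_rows = []
    for rec in records:
        if rec.length < config.window_size:
            continue
        for lab in config.track_classes:
            track = frequency_track(rec, config.window_size, lab)
            safe = lab.replace("+", "_")
            write_track(track, _save(f"track_{rec.record_id}_{safe}",
                                     f"tracks/{rec.record_id}_{safe}.tsv"))
            if np.isfinite(track.values).sum() >= 10:
                for wi in flag_peaks(track):
                    peak_rows.append(
                        {"chrom": rec.record_id, "class": lab,
                         "start": int(track.starts[wi]),
                         "end": int(track.starts[wi]) + config.window_size,
                         "value": float(track.values[wi])}
                    )
    pd.DataFrame(peak_rows, columns=["chrom", "class", "start", "end", "value"]).to_csv(
        _save("peaks", "peaks.tsv"), sep="\t", index=False
    )

    manifest = {
        "genosig_version": __version__,
        "config_hash": _config_hash(config, inputs),
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "inputs": dict(sorted(inputs.items())),
        "n_fragments": int(matrix.n_fragments),
        "lattice": [model.I, model.J],
        "map_purity": purity,
        "vacant_nodes": vacant,
        "multiple_nodes": multiple,
        "n_special_zones": len(zones),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
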