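"""FASTA ingestion, N-separator concatenation of short scaffolds, and window tiling.

Assemblies registered only as scaffolds would lose most of their sequence if
fragments were taken per-scaffold at Mb window sizes.  Scaffolds shorter than
the analysis window are therefore concatenated with a single ``N`` between
neighbours; every k-mer window crossing a junction then contains an N and is
excluded by the composition counter, so concatenation never creates
artificial oligonucleotides.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass
class SequenceRecord:
    """One chromosome or scaffold, normalized to uppercase A/C/G/T/N."""

    record_id: str
    species_label: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Fragment:
    """One fixed-size window of a source sequence.

    ``valid_fraction`` is the fraction of A/C/G/T (non-N) bases in the
    window.  ``sequence`` is attached when the fragment is produced by
    :func:`tile_windows` so downstream counting does not need to re-slice.
    """

    species_label: str
    source_id: str
    start: int
    end: int
    window_size: int
    valid_fraction: float
    sequence: str | None = field(default=None, repr=False)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map every non-A/C/G/T character (IUPAC codes etc.) to N."""
    return _NON_ACGTN.sub("N", seq.upper())


def read_fasta(path, species_label: str) -> list[SequenceRecord]:
    """Read a (plain or gzipped) FASTA file into normalized records.

    Raises on an empty file or a zero-length record, naming the record.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[SequenceRecord] = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = normalize_sequence(str(rec.seq))
            if not seq:
                raise ValueError(f"zero-length FASTA record {rec.id!r} in {path}")
            records.append(SequenceRecord(rec.id, species_label, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen = set()
    for r in records:
        if r.record_id in seen:
            raise ValueError(f"duplicate record id {r.record_id!r} in {path}")
        seen.add(r.record_id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    """Write records as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.record_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def concatenate_with_n(
    records: Sequence[SequenceRecord], min_length: int
) -> list[SequenceRecord]:
    """Pool sub-window scaffolds into one N-joined record per species.

    Records of length >= ``min_length`` pass through unchanged.  All shorter
    records of a species are joined in input order with a single ``N``
    between consecutive scaffolds; the joined record is appended after the
    species' long records with a synthetic id.  One N suffices because every
    downstream k-mer window crossing a junction contains it and is skipped.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    out: list[SequenceRecord] = []
    shorts: dict[str, list[SequenceRecord]] = {}
    species_order: list[str] = []
    for rec in records:
        if rec.species_label not in species_order:
            species_order.append(rec.species_label)
        if rec.length >= min_length:
            out.append(rec)
        else:
            shorts.setdefault(rec.species_label, []).append(rec)
    for sp in species_order:
        group = shorts.get(sp)
        if not group:
            continue
        joined = "N".join(r.sequence for r in group)
        rid = f"{sp}_concat_{len(group)}scaffolds"
        logger.info(
            "species %s: concatenated %d scaffolds < %d bp into %s (%d bp)",
            sp, len(group), min_length, rid, len(joined),
        )
        out.append(SequenceRecord(rid, sp, joined))
    return out


def tile_windows(
    record: SequenceRecord, window_size: int, min_valid_fraction: float = 0.5
) -> list[Fragment]:
    """Tile a record into non-overlapping fixed-size fragments.

    Windows are ``[0, w), [w, 2w), ...``; the trailing partial window is
    discarded so every composition vector describes the same amount of
    sequence.  Windows whose A/C/G/T fraction falls below
    ``min_valid_fraction`` are dropped and logged.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not 0.0 <= min_valid_fraction <= 1.0:
        raise ValueError("min_valid_fraction must be in [0, 1]")
    fragments: list[Fragment] = []
    n_dropped = 0
    for start in range(0, record.length - window_size + 1, window_size):
        end = start + window_size
        window = record.sequence[start:end]
        valid = 1.0 - window.count("N") / window_size
        if valid < min_valid_fraction:
            n_dropped += 1
            logger.info(
                "dropping window %s:%d-%d: valid fraction %.3f < %.3f",
                record.record_id, start, end, valid, min_valid_fraction,
            )
            continue
        fragments.append(
            Fragment(
                species_label=record.species_label,
                source_id=record.record_id,
                start=start,
                end=end,
                window_size=window_size,
                valid_fraction=valid,
                sequence=window,
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d N-rich windows", record.record_id, n_dropped)
    return fragments


def fragment_manifest(fragments: Sequence[Fragment]) -> pd.DataFrame:
    """Fragment provenance table (0-based half-open coordinates)."""
    return pd.DataFrame(
        {
            "species": [f.species_label for f in fragments],
            "source": [f.source_id for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
            "valid_fraction": [f.valid_fraction for f in fragments],
        }
    )
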