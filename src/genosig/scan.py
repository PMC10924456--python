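"""Chromosomal window tracks: oligonucleotide frequency and motif counts.

A track tiles one chromosome into fixed windows and reports either the
percentage of a degenerate oligonucleotide class per window or the number of
exact occurrences of a motif set per window.  Terminal enrichment of GA+TC
style tracks marks pericentromeric sequence on acrocentric chromosomes;
peaks are flagged with a robust (median/MAD) z-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import SequenceRecord, tile_windows
from .kmer import encode, revcomp


@dataclass
class WindowTrack:
    """Ordered per-window values along one source sequence.

    Windows are 0-based half-open and tile the source in order; a window
    with no valid (N-free) oligonucleotide is flagged missing (NaN value).
    """

    source_id: str
    window_size: int
    starts: np.ndarray
    values: np.ndarray
    value_kind: str  # "frequency_percent" or "motif_count"

    @property
    def n_windows(self) -> int:
        return self.starts.size

    def to_frame(self) -> pd.DataFrame:
        """BED-like 4-column table (chrom, start, end, value)."""
        return pd.DataFrame(
            {
                "chrom": self.source_id,
                "start": self.starts,
                "end": self.starts + self.window_size,
                "value": self.values,
            }
        )


@dataclass
class MotifSet:
    """Fixed-length motifs, optionally merged with reverse complements."""

    name: str
    motifs: tuple[str, ...]
    strand_merged: bool = True

    def __post_init__(self):
        motifs = tuple(m.strip().upper() for m in self.motifs if m.strip())
        if not motifs:
            raise ValueError("empty motif set")
        lengths = {len(m) for m in motifs}
        if len(lengths) != 1:
            raise ValueError("motifs must share one length")
        for m in motifs:
            if any(b not in "ACGT" for b in m):
                raise ValueError(f"motif {m!r} is not over A/C/G/T")
        object.__setattr__(self, "motifs", motifs)

    @property
    def length(self) -> int:
        return len(self.motifs[0])

    def search_set(self) -> tuple[str, ...]:
        """Deduplicated motifs to search, including reverse complements."""
        out = list(self.motifs)
        if self.strand_merged:
            out += [revcomp(m) for m in self.motifs]
        seen, uniq = set(), []
        for m in out:
            if m not in seen:
                seen.add(m)
                uniq.append(m)
        return tuple(uniq)

    @classmethod
    def from_file(cls, path, name: str | None = None, strand_merged: bool = True):
        """Read a plain-text motif file, one motif per line ('#' comments)."""
        from pathlib import Path

        lines = [
            ln.strip()
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        return cls(name=name or Path(path).stem, motifs=tuple(lines), strand_merged=strand_merged)


def _tile(record: SequenceRecord, window_size: int):
    # track windows share the ingest tiling rule, but N-rich windows are kept
    # and flagged missing rather than dropped
    return tile_windows(record, window_size, min_valid_fraction=0.0)


def frequency_track(
    record: SequenceRecord, window_size: int, class_label: str
) -> WindowTrack:
    """Per-window percentage of a degenerate oligonucleotide class.

    Any class width is accepted ("CG", "GA+TC", "GAGAG+CTCTC"); windows with
    no valid (N-free) oligonucleotide window are NaN-flagged.
    """
    from .kmer import window_codes

    members = [m.strip().upper() for m in class_label.split("+")]
    k = len(members[0])
    if any(len(m) != k or any(b not in "ACGT" for b in m) for m in members):
        raise ValueError(f"invalid oligonucleotide class label {class_label!r}")
    member_codes = []
    for m in members:
        code = 0
        for b in m:
            code = code * 4 + "ACGT".index(b)
        member_codes.append(code)
    starts, values = [], []
    for frag in _tile(record, window_size):
        kcode, valid = window_codes(encode(frag.sequence), k)
        n_valid = int(valid.sum())
        starts.append(frag.start)
        if n_valid == 0:
            values.append(np.nan)
        else:
            hits = int(np.isin(kcode[valid], member_codes).sum())
            values.append(100.0 * hits / n_valid)
    return WindowTrack(
        source_id=record.record_id,
        window_size=window_size,
        starts=np.asarray(starts, dtype=np.int64),
        values=np.asarray(values, dtype=float),
        value_kind="frequency_percent",
    )


def _count_occurrences(codes: np.ndarray, motif: str) -> int:
    """Overlapping exact occurrences of a motif; N never matches."""
    L = len(motif)
    m = codes.size - L + 1
    if m <= 0:
        return 0
    hit = np.ones(m, dtype=bool)
    for i, b in enumerate(motif):
        hit &= codes[i : i + m] == "ACGT".index(b)
    return int(hit.sum())


def motif_track(
    record: SequenceRecord, window_size: int, motifs: MotifSet
) -> WindowTrack:
    """Per-window count of overlapping exact motif occurrences.

    All motifs in the set (plus reverse complements when strand-merged) are
    summed; positions containing N never match.
    """
    if motifs.length > window_size:
        raise ValueError("motif longer than window")
    search = motifs.search_set()
    starts, values = [], []
    for frag in _tile(record, window_size):
        codes = encode(frag.sequence)
        starts.append(frag.start)
        values.append(float(sum(_count_occurrences(codes, m) for m in search)))
    return WindowTrack(
        source_id=record.record_id,
        window_size=window_size,
        starts=np.asarray(starts, dtype=np.int64),
        values=np.asarray(values, dtype=float),
        value_kind="motif_count",
    )


def flag_peaks(track: WindowTrack, z_threshold: float = 5.0) -> list[int]:
    """Indices of windows whose value is a robust-z outlier above the median.

    z = (v - median) / (1.4826 * MAD); a zero MAD degenerates to flagging
    every window strictly above the median (any excess is then infinitely
    many MADs away).  Requires >= 10 non-missing windows.
    """
    v = track.values
    finite = np.isfinite(v)
    if finite.sum() < 10:
        raise ValueError("need at least 10 non-missing windows")
    med = float(np.median(v[finite]))
    mad = float(np.median(np.abs(v[finite] - med)))
    scale = 1.4826 * mad
    if scale == 0.0:
        flagged = finite & (v > med)
    else:
        flagged = finite & (v > med + z_threshold * scale)
    return [int(i) for i in np.flatnonzero(flagged)]


def write_track(track: WindowTrack, path) -> None:
    """Write a track as 4-column BED-like TSV (0-based half-open)."""
    track.to_frame().to_csv(path, sep="\t", index=False, header=False)
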