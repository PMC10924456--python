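"""Degenerate (strand-merged) oligonucleotide alphabets and composition vectors.

Genome assemblies deposit an arbitrary one of the two complementary strands,
so strand-specific k-mer counts are not comparable across records.  The
degenerate alphabet merges every k-mer with its reverse complement into one
class (e.g. ``GA+TC``); self-complementary k-mers such as ``AT`` or ``CG``
form singleton classes.  Composition vectors are percentages of overlapping
width-k windows, with windows containing ``N`` excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import Fragment

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)  # everything not A/C/G/T codes as N (=4)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes A=0, C=1, G=2, T=3, N=4."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(sequence: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _kmer_string(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _revcomp_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


@dataclass(frozen=True)
class DegeClassIndex:
    """Strand-merged k-mer alphabet.

    Attributes
    ----------
    k : width of the oligonucleotide.
    classes : canonical class labels, ordered lexicographically by the
        canonical (lexicographically smaller) member; non-palindromic pairs
        are written ``"GA+TC"`` style with the canonical member first.
    kmer_to_class : int32 array of length 4**k mapping every k-mer code to
        its class index.
    """

    k: int
    classes: tuple[str, ...]
    kmer_to_class: np.ndarray = field(repr=False)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_index(self, label: str) -> int:
        """Index of a class given either its full label or any member k-mer."""
        try:
            return self.classes.index(label)
        except ValueError:
            pass
        member = label.split("+")[0].strip().upper()
        if len(member) != self.k or any(b not in BASES for b in member):
            raise KeyError(f"unknown oligonucleotide class {label!r} for k={self.k}")
        code = 0
        for b in member:
            code = (code << 2) | BASES.index(b)
        return int(self.kmer_to_class[code])

    def members(self, label: str) -> tuple[str, ...]:
        """The one or two member k-mers of a class."""
        idx = self.class_index(label)
        lab = self.classes[idx]
        return tuple(lab.split("+"))


def build_dege_index(k: int) -> DegeClassIndex:
    """Build the degenerate alphabet for width ``k``.

    The class count is 4**k / 2 for odd k and (4**k + 4**(k/2)) / 2 for even
    k (even-width k-mers can be self-complementary).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = 4**k
    kmer_to_class = np.empty(n, dtype=np.int32)
    canon_codes = []
    for code in range(n):
        rc = _revcomp_code(code, k)
        if code <= rc:
            canon_codes.append(code)
    # canonical codes in numeric order == lexicographic order of the strings
    labels = []
    for ci, code in enumerate(canon_codes):
        rc = _revcomp_code(code, k)
        kmer_to_class[code] = ci
        kmer_to_class[rc] = ci
        s = _kmer_string(code, k)
        labels.append(s if rc == code else f"{s}+{_kmer_string(rc, k)}")
    return DegeClassIndex(k=k, classes=tuple(labels), kmer_to_class=kmer_to_class)


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes of all overlapping width-k windows plus a validity mask.

    Windows containing an N are marked invalid; their codes are undefined
    (set to 0) and must not be used.
    """
    m = codes.size - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    kcode = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for i in range(k):
        c = codes[i : i + m]
        isn = c == 4
        valid &= ~isn
        kcode = kcode * 4 + np.where(isn, 0, c)
    return kcode, valid


def class_counts(sequence: str, index: DegeClassIndex) -> tuple[np.ndarray, int]:
    """Raw degenerate-class counts over overlapping windows, N-windows skipped.

    Returns (counts vector of length n_classes, number of valid windows).
    """
    codes = encode(sequence)
    kcode, valid = window_codes(codes, index.k)
    if kcode.size == 0:
        return np.zeros(index.n_classes, dtype=np.int64), 0
    hits = index.kmer_to_class[kcode[valid]]
    counts = np.bincount(hits, minlength=index.n_classes).astype(np.int64)
    return counts, int(valid.sum())


def count_composition(sequence: str, index: DegeClassIndex) -> tuple[np.ndarray, int]:
    """Percentage composition vector of one fragment sequence.

    Each valid overlapping window increments its degenerate class; the vector
    is ``100 * counts / valid_count``.  A fragment with no valid window (all
    N, or shorter than k) returns the all-zero vector with ``valid_count`` 0,
    which callers must treat as flagged-invalid.
    """
    counts, valid_count = class_counts(sequence, index)
    if valid_count == 0:
        return np.zeros(index.n_classes, dtype=np.float64), 0
    return 100.0 * counts / valid_count, valid_count


PROVENANCE_COLUMNS = ("species", "source", "start", "end", "valid_fraction")


@dataclass
class CompositionMatrix:
    """Fragments x degenerate-class percentage matrix with provenance.

    ``fragments`` is a DataFrame with columns species / source / start / end /
    valid_fraction, row-aligned with ``values``.  Rows sum to 100 (within
    float tolerance) because every counted window belongs to exactly one
    class.
    """

    fragments: pd.DataFrame
    index: DegeClassIndex
    values: np.ndarray
    valid_counts: np.ndarray

    @property
    def n_fragments(self) -> int:
        return self.values.shape[0]

    def labels(self, mode: str = "species") -> np.ndarray:
        """Per-fragment category labels: 'species', 'source' (chromosome)."""
        if mode not in ("species", "source"):
            raise ValueError(f"unknown label mode {mode!r}")
        return self.fragments[mode].to_numpy()

    def to_tsv(self, path) -> None:
        df = self.fragments.copy()
        df["valid_count"] = self.valid_counts
        for j, lab in enumerate(self.index.classes):
            df[lab] = self.values[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, index: DegeClassIndex | None = None) -> "CompositionMatrix":
        df = pd.read_csv(path, sep="\t")
        prov = [c for c in df.columns if c in PROVENANCE_COLUMNS + ("valid_count",)]
        class_cols = [c for c in df.columns if c not in prov]
        if index is None:
            index = build_dege_index(len(class_cols[0].split("+")[0]))
        if list(class_cols) != list(index.classes):
            raise ValueError("class columns do not match the degenerate index")
        return cls(
            fragments=df[[c for c in PROVENANCE_COLUMNS if c in df.columns]].copy(),
            index=index,
            values=df[class_cols].to_numpy(dtype=np.float64),
            valid_counts=df["valid_count"].to_numpy(dtype=np.int64),
        )


def composition_matrix(
    fragments: Sequence[Fragment], index: DegeClassIndex
) -> CompositionMatrix:
    """Composition vectors for a list of sequence-bearing fragments.

    Fragments with no valid window are excluded from the matrix and logged.
    Raises if every fragment is invalid.
    """
    fragments = list(fragments)
    if not fragments:
        raise ValueError("empty fragment list")
    rows, counts, kept = [], [], []
    n_dropped = 0
    for frag in fragments:
        if frag.sequence is None:
            raise ValueError(f"fragment {frag.source_id}:{frag.start} carries no sequence")
        vec, vc = count_composition(frag.sequence, index)
        if vc == 0:
            n_dropped += 1
            logger.info(
                "dropping fragment %s:%d-%d: no valid %d-mer window",
                frag.source_id, frag.start, frag.end, index.k,
            )
            continue
        rows.append(vec)
        counts.append(vc)
        kept.append(frag)
    if not rows:
        raise ValueError("all fragments lack valid windows")
    if n_dropped:
        logger.info("excluded %d/%d fragments with no valid window", n_dropped, len(fragments))
    prov = pd.DataFrame(
        {
            "species": [f.species_label for f in kept],
            "source": [f.source_id for f in kept],
            "start": [f.start for f in kept],
            "end": [f.end for f in kept],
            "valid_fraction": [f.valid_fraction for f in kept],
        }
    )
    return CompositionMatrix(
        fragments=prov,
        index=index,
        values=np.vstack(rows),
        valid_counts=np.asarray(counts, dtype=np.int64),
    )
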