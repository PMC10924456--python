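"""Synthetic multi-species genomes with controllable genome signatures.

Each species is an order-1 Markov chain over A/C/G/T calibrated so that its
stationary G+C% hits a target exactly and chosen dinucleotides are enriched
or depleted by a target odds ratio (observed / mononucleotide-expected).
Chromosomes are sampled from the chain; optional terminal or internal zones
are resampled from a modified emitter whose member-dinucleotide odds ratios
are scaled by the requested fold at the background's G+C, so the class
enrichment (e.g. GA+TC) is not a mononucleotide artifact.  Species can also
be emitted as short scaffolds to exercise N-concatenation.

Everything is deterministic under the model seed, and the community
generator returns truth tables sufficient to score territory purity and
zone recovery without re-reading generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .ingest import SequenceRecord
from .kmer import encode, window_codes

BASES = "ACGT"
_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _stationary(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 4-state chain (left eigenvector)."""
    a = np.vstack([transition.T - np.eye(4), np.ones(4)])
    b = np.zeros(5)
    b[4] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass(frozen=True)
class SpeciesModel:
    """Order-0/1 Markov emitter with a species-specific genome signature."""

    species_label: str
    order: int
    transition: np.ndarray = field(repr=False)
    target_gc: float
    dinucleotide_bias: tuple[tuple[str, float], ...]
    seed: int

    def stationary(self) -> np.ndarray:
        return _stationary(self.transition)

    def analytic_gc(self) -> float:
        pi = self.stationary()
        return 100.0 * float(pi[1] + pi[2])

    def analytic_dinucleotide_freq(self, dinuc: str) -> float:
        """Stationary probability of one dinucleotide window."""
        a, b = (BASES.index(c) for c in dinuc.upper())
        pi = self.stationary()
        return float(pi[a] * self.transition[a, b])

    def analytic_class_percent(self, class_label: str) -> float:
        """Stationary percentage of a (possibly merged) dinucleotide class."""
        members = [m.strip().upper() for m in class_label.split("+")]
        return 100.0 * sum(self.analytic_dinucleotide_freq(m) for m in members)

    def analytic_odds_ratio(self, dinuc: str = "CG") -> float:
        """Stationary observed/expected ratio for one dinucleotide."""
        a, b = (BASES.index(c) for c in dinuc.upper())
        pi = self.stationary()
        return float(self.transition[a, b] / pi[b])


def make_species_model(
    label: str,
    target_gc: float,
    dinucleotide_bias: dict[str, float] | float | None = None,
    seed: int = 0,
) -> SpeciesModel:
    """Calibrate a Markov chain to a target G+C% and dinucleotide odds ratios.

    ``dinucleotide_bias`` maps dinucleotides to target odds ratios (observed
    over mononucleotide-expected); a bare float is shorthand for
    ``{"CG": value}``.  With no bias the chain is i.i.d. and the stationary
    G+C equals the target exactly.  The joint calibration (stationary G+C
    and every requested odds ratio) is solved by fixed-point iteration on
    the base probabilities and the biased transition entries; an infeasible
    combination fails to converge and raises.
    """
    if not 10.0 <= target_gc <= 90.0:
        raise ValueError("target_gc must be in [10, 90]")
    if dinucleotide_bias is None:
        bias: dict[str, float] = {}
    elif isinstance(dinucleotide_bias, (int, float)):
        bias = {"CG": float(dinucleotide_bias)}
    else:
        bias = {k.upper(): float(v) for k, v in dinucleotide_bias.items()}
    for d, v in bias.items():
        if len(d) != 2 or any(c not in BASES for c in d):
            raise ValueError(f"invalid dinucleotide {d!r}")
        if v <= 0:
            raise ValueError("odds-ratio targets must be positive")

    gc = target_gc / 100.0
    q = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if not bias:
        transition = np.tile(q, (4, 1))
        return SpeciesModel(label, 0, transition, target_gc, tuple(), seed)

    mult = {d: v for d, v in bias.items()}
    transition = np.tile(q, (4, 1))
    for _ in range(500):
        transition = np.tile(q, (4, 1))
        for d, m in mult.items():
            a, b = BASES.index(d[0]), BASES.index(d[1])
            transition[a, b] = q[b] * m
        transition /= transition.sum(axis=1, keepdims=True)
        pi = _stationary(transition)
        gc_err = (pi[1] + pi[2]) - gc
        max_err = abs(gc_err)
        # nudge base probabilities to fix stationary G+C
        scale = gc / max(pi[1] + pi[2], 1e-12)
        at_scale = (1 - gc) / max(pi[0] + pi[3], 1e-12)
        q = q * np.array([at_scale, scale, scale, at_scale])
        q /= q.sum()
        # nudge biased entries to fix odds ratios
        for d, target in bias.items():
            a, b = BASES.index(d[0]), BASES.index(d[1])
            achieved = transition[a, b] / pi[b]
            max_err = max(max_err, abs(achieved - target))
            mult[d] *= target / max(achieved, 1e-12)
            if mult[d] > 1e3:
                raise ValueError(f"infeasible bias/G+C combination for {d!r}")
        if max_err < 1e-12:
            break
    else:
        raise ValueError("calibration did not converge; infeasible bias/G+C combination")
    if not np.all(transition >= 0) or np.any(transition > 1):
        raise ValueError("infeasible bias/G+C combination")
    return SpeciesModel(label, 1, transition, target_gc, tuple(sorted(bias.items())), seed)


@dataclass(frozen=True)
class ZoneSpec:
    """An interval enriched for a degenerate dinucleotide class.

    ``placement`` is "terminal" (at the chromosome end, emulating
    pericentromeric sequence on an acrocentric chromosome) or "internal"
    with an explicit 0-based ``offset``.
    """

    chromosome: int
    length: int
    enriched_class: str = "GA+TC"
    fold: float = 2.0
    placement: str = "terminal"
    offset: int | None = None

    def interval(self, chrom_length: int) -> tuple[int, int]:
        if self.length >= chrom_length:
            raise ValueError("zone length must be smaller than the chromosome")
        if self.placement == "terminal":
            return chrom_length - self.length, chrom_length
        if self.placement == "internal":
            if self.offset is None:
                raise ValueError("internal zone needs an offset")
            if self.offset + self.length > chrom_length:
                raise ValueError("internal zone extends past the chromosome")
            return self.offset, self.offset + self.length
        raise ValueError(f"unknown placement {self.placement!r}")

    def __post_init__(self):
        if self.fold <= 1.0:
            raise ValueError("fold must be > 1")


@njit(cache=True)
def _emit_chain(cum: np.ndarray, start_state: np.int64, u: np.ndarray) -> np.ndarray:
    out = np.empty(u.size, dtype=np.uint8)
    s = start_state
    for i in range(u.size):
        ui = u[i]
        b = 0
        while cum[s, b] < ui and b < 3:
            b += 1
        out[i] = b
        s = b
    return out


def _sample_codes(model: SpeciesModel, length: int, rng: np.random.Generator) -> np.ndarray:
    pi = model.stationary()
    cum = np.cumsum(model.transition, axis=1)
    cum[:, 3] = 1.0
    start = int(rng.choice(4, p=pi))
    u = rng.random(length)
    return _emit_chain(cum, np.int64(start), u)


def zone_emitter(model: SpeciesModel, class_label: str, fold: float) -> SpeciesModel:
    """A modified emitter whose class odds ratios are ``fold`` times the
    background's, at the background's G+C.  Because the calibrated chain
    keeps the mononucleotide composition of the background, the stationary
    class frequency is enriched by the same fold, so the enrichment is not a
    mononucleotide artifact."""
    bias = dict(model.dinucleotide_bias)
    for m in (x.strip().upper() for x in class_label.split("+")):
        bias[m] = fold * model.analytic_odds_ratio(m)
    return make_species_model(
        f"{model.species_label}_zone", model.target_gc, bias, seed=model.seed
    )


def _codes_to_str(codes: np.ndarray) -> str:
    return _ASCII[codes].tobytes().decode("ascii")


def generate_genome(
    model: SpeciesModel,
    chromosome_lengths: list[int],
    zones: list[ZoneSpec] | None = None,
    scaffold_split: int | None = None,
) -> list[SequenceRecord]:
    """Sample chromosomes from a species model.

    Zones are resampled intervals enriched for their class; with
    ``scaffold_split`` each chromosome is cut into scaffolds of that length
    (the remainder kept), emulating fragmented assemblies.  Fully
    reproducible from ``model.seed``.
    """
    zones = list(zones or [])
    for L in chromosome_lengths:
        if L < 10_000:
            raise ValueError("chromosome lengths must be >= 10 kb")
    by_chrom: dict[int, list[ZoneSpec]] = {}
    for z in zones:
        if not 0 <= z.chromosome < len(chromosome_lengths):
            raise ValueError(f"zone chromosome index {z.chromosome} out of range")
        by_chrom.setdefault(z.chromosome, []).append(z)
    for ci, zlist in by_chrom.items():
        ivals = sorted(z.interval(chromosome_lengths[ci]) for z in zlist)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping zones on chromosome {ci}")
    rng = np.random.default_rng(model.seed)
    records: list[SequenceRecord] = []
    for ci, length in enumerate(chromosome_lengths):
        codes = _sample_codes(model, length, rng)
        for z in by_chrom.get(ci, []):
            s, e = z.interval(length)
            emitter = zone_emitter(model, z.enriched_class, z.fold)
            codes[s:e] = _sample_codes(emitter, e - s, rng)
        chrom_id = f"{model.species_label}_chr{ci + 1}"
        seq = _codes_to_str(codes)
        if scaffold_split is None:
            records.append(SequenceRecord(chrom_id, model.species_label, seq))
        else:
            for si, off in enumerate(range(0, length, scaffold_split)):
                piece = seq[off : off + scaffold_split]
                if piece:
                    records.append(
                        SequenceRecord(f"{chrom_id}_s{si + 1}", model.species_label, piece)
                    )
    return records


@dataclass
class CommunityDataset:
    """A labeled multi-species synthetic community plus its ground truth."""

    records: list[SequenceRecord]
    models: list[SpeciesModel]
    zones: dict[str, list[ZoneSpec]]
    truth_species: pd.DataFrame
    truth_zones: pd.DataFrame
    window_size: int

    @property
    def species_labels(self) -> list[str]:
        return [m.species_label for m in self.models]


def generate_community(
    n_species: int = 5,
    window_size: int = 100_000,
    seed: int = 0,
    chromosomes_per_species: int = 2,
    chromosome_windows: int = 15,
    zone_windows: int = 5,
    zone_fold: float = 2.0,
    scaffold_species: bool = True,
) -> CommunityDataset:
    """Generate the canonical labeled community.

    Species G+C% targets are spaced >= 3 points apart across the realistic
    genome range, CG odds-ratio targets are pairwise distinct, the first
    species carries terminal GA+TC-enriched zones on every chromosome, and
    the last species is emitted as sub-window scaffolds (to exercise
    N-concatenation).  Deterministic per seed.
    """
    if not 2 <= n_species <= 30:
        raise ValueError("n_species must be in [2, 30]")
    spacing = max(3.0, min(6.0, 80.0 / (n_species - 1)))
    top = 28.0 + spacing * (n_species - 1)
    if top > 90.0:
        raise ValueError("too many species for >= 3-point G+C spacing")
    gc_targets = 28.0 + spacing * np.arange(n_species)
    cg_targets = np.round(np.linspace(0.55, 1.45, n_species), 3)
    chrom_len = chromosome_windows * window_size
    models, records = [], []
    zones_by_species: dict[str, list[ZoneSpec]] = {}
    zone_rows, species_rows = [], []
    for si in range(n_species):
        label = f"sp{si + 1:02d}"
        model = make_species_model(
            label,
            float(gc_targets[si]),
            {"CG": float(cg_targets[si])},
            seed=int(np.random.default_rng([seed, si]).integers(2**31 - 1)),
        )
        models.append(model)
        zones = []
        if si == 0:
            zones = [
                ZoneSpec(chromosome=ci, length=zone_windows * window_size,
                         enriched_class="GA+TC", fold=zone_fold)
                for ci in range(chromosomes_per_species)
            ]
        split = None
        if scaffold_species and si == n_species - 1:
            split = max(10_000, int(0.4 * window_size))
        recs = generate_genome(
            model, [chrom_len] * chromosomes_per_species, zones, scaffold_split=split
        )
        records.extend(recs)
        zones_by_species[label] = zones
        species_rows.append(
            {
                "species": label,
                "target_gc": float(gc_targets[si]),
                "cg_odds_target": float(cg_targets[si]),
                "n_chromosomes": chromosomes_per_species,
                "chromosome_length": chrom_len,
                "scaffold_split": split if split is not None else 0,
            }
        )
        for z in zones:
            s, e = z.interval(chrom_len)
            zone_rows.append(
                {
                    "species": label,
                    "source": f"{label}_chr{z.chromosome + 1}",
                    "start": s,
                    "end": e,
                    "enriched_class": z.enriched_class,
                    "fold": z.fold,
                }
            )
    return CommunityDataset(
        records=records,
        models=models,
        zones=zones_by_species,
        truth_species=pd.DataFrame(species_rows),
        truth_zones=pd.DataFrame(
            zone_rows,
            columns=["species", "source", "start", "end", "enriched_class", "fold"],
        ),
        window_size=window_size,
    )


def write_community(dataset: CommunityDataset, out_dir) -> dict[str, str]:
    """Write one FASTA per species plus truth TSVs; returns the file map."""
    from pathlib import Path

    from .ingest import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for model in dataset.models:
        recs = [r for r in dataset.records if r.species_label == model.species_label]
        p = out_dir / f"{model.species_label}.fasta"
        write_fasta(recs, p)
        paths[model.species_label] = str(p)
    dataset.truth_species.to_csv(out_dir / "truth_species.tsv", sep="\t", index=False)
    dataset.truth_zones.to_csv(out_dir / "truth_zones.tsv", sep="\t", index=False)
    paths["truth_species"] = str(out_dir / "truth_species.tsv")
    paths["truth_zones"] = str(out_dir / "truth_zones.tsv")
    return paths
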