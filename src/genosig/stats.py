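"""Composition statistics: G+C%, dinucleotide %, CG odds ratio, box plots.

CG deficiency is the classic genome-signature statistic: the observed CG
dinucleotide frequency divided by the frequency expected from the fragment's
mononucleotide composition (p_C * p_G).  Values below 1 mark CG depletion,
which in vertebrates tracks C-methylation of CpG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmer import encode, window_codes


def gc_percent(sequence: str) -> float:
    """G+C percentage over A/C/G/T bases; N excluded from the denominator.

    Raises on a sequence with no countable base.
    """
    codes = encode(sequence)
    n_acgt = int((codes != 4).sum())
    if n_acgt == 0:
        raise ValueError("no A/C/G/T bases: G+C% undefined")
    n_gc = int(((codes == 1) | (codes == 2)).sum())
    return 100.0 * n_gc / n_acgt


def base_fractions(sequence: str) -> np.ndarray:
    """Mononucleotide fractions (A, C, G, T) over non-N bases."""
    codes = encode(sequence)
    counts = np.bincount(codes[codes != 4], minlength=4).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no A/C/G/T bases")
    return counts / total


def _dinucleotide_members(class_label: str) -> list[str]:
    members = [m.strip().upper() for m in class_label.split("+")]
    for m in members:
        if len(m) != 2 or any(b not in "ACGT" for b in m):
            raise ValueError(f"invalid dinucleotide class label {class_label!r}")
    return members


def dinucleotide_percent(sequence: str, class_label: str) -> float:
    """Percentage of overlapping dinucleotide windows matching the class.

    ``class_label`` is a single dinucleotide ("CG") or a strand-merged pair
    ("GA+TC"); windows containing N are excluded.  Raises when the sequence
    has no valid window.
    """
    members = _dinucleotide_members(class_label)
    codes = encode(sequence)
    kcode, valid = window_codes(codes, 2)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid dinucleotide window")
    member_codes = ["ACGT".index(m[0]) * 4 + "ACGT".index(m[1]) for m in members]
    hits = np.isin(kcode[valid], member_codes).sum()
    return 100.0 * float(hits) / n_valid


@dataclass
class OddsRatioRecord:
    """Observed vs. mononucleotide-expected frequency of one dinucleotide."""

    class_label: str
    observed_freq: float
    expected_freq: float
    odds_ratio: float


def cg_odds_ratio(sequence: str) -> OddsRatioRecord:
    """CG odds ratio: observed CG window frequency / (p_C * p_G).

    The expectation uses the fragment's own mononucleotide fractions, so a
    ratio of 1 means CG occurs exactly as often as base composition alone
    predicts.  Raises when p_C * p_G is zero (no C or no G).
    """
    p = base_fractions(sequence)
    expected = float(p[1] * p[2])
    if expected == 0.0:
        raise ValueError("expected CG frequency is zero: odds ratio undefined")
    observed = dinucleotide_percent(sequence, "CG") / 100.0
    return OddsRatioRecord("CG", observed, expected, observed / expected)


def cg_gc_ratio(sequence: str) -> float:
    """CG% / GC% of a sequence; ratios below 1 indicate CG deficiency."""
    gc_pct = dinucleotide_percent(sequence, "GC")
    if gc_pct == 0.0:
        raise ValueError("GC% is zero: CG/GC ratio undefined")
    return dinucleotide_percent(sequence, "CG") / gc_pct


@dataclass
class BoxplotSummary:
    """Tukey box-plot five-number summary with 1.5*IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    whisker_multiplier: float = 1.5


def boxplot_summary(values, whisker_multiplier: float = 1.5) -> BoxplotSummary:
    """Tukey box-plot statistics of a sample.

    Quartiles use linear interpolation (p(k) = (k-1)/(n-1)); whiskers extend
    to the most extreme data point within ``whisker_multiplier * IQR`` of
    the nearest quartile, and anything beyond is an outlier.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence = q1 - whisker_multiplier * iqr
    hi_fence = q3 + whisker_multiplier * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(outliers),
        whisker_multiplier=whisker_multiplier,
    )


def fragment_stats_table(fragments) -> pd.DataFrame:
    """Per-fragment statistics table: G+C%, CG%, GC%, CG/GC, CG odds ratio."""
    rows = []
    for frag in fragments:
        seq = frag.sequence
        row = {
            "species": frag.species_label,
            "source": frag.source_id,
            "start": frag.start,
            "end": frag.end,
            "gc_percent": np.nan,
            "cg_percent": np.nan,
            "gc_di_percent": np.nan,
            "cg_gc_ratio": np.nan,
            "cg_odds_ratio": np.nan,
        }
        try:
            row["gc_percent"] = gc_percent(seq)
            row["cg_percent"] = dinucleotide_percent(seq, "CG")
            row["gc_di_percent"] = dinucleotide_percent(seq, "GC")
            row["cg_gc_ratio"] = cg_gc_ratio(seq)
            row["cg_odds_ratio"] = cg_odds_ratio(seq).odds_ratio
        except ValueError:
            pass  # degenerate fragment: stats left NaN-flagged
        rows.append(row)
    return pd.DataFrame(rows)


def species_boxplot_table(stats: pd.DataFrame, column: str) -> pd.DataFrame:
    """Per-species Tukey summary of one fragment statistic."""
    rows = []
    for sp, group in stats.groupby("species", sort=True):
        vals = group[column].dropna().to_numpy()
        if vals.size == 0:
            continue
        s = boxplot_summary(vals)
        rows.append(
            {
                "species": sp,
                "statistic": column,
                "n": vals.size,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "whisker_low": s.whisker_low,
                "whisker_high": s.whisker_high,
                "n_outliers": s.outliers.size,
            }
        )
    return pd.DataFrame(rows)


def render_species_boxplots(stats: pd.DataFrame, column: str, path, title: str = "") -> None:
    """Box plots of one statistic grouped by species (whiskers at 1.5*IQR)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [(sp, g[column].dropna().to_numpy()) for sp, g in stats.groupby("species", sort=True)]
    groups = [(sp, v) for sp, v in groups if v.size]
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    ax.boxplot([v for _, v in groups], tick_labels=[sp for sp, _ in groups], whis=1.5)
    ax.set_ylabel(column)
    ax.set_title(title or column)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
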